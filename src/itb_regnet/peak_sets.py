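"""Common / stage-specific peak sets and cross-species conservation.

Two overlap dialects cover every comparison the pipeline makes: a fractional
rule (a query peak is kept when a partner covers at least half of it, the
bedtools ``-f 0.5`` reading) and a minimal 1-bp rule used for conservation
calls against reference open-chromatin or histone-mark peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import PeakSet, ValidationError
from .stats_core import (
    TestResult,
    fisher_greater,
    two_proportion_greater,
    wilcoxon_rank_sum,
)


@dataclass(frozen=True)
class OverlapRule:
    """Either a minimum overlap fraction of the query peak, or a minimum bp count."""

    min_fraction: float | None = None
    min_bp: int | None = None
    reference_frame: str = "query"  # query | reciprocal

    def __post_init__(self) -> None:
        if (self.min_fraction is None) == (self.min_bp is None):
            raise ValidationError("set exactly one of min_fraction / min_bp")
        if self.min_fraction is not None and not 0.0 < self.min_fraction <= 1.0:
            raise ValidationError("min_fraction must lie in (0,1]")
        if self.min_bp is not None and self.min_bp < 1:
            raise ValidationError("min_bp must be >= 1")


COMMON_RULE = OverlapRule(min_fraction=0.5)
CONSERVED_RULE = OverlapRule(min_bp=1)


def _trees(peaks: PeakSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)
    return trees


def _passes(query, partner, rule: OverlapRule) -> bool:
    ov = min(query.end, partner.end) - max(query.start, partner.start)
    if ov <= 0:
        return False
    if rule.min_bp is not None:
        return ov >= rule.min_bp
    if ov / query.length < rule.min_fraction:
        return False
    if rule.reference_frame == "reciprocal" and ov / partner.length < rule.min_fraction:
        return False
    return True


def common_peaks(
    set_a: PeakSet,
    set_b: PeakSet,
    rule: OverlapRule = COMMON_RULE,
    report_partner: bool = True,
) -> tuple[PeakSet, dict[str, str]]:
    """Peaks of ``set_a`` having a qualifying overlap with some peak of ``set_b``.

    Each retained peak appears once, in ``set_a`` coordinates; the id of the
    best-overlapping partner (most shared bp, earlier id on ties) is returned
    alongside so callers can switch to partner coordinates when needed.
    """
    trees = _trees(set_b)
    kept, partners = [], {}
    for peak in set_a:
        tree = trees.get(peak.chrom)
        if tree is None:
            continue
        best_partner, best_ov = None, -1
        for iv in tree.overlap(peak.start, peak.end):
            partner = iv.data
            if _passes(peak, partner, rule):
                ov = min(peak.end, partner.end) - max(peak.start, partner.start)
                if ov > best_ov or (ov == best_ov and partner.id < best_partner.id):
                    best_partner, best_ov = partner, ov
        if best_partner is not None:
            kept.append(peak)
            if report_partner:
                partners[peak.id] = best_partner.id
    return PeakSet(kept), partners


def conserved_overlap(
    mapped: PeakSet, reference: PeakSet, rule: OverlapRule = CONSERVED_RULE
) -> tuple[PeakSet, dict[str, int]]:
    """Subset of mapped peaks overlapping any reference peak by the rule (>=1 bp).

    ``mapped`` must already be in reference coordinates. Returns the conserved
    subset plus {"conserved": n, "total": m} counts.
    """
    conserved, _ = common_peaks(mapped, reference, rule=rule, report_partner=False)
    return conserved, {"conserved": len(conserved), "total": len(mapped)}


def conservation_proportion_compare(
    conserved_a: int, total_a: int, conserved_b: int, total_b: int
) -> TestResult:
    """Is the conserved proportion of set A greater than that of set B?"""
    return two_proportion_greater(conserved_a, total_a, conserved_b, total_b)


def chromatin_mark_overlap(
    peaks: PeakSet, marks: PeakSet, universe: PeakSet
) -> TestResult:
    """Fisher test: do query peaks overlap a mark more than the rest of the universe?

    2x2 table over the universe peaks: membership in the query set x >=1 bp
    overlap with any mark peak.
    """
    query_ids = set(peaks.ids())
    universe_ids = set(universe.ids())
    if not query_ids <= universe_ids:
        raise ValidationError("query peaks must be a subset of the universe")
    overlapping, _ = common_peaks(universe, marks, rule=CONSERVED_RULE,
                                  report_partner=False)
    hit_ids = set(overlapping.ids())
    a = len(query_ids & hit_ids)
    b = len(query_ids - hit_ids)
    c = len((universe_ids - query_ids) & hit_ids)
    d = len(universe_ids - query_ids - hit_ids)
    return fisher_greater([[a, b], [c, d]])


def peaks_with_min_count_comparison(
    rat_links: Mapping[str, int],
    ref_links: Mapping[str, int],
    orthology: pd.DataFrame,
    k: int = 3,
) -> TestResult:
    """Do genes with >= k peaks in one species carry more peaks in the other?

    ``orthology`` has columns source_gene, target_gene; one-to-many rows are
    dropped (only one-to-one orthologs are comparable). Reference peak counts
    of genes absent from ``ref_links`` count as zero.
    """
    if not {"source_gene", "target_gene"}.issubset(orthology.columns):
        raise ValidationError("orthology needs columns source_gene, target_gene")
    o = orthology.drop_duplicates()
    o = o[~o["source_gene"].duplicated(keep=False)]
    o = o[~o["target_gene"].duplicated(keep=False)]
    pairs = [
        (s, t) for s, t in zip(o["source_gene"], o["target_gene"]) if s in rat_links
    ]
    if not pairs:
        raise ValidationError("no shared one-to-one orthologs")
    high = [ref_links.get(t, 0) for s, t in pairs if rat_links[s] >= k]
    low = [ref_links.get(t, 0) for s, t in pairs if rat_links[s] < k]
    if not high or not low:
        raise ValidationError("one of the >=k / <k ortholog groups is empty")
    return wilcoxon_rank_sum(high, low)


def overlap_percentage(overlapping: int, total: int) -> float:
    """Percentage of a peak set overlapping a reference, rounded to 2 decimals.

    The rounding convention matches how such overlaps are conventionally
    reported (e.g. 208 of 439 -> 47.38).
    """
    if total <= 0:
        raise ValidationError("total must be positive")
    if not 0 <= overlapping <= total:
        raise ValidationError("overlapping must lie in [0, total]")
    return round(100.0 * overlapping / total, 2)
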