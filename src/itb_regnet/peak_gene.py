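"""Peak-to-gene association and gene-list statistics.

Distances are measured from the peak edge to the gene's strand-aware TSS and
stored signed (negative when the peak lies upstream of the TSS in the gene's
reading direction); thresholds always use the magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneRecord, PeakSet, ValidationError
from .stats_core import TestResult, bh_adjust, hypergeom_overlap, wilcoxon_rank_sum


@dataclass(frozen=True)
class PeakGeneLink:
    peak_id: str
    gene_id: str
    distance: int  # signed bp; 0 if the TSS falls inside the peak
    rule: str  # nearest_start | great_1mb
    tie: bool = False


@dataclass(frozen=True)
class EnrichedTerm:
    term_id: str
    observed: int
    expected: float
    enrichment_rate: float
    p_value: float
    fdr: float


def _peak_tss_distance(start: int, end: int, gene: GeneRecord) -> tuple[int, int]:
    """(magnitude, signed) distance from a peak interval to a gene's TSS.

    Zero if the TSS lies within the half-open peak. The sign is strand-aware:
    negative when the peak is upstream of the TSS.
    """
    tss = gene.tss
    if start <= tss < end:
        return 0, 0
    if tss >= end:  # peak entirely left of the TSS: gap from the peak end
        mag = tss - end
        sign = -1 if gene.strand == "+" else 1
    else:  # peak entirely right of the TSS
        mag = start - tss
        sign = 1 if gene.strand == "+" else -1
    return mag, sign * mag


def nearest_gene(
    peaks: PeakSet,
    genes: Sequence[GeneRecord],
    max_dist: int | None = None,
    rule: str = "nearest_start",
    use_plus_strand_start: bool = False,
) -> list[PeakGeneLink]:
    """Associate each peak with the nearest same-chromosome TSS.

    Ties on distance are broken toward the lexicographically smaller gene_id
    and flagged. Peaks on chromosomes without genes — or, when ``max_dist``
    is set, with no TSS within that bound — are left unassigned (omitted).
    ``use_plus_strand_start`` measures to the annotated start coordinate
    regardless of strand instead of the strand-aware TSS.
    """
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        if use_plus_strand_start:
            g = GeneRecord(g.gene_id, g.chrom, "+", g.start, g.end)
        by_chrom.setdefault(g.chrom, []).append(g)
    for glist in by_chrom.values():
        glist.sort(key=lambda g: (g.tss, g.gene_id))
    tss_arrays = {
        c: np.array([g.tss for g in glist]) for c, glist in by_chrom.items()
    }

    links = []
    for peak in peaks:
        glist = by_chrom.get(peak.chrom)
        if not glist:
            continue
        tss = tss_arrays[peak.chrom]
        # candidate genes: the two flanking the peak in TSS order, plus any
        # whose TSS lies inside; scanning a small window around the insertion
        # points is equivalent to the full scan
        lo = max(0, int(np.searchsorted(tss, peak.start)) - 2)
        hi = min(len(glist), int(np.searchsorted(tss, peak.end)) + 2)
        # expand over runs of identical TSS so lexicographic tie-breaks see
        # every gene at the flanking positions
        while lo > 0 and glist[lo - 1].tss == glist[lo].tss:
            lo -= 1
        while hi < len(glist) and glist[hi - 1].tss == glist[hi].tss:
            hi += 1
        best: tuple[int, str] | None = None
        best_signed = 0
        tie = False
        for g in glist[lo:hi]:
            mag, signed = _peak_tss_distance(peak.start, peak.end, g)
            key = (mag, g.gene_id)
            if best is None or key < best:
                tie = best is not None and mag == best[0]
                best, best_signed = key, signed
            elif mag == best[0]:
                tie = True
        if best is None:
            continue
        if max_dist is not None and best[0] > max_dist:
            continue
        links.append(
            PeakGeneLink(peak.id, best[1], best_signed, rule, tie)
        )
    return links


def great_nearest_gene(
    peaks: PeakSet, genes: Sequence[GeneRecord], max_dist: int = 1_000_000
) -> list[PeakGeneLink]:
    """Nearest-TSS association with a maximum distance (GREAT single-nearest)."""
    return nearest_gene(peaks, genes, max_dist=max_dist, rule="great_1mb")


def distal_fraction(links: Sequence[PeakGeneLink], cutoff: int = 5000) -> float:
    """Fraction of links strictly farther than ``cutoff`` bp from the TSS."""
    if not links:
        raise ValidationError("no links; distal fraction undefined")
    return sum(abs(l.distance) > cutoff for l in links) / len(links)


def peaks_per_gene(
    links: Sequence[PeakGeneLink],
) -> tuple[dict[str, int], pd.Series]:
    """Distinct peaks per gene and the histogram over those counts."""
    seen = {(l.peak_id, l.gene_id) for l in links}
    counts: dict[str, int] = {}
    for _, gene_id in seen:
        counts[gene_id] = counts.get(gene_id, 0) + 1
    histogram = pd.Series(counts, dtype=int).value_counts().sort_index()
    return counts, histogram


def expression_by_peakcount(
    counts: Mapping[str, int],
    expression: Mapping[str, float],
    k: int = 3,
    pseudo: float = 1e-5,
) -> tuple[TestResult, pd.DataFrame]:
    """Compare expression between genes with >= k vs < k associated peaks.

    Only genes present in both maps are used. Group medians are reported on
    the log10(average expression + pseudo) scale.
    """
    genes = [g for g in counts if g in expression]
    high = [expression[g] for g in genes if counts[g] >= k]
    low = [expression[g] for g in genes if counts[g] < k]
    if not high or not low:
        empty = f">={k}" if not high else f"<{k}"
        raise ValidationError(f"group {empty} peaks is empty")
    result = wilcoxon_rank_sum(high, low)
    summary = pd.DataFrame(
        {
            "group": [f">={k}", f"<{k}"],
            "n": [len(high), len(low)],
            "median_log10_expr": [
                float(np.median(np.log10(np.asarray(v) + pseudo)))
                for v in (high, low)
            ],
        }
    )
    return result, summary


def marker_overlap(
    genes_with_k_peaks: Iterable[str],
    markers: Iterable[str],
    universe: Iterable[str],
    tail: str = "greater",
) -> TestResult:
    """Hypergeometric overlap of a gene group with a marker list."""
    gset, mset, uset = set(genes_with_k_peaks), set(markers), set(universe)
    if not gset <= uset or not mset <= uset:
        raise ValidationError("gene and marker sets must lie within the universe")
    return hypergeom_overlap(
        len(gset & mset), len(gset), len(mset), len(uset), tail=tail
    )


def ora(
    gene_list: Iterable[str],
    gmt: Mapping[str, set[str]],
    universe: Iterable[str],
    min_rate: float = 1.5,
    min_observed: int = 5,
    fdr_cut: float = 0.05,
) -> list[EnrichedTerm]:
    """Over-representation of a gene list against a gene-set collection.

    Per term: hypergeometric upper-tail p over the universe, BH adjustment
    across tested terms, then the enrichment-rate / observed-count / FDR
    filters. expected = |list| * |term in universe| / |universe|.
    """
    uset = set(universe)
    if not uset:
        raise ValidationError("empty universe")
    gset = set(gene_list) & uset
    terms, observed, expected, rates, pvals = [], [], [], [], []
    for term, members in gmt.items():
        in_universe = members & uset
        if not in_universe:
            continue
        obs = len(gset & in_universe)
        exp = len(gset) * len(in_universe) / len(uset)
        terms.append(term)
        observed.append(obs)
        expected.append(exp)
        rates.append(obs / exp if exp > 0 else np.nan)
        pvals.append(
            hypergeom_overlap(
                obs, len(gset), len(in_universe), len(uset), tail="greater"
            ).p_value
        )
    fdrs = bh_adjust(pvals) if terms else np.array([])
    results = [
        EnrichedTerm(t, o, e, r, p, f)
        for t, o, e, r, p, f in zip(terms, observed, expected, rates, pvals, fdrs)
        if f < fdr_cut and r >= min_rate and o >= min_observed
    ]
    return sorted(results, key=lambda t: t.fdr)


def links_table(links: Sequence[PeakGeneLink]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peak_id": [l.peak_id for l in links],
            "gene_id": [l.gene_id for l in links],
            "distance": [l.distance for l in links],
            "rule": [l.rule for l in links],
            "tie": [l.tie for l in links],
        }
    )
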