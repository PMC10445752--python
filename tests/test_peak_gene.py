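"""Peak-to-gene association rules and gene-list statistics."""

import numpy as np
import pytest

from itb_regnet.io_formats import GeneRecord, Peak, PeakSet, ValidationError
from itb_regnet.peak_gene import (
    PeakGeneLink,
    distal_fraction,
    expression_by_peakcount,
    great_nearest_gene,
    marker_overlap,
    nearest_gene,
    ora,
    peaks_per_gene,
)


def gene(gid, tss, chrom="chr1", strand="+"):
    if strand == "+":
        return GeneRecord(gid, chrom, "+", tss, tss + 1000)
    return GeneRecord(gid, chrom, "-", max(0, tss - 999), tss + 1)


# ---------------------------------------------------------------------------
# Nearest gene
# ---------------------------------------------------------------------------

def test_tss_inside_peak_is_distance_zero():
    links = nearest_gene(PeakSet([Peak("chr1", 100, 200, "p")]), [gene("g", 150)])
    assert links == [PeakGeneLink("p", "g", 0, "nearest_start", False)]


def test_nearest_of_two_downstream_genes():
    links = nearest_gene(
        PeakSet([Peak("chr1", 100, 200, "p")]), [gene("a", 300), gene("b", 350)]
    )
    assert links[0].gene_id == "a"
    assert abs(links[0].distance) == 100  # gap from peak end (200) to tss 300


def test_equidistant_tie_breaks_lexicographically():
    peaks = PeakSet([Peak("chr1", 450, 550, "p")])
    genes = [gene("gB", 650), gene("gA", 350)]  # both 100 bp from an edge
    links = nearest_gene(peaks, genes)
    assert links[0].gene_id == "gA" and links[0].tie


def test_chromosome_without_genes_unassigned():
    links = nearest_gene(PeakSet([Peak("chrX", 0, 100, "p")]), [gene("g", 50)])
    assert links == []


def test_nearest_gene_matches_brute_force(rng):
    """Sorted-scan implementation vs an O(n*m) brute-force oracle."""

    def brute(peaks, genes):
        out = {}
        for p in peaks:
            best = None
            for g in genes:
                if g.chrom != p.chrom:
                    continue
                if p.start <= g.tss < p.end:
                    mag = 0
                elif g.tss >= p.end:
                    mag = g.tss - p.end
                else:
                    mag = p.start - g.tss
                if best is None or (mag, g.gene_id) < best:
                    best = (mag, g.gene_id)
            if best is not None:
                out[p.id] = best[1]
        return out

    for trial in range(100):
        n_genes = int(rng.integers(1, 15))
        n_peaks = int(rng.integers(1, 15))
        chroms = ["c1", "c2"]
        genes = [
            gene(
                f"g{i:02d}",
                int(rng.integers(0, 5000)),
                chrom=chroms[int(rng.integers(0, 2))],
                strand="+-"[int(rng.integers(0, 2))],
            )
            for i in range(n_genes)
        ]
        peaks = PeakSet(
            [
                Peak(
                    chroms[int(rng.integers(0, 2))],
                    s := int(rng.integers(0, 5000)),
                    s + int(rng.integers(1, 400)),
                    f"p{i}",
                )
                for i in range(n_peaks)
            ]
        )
        got = {l.peak_id: l.gene_id for l in nearest_gene(peaks, genes)}
        assert got == brute(peaks, genes), f"trial {trial}"


def test_great_distance_bound():
    peaks = PeakSet([Peak("chr1", 0, 100, "near"), Peak("chr2", 0, 100, "far")])
    genes = [gene("g1", 100_098), gene("g2", 1_000_101, chrom="chr2")]
    links = great_nearest_gene(peaks, genes)
    assert [l.peak_id for l in links] == ["near"]
    # exactly at the bound is still assigned
    at_bound = great_nearest_gene(
        PeakSet([Peak("chr1", 0, 100, "p")]), [gene("g", 99 + 1_000_000)]
    )
    assert len(at_bound) == 1


def test_great_unbounded_equals_nearest(rng):
    genes = [gene(f"g{i}", int(rng.integers(0, 10000))) for i in range(10)]
    peaks = PeakSet(
        [
            Peak("chr1", s := int(rng.integers(0, 10000)), s + 50, f"p{i}")
            for i in range(20)
        ]
    )
    unbounded = great_nearest_gene(peaks, genes, max_dist=10**12)
    plain = nearest_gene(peaks, genes)
    assert [(l.peak_id, l.gene_id) for l in unbounded] == [
        (l.peak_id, l.gene_id) for l in plain
    ]


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def link(pid, gid, dist):
    return PeakGeneLink(pid, gid, dist, "nearest_start")


def test_distal_fraction_strict_cutoff():
    links = [link("a", "g", 0), link("b", "g", 6000), link("c", "g", -10000),
             link("d", "g", 1000)]
    assert distal_fraction(links) == 0.5
    assert distal_fraction([link("a", "g", 5000)]) == 0.0  # exactly 5 kb: proximal
    with pytest.raises(ValidationError):
        distal_fraction([])


def test_peaks_per_gene_collapses_duplicates():
    links = [link("p1", "g1", 0), link("p2", "g1", 10), link("p3", "g1", 5),
             link("p1", "g1", 0)]
    counts, hist = peaks_per_gene(links)
    assert counts == {"g1": 3}
    assert hist.to_dict() == {3: 1}
    assert peaks_per_gene([])[0] == {}


def test_expression_by_peakcount_enumeration():
    counts = {f"g{i}": c for i, c in enumerate([3, 4, 5, 1, 2, 0])}
    expr = {f"g{i}": e for i, e in enumerate([10.0, 11.0, 12.0, 1.0, 2.0, 3.0])}
    result, summary = expression_by_peakcount(counts, expr, k=3)
    assert result.p_value == pytest.approx(0.1)  # 3v3 fully separated ranks
    assert summary["n"].tolist() == [3, 3]


def test_expression_by_peakcount_empty_group_error():
    with pytest.raises(ValidationError, match="<1"):
        expression_by_peakcount({"g": 2}, {"g": 1.0}, k=1)


def test_marker_overlap_matches_oracle():
    universe = [f"u{i}" for i in range(10)]
    genes = universe[:4]
    markers = universe[:4] + [universe[5]]
    r = marker_overlap(genes, markers, universe)
    assert r.p_value == pytest.approx(5 / 210)
    with pytest.raises(ValidationError):
        marker_overlap(["not_in_universe"], markers, universe)


def test_marker_overlap_forced_full_overlap():
    universe = [f"u{i}" for i in range(8)]
    r = marker_overlap(universe[:3], universe, universe)
    assert r.p_value == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# ORA
# ---------------------------------------------------------------------------

def test_ora_rate_closed_form():
    genes = {f"g{i}" for i in range(10)}
    universe = {f"g{i}" for i in range(20)}
    results = ora(genes, {"T": set(genes)}, universe, min_rate=1.5)
    assert len(results) == 1
    assert results[0].enrichment_rate == pytest.approx(2.0)
    assert results[0].observed == 10


def test_ora_min_observed_filter():
    genes = {f"g{i}" for i in range(4)}
    universe = {f"g{i}" for i in range(40)}
    # perfectly enriched but only 4 observed: filtered
    assert ora(genes, {"T": set(genes)}, universe, min_rate=1.5) == []


def test_ora_null_terms_not_enriched(rng):
    universe = [f"g{i}" for i in range(200)]
    gene_list = set(rng.choice(universe, size=30, replace=False))
    gmt = {
        f"T{k}": set(rng.choice(universe, size=25, replace=False)) for k in range(20)
    }
    hits = ora(gene_list, gmt, universe, min_rate=1.5)
    assert len(hits) == 0


def test_ora_invariant_to_gene_relabeling(rng):
    universe = [f"g{i}" for i in range(50)]
    gene_list = set(universe[:20])
    gmt = {"T": set(universe[10:30])}
    base = ora(gene_list, gmt, universe, min_rate=0.1, min_observed=1, fdr_cut=1.1)
    relabel = {g: f"x{g}" for g in universe}
    remapped = ora(
        {relabel[g] for g in gene_list},
        {"T": {relabel[g] for g in gmt["T"]}},
        [relabel[g] for g in universe],
        min_rate=0.1,
        min_observed=1,
        fdr_cut=1.1,
    )
    assert base[0].enrichment_rate == pytest.approx(remapped[0].enrichment_rate)
    assert base[0].p_value == pytest.approx(remapped[0].p_value)
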