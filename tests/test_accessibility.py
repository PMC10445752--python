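"""QC semantics, normalization closed forms, and the LR differential test."""

import numpy as np
import pytest
import scipy.sparse
import scipy.stats

from itb_regnet.accessibility import (
    QCThresholds,
    differential_table,
    gene_activity,
    lr_differential_test,
    qc_filter,
    stage_specific_test,
    tfidf_normalize,
)
from itb_regnet.io_formats import CountMatrix, GeneRecord, Peak, PeakSet, ValidationError
from itb_regnet.synthetic_data import SimConfig, generate_dataset


def make_matrix(counts, labels, peaks=None):
    counts = np.asarray(counts)
    n_peaks, n_nuclei = counts.shape
    if peaks is None:
        peaks = PeakSet(
            [Peak("chr1", 1000 * i, 1000 * i + 500, f"p{i + 1}") for i in range(n_peaks)]
        )
    barcodes = [f"b{j + 1}" for j in range(n_nuclei)]
    return CountMatrix(
        peaks=peaks,
        nuclei=barcodes,
        counts=scipy.sparse.csr_matrix(counts),
        labels=dict(zip(barcodes, labels)),
    )


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def test_qc_boundary_semantics():
    # depths: 500 (below floor), 1000 (at floor, retained by depth), 1500 (mid)
    counts = np.array([[500, 1000, 1500]])
    m = make_matrix(counts, ["A", "A", "A"])
    # b2 sits exactly at the depth floor (inclusive: kept by depth) and at
    # frip 0.15 (strict >: removed by frip)
    total_reads = np.array([1000.0, 1000 / 0.15, 1500 / 0.20])
    tss = np.array([2.0, 2.0, 2.0])
    filtered, report = qc_filter(m, total_reads, tss)
    assert filtered.nuclei == ["b3"]
    assert report.removed_low_depth == 1
    assert report.removed_frip == 1
    assert report.n_retained == 1


def test_qc_reports_each_criterion():
    counts = np.array([[1500, 25000, 1500, 1500]])
    m = make_matrix(counts, list("AAAA"))
    total = np.array([3000.0, 50000.0, 15000.0, 3000.0])  # b3 frip = 0.1
    tss = np.array([3.0, 3.0, 3.0, 1.0])  # b4 fails tss
    filtered, report = qc_filter(m, total, tss)
    assert filtered.nuclei == ["b1"]
    assert (report.removed_high_depth, report.removed_frip, report.removed_tss) == (1, 1, 1)


def test_qc_misaligned_vectors_rejected():
    m = make_matrix(np.array([[1, 2]]), ["A", "A"])
    with pytest.raises(ValidationError):
        qc_filter(m, [1.0], [1.0, 1.0])


# ---------------------------------------------------------------------------
# TF-IDF
# ---------------------------------------------------------------------------

def test_tfidf_closed_forms():
    m = make_matrix(np.array([[1], [0]]), ["A"])
    values = tfidf_normalize(m, scale=1e4)
    # single nucleus: tf = log(1 + 1e4 * 1/1); idf = log(1 + 1/(1+1))
    assert values[0, 0] == pytest.approx(np.log(1 + 1e4) * np.log(1.5))
    assert values[1, 0] == 0.0


def test_tfidf_ubiquitous_peak_downweighted():
    counts = np.array([[5, 5, 5], [5, 0, 0]])
    m = make_matrix(counts, list("AAA"))
    v = tfidf_normalize(m)
    # same tf in nucleus 1, but the peak seen everywhere has a smaller idf
    assert v[0, 0] < v[1, 0]


def test_tfidf_requires_positive_depth():
    m = make_matrix(np.array([[1, 0]]), ["A", "A"])
    with pytest.raises(ValidationError, match="depth"):
        tfidf_normalize(m)


# ---------------------------------------------------------------------------
# Gene activity
# ---------------------------------------------------------------------------

def test_gene_activity_closed_form_and_window_edges():
    peaks = PeakSet(
        [
            Peak("chr1", 4000, 4500, "inside"),  # wholly inside the window
            Peak("chr1", 6999, 7100, "edge"),  # overlaps window end by 1 bp
            Peak("chr1", 7000, 7200, "outside"),  # starts exactly at tss+window
        ]
    )
    counts = np.array([[4], [0], [4]])
    m = make_matrix(counts, ["A"], peaks=peaks)
    genes = [GeneRecord("g1", "chr1", "+", 5000, 9000)]  # tss 5000, window ±2000
    activity = gene_activity(m, genes, window=2000)
    # depth 8; only "inside" and "edge" overlap [3000, 7000)
    assert activity.loc["g1", "A"] == pytest.approx(4 / 8 * 1e4)


def test_gene_activity_zero_without_nearby_peak():
    m = make_matrix(np.array([[3]]), ["A"])
    genes = [GeneRecord("far", "chr2", "+", 0, 100)]
    assert gene_activity(m, genes).loc["far", "A"] == 0.0


def test_gene_activity_invariant_to_orderings(rng):
    counts = rng.poisson(2.0, size=(6, 8)) + 1
    labels = list("AABBABAB")
    m = make_matrix(counts, labels)
    genes = [
        GeneRecord("g1", "chr1", "+", 900, 4000),
        GeneRecord("g2", "chr1", "-", 100, 3100),
    ]
    base = gene_activity(m, genes)
    perm_peaks = rng.permutation(6)
    perm_nuclei = rng.permutation(8)
    m_shuffled = make_matrix(
        counts[np.ix_(perm_peaks, perm_nuclei)],
        [labels[j] for j in perm_nuclei],
        peaks=PeakSet([m.peaks.peaks[i] for i in perm_peaks]),
    )
    shuffled = gene_activity(m_shuffled, genes)
    assert np.allclose(base.to_numpy(), shuffled.to_numpy())


# ---------------------------------------------------------------------------
# LR differential test
# ---------------------------------------------------------------------------

def test_degenerate_peak_has_no_signal():
    counts = np.array([[0, 0, 0, 0], [1, 5, 1, 5]])
    m = make_matrix(counts, ["T", "T", "O", "O"])
    res = lr_differential_test(m, "T")
    flat = next(r for r in res if r.peak_id == "p1")
    assert flat.p_value == 1.0 and flat.log2fc == 0.0


def test_planted_peak_called_specific():
    rng = np.random.default_rng(5)
    n = 100
    depth_base = rng.integers(900, 1100, size=2 * n)
    target_counts = rng.poisson(3.0, size=n)  # a' ~ 30 in targets
    counts = np.zeros((2, 2 * n), dtype=int)
    counts[0, :n] = target_counts
    counts[1] = depth_base  # filler peak puts every depth near 1000
    m = make_matrix(counts, ["T"] * n + ["O"] * n)
    res = lr_differential_test(m, "T")
    planted = next(r for r in res if r.peak_id == "p1")
    assert planted.specific and planted.converged


def test_lr_requires_two_nuclei_per_side():
    m = make_matrix(np.array([[1, 2, 3]]), ["T", "O", "O"])
    with pytest.raises(ValidationError, match="2 nuclei"):
        lr_differential_test(m, "T")


def test_stage_test_on_relabeled_identical_matrices(small_bundle):
    m = small_bundle.stages["gd15"].matrix
    sub = m.subset_nuclei(range(80))
    res = stage_specific_test(sub, sub, "iTB")
    assert not any(r.specific for r in res)


def test_stage_test_empty_peak_intersection():
    m1 = make_matrix(np.array([[1, 2, 1, 2]]), ["A", "A", "B", "B"])
    m2 = make_matrix(
        np.array([[1, 2, 1, 2]]),
        ["A", "A", "B", "B"],
        peaks=PeakSet([Peak("chr9", 0, 100, "other")]),
    )
    with pytest.raises(ValidationError, match="intersection"):
        stage_specific_test(m1, m2, "A")


def test_differential_table_columns(small_bundle):
    res = lr_differential_test(small_bundle.stages["gd15"].matrix, "iTB")
    table = differential_table(res)
    assert list(table.columns) == [
        "peak_id", "group", "log2fc", "p", "adj_p", "specific", "converged",
    ]
    assert (table["adj_p"] >= table["p"] - 1e-15).all()
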