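"""PWM scanning, score-threshold DP, matched backgrounds, family statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from itb_regnet import motif_enrichment as me
from itb_regnet.io_formats import Peak, PeakSet, ValidationError
from itb_regnet.motif_enrichment import (
    MotifHitTable,
    counts_to_probs,
    families_per_peak,
    filter_expressed_tfs,
    gc_content,
    group_families,
    motif_enrichment_test,
    pairwise_family_tests,
    sample_matched_background,
    scan_motifs,
    score_threshold,
)
from itb_regnet.synthetic_data import consensus_pwm

RC = str.maketrans("ACGT", "TGCA")


def brute_force_threshold(pwm, p_cutoff, granularity=1e-3):
    """Enumerate all 4^L words under the uniform background."""
    ints = me._int_scores(pwm, (0.25,) * 4, granularity)[:4]
    L = pwm.length
    scores = np.array(
        [ints[list(w), range(L)].sum() for w in itertools.product(range(4), repeat=L)]
    )
    for s in np.unique(scores):
        if (scores >= s).sum() / scores.size <= p_cutoff:
            return int(s)
    return int(scores.max()) + 1


def test_counts_to_probs_zero_column_uniform():
    probs = counts_to_probs(np.zeros((4, 2)))
    assert probs == pytest.approx(np.full((4, 2), 0.25))
    with pytest.raises(ValidationError):
        counts_to_probs(np.zeros((3, 2)))


def test_consensus_hit_and_miss():
    pwm = consensus_pwm("M", "M", "ACGT", "F", ("TF",), strength=997.0)
    hits = scan_motifs({"yes": "ACGT", "no": "AAAA"}, [pwm], p_cutoff=5e-3)
    assert bool(hits.hits.loc["yes", "M"]) and not bool(hits.hits.loc["no", "M"])


def test_reverse_complement_of_consensus_hits():
    pwm = consensus_pwm("M", "M", "ACGGT", "F", ("TF",), strength=997.0)
    hits = scan_motifs({"rc": "ACCGT"}, [pwm], p_cutoff=1e-3)  # revcomp of ACGGT
    assert bool(hits.hits.loc["rc", "M"])


def test_short_sequence_and_n_never_match():
    pwm = consensus_pwm("M", "M", "ACGTAC", "F", ("TF",), strength=997.0)
    hits = scan_motifs({"short": "ACG", "with_n": "ACGNAC"}, [pwm], p_cutoff=0.5)
    assert not hits.hits.to_numpy().any()


def test_dp_threshold_equals_enumeration(rng):
    for trial in range(30):
        L = int(rng.integers(3, 9))
        counts = rng.integers(0, 40, size=(4, L)).astype(float)
        pwm = me.PWM(f"T{trial}", "t", counts_to_probs(counts))
        for p_cutoff in (5e-5, 1e-3, 0.02):
            assert score_threshold(pwm, p_cutoff=p_cutoff) == brute_force_threshold(
                pwm, p_cutoff
            ), (trial, L, p_cutoff)


def test_scan_is_strand_symmetric(rng):
    pwms = [
        me.PWM(f"R{k}", "r", counts_to_probs(rng.integers(0, 30, size=(4, 6)).astype(float)))
        for k in range(5)
    ]
    seqs = {
        f"s{i}": "".join(rng.choice(list("ACGT"), size=200)) for i in range(20)
    }
    fwd = scan_motifs(seqs, pwms, p_cutoff=1e-3)
    rc = scan_motifs(
        {k: v.translate(RC)[::-1] for k, v in seqs.items()}, pwms, p_cutoff=1e-3
    )
    assert fwd.hits.equals(rc.hits)


# ---------------------------------------------------------------------------
# Matched background
# ---------------------------------------------------------------------------

def _seq(rng, length, gc):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def test_homogeneous_pool_matches_exactly(rng):
    fg = PeakSet([Peak("c", i * 200, i * 200 + 100, f"f{i}") for i in range(5)])
    pool = PeakSet([Peak("c", i * 200, i * 200 + 100, f"b{i}") for i in range(50)])
    fg_seqs = {p.id: _seq(rng, 100, 0.5) for p in fg}
    pool_seqs = {p.id: _seq(rng, 100, 0.5) for p in pool}
    sample = sample_matched_background(fg, fg_seqs, pool, pool_seqs, n=500, seed=1)
    assert len(sample.ids) == 500
    assert all(len(pool_seqs[i]) == 100 for i in sample.ids)


def test_zero_draws_gives_empty_sample(rng):
    fg = PeakSet([Peak("c", 0, 100, "f")])
    pool = PeakSet([Peak("c", 0, 100, "b")])
    seqs = {"f": _seq(rng, 100, 0.5), "b": _seq(rng, 100, 0.5)}
    sample = sample_matched_background(fg, {"f": seqs["f"]}, pool, {"b": seqs["b"]}, n=0, seed=1)
    assert sample.ids == []


def test_heterogeneous_gc_distribution_matched(rng):
    """Sampled GC histogram stays within 0.02 total variation of the target."""
    fg_peaks, fg_seqs = [], {}
    for i in range(400):
        gc = float(rng.uniform(0.35, 0.65))
        fg_peaks.append(Peak("c", i * 200, i * 200 + 150, f"f{i}"))
        fg_seqs[f"f{i}"] = _seq(rng, 150, gc)
    pool_peaks, pool_seqs = [], {}
    for i in range(4000):
        gc = float(rng.uniform(0.30, 0.70))
        pool_peaks.append(Peak("c", i * 200, i * 200 + 150, f"b{i}"))
        pool_seqs[f"b{i}"] = _seq(rng, 150, gc)
    fg, pool = PeakSet(fg_peaks), PeakSet(pool_peaks)
    sample = sample_matched_background(fg, fg_seqs, pool, pool_seqs, n=50000, seed=7)
    edges = np.quantile([gc_content(s) for s in fg_seqs.values()],
                        np.linspace(0, 1, 11)[1:-1])
    fg_hist = np.bincount(
        np.digitize([gc_content(s) for s in fg_seqs.values()], edges), minlength=10
    ) / len(fg_seqs)
    bg_hist = np.bincount(
        np.digitize([gc_content(pool_seqs[i]) for i in sample.ids], edges),
        minlength=10,
    ) / len(sample.ids)
    assert 0.5 * np.abs(fg_hist - bg_hist).sum() <= 0.02


# ---------------------------------------------------------------------------
# Enrichment, filtering, grouping
# ---------------------------------------------------------------------------

def hit_table(bools, motifs, prefix):
    arr = np.asarray(bools, dtype=bool)
    return MotifHitTable(
        hits=pd.DataFrame(
            arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])], columns=motifs
        ),
        p_cutoff=5e-5,
        bg=(0.25,) * 4,
    )


def test_enrichment_fold_change_and_oracle_p():
    fg = hit_table([[1]] * 8 + [[0]] * 2, ["M"], "f")
    bg = hit_table([[1]] * 2 + [[0]] * 8, ["M"], "b")
    res = motif_enrichment_test(fg, bg)
    assert res.loc["M", "fold_change"] == pytest.approx(4.0)
    # same tail as drawing 10 from 20 with 10 marked, observing 8
    from itb_regnet.stats_core import hypergeom_overlap
    assert res.loc["M", "p"] == pytest.approx(
        hypergeom_overlap(8, 10, 10, 20).p_value
    )


def test_enrichment_identical_tables_flat():
    fg = hit_table([[1, 0], [0, 1], [1, 1]], ["M1", "M2"], "f")
    res = motif_enrichment_test(fg, fg)
    assert res["fold_change"].to_numpy() == pytest.approx([1.0, 1.0])
    assert (res["p"] >= 0.5).all()


def test_enrichment_empty_background_fraction():
    fg = hit_table([[1]] * 5, ["M"], "f")
    bg = hit_table([[0]] * 5, ["M"], "b")
    res = motif_enrichment_test(fg, bg)
    assert np.isinf(res.loc["M", "fold_change"])
    assert 0.0 < res.loc["M", "p"] < 1.0


def test_expression_filter_boundaries():
    expr = {"A": (0.5, 0.5), "B": (0.6, 0.4), "C": (2.0, 2.0)}
    mapping = {"m1": ["A"], "m2": ["B"], "m3": ["B", "C"], "m4": []}
    with pytest.warns(UserWarning, match="m4"):
        kept = filter_expressed_tfs(["m1", "m2", "m3", "m4"], mapping, expr)
    assert kept == {"m1": ["A"], "m3": ["C"]}  # inclusive at 0.5; dimer passes via C


def test_family_union_property_and_representatives(rng):
    pwms = [
        consensus_pwm("M1", "TFA_motif", "ACGTAC", "FAM", ("TFA",)),
        consensus_pwm("M2", "TFB_motif", "GGTACC", "FAM", ("TFB",)),
        consensus_pwm("M3", "TFC_motif", "TTTACG", "LONE", ("TFC",)),
    ]
    fg = hit_table(rng.random((30, 3)) < 0.4, ["M1", "M2", "M3"], "f")
    bg = hit_table(rng.random((100, 3)) < 0.2, ["M1", "M2", "M3"], "b")
    enrich = motif_enrichment_test(fg, bg)
    expr = {"TFA": (1.0, 1.0), "TFB": (3.0, 3.0), "TFC": (2.0, 2.0)}
    fams = group_families(pwms, enrich, fg, bg, expr)
    fam = fams["FAM"]
    member_max = max(
        enrich.loc["M1", "fg_fraction"], enrich.loc["M2", "fg_fraction"]
    )
    assert fam.fg_fraction >= member_max  # union can only add peaks
    assert set(fam.representative_motifs) <= {"M1", "M2"}
    assert fams["LONE"].representative_motifs == ("M3",)
    # single-motif family aggregates to exactly its member's fractions
    assert fams["LONE"].fg_fraction == pytest.approx(enrich.loc["M3", "fg_fraction"])


def test_pairwise_tests_symmetric_with_oracle_cell():
    genes = {
        "F1": {f"g{i}" for i in range(4)},
        "F2": {f"g{i}" for i in range(1, 6)},  # overlap 3... adjust below
    }
    genes["F2"] = {"g0", "g1", "g2", "g3", "g9"}  # overlap 4, sizes 4 and 5
    peaks = {"F1": {"p1"}, "F2": {"p2"}}
    gm, pm = pairwise_family_tests(genes, peaks, gene_universe=10, peak_universe=10)
    assert gm.loc["F1", "F2"] == gm.loc["F2", "F1"]
    # single pair: BH leaves the raw enumeration value untouched
    assert gm.loc["F1", "F2"] == pytest.approx(5 / 210)
    assert pm.loc["F1", "F2"] == pytest.approx(1.0)  # disjoint peak sets


def test_pairwise_requires_two_families():
    with pytest.raises(ValidationError):
        pairwise_family_tests({"F": set()}, {"F": set()}, 10, 10)


def test_families_per_peak_histogram_conserves_peaks():
    peaks = PeakSet([Peak("c", i * 100, i * 100 + 50, f"p{i}") for i in range(5)])
    fams = {"F1": {"p0", "p1", "p2"}, "F2": {"p0"}, "F3": {"p0"}}
    hist = families_per_peak(fams, peaks)
    assert hist.sum() == len(peaks)
    assert hist.loc[0] == 2 and hist.loc[1] == 2 and hist.loc[3] == 1
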