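"""PWM scanning, matched backgrounds, motif/family enrichment, co-occurrence.

Motif presence is a thresholded log-odds scan: a peak is hit when any window
on either strand reaches the score whose exact null tail probability under
the background base composition is at most ``p_cutoff``. The null score
distribution is computed by dynamic programming over per-position scores
discretized to a fixed granularity; scanning uses the same discretized scores,
so scan calls are exactly consistent with the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import PeakSet, ValidationError
from .stats_core import bh_adjust, hypergeom_overlap

UNIFORM_BG = (0.25, 0.25, 0.25, 0.25)
PSEUDOCOUNT = 0.8  # distributed by background frequency, TFBSTools convention
SCORE_GRANULARITY = 1e-3
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_N_CODE = 4
_MIN_SCORE = np.iinfo(np.int32).min // 2  # sentinel: N never matches


@dataclass(frozen=True)
class PWM:
    """A position probability matrix with TF and family annotations."""

    motif_id: str
    name: str
    probs: np.ndarray  # 4 x L, rows A/C/G/T
    tf_names: tuple[str, ...] = ()
    family: str = ""
    tf_class: str = ""

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "tf_names", tuple(self.tf_names))
        if probs.ndim != 2 or probs.shape[0] != 4 or probs.shape[1] < 1:
            raise ValidationError(f"motif {self.motif_id}: probs must be 4 x L")
        if not np.allclose(probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValidationError(
                f"motif {self.motif_id}: columns must sum to 1"
            )

    @property
    def length(self) -> int:
        return self.probs.shape[1]


@dataclass
class MotifHitTable:
    """Boolean peak x motif occurrence with the scan parameters that fixed it."""

    hits: pd.DataFrame  # bool; index sequence/sample ids, columns motif ids
    p_cutoff: float
    bg: tuple[float, float, float, float]

    @property
    def motif_ids(self) -> list[str]:
        return list(self.hits.columns)

    def fraction(self) -> pd.Series:
        return self.hits.mean(axis=0)


@dataclass(frozen=True)
class FamilyEnrichment:
    family: str
    member_motifs: tuple[str, ...]
    representative_motifs: tuple[str, ...]
    fg_fraction: float
    bg_fraction: float
    fold_change: float
    adj_p: float

    @property
    def enriched(self) -> bool:
        return self.adj_p <= 0.05 and self.fold_change >= 1.5


# ---------------------------------------------------------------------------
# PWM arithmetic
# ---------------------------------------------------------------------------

def counts_to_probs(
    counts: np.ndarray,
    pseudocount: float = PSEUDOCOUNT,
    bg: Sequence[float] = UNIFORM_BG,
) -> np.ndarray:
    """Convert a 4 x L count matrix to probabilities.

    The pseudocount is distributed over bases proportionally to the background
    frequencies before normalization, so an all-zero column becomes the
    background distribution (uniform 0.25 by default).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4:
        raise ValidationError("count matrix must be 4 x L (rows A/C/G/T)")
    bg = np.asarray(bg, dtype=float)[:, np.newaxis]
    padded = counts + pseudocount * bg
    return padded / padded.sum(axis=0)


def _int_scores(pwm: PWM, bg: Sequence[float], granularity: float) -> np.ndarray:
    """Per-position log2-odds scores discretized to integer granularity units.

    Shape 5 x L: row 4 is the non-ACGT (N) sentinel that can never reach any
    threshold.
    """
    bg = np.asarray(bg, dtype=float)
    with np.errstate(divide="ignore"):
        logodds = np.log2(pwm.probs / bg[:, np.newaxis])
    ints = np.rint(logodds / granularity)
    ints[~np.isfinite(ints)] = _MIN_SCORE
    out = np.full((5, pwm.length), _MIN_SCORE, dtype=np.int64)
    out[:4] = ints.astype(np.int64)
    return out


def score_threshold(
    pwm: PWM,
    p_cutoff: float = 5e-5,
    bg: Sequence[float] = UNIFORM_BG,
    granularity: float = SCORE_GRANULARITY,
) -> int:
    """Smallest discretized score whose exact null tail probability is <= p_cutoff.

    The null distribution of the window score under iid background bases is
    built by dynamic programming: one convolution per motif position over the
    integer score offsets. Returned in integer granularity units (the same
    units :func:`scan_motifs` scores windows in).
    """
    if not 0.0 < p_cutoff < 1.0:
        raise ValidationError("p_cutoff must lie in (0,1)")
    scores = _int_scores(pwm, bg, granularity)[:4]
    bg = np.asarray(bg, dtype=float)
    finite = scores != _MIN_SCORE
    # a base with probability zero yields a -inf window score: it can never
    # reach any threshold, so it is dropped from the DP support (its mass
    # simply never appears in the tail)
    offset = np.where(finite, scores, np.iinfo(np.int64).max).min(axis=0)
    span = int(np.where(finite, scores - offset[np.newaxis, :], 0).max(axis=0).sum())
    dist = np.zeros(span + 1)
    dist[0] = 1.0
    pos_total = 0
    for j in range(pwm.length):
        width = int(scores[finite[:, j], j].max() - offset[j]) + 1
        new = np.zeros(pos_total + width)
        # per position the support has at most 4 mass points: convolve by
        # shifted adds instead of a dense kernel
        for b in range(4):
            if finite[b, j]:
                shift = int(scores[b, j] - offset[j])
                new[shift : shift + pos_total + 1] += bg[b] * dist[: pos_total + 1]
        dist[: new.size] = new
        pos_total = new.size - 1
    tail = np.cumsum(dist[::-1])[::-1]
    # threshold must be an achievable window score (dist mass > 0), matching
    # what exhaustive word enumeration returns
    above = np.flatnonzero((tail <= p_cutoff) & (dist > 0))
    if above.size == 0:
        # even the best possible score is too probable: unreachable threshold
        return int(np.where(finite, scores, _MIN_SCORE).max(axis=0).sum()) + 1
    return int(above[0] + offset.sum())


def _encode(seq: str) -> np.ndarray:
    codes = np.full(len(seq), _N_CODE, dtype=np.int8)
    for base, code in _BASE_INDEX.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = code
    return codes


def _revcomp_int_scores(scores: np.ndarray) -> np.ndarray:
    """Reverse-complement a 5 x L integer score matrix (exactly, no re-rounding)."""
    out = scores[:, ::-1].copy()
    out[[0, 1, 2, 3]] = out[[3, 2, 1, 0]]
    return out


def scan_motifs(
    sequences: Mapping[str, str],
    pwms: Sequence[PWM],
    p_cutoff: float = 5e-5,
    bg: Sequence[float] = UNIFORM_BG,
    granularity: float = SCORE_GRANULARITY,
) -> MotifHitTable:
    """Call motif presence per sequence on both strands.

    A sequence shorter than the motif simply has no windows (no hit, not an
    error); windows containing non-ACGT characters never match.
    """
    names = list(sequences)
    # scan one concatenated string: a single N separator makes every
    # boundary-crossing window carry the sentinel score, so it never matches
    encoded = [_encode(sequences[name].upper()) for name in names]
    starts = np.cumsum([0] + [c.size + 1 for c in encoded[:-1]])
    concat = np.full(sum(c.size for c in encoded) + len(encoded), _N_CODE,
                     dtype=np.int8)
    for st, codes in zip(starts, encoded):
        concat[st : st + codes.size] = codes

    hits = np.zeros((len(names), len(pwms)), dtype=bool)
    for mi, pwm in enumerate(pwms):
        fwd = _int_scores(pwm, bg, granularity)
        rev = _revcomp_int_scores(fwd)
        thr = score_threshold(pwm, p_cutoff=p_cutoff, bg=bg, granularity=granularity)
        L = pwm.length
        n_win = concat.size - L + 1
        if n_win <= 0:
            continue
        hit_idx: list[np.ndarray] = []
        for mat in (fwd, rev):
            scores = np.zeros(n_win, dtype=np.int64)
            for j in range(L):
                scores += mat[:, j][concat[j : j + n_win]]
            hit_idx.append(np.flatnonzero(scores >= thr))
        pos = np.unique(np.concatenate(hit_idx))
        if pos.size:
            seq_idx = np.searchsorted(starts, pos, side="right") - 1
            hits[np.unique(seq_idx), mi] = True
    return MotifHitTable(
        hits=pd.DataFrame(hits, index=names, columns=[p.motif_id for p in pwms]),
        p_cutoff=p_cutoff,
        bg=tuple(bg),
    )


# ---------------------------------------------------------------------------
# GC/length-matched background
# ---------------------------------------------------------------------------

def gc_content(seq: str) -> float:
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    return (seq.count("G") + seq.count("C")) / acgt if acgt else 0.0


@dataclass
class BackgroundSample:
    """A with-replacement background draw matched to a foreground.

    ``ids`` lists the drawn pool peak ids (repeats allowed); ``max_bin_deviation``
    is the largest absolute difference between foreground and sample mass in
    any (GC decile x length decile) bin.
    """

    ids: list[str]
    max_bin_deviation: float
    fallback_bins: int = 0

    def hit_table(self, pool_hits: MotifHitTable) -> MotifHitTable:
        """Expand a hit table scanned on unique pool sequences to the sample."""
        return MotifHitTable(
            hits=pool_hits.hits.loc[self.ids],
            p_cutoff=pool_hits.p_cutoff,
            bg=pool_hits.bg,
        )


def sample_matched_background(
    fg: PeakSet,
    fg_sequences: Mapping[str, str],
    pool: PeakSet,
    pool_sequences: Mapping[str, str],
    n: int = 50000,
    seed: int | np.random.Generator = 0,
    n_bins: int = 10,
) -> BackgroundSample:
    """Sample pool regions so GC x length deciles match the foreground.

    Bins are foreground deciles of GC content and sequence length; ``n`` draws
    with replacement are allocated to bins proportionally to foreground mass.
    A foreground bin with no pool members falls back to the nearest populated
    bin (warning).
    """
    if len(pool) == 0:
        raise ValidationError("empty background pool")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )

    def features(peaks: PeakSet, seqs: Mapping[str, str]):
        gc = np.array([gc_content(seqs[p.id]) for p in peaks])
        ln = np.array([len(seqs[p.id]) for p in peaks], dtype=float)
        return gc, ln

    fg_gc, fg_len = features(fg, fg_sequences)
    pool_gc, pool_len = features(pool, pool_sequences)
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    gc_edges = np.quantile(fg_gc, qs)
    len_edges = np.quantile(fg_len, qs)

    def bin_of(gc, ln):
        return np.digitize(gc, gc_edges), np.digitize(ln, len_edges)

    fg_bins = np.ravel_multi_index(bin_of(fg_gc, fg_len), (n_bins, n_bins))
    pool_bins = np.ravel_multi_index(bin_of(pool_gc, pool_len), (n_bins, n_bins))
    fg_mass = np.bincount(fg_bins, minlength=n_bins * n_bins) / len(fg)

    pool_members: dict[int, np.ndarray] = {
        int(b): np.flatnonzero(pool_bins == b) for b in np.unique(pool_bins)
    }
    populated = np.array(sorted(pool_members))

    counts = rng.multinomial(n, fg_mass)
    chosen: list[int] = []
    fallback_bins = 0
    for b in np.flatnonzero(counts):
        members = pool_members.get(int(b))
        if members is None:
            gi, li = divmod(int(b), n_bins)
            pg, pl = np.divmod(populated, n_bins)
            nearest = populated[np.argmin(np.abs(pg - gi) + np.abs(pl - li))]
            warnings.warn(
                f"background pool empty in foreground bin {b}; "
                f"falling back to nearest bin {nearest}"
            )
            fallback_bins += 1
            members = pool_members[int(nearest)]
        chosen.extend(rng.choice(members, size=counts[b], replace=True))

    pool_ids = pool.ids()
    sample_ids = [pool_ids[i] for i in chosen]
    sample_mass = np.bincount(
        pool_bins[np.asarray(chosen, dtype=int)], minlength=n_bins * n_bins
    ) / max(len(chosen), 1)
    deviation = float(np.abs(sample_mass - fg_mass).max()) if chosen else 0.0
    return BackgroundSample(sample_ids, deviation, fallback_bins)


# ---------------------------------------------------------------------------
# Enrichment, filtering, family grouping
# ---------------------------------------------------------------------------

def motif_enrichment_test(
    fg_hits: MotifHitTable, bg_hits: MotifHitTable
) -> pd.DataFrame:
    """Per-motif fold change and hypergeometric enrichment (BH across motifs).

    The test draws the foreground from the pooled foreground+background: the
    overlap is the foreground hit count, marked elements are all hits. A
    motif absent from the background but present in the foreground gets an
    infinite fold change; its p-value is still computed.
    """
    if list(fg_hits.hits.columns) != list(bg_hits.hits.columns):
        raise ValidationError("foreground and background motif sets differ")
    n_fg, n_bg = len(fg_hits.hits), len(bg_hits.hits)
    fg_count = fg_hits.hits.sum(axis=0).to_numpy()
    bg_count = bg_hits.hits.sum(axis=0).to_numpy()
    fg_frac = fg_count / n_fg
    bg_frac = bg_count / n_bg
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(
            bg_frac > 0, fg_frac / bg_frac, np.where(fg_frac > 0, np.inf, np.nan)
        )
    pvals = np.array(
        [
            hypergeom_overlap(
                int(k), n_fg, int(k + kb), n_fg + n_bg, tail="greater"
            ).p_value
            for k, kb in zip(fg_count, bg_count)
        ]
    )
    return pd.DataFrame(
        {
            "fg_fraction": fg_frac,
            "bg_fraction": bg_frac,
            "fold_change": fold,
            "p": pvals,
            "adj_p": bh_adjust(pvals),
        },
        index=fg_hits.hits.columns,
    )


def enriched_motifs(
    enrichment: pd.DataFrame, adj_p_cut: float = 0.05, min_fold: float = 1.5
) -> list[str]:
    """Motif ids passing the enrichment thresholds (adj p and fold change)."""
    keep = (enrichment["adj_p"] <= adj_p_cut) & (
        enrichment["fold_change"] >= min_fold
    )
    return list(enrichment.index[keep])


def filter_expressed_tfs(
    motif_ids: Iterable[str],
    motif_to_tfs: Mapping[str, Sequence[str]],
    expression: Mapping[str, tuple[float, float]],
    min_expr: float = 0.5,
) -> dict[str, list[str]]:
    """Keep motifs with at least one TF expressed (>= min_expr) at both stages.

    Returns motif -> surviving TFs. Motifs with no TF mapping are dropped with
    a warning. For dimer motifs one passing subunit suffices.
    """
    kept: dict[str, list[str]] = {}
    for motif in motif_ids:
        tfs = motif_to_tfs.get(motif)
        if not tfs:
            warnings.warn(f"motif {motif} has no TF mapping; dropped")
            continue
        passing = [
            tf
            for tf in tfs
            if tf in expression
            and expression[tf][0] >= min_expr
            and expression[tf][1] >= min_expr
        ]
        if passing:
            kept[motif] = passing
    return kept


def group_families(
    pwms: Sequence[PWM],
    enrichment: pd.DataFrame,
    fg_hits: MotifHitTable,
    bg_hits: MotifHitTable,
    expression: Mapping[str, tuple[float, float]],
    motif_ids: Iterable[str] | None = None,
) -> dict[str, FamilyEnrichment]:
    """Aggregate motif hits to TF families (a peak is hit by the family iff
    hit by any member motif) and pick representative motifs.

    Representatives follow the reporting convention: among the family's two
    most highly expressed TFs (mean over the two stages), each TF contributes
    its member motif with the highest fold change. The family adjusted p is
    the best (smallest) member adjusted p.
    """
    wanted = set(motif_ids) if motif_ids is not None else set(enrichment.index)
    by_family: dict[str, list[PWM]] = {}
    for pwm in pwms:
        if pwm.motif_id in wanted:
            if not pwm.family:
                raise ValidationError(f"motif {pwm.motif_id} has no family label")
            by_family.setdefault(pwm.family, []).append(pwm)

    out: dict[str, FamilyEnrichment] = {}
    for family, members in by_family.items():
        ids = [m.motif_id for m in members]
        fg_any = fg_hits.hits[ids].any(axis=1)
        bg_any = bg_hits.hits[ids].any(axis=1)
        fg_frac = float(fg_any.mean())
        bg_frac = float(bg_any.mean())
        fold = fg_frac / bg_frac if bg_frac > 0 else (np.inf if fg_frac else np.nan)

        def tf_expr(tf: str) -> float:
            e = expression.get(tf, (-np.inf, -np.inf))
            return (e[0] + e[1]) / 2.0

        tfs = sorted(
            {tf for m in members for tf in m.tf_names}, key=tf_expr, reverse=True
        )[:2]
        reps = []
        for tf in tfs:
            candidates = [m.motif_id for m in members if tf in m.tf_names]
            if candidates:
                reps.append(
                    max(candidates, key=lambda mid: enrichment.loc[mid, "fold_change"])
                )
        out[family] = FamilyEnrichment(
            family=family,
            member_motifs=tuple(ids),
            representative_motifs=tuple(dict.fromkeys(reps)),
            fg_fraction=fg_frac,
            bg_fraction=bg_frac,
            fold_change=float(fold),
            adj_p=float(enrichment.loc[ids, "adj_p"].min()),
        )
    return out


def family_hit_peaks(
    families: Mapping[str, FamilyEnrichment], fg_hits: MotifHitTable
) -> dict[str, set[str]]:
    """Foreground peaks hit by each family (union over member motifs)."""
    return {
        name: set(fg_hits.hits.index[fg_hits.hits[list(fam.member_motifs)].any(axis=1)])
        for name, fam in families.items()
    }


def pairwise_family_tests(
    family_genes: Mapping[str, set[str]],
    family_peaks: Mapping[str, set[str]],
    gene_universe: int,
    peak_universe: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shared-target-gene and shared-binding-location over-representation.

    For each unordered family pair, the overlap of their target-gene sets
    (resp. hit-peak sets) is tested hypergeometrically against the given
    universe size; BH is applied across all pairs within each matrix. Returns
    two symmetric DataFrames of adjusted p-values (diagonal NaN).
    """
    names = sorted(set(family_genes) | set(family_peaks))
    if len(names) < 2:
        raise ValidationError("need at least two families")

    def matrix(sets: Mapping[str, set[str]], universe: int) -> pd.DataFrame:
        for name, s in sets.items():
            if len(s) > universe:
                raise ValidationError(
                    f"family {name} set size {len(s)} exceeds universe {universe}"
                )
        pairs = [
            (a, b) for i, a in enumerate(names) for b in names[i + 1 :]
        ]
        raw = [
            hypergeom_overlap(
                len(sets.get(a, set()) & sets.get(b, set())),
                len(sets.get(a, set())),
                len(sets.get(b, set())),
                universe,
                tail="greater",
            ).p_value
            for a, b in pairs
        ]
        adj = bh_adjust(raw)
        out = pd.DataFrame(np.nan, index=names, columns=names)
        for (a, b), p in zip(pairs, adj):
            out.loc[a, b] = out.loc[b, a] = p
        return out

    return matrix(family_genes, gene_universe), matrix(family_peaks, peak_universe)


def families_per_peak(
    family_peaks: Mapping[str, set[str]], peaks: PeakSet
) -> pd.Series:
    """Histogram of the number of families hitting each peak (zero class kept)."""
    counts = {
        p.id: sum(p.id in hits for hits in family_peaks.values()) for p in peaks
    }
    per_peak = pd.Series(counts, dtype=int)
    histogram = per_peak.value_counts().sort_index()
    histogram.index.name = "n_families"
    return histogram.reindex(
        range(0, (int(per_peak.max()) if len(per_peak) else 0) + 1), fill_value=0
    )
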