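"""Nucleus QC, normalization, gene activity, and differential accessibility.

The differential test is a logistic regression of cell-population membership
on a peak's normalized accessibility with log total fragments-in-peaks as a
covariate, compared with the covariate-only null by a likelihood-ratio
chi-square with one degree of freedom. This restates the Seurat/Signac
"LR with latent variable" behavior as an explicit model: membership is the
outcome, sequencing depth is adjusted for, and the peak's contribution is the
single tested term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse
import scipy.special
import scipy.stats

from .io_formats import CountMatrix, GeneRecord, ValidationError
from .stats_core import bh_adjust

LOG2_FC_CUT = np.log2(1.5)
ADJ_P_CUT = 0.05
NORM_SCALE = 1e4


@dataclass(frozen=True)
class QCThresholds:
    """Nucleus-level quality thresholds.

    Fragments-in-peaks bounds are inclusive; the fraction-of-reads-in-peaks
    (FRiP) and TSS-enrichment cuts are strict, mirroring "ranging from 1000 to
    20,000" versus "greater than 15%" semantics.
    """

    min_fragments: int = 1000
    max_fragments: int = 20000
    min_frip: float = 0.15
    min_tss_enrichment: float = 1.5

    def __post_init__(self) -> None:
        if not self.min_fragments < self.max_fragments:
            raise ValidationError("min_fragments must be < max_fragments")
        if not 0.0 < self.min_frip < 1.0:
            raise ValidationError("min_frip must lie in (0,1)")


@dataclass(frozen=True)
class DifferentialPeak:
    peak_id: str
    group: str
    log2fc: float
    p_value: float
    adj_p: float
    converged: bool = True

    @property
    def specific(self) -> bool:
        return self.adj_p <= ADJ_P_CUT and self.log2fc >= LOG2_FC_CUT


@dataclass
class QCReport:
    n_input: int
    n_retained: int
    removed_low_depth: int
    removed_high_depth: int
    removed_frip: int
    removed_tss: int


def qc_filter(
    matrix: CountMatrix,
    per_nucleus_total_reads: Sequence[float],
    tss_enrichment: Sequence[float],
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[CountMatrix, QCReport]:
    """Retain nuclei passing depth, FRiP and TSS-enrichment thresholds.

    A nucleus can fail several criteria at once; the report counts each
    criterion independently.
    """
    total = np.asarray(per_nucleus_total_reads, dtype=float)
    tss = np.asarray(tss_enrichment, dtype=float)
    if total.size != len(matrix.nuclei) or tss.size != len(matrix.nuclei):
        raise ValidationError(
            "per-nucleus vectors must align with the matrix nuclei"
        )
    depth = matrix.depth
    with np.errstate(divide="ignore", invalid="ignore"):
        frip = np.where(total > 0, depth / total, 0.0)
    low = depth < thresholds.min_fragments
    high = depth > thresholds.max_fragments
    bad_frip = ~(frip > thresholds.min_frip)
    bad_tss = ~(tss > thresholds.min_tss_enrichment)
    keep = ~(low | high | bad_frip | bad_tss)
    report = QCReport(
        n_input=len(matrix.nuclei),
        n_retained=int(keep.sum()),
        removed_low_depth=int(low.sum()),
        removed_high_depth=int(high.sum()),
        removed_frip=int(bad_frip.sum()),
        removed_tss=int(bad_tss.sum()),
    )
    return matrix.subset_nuclei(np.flatnonzero(keep)), report


def tfidf_normalize(matrix: CountMatrix, scale: float = NORM_SCALE) -> np.ndarray:
    """log(term frequency) x log(IDF) normalization of the count matrix.

    value(i,j) = log(1 + scale * counts[i,j]/depth[j])
               * log(1 + n_nuclei / (1 + n_nuclei_with_peak_i)).
    Zero counts map exactly to zero.
    """
    if (matrix.depth == 0).any():
        raise ValidationError("zero-depth nucleus; run qc_filter first")
    counts = matrix.counts.toarray().astype(float)
    tf = np.log1p(scale * counts / matrix.depth[np.newaxis, :])
    n_with_peak = (counts > 0).sum(axis=1)
    idf = np.log(1.0 + len(matrix.nuclei) / (1.0 + n_with_peak))
    return tf * idf[:, np.newaxis]


def gene_activity(
    matrix: CountMatrix,
    genes: Sequence[GeneRecord],
    window: int = 2000,
) -> pd.DataFrame:
    """Promoter-proximal accessibility per gene and cell type.

    For each gene, fragment counts of peaks overlapping [tss - window,
    tss + window) are summed per nucleus, depth-normalized (x 1e4), and
    averaged within each cell-type label. Returns genes x cell types.
    """
    labels = matrix.label_array
    celltypes = sorted(set(labels))
    peak_list = matrix.peaks.peaks
    starts = np.array([p.start for p in peak_list])
    ends = np.array([p.end for p in peak_list])
    chroms = np.array([p.chrom for p in peak_list])

    norm = matrix.counts.multiply(NORM_SCALE / matrix.depth[np.newaxis, :]).tocsr()
    type_masks = {ct: labels == ct for ct in celltypes}

    values = np.zeros((len(genes), len(celltypes)))
    for gi, gene in enumerate(genes):
        lo, hi = gene.tss - window, gene.tss + window
        # half-open interval intersection
        hit = (chroms == gene.chrom) & (starts < hi) & (ends > lo)
        if not hit.any():
            continue
        per_nucleus = np.asarray(norm[np.flatnonzero(hit), :].sum(axis=0)).ravel()
        for ci, ct in enumerate(celltypes):
            values[gi, ci] = per_nucleus[type_masks[ct]].mean()
    return pd.DataFrame(
        values, index=[g.gene_id for g in genes], columns=celltypes
    )


# ---------------------------------------------------------------------------
# Logistic-regression likelihood-ratio differential test
# ---------------------------------------------------------------------------

def _logistic_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log(1 + e^eta) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _fit_logistic(
    X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10
) -> tuple[np.ndarray, float, bool]:
    """Newton fit with step halving; converges on log-likelihood.

    Under quasi-complete separation the coefficients diverge but the
    log-likelihood approaches its supremum, so declaring convergence on the
    likelihood keeps the LRT statistic well defined.
    """
    beta = np.zeros(X.shape[1])
    ll = _logistic_loglik(X, y, beta)
    for _ in range(max_iter):
        eta = X @ beta
        mu = scipy.special.expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        grad = X.T @ (y - mu)
        hess = (X * w[:, np.newaxis]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # step halving: never accept a decrease in log-likelihood
        scale = 1.0
        for _ in range(30):
            ll_new = _logistic_loglik(X, y, beta + scale * step)
            if ll_new >= ll - 1e-13:
                break
            scale *= 0.5
        else:
            return beta, ll, True  # no uphill step exists: at the optimum
        beta = beta + scale * step
        if ll_new - ll < tol * (abs(ll) + 1.0):
            return beta, ll_new, True
        ll = ll_new
    return beta, ll, False


def lr_differential_test(
    matrix: CountMatrix,
    target: str,
    group_name: str | None = None,
) -> list[DifferentialPeak]:
    """One-vs-rest differential accessibility via a depth-adjusted LR test.

    Per peak, the full model logit P(nucleus in target) ~ b0 + b1*a +
    b2*log(depth) with a = log(1 + 1e4*count/depth) is compared against the
    null omitting b1 (fit once per comparison, since it does not involve the
    peak). log2 fold change uses a' = 1e4*count/depth with pseudocount 1.
    """
    labels = matrix.label_array
    y = (labels == target).astype(float)
    n_target = int(y.sum())
    if n_target < 2 or (y.size - n_target) < 2:
        raise ValidationError(
            f"need >= 2 nuclei on each side; target {target!r} has {n_target}"
        )
    depth = matrix.depth.astype(float)
    if (depth == 0).any():
        raise ValidationError("zero-depth nucleus; run qc_filter first")
    log_depth = np.log(depth)

    X_null = np.column_stack([np.ones_like(y), log_depth])
    _, ll_null, _ = _fit_logistic(X_null, y)

    norm = NORM_SCALE * matrix.counts.toarray() / depth[np.newaxis, :]
    a = np.log1p(norm)
    target_mask = y == 1.0

    stats = np.zeros(len(matrix.peaks))
    converged = np.ones(len(matrix.peaks), dtype=bool)
    log2fc = np.log2(
        (norm[:, target_mask].mean(axis=1) + 1.0)
        / (norm[:, ~target_mask].mean(axis=1) + 1.0)
    )
    X_full = np.column_stack([np.ones_like(y), np.zeros_like(y), log_depth])
    for i in range(len(matrix.peaks)):
        ai = a[i]
        if ai.max() == ai.min():  # degenerate predictor: no information
            stats[i] = 0.0
            continue
        X_full[:, 1] = ai
        _, ll_full, ok = _fit_logistic(X_full, y)
        stats[i] = max(0.0, 2.0 * (ll_full - ll_null))
        converged[i] = ok

    p = scipy.stats.chi2.sf(stats, df=1)
    p[~converged] = 1.0  # never silently report an unconverged fit
    adj = bh_adjust(p)
    group = group_name if group_name is not None else target
    return [
        DifferentialPeak(
            peak_id=pid,
            group=group,
            log2fc=float(log2fc[i]),
            p_value=float(p[i]),
            adj_p=float(adj[i]),
            converged=bool(converged[i]),
        )
        for i, pid in enumerate(matrix.peaks.ids())
    ]


def stage_specific_test(
    matrix_a: CountMatrix,
    matrix_b: CountMatrix,
    celltype: str,
    stage_names: tuple[str, str] = ("stage_a", "stage_b"),
) -> list[DifferentialPeak]:
    """Differential accessibility between stages within one cell type.

    Nuclei of ``celltype`` from both matrices are pooled over the shared peak
    universe and the same LR test is run with stage as the group label;
    reported effect/p are for stage A vs stage B.
    """
    shared = [pid for pid in matrix_a.peaks.ids() if pid in matrix_b.peaks]
    if not shared:
        raise ValidationError("empty intersection of peak universes")

    def stage_slice(matrix: CountMatrix, stage: str) -> tuple:
        sub = matrix.subset_peaks(shared)
        keep = np.flatnonzero(sub.label_array == celltype)
        if keep.size == 0:
            raise ValidationError(f"no {celltype!r} nuclei in {stage}")
        sub = sub.subset_nuclei(keep)
        return sub, [f"{stage}:{b}" for b in sub.nuclei]

    sub_a, bc_a = stage_slice(matrix_a, stage_names[0])
    sub_b, bc_b = stage_slice(matrix_b, stage_names[1])
    pooled = CountMatrix(
        peaks=sub_a.peaks,
        nuclei=bc_a + bc_b,
        counts=scipy.sparse.hstack(
            [sub_a.counts, sub_b.counts], format="csr"
        ),
        labels={
            **{b: stage_names[0] for b in bc_a},
            **{b: stage_names[1] for b in bc_b},
        },
    )
    return lr_differential_test(
        pooled, target=stage_names[0], group_name=f"{celltype}:{stage_names[0]}"
    )


def differential_table(results: Sequence[DifferentialPeak]) -> pd.DataFrame:
    """Tabulate test results (columns peak_id, group, log2fc, p, adj_p, specific)."""
    return pd.DataFrame(
        {
            "peak_id": [r.peak_id for r in results],
            "group": [r.group for r in results],
            "log2fc": [r.log2fc for r in results],
            "p": [r.p_value for r in results],
            "adj_p": [r.adj_p for r in results],
            "specific": [r.specific for r in results],
            "converged": [r.converged for r in results],
        }
    )
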