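"""Synthetic two-stage snATAC-seq bundles with planted ground truth.

The generator emulates the study design the pipeline targets: two
"gestational-day" datasets of multi-cell-type nuclei with lognormal depth
heterogeneity, Poisson fragment counts, planted cell-type-specific peaks
partially shared between stages, peak sequences with controlled GC content
and planted motif occurrences, per-cell-type expression monotonically coupled
to promoter-proximal accessibility, a partial cross-species conservation map
with reference peak sets, and the implied TF-family -> target-gene network.

Every consumed input exists in the bundle, either in memory or — via
:meth:`SimBundle.write` — as the plain-text files :mod:`~itb_regnet.io_formats`
reads, so the full pipeline is testable with no external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse
import yaml

from .io_formats import (
    CountMatrix,
    GeneRecord,
    IntervalMapping,
    MappingRecord,
    Peak,
    PeakSet,
    ValidationError,
    write_bed,
    write_count_matrix,
    write_fasta,
    write_gene_annotation,
    write_gmt,
    write_interval_mapping,
    write_matrix_pwm,
)
from .motif_enrichment import PWM, counts_to_probs

STAGES = ("gd15", "gd19")
CELLTYPE_POOL = ("iTB", "NK", "Macrophage", "Endothelial", "SmoothMuscle")
NORM_SCALE = 1e4

# Planted motif catalogue: near-deterministic consensus PWMs grouped into
# TF families, echoing the kinds of families recovered in invasive
# trophoblast chromatin (AP-2, bZIP, E2A, nuclear receptors, STAT).
PLANTED_MOTIF_SPECS = (
    ("M001", "TFAP2C", "GCCTGAGGCTAA", "AP-2", ("TFAP2C",)),
    ("M002", "TFAP2A", "GCCCTAGGCTTG", "AP-2", ("TFAP2A",)),
    ("M003", "JUNB", "TGACTCATCGAC", "bZIP", ("JUNB",)),
    ("M004", "TCF4", "CACCTGTTGCAT", "E2A", ("TCF4",)),
    ("M005", "NR2F6", "TGACCTTTGACC", "NR-C4", ("NR2F6",)),
    ("M006", "STAT3", "TTCCCGGAAATG", "STAT", ("STAT3",)),
)


def consensus_pwm(
    motif_id: str,
    name: str,
    consensus: str,
    family: str,
    tf_names: Sequence[str],
    strength: float = 97.0,
) -> PWM:
    """A PWM putting ``strength``/(strength+3) probability on each consensus base."""
    counts = np.ones((4, len(consensus)))
    index = {"A": 0, "C": 1, "G": 2, "T": 3}
    for j, base in enumerate(consensus):
        counts[index[base], j] = strength
    return PWM(
        motif_id=motif_id,
        name=name,
        probs=counts_to_probs(counts),
        tf_names=tuple(tf_names),
        family=family,
        tf_class=family,
    )


def default_motif_set() -> list[PWM]:
    return [consensus_pwm(*spec) for spec in PLANTED_MOTIF_SPECS]


def decoy_motifs(n: int, rng: np.random.Generator, length: int = 12) -> list[PWM]:
    """Random consensus PWMs that are never planted (negative controls)."""
    bases = np.array(list("ACGT"))
    out = []
    for k in range(n):
        consensus = "".join(rng.choice(bases, size=length))
        out.append(
            consensus_pwm(
                f"D{k + 1:03d}",
                f"DECOY{k + 1}",
                consensus,
                f"DECOY_FAM{k + 1}",
                (f"DECOYTF{k + 1}",),
            )
        )
    return out


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic bundle.

    Defaults are the generator's standing study conditions: five cell types of
    200 nuclei per stage over 2000 peaks, 50 specific peaks per type with 80%
    of the target type's shared between stages, lognormal depths (meanlog 7.5,
    sdlog 0.4, i.e. a median of ~1800 fragments in peaks), an accessibility
    effect of +10 on the 1e4-normalized count scale, motifs planted into 30%
    of the target's common peaks, 60% of peaks carrying a conservation record,
    and expression noise of 1.7 standard deviations on the standardized
    accessibility scale (placing the expression-accessibility Spearman rho in
    the documented 0.4-0.6 band).
    """

    n_celltypes: int = 5
    n_nuclei_per_type: int = 200
    n_peaks: int = 2000
    n_specific_per_type: int = 50
    effect_size: float = 10.0
    depth_lognormal: tuple[float, float] = (7.5, 0.4)
    genome: tuple[tuple[str, int], ...] = (("chr1", 2_400_000), ("chr2", 1_600_000))
    n_genes: int = 300
    planted_fraction: float = 0.3
    conserved_fraction: float = 0.6
    expr_noise_sd: float = 1.7
    seed: int = 0
    # secondary knobs
    shared_specific_fraction: float = 0.8
    peak_length_range: tuple[int, int] = (300, 500)
    gc_mean: float = 0.45
    gc_sd: float = 0.07
    junk_fraction: float = 0.05
    ref_atac_coverage: float = 0.85
    n_decoy_motifs: int = 50
    plant_consensus: bool = False
    target_celltype: str = "iTB"

    def __post_init__(self) -> None:
        for name in ("n_celltypes", "n_nuclei_per_type", "n_peaks",
                     "n_specific_per_type", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("planted_fraction", "conserved_fraction",
                     "shared_specific_fraction", "junk_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0,1]")
        if self.n_celltypes > len(CELLTYPE_POOL):
            raise ValidationError(
                f"at most {len(CELLTYPE_POOL)} cell types supported"
            )
        if self.n_specific_per_type * self.n_celltypes * 2 > self.n_peaks:
            raise ValidationError("too many specific peaks for n_peaks")

    @property
    def celltypes(self) -> tuple[str, ...]:
        return CELLTYPE_POOL[: self.n_celltypes]

    @classmethod
    def noiseless(cls, seed: int = 0, **overrides) -> "SimConfig":
        """The noiseless end-to-end configuration: strong planted effects,
        exhaustive motif planting with exact consensus insertion, no
        expression noise, no junk nuclei."""
        params = dict(
            effect_size=150.0,
            planted_fraction=1.0,
            expr_noise_sd=0.0,
            junk_fraction=0.0,
            plant_consensus=True,
            n_peaks=1000,
            n_celltypes=3,
            n_nuclei_per_type=150,
            n_specific_per_type=40,
            n_genes=250,
            seed=seed,
        )
        params.update(overrides)
        return cls(**params)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("depth_lognormal", "peak_length_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "genome" in raw:
            raw["genome"] = tuple((c, int(n)) for c, n in raw["genome"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["genome"] = [list(g) for g in self.genome]
        raw["depth_lognormal"] = list(self.depth_lognormal)
        raw["peak_length_range"] = list(self.peak_length_range)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class StageData:
    matrix: CountMatrix
    qc: pd.DataFrame  # index barcode; columns total_reads, tss_enrichment


@dataclass
class SimBundle:
    """Everything the pipeline consumes, plus the planted ground truth."""

    config: SimConfig
    stages: dict[str, StageData]
    genes: list[GeneRecord]
    sequences: dict[str, str]
    pwms: list[PWM]
    planted_motif_ids: list[str]
    expression: dict[str, pd.DataFrame]  # stage -> genes x celltypes
    tf_expression: pd.DataFrame  # index tf; columns gd15, gd19
    mapping: IntervalMapping
    ref_atac: PeakSet
    ref_h3k27ac: PeakSet
    ref_chip: PeakSet
    ref_genes: list[GeneRecord]
    orthology: pd.DataFrame
    markers: dict[str, set[str]]
    conserved_markers: set[str]
    gene_sets: dict[str, set[str]]
    ground_truth: dict

    @property
    def peaks(self) -> PeakSet:
        return self.stages[STAGES[0]].matrix.peaks

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the bundle as plain-text files; returns path map."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for stage, data in self.stages.items():
            stage_paths = write_count_matrix(data.matrix, out, prefix=f"{stage}_")
            paths.update({f"{stage}_{k}": v for k, v in stage_paths.items()})
            qc_path = out / f"{stage}_qc.tsv"
            data.qc.rename_axis("barcode").to_csv(qc_path, sep="\t")
            paths[f"{stage}_qc"] = qc_path
            expr_path = out / f"{stage}_expression.tsv"
            self.expression[stage].rename_axis("gene_id").to_csv(expr_path, sep="\t")
            paths[f"{stage}_expression"] = expr_path
        write_gene_annotation(self.genes, out / "annotation.tsv")
        write_fasta(self.sequences, out / "peaks.fasta")
        write_matrix_pwm(self.pwms, out / "motifs.jaspar")
        self.tf_expression.rename_axis("tf").to_csv(out / "tf_expression.tsv", sep="\t")
        write_interval_mapping(self.mapping, out / "mapping.tsv")
        write_bed(self.ref_atac, out / "ref_atac.bed")
        write_bed(self.ref_h3k27ac, out / "ref_h3k27ac.bed")
        write_bed(self.ref_chip, out / "ref_chip.bed")
        write_gene_annotation(self.ref_genes, out / "ref_annotation.tsv")
        self.orthology.to_csv(out / "orthology.tsv", sep="\t", index=False)
        for stage in STAGES:
            pd.DataFrame({"gene_id": sorted(self.markers[stage])}).to_csv(
                out / f"{stage}_markers.tsv", sep="\t", index=False
            )
        pd.DataFrame({"gene_id": sorted(self.conserved_markers)}).to_csv(
            out / "conserved_markers.tsv", sep="\t", index=False
        )
        write_gmt(self.gene_sets, out / "gene_sets.gmt")
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth, fh, indent=1, sort_keys=True)
        paths.update(
            {
                "annotation": out / "annotation.tsv",
                "peaks_fasta": out / "peaks.fasta",
                "motifs": out / "motifs.jaspar",
                "tf_expression": out / "tf_expression.tsv",
                "mapping": out / "mapping.tsv",
                "ref_atac": out / "ref_atac.bed",
                "ref_h3k27ac": out / "ref_h3k27ac.bed",
                "ref_chip": out / "ref_chip.bed",
                "ref_annotation": out / "ref_annotation.tsv",
                "orthology": out / "orthology.tsv",
                "conserved_markers": out / "conserved_markers.tsv",
                "gene_sets": out / "gene_sets.gmt",
                "ground_truth": out / "ground_truth.json",
            }
        )
        return paths


# ---------------------------------------------------------------------------
# Internal construction steps
# ---------------------------------------------------------------------------

def _make_peaks(config: SimConfig, rng: np.random.Generator) -> PeakSet:
    total_len = sum(n for _, n in config.genome)
    spacing = total_len // config.n_peaks
    if spacing < config.peak_length_range[1] + 200:
        raise ValidationError(
            "genome too small for n_peaks with the required spacing"
        )
    per_chrom = [
        max(1, round(config.n_peaks * n / total_len)) for _, n in config.genome
    ]
    # keep the total exact despite rounding
    per_chrom[-1] += config.n_peaks - sum(per_chrom)
    peaks = []
    for (chrom, length), n_chrom in zip(config.genome, per_chrom):
        grid = length // n_chrom
        for i in range(n_chrom):
            size = int(rng.integers(*config.peak_length_range))
            slack = grid - size
            start = i * grid + int(rng.integers(0, max(1, slack)))
            peaks.append(Peak(chrom, start, start + size, f"peak_{len(peaks) + 1}"))
    return PeakSet(peaks)


def _plant_specific(config: SimConfig, rng: np.random.Generator, peaks: PeakSet):
    """Assign specific peaks per (cell type, stage) as runs of adjacent peaks.

    Real cell-type-specific accessibility clusters around regulated genes, so
    specific peaks are planted in runs of 1-4 consecutive peaks; a run's
    middle peak later hosts the regulated gene, giving genes with several
    specific peaks. A fraction of each type's peaks (whole runs) is shared
    between the two stages. Runs are kept two grid cells apart so every run
    member's nearest gene is its own run's host.
    """
    ids = peaks.ids()
    chrom_of = [p.chrom for p in peaks]
    n = len(ids)
    blocked: set[int] = set()  # run members plus 2-cell margins

    def draw_runs(total: int) -> list[list[int]]:
        runs, placed, attempts = [], 0, 0
        while placed < total:
            attempts += 1
            if attempts > 100_000:
                raise ValidationError(
                    "could not place specific-peak runs; peak universe too dense"
                )
            length = int(rng.integers(1, min(4, total - placed) + 1))
            start = int(rng.integers(0, n - length + 1))
            members = list(range(start, start + length))
            if any(m in blocked for m in members):
                continue
            if len({chrom_of[m] for m in members}) != 1:
                continue
            runs.append(members)
            blocked.update(range(max(0, start - 2), min(n, start + length + 2)))
            placed += length
        return runs

    n_shared = round(config.shared_specific_fraction * config.n_specific_per_type)
    n_extra = config.n_specific_per_type - n_shared
    specific: dict[str, dict[str, list[str]]] = {s: {} for s in STAGES}
    shared: dict[str, list[str]] = {}
    anchors: dict[str, list[int]] = {}
    for celltype in config.celltypes:
        shared_runs = draw_runs(n_shared)
        extra_runs = {stage: draw_runs(n_extra) for stage in STAGES}
        shared[celltype] = sorted(ids[m] for r in shared_runs for m in r)
        for stage in STAGES:
            specific[stage][celltype] = sorted(
                shared[celltype] + [ids[m] for r in extra_runs[stage] for m in r]
            )
        anchors[celltype] = [r[len(r) // 2] for r in shared_runs] + [
            r[len(r) // 2] for stage in STAGES for r in extra_runs[stage]
        ]
    return specific, shared, anchors, blocked


def _stage_counts(
    config: SimConfig,
    rng: np.random.Generator,
    peaks: PeakSet,
    weights: np.ndarray,
    specific: Mapping[str, Sequence[str]],
    stage: str,
) -> StageData:
    celltypes = config.celltypes
    n_good = config.n_nuclei_per_type * len(celltypes)
    n_junk = round(config.junk_fraction * n_good)
    labels_arr = np.repeat(celltypes, config.n_nuclei_per_type)
    if n_junk:
        labels_arr = np.concatenate(
            [labels_arr, rng.choice(celltypes, size=n_junk)]
        )
    n_total = labels_arr.size
    barcodes = [f"{stage}_BC{j + 1:05d}" for j in range(n_total)]

    mu, sigma = config.depth_lognormal
    depth_target = rng.lognormal(mu, sigma, size=n_total)
    if n_junk:
        depth_target[n_good:] = rng.lognormal(6.0, 0.3, size=n_junk)

    peak_index = {pid: i for i, pid in enumerate(peaks.ids())}
    boost = np.zeros((len(peaks), len(celltypes)))
    for ci, celltype in enumerate(celltypes):
        for pid in specific[celltype]:
            boost[peak_index[pid], ci] = config.effect_size / NORM_SCALE

    type_of = np.array([celltypes.index(l) for l in labels_arr])
    rates = (weights[:, np.newaxis] + boost[:, type_of]) * depth_target[np.newaxis, :]
    counts = rng.poisson(rates)

    frip = rng.uniform(0.4, 0.7, size=n_total)
    tss_enr = rng.uniform(3.0, 8.0, size=n_total)
    if n_junk:
        frip[n_good:] = rng.uniform(0.05, 0.12, size=n_junk)
        tss_enr[n_good:] = rng.uniform(0.5, 1.2, size=n_junk)
    realized_depth = counts.sum(axis=0)
    total_reads = np.maximum(realized_depth, 1) / frip

    matrix = CountMatrix(
        peaks=peaks,
        nuclei=barcodes,
        counts=scipy.sparse.csr_matrix(counts),
        labels=dict(zip(barcodes, labels_arr)),
    )
    qc = pd.DataFrame(
        {"total_reads": total_reads, "tss_enrichment": tss_enr}, index=barcodes
    )
    return StageData(matrix=matrix, qc=qc)


def _make_genes(
    config: SimConfig,
    rng: np.random.Generator,
    peaks: PeakSet,
    anchor_indices: Sequence[int],
    blocked: set[int],
) -> list[GeneRecord]:
    """One gene per host peak.

    Hosts are the run anchors first (so every specific-peak run has a resident
    gene), then randomly chosen peaks outside the blocked margins around the
    runs; if the genome runs out of unblocked peaks the remainder spills into
    any unused peak.
    """
    filler = [i for i in range(len(peaks)) if i not in blocked]
    rng.shuffle(filler)
    spill = [i for i in range(len(peaks)) if i in blocked and i not in set(anchor_indices)]
    hosts = (list(dict.fromkeys(anchor_indices)) + filler + spill)[: config.n_genes]
    genes = []
    chrom_len = dict(config.genome)
    for k, host in enumerate(hosts):
        peak = peaks.peaks[host]
        tss = (peak.start + peak.end) // 2 + int(rng.integers(-100, 101))
        tss = max(1, min(tss, chrom_len[peak.chrom] - 2))
        strand = "+" if rng.random() < 0.5 else "-"
        span = 5000
        if strand == "+":
            start, end = tss, min(tss + span, chrom_len[peak.chrom])
        else:
            end = tss + 1
            start = max(0, end - span)
        genes.append(GeneRecord(f"gene_{k + 1:04d}", peak.chrom, strand, start, end))
    return genes


def _nearest_gene_of(peak: Peak, genes: Sequence[GeneRecord]) -> str | None:
    """Brute-force strand-aware nearest-TSS rule (edge distance, lexicographic
    ties), independent of :func:`itb_regnet.peak_gene.nearest_gene`."""
    best = None
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        tss = g.tss
        if peak.start <= tss < peak.end:
            mag = 0
        elif tss >= peak.end:
            mag = tss - peak.end
        else:
            mag = peak.start - tss
        key = (mag, g.gene_id)
        if best is None or key < best:
            best = key
    return best[1] if best else None


def _make_sequences(
    config: SimConfig,
    rng: np.random.Generator,
    peaks: PeakSet,
    planted_pwms: Sequence[PWM],
    plant_targets: Mapping[str, Sequence[str]],
) -> tuple[dict[str, str], dict[str, dict[str, list[int]]]]:
    """Draw iid sequences with per-peak GC and insert planted motifs."""
    bases = np.array(list("ACGT"))
    sequences: dict[str, str] = {}
    gc = np.clip(
        rng.normal(config.gc_mean, config.gc_sd, size=len(peaks)), 0.30, 0.60
    )
    for i, peak in enumerate(peaks):
        p = np.array(
            [(1 - gc[i]) / 2, gc[i] / 2, gc[i] / 2, (1 - gc[i]) / 2]
        )
        sequences[peak.id] = "".join(rng.choice(bases, size=peak.length, p=p))

    placements: dict[str, dict[str, list[int]]] = {p.motif_id: {} for p in planted_pwms}
    occupied: dict[str, list[tuple[int, int]]] = {}
    index = {"A": 0, "C": 1, "G": 2, "T": 3}
    for pwm in planted_pwms:
        L = pwm.length
        consensus = "".join("ACGT"[b] for b in np.argmax(pwm.probs, axis=0))
        for pid in plant_targets.get(pwm.motif_id, []):
            seq = sequences[pid]
            if len(seq) < L:
                continue
            taken = occupied.setdefault(pid, [])
            pos = None
            for _ in range(50):  # find a slot not clobbering earlier insertions
                cand = int(rng.integers(0, len(seq) - L + 1))
                if all(cand + L <= s or cand >= e for s, e in taken):
                    pos = cand
                    break
            if pos is None:
                continue
            if config.plant_consensus:
                insert = consensus
            else:
                insert = "".join(
                    bases[rng.choice(4, p=pwm.probs[:, j])] for j in range(L)
                )
            sequences[pid] = seq[:pos] + insert + seq[pos + L :]
            taken.append((pos, pos + L))
            placements[pwm.motif_id].setdefault(pid, []).append(pos)
    return sequences, placements


def _promoter_accessibility(
    matrix: CountMatrix,
    genes: Sequence[GeneRecord],
    celltype: str,
    window: int = 2000,
) -> np.ndarray:
    """Mean depth-normalized (x1e4) promoter-window counts over one cell type."""
    mask = matrix.label_array == celltype
    depth = matrix.depth.astype(float)
    norm = matrix.counts[:, np.flatnonzero(mask)].toarray() / depth[mask] * NORM_SCALE
    peak_list = matrix.peaks.peaks
    starts = np.array([p.start for p in peak_list])
    ends = np.array([p.end for p in peak_list])
    chroms = np.array([p.chrom for p in peak_list])
    out = np.zeros(len(genes))
    for gi, gene in enumerate(genes):
        hit = (
            (chroms == gene.chrom)
            & (starts < gene.tss + window)
            & (ends > gene.tss - window)
        )
        if hit.any():
            out[gi] = norm[hit].sum(axis=0).mean()
    return out


def _expression_tables(
    config: SimConfig,
    rng: np.random.Generator,
    stages: Mapping[str, StageData],
    genes: Sequence[GeneRecord],
) -> dict[str, pd.DataFrame]:
    """Per-stage gene x cell-type expression coupled to promoter accessibility.

    expression = 5 + z(accessibility) + N(0, expr_noise_sd), floored at zero;
    the standardization makes the noise scale interpretable across configs.
    """
    tables = {}
    for stage, data in stages.items():
        cols = {}
        for celltype in config.celltypes:
            acc = _promoter_accessibility(data.matrix, genes, celltype)
            sd = acc.std()
            z = (acc - acc.mean()) / sd if sd > 0 else np.zeros_like(acc)
            noise = (
                rng.normal(0.0, config.expr_noise_sd, size=len(genes))
                if config.expr_noise_sd > 0
                else 0.0
            )
            cols[celltype] = np.maximum(0.0, 5.0 + z + noise)
        tables[stage] = pd.DataFrame(
            cols, index=[g.gene_id for g in genes]
        )
    return tables


# ---------------------------------------------------------------------------
# Public generators
# ---------------------------------------------------------------------------

def generate_dataset(config: SimConfig) -> SimBundle:
    """Generate the full two-stage bundle with planted ground truth.

    Deterministic given ``config`` (including its seed): repeated calls return
    identical bundles, and :meth:`SimBundle.write` produces byte-identical
    files.
    """
    rng = np.random.default_rng(config.seed)
    target = config.target_celltype
    if target not in config.celltypes:
        raise ValidationError(f"target cell type {target!r} not in celltypes")

    peaks = _make_peaks(config, rng)
    specific, shared, anchors, blocked = _plant_specific(config, rng, peaks)
    common_target = sorted(shared[target])

    # peak weights: heterogeneous baseline accessibility, mean 1/n_peaks
    weights = rng.gamma(2.0, 1.0, size=len(peaks))
    weights /= weights.sum()

    stages = {
        stage: _stage_counts(config, rng, peaks, weights, specific[stage], stage)
        for stage in STAGES
    }

    # genes: run anchors of the target type first, then the other types' runs
    anchor_order = list(anchors[target]) + [
        idx for ct in config.celltypes if ct != target for idx in anchors[ct]
    ]
    genes = _make_genes(config, rng, peaks, anchor_order, blocked)

    # motif planting into the target's common peaks
    planted_pwms = default_motif_set()
    n_plant = round(config.planted_fraction * len(common_target))
    plant_targets = {
        pwm.motif_id: sorted(
            rng.choice(common_target, size=n_plant, replace=False)
        )
        if n_plant
        else []
        for pwm in planted_pwms
    }
    sequences, placements = _make_sequences(
        config, rng, peaks, planted_pwms, plant_targets
    )
    pwms = planted_pwms + decoy_motifs(config.n_decoy_motifs, rng)

    # conservation: identity-plus-offset records over a fraction of peaks
    offset = 1_000_000
    conserved_ids = {
        p.id for p in peaks if rng.random() < config.conserved_fraction
    }
    mapping = IntervalMapping(
        MappingRecord(
            p.chrom, p.start, p.end, f"h{p.chrom}", p.start + offset,
            p.end + offset, "+",
        )
        for p in peaks
        if p.id in conserved_ids
    )

    def image(pid: str, new_id: str) -> Peak:
        p = peaks[pid]
        return Peak(f"h{p.chrom}", p.start + offset, p.end + offset, new_id)

    # a peak is conserved iff it maps AND its image lands in reference open
    # chromatin; the reference covers only part of the mappable common peaks,
    # so conservation is a genuine second filter after mappability
    mappable_common = sorted(set(common_target) & conserved_ids)
    n_covered = round(config.ref_atac_coverage * len(mappable_common))
    conserved_common = (
        sorted(rng.choice(mappable_common, size=n_covered, replace=False))
        if n_covered
        else []
    )

    # reference open chromatin: images of conserved common peaks, a minority of
    # conserved stage-specific target peaks, plus decoy regions
    stage_only = {
        stage: sorted(
            (set(specific[stage][target]) - set(common_target)) & conserved_ids
        )
        for stage in STAGES
    }
    ref_atac_peaks = [
        image(pid, f"refATAC_{k + 1}") for k, pid in enumerate(conserved_common)
    ]
    for stage in STAGES:
        chosen = stage_only[stage][: max(1, len(stage_only[stage]) // 5)]
        ref_atac_peaks += [
            image(pid, f"refATAC_{stage}_{k + 1}") for k, pid in enumerate(chosen)
        ]
    for k in range(30):
        start = int(rng.integers(0, 900_000 - 600))
        ref_atac_peaks.append(
            Peak("hchr1", start, start + int(rng.integers(200, 600)), f"refATAC_decoy_{k + 1}")
        )
    ref_atac = PeakSet(ref_atac_peaks)

    # active-enhancer marks: most conserved common peak images + decoys
    n_marked = round(0.8 * len(conserved_common))
    ref_h3k27ac = PeakSet(
        [
            image(pid, f"refH3K_{k + 1}")
            for k, pid in enumerate(conserved_common[:n_marked])
        ]
        + [
            Peak(
                "hchr2",
                s := int(rng.integers(0, 900_000 - 600)),
                s + int(rng.integers(200, 600)),
                f"refH3K_decoy_{k + 1}",
            )
            for k in range(20)
        ]
    )

    # TFAP2C-like ChIP reference: images of conserved peaks planted with the
    # first motif
    chip_source = sorted(
        set(plant_targets[planted_pwms[0].motif_id]) & conserved_ids
    )
    ref_chip = PeakSet(
        image(pid, f"refChIP_{k + 1}") for k, pid in enumerate(chip_source)
    )

    # expression coupled to promoter accessibility
    expression = _expression_tables(config, rng, stages, genes)

    # TF expression: planted TFs comfortably above the filter at both stages;
    # half the decoy TFs below it to exercise the expression filter
    tf_rows = {}
    for pwm in planted_pwms:
        for tf in pwm.tf_names:
            tf_rows[tf] = (
                float(rng.uniform(1.0, 3.0)), float(rng.uniform(1.0, 3.0))
            )
    for k, pwm in enumerate(pwms[len(planted_pwms):]):
        for tf in pwm.tf_names:
            if k % 2 == 0:
                tf_rows[tf] = (
                    float(rng.uniform(0.6, 2.0)), float(rng.uniform(0.6, 2.0))
                )
            else:
                tf_rows[tf] = (
                    float(rng.uniform(0.0, 0.4)), float(rng.uniform(0.0, 0.4))
                )
    tf_expression = pd.DataFrame(tf_rows, index=list(STAGES)).T

    # orthology: one-to-one for most genes, a few one-to-many rows
    ortho_rows = []
    for k, g in enumerate(genes):
        r = k % 20
        if r == 0:
            continue  # no ortholog
        ortho_rows.append({"source_gene": g.gene_id, "target_gene": f"H_{g.gene_id}"})
        if r == 1:  # one-to-many: must be dropped downstream
            ortho_rows.append(
                {"source_gene": g.gene_id, "target_gene": f"H_{g.gene_id}_b"}
            )
    orthology = pd.DataFrame(ortho_rows)

    ref_genes = [
        GeneRecord(f"H_{g.gene_id}", f"h{g.chrom}", g.strand, g.start + offset,
                   g.end + offset)
        for g in genes
    ]

    # markers and the implied regulatory network
    nearest = {pid: _nearest_gene_of(peaks[pid], genes) for pid in common_target}
    candidates = sorted({g for g in nearest.values() if g is not None})
    held_out = set(candidates[:: 10])  # every tenth candidate withheld
    conserved_markers = set(candidates) - held_out
    markers = {}
    all_gene_ids = [g.gene_id for g in genes]
    for stage in STAGES:
        stage_nearest = {
            _nearest_gene_of(peaks[pid], genes)
            for pid in specific[stage][target]
        }
        extra = set(rng.choice(all_gene_ids, size=30, replace=False))
        markers[stage] = {g for g in stage_nearest if g} | extra | set(candidates)

    network_edges: dict[str, dict[str, list[str]]] = {}
    for pwm in planted_pwms:
        fam = pwm.family
        for pid in plant_targets[pwm.motif_id]:
            if pid not in conserved_common:
                continue
            gene = nearest.get(pid)
            if gene is None or gene not in conserved_markers:
                continue
            network_edges.setdefault(fam, {}).setdefault(gene, [])
            if pid not in network_edges[fam][gene]:
                network_edges[fam][gene].append(pid)
    for fam in network_edges:
        for gene in network_edges[fam]:
            network_edges[fam][gene].sort()

    # gene sets: the planted target genes as one coherent term + random terms
    target_genes = sorted(
        {g for fam in network_edges.values() for g in fam}
    )
    gene_sets: dict[str, set[str]] = {}
    if target_genes:
        gene_sets["PLANTED_TARGETS"] = set(target_genes)
    for k in range(9):
        gene_sets[f"RANDOM_SET_{k + 1}"] = set(
            rng.choice(all_gene_ids, size=20, replace=False)
        )

    ground_truth = {
        "specific_peaks": {
            stage: {ct: sorted(ids) for ct, ids in specific[stage].items()}
            for stage in STAGES
        },
        "common_target_peaks": common_target,
        "conserved_common_peaks": conserved_common,
        "motif_placements": placements,
        "planted_motifs": [p.motif_id for p in planted_pwms],
        "family_tfs": {
            fam: sorted(
                {tf for p in planted_pwms if p.family == fam for tf in p.tf_names}
            )
            for fam in {p.family for p in planted_pwms}
        },
        "network_edges": network_edges,
        "conserved_markers": sorted(conserved_markers),
    }

    return SimBundle(
        config=config,
        stages=stages,
        genes=genes,
        sequences=sequences,
        pwms=pwms,
        planted_motif_ids=[p.motif_id for p in planted_pwms],
        expression=expression,
        tf_expression=tf_expression,
        mapping=mapping,
        ref_atac=ref_atac,
        ref_h3k27ac=ref_h3k27ac,
        ref_chip=ref_chip,
        ref_genes=ref_genes,
        orthology=orthology,
        markers=markers,
        conserved_markers=conserved_markers,
        gene_sets=gene_sets,
        ground_truth=ground_truth,
    )


def generate_null(config: SimConfig) -> SimBundle:
    """The matched null bundle: no accessibility effects, no planted motifs.

    Used for calibration: differential-accessibility p-values should be
    approximately uniform and motif discoveries should stay at the nominal
    false-discovery level. The ground truth lists zero planted entities.
    """
    null_config = SimConfig(
        **{
            **asdict(config),
            "effect_size": 0.0,
            "planted_fraction": 0.0,
            "genome": config.genome,
            "depth_lognormal": config.depth_lognormal,
            "peak_length_range": config.peak_length_range,
        }
    )
    bundle = generate_dataset(null_config)
    # under the null nothing is planted: the structural assignments used for
    # rate construction carry no effect, so the ground truth lists no entities
    bundle.ground_truth["specific_peaks"] = {
        stage: {ct: [] for ct in null_config.celltypes} for stage in STAGES
    }
    bundle.ground_truth["common_target_peaks"] = []
    bundle.ground_truth["conserved_common_peaks"] = []
    bundle.ground_truth["network_edges"] = {}
    bundle.ground_truth["motif_placements"] = {
        m: {} for m in bundle.ground_truth["motif_placements"]
    }
    return bundle
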