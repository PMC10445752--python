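"""Readers/writers for every external format the pipeline touches.

All genomic coordinates are normalized to the BED convention (0-based,
half-open) on read; GTF input (1-based, inclusive) is shifted once here so no
other module deals with coordinate dialects.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ParseError(ValueError):
    """Malformed input file (reports the offending line where possible)."""


class ValidationError(ValueError):
    """Structurally parseable input violating a contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Peak:
    """A genomic interval of elevated accessibility (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    id: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"peak {self.id}: negative start {self.start}")
        if self.start >= self.end:
            raise ValidationError(
                f"peak {self.id}: empty or inverted interval [{self.start},{self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class PeakSet:
    """An ordered collection of uniquely identified peaks."""

    def __init__(self, peaks: Iterable[Peak]):
        self.peaks: list[Peak] = list(peaks)
        ids = [p.id for p in self.peaks]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).value_counts()
            raise ValidationError(
                f"duplicate peak ids: {list(dup[dup > 1].index[:5])}"
            )
        self._by_id = {p.id: p for p in self.peaks}

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def __contains__(self, peak_id: str) -> bool:
        return peak_id in self._by_id

    def __getitem__(self, peak_id: str) -> Peak:
        return self._by_id[peak_id]

    def ids(self) -> list[str]:
        return [p.id for p in self.peaks]

    def subset(self, ids: Iterable[str]) -> "PeakSet":
        wanted = set(ids)
        return PeakSet(p for p in self.peaks if p.id in wanted)

    def __eq__(self, other) -> bool:
        return isinstance(other, PeakSet) and self.peaks == other.peaks

    def __repr__(self) -> str:
        return f"PeakSet({len(self.peaks)} peaks)"


@dataclass(frozen=True)
class GeneRecord:
    """A gene with a strand-aware transcription start site.

    ``tss`` is the first transcribed base in 0-based coordinates: ``start`` on
    the plus strand, ``end - 1`` on the minus strand.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(
                f"gene {self.gene_id}: unknown strand {self.strand!r}"
            )
        if self.start >= self.end:
            raise ValidationError(
                f"gene {self.gene_id}: empty interval [{self.start},{self.end})"
            )

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class CountMatrix:
    """Peak x nucleus fragment counts with labels and per-nucleus depths.

    ``depth`` is always the column sum of ``counts`` (fragments in peaks).
    """

    peaks: PeakSet
    nuclei: list[str]
    counts: scipy.sparse.csr_matrix  # peaks x nuclei
    labels: dict[str, str]

    depth: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = scipy.sparse.csr_matrix(self.counts)
        if self.counts.shape != (len(self.peaks), len(self.nuclei)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.peaks)} peaks x {len(self.nuclei)} nuclei"
            )
        missing = [b for b in self.nuclei if b not in self.labels]
        if missing:
            raise ValidationError(f"unlabeled barcodes: {missing[:5]}")
        if (self.counts.data < 0).any():
            raise ValidationError("negative fragment counts")
        self.depth = np.asarray(self.counts.sum(axis=0)).ravel()

    @property
    def label_array(self) -> np.ndarray:
        return np.array([self.labels[b] for b in self.nuclei])

    def subset_nuclei(self, keep: Sequence[int]) -> "CountMatrix":
        keep = list(keep)
        return CountMatrix(
            peaks=self.peaks,
            nuclei=[self.nuclei[j] for j in keep],
            counts=self.counts[:, keep],
            labels={self.nuclei[j]: self.labels[self.nuclei[j]] for j in keep},
        )

    def subset_peaks(self, peak_ids: Sequence[str]) -> "CountMatrix":
        index = {pid: i for i, pid in enumerate(self.peaks.ids())}
        rows = [index[pid] for pid in peak_ids]
        return CountMatrix(
            peaks=self.peaks.subset(peak_ids),
            nuclei=list(self.nuclei),
            counts=self.counts[rows, :],
            labels=dict(self.labels),
        )


@dataclass(frozen=True)
class MappingRecord:
    source_chrom: str
    source_start: int
    source_end: int
    target_chrom: str
    target_start: int
    target_end: int
    strand: str

    def __post_init__(self) -> None:
        if self.source_end - self.source_start != self.target_end - self.target_start:
            raise ValidationError("mapping record with unequal source/target length")
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"mapping record with strand {self.strand!r}")


class IntervalMapping:
    """A simplified cross-species interval map (7-column TSV dialect).

    Each record maps a source block to an equal-length target block, optionally
    strand-reversed. Source blocks must not overlap one another.
    """

    def __init__(self, records: Iterable[MappingRecord]):
        self.records = sorted(
            records, key=lambda r: (r.source_chrom, r.source_start)
        )
        prev: MappingRecord | None = None
        for rec in self.records:
            if (
                prev is not None
                and rec.source_chrom == prev.source_chrom
                and rec.source_start < prev.source_end
            ):
                raise ValidationError(
                    f"overlapping source records at {rec.source_chrom}:{rec.source_start}"
                )
            prev = rec

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> PeakSet:
    """Read a BED3/BED4 file into a :class:`PeakSet`.

    Ids come from column 4 when present, otherwise synthesized as ``peak_<n>``
    (1-based file order).
    """
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            pid = fields[3] if len(fields) >= 4 and fields[3] else f"peak_{len(peaks) + 1}"
            try:
                peaks.append(Peak(fields[0], start, end, pid))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(peaks)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.id}\n")


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

_GTF_GENE_ID = re.compile(r'gene_id "([^"]+)"')


def read_gene_annotation(path: str | Path, dialect: str = "tsv") -> list[GeneRecord]:
    """Read gene records from GTF (1-based inclusive) or TSV (0-based half-open).

    The TSV dialect has a header and columns gene_id, chrom, strand, start, end.
    Only ``gene`` features of a GTF are used; attributes are parsed for gene_id
    only. Coordinates are normalized to 0-based half-open.
    """
    if dialect == "gtf":
        genes = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 9:
                    raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
                if fields[2] != "gene":
                    continue
                m = _GTF_GENE_ID.search(fields[8])
                if not m:
                    raise ParseError(f"{path}:{lineno}: no gene_id attribute")
                genes.append(
                    GeneRecord(
                        gene_id=m.group(1),
                        chrom=fields[0],
                        strand=fields[6],
                        start=int(fields[3]) - 1,  # 1-based inclusive -> 0-based
                        end=int(fields[4]),
                    )
                )
        return genes
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
        required = {"gene_id", "chrom", "strand", "start", "end"}
        if not required.issubset(df.columns):
            raise ParseError(f"{path}: missing columns {required - set(df.columns)}")
        return [
            GeneRecord(r.gene_id, r.chrom, r.strand, int(r.start), int(r.end))
            for r in df.itertuples()
        ]
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def write_gene_annotation(genes: Sequence[GeneRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Count matrix (MatrixMarket + sidecar tables)
# ---------------------------------------------------------------------------

def read_count_matrix(
    mtx: str | Path,
    peaks_bed: str | Path,
    barcodes_tsv: str | Path,
    labels_tsv: str | Path,
) -> CountMatrix:
    """Assemble a :class:`CountMatrix` from MTX triplets and sidecar tables.

    ``barcodes_tsv`` is one barcode per line (no header); ``labels_tsv`` has
    header columns barcode, label and must cover every barcode.
    """
    peaks = read_bed(peaks_bed)
    with open(barcodes_tsv) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    counts = scipy.sparse.csr_matrix(scipy.io.mmread(mtx))
    if counts.shape != (len(peaks), len(barcodes)):
        raise ValidationError(
            f"matrix dimensions {counts.shape} do not match "
            f"{len(peaks)} peaks x {len(barcodes)} barcodes"
        )
    ldf = pd.read_csv(labels_tsv, sep="\t", dtype=str)
    if not {"barcode", "label"}.issubset(ldf.columns):
        raise ParseError(f"{labels_tsv}: expected columns barcode, label")
    labels = dict(zip(ldf["barcode"], ldf["label"]))
    return CountMatrix(peaks=peaks, nuclei=barcodes, counts=counts, labels=labels)


def write_count_matrix(matrix: CountMatrix, out_dir: str | Path, prefix: str = "") -> dict[str, Path]:
    """Write the MTX + BED + barcode + label sidecar files; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": out_dir / f"{prefix}counts.mtx",
        "peaks_bed": out_dir / f"{prefix}peaks.bed",
        "barcodes_tsv": out_dir / f"{prefix}barcodes.tsv",
        "labels_tsv": out_dir / f"{prefix}labels.tsv",
    }
    scipy.io.mmwrite(paths["mtx"], scipy.sparse.coo_matrix(matrix.counts))
    write_bed(matrix.peaks, paths["peaks_bed"])
    with open(paths["barcodes_tsv"], "w") as fh:
        fh.writelines(b + "\n" for b in matrix.nuclei)
    pd.DataFrame(
        {"barcode": matrix.nuclei, "label": [matrix.labels[b] for b in matrix.nuclei]}
    ).to_csv(paths["labels_tsv"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# JASPAR-style PWM text
# ---------------------------------------------------------------------------

_JASPAR_ROW = re.compile(r"^\s*([ACGT])\s*\[?\s*([0-9.\s]+?)\s*\]?\s*$")


def read_matrix_pwm(path: str | Path):
    """Read JASPAR-style count matrices into :class:`~itb_regnet.motif_enrichment.PWM` records.

    Header lines look like ``>MA0003.1 TFAP2A`` and may carry optional
    ``family=...``/``class=...``/``tfs=a,b`` key=value annotations; the four
    following rows are A/C/G/T counts. Counts are converted to probabilities
    with a pseudocount (see :func:`~itb_regnet.motif_enrichment.counts_to_probs`).
    """
    from .motif_enrichment import PWM, counts_to_probs

    pwms = []
    header: str | None = None
    rows: dict[str, list[float]] = {}

    def flush(lineno: int) -> None:
        nonlocal header, rows
        if header is None:
            return
        if set(rows) != {"A", "C", "G", "T"}:
            raise ParseError(
                f"{path}:{lineno}: motif {header.split()[0]} has rows "
                f"{sorted(rows)}; expected A/C/G/T"
            )
        lengths = {len(v) for v in rows.values()}
        if len(lengths) != 1:
            raise ParseError(
                f"{path}:{lineno}: row-length mismatch in motif {header.split()[0]}"
            )
        tokens = header.split()
        motif_id = tokens[0]
        name = tokens[1] if len(tokens) > 1 and "=" not in tokens[1] else motif_id
        meta = dict(t.split("=", 1) for t in tokens if "=" in t)
        counts = np.array([rows[b] for b in "ACGT"])
        pwms.append(
            PWM(
                motif_id=motif_id,
                name=name,
                probs=counts_to_probs(counts),
                tf_names=meta.get("tfs", name).split(","),
                family=meta.get("family", ""),
                tf_class=meta.get("class", ""),
            )
        )
        header, rows = None, {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush(lineno)
                header = line[1:].strip()
                continue
            m = _JASPAR_ROW.match(line)
            if not m:
                raise ParseError(f"{path}:{lineno}: unparseable matrix row")
            rows[m.group(1)] = [float(x) for x in m.group(2).split()]
        flush(lineno if header else 0)
    return pwms


def write_matrix_pwm(pwms, path: str | Path, counts_scale: int = 100) -> None:
    """Write PWMs back out as JASPAR-style integer count matrices."""
    with open(path, "w") as fh:
        for pwm in pwms:
            meta = f"family={pwm.family}" if pwm.family else ""
            tfs = f"tfs={','.join(pwm.tf_names)}" if pwm.tf_names else ""
            cls = f"class={pwm.tf_class}" if pwm.tf_class else ""
            extras = " ".join(x for x in (meta, cls, tfs) if x)
            fh.write(f">{pwm.motif_id} {pwm.name} {extras}".rstrip() + "\n")
            counts = np.rint(pwm.probs * counts_scale).astype(int)
            for i, base in enumerate("ACGT"):
                fh.write(f"{base} [ " + " ".join(map(str, counts[i])) + " ]\n")


# ---------------------------------------------------------------------------
# Cross-species interval mapping
# ---------------------------------------------------------------------------

def read_interval_mapping(path: str | Path) -> IntervalMapping:
    """Read the 7-column mapping TSV (header: source_chrom .. strand)."""
    df = pd.read_csv(path, sep="\t", dtype={"source_chrom": str, "target_chrom": str})
    records = [
        MappingRecord(
            r.source_chrom,
            int(r.source_start),
            int(r.source_end),
            r.target_chrom,
            int(r.target_start),
            int(r.target_end),
            r.strand,
        )
        for r in df.itertuples()
    ]
    return IntervalMapping(records)


def write_interval_mapping(mapping: IntervalMapping, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "source_chrom": r.source_chrom,
                "source_start": r.source_start,
                "source_end": r.source_end,
                "target_chrom": r.target_chrom,
                "target_start": r.target_start,
                "target_end": r.target_end,
                "strand": r.strand,
            }
            for r in mapping.records
        ]
    ).to_csv(path, sep="\t", index=False)


def map_intervals(peaks: PeakSet, mapping: IntervalMapping) -> tuple[PeakSet, list[str]]:
    """Project peaks through the interval mapping.

    A peak maps iff it lies entirely within one source record; the output
    interval keeps the same offset within the target block (mirrored when the
    record is minus-strand). Peaks spanning record boundaries or hitting no
    record are returned in the unmapped list — that is a result, not an error.
    """
    by_chrom: dict[str, list[MappingRecord]] = {}
    for rec in mapping.records:
        by_chrom.setdefault(rec.source_chrom, []).append(rec)
    starts = {
        c: np.array([r.source_start for r in recs]) for c, recs in by_chrom.items()
    }

    mapped, unmapped = [], []
    for peak in peaks:
        recs = by_chrom.get(peak.chrom)
        if not recs:
            unmapped.append(peak.id)
            continue
        # source records are sorted and non-overlapping: only the rightmost
        # record starting at or before the peak can contain it
        idx = int(np.searchsorted(starts[peak.chrom], peak.start, side="right")) - 1
        if idx < 0:
            unmapped.append(peak.id)
            continue
        rec = recs[idx]
        if not (rec.source_start <= peak.start and peak.end <= rec.source_end):
            unmapped.append(peak.id)
            continue
        if rec.strand == "+":
            new_start = rec.target_start + (peak.start - rec.source_start)
        else:
            new_start = rec.target_start + (rec.source_end - peak.end)
        mapped.append(
            Peak(rec.target_chrom, new_start, new_start + peak.length, peak.id)
        )
    return PeakSet(mapped), unmapped


# ---------------------------------------------------------------------------
# FASTA / GMT / generic tables
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences keyed by record id, uppercased."""
    with open(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: term, description, genes... per line."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected term, description, genes")
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, genes in sets.items():
            fh.write("\t".join([term, term] + sorted(genes)) + "\n")
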