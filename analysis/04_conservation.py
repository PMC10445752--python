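"""Common and stage-specific peak sets, and cross-species conservation.

Derives the common (both-stage) invasive-population peak set with the 50%
base-pair rule, maps it to reference coordinates, calls conservation against
reference open chromatin (>= 1 bp), compares conserved proportions between
common and stage-specific sets, tests overlap with active-enhancer
(H3K27ac-like) marks, and compares per-gene peak counts across species through
one-to-one orthologs.
"""

from pathlib import Path

import pandas as pd

from itb_regnet.io_formats import (
    map_intervals,
    read_bed,
    read_gene_annotation,
    read_interval_mapping,
    write_bed,
)
from itb_regnet.peak_gene import great_nearest_gene, nearest_gene, peaks_per_gene
from itb_regnet.peak_sets import (
    chromatin_mark_overlap,
    common_peaks,
    conservation_proportion_compare,
    conserved_overlap,
    peaks_with_min_count_comparison,
)
from itb_regnet.synthetic_data import STAGES

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim_default"
RESULTS = ROOT / "results"
TARGET = "iTB"


def specific_ids(stage: str) -> list[str]:
    table = pd.read_csv(ROOT / "scratch" / f"da_{stage}_{TARGET}.tsv", sep="\t")
    return table.loc[table["specific"], "peak_id"].tolist()


def main() -> None:
    peaks = read_bed(SIM / f"{STAGES[0]}_peaks.bed")
    mapping = read_interval_mapping(SIM / "mapping.tsv")
    ref_atac = read_bed(SIM / "ref_atac.bed")
    ref_h3k = read_bed(SIM / "ref_h3k27ac.bed")

    sets = {stage: peaks.subset(specific_ids(stage)) for stage in STAGES}
    common, _ = common_peaks(sets[STAGES[0]], sets[STAGES[1]])
    stage_only = {
        stage: sets[stage].subset(
            [pid for pid in sets[stage].ids() if pid not in common]
        )
        for stage in STAGES
    }
    write_bed(common, ROOT / "scratch" / "common_peaks.bed")

    conservation = {}
    rows = []
    for name, pset in {"common": common, **{f"{s}_specific": stage_only[s] for s in STAGES}}.items():
        mapped, unmapped = map_intervals(pset, mapping)
        conserved, counts = conserved_overlap(mapped, ref_atac)
        conservation[name] = (conserved, counts)
        rows.append(
            {
                "set": name,
                "total": counts["total"] + len(unmapped),
                "mapped": counts["total"],
                "conserved": counts["conserved"],
                "conserved_fraction": round(
                    counts["conserved"] / max(counts["total"] + len(unmapped), 1), 4
                ),
            }
        )
    summary = pd.DataFrame(rows)

    common_counts = conservation["common"][1]
    gd19_counts = conservation[f"{STAGES[1]}_specific"][1]
    prop = conservation_proportion_compare(
        common_counts["conserved"], len(common),
        gd19_counts["conserved"], len(stage_only[STAGES[1]]),
    )

    mapped_common, _ = map_intervals(common, mapping)
    mark_test = chromatin_mark_overlap(
        conservation["common"][0], ref_h3k, mapped_common
    )

    genes = read_gene_annotation(SIM / "annotation.tsv", dialect="tsv")
    ref_genes = read_gene_annotation(SIM / "ref_annotation.tsv", dialect="tsv")
    orthology = pd.read_csv(SIM / "orthology.tsv", sep="\t")
    rat_counts, _ = peaks_per_gene(nearest_gene(common, genes))
    ref_counts, _ = peaks_per_gene(great_nearest_gene(ref_atac, ref_genes))
    cross = peaks_with_min_count_comparison(rat_counts, ref_counts, orthology, k=3)

    write_bed(conservation["common"][0], ROOT / "scratch" / "conserved_common.bed")
    RESULTS.mkdir(exist_ok=True)
    summary.to_csv(RESULTS / "04_conservation_summary.tsv", sep="\t", index=False)

    print(summary.to_string(index=False))
    print(f"conserved proportion, common > {STAGES[1]}-specific: p = {prop.p_value:.3g}")
    print(f"H3K27ac-mark overlap (Fisher greater): p = {mark_test.p_value:.3g}")
    print(f"cross-species peaks-per-gene (Wilcoxon, >=3 vs <3): p = {cross.p_value:.3g}")


if __name__ == "__main__":
    main()
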