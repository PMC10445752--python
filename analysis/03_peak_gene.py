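"""Associate invasive-population specific peaks with genes and test
peak-count/expression structure.

Computes nearest-gene links per stage, the distal fraction (>5 kb from the
TSS), peaks-per-gene histograms, the expression comparison between genes with
>= 3 vs < 3 peaks, the marker-overlap test, and over-representation of
multi-peak genes against the bundled gene-set collection.
"""

from pathlib import Path

import pandas as pd

from itb_regnet.io_formats import read_bed, read_gene_annotation, read_gmt
from itb_regnet.peak_gene import (
    distal_fraction,
    expression_by_peakcount,
    links_table,
    marker_overlap,
    nearest_gene,
    ora,
    peaks_per_gene,
)
from itb_regnet.synthetic_data import STAGES

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim_default"
RESULTS = ROOT / "results"
TARGET = "iTB"
MIN_PEAKS = 3


def specific_ids(stage: str) -> list[str]:
    table = pd.read_csv(ROOT / "scratch" / f"da_{stage}_{TARGET}.tsv", sep="\t")
    return table.loc[table["specific"], "peak_id"].tolist()


def main() -> None:
    genes = read_gene_annotation(SIM / "annotation.tsv", dialect="tsv")
    universe = [g.gene_id for g in genes]
    gmt = read_gmt(SIM / "gene_sets.gmt")

    rows = []
    for stage in STAGES:
        peaks = read_bed(SIM / f"{stage}_peaks.bed").subset(specific_ids(stage))
        links = nearest_gene(peaks, genes)
        links_table(links).to_csv(
            ROOT / "scratch" / f"links_{stage}_{TARGET}.tsv", sep="\t", index=False
        )
        counts, histogram = peaks_per_gene(links)
        histogram.rename("n_genes").rename_axis("peaks_per_gene").to_csv(
            RESULTS / f"03_peaks_per_gene_{stage}.tsv", sep="\t"
        )

        expression = pd.read_csv(
            SIM / f"{stage}_expression.tsv", sep="\t", index_col="gene_id"
        )[TARGET].to_dict()
        wilcoxon, groups = expression_by_peakcount(counts, expression, k=MIN_PEAKS)

        markers = set(
            pd.read_csv(SIM / f"{stage}_markers.tsv", sep="\t")["gene_id"]
        )
        multi = {g for g, c in counts.items() if c >= MIN_PEAKS}
        overlap = marker_overlap(multi, markers, universe)

        enriched = ora(multi, gmt, universe, min_rate=1.5)
        rows.append(
            {
                "stage": stage,
                "n_links": len(links),
                "distal_fraction_gt5kb": round(distal_fraction(links), 4),
                "n_genes_ge3_peaks": len(multi),
                "expr_wilcoxon_p": wilcoxon.p_value,
                "median_log10_expr_ge3": groups["median_log10_expr"][0],
                "median_log10_expr_lt3": groups["median_log10_expr"][1],
                "marker_overlap": len(multi & markers),
                "marker_overlap_p": overlap.p_value,
                "n_enriched_terms": len(enriched),
                "top_term": enriched[0].term_id if enriched else "",
            }
        )

    summary = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    summary.to_csv(RESULTS / "03_peak_gene_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
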