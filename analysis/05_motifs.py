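"""Motif enrichment in common peaks and TF-family co-occurrence statistics.

Scans the bundled PWM collection over common-peak sequences against a 50,000-
draw GC/length-matched background, keeps motifs passing the enrichment
(adjusted P <= 0.05, fold change >= 1.5) and TF-expression (>= 0.5 at both
stages) filters, groups them into families, and tests family pairs for shared
target genes and shared binding locations. Also validates the top motif's
peaks against the reference ChIP peak set.
"""

from pathlib import Path

import pandas as pd

from itb_regnet import motif_enrichment as me
from itb_regnet.io_formats import (
    map_intervals,
    read_bed,
    read_fasta,
    read_gene_annotation,
    read_interval_mapping,
    read_matrix_pwm,
)
from itb_regnet.peak_gene import nearest_gene
from itb_regnet.peak_sets import conserved_overlap, overlap_percentage
from itb_regnet.stats_core import fisher_greater
from itb_regnet.synthetic_data import STAGES

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim_default"
RESULTS = ROOT / "results"
BACKGROUND_N = 50000
SEED = 0


def main() -> None:
    peaks = read_bed(SIM / f"{STAGES[0]}_peaks.bed")
    common = read_bed(ROOT / "scratch" / "common_peaks.bed")
    sequences = read_fasta(SIM / "peaks.fasta")
    pwms = read_matrix_pwm(SIM / "motifs.jaspar")
    tf_expression = pd.read_csv(SIM / "tf_expression.tsv", sep="\t", index_col="tf")
    tf_expr = {
        tf: (row[STAGES[0]], row[STAGES[1]]) for tf, row in tf_expression.iterrows()
    }

    fg = peaks.subset(common.ids())
    fg_seqs = {pid: sequences[pid] for pid in fg.ids()}
    pool_ids = [p.id for p in peaks if p.id not in fg]
    pool = peaks.subset(pool_ids)
    pool_seqs = {pid: sequences[pid] for pid in pool_ids}

    sample = me.sample_matched_background(
        fg, fg_seqs, pool, pool_seqs, n=BACKGROUND_N, seed=SEED
    )
    fg_hits = me.scan_motifs(fg_seqs, pwms)
    pool_hits = me.scan_motifs(pool_seqs, pwms)
    bg_hits = sample.hit_table(pool_hits)
    enrichment = me.motif_enrichment_test(fg_hits, bg_hits)
    enrichment.rename_axis("motif").to_csv(
        RESULTS / "05_motif_enrichment.tsv", sep="\t"
    )

    enriched = me.enriched_motifs(enrichment)
    expressed = me.filter_expressed_tfs(
        enriched, {p.motif_id: list(p.tf_names) for p in pwms}, tf_expr
    )
    families = me.group_families(
        pwms, enrichment, fg_hits, bg_hits, tf_expr, motif_ids=expressed
    )
    print(
        f"{len(enriched)} motifs enriched; {len(expressed)} expressed; "
        f"{len(families)} TF families "
        f"(background deviation {sample.max_bin_deviation:.3f})"
    )
    fam_table = pd.DataFrame(
        {
            "family": list(families),
            "representatives": ["|".join(f.representative_motifs) for f in families.values()],
            "fg_fraction": [f.fg_fraction for f in families.values()],
            "bg_fraction": [f.bg_fraction for f in families.values()],
            "fold_change": [f.fold_change for f in families.values()],
            "adj_p": [f.adj_p for f in families.values()],
        }
    )
    fam_table.to_csv(RESULTS / "05_family_enrichment.tsv", sep="\t", index=False)

    # family co-occurrence: shared target genes and shared binding locations
    genes = read_gene_annotation(SIM / "annotation.tsv", dialect="tsv")
    links = {l.peak_id: l.gene_id for l in nearest_gene(fg, genes)}
    family_peaks = me.family_hit_peaks(families, fg_hits)
    family_genes = {
        fam: {links[p] for p in hits if p in links}
        for fam, hits in family_peaks.items()
    }
    if len(families) >= 2:
        gene_matrix, peak_matrix = me.pairwise_family_tests(
            family_genes, family_peaks, gene_universe=len(genes),
            peak_universe=len(fg),
        )
        gene_matrix.to_csv(RESULTS / "05_shared_genes_adjp.tsv", sep="\t")
        peak_matrix.to_csv(RESULTS / "05_shared_peaks_adjp.tsv", sep="\t")
        n_gene_pairs = int((gene_matrix.to_numpy() <= 0.05).sum() // 2)
        n_peak_pairs = int((peak_matrix.to_numpy() <= 0.05).sum() // 2)
        print(
            f"family pairs sharing genes: {n_gene_pairs}; "
            f"sharing binding locations: {n_peak_pairs}"
        )

    histogram = me.families_per_peak(family_peaks, fg)
    histogram.rename("n_peaks").to_csv(
        RESULTS / "05_families_per_peak.tsv", sep="\t"
    )

    # ChIP validation: the bundled reference ChIP peaks correspond to the
    # TFAP2C-like factor, so validate that motif's carrier peaks against them
    chip_motif = next(
        (p.motif_id for p in pwms if p.name == "TFAP2C" and p.motif_id in enriched),
        None,
    )
    if chip_motif is not None:
        carriers = fg.subset(fg_hits.hits.index[fg_hits.hits[chip_motif]])
        mapping = read_interval_mapping(SIM / "mapping.tsv")
        ref_chip = read_bed(SIM / "ref_chip.bed")
        mapped, unmapped = map_intervals(carriers, mapping)
        overlapping, counts = conserved_overlap(mapped, ref_chip)
        total = counts["total"] + len(unmapped)
        pct = overlap_percentage(counts["conserved"], total) if total else 0.0
        mapped_all, un_all = map_intervals(fg, mapping)
        all_hit, _ = conserved_overlap(mapped_all, ref_chip)
        carrier_set = set(carriers.ids())
        hit_set = set(all_hit.ids())
        others = set(fg.ids()) - carrier_set
        fisher = fisher_greater(
            [
                [len(carrier_set & hit_set), len(carrier_set - hit_set)],
                [len(others & hit_set), len(others - hit_set)],
            ]
        )
        print(
            f"ChIP-validated motif {chip_motif}: {counts['conserved']} of {total} carrier peaks "
            f"({pct}%) overlap reference ChIP peaks (Fisher p = {fisher.p_value:.3g})"
        )


if __name__ == "__main__":
    main()
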