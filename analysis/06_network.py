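"""Assemble the conserved TF-family -> target-gene regulatory network.

Combines conserved common peaks, family motif hits, nearest-gene links and
the conserved-marker list into the bipartite network, reports in-degree
centrality, and exports the edge list in TSV/SIF/GraphML. Compares the
recovered edges against the generator's planted ground truth.
"""

import json
from pathlib import Path

import pandas as pd

from itb_regnet import motif_enrichment as me
from itb_regnet.io_formats import read_bed, read_fasta, read_gene_annotation, read_matrix_pwm
from itb_regnet.network import build_network, export_network, in_degree
from itb_regnet.peak_gene import nearest_gene
from itb_regnet.synthetic_data import STAGES

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim_default"
RESULTS = ROOT / "results"


def main() -> None:
    peaks = read_bed(SIM / f"{STAGES[0]}_peaks.bed")
    conserved = read_bed(ROOT / "scratch" / "conserved_common.bed")
    common = read_bed(ROOT / "scratch" / "common_peaks.bed")
    sequences = read_fasta(SIM / "peaks.fasta")
    pwms = read_matrix_pwm(SIM / "motifs.jaspar")
    genes = read_gene_annotation(SIM / "annotation.tsv", dialect="tsv")
    markers = set(pd.read_csv(SIM / "conserved_markers.tsv", sep="\t")["gene_id"])
    enrichment = pd.read_csv(
        RESULTS / "05_motif_enrichment.tsv", sep="\t", index_col="motif"
    )
    families = pd.read_csv(RESULTS / "05_family_enrichment.tsv", sep="\t")

    # re-derive family hits on the conserved common peaks
    member_motifs = {
        pwm.family: [p.motif_id for p in pwms if p.family == pwm.family]
        for pwm in pwms
        if pwm.family in set(families["family"])
    }
    fg_seqs = {pid: sequences[pid] for pid in common.ids()}
    fg_hits = me.scan_motifs(fg_seqs, pwms)
    conserved_ids = set(conserved.ids())
    family_peaks = {
        fam: {
            pid
            for pid in fg_hits.hits.index[fg_hits.hits[members].any(axis=1)]
            if pid in conserved_ids
        }
        for fam, members in member_motifs.items()
    }

    conserved_source = peaks.subset(sorted(conserved_ids))
    links = nearest_gene(conserved_source, genes)
    network = build_network(conserved_source, family_peaks, links, markers)

    export_network(network, RESULTS / "06_network_edges.tsv", format="edge_tsv")
    export_network(network, ROOT / "scratch" / "network.sif", format="sif")
    export_network(network, ROOT / "scratch" / "network.graphml", format="graphml")

    degrees = in_degree(network)
    degree_table = (
        pd.Series(degrees, name="in_degree")
        .rename_axis("gene")
        .sort_values(ascending=False)
    )
    degree_table.to_csv(RESULTS / "06_in_degree.tsv", sep="\t")

    truth = json.load(open(SIM / "ground_truth.json"))["network_edges"]
    truth_edges = {(fam, g) for fam, targets in truth.items() for g in targets}
    recovered = network.edge_set()
    tp = len(recovered & truth_edges)
    print(
        f"network: {len(network.families)} families -> {len(network.genes)} genes, "
        f"{len(network)} edges"
    )
    print(
        f"vs planted truth: {tp}/{len(truth_edges)} edges recovered, "
        f"{len(recovered - truth_edges)} extra"
    )
    if len(degree_table):
        top = degree_table.head(5)
        print("highest in-degree targets:")
        print(top.to_string())


if __name__ == "__main__":
    main()
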