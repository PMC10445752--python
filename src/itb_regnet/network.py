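"""Bipartite TF-family -> target-gene network over conserved common peaks.

An edge (family, gene) exists when some conserved common peak carries the
family's motif and has the gene as its nearest gene, and the gene is on the
conserved-marker list. Edges are deduplicated; every mediating peak is kept on
the edge.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .io_formats import PeakSet, ValidationError
from .peak_gene import PeakGeneLink


class RegulatoryNetwork:
    """Directed bipartite graph: family nodes -> gene nodes, peaks on edges."""

    def __init__(self) -> None:
        self.graph = nx.DiGraph()

    def add_edge(self, family: str, gene: str, peak_id: str) -> None:
        if not self.graph.has_node(family):
            self.graph.add_node(family, kind="family")
        if not self.graph.has_node(gene):
            self.graph.add_node(gene, kind="gene")
        if self.graph.has_edge(family, gene):
            peaks = self.graph.edges[family, gene]["peaks"]
            if peak_id not in peaks:
                peaks.append(peak_id)
        else:
            self.graph.add_edge(family, gene, peaks=[peak_id])

    @property
    def families(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["kind"] == "family"
        )

    @property
    def genes(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["kind"] == "gene"
        )

    def edges(self) -> list[tuple[str, str, tuple[str, ...]]]:
        return sorted(
            (u, v, tuple(sorted(d["peaks"])))
            for u, v, d in self.graph.edges(data=True)
        )

    def edge_set(self) -> set[tuple[str, str]]:
        return {(u, v) for u, v in self.graph.edges()}

    def __len__(self) -> int:
        return self.graph.number_of_edges()


def build_network(
    conserved_common: PeakSet,
    family_hits: Mapping[str, Iterable[str]],
    links: Sequence[PeakGeneLink],
    conserved_markers: Iterable[str],
) -> RegulatoryNetwork:
    """Assemble the bipartite network from its three evidence layers.

    ``family_hits`` maps each enriched family to the peaks carrying its motif;
    ``links`` are nearest-gene links computed on the conserved common peaks;
    ``conserved_markers`` restricts targets. Families whose hits mediate no
    surviving edge are omitted from the output.
    """
    peak_ids = set(conserved_common.ids())
    for link in links:
        if link.peak_id not in peak_ids:
            raise ValidationError(
                f"link references unknown peak {link.peak_id}"
            )
    nearest = {l.peak_id: l.gene_id for l in links}
    markers = set(conserved_markers)

    net = RegulatoryNetwork()
    for family, hits in family_hits.items():
        for peak_id in sorted(set(hits) & peak_ids):
            gene = nearest.get(peak_id)
            if gene is not None and gene in markers:
                net.add_edge(family, gene, peak_id)
    return net


def in_degree(network: RegulatoryNetwork) -> dict[str, int]:
    """Number of distinct regulating families per target gene."""
    return {g: int(network.graph.in_degree(g)) for g in network.genes}


def export_network(
    network: RegulatoryNetwork, path: str | Path, format: str = "edge_tsv"
) -> Path:
    """Write the network as GraphML, SIF ("regulates" relation) or edge TSV.

    The edge TSV is lossless (mediating peak ids are comma-joined in a
    ``peaks`` column); SIF and GraphML carry the edge list only.
    """
    path = Path(path)
    if format == "edge_tsv":
        pd.DataFrame(
            [
                {"source": u, "target": v, "peaks": ",".join(p)}
                for u, v, p in network.edges()
            ],
            columns=["source", "target", "peaks"],
        ).to_csv(path, sep="\t", index=False)
    elif format == "sif":
        with open(path, "w") as fh:
            for u, v, _ in network.edges():
                fh.write(f"{u}\tregulates\t{v}\n")
    elif format == "graphml":
        g = nx.DiGraph()
        for node, data in network.graph.nodes(data=True):
            g.add_node(node, kind=data["kind"])
        for u, v, p in network.edges():
            g.add_edge(u, v, peaks=",".join(p))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def import_edge_tsv(path: str | Path) -> RegulatoryNetwork:
    """Round-trip reader for :func:`export_network`'s edge TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    net = RegulatoryNetwork()
    for row in df.itertuples():
        for peak_id in str(row.peaks).split(","):
            net.add_edge(row.source, row.target, peak_id)
    return net
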