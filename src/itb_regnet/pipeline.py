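"""Orchestration glue: run the full inference chain on a synthetic bundle.

Each step delegates to the module that owns the computation; this module only
wires outputs to inputs in the order the analysis runs them:
differential accessibility -> common peaks -> conservation -> motif
enrichment -> family grouping -> network assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import motif_enrichment as me
from .accessibility import lr_differential_test
from .io_formats import PeakSet, map_intervals
from .network import RegulatoryNetwork, build_network
from .peak_gene import PeakGeneLink, nearest_gene
from .peak_sets import common_peaks, conserved_overlap
from .synthetic_data import STAGES, SimBundle


@dataclass
class PipelineResult:
    specific: dict[str, list[str]]  # stage -> specific peak ids (target type)
    common: PeakSet
    mapped: PeakSet
    unmapped: list[str]
    conserved: PeakSet
    enrichment: pd.DataFrame
    enriched_motif_ids: list[str]
    expressed_motifs: dict[str, list[str]]
    families: dict[str, me.FamilyEnrichment]
    family_peaks: dict[str, set[str]]
    links: list[PeakGeneLink] = field(default_factory=list)
    network: RegulatoryNetwork = field(default_factory=RegulatoryNetwork)


def call_specific_peaks(bundle: SimBundle, stage: str) -> list[str]:
    """Target-population specific peaks for one stage (adj P and fold-change cuts)."""
    results = lr_differential_test(
        bundle.stages[stage].matrix, bundle.config.target_celltype
    )
    return [r.peak_id for r in results if r.specific]


def run_pipeline(
    bundle: SimBundle,
    p_cutoff: float = 5e-5,
    background_n: int = 50000,
    background_seed: int = 0,
) -> PipelineResult:
    """Run the whole chain on an in-memory bundle and return every layer."""
    specific = {stage: call_specific_peaks(bundle, stage) for stage in STAGES}

    set_a = bundle.peaks.subset(specific[STAGES[0]])
    set_b = bundle.peaks.subset(specific[STAGES[1]])
    common, _ = common_peaks(set_a, set_b)

    mapped, unmapped = map_intervals(common, bundle.mapping)
    conserved, _ = conserved_overlap(mapped, bundle.ref_atac)

    fg_seqs = {pid: bundle.sequences[pid] for pid in common.ids()}
    pool_ids = [p.id for p in bundle.peaks if p.id not in set(common.ids())]
    pool = bundle.peaks.subset(pool_ids)
    pool_seqs = {pid: bundle.sequences[pid] for pid in pool_ids}
    sample = me.sample_matched_background(
        common, fg_seqs, pool, pool_seqs, n=background_n, seed=background_seed
    )
    fg_hits = me.scan_motifs(fg_seqs, bundle.pwms, p_cutoff=p_cutoff)
    pool_hits = me.scan_motifs(pool_seqs, bundle.pwms, p_cutoff=p_cutoff)
    bg_hits = sample.hit_table(pool_hits)
    enrichment = me.motif_enrichment_test(fg_hits, bg_hits)
    enriched_ids = me.enriched_motifs(enrichment)

    tf_expr = {
        tf: (row[STAGES[0]], row[STAGES[1]])
        for tf, row in bundle.tf_expression.iterrows()
    }
    expressed = me.filter_expressed_tfs(
        enriched_ids,
        {p.motif_id: list(p.tf_names) for p in bundle.pwms},
        tf_expr,
    )
    families = me.group_families(
        bundle.pwms, enrichment, fg_hits, bg_hits, tf_expr, motif_ids=expressed
    )
    family_peaks = {
        fam: hits & set(conserved.ids())
        for fam, hits in me.family_hit_peaks(families, fg_hits).items()
    }

    conserved_source = bundle.peaks.subset(sorted(conserved.ids()))
    links = nearest_gene(conserved_source, bundle.genes)
    network = build_network(
        conserved_source, family_peaks, links, bundle.conserved_markers
    )
    return PipelineResult(
        specific=specific,
        common=common,
        mapped=mapped,
        unmapped=unmapped,
        conserved=conserved,
        enrichment=enrichment,
        enriched_motif_ids=enriched_ids,
        expressed_motifs=expressed,
        families=families,
        family_peaks=family_peaks,
        links=links,
        network=network,
    )
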