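"""End-to-end orchestration of the synthetic ASE study.

Chains the stages: simulate a phased transcriptome -> pileup counts ->
haplotype tallies -> sex-chromosome exclusion -> significance cascade ->
consequence annotation -> histone-peak overlap -> cohort validation ->
summary tables and pathway enrichment. Each stage is also usable on its own
(and from the CLI) on TSV/VCF/pileup intermediates; this module wires them
together for simulation studies where the ground truth is known.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import allele_quant, ase_stats, cohort_validation, consequence, epigenome_overlap
from . import reporting, synthetic_data
from .model import (
    ASEEvent,
    ConsequenceRecord,
    GroundTruthRecord,
    HaplotypeExpression,
    HetLocus,
    PhasedEvent,
    ValidationSummary,
)

logger = logging.getLogger(__name__)


@dataclass
class DiscoveryResult:
    """Everything the discovery arm produces, with its simulation truth."""

    config: synthetic_data.SimulationConfig
    phased_events: list[PhasedEvent]
    truth: list[GroundTruthRecord]
    expressions: list[HaplotypeExpression]
    sex_dropped: list[HaplotypeExpression]
    events: list[ASEEvent]

    @property
    def significant(self) -> list[ASEEvent]:
        return [e for e in self.events if e.significant]

    @property
    def tested(self) -> list[ASEEvent]:
        return [e for e in self.events if e.prefilter_pass]

    def recovery(self) -> tuple[int, int, float]:
        """(n_true_ase_flagged, n_true_ase, fraction) over autosomal genes."""
        truth_map = {t.gene_id: t for t in self.truth}
        tested_genes = {e.gene_id for e in self.events}
        true_ase = {
            g for g, t in truth_map.items() if t.is_ase and g in tested_genes
        }
        flagged = {e.gene_id for e in self.significant}
        hit = len(true_ase & flagged)
        return hit, len(true_ase), hit / len(true_ase) if true_ase else float("nan")

    def false_positive_rate(self) -> tuple[int, int, float]:
        """(n_null_flagged, n_null_tested, fraction) among tested events of
        genes with no simulated imbalance."""
        truth_map = {t.gene_id: t for t in self.truth}
        null_tested = [e for e in self.tested if not truth_map[e.gene_id].is_ase]
        flagged = sum(1 for e in null_tested if e.significant)
        n = len(null_tested)
        return flagged, n, flagged / n if n else 0.0

    def discovery_directions(self) -> dict[tuple[str, int], int]:
        """Per-locus imbalance sign of the significant discovery events."""
        by_gene = {e.gene_id: e for e in self.significant}
        out: dict[tuple[str, int], int] = {}
        for pe in self.phased_events:
            ev = by_gene.get(pe.gene_id)
            if ev is None:
                continue
            for locus in pe.loci:
                out[(locus.chrom, locus.pos)] = ev.direction
        return out

    def significant_loci(self) -> list[HetLocus]:
        sig_genes = {e.gene_id for e in self.significant}
        return [
            locus
            for pe in self.phased_events
            if pe.gene_id in sig_genes
            for locus in pe.loci
        ]


@dataclass
class StudyResult:
    """Discovery plus the downstream context and validation stages."""

    discovery: DiscoveryResult
    consequences: list[ConsequenceRecord]
    consequences_kept: list[ConsequenceRecord]
    consequences_dropped: list[ConsequenceRecord]
    consequence_table: pd.DataFrame
    overlaps: list
    combination_summary: epigenome_overlap.CombinationSummary
    validation_records: list
    validation_summary: ValidationSummary
    tissue_table: pd.DataFrame
    asdeg_multi: list[str]
    enrichment: list


def run_discovery(config: synthetic_data.SimulationConfig) -> DiscoveryResult:
    """Simulate one dataset and run it through the significance cascade."""
    phased, truth = synthetic_data.generate_phased_transcriptome(config)
    counts = synthetic_data.simulate_counts(phased, truth, config)
    expressions = allele_quant.tally_events(
        phased, counts, tissue=config.tissue, sample=config.sample
    )
    kept, dropped = allele_quant.drop_sex_chromosomes(expressions)
    events = ase_stats.test_events(kept)
    logger.info(
        "discovery: %d genes, %d autosomal events, %d tested, %d significant",
        len(phased), len(kept),
        sum(e.prefilter_pass for e in events),
        sum(e.significant for e in events),
    )
    return DiscoveryResult(
        config=config, phased_events=phased, truth=truth,
        expressions=kept, sex_dropped=dropped, events=events,
    )


def run_study(
    config: synthetic_data.SimulationConfig,
    peak_coverage: Mapping[str, float] | None = None,
) -> StudyResult:
    """Full synthetic study: discovery, annotation, peaks, validation, tables."""
    disc = run_discovery(config)

    # Consequence context at the significant events' loci
    models = synthetic_data.generate_transcript_models(disc.phased_events, config)
    reference = synthetic_data.SyntheticReference(disc.phased_events, config)
    sig_loci = disc.significant_loci()
    records = [
        consequence.classify_consequence(locus, models, reference)
        for locus in sig_loci
    ]
    kept, dropped = consequence.filter_nonfunctional(records)
    cons_table = consequence.summarize_consequences(kept)

    # Histone-mark overlap of the significant event regions
    if peak_coverage is None:
        peak_coverage = {"H3K27ac": 0.55, "H3K4me3": 0.43,
                         "H3K4me1": 0.39, "H3K27me3": 0.25}
    peaks = [
        synthetic_data.generate_peak_track(
            disc.phased_events, mark, config.tissue, frac, config.seed,
            sample=config.sample,
        )
        for mark, frac in peak_coverage.items()
    ]
    overlaps = epigenome_overlap.overlap_events(disc.significant, peaks)
    combo = epigenome_overlap.combination_table(overlaps)

    # Multi-sample replication of the significant loci
    if sig_loci:
        cohort_counts, _masks = synthetic_data.generate_validation_cohort(
            sig_loci, disc.truth, config
        )
        vrecords = cohort_validation.validate_loci(sig_loci, cohort_counts)
        vsummary = cohort_validation.summarize_validation(
            vrecords, disc.discovery_directions()
        )
    else:
        vrecords = []
        vsummary = cohort_validation.summarize_validation([], {})

    # Summary tables and enrichment over the tested-gene universe
    tissue_table = reporting.tissue_summary(disc.events)
    _matrix, multi = reporting.asdeg_matrix(disc.events)
    universe = {e.gene_id for e in disc.tested}
    asdeg_genes = {e.gene_id for e in disc.significant}
    pathways = synthetic_data.generate_pathway_map(
        sorted(universe), seed=config.seed
    )
    enrichment = (
        reporting.enrich(asdeg_genes, pathways, universe) if asdeg_genes else []
    )

    return StudyResult(
        discovery=disc,
        consequences=records,
        consequences_kept=kept,
        consequences_dropped=dropped,
        consequence_table=cons_table,
        overlaps=overlaps,
        combination_summary=combo,
        validation_records=vrecords,
        validation_summary=vsummary,
        tissue_table=tissue_table,
        asdeg_multi=multi,
        enrichment=enrichment,
    )
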