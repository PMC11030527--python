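"""Generator contracts: determinism, noise model, boundary behavior."""

from __future__ import annotations

import numpy as np
import pytest

from haplase import ase_stats
from haplase.errors import ConfigurationError, ConsistencyError
from haplase.synthetic_data import (
    SEX_CHROM,
    SimulationConfig,
    generate_pathway_map,
    generate_peak_track,
    generate_phased_transcriptome,
    generate_validation_cohort,
    simulate_counts,
    write_dataset,
)


def test_identical_seed_and_config_is_byte_identical(tmp_path):
    config = SimulationConfig(n_genes=30, seed=42)
    files_a = write_dataset(config, tmp_path / "a")
    files_b = write_dataset(config, tmp_path / "b")
    for name in files_a:
        assert files_a[name].read_bytes() == files_b[name].read_bytes(), name


def test_seed_changes_output(tmp_path):
    a = write_dataset(SimulationConfig(n_genes=30, seed=1), tmp_path / "a")
    b = write_dataset(SimulationConfig(n_genes=30, seed=2), tmp_path / "b")
    assert a["pileup"].read_bytes() != b["pileup"].read_bytes()


def test_transcriptome_shape_invariants():
    config = SimulationConfig(n_genes=200, seed=0, sex_chrom_fraction=0.2)
    events, truth = generate_phased_transcriptome(config)
    assert len(events) == len(truth) == 200
    assert len({t.gene_id for t in truth}) == 200  # each gene exactly once
    for event in events:
        assert len(event.hap1_string) == len(event.loci)
        positions = [l.pos for l in event.loci]
        assert positions == sorted(positions) and len(set(positions)) == len(positions)
        assert all(l.hap1_base != l.hap2_base for l in event.loci)
    assert any(e.chrom == SEX_CHROM for e in events)


def test_ase_fraction_zero_means_all_null():
    _, truth = generate_phased_transcriptome(
        SimulationConfig(n_genes=100, ase_fraction=0.0, seed=1)
    )
    assert all(not t.is_ase and t.true_fold_change == 1.0 for t in truth)


def test_fixed_seed_ase_count_matches_recorded_draw():
    """Binomial(100, 0.1) draw under seed 7, recorded from an independent run."""
    _, truth = generate_phased_transcriptome(
        SimulationConfig(n_genes=100, ase_fraction=0.1, seed=7)
    )
    assert sum(t.is_ase for t in truth) == 13


def test_invalid_config_rejected():
    with pytest.raises(ConfigurationError):
        SimulationConfig(n_genes=0).validate()
    with pytest.raises(ConfigurationError):
        SimulationConfig(loci_per_gene=0).validate()
    with pytest.raises(ConfigurationError):
        SimulationConfig(ase_fraction=1.5).validate()
    with pytest.raises(ConfigurationError):
        SimulationConfig(fold_change=-1.0).validate()


def test_counts_conserve_depth():
    """Haplotype + other tallies account for every read at every locus."""
    config = SimulationConfig(n_genes=100, seed=3, error_rate=0.05)
    events, truth = generate_phased_transcriptome(config)
    for lc in simulate_counts(events, truth, config):
        assert sum(lc.tallies.values()) == lc.depth


def test_null_allele_fraction_calibrated():
    """With FC=1 everywhere the mean allele-1 fraction sits within 3 standard
    errors of 0.5 over ~10,000 loci (CLT bound)."""
    config = SimulationConfig(
        n_genes=2500, loci_per_gene=4, ase_fraction=0.0, mean_depth=80, seed=13
    )
    events, truth = generate_phased_transcriptome(config)
    counts = simulate_counts(events, truth, config)
    hap1 = {(l.chrom, l.pos): l.hap1_base for e in events for l in e.loci}
    fracs = [
        lc.get(hap1[(lc.chrom, lc.pos)]) / lc.depth for lc in counts if lc.depth > 0
    ]
    n = len(fracs)
    assert n >= 9_000
    # per-locus fraction variance ~ 1/(4*depth); SE of the mean is bounded by
    # the empirical SD
    se = np.std(fracs, ddof=1) / np.sqrt(n)
    assert abs(np.mean(fracs) - 0.5) < 3 * se + 1e-9


def test_expected_favored_fraction_under_imbalance():
    """FC=4 puts the favored-haplotype read fraction near 4/5 = 0.8."""
    config = SimulationConfig(
        n_genes=400, loci_per_gene=5, ase_fraction=1.0, fold_change=4.0,
        mean_depth=100, seed=17,
    )
    events, truth = generate_phased_transcriptome(config)
    counts = simulate_counts(events, truth, config)
    favored = {}
    for event, t in zip(events, truth):
        for l in event.loci:
            favored[(l.chrom, l.pos)] = (
                l.hap1_base if t.favored_haplotype == 1 else l.hap2_base
            )
    fracs = [
        lc.get(favored[(lc.chrom, lc.pos)]) / lc.depth for lc in counts if lc.depth > 0
    ]
    assert np.mean(fracs) == pytest.approx(0.8, abs=0.01)


def test_zero_depth_removes_everything_downstream():
    config = SimulationConfig(n_genes=20, mean_depth=0.0, seed=1)
    events, truth = generate_phased_transcriptome(config)
    counts = simulate_counts(events, truth, config)
    assert all(lc.depth == 0 for lc in counts)
    from haplase import allele_quant

    tallied = allele_quant.tally_events(events, counts)
    assert not any(
        ase_stats.prefilter(e.allele1_exp, e.allele2_exp) for e in tallied
    )


def test_counts_require_truth_coverage():
    config = SimulationConfig(n_genes=5, seed=1)
    events, truth = generate_phased_transcriptome(config)
    with pytest.raises(ConsistencyError):
        simulate_counts(events, truth[:-1], config)


# ------------------------------------------------------------- peaks -------

def test_peak_track_coverage_extremes():
    config = SimulationConfig(n_genes=50, seed=2)
    events, _ = generate_phased_transcriptome(config)
    empty = generate_peak_track(events, "H3K27ac", "liver", 0.0, seed=2)
    assert empty.intervals == []
    full = generate_peak_track(events, "H3K27ac", "liver", 1.0, seed=2)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in full.intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    for event in events:
        chrom, first, last = event.region
        assert any(
            s < last and e > first - 1 for s, e in by_chrom.get(chrom, [])
        ), event.gene_id


def test_peak_track_sorted_non_overlapping():
    config = SimulationConfig(n_genes=200, seed=4)
    events, _ = generate_phased_transcriptome(config)
    track = generate_peak_track(events, "H3K4me1", "liver", 0.7, seed=4)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in track.intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    for ivs in by_chrom.values():
        assert ivs == sorted(ivs)
        assert all(a[1] < b[0] for a, b in zip(ivs, ivs[1:]))  # disjoint


# ------------------------------------------------------------- cohort ------

def test_cohort_het_rate_extremes():
    config = SimulationConfig(n_genes=10, loci_per_gene=2, n_samples=5, seed=1)
    events, truth = generate_phased_transcriptome(config)
    loci = [l for e in events for l in e.loci]

    all_in, _ = generate_validation_cohort(
        loci, truth, SimulationConfig(n_genes=10, loci_per_gene=2, n_samples=5,
                                      het_rate=1.0, seed=1)
    )
    assert all(len(v) == len(loci) for v in all_in.values())

    none_in, _ = generate_validation_cohort(
        loci, truth, SimulationConfig(n_genes=10, loci_per_gene=2, n_samples=5,
                                      het_rate=0.0, seed=1)
    )
    assert all(len(v) == 0 for v in none_in.values())


def test_cohort_fixed_seed_comparison_count():
    """60 loci x 66 samples at het_rate 0.8 under seed 7: 3,133 count records
    (recorded from an independent run)."""
    config = SimulationConfig(n_genes=20, loci_per_gene=3, n_samples=66,
                              het_rate=0.8, seed=7)
    events, truth = generate_phased_transcriptome(config)
    loci = [l for e in events for l in e.loci]
    assert len(loci) == 60
    counts, masks = generate_validation_cohort(loci, truth, config)
    assert len(counts) == 66
    assert sum(len(v) for v in counts.values()) == 3133
    for sample, recs in counts.items():
        assert {(r.chrom, r.pos) for r in recs} == masks[sample]


def test_cohort_requires_loci_and_samples():
    config = SimulationConfig(n_genes=5, seed=1)
    events, truth = generate_phased_transcriptome(config)
    loci = [l for e in events for l in e.loci]
    with pytest.raises(ConfigurationError):
        generate_validation_cohort([], truth, config)
    with pytest.raises(ConfigurationError):
        generate_validation_cohort(
            loci, truth, SimulationConfig(n_genes=5, n_samples=0, seed=1)
        )


def test_pathway_map_is_deterministic():
    genes = [f"G{i:05d}" for i in range(200)]
    assert generate_pathway_map(genes, seed=3) == generate_pathway_map(genes, seed=3)
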