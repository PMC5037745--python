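"""Planted-truth generator: determinism, self-consistency, shape contracts."""

import numpy as np
import pytest

from episcreen.expression import correlate
from episcreen.sequence_features import find_cpg_islands, scan_stat3_sites
from episcreen.synthetic import (
    CohortSimSpec,
    GenomeSimSpec,
    PlantedTruth,
    SimulationError,
    generate_clinical,
    generate_expression,
    generate_genome,
    generate_methylation_levels,
    generate_pyrograms,
)

SMALL = dict(n_genes=10, n_target_genes=3, chrom_length=200_000)


# -- genome -----------------------------------------------------------------

def test_fixed_seed_reproduces_genome_byte_identically():
    a = generate_genome(GenomeSimSpec(**SMALL, seed=9))
    b = generate_genome(GenomeSimSpec(**SMALL, seed=9))
    assert a[0] == b[0]
    assert a[1] == b[1]
    assert a[2].island_intervals == b[2].island_intervals
    c = generate_genome(GenomeSimSpec(**SMALL, seed=10))
    assert c[0] != a[0]


def test_zero_genes_gives_background_only():
    seqs, genes, truth = generate_genome(
        GenomeSimSpec(n_genes=0, n_target_genes=0, chrom_length=50_000)
    )
    assert genes == []
    assert truth.target_gene_ids == []
    assert len(seqs["chr1"]) == 50_000


def test_saturated_targets_cover_every_gene():
    seqs, genes, truth = generate_genome(
        GenomeSimSpec(n_genes=5, n_target_genes=5, chrom_length=120_000, seed=2)
    )
    assert set(truth.target_gene_ids) == {g.gene_id for g in genes}
    assert set(truth.island_intervals) == set(truth.target_gene_ids)
    assert all(truth.motif_positions[g] for g in truth.target_gene_ids)


def test_chromosome_too_small_raises_sizing_error():
    with pytest.raises(SimulationError, match="too small"):
        generate_genome(GenomeSimSpec(n_genes=50, n_target_genes=5, chrom_length=100_000))


def test_recorded_motifs_are_recoverable_by_rescanning(small_genome):
    """Planted truth is self-consistent with the emitted sequence."""
    _, sequences, _, truth = small_genome
    seq = sequences["chr1"]
    scanned = {(h.start, h.end) for h in scan_stat3_sites(seq)}
    for gid, positions in truth.motif_positions.items():
        for s, e in positions:
            assert (s, e) in scanned


def test_planted_islands_detected_at_planted_positions(small_genome):
    _, sequences, _, truth = small_genome
    detected = find_cpg_islands(sequences["chr1"])
    for gid, (s, e) in truth.island_intervals.items():
        overlapping = [i for i in detected if i.start < e and i.end > s]
        assert overlapping, f"planted island of {gid} not detected"


def test_invalid_genome_specs_rejected():
    with pytest.raises(SimulationError):
        GenomeSimSpec(n_genes=5, n_target_genes=6)
    with pytest.raises(SimulationError):
        GenomeSimSpec(background_gc=0.6, island_gc=0.5)


# -- expression -------------------------------------------------------------

def minimal_truth():
    return PlantedTruth(target_gene_ids=["TGT"], regulator_gene_id="REG")


# background genes keep library sizes stable: RPKM is compositional, and
# a matrix dominated by the regulator's own counts distorts pairwise
# correlations; at genome scale (~200 genes) the effect is negligible
GENE_IDS = ["REG", "TGT"] + [f"BG{i:03d}" for i in range(200)]


def test_expression_shape_contract():
    m = generate_expression(CohortSimSpec(n_pairs=3, seed=1), minimal_truth(), ["REG", "TGT", "X"])
    assert len(m.sample_ids) == 6
    assert len(m.pairing) == 3
    for p, (t, n) in m.pairing.items():
        assert t == f"{p}_T" and n == f"{p}_N"
    assert (m.counts.values >= 0).all()
    assert m.counts.values.dtype.kind == "i"


def test_null_configuration_centers_correlation_at_zero():
    """rho=0, log2FC=0: sample correlations scatter around 0 over seeds."""
    rs = []
    for seed in range(40):
        spec = CohortSimSpec(
            n_pairs=12, regulator_target_corr=0.0,
            tumor_downregulation_log2fc=0.0, seed=seed,
        )
        m = generate_expression(spec, minimal_truth(), GENE_IDS)
        rs.append(correlate(m.log_rpkm("REG"), m.log_rpkm("TGT")).r)
    rs = np.array(rs)
    assert abs(rs.mean()) < 3 / np.sqrt(len(rs) * 24)  # ~3 SE of the mean r


def test_planted_correlation_within_fisher_interval_most_of_the_time():
    """Empirical r covers the planted rho at close-to-nominal CI rate."""
    rho = -0.6
    hw = 1.96 / np.sqrt(46 - 3)
    covered = 0
    reps = 100
    for seed in range(reps):
        m = generate_expression(CohortSimSpec(seed=seed), minimal_truth(), GENE_IDS)
        r = correlate(m.log_rpkm("REG"), m.log_rpkm("TGT")).r
        z = np.arctanh(r)
        covered += np.tanh(z - hw) <= rho <= np.tanh(z + hw)
    assert covered / reps >= 0.8


def test_regulator_runs_high_in_tumors():
    m = generate_expression(CohortSimSpec(seed=4), minimal_truth(), GENE_IDS)
    vals = m.log_rpkm("REG")
    assert vals[m.tumor_columns()].mean() > vals[m.normal_columns()].mean()


def test_extreme_correlation_rejected():
    with pytest.raises(SimulationError):
        CohortSimSpec(regulator_target_corr=-1.0)


# -- pyrograms --------------------------------------------------------------

def test_pyrogram_count_and_structure():
    pyros = generate_pyrograms([0.3, 0.7], n_cpgs=4, noise_sd=0.0, seed=0)
    assert len(pyros) == 2
    for p in pyros:
        table = p.cpg_intensities()
        assert sorted(table) == [0, 1, 2, 3]


def test_negative_noise_rejected():
    with pytest.raises(SimulationError):
        generate_pyrograms([0.5], noise_sd=-0.1)


def test_out_of_range_fraction_rejected():
    with pytest.raises(SimulationError):
        generate_pyrograms([1.5], noise_sd=0.0)


# -- methylation levels -----------------------------------------------------

def test_planted_mixture_has_exact_high_count():
    levels = generate_methylation_levels(60, seed=11)
    assert np.sum(levels > 35.0) == 39  # 65% of 60


def test_custom_high_count():
    levels = generate_methylation_levels(20, n_high=5, seed=2)
    assert np.sum(levels > 35.0) == 5


# -- clinical ---------------------------------------------------------------

def test_clinical_shape_contract():
    spec = CohortSimSpec(n_patients=60, seed=3)
    levels = generate_methylation_levels(60, seed=3)
    df = generate_clinical(spec, levels)
    assert len(df) == 60
    assert set(df["event"].unique()) <= {0, 1}
    assert (df["os_months"] >= 0).all()
    assert df["stage"].isin(["I", "II", "III", "IV"]).all()


def test_clinical_determinism_and_truth_recording():
    spec = CohortSimSpec(n_patients=30, seed=5)
    levels = generate_methylation_levels(30, seed=5)
    truth = PlantedTruth()
    a = generate_clinical(spec, levels, truth=truth)
    b = generate_clinical(spec, levels)
    assert a.equals(b)
    assert len(truth.per_patient_true_meth) == 30
    assert truth.true_group_hazards["high"] == pytest.approx(
        truth.true_group_hazards["low"] * spec.hazard_ratio_high_meth
    )


def test_wrong_level_count_rejected():
    with pytest.raises(SimulationError):
        generate_clinical(CohortSimSpec(n_patients=10), np.zeros(5))


def test_censor_rate_zero_observes_every_event():
    spec = CohortSimSpec(n_patients=40, censor_rate=0.0, seed=6)
    df = generate_clinical(spec, generate_methylation_levels(40, seed=6))
    assert df["event"].all()


def test_high_methylation_group_dies_faster_on_average():
    spec = CohortSimSpec(n_patients=200, hazard_ratio_high_meth=3.0, censor_rate=0.0, seed=8)
    df = generate_clinical(spec, generate_methylation_levels(200, seed=8))
    assert (
        df.loc[df.meth_group == "high", "os_months"].mean()
        < df.loc[df.meth_group == "low", "os_months"].mean()
    )
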