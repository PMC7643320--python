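"""Synthetic-data generator: determinism, moments, planted effects."""

import numpy as np
import pytest
from scipy import stats

from epidmr import (
    SimulationConfig,
    plant_epimutations,
    simulate_dataset,
    simulate_genome,
    simulate_window_counts,
)
from epidmr.errors import ConfigurationError


def test_genome_tiling_arithmetic():
    cfg = SimulationConfig(
        n_chromosomes=1, windows_per_chromosome=10, window_size=1000,
        n_dmrs=0,
    )
    genome = simulate_genome(cfg)
    assert genome.chrom_lengths == {"chr1": 10_000}
    assert genome.n_windows == 10
    assert (genome.windows["end"] - genome.windows["start"]).sum() == 10_000


def test_cpg_rate_controls_mean_density():
    cfg = SimulationConfig(
        n_chromosomes=1, windows_per_chromosome=5000, cpg_rate=2.0, n_dmrs=0,
        seed=5,
    )
    genome = simulate_genome(cfg)
    # expected ~20 CpG per 1 kb window; MC s.e. ~ sqrt(20/5000) ~ 0.06
    assert genome.cpg_counts.mean() == pytest.approx(20.0, abs=0.3)
    assert (genome.cpg_counts <= cfg.window_size // 2).all()


def test_seeded_determinism_is_bit_identical():
    cfg = SimulationConfig(
        n_chromosomes=2, windows_per_chromosome=300, n_dmrs=4, seed=42
    )
    g1, t1, m1 = simulate_dataset(cfg)
    g2, t2, m2 = simulate_dataset(cfg)
    assert (g1.cpg_counts == g2.cpg_counts).all()
    assert t1.regions.equals(t2.regions)
    assert (m1.counts == m2.counts).all()


def test_sequence_consistent_with_cpg_counts():
    cfg = SimulationConfig(
        n_chromosomes=1, windows_per_chromosome=50, n_dmrs=0, seed=9
    )
    genome = simulate_genome(cfg, store_sequence=True)
    seq = genome.sequences["chr1"]
    for i, (_, w) in enumerate(genome.windows.iterrows()):
        assert seq[w["start"]: w["end"]].count("CG") == genome.cpg_counts[i]


def test_plant_none_gives_empty_truth():
    cfg = SimulationConfig(
        n_chromosomes=1, windows_per_chromosome=100, n_dmrs=0
    )
    genome = simulate_genome(cfg)
    truth = plant_epimutations(genome, cfg)
    assert len(truth.regions) == 0
    assert not truth.window_mask.any()


def test_planted_regions_disjoint_grid_aligned():
    cfg = SimulationConfig(
        n_chromosomes=1, windows_per_chromosome=200, n_dmrs=5, dmr_span=3,
        seed=1,
    )
    genome = simulate_genome(cfg)
    truth = plant_epimutations(genome, cfg)
    regs = truth.regions
    assert len(regs) == 5
    assert ((regs["end"] - regs["start"]) == 3000).all()
    assert regs["start"].mod(1000).eq(0).all()
    srt = regs.sort_values(["chrom", "start"])
    assert (srt["start"].to_numpy()[1:] >= srt["end"].to_numpy()[:-1]).all()
    # ~50/50 direction split
    assert set(regs["direction"]) <= {"hyper", "hypo"}
    assert abs((regs["direction"] == "hyper").sum() - 2.5) <= 0.5


def test_different_seeds_move_placements_not_counts():
    base = dict(n_chromosomes=1, windows_per_chromosome=500, n_dmrs=6,
                dmr_span=2)
    g1 = simulate_genome(SimulationConfig(**base, seed=1))
    g2 = simulate_genome(SimulationConfig(**base, seed=2))
    t1 = plant_epimutations(g1, SimulationConfig(**base, seed=1))
    t2 = plant_epimutations(g2, SimulationConfig(**base, seed=2))
    assert len(t1.regions) == len(t2.regions) == 6
    assert ((t1.regions["end"] - t1.regions["start"])
            == (t2.regions["end"] - t2.regions["start"])).all()
    assert not t1.regions["start"].equals(t2.regions["start"])


def test_insufficient_space_raises():
    cfg = SimulationConfig(
        n_chromosomes=1, windows_per_chromosome=10, n_dmrs=5, dmr_span=4
    )
    genome = simulate_genome(cfg)
    with pytest.raises(ConfigurationError):
        plant_epimutations(genome, cfg)


def test_invalid_config_rejected():
    with pytest.raises(ConfigurationError):
        SimulationConfig(n_chromosomes=0)
    with pytest.raises(ConfigurationError):
        SimulationConfig(dispersion=-0.1)


def test_null_groups_share_distribution():
    """With no planted effect, group means are statistically indistinguishable."""
    pvals = []
    for seed in range(5):
        cfg = SimulationConfig(
            n_chromosomes=1, windows_per_chromosome=2000, n_dmrs=0,
            effect_log2=0.0, seed=100 + seed,
        )
        genome, truth, m = simulate_dataset(cfg)
        a = m.counts[:, m.group_indices("disease")].mean(axis=0)
        b = m.counts[:, m.group_indices("no_disease")].mean(axis=0)
        pvals.append(stats.ttest_ind(a, b).pvalue)
    assert sum(p > 0.01 for p in pvals) >= 4


def test_poisson_limit_variance_equals_mean():
    cfg = SimulationConfig(
        n_chromosomes=1, windows_per_chromosome=10_000, dispersion=0.0,
        libsize_factor_sd=0.0, n_dmrs=0, baseline_mean=50.0, seed=12,
    )
    _, _, m = simulate_dataset(cfg)
    mean = m.counts.mean()
    var = m.counts.var()
    assert mean == pytest.approx(50.0, rel=0.02)
    assert var / mean == pytest.approx(1.0, rel=0.05)


def test_nb_moments_recovered():
    """Empirical mean/variance of unplanted windows match NB(mu, phi)."""
    mu, phi = 50.0, 0.2
    cfg = SimulationConfig(
        n_chromosomes=1, windows_per_chromosome=10_000, dispersion=phi,
        baseline_mean=mu, libsize_factor_sd=0.0, n_dmrs=0, seed=21,
    )
    _, _, m = simulate_dataset(cfg)
    x = m.counts.ravel().astype(float)
    n = x.size
    true_var = mu + phi * mu * mu
    se_mean = np.sqrt(true_var / n)
    assert abs(x.mean() - mu) < 3 * se_mean
    # variance of the sample variance for NB via 4th central moment
    m4 = ((x - x.mean()) ** 4).mean()
    se_var = np.sqrt((m4 - true_var**2) / n)
    assert abs(x.var(ddof=1) - true_var) < 3 * se_var


def test_planted_effect_recovered():
    cfg = SimulationConfig(seed=33)  # defaults: effect_log2 = 2, 20 x 3 windows
    genome, truth, m = simulate_dataset(cfg)
    dis = m.counts[:, m.group_indices("disease")].mean(axis=1)
    ctl = m.counts[:, m.group_indices("no_disease")].mean(axis=1)
    ratio = np.log2(dis[truth.window_mask] / ctl[truth.window_mask])
    signed = ratio * truth.window_sign[truth.window_mask]
    assert signed.mean() == pytest.approx(cfg.effect_log2, abs=0.1)
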