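"""NB exact test against brute-force enumeration, dispersion recovery, BH."""

import numpy as np
import pytest
from scipy import stats

from epidmr import (
    SimulationConfig,
    bh_adjust,
    estimate_common_dispersion,
    nb_exact_test,
    simulate_dataset,
    test_all_windows,
)
from epidmr.counts import WindowCountMatrix, tile_genome
from epidmr.diffmeth import _batch_exact_pvalues, _conditional_pvalue
from epidmr.errors import InputError, InsufficientDataError


def oracle_conditional_p(s_a, s_b, n_a, n_b, phi):
    """Independent enumeration of the conditional split distribution using
    scipy's pmf implementations."""
    total = s_a + s_b
    if total == 0:
        return 1.0
    mu = total / (n_a + n_b)
    s = np.arange(total + 1)
    if phi == 0:
        pa = stats.poisson.pmf(s, n_a * mu)
        pb = stats.poisson.pmf(total - s, n_b * mu)
    else:
        r_a, r_b = n_a / phi, n_b / phi
        pa = stats.nbinom.pmf(s, r_a, r_a / (r_a + n_a * mu))
        pb = stats.nbinom.pmf(total - s, r_b, r_b / (r_b + n_b * mu))
    probs = pa * pb
    probs = probs / probs.sum()
    include = probs <= probs[s_a] * (1 + 1e-10)
    return 1.0 if include.all() else min(float(probs[include].sum()), 1.0)


def group_counts(total, n):
    """Spread an integer group sum over n samples (sums drive the test)."""
    base = [total // n] * n
    base[0] += total - sum(base)
    return base


@pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
@pytest.mark.parametrize("n_a,n_b", [(1, 1), (2, 3), (8, 8)])
def test_exact_test_matches_enumeration_oracle(phi, n_a, n_b):
    """All instances with total <= 30 agree with the oracle to 1e-12."""
    for total in range(0, 31, 3):
        for s_a in range(total + 1):
            p, _ = nb_exact_test(
                group_counts(s_a, n_a), group_counts(total - s_a, n_b),
                phi=phi,
            )
            expected = oracle_conditional_p(s_a, total - s_a, n_a, n_b, phi)
            assert p == pytest.approx(expected, abs=1e-12)


def test_poisson_limit_closed_form():
    """phi=0, 10 vs 0 with equal sizes: conditional law Binomial(10, 1/2)."""
    p, lfc = nb_exact_test([10], [0], phi=0.0)
    assert p == pytest.approx(2 / 1024, abs=1e-15)
    assert lfc == pytest.approx(np.log2(10.5 / 0.5))


def test_identical_groups_modal():
    p, lfc = nb_exact_test([7, 3], [3, 7], phi=0.2)
    assert p == 1.0
    assert lfc == 0.0


def test_group_swap_symmetry():
    rng = np.random.default_rng(4)
    for _ in range(25):
        a = rng.poisson(20, 4)
        b = rng.poisson(35, 4)
        p_ab, f_ab = nb_exact_test(a, b, phi=0.15)
        p_ba, f_ba = nb_exact_test(b, a, phi=0.15)
        assert p_ab == pytest.approx(p_ba, rel=1e-12)
        assert f_ab == pytest.approx(-f_ba, rel=1e-12)


def test_library_size_equalization_shifts_sums():
    # double library size with double counts is a null observation
    p, lfc = nb_exact_test(
        [40], [20], lib_sizes_a=[2_000_000], lib_sizes_b=[1_000_000], phi=0.0
    )
    assert lfc == 0.0
    assert p == 1.0


def test_batch_matches_scalar_path():
    rng = np.random.default_rng(5)
    s_a = rng.integers(0, 400, 50)
    s_b = rng.integers(0, 400, 50)
    for phi in (0.0, 0.1):
        batch = _batch_exact_pvalues(s_a, s_b, 8, 8, phi)
        scalar = [
            _conditional_pvalue(int(x), int(y), 8, 8, phi)
            for x, y in zip(s_a, s_b)
        ]
        assert batch == pytest.approx(scalar, rel=1e-9)


def test_exact_test_input_validation():
    with pytest.raises(InputError):
        nb_exact_test([], [1], phi=0.0)
    with pytest.raises(InputError):
        nb_exact_test([-1], [1], phi=0.0)
    with pytest.raises(InputError):
        nb_exact_test([1], [1], phi=-0.5)


def _sim_matrix(phi, seed, n_windows=10_000, n=10, mu=50.0):
    cfg = SimulationConfig(
        n_chromosomes=1,
        windows_per_chromosome=n_windows,
        n_disease=n,
        n_control=n,
        baseline_mean=mu,
        dispersion=phi,
        libsize_factor_sd=0.1,
        n_dmrs=0,
        seed=seed,
    )
    return simulate_dataset(cfg)[2]


def test_dispersion_poisson_data_near_zero():
    m = _sim_matrix(phi=0.0, seed=6)
    est = estimate_common_dispersion(m)
    assert est.common_dispersion <= 0.01
    assert est.n_windows_used == 10_000


def test_dispersion_recovers_true_value():
    m = _sim_matrix(phi=0.2, seed=7)
    est = estimate_common_dispersion(m)
    assert 0.15 <= est.common_dispersion <= 0.25


def test_dispersion_constant_counts_zero():
    windows = tile_genome({"chr1": 60_000}, 1000)
    m = WindowCountMatrix(
        windows=windows,
        counts=np.full((60, 6), 5),
        samples=[f"s{i}" for i in range(6)],
        groups=["disease"] * 3 + ["no_disease"] * 3,
    )
    assert estimate_common_dispersion(m).common_dispersion == 0.0


def test_dispersion_needs_replication():
    windows = tile_genome({"chr1": 60_000}, 1000)
    m = WindowCountMatrix(
        windows=windows,
        counts=np.full((60, 2), 5),
        samples=["a", "b"],
        groups=["disease", "no_disease"],
    )
    with pytest.raises(InsufficientDataError):
        estimate_common_dispersion(m)


def test_all_windows_coverage_floor_and_determinism():
    windows = tile_genome({"chr1": 60_000}, 1000)
    m = WindowCountMatrix(
        windows=windows,
        counts=np.zeros((60, 6), dtype=int),
        samples=[f"s{i}" for i in range(6)],
        groups=["disease"] * 3 + ["no_disease"] * 3,
    )
    res = test_all_windows(m, phi=0.1)
    assert not res["tested"].any()
    assert (res["p_value"] == 1.0).all()

    m2 = _sim_matrix(phi=0.1, seed=8, n_windows=500, n=4)
    r1 = test_all_windows(m2, phi=0.1)
    r2 = test_all_windows(m2, phi=0.1)
    assert r1.equals(r2)


def test_planted_windows_rank_low(small_dataset):
    genome, truth, matrix = small_dataset
    res = test_all_windows(matrix)
    planted = res["p_value"].to_numpy()[truth.window_mask]
    background = res["p_value"].to_numpy()[~truth.window_mask]
    assert np.median(planted) < np.median(background)


def bh_reference(p):
    """Quadratic-time BH: q_i = min over j with p_j >= p_i of m*p_j/rank_j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = np.empty(m)
    for i in range(m):
        q[i] = min(
            min(m * ranked[j] / (j + 1) for j in range(i, m)), 1.0
        )
    out = np.empty(m)
    out[order] = q
    return out


def test_bh_hand_example_and_edge_cases():
    assert bh_adjust([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])
    assert bh_adjust([0.2]) == pytest.approx([0.2])
    assert bh_adjust([0.3, 0.3, 0.3]) == pytest.approx([0.3, 0.3, 0.3])


def test_bh_matches_quadratic_reference():
    rng = np.random.default_rng(9)
    for _ in range(50):
        p = rng.uniform(0, 1, rng.integers(1, 40))
        assert bh_adjust(p) == pytest.approx(bh_reference(p), rel=1e-12)


def test_bh_dominates_raw_p_and_validates():
    rng = np.random.default_rng(10)
    p = rng.uniform(0, 1, 100)
    q = bh_adjust(p)
    assert (q >= p - 1e-15).all()
    with pytest.raises(InputError):
        bh_adjust([0.5, 1.5])
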