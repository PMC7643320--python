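"""Per-window two-group differential methylation testing.

The statistic is a common-dispersion negative binomial exact test on
library-size-equalized counts, the window-level analogue of the classic exact
test for overdispersed count data. Counts are rescaled to a common library
size (geometric mean of the effective sizes) and rounded; within-group sums
``S_A`` and ``S_B`` are formed, each distributed (under a common-mean null) as
NB with mean ``n_g · μ̂`` and dispersion ``φ / n_g``; conditioning on
``S = S_A + S_B`` gives a discrete law over the possible splits, and the
two-sided p-value sums the probabilities of every split no more probable than
the observed one (minimum-likelihood rule). ``φ = 0`` is the Poisson limit,
where the conditional law is Binomial(S, n_A / (n_A + n_B)).

The common dispersion is estimated by the method of moments on
library-size-adjusted counts, pooled within groups and averaged over windows
with mean-proportional weights. Multiple testing uses Benjamini–Hochberg over
the tested windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .counts import WindowCountMatrix, equalized_counts
from .errors import InputError, InsufficientDataError

#: Relative tolerance when deciding whether a split is "no more probable than"
#: the observed one; absorbs float noise in exactly tied probabilities.
TIE_REL_TOL = 1e-10


@dataclass(frozen=True)
class DispersionEstimate:
    common_dispersion: float
    n_windows_used: int
    method: str = "moments-pooled"


def _nb_logpmf(x: np.ndarray, mean: np.ndarray, phi: float) -> np.ndarray:
    """log pmf of NB with variance mean + phi·mean² (Poisson when phi = 0)."""
    x = np.asarray(x, dtype=float)
    mean = np.asarray(mean, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if phi == 0.0:
            ll = x * np.log(mean) - mean - gammaln(x + 1.0)
            ll = np.where((mean == 0) & (x == 0), 0.0, ll)
            ll = np.where((mean == 0) & (x > 0), -np.inf, ll)
        else:
            r = 1.0 / phi
            ll = (
                gammaln(x + r)
                - gammaln(r)
                - gammaln(x + 1.0)
                + r * np.log(r / (r + mean))
                + x * np.log(mean / (r + mean))
            )
            ll = np.where((mean == 0) & (x == 0), 0.0, ll)
            ll = np.where((mean == 0) & (x > 0), -np.inf, ll)
    return ll


def _conditional_pvalue(
    s_a: int, s_b: int, n_a: int, n_b: int, phi: float
) -> float:
    """Exact two-sided p-value for the split (s_a, s_b) given the total."""
    total = s_a + s_b
    if total == 0:
        return 1.0
    mu = total / (n_a + n_b)
    s = np.arange(total + 1)
    ll = _nb_logpmf(s, n_a * mu, phi / n_a) + _nb_logpmf(
        total - s, n_b * mu, phi / n_b
    )
    ll -= logsumexp(ll)
    probs = np.exp(ll)
    p_obs = probs[s_a]
    include = probs <= p_obs * (1.0 + TIE_REL_TOL)
    if include.all():
        return 1.0
    return min(float(probs[include].sum()), 1.0)


def nb_exact_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    lib_sizes_a: np.ndarray | None = None,
    lib_sizes_b: np.ndarray | None = None,
    phi: float = 0.0,
) -> tuple[float, float]:
    """Exact NB test for one window; returns ``(p_value, log2_fold_change)``.

    ``counts_a``/``counts_b`` are per-sample raw counts for the two groups;
    ``lib_sizes_a``/``lib_sizes_b`` their effective library sizes (omitted =
    already comparable). The log2 fold change is group A over group B on the
    equalized per-sample means with a 0.5 pseudo-count.
    """
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    if counts_a.size == 0 or counts_b.size == 0:
        raise InputError("both groups must be non-empty")
    if (counts_a < 0).any() or (counts_b < 0).any():
        raise InputError("counts must be non-negative")
    if phi < 0:
        raise InputError(f"dispersion must be >= 0, got {phi}")

    n_a, n_b = counts_a.size, counts_b.size
    if lib_sizes_a is None and lib_sizes_b is None:
        sa = counts_a
        sb = counts_b
    else:
        libs = np.concatenate(
            [np.asarray(lib_sizes_a, float), np.asarray(lib_sizes_b, float)]
        )
        if (libs <= 0).any():
            raise InputError("library sizes must be positive")
        common = np.exp(np.mean(np.log(libs)))
        scale = common / libs
        sa = counts_a * scale[:n_a]
        sb = counts_b * scale[n_a:]
    s_a = int(np.rint(sa).sum())
    s_b = int(np.rint(sb).sum())

    p = _conditional_pvalue(s_a, s_b, n_a, n_b, phi)
    log2fc = float(np.log2((s_a / n_a + 0.5) / (s_b / n_b + 0.5)))
    return p, log2fc


def _batch_exact_pvalues(
    s_a: np.ndarray,
    s_b: np.ndarray,
    n_a: int,
    n_b: int,
    phi: float,
    chunk_size: int = 2048,
) -> np.ndarray:
    """Vectorized :func:`_conditional_pvalue` over many windows."""
    s_a = np.asarray(s_a, dtype=np.int64)
    s_b = np.asarray(s_b, dtype=np.int64)
    total = s_a + s_b
    pvals = np.ones(len(s_a))
    nonzero = np.where(total > 0)[0]
    for lo in range(0, len(nonzero), chunk_size):
        idx = nonzero[lo : lo + chunk_size]
        t = total[idx]
        max_t = int(t.max())
        grid = np.arange(max_t + 1)
        x_b = t[:, None] - grid[None, :]
        valid = x_b >= 0
        x_b = np.maximum(x_b, 0)
        mu = t / (n_a + n_b)
        mean_a = n_a * mu
        mean_b = n_b * mu

        # Counts are integers, so gammaln only ever sees grid + const:
        # precompute 1-D tables and index, instead of 2-D gammaln calls.
        with np.errstate(divide="ignore"):
            if phi == 0.0:
                gfact = gammaln(grid + 1.0)
                ll = (
                    grid[None, :] * np.log(mean_a)[:, None]
                    - gfact[None, :]
                    + x_b * np.log(mean_b)[:, None]
                    - gfact[x_b]
                )
            else:
                r_a = n_a / phi
                r_b = n_b / phi
                gfact = gammaln(grid + 1.0)
                tab_a = gammaln(grid + r_a) - gammaln(r_a) - gfact
                tab_b = gammaln(grid + r_b) - gammaln(r_b) - gfact
                ll = (
                    tab_a[None, :]
                    + grid[None, :]
                    * np.log(mean_a / (r_a + mean_a))[:, None]
                    + r_a * np.log(r_a / (r_a + mean_a))[:, None]
                    + tab_b[x_b]
                    + x_b * np.log(mean_b / (r_b + mean_b))[:, None]
                    + r_b * np.log(r_b / (r_b + mean_b))[:, None]
                )
        ll = np.where(valid, ll, -np.inf)
        w = np.exp(ll - ll.max(axis=1, keepdims=True))
        probs = w / w.sum(axis=1, keepdims=True)
        p_obs = probs[np.arange(len(idx)), s_a[idx]]
        include = probs <= p_obs[:, None] * (1.0 + TIE_REL_TOL)
        p_chunk = np.minimum((probs * include).sum(axis=1), 1.0)
        # when every outcome is included the p-value is exactly 1
        all_in = (include | ~valid).all(axis=1)
        pvals[idx] = np.where(all_in, 1.0, p_chunk)
    return pvals


def estimate_common_dispersion(
    matrix: WindowCountMatrix,
    min_mean_count: float = 1.0,
    min_windows: int = 50,
) -> DispersionEstimate:
    """Method-of-moments common dispersion from library-adjusted counts.

    Per window, the within-group variance (pooled across the two groups, n−1
    denominators) and grand mean ``m`` of counts scaled to the common library
    size give ``φ_w = max(0, (v − m) / m²)``; the common value is the
    mean-weighted average over windows passing the coverage floor.
    """
    idx_a = matrix.group_indices("disease")
    idx_b = matrix.group_indices("no_disease")
    if max(len(idx_a), len(idx_b)) < 2:
        raise InsufficientDataError(
            "dispersion estimation needs >= 2 samples in at least one group"
        )
    scaled, _ = equalized_counts(matrix)
    adj = scaled.astype(float)

    keep = matrix.counts.mean(axis=1) >= min_mean_count
    if int(keep.sum()) < min_windows:
        raise InsufficientDataError(
            f"only {int(keep.sum())} windows pass the coverage floor; "
            f"need >= {min_windows}"
        )
    adj = adj[keep]

    parts_var = []
    dfs = []
    for idx in (idx_a, idx_b):
        if len(idx) >= 2:
            parts_var.append(adj[:, idx].var(axis=1, ddof=1))
            dfs.append(len(idx) - 1)
    v = sum(df * pv for df, pv in zip(dfs, parts_var)) / sum(dfs)
    m = adj.mean(axis=1)
    ok = m > 0
    phi_w = np.zeros(len(m))
    phi_w[ok] = np.maximum(0.0, (v[ok] - m[ok]) / m[ok] ** 2)
    weights = m
    if weights.sum() == 0:
        return DispersionEstimate(0.0, int(keep.sum()))
    phi = float((phi_w * weights).sum() / weights.sum())
    return DispersionEstimate(phi, int(keep.sum()))


def test_all_windows(
    matrix: WindowCountMatrix,
    phi: float | DispersionEstimate | None = None,
    min_mean_count: float = 1.0,
) -> pd.DataFrame:
    """Exact NB test for every window; returns the per-window results table.

    Columns: chrom, start, end, p_value, q_value, log2_fold_change,
    mean_disease, mean_control, tested. Windows with mean raw count below
    ``min_mean_count`` are not tested (p = 1, tested = False) and are excluded
    from the BH adjustment; ``phi=None`` estimates the common dispersion from
    the matrix first.
    """
    if phi is None:
        phi = estimate_common_dispersion(matrix, min_mean_count)
    if isinstance(phi, DispersionEstimate):
        phi = phi.common_dispersion
    if phi < 0:
        raise InputError(f"dispersion must be >= 0, got {phi}")
    idx_a = matrix.group_indices("disease")
    idx_b = matrix.group_indices("no_disease")
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise InputError("both groups must be non-empty")

    tested_mask = matrix.counts.mean(axis=1) >= min_mean_count
    if not tested_mask.any():
        out = matrix.windows[["chrom", "start", "end"]].copy()
        out["p_value"] = 1.0
        out["q_value"] = 1.0
        out["log2_fold_change"] = 0.0
        out["mean_disease"] = matrix.counts[:, idx_a].mean(axis=1)
        out["mean_control"] = matrix.counts[:, idx_b].mean(axis=1)
        out["tested"] = False
        return out

    scaled, _ = equalized_counts(matrix)
    s_a = scaled[:, idx_a].sum(axis=1)
    s_b = scaled[:, idx_b].sum(axis=1)
    n_a, n_b = len(idx_a), len(idx_b)

    tested = matrix.counts.mean(axis=1) >= min_mean_count
    pvals = np.ones(matrix.n_windows)
    if tested.any():
        pvals[tested] = _batch_exact_pvalues(
            s_a[tested], s_b[tested], n_a, n_b, phi
        )
    log2fc = np.log2((s_a / n_a + 0.5) / (s_b / n_b + 0.5))

    qvals = np.ones(matrix.n_windows)
    if tested.any():
        qvals[tested] = bh_adjust(pvals[tested])

    out = matrix.windows[["chrom", "start", "end"]].copy()
    out["p_value"] = pvals
    out["q_value"] = qvals
    out["log2_fold_change"] = log2fc
    out["mean_disease"] = s_a / n_a
    out["mean_control"] = s_b / n_b
    out["tested"] = tested
    return out


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
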