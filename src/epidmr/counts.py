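"""Genome tiling, read binning, and count normalization.

Coordinates are 0-based half-open throughout (BED convention). The genome is
tiled into fixed-size non-overlapping windows (1000 bp by default, the
resolution at which differential methylation is tested); aligned reads are
assigned to exactly one window by their midpoint. Normalization quantities are
RPKM (reads per kilobase per million mapped reads) and trimmed-mean-of-M-values
(TMM) scaling factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, InsufficientDataError


@dataclass
class WindowCountMatrix:
    """Raw read counts over the window grid, with sample metadata.

    ``windows``: DataFrame (chrom, start, end), one row per window, genome
    order. ``counts``: int array, windows × samples. ``groups``: per-sample
    label, "disease" or "no_disease". ``library_sizes``: total mapped reads
    per sample (defaults to column sums). ``norm_factors``: per-sample TMM-style
    scaling factors (default 1.0); effective library size is
    ``library_sizes * norm_factors``.
    """

    windows: pd.DataFrame
    counts: np.ndarray
    samples: list[str]
    groups: list[str]
    library_sizes: np.ndarray | None = None
    norm_factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise InputError("counts must be a 2-D window × sample array")
        n_w, n_s = self.counts.shape
        if len(self.windows) != n_w:
            raise InputError(
                f"{len(self.windows)} windows but {n_w} count rows"
            )
        if len(self.samples) != n_s or len(self.groups) != n_s:
            raise InputError("samples/groups length must match count columns")
        if (self.counts < 0).any():
            raise InputError("counts must be non-negative")
        colsums = self.counts.sum(axis=0)
        if self.library_sizes is None:
            self.library_sizes = colsums.astype(np.int64)
        else:
            self.library_sizes = np.asarray(self.library_sizes)
            if (self.library_sizes < colsums).any():
                raise InputError(
                    "library sizes must be at least the column sums"
                )
        if self.norm_factors is None:
            self.norm_factors = np.ones(n_s)
        else:
            self.norm_factors = np.asarray(self.norm_factors, dtype=float)

    @property
    def n_windows(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def effective_library_sizes(self) -> np.ndarray:
        return self.library_sizes * self.norm_factors

    def group_indices(self, group: str) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.groups) if g == group])

    def window_ids(self) -> pd.Series:
        w = self.windows
        return (
            w["chrom"].astype(str)
            + ":"
            + w["start"].astype(str)
            + "-"
            + w["end"].astype(str)
        )


def tile_genome(
    chrom_lengths: dict[str, int], window_size: int = 1000
) -> pd.DataFrame:
    """Tile each chromosome into half-open windows; the last window of a
    chromosome is truncated at the chromosome end."""
    if window_size <= 0:
        raise InputError(f"window_size must be > 0, got {window_size}")
    rows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise InputError(f"chromosome {chrom} has non-positive length")
        starts = np.arange(0, length, window_size)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": np.minimum(starts + window_size, length),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def bin_reads(
    reads: pd.DataFrame, windows: pd.DataFrame
) -> tuple[np.ndarray, int]:
    """Count reads per window by the read-midpoint rule.

    ``reads`` needs columns (chrom, start, end). Each read falls in exactly
    one window — the one containing its midpoint ``(start + end) // 2`` under
    half-open semantics. Reads on chromosomes absent from the grid are
    skipped; returns ``(counts, n_skipped)`` with
    ``counts.sum() + n_skipped == len(reads)``.
    """
    if (reads["start"] >= reads["end"]).any():
        bad = reads.index[reads["start"] >= reads["end"]][0]
        raise InputError(f"malformed read interval at row {bad} (start >= end)")
    counts = np.zeros(len(windows), dtype=np.int64)
    skipped = 0
    grid = {
        chrom: (sub["start"].to_numpy(), sub.index.to_numpy())
        for chrom, sub in windows.groupby("chrom", sort=False)
    }
    chrom_ends = {
        chrom: int(sub["end"].max())
        for chrom, sub in windows.groupby("chrom", sort=False)
    }
    for chrom, sub in reads.groupby("chrom", sort=False):
        if chrom not in grid:
            skipped += len(sub)
            continue
        starts, idx = grid[chrom]
        mid = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
        inside = (mid >= 0) & (mid < chrom_ends[chrom])
        skipped += int((~inside).sum())
        mid = mid[inside]
        pos = np.searchsorted(starts, mid, side="right") - 1
        np.add.at(counts, idx[pos], 1)
    return counts, skipped


def rpkm_matrix(matrix: WindowCountMatrix) -> np.ndarray:
    """Reads per kilobase of window per million mapped reads."""
    libs = np.asarray(matrix.library_sizes, dtype=float)
    if (libs <= 0).any():
        raise InputError("library sizes must be positive for RPKM")
    lengths_kb = (
        (matrix.windows["end"] - matrix.windows["start"]).to_numpy() / 1000.0
    )
    return matrix.counts / (lengths_kb[:, None] * (libs[None, :] / 1e6))


def tmm_factors(
    matrix: WindowCountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    M-values are log2 ratios of library-size-normalized counts against a
    reference sample (the one whose upper-quartile normalized count is closest
    to the mean upper quartile); the most extreme ``trim_m`` fraction of
    M-values and ``trim_a`` of A-values are trimmed from each tail before
    averaging. Windows with a zero count in either sample are excluded.
    """
    if matrix.n_samples < 2:
        raise InsufficientDataError("TMM needs at least 2 samples")
    zero_cols = np.where(matrix.counts.sum(axis=0) == 0)[0]
    if len(zero_cols):
        raise InputError(
            f"sample {matrix.samples[zero_cols[0]]!r} has all-zero counts"
        )
    libs = np.asarray(matrix.library_sizes, dtype=float)
    rates = matrix.counts / libs[None, :]

    uq = np.quantile(rates, 0.75, axis=0)
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    log_factors = np.zeros(matrix.n_samples)
    for s in range(matrix.n_samples):
        if s == ref:
            continue
        ok = (matrix.counts[:, s] > 0) & (matrix.counts[:, ref] > 0)
        if not ok.any():
            log_factors[s] = 0.0
            continue
        ls = np.log2(rates[ok, s])
        lr = np.log2(rates[ok, ref])
        m = ls - lr
        a = 0.5 * (ls + lr)
        keep = np.ones(len(m), dtype=bool)
        if len(m) > 1:
            m_lo, m_hi = np.quantile(m, [trim_m, 1.0 - trim_m])
            a_lo, a_hi = np.quantile(a, [trim_a, 1.0 - trim_a])
            keep = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
            if not keep.any():
                keep[:] = True
        log_factors[s] = float(m[keep].mean())

    log_factors -= log_factors.mean()  # geometric mean 1
    return np.power(2.0, log_factors)


def equalized_counts(matrix: WindowCountMatrix) -> tuple[np.ndarray, float]:
    """Counts rescaled to a common library size (the geometric mean of the
    effective sizes) and rounded to integers, ties to even.

    Returns ``(scaled_counts, common_size)``. Integer counts are required by
    the exact test's conditional law.
    """
    eff = np.asarray(matrix.effective_library_sizes, dtype=float)
    if (eff <= 0).any():
        raise InputError("effective library sizes must be positive")
    common = float(np.exp(np.mean(np.log(eff))))
    scaled = np.rint(matrix.counts * (common / eff)[None, :]).astype(np.int64)
    return scaled, common
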