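"""Seed-and-extend DMR assembly from per-window p-values.

A window is a *seed* when its p-value is below the strict seed threshold
(default 1e-4). Maximal runs of adjacent seed windows initialize candidate
regions; region edges are then extended iteratively: any tested window with a
p-value below the relaxed extension threshold (default 0.1) whose interval
lies within the extension reach (default 1000 bp; a gap strictly smaller than
the reach — adjacent windows qualify, a gap of one full 1000 bp window does
not) of a region edge is absorbed, and regions that come to touch or overlap
are merged. Iteration stops at a fixed point: no absorbable window remains
near any edge. Extension windows widen the reported interval but only seed
windows count toward ``n_significant_windows``.

Untested (low-coverage) windows carry p = 1 and therefore block extension.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError
from .simulate import GenomeModel


def seed_select(results: pd.DataFrame, seed_threshold: float) -> np.ndarray:
    """Indices (into ``results``) of tested windows with p strictly below the
    seed threshold."""
    p = results["p_value"].to_numpy()
    tested = results["tested"].to_numpy() if "tested" in results else np.ones(
        len(results), bool
    )
    return np.where(tested & (p < seed_threshold))[0]


def _check_sorted_windows(results: pd.DataFrame) -> None:
    for _, sub in results.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if (np.diff(starts) <= 0).any() or (starts[1:] < ends[:-1]).any():
            raise InputError("windows must be sorted and non-overlapping")


def _assemble_chrom(
    sub: pd.DataFrame,
    seed_threshold: float,
    extend_threshold: float,
    reach: int,
) -> list[dict]:
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    p = sub["p_value"].to_numpy()
    tested = (
        sub["tested"].to_numpy()
        if "tested" in sub
        else np.ones(len(sub), bool)
    )
    is_seed = tested & (p < seed_threshold)
    extendable = tested & (p < extend_threshold)

    seed_idx = np.where(is_seed)[0]
    if len(seed_idx) == 0:
        return []

    # initial regions: maximal runs of adjacent (touching) seed windows
    regions: list[list[int]] = []  # member window indices
    current = [int(seed_idx[0])]
    for i in seed_idx[1:]:
        prev = current[-1]
        if i == prev + 1 and starts[i] == ends[prev]:
            current.append(int(i))
        else:
            regions.append(current)
            current = [int(i)]
    regions.append(current)

    member = np.zeros(len(sub), dtype=bool)
    for reg in regions:
        member[reg] = True

    # fixed-point extension: absorb extendable windows with gap < reach
    changed = True
    while changed:
        changed = False
        for reg in regions:
            # walk left from the region's current left edge
            j = reg[0] - 1
            while j >= 0 and not member[j]:
                gap = starts[reg[0]] - ends[j]
                if gap >= reach:
                    break
                if extendable[j]:
                    reg.insert(0, j)
                    member[j] = True
                    changed = True
                j -= 1
            # walk right from the region's current right edge
            j = reg[-1] + 1
            while j < len(sub) and not member[j]:
                gap = starts[j] - ends[reg[-1]]
                if gap >= reach:
                    break
                if extendable[j]:
                    reg.append(j)
                    member[j] = True
                    changed = True
                j += 1
        # merge regions that touch or overlap
        merged: list[list[int]] = []
        for reg in sorted(regions, key=lambda r: r[0]):
            if merged and starts[reg[0]] <= ends[merged[-1][-1]]:
                merged[-1].extend(reg)
                merged[-1].sort()
            else:
                merged.append(reg)
        regions = merged

    chrom = sub["chrom"].iloc[0]
    out = []
    for reg in regions:
        members = np.array(reg)
        out.append(
            {
                "chrom": chrom,
                "start": int(starts[members[0]]),
                "end": int(ends[members[-1]]),
                "member_index": sub.index.to_numpy()[members],
                "n_significant_windows": int(is_seed[members].sum()),
            }
        )
    return out


def assemble_dmrs(
    results: pd.DataFrame,
    seed_threshold: float = 1e-4,
    extend_threshold: float = 0.1,
    reach: int = 1000,
    genome: GenomeModel | None = None,
) -> pd.DataFrame:
    """Assemble DMRs from a per-window results table.

    ``results`` is the table from :func:`epidmr.diffmeth.test_all_windows`
    (sorted by genome position; one row per tiling window). Returns the DMR
    summary table with one row per region: name, chromosome, start, stop,
    length, number of seed-significant windows, minimum p, the member log2
    fold change of largest magnitude (sign preserved), CpG number and density
    (when a genome model is supplied), and direction.
    """
    if not (0 < seed_threshold <= 1) or not (0 < extend_threshold <= 1):
        raise InputError("thresholds must lie in (0, 1]")
    if reach < 0:
        raise InputError("reach must be >= 0")
    _check_sorted_windows(results)

    raw: list[dict] = []
    for _, sub in results.groupby("chrom", sort=False):
        raw.extend(
            _assemble_chrom(sub, seed_threshold, extend_threshold, reach)
        )

    cpg = genome.cpg_counts if genome is not None else None
    rows = []
    for reg in sorted(raw, key=lambda r: (r["chrom"], r["start"])):
        members = reg["member_index"]
        sub = results.loc[members]
        lfc = sub["log2_fold_change"].to_numpy()
        max_lfc = float(lfc[np.argmax(np.abs(lfc))])
        length = reg["end"] - reg["start"]
        row = {
            "name": f"{reg['chrom']}:{reg['start']}",
            "chrom": reg["chrom"],
            "start": reg["start"],
            "end": reg["end"],
            "length": length,
            "n_significant_windows": reg["n_significant_windows"],
            "min_p": float(sub["p_value"].min()),
            "max_log2_fold_change": max_lfc,
        }
        if cpg is not None:
            n_cpg = int(cpg[members].sum())
            row["cpg_number"] = n_cpg
            row["cpg_density"] = 100.0 * n_cpg / length
        row["direction"] = (
            "hyper" if max_lfc > 0 else ("hypo" if max_lfc < 0 else "none")
        )
        rows.append(row)

    columns = [
        "name", "chrom", "start", "end", "length",
        "n_significant_windows", "min_p", "max_log2_fold_change",
    ]
    if cpg is not None:
        columns += ["cpg_number", "cpg_density"]
    columns += ["direction"]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows, columns=columns)


def audit_fixed_point(
    results: pd.DataFrame,
    dmrs: pd.DataFrame,
    extend_threshold: float = 0.1,
    reach: int = 1000,
) -> int:
    """Count tested windows with p below the extension threshold lying within
    the extension reach of a DMR edge without being members. Zero after a
    correct assembly."""
    violations = 0
    for _, sub in results.groupby("chrom", sort=False):
        d = dmrs[dmrs["chrom"] == sub["chrom"].iloc[0]]
        if d.empty:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        p = sub["p_value"].to_numpy()
        tested = (
            sub["tested"].to_numpy()
            if "tested" in sub
            else np.ones(len(sub), bool)
        )
        hot = tested & (p < extend_threshold)
        for _, reg in d.iterrows():
            inside = (starts >= reg["start"]) & (ends <= reg["end"])
            gap_left = reg["start"] - ends
            gap_right = starts - reg["end"]
            near = (
                ((gap_left >= 0) & (gap_left < reach))
                | ((gap_right >= 0) & (gap_right < reach))
            )
            violations += int((hot & near & ~inside).sum())
    return violations


def threshold_sweep(
    results: pd.DataFrame,
    thresholds: list[float] | None = None,
    extend_threshold: float = 0.1,
    reach: int = 1000,
) -> pd.DataFrame:
    """DMR counts across seed thresholds (descending): all DMRs and those with
    at least two seed-significant windows ("multiple window" DMRs)."""
    if thresholds is None:
        thresholds = [10.0 ** -k for k in range(2, 8)]
    rows = []
    for thr in thresholds:
        dmrs = assemble_dmrs(results, thr, extend_threshold, reach)
        rows.append(
            {
                "threshold": thr,
                "all_window": len(dmrs),
                "multiple_window": int(
                    (dmrs["n_significant_windows"] >= 2).sum()
                )
                if len(dmrs)
                else 0,
            }
        )
    return pd.DataFrame(rows)


def _reciprocal_hit(
    intervals: pd.DataFrame, targets: pd.DataFrame, min_fraction: float
) -> int:
    hits = 0
    for _, x in intervals.iterrows():
        cand = targets[
            (targets["chrom"] == x["chrom"])
            & (targets["end"] > x["start"])
            & (targets["start"] < x["end"])
        ]
        for _, r in cand.iterrows():
            shared = min(x["end"], r["end"]) - max(x["start"], r["start"])
            if shared >= min_fraction * (
                x["end"] - x["start"]
            ) and shared >= min_fraction * (r["end"] - r["start"]):
                hits += 1
                break
    return hits


def evaluate_recovery(
    dmrs: pd.DataFrame,
    truth_regions: pd.DataFrame,
    min_reciprocal: float = 0.5,
) -> dict:
    """Sensitivity and precision of called DMRs against planted regions.

    A planted region is recovered (and a called DMR is a true positive) when
    the two intervals share at least ``min_reciprocal`` of each one's length.
    """
    n_truth = len(truth_regions)
    n_called = len(dmrs)
    recovered = _reciprocal_hit(truth_regions, dmrs, min_reciprocal)
    true_pos = _reciprocal_hit(dmrs, truth_regions, min_reciprocal)
    return {
        "sensitivity": recovered / n_truth if n_truth else None,
        "precision": true_pos / n_called if n_called else None,
        "n_truth": n_truth,
        "n_called": n_called,
    }


def classify_direction(dmrs: pd.DataFrame) -> tuple[pd.Series, float | None]:
    """Per-DMR methylation direction and the hypermethylated fraction.

    Direction is the sign of the max-magnitude log2 fold change; DMRs with a
    zero fold change are "none" and excluded from the fraction's denominator.
    Returns ``(directions, hyper_fraction)``; the fraction is None when no DMR
    has a nonzero direction.
    """
    if len(dmrs) == 0:
        return pd.Series(dtype=object), None
    directions = dmrs["direction"]
    n_signed = int((directions != "none").sum())
    if n_signed == 0:
        return directions, None
    return directions, float((directions == "hyper").sum() / n_signed)
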