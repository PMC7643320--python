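"""Cross-phenotype DMR comparisons: pairwise interval overlap, Venn-region
counts, extended overlap at a relaxed threshold, the common core shared by all
sets, and PCA of RPKM depths at DMR windows.

Overlap between two DMRs means at least one shared base pair (half-open
semantics); a minimum reciprocal-overlap fraction can be required instead.
Venn counts are reported per set: each DMR of a set is assigned to exactly one
region of that set's partition by which other sets it overlaps (sets have
different cardinalities, so a shared "element" is an overlap relation, not a
merged interval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from sklearn.metrics import silhouette_score

from .errors import InputError


@dataclass
class DMRSet:
    """A labelled collection of DMR intervals from one phenotype comparison."""

    label: str
    intervals: pd.DataFrame  # columns chrom, start, end; sorted, disjoint
    threshold: float | None = None

    def __post_init__(self) -> None:
        df = self.intervals
        for _, sub in df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if (np.diff(starts) < 0).any() or (starts[1:] < ends[:-1]).any():
                raise InputError(
                    f"set {self.label!r}: intervals must be sorted and disjoint"
                )

    def __len__(self) -> int:
        return len(self.intervals)


def _trees(intervals: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in intervals.groupby("chrom", sort=False):
        trees[chrom] = IntervalTree.from_tuples(
            zip(sub["start"], sub["end"])
        )
    return trees


def _overlaps(
    row, trees: dict[str, IntervalTree], min_fraction: float = 0.0
) -> bool:
    tree = trees.get(row["chrom"])
    if tree is None:
        return False
    hits = tree.overlap(row["start"], row["end"])
    if not hits:
        return False
    if min_fraction <= 0:
        return True
    for hit in hits:
        shared = min(row["end"], hit.end) - max(row["start"], hit.begin)
        len_a = row["end"] - row["start"]
        len_b = hit.end - hit.begin
        if shared >= min_fraction * len_a and shared >= min_fraction * len_b:
            return True
    return False


def interval_overlap(
    set_a: DMRSet, set_b: DMRSet, min_fraction: float = 0.0
) -> pd.DataFrame:
    """Flag each interval of ``set_a`` that overlaps ``set_b``.

    Returns ``set_a.intervals`` with an ``overlaps`` boolean column; each
    interval is reported once regardless of how many partners it touches.
    """
    trees = _trees(set_b.intervals)
    out = set_a.intervals.copy()
    out["overlaps"] = [
        _overlaps(row, trees, min_fraction) for _, row in out.iterrows()
    ]
    return out


def overlap_counts(
    set_a: DMRSet, set_b: DMRSet, min_fraction: float = 0.0
) -> dict:
    """Pairwise summary: how many of ``set_a``'s DMRs overlap ``set_b``."""
    flagged = interval_overlap(set_a, set_b, min_fraction)
    n = int(flagged["overlaps"].sum())
    total = len(set_a)
    return {
        "set": set_a.label,
        "other": set_b.label,
        "n_overlapping": n,
        "n_unique": total - n,
        "percent": (100.0 * n / total) if total else None,
    }


def venn_counts(sets: list[DMRSet], min_fraction: float = 0.0) -> pd.DataFrame:
    """Venn-region counts per set for 2–4 DMR sets.

    Each DMR is assigned the signature of sets it overlaps (always including
    its own); rows are (set, region, count) and the counts for one set sum to
    that set's cardinality.
    """
    if not 2 <= len(sets) <= 4:
        raise InputError("venn_counts supports 2 to 4 sets")
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise InputError("set labels must be unique")
    trees = {s.label: _trees(s.intervals) for s in sets}
    rows = []
    for s in sets:
        signatures: dict[str, int] = {}
        for _, row in s.intervals.iterrows():
            members = [s.label]
            for other in sets:
                if other.label == s.label:
                    continue
                if _overlaps(row, trees[other.label], min_fraction):
                    members.append(other.label)
            key = "&".join(sorted(members))
            signatures[key] = signatures.get(key, 0) + 1
        for key, n in sorted(signatures.items()):
            rows.append({"set": s.label, "region": key, "count": n})
    return pd.DataFrame(rows, columns=["set", "region", "count"])


def extended_overlap(
    strict_set: DMRSet, relaxed_set: DMRSet, min_fraction: float = 0.0
) -> dict:
    """Overlap of a strict-threshold DMR set against another comparison's DMRs
    assembled at a relaxed threshold (e.g. p < 0.05).

    Returns count and percent of the strict set's DMRs overlapping the relaxed
    set; percent is None when the strict set is empty.
    """
    if len(strict_set) == 0:
        return {
            "strict_set": strict_set.label,
            "relaxed_set": relaxed_set.label,
            "n_overlapping": 0,
            "percent": None,
        }
    flagged = interval_overlap(strict_set, relaxed_set, min_fraction)
    n = int(flagged["overlaps"].sum())
    return {
        "strict_set": strict_set.label,
        "relaxed_set": relaxed_set.label,
        "n_overlapping": n,
        "percent": 100.0 * n / len(strict_set),
    }


def common_core(
    sets: list[DMRSet],
    strict_sets: list[DMRSet] | None = None,
    min_fraction: float = 0.0,
) -> pd.DataFrame:
    """Intervals of the first set overlapping every other set.

    When ``strict_sets`` is given, each core interval is additionally flagged
    per strict set it overlaps, so the core found at a relaxed threshold can
    be re-checked against the strict-threshold sets.
    """
    if len(sets) < 2:
        raise InputError("common_core needs at least 2 sets")
    first = sets[0]
    core = first.intervals.copy()
    keep = np.ones(len(core), dtype=bool)
    for other in sets[1:]:
        trees = _trees(other.intervals)
        keep &= np.array(
            [_overlaps(row, trees, min_fraction) for _, row in core.iterrows()]
        )
    core = core[keep].reset_index(drop=True)
    if strict_sets:
        for s in strict_sets:
            trees = _trees(s.intervals)
            core[f"in_strict_{s.label}"] = [
                _overlaps(row, trees, min_fraction)
                for _, row in core.iterrows()
            ]
    return core


def pca_rpkm(
    rpkm: np.ndarray,
    groups: list[str],
    scale: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on RPKM depth at DMR windows.

    ``rpkm`` is windows × samples; samples are the observations and windows
    the (centered, optionally unit-variance scaled) features. Returns sample
    coordinates on the two leading components plus each component's fraction
    of variance explained. The sign of each component is fixed by forcing its
    largest-magnitude window loading positive.
    """
    x = np.asarray(rpkm, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise InputError("pca_rpkm needs >= 2 windows and >= 2 samples")
    if len(groups) != x.shape[1]:
        raise InputError("groups length must match sample count")
    centered = x - x.mean(axis=1, keepdims=True)
    if scale:
        sd = centered.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        centered = centered / sd
    if not centered.any():
        coords = pd.DataFrame(
            {
                "group": groups,
                "pc1": np.zeros(x.shape[1]),
                "pc2": np.zeros(x.shape[1]),
            }
        )
        return coords, np.zeros(2)

    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    for k in range(min(2, len(s))):
        lead = np.argmax(np.abs(u[:, k]))
        if u[lead, k] < 0:
            u[:, k] = -u[:, k]
            vt[k, :] = -vt[k, :]
    var = s**2
    var_explained = var / var.sum() if var.sum() > 0 else var
    coords = pd.DataFrame(
        {
            "group": groups,
            "pc1": s[0] * vt[0, :],
            "pc2": s[1] * vt[1, :] if len(s) > 1 else np.zeros(x.shape[1]),
        }
    )
    return coords, var_explained[:2]


def group_silhouette(coords: pd.DataFrame) -> float:
    """Mean silhouette of the group labels on the (PC1, PC2) plane."""
    labels = coords["group"].to_numpy()
    if len(set(labels)) < 2:
        raise InputError("silhouette needs at least two groups")
    return float(
        silhouette_score(coords[["pc1", "pc2"]].to_numpy(), labels)
    )
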