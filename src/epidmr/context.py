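"""Genomic features of DMRs: CpG density and length histograms, chromosomal
cluster detection, gene association against a supplied annotation, and
functional-category tabulation.

Gene association uses a plain distance rule: a gene qualifies when the minimum
genomic distance between the DMR interval and the gene body is at most
``max_distance`` (default 10 kb, inclusive; 0 means overlap). Categories come
from a user-supplied single-category-per-gene mapping table — no live database
queries are performed.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, ParseError

logger = logging.getLogger(__name__)


def cpg_density_histogram(dmrs: pd.DataFrame, max_bin: int = 10) -> pd.Series:
    """DMR counts per integer CpG-density bin (CpG per 100 bp, floored).

    Densities of ``max_bin`` or more land in the final open-ended bin. Counts
    sum to the number of DMRs.
    """
    bins = np.arange(0, max_bin + 1)
    labels = [str(b) for b in bins[:-1]] + [f"{max_bin}+"]
    counts = pd.Series(0, index=labels, dtype=int)
    if len(dmrs):
        binned = np.minimum(
            np.floor(dmrs["cpg_density"].to_numpy()).astype(int), max_bin
        )
        vc = pd.Series(binned).value_counts()
        for b, n in vc.items():
            counts.iloc[b] = int(n)
    counts.index.name = "cpg_per_100bp"
    return counts


def length_histogram(
    dmrs: pd.DataFrame, bin_size: int = 1000, max_bin_kb: int = 10
) -> pd.Series:
    """DMR counts per length bin (1 kb bins by default; lengths are binned by
    ``ceil(length / bin_size)`` so a 1-window DMR lands in the 1 kb bin)."""
    bins = np.arange(1, max_bin_kb + 1)
    labels = [str(b) for b in bins[:-1]] + [f"{max_bin_kb}+"]
    counts = pd.Series(0, index=labels, dtype=int)
    if len(dmrs):
        binned = np.ceil(dmrs["length"].to_numpy() / bin_size).astype(int)
        binned = np.clip(binned, 1, max_bin_kb)
        vc = pd.Series(binned).value_counts()
        for b, n in vc.items():
            counts.iloc[b - 1] = int(n)
    counts.index.name = "length_kb"
    return counts


def find_dmr_clusters(
    dmrs: pd.DataFrame,
    cluster_window: int = 2_000_000,
    min_cluster_size: int = 3,
) -> pd.DataFrame:
    """Maximal chromosomal runs of at least ``min_cluster_size`` DMRs in which
    consecutive members are at most ``cluster_window`` bp apart."""
    rows = []
    if len(dmrs) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_dmrs", "members"])
    for chrom, sub in dmrs.sort_values(["chrom", "start"]).groupby(
        "chrom", sort=False
    ):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        names = sub["name"].tolist()
        run = [0]
        for i in range(1, len(sub)):
            if starts[i] - ends[run[-1]] <= cluster_window:
                run.append(i)
            else:
                if len(run) >= min_cluster_size:
                    rows.append(
                        {
                            "chrom": chrom,
                            "start": int(starts[run[0]]),
                            "end": int(ends[run[-1]]),
                            "n_dmrs": len(run),
                            "members": [names[j] for j in run],
                        }
                    )
                run = [i]
        if len(run) >= min_cluster_size:
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(starts[run[0]]),
                    "end": int(ends[run[-1]]),
                    "n_dmrs": len(run),
                    "members": [names[j] for j in run],
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_dmrs", "members"]
    )


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read gene intervals from BED (4+ columns) or GTF (gene features).

    Returns a DataFrame (gene, chrom, start, end, strand) with 0-based
    half-open coordinates.
    """
    path = Path(path)
    if path.suffix.lower() in {".gtf", ".gff"}:
        rows = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 9:
                    raise ParseError(f"{path}:{ln}: expected 9 GTF columns")
                if parts[2] != "gene":
                    continue
                m = re.search(r'gene_(?:id|name) "([^"]+)"', parts[8])
                name = m.group(1) if m else f"gene_{ln}"
                rows.append(
                    {
                        "gene": name,
                        "chrom": parts[0],
                        "start": int(parts[3]) - 1,  # GTF is 1-based closed
                        "end": int(parts[4]),
                        "strand": parts[6] if parts[6] in "+-" else "unknown",
                    }
                )
        return pd.DataFrame(rows)
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ParseError(f"{path}: BED annotation needs >= 4 columns")
    out = pd.DataFrame(
        {
            "gene": df[3].astype(str),
            "chrom": df[0].astype(str),
            "start": df[1].astype(int),
            "end": df[2].astype(int),
            "strand": df[5] if df.shape[1] > 5 else "unknown",
        }
    )
    return out


def associate_genes(
    dmrs: pd.DataFrame,
    annotation: pd.DataFrame,
    max_distance: int = 10_000,
) -> pd.DataFrame:
    """Per-DMR gene association by minimum interval distance.

    A gene is associated when the gap between the DMR and the gene body is at
    most ``max_distance`` (inclusive; 0 for overlapping intervals). Annotation
    rows on chromosomes absent from the DMR set are skipped with a log note.
    Returns the DMR table with an added ``genes`` column (sorted list).
    """
    if (annotation["end"] <= annotation["start"]).any():
        raise InputError("gene annotation intervals must satisfy end > start")
    dmr_chroms = set(dmrs["chrom"]) if len(dmrs) else set()
    unknown = set(annotation["chrom"]) - dmr_chroms
    if unknown:
        logger.info(
            "skipping %d annotation rows on chromosomes without DMRs: %s",
            int(annotation["chrom"].isin(unknown).sum()),
            sorted(unknown),
        )

    out = dmrs.copy()
    gene_lists: list[list[str]] = []
    ann_by_chrom = dict(tuple(annotation.groupby("chrom", sort=False)))
    for _, row in dmrs.iterrows():
        sub = ann_by_chrom.get(row["chrom"])
        if sub is None:
            gene_lists.append([])
            continue
        gap = np.maximum(
            sub["start"].to_numpy() - row["end"],
            row["start"] - sub["end"].to_numpy(),
        )
        gap = np.maximum(gap, 0)
        hits = sub.loc[gap <= max_distance, "gene"]
        gene_lists.append(sorted(set(hits)))
    out["genes"] = gene_lists
    return out


def interval_distance(
    start_a: int, end_a: int, start_b: int, end_b: int
) -> int:
    """Minimum genomic distance between two half-open intervals (0 = overlap)."""
    return max(0, start_b - end_a, start_a - end_b)


def read_category_table(path: str | Path) -> dict[str, str]:
    """Read a (gene, category) TSV into a mapping; a gene listed under more
    than one category is rejected."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "category"} <= set(df.columns):
        df = pd.read_csv(path, sep="\t", header=None, names=["gene", "category"])
    dup = df[df.duplicated("gene", keep=False)]
    conflict = dup.groupby("gene")["category"].nunique()
    bad = conflict[conflict > 1]
    if len(bad):
        raise InputError(
            f"genes mapped to multiple categories: {list(bad.index)}"
        )
    return dict(zip(df["gene"].astype(str), df["category"].astype(str)))


def categorize_genes(
    associated: pd.DataFrame | list[list[str]],
    categories: dict[str, str],
) -> pd.Series:
    """Counts of associated genes per functional category.

    A gene hit by several DMRs counts once; genes missing from the mapping
    fall into "unknown".
    """
    if isinstance(associated, pd.DataFrame):
        lists = associated["genes"].tolist()
    else:
        lists = list(associated)
    genes = sorted({g for lst in lists for g in lst})
    counts: dict[str, int] = {}
    for g in genes:
        cat = categories.get(g, "unknown")
        counts[cat] = counts.get(cat, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()
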