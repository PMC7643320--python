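"""On-disk formats: counts/groups TSV, BED, FASTA, and results tables.

All genomic coordinates on disk are 0-based half-open (BED convention).
Counts TSVs have a ``window`` column of ``chrom:start-end`` identifiers and
one column per sample; group TSVs map sample to group label. Round-trips are
exact for integer tables.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .counts import WindowCountMatrix
from .errors import ParseError
from .simulate import GenomeModel, TruthSet

_WINDOW_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def parse_window_ids(ids: pd.Series) -> pd.DataFrame:
    rows = []
    for i, wid in enumerate(ids):
        m = _WINDOW_RE.match(str(wid))
        if not m:
            raise ParseError(f"malformed window id {wid!r} at row {i + 1}")
        rows.append(
            (m["chrom"], int(m["start"]), int(m["end"]))
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def write_counts_tsv(matrix: WindowCountMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.counts, columns=matrix.samples)
    df.insert(0, "window", matrix.window_ids())
    df.to_csv(path, sep="\t", index=False)


def write_groups_tsv(matrix: WindowCountMatrix, path: str | Path) -> None:
    pd.DataFrame({"sample": matrix.samples, "group": matrix.groups}).to_csv(
        path, sep="\t", index=False
    )


def read_counts_tsv(
    counts_path: str | Path, groups_path: str | Path
) -> WindowCountMatrix:
    df = pd.read_csv(counts_path, sep="\t")
    if "window" not in df.columns:
        raise ParseError(f"{counts_path}: missing 'window' column")
    windows = parse_window_ids(df["window"])
    samples = [c for c in df.columns if c != "window"]
    counts = df[samples].to_numpy()
    if not np.issubdtype(counts.dtype, np.integer):
        bad = np.argwhere(df[samples].to_numpy() % 1 != 0)
        if len(bad):
            r, c = bad[0]
            raise ParseError(
                f"{counts_path}: non-integer count at row {r + 2}, "
                f"column {samples[c]!r}"
            )
        counts = counts.astype(np.int64)

    gdf = pd.read_csv(groups_path, sep="\t")
    group_map = dict(zip(gdf["sample"].astype(str), gdf["group"].astype(str)))
    missing = [s for s in samples if s not in group_map]
    if missing:
        raise ParseError(f"{groups_path}: no group for samples {missing}")
    groups = [group_map[s] for s in samples]
    return WindowCountMatrix(
        windows=windows, counts=counts, samples=samples, groups=groups
    )


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write intervals as BED; optional name/score/strand columns are used
    when present."""
    cols = ["chrom", "start", "end"]
    out = intervals[cols].copy()
    if "name" in intervals:
        out["name"] = intervals["name"]
        if "score" in intervals:
            out["score"] = intervals["score"]
            if "strand" in intervals:
                out["strand"] = intervals["strand"]
    out.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file; empty files yield an empty interval table."""
    path = Path(path)
    if path.stat().st_size == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["start"] >= df["end"]).any():
        ln = int(df.index[df["start"] >= df["end"]][0]) + 1
        raise ParseError(f"{path}:{ln}: start >= end")
    return df


def write_truth_bed(truth: TruthSet, path: str | Path) -> None:
    """Planted regions as 6-column BED; strand encodes direction (+ hyper)."""
    df = truth.regions.copy()
    bed = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "name": df["name"],
            "score": (df["effect_log2"].abs() * 100).round().astype(int),
            "strand": np.where(df["direction"] == "hyper", "+", "-"),
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def write_genome_fasta(genome: GenomeModel, path: str | Path) -> None:
    if genome.sequences is None:
        raise ParseError("genome carries no explicit sequence")
    records = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in genome.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "length"]
    )
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))


def write_results_tsv(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False)


def read_results_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "tested" in df.columns:
        df["tested"] = df["tested"].astype(bool)
    return df


def dmr_bed_frame(dmrs: pd.DataFrame) -> pd.DataFrame:
    """DMR table rendered as BED6 (score = round(−10·log10 min p), capped)."""
    if len(dmrs):
        safe_p = np.maximum(dmrs["min_p"].to_numpy(), 1e-100)
        score = np.minimum(1000, np.round(-10.0 * np.log10(safe_p))).astype(int)
    else:
        score = []
    return pd.DataFrame(
        {
            "chrom": dmrs["chrom"],
            "start": dmrs["start"],
            "end": dmrs["end"],
            "name": dmrs["name"],
            "score": score,
            "strand": dmrs["direction"].map(
                {"hyper": "+", "hypo": "-", "none": "."}
            )
            if len(dmrs)
            else [],
        }
    )
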