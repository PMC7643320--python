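"""Histopathology classification and disease-incidence arm.

Tissue sections (testis, prostate, kidney) are scored by blinded observers for
abnormality counts over a measured section area. A tissue is called "diseased"
when its abnormality density exceeds the control-group mean plus two standard
deviations, and a final call requires agreement of at least two observers (a
third observer is consulted only when the first two disagree). Per-animal
disease flags are collected in a presence/absence table; incidence is the
fraction of evaluable (non-missing) animals flagged positive, and group
comparisons use Fisher's exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .errors import InputError, InsufficientDataError, ParseError

#: The six primary pathology columns; "multiple disease" is derived from them.
PRIMARY_PATHOLOGIES = (
    "late_puberty",
    "testis",
    "prostate",
    "kidney",
    "obesity",
    "tumor",
)

ALL_PATHOLOGIES = PRIMARY_PATHOLOGIES + ("multiple_disease",)

# Symbols accepted in disease tables. ASCII and typographic dashes both occur
# in transcriptions; "n/a" marks a section that could not be evaluated.
_PRESENT = {"+"}
_ABSENT = {"-", "−", "–", "—"}
_MISSING = {"n/a", "na", "n.a.", "n·a", ""}


@dataclass(frozen=True)
class AbnormalityRecord:
    """One observer's abnormality count for one tissue section."""

    animal_id: str
    tissue: str
    observer_id: str
    abnormality_count: int
    section_area_mm2: float


@dataclass(frozen=True)
class IncidenceRow:
    pathology: str
    n_positive: int
    n_evaluable: int
    percentage: int  # rounded half-up to whole percent


def abnormality_density(count: float, area_mm2: float) -> float:
    """Abnormalities per mm² of section area."""
    if area_mm2 <= 0:
        raise InputError(f"section area must be positive, got {area_mm2}")
    if count < 0:
        raise InputError(f"abnormality count must be non-negative, got {count}")
    return count / area_mm2


def control_threshold(control_densities: Sequence[float]) -> float:
    """Disease cutoff: control mean plus two sample standard deviations.

    The standard deviation uses the n-1 denominator, the conventional
    estimator for a control sample.
    """
    vals = [float(v) for v in control_densities]
    if len(vals) < 2:
        raise InsufficientDataError(
            f"need at least 2 control densities, got {len(vals)}"
        )
    n = len(vals)
    mean = sum(vals) / n
    var = sum((v - mean) ** 2 for v in vals) / (n - 1)
    return mean + 2.0 * math.sqrt(var)


def consensus_disease_call(observer_calls: Sequence[bool]) -> bool:
    """Diseased iff at least two of the available observer calls agree on
    disease. Two calls suffice when they agree; a third observer is consulted
    only on disagreement."""
    if len(observer_calls) == 0:
        raise InputError("no observer calls provided")
    return sum(bool(c) for c in observer_calls) >= 2


def classify_tissue(
    densities_by_observer: Sequence[float], cutoff: float
) -> bool:
    """Apply the two-SD cutoff per observer, then take the consensus call."""
    calls = [d > cutoff for d in densities_by_observer]
    return consensus_disease_call(calls)


def _parse_flag(token: str, animal: str, column: str) -> object:
    tok = str(token).strip()
    if tok in _PRESENT:
        return True
    if tok in _ABSENT:
        return False
    if tok.lower() in _MISSING:
        return pd.NA
    raise ParseError(
        f"unknown symbol {token!r} for animal {animal}, column {column}"
    )


def parse_disease_table(rows: pd.DataFrame | str | Path) -> pd.DataFrame:
    """Parse a per-animal +/−/n-a disease table into boolean flags.

    Accepts a DataFrame or a TSV/CSV path with an ``animal_id`` column and one
    column per primary pathology. Missing entries (``n/a``) become ``NA`` and
    are excluded from incidence denominators. The derived columns
    ``total_disease`` (count of present flags among the six primary
    pathologies) and ``multiple_disease`` (total ≥ 2) are recomputed; if the
    input carries either column, it is cross-checked against the derivation.
    """
    if not isinstance(rows, pd.DataFrame):
        path = Path(rows)
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        rows = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df = rows.copy()
    if "animal_id" not in df.columns:
        raise ParseError("disease table must have an 'animal_id' column")
    missing_cols = [c for c in PRIMARY_PATHOLOGIES if c not in df.columns]
    if missing_cols:
        raise ParseError(f"disease table missing columns: {missing_cols}")

    out = pd.DataFrame({"animal_id": df["animal_id"].astype(str)})
    for col in PRIMARY_PATHOLOGIES:
        out[col] = [
            _parse_flag(v, a, col)
            for v, a in zip(df[col], out["animal_id"])
        ]
        out[col] = out[col].astype("boolean")

    flags = out[list(PRIMARY_PATHOLOGIES)]
    out["total_disease"] = flags.fillna(False).sum(axis=1).astype(int)
    out["multiple_disease"] = (out["total_disease"] >= 2).astype("boolean")

    for derived in ("total_disease", "multiple_disease"):
        if derived in df.columns:
            given = df[derived]
            if derived == "total_disease":
                given = given.astype(int)
                bad = out.loc[given.values != out[derived].values, "animal_id"]
            else:
                given_flags = pd.array(
                    [_parse_flag(v, a, derived)
                     for v, a in zip(given, out["animal_id"])],
                    dtype="boolean",
                )
                bad = out.loc[
                    (given_flags != out[derived].values).fillna(True),
                    "animal_id",
                ]
            if len(bad):
                raise ParseError(
                    f"column {derived!r} disagrees with derivation for "
                    f"animals: {list(bad)}"
                )
    return out


def incidence_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-pathology incidence: positives / evaluable animals, with the
    percentage rounded half-up to a whole percent."""
    records = []
    for col in ALL_PATHOLOGIES:
        flags = table[col]
        n_eval = int(flags.notna().sum())
        if n_eval == 0:
            raise InsufficientDataError(f"no evaluable animals for {col}")
        n_pos = int((flags == True).sum())  # noqa: E712 (boolean NA semantics)
        pct = int(math.floor(100.0 * n_pos / n_eval + 0.5))
        records.append(IncidenceRow(col, n_pos, n_eval, pct))
    return pd.DataFrame([r.__dict__ for r in records])


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for a 2×2 table [[a, b], [c, d]].

    Two-sided by the minimum-likelihood rule: the sum of hypergeometric
    probabilities (margins fixed) of all tables no more probable than the
    observed one.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise InputError(f"negative cell count in {cells}")
    if sum(cells) == 0 or (a + b == 0 and c + d == 0):
        raise InputError("at least one margin must be positive")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(min(p, 1.0))


def compare_incidence(
    n_pos_a: int, n_total_a: int, n_pos_b: int, n_total_b: int
) -> float:
    """Fisher exact comparison of two incidence proportions."""
    return fisher_exact_2x2(
        n_pos_a, n_total_a - n_pos_a, n_pos_b, n_total_b - n_pos_b
    )


def load_f3_disease_table() -> pd.DataFrame:
    """The packaged 41-animal F3 pesticide-lineage disease table, parsed."""
    ref = resources.files("epidmr") / "data" / "f3_pesticide_disease_table.tsv"
    with resources.as_file(ref) as path:
        return parse_disease_table(path)


def read_abnormality_counts(path: str | Path) -> pd.DataFrame:
    """Read an observer abnormality-count TSV
    (animal_id, tissue, observer_id, abnormality_count, area_mm2)."""
    df = pd.read_csv(path, sep="\t")
    required = {"animal_id", "tissue", "observer_id",
                "abnormality_count", "area_mm2"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"abnormality table missing columns: {sorted(missing)}")
    if (df["area_mm2"] <= 0).any():
        bad = df.loc[df["area_mm2"] <= 0].index[0]
        raise InputError(f"non-positive section area at row {bad}")
    return df


def classify_animals(
    abnormalities: pd.DataFrame,
    control_ids: Iterable[str],
    per_type: bool = False,
) -> pd.DataFrame:
    """Full classification arm: density → control two-SD cutoff (per observer)
    → consensus call, per animal and tissue.

    By default the two-SD rule is applied to the summed abnormality density
    per tissue; ``per_type=True`` applies it per abnormality type instead
    (requires an ``abnormality_type`` column) and calls a tissue diseased if
    any type exceeds its cutoff.
    """
    df = abnormalities.copy()
    df["density"] = df["abnormality_count"] / df["area_mm2"]
    controls = set(str(c) for c in control_ids)
    group_cols = ["tissue"] + (["abnormality_type"] if per_type else [])
    if per_type and "abnormality_type" not in df.columns:
        raise InputError("per_type=True requires an 'abnormality_type' column")

    # Densities are per observer; sum over types unless per_type.
    key = ["animal_id", "tissue", "observer_id"] + (
        ["abnormality_type"] if per_type else []
    )
    dens = df.groupby(key, as_index=False)["density"].sum()

    cutoffs = {}
    for name, grp in dens.groupby(group_cols):
        key = name if isinstance(name, tuple) else (name,)
        ctrl = grp[grp["animal_id"].astype(str).isin(controls)]["density"]
        cutoffs[key] = control_threshold(list(ctrl))

    records = []
    for (animal, tissue), grp in dens.groupby(["animal_id", "tissue"]):
        by_obs = {}
        for obs, og in grp.groupby("observer_id"):
            if per_type:
                call = any(
                    row["density"] > cutoffs[(tissue, row["abnormality_type"])]
                    for _, row in og.iterrows()
                )
            else:
                call = float(og["density"].sum()) > cutoffs[(tissue,)]
            by_obs[obs] = call
        records.append(
            {
                "animal_id": animal,
                "tissue": tissue,
                "n_observers": len(by_obs),
                "diseased": consensus_disease_call(list(by_obs.values())),
            }
        )
    return pd.DataFrame(records)
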