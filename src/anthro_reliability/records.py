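"""Measurement data model for anthropometric standardisation exercises.

A standardisation exercise produces a long-format table of repeated
measurements: each row records one observation of one volunteer by one
rater (a measurer or measurer pair) for one anthropometric parameter in
one of two measurement rounds.  This module defines the schema, reads and
validates CSV input, assigns volunteer age groups, and derives the two
replicate structures every reliability statistic consumes:

* the **inter-rater view** — per volunteer, the first-round measurements
  of all raters who measured that volunteer (volunteers seen by a single
  rater are excluded, since a single measurement carries no information
  about between-rater agreement);
* the **intra-rater view** — per (volunteer, rater) pair, the round-1 and
  round-2 measurements by that rater.

Both views are instances of :class:`ReplicateGroupSet`: a list of groups
of replicate measurements of an unchanged quantity, which is the only
structure the TEM and one-way ICC estimators need.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PARAMETERS",
    "RATER_GROUPS",
    "AGE_GROUPS",
    "PRECISION",
    "UNITS",
    "REQUIRED_COLUMNS",
    "Stratum",
    "ReplicateGroupSet",
    "ValidationReport",
    "assign_age_group",
    "read_measurements",
    "write_measurements",
    "validate",
    "build_inter_view",
    "build_intra_view",
]

#: Anthropometric parameters measured in the exercise.
PARAMETERS = ("weight", "length_height", "muac", "waist", "calf")

#: Rater groups: the trainer-anthropometrists managing a site vs the
#: trained two-person teams performing field measurements.
RATER_GROUPS = ("site_lead", "fieldworker")

#: Volunteer age strata: infants/toddlers, children, adolescents/adults.
AGE_GROUPS = ("under2", "two_to_12", "over12")

#: Instrument reading precision: scales read to 0.01 kg, tapes and
#: boards to 0.1 cm.
PRECISION = {
    "weight": 0.01,
    "length_height": 0.1,
    "muac": 0.1,
    "waist": 0.1,
    "calf": 0.1,
}

UNITS = {
    "weight": "kg",
    "length_height": "cm",
    "muac": "cm",
    "waist": "cm",
    "calf": "cm",
}

REQUIRED_COLUMNS = (
    "volunteer_id",
    "rater_id",
    "rater_group",
    "parameter",
    "round",
    "value",
    "age_years",
)

OPTIONAL_COLUMNS = ("site_id",)

#: Tolerance when checking that a value sits on the instrument grid.
_GRID_TOL = 1e-9


class SchemaError(ValueError):
    """Raised when the input table cannot be interpreted at all."""


class DuplicateRecordError(ValueError):
    """Raised when (volunteer, rater, parameter, round) is not unique."""


def assign_age_group(age_years: float, *, boundaries: tuple[float, float] = (2.0, 12.0)) -> str:
    """Map an age in years to its age stratum.

    The convention is ``[0, 2) -> under2``, ``[2, 12] -> two_to_12``,
    ``(12, inf) -> over12``: ages at exactly 2 years fall in the child
    group and ages at exactly 12 years are still children, so "over 12"
    is literal.  The boundaries are configurable for sensitivity checks.

    Raises
    ------
    ValueError
        If ``age_years`` is negative or not finite.
    """
    lo, hi = boundaries
    if not np.isfinite(age_years) or age_years < 0:
        raise ValueError(f"age_years must be a finite non-negative number, got {age_years!r}")
    if age_years < lo:
        return "under2"
    if age_years <= hi:
        return "two_to_12"
    return "over12"


def _assign_age_groups(age_years: pd.Series, boundaries: tuple[float, float] = (2.0, 12.0)) -> pd.Series:
    lo, hi = boundaries
    out = pd.Series(
        np.where(age_years < lo, "under2", np.where(age_years <= hi, "two_to_12", "over12")),
        index=age_years.index,
    )
    return out


@dataclass(frozen=True)
class Stratum:
    """Which slice of the data a statistic was computed on.

    ``None`` means "not restricted": e.g. ``Stratum("fieldworker", None)``
    is the whole-sample fieldworker stratum.
    """

    rater_group: str | None = None
    age_group: str | None = None

    def label(self) -> str:
        rg = self.rater_group or "all_raters"
        ag = self.age_group or "all_ages"
        return f"{rg}/{ag}"


@dataclass
class ReplicateGroupSet:
    """Groups of replicate measurements of an unchanged quantity.

    In *inter* mode each group is one volunteer with one first-round
    measurement per rater (k_i >= 2).  In *intra* mode each group is one
    (volunteer, rater) pair with its round-1 and round-2 measurements in
    that order (k_i == 2).
    """

    mode: str  # "inter" | "intra"
    parameter: str
    stratum: Stratum
    groups: list[tuple[str, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in ("inter", "intra"):
            raise ValueError(f"mode must be 'inter' or 'intra', got {self.mode!r}")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_obs(self) -> int:
        """Total observation count Sum k_i (the 'n' of a report row)."""
        return int(sum(len(v) for _, v in self.groups))

    @property
    def error_df(self) -> int:
        """Degrees of freedom of the pooled within-group variance, Sum (k_i - 1)."""
        return int(sum(len(v) - 1 for _, v in self.groups))

    @property
    def n_volunteers(self) -> int:
        if self.mode == "inter":
            return self.n_groups
        return len({key[0] if isinstance(key, tuple) else str(key).split("|")[0] for key, _ in self.groups})

    def values(self) -> np.ndarray:
        """All observations in the set, concatenated."""
        if not self.groups:
            return np.empty(0)
        return np.concatenate([np.asarray(v, dtype=float) for _, v in self.groups])

    def group_sizes(self) -> np.ndarray:
        return np.array([len(v) for _, v in self.groups], dtype=int)


@dataclass
class ValidationReport:
    """Summary of structural checks on a measurement table."""

    n_records: int = 0
    n_volunteers: int = 0
    n_raters: int = 0
    duplicates: list = field(default_factory=list)
    off_grid: list = field(default_factory=list)
    single_rater_volunteers: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.duplicates

    def summary(self) -> str:
        lines = [
            f"records:    {self.n_records}",
            f"volunteers: {self.n_volunteers}",
            f"raters:     {self.n_raters}",
            f"duplicate keys: {len(self.duplicates)}",
            f"off-grid values: {len(self.off_grid)}",
        ]
        for param, vols in sorted(self.single_rater_volunteers.items()):
            if vols:
                lines.append(f"single-rater volunteers ({param}): {len(vols)}")
        lines.extend(self.warnings)
        return "\n".join(lines)


def _normalise_columns(df: pd.DataFrame, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    renames = {c: c.strip().lower() for c in df.columns}
    df = df.rename(columns=renames)
    if column_map:
        df = df.rename(columns={k.strip().lower(): v for k, v in column_map.items()})
    return df


def read_measurements(
    path: str | Path,
    *,
    column_map: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Read a long-format measurement CSV.

    Parameters
    ----------
    path
        CSV file with at least the columns in :data:`REQUIRED_COLUMNS`
        (case-insensitive; ``column_map`` renames non-standard headers,
        mapping input name -> canonical name).

    Returns
    -------
    (records, errors)
        ``records`` is the table of parseable rows with canonical dtypes;
        ``errors`` is a list of ``{"row": <1-based data row>, "reason": ...}``
        for rows that violate the domain (bad round, non-positive or
        non-numeric value, unknown parameter or rater group, negative
        age).  Bad rows are reported, never silently dropped.

    Raises
    ------
    SchemaError
        If the file is empty or a required column is missing.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    raw = _normalise_columns(raw, column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    if raw.empty:
        raise SchemaError(f"{path}: no data rows")

    errors: list[dict] = []
    rows: list[dict] = []
    for idx, row in raw.iterrows():
        rowno = int(idx) + 1  # 1-based data row (header not counted)
        problems: list[str] = []
        rec: dict = {
            "volunteer_id": str(row["volunteer_id"]).strip(),
            "rater_id": str(row["rater_id"]).strip(),
            "rater_group": str(row["rater_group"]).strip().lower(),
            "parameter": str(row["parameter"]).strip().lower(),
        }
        if rec["rater_group"] not in RATER_GROUPS:
            problems.append(f"unknown rater_group {row['rater_group']!r}")
        if rec["parameter"] not in PARAMETERS:
            problems.append(f"unknown parameter {row['parameter']!r}")
        try:
            rnd = int(float(row["round"]))
            if rnd not in (1, 2) or float(row["round"]) != rnd:
                problems.append(f"round must be 1 or 2, got {row['round']!r}")
            rec["round"] = rnd
        except (TypeError, ValueError):
            problems.append(f"unparseable round {row['round']!r}")
        try:
            val = float(row["value"])
            if not np.isfinite(val) or val <= 0:
                problems.append(f"value must be a positive number, got {row['value']!r}")
            rec["value"] = val
        except (TypeError, ValueError):
            problems.append(f"unparseable value {row['value']!r}")
        try:
            age = float(row["age_years"])
            if not np.isfinite(age) or age < 0:
                problems.append(f"age_years must be non-negative, got {row['age_years']!r}")
            rec["age_years"] = age
        except (TypeError, ValueError):
            problems.append(f"unparseable age_years {row['age_years']!r}")
        rec["site_id"] = str(row["site_id"]).strip() if "site_id" in raw.columns and pd.notna(row.get("site_id")) else ""

        if problems:
            errors.append({"row": rowno, "reason": "; ".join(problems)})
        else:
            rows.append(rec)

    records = pd.DataFrame(
        rows,
        columns=["volunteer_id", "rater_id", "rater_group", "parameter", "round", "value", "age_years", "site_id"],
    )
    if not records.empty:
        records["round"] = records["round"].astype(int)
        records["value"] = records["value"].astype(float)
        records["age_years"] = records["age_years"].astype(float)
        records["age_group"] = _assign_age_groups(records["age_years"])
    return records, errors


def write_measurements(records: pd.DataFrame, path: str | Path) -> None:
    """Write a record table back to CSV (round-trips with ``read_measurements``)."""
    cols = [c for c in ("volunteer_id", "rater_id", "rater_group", "parameter", "round", "value", "age_years", "site_id") if c in records.columns]
    records.to_csv(path, index=False, columns=cols)


def ensure_age_groups(records: pd.DataFrame, boundaries: tuple[float, float] = (2.0, 12.0)) -> pd.DataFrame:
    """Return a copy of ``records`` with the ``age_group`` column present."""
    out = records.copy()
    out["age_group"] = _assign_age_groups(out["age_years"], boundaries)
    return out


def validate(records: pd.DataFrame, *, on_duplicate: str = "error") -> tuple[pd.DataFrame, ValidationReport]:
    """Structural validation of a parsed record table.

    Checks performed:

    * at most one record per (volunteer, rater, parameter, round) —
      fatal by default, ``on_duplicate="keep_first"`` keeps the first
      occurrence instead (silently averaging duplicates would bias the
      TEM downward, so averaging is never offered);
    * values on the instrument grid (0.01 kg for weight, 0.1 cm
      otherwise) — off-grid values are *warnings*, since legitimate data
      can leave the grid through unit conversion;
    * volunteers measured by a single rater, listed per parameter and
      rater group (they will be excluded from inter-rater analyses).

    Returns the (possibly deduplicated) table and a :class:`ValidationReport`.
    """
    if on_duplicate not in ("error", "keep_first"):
        raise ValueError("on_duplicate must be 'error' or 'keep_first'")
    report = ValidationReport()
    if records.empty:
        report.warnings.append("empty record table")
        return records, report

    records = ensure_age_groups(records)
    key_cols = ["volunteer_id", "rater_id", "parameter", "round"]
    dup_mask = records.duplicated(subset=key_cols, keep="first")
    if dup_mask.any():
        dups = records.loc[dup_mask, key_cols].to_dict("records")
        report.duplicates = dups
        if on_duplicate == "error":
            raise DuplicateRecordError(
                f"{len(dups)} duplicate (volunteer, rater, parameter, round) record(s); "
                "first: " + repr(dups[0])
            )
        records = records[~dup_mask].copy()
        report.warnings.append(f"kept first of {len(dups)} duplicated record key(s)")

    prec = records["parameter"].map(PRECISION)
    ratio = records["value"] / prec
    off = (ratio - ratio.round()).abs() * prec > _GRID_TOL
    if off.any():
        report.off_grid = records.loc[off, ["volunteer_id", "rater_id", "parameter", "round", "value"]].to_dict("records")
        report.warnings.append(f"{int(off.sum())} value(s) off the instrument precision grid")

    for (param, rg), sub in records[records["round"] == 1].groupby(["parameter", "rater_group"]):
        counts = sub.groupby("volunteer_id")["rater_id"].nunique()
        singles = sorted(counts[counts < 2].index)
        if singles:
            report.single_rater_volunteers[f"{param}/{rg}"] = singles

    report.n_records = len(records)
    report.n_volunteers = records["volunteer_id"].nunique()
    report.n_raters = records["rater_id"].nunique()
    return records, report


def _filter_stratum(records: pd.DataFrame, parameter: str, stratum: Stratum) -> pd.DataFrame:
    if parameter not in PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}")
    sub = records[records["parameter"] == parameter]
    if stratum.rater_group is not None:
        sub = sub[sub["rater_group"] == stratum.rater_group]
    if stratum.age_group is not None:
        if "age_group" not in sub.columns:
            sub = ensure_age_groups(sub)
        sub = sub[sub["age_group"] == stratum.age_group]
    return sub


def build_inter_view(
    records: pd.DataFrame,
    parameter: str,
    stratum: Stratum = Stratum(),
) -> ReplicateGroupSet:
    """Inter-rater replicate groups: per volunteer, round-1 values across raters.

    Volunteers measured by fewer than two distinct raters in the stratum
    are dropped (between-rater agreement is undefined for them); the
    drop is visible through ``n_volunteers`` vs the validation report.
    An empty result is returned as an empty group set, not an error —
    downstream statistics emit undefined markers.
    """
    sub = _filter_stratum(records, parameter, stratum)
    sub = sub[sub["round"] == 1]
    groups: list[tuple[str, np.ndarray]] = []
    for vol, g in sub.sort_values(["volunteer_id", "rater_id"]).groupby("volunteer_id"):
        if g["rater_id"].nunique() < 2:
            continue
        groups.append((str(vol), g["value"].to_numpy(dtype=float)))
    return ReplicateGroupSet(mode="inter", parameter=parameter, stratum=stratum, groups=groups)


def build_intra_view(
    records: pd.DataFrame,
    parameter: str,
    stratum: Stratum = Stratum(),
) -> ReplicateGroupSet:
    """Intra-rater replicate groups: per (volunteer, rater), the two rounds.

    Pairs missing either round are dropped; values are ordered
    [round 1, round 2] so agreement analyses can attach a sign.
    """
    sub = _filter_stratum(records, parameter, stratum)
    groups: list[tuple[tuple[str, str], np.ndarray]] = []
    for (vol, rater), g in sub.sort_values(["volunteer_id", "rater_id", "round"]).groupby(
        ["volunteer_id", "rater_id"]
    ):
        rounds = set(g["round"])
        if rounds != {1, 2}:
            continue
        v1 = float(g.loc[g["round"] == 1, "value"].iloc[0])
        v2 = float(g.loc[g["round"] == 2, "value"].iloc[0])
        groups.append(((str(vol), str(rater)), np.array([v1, v2])))
    return ReplicateGroupSet(mode="intra", parameter=parameter, stratum=stratum, groups=groups)
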