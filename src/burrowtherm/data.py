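"""Domain types and CSV ingestion for field thermoregulation records.

A record is one surface-active crab: its body temperature ``Tb``, the
surface (sediment) temperature ``S`` where it was caught, and — when a
reference burrow reading was taken near in time — the temperature ``B`` at
the bottom of a 30 cm reference burrow.  From ``(Tb, S, B)`` the two
thermoregulation-axes coordinates are derived:

* cooling capacity  ``x = B - S``  (negative: the burrow is cooler), and
* thermoregulation capacity  ``y = Tb - S``  (how far the body is held
  from the surface temperature).

Records missing ``B`` cannot enter the axes analysis but remain usable for
the ``Tb - S`` versus ``S`` regressions; ingestion therefore flags rather
than drops them, and every rejected or flagged row is reason-coded in a
validation report so accepted + flagged + rejected always sums to the
input row count.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Sex",
    "Month",
    "SizeClass",
    "ObservationRecord",
    "ThermoPoint",
    "ValidationIssue",
    "ValidationReport",
    "SIZE_CLASS_BOUNDS",
    "assign_size_class",
    "compute_axes",
    "read_records",
    "records_to_frame",
    "write_records_csv",
    "DEFAULT_COLUMNS",
    "TEMP_WINDOW_C",
]


class Sex(str, enum.Enum):
    female = "female"
    male = "male"


class Month(str, enum.Enum):
    """Sampling months of the field season (spring through fall)."""

    march = "March"
    may = "May"
    august = "August"
    october = "October"

    @classmethod
    def parse(cls, value: str) -> "Month":
        v = str(value).strip().lower()
        # "September" appears as an occasional alias for the fall
        # collection; normalise it to October.
        aliases = {"september": "october", "sep": "october", "oct": "october",
                   "mar": "march", "aug": "august"}
        v = aliases.get(v, v)
        for m in cls:
            if m.value.lower() == v:
                return m
        raise ValueError(f"unknown month {value!r}")


class SizeClass(str, enum.Enum):
    small_female = "small_female"
    large_female = "large_female"
    small_male = "small_male"
    large_male = "large_male"
    out_of_range = "out_of_range"


#: Carapace-width class bounds (mm), closed on both printed endpoints.
#: Calipers read in 0.1 mm increments, so the open gap between e.g. 12.9
#: and 13 is unreachable in practice; widths that nevertheless fall in a
#: gap are assigned to the lower class.
SIZE_CLASS_BOUNDS: dict[SizeClass, tuple[Sex, float, float]] = {
    SizeClass.small_female: (Sex.female, 9.0, 12.9),
    SizeClass.large_female: (Sex.female, 13.0, 17.0),
    SizeClass.small_male: (Sex.male, 10.0, 14.9),
    SizeClass.large_male: (Sex.male, 15.0, 20.0),
}

#: Default plausibility window for all three temperatures (°C).
TEMP_WINDOW_C: tuple[float, float] = (0.0, 60.0)

#: Default CSV column names, overridable through ``read_records(schema=...)``.
DEFAULT_COLUMNS = {
    "crab_id": "crab_id",
    "date": "date",
    "site": "site",
    "sex": "sex",
    "carapace_width_mm": "carapace_width_mm",
    "body_temp_c": "body_temp_c",
    "surface_temp_c": "surface_temp_c",
    "burrow_temp_c": "burrow_temp_c",
    "month": "month",
}

REQUIRED_FIELDS = ("crab_id", "sex", "carapace_width_mm", "body_temp_c",
                   "surface_temp_c", "month")


@dataclass(frozen=True)
class ObservationRecord:
    """One crab's field measurement."""

    crab_id: str
    sex: Sex
    carapace_width_mm: float
    body_temp_c: float
    surface_temp_c: float
    burrow_temp_c: float | None
    month: Month
    site: str = ""

    def __post_init__(self) -> None:
        if not self.carapace_width_mm > 0:
            raise ValueError("carapace width must be positive")

    @property
    def size_class(self) -> SizeClass:
        return assign_size_class(self.sex, self.carapace_width_mm)

    @property
    def has_burrow_reading(self) -> bool:
        return self.burrow_temp_c is not None


@dataclass(frozen=True)
class ThermoPoint:
    """A point on the thermoregulation axes.

    ``cooling_capacity_c`` is x = B - S and ``thermoreg_capacity_c`` is
    y = Tb - S; negative x means the burrow is cooler than the surface.
    """

    cooling_capacity_c: float
    thermoreg_capacity_c: float


@dataclass(frozen=True)
class ValidationIssue:
    row: int
    crab_id: str
    reason: str
    fatal: bool  # fatal rows are rejected; non-fatal rows are kept, flagged


@dataclass
class ValidationReport:
    n_input: int = 0
    n_accepted: int = 0
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return sum(1 for i in self.issues if i.fatal)

    @property
    def n_flagged(self) -> int:
        return sum(1 for i in self.issues if not i.fatal)

    @property
    def ok(self) -> bool:
        return not self.issues

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_accepted": self.n_accepted,
                "n_rejected": self.n_rejected,
                "n_flagged": self.n_flagged,
                "issues": [
                    {"row": i.row, "crab_id": i.crab_id, "reason": i.reason,
                     "rejected": i.fatal}
                    for i in self.issues
                ],
            },
            indent=2,
        )


def assign_size_class(sex: Sex | str, carapace_width_mm: float) -> SizeClass:
    """Assign a crab to one of the four sex-by-size classes.

    Class intervals (mm CW, closed on both endpoints): small females
    9–12.9, large females 13–17, small males 10–14.9, large males 15–20.
    Widths strictly inside the 0.1 mm gap between classes go to the lower
    class; widths outside a sex's full range are ``out_of_range``.
    """
    sex = Sex(sex)
    if not carapace_width_mm > 0:
        raise ValueError("carapace width must be positive")
    w = float(carapace_width_mm)
    if sex is Sex.female:
        small, large = SizeClass.small_female, SizeClass.large_female
    else:
        small, large = SizeClass.small_male, SizeClass.large_male
    _, lo_s, hi_s = SIZE_CLASS_BOUNDS[small]
    _, lo_l, hi_l = SIZE_CLASS_BOUNDS[large]
    if lo_s <= w < lo_l:  # closed small class plus the unreachable gap
        return small
    if lo_l <= w <= hi_l:
        return large
    return SizeClass.out_of_range


def compute_axes(record: ObservationRecord) -> ThermoPoint:
    """Derive (x, y) = (B - S, Tb - S) for one record.

    Raises ``ValueError`` if the burrow temperature is missing: such a
    record cannot enter the thermoregulation-axes analysis (it may still
    enter the Tb - S versus S analysis).
    """
    if record.burrow_temp_c is None:
        raise ValueError(
            f"record {record.crab_id!r} has no burrow reading; it cannot "
            "enter the thermoregulation-axes analysis"
        )
    return ThermoPoint(
        cooling_capacity_c=record.burrow_temp_c - record.surface_temp_c,
        thermoreg_capacity_c=record.body_temp_c - record.surface_temp_c,
    )


def _parse_temp(raw, name: str, window: tuple[float, float]):
    """Return (value_or_None, issue_reason_or_None, fatal)."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None, f"missing {name}", True
    s = str(raw).strip()
    if s == "" or s.upper() in {"NA", "NAN", "NULL", "NONE"}:
        return None, f"missing {name}", True
    try:
        v = float(s)
    except ValueError:
        return None, f"unparseable number in {name}: {s!r}", True
    lo, hi = window
    if not (lo <= v <= hi):
        return v, (f"temperature outside plausibility window "
                   f"[{lo:g}, {hi:g}] in {name}: {v:g}"), True
    return v, None, False


def read_records(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    temp_window: tuple[float, float] = TEMP_WINDOW_C,
) -> tuple[list[ObservationRecord], ValidationReport]:
    """Read field records from CSV with validation.

    Parameters
    ----------
    path
        CSV file with one row per crab.
    schema
        Optional mapping from the canonical field names (keys of
        ``DEFAULT_COLUMNS``) to the column names actually present.
    temp_window
        Plausibility window applied to all temperatures (°C); readings
        outside it reject the row with a reason code.

    Returns
    -------
    (records, report)
        Accepted records and a reason-coded report covering every input
        row that was rejected or flagged.  A missing burrow temperature
        is a flag ("no burrow reading"), not a rejection.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cols = dict(DEFAULT_COLUMNS)
    if schema:
        cols.update(schema)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for fieldname in REQUIRED_FIELDS:
        if cols[fieldname] not in df.columns:
            raise ValueError(
                f"required column {cols[fieldname]!r} (for {fieldname}) "
                f"missing from {path}"
            )
    has_burrow_col = cols["burrow_temp_c"] in df.columns
    has_site_col = cols["site"] in df.columns

    records: list[ObservationRecord] = []
    report = ValidationReport(n_input=len(df))
    for idx, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        crab_id = str(row.get(cols["crab_id"], "")).strip() or f"row{idx}"
        reasons: list[str] = []

        try:
            sex = Sex(str(row[cols["sex"]]).strip().lower())
        except ValueError:
            report.issues.append(ValidationIssue(
                idx, crab_id, f"unknown sex {row[cols['sex']]!r}", True))
            continue
        try:
            month = Month.parse(row[cols["month"]])
        except ValueError as e:
            report.issues.append(ValidationIssue(idx, crab_id, str(e), True))
            continue
        try:
            cw = float(str(row[cols["carapace_width_mm"]]).strip())
            if not cw > 0:
                raise ValueError
        except ValueError:
            report.issues.append(ValidationIssue(
                idx, crab_id,
                f"invalid carapace width {row[cols['carapace_width_mm']]!r}",
                True))
            continue

        tb, reason, fatal = _parse_temp(row[cols["body_temp_c"]],
                                        "body_temp_c", temp_window)
        if fatal:
            report.issues.append(ValidationIssue(idx, crab_id, reason, True))
            continue
        s, reason, fatal = _parse_temp(row[cols["surface_temp_c"]],
                                       "surface_temp_c", temp_window)
        if fatal:
            report.issues.append(ValidationIssue(idx, crab_id, reason, True))
            continue

        b: float | None = None
        if has_burrow_col:
            raw_b = row[cols["burrow_temp_c"]]
            b, reason, fatal = _parse_temp(raw_b, "burrow_temp_c", temp_window)
            if fatal:
                if reason.startswith("missing"):
                    b = None
                    reasons.append("no burrow reading")
                else:
                    report.issues.append(
                        ValidationIssue(idx, crab_id, reason, True))
                    continue
        else:
            reasons.append("no burrow reading")

        site = str(row.get(cols["site"], "")).strip() if has_site_col else ""
        records.append(ObservationRecord(
            crab_id=crab_id, sex=sex, carapace_width_mm=cw,
            body_temp_c=tb, surface_temp_c=s, burrow_temp_c=b,
            month=month, site=site))
        report.n_accepted += 1
        for r in reasons:
            report.issues.append(ValidationIssue(idx, crab_id, r, False))
    return records, report


def records_to_frame(records: Iterable[ObservationRecord]) -> pd.DataFrame:
    """Tabulate records with derived size class and axes coordinates.

    ``cooling_capacity_c`` / ``thermoreg_capacity_c`` are NaN where the
    burrow reading is missing.
    """
    rows = []
    for r in records:
        rows.append({
            "crab_id": r.crab_id,
            "site": r.site,
            "sex": r.sex.value,
            "carapace_width_mm": r.carapace_width_mm,
            "body_temp_c": r.body_temp_c,
            "surface_temp_c": r.surface_temp_c,
            "burrow_temp_c": r.burrow_temp_c,
            "month": r.month.value,
            "size_class": r.size_class.value,
            "thermoreg_capacity_c": r.body_temp_c - r.surface_temp_c,
            "cooling_capacity_c": (
                r.burrow_temp_c - r.surface_temp_c
                if r.burrow_temp_c is not None else float("nan")),
        })
    cols = ["crab_id", "site", "sex", "carapace_width_mm", "body_temp_c",
            "surface_temp_c", "burrow_temp_c", "month", "size_class",
            "thermoreg_capacity_c", "cooling_capacity_c"]
    return pd.DataFrame(rows, columns=cols)


def write_records_csv(records: Sequence[ObservationRecord],
                      path: str | Path) -> None:
    """Write records in the input CSV schema.

    Temperatures are written at 0.1 °C and widths at 0.1 mm, matching the
    probe and caliper increments, so a read/write cycle round-trips
    exactly at the declared precision.
    """
    path = Path(path)
    lines = ["crab_id,site,sex,carapace_width_mm,body_temp_c,"
             "surface_temp_c,burrow_temp_c,month"]
    for r in records:
        b = "" if r.burrow_temp_c is None else f"{r.burrow_temp_c:.1f}"
        lines.append(
            f"{r.crab_id},{r.site},{r.sex.value},{r.carapace_width_mm:.1f},"
            f"{r.body_temp_c:.1f},{r.surface_temp_c:.1f},{b},{r.month.value}")
    path.write_text("\n".join(lines) + "\n")
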