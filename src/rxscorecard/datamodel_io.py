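"""Domain types and CSV readers/writers for the scorecard pipeline.

The pipeline consumes three flat files — an ambulatory opioid prescription
extract, a provider roster, and an opioid conversion-factor table — plus a
run configuration (JSON or YAML).  Readers validate row by row: a row that
violates an invariant is collected into a rejects report with the offending
row number and reason, never silently dropped and never imputed.  Scorecards
are audit artifacts, so conservation holds everywhere:
``accepted rows + rejected rows == input rows``.

Dates are ISO-8601 calendar dates and every time window in the pipeline is
half-open ``[start, end)`` so that quarter partitions of a year are disjoint
and exhaustive.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("rxscorecard")

OPIOID_CLASSES = ("analgesic", "antitussive", "combination")
PROVIDER_ROLES = ("attending", "nurse_practitioner", "physician_assistant", "resident")

PRESCRIPTION_COLUMNS = [
    "rx_id", "patient_id", "prescriber_id", "authorizing_id", "drug_code",
    "units_per_dose", "max_doses_per_day", "quantity_dispensed", "refills",
    "written_date",
]
DRUG_COLUMNS = ["drug_code", "drug_name", "opioid_class", "strength_mg_per_unit", "mme_factor"]
PROVIDER_COLUMNS = ["provider_id", "name", "role", "specialty", "division"]


class SchemaError(ValueError):
    """A file-level problem: missing column, duplicate key, bad header."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DrugEntry:
    """One opioid product: mg of opioid per dispensing unit and its oral-MME factor."""

    drug_code: str
    drug_name: str
    opioid_class: str
    strength_mg_per_unit: float
    mme_factor: float

    def __post_init__(self) -> None:
        if self.opioid_class not in OPIOID_CLASSES:
            raise ValueError(f"unknown opioid_class {self.opioid_class!r}")
        if self.strength_mg_per_unit < 0:
            raise ValueError("strength_mg_per_unit must be >= 0")
        if self.mme_factor < 0:
            raise ValueError("mme_factor must be >= 0")


@dataclass(frozen=True)
class ProviderRecord:
    provider_id: str
    name: str
    role: str
    specialty: str
    division: str

    def __post_init__(self) -> None:
        if self.role not in PROVIDER_ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if not self.specialty or not self.division:
            raise ValueError("specialty and division must be non-empty")


@dataclass(frozen=True)
class PrescriptionRecord:
    """One ambulatory opioid prescription (one row = one prescription).

    The dosage instruction (sig) arrives pre-parsed as
    ``units_per_dose`` x ``max_doses_per_day``; free-text sig parsing is out
    of scope.  ``authorizing_id`` is the supervising provider for orders
    placed by advanced-practice providers or house staff, when one exists.
    """

    rx_id: str
    patient_id: str
    prescriber_id: str
    authorizing_id: str | None
    drug_code: str
    units_per_dose: float
    max_doses_per_day: float
    quantity_dispensed: float
    refills: int
    written_date: dt.date

    def __post_init__(self) -> None:
        if self.quantity_dispensed <= 0:
            raise ValueError("quantity_dispensed must be > 0")
        if self.units_per_dose <= 0:
            raise ValueError("units_per_dose must be > 0")
        if self.max_doses_per_day <= 0:
            raise ValueError("max_doses_per_day must be > 0")
        if self.refills < 0:
            raise ValueError("refills must be >= 0")


@dataclass(frozen=True)
class QuarterWindow:
    """A half-open calendar quarter [start_date, end_date)."""

    start_date: dt.date
    end_date: dt.date
    label: str

    def __post_init__(self) -> None:
        if self.end_date <= self.start_date:
            raise ValueError("end_date must be after start_date")

    def contains(self, day: dt.date) -> bool:
        return self.start_date <= day < self.end_date

    @classmethod
    def from_label(cls, label: str) -> "QuarterWindow":
        """Parse a label like ``2021Q3`` into its calendar window."""
        year, q = int(label[:4]), int(label[5])
        if not 1 <= q <= 4 or label[4] not in "Qq":
            raise ValueError(f"bad quarter label {label!r}")
        start = dt.date(year, 3 * (q - 1) + 1, 1)
        end = dt.date(year + 1, 1, 1) if q == 4 else dt.date(year, 3 * q + 1, 1)
        return cls(start, end, f"{year}Q{q}")


@dataclass
class RunConfig:
    """Tunable policy for one scorecard run.

    Defaults encode the institutional guideline thresholds: acute
    prescriptions should stay at or under a 5-day supply and 50 MEDD, chronic
    patients at or under 90 MEDD; chronic use is >=3 prescriptions in the
    trailing year with one still active; outlier cutoffs are 1.5 x IQR with
    extreme outliers at 3 x the outlier cutoff.
    """

    quarter: str | None = None
    threshold_mode: str = "iqr_multiple"          # or "tukey_fence"
    outlier_k: float = 1.5
    extreme_multiplier: float = 3.0
    metric4_unit: str = "patients"                # or "prescriptions"
    metric5_unit: str = "patients"
    day_supply_threshold: float = 5.0
    medd_acute_threshold: float = 50.0
    medd_chronic_threshold: float = 90.0
    chronic_min_rx: int = 3
    lookback_days: int = 365
    min_group_size: int = 5
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("iqr_multiple", "tukey_fence"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        for unit in (self.metric4_unit, self.metric5_unit):
            if unit not in ("patients", "prescriptions"):
                raise ValueError(f"unknown metric unit {unit!r}")
        for name in ("outlier_k", "extreme_multiplier", "day_supply_threshold",
                     "medd_acute_threshold", "medd_chronic_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.chronic_min_rx < 1 or self.lookback_days < 1:
            raise ValueError("chronic_min_rx and lookback_days must be >= 1")
        if self.min_group_size < 0:
            raise ValueError("min_group_size must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if data is None:
            data = {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ReadResult:
    """Accepted records plus a row-level rejects report (conservation holds)."""

    records: list
    rejects: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["row", "rx_id", "reason"]))

    @property
    def frame(self) -> pd.DataFrame:
        """Accepted records as a DataFrame (written_date as datetime64)."""
        if not self.records:
            return pd.DataFrame(columns=PRESCRIPTION_COLUMNS)
        df = pd.DataFrame([dataclasses.asdict(r) for r in self.records])
        if "written_date" in df.columns:
            df["written_date"] = pd.to_datetime(df["written_date"])
        return df


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _check_header(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def read_drug_table(path: str | Path) -> dict[str, DrugEntry]:
    """Read the conversion-factor table; returns a lookup keyed by drug_code.

    Duplicate codes and negative factors are fatal: silently resolving either
    would corrupt every downstream MEDD.
    """
    df = pd.read_csv(path, dtype=str, comment="#")
    _check_header(df, DRUG_COLUMNS, "drug table")
    if df.empty:
        logger.warning("drug table %s is empty", path)
        return {}
    dupes = df["drug_code"][df["drug_code"].duplicated()].unique().tolist()
    if dupes:
        raise SchemaError(f"duplicate drug_code(s): {dupes}")
    table: dict[str, DrugEntry] = {}
    for _, row in df.iterrows():
        try:
            entry = DrugEntry(
                drug_code=row["drug_code"],
                drug_name=row["drug_name"],
                opioid_class=row["opioid_class"],
                strength_mg_per_unit=float(row["strength_mg_per_unit"]),
                mme_factor=float(row["mme_factor"]),
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"drug {row['drug_code']!r}: {exc}") from exc
        table[entry.drug_code] = entry
    return table


def read_providers(path: str | Path) -> dict[str, ProviderRecord]:
    """Read the provider roster, keyed by provider_id; duplicates are fatal."""
    df = pd.read_csv(path, dtype=str, comment="#").fillna("")
    _check_header(df, PROVIDER_COLUMNS, "provider roster")
    dupes = df["provider_id"][df["provider_id"].duplicated()].unique().tolist()
    if dupes:
        raise SchemaError(f"duplicate provider_id(s): {dupes}")
    roster: dict[str, ProviderRecord] = {}
    for i, row in df.iterrows():
        try:
            rec = ProviderRecord(row["provider_id"], row["name"], row["role"],
                                 row["specialty"], row["division"])
        except ValueError as exc:
            raise SchemaError(f"provider row {i}: {exc}") from exc
        roster[rec.provider_id] = rec
    return roster


def read_prescriptions(path: str | Path, drug_table: Mapping[str, DrugEntry]) -> ReadResult:
    """Read the prescription extract, validating each row.

    Rows with an unparseable number/date, a violated invariant, or a
    drug_code absent from ``drug_table`` land in the rejects report with a
    reason; the header must match the documented schema exactly or the read
    fails outright.
    """
    df = pd.read_csv(path, dtype=str, comment="#")
    _check_header(df, PRESCRIPTION_COLUMNS, "prescriptions")
    records: list[PrescriptionRecord] = []
    rejects: list[dict] = []
    for i, row in df.iterrows():
        rx_id = row["rx_id"]
        try:
            drug_code = row["drug_code"]
            if pd.isna(drug_code) or drug_code not in drug_table:
                raise ValueError("unresolvable drug_code")
            auth = row["authorizing_id"]
            auth = None if (pd.isna(auth) or auth == "") else str(auth)
            rec = PrescriptionRecord(
                rx_id=str(rx_id),
                patient_id=str(row["patient_id"]),
                prescriber_id=str(row["prescriber_id"]),
                authorizing_id=auth,
                drug_code=str(drug_code),
                units_per_dose=float(row["units_per_dose"]),
                max_doses_per_day=float(row["max_doses_per_day"]),
                quantity_dispensed=float(row["quantity_dispensed"]),
                refills=int(row["refills"]),
                written_date=dt.date.fromisoformat(str(row["written_date"])),
            )
        except (ValueError, TypeError) as exc:
            rejects.append({"row": int(i), "rx_id": rx_id, "reason": str(exc)})
            continue
        records.append(rec)
    rej = pd.DataFrame(rejects, columns=["row", "rx_id", "reason"])
    if len(rej):
        logger.warning("prescriptions %s: %d row(s) rejected", path, len(rej))
    assert len(records) + len(rej) == len(df)
    return ReadResult(records=records, rejects=rej)


# ---------------------------------------------------------------------------
# Writers (round-trip partners of the readers)
# ---------------------------------------------------------------------------

def write_prescriptions(records: Iterable[PrescriptionRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d["authorizing_id"] = d["authorizing_id"] or ""
        d["written_date"] = r.written_date.isoformat()
        rows.append(d)
    pd.DataFrame(rows, columns=PRESCRIPTION_COLUMNS).to_csv(path, index=False)


def write_drug_table(entries: Iterable[DrugEntry], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(e) for e in entries],
                 columns=DRUG_COLUMNS).to_csv(path, index=False)


def write_providers(records: Iterable[ProviderRecord], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records],
                 columns=PROVIDER_COLUMNS).to_csv(path, index=False)


def bundled_drug_table_path() -> Path:
    """Path of the versioned oral-MME conversion table shipped with the package."""
    return Path(__file__).parent / "data" / "drugs.csv"
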