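"""Prescriber eligibility, attribution, chronic-use registry, quarter windows.

Attribution: a prescription counts toward the *authorizing* provider when one
exists (orders placed by advanced-practice providers or house staff under a
supervising physician), otherwise toward the ordering prescriber.

Eligibility: a provider enters a quarter's scorecard population iff they have
at least one attributed opioid prescription in the trailing 12 months; they
then appear even with zero in-quarter prescriptions.

Chronic-use registry: a patient is on the registry as of a date iff they have
>= ``chronic_min_rx`` opioid prescriptions in the trailing year *and* at
least one of those is still active.  "Active" means
``written_date + ceil(day_supply x (refills + 1)) >= as_of_date`` — the most
inclusive defensible reading, since renewals extend the period a patient is
plausibly still taking the drug.  A prescription's own chronic/nonchronic
label is evaluated on the day it was written with itself excluded from the
count, so a prescription can never flip its own patient's class.

All trailing windows are half-open ``(as_of - lookback, as_of]``, matching
the half-open quarter convention.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datamodel_io import PrescriptionRecord, QuarterWindow, RunConfig


@dataclass(frozen=True)
class RegistrySnapshot:
    as_of_date: dt.date
    chronic_patient_ids: frozenset


# ---------------------------------------------------------------------------
# Attribution
# ---------------------------------------------------------------------------

def attribute(rx: PrescriptionRecord) -> str:
    """Provider a prescription counts toward: authorizer if present, else prescriber."""
    return rx.authorizing_id if rx.authorizing_id else rx.prescriber_id


def attribute_series(rx_frame: pd.DataFrame) -> pd.Series:
    """Vectorized attribution over a prescription frame."""
    auth = rx_frame["authorizing_id"]
    blank = auth.isna() | (auth == "")
    return auth.where(~blank, rx_frame["prescriber_id"])


# ---------------------------------------------------------------------------
# Eligibility
# ---------------------------------------------------------------------------

def eligible_prescribers(rx_frame: pd.DataFrame, as_of_date: dt.date,
                         lookback_days: int = 365) -> set[str]:
    """Providers with >=1 attributed prescription in (as_of - lookback, as_of]."""
    if rx_frame.empty:
        return set()
    dates = pd.to_datetime(rx_frame["written_date"])
    as_of = pd.Timestamp(as_of_date)
    lo = as_of - pd.Timedelta(days=lookback_days)
    in_window = (dates > lo) & (dates <= as_of)
    return set(attribute_series(rx_frame[in_window]))


# ---------------------------------------------------------------------------
# Chronic-use registry
# ---------------------------------------------------------------------------

def _active_end_days(dates_d: np.ndarray, day_supply: np.ndarray,
                     refills: np.ndarray) -> np.ndarray:
    """Last day (ordinal) each prescription is considered active."""
    return dates_d + np.ceil(day_supply * (refills + 1)).astype(np.int64)


def chronic_registry(rx_frame: pd.DataFrame, derived: pd.DataFrame,
                     as_of_date: dt.date, config: RunConfig) -> RegistrySnapshot:
    """Snapshot of the chronic-opioid-use registry on ``as_of_date``."""
    if rx_frame.empty:
        return RegistrySnapshot(as_of_date, frozenset())
    dates = pd.to_datetime(rx_frame["written_date"])
    as_of = pd.Timestamp(as_of_date)
    lo = as_of - pd.Timedelta(days=config.lookback_days)
    in_window = (dates > lo) & (dates <= as_of)
    sub = rx_frame[in_window]
    if sub.empty:
        return RegistrySnapshot(as_of_date, frozenset())
    d = dates[in_window].values.astype("datetime64[D]").astype(np.int64)
    active_end = _active_end_days(
        d,
        derived.loc[sub.index, "day_supply"].to_numpy(float),
        sub["refills"].to_numpy(np.int64),
    )
    as_of_d = np.datetime64(as_of_date, "D").astype(np.int64)
    tab = pd.DataFrame({
        "patient_id": sub["patient_id"].to_numpy(),
        "active": active_end >= as_of_d,
    })
    g = tab.groupby("patient_id")["active"].agg(["count", "any"])
    chronic = g.index[(g["count"] >= config.chronic_min_rx) & g["any"]]
    return RegistrySnapshot(as_of_date, frozenset(chronic))


def classify_rx_chronicity(rx: PrescriptionRecord, registry: RegistrySnapshot) -> str:
    """Label one prescription by its patient's registry status when written."""
    return "chronic" if rx.patient_id in registry.chronic_patient_ids else "nonchronic"


def label_chronicity(rx_frame: pd.DataFrame, derived: pd.DataFrame,
                     config: RunConfig) -> pd.Series:
    """Chronic/nonchronic label for every prescription, evaluated at its own
    written date with the prescription itself excluded from the count.

    Returns a Series aligned with ``rx_frame`` holding "chronic"/"nonchronic".
    """
    labels = pd.Series("nonchronic", index=rx_frame.index, dtype=object)
    if rx_frame.empty:
        return labels
    dates_d = pd.to_datetime(rx_frame["written_date"]).values \
        .astype("datetime64[D]").astype(np.int64)
    active_end = _active_end_days(
        dates_d,
        derived["day_supply"].to_numpy(float),
        rx_frame["refills"].to_numpy(np.int64),
    )
    lb = config.lookback_days
    need = config.chronic_min_rx
    for _, idx in rx_frame.groupby("patient_id", sort=False).indices.items():
        if len(idx) <= need:           # self excluded: can never reach the count
            continue
        d = dates_d[idx]
        ae = active_end[idx]
        # pairwise: rx j is in rx i's trailing window, excluding i itself
        in_win = (d[None, :] > d[:, None] - lb) & (d[None, :] <= d[:, None])
        np.fill_diagonal(in_win, False)
        counts = in_win.sum(axis=1)
        any_active = (in_win & (ae[None, :] >= d[:, None])).any(axis=1)
        chronic = (counts >= need) & any_active
        labels.iloc[idx[chronic]] = "chronic"
    return labels


# ---------------------------------------------------------------------------
# Quarter windows
# ---------------------------------------------------------------------------

def quarter_windows(years: int | Iterable[int]) -> list[QuarterWindow]:
    """Calendar-quarter windows for the given year(s): disjoint, exhaustive."""
    if isinstance(years, int):
        years = [years]
    return [QuarterWindow.from_label(f"{y}Q{q}") for y in years for q in (1, 2, 3, 4)]


def window_mask(rx_frame: pd.DataFrame, window: QuarterWindow) -> pd.Series:
    """Boolean mask of prescriptions written inside a half-open window."""
    dates = pd.to_datetime(rx_frame["written_date"])
    return (dates >= pd.Timestamp(window.start_date)) & (dates < pd.Timestamp(window.end_date))
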