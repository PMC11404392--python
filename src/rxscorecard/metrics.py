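"""The five per-provider, per-quarter scorecard metrics.

For each eligible provider in a calendar quarter:

* ``m1_rx_count`` — total attributed opioid prescriptions;
* ``m2_patient_count`` — distinct patients prescribed to;
* ``m3_gt5day`` — prescriptions to nonchronic patients with a calculated day
  supply strictly greater than the 5-day guideline;
* ``m4_gt50medd`` — nonchronic patients (default unit; prescriptions by
  config) with MEDD strictly greater than 50;
* ``m5_gt90medd`` — chronic patients (default unit) with MEDD strictly
  greater than 90.

Providers eligible through the 12-month lookback but silent in the quarter
get an explicit zero row: the peer distribution a threshold is computed from
must include non-prescribers.  Metrics are not mutually exclusive — one
prescription may count toward several.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import pandas as pd

from .cohort import attribute_series, eligible_prescribers, window_mask
from .datamodel_io import QuarterWindow, RunConfig

METRIC_NAMES = ["m1_rx_count", "m2_patient_count", "m3_gt5day",
                "m4_gt50medd", "m5_gt90medd"]

METRICS_COLUMNS = ["provider_id", "quarter"] + METRIC_NAMES


@dataclass
class MetricsResult:
    """Per-provider metric table plus rejected (unattributable) prescriptions."""

    table: pd.DataFrame
    rejects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["rx_id", "provider_id", "reason"]))


def _unit_count(sub: pd.DataFrame, unit: str) -> pd.Series:
    """Count qualifying rows per provider in patients or prescriptions."""
    if unit == "patients":
        return sub.groupby("attributed")["patient_id"].nunique()
    return sub.groupby("attributed").size()


def compute_metrics(rx_frame: pd.DataFrame, derived: pd.DataFrame,
                    chronicity: pd.Series, quarter: QuarterWindow,
                    config: RunConfig, eligible: set[str] | None = None,
                    roster: dict | None = None) -> MetricsResult:
    """Compute ProviderQuarterMetrics for every eligible provider.

    Parameters
    ----------
    rx_frame
        Full prescription history (may extend beyond the quarter; the
        lookback needs it).  Filtered to ``quarter`` internally.
    derived, chronicity
        Row-aligned outputs of :func:`rxscorecard.opioid_math.derive_frame`
        and :func:`rxscorecard.cohort.label_chronicity` on ``rx_frame``.
    eligible
        Provider population to report on.  Defaults to the 12-month trailing
        eligibility rule evaluated at the quarter's last day.
    roster
        Optional provider roster; attributed ids absent from it are moved to
        the rejects report rather than silently kept.
    """
    if eligible is None:
        as_of = quarter.end_date - dt.timedelta(days=1)
        eligible = eligible_prescribers(rx_frame, as_of, config.lookback_days)

    mask = window_mask(rx_frame, quarter)
    sub = rx_frame[mask].copy()
    sub["attributed"] = attribute_series(sub)
    sub["day_supply"] = derived.loc[sub.index, "day_supply"]
    sub["medd"] = derived.loc[sub.index, "medd"]
    sub["gt5day"] = derived.loc[sub.index, "exceeds_day_threshold"]
    sub["gt50"] = derived.loc[sub.index, "exceeds_acute_medd"]
    sub["gt90"] = derived.loc[sub.index, "exceeds_chronic_medd"]
    sub["chronic"] = chronicity.loc[sub.index] == "chronic"

    rejects = pd.DataFrame(columns=["rx_id", "provider_id", "reason"])
    if roster is not None:
        unknown = ~sub["attributed"].isin(roster)
        if unknown.any():
            rejects = pd.DataFrame({
                "rx_id": sub.loc[unknown, "rx_id"],
                "provider_id": sub.loc[unknown, "attributed"],
                "reason": "attributed to unknown provider",
            }).reset_index(drop=True)
            sub = sub[~unknown]

    providers = sorted(eligible)
    out = pd.DataFrame({"provider_id": providers})
    out["quarter"] = quarter.label

    m1 = sub.groupby("attributed").size()
    m2 = sub.groupby("attributed")["patient_id"].nunique()
    m3 = sub[~sub["chronic"] & sub["gt5day"]].groupby("attributed").size()
    m4 = _unit_count(sub[~sub["chronic"] & sub["gt50"]], config.metric4_unit)
    m5 = _unit_count(sub[sub["chronic"] & sub["gt90"]], config.metric5_unit)
    for name, series in zip(METRIC_NAMES, (m1, m2, m3, m4, m5)):
        out[name] = out["provider_id"].map(series).fillna(0).astype(int)

    table = out[METRICS_COLUMNS]
    _check_invariants(table, config)
    return MetricsResult(table=table, rejects=rejects)


def _check_invariants(table: pd.DataFrame, config: RunConfig) -> None:
    if (table[METRIC_NAMES] < 0).any().any():
        raise AssertionError("negative metric count")
    if (table["m2_patient_count"] > table["m1_rx_count"]).any():
        raise AssertionError("m2 > m1")
    if (table["m3_gt5day"] > table["m1_rx_count"]).any():
        raise AssertionError("m3 > m1")
    if config.metric4_unit == "patients" and \
            (table["m4_gt50medd"] > table["m2_patient_count"]).any():
        raise AssertionError("patient-unit m4 > m2")
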