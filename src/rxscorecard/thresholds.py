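"""Per-(division, specialty) peer distributions, outlier thresholds, flags.

Each quarter, for every metric, the distribution of provider values within a
(division, specialty) peer group is summarized by its quartiles.  The
outlier threshold is, by default, the literal ``outlier_k x IQR`` (the
institutional rule as stated); ``tukey_fence`` mode gives the conventional
``q3 + outlier_k x IQR`` upper fence instead, since the two readings cannot
be distinguished from the rule's wording.  The extreme-outlier threshold is
``extreme_multiplier x outlier_threshold`` (default 3x), feeding the
chief-medical-officer report.

Quantiles use linear interpolation between closest ranks (numpy's default),
pinned so that thresholds are reproducible across implementations.  All
comparisons are strict ``>``: a provider sitting exactly on a threshold is
within.  Groups smaller than ``min_group_size`` still get thresholds but
carry ``low_n_flag`` — small peer groups make noisy fences, and suppressing
them would hide providers from audit entirely.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel_io import ProviderRecord, RunConfig
from .metrics import METRIC_NAMES

THRESHOLD_COLUMNS = ["division", "specialty", "metric", "n_providers",
                     "q1", "median", "q3", "iqr",
                     "outlier_threshold", "extreme_threshold", "low_n_flag"]

FLAG_COLUMNS = ["provider_id", "quarter", "division", "specialty", "metric",
                "value", "outlier_threshold", "extreme_threshold", "status"]

STATUSES = ("within", "outlier", "extreme_outlier")


def quartiles(values: Sequence[float]) -> tuple[float, float, float]:
    """(q1, median, q3) by linear interpolation; errors on empty input."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("quartiles of an empty sequence")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method="linear")
    return float(q1), float(med), float(q3)


def _attach_groups(metrics: pd.DataFrame,
                   roster: Mapping[str, ProviderRecord]) -> pd.DataFrame:
    df = metrics.copy()
    df["division"] = df["provider_id"].map(
        {p: r.division for p, r in roster.items()})
    df["specialty"] = df["provider_id"].map(
        {p: r.specialty for p, r in roster.items()})
    if df["division"].isna().any() or df["specialty"].isna().any():
        bad = df.loc[df["division"].isna() | df["specialty"].isna(),
                     "provider_id"].tolist()
        raise KeyError(f"provider(s) missing from roster: {bad}")
    return df


def compute_thresholds(metrics: pd.DataFrame,
                       roster: Mapping[str, ProviderRecord],
                       config: RunConfig) -> pd.DataFrame:
    """ThresholdSet rows for every (division, specialty, metric).

    ``metrics`` must already contain the zero rows for eligible
    non-prescribers; they are part of the peer distribution.
    """
    df = _attach_groups(metrics, roster)
    rows = []
    for (division, specialty), grp in df.groupby(["division", "specialty"], sort=True):
        n = len(grp)
        for metric in METRIC_NAMES:
            q1, med, q3 = quartiles(grp[metric].to_numpy())
            iqr = q3 - q1
            if config.threshold_mode == "iqr_multiple":
                thr = config.outlier_k * iqr
            else:  # tukey_fence
                thr = q3 + config.outlier_k * iqr
            rows.append({
                "division": division, "specialty": specialty, "metric": metric,
                "n_providers": n, "q1": q1, "median": med, "q3": q3, "iqr": iqr,
                "outlier_threshold": thr,
                "extreme_threshold": config.extreme_multiplier * thr,
                "low_n_flag": n < config.min_group_size,
            })
    return pd.DataFrame(rows, columns=THRESHOLD_COLUMNS)


def status_of(value: float, outlier_threshold: float,
              extreme_threshold: float) -> str:
    """Strict-inequality status of one value against its thresholds."""
    if value > extreme_threshold:
        return "extreme_outlier"
    if value > outlier_threshold:
        return "outlier"
    return "within"


def flag_providers(metrics: pd.DataFrame, thresholds: pd.DataFrame,
                   roster: Mapping[str, ProviderRecord]) -> pd.DataFrame:
    """Long-form OutlierAssessment: one row per provider per metric.

    ``status`` is the highest category whose threshold the value strictly
    exceeds; ``extreme_outlier`` implies outlier.
    """
    df = _attach_groups(metrics, roster)
    long = df.melt(
        id_vars=["provider_id", "quarter", "division", "specialty"],
        value_vars=METRIC_NAMES, var_name="metric", value_name="value")
    merged = long.merge(
        thresholds[["division", "specialty", "metric",
                    "outlier_threshold", "extreme_threshold"]],
        on=["division", "specialty", "metric"], how="left", validate="m:1")
    if merged["outlier_threshold"].isna().any():
        bad = merged.loc[merged["outlier_threshold"].isna(),
                         "provider_id"].unique().tolist()
        raise KeyError(f"no threshold group for provider(s): {bad}")
    merged["status"] = np.select(
        [merged["value"] > merged["extreme_threshold"],
         merged["value"] > merged["outlier_threshold"]],
        ["extreme_outlier", "outlier"], default="within")
    merged = merged.sort_values(["provider_id", "metric"]).reset_index(drop=True)
    return merged[FLAG_COLUMNS]


def any_outlier(flags: pd.DataFrame) -> pd.Series:
    """Per-provider boolean: outlier (or extreme) on at least one metric."""
    return (flags["status"] != "within").groupby(flags["provider_id"]).any()
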