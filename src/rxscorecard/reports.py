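"""The three report tiers: provider scorecard, leadership scorecard, CMO report.

* **Provider scorecard** — one per eligible provider: each of the five
  metrics as a panel holding the provider's value, the specialty median, the
  outlier threshold, and a status/color key (``outlier`` vs ``consistent``;
  the median bar is its own key).  Values are copied from the upstream metric
  and flag tables, never recomputed here.
* **Leadership scorecard** — one per (division, specialty): per metric, the
  partition *included = zero-prescribers + within + outliers*, a top-15
  ranked provider list (value descending, ties broken by provider_id), a
  status-coded scatter series, and a histogram (Freedman–Diaconis bins with
  a floor of 5).
* **CMO report** — tabular, per division plus an enterprise roll-up: one row
  per provider who is an extreme outlier on at least one metric (optionally
  every outlier), sorted by how far the provider sits above their thresholds.

Rendering to JSON/CSV is deterministic and byte-stable; chart PNGs (bar /
scatter / histogram) are best-effort extras and excluded from any
bit-exactness contract.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel_io import ProviderRecord, RunConfig
from .metrics import METRIC_NAMES


@dataclass
class ProviderScorecard:
    provider_id: str
    quarter: str
    panels: list  # one dict per metric

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class LeadershipScorecard:
    division: str
    specialty: str
    quarter: str
    metric_pages: list

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class CmoReport:
    scope: str  # division name or "enterprise"
    quarter: str
    rows: list

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ScorecardBundle:
    quarter: str
    config: dict
    provider_scorecards: list
    leadership_scorecards: list
    cmo_reports: list


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def build_provider_scorecards(metrics: pd.DataFrame, thresholds: pd.DataFrame,
                              flags: pd.DataFrame, quarter: str) -> list[ProviderScorecard]:
    """One scorecard per provider present in ``metrics``; values copied from flags."""
    med = thresholds.set_index(["division", "specialty", "metric"])["median"]
    cards = []
    for pid, grp in flags.groupby("provider_id", sort=True):
        panels = []
        for _, row in grp.sort_values("metric").iterrows():
            panels.append({
                "metric": row["metric"],
                "value": float(row["value"]),
                "specialty_median": float(
                    med.loc[(row["division"], row["specialty"], row["metric"])]),
                "outlier_threshold": float(row["outlier_threshold"]),
                "status": row["status"],
                "color": "consistent" if row["status"] == "within" else "outlier",
            })
        if len(panels) != len(METRIC_NAMES):
            raise AssertionError(f"provider {pid}: expected "
                                 f"{len(METRIC_NAMES)} panels, got {len(panels)}")
        cards.append(ProviderScorecard(provider_id=pid, quarter=quarter, panels=panels))
    return cards


def _histogram(values: np.ndarray) -> tuple[list, list]:
    """Freedman–Diaconis bins with a floor of 5."""
    edges = np.histogram_bin_edges(values, bins="fd")
    if len(edges) - 1 < 5:
        edges = np.histogram_bin_edges(values, bins=5)
    counts, edges = np.histogram(values, bins=edges)
    return edges.tolist(), counts.tolist()


def build_leadership_scorecard(division: str, specialty: str,
                               metrics: pd.DataFrame, flags: pd.DataFrame,
                               roster: Mapping[str, ProviderRecord],
                               quarter: str, top_n: int = 15) -> LeadershipScorecard:
    grp_flags = flags[(flags["division"] == division)
                      & (flags["specialty"] == specialty)]
    if grp_flags.empty:
        raise KeyError(f"no providers for {division}/{specialty}")
    pids = grp_flags["provider_id"].unique()
    m = metrics.set_index("provider_id").loc[pids]
    zero = set(m.index[m["m1_rx_count"] == 0])

    pages = []
    for metric in METRIC_NAMES:
        mf = grp_flags[grp_flags["metric"] == metric].set_index("provider_id")
        n_included = len(mf)
        n_zero = len(zero)
        n_outlier = int((mf["status"] != "within").sum())
        n_within = n_included - n_zero - n_outlier
        ranked = mf.sort_values(["value", "provider_id"],
                                ascending=[False, True], kind="mergesort")
        top = [{
            "provider_id": pid,
            "name": roster[pid].name if pid in roster else pid,
            "value": float(row["value"]),
            "status": row["status"],
        } for pid, row in ranked.head(top_n).iterrows()]
        scatter = [{"provider_id": pid, "value": float(row["value"]),
                    "status": row["status"]}
                   for pid, row in mf.sort_index().iterrows()]
        edges, counts = _histogram(mf["value"].to_numpy(float))
        if sum(counts) != n_included:
            raise AssertionError("histogram counts do not sum to n_included")
        pages.append({
            "metric": metric,
            "n_included": n_included,
            "n_zero_prescribers": n_zero,
            "n_within": n_within,
            "n_outlier": n_outlier,
            "outlier_threshold": float(mf["outlier_threshold"].iloc[0]),
            "top_prescribers": top,
            "scatter": scatter,
            "histogram": {"bin_edges": edges, "counts": counts},
        })
    return LeadershipScorecard(division=division, specialty=specialty,
                               quarter=quarter, metric_pages=pages)


def build_all_leadership_scorecards(metrics: pd.DataFrame, flags: pd.DataFrame,
                                    roster: Mapping[str, ProviderRecord],
                                    quarter: str) -> list[LeadershipScorecard]:
    groups = flags[["division", "specialty"]].drop_duplicates().sort_values(
        ["division", "specialty"])
    return [build_leadership_scorecard(d, s, metrics, flags, roster, quarter)
            for d, s in groups.itertuples(index=False)]


def build_cmo_report(flags: pd.DataFrame, metrics: pd.DataFrame,
                     thresholds: pd.DataFrame, scope: str, quarter: str,
                     roster: Mapping[str, ProviderRecord],
                     include_all_outliers: bool = False) -> CmoReport:
    """Extreme-outlier table for one division, or for the whole enterprise.

    The division filter is applied before the extreme filter, so the
    enterprise report's rows are exactly the union of the division reports'.
    """
    f = flags if scope == "enterprise" else flags[flags["division"] == scope]
    wanted = ("outlier", "extreme_outlier") if include_all_outliers \
        else ("extreme_outlier",)
    hit_pids = f.loc[f["status"].isin(wanted), "provider_id"].unique()

    rows = []
    for pid in hit_pids:
        sub = f[f["provider_id"] == pid].set_index("metric")
        ratios = []
        per_metric = {}
        for metric in METRIC_NAMES:
            row = sub.loc[metric]
            thr = float(row["outlier_threshold"])
            val = float(row["value"])
            ratio = val / thr if thr > 0 else (np.inf if val > 0 else 0.0)
            ratios.append(ratio)
            per_metric[metric] = {
                "value": val,
                "outlier_threshold": thr,
                "extreme_threshold": float(row["extreme_threshold"]),
                "status": row["status"],
            }
        rows.append({
            "provider_id": pid,
            "name": roster[pid].name if pid in roster else pid,
            "division": sub["division"].iloc[0],
            "specialty": sub["specialty"].iloc[0],
            "max_ratio": float(max(ratios)),
            "metrics": per_metric,
        })
    rows.sort(key=lambda r: (-r["max_ratio"], r["provider_id"]))
    return CmoReport(scope=scope, quarter=quarter, rows=rows)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _json_dump(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True,
                               allow_nan=False) + "\n")


def _cmo_csv(report: CmoReport, path: Path) -> None:
    rows = []
    for r in report.rows:
        flat = {"provider_id": r["provider_id"], "name": r["name"],
                "division": r["division"], "specialty": r["specialty"],
                "max_ratio": r["max_ratio"]}
        for metric, d in r["metrics"].items():
            flat[f"{metric}"] = d["value"]
            flat[f"{metric}_outlier_threshold"] = d["outlier_threshold"]
            flat[f"{metric}_extreme_threshold"] = d["extreme_threshold"]
            flat[f"{metric}_status"] = d["status"]
        rows.append(flat)
    cols = ["provider_id", "name", "division", "specialty", "max_ratio"]
    for metric in METRIC_NAMES:
        cols += [metric, f"{metric}_outlier_threshold",
                 f"{metric}_extreme_threshold", f"{metric}_status"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def render(bundle: ScorecardBundle, out_dir: str | Path,
           charts: bool = False) -> list[Path]:
    """Write the bundle under ``out_dir/<quarter>/``; returns written paths."""
    base = Path(out_dir) / bundle.quarter
    written: list[Path] = []

    pdir = base / "providers"
    pdir.mkdir(parents=True, exist_ok=True)
    for card in bundle.provider_scorecards:
        path = pdir / f"{card.provider_id}.json"
        _json_dump(card.to_dict(), path)
        written.append(path)

    ldir = base / "leadership"
    ldir.mkdir(parents=True, exist_ok=True)
    for sc in bundle.leadership_scorecards:
        path = ldir / f"{sc.division}__{sc.specialty}.json"
        _json_dump(sc.to_dict(), path)
        written.append(path)
        if charts:
            _leadership_charts(sc, ldir)

    cdir = base / "cmo"
    cdir.mkdir(parents=True, exist_ok=True)
    for rep in bundle.cmo_reports:
        path = cdir / f"{rep.scope}.csv"
        _cmo_csv(rep, path)
        written.append(path)

    _json_dump({"quarter": bundle.quarter, "config": bundle.config},
               base / "manifest_config.json")
    written.append(base / "manifest_config.json")
    return written


def _leadership_charts(sc: LeadershipScorecard, out_dir: Path) -> None:
    """Best-effort top-15 bar / scatter / histogram PNGs for one specialty."""
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:  # charts are optional
        return
    for page in sc.metric_pages:
        fig, axes = plt.subplots(1, 3, figsize=(13, 3.5))
        top = page["top_prescribers"]
        colors = ["navy" if t["status"] != "within" else "teal" for t in top]
        axes[0].bar([t["name"] for t in top], [t["value"] for t in top], color=colors)
        axes[0].axhline(page["outlier_threshold"], color="gray", ls="--")
        axes[0].tick_params(axis="x", rotation=90, labelsize=5)
        axes[0].set_title(f"top prescribers — {page['metric']}", fontsize=8)
        pts = page["scatter"]
        axes[1].scatter(range(len(pts)), [p["value"] for p in pts],
                        c=["navy" if p["status"] != "within" else "teal" for p in pts],
                        s=8)
        axes[1].axhline(page["outlier_threshold"], color="gray", ls="--")
        axes[1].set_title("all providers", fontsize=8)
        h = page["histogram"]
        axes[2].stairs(h["counts"], h["bin_edges"], fill=True, color="teal")
        axes[2].set_title("distribution", fontsize=8)
        fig.tight_layout()
        fig.savefig(out_dir / f"{sc.division}__{sc.specialty}__{page['metric']}.png",
                    dpi=90)
        plt.close(fig)
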