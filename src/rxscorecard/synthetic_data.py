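"""Seeded generator of multi-division prescription datasets with ground truth.

The generator emulates the population the scorecard was built for: a
hospital enterprise of a few divisions and tens of specialties, a couple of
thousand active opioid prescribers with strongly right-skewed prescribing
volumes, a small minority of genuinely inflated prescribers, a chronic-use
patient minority, and (optionally) a slow multiplicative quarterly decline
in volume.

Mechanics, per provider and quarter:

* a latent quarterly rate is drawn log-normally per provider (specialty
  scale x provider heterogeneity); injected outlier providers get the rate
  multiplied by ``outlier_rate_multiplier``;
* the realized count is negative-binomial around that rate (Gamma-Poisson
  mixture, dispersion ``nb_dispersion``) — overdispersion and a heavy right
  tail are the phenomenon the scorecard targets, so the generator must
  produce them;
* each prescription lands on a chronic-pool patient with probability
  ``chronic_rx_fraction`` (chronic patients draw from a small per-specialty
  pool and carry refills, so they accumulate >=3 active prescriptions per
  year by construction) or on a fresh nonchronic patient otherwise;
* dose and duration are chosen from a small formulary lookup so that the
  configured fractions of prescriptions exceed the 5-day / 50-MEDD /
  90-MEDD guideline thresholds.

``truth.csv`` labels the injected outlier providers and chronic-pool
patients; it is the contract between generator and tests, and pipeline code
never reads it.

The module also ships :func:`generate_worked_fixture`, a 21-prescription
hand-auditable dataset covering every flag boundary (exactly 5.0 days,
exactly 50 MEDD, chronicity on the third prescription, a zero-prescriber, an
extreme outlier) together with its hand-computed expected metric table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel_io import (DRUG_COLUMNS, PRESCRIPTION_COLUMNS, PROVIDER_COLUMNS,
                           bundled_drug_table_path)

DIVISION_NAMES = ["Center City", "New Jersey", "Northern"]

# (drug_code, units_per_dose, max_doses_per_day): MEDD of each sig using the
# bundled conversion table.  daily_units = units_per_dose * max_doses_per_day.
_SIG_LOW_MEDD = ("HYDAPAP5", 1, 4)       # 5 mg x 4 x 1.0  = 20 MEDD
_SIG_MID_MEDD = ("OXY5", 1, 4)           # 5 mg x 4 x 1.5  = 30 MEDD
_SIG_GT50 = ("OXY10", 1, 4)              # 10 mg x 4 x 1.5 = 60 MEDD
_SIG_CHRONIC_LE90 = ("MOR15", 1, 4)      # 15 mg x 4 x 1.0 = 60 MEDD
_SIG_CHRONIC_GT90 = ("MOR30", 1, 4)      # 30 mg x 4 x 1.0 = 120 MEDD

ROLE_PROBS = {"attending": 0.70, "nurse_practitioner": 0.16,
              "physician_assistant": 0.08, "resident": 0.06}


@dataclass
class SimConfig:
    """Study-condition knobs for the synthetic enterprise.

    Defaults approximate the published setting scaled to a tractable run:
    3 divisions, 68 specialties, ~2,000 active prescribers, 5 quarters,
    exceedance fractions near the published pre-period proportions (27% of
    nonchronic prescriptions > 5 days, 13% > 50 MEDD, 6.6% of chronic
    prescriptions > 90 MEDD), a ~10% chronic-prescription share, and a flat
    trend unless a quarterly ratio is configured.
    """

    n_divisions: int = 3
    n_specialties: int = 68
    n_providers: int = 2000
    rate_lognorm_mu: float = float(np.log(8.0))  # median quarterly rx per provider
    rate_lognorm_sigma: float = 0.8
    nb_dispersion: float = 6.0
    outlier_fraction: float = 0.04
    outlier_rate_multiplier: float = 5.0
    frac_gt5day: float = 0.27
    frac_gt50medd: float = 0.13
    frac_gt90medd_chronic: float = 0.066
    chronic_rx_fraction: float = 0.10
    trend_ratio: float = 1.0
    n_quarters: int = 5
    start_year: int = 2020
    start_quarter: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("outlier_fraction", "frac_gt5day", "frac_gt50medd",
                     "frac_gt90medd_chronic", "chronic_rx_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.outlier_rate_multiplier < 1:
            raise ValueError("outlier_rate_multiplier must be >= 1")
        if min(self.n_divisions, self.n_specialties, self.n_providers,
               self.n_quarters) < 1:
            raise ValueError("population sizes must be >= 1")
        if self.trend_ratio <= 0:
            raise ValueError("trend_ratio must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _quarter_labels(cfg: SimConfig) -> list[str]:
    labels = []
    y, q = cfg.start_year, cfg.start_quarter
    for _ in range(cfg.n_quarters):
        labels.append(f"{y}Q{q}")
        q += 1
        if q == 5:
            y, q = y + 1, 1
    return labels


def _quarter_bounds(label: str) -> tuple[np.datetime64, int]:
    """(start date, length in days) of a quarter label."""
    year, q = int(label[:4]), int(label[5])
    start = np.datetime64(f"{year}-{3 * (q - 1) + 1:02d}-01", "D")
    if q == 4:
        end = np.datetime64(f"{year + 1}-01-01", "D")
    else:
        end = np.datetime64(f"{year}-{3 * q + 1:02d}-01", "D")
    return start, int((end - start) / np.timedelta64(1, "D"))


def generate(cfg: SimConfig, out_dir: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Generate providers, drugs, prescriptions, and ground truth.

    Returns a dict of DataFrames keyed ``providers / drugs / prescriptions /
    truth``; if ``out_dir`` is given the same four tables are written as CSV
    with those names.  Byte-identical output for a fixed config and seed.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.n_divisions <= len(DIVISION_NAMES):
        divisions = DIVISION_NAMES[:cfg.n_divisions]
    else:
        divisions = [f"Division{i:02d}" for i in range(cfg.n_divisions)]

    # --- providers -------------------------------------------------------
    specialties = [f"Specialty{i:02d}" for i in range(cfg.n_specialties)]
    spec_division = rng.integers(0, cfg.n_divisions, size=cfg.n_specialties)
    # heavy-tailed specialty sizes (a few big surgical/medicine departments)
    spec_weights = rng.lognormal(0.0, 1.0, size=cfg.n_specialties)
    spec_weights /= spec_weights.sum()
    spec_of_provider = rng.choice(cfg.n_specialties, size=cfg.n_providers,
                                  p=spec_weights)
    roles = rng.choice(list(ROLE_PROBS), size=cfg.n_providers,
                       p=list(ROLE_PROBS.values()))
    provider_ids = np.array([f"PRV{i:05d}" for i in range(cfg.n_providers)])
    providers = pd.DataFrame({
        "provider_id": provider_ids,
        "name": [f"Provider {i:05d}" for i in range(cfg.n_providers)],
        "role": roles,
        "specialty": [specialties[s] for s in spec_of_provider],
        "division": [divisions[spec_division[s]] for s in spec_of_provider],
    })

    # --- latent rates ----------------------------------------------------
    spec_scale = rng.lognormal(0.0, 0.3, size=cfg.n_specialties)
    base_rate = rng.lognormal(cfg.rate_lognorm_mu, cfg.rate_lognorm_sigma,
                              size=cfg.n_providers) * spec_scale[spec_of_provider]
    is_outlier = rng.random(cfg.n_providers) < cfg.outlier_fraction
    # injected outliers prescribe at >= multiplier x their specialty's median
    # latent rate (the group median is exp(mu) x specialty scale)
    spec_median = np.exp(cfg.rate_lognorm_mu) * spec_scale[spec_of_provider]
    rate = np.where(is_outlier,
                    np.maximum(base_rate,
                               cfg.outlier_rate_multiplier * spec_median),
                    base_rate)

    # --- chronic patient pools (per specialty) ---------------------------
    # pool sized for ~12 chronic scripts per patient-year, so pool members
    # accumulate >=3 in-year prescriptions and stay active via refills
    expected_total = rate.sum() * cfg.n_quarters
    years = cfg.n_quarters / 4.0
    n_chronic_pool = max(1, int(expected_total * cfg.chronic_rx_fraction
                                / (12.0 * years)))
    chronic_pool = np.array([f"PATC{i:06d}" for i in range(n_chronic_pool)])

    labels = _quarter_labels(cfg)
    drug_table = pd.read_csv(bundled_drug_table_path(), dtype=str)

    rows_pid, rows_pat, rows_auth = [], [], []
    rows_drug, rows_upd, rows_mdd, rows_qty, rows_ref, rows_date = [], [], [], [], [], []
    attending_of_spec = {}
    attending_mask = providers["role"].to_numpy() == "attending"
    for s in range(cfg.n_specialties):
        cand = provider_ids[(spec_of_provider == s) & attending_mask]
        attending_of_spec[s] = cand

    rx_serial = 0
    fresh_serial = 0
    for qi, label in enumerate(labels):
        start, n_days = _quarter_bounds(label)
        lam = rate * cfg.trend_ratio ** qi
        # Gamma-Poisson = negative binomial with mean lam, dispersion k
        gam = rng.gamma(cfg.nb_dispersion, lam / cfg.nb_dispersion)
        counts = rng.poisson(gam)
        total = int(counts.sum())
        if total == 0:
            continue
        owner = np.repeat(np.arange(cfg.n_providers), counts)
        dates = start + rng.integers(0, n_days, size=total).astype("timedelta64[D]")

        chronic_rx = rng.random(total) < cfg.chronic_rx_fraction
        patients = np.empty(total, dtype=object)
        n_chron = int(chronic_rx.sum())
        patients[chronic_rx] = rng.choice(chronic_pool, size=n_chron)
        n_fresh = total - n_chron
        patients[~chronic_rx] = [f"PATN{fresh_serial + i:07d}" for i in range(n_fresh)]
        fresh_serial += n_fresh

        # dose/duration mixture, vectorized over the formulary lookup
        gt5 = rng.random(total) < cfg.frac_gt5day
        gt50 = rng.random(total) < cfg.frac_gt50medd
        gt90 = rng.random(total) < cfg.frac_gt90medd_chronic
        coin = rng.random(total) < 0.5
        formulary = [_SIG_CHRONIC_GT90, _SIG_CHRONIC_LE90, _SIG_GT50,
                     _SIG_MID_MEDD, _SIG_LOW_MEDD]
        which = np.select(
            [chronic_rx & gt90, chronic_rx, gt50, coin],
            [0, 1, 2, 3], default=4)
        drug_arr = np.array([t[0] for t in formulary], dtype=object)[which]
        upd_arr = np.array([t[1] for t in formulary])[which]
        mdd_arr = np.array([t[2] for t in formulary])[which]
        daily_units = upd_arr * mdd_arr
        # quantity: > 5 days or <= 5 days at the sig's daily units
        days_over = rng.integers(7, 15, size=total)
        days_under = rng.integers(2, 6, size=total)     # 2..5 days inclusive
        days = np.where(gt5 | chronic_rx, np.maximum(days_over, 1), days_under)
        # chronic-pool scripts run long (30 days) with 3-5 refills, keeping
        # members continuously covered between scripts
        days = np.where(chronic_rx, 30, days)
        qty = days * daily_units
        refills = np.where(chronic_rx, rng.integers(3, 6, size=total), 0)

        # authorizing provider for a fraction of APP/resident orders
        owner_roles = roles[owner]
        needs_auth = np.isin(owner_roles, ("nurse_practitioner",
                                           "physician_assistant", "resident"))
        has_auth = needs_auth & (rng.random(total) < 0.10)
        auth = np.full(total, "", dtype=object)
        for i in np.flatnonzero(has_auth):
            cand = attending_of_spec[spec_of_provider[owner[i]]]
            if len(cand):
                auth[i] = rng.choice(cand)

        rows_pid.append(provider_ids[owner])
        rows_pat.append(patients)
        rows_auth.append(auth)
        rows_drug.append(drug_arr)
        rows_upd.append(upd_arr)
        rows_mdd.append(mdd_arr)
        rows_qty.append(qty)
        rows_ref.append(refills)
        rows_date.append(dates)
        rx_serial += total

    total_rx = rx_serial
    prescriptions = pd.DataFrame({
        "rx_id": [f"RX{i:08d}" for i in range(total_rx)],
        "patient_id": np.concatenate(rows_pat) if rows_pat else [],
        "prescriber_id": np.concatenate(rows_pid) if rows_pid else [],
        "authorizing_id": np.concatenate(rows_auth) if rows_auth else [],
        "drug_code": np.concatenate(rows_drug) if rows_drug else [],
        "units_per_dose": np.concatenate(rows_upd) if rows_upd else [],
        "max_doses_per_day": np.concatenate(rows_mdd) if rows_mdd else [],
        "quantity_dispensed": np.concatenate(rows_qty) if rows_qty else [],
        "refills": np.concatenate(rows_ref) if rows_ref else [],
        "written_date": np.concatenate(rows_date) if rows_date else [],
    }, columns=PRESCRIPTION_COLUMNS)
    prescriptions["written_date"] = pd.to_datetime(
        prescriptions["written_date"]).dt.strftime("%Y-%m-%d")

    truth = pd.concat([
        pd.DataFrame({"entity_type": "provider",
                      "entity_id": provider_ids[is_outlier],
                      "label": "injected_outlier"}),
        pd.DataFrame({"entity_type": "patient",
                      "entity_id": chronic_pool,
                      "label": "chronic_pool"}),
    ], ignore_index=True)

    out = {"providers": providers, "drugs": drug_table,
           "prescriptions": prescriptions, "truth": truth}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in out.items():
            df.to_csv(out_dir / f"{name}.csv", index=False)
    return out


# ---------------------------------------------------------------------------
# Hand-audited worked fixture
# ---------------------------------------------------------------------------

_FIXTURE_PROVIDERS = [
    # provider_id, name, role, specialty, division
    ("P01", "Alice Chen", "attending", "Surgery", "Center City"),
    ("P02", "Bob Diaz", "nurse_practitioner", "Surgery", "Center City"),
    ("P03", "Carol Evans", "attending", "Medicine", "Center City"),
    ("P04", "Dan Fox", "attending", "Surgery", "Center City"),
    ("P05", "Eve Gray", "attending", "Medicine", "Center City"),
    ("P06", "Frank Hill", "attending", "Surgery", "Center City"),
    ("P07", "Gina Ito", "attending", "Surgery", "Center City"),
    ("P08", "Hal Jones", "physician_assistant", "Surgery", "Center City"),
]

_FIXTURE_RX = [
    # rx_id, patient, prescriber, authorizing, drug, upd, mdd, qty, refills, date
    # chronic patient PAC: three qualifying scripts, then an in-quarter one
    ("R01", "PAC", "P03", "", "MOR30", 1, 3, 90, 3, "2021-02-01"),
    ("R02", "PAC", "P03", "", "MOR30", 1, 3, 90, 3, "2021-04-01"),
    ("R03", "PAC", "P03", "", "MOR30", 1, 3, 90, 3, "2021-06-01"),  # 3rd rx: still nonchronic when written
    ("R04", "PAC", "P03", "", "MOR30", 1, 4, 120, 1, "2021-08-15"),  # chronic, 120 MEDD
    # P01, Surgery
    ("R05", "PA1", "P01", "", "OXY5", 1, 4, 20, 0, "2021-07-05"),    # exactly 5.0 days
    ("R06", "PA2", "P01", "", "HYDAPAP10", 1, 5, 50, 0, "2021-07-10"),  # exactly 50 MEDD, 10 days
    ("R07", "PA3", "P01", "", "OXY10", 1, 4, 30, 0, "2021-08-01"),   # 60 MEDD, 7.5 days
    ("R08", "PA3", "P01", "", "OXY5", 1, 4, 12, 0, "2021-09-01"),
    # P02 orders, one authorized by P01
    ("R09", "PA4", "P02", "P01", "OXY5", 1, 4, 40, 0, "2021-07-20"),  # attributed to P01
    ("R10", "PA5", "P02", "", "HYDAPAP5", 1, 4, 16, 0, "2021-08-05"),
    ("R11", "PA6", "P02", "", "OXY10", 1, 6, 60, 1, "2021-09-10"),   # 90 MEDD (>50, not >90), 10 days
    # P03 additional
    ("R12", "PA7", "P03", "", "TRAM50", 2, 3, 36, 0, "2021-07-15"),  # 30 MEDD, 6 days
    # P05
    ("R13", "PA8", "P05", "", "OXY5", 1, 4, 20, 0, "2021-09-20"),
    # P04 eligible via this pre-quarter rx only (zero in-quarter)
    ("R14", "PA1", "P04", "", "OXY5", 1, 4, 20, 0, "2021-03-15"),
    # P06's only rx is outside the 12-month lookback: not eligible
    ("R15", "PA1", "P06", "", "OXY5", 1, 4, 20, 0, "2020-06-01"),
    # P02 extreme outlier on m4: five distinct nonchronic patients > 50 MEDD
    ("R16", "PA9", "P02", "", "OXY10", 1, 4, 16, 0, "2021-09-12"),
    ("R17", "PA10", "P02", "", "OXY10", 1, 4, 16, 0, "2021-09-14"),
    ("R18", "PA11", "P02", "", "OXY10", 1, 4, 16, 0, "2021-09-16"),
    ("R19", "PA12", "P02", "", "OXY10", 1, 4, 16, 0, "2021-09-18"),
    # P07 / P08 pad the Surgery peer group to n=5 eligible providers
    ("R20", "PA13", "P07", "", "OXY10", 1, 4, 16, 0, "2021-08-20"),
    ("R21", "PA14", "P08", "", "OXY5", 1, 4, 12, 0, "2021-08-25"),
]

#: Hand-computed ProviderQuarterMetrics for the fixture's quarter (2021Q3).
#: Audited once against the definitions; tests and the acceptance script
#: recompute the pipeline and compare to this table.
WORKED_EXPECTED_METRICS = pd.DataFrame(
    [("P01", "2021Q3", 5, 4, 3, 1, 0),
     ("P02", "2021Q3", 6, 6, 1, 5, 0),
     ("P03", "2021Q3", 2, 2, 1, 0, 1),
     ("P04", "2021Q3", 0, 0, 0, 0, 0),
     ("P05", "2021Q3", 1, 1, 0, 0, 0),
     ("P07", "2021Q3", 1, 1, 0, 1, 0),
     ("P08", "2021Q3", 1, 1, 0, 0, 0)],
    columns=["provider_id", "quarter", "m1_rx_count", "m2_patient_count",
             "m3_gt5day", "m4_gt50medd", "m5_gt90medd"])

WORKED_QUARTER = "2021Q3"


def generate_worked_fixture(out_dir: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """The 21-prescription hand-auditable dataset and its expected metrics.

    Deterministic by construction (no randomness).  Covers: the 5.0-day and
    50-MEDD compliance boundaries, chronicity attained only on the fourth
    prescription, attribution to an authorizing provider, an eligible
    zero-prescriber, an ineligible provider, and one extreme outlier.
    """
    providers = pd.DataFrame(_FIXTURE_PROVIDERS, columns=PROVIDER_COLUMNS)
    prescriptions = pd.DataFrame(_FIXTURE_RX, columns=PRESCRIPTION_COLUMNS)
    drugs = pd.read_csv(bundled_drug_table_path(), dtype=str)[DRUG_COLUMNS]
    truth = pd.DataFrame(
        [("patient", "PAC", "chronic_pool"),
         ("provider", "P02", "injected_outlier")],
        columns=["entity_type", "entity_id", "label"])
    out = {"providers": providers, "drugs": drugs,
           "prescriptions": prescriptions, "truth": truth,
           "expected_metrics": WORKED_EXPECTED_METRICS.copy()}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in out.items():
            df.to_csv(out_dir / f"{name}.csv", index=False)
    return out
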