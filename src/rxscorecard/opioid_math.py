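"""Per-prescription morphine-equivalent daily dose and calculated day supply.

MEDD (morphine equivalent daily dose) converts a prescription's maximum
daily opioid dose into oral-morphine milligrams:

    MEDD = strength_mg_per_unit x units_per_dose x max_doses_per_day x mme_factor

Calculated day supply is how long the dispensed quantity lasts at the
maximum frequency the sig permits:

    day_supply = quantity_dispensed / (units_per_dose x max_doses_per_day)

Two deliberate choices: PRN sigs contribute their *maximum* permitted
frequency (conservative, standard MME audit practice), and refills are
excluded — the prescription as written, not its renewals, is the audited
act.  Refills re-enter only in the chronic-registry "active prescription"
computation.  Guideline flags use strict ``>``: a prescription at exactly
5.0 days or exactly 50 MEDD is compliant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel_io import DrugEntry, PrescriptionRecord, RunConfig


@dataclass(frozen=True)
class RxDerived:
    rx_id: str
    medd: float
    day_supply: float
    exceeds_day_threshold: bool
    exceeds_acute_medd: bool
    exceeds_chronic_medd: bool


def medd_of_prescription(rx: PrescriptionRecord, drug: DrugEntry) -> float:
    """Oral-morphine mg equivalents per day at the sig's maximum frequency."""
    if drug.mme_factor is None or np.isnan(drug.mme_factor):
        raise ValueError(f"drug {drug.drug_code}: missing mme_factor")
    medd = (drug.strength_mg_per_unit * rx.units_per_dose
            * rx.max_doses_per_day * drug.mme_factor)
    if not np.isfinite(medd) or medd < 0:
        raise ValueError(f"rx {rx.rx_id}: non-finite MEDD")
    return medd


def calculated_day_supply(rx: PrescriptionRecord) -> float:
    """Days the dispensed quantity lasts at maximum sig frequency (unrounded)."""
    daily_units = rx.units_per_dose * rx.max_doses_per_day
    if daily_units <= 0:
        raise ValueError(f"rx {rx.rx_id}: non-positive daily units")
    return rx.quantity_dispensed / daily_units


def derive(rx: PrescriptionRecord, drug: DrugEntry, config: RunConfig) -> RxDerived:
    """MEDD, day supply, and the three guideline-exceedance flags for one rx."""
    medd = medd_of_prescription(rx, drug)
    days = calculated_day_supply(rx)
    return RxDerived(
        rx_id=rx.rx_id,
        medd=medd,
        day_supply=days,
        exceeds_day_threshold=days > config.day_supply_threshold,
        exceeds_acute_medd=medd > config.medd_acute_threshold,
        exceeds_chronic_medd=medd > config.medd_chronic_threshold,
    )


def derive_frame(rx_frame: pd.DataFrame, drug_table: Mapping[str, DrugEntry],
                 config: RunConfig) -> pd.DataFrame:
    """Vectorized :func:`derive` over a prescription DataFrame.

    Returns a frame indexed like ``rx_frame`` with columns
    ``rx_id, medd, day_supply, exceeds_day_threshold, exceeds_acute_medd,
    exceeds_chronic_medd``.
    """
    strength = rx_frame["drug_code"].map(
        {c: d.strength_mg_per_unit for c, d in drug_table.items()})
    factor = rx_frame["drug_code"].map(
        {c: d.mme_factor for c, d in drug_table.items()})
    if strength.isna().any():
        bad = rx_frame.loc[strength.isna(), "drug_code"].unique().tolist()
        raise KeyError(f"unresolvable drug_code(s): {bad}")
    daily_units = rx_frame["units_per_dose"] * rx_frame["max_doses_per_day"]
    medd = strength * daily_units * factor
    days = rx_frame["quantity_dispensed"] / daily_units
    return pd.DataFrame({
        "rx_id": rx_frame["rx_id"],
        "medd": medd.astype(float),
        "day_supply": days.astype(float),
        "exceeds_day_threshold": days > config.day_supply_threshold,
        "exceeds_acute_medd": medd > config.medd_acute_threshold,
        "exceeds_chronic_medd": medd > config.medd_chronic_threshold,
    }, index=rx_frame.index)
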