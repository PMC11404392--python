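import dataclasses
import datetime as dt

import pandas as pd
import pytest

import rxscorecard as rx
from rxscorecard.cli import load_dataset


def as_pipeline_frame(raw: pd.DataFrame) -> pd.DataFrame:
    """Coerce a raw generator prescriptions table to the typed frame the
    pipeline operates on (what read_prescriptions would produce)."""
    df = raw.copy()
    df["written_date"] = pd.to_datetime(df["written_date"])
    for c in ("units_per_dose", "max_doses_per_day", "quantity_dispensed", "refills"):
        df[c] = df[c].astype(float)
    df["authorizing_id"] = df["authorizing_id"].fillna("")
    return df


def make_rx(**kw) -> rx.PrescriptionRecord:
    base = dict(rx_id="R1", patient_id="PA1", prescriber_id="P1",
                authorizing_id=None, drug_code="OXY5", units_per_dose=1.0,
                max_doses_per_day=4.0, quantity_dispensed=20.0, refills=0,
                written_date=dt.date(2021, 7, 1))
    base.update(kw)
    return rx.PrescriptionRecord(**base)


def records_to_frame(records) -> pd.DataFrame:
    cols = [f.name for f in dataclasses.fields(rx.PrescriptionRecord)]
    df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=cols)
    df["written_date"] = pd.to_datetime(df["written_date"])
    df["authorizing_id"] = df["authorizing_id"].fillna("")
    return df


@pytest.fixture(scope="session")
def config() -> rx.RunConfig:
    return rx.RunConfig()


@pytest.fixture(scope="session")
def drug_table():
    return rx.read_drug_table(rx.bundled_drug_table_path())


@pytest.fixture(scope="session")
def worked(tmp_path_factory):
    """The hand-audited fixture, loaded through the real IO path."""
    tmp = tmp_path_factory.mktemp("worked")
    frames = rx.generate_worked_fixture(tmp)
    drug_table, roster, result = load_dataset(tmp)
    return {"dir": tmp, "frames": frames, "drug_table": drug_table,
            "roster": roster, "read_result": result,
            "expected": frames["expected_metrics"]}


@pytest.fixture(scope="session")
def worked_scored(worked, config):
    from rxscorecard.cli import score_quarter
    table, thr, flags, bundle = score_quarter(
        worked["read_result"].frame, worked["drug_table"], worked["roster"],
        config, rx.synthetic_data.WORKED_QUARTER)
    return {"metrics": table, "thresholds": thr, "flags": flags,
            "bundle": bundle}


@pytest.fixture(scope="session")
def sim_small():
    """A small but structured synthetic enterprise, typed for the pipeline."""
    cfg = rx.SimConfig(seed=11, n_providers=300, n_specialties=10,
                       n_quarters=4, start_year=2020, start_quarter=4)
    data = rx.generate(cfg)
    roster = {r.provider_id: rx.ProviderRecord(r.provider_id, r.name, r.role,
                                               r.specialty, r.division)
              for r in data["providers"].itertuples()}
    return {"cfg": cfg, "data": data, "roster": roster,
            "rx_frame": as_pipeline_frame(data["prescriptions"])}
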