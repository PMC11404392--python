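import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rxscorecard as rx
from rxscorecard.cohort import (attribute, chronic_registry,
                                classify_rx_chronicity, eligible_prescribers,
                                label_chronicity, quarter_windows, window_mask)

from conftest import make_rx, records_to_frame


AS_OF = dt.date(2021, 9, 30)


def frame_of(*recs):
    return records_to_frame(list(recs))


def simple_derived(frame, day_supply):
    return pd.DataFrame({"day_supply": [float(day_supply)] * len(frame)},
                        index=frame.index)


def test_attribution_prefers_authorizer():
    assert attribute(make_rx(authorizing_id="A", prescriber_id="B")) == "A"
    assert attribute(make_rx(authorizing_id=None, prescriber_id="B")) == "B"
    assert attribute(make_rx(authorizing_id="B", prescriber_id="B")) == "B"


def test_eligibility_window_boundaries(config):
    inside = make_rx(rx_id="a", prescriber_id="P_in",
                     written_date=AS_OF - dt.timedelta(days=364))
    outside = make_rx(rx_id="b", prescriber_id="P_out",
                      written_date=AS_OF - dt.timedelta(days=366))
    got = eligible_prescribers(frame_of(inside, outside), AS_OF, 365)
    assert got == {"P_in"}
    assert eligible_prescribers(frame_of(), AS_OF, 365) == set()


def test_registry_requires_count_and_activity(config):
    recs = [make_rx(rx_id=f"r{i}", patient_id="PAT",
                    written_date=AS_OF - dt.timedelta(days=300 - 100 * i))
            for i in range(3)]
    f = frame_of(*recs)
    # last rx 100 days before as_of; 30-day supply x (refills 3 + 1) = 120 days
    f["refills"] = 3.0
    reg = chronic_registry(f, simple_derived(f, 30.0), AS_OF, config)
    assert reg.chronic_patient_ids == {"PAT"}
    assert classify_rx_chronicity(make_rx(patient_id="PAT"), reg) == "chronic"
    # all supplies long expired: condition (b) fails even with 5 scripts
    f5 = frame_of(*[make_rx(rx_id=f"r{i}", patient_id="PAT",
                            written_date=AS_OF - dt.timedelta(days=360 - i))
                    for i in range(5)])
    reg = chronic_registry(f5, simple_derived(f5, 3.0), AS_OF, config)
    assert reg.chronic_patient_ids == frozenset()
    # only two scripts: condition (a) fails even though one is active
    f2 = frame_of(*[make_rx(rx_id=f"r{i}", patient_id="PAT",
                            written_date=AS_OF - dt.timedelta(days=5 + i))
                    for i in range(2)])
    reg = chronic_registry(f2, simple_derived(f2, 30.0), AS_OF, config)
    assert reg.chronic_patient_ids == frozenset()


def _brute_force_labels(frame, derived, config):
    """Replay the registry rule independently for every prescription."""
    out = []
    dates = pd.to_datetime(frame["written_date"]).dt.date.to_list()
    for i in range(len(frame)):
        me = frame.iloc[i]
        d_i = dates[i]
        count = 0
        active = False
        for j in range(len(frame)):
            if j == i or frame.iloc[j]["patient_id"] != me["patient_id"]:
                continue
            d_j = dates[j]
            if not (d_i - dt.timedelta(days=config.lookback_days) < d_j <= d_i):
                continue
            count += 1
            ends = d_j + dt.timedelta(days=int(np.ceil(
                derived.iloc[j]["day_supply"] * (frame.iloc[j]["refills"] + 1))))
            if ends >= d_i:
                active = True
        out.append("chronic" if count >= config.chronic_min_rx and active
                   else "nonchronic")
    return out


def test_third_rx_does_not_self_qualify(config):
    recs = [make_rx(rx_id=f"r{i}", patient_id="PAT", refills=3,
                    written_date=dt.date(2021, 1, 1) + dt.timedelta(days=60 * i))
            for i in range(4)]
    f = frame_of(*recs)
    der = simple_derived(f, 30.0)
    labels = label_chronicity(f, der, config)
    # 1st, 2nd, 3rd scripts written while <3 others existed: nonchronic
    assert labels.tolist() == ["nonchronic"] * 3 + ["chronic"]
    assert labels.tolist() == _brute_force_labels(f, der, config)


@given(st.data())
@settings(max_examples=30, deadline=None)
def test_chronicity_labels_match_brute_force(config, data):
    n = data.draw(st.integers(2, 25))
    base = dt.date(2021, 1, 1)
    recs = []
    for i in range(n):
        recs.append(make_rx(
            rx_id=f"r{i}",
            patient_id=f"PAT{data.draw(st.integers(0, 3))}",
            refills=data.draw(st.integers(0, 3)),
            quantity_dispensed=float(data.draw(st.integers(4, 120))),
            written_date=base + dt.timedelta(days=data.draw(st.integers(0, 500))),
        ))
    f = frame_of(*recs)
    der = pd.DataFrame({"day_supply": (f["quantity_dispensed"] / 4.0)},
                       index=f.index)
    fast = label_chronicity(f, der, config).tolist()
    assert fast == _brute_force_labels(f, der, config)


def test_registry_monotone_in_prescriptions(config):
    recs = [make_rx(rx_id=f"r{i}", patient_id="PAT", refills=3,
                    written_date=AS_OF - dt.timedelta(days=200 - 50 * i))
            for i in range(3)]
    f3 = frame_of(*recs)
    reg3 = chronic_registry(f3, simple_derived(f3, 30.0), AS_OF, rx.RunConfig())
    f4 = frame_of(*recs, make_rx(rx_id="extra", patient_id="PAT",
                                 written_date=AS_OF - dt.timedelta(days=10)))
    reg4 = chronic_registry(f4, simple_derived(f4, 30.0), AS_OF, rx.RunConfig())
    assert reg3.chronic_patient_ids <= reg4.chronic_patient_ids


def test_quarter_windows_tile_the_year():
    windows = quarter_windows(2021)
    assert len(windows) == 4
    assert windows[0].label == "2021Q1"
    assert windows[0].start_date == dt.date(2021, 1, 1)
    assert windows[0].end_date == dt.date(2021, 4, 1)
    day = dt.date(2021, 1, 1)
    while day < dt.date(2022, 1, 1):
        assert sum(w.contains(day) for w in windows) == 1
        day += dt.timedelta(days=1)
    assert windows[3].contains(dt.date(2021, 12, 31))


def test_window_mask_half_open(worked):
    frame = worked["read_result"].frame
    w = rx.QuarterWindow.from_label("2021Q3")
    m = window_mask(frame, w)
    dates = pd.to_datetime(frame["written_date"])
    assert m.equals((dates >= "2021-07-01") & (dates < "2021-10-01"))
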