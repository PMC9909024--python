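"""Cohort I/O, preprocessing rules and the split protocol."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perioprisk import (
    Cohort,
    PatientRecord,
    SplitSpec,
    clean_text,
    normalize_tabular,
    read_cohort,
    read_cohort_dir,
    select_nearest_test,
    select_top_monitoring_attributes,
    split_cohort,
    write_cohort,
)
from perioprisk.cohort import CohortIntegrityError, CohortParseError

SURGERY = dt.date(2019, 10, 28)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def test_read_cohort_tabular_only(tmp_path):
    p = tmp_path / "tab.csv"
    p.write_text("patient_id,label,a,b\np1,0,1.0,\np2,1,2.0,3.0\np3,0,,\n")
    cohort = read_cohort(p)
    assert len(cohort) == 3
    assert cohort.schema == ["a", "b"]
    assert cohort.records[0].tabular == {"a": 1.0, "b": None}
    assert all(r.monitoring == {} for r in cohort.records)


def test_read_cohort_monitoring_series_resorted(tmp_path):
    tab = tmp_path / "tab.csv"
    tab.write_text("patient_id,label,a\np1,0,1.0\n")
    mon = tmp_path / "mon.csv"
    mon.write_text(
        "patient_id,attribute,t_minutes,value\n"
        "p1,HR,2,74\np1,HR,1,73\np1,HR,0,72\n"
    )
    cohort = read_cohort(tab, mon)
    t, v = cohort.records[0].monitoring["HR"]
    assert t.tolist() == [0.0, 1.0, 2.0]
    assert v.tolist() == [72.0, 73.0, 74.0]


def test_duplicate_patient_id_is_integrity_error(tmp_path):
    p = tmp_path / "tab.csv"
    p.write_text("patient_id,label,a\np1,0,1\np1,1,2\n")
    with pytest.raises(CohortIntegrityError, match="p1"):
        read_cohort(p)


def test_malformed_text_json_names_line(tmp_path):
    tab = tmp_path / "tab.csv"
    tab.write_text("patient_id,label,a\np1,0,1\n")
    txt = tmp_path / "text.jsonl"
    txt.write_text('{"patient_id": "p1"}\nnot json at all\n')
    with pytest.raises(CohortParseError, match="line 2"):
        read_cohort(tab, None, txt)


def test_write_read_roundtrip(tmp_path, tiny_cohort):
    write_cohort(tiny_cohort, tmp_path / "c")
    back = read_cohort_dir(tmp_path / "c")
    assert len(back) == len(tiny_cohort)
    assert back.schema == tiny_cohort.schema
    for a, b in zip(tiny_cohort.records, back.records):
        assert a.patient_id == b.patient_id and a.label == b.label
        assert a.text == b.text
        for attr, val in a.tabular.items():
            if val is None:
                assert b.tabular[attr] is None
            else:
                assert b.tabular[attr] == pytest.approx(val, abs=1e-12)
        for attr, (t, v) in a.monitoring.items():
            t2, v2 = b.monitoring[attr]
            np.testing.assert_allclose(t, t2)
            np.testing.assert_allclose(v, v2)


# ---------------------------------------------------------------------------
# nearest preoperative test selection
# ---------------------------------------------------------------------------


def test_nearest_test_most_recent_value():
    # surgery 28/10/2019 -> value of the 26/10/2019 test
    assert select_nearest_test([(dt.date(2019, 10, 26), 5.1)], SURGERY) == 5.1


def test_nearest_test_walks_back_past_null():
    obs = [(dt.date(2019, 10, 26), None), (dt.date(2019, 10, 20), 4.8)]
    assert select_nearest_test(obs, SURGERY) == 4.8


def test_nearest_test_outside_two_week_window_is_missing():
    assert select_nearest_test([(dt.date(2019, 10, 1), 4.8)], SURGERY) is None


def test_observation_after_surgery_rejected():
    with pytest.raises(ValueError, match="after surgery"):
        select_nearest_test([(dt.date(2019, 10, 29), 5.0)], SURGERY)


@given(
    st.lists(
        st.tuples(st.integers(min_value=0, max_value=60), st.one_of(st.none(), st.floats(-5, 5))),
        max_size=8,
    )
)
@settings(max_examples=100, deadline=None)
def test_nearest_test_never_outside_window(days_and_values):
    obs = [(SURGERY - dt.timedelta(days=d), v) for d, v in days_and_values]
    result = select_nearest_test(obs, SURGERY)
    in_window = {v for d, v in obs if v is not None and (SURGERY - d).days <= 14}
    if result is None:
        # the most recent non-null observation (if any) must lie outside the window
        assert not in_window or max(d for d, v in obs if v is not None) < SURGERY - dt.timedelta(days=14)
    else:
        assert result in in_window


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def _cohort_from_values(values):
    records = [
        PatientRecord(patient_id=f"p{i}", label=0, tabular={"x": v})
        for i, v in enumerate(values)
    ]
    return Cohort(records, schema=["x"])


@pytest.mark.parametrize(
    "values,expected",
    [
        ([10.0, 20.0], [0.0, 1.0]),
        ([10.0, 15.0, 20.0], [0.0, 0.5, 1.0]),
        ([7.0, 7.0, 7.0], [0.5, 0.5, 0.5]),
    ],
)
def test_normalize_tabular(values, expected):
    normed, stats = normalize_tabular(_cohort_from_values(values))
    assert [r.tabular["x"] for r in normed.records] == pytest.approx(expected)


def test_normalize_preserves_missing_and_uses_train_stats():
    train = _cohort_from_values([0.0, 10.0])
    _, stats = normalize_tabular(train)
    other = _cohort_from_values([5.0, None, 20.0])
    normed, _ = normalize_tabular(other, stats)
    vals = [r.tabular["x"] for r in normed.records]
    assert vals[0] == pytest.approx(0.5)
    assert vals[1] is None
    assert vals[2] == pytest.approx(1.0)  # clipped into [0, 1]


def test_normalize_idempotent_on_normalized_data():
    once, _ = normalize_tabular(_cohort_from_values([1.0, 3.0, 5.0]))
    twice, stats = normalize_tabular(once)
    assert stats.table["x"] == (0.0, 1.0)
    for a, b in zip(once.records, twice.records):
        assert a.tabular["x"] == pytest.approx(b.tabular["x"])


def test_all_missing_attribute_dropped():
    records = [PatientRecord(patient_id=f"p{i}", label=0, tabular={"x": 1.0 * i, "y": None}) for i in range(3)]
    normed, stats = normalize_tabular(Cohort(records, schema=["x", "y"]))
    assert "y" not in stats.table
    assert normed.schema == ["x"]


# ---------------------------------------------------------------------------
# text cleaning
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("Sinus rhythm, normal ECG.", ["sinus", "rhythm", "normal", "ecg"]),
        ("", []),
        ("T-wave;; inversion", ["t-wave", "inversion"]),
        ("  (mild)  LVH?  ", ["mild", "lvh"]),
    ],
)
def test_clean_text(raw, expected):
    assert clean_text(raw) == expected


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def _labelled_cohort(n, n_pos, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.array([1] * n_pos + [0] * (n - n_pos))
    rng.shuffle(labels)
    records = [
        PatientRecord(patient_id=f"p{i}", label=int(labels[i]), tabular={"x": float(i)})
        for i in range(n)
    ]
    return Cohort(records, schema=["x"])


def test_split_sizes_exact_n100():
    cohort = _labelled_cohort(100, 14)
    tr, va, te = split_cohort(cohort, SplitSpec(seed=3))
    assert (len(tr), len(va), len(te)) == (70, 20, 10)


def test_split_sizes_rounding_n10():
    tr, va, te = split_cohort(_labelled_cohort(10, 3), SplitSpec(seed=3))
    assert (len(tr), len(va), len(te)) == (7, 2, 1)


def test_split_deterministic():
    cohort = _labelled_cohort(57, 9)
    a = split_cohort(cohort, SplitSpec(seed=5))
    b = split_cohort(cohort, SplitSpec(seed=5))
    for ca, cb in zip(a, b):
        assert [r.patient_id for r in ca.records] == [r.patient_id for r in cb.records]


def test_split_stratification_positive_rate():
    cohort = _labelled_cohort(200, 28)
    tr, va, te = split_cohort(cohort, SplitSpec(seed=1, stratified=True))
    global_rate = 28 / 200
    for part in (tr, va, te):
        ideal = global_rate * len(part)
        assert abs(part.labels.sum() - ideal) < 1.0


@given(n=st.integers(min_value=3, max_value=300), seed=st.integers(0, 2**16),
       frac_pos=st.floats(0.05, 0.5))
@settings(max_examples=40, deadline=None)
def test_split_disjoint_exhaustive(n, seed, frac_pos):
    cohort = _labelled_cohort(n, max(1, int(frac_pos * n)), seed=seed)
    parts = split_cohort(cohort, SplitSpec(seed=seed))
    ids = [r.patient_id for p in parts for r in p.records]
    assert len(ids) == n and len(set(ids)) == n


# ---------------------------------------------------------------------------
# monitoring attribute selection
# ---------------------------------------------------------------------------


def _mon_cohort(counts):
    """counts: attr -> number of patients carrying a nonempty series."""
    n = max(counts.values())
    records = []
    for i in range(n):
        series = {
            attr: (np.arange(2, dtype=float), np.array([70.0, 71.0]))
            for attr, c in counts.items()
            if i < c
        }
        records.append(PatientRecord(patient_id=f"p{i}", label=0, monitoring=series))
    return Cohort(records, schema=[])


def test_top_monitoring_by_coverage():
    cohort = _mon_cohort({"HR": 90, "CVP": 12})
    assert select_top_monitoring_attributes(cohort, 1) == ["HR"]


def test_top_monitoring_tie_breaks_alphabetically():
    cohort = _mon_cohort({"SBP": 50, "DBP": 50})
    assert select_top_monitoring_attributes(cohort, 2) == ["DBP", "SBP"]


def test_top_monitoring_n_exceeds_available():
    cohort = _mon_cohort({"HR": 5, "RR": 3})
    assert select_top_monitoring_attributes(cohort, 10) == ["HR", "RR"]
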