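"""Filter semantics, stage order, and the temporal split."""

import numpy as np
import pandas as pd
import pytest

import wbitlab as wl

from conftest import make_cohort, make_events


def test_transfusion_window_boundary_arithmetic():
    cohort = make_cohort([("p1", 10, "W"), ("p1", 100, "W"), ("p1", 111, "W")])
    events = make_events([("p1", 20)])
    kept = wl.filter_transfusions(cohort, events, 90)
    assert sorted(kept.samples["drawn_at"].dt.day_of_year - 1) == [10, 111]


def test_transfusion_window_endpoints_inclusive():
    cohort = make_cohort([("p1", 20, "W"), ("p1", 110, "W"), ("p1", 110.5, "W")])
    events = make_events([("p1", 20)])
    kept = wl.filter_transfusions(cohort, events, 90)
    # day 20 (t itself) and day 110 (t+90) removed; 110.5 survives
    assert kept.samples["sample_id"].tolist() == ["s002"]


def test_patients_without_events_untouched():
    cohort = make_cohort([("p1", 5, "W"), ("p2", 5, "W")])
    events = make_events([("p9", 1)])
    assert len(wl.filter_transfusions(cohort, events, 90)) == 2


def test_transfusion_filter_matches_brute_force_double_loop():
    rng = np.random.default_rng(4)
    rows = [(f"p{rng.integers(8)}", float(rng.uniform(0, 300)), "W")
            for _ in range(120)]
    cohort = make_cohort(rows)
    events = make_events([(f"p{i}", float(rng.uniform(0, 300)))
                          for i in range(8) if rng.random() < 0.6])
    kept = wl.filter_transfusions(cohort, events, 90)

    expected = []
    for _, s in cohort.samples.iterrows():
        hit = False
        for _, e in events.iterrows():
            if e["patient_id"] != s["patient_id"]:
                continue
            d = (s["drawn_at"] - e["transfused_at"]).total_seconds() / 86400.0
            if 0 <= d <= 90:
                hit = True
        if not hit:
            expected.append(s["sample_id"])
    assert kept.samples["sample_id"].tolist() == expected


def test_singleton_removal_and_stage_order():
    # p2 has two samples but loses one to the transfusion window, becoming
    # a singleton at the later stage
    cohort = make_cohort([
        ("p1", 0, "W"), ("p2", 0, "W"), ("p2", 30, "W"),
        ("p3", 0, "W"), ("p3", 1, "W")])
    events = make_events([("p2", 25)])
    filtered, trace = wl.apply_filters(cohort, events, 90)
    assert set(filtered.samples["patient_id"]) == {"p3"}
    names = [s for s, _, _ in trace.stages]
    assert names == ["input", "transfusion", "singletons", "cbc_complete"]


def test_singleton_filter_leaves_min_two_per_patient():
    rng = np.random.default_rng(10)
    rows = [(f"p{rng.integers(30)}", float(i), "W") for i in range(100)]
    kept = wl.filter_singletons(make_cohort(rows))
    assert (kept.samples.groupby("patient_id").size() >= 2).all()


def test_complete_cbc_filter_respects_panel():
    cohort = make_cohort([
        ("p1", 0, "W", {"RDW": np.nan}),
        ("p1", 1, "W"),
        ("p2", 0, "W", {"MCV": np.nan})])
    full = wl.filter_complete_cbc(cohort, wl.ANALYTES)
    assert full.samples["sample_id"].tolist() == ["s001"]
    mcv_only = wl.filter_complete_cbc(cohort, ("MCV",))
    assert mcv_only.samples["sample_id"].tolist() == ["s000", "s001"]
    with pytest.raises(ValueError):
        wl.filter_complete_cbc(cohort, ())


def test_complete_cbc_matches_brute_force_scan():
    rng = np.random.default_rng(6)
    rows = []
    for i in range(80):
        over = {a: np.nan for a in wl.ANALYTES if rng.random() < 0.1}
        rows.append((f"p{i % 9}", float(i), "W", over))
    cohort = make_cohort(rows)
    kept = wl.filter_complete_cbc(cohort, wl.ANALYTES)
    expected = [s["sample_id"] for _, s in cohort.samples.iterrows()
                if all(pd.notna(s[a]) for a in wl.ANALYTES)]
    assert kept.samples["sample_id"].tolist() == expected


def test_per_patient_filters_commute_with_partitioning():
    """Filtering one patient's samples in isolation gives the same
    survivors as filtering the whole cohort (transfusion + completeness;
    the singleton filter is global per patient by design)."""
    rng = np.random.default_rng(13)
    rows = []
    for i in range(60):
        over = {"RDW": np.nan} if rng.random() < 0.2 else {}
        rows.append((f"p{rng.integers(6)}", float(rng.uniform(0, 200)), "W",
                     over))
    cohort = make_cohort(rows)
    events = make_events([(f"p{i}", float(rng.uniform(0, 200)))
                          for i in range(6)])
    whole = wl.filter_complete_cbc(
        wl.filter_transfusions(cohort, events, 90), wl.ANALYTES)
    for pid in cohort.samples["patient_id"].unique():
        alone = cohort.subset(cohort.samples["patient_id"] == pid)
        alone_f = wl.filter_complete_cbc(
            wl.filter_transfusions(alone, events, 90), wl.ANALYTES)
        assert alone_f.samples["sample_id"].tolist() == \
            whole.samples.loc[whole.samples["patient_id"] == pid,
                              "sample_id"].tolist()


def test_temporal_split_partitions_by_day():
    cohort = make_cohort([("p1", float(d), "W") for d in range(10)])
    train, test = wl.temporal_split(cohort, 8)
    assert (train.day_group() < 8).all()
    assert (test.day_group() >= 8).all()
    all_ids = set(cohort.samples["sample_id"])
    assert set(train.samples["sample_id"]) | set(test.samples["sample_id"]) == all_ids
    assert not set(train.samples["sample_id"]) & set(test.samples["sample_id"])


def test_temporal_split_empty_test_reported():
    cohort = make_cohort([("p1", 0.2, "W"), ("p2", 0.7, "W")])
    train, test = wl.temporal_split(cohort, 1)
    assert len(test) == 0
    assert any("empty test set" in w for w in test.warnings)


def test_temporal_split_out_of_span_fails():
    cohort = make_cohort([("p1", 0, "W"), ("p1", 5, "W")])
    with pytest.raises(ValueError, match="span"):
        wl.temporal_split(cohort, 500)


def test_filter_trace_counts_monotone():
    cfg = wl.CohortConfig(n_patients=300, duration_days=200,
                          transfusion_rate=0.2, rng_seed=2)
    cohort, events = wl.generate_cohort(cfg)
    _, trace = wl.apply_filters(cohort, events, 90)
    samples = [s for _, s, _ in trace.stages]
    patients = [p for _, _, p in trace.stages]
    assert samples == sorted(samples, reverse=True)
    assert patients == sorted(patients, reverse=True)
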