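"""Shared fixtures: hand-built micro-cohorts and seeded synthetic data."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import wbitlab as wl

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

ORIGIN = pd.Timestamp("2019-01-01")

_DEFAULTS = {"ERY": 4.1, "HB": 12.4, "MCV": 90.5, "RDW": 14.4,
             "PLT": 238.0, "LEUKO": 8.0}


def make_cohort(rows):
    """Build a CohortTable from (patient_id, day, ward[, analyte overrides]).

    Analytes default to population medians with derived values consistent;
    overrides may set any analyte (including NaN to mark it missing).
    """
    records = []
    for i, row in enumerate(rows):
        pid, day, ward = row[:3]
        overrides = row[3] if len(row) > 3 else {}
        hk, mch, mchc = wl.derive_calculated_analytes(
            _DEFAULTS["ERY"], _DEFAULTS["HB"], _DEFAULTS["MCV"])
        full = {**_DEFAULTS, "HK": hk, "MCH": mch, "MCHC": mchc}
        full.update(overrides)
        records.append({
            "sample_id": f"s{i:03d}", "patient_id": pid,
            "drawn_at": ORIGIN + pd.Timedelta(days=float(day)),
            "ward": ward, "sex": "female", "age": 60, **full})
    df = pd.DataFrame(records)
    return wl.CohortTable(df, time_origin=ORIGIN)


def make_events(entries):
    """Transfusion table from (patient_id, day) tuples."""
    return pd.DataFrame({
        "patient_id": [p for p, _ in entries],
        "transfused_at": [ORIGIN + pd.Timedelta(days=float(d))
                          for _, d in entries]})


@pytest.fixture(scope="session")
def planted_features():
    """Swapped pair features where only MCV and RDW carry class signal."""
    cfg = wl.CohortConfig(
        n_patients=1100, duration_days=60, wards=("A", "B", "C", "D"),
        samples_per_patient={"1": 0.1, "2": 0.5, "3-5": 0.3, ">5": 0.1},
        gap_weights={"<1d": 0.4, "1-7d": 0.4, "7-30d": 0.15, ">30d": 0.05},
        transfusion_rate=0.0, variation=wl.planted_signal_variation(),
        rng_seed=11)
    cohort, _ = wl.generate_cohort(cfg)
    pairs = wl.build_nonwbit_pairs(cohort, 30)
    swapped = wl.simulate_wbit(pairs, seed=12)
    return wl.delta_features(swapped)


@pytest.fixture(scope="session")
def dense_swapped_pairs():
    """Large dense cohort: >= 5000 pairs, all (day x ward) groups big."""
    cfg = wl.CohortConfig(
        n_patients=4200, duration_days=40, wards=("A", "B"),
        samples_per_patient={"1": 0.1, "2": 0.5, "3-5": 0.3, ">5": 0.1},
        gap_weights={"<1d": 0.45, "1-7d": 0.4, "7-30d": 0.1, ">30d": 0.05},
        transfusion_rate=0.0, rng_seed=7)
    cohort, _ = wl.generate_cohort(cfg)
    pairs = wl.build_nonwbit_pairs(cohort, 30)
    return pairs, wl.simulate_wbit(pairs, seed=5)


@pytest.fixture(scope="session")
def realistic_features():
    """Moderate realistic cohort run through the full preparation chain."""
    cfg = wl.CohortConfig(n_patients=900, duration_days=300, rng_seed=21)
    cohort, events = wl.generate_cohort(cfg)
    filtered, _ = wl.apply_filters(cohort, events, 90)
    pairs = wl.build_nonwbit_pairs(filtered, 30)
    swapped = wl.simulate_wbit(pairs, seed=22)
    return wl.delta_features(swapped)
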