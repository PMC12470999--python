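"""Cohort filtering and temporal splitting.

Three filter stages run in a fixed order before any pairing:

1. **transfusion filter** — drop samples drawn within a window (default
   90 days) *after* a transfusion of the same patient, because transfused
   blood shifts the recipient's CBC away from their own set points;
2. **singleton filter** — drop patients left with fewer than two samples,
   since pairing needs at least two draws;
3. **complete-CBC filter** — drop samples missing any analyte of the
   requested panel.

The temporal split assigns the first ``train_days`` of the cohort to
training/validation and the remainder to the test set; patient-level
separation is deliberately not enforced, mirroring a deployment setting
where a periodically retrained model sees both new and known patients.
All later preprocessing (pairing, swap simulation) runs independently per
split so nothing leaks across the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json
import numpy as np
import pandas as pd

from .io_core import ANALYTES, CohortTable

__all__ = [
    "FilterTrace",
    "filter_transfusions",
    "filter_singletons",
    "filter_complete_cbc",
    "apply_filters",
    "temporal_split",
]


@dataclass
class FilterTrace:
    """Sample/patient counts after each filter stage, in stage order."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)

    def record(self, name: str, cohort: CohortTable) -> None:
        n_samples, n_patients = len(cohort), cohort.n_patients
        if self.stages:
            _, prev_s, prev_p = self.stages[-1]
            if n_samples > prev_s or n_patients > prev_p:
                raise ValueError("filter stages must not increase counts")
        self.stages.append((name, n_samples, n_patients))

    def to_json(self) -> str:
        return json.dumps(
            [{"stage": s, "samples": n, "patients": p}
             for s, n, p in self.stages], indent=2)


def filter_transfusions(cohort: CohortTable, events: pd.DataFrame,
                        window_days: int) -> CohortTable:
    """Drop samples drawn in ``[t, t + window_days]`` after a transfusion
    at time ``t`` of the same patient (both endpoints inclusive).

    Samples strictly before every transfusion of the patient are retained,
    as are all samples of patients without events.
    """
    if window_days < 0:
        raise ValueError("window_days must be >= 0")
    if events is None or not len(events):
        return cohort.subset(pd.Series(True, index=cohort.samples.index))
    by_patient: dict[str, np.ndarray] = {
        pid: grp["transfused_at"].to_numpy()
        for pid, grp in events.groupby("patient_id")
    }
    window = np.timedelta64(window_days * 86400, "s")
    keep = np.ones(len(cohort.samples), dtype=bool)
    times = cohort.samples["drawn_at"].to_numpy()
    for i, (pid, t) in enumerate(zip(cohort.samples["patient_id"], times)):
        ev = by_patient.get(pid)
        if ev is None:
            continue
        delta = t - ev
        if np.any((delta >= np.timedelta64(0, "s")) & (delta <= window)):
            keep[i] = False
    return cohort.subset(pd.Series(keep, index=cohort.samples.index))


def filter_singletons(cohort: CohortTable) -> CohortTable:
    """Drop patients with fewer than two remaining samples."""
    counts = cohort.samples.groupby("patient_id")["sample_id"].transform("size")
    return cohort.subset(counts >= 2)


def filter_complete_cbc(cohort: CohortTable,
                        panel: tuple[str, ...] = ANALYTES) -> CohortTable:
    """Keep only samples with a value for every analyte in ``panel``."""
    if not panel:
        raise ValueError("panel must not be empty")
    mask = cohort.samples[list(panel)].notna().all(axis=1)
    return cohort.subset(mask)


def apply_filters(cohort: CohortTable, events: pd.DataFrame,
                  window_days: int = 90,
                  panel: tuple[str, ...] = ANALYTES,
                  refilter_singletons: bool = False,
                  ) -> tuple[CohortTable, FilterTrace]:
    """Run the full filter chain, recording counts after each stage.

    Singleton status is re-evaluated once, after the transfusion filter.
    ``refilter_singletons=True`` additionally re-runs the singleton filter
    after the completeness filter (off by default).
    """
    trace = FilterTrace()
    trace.record("input", cohort)
    cohort = filter_transfusions(cohort, events, window_days)
    trace.record("transfusion", cohort)
    cohort = filter_singletons(cohort)
    trace.record("singletons", cohort)
    cohort = filter_complete_cbc(cohort, panel)
    trace.record("cbc_complete", cohort)
    if refilter_singletons:
        cohort = filter_singletons(cohort)
        trace.record("singletons_recheck", cohort)
    return cohort, trace


def temporal_split(cohort: CohortTable, train_days: int,
                   ) -> tuple[CohortTable, CohortTable]:
    """Split by calendar day index: day < ``train_days`` goes to train,
    everything else to test.  Fails if ``train_days`` is outside the
    cohort's span; an empty test set is allowed but reported."""
    span = cohort.span_days()
    if not 0 < train_days <= span + 1:
        raise ValueError(
            f"train_days={train_days} outside cohort span of {span:.1f} days")
    day = cohort.day_group()
    train = cohort.subset(day < train_days)
    test = cohort.subset(day >= train_days)
    if not len(test):
        test.warnings.append("temporal split produced an empty test set")
    return train, test
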