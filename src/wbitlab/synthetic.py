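"""Synthetic longitudinal CBC cohorts with realistic biological variation.

The generator reproduces the statistical structure the downstream analysis
relies on, without modeling pathology:

* every patient has a per-analyte *set point* drawn from a between-individual
  distribution; individual draws fluctuate around that set point with a
  (smaller) within-individual variation.  Low within-to-between variation
  ratios are exactly what makes red-cell indices such as MCV and RDW good
  identity signals;
* only the six directly measured analytes (ERY, HB, MCV, RDW, PLT, LEUKO)
  are sampled; hematocrit, MCH and MCHC are derived through the analyzer
  identities, preserving the redundancy structure of real CBC panels;
* draws cluster in wards and days: a patient keeps one ward per admission
  episode, and inter-sample gaps mix same-day redraws with gaps of days,
  weeks and months;
* a configurable fraction of patients has transfusion events, so the
  post-transfusion exclusion filter has something to remove.

Platelets and white cells use a lognormal family (their population
distributions are strongly right-skewed); the erythrocyte indices are
normal.  Everything is fully determined by the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_core import ANALYTES, CohortTable, MEASURED_ANALYTES

__all__ = [
    "AnalyteVariationSpec",
    "CohortConfig",
    "derive_calculated_analytes",
    "generate_cohort",
    "planted_signal_variation",
]


def derive_calculated_analytes(ery, hb, mcv):
    """Analyzer identities for the derived analytes.

    hk [%] = ery [10^6/uL] * mcv [fL] / 10
    mch [pg] = 10 * hb [g/dL] / ery [10^6/uL]
    mchc [g/dL] = 100 * hb [g/dL] / hk [%]

    Exact identities, no noise; accepts scalars or arrays.  Raises on any
    nonpositive input, since all three ratios are undefined there.
    """
    ery = np.asarray(ery, dtype=float)
    hb = np.asarray(hb, dtype=float)
    mcv = np.asarray(mcv, dtype=float)
    if np.any(ery <= 0) or np.any(hb <= 0) or np.any(mcv <= 0):
        raise ValueError("derived analytes require strictly positive ERY, HB, MCV")
    hk = ery * mcv / 10.0
    mch = 10.0 * hb / ery
    mchc = 100.0 * hb / hk
    if hk.ndim == 0:
        return float(hk), float(mch), float(mchc)
    return hk, mch, mchc


@dataclass(frozen=True)
class AnalyteSpec:
    """Generative parameters for one measured analyte."""

    population_mean: float
    cv_between: float  # between-individual coefficient of variation
    cv_within: float   # within-individual coefficient of variation
    family: str = "normal"  # "normal" | "lognormal"

    def __post_init__(self) -> None:
        if self.cv_between <= 0 or self.cv_within <= 0:
            raise ValueError("coefficients of variation must be positive")
        if self.family not in ("normal", "lognormal"):
            raise ValueError(f"unknown distribution family {self.family!r}")

    @property
    def cv_total(self) -> float:
        return float(np.hypot(self.cv_between, self.cv_within))


def _default_specs() -> dict[str, AnalyteSpec]:
    # Population means and total CVs track a large central-European
    # inpatient population; the within-individual CVs follow published
    # biological-variation estimates (MCV and RDW vary little within a
    # person relative to between people, platelets and white cells a lot).
    return {
        "ERY": AnalyteSpec(4.11, 0.177, 0.035),
        "HB": AnalyteSpec(12.27, 0.180, 0.030),
        "MCV": AnalyteSpec(90.7, 0.081, 0.010),
        "RDW": AnalyteSpec(14.89, 0.133, 0.025),
        "PLT": AnalyteSpec(255.4, 0.431, 0.090, family="lognormal"),
        "LEUKO": AnalyteSpec(9.03, 0.676, 0.140, family="lognormal"),
    }


@dataclass
class AnalyteVariationSpec:
    """Per-analyte generative model for the six measured analytes."""

    specs: dict[str, AnalyteSpec] = field(default_factory=_default_specs)

    def __post_init__(self) -> None:
        missing = set(MEASURED_ANALYTES) - set(self.specs)
        if missing:
            raise ValueError(f"variation spec missing analytes: {sorted(missing)}")


def planted_signal_variation(signal: tuple[str, ...] = ("MCV", "RDW"),
                             ) -> AnalyteVariationSpec:
    """Variation spec where only ``signal`` analytes separate patients.

    Signal analytes keep realistic between-individual spread with very low
    within-individual noise; every other measured analyte gets a negligible
    between-individual spread, so its first-order differences look the same
    for same-patient and swapped pairs.  Used to test that subset search
    and the importance metrics recover a known ground truth.
    """
    base = _default_specs()
    specs = {}
    for name, s in base.items():
        if name in signal:
            specs[name] = replace(s, cv_within=min(s.cv_within, 0.008))
        else:
            specs[name] = replace(s, cv_between=0.004,
                                  cv_within=max(s.cv_within, 0.06))
    return AnalyteVariationSpec(specs)


@dataclass
class CohortConfig:
    """Shape of the generated cohort.

    ``samples_per_patient`` gives weights for drawing each patient's draw
    count from the strata {1, 2, 3-5, >5}; ``gap_weights`` gives the
    probability of an inter-sample gap being <1 day, 1-7 days, 7-30 days or
    >30 days.  Defaults approximate the stratum proportions of a filtered
    tertiary-care cohort (singletons exist pre-filtering).
    """

    n_patients: int = 1000
    duration_days: int = 1585
    wards: tuple[str, ...] = tuple(f"W{i:02d}" for i in range(12))
    samples_per_patient: dict[str, float] = field(default_factory=lambda: {
        "1": 0.25, "2": 0.22, "3-5": 0.27, ">5": 0.26})
    gap_weights: dict[str, float] = field(default_factory=lambda: {
        "<1d": 0.34, "1-7d": 0.21, "7-30d": 0.12, ">30d": 0.33})
    transfusion_rate: float = 0.05
    episode_break_days: float = 7.0  # a longer gap starts a new admission
    variation: AnalyteVariationSpec = field(default_factory=AnalyteVariationSpec)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.duration_days < 1:
            raise ValueError("duration_days must be >= 1")
        if not self.wards:
            raise ValueError("at least one ward is required")
        for name, weights in (("samples_per_patient", self.samples_per_patient),
                              ("gap_weights", self.gap_weights)):
            total = sum(weights.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"{name} weights must sum to 1, got {total}")
        if not 0.0 <= self.transfusion_rate <= 1.0:
            raise ValueError("transfusion_rate must lie in [0, 1]")


_COUNT_STRATA = ("1", "2", "3-5", ">5")
_GAP_STRATA = ("<1d", "1-7d", "7-30d", ">30d")


def _draw_count(rng: np.random.Generator, weights: dict[str, float]) -> int:
    stratum = rng.choice(_COUNT_STRATA, p=[weights.get(s, 0.0) for s in _COUNT_STRATA])
    if stratum == "1":
        return 1
    if stratum == "2":
        return 2
    if stratum == "3-5":
        return int(rng.integers(3, 6))
    return int(6 + rng.geometric(0.35))  # heavy tail of long-stay patients


def _draw_gap(rng: np.random.Generator, weights: dict[str, float]) -> float:
    stratum = rng.choice(_GAP_STRATA, p=[weights.get(s, 0.0) for s in _GAP_STRATA])
    if stratum == "<1d":
        return float(rng.uniform(2.0, 22.0)) / 24.0
    if stratum == "1-7d":
        return float(rng.uniform(1.0, 7.0))
    if stratum == "7-30d":
        return float(rng.uniform(7.0, 30.0))
    return float(rng.uniform(31.0, 75.0))


def gap_stratum(gap_days: float) -> str:
    """Stratum label for a realized inter-sample gap, matching the config."""
    if gap_days < 1.0:
        return "<1d"
    if gap_days < 7.0:
        return "1-7d"
    if gap_days <= 30.0:
        return "7-30d"
    return ">30d"


def _measured_values(rng: np.random.Generator, spec: AnalyteSpec,
                     n_draws: int) -> np.ndarray:
    """Set point + within-individual noise for one patient, one analyte.

    For the normal family the total SD is exactly
    mean * sqrt(cv_between^2 + cv_within^2); the lognormal family matches
    the same total SD by partitioning the log-variance proportionally.
    """
    m = spec.population_mean
    if spec.family == "normal":
        setpoint = rng.normal(m, spec.cv_between * m)
        values = setpoint + rng.normal(0.0, spec.cv_within * m, n_draws)
    else:
        s_tot2 = np.log1p(spec.cv_total ** 2)
        s_b2 = s_tot2 * spec.cv_between ** 2 / spec.cv_total ** 2
        s_w2 = s_tot2 - s_b2
        mu = np.log(m) - s_tot2 / 2.0
        setpoint = rng.normal(mu, np.sqrt(s_b2))
        values = np.exp(setpoint + rng.normal(0.0, np.sqrt(s_w2), n_draws))
    # Physiological floor: analyte concentrations are strictly positive.
    return np.maximum(values, 0.02 * m)


def generate_cohort(cfg: CohortConfig,
                    ) -> tuple[CohortTable, pd.DataFrame]:
    """Generate a cohort and its transfusion-event table.

    Returns the :class:`~wbitlab.io_core.CohortTable` plus a DataFrame with
    columns ``patient_id, transfused_at``.  Byte-identical output for a
    fixed ``cfg.rng_seed``.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    origin = pd.Timestamp("2019-01-01")
    specs = cfg.variation.specs

    rows: list[dict] = []
    transfusions: list[dict] = []
    sample_no = 0
    for p in range(cfg.n_patients):
        pid = f"P{p:06d}"
        n_draws = _draw_count(rng, cfg.samples_per_patient)
        gaps = [_draw_gap(rng, cfg.gap_weights) for _ in range(n_draws - 1)]
        span = float(np.sum(gaps))
        if span < cfg.duration_days:
            start = float(rng.uniform(0.0, cfg.duration_days - span))
        else:
            start = 0.0
        times = start + np.concatenate([[0.0], np.cumsum(gaps)])
        keep = times <= cfg.duration_days
        times = times[keep]
        n_draws = len(times)

        # one ward per admission episode; long gaps start a new episode
        wards = np.empty(n_draws, dtype=object)
        ward = rng.choice(cfg.wards)
        wards[0] = ward
        for i in range(1, n_draws):
            if times[i] - times[i - 1] > cfg.episode_break_days:
                ward = rng.choice(cfg.wards)
            wards[i] = ward

        measured = {a: _measured_values(rng, specs[a], n_draws)
                    for a in MEASURED_ANALYTES}
        hk, mch, mchc = derive_calculated_analytes(
            measured["ERY"], measured["HB"], measured["MCV"])

        sex = rng.choice(("male", "female", "unidentified"),
                         p=(0.4964, 0.5034, 0.0002))
        age = int(np.clip(round(rng.normal(63.8, 20.2)), 0, 106))

        for i in range(n_draws):
            rows.append({
                "sample_id": f"S{sample_no:07d}",
                "patient_id": pid,
                "drawn_at": origin + pd.Timedelta(days=float(times[i])),
                "ward": wards[i],
                "sex": sex,
                "age": age,
                "ERY": measured["ERY"][i], "HB": measured["HB"][i],
                "HK": hk[i], "MCV": measured["MCV"][i], "MCHC": mchc[i],
                "MCH": mch[i], "RDW": measured["RDW"][i],
                "PLT": measured["PLT"][i], "LEUKO": measured["LEUKO"][i],
            })
            sample_no += 1

        if rng.random() < cfg.transfusion_rate:
            t = float(rng.uniform(0.0, cfg.duration_days))
            transfusions.append({
                "patient_id": pid,
                "transfused_at": origin + pd.Timedelta(days=t),
            })

    columns = ["sample_id", "patient_id", "drawn_at", "ward", "sex", "age",
               *ANALYTES]
    samples = pd.DataFrame(rows, columns=columns)
    samples["drawn_at"] = samples["drawn_at"].dt.round("s")
    events = pd.DataFrame(transfusions, columns=["patient_id", "transfused_at"])
    if len(events):
        events["transfused_at"] = events["transfused_at"].dt.round("s")
    cohort = CohortTable(samples, time_origin=origin)
    return cohort, events
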