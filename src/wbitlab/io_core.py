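"""Data model, readers/writers, configuration and validation for CBC cohorts.

A cohort is a longitudinal table of complete-blood-count (CBC) draws: one row
per blood sample with a patient identifier, a timestamp, the hospital ward,
demographics, and the nine CBC analytes reported by a standard hematology
analyzer.  Everything downstream (pairing, wrong-blood-in-tube simulation,
model search) consumes the :class:`CohortTable` defined here.

Analyte naming and units follow common German laboratory convention:

======  ==============================  ===========
name    analyte                         unit
======  ==============================  ===========
ERY     red blood cells                 10^6/uL
HB      hemoglobin                      g/dL
HK      hematocrit                      %
MCV     mean corpuscular volume         fL
MCH     mean corpuscular hemoglobin     pg
MCHC    MCH concentration               g/dL
RDW     red cell distribution width     %
PLT     platelets                       10^3/uL
LEUKO   white blood cells               10^3/uL
======  ==============================  ===========

HK, MCH and MCHC are derived by the analyzer from ERY, HB and MCV; see
:func:`wbitlab.synthetic.derive_calculated_analytes`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: Canonical analyte panel (order fixed; used everywhere downstream).
ANALYTES: tuple[str, ...] = (
    "ERY", "HB", "HK", "MCV", "MCHC", "MCH", "RDW", "PLT", "LEUKO",
)

#: Analytes measured directly by the analyzer.
MEASURED_ANALYTES: tuple[str, ...] = ("ERY", "HB", "MCV", "RDW", "PLT", "LEUKO")

#: Analytes the analyzer computes from the measured ones.
DERIVED_ANALYTES: tuple[str, ...] = ("HK", "MCH", "MCHC")

#: Columns every cohort file must provide.
MANDATORY_COLUMNS: tuple[str, ...] = ("sample_id", "patient_id", "drawn_at", "ward")

#: Physically plausible value ranges, at least as wide as observed
#: population min/max.  Values outside these are flagged by
#: :func:`validate_cohort`, never silently altered.
PLAUSIBILITY_BOUNDS: dict[str, tuple[float, float]] = {
    "ERY": (0.1, 15.0),
    "HB": (0.5, 30.0),
    "HK": (1.0, 95.0),
    "MCV": (20.0, 160.0),
    "MCHC": (5.0, 160.0),
    "MCH": (5.0, 120.0),
    "RDW": (5.0, 50.0),
    "PLT": (1.0, 3000.0),
    "LEUKO": (0.05, 600.0),
}

SEX_CATEGORIES = ("male", "female", "unidentified")


@dataclass
class CohortTable:
    """Longitudinal sample table plus its time origin.

    ``samples`` has one row per blood draw with columns
    ``sample_id, patient_id, drawn_at, ward, sex, age`` and the nine
    analyte columns (NaN where an analyte was not measured).

    ``time_origin`` is midnight of the earliest draw; day indices are whole
    days since that instant, so every window rule (90-day transfusion
    window, 30-day pairing gap, 24-h swap bins) operates on real-valued
    day differences from a single anchor.
    """

    samples: pd.DataFrame
    time_origin: pd.Timestamp | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.samples
        if len(df) and df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].unique()
            raise ValueError(f"duplicate sample_id values: {list(dupes[:5])}")
        if self.time_origin is None and len(df):
            self.time_origin = pd.Timestamp(df["drawn_at"].min()).normalize()

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def n_patients(self) -> int:
        return self.samples["patient_id"].nunique()

    def day_index(self) -> pd.Series:
        """Real-valued days since the time origin, one per sample."""
        if self.time_origin is None:
            return pd.Series(dtype=float)
        delta = self.samples["drawn_at"] - self.time_origin
        return delta.dt.total_seconds() / 86400.0

    def day_group(self) -> pd.Series:
        """Integer calendar-day index (floor of :meth:`day_index`)."""
        return np.floor(self.day_index()).astype(int)

    def span_days(self) -> float:
        """Total time span of the cohort in days."""
        if not len(self.samples):
            return 0.0
        return float(self.day_index().max())

    def subset(self, mask: pd.Series) -> "CohortTable":
        """New cohort with the masked rows; the time origin is retained so
        day indices stay comparable across filter stages and splits."""
        return CohortTable(
            self.samples.loc[mask].reset_index(drop=True).copy(),
            time_origin=self.time_origin,
        )


@dataclass
class PipelineConfig:
    """All tunable knobs of the detection pipeline, with study defaults.

    The windows (90-day post-transfusion exclusion, 30-day maximum pairing
    gap, 24-h swap intervals), the ~50 % simulated-error target, the
    1269/316-day temporal split, 5-fold cross-validation, 1000-iteration
    bootstrap at the 95 % level, an assumed deployment prevalence of 0.5 %
    and a 0.5 decision threshold are the conditions of the analysis this
    package reproduces.
    """

    transfusion_window_days: int = 90
    max_pair_gap_days: int = 30
    wbit_interval_hours: int = 24
    wbit_target_fraction: float = 0.5
    train_days: int = 1269
    test_days: int = 316
    cv_folds: int = 5
    bootstrap_iterations: int = 1000
    ci_level: float = 0.95
    assumed_prevalence: float = 0.005
    decision_threshold: float = 0.5
    n_trees: int = 100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("wbit_target_fraction", "ci_level", "assumed_prevalence",
                     "decision_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name in ("max_pair_gap_days", "wbit_interval_hours", "train_days",
                     "test_days", "cv_folds", "bootstrap_iterations", "n_trees"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.transfusion_window_days < 0:
            raise ValueError("transfusion_window_days must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) \
            else json.loads(text)
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(data, sort_keys=False))
        else:
            path.write_text(json.dumps(data, indent=2))


@dataclass
class ValidationReport:
    """Summary of a cohort scan; purely descriptive, never mutates data."""

    n_samples: int
    n_patients: int
    out_of_range: dict[str, int]
    missing: dict[str, int]

    @property
    def total_violations(self) -> int:
        return sum(self.out_of_range.values())

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_cohort(path: str | Path,
                dialect: dict[str, str] | None = None) -> CohortTable:
    """Read a delimited cohort table (CSV/TSV by extension, UTF-8, header row).

    Parameters
    ----------
    path
        Delimited text file, one row per blood draw.
    dialect
        Optional mapping from the file's column names to the canonical ones
        (``sample_id``, ``patient_id``, ``drawn_at``, ``ward``, ``sex``,
        ``age``, and analyte names), so site exports with local headers can
        be read without rewriting the file.

    Missing analyte columns are recorded as all-missing (NaN) and noted in
    ``CohortTable.warnings``; rows whose mandatory fields fail to parse are
    dropped and reported in the warnings, never silently.
    """
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"sample_id": str,
                                                      "patient_id": str})
    if dialect:
        df = df.rename(columns=dialect)
    missing_cols = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort file is missing mandatory columns: {missing_cols}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].unique()
        raise ValueError(f"duplicate sample_id values: {list(dupes[:5])}")

    warnings: list[str] = []
    drawn = pd.to_datetime(df["drawn_at"], errors="coerce", format="mixed")
    bad = drawn.isna() | df["sample_id"].isna() | df["patient_id"].isna()
    if bad.any():
        warnings.append(
            f"dropped {int(bad.sum())} rows with unparseable mandatory fields: "
            f"sample_ids {df.loc[bad, 'sample_id'].tolist()[:10]}")
        df = df.loc[~bad].reset_index(drop=True)
        drawn = drawn.loc[~bad].reset_index(drop=True)
    df = df.copy()
    df["drawn_at"] = drawn

    for col in ("sex", "age"):
        if col not in df.columns:
            df[col] = "unidentified" if col == "sex" else np.nan
            warnings.append(f"column {col!r} absent; filled with defaults")
    for analyte in ANALYTES:
        if analyte not in df.columns:
            df[analyte] = np.nan
            warnings.append(f"analyte column {analyte!r} absent; marked missing")
        else:
            df[analyte] = pd.to_numeric(df[analyte], errors="coerce")

    cols = list(MANDATORY_COLUMNS) + ["sex", "age"] + list(ANALYTES)
    cohort = CohortTable(df[cols].reset_index(drop=True))
    cohort.warnings = warnings
    return cohort


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort as delimited text; inverse of :func:`read_cohort`."""
    df = cohort.samples.copy()
    df["drawn_at"] = df["drawn_at"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_transfusions(path: str | Path) -> pd.DataFrame:
    """Read a transfusion-event table: columns patient_id, transfused_at."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"patient_id": str})
    for col in ("patient_id", "transfused_at"):
        if col not in df.columns:
            raise ValueError(f"transfusion file is missing column {col!r}")
    df = df.copy()
    df["transfused_at"] = pd.to_datetime(df["transfused_at"], format="mixed")
    return df[["patient_id", "transfused_at"]]


def write_transfusions(events: pd.DataFrame, path: str | Path) -> None:
    df = events.copy()
    df["transfused_at"] = df["transfused_at"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, sep=_sep_for(path), index=False)


def validate_cohort(cohort: CohortTable,
                    bounds: dict[str, tuple[float, float]] | None = None,
                    ) -> ValidationReport:
    """Scan a cohort for out-of-range and missing analyte values.

    ``bounds`` defaults to :data:`PLAUSIBILITY_BOUNDS`.  A value is a
    violation when it is present but nonpositive or outside its bounds.
    """
    bounds = bounds or PLAUSIBILITY_BOUNDS
    df = cohort.samples
    out_of_range: dict[str, int] = {}
    missing: dict[str, int] = {}
    for analyte in ANALYTES:
        values = df[analyte] if analyte in df.columns else pd.Series(dtype=float)
        present = values.notna()
        missing[analyte] = int((~present).sum()) if len(df) else 0
        lo, hi = bounds.get(analyte, (0.0, np.inf))
        bad = present & ((values <= 0) | (values < lo) | (values > hi))
        out_of_range[analyte] = int(bad.sum())
    return ValidationReport(
        n_samples=len(df),
        n_patients=df["patient_id"].nunique() if len(df) else 0,
        out_of_range=out_of_range,
        missing=missing,
    )
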