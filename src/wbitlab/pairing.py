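"""Sample pairing, wrong-blood-in-tube simulation, and delta features.

The unit of classification is a *pair* of consecutively drawn samples.
Same-patient pairs are the non-WBIT class; WBIT (wrong blood in tube)
cases are simulated by swapping the *second* (more recent) samples of two
pairs whose patients differ, restricted to pairs whose second samples share
the same calendar day and ward — a mislabeled tube can only be confused
with tubes drawn around the same time and place.

Model features are first-order differences: for each analyte, the value of
the earlier sample subtracted from the later one.  For a same-patient pair
the difference reflects within-individual variation only; a swap injects
between-individual variation, which is what the classifier learns to see.

Pairs are held in a flat :class:`pandas.DataFrame` (one row per pair) with
``first_*``/``second_*`` columns for ids, timestamps and all nine analytes,
plus ``label`` ("non-WBIT"/"WBIT"), ``day_group``, ``ward_group`` and
``gap_days``.  Group keys and gaps always refer to the pair as originally
drawn; a swap changes only the second sample's payload and the label.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .io_core import ANALYTES, CohortTable

__all__ = ["build_nonwbit_pairs", "simulate_wbit", "delta_features",
           "wbit_fraction", "PAIR_META_COLUMNS"]

NON_WBIT = "non-WBIT"
WBIT = "WBIT"

PAIR_META_COLUMNS = (
    "first_sample_id", "second_sample_id",
    "first_patient_id", "second_patient_id",
    "first_drawn_at", "second_drawn_at",
    "label", "day_group", "ward_group", "gap_days",
)

# second-sample columns exchanged by a swap (payload, not group metadata)
_SWAP_COLUMNS = ["second_sample_id", "second_patient_id",
                 *[f"second_{a}" for a in ANALYTES]]


def build_nonwbit_pairs(cohort: CohortTable, max_gap_days: float,
                        ) -> pd.DataFrame:
    """Pair each patient's consecutive draws, keeping gaps <= ``max_gap_days``.

    Samples are sorted by draw time (sample id breaking ties); every
    adjacent pair within the gap limit yields one non-WBIT row.  Chains
    overlap: a sample may be the second member of one pair and the first of
    the next.
    """
    if max_gap_days <= 0:
        raise ValueError("max_gap_days must be positive")
    df = cohort.samples.sort_values(
        ["patient_id", "drawn_at", "sample_id"], kind="mergesort")
    day = cohort.day_index()
    first = df.iloc[:-1].reset_index(drop=True) if len(df) else df
    second = df.iloc[1:].reset_index(drop=True) if len(df) else df
    if not len(df) or len(df) < 2:
        return _empty_pairs()

    same_patient = first["patient_id"].to_numpy() == second["patient_id"].to_numpy()
    gap = (second["drawn_at"].to_numpy() - first["drawn_at"].to_numpy()
           ) / np.timedelta64(1, "D")
    keep = same_patient & (gap <= max_gap_days)

    first, second, gap = first[keep], second[keep], gap[keep]
    origin = cohort.time_origin
    day_group = np.floor(
        (second["drawn_at"] - origin).dt.total_seconds() / 86400.0
    ).astype(int)

    out = pd.DataFrame({
        "first_sample_id": first["sample_id"].to_numpy(),
        "second_sample_id": second["sample_id"].to_numpy(),
        "first_patient_id": first["patient_id"].to_numpy(),
        "second_patient_id": second["patient_id"].to_numpy(),
        "first_drawn_at": first["drawn_at"].to_numpy(),
        "second_drawn_at": second["drawn_at"].to_numpy(),
        "label": NON_WBIT,
        "day_group": day_group.to_numpy(),
        "ward_group": second["ward"].to_numpy(),
        "gap_days": gap,
    })
    for a in ANALYTES:
        out[f"first_{a}"] = first[a].to_numpy()
        out[f"second_{a}"] = second[a].to_numpy()
    return out.reset_index(drop=True)


def _empty_pairs() -> pd.DataFrame:
    cols = list(PAIR_META_COLUMNS) + [f"{w}_{a}" for a in ANALYTES
                                      for w in ("first", "second")]
    return pd.DataFrame(columns=cols)


def simulate_wbit(pairs: pd.DataFrame, interval_hours: int = 24,
                  target_fraction: float = 0.5, seed: int = 0,
                  ) -> pd.DataFrame:
    """Simulate wrong-blood-in-tube errors by constrained swapping.

    Pairs are grouped by the calendar bin (``interval_hours``-wide,
    anchored where day index 0 starts) and ward of their *second* sample.
    Within each group holding at least two distinct second-sample patients,
    swaps are drawn uniformly at random without replacement: two
    not-yet-swapped pairs with different second patients exchange their
    second samples and both become WBIT.  ``ceil(target_fraction * group
    size / 2)`` swaps are attempted per group, capped by eligibility, so a
    group of two converts fully and an odd group retains one unmatched
    non-WBIT pair.  Groups with fewer than two distinct patients pass
    through untouched.  Deterministic given ``seed``.
    """
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target_fraction must lie in (0, 1)")
    if (pairs["label"] == WBIT).any():
        raise ValueError("input already contains WBIT pairs; "
                         "simulate_wbit must not be applied twice")
    out = pairs.reset_index(drop=True).copy()
    if not len(out):
        return out
    rng = np.random.default_rng(seed)

    if interval_hours == 24:
        bins = out["day_group"].to_numpy()
    else:
        hours = out["day_group"].to_numpy() * 24.0 + (
            (out["second_drawn_at"]
             - out["second_drawn_at"].dt.normalize()).dt.total_seconds() / 3600.0)
        bins = np.floor(hours / interval_hours).astype(int)

    groups = pd.DataFrame({"bin": bins, "ward": out["ward_group"]}).groupby(
        ["bin", "ward"], sort=True).indices

    swap_cols = out.columns.intersection(_SWAP_COLUMNS)
    labels = out["label"].to_numpy(dtype=object)
    payload = out[swap_cols].to_numpy(dtype=object)
    patients = out["second_patient_id"].to_numpy(dtype=object)

    for key in sorted(groups):
        idx = np.asarray(groups[key])
        if len(np.unique(patients[idx])) < 2:
            continue
        n_swaps = math.ceil(target_fraction * len(idx) / 2.0)
        order = rng.permutation(idx)
        available = list(order)
        done = 0
        while done < n_swaps and len(available) >= 2:
            a = available.pop(0)
            partner_pos = next(
                (j for j, b in enumerate(available)
                 if patients[b] != patients[a]), None)
            if partner_pos is None:
                continue  # a stays non-WBIT; no partner with another patient
            b = available.pop(partner_pos)
            payload[[a, b]] = payload[[b, a]]
            labels[a] = labels[b] = WBIT
            done += 1

    out[swap_cols.tolist()] = payload
    out["label"] = labels
    # a swap pairs two pairs with different second patients; since every
    # input pair is same-patient, the new second patient always differs
    # from the first -- assert the labeling invariant anyway
    is_wbit = out["label"] == WBIT
    mismatch = out["first_patient_id"] != out["second_patient_id"]
    if not (is_wbit == mismatch).all():
        raise AssertionError("label/patient mismatch after swap simulation")
    return out


def wbit_fraction(pairs: pd.DataFrame) -> float:
    """Fraction of pairs labeled WBIT."""
    if not len(pairs):
        return 0.0
    return float((pairs["label"] == WBIT).mean())


def delta_features(pairs: pd.DataFrame,
                   subset: tuple[str, ...] = ANALYTES) -> pd.DataFrame:
    """First-order differences (second minus first) over ``subset``.

    Returns a DataFrame with one delta column per analyte (in ``subset``
    order) plus the inherited ``label`` column.  A missing analyte value
    anywhere in ``subset`` is a hard error naming the pair and analyte.
    """
    if not subset:
        raise ValueError("analyte subset must not be empty")
    unknown = [a for a in subset if a not in ANALYTES]
    if unknown:
        raise ValueError(f"unknown analytes: {unknown}")
    out = pd.DataFrame(index=pairs.index)
    for a in subset:
        f, s = pairs[f"first_{a}"], pairs[f"second_{a}"]
        bad = f.isna() | s.isna()
        if bad.any():
            i = bad.idxmax()
            raise ValueError(
                f"analyte {a!r} missing for pair "
                f"({pairs.loc[i, 'first_sample_id']}, "
                f"{pairs.loc[i, 'second_sample_id']})")
        out[a] = (s - f).astype(float)
    out["label"] = pairs["label"].to_numpy()
    if not np.isfinite(out[list(subset)].to_numpy()).all():
        raise ValueError("non-finite delta feature encountered")
    return out
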