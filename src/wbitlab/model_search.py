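"""Cross-validated Random-Forest training and exhaustive subset ranking.

The classifier is a Random Forest over delta features, trained with
class-balanced weights; all other hyperparameters stay at the scikit-learn
defaults, with the forest size pinned in configuration for cross-version
reproducibility.  For each analyte-set size ``n`` every one of the
``C(9, n)`` combinations is scored by stratified K-fold cross-validation
and ranked by mean F1.  The fold partition is created once per search and
shared across all subsets so fold scores stay aligned — the paired t-tests
comparing subsets require exactly that alignment.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .io_core import ANALYTES
from .pairing import WBIT

__all__ = ["FoldScores", "SubsetResult", "train_forest", "fold_partition",
           "crossval_subset", "exhaustive_search", "paired_fold_ttest",
           "results_table", "labels_to_binary"]

METRICS = ("accuracy", "f1", "roc_auc", "ppv", "sensitivity")


def labels_to_binary(labels) -> np.ndarray:
    """Map pair labels to {0: non-WBIT, 1: WBIT}."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "OUS":
        return (arr == WBIT).astype(int)
    return arr.astype(int)


@dataclass
class FoldScores:
    """Per-fold scores plus the confusion counts they derive from."""

    accuracy: np.ndarray
    f1: np.ndarray
    roc_auc: np.ndarray
    ppv: np.ndarray
    sensitivity: np.ndarray
    confusion: np.ndarray  # (k, 4) rows of (tp, fp, fn, tn)

    @property
    def k(self) -> int:
        return len(self.f1)

    def mean(self, metric: str) -> float:
        return float(np.nanmean(getattr(self, metric)))

    def sd(self, metric: str) -> float:
        return float(np.nanstd(getattr(self, metric), ddof=1))


@dataclass(order=True)
class SubsetResult:
    """Cross-validated result for one analyte combination.

    Orders by descending mean F1 with lexicographic subset tie-break, so
    sorting a list of results is deterministic.
    """

    sort_key: tuple = field(init=False, repr=False)
    subset: tuple[str, ...]
    scores: FoldScores

    def __post_init__(self) -> None:
        self.sort_key = (-self.scores.mean("f1"), self.subset)

    @property
    def n(self) -> int:
        return len(self.subset)

    @property
    def rank_key(self) -> float:
        return self.scores.mean("f1")


def train_forest(X: np.ndarray, y: np.ndarray, seed: int,
                 n_trees: int = 100) -> RandomForestClassifier:
    """Fit the study's classifier: Random Forest, class-balanced weights,
    library defaults otherwise.  Deterministic given ``seed``."""
    y = labels_to_binary(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    model = RandomForestClassifier(
        n_estimators=n_trees, class_weight="balanced",
        random_state=seed, n_jobs=1)
    model.fit(np.asarray(X, dtype=float), y)
    return model


def fold_partition(y: np.ndarray, k: int, seed: int,
                   ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified, shuffled K-fold partition, fixed by ``seed``.

    Stratification keeps the ~50/50 class balance stable per fold; the
    same partition must be reused for every subset that will be compared
    by :func:`paired_fold_ttest`.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = labels_to_binary(y)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(splitter.split(np.zeros((len(y), 1)), y))


def _fold_scores(y_true: np.ndarray, prob: np.ndarray,
                 threshold: float) -> tuple[list[float], np.ndarray]:
    # local import avoids a cycle: evaluation also imports nothing from here
    from .evaluation import confusion_metrics, roc_curve

    m = confusion_metrics(y_true, prob, threshold)
    auc = roc_curve(y_true, prob).auc
    return ([m["accuracy"], m["f1"], auc, m["ppv"], m["sensitivity"]],
            np.array([m["tp"], m["fp"], m["fn"], m["tn"]]))


def crossval_subset(features: pd.DataFrame, subset: tuple[str, ...],
                    k: int = 5, seed: int = 0, n_trees: int = 100,
                    threshold: float = 0.5,
                    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
                    ) -> SubsetResult:
    """Stratified K-fold cross-validation of one analyte subset.

    ``features`` is a delta-feature table over the full panel (as produced
    by :func:`wbitlab.pairing.delta_features`) with a ``label`` column;
    only the ``subset`` columns are fed to the model.  ``folds`` may carry
    a precomputed partition (shared across subsets); otherwise the
    partition is derived from ``seed`` and is identical for every subset
    given the same labels.
    """
    subset = tuple(subset)
    if not subset:
        raise ValueError("analyte subset must not be empty")
    missing = [a for a in subset if a not in features.columns]
    if missing:
        raise ValueError(f"features table lacks columns {missing}")
    y = labels_to_binary(features["label"].to_numpy())
    X = features[list(subset)].to_numpy(dtype=float)
    if folds is None:
        folds = fold_partition(y, k, seed)

    per_metric = {m: [] for m in METRICS}
    confusion = []
    for train_idx, test_idx in folds:
        y_tr, y_te = y[train_idx], y[test_idx]
        if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
            raise ValueError("a fold contains a single class; "
                             "use more data or fewer folds")
        model = train_forest(X[train_idx], y_tr, seed=seed, n_trees=n_trees)
        prob = model.predict_proba(X[test_idx])[:, 1]
        row, conf = _fold_scores(y_te, prob, threshold)
        for name, value in zip(METRICS, row):
            per_metric[name].append(value)
        confusion.append(conf)

    scores = FoldScores(
        **{m: np.asarray(per_metric[m], dtype=float) for m in METRICS},
        confusion=np.asarray(confusion))
    return SubsetResult(subset=subset, scores=scores)


def _data_fingerprint(features: pd.DataFrame) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(
        features.select_dtypes("number").to_numpy(dtype=float)).tobytes())
    h.update("".join(map(str, features["label"].tolist())).encode())
    return h.hexdigest()[:16]


def exhaustive_search(features: pd.DataFrame,
                      sizes: range | tuple[int, ...] = range(1, 10),
                      k: int = 5, seed: int = 0, n_trees: int = 100,
                      threshold: float = 0.5,
                      panel: tuple[str, ...] = ANALYTES,
                      cache_dir: str | Path | None = None,
                      ) -> list[SubsetResult]:
    """Cross-validate every analyte combination of the requested sizes.

    Returns one :class:`SubsetResult` per combination — ``C(len(panel), n)``
    per size, 511 in total for the full 1..9 range — sorted within each
    size by descending mean F1 (ties broken by subset name).  When
    ``cache_dir`` is given, per-subset fold scores are written as JSON
    keyed by (subset, seed, k, forest size, data fingerprint), making long
    searches resumable.
    """
    sizes = sorted(set(sizes))
    if any(n < 1 or n > len(panel) for n in sizes):
        raise ValueError(f"sizes must lie in 1..{len(panel)}")
    y = features["label"].to_numpy()
    folds = fold_partition(y, k, seed)
    fingerprint = _data_fingerprint(features) if cache_dir else ""
    if cache_dir:
        cache_dir = Path(cache_dir)
        cache_dir.mkdir(parents=True, exist_ok=True)

    results: list[SubsetResult] = []
    for n in sizes:
        size_results = []
        for subset in itertools.combinations(sorted(panel), n):
            cached = None
            if cache_dir:
                key = "-".join(subset) + f"_{seed}_{k}_{n_trees}_{fingerprint}"
                path = cache_dir / f"{key}.json"
                if path.exists():
                    data = json.loads(path.read_text())
                    cached = SubsetResult(
                        subset=subset,
                        scores=FoldScores(
                            **{m: np.asarray(data[m]) for m in METRICS},
                            confusion=np.asarray(data["confusion"])))
            if cached is None:
                cached = crossval_subset(features, subset, k=k, seed=seed,
                                         n_trees=n_trees, threshold=threshold,
                                         folds=folds)
                if cache_dir:
                    payload = {m: getattr(cached.scores, m).tolist()
                               for m in METRICS}
                    payload["confusion"] = cached.scores.confusion.tolist()
                    path.write_text(json.dumps(payload))
            size_results.append(cached)
        results.extend(sorted(size_results))
    return results


def paired_fold_ttest(a: FoldScores, b: FoldScores, metric: str = "f1",
                      ) -> tuple[float, float]:
    """Two-sided paired t-test on aligned per-fold scores.

    Degenerate-variance conventions: all differences exactly zero gives
    (0, 1); zero variance with a nonzero mean gives (+/-inf, 0).
    """
    if a.k != b.k:
        raise ValueError("fold counts differ; scores are not comparable")
    diff = getattr(a, metric) - getattr(b, metric)
    if np.allclose(diff, 0.0):
        return 0.0, 1.0
    if np.isclose(np.std(diff, ddof=1), 0.0):
        return float(np.sign(diff.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(getattr(a, metric), getattr(b, metric))
    return float(t), float(p)


def results_table(results: list[SubsetResult], top: int | None = 5,
                  ) -> pd.DataFrame:
    """Ranked summary table (percent scale, mean +/- SD per metric)."""
    rows = []
    for n in sorted({r.n for r in results}):
        of_size = sorted(r for r in results if r.n == n)
        for r in of_size[:top] if top else of_size:
            row = {"n": n, "combination": ", ".join(r.subset)}
            for m in METRICS:
                row[m] = 100.0 * r.scores.mean(m)
                row[f"{m}_sd"] = 100.0 * r.scores.sd(m)
            rows.append(row)
    return pd.DataFrame(rows)
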