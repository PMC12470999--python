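"""Analyte-importance metrics for a fitted detection model.

Three complementary views of what the classifier relies on:

* **MDI** (mean decrease in impurity) — impurity reductions summed over
  every split on the analyte, averaged over trees and normalized to sum
  to one.  Cheap, training-data based, biased toward high-cardinality
  features (all delta features are continuous, so comparable here).
* **Permutation importance** — the drop in a held-out performance metric
  (F1 by default) when the analyte's column is shuffled, averaged over
  repeats; reflects what the model actually uses, interactions included.
* **Shapley attribution** — mean absolute per-sample attribution of the
  positive-class probability, from the path-dependent tree Shapley
  implementation in :mod:`wbitlab._treeshap`.

MDI shares are unitless fractions; Shapley means are in probability
units; permutation scores are metric drops in [0, 1] (negative raw drops
are clipped to zero — a shuffled feature cannot be genuinely helpful).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.utils.validation import check_is_fitted

from ._treeshap import exact_shapley, forest_shap_values
from .evaluation import confusion_metrics, roc_curve
from .model_search import labels_to_binary

__all__ = ["mdi_importance", "permutation_importance", "shap_importance",
           "shap_local", "importance_table", "exact_shapley"]


def mdi_importance(model, feature_names: tuple[str, ...] | None = None,
                   ) -> pd.Series:
    """Normalized impurity-decrease share per feature (sums to 1)."""
    check_is_fitted(model)
    values = np.asarray(model.feature_importances_, dtype=float)
    names = feature_names or tuple(getattr(model, "feature_names_in_",
                                           range(len(values))))
    return pd.Series(values, index=list(names), name="mdi")


def _metric_fn(metric: str):
    if metric == "f1":
        return lambda y, p: confusion_metrics(y, p)["f1"]
    if metric == "accuracy":
        return lambda y, p: confusion_metrics(y, p)["accuracy"]
    if metric == "roc_auc":
        return lambda y, p: roc_curve(y, p).auc
    raise ValueError(f"unknown metric {metric!r}")


def permutation_importance(model, X, labels, metric: str = "f1",
                           repeats: int = 10, seed: int = 0,
                           feature_names: tuple[str, ...] | None = None,
                           ) -> pd.Series:
    """Mean held-out metric drop per shuffled feature, clipped at zero.

    Repeats where the metric is undefined on the permuted predictions
    (e.g. a degenerate confusion table) are excluded from that feature's
    mean rather than counted as zero.  Deterministic given ``seed``.
    """
    check_is_fitted(model)
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.n_features_in_:
        raise ValueError(
            f"model expects {model.n_features_in_} features, got {X.shape[1]}")
    y = labels_to_binary(labels)
    score = _metric_fn(metric)
    rng = np.random.default_rng(seed)

    baseline = score(y, model.predict_proba(X)[:, 1])
    names = feature_names or tuple(getattr(model, "feature_names_in_",
                                           range(X.shape[1])))
    out = {}
    for j, name in enumerate(names):
        drops = []
        for _ in range(repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
            s = score(y, model.predict_proba(Xp)[:, 1])
            if not np.isnan(s):
                drops.append(baseline - s)
        out[name] = max(0.0, float(np.mean(drops))) if drops else float("nan")
    return pd.Series(out, name=f"pi_{metric}")


def shap_local(model, X) -> tuple[np.ndarray, float]:
    """Per-sample Shapley attributions of the WBIT probability.

    Returns ``(phi, base)``; ``phi.sum(axis=1) + base`` reproduces the
    predicted probability (local accuracy).  Exposed so individual alerts
    can be explained analyte by analyte, not just ranked globally.
    """
    check_is_fitted(model)
    if not hasattr(model, "estimators_"):
        raise ValueError("Shapley attribution requires a tree ensemble")
    return forest_shap_values(model, np.asarray(X, dtype=float))


def shap_importance(model, X,
                    feature_names: tuple[str, ...] | None = None) -> pd.Series:
    """Mean absolute Shapley attribution per feature."""
    phi, _ = shap_local(model, X)
    names = feature_names or tuple(getattr(model, "feature_names_in_",
                                           range(phi.shape[1])))
    return pd.Series(np.abs(phi).mean(axis=0), index=list(names), name="shap")


def importance_table(model, X, labels,
                     feature_names: tuple[str, ...] | None = None,
                     metric: str = "f1", repeats: int = 10, seed: int = 0,
                     ) -> pd.DataFrame:
    """All three importance metrics for one fitted model, sorted by MDI.

    ``X``/``labels`` should be held-out evaluation data (the permutation
    scores are only meaningful out of sample)."""
    names = feature_names or tuple(getattr(model, "feature_names_in_",
                                           range(np.asarray(X).shape[1])))
    table = pd.DataFrame({
        "mdi": mdi_importance(model, names),
        "shap": shap_importance(model, X, names),
        "pi": permutation_importance(model, X, labels, metric=metric,
                                     repeats=repeats, seed=seed,
                                     feature_names=names),
    })
    return table.sort_values("mdi", ascending=False)
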