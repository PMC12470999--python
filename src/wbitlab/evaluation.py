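"""Test-set evaluation: confusion metrics, ROC, prevalence-adjusted PPV,
bootstrap confidence intervals, and decision-region plots.

The simulated pair sets are roughly class-balanced (~50 % WBIT), but real
mislabeling is rare — on the order of 5 per 1000 samples.  Raw PPV on the
balanced test set therefore wildly overstates deployment precision.
:func:`ppv_at_sensitivity` reweights an ROC operating point to an assumed
prevalence pi:

    PPV = (tpr * pi) / (tpr * pi + fpr * (1 - pi))

which is the precision a laboratory would actually see at that threshold.
Confidence intervals are percentile bootstrap over case resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from sklearn import metrics as skmetrics  # noqa: E402

from .model_search import labels_to_binary  # noqa: E402

__all__ = ["RocCurve", "EvalReport", "confusion_metrics", "roc_curve",
           "ppv_at_sensitivity", "bootstrap_ci", "evaluate_model",
           "plot_decision_regions", "grid_predictions"]


def confusion_metrics(labels, probabilities, threshold: float = 0.5) -> dict:
    """Confusion-table metrics at a probability threshold.

    Returns a dict with tp/fp/fn/tn counts and accuracy, ppv, sensitivity,
    specificity and f1.  Ratios with an empty denominator are NaN
    (undefined), never silently zero.  F1 is the harmonic mean of PPV and
    sensitivity.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    y = labels_to_binary(labels)
    if not len(y):
        raise ValueError("empty input")
    pred = (np.asarray(probabilities, dtype=float) >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))

    def ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    ppv = ratio(tp, tp + fp)
    sens = ratio(tp, tp + fn)
    if np.isnan(ppv) or np.isnan(sens) or (ppv + sens) == 0:
        f1 = float("nan")
    else:
        f1 = 2.0 * ppv * sens / (ppv + sens)
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "accuracy": (tp + tn) / len(y),
        "ppv": ppv,
        "sensitivity": sens,
        "specificity": ratio(tn, tn + fp),
        "f1": f1,
    }


@dataclass
class RocCurve:
    """ROC points (one vertex per distinct score, ties grouped) plus AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_curve(labels, probabilities) -> RocCurve:
    """Threshold-sweep ROC with trapezoid AUC.

    Requires both classes present.  The returned curve starts at (0, 0)
    and ends at (1, 1); tied scores collapse to a single vertex.
    """
    y = labels_to_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = skmetrics.roc_curve(y, np.asarray(probabilities, float),
                                        drop_intermediate=False)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr,
                    auc=float(np.trapezoid(tpr, fpr)))


def ppv_at_sensitivity(roc: RocCurve, sens_target: float,
                       prevalence: float) -> float:
    """PPV at the first operating point reaching the target sensitivity,
    reweighted to the assumed deployment prevalence.

    The operating point is the ROC vertex with the smallest tpr >=
    ``sens_target`` (no interpolation between vertices); among vertices
    with that tpr the smallest fpr is used.  With ``prevalence`` equal to
    the sample prevalence this reproduces the raw PPV at the same point.
    """
    if not 0.0 < sens_target < 1.0 or not 0.0 < prevalence < 1.0:
        raise ValueError("sens_target and prevalence must lie in (0, 1)")
    reach = roc.tpr >= sens_target
    if not reach.any():
        raise ValueError(
            f"no operating point reaches sensitivity {sens_target}; "
            f"maximum achievable tpr is {roc.tpr.max():.4f}")
    tpr_sel = roc.tpr[reach].min()
    fpr_sel = roc.fpr[reach & (roc.tpr == tpr_sel)].min()
    pos = tpr_sel * prevalence
    neg = fpr_sel * (1.0 - prevalence)
    return float(pos / (pos + neg)) if (pos + neg) else float("nan")


_STATISTICS: dict[str, Callable] = {
    "f1": lambda y, p: confusion_metrics(y, p)["f1"],
    "accuracy": lambda y, p: confusion_metrics(y, p)["accuracy"],
    "roc_auc": lambda y, p: roc_curve(y, p).auc,
}


def bootstrap_ci(labels, probabilities, statistic,
                 iterations: int = 1000, level: float = 0.95, seed: int = 0,
                 max_redraws: int = 100,
                 ) -> tuple[float, float, float]:
    """Percentile bootstrap interval by case resampling.

    ``statistic`` is either a name ("f1", "roc_auc", "accuracy") or a
    callable ``(labels, probabilities) -> float``.  When the original data
    holds both classes, single-class resamples are redrawn (at most
    ``max_redraws`` attempts per iteration — exceeding the cap is a hard
    error suggesting more data).  Deterministic given ``seed``.
    """
    if iterations < 100:
        raise ValueError("iterations must be >= 100")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    y = labels_to_binary(labels)
    p = np.asarray(probabilities, dtype=float)
    if len(y) != len(p) or not len(y):
        raise ValueError("labels and probabilities must be equal-length, non-empty")
    stat = _STATISTICS[statistic] if isinstance(statistic, str) else statistic
    two_class = len(np.unique(y)) == 2
    rng = np.random.default_rng(seed)
    n = len(y)

    point = float(stat(y, p))
    draws = np.empty(iterations)
    for i in range(iterations):
        for attempt in range(max_redraws + 1):
            idx = rng.integers(0, n, n)
            if not two_class or len(np.unique(y[idx])) == 2:
                break
        else:
            raise ValueError(
                "could not draw a two-class bootstrap resample within "
                f"{max_redraws} attempts; more data is needed")
        draws[i] = stat(y[idx], p[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
    return point, float(lo), float(hi)


@dataclass
class EvalReport:
    """Headline test-set metrics with bootstrap confidence intervals."""

    f1: tuple[float, float, float]
    roc_auc: tuple[float, float, float]
    ppv_at: dict[tuple[float, float], tuple[float, float, float]]
    confusion: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def fmt(t):
            return {"value": t[0], "ci_lo": t[1], "ci_hi": t[2]}

        return {
            "f1": fmt(self.f1),
            "roc_auc": fmt(self.roc_auc),
            "ppv_at": {
                f"PPV@S{s:g}E{p:g}": fmt(v)
                for (s, p), v in self.ppv_at.items()},
            "confusion": self.confusion,
        }


def evaluate_model(model, X, labels, threshold: float = 0.5,
                   sensitivity_targets: tuple[float, ...] = (0.8, 0.5),
                   prevalence: float = 0.005, iterations: int = 1000,
                   level: float = 0.95, seed: int = 0) -> EvalReport:
    """Full held-out evaluation of a fitted classifier.

    F1 and ROC AUC carry percentile-bootstrap intervals; PPV at each
    sensitivity target is prevalence-adjusted and bootstrapped jointly by
    case resampling (the operating point is re-derived per resample).
    """
    y = labels_to_binary(labels)
    prob = model.predict_proba(np.asarray(X, dtype=float))[:, 1]

    report = EvalReport(
        f1=bootstrap_ci(y, prob, "f1", iterations, level, seed),
        roc_auc=bootstrap_ci(y, prob, "roc_auc", iterations, level, seed + 1),
        ppv_at={},
        confusion=confusion_metrics(y, prob, threshold),
    )
    for i, s_target in enumerate(sensitivity_targets):
        def stat(yy, pp, s=s_target):
            return ppv_at_sensitivity(roc_curve(yy, pp), s, prevalence)

        report.ppv_at[(s_target, prevalence)] = bootstrap_ci(
            y, prob, stat, iterations, level, seed + 2 + i)
    return report


def grid_predictions(model, bounds: list[tuple[float, float]],
                     resolution: int) -> tuple[np.ndarray, np.ndarray]:
    """Predicted class at every node of a regular grid over ``bounds``.

    Returns (grid points as an (m, d) array, predicted labels).  Used for
    decision-region shading; kept public so the shading can be checked
    pointwise against direct model predictions.
    """
    axes = [np.linspace(lo, hi, resolution) for lo, hi in bounds]
    mesh = np.meshgrid(*axes, indexing="ij")
    points = np.stack([m.ravel() for m in mesh], axis=1)
    return points, model.predict(points)


def plot_decision_regions(model, X, labels, path,
                          reference_model=None, resolution: int | None = None,
                          feature_names: tuple[str, ...] | None = None):
    """Scatter of delta features with model decision regions (2D or 3D).

    True WBIT points are red, non-WBIT blue; misclassified points are
    crossed.  With a ``reference_model`` (e.g. the full-panel model over
    the same rows), points this model gets wrong but the reference gets
    right are marked green.  2D uses a shaded background grid; 3D shades a
    translucent lattice of grid nodes predicted WBIT.
    """
    X = np.asarray(X, dtype=float)
    y = labels_to_binary(labels)
    d = X.shape[1]
    if d not in (2, 3):
        raise ValueError("decision regions can be drawn for 2 or 3 features only")
    if resolution is None:
        resolution = 300 if d == 2 else 60
    pad = 0.05 * (X.max(axis=0) - X.min(axis=0) + 1e-9)
    bounds = [(X[:, j].min() - pad[j], X[:, j].max() + pad[j]) for j in range(d)]
    names = feature_names or tuple(f"delta {j}" for j in range(d))

    pred = model.predict(X)
    wrong = pred != y
    rescued = np.zeros(len(y), dtype=bool)
    if reference_model is not None:
        rescued = wrong & (reference_model.predict(X) == y)

    points, grid_pred = grid_predictions(model, bounds, resolution)
    fig = plt.figure(figsize=(7, 6))
    if d == 2:
        ax = fig.add_subplot(111)
        zz = grid_pred.reshape(resolution, resolution)
        xx = points[:, 0].reshape(resolution, resolution)
        yy = points[:, 1].reshape(resolution, resolution)
        ax.contourf(xx, yy, zz, levels=[-0.5, 0.5, 1.5],
                    colors=["#c6d4f2", "#f2c6c6"], alpha=0.6)
    else:
        ax = fig.add_subplot(111, projection="3d")
        hot = points[grid_pred == 1]
        if len(hot):
            step = max(1, len(hot) // 4000)
            ax.scatter(*hot[::step].T, c="#f2c6c6", s=2, alpha=0.08,
                       depthshade=False)

    for cls, color in ((0, "tab:blue"), (1, "tab:red")):
        ok = (y == cls) & ~wrong
        bad = (y == cls) & wrong & ~rescued
        ax.scatter(*X[ok].T, c=color, marker="o", s=12,
                   label=f"{'non-WBIT' if cls == 0 else 'WBIT'} (correct)")
        ax.scatter(*X[bad].T, c=color, marker="x", s=24,
                   label=f"{'non-WBIT' if cls == 0 else 'WBIT'} (missed)")
    if rescued.any():
        ax.scatter(*X[rescued].T, c="green", marker="x", s=24,
                   label="missed here, caught by reference model")

    ax.set_xlabel(names[0])
    ax.set_ylabel(names[1])
    if d == 3:
        ax.set_zlabel(names[2])
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
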