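"""Confusion metrics, ROC, prevalence-adjusted PPV, bootstrap, plots."""

import itertools

import numpy as np
import pytest
from sklearn.dummy import DummyClassifier
from sklearn.tree import DecisionTreeClassifier

import wbitlab as wl
from wbitlab.evaluation import grid_predictions


def test_confusion_metrics_perfect_predictions():
    y = np.array([0, 1, 0, 1])
    m = wl.confusion_metrics(y, y.astype(float), 0.5)
    for key in ("accuracy", "ppv", "sensitivity", "specificity", "f1"):
        assert m[key] == 1.0


def test_confusion_metrics_hand_computed_table():
    # TP=3 FP=1 FN=2 TN=4
    y = np.array([1, 1, 1, 0, 1, 1, 0, 0, 0, 0])
    p = np.array([.9, .9, .9, .9, .1, .1, .1, .1, .1, .1])
    m = wl.confusion_metrics(y, p, 0.5)
    assert (m["tp"], m["fp"], m["fn"], m["tn"]) == (3, 1, 2, 4)
    assert m["ppv"] == pytest.approx(0.75)
    assert m["sensitivity"] == pytest.approx(0.6)
    assert m["f1"] == pytest.approx(2 * 0.75 * 0.6 / 1.35)


def test_confusion_metrics_undefined_ratios_are_nan():
    y = np.zeros(4)
    p = np.zeros(4)
    m = wl.confusion_metrics(y, p, 0.5)
    assert np.isnan(m["ppv"]) and np.isnan(m["sensitivity"])
    assert np.isnan(m["f1"])
    with pytest.raises(ValueError):
        wl.confusion_metrics([], [], 0.5)


def test_f1_equals_harmonic_mean_recomputation():
    rng = np.random.default_rng(1)
    y = rng.integers(0, 2, 200)
    p = rng.random(200)
    for thr in (0.2, 0.5, 0.8):
        m = wl.confusion_metrics(y, p, thr)
        if not np.isnan(m["f1"]):
            assert m["f1"] == pytest.approx(
                2 * m["ppv"] * m["sensitivity"] / (m["ppv"] + m["sensitivity"]))


def test_roc_perfect_and_chance():
    y = np.array([0, 0, 1, 1])
    assert wl.roc_curve(y, y.astype(float)).auc == 1.0
    assert wl.roc_curve(y, np.full(4, 0.5)).auc == 0.5
    with pytest.raises(ValueError):
        wl.roc_curve(np.zeros(4), np.linspace(0, 1, 4))


def test_roc_endpoints_and_monotonicity():
    rng = np.random.default_rng(2)
    y = rng.integers(0, 2, 50)
    roc = wl.roc_curve(y, rng.random(50))
    assert roc.fpr[0] == 0 and roc.tpr[0] == 0
    assert roc.fpr[-1] == 1 and roc.tpr[-1] == 1
    assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()


def test_auc_equals_concordance_counting_small_instances():
    """Trapezoid AUC vs exhaustive Mann-Whitney pair counting, n <= 20."""
    rng = np.random.default_rng(3)
    for trial in range(30):
        n = int(rng.integers(4, 21))
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            continue
        p = np.round(rng.random(n), 1)  # coarse grid forces ties
        auc = wl.roc_curve(y, p).auc
        pos = p[y == 1]
        neg = p[y == 0]
        conc = sum(1.0 if a > b else 0.5 if a == b else 0.0
                   for a, b in itertools.product(pos, neg))
        assert auc == pytest.approx(conc / (len(pos) * len(neg)), abs=1e-12)


def _roc_point(tpr, fpr):
    return wl.RocCurve(fpr=np.array([0.0, fpr, 1.0]),
                       tpr=np.array([0.0, tpr, 1.0]),
                       thresholds=np.array([np.inf, 0.5, 0.0]), auc=0.0)


def test_ppv_closed_form_and_limits():
    assert wl.ppv_at_sensitivity(_roc_point(1.0, 0.0), 0.8, 0.3) == 1.0
    ppv = wl.ppv_at_sensitivity(_roc_point(0.8, 0.1), 0.8, 0.005)
    assert ppv == pytest.approx(0.004 / (0.004 + 0.0995), abs=1e-12)
    # monotone in prevalence, -> 1 as prevalence -> 1
    grid = [wl.ppv_at_sensitivity(_roc_point(0.8, 0.1), 0.8, pi)
            for pi in (0.005, 0.05, 0.5, 0.999)]
    assert all(a < b for a, b in itertools.pairwise(grid))
    assert grid[-1] > 0.99


def test_ppv_at_sample_prevalence_recovers_raw_ppv():
    rng = np.random.default_rng(4)
    y = rng.integers(0, 2, 300)
    p = np.clip(y * 0.4 + rng.random(300) * 0.6, 0, 1)
    roc = wl.roc_curve(y, p)
    prevalence = y.mean()
    ppv_adj = wl.ppv_at_sensitivity(roc, 0.8, prevalence)
    # raw ppv at the same operating point
    reach = roc.tpr >= 0.8
    tpr_sel = roc.tpr[reach].min()
    thr = roc.thresholds[reach & (roc.tpr == tpr_sel)].max()
    m = wl.confusion_metrics(y, p, min(max(thr, 1e-9), 1 - 1e-9))
    assert ppv_adj == pytest.approx(m["ppv"], abs=1e-9)


def test_ppv_unreachable_sensitivity_fails():
    roc = _roc_point(0.6, 0.1)
    roc.tpr[-1] = 0.6  # curve never reaches 0.8
    with pytest.raises(ValueError, match="0.6"):
        wl.ppv_at_sensitivity(roc, 0.8, 0.005)


def test_bootstrap_constant_statistic_degenerate_interval():
    y = np.array([0, 1] * 20)
    p = np.linspace(0, 1, 40)
    point, lo, hi = wl.bootstrap_ci(y, p, lambda yy, pp: 0.7,
                                    iterations=200, seed=5)
    assert point == lo == hi == 0.7


def test_bootstrap_deterministic_given_seed():
    rng = np.random.default_rng(6)
    y = rng.integers(0, 2, 100)
    p = rng.random(100)
    a = wl.bootstrap_ci(y, p, "f1", iterations=200, seed=7)
    b = wl.bootstrap_ci(y, p, "f1", iterations=200, seed=7)
    assert a == b
    with pytest.raises(ValueError):
        wl.bootstrap_ci(y, p, "f1", iterations=50, seed=7)


def test_bootstrap_interval_width_scales_as_root_n():
    """Percentile-interval width shrinks ~ n^(-1/2) for a mean statistic."""
    rng = np.random.default_rng(8)
    sizes = np.array([50, 200, 800])
    widths = []
    for n in sizes:
        x = rng.normal(0, 1, n)
        _, lo, hi = wl.bootstrap_ci(np.zeros(n), x,
                                    lambda yy, pp: float(pp.mean()),
                                    iterations=400, seed=9)
        widths.append(hi - lo)
    slope = np.polyfit(np.log(sizes), np.log(widths), 1)[0]
    assert slope == pytest.approx(-0.5, abs=0.15)


def test_evaluate_model_report_structure(realistic_features):
    names = list(wl.ANALYTES)
    df = realistic_features
    split = int(0.7 * len(df))
    model = wl.train_forest(df[names][:split], df["label"][:split],
                            seed=10, n_trees=30)
    report = wl.evaluate_model(model, df[names][split:], df["label"][split:],
                               iterations=200, seed=11)
    for point, lo, hi in (report.f1, report.roc_auc,
                          *report.ppv_at.values()):
        assert lo <= point <= hi
        assert 0.0 <= lo and hi <= 1.0
    key = f"PPV@S0.8E0.005"
    assert key in report.to_dict()["ppv_at"]


def test_grid_predictions_agree_with_direct_model_calls():
    rng = np.random.default_rng(12)
    X = rng.normal(0, 1, (200, 2))
    y = (X[:, 0] + X[:, 1] > 0).astype(int)
    model = wl.train_forest(X, y, seed=13, n_trees=10)
    points, pred = grid_predictions(model, [(-2, 2), (-2, 2)], 15)
    for i in range(0, len(points), 17):  # pointwise spot checks
        assert model.predict(points[i:i + 1])[0] == pred[i]


def test_plot_single_class_model_one_region(tmp_path):
    X = np.random.default_rng(14).normal(0, 1, (50, 2))
    y = np.array([0, 1] * 25)
    model = DummyClassifier(strategy="constant", constant=0).fit(X, y)
    out = wl.plot_decision_regions(model, X, y, tmp_path / "flat.png")
    assert out.exists()
    _, pred = grid_predictions(model, [(-2, 2), (-2, 2)], 20)
    assert len(np.unique(pred)) == 1


def test_single_split_tree_gives_axis_aligned_boundary(tmp_path):
    rng = np.random.default_rng(15)
    X = rng.normal(0, 1, (300, 2))
    y = (X[:, 0] > 0.2).astype(int)
    stump = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
    points, pred = grid_predictions(stump, [(-3, 3), (-3, 3)], 40)
    grid = pred.reshape(40, 40)
    # prediction varies along the split feature only
    assert (grid == grid[:, :1]).all()
    assert len(np.unique(grid[:, 0])) == 2
    out = wl.plot_decision_regions(stump, X, y, tmp_path / "stump.png")
    assert out.exists()


def test_plot_3d_and_reference_model(tmp_path, realistic_features):
    names = ["MCV", "RDW", "MCH"]
    df = realistic_features.iloc[:400]
    model = wl.train_forest(df[names], df["label"], seed=16, n_trees=15)
    ref = wl.train_forest(df[list(wl.ANALYTES)], df["label"], seed=16,
                          n_trees=15)

    class RefOnSubset:
        def predict(self, X3):  # reference model sees the full panel rows
            return ref.predict(df[list(wl.ANALYTES)].to_numpy())

    out = wl.plot_decision_regions(
        model, df[names], df["label"], tmp_path / "cube.png",
        reference_model=RefOnSubset(), resolution=12, feature_names=names)
    assert out.exists()
    with pytest.raises(ValueError, match="2 or 3"):
        wl.plot_decision_regions(
            model, np.zeros((5, 4)), np.array([0, 1, 0, 1, 0]),
            tmp_path / "bad.png")
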