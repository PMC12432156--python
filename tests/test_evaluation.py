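"""Metric oracles (pair enumeration, explicit confusion matrices), the
paired bootstrap contract, and the classical baseline runner."""

import numpy as np
import pytest

from conftest import make_bundle
from omixfuse import evaluation as ev


# -- independent oracles ----------------------------------------------------

def cindex_oracle(risk, time, event):
    conc = comp = 0.0
    n = len(risk)
    for i in range(n):
        if event[i] != 1:
            continue
        for j in range(n):
            if time[j] > time[i]:
                comp += 1
                if risk[i] > risk[j]:
                    conc += 1
                elif risk[i] == risk[j]:
                    conc += 0.5
    return conc / comp if comp else np.nan


def balanced_accuracy_oracle(truth, pred):
    return np.mean([np.mean(pred[truth == c] == c) for c in np.unique(truth)])


def kappa_oracle(truth, pred):
    classes = np.unique(np.concatenate([truth, pred]))
    n = len(truth)
    cm = np.zeros((len(classes), len(classes)))
    idx = {c: i for i, c in enumerate(classes)}
    for t, p in zip(truth, pred):
        cm[idx[t], idx[p]] += 1
    po = np.trace(cm) / n
    pe = (cm.sum(1) * cm.sum(0)).sum() / n**2
    return (po - pe) / (1 - pe) if pe < 1 else 1.0


# -- regression -------------------------------------------------------------

def test_regression_perfect_and_constant():
    t = np.array([1.0, 2.0, 3.0])
    perfect = ev.evaluate_regression(t, t)
    assert perfect == pytest.approx({"mse": 0, "r_squared": 1, "pearson_r": 1})
    const = ev.evaluate_regression(np.full(3, 2.0), t)
    assert const["r_squared"] == pytest.approx(0.0)


def test_regression_closed_form():
    pred = np.array([1.0, 2.0, 3.0])
    truth = np.array([2.0, 2.0, 2.0 + 1e-3])
    got = ev.evaluate_regression(pred, truth)
    ss_res = np.sum((pred - truth) ** 2)
    ss_tot = np.sum((truth - truth.mean()) ** 2)
    assert got["mse"] == pytest.approx(ss_res / 3)
    assert got["r_squared"] == pytest.approx(1 - ss_res / ss_tot)


def test_regression_zero_variance_truth_pearson_nan():
    out = ev.evaluate_regression([1.0, 2.0], [5.0, 5.0])
    assert np.isnan(out["pearson_r"])


# -- classification ---------------------------------------------------------

def test_classification_perfect():
    scores = np.eye(3)[np.array([0, 1, 2, 1])] * 5
    out = ev.evaluate_classification(scores, [0, 1, 2, 1])
    for k in ("balanced_accuracy", "f1_weighted", "auroc_weighted", "aupr_weighted", "kappa"):
        assert out[k] == pytest.approx(1.0)


def test_classification_hand_confusion():
    # truth [A,A,B,B], pred [A,B,B,B] -> balanced accuracy (0.5 + 1)/2
    scores = np.array([[2.0, 0], [0, 2.0], [0, 2.0], [0, 2.0]])
    out = ev.evaluate_classification(scores, [0, 0, 1, 1])
    assert out["balanced_accuracy"] == pytest.approx(0.75)


def test_classification_single_class_errors():
    with pytest.raises(ValueError):
        ev.evaluate_classification(np.zeros((3, 2)), [1, 1, 1])


def test_classification_matches_oracles_on_random_instances():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n, K = int(rng.integers(6, 30)), int(rng.integers(2, 5))
        truth = rng.integers(0, K, n)
        if len(np.unique(truth)) < 2:
            continue
        scores = rng.standard_normal((n, K))
        pred = np.argmax(scores, 1)
        out = ev.evaluate_classification(scores, truth)
        assert out["balanced_accuracy"] == pytest.approx(
            balanced_accuracy_oracle(truth, pred), abs=1e-10)
        assert out["kappa"] == pytest.approx(kappa_oracle(truth, pred), abs=1e-10)


# -- concordance ------------------------------------------------------------

def test_cindex_perfect_ties_and_null():
    assert ev.concordance_index([3, 2, 1], [1, 2, 3], [1, 1, 1]) == 1.0
    assert ev.concordance_index([1, 1, 1], [1, 2, 3], [1, 1, 1]) == 0.5
    rng = np.random.default_rng(0)
    n = 4000
    c = ev.concordance_index(rng.standard_normal(n), rng.exponential(1, n), np.ones(n))
    assert abs(c - 0.5) < 0.05


def test_cindex_matches_pair_enumeration_oracle():
    rng = np.random.default_rng(1)
    for _ in range(100):
        n = int(rng.integers(3, 15))
        risk = rng.integers(0, 4, n).astype(float)  # ties included
        time = rng.exponential(1, n)
        event = rng.integers(0, 2, n).astype(float)
        got = ev.concordance_index(risk, time, event)
        want = cindex_oracle(risk, time, event)
        if np.isnan(want):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(want, abs=1e-10)


def test_cindex_negation_symmetry():
    rng = np.random.default_rng(2)
    risk = rng.standard_normal(40)
    time = rng.exponential(1, 40)
    event = rng.integers(0, 2, 40).astype(float)
    event[0] = 1
    a = ev.concordance_index(risk, time, event)
    b = ev.concordance_index(-risk, time, event)
    assert a == pytest.approx(1 - b, abs=1e-10)


def test_cindex_agrees_with_established_implementation():
    from sksurv.metrics import concordance_index_censored

    rng = np.random.default_rng(3)
    risk = rng.standard_normal(60)
    time = rng.exponential(1, 60)
    event = rng.integers(0, 2, 60).astype(bool)
    event[:2] = True
    want = concordance_index_censored(event, time, risk)[0]
    got = ev.concordance_index(risk, time, event.astype(float))
    assert got == pytest.approx(want, abs=1e-10)


# -- paired bootstrap -------------------------------------------------------

def metric_acc(pred, truth):
    return np.mean(pred == truth)


def test_bootstrap_identical_models():
    rng = np.random.default_rng(0)
    truth = rng.integers(0, 2, 50)
    pred = truth.copy()
    cmp_ = ev.paired_bootstrap(pred, pred, truth, metric_acc, n_boot=50, seed=0)
    assert cmp_.mean_difference == 0
    assert cmp_.p_value == pytest.approx(1.0)


def test_bootstrap_planted_difference_significant():
    rng = np.random.default_rng(1)
    truth = rng.integers(0, 2, 100)
    perfect = truth.copy()
    random = rng.integers(0, 2, 100)
    cmp_ = ev.paired_bootstrap(perfect, random, truth, metric_acc, n_boot=100, seed=1)
    diffs = cmp_.scores_a - cmp_.scores_b
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    assert lo > 0
    assert cmp_.p_value < 0.01
    assert cmp_.n_boot == 100 and len(cmp_.scores_a) == 100


def test_bootstrap_identical_indices_per_replicate():
    rng = np.random.default_rng(2)
    truth = rng.standard_normal(30)
    seen = []

    def spy_metric(pred, t):
        seen.append(t.copy())
        return float(np.mean((pred - t) ** 2))

    ev.paired_bootstrap(truth + 0.1, truth - 0.1, truth, spy_metric, n_boot=10, seed=3)
    # metric called twice per replicate with identical resampled truth
    for a, b in zip(seen[0::2], seen[1::2]):
        assert np.array_equal(a, b)


def test_bootstrap_redraws_degenerate_replicates():
    truth = np.array([0] * 29 + [1])  # single-class resamples are likely

    def fragile(pred, t):
        if len(np.unique(t)) < 2:
            raise ValueError("one class")
        return float(np.mean(pred == t))

    cmp_ = ev.paired_bootstrap(truth, truth, truth, fragile, n_boot=20, seed=0)
    assert len(cmp_.scores_a) == 20
    assert cmp_.n_redrawn > 0


# -- baselines --------------------------------------------------------------

def test_baselines_on_separable_classification():
    # two well-separated Gaussian blobs (margin ~4 sd along 5 features)
    from omixfuse.data_io import HarmonizedBundle, TaskSpec, Target

    rng = np.random.default_rng(9)
    n, nt, p = 80, 40, 15
    y = rng.integers(0, 2, n).astype(float)
    yt = rng.integers(0, 2, nt).astype(float)
    X = rng.standard_normal((n, p))
    Xt = rng.standard_normal((nt, p))
    X[:, :5] += 4 * y[:, None]
    Xt[:, :5] += 4 * yt[:, None]
    ts = TaskSpec((Target("y", "classification"),))
    bundle = HarmonizedBundle(
        ["A"], {"A": X}, {"A": Xt}, {"A": [f"f{i}" for i in range(p)]}, {},
        {"y": {"y": y, "mask": np.ones(n, bool)}},
        {"y": {"y": yt, "mask": np.ones(nt, bool)}},
        {"y": {"0": 0, "1": 1}}, [f"s{i}" for i in range(n)],
        [f"t{i}" for i in range(nt)], ts)
    out = ev.run_baselines(bundle, cv_folds=3, seed=0)
    for learner, res in out["y"].items():
        assert res["metrics"]["f1_weighted"] >= 0.9, learner
        assert res["cv_folds"] == 3 and res["grid"]


def test_baselines_survival_random_survival_forest():
    bundle = make_bundle(n=100, n_test=40, p=10, kind="survival", seed=3,
                         modalities=("A",))
    out = ev.run_baselines(bundle, cv_folds=3, seed=0)
    res = out["y"]["random_survival_forest"]
    assert 0.5 < res["metrics"]["c_index"] <= 1.0
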