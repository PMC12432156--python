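"""Task-appropriate metrics, classical baselines, paired bootstrap comparison.

Metric conventions:

* regression — MSE, R² = 1 - SS_res/SS_tot, Pearson r
* classification — balanced accuracy (mean per-class recall), weighted F1,
  one-vs-rest prevalence-weighted AUROC/AUPR, Cohen's kappa
* survival — Harrell's C-index over comparable pairs (event i, and j with
  t_j > t_i), risk ties counted 0.5; higher risk ⇒ earlier event
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr, ttest_rel
from sklearn.ensemble import GradientBoostingClassifier  # noqa: F401  (xgboost preferred)
from sklearn.metrics import (
    average_precision_score,
    balanced_accuracy_score,
    cohen_kappa_score,
    f1_score,
    roc_auc_score,
)
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.svm import SVC, SVR

logger = logging.getLogger(__name__)

__all__ = ["evaluate_regression", "evaluate_classification", "concordance_index",
           "evaluate_model", "run_baselines", "paired_bootstrap", "BootstrapComparison"]


def evaluate_regression(pred, truth, mask=None) -> dict[str, float]:
    pred = np.asarray(pred, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if mask is not None:
        m = np.asarray(mask, dtype=bool).ravel()
        pred, truth = pred[m], truth[m]
    if pred.size < 2:
        raise ValueError("need at least 2 observed pairs")
    mse = float(np.mean((pred - truth) ** 2))
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    r2 = 1.0 - float(np.sum((pred - truth) ** 2)) / ss_tot if ss_tot > 0 else np.nan
    if ss_tot == 0 or np.std(pred) == 0:
        logger.warning("pearson undefined (zero variance); reported as NaN")
        r = np.nan
    else:
        r = float(pearsonr(pred, truth)[0])
    return {"mse": mse, "r_squared": r2, "pearson_r": r}


def evaluate_classification(pred_scores, truth_codes, mask=None) -> dict[str, float]:
    """``pred_scores``: (n, K) logits or probabilities; ``truth_codes`` ints."""
    scores = np.atleast_2d(np.asarray(pred_scores, dtype=float))
    truth = np.asarray(truth_codes).astype(int).ravel()
    if mask is not None:
        m = np.asarray(mask, dtype=bool).ravel()
        scores, truth = scores[m], truth[m]
    classes = np.unique(truth)
    if classes.size < 2:
        raise ValueError("need at least 2 classes present in truth")
    K = scores.shape[1]
    pred = np.argmax(scores, axis=1)
    # softmax for probability-based metrics
    e = np.exp(scores - scores.max(axis=1, keepdims=True))
    prob = e / e.sum(axis=1, keepdims=True)
    out = {
        "balanced_accuracy": float(balanced_accuracy_score(truth, pred)),
        "f1_weighted": float(f1_score(truth, pred, average="weighted")),
        "kappa": float(cohen_kappa_score(truth, pred)),
    }
    try:
        if classes.size == K:
            if K == 2:
                out["auroc_weighted"] = float(roc_auc_score(truth, prob[:, 1]))
            else:
                out["auroc_weighted"] = float(roc_auc_score(
                    truth, prob, multi_class="ovr", average="weighted", labels=np.arange(K)))
        else:  # some training classes absent from truth: one-vs-rest on present ones
            aurocs, weights = [], []
            for c in classes:
                aurocs.append(roc_auc_score((truth == c).astype(int), prob[:, c]))
                weights.append(np.mean(truth == c))
            out["auroc_weighted"] = float(np.average(aurocs, weights=weights))
        auprs, weights = [], []
        for c in classes:
            auprs.append(average_precision_score((truth == c).astype(int), prob[:, c]))
            weights.append(np.mean(truth == c))
        out["aupr_weighted"] = float(np.average(auprs, weights=weights))
    except ValueError as e:
        logger.warning("AUROC/AUPR undefined: %s", e)
        out.setdefault("auroc_weighted", np.nan)
        out.setdefault("aupr_weighted", np.nan)
    return out


def concordance_index(risk, time, event, mask=None) -> float:
    """Harrell's C: fraction of comparable pairs ordered correctly by risk."""
    risk = np.asarray(risk, dtype=float).ravel()
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event, dtype=float).ravel()
    if mask is not None:
        m = np.asarray(mask, dtype=bool).ravel()
        risk, time, event = risk[m], time[m], event[m]
    conc = 0.0
    n_comp = 0
    ev_idx = np.where(event == 1)[0]
    for i in ev_idx:
        later = time > time[i]
        n_comp += int(later.sum())
        conc += float((risk[i] > risk[later]).sum()) + 0.5 * float((risk[i] == risk[later]).sum())
    if n_comp == 0:
        logger.warning("no comparable pairs; C-index undefined")
        return np.nan
    return conc / n_comp


def evaluate_model(trained, bundle) -> dict[str, dict[str, float]]:
    """Test-set metrics for every target of a TrainedModel."""
    batch = {m: bundle.test[m] for m in bundle.modality_names}
    preds = trained.predict(batch)
    report: dict[str, dict[str, float]] = {}
    for t in bundle.task_spec.targets:
        lab = bundle.test_labels[t.name]
        mask = lab["mask"]
        if t.kind == "regression":
            report[t.name] = evaluate_regression(preds[t.name].ravel(), lab["y"], mask)
        elif t.kind == "classification":
            report[t.name] = evaluate_classification(preds[t.name], lab["y"], mask)
        else:
            c = concordance_index(preds[t.name].ravel(), lab["time"], lab["event"], mask)
            report[t.name] = {"c_index": c}
    return report


# ---------------------------------------------------------------------------
# classical baselines
# ---------------------------------------------------------------------------


def _early_fused(bundle, split: str) -> np.ndarray:
    src = bundle.train if split == "train" else bundle.test
    return np.concatenate([src[m] for m in bundle.modality_names], axis=1)


def run_baselines(bundle, cv_folds: int = 5, seed: int = 0,
                  learners: tuple[str, ...] | None = None) -> dict[str, dict]:
    """RF / SVM / XGBoost for regression & classification, random survival
    forest for survival; small grids tuned by k-fold CV on train, evaluated
    on test with the same metrics as the neural models."""
    import xgboost as xgb

    Xtr, Xte = _early_fused(bundle, "train"), _early_fused(bundle, "test")
    out: dict[str, dict] = {}
    for t in bundle.task_spec.targets:
        tr_lab, te_lab = bundle.train_labels[t.name], bundle.test_labels[t.name]
        tr_m, te_m = tr_lab["mask"], te_lab["mask"]
        target_out: dict[str, dict] = {}
        if t.kind == "survival":
            from sksurv.ensemble import RandomSurvivalForest
            from sksurv.util import Surv

            y_tr = Surv.from_arrays(tr_lab["event"][tr_m].astype(bool),
                                    tr_lab["time"][tr_m])
            best, best_score = None, -np.inf
            grid = [{"n_estimators": n, "min_samples_leaf": l}
                    for n in (50, 100) for l in (3, 10)]
            kf = KFold(cv_folds, shuffle=True, random_state=seed)
            Xs = Xtr[tr_m]
            for g in grid:
                scores = []
                for tr_i, va_i in kf.split(Xs):
                    rsf = RandomSurvivalForest(random_state=seed, **g).fit(Xs[tr_i], y_tr[tr_i])
                    risk = rsf.predict(Xs[va_i])
                    scores.append(concordance_index(risk, tr_lab["time"][tr_m][va_i],
                                                    tr_lab["event"][tr_m][va_i]))
                s = np.nanmean(scores)
                if s > best_score:
                    best, best_score = g, s
            rsf = RandomSurvivalForest(random_state=seed, **best).fit(Xs, y_tr)
            risk = rsf.predict(Xte[te_m])
            target_out["random_survival_forest"] = {
                "metrics": {"c_index": concordance_index(
                    risk, te_lab["time"][te_m], te_lab["event"][te_m])},
                "grid": grid, "cv_folds": cv_folds, "best_params": best,
            }
            out[t.name] = target_out
            continue

        y_tr = tr_lab["y"][tr_m]
        if t.kind == "classification":
            y_tr = y_tr.astype(int)
            models = {
                "random_forest": (RandomForestClassifier(random_state=seed),
                                  {"n_estimators": [100, 300], "max_depth": [None, 10]}),
                "svm": (SVC(probability=True, random_state=seed),
                        {"C": [0.1, 1, 10]}),
                "xgboost": (xgb.XGBClassifier(random_state=seed, verbosity=0,
                                              eval_metric="logloss"),
                            {"n_estimators": [100], "max_depth": [3, 6]}),
            }
            scoring = "f1_weighted"
        else:
            models = {
                "random_forest": (RandomForestRegressor(random_state=seed),
                                  {"n_estimators": [100, 300], "max_depth": [None, 10]}),
                "svm": (SVR(), {"C": [0.1, 1, 10]}),
                "xgboost": (xgb.XGBRegressor(random_state=seed, verbosity=0),
                            {"n_estimators": [100], "max_depth": [3, 6]}),
            }
            scoring = "neg_mean_squared_error"
        for name, (est, grid) in models.items():
            gs = GridSearchCV(est, grid, cv=cv_folds, scoring=scoring).fit(Xtr[tr_m], y_tr)
            logger.info("%s/%s: grid=%s folds=%d best=%s", t.name, name, grid,
                        cv_folds, gs.best_params_)
            if t.kind == "classification":
                prob = gs.predict_proba(Xte[te_m])
                metrics = evaluate_classification(prob, te_lab["y"][te_m].astype(int))
            else:
                pred = gs.predict(Xte[te_m])
                metrics = evaluate_regression(pred, te_lab["y"][te_m])
            target_out[name] = {"metrics": metrics, "grid": grid,
                                "cv_folds": cv_folds, "best_params": gs.best_params_}
        out[t.name] = target_out
    return out


# ---------------------------------------------------------------------------
# paired bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapComparison:
    n_boot: int
    scores_a: np.ndarray
    scores_b: np.ndarray
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    t_statistic: float
    p_value: float
    n_redrawn: int
    seed: int
    indices: list[np.ndarray]

    @property
    def mean_difference(self) -> float:
        return float(np.mean(self.scores_a - self.scores_b))


def paired_bootstrap(preds_a, preds_b, truth, metric, n_boot: int = 100,
                     seed: int = 0, max_redraws: int = 1000) -> BootstrapComparison:
    """Resample test instances with replacement; evaluate both models on
    *identical* indices per replicate; percentile 95% CIs and a paired
    t-test on per-replicate scores.  Replicates where the metric is
    undefined (e.g. a single class drawn) are redrawn, keeping n_boot
    constant."""
    preds_a, preds_b = np.asarray(preds_a), np.asarray(preds_b)
    truth = np.asarray(truth)
    n = len(truth)
    if len(preds_a) != n or len(preds_b) != n:
        raise ValueError("predictions must align with truth")
    rng = np.random.default_rng(seed)
    scores_a, scores_b, indices = [], [], []
    n_redrawn = 0
    while len(scores_a) < n_boot:
        idx = rng.integers(0, n, size=n)
        try:
            sa = float(metric(preds_a[idx], truth[idx]))
            sb = float(metric(preds_b[idx], truth[idx]))
            if np.isnan(sa) or np.isnan(sb):
                raise ValueError("metric returned NaN")
        except ValueError:
            n_redrawn += 1
            if n_redrawn > max_redraws:
                raise RuntimeError("too many degenerate bootstrap replicates")
            continue
        scores_a.append(sa)
        scores_b.append(sb)
        indices.append(idx)
    if n_redrawn:
        logger.info("redrew %d degenerate bootstrap replicates", n_redrawn)
    sa, sb = np.array(scores_a), np.array(scores_b)
    diffs = sa - sb
    if np.allclose(diffs, 0):
        t, p = 0.0, 1.0
    else:
        t, p = ttest_rel(sa, sb)
    return BootstrapComparison(
        n_boot, sa, sb,
        (float(np.percentile(sa, 2.5)), float(np.percentile(sa, 97.5))),
        (float(np.percentile(sb, 2.5)), float(np.percentile(sb, 97.5))),
        float(t), float(p), n_redrawn, seed, indices,
    )
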