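"""Training orchestration: train/validation splitting, minibatch Adam with
early stopping, Gaussian-process Bayesian hyperparameter search, and the
fine-tuning procedure for distribution-shifted test domains.

All randomness is seeded; a run is a pure function of (data, spec, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern
from scipy.stats import norm

from . import losses as L
from .autodiff import Tensor, no_grad
from .data_io import HarmonizedBundle
from .models import ModelSpec, HyperConfig, TrainedModel, build_model, MultiTripletNetwork
from .nn import Adam

logger = logging.getLogger(__name__)

__all__ = ["TrainingPolicy", "SearchSpace", "FinetunePolicy", "split_train_val",
           "train_once", "hpo_search", "finetune", "compute_losses"]


@dataclass
class TrainingPolicy:
    val_fraction: float = 0.2
    k_folds: int | None = None
    early_stop_patience: int = 10
    hpo_iterations: int = 10
    seed: int = 0

    def validate(self):
        if self.k_folds is None:
            if not 0 < self.val_fraction < 1:
                raise ValueError("val_fraction must be in (0,1)")
        elif self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


@dataclass
class FinetunePolicy:
    holdin_fraction: float = 0.5
    lr_grid: tuple[float, ...] = (1e-4, 1e-3, 1e-2)
    freeze_strategies: tuple[str, ...] = ("freeze_encoders", "freeze_heads", "freeze_none")
    cv_folds: int = 5
    patience: int = 3
    max_epochs: int = 30


def _stratify_labels(bundle: HarmonizedBundle) -> np.ndarray | None:
    for t in bundle.task_spec.targets:
        if t.kind == "classification":
            lab = bundle.train_labels[t.name]
            if lab["mask"].all():
                return lab["y"].astype(int)
    return None


def split_train_val(
    bundle: HarmonizedBundle, policy: TrainingPolicy
) -> tuple[np.ndarray, np.ndarray] | list[tuple[np.ndarray, np.ndarray]]:
    """80/20 (default) split or k folds; stratified on the first fully
    observed classification target when every class allows it."""
    policy.validate()
    n = bundle.n_train
    rng = np.random.default_rng(policy.seed)
    strat = _stratify_labels(bundle)
    if strat is not None:
        counts = np.bincount(strat)
        need = policy.k_folds or 2
        if counts.min() < need:
            logger.warning("a class has < %d samples; falling back to unstratified", need)
            strat = None

    if policy.k_folds:
        k = policy.k_folds
        order = np.empty(n, dtype=int)
        if strat is None:
            order = rng.permutation(n)
        else:
            pieces = []
            for c in np.unique(strat):
                idx = np.where(strat == c)[0]
                pieces.append(rng.permutation(idx))
            order = np.concatenate(pieces)
        folds = [order[i::k] for i in range(k)]
        return [(np.sort(np.concatenate([folds[j] for j in range(k) if j != i])),
                 np.sort(folds[i])) for i in range(k)]

    n_val = max(1, int(round(policy.val_fraction * n)))
    if strat is None:
        perm = rng.permutation(n)
        return np.sort(perm[n_val:]), np.sort(perm[:n_val])
    val_parts = []
    for c in np.unique(strat):
        idx = rng.permutation(np.where(strat == c)[0])
        k = max(1, int(round(policy.val_fraction * len(idx))))
        val_parts.append(idx[:k])
    val = np.sort(np.concatenate(val_parts))
    train = np.sort(np.setdiff1d(np.arange(n), val))
    return train, val


def compute_losses(
    model, out: dict, labels: dict[str, dict[str, np.ndarray]], idx: np.ndarray,
    spec: ModelSpec, rng: np.random.Generator,
) -> tuple[list[L.TaskLoss], list[L.TaskLoss]]:
    """Task losses for each target plus the architecture's auxiliary terms
    (reconstruction, MMD, triplet) on the given batch indices."""
    task_losses: list[L.TaskLoss] = []
    for t in spec.task_spec.targets:
        lab = labels[t.name]
        pred = out["predictions"][t.name]
        if t.kind == "regression":
            task_losses.append(L.masked_mse(pred, lab["y"][idx], lab["mask"][idx], t.name))
        elif t.kind == "classification":
            task_losses.append(L.masked_cross_entropy(pred, lab["y"][idx],
                                                      lab["mask"][idx], t.name))
        else:
            task_losses.append(L.cox_ph_loss(pred, lab["time"][idx], lab["event"][idx],
                                             lab["mask"][idx], t.name))
    aux: list[L.TaskLoss] = []
    if "reconstruction" in out.get("aux", {}) and out["aux"]["reconstruction"] is not None:
        aux.append(L.TaskLoss("reconstruction", out["aux"]["reconstruction"], len(idx)))
        mmd = L.mmd_loss(out["aux"]["latent"], seed=int(rng.integers(2**31)))
        aux.append(L.TaskLoss("mmd", mmd, len(idx)))
    if isinstance(model, MultiTripletNetwork):
        anchor = model.anchor_target()
        lab = labels[anchor]
        trip = model.sample_triplets(lab["y"][idx].astype(int), lab["mask"][idx], rng)
        if trip is None:
            logger.warning("triplet term skipped: batch has < 2 classes")
        else:
            a, p, ng = trip
            emb = out["embeddings"]
            aux.append(L.TaskLoss("triplet",
                                  L.triplet_loss(emb[a], emb[p], emb[ng],
                                                 spec.triplet_margin), len(a)))
    return task_losses, aux


def _loss_task_names(spec: ModelSpec) -> list[str]:
    names = [t.name for t in spec.task_spec.targets]
    if spec.architecture in ("supervised_vae", "CrossModalPred"):
        names += ["reconstruction", "mmd"]
    if spec.architecture == "MultiTripletNetwork":
        names += ["triplet"]
    return names


def _total_loss(model, batch, labels, idx, spec, weights, rng, training):
    out = model.forward(batch, training=training, rng=rng)
    task_losses, aux = compute_losses(model, out, labels, idx, spec, rng)
    total = L.combine_losses(task_losses, aux, weights)
    return total, task_losses, aux


def train_once(
    model_spec: ModelSpec,
    bundle: HarmonizedBundle,
    policy: TrainingPolicy | None = None,
    seed: int = 0,
    model=None,
    train_idx: np.ndarray | None = None,
    val_idx: np.ndarray | None = None,
    trainable_params=None,
    max_epochs: int | None = None,
    patience: int | None = None,
) -> TrainedModel:
    """Minibatch Adam with early stopping on the validation total loss;
    the best-validation parameters are restored on exit.

    ``model``/``train_idx``/``val_idx``/``trainable_params`` allow the
    fine-tuning path to continue training an existing model on custom
    subsets with frozen parameter groups.
    """
    policy = policy or TrainingPolicy()
    model_spec.validate()
    n_classes = {t.name: len(bundle.class_maps.get(t.name, {}))
                 for t in model_spec.task_spec.targets if t.kind == "classification"}
    if model is None:
        model = build_model(model_spec, bundle.input_dims(), n_classes, seed=seed)
    if train_idx is None or val_idx is None:
        split = split_train_val(bundle, replace(policy, seed=policy.seed))
        if isinstance(split, list):
            train_idx, val_idx = split[0]
        else:
            train_idx, val_idx = split

    weights = L.UncertaintyWeights(_loss_task_names(model_spec),
                                   enabled=model_spec.uncertainty_weighting)
    params = list(trainable_params) if trainable_params is not None else model.parameters()
    params = params + weights.parameters()
    opt = Adam(params, lr=model_spec.hyper.lr)
    rng = np.random.default_rng(seed + 1)
    bs = model_spec.hyper.batch_size
    n_epochs = max_epochs if max_epochs is not None else model_spec.hyper.max_epochs
    stop_patience = patience if patience is not None else policy.early_stop_patience
    labels = bundle.train_labels
    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state = None
    best_w_state = None
    best_epoch = -1
    val_batch = {m: bundle.train[m][val_idx] for m in bundle.modality_names
                 if m in model_spec.input_modalities or m in model_spec.output_modalities}

    for epoch in range(n_epochs):
        perm = rng.permutation(train_idx)
        ep_losses = []
        for start in range(0, len(perm), bs):
            idx = perm[start:start + bs]
            if len(idx) < 2:
                continue
            batch = {m: bundle.train[m][idx] for m in val_batch}
            total, task_losses, aux = _total_loss(model, batch, labels, idx,
                                                  model_spec, weights, rng, True)
            if not np.isfinite(total.data):
                bad = [tl.task_name for tl in task_losses + aux
                       if not np.isfinite(tl.value.data)]
                raise RuntimeError(f"non-finite loss in terms {bad} at epoch {epoch}")
            opt.zero_grad()
            total.backward()
            opt.step()
            ep_losses.append(float(total.data))
        # deterministic validation pass
        vrng = np.random.default_rng(policy.seed + 9999)
        vtotal, _, _ = _total_loss(model, val_batch, labels, val_idx,
                                   model_spec, weights, vrng, False)
        vloss = float(vtotal.data)
        history["train_loss"].append(float(np.mean(ep_losses)) if ep_losses else np.nan)
        history["val_loss"].append(vloss)
        if vloss < best_val - 1e-12:
            best_val = vloss
            best_state = model.state_arrays()
            best_w_state = {k: v.data.copy() for k, v in weights.s.items()}
            best_epoch = epoch
        elif epoch - best_epoch >= stop_patience:
            break
    if best_state is not None:
        model.load_state_arrays(best_state)
        for k, v in best_w_state.items():
            weights.s[k].data = v
    return TrainedModel(model, model_spec, history, uncertainty=weights,
                        best_epoch=best_epoch)


# ---------------------------------------------------------------------------
# Bayesian sequential hyperparameter optimization
# ---------------------------------------------------------------------------

_BATCH_SIZES = (32, 64, 128)


@dataclass
class SearchSpace:
    """Bounds of the default search space; lr is searched on log10 scale."""

    latent_dim: tuple[int, int] = (16, 128)
    hidden_dim_factor: tuple[float, float] = (0.2, 0.5)
    lr: tuple[float, float] = (1e-4, 1e-2)
    supervisor_hidden_dim: tuple[int, int] = (8, 32)
    batch_sizes: tuple[int, ...] = _BATCH_SIZES
    # GNN extras
    node_embedding_dim: tuple[int, int] = (4, 32)
    num_convs: tuple[int, int] = (1, 4)
    conv_types: tuple[str, ...] = ("GraphConv", "GCNConv", "SAGEConv")

    def dims(self, gnn: bool) -> int:
        return 8 if gnn else 5

    def decode(self, u: np.ndarray, gnn: bool, base: HyperConfig) -> HyperConfig:
        """Map a point in the unit cube to a HyperConfig."""

        def lin(lo, hi, x):
            return lo + (hi - lo) * x

        cfg = replace(
            base,
            latent_dim=int(round(lin(*self.latent_dim, u[0]))),
            hidden_dim_factor=float(lin(*self.hidden_dim_factor, u[1])),
            lr=float(10 ** lin(np.log10(self.lr[0]), np.log10(self.lr[1]), u[2])),
            supervisor_hidden_dim=int(round(lin(*self.supervisor_hidden_dim, u[3]))),
            batch_size=self.batch_sizes[min(int(u[4] * len(self.batch_sizes)),
                                            len(self.batch_sizes) - 1)],
        )
        if gnn:
            cfg = replace(
                cfg,
                node_embedding_dim=int(round(lin(*self.node_embedding_dim, u[5]))),
                num_convs=int(round(lin(*self.num_convs, u[6]))),
                conv_type=self.conv_types[min(int(u[7] * len(self.conv_types)),
                                              len(self.conv_types) - 1)],
            )
        return cfg


def hpo_search(
    model_spec_template: ModelSpec,
    bundle: HarmonizedBundle,
    space: SearchSpace | None = None,
    n_iter: int = 10,
    seed: int = 0,
    n_init: int = 5,
    policy: TrainingPolicy | None = None,
    objective=None,
) -> tuple[HyperConfig, list[dict]]:
    """Sequential model-based search: ``n_init`` random points, then a
    Gaussian-process surrogate proposing the expected-improvement argmax
    over a random candidate pool.  The objective is the final validation
    loss of :func:`train_once` (injectable for testing).

    Returns the best config and the full trials log.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    space = space or SearchSpace()
    policy = policy or TrainingPolicy(seed=seed)
    gnn = model_spec_template.architecture == "GNN"
    d = space.dims(gnn)
    rng = np.random.default_rng(seed)
    if n_iter < n_init:
        logger.warning("n_iter=%d < n_init=%d: all-random search", n_iter, n_init)

    def default_objective(cfg: HyperConfig) -> float:
        spec = replace(model_spec_template, hyper=cfg)
        tm = train_once(spec, bundle, policy, seed=seed)
        return float(np.min(tm.history["val_loss"]))

    objective = objective or default_objective
    X: list[np.ndarray] = []
    y: list[float] = []
    trials: list[dict] = []
    for it in range(n_iter):
        if it < n_init or len(set(np.round(y, 12))) < 2:
            u = rng.random(d)
        else:
            gp = GaussianProcessRegressor(
                kernel=ConstantKernel(1.0, constant_value_bounds="fixed")
                * Matern(length_scale=np.full(d, 0.3), nu=2.5,
                         length_scale_bounds="fixed"),
                normalize_y=True, alpha=1e-6, random_state=int(seed % 2**31))
            gp.fit(np.array(X), np.array(y))
            cand = rng.random((256, d))
            mu, sd = gp.predict(cand, return_std=True)
            best = np.min(y)
            sd = np.maximum(sd, 1e-12)
            z = (best - mu) / sd
            ei = (best - mu) * norm.cdf(z) + sd * norm.pdf(z)
            u = cand[int(np.argmax(ei))]
        cfg = space.decode(u, gnn, model_spec_template.hyper)
        cfg.validate()
        val = float(objective(cfg))
        X.append(u)
        y.append(val)
        trials.append({"iteration": it, "config": cfg, "val_loss": val})
    best_i = int(np.argmin(y))
    return trials[best_i]["config"], trials


# ---------------------------------------------------------------------------
# Fine-tuning
# ---------------------------------------------------------------------------


def _param_groups(model) -> dict[str, list]:
    head_params = []
    for head in model.heads.values():
        head_params.extend(head.parameters())
    head_ids = {id(p) for p in head_params}
    enc_params = [p for p in model.parameters() if id(p) not in head_ids]
    return {"encoders": enc_params, "heads": head_params}


def _clone(trained: TrainedModel, bundle: HarmonizedBundle):
    n_classes = {t.name: len(bundle.class_maps.get(t.name, {}))
                 for t in trained.spec.task_spec.targets if t.kind == "classification"}
    m = build_model(trained.spec, trained.model.input_dims, n_classes, seed=0)
    m.load_state_arrays(trained.model.state_arrays())
    return m


def _as_train_bundle(bundle: HarmonizedBundle, idx: np.ndarray) -> HarmonizedBundle:
    """View of the *test* portion as a training bundle (for fine-tuning)."""
    return HarmonizedBundle(
        list(bundle.modality_names),
        {m: bundle.test[m][idx] for m in bundle.modality_names},
        dict(bundle.test), dict(bundle.feature_lists), dict(bundle.scalers),
        {t: {k: v[idx] for k, v in d.items()} for t, d in bundle.test_labels.items()},
        dict(bundle.test_labels), dict(bundle.class_maps),
        [bundle.test_sample_ids[i] for i in idx], list(bundle.test_sample_ids),
        bundle.task_spec,
    )


def finetune(
    trained: TrainedModel,
    bundle: HarmonizedBundle,
    policy: FinetunePolicy | None = None,
    seed: int = 0,
) -> tuple[TrainedModel, np.ndarray]:
    """Grid of (lr x freeze strategy) scored by k-fold CV on a held-in
    slice of the test set; the winner is retrained on the full held-in
    slice (patience 3) and returned with the held-out evaluation indices.
    Held-in and held-out never overlap."""
    policy = policy or FinetunePolicy()
    n_test = bundle.n_test
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_test)
    n_in = int(round(policy.holdin_fraction * n_test))
    if n_in < max(5, policy.cv_folds):
        raise ValueError(f"held-in portion ({n_in}) too small for {policy.cv_folds}-fold CV")
    holdin, holdout = np.sort(perm[:n_in]), np.sort(perm[n_in:])
    spec = trained.spec
    k = policy.cv_folds
    fold_assign = rng.permutation(n_in) % k

    def cv_score(lr: float, strategy: str) -> float:
        scores = []
        for f in range(k):
            tr = holdin[fold_assign != f]
            va = holdin[fold_assign == f]
            if len(tr) < 2 or len(va) < 1:
                continue
            m = _clone(trained, bundle)
            groups = _param_groups(m)
            if strategy == "freeze_encoders":
                params = groups["heads"]
            elif strategy == "freeze_heads":
                params = groups["encoders"]
            elif strategy == "freeze_none":
                params = groups["encoders"] + groups["heads"]
            else:
                raise ValueError(f"unknown freeze strategy {strategy!r}")
            ft_bundle = _as_train_bundle(bundle, np.arange(n_test))
            ft_spec = replace(spec, hyper=replace(spec.hyper, lr=lr,
                                                  batch_size=spec.hyper.batch_size))
            tm = train_once(ft_spec, ft_bundle, TrainingPolicy(seed=seed),
                            seed=seed, model=m, train_idx=tr, val_idx=va,
                            trainable_params=params, max_epochs=policy.max_epochs,
                            patience=policy.patience)
            scores.append(np.min(tm.history["val_loss"]))
        return float(np.mean(scores)) if scores else np.inf

    results = {(lr, st): cv_score(lr, st)
               for lr in policy.lr_grid for st in policy.freeze_strategies}
    (best_lr, best_st), _ = min(results.items(), key=lambda kv: kv[1])
    logger.info("fine-tune grid winner: lr=%g strategy=%s", best_lr, best_st)

    m = _clone(trained, bundle)
    groups = _param_groups(m)
    params = {"freeze_encoders": groups["heads"], "freeze_heads": groups["encoders"],
              "freeze_none": groups["encoders"] + groups["heads"]}[best_st]
    ft_bundle = _as_train_bundle(bundle, np.arange(n_test))
    # small validation split inside held-in for early stopping
    n_val = max(1, len(holdin) // 5)
    vperm = rng.permutation(holdin)
    tr, va = np.sort(vperm[n_val:]), np.sort(vperm[:n_val])
    ft_spec = replace(spec, hyper=replace(spec.hyper, lr=best_lr))
    tm = train_once(ft_spec, ft_bundle, TrainingPolicy(seed=seed), seed=seed,
                    model=m, train_idx=tr, val_idx=va, trainable_params=params,
                    max_epochs=policy.max_epochs, patience=policy.patience)
    tm.history["finetune_grid"] = [
        {"lr": lr, "strategy": st, "cv_loss": v} for (lr, st), v in results.items()
    ]
    return tm, holdout
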