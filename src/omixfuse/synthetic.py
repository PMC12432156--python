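"""Synthetic multi-omics data with known latent structure.

Samples share a low-dimensional latent representation; each modality is a
noisy linear readout of that latent, and outcome variables (numeric,
categorical, survival) are driven by it.  Batch shift and label
missingness can be layered on top, so every downstream component —
harmonization, fusion encoders, survival heads, fine-tuning, batch
alignment — can be exercised with ground truth in hand.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_io import OmicsMatrix

__all__ = [
    "ModalitySpec",
    "TargetSpec",
    "SyntheticSpec",
    "generate_latent",
    "generate_clustered_latent",
    "generate_modality",
    "generate_targets",
    "apply_batch_shift",
    "mask_labels",
    "simulate_dataset",
]


@dataclass(frozen=True)
class ModalitySpec:
    name: str
    n_features: int
    noise_sd: float = 0.1


@dataclass(frozen=True)
class TargetSpec:
    name: str
    kind: str  # numeric | categorical | survival
    effect_size: float = 1.0
    n_classes: int = 2
    censoring_rate: float = 0.0
    noise_sd: float = 0.1  # numeric targets only


@dataclass(frozen=True)
class SyntheticSpec:
    n_train: int = 400
    n_test: int = 100
    latent_dim_true: int = 4
    modalities: tuple[ModalitySpec, ...] = (
        ModalitySpec("omics1", 200, 0.1),
        ModalitySpec("omics2", 200, 0.1),
    )
    targets: tuple[TargetSpec, ...] = (TargetSpec("label", "categorical", 2.0, 3),)
    label_missing_frac: float = 0.0
    batch_shift: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_train < 1:
            problems.append("n_train must be >= 1")
        if self.n_test < 0:
            problems.append("n_test must be >= 0")
        if self.latent_dim_true < 1:
            problems.append("latent_dim_true must be >= 1")
        if not self.modalities:
            problems.append("at least one modality required")
        for m in self.modalities:
            if m.n_features < 1:
                problems.append(f"modality {m.name!r}: n_features must be >= 1")
            if m.noise_sd < 0:
                problems.append(f"modality {m.name!r}: noise_sd must be >= 0")
        for t in self.targets:
            if t.kind not in ("numeric", "categorical", "survival"):
                problems.append(f"target {t.name!r}: unknown kind {t.kind!r}")
            if t.kind == "categorical" and t.n_classes < 2:
                problems.append(f"target {t.name!r}: n_classes must be >= 2")
            if t.kind == "survival" and not 0 <= t.censoring_rate < 1:
                problems.append(f"target {t.name!r}: censoring_rate must be in [0,1)")
        if not 0 <= self.label_missing_frac <= 1:
            problems.append("label_missing_frac must be in [0,1]")
        if problems:
            raise ValueError("invalid SyntheticSpec: " + "; ".join(problems))

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["modalities"] = [dataclasses.asdict(m) for m in self.modalities]
        d["targets"] = [dataclasses.asdict(t) for t in self.targets]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @staticmethod
    def from_yaml(path: str | Path) -> "SyntheticSpec":
        d = yaml.safe_load(Path(path).read_text())
        d["modalities"] = tuple(ModalitySpec(**m) for m in d.get("modalities", []))
        d["targets"] = tuple(TargetSpec(**t) for t in d.get("targets", []))
        return SyntheticSpec(**d)


def generate_latent(spec: SyntheticSpec, n: int | None = None) -> np.ndarray:
    """Draw ``n`` (default ``spec.n_train``) i.i.d. standard-normal latent rows."""
    spec.validate()
    n = spec.n_train if n is None else n
    if n < 1:
        raise ValueError("number of samples must be >= 1")
    rng = np.random.default_rng(spec.seed)
    return rng.standard_normal((n, spec.latent_dim_true))


def generate_clustered_latent(
    n: int, latent_dim: int, n_clusters: int, separation: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Latent drawn from ``n_clusters`` unit-variance Gaussian blobs.

    Blob centres sit at ``separation`` times a random set of orthonormal
    directions (requires ``n_clusters <= latent_dim``), so every pair of
    centres is equidistant (separation * sqrt(2)) and cluster difficulty is
    controlled by a single knob.  Returns ``(latent, cluster_labels)``.
    Used for unsupervised and clustering experiments that need ground-truth
    group structure.
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if n_clusters > latent_dim:
        raise ValueError("n_clusters must be <= latent_dim for orthogonal centres")
    rng = np.random.default_rng(seed)
    Q, _ = np.linalg.qr(rng.standard_normal((latent_dim, latent_dim)))
    centers = separation * Q[:, :n_clusters].T
    labels = rng.integers(0, n_clusters, size=n)
    latent = centers[labels] + rng.standard_normal((n, latent_dim))
    return latent, labels


def generate_modality(
    latent: np.ndarray,
    loading_seed: int,
    n_features: int,
    noise_sd: float,
    name: str = "omics",
    sample_ids: list[str] | None = None,
    noise_seed: int | None = None,
) -> OmicsMatrix:
    """Linear readout ``X = latent @ W.T + noise`` as a features x samples matrix.

    The loading matrix ``W`` (n_features x latent_dim) has i.i.d. N(0,1)
    entries fixed by ``loading_seed``, so train and test splits generated
    from different latent draws share the same map.
    """
    latent = np.asarray(latent, dtype=float)
    if latent.ndim != 2 or latent.shape[0] == 0:
        raise ValueError("latent must be a non-empty 2-D array")
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    rng = np.random.default_rng(loading_seed)
    W = rng.standard_normal((n_features, latent.shape[1]))
    X = latent @ W.T
    if noise_sd > 0:
        nseed = loading_seed + 1 if noise_seed is None else noise_seed
        X = X + np.random.default_rng(nseed).normal(0, noise_sd, size=X.shape)
    n = latent.shape[0]
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    feature_ids = [f"feat_{name}_{i}" for i in range(n_features)]
    return OmicsMatrix(name, feature_ids, list(sample_ids), X.T)


def _calibrate_censoring(event_times: np.ndarray, censoring_rate: float) -> float:
    """Bisect the exponential censor rate c so that the expected fraction of
    samples with C < T equals ``censoring_rate``."""
    if censoring_rate <= 0:
        return 0.0

    def frac(c):
        return float(np.mean(1.0 - np.exp(-c * event_times)))

    lo, hi = 1e-12, 1.0
    while frac(hi) < censoring_rate:
        hi *= 2
        if hi > 1e12:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) < censoring_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_targets(
    latent: np.ndarray,
    target_specs: list[TargetSpec] | tuple[TargetSpec, ...],
    seed: int,
    sample_ids: list[str] | None = None,
    noise_seed: int | None = None,
) -> pd.DataFrame:
    """Outcome table driven by the latent.

    numeric      y = latent @ beta + eps, ||beta|| = effect_size
    categorical  Gumbel-max draw from softmax((2*effect_size)^2 * latent @ B):
                 effect 0 -> uniform labels, large effect -> near-deterministic
    survival     T ~ Exponential(rate = exp(latent @ gamma)), ||gamma|| =
                 effect_size, with independent exponential censoring whose
                 rate is calibrated by bisection to the requested fraction;
                 emitted as <name>_time / <name>_event columns

    Coefficient vectors are drawn from ``seed``; stochastic draws (noise,
    Gumbel label sampling, censoring times) come from ``noise_seed``
    (default ``seed + 1``), so train and test splits generated with the
    same ``seed`` but different ``noise_seed`` share the latent-to-outcome
    map.
    """
    latent = np.asarray(latent, dtype=float)
    if latent.ndim != 2 or latent.shape[0] == 0:
        raise ValueError("latent must be a non-empty 2-D array")
    n, d = latent.shape
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    rng = np.random.default_rng(seed)
    nrng = np.random.default_rng(seed + 1 if noise_seed is None else noise_seed)
    cols: dict[str, np.ndarray] = {}
    for t in target_specs:
        if t.kind == "numeric":
            beta = rng.standard_normal(d)
            beta *= t.effect_size / max(np.linalg.norm(beta), 1e-12)
            cols[t.name] = latent @ beta + nrng.normal(0, t.noise_sd, size=n)
        elif t.kind == "categorical":
            B = rng.standard_normal((d, t.n_classes))
            # quadratic separation (2*effect)^2, calibrated against the Bayes
            # classifier: effect 0 = uniform labels, effect 1 = moderate
            # signal (Bayes accuracy ~0.9), effect 2 = near-noiseless (~0.98)
            logits = (2.0 * t.effect_size) ** 2 * (latent @ B)
            gumbel = nrng.gumbel(size=(n, t.n_classes))
            codes = np.argmax(logits + gumbel, axis=1)
            cols[t.name] = np.array([f"C{c}" for c in codes], dtype=object)
        elif t.kind == "survival":
            gamma = rng.standard_normal(d)
            gamma *= t.effect_size / max(np.linalg.norm(gamma), 1e-12)
            rate = np.exp(latent @ gamma)
            event_t = nrng.exponential(1.0 / rate)
            c = _calibrate_censoring(event_t, t.censoring_rate)
            if c > 0:
                censor_t = nrng.exponential(1.0 / c, size=n)
            else:
                censor_t = np.full(n, np.inf)
            cols[f"{t.name}_time"] = np.minimum(event_t, censor_t)
            cols[f"{t.name}_event"] = (event_t <= censor_t).astype(float)
        else:
            raise ValueError(f"unknown target kind {t.kind!r}")
    return pd.DataFrame(cols, index=pd.Index(sample_ids, name="sample_id"))


def apply_batch_shift(
    matrix: OmicsMatrix, offset: float, scale: float = 1.0, seed: int = 0
) -> OmicsMatrix:
    """Per-feature affine distribution shift ``x -> scale * x + delta_f``.

    ``delta_f`` is drawn per feature around ``offset`` (sd = 0.1*|offset|)
    so the average feature-mean displacement equals ``offset``.  Identity
    at ``offset=0, scale=1``.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    if offset == 0 and scale == 1:
        return matrix
    rng = np.random.default_rng(seed)
    delta = rng.normal(offset, 0.1 * abs(offset), size=matrix.n_features)
    values = scale * matrix.values + delta[:, None]
    return OmicsMatrix(matrix.modality_name, list(matrix.feature_ids),
                       list(matrix.sample_ids), values)


def mask_labels(
    metadata: pd.DataFrame, variable: str, fraction: float, seed: int = 0
) -> pd.DataFrame:
    """Set exactly ``floor(fraction * n)`` entries of one column to NaN."""
    if variable not in metadata.columns:
        raise KeyError(f"unknown variable {variable!r}")
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0,1]")
    out = metadata.copy()
    n_mask = int(np.floor(fraction * len(out)))
    if n_mask:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(out), size=n_mask, replace=False)
        col = out[variable].astype(object) if out[variable].dtype == object else out[variable].astype(float)
        col.iloc[idx] = np.nan
        out[variable] = col
    return out


def simulate_dataset(
    spec: SyntheticSpec, out_dir: str | Path | None = None
) -> dict:
    """Generate a full train/test dataset under ``spec``.

    Returns ``{"train": {"omics": [OmicsMatrix...], "clin": DataFrame},
    "test": {...}}``; if ``out_dir`` is given, writes the on-disk layout
    consumed by :func:`omixfuse.data_io.read_dataset`
    (``train/omics_<name>.csv``, ``train/clin.csv``, same under ``test/``).
    Batch shift, when nonzero, is applied to the *test* modalities to
    emulate a distribution-shifted target domain.
    """
    spec.validate()
    result: dict = {}
    for split, n, seed_off in (("train", spec.n_train, 0), ("test", spec.n_test, 1)):
        if n == 0:
            result[split] = {"omics": [], "clin": pd.DataFrame()}
            continue
        sample_ids = [f"{split}{i}" for i in range(n)]
        latent_rng = np.random.default_rng(spec.seed * 2 + seed_off)
        latent = latent_rng.standard_normal((n, spec.latent_dim_true))
        omics = []
        for j, m in enumerate(spec.modalities):
            om = generate_modality(latent, spec.seed * 1000 + j * 10, m.n_features,
                                   m.noise_sd, name=m.name, sample_ids=sample_ids,
                                   noise_seed=spec.seed * 1000 + j * 10 + seed_off + 1)
            if split == "test" and spec.batch_shift:
                om = apply_batch_shift(om, spec.batch_shift, 1.0,
                                       seed=spec.seed * 1000 + j * 10 + 5)
            omics.append(om)
        clin = generate_targets(latent, spec.targets, spec.seed * 100 + 7,
                                sample_ids=sample_ids,
                                noise_seed=spec.seed * 100 + 17 + seed_off)
        if split == "train" and spec.label_missing_frac > 0:
            for t in spec.targets:
                if t.kind == "survival":
                    continue
                clin = mask_labels(clin, t.name, spec.label_missing_frac,
                                   seed=spec.seed * 100 + 13)
        result[split] = {"omics": omics, "clin": clin}

    if out_dir is not None:
        out_dir = Path(out_dir)
        for split in ("train", "test"):
            d = out_dir / split
            d.mkdir(parents=True, exist_ok=True)
            for om in result[split]["omics"]:
                om.to_frame().to_csv(d / f"omics_{om.modality_name}.csv")
            result[split]["clin"].to_csv(d / "clin.csv")
    return result
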