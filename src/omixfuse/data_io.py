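"""Reading, validation and leakage-safe harmonization of multi-omics tables.

On-disk layout::

    <dir>/train/omics_<name>.csv   features x samples, first column = feature id,
    <dir>/train/clin.csv           header row = sample ids
    <dir>/test/...

Cleaning (imputation, variance filter), scaling and feature selection are
fit on the training split only; the test split is transformed with the
train-fitted statistics and restricted to the train-selected features, so
test data never influences normalization or selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OmicsMatrix",
    "Target",
    "TaskSpec",
    "Scaler",
    "HarmonizedBundle",
    "read_dataset",
    "write_dataset",
    "clean_training_modality",
    "fit_scaler",
    "harmonize_test",
    "encode_covariates",
    "encode_targets",
    "harmonize",
]


@dataclass
class OmicsMatrix:
    """One modality: named numeric matrix, features x samples."""

    modality_name: str
    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # (n_features, n_samples), NaN allowed on input

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError(f"{self.modality_name}: duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError(f"{self.modality_name}: duplicate sample ids")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"{self.modality_name}: values shape {self.values.shape} does not "
                f"match {len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.feature_ids, name="feature_id"),
                            columns=self.sample_ids)

    @staticmethod
    def from_frame(name: str, df: pd.DataFrame) -> "OmicsMatrix":
        return OmicsMatrix(name, [str(i) for i in df.index],
                           [str(c) for c in df.columns], df.to_numpy(dtype=float))

    def subset_samples(self, sample_ids: list[str]) -> "OmicsMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return OmicsMatrix(self.modality_name, list(self.feature_ids),
                           list(sample_ids), self.values[:, idx])


@dataclass(frozen=True)
class Target:
    name: str
    kind: str  # regression | classification | survival
    time_col: str | None = None   # survival only
    event_col: str | None = None  # survival only

    def __post_init__(self):
        if self.kind not in ("regression", "classification", "survival"):
            raise ValueError(f"unknown task kind {self.kind!r}")
        if self.kind == "survival" and not (self.time_col and self.event_col):
            raise ValueError(f"survival target {self.name!r} needs time_col and event_col")


@dataclass(frozen=True)
class TaskSpec:
    targets: tuple[Target, ...]
    covariates: tuple[str, ...] = ()

    def validate_against(self, meta: pd.DataFrame) -> None:
        missing = []
        for t in self.targets:
            cols = [t.time_col, t.event_col] if t.kind == "survival" else [t.name]
            missing += [c for c in cols if c not in meta.columns]
        missing += [c for c in self.covariates if c not in meta.columns]
        if missing:
            raise KeyError(f"metadata is missing columns: {missing}")


@dataclass
class Scaler:
    """Train-fitted per-feature centers/scales, plus the log1p flag."""

    centers: np.ndarray
    scales: np.ndarray
    log_transform: bool
    feature_ids: list[str]

    def transform(self, values: np.ndarray) -> np.ndarray:
        """Apply to a features x samples matrix using train statistics only."""
        v = np.asarray(values, dtype=float)
        if self.log_transform:
            if np.nanmin(v) < 0:
                raise ValueError("log transform requested but negative values present")
            v = np.log1p(v)
        return (v - self.centers[:, None]) / self.scales[:, None]


def _read_omics_csv(path: Path, name: str) -> OmicsMatrix:
    if not path.exists():
        raise FileNotFoundError(f"missing omics file: {path}")
    df = pd.read_csv(path, index_col=0)
    raw = df.to_numpy()
    # locate non-numeric cells before coercion so the error names coordinates
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {raw[r, c]!r} at feature "
            f"{df.index[r]!r}, sample {df.columns[c]!r}"
        )
    return OmicsMatrix.from_frame(name, coerced)


def read_dataset(
    train_dir: str | Path,
    test_dir: str | Path,
    modality_names: list[str] | None = None,
    on_modality_mismatch: str = "intersect",
) -> tuple[dict[str, dict[str, OmicsMatrix]], dict[str, pd.DataFrame]]:
    """Read both splits; restrict each split to samples present everywhere.

    Returns ``(omics, meta)`` where ``omics[split][modality]`` is an
    :class:`OmicsMatrix` and ``meta[split]`` a sample-indexed DataFrame.
    Modalities are restricted to those present in both splits
    (``on_modality_mismatch='intersect'`` warns; ``'error'`` raises).
    """
    dirs = {"train": Path(train_dir), "test": Path(test_dir)}
    available = {}
    for split, d in dirs.items():
        if not (d / "clin.csv").exists():
            raise FileNotFoundError(f"missing metadata file: {d / 'clin.csv'}")
        found = sorted(p.stem.removeprefix("omics_") for p in d.glob("omics_*.csv"))
        available[split] = found if modality_names is None else [
            m for m in modality_names if (d / f"omics_{m}.csv").exists()
        ]
        if modality_names is not None:
            missing = [m for m in modality_names if m not in available[split]]
            if missing and split == "train":
                raise FileNotFoundError(
                    f"missing omics files in {d}: " + ", ".join(f"omics_{m}.csv" for m in missing)
                )
    common = [m for m in available["train"] if m in available["test"]]
    if not common:
        raise ValueError("no modality common to train and test")
    dropped = set(available["train"]) ^ set(available["test"])
    if dropped:
        msg = f"modalities not shared by both splits dropped: {sorted(dropped)}"
        if on_modality_mismatch == "error":
            raise ValueError(msg)
        logger.warning(msg)

    omics: dict[str, dict[str, OmicsMatrix]] = {}
    meta: dict[str, pd.DataFrame] = {}
    for split, d in dirs.items():
        clin = pd.read_csv(d / "clin.csv", index_col=0)
        clin.index = clin.index.astype(str)
        if clin.index.duplicated().any():
            raise ValueError(f"{d / 'clin.csv'}: duplicate sample ids")
        mats = {m: _read_omics_csv(d / f"omics_{m}.csv", m) for m in common}
        ids = set(clin.index)
        for om in mats.values():
            ids &= set(om.sample_ids)
        if not ids:
            raise ValueError(f"{split}: empty sample intersection across files")
        # keep clin.csv order for determinism
        order = [s for s in clin.index if s in ids]
        n_drop = len(clin) - len(order)
        if n_drop:
            logger.info("%s: dropped %d samples absent from some modality", split, n_drop)
        meta[split] = clin.loc[order]
        omics[split] = {m: om.subset_samples(order) for m, om in mats.items()}
    return omics, meta


def write_dataset(out_dir: str | Path, omics: dict[str, OmicsMatrix], clin: pd.DataFrame) -> None:
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    for name, om in omics.items():
        om.to_frame().to_csv(d / f"omics_{name}.csv")
    clin.to_csv(d / "clin.csv")


def clean_training_modality(
    m: OmicsMatrix, variance_quantile: float = 0.01, impute: bool = True
) -> OmicsMatrix:
    """Impute (per-feature median), drop all-missing samples, drop
    low-variance features (below the given quantile of feature variances;
    zero-variance features always go)."""
    if m.n_features == 0 or m.n_samples == 0:
        raise ValueError(f"{m.modality_name}: empty matrix")
    values = m.values.copy()
    all_missing = np.all(np.isnan(values), axis=0)
    if all_missing.any():
        logger.info("%s: dropped %d all-missing samples", m.modality_name, all_missing.sum())
    keep_s = ~all_missing
    values = values[:, keep_s]
    sample_ids = [s for s, k in zip(m.sample_ids, keep_s) if k]
    if impute and np.isnan(values).any():
        med = np.nanmedian(values, axis=1)
        med = np.where(np.isnan(med), 0.0, med)
        nan_r, nan_c = np.where(np.isnan(values))
        values[nan_r, nan_c] = med[nan_r]
    var = values.var(axis=1)
    cutoff = np.quantile(var, variance_quantile) if variance_quantile > 0 else 0.0
    keep_f = (var > 0) & (var >= cutoff)
    if not keep_f.any():
        raise ValueError(
            f"{m.modality_name}: variance filter removed every feature; "
            f"lower variance_quantile (was {variance_quantile})"
        )
    if (~keep_f).any():
        logger.info("%s: variance filter removed %d/%d features",
                    m.modality_name, int((~keep_f).sum()), m.n_features)
    feature_ids = [f for f, k in zip(m.feature_ids, keep_f) if k]
    return OmicsMatrix(m.modality_name, feature_ids, sample_ids, values[keep_f])


def fit_scaler(train: OmicsMatrix, log_transform: bool = False) -> tuple[OmicsMatrix, Scaler]:
    """Center/scale each feature to mean 0, sd 1 (population sd, ddof=0),
    optionally log1p first.  Returns the transformed matrix and the fitted
    scaler for later test harmonization."""
    v = train.values
    if log_transform:
        if np.nanmin(v) < 0:
            raise ValueError(f"{train.modality_name}: negative values, cannot log-transform")
        v = np.log1p(v)
    centers = v.mean(axis=1)
    scales = v.std(axis=1)
    if np.any(scales == 0):
        raise ValueError(f"{train.modality_name}: zero-variance feature after cleaning")
    scaler = Scaler(centers, scales, log_transform, list(train.feature_ids))
    transformed = OmicsMatrix(train.modality_name, list(train.feature_ids),
                              list(train.sample_ids), (v - centers[:, None]) / scales[:, None])
    return transformed, scaler


def harmonize_test(
    test: OmicsMatrix, scaler: Scaler, selected_features: list[str]
) -> np.ndarray:
    """Restrict test to the train-selected features (train order) and apply
    the train-fitted transform.  Returns samples x features.  No test-set
    statistic is ever computed."""
    pos = {f: i for i, f in enumerate(test.feature_ids)}
    missing = [f for f in selected_features if f not in pos]
    if missing:
        raise KeyError(
            f"{test.modality_name}: {len(missing)} selected features absent from "
            f"test data: {missing[:10]}"
        )
    scaler_pos = {f: i for i, f in enumerate(scaler.feature_ids)}
    sidx = [scaler_pos[f] for f in selected_features]
    sub_scaler = Scaler(scaler.centers[sidx], scaler.scales[sidx],
                        scaler.log_transform, list(selected_features))
    values = test.values[[pos[f] for f in selected_features]]
    if np.isnan(values).any():
        # impute with TRAIN centers (pre-transform scale) to avoid leakage
        fill = sub_scaler.centers
        if sub_scaler.log_transform:
            fill = np.expm1(fill)
        nan_r, nan_c = np.where(np.isnan(values))
        values = values.copy()
        values[nan_r, nan_c] = fill[nan_r]
    return sub_scaler.transform(values).T


def encode_covariates(
    meta: pd.DataFrame,
    covariates: list[str],
    levels: dict[str, list[str]] | None = None,
) -> tuple[OmicsMatrix | None, dict[str, list[str]]]:
    """One-hot categorical covariates, pass through numerics (median-imputed).

    ``levels`` carries the train-fitted category sets; pass the fitted dict
    back in when encoding test data so indicator columns line up.  Returns
    ``(modality named 'covariates' or None, fitted levels)``.
    """
    fitting = levels is None
    levels = {} if fitting else levels
    cols: list[np.ndarray] = []
    names: list[str] = []
    for c in covariates:
        if c not in meta.columns:
            raise KeyError(f"unknown covariate column {c!r}")
        s = meta[c]
        if pd.api.types.is_numeric_dtype(s):
            v = s.astype(float).to_numpy()
            if np.isnan(v).all():
                logger.warning("covariate %r all-missing, dropped", c)
                continue
            v = np.where(np.isnan(v), np.nanmedian(v), v)
            cols.append(v)
            names.append(c)
        else:
            if fitting:
                lvs = sorted(s.dropna().astype(str).unique())
                if len(lvs) < 2:
                    logger.warning("covariate %r has a single level, dropped", c)
                    continue
                levels[c] = lvs
            if c not in levels:
                continue
            for lv in levels[c]:
                cols.append((s.astype(str) == lv).astype(float).to_numpy())
                names.append(f"{c}={lv}")
    if not cols:
        return None, levels
    return OmicsMatrix("covariates", names, [str(i) for i in meta.index], np.vstack(cols)), levels


def encode_targets(
    meta: pd.DataFrame,
    task_spec: TaskSpec,
    class_maps: dict[str, dict[str, int]] | None = None,
) -> tuple[dict[str, dict[str, np.ndarray]], dict[str, dict[str, int]]]:
    """Label arrays + missingness masks per target.

    classification -> integer codes via a train-fitted code map (labels
    unseen in train are masked out with a warning); survival -> (time,
    event) pair with a joint mask (missing if either is).  Returns
    ``(labels, class_maps)`` where ``labels[name]`` holds ``y`` (and
    ``time``/``event`` for survival) plus boolean ``mask``.
    """
    task_spec.validate_against(meta)
    fitting = class_maps is None
    class_maps = {} if fitting else class_maps
    labels: dict[str, dict[str, np.ndarray]] = {}
    n = len(meta)
    for t in task_spec.targets:
        if t.kind == "survival":
            time = pd.to_numeric(meta[t.time_col], errors="coerce").to_numpy(dtype=float)
            event = pd.to_numeric(meta[t.event_col], errors="coerce").to_numpy(dtype=float)
            mask = ~(np.isnan(time) | np.isnan(event))
            ok = event[mask]
            if not np.isin(ok, (0.0, 1.0)).all():
                raise ValueError(f"{t.name}: event column must contain only 0/1")
            if mask.any() and np.nanmin(time[mask]) < 0:
                raise ValueError(f"{t.name}: negative times present")
            labels[t.name] = {"time": np.where(mask, time, 0.0),
                              "event": np.where(mask, event, 0.0), "mask": mask}
        elif t.kind == "classification":
            s = meta[t.name]
            present = s.notna().to_numpy()
            vals = s.astype(object).where(s.notna(), None)
            if fitting:
                levels = sorted({str(v) for v in vals if v is not None})
                if len(levels) < 2:
                    raise ValueError(f"{t.name}: fewer than 2 classes in training labels")
                class_maps[t.name] = {lv: i for i, lv in enumerate(levels)}
            cmap = class_maps[t.name]
            codes = np.zeros(n, dtype=float)
            mask = present.copy()
            for i, v in enumerate(vals):
                if v is None:
                    continue
                key = str(v)
                if key in cmap:
                    codes[i] = cmap[key]
                else:
                    mask[i] = False
            unseen = int(present.sum() - mask.sum())
            if unseen:
                logger.warning("%s: %d labels unseen in training were masked", t.name, unseen)
            labels[t.name] = {"y": codes, "mask": mask}
        else:  # regression
            y = pd.to_numeric(meta[t.name], errors="coerce").to_numpy(dtype=float)
            mask = ~np.isnan(y)
            labels[t.name] = {"y": np.where(mask, y, 0.0), "mask": mask}
    return labels, class_maps


@dataclass
class HarmonizedBundle:
    """Model-ready train/test arrays with the fitted transforms attached."""

    modality_names: list[str]
    train: dict[str, np.ndarray]          # samples x selected features
    test: dict[str, np.ndarray]
    feature_lists: dict[str, list[str]]
    scalers: dict[str, Scaler]
    train_labels: dict[str, dict[str, np.ndarray]]
    test_labels: dict[str, dict[str, np.ndarray]]
    class_maps: dict[str, dict[str, int]]
    train_sample_ids: list[str]
    test_sample_ids: list[str]
    task_spec: TaskSpec

    @property
    def n_train(self) -> int:
        return len(self.train_sample_ids)

    @property
    def n_test(self) -> int:
        return len(self.test_sample_ids)

    def input_dims(self) -> dict[str, int]:
        return {m: self.train[m].shape[1] for m in self.modality_names}

    def subset(self, split: str, idx: np.ndarray) -> "HarmonizedBundle":
        """A bundle whose *train* portion is the given subset of ``split``
        (test portion copied unchanged) — used by CV and fine-tuning."""
        src = self.train if split == "train" else self.test
        labels = self.train_labels if split == "train" else self.test_labels
        ids = self.train_sample_ids if split == "train" else self.test_sample_ids
        sub_labels = {
            t: {k: v[idx] for k, v in d.items()} for t, d in labels.items()
        }
        return HarmonizedBundle(
            list(self.modality_names),
            {m: src[m][idx] for m in self.modality_names},
            dict(self.test), dict(self.feature_lists), dict(self.scalers),
            sub_labels, dict(self.test_labels), dict(self.class_maps),
            [ids[i] for i in idx], list(self.test_sample_ids), self.task_spec,
        )


def harmonize(
    omics: dict[str, dict[str, OmicsMatrix]],
    meta: dict[str, pd.DataFrame],
    task_spec: TaskSpec,
    variance_quantile: float = 0.01,
    log_transform: bool = False,
    feature_selector=None,
) -> HarmonizedBundle:
    """Clean/scale train, select features on train, transform test.

    ``feature_selector(modality_name, X_samples_by_features, feature_ids)
    -> selected feature ids`` hooks in Laplacian-score selection; ``None``
    keeps all cleaned features.
    """
    train_names: list[str] = []
    train_arrays: dict[str, np.ndarray] = {}
    test_arrays: dict[str, np.ndarray] = {}
    feature_lists: dict[str, list[str]] = {}
    scalers: dict[str, Scaler] = {}
    for name, m_train in omics["train"].items():
        cleaned = clean_training_modality(m_train, variance_quantile)
        if cleaned.n_samples != m_train.n_samples:
            raise ValueError(
                f"{name}: all-missing training samples present; drop them from "
                "every modality before harmonizing"
            )
        transformed, scaler = fit_scaler(cleaned, log_transform)
        X = transformed.values.T  # samples x features
        selected = list(transformed.feature_ids)
        if feature_selector is not None:
            selected = list(feature_selector(name, X, selected))
        pos = {f: i for i, f in enumerate(transformed.feature_ids)}
        idx = [pos[f] for f in selected]
        train_arrays[name] = X[:, idx]
        feature_lists[name] = selected
        scalers[name] = scaler
        test_arrays[name] = harmonize_test(omics["test"][name], scaler, selected)
        train_names.append(name)

    cov_train, cov_levels = (
        encode_covariates(meta["train"], list(task_spec.covariates))
        if task_spec.covariates else (None, {})
    )
    if cov_train is not None:
        cov_test, _ = encode_covariates(meta["test"], list(task_spec.covariates), cov_levels)
        transformed, scaler = fit_scaler(cov_train, False)
        train_arrays["covariates"] = transformed.values.T
        feature_lists["covariates"] = list(transformed.feature_ids)
        scalers["covariates"] = scaler
        test_arrays["covariates"] = harmonize_test(cov_test, scaler,
                                                   list(transformed.feature_ids))
        train_names.append("covariates")

    train_labels, class_maps = encode_targets(meta["train"], task_spec)
    test_labels, _ = encode_targets(meta["test"], task_spec, class_maps)
    return HarmonizedBundle(
        train_names, train_arrays, test_arrays, feature_lists, scalers,
        train_labels, test_labels, class_maps,
        [str(i) for i in meta["train"].index], [str(i) for i in meta["test"].index],
        task_spec,
    )
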