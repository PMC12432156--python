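"""YAML run configuration with strict key validation.

CLI flags override file values; the effective configuration is echoed
into the run manifest.  Learning rates outside the default search bounds
are rejected unless ``allow_override`` is set.
"""

from __future__ import annotations

from pathlib import Path

import yaml

__all__ = ["DEFAULTS", "load_config", "merge_config"]

DEFAULTS: dict = {
    "data_path": None,
    "data_types": None,            # list of modality names; None = discover
    "target_variables": [],        # regression/classification column names
    "categorical_variables": [],   # subset of target_variables forced categorical
    "surv_time_var": None,
    "surv_event_var": None,
    "covariates": [],
    "model_class": "DirectPred",
    "fusion": "intermediate",
    "output_modalities": [],
    "hpo_iter": 5,
    "finetune_fraction": 0.0,
    "features_top_pct": 100.0,
    "min_features": 10,
    "variance_quantile": 0.01,
    "log_transform": False,
    "edge_list": None,
    "uncertainty_weighting": True,
    "early_stop_patience": 10,
    "max_epochs": None,
    "lr": None,                    # fixed lr (skips searching it); bounds-checked
    "outdir": "output",
    "seed": 0,
    "allow_override": False,
}

_LR_BOUNDS = (1e-4, 1e-2)


def load_config(path: str | Path | None) -> dict:
    """Read a YAML config; unknown keys are an error, missing keys default."""
    cfg = dict(DEFAULTS)
    if path is None:
        return cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = sorted(set(raw) - set(DEFAULTS))
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {unknown}")
    cfg.update(raw)
    _validate(cfg)
    return cfg


def merge_config(cfg: dict, overrides: dict) -> dict:
    """Apply non-None CLI overrides on top of the file values."""
    out = dict(cfg)
    for k, v in overrides.items():
        if v is not None:
            if k not in DEFAULTS:
                raise ValueError(f"unknown config key: {k}")
            out[k] = v
    _validate(out)
    return out


def _validate(cfg: dict) -> None:
    lr = cfg.get("lr")
    if lr is not None and not cfg.get("allow_override"):
        if not _LR_BOUNDS[0] <= lr <= _LR_BOUNDS[1]:
            raise ValueError(
                f"lr={lr} outside the default search bounds {_LR_BOUNDS}; "
                "pass allow_override to force it")
    if cfg["fusion"] not in ("early", "intermediate"):
        raise ValueError("fusion must be 'early' or 'intermediate'")
    if not 0 <= cfg["finetune_fraction"] < 1:
        raise ValueError("finetune_fraction must be in [0, 1)")
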