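"""End-to-end workflow: import -> clean/harmonize -> feature selection ->
hyperparameter search -> final training -> evaluation -> attribution,
with run manifests for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .attribution import integrated_gradients, rank_markers
from .data_io import HarmonizedBundle, TaskSpec, harmonize, read_dataset
from .evaluation import evaluate_model
from .feature_selection import rank_and_select, read_edge_list, restrict_to_graph
from .models import ModelSpec, TrainedModel
from .training import SearchSpace, TrainingPolicy, FinetunePolicy, finetune, hpo_search, train_once

logger = logging.getLogger(__name__)

__all__ = ["run_training", "apply_graph_restriction", "write_manifest"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def apply_graph_restriction(bundle: HarmonizedBundle, edge_list) -> tuple[HarmonizedBundle, tuple]:
    """Drop features absent from the interaction graph (per modality) and
    compute edge indices into the early-fused feature axis."""
    nodes = {a for a, _ in edge_list} | {b for _, b in edge_list}
    new_train, new_test, new_feats = {}, {}, {}
    fused_ids: list[str] = []
    for m in bundle.modality_names:
        keep = [i for i, f in enumerate(bundle.feature_lists[m]) if f in nodes]
        if not keep:
            raise ValueError(f"{m}: no features overlap the interaction graph")
        new_train[m] = bundle.train[m][:, keep]
        new_test[m] = bundle.test[m][:, keep]
        new_feats[m] = [bundle.feature_lists[m][i] for i in keep]
        fused_ids.extend(new_feats[m])
    pos = {f: i for i, f in enumerate(fused_ids)}
    edges = tuple(sorted({(pos[a], pos[b]) for a, b in edge_list
                          if a in pos and b in pos and a != b}))
    if not edges:
        raise ValueError("no graph edge connects two retained features")
    out = replace_bundle(bundle, new_train, new_test, new_feats)
    return out, edges


def replace_bundle(bundle, train, test, feats) -> HarmonizedBundle:
    return HarmonizedBundle(
        list(bundle.modality_names), train, test, feats, dict(bundle.scalers),
        dict(bundle.train_labels), dict(bundle.test_labels), dict(bundle.class_maps),
        list(bundle.train_sample_ids), list(bundle.test_sample_ids), bundle.task_spec,
    )


def run_training(
    data_path: str | Path,
    task_spec: TaskSpec,
    architecture: str = "DirectPred",
    fusion: str = "intermediate",
    modalities: list[str] | None = None,
    outdir: str | Path = "output",
    hpo_iter: int = 5,
    features_top_pct: float = 100.0,
    min_features: int = 10,
    variance_quantile: float = 0.01,
    log_transform: bool = False,
    edge_list_path: str | Path | None = None,
    output_modalities: tuple[str, ...] = (),
    finetune_fraction: float = 0.0,
    uncertainty_weighting: bool = True,
    early_stop_patience: int = 10,
    max_epochs: int | None = None,
    seed: int = 0,
    attribution_top_n: int = 10,
) -> dict:
    """Run the full workflow on a train/test data folder; returns a summary
    dict and writes checkpoint, embeddings, metrics, attributions and a
    manifest under ``outdir``."""
    t0 = time.time()
    data_path = Path(data_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    rng = np.random.default_rng(seed)

    omics, meta = read_dataset(data_path / "train", data_path / "test", modalities)
    input_files = sorted((data_path / "train").glob("*.csv")) + \
        sorted((data_path / "test").glob("*.csv"))
    timings["import"] = time.time() - t0

    selector = None
    if features_top_pct < 100.0:
        def selector(name, X, feats):
            return rank_and_select(name, X, feats,
                                   top_fraction=features_top_pct / 100.0,
                                   min_features=min_features).selected
    t1 = time.time()
    bundle = harmonize(omics, meta, task_spec, variance_quantile, log_transform,
                       feature_selector=selector)
    timings["harmonize"] = time.time() - t1

    edges: tuple = ()
    if architecture == "GNN":
        if edge_list_path is None:
            raise ValueError("GNN requires an edge list (--edge_list)")
        bundle, edges = apply_graph_restriction(bundle, read_edge_list(edge_list_path))

    spec = ModelSpec(architecture, fusion, tuple(bundle.modality_names), task_spec,
                     output_modalities=tuple(output_modalities),
                     uncertainty_weighting=uncertainty_weighting, edges=edges)
    policy = TrainingPolicy(early_stop_patience=early_stop_patience,
                            hpo_iterations=hpo_iter, seed=seed)
    if max_epochs is not None:
        spec = replace(spec, hyper=replace(spec.hyper, max_epochs=max_epochs))

    t2 = time.time()
    best_cfg, trials = hpo_search(spec, bundle, SearchSpace(), n_iter=hpo_iter,
                                  seed=seed, policy=policy)
    if max_epochs is not None:
        best_cfg = replace(best_cfg, max_epochs=max_epochs)
    timings["hpo"] = time.time() - t2
    (outdir / "hpo_trials.json").write_text(json.dumps(
        [{"iteration": t["iteration"], "config": asdict(t["config"]),
          "val_loss": t["val_loss"]} for t in trials], indent=2))

    t3 = time.time()
    final_spec = replace(spec, hyper=best_cfg)
    trained = train_once(final_spec, bundle, policy, seed=seed)
    timings["train"] = time.time() - t3

    heldout = np.arange(bundle.n_test)
    if finetune_fraction > 0:
        t4 = time.time()
        trained, heldout = finetune(trained, bundle,
                                    FinetunePolicy(holdin_fraction=finetune_fraction),
                                    seed=seed)
        timings["finetune"] = time.time() - t4

    t5 = time.time()
    eval_bundle = bundle if finetune_fraction == 0 else _heldout_view(bundle, heldout)
    metrics = evaluate_model(trained, eval_bundle)
    timings["evaluate"] = time.time() - t5
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2, default=float))

    # embeddings
    for split, ids in (("train", bundle.train_sample_ids), ("test", bundle.test_sample_ids)):
        src = bundle.train if split == "train" else bundle.test
        emb = trained.embeddings({m: src[m] for m in bundle.modality_names})
        pd.DataFrame(emb, index=ids).to_csv(outdir / f"embeddings_{split}.csv")

    # attribution on test samples, per target (first class for classification)
    t6 = time.time()
    tables = []
    test_batch = {m: bundle.test[m] for m in bundle.modality_names}
    for t in task_spec.targets:
        if t.kind == "classification":
            for label, code in sorted(bundle.class_maps[t.name].items(), key=lambda kv: kv[1]):
                attr = integrated_gradients(trained, test_batch, t.name, class_idx=code)
                tables.append(rank_markers(attr, bundle.feature_lists, t.name,
                                           attribution_top_n, class_label=label))
        else:
            attr = integrated_gradients(trained, test_batch, t.name)
            tables.append(rank_markers(attr, bundle.feature_lists, t.name, attribution_top_n))
    if tables:
        pd.concat(tables).to_csv(outdir / "attributions.csv", index=False)
    timings["attribution"] = time.time() - t6

    trained.save(outdir / "model.npz")
    timings["total"] = time.time() - t0
    manifest = write_manifest(outdir, {
        "architecture": architecture, "fusion": fusion,
        "hyper": asdict(best_cfg), "hpo_iter": hpo_iter, "seed": seed,
        "finetune_fraction": finetune_fraction,
        "targets": [t.name for t in task_spec.targets],
    }, input_files, timings)
    return {"metrics": metrics, "best_config": best_cfg, "trained": trained,
            "bundle": bundle, "manifest": manifest, "heldout": heldout}


def _heldout_view(bundle: HarmonizedBundle, heldout: np.ndarray) -> HarmonizedBundle:
    return HarmonizedBundle(
        list(bundle.modality_names), dict(bundle.train),
        {m: bundle.test[m][heldout] for m in bundle.modality_names},
        dict(bundle.feature_lists), dict(bundle.scalers), dict(bundle.train_labels),
        {t: {k: v[heldout] for k, v in d.items()} for t, d in bundle.test_labels.items()},
        dict(bundle.class_maps), list(bundle.train_sample_ids),
        [bundle.test_sample_ids[i] for i in heldout], bundle.task_spec,
    )


def write_manifest(outdir: Path, config: dict, input_files, timings: dict) -> dict:
    outputs = {}
    for p in sorted(Path(outdir).iterdir()):
        if p.name != "manifest.json" and p.is_file():
            outputs[p.name] = _sha256(p)
    manifest = {
        "package_version": __version__,
        "config": config,
        "inputs": {str(p): _sha256(Path(p)) for p in input_files},
        "timings_sec": {k: round(v, 3) for k, v in timings.items()},
        "outputs": outputs,
    }
    (Path(outdir) / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
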