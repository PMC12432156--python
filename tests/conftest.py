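import logging

import numpy as np
import pytest

from omixfuse.data_io import HarmonizedBundle, TaskSpec, Target

logging.getLogger("omixfuse").setLevel(logging.ERROR)


def make_bundle(n=120, n_test=60, p=40, kind="classification", seed=0,
                n_classes=3, modalities=("A", "B")):
    """Small harmonized bundle with a planted linear signal, built directly
    in scaled feature space (bypasses file I/O for speed)."""
    rng = np.random.default_rng(seed)
    d = 4
    lat_tr = rng.standard_normal((n, d))
    lat_te = rng.standard_normal((n_test, d))
    train, test, feats = {}, {}, {}
    for m in modalities:
        W = rng.standard_normal((p, d))
        train[m] = lat_tr @ W.T + rng.normal(0, 0.1, (n, p))
        test[m] = lat_te @ W.T + rng.normal(0, 0.1, (n_test, p))
        feats[m] = [f"feat_{m}_{i}" for i in range(p)]
    if kind == "classification":
        B = rng.standard_normal((d, n_classes))
        y_tr = np.argmax(lat_tr @ B, axis=1).astype(float)
        y_te = np.argmax(lat_te @ B, axis=1).astype(float)
        targets = (Target("y", "classification"),)
        tr_lab = {"y": {"y": y_tr, "mask": np.ones(n, bool)}}
        te_lab = {"y": {"y": y_te, "mask": np.ones(n_test, bool)}}
        cmaps = {"y": {f"C{i}": i for i in range(n_classes)}}
    elif kind == "regression":
        beta = rng.standard_normal(d)
        y_tr = lat_tr @ beta + rng.normal(0, 0.1, n)
        y_te = lat_te @ beta + rng.normal(0, 0.1, n_test)
        targets = (Target("y", "regression"),)
        tr_lab = {"y": {"y": y_tr, "mask": np.ones(n, bool)}}
        te_lab = {"y": {"y": y_te, "mask": np.ones(n_test, bool)}}
        cmaps = {}
    elif kind == "survival":
        gamma = rng.standard_normal(d)
        gamma /= np.linalg.norm(gamma)
        t_tr = rng.exponential(1 / np.exp(lat_tr @ gamma))
        t_te = rng.exponential(1 / np.exp(lat_te @ gamma))
        targets = (Target("y", "survival", time_col="t", event_col="e"),)
        tr_lab = {"y": {"time": t_tr, "event": np.ones(n), "mask": np.ones(n, bool)}}
        te_lab = {"y": {"time": t_te, "event": np.ones(n_test), "mask": np.ones(n_test, bool)}}
        cmaps = {}
    else:  # unsupervised
        targets = ()
        tr_lab, te_lab, cmaps = {}, {}, {}
    ts = TaskSpec(targets)
    return HarmonizedBundle(
        list(modalities), train, test, feats, {}, tr_lab, te_lab, cmaps,
        [f"s{i}" for i in range(n)], [f"t{i}" for i in range(n_test)], ts)


@pytest.fixture(scope="session")
def clf_bundle():
    return make_bundle(kind="classification")


@pytest.fixture(scope="session")
def reg_bundle():
    return make_bundle(kind="regression")
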