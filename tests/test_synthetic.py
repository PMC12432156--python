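"""Generator contracts: determinism, planted-signal recovery by analytic
oracles (PCA, OLS, logistic fit on the true latent), censoring calibration."""

import numpy as np
import pandas as pd
import pytest

from omixfuse import synthetic as syn
from omixfuse.evaluation import concordance_index


def small_spec(**kw):
    defaults = dict(n_train=100, n_test=20, latent_dim_true=4,
                    modalities=(syn.ModalitySpec("rna", 30, 0.1),),
                    targets=(syn.TargetSpec("label", "categorical", 1.0, 3),),
                    seed=7)
    defaults.update(kw)
    return syn.SyntheticSpec(**defaults)


def test_latent_deterministic_and_shaped():
    spec = small_spec()
    a = syn.generate_latent(spec)
    b = syn.generate_latent(spec)
    assert a.shape == (100, 4)
    assert np.array_equal(a, b)


def test_latent_moments_near_standard_normal():
    spec = small_spec(n_train=400, latent_dim_true=1)
    z = syn.generate_latent(spec, n=400)
    assert abs(z.mean()) < 0.2
    assert abs(z.std() - 1) < 0.2


def test_invalid_spec_lists_offending_fields():
    with pytest.raises(ValueError, match="n_train"):
        syn.generate_latent(small_spec(n_train=0))
    with pytest.raises(ValueError, match="n_classes"):
        small_spec(targets=(syn.TargetSpec("x", "categorical", 1.0, 1),)).validate()


def test_modality_noiseless_rank_bounded_by_latent_dim():
    z = syn.generate_latent(small_spec())
    om = syn.generate_modality(z, 5, 20, noise_sd=0.0)
    assert np.linalg.matrix_rank(om.values) <= 4
    assert om.values.shape == (20, 100)
    assert om.feature_ids[0] == "feat_omics_0"


def test_modality_pca_recovers_latent_variance():
    spec = small_spec(n_train=400)
    z = syn.generate_latent(spec, n=400)
    om = syn.generate_modality(z, 5, 200, noise_sd=0.1)
    X = om.values.T
    X = X - X.mean(0)
    sv = np.linalg.svd(X, compute_uv=False) ** 2
    assert sv[:4].sum() / sv.sum() >= 0.9


def test_modality_deterministic_and_validates():
    z = syn.generate_latent(small_spec())
    a = syn.generate_modality(z, 5, 10, 0.2)
    b = syn.generate_modality(z, 5, 10, 0.2)
    assert np.array_equal(a.values, b.values)
    with pytest.raises(ValueError):
        syn.generate_modality(z, 5, 0, 0.1)


def test_null_effect_labels_independent_of_latent():
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import balanced_accuracy_score

    z = np.random.default_rng(0).standard_normal((600, 4))
    meta = syn.generate_targets(z[:400], [syn.TargetSpec("c", "categorical", 0.0, 3)], seed=1)
    meta2 = syn.generate_targets(z[400:], [syn.TargetSpec("c", "categorical", 0.0, 3)],
                                 seed=1, noise_seed=99)
    y = meta["c"].str.removeprefix("C").astype(int)
    y2 = meta2["c"].str.removeprefix("C").astype(int)
    clf = LogisticRegression(max_iter=500).fit(z[:400], y)
    acc = balanced_accuracy_score(y2, clf.predict(z[400:]))
    assert abs(acc - 1 / 3) < 0.12


def test_numeric_target_ols_recovery():
    from sklearn.linear_model import LinearRegression

    z = np.random.default_rng(1).standard_normal((400, 4))
    meta = syn.generate_targets(z, [syn.TargetSpec("y", "numeric", 2.0, noise_sd=0.1)], seed=2)
    r2 = LinearRegression().fit(z, meta["y"]).score(z, meta["y"])
    assert r2 >= 0.95


def test_survival_censoring_zero_all_events():
    z = np.random.default_rng(2).standard_normal((50, 4))
    meta = syn.generate_targets(z, [syn.TargetSpec("os", "survival", 1.0, censoring_rate=0.0)], seed=3)
    assert (meta["os_event"] == 1).all()


def test_survival_censoring_calibrated_within_5pct():
    z = np.random.default_rng(3).standard_normal((800, 4))
    meta = syn.generate_targets(z, [syn.TargetSpec("os", "survival", 1.0, censoring_rate=0.3)], seed=4)
    assert abs((1 - meta["os_event"].mean()) - 0.3) <= 0.05


def test_survival_true_predictor_concordance():
    # C-index of the generating linear predictor against simulated times
    z = np.random.default_rng(4).standard_normal((400, 4))
    rng = np.random.default_rng(11)
    gamma = rng.standard_normal(4)
    gamma /= np.linalg.norm(gamma)
    meta = syn.generate_targets(z, [syn.TargetSpec("os", "survival", 1.0, censoring_rate=0.2)], seed=11)
    c = concordance_index(z @ gamma, meta["os_time"], meta["os_event"])
    assert c >= 0.7


def test_unknown_target_kind_errors():
    z = np.ones((5, 2))
    with pytest.raises(ValueError):
        syn.generate_targets(z, [syn.TargetSpec("x", "wavelet")], seed=0)


def test_batch_shift_identity_and_mean():
    z = syn.generate_latent(small_spec())
    om = syn.generate_modality(z, 5, 30, 0.1)
    same = syn.apply_batch_shift(om, offset=0.0, scale=1.0)
    assert np.array_equal(same.values, om.values)
    shifted = syn.apply_batch_shift(om, offset=5.0, seed=1)
    diffs = (shifted.values - om.values).mean(axis=1)
    assert abs(diffs.mean() - 5.0) < 0.3
    with pytest.raises(ValueError):
        syn.apply_batch_shift(om, offset=1.0, scale=-1.0)


def test_mask_labels_exact_count():
    meta = pd.DataFrame({"a": np.arange(100.0), "b": np.arange(100.0)})
    out = syn.mask_labels(meta, "a", 0.3, seed=0)
    assert out["a"].isna().sum() == 30
    assert out["b"].isna().sum() == 0
    assert syn.mask_labels(meta, "a", 0.0)["a"].isna().sum() == 0
    assert syn.mask_labels(meta, "a", 1.0)["a"].isna().sum() == 100
    with pytest.raises(KeyError):
        syn.mask_labels(meta, "zzz", 0.5)


def test_signal_monotonicity_in_effect_size():
    """Held-out balanced accuracy of a logistic oracle on the true latent is
    non-decreasing in effect size (tolerance for sampling noise)."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import balanced_accuracy_score

    for seed in (0, 1, 2):
        z = np.random.default_rng(seed).standard_normal((800, 4))
        accs = []
        for eff in (0.0, 0.5, 1.0, 2.0):
            meta = syn.generate_targets(z, [syn.TargetSpec("c", "categorical", eff, 3)],
                                        seed=100 + seed)
            y = meta["c"].str.removeprefix("C").astype(int).to_numpy()
            clf = LogisticRegression(max_iter=500).fit(z[:500], y[:500])
            accs.append(balanced_accuracy_score(y[500:], clf.predict(z[500:])))
        assert all(b >= a - 0.05 for a, b in zip(accs, accs[1:])), accs


def test_clustered_latent_equidistant_centers():
    lat, lab = syn.generate_clustered_latent(200, 5, 4, separation=6.0, seed=0)
    assert lat.shape == (200, 5) and set(lab) <= {0, 1, 2, 3}
    lat2, lab2 = syn.generate_clustered_latent(200, 5, 4, separation=6.0, seed=0)
    assert np.array_equal(lat, lat2) and np.array_equal(lab, lab2)
    with pytest.raises(ValueError):
        syn.generate_clustered_latent(50, 3, 4, 6.0, 0)


def test_simulate_dataset_layout_and_spec_roundtrip(tmp_path):
    spec = small_spec(n_test=30)
    syn.simulate_dataset(spec, tmp_path)
    for split in ("train", "test"):
        assert (tmp_path / split / "omics_rna.csv").exists()
        assert (tmp_path / split / "clin.csv").exists()
    spec.to_yaml(tmp_path / "spec.yaml")
    assert syn.SyntheticSpec.from_yaml(tmp_path / "spec.yaml") == spec


def test_simulate_dataset_shares_target_map_across_splits():
    """The latent-to-label map must be identical for train and test, else
    generalization would be impossible by construction."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import balanced_accuracy_score

    spec = small_spec(n_train=400, n_test=200,
                      targets=(syn.TargetSpec("label", "categorical", 2.0, 3),))
    data = syn.simulate_dataset(spec)
    lat_tr = np.random.default_rng(spec.seed * 2).standard_normal((400, 4))
    lat_te = np.random.default_rng(spec.seed * 2 + 1).standard_normal((200, 4))
    y_tr = data["train"]["clin"]["label"].str.removeprefix("C").astype(int)
    y_te = data["test"]["clin"]["label"].str.removeprefix("C").astype(int)
    clf = LogisticRegression(max_iter=500).fit(lat_tr, y_tr)
    assert balanced_accuracy_score(y_te, clf.predict(lat_te)) > 0.8
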