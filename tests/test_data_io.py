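"""Import validation, cleaning, leakage-safe scaling and target encoding."""

import numpy as np
import pandas as pd
import pytest

from omixfuse import data_io as dio


def write_split(d, omics: dict, clin: pd.DataFrame):
    d.mkdir(parents=True, exist_ok=True)
    for name, df in omics.items():
        df.to_csv(d / f"omics_{name}.csv")
    clin.to_csv(d / "clin.csv")


@pytest.fixture
def tiny_dataset(tmp_path):
    rng = np.random.default_rng(0)
    samples = [f"s{i}" for i in range(4)]
    rna = pd.DataFrame(rng.standard_normal((3, 4)),
                       index=["g1", "g2", "g3"], columns=samples)
    cnv = pd.DataFrame(rng.standard_normal((2, 4)),
                       index=["c1", "c2"], columns=samples)
    clin = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0]}, index=samples)
    write_split(tmp_path / "train", {"rna": rna, "cnv": cnv}, clin)
    write_split(tmp_path / "test", {"rna": rna, "cnv": cnv}, clin)
    return tmp_path


def test_read_dataset_two_modalities(tiny_dataset):
    omics, meta = dio.read_dataset(tiny_dataset / "train", tiny_dataset / "test")
    assert set(omics["train"]) == {"rna", "cnv"}
    assert omics["train"]["rna"].n_samples == 4
    assert list(meta["train"].index) == [f"s{i}" for i in range(4)]


def test_read_dataset_drops_samples_missing_from_clin(tiny_dataset):
    clin = pd.read_csv(tiny_dataset / "train" / "clin.csv", index_col=0).iloc[:3]
    clin.to_csv(tiny_dataset / "train" / "clin.csv")
    omics, meta = dio.read_dataset(tiny_dataset / "train", tiny_dataset / "test")
    assert omics["train"]["rna"].n_samples == 3
    assert set(omics["train"]["rna"].sample_ids) == set(meta["train"].index)


def test_read_dataset_modality_intersection(tiny_dataset):
    (tiny_dataset / "test" / "omics_cnv.csv").unlink()
    omics, _ = dio.read_dataset(tiny_dataset / "train", tiny_dataset / "test")
    assert set(omics["train"]) == {"rna"}
    with pytest.raises(ValueError, match="not shared"):
        dio.read_dataset(tiny_dataset / "train", tiny_dataset / "test",
                         on_modality_mismatch="error")


def test_read_dataset_missing_file_named(tiny_dataset):
    (tiny_dataset / "train" / "clin.csv").unlink()
    with pytest.raises(FileNotFoundError, match="clin.csv"):
        dio.read_dataset(tiny_dataset / "train", tiny_dataset / "test")


def test_read_dataset_non_numeric_cell_coordinates(tiny_dataset):
    p = tiny_dataset / "train" / "omics_rna.csv"
    df = pd.read_csv(p, index_col=0).astype(object)
    df.iloc[1, 2] = "oops"
    df.to_csv(p)
    with pytest.raises(ValueError, match="g2.*s2"):
        dio.read_dataset(tiny_dataset / "train", tiny_dataset / "test")


def test_duplicate_ids_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        dio.OmicsMatrix("m", ["a", "a"], ["s1"], np.zeros((2, 1)))
    with pytest.raises(ValueError, match="duplicate"):
        dio.OmicsMatrix("m", ["a"], ["s1", "s1"], np.zeros((1, 2)))


def test_roundtrip_full_precision(tmp_path, tiny_dataset):
    omics, meta = dio.read_dataset(tiny_dataset / "train", tiny_dataset / "test")
    dio.write_dataset(tmp_path / "out", omics["train"], meta["train"])
    omics2, _ = dio.read_dataset(tmp_path / "out", tmp_path / "out")
    assert np.array_equal(omics["train"]["rna"].values, omics2["train"]["rna"].values)


# -- cleaning ---------------------------------------------------------------

def test_clean_removes_constant_feature_and_imputes_median():
    m = dio.OmicsMatrix("m", ["const", "f"], [f"s{i}" for i in range(4)],
                        np.array([[5.0, 5, 5, 5], [1.0, 2, 3, np.nan]]))
    out = dio.clean_training_modality(m, variance_quantile=0.0)
    assert out.feature_ids == ["f"]
    assert out.values[0, 3] == 2.0  # median of {1,2,3}


def test_clean_drops_all_missing_sample():
    vals = np.array([[1.0, np.nan, 3.0], [2.0, np.nan, 4.0]])
    out = dio.clean_training_modality(
        dio.OmicsMatrix("m", ["a", "b"], ["s1", "s2", "s3"], vals), 0.0)
    assert out.sample_ids == ["s1", "s3"]


def test_clean_all_features_removed_errors():
    m = dio.OmicsMatrix("m", ["a"], ["s1", "s2"], np.array([[1.0, 1.0]]))
    with pytest.raises(ValueError, match="variance"):
        dio.clean_training_modality(m)


# -- scaling / harmonization ------------------------------------------------

def test_fit_scaler_zero_mean_unit_sd():
    rng = np.random.default_rng(1)
    m = dio.OmicsMatrix("m", [f"f{i}" for i in range(5)],
                        [f"s{i}" for i in range(20)], rng.standard_normal((5, 20)) * 3 + 1)
    out, scaler = dio.fit_scaler(m)
    assert np.allclose(out.values.mean(axis=1), 0, atol=1e-9)
    assert np.allclose(out.values.std(axis=1), 1, atol=1e-9)


def test_fit_scaler_hand_example_population_sd():
    m = dio.OmicsMatrix("m", ["f"], ["a", "b"], np.array([[2.0, 4.0]]))
    out, _ = dio.fit_scaler(m)
    assert np.allclose(out.values, [[-1.0, 1.0]])  # sd with ddof=0 is 1


def test_fit_scaler_log_negative_errors():
    m = dio.OmicsMatrix("m", ["f"], ["a", "b"], np.array([[-1.0, 4.0]]))
    with pytest.raises(ValueError, match="log"):
        dio.fit_scaler(m, log_transform=True)


def test_harmonize_test_identity_and_leakage():
    rng = np.random.default_rng(2)
    train = dio.OmicsMatrix("m", [f"f{i}" for i in range(4)],
                            [f"s{i}" for i in range(30)], rng.standard_normal((4, 30)))
    _, scaler = dio.fit_scaler(train)
    same = dio.harmonize_test(train, scaler, list(train.feature_ids))
    assert np.allclose(same.mean(axis=0), 0, atol=1e-9)
    # shift every test value of feature 0 by +10: transformed mean must land
    # at 10/scale, NOT be re-centred to 0
    shifted_vals = train.values.copy()
    shifted_vals[0] += 10
    shifted = dio.OmicsMatrix("m", list(train.feature_ids), list(train.sample_ids), shifted_vals)
    out = dio.harmonize_test(shifted, scaler, list(train.feature_ids))
    assert out[:, 0].mean() == pytest.approx(10 / scaler.scales[0], rel=1e-9)


def test_harmonize_test_missing_selected_feature_errors():
    rng = np.random.default_rng(3)
    train = dio.OmicsMatrix("m", [f"f{i}" for i in range(5)],
                            ["a", "b", "c"], rng.standard_normal((5, 3)))
    _, scaler = dio.fit_scaler(train)
    test = dio.OmicsMatrix("m", [f"f{i}" for i in range(4)],
                           ["a", "b", "c"], rng.standard_normal((4, 3)))
    with pytest.raises(KeyError, match="f4"):
        dio.harmonize_test(test, scaler, [f"f{i}" for i in range(5)])


# -- covariates & targets ---------------------------------------------------

def test_encode_covariates_onehot_and_median():
    meta = pd.DataFrame({"grade": ["A", "B", "C", "A"],
                         "age": [1.0, np.nan, 3.0, 2.0],
                         "flat": ["x", "x", "x", "x"]},
                        index=["s1", "s2", "s3", "s4"])
    om, levels = dio.encode_covariates(meta, ["grade", "age", "flat"])
    assert om.modality_name == "covariates"
    onehot = om.values[:3]
    assert np.allclose(onehot.sum(axis=0), 1)
    age = om.values[om.feature_ids.index("age")]
    assert age[1] == 2.0  # median of {1,3,2}
    assert not any(f.startswith("flat") for f in om.feature_ids)
    # test-split encoding reuses train levels even if a level is absent
    om2, _ = dio.encode_covariates(meta.iloc[:2], ["grade", "age", "flat"], levels)
    assert [f for f in om2.feature_ids if "=" in f] == [f for f in om.feature_ids if "=" in f]


def test_encode_targets_codes_masks_and_unseen():
    ts = dio.TaskSpec((dio.Target("y", "classification"),))
    train = pd.DataFrame({"y": ["A", "A", "B"]})
    labels, maps = dio.encode_targets(train, ts)
    assert list(labels["y"]["y"]) == [0, 0, 1]
    assert labels["y"]["mask"].all()
    test = pd.DataFrame({"y": ["B", np.nan, "Z"]})
    te, _ = dio.encode_targets(test, ts, maps)
    assert list(te["y"]["mask"]) == [True, False, False]


def test_encode_targets_survival_joint_mask():
    ts = dio.TaskSpec((dio.Target("os", "survival", time_col="t", event_col="e"),))
    meta = pd.DataFrame({"t": [1.0, 2.0, np.nan], "e": [1.0, np.nan, 0.0]})
    labels, _ = dio.encode_targets(meta, ts)
    assert list(labels["os"]["mask"]) == [True, False, False]


def test_encode_targets_bad_event_values():
    ts = dio.TaskSpec((dio.Target("os", "survival", time_col="t", event_col="e"),))
    meta = pd.DataFrame({"t": [1.0], "e": [2.0]})
    with pytest.raises(ValueError, match="0/1"):
        dio.encode_targets(meta, ts)


# -- end-to-end harmonize ---------------------------------------------------

def test_harmonize_sample_alignment_and_leakage_invariant(tiny_dataset):
    omics, meta = dio.read_dataset(tiny_dataset / "train", tiny_dataset / "test")
    ts = dio.TaskSpec((dio.Target("y", "regression"),))
    b = dio.harmonize(omics, meta, ts, variance_quantile=0.0)
    assert b.train_sample_ids == b.test_sample_ids  # same files here
    for m in b.modality_names:
        assert b.feature_lists[m] == b.scalers[m].feature_ids
        # leakage check: recompute scaler on test and verify it was NOT used
        test_scaled = b.test[m]
        train_scaled = b.train[m]
        assert np.allclose(test_scaled, train_scaled)  # identical inputs here
        assert np.allclose(b.scalers[m].centers,
                           omics["train"][m].values.mean(axis=1))
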