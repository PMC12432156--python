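"""Architecture contracts: layer plans, fusion widths, head shapes,
determinism, masked-gradient flow, and checkpoint round-trips."""

import numpy as np
import pytest

from omixfuse import losses as L
from omixfuse.autodiff import Tensor
from omixfuse.data_io import TaskSpec, Target
from omixfuse.models import (HyperConfig, ModelSpec, TrainedModel, attach_heads,
                             build_encoder, build_model, fuse)

TS3 = TaskSpec((Target("reg", "regression"), Target("cls", "classification"),
                Target("os", "survival", time_col="t", event_col="e")))
TS_CLS = TaskSpec((Target("cls", "classification"),))


def rng_batch(dims, n=8, seed=0):
    rng = np.random.default_rng(seed)
    return {m: rng.standard_normal((n, d)) for m, d in dims.items()}


def test_build_encoder_arithmetic_and_floor():
    assert build_encoder(1000, HyperConfig(latent_dim=64, hidden_dim_factor=0.3)) == [1000, 300, 64]
    plan = build_encoder(2, HyperConfig(latent_dim=64, hidden_dim_factor=0.2))
    assert plan == [2, 1, 64]  # hidden smaller than latent is allowed
    with pytest.raises(ValueError):
        build_encoder(0, HyperConfig())


def test_hyperconfig_bounds():
    with pytest.raises(ValueError, match="latent_dim"):
        HyperConfig(latent_dim=4).validate()
    with pytest.raises(ValueError, match="batch_size"):
        HyperConfig(batch_size=48).validate()
    HyperConfig().validate()


def test_fuse_widths_and_mismatch():
    a, b = np.ones((5, 100)), np.ones((5, 50))
    assert fuse([a, b], "early").shape == (5, 150)
    la, lb = np.ones((5, 64)), np.ones((5, 64))
    assert fuse([la, lb], "intermediate").shape == (5, 128)
    with pytest.raises(ValueError, match="sample counts"):
        fuse([np.ones((5, 3)), np.ones((4, 3))], "early")


def test_attach_heads_output_dims():
    rng = np.random.default_rng(0)
    heads = attach_heads(32, TS3, 16, {"cls": 4}, rng)
    x = Tensor(np.zeros((3, 32)))
    assert heads["reg"](x).shape == (3, 1)
    assert heads["cls"](x).shape == (3, 4)
    assert heads["os"](x).shape == (3, 1)
    with pytest.raises(ValueError, match="2 classes"):
        attach_heads(32, TS_CLS, 16, {"cls": 1}, rng)


def test_model_spec_validation():
    with pytest.raises(ValueError, match="architecture"):
        ModelSpec("NotANet", "early", ("A",), TS_CLS).validate()
    with pytest.raises(ValueError, match="early fusion"):
        ModelSpec("GNN", "intermediate", ("A",), TS_CLS).validate()
    with pytest.raises(ValueError, match="output_modalities"):
        ModelSpec("CrossModalPred", "early", ("A",), TS_CLS).validate()
    with pytest.raises(ValueError, match="target"):
        ModelSpec("DirectPred", "early", ("A",), TaskSpec(())).validate()
    # supervised_vae with zero targets is legal (pure reconstruction + MMD)
    ModelSpec("supervised_vae", "early", ("A",), TaskSpec(())).validate()


@pytest.mark.parametrize("arch", ["DirectPred", "supervised_vae", "MultiTripletNetwork"])
@pytest.mark.parametrize("fusion", ["early", "intermediate"])
def test_embedding_width_contract(arch, fusion):
    dims = {"A": 30, "B": 20}
    hyper = HyperConfig(latent_dim=16)
    spec = ModelSpec(arch, fusion, ("A", "B"), TS_CLS, hyper)
    model = build_model(spec, dims, {"cls": 3}, seed=0)
    out = model.forward(rng_batch(dims), training=False)
    width = 16 * (2 if fusion == "intermediate" else 1)
    assert out["embeddings"].shape == (8, width)
    assert out["predictions"]["cls"].shape == (8, 3)


def test_forward_deterministic_in_eval_and_seeded_init():
    dims = {"A": 25}
    spec = ModelSpec("DirectPred", "early", ("A",), TS_CLS, HyperConfig(latent_dim=16))
    m1 = build_model(spec, dims, {"cls": 2}, seed=5)
    m2 = build_model(spec, dims, {"cls": 2}, seed=5)
    batch = rng_batch(dims)
    o1 = m1.forward(batch)["predictions"]["cls"].data
    o2 = m1.forward(batch)["predictions"]["cls"].data
    o3 = m2.forward(batch)["predictions"]["cls"].data
    assert np.array_equal(o1, o2) and np.array_equal(o1, o3)


def test_wrong_feature_width_errors():
    dims = {"A": 25}
    spec = ModelSpec("DirectPred", "early", ("A",), TS_CLS, HyperConfig(latent_dim=16))
    m = build_model(spec, dims, {"cls": 2}, seed=0)
    with pytest.raises(ValueError, match="expected 25"):
        m.forward({"A": np.zeros((4, 10))})


def test_fully_masked_head_sends_zero_gradient_to_encoder():
    dims = {"A": 20}
    ts = TaskSpec((Target("a", "classification"), Target("b", "regression")))
    spec = ModelSpec("DirectPred", "early", ("A",), ts, HyperConfig(latent_dim=16))
    model = build_model(spec, dims, {"a": 2}, seed=0)
    batch = rng_batch(dims)
    out = model.forward(batch, training=True)
    # only the fully masked target contributes
    tl = L.masked_mse(out["predictions"]["b"], np.zeros(8), np.zeros(8, bool), "b")
    total = L.combine_losses([tl])
    model.zero_grad()
    total.backward()
    for p in model.encoders["__fused__"].parameters():
        assert p.grad is None or np.allclose(p.grad, 0)


def test_vae_zero_decoder_reconstruction_equals_mean_square_input():
    dims = {"A": 12}
    spec = ModelSpec("supervised_vae", "early", ("A",), TaskSpec(()), HyperConfig(latent_dim=16))
    model = build_model(spec, dims, {}, seed=0)
    for layer in model.decoders["__fused__"].layers:
        layer.W.data[:] = 0
        layer.b.data[:] = 0
    batch = rng_batch(dims)
    out = model.forward(batch, training=False)
    assert out["aux"]["reconstruction"].item() == pytest.approx(np.mean(batch["A"] ** 2))


def test_vae_mmd_term_matches_losses_module():
    dims = {"A": 12}
    spec = ModelSpec("supervised_vae", "early", ("A",), TaskSpec(()), HyperConfig(latent_dim=16))
    model = build_model(spec, dims, {}, seed=0)
    out = model.forward(rng_batch(dims), training=False)
    z = out["aux"]["latent"].data
    prior = np.random.default_rng(0).standard_normal((8, 16))
    direct = L.mmd_loss(z, prior_samples=prior).item()
    again = L.mmd_loss(out["aux"]["latent"], prior_samples=prior).item()
    assert direct == pytest.approx(again, abs=1e-12)


def test_crossmodal_decoder_width_and_loss_target():
    dims = {"rna": 30, "mut": 14}
    spec = ModelSpec("CrossModalPred", "early", ("rna",), TaskSpec(()),
                     HyperConfig(latent_dim=16), output_modalities=("mut",))
    model = build_model(spec, dims, {}, seed=0)
    batch = rng_batch(dims)
    out = model.forward(batch, training=False)
    assert out["reconstructions"]["mut"].shape == (8, 14)
    want = np.mean((out["reconstructions"]["mut"].data - batch["mut"]) ** 2)
    assert out["aux"]["reconstruction"].item() == pytest.approx(want)


def test_triplet_sampling_reproducible_and_single_class_skips():
    dims = {"A": 20}
    spec = ModelSpec("MultiTripletNetwork", "early", ("A",), TS_CLS, HyperConfig(latent_dim=16))
    model = build_model(spec, dims, {"cls": 3}, seed=0)
    labels = np.array([0, 0, 1, 1, 2, 2, 0, 1])
    mask = np.ones(8, bool)
    t1 = model.sample_triplets(labels, mask, np.random.default_rng(3))
    t2 = model.sample_triplets(labels, mask, np.random.default_rng(3))
    assert all(np.array_equal(a, b) for a, b in zip(t1, t2))
    assert model.sample_triplets(np.zeros(8, int), mask, np.random.default_rng(0)) is None


def test_gnn_zero_edges_rejected_and_no_edge_node_self_only():
    dims = {"A": 6}
    ts = TS_CLS
    with pytest.raises(ValueError, match="edge"):
        build_model(ModelSpec("GNN", "early", ("A",), ts, HyperConfig(latent_dim=16)),
                    dims, {"cls": 2}, seed=0)
    # graph with one isolated pair: isolated nodes get no neighbor term
    spec = ModelSpec("GNN", "early", ("A",), ts,
                     HyperConfig(latent_dim=16, num_convs=1, conv_type="GraphConv"),
                     edges=((0, 1),))
    m = build_model(spec, dims, {"cls": 2}, seed=0)
    out = m.forward(rng_batch(dims))
    assert out["embeddings"].shape == (8, 16)


def test_sage_star_graph_center_gets_leaf_mean():
    """One SAGEConv layer with identity weights: the centre node's neighbour
    term equals the mean of the leaves' embedded values."""
    p = 5  # star: node 0 center, 1..4 leaves
    edges = tuple((0, i) for i in range(1, p))
    dims = {"A": p}
    spec = ModelSpec("GNN", "early", ("A",), TS_CLS,
                     HyperConfig(latent_dim=16, num_convs=1, conv_type="SAGEConv",
                                 node_embedding_dim=4),
                     edges=edges)
    m = build_model(spec, dims, {"cls": 2}, seed=0)
    d = 4
    # identity-ish weights: W_self = 0, W_neigh = I, biases 0
    m.conv_self[0].W.data[:] = 0
    m.conv_self[0].b.data[:] = 0
    m.conv_neigh[0].W.data = np.eye(d)
    m.conv_neigh[0].b.data[:] = 0
    x = np.arange(p, dtype=float).reshape(1, p)
    H0 = x.reshape(1, p, 1) @ m.node_embed.W.data + m.node_embed.b.data
    A = m._A  # row-normalized adjacency
    neigh_center = (A @ H0)[0, 0]
    assert np.allclose(neigh_center, H0[0, 1:].mean(axis=0))


def test_checkpoint_roundtrip_bitstable(tmp_path):
    dims = {"A": 18, "B": 9}
    spec = ModelSpec("DirectPred", "intermediate", ("A", "B"), TS_CLS,
                     HyperConfig(latent_dim=16))
    model = build_model(spec, dims, {"cls": 3}, seed=1)
    tm = TrainedModel(model, spec, {}, best_epoch=3)
    batch = rng_batch(dims)
    before = tm.predict(batch)["cls"]
    tm.save(tmp_path / "ckpt.npz")
    tm2 = TrainedModel.load(tmp_path / "ckpt.npz", TS_CLS)
    after = tm2.predict(batch)["cls"]
    assert np.array_equal(before, after)
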