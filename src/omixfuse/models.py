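"""The encoder architectures, fusion modes and supervisor heads.

Five architectures over tabular multi-omics input:

DirectPred          feed-forward encoder(s) + MLP heads
supervised_vae      per-modality VAE with MMD prior-matching loss; heads on z
CrossModalPred      VAE variant whose decoders reconstruct a chosen subset
                    of *output* modalities from the fused latent
MultiTripletNetwork DirectPred plus a triplet contrastive term on the
                    embedding, anchored on the first classification target
GNN                 per-sample graph over features (nodes = features carrying
                    the sample's value), GraphConv/GCNConv/SAGEConv stacks,
                    mean-pooled readout; early fusion only

Fusion: 'early' concatenates modality matrices before one encoder;
'intermediate' gives each modality its own encoder and concatenates the
latents before the heads, so the embedding width is
latent_dim x n_modalities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, concatenate, no_grad
from .nn import MLP, Adam, Linear, Module
from .data_io import TaskSpec

logger = logging.getLogger(__name__)

__all__ = ["HyperConfig", "ModelSpec", "TrainedModel", "build_encoder", "fuse",
           "attach_heads", "build_model", "ARCHITECTURES", "CONV_TYPES"]

ARCHITECTURES = ("DirectPred", "supervised_vae", "CrossModalPred",
                 "MultiTripletNetwork", "GNN")
CONV_TYPES = ("GraphConv", "GCNConv", "SAGEConv")


@dataclass
class HyperConfig:
    """One point in the hyperparameter search space."""

    latent_dim: int = 32
    hidden_dim_factor: float = 0.3
    lr: float = 1e-3
    supervisor_hidden_dim: int = 16
    max_epochs: int = 500
    batch_size: int = 32
    # GNN extras
    node_embedding_dim: int = 8
    num_convs: int = 2
    conv_type: str = "GraphConv"
    activation: str = "relu"

    def validate(self) -> None:
        problems = []
        if not 16 <= self.latent_dim <= 128:
            problems.append("latent_dim must be in [16, 128]")
        if not 0.2 <= self.hidden_dim_factor <= 0.5:
            problems.append("hidden_dim_factor must be in [0.2, 0.5]")
        if not 1e-4 <= self.lr <= 1e-2:
            problems.append("lr must be in [1e-4, 1e-2]")
        if not 8 <= self.supervisor_hidden_dim <= 32:
            problems.append("supervisor_hidden_dim must be in [8, 32]")
        if not (32 <= self.batch_size <= 128 and (self.batch_size & (self.batch_size - 1)) == 0):
            problems.append("batch_size must be a power of two in [32, 128]")
        if not 4 <= self.node_embedding_dim <= 32:
            problems.append("node_embedding_dim must be in [4, 32]")
        if not 1 <= self.num_convs <= 4:
            problems.append("num_convs must be in [1, 4]")
        if self.conv_type not in CONV_TYPES:
            problems.append(f"conv_type must be one of {CONV_TYPES}")
        if self.activation != "relu":
            problems.append("activation must be 'relu'")
        if problems:
            raise ValueError("invalid HyperConfig: " + "; ".join(problems))


@dataclass
class ModelSpec:
    architecture: str
    fusion: str  # early | intermediate
    input_modalities: tuple[str, ...]
    task_spec: TaskSpec
    hyper: HyperConfig = field(default_factory=HyperConfig)
    output_modalities: tuple[str, ...] = ()   # CrossModalPred only
    uncertainty_weighting: bool = True
    triplet_margin: float = 1.0
    mlp_activation: str = "relu"   # encoder/head nonlinearity (relu | tanh)
    edges: tuple[tuple[int, int], ...] = ()   # GNN: indices into fused features

    def validate(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; valid: {ARCHITECTURES}")
        if self.fusion not in ("early", "intermediate"):
            raise ValueError("fusion must be 'early' or 'intermediate'")
        if self.architecture == "GNN" and self.fusion != "early":
            raise ValueError("GNN supports early fusion only")
        if self.architecture == "CrossModalPred" and not self.output_modalities:
            raise ValueError("CrossModalPred needs non-empty output_modalities")
        if not self.input_modalities:
            raise ValueError("need at least one input modality")
        n_targets = len(self.task_spec.targets)
        if n_targets == 0 and self.architecture not in ("supervised_vae", "CrossModalPred"):
            raise ValueError(f"{self.architecture} requires at least one target")
        if self.architecture == "MultiTripletNetwork":
            kinds = [t.kind for t in self.task_spec.targets]
            if "classification" not in kinds:
                raise ValueError("MultiTripletNetwork needs a classification target")
        self.hyper.validate()


def build_encoder(input_dim: int, hyper: HyperConfig) -> list[int]:
    """Layer-size plan input -> ceil(hidden_dim_factor * input) -> latent."""
    if input_dim < 1:
        raise ValueError("input_dim must be >= 1")
    hidden = int(np.ceil(hyper.hidden_dim_factor * input_dim))
    if hidden < 1:
        logger.warning("hidden layer size computed to 0; flooring at 1")
        hidden = 1
    return [input_dim, hidden, hyper.latent_dim]


def fuse(arrays, mode: str):
    """Concatenate along features (early: raw matrices; intermediate: latents)."""
    if mode not in ("early", "intermediate"):
        raise ValueError("fusion must be 'early' or 'intermediate'")
    ns = {a.shape[0] for a in arrays}
    if len(ns) != 1:
        raise ValueError(f"mismatched sample counts across inputs: {sorted(ns)}")
    if isinstance(arrays[0], Tensor):
        return concatenate(list(arrays), axis=1)
    return np.concatenate([np.asarray(a) for a in arrays], axis=1)


def attach_heads(
    embedding_width: int,
    task_spec: TaskSpec,
    supervisor_hidden_dim: int,
    n_classes: dict[str, int],
    rng: np.random.Generator,
    activation: str = "relu",
) -> dict[str, MLP]:
    """One MLP per target: embedding -> hidden -> (1 | n_classes | 1 risk)."""
    if embedding_width < 1:
        raise ValueError("embedding_width must be >= 1")
    heads: dict[str, MLP] = {}
    for t in task_spec.targets:
        if t.kind == "classification":
            k = n_classes[t.name]
            if k < 2:
                raise ValueError(f"{t.name}: classification needs >= 2 classes")
            out = k
        else:
            out = 1
        heads[t.name] = MLP([embedding_width, supervisor_hidden_dim, out], rng, activation)
    return heads


def _as_t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


class _HeadedModel(Module):
    """Shared head plumbing: subclasses implement embed()."""

    def __init__(self, spec: ModelSpec, input_dims: dict[str, int],
                 n_classes: dict[str, int], rng: np.random.Generator):
        spec.validate()
        self.spec = spec
        self.input_dims = dict(input_dims)
        self.n_classes = dict(n_classes)
        self.embedding_width = self._embedding_width()
        self.heads = attach_heads(self.embedding_width, spec.task_spec,
                                  spec.hyper.supervisor_hidden_dim, n_classes, rng,
                                  spec.mlp_activation)

    def _embedding_width(self) -> int:
        h = self.spec.hyper
        if self.spec.fusion == "intermediate":
            return h.latent_dim * len(self.spec.input_modalities)
        return h.latent_dim

    def _check_batch(self, batch: dict) -> dict[str, Tensor]:
        out = {}
        for m in self.spec.input_modalities:
            x = _as_t(batch[m])
            if x.shape[1] != self.input_dims[m]:
                raise ValueError(
                    f"{m}: expected {self.input_dims[m]} features, got {x.shape[1]}")
            out[m] = x
        return out

    def predict_heads(self, emb: Tensor) -> dict[str, Tensor]:
        return {name: head(emb) for name, head in self.heads.items()}

    def forward(self, batch: dict, training: bool = False,
                rng: np.random.Generator | None = None) -> dict:
        emb = self.embed(self._check_batch(batch), training=training, rng=rng)
        return {"embeddings": emb, "predictions": self.predict_heads(emb), "aux": {}}

    def embeddings(self, batch: dict) -> np.ndarray:
        with no_grad():
            return self.forward(batch)["embeddings"].data


class DirectPred(_HeadedModel):
    def __init__(self, spec, input_dims, n_classes, rng):
        super().__init__(spec, input_dims, n_classes, rng)
        h = spec.hyper
        act = spec.mlp_activation
        if spec.fusion == "early":
            total = sum(input_dims[m] for m in spec.input_modalities)
            self.encoders = {"__fused__": MLP(build_encoder(total, h), rng, act)}
        else:
            self.encoders = {m: MLP(build_encoder(input_dims[m], h), rng, act)
                             for m in spec.input_modalities}

    def embed(self, xs: dict[str, Tensor], training=False, rng=None) -> Tensor:
        if self.spec.fusion == "early":
            fused = fuse([xs[m] for m in self.spec.input_modalities], "early")
            return self.encoders["__fused__"](fused)
        latents = [self.encoders[m](xs[m]) for m in self.spec.input_modalities]
        return fuse(latents, "intermediate")


class _VAEBase(_HeadedModel):
    """Gaussian encoder(s) with reparameterization; MMD pulls z to N(0, I)."""

    def __init__(self, spec, input_dims, n_classes, rng):
        super().__init__(spec, input_dims, n_classes, rng)
        h = spec.hyper
        self.enc_hidden: dict[str, MLP] = {}
        self.enc_mu: dict[str, Linear] = {}
        self.enc_logvar: dict[str, Linear] = {}
        groups = (["__fused__"] if spec.fusion == "early"
                  else list(spec.input_modalities))
        for g in groups:
            dim = (sum(input_dims[m] for m in spec.input_modalities)
                   if g == "__fused__" else input_dims[g])
            plan = build_encoder(dim, h)
            self.enc_hidden[g] = MLP(plan[:-1], rng, spec.mlp_activation)
            self.enc_mu[g] = Linear(plan[-2], h.latent_dim, rng)
            self.enc_logvar[g] = Linear(plan[-2], h.latent_dim, rng)

    def _encode_groups(self, xs, training, rng):
        groups = (["__fused__"] if self.spec.fusion == "early"
                  else list(self.spec.input_modalities))
        zs, mus = [], []
        for g in groups:
            x = (fuse([xs[m] for m in self.spec.input_modalities], "early")
                 if g == "__fused__" else xs[g])
            hcode = self.enc_hidden[g](x)
            hcode = hcode.relu() if self.spec.mlp_activation == "relu" else hcode.tanh()
            mu = self.enc_mu[g](hcode)
            logvar = self.enc_logvar[g](hcode)
            if training:
                eps = (rng or np.random.default_rng()).standard_normal(mu.shape)
                z = mu + (0.5 * logvar).exp() * Tensor(eps)
            else:
                z = mu
            zs.append(z)
            mus.append(mu)
        return zs, mus, groups

    def embed(self, xs, training=False, rng=None) -> Tensor:
        zs, _, _ = self._encode_groups(xs, training, rng)
        return zs[0] if len(zs) == 1 else fuse(zs, "intermediate")


class SupervisedVAE(_VAEBase):
    """Per-group decoder reconstructs its own input; heads read z."""

    def __init__(self, spec, input_dims, n_classes, rng):
        super().__init__(spec, input_dims, n_classes, rng)
        h = spec.hyper
        self.decoders: dict[str, MLP] = {}
        groups = (["__fused__"] if spec.fusion == "early"
                  else list(spec.input_modalities))
        for g in groups:
            dim = (sum(input_dims[m] for m in spec.input_modalities)
                   if g == "__fused__" else input_dims[g])
            plan = build_encoder(dim, h)
            self.decoders[g] = MLP(plan[::-1], rng, spec.mlp_activation)

    def forward(self, batch, training=False, rng=None):
        xs = self._check_batch(batch)
        zs, _, groups = self._encode_groups(xs, training, rng)
        emb = zs[0] if len(zs) == 1 else fuse(zs, "intermediate")
        recon_terms = []
        recons = {}
        for g, z in zip(groups, zs):
            target = (fuse([xs[m] for m in self.spec.input_modalities], "early")
                      if g == "__fused__" else xs[g])
            rec = self.decoders[g](z)
            recons[g] = rec
            recon_terms.append(((rec - target) ** 2).mean())
        recon = recon_terms[0]
        for t in recon_terms[1:]:
            recon = recon + t
        return {"embeddings": emb, "predictions": self.predict_heads(emb),
                "reconstructions": recons,
                "aux": {"reconstruction": recon, "latent": emb}}


class CrossModalPred(_VAEBase):
    """Encode the input subset, decode the output subset from the fused z."""

    def __init__(self, spec, input_dims, n_classes, rng):
        super().__init__(spec, input_dims, n_classes, rng)
        h = spec.hyper
        for m in spec.output_modalities:
            if m not in input_dims:
                raise ValueError(f"output modality {m!r} has unknown width")
        self.decoders = {
            m: MLP([self.embedding_width,
                    max(1, int(np.ceil(h.hidden_dim_factor * input_dims[m]))),
                    input_dims[m]], rng, spec.mlp_activation)
            for m in spec.output_modalities
        }

    def forward(self, batch, training=False, rng=None):
        xs = self._check_batch(batch)
        zs, _, _ = self._encode_groups(xs, training, rng)
        emb = zs[0] if len(zs) == 1 else fuse(zs, "intermediate")
        recons = {m: self.decoders[m](emb) for m in self.spec.output_modalities}
        recon = None
        for m, rec in recons.items():
            target = _as_t(batch[m])
            term = ((rec - target) ** 2).mean()
            recon = term if recon is None else recon + term
        return {"embeddings": emb, "predictions": self.predict_heads(emb),
                "reconstructions": recons,
                "aux": {"reconstruction": recon, "latent": emb}}

    def _check_batch(self, batch):
        out = super()._check_batch(batch)
        return out


class MultiTripletNetwork(DirectPred):
    """DirectPred embedding shaped additionally by a triplet margin loss.

    Positives/negatives are sampled within the batch using the first
    classification target's labels; single-class batches skip the term.
    """

    def anchor_target(self) -> str:
        for t in self.spec.task_spec.targets:
            if t.kind == "classification":
                return t.name
        raise ValueError("no classification target for triplet anchoring")

    def sample_triplets(self, labels: np.ndarray, mask: np.ndarray,
                        rng: np.random.Generator):
        """(anchor_idx, pos_idx, neg_idx) arrays, or None if < 2 classes."""
        valid = np.where(mask)[0]
        classes = np.unique(labels[valid])
        if len(classes) < 2:
            return None
        by_class = {c: valid[labels[valid] == c] for c in classes}
        anchors, pos, neg = [], [], []
        for i in valid:
            c = labels[i]
            same = by_class[c]
            if len(same) < 2:
                continue
            p = i
            while p == i:
                p = same[rng.integers(len(same))]
            others = classes[classes != c]
            oc = others[rng.integers(len(others))]
            n = by_class[oc][rng.integers(len(by_class[oc]))]
            anchors.append(i)
            pos.append(p)
            neg.append(n)
        if not anchors:
            return None
        return np.array(anchors), np.array(pos), np.array(neg)


def _gcn_norm(adj: np.ndarray) -> np.ndarray:
    a = adj + np.eye(adj.shape[0])
    d = a.sum(axis=1)
    dinv = 1.0 / np.sqrt(np.where(d > 0, d, 1.0))
    return a * dinv[:, None] * dinv[None, :]


def _mean_norm(adj: np.ndarray) -> np.ndarray:
    d = adj.sum(axis=1, keepdims=True)
    return adj / np.where(d > 0, d, 1.0)


class GNN(_HeadedModel):
    """Per-sample graph over (early-fused) features.

    Each feature is a node carrying the sample's scalar value, embedded to
    ``node_embedding_dim`` by a shared linear map; ``num_convs`` rounds of
    the chosen convolution; mean pooling over nodes; linear to latent.
    """

    def __init__(self, spec, input_dims, n_classes, rng):
        super().__init__(spec, input_dims, n_classes, rng)
        h = spec.hyper
        if not spec.edges:
            raise ValueError("GNN requires a non-empty edge set")
        self.n_nodes = sum(input_dims[m] for m in spec.input_modalities)
        adj = np.zeros((self.n_nodes, self.n_nodes))
        for i, j in spec.edges:
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValueError(f"edge ({i},{j}) outside node range")
            adj[i, j] = adj[j, i] = 1.0
        d = h.node_embedding_dim
        self.node_embed = Linear(1, d, rng)
        self.conv_self = [Linear(d, d, rng) for _ in range(h.num_convs)]
        self.conv_neigh = [Linear(d, d, rng) for _ in range(h.num_convs)]
        self.readout = Linear(d, h.latent_dim, rng)
        if h.conv_type == "GCNConv":
            self._A = _gcn_norm(adj)
        elif h.conv_type == "SAGEConv":
            self._A = _mean_norm(adj)
        else:
            self._A = adj

    def embed(self, xs, training=False, rng=None) -> Tensor:
        fused = fuse([xs[m] for m in self.spec.input_modalities], "early")
        n = fused.shape[0]
        # (n, p, 1) -> shared linear -> (n, p, d)
        H = fused.reshape(n, self.n_nodes, 1) @ self.node_embed.W + self.node_embed.b
        A = Tensor(self._A)
        conv = self.spec.hyper.conv_type
        for k in range(self.spec.hyper.num_convs):
            neigh = A @ H
            if conv == "GCNConv":
                H = neigh @ self.conv_neigh[k].W + self.conv_neigh[k].b
            else:  # GraphConv / SAGEConv: self term + (sum | mean) neighbor term
                H = self.conv_self[k](H) + neigh @ self.conv_neigh[k].W
            H = H.relu()
        pooled = H.mean(axis=1)
        return self.readout(pooled)


_MODEL_CLASSES = {
    "DirectPred": DirectPred,
    "supervised_vae": SupervisedVAE,
    "CrossModalPred": CrossModalPred,
    "MultiTripletNetwork": MultiTripletNetwork,
    "GNN": GNN,
}


def build_model(spec: ModelSpec, input_dims: dict[str, int],
                n_classes: dict[str, int], seed: int = 0):
    """Instantiate the architecture named by ``spec`` with seeded init."""
    spec.validate()
    rng = np.random.default_rng(seed)
    return _MODEL_CLASSES[spec.architecture](spec, input_dims, n_classes, rng)


@dataclass
class TrainedModel:
    """A fitted model plus everything needed to predict on new data."""

    model: Module
    spec: ModelSpec
    history: dict[str, list[float]]
    uncertainty: "object" = None  # losses.UncertaintyWeights
    best_epoch: int = -1

    def forward_eval(self, batch: dict) -> dict:
        with no_grad():
            return self.model.forward(batch, training=False)

    def predict(self, batch: dict) -> dict[str, np.ndarray]:
        out = self.forward_eval(batch)
        return {k: v.data for k, v in out["predictions"].items()}

    def embeddings(self, batch: dict) -> np.ndarray:
        return self.forward_eval(batch)["embeddings"].data

    def save(self, path) -> None:
        import json

        arrays = self.model.state_arrays()
        meta = {
            "architecture": self.spec.architecture,
            "fusion": self.spec.fusion,
            "input_modalities": list(self.spec.input_modalities),
            "output_modalities": list(self.spec.output_modalities),
            "hyper": asdict(self.spec.hyper),
            "input_dims": self.model.input_dims,
            "n_classes": self.model.n_classes,
            "best_epoch": self.best_epoch,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **{f"p{i}": a for i, a in enumerate(arrays)})

    @staticmethod
    def load(path, task_spec: TaskSpec, edges=()) -> "TrainedModel":
        import json

        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            arrays = [z[f"p{i}"] for i in range(len(z.files) - 1)]
        spec = ModelSpec(meta["architecture"], meta["fusion"],
                         tuple(meta["input_modalities"]), task_spec,
                         HyperConfig(**meta["hyper"]),
                         tuple(meta["output_modalities"]), edges=tuple(edges))
        model = build_model(spec, meta["input_dims"],
                            {k: int(v) for k, v in meta["n_classes"].items()}, seed=0)
        model.load_state_arrays(arrays)
        return TrainedModel(model, spec, {}, best_epoch=meta["best_epoch"])
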