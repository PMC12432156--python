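"""Loss functions for multi-task training.

Every supervised loss is *masked*: samples whose label is missing
contribute nothing to the value and no gradient flows from them, which is
what lets one model train jointly on targets with different missingness
patterns.  All functions accept either :class:`~omixfuse.autodiff.Tensor`
or plain arrays for the prediction argument; labels and masks are plain
arrays.

Conventions pinned here:

* Cox partial likelihood uses the Breslow tie approximation with risk
  sets {j : t_j >= t_i}, averaged over events.
* MMD² is the biased V-statistic with a Gaussian kernel
  k(a,b) = exp(-||a-b||² / bandwidth); the prior sample is standard
  normal, drawn fresh per call from the supplied seed.
* Uncertainty weighting (when enabled) combines task losses as
  sum_t [exp(-s_t)·L_t + s_t] with one trainable log-variance s_t per
  task; disabled = plain sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .nn import Module

logger = logging.getLogger(__name__)

__all__ = ["TaskLoss", "UncertaintyWeights", "masked_mse", "masked_cross_entropy",
           "cox_ph_loss", "mmd_loss", "triplet_loss", "combine_losses"]


@dataclass
class TaskLoss:
    task_name: str
    value: Tensor          # scalar
    n_observed: int


def _as_t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def _zero() -> Tensor:
    return Tensor(np.zeros(()))


def masked_mse(pred, target, mask, name: str = "mse") -> TaskLoss:
    """Mean squared error over unmasked entries."""
    pred = _as_t(pred)
    target = np.asarray(target, dtype=float).ravel()
    mask = np.asarray(mask, dtype=bool).ravel()
    if pred.data.size != target.size or target.size != mask.size:
        raise ValueError("pred/target/mask lengths differ")
    n = int(mask.sum())
    if n == 0:
        return TaskLoss(name, _zero(), 0)
    idx = np.where(mask)[0]
    diff = pred.reshape(-1)[idx] - target[idx]
    return TaskLoss(name, (diff * diff).mean(), n)


def masked_cross_entropy(logits, class_codes, mask, name: str = "ce") -> TaskLoss:
    """Mean negative log-softmax of the true class over unmasked entries."""
    logits = _as_t(logits)
    codes = np.asarray(class_codes).astype(int).ravel()
    mask = np.asarray(mask, dtype=bool).ravel()
    if logits.shape[0] != codes.size or codes.size != mask.size:
        raise ValueError("logits/codes/mask lengths differ")
    n = int(mask.sum())
    if n == 0:
        return TaskLoss(name, _zero(), 0)
    idx = np.where(mask)[0]
    K = logits.shape[1]
    if (codes[idx] < 0).any() or (codes[idx] >= K).any():
        raise ValueError("class code out of range under an unmasked position")
    sub = logits[idx]
    lse = sub.logsumexp(axis=1)
    true_logit = sub[np.arange(n), codes[idx]]
    return TaskLoss(name, (lse - true_logit).mean(), n)


def cox_ph_loss(risk, time, event, mask=None, name: str = "cox") -> TaskLoss:
    """Negative Breslow partial log-likelihood, averaged over events.

    -(1/E) * sum_{i: event_i=1} [risk_i - log sum_{j: t_j >= t_i} exp(risk_j)]
    over unmasked samples.  Returns 0 with n_observed = 0 when no events.
    """
    risk = _as_t(risk).reshape(-1)
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event, dtype=float).ravel()
    mask = np.ones_like(time, dtype=bool) if mask is None else np.asarray(mask, dtype=bool).ravel()
    if not (risk.data.size == time.size == event.size == mask.size):
        raise ValueError("risk/time/event/mask lengths differ")
    if (time[mask] < 0).any():
        raise ValueError("negative times")
    if not np.isin(event[mask], (0.0, 1.0)).all():
        raise ValueError("event must be 0/1 where unmasked")
    obs = np.where(mask)[0]
    ev = obs[event[obs] == 1]
    if ev.size == 0:
        logger.warning("%s: zero unmasked events; loss contributes 0", name)
        return TaskLoss(name, _zero(), 0)
    r = risk[obs]
    # risk-set membership matrix: events x observed, True where t_j >= t_i
    t_obs = time[obs]
    t_ev = time[ev]
    at_risk = t_obs[None, :] >= t_ev[:, None]
    neg_fill = np.where(at_risk, 0.0, -np.inf)
    lse = (r.reshape(1, -1) + neg_fill).logsumexp(axis=1)
    ev_pos = np.searchsorted(obs, ev)
    ll = (r[ev_pos] - lse).mean()
    return TaskLoss(name, -ll, int(ev.size))


def mmd_loss(latent_batch, n_prior_samples: int | None = None,
             bandwidth: float | None = None, seed: int = 0,
             prior_samples: np.ndarray | None = None) -> Tensor:
    """Biased V-statistic MMD² between the latent batch and a standard
    normal prior sample under a Gaussian kernel.

    bandwidth defaults to 2 * latent_dim; the prior can be supplied
    explicitly (tests) or is drawn from ``seed``.
    """
    z = _as_t(latent_batch)
    if z.ndim != 2 or z.shape[0] == 0:
        raise ValueError("latent batch must be non-empty 2-D")
    d = z.shape[1]
    if bandwidth is None:
        bandwidth = 2.0 * d
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    if prior_samples is None:
        m = z.shape[0] if n_prior_samples is None else int(n_prior_samples)
        prior_samples = np.random.default_rng(seed).standard_normal((m, d))
    p = np.asarray(prior_samples, dtype=float)

    def gram(a, b):
        # ||a_i - b_j||^2 via the polarization identity, kept differentiable
        aa = (a * a).sum(axis=1, keepdims=True) if isinstance(a, Tensor) else Tensor((a * a).sum(1, keepdims=True))
        bb = (b * b).sum(axis=1, keepdims=True) if isinstance(b, Tensor) else Tensor((b * b).sum(1, keepdims=True))
        ab = (a if isinstance(a, Tensor) else Tensor(a)) @ (b.T if isinstance(b, Tensor) else Tensor(b.T))
        sq = aa + bb.T - 2.0 * ab
        return ((-1.0 / bandwidth) * sq).exp()

    k_zz = gram(z, z).mean()
    k_pp = gram(Tensor(p), Tensor(p)).mean()
    k_zp = gram(z, Tensor(p)).mean()
    return k_zz + k_pp - 2.0 * k_zp


def triplet_loss(anchor, positive, negative, margin: float = 1.0) -> Tensor:
    """Mean over triplets of max(0, ||a-p|| - ||a-n|| + margin)."""
    a, pos, neg = _as_t(anchor), _as_t(positive), _as_t(negative)
    if not (a.shape == pos.shape == neg.shape):
        raise ValueError("anchor/positive/negative shapes differ")
    eps = 1e-12
    d_ap = (((a - pos) ** 2).sum(axis=-1) + eps).sqrt()
    d_an = (((a - neg) ** 2).sum(axis=-1) + eps).sqrt()
    return (d_ap - d_an + margin).relu().mean()


class UncertaintyWeights(Module):
    """Trainable per-task log-variances s_t for loss balancing."""

    def __init__(self, task_names: list[str], enabled: bool = True):
        self.task_names = list(task_names)
        self.enabled = enabled
        self.s = {t: Tensor(np.zeros(()), requires_grad=True) for t in task_names}

    def weight(self, task: str) -> float:
        return float(np.exp(-self.s[task].data)) if self.enabled else 1.0


def combine_losses(
    task_losses: list[TaskLoss],
    aux_losses: list[TaskLoss] | None = None,
    weights: UncertaintyWeights | None = None,
) -> Tensor:
    """Total loss: plain sum, or uncertainty-weighted
    sum_t [exp(-s_t) L_t + s_t] when ``weights`` is enabled.  Tasks with
    no observed labels are excluded entirely (no gradient to their s_t)."""
    all_losses = list(task_losses) + list(aux_losses or [])
    if not all_losses:
        raise ValueError("no loss terms to combine")
    total: Tensor | None = None
    for tl in all_losses:
        if tl.n_observed == 0 and float(tl.value.data) == 0.0:
            continue
        if weights is not None and weights.enabled and tl.task_name in weights.s:
            s = weights.s[tl.task_name]
            term = (-s).exp() * tl.value + s
        else:
            term = tl.value
        total = term if total is None else total + term
    return total if total is not None else _zero()
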