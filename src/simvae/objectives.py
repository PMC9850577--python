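"""Metric-learning objective: reconstruction + contractive + margin losses.

The training unit is a triplet (source, target, negative). Reconstruction is
the usual teacher-forced token NLL of each string from its own sampled
latent. The contractive term is the Fréchet (2-Wasserstein squared) distance
between the source and target posterior Gaussians — for diagonal covariances

    ||mu_t - mu_s||^2 + sum_i (sqrt(var_t_i) - sqrt(var_s_i))^2

— pulling similar molecules onto the same latent point. The margin term
softplus(1 - ||mu - mu_n||^2) pushes the dissimilar negative's mean away
from both pair members while its softplus form prevents unbounded spread.
This objective replaces the standard-normal KL prior of a vanilla VAE
entirely; no N(0, I) term is added.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .autograd import Tensor
from .data import Triplet
from .model import LatentGaussian, SmilesVae

__all__ = [
    "LossBreakdown",
    "MetricTrainConfig",
    "contractive_loss",
    "margin_loss",
    "metric_objective",
    "train_metric_phase",
    "triplet_hinge_loss",
    "contrastive_loss",
]


@dataclass(frozen=True)
class LossBreakdown:
    reconstruction: float
    contractive: float
    margin: float

    @property
    def total(self) -> float:
        return self.reconstruction + self.contractive + self.margin


def _check_dims(a: LatentGaussian, b: LatentGaussian) -> None:
    if a.mean.data.shape[-1] != b.mean.data.shape[-1]:
        raise ValueError(
            f"latent dimension mismatch: {a.mean.data.shape} vs {b.mean.data.shape}"
        )


def contractive_loss(a: LatentGaussian, b: LatentGaussian) -> Tensor:
    """Fréchet distance between two diagonal Gaussians (per batch row).

    Closed form for commuting covariances; equals the general
    tr[S_a + S_b - 2 (S_a S_b)^{1/2}] trace term plus the squared mean gap.
    Symmetric, non-negative, zero iff the Gaussians coincide.
    """
    _check_dims(a, b)
    dmu = a.mean - b.mean
    dsd = a.variance.sqrt() - b.variance.sqrt()
    return (dmu * dmu).sum(axis=-1) + (dsd * dsd).sum(axis=-1)


def margin_loss(mu_a: Tensor, mu_b: Tensor) -> Tensor:
    """softplus(1 - squared Euclidean distance) between two mean vectors."""
    if mu_a.data.shape[-1] != mu_b.data.shape[-1]:
        raise ValueError("latent dimension mismatch")
    d = mu_a - mu_b
    return (1.0 - (d * d).sum(axis=-1)).softplus()


def triplet_hinge_loss(mu_s: Tensor, mu_t: Tensor, mu_n: Tensor, margin: float = 1.0) -> Tensor:
    """Classic triplet hinge max(0, m + d(s,t) - d(s,n)) — comparison only."""
    dp = ((mu_s - mu_t) * (mu_s - mu_t)).sum(axis=-1)
    dn = ((mu_s - mu_n) * (mu_s - mu_n)).sum(axis=-1)
    return _relu(dp - dn + margin)


def _relu(x: Tensor) -> Tensor:
    mask = (x.data > 0).astype(np.float64)
    return x * Tensor(mask)


def contrastive_loss(mu_a: Tensor, mu_b: Tensor, similar: bool, margin: float = 1.0) -> Tensor:
    """Pairwise contrastive loss (comparison baseline, not the main objective)."""
    d2 = ((mu_a - mu_b) * (mu_a - mu_b)).sum(axis=-1)
    if similar:
        return d2
    return _relu(margin - d2)


def _reparam(g: LatentGaussian, eps: np.ndarray) -> Tensor:
    return g.mean + g.variance.sqrt() * Tensor(eps)


def _batch_objective(
    model: SmilesVae,
    batch: Sequence[Triplet],
    rng: np.random.Generator,
    use_contractive: bool = True,
    use_margin: bool = True,
) -> tuple[Tensor, LossBreakdown]:
    """Mean-over-batch objective with the per-term breakdown.

    Reconstruction NLL is summed over tokens and averaged over the batch;
    each string is reconstructed from a single reparameterized sample of its
    own posterior.
    """
    enc = lambda smis: model.encode_batch(
        [model.vocab.encode(s, model.config.max_len) for s in smis]
    )
    srcs = [t.source for t in batch]
    tgts = [t.target for t in batch]
    negs = [t.negative for t in batch]
    g_s, g_t, g_n = enc(srcs), enc(tgts), enc(negs)

    recon_terms = []
    for g, smis in ((g_t, tgts), (g_s, srcs), (g_n, negs)):
        eps = rng.standard_normal(g.mean.data.shape)
        z = _reparam(g, eps)
        seqs = [model.vocab.encode(s, model.config.max_len) for s in smis]
        recon_terms.append(model.decode_nll_batch(z, seqs).mean())
    recon = recon_terms[0] + recon_terms[1] + recon_terms[2]

    contract = contractive_loss(g_t, g_s).mean()
    marg = (margin_loss(g_t.mean, g_n.mean) + margin_loss(g_s.mean, g_n.mean)).mean()

    total = recon
    if use_contractive:
        total = total + contract
    if use_margin:
        total = total + marg
    breakdown = LossBreakdown(
        reconstruction=float(recon.data),
        contractive=float(contract.data) if use_contractive else 0.0,
        margin=float(marg.data) if use_margin else 0.0,
    )
    return total, breakdown


def metric_objective(
    t: Triplet, model: SmilesVae, rng: np.random.Generator
) -> LossBreakdown:
    """Per-triplet loss breakdown (reconstruction, contractive, margin)."""
    _, breakdown = _batch_objective(model, [t], rng)
    return breakdown


@dataclass
class MetricTrainConfig:
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 3e-3
    seed: int = 0
    use_contractive: bool = True
    use_margin: bool = True


def train_metric_phase(
    triplets: Sequence[Triplet],
    model: SmilesVae,
    config: MetricTrainConfig | None = None,
) -> list[LossBreakdown]:
    """Minibatch Adam on the triplet objective; returns per-epoch mean losses.

    Deterministic for a fixed seed on one CPU thread. Aborts with a
    diagnostic if the loss goes non-finite.
    """
    if not triplets:
        raise ValueError("empty triplet set")
    cfg = config or MetricTrainConfig()
    rng = np.random.default_rng(cfg.seed)
    opt = model.make_optimizer(cfg.learning_rate)
    history: list[LossBreakdown] = []
    triplets = list(triplets)
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(triplets))
        sums = np.zeros(3)
        n_batches = 0
        for start in range(0, len(triplets), cfg.batch_size):
            batch = [triplets[int(i)] for i in order[start : start + cfg.batch_size]]
            opt.zero_grad()
            total, br = _batch_objective(
                model, batch, rng, cfg.use_contractive, cfg.use_margin
            )
            if not np.isfinite(total.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {br}"
                )
            total.backward()
            opt.step()
            sums += (br.reconstruction, br.contractive, br.margin)
            n_batches += 1
        history.append(LossBreakdown(*(sums / n_batches)))
    return history


def write_loss_history(path, history: Sequence[LossBreakdown]) -> None:
    with open(path, "w") as fh:
        fh.write("epoch,reconstruction,contractive,margin,total\n")
        for i, h in enumerate(history):
            fh.write(f"{i},{h.reconstruction},{h.contractive},{h.margin},{h.total}\n")
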