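"""Sequence VAE over SMILES: GRU encoder to a diagonal Gaussian latent,
GRU decoder back to token distributions, and sampling-based generation.

The encoder q(z|x) maps a token sequence to (mean, variance) of a diagonal
Gaussian; latents are drawn by the reparameterization trick. The decoder
p(x|z) is conditioned strongly on z: z initializes the hidden state and is
concatenated to every input embedding. Generation is multinomial sampling
from the token distributions (the 20-samples-per-source protocol presumes
stochastic outputs); validity of generated text is not guaranteed and is
checked downstream.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from . import chem
from .autograd import Tensor
from .codec import Vocabulary
from .layers import Adam, Embedding, GRUCell, Linear, Module

__all__ = ["VaeConfig", "LatentGaussian", "SmilesVae", "sample_latent"]

_VAR_FLOOR = 1e-6


@dataclass
class VaeConfig:
    latent_dim: int = 32
    hidden_size: int = 64
    embed_size: int = 32
    max_len: int = 120
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LatentGaussian:
    """Diagonal Gaussian over latent space: mean and per-coordinate variance.

    Fields are autograd tensors so losses can differentiate through them;
    ``mean_np`` / ``variance_np`` give plain arrays for analysis.
    """

    mean: Tensor
    variance: Tensor

    def __post_init__(self):
        if not np.all(np.isfinite(self.mean.data)):
            raise ValueError("non-finite latent mean")
        if np.any(self.variance.data <= 0):
            raise ValueError("latent variance must be strictly positive")

    @property
    def mean_np(self) -> np.ndarray:
        return np.asarray(self.mean.data)

    @property
    def variance_np(self) -> np.ndarray:
        return np.asarray(self.variance.data)


def sample_latent(g: LatentGaussian, rng: np.random.Generator) -> np.ndarray:
    """One reparameterized draw: mean + sqrt(variance) * N(0, I)."""
    eps = rng.standard_normal(g.mean_np.shape[-1])
    return g.mean_np.reshape(-1) + np.sqrt(g.variance_np.reshape(-1)) * eps


class SmilesVae(Module):
    """GRU encoder/decoder VAE with explicitly separated parameter groups.

    Encoder and decoder have independent embeddings so the policy-gradient
    phase can update decoder parameters while leaving the encoder untouched
    as a hard contract.
    """

    def __init__(self, vocab: Vocabulary, config: VaeConfig | None = None):
        super().__init__()
        self.vocab = vocab
        self.config = config or VaeConfig()
        c = self.config
        rng = np.random.default_rng(c.seed)
        V = len(vocab)

        self.enc_emb = self.register("enc_emb", Embedding(rng, V, c.embed_size))
        self.enc_gru = self.register("enc_gru", GRUCell(rng, c.embed_size, c.hidden_size))
        self.enc_mu = self.register("enc_mu", Linear(rng, c.hidden_size, c.latent_dim))
        self.enc_var = self.register("enc_var", Linear(rng, c.hidden_size, c.latent_dim))

        self.dec_emb = self.register("dec_emb", Embedding(rng, V, c.embed_size))
        self.dec_init = self.register("dec_init", Linear(rng, c.latent_dim, c.hidden_size))
        self.dec_gru = self.register(
            "dec_gru", GRUCell(rng, c.embed_size + c.latent_dim, c.hidden_size)
        )
        self.dec_out = self.register("dec_out", Linear(rng, c.hidden_size, V))

    # -- parameter groups --------------------------------------------------
    def encoder_parameters(self) -> dict[str, Tensor]:
        return {k: v for k, v in self._params.items() if k.startswith("enc_")}

    def decoder_parameters(self) -> dict[str, Tensor]:
        return {k: v for k, v in self._params.items() if k.startswith("dec_")}

    def encoder_checksum(self) -> float:
        return float(
            sum(v.data.sum() for _, v in sorted(self.encoder_parameters().items()))
        )

    # -- encoding ----------------------------------------------------------
    def _pad_batch(self, seqs: Sequence[Sequence[int]]) -> tuple[np.ndarray, np.ndarray]:
        if any(len(s) == 0 for s in seqs):
            raise ValueError("empty token sequence")
        L = max(len(s) for s in seqs)
        batch = np.full((len(seqs), L), self.vocab.pad, dtype=np.intp)
        for i, s in enumerate(seqs):
            batch[i, : len(s)] = s
        mask = (batch != self.vocab.pad).astype(np.float64)
        return batch, mask

    def encode_batch(self, seqs: Sequence[Sequence[int]]) -> LatentGaussian:
        """Encode a batch of token sequences to a batched LatentGaussian."""
        batch, mask = self._pad_batch(seqs)
        B, L = batch.shape
        h = Tensor(np.zeros((B, self.config.hidden_size)))
        for t in range(L):
            x = self.enc_emb(batch[:, t])
            h = self.enc_gru.step_masked(x, h, mask[:, t])
        mu = self.enc_mu(h)
        var = self.enc_var(h).softplus() + _VAR_FLOOR
        return LatentGaussian(mu, var)

    def encode(self, seq: Sequence[int]) -> LatentGaussian:
        """Deterministic map from one token sequence to its latent Gaussian."""
        g = self.encode_batch([list(seq)])
        return g

    def encode_smiles(self, smiles: str) -> LatentGaussian:
        return self.encode(self.vocab.encode(smiles, self.config.max_len))

    # -- decoding ----------------------------------------------------------
    def decode_nll_batch(self, z: Tensor, seqs: Sequence[Sequence[int]]) -> Tensor:
        """Teacher-forced per-sequence summed token NLL, shape (B,).

        Inputs are ``seq[:-1]`` (BOS..), targets ``seq[1:]`` (..EOS); PAD
        targets are masked out of the sum.
        """
        if z.data.shape[-1] != self.config.latent_dim:
            raise ValueError(
                f"latent dimension mismatch: {z.data.shape[-1]} != {self.config.latent_dim}"
            )
        batch, _ = self._pad_batch(seqs)
        B, L = batch.shape
        inputs, targets = batch[:, :-1], batch[:, 1:]
        tmask = (targets != self.vocab.pad).astype(np.float64)
        h = self.dec_init(z).tanh()
        nll_terms = []
        for t in range(L - 1):
            emb = self.dec_emb(inputs[:, t])
            x = _concat2(emb, z)
            h = self.dec_gru.step_masked(x, h, tmask[:, t])
            logp = self.dec_out(h).log_softmax()
            picked = logp.gather_last(targets[:, t])
            nll_terms.append(-1.0 * picked * Tensor(tmask[:, t]))
        total = nll_terms[0]
        for term in nll_terms[1:]:
            total = total + term
        return total

    def decode_nll(self, z, seq: Sequence[int]) -> float:
        """Summed token NLL of one sequence given one latent vector."""
        zt = z if isinstance(z, Tensor) else Tensor(np.asarray(z).reshape(1, -1))
        if zt.data.ndim == 1:
            zt = Tensor(zt.data.reshape(1, -1))
        return float(self.decode_nll_batch(zt, [list(seq)]).data[0])

    # -- generation --------------------------------------------------------
    def generate_tokens(
        self, z: np.ndarray, rng: np.random.Generator, max_len: int | None = None
    ) -> list[int]:
        """Autoregressive multinomial sampling until EOS or max_len tokens."""
        max_len = max_len or self.config.max_len
        z = np.asarray(z, dtype=np.float64).reshape(1, -1)
        if z.shape[-1] != self.config.latent_dim:
            raise ValueError("latent dimension mismatch")
        zt = Tensor(z)
        h = self.dec_init(zt).tanh()
        tok = self.vocab.bos
        out = [tok]
        for _ in range(max_len - 1):
            emb = self.dec_emb(np.array([tok]))
            h = self.dec_gru(_concat2(emb, zt), h)
            logits = self.dec_out(h).log_softmax().data[0]
            p = np.exp(logits)
            p /= p.sum()
            tok = int(rng.choice(len(p), p=p))
            out.append(tok)
            if tok == self.vocab.eos:
                break
        return out

    def generate(
        self, z: np.ndarray, rng: np.random.Generator, max_len: int | None = None
    ) -> str:
        return self.vocab.decode(self.generate_tokens(z, rng, max_len))

    def translate(
        self, source: str, rng: np.random.Generator, k: int = 20
    ) -> list[str]:
        """Encode a source molecule and decode ``k`` independent samples."""
        if not chem.is_valid(source):
            raise ValueError(f"invalid source SMILES: {source!r}")
        g = self.encode_smiles(source)
        outs = []
        for _ in range(k):
            z = sample_latent(g, rng)
            outs.append(self.generate(z, rng))
        return outs

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        """Single-archive checkpoint: parameters + vocabulary + config."""
        state = {k: v.tolist() for k, v in self.state_dict().items()}
        payload = {
            "config": self.config.to_dict(),
            "vocab": list(self.vocab.tokens),
            "params": state,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "SmilesVae":
        with open(path) as fh:
            payload = json.load(fh)
        vocab = Vocabulary(tuple(payload["vocab"]))
        model = cls(vocab, VaeConfig(**payload["config"]))
        model.load_state_dict(
            {k: np.asarray(v, dtype=np.float64) for k, v in payload["params"].items()}
        )
        return model

    def make_optimizer(self, lr: float, decoder_only: bool = False) -> Adam:
        params = self.decoder_parameters() if decoder_only else self.parameters()
        return Adam(params, lr=lr)


def _concat2(a: Tensor, b: Tensor) -> Tensor:
    from .autograd import concat

    return concat([a, b], axis=-1)
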