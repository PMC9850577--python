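"""Scikit-learn-style estimator facade over the two training phases.

``MolecularTranslator`` bundles vocabulary building, triplet construction,
metric learning and optional REINFORCE fine-tuning behind the familiar
``fit`` / ``predict`` / ``get_params`` surface, so the whole pipeline can sit
inside sklearn model-selection utilities. The underlying phase functions in
:mod:`simvae.objectives` and :mod:`simvae.rl` remain the primary API.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from . import chem
from .codec import build_vocab
from .data import MoleculePair, Triplet, build_triplets
from .metrics import compute_metrics, make_generation_set
from .model import SmilesVae, VaeConfig
from .objectives import MetricTrainConfig, train_metric_phase
from .rl import RewardConfig, RlTrainConfig, train_rl_phase

__all__ = ["MolecularTranslator"]


class MolecularTranslator(BaseEstimator):
    """Structure-constrained molecule-to-molecule translator.

    Parameters
    ----------
    latent_dim, hidden_size, embed_size, max_len
        VAE architecture sizes.
    metric_epochs, rl_epochs, batch_size, learning_rate, rl_learning_rate
        Phase schedules; ``rl_epochs=0`` skips fine-tuning.
    use_contractive, use_margin
        Ablation switches for the two latent-geometry loss terms.
    negative_threshold
        Tanimoto ceiling for triplet negatives.
    reward_config
        A :class:`simvae.rl.RewardConfig`; required when ``rl_epochs > 0``.
    k
        Samples generated per source by :meth:`predict`.
    seed
        Master seed for initialisation, triplet sampling and both phases.

    Attributes (after ``fit``)
    --------------------------
    model_ : SmilesVae
    vocab_ : Vocabulary
    loss_history_ : list of per-epoch metric-phase loss breakdowns
    reward_history_ : list of per-epoch mean rewards (empty if no RL phase)
    """

    def __init__(
        self,
        latent_dim: int = 32,
        hidden_size: int = 64,
        embed_size: int = 32,
        max_len: int = 120,
        metric_epochs: int = 30,
        rl_epochs: int = 0,
        batch_size: int = 32,
        learning_rate: float = 3e-3,
        rl_learning_rate: float = 1e-3,
        use_contractive: bool = True,
        use_margin: bool = True,
        negative_threshold: float = 0.4,
        reward_config: RewardConfig | None = None,
        k: int = 20,
        seed: int = 0,
    ):
        self.latent_dim = latent_dim
        self.hidden_size = hidden_size
        self.embed_size = embed_size
        self.max_len = max_len
        self.metric_epochs = metric_epochs
        self.rl_epochs = rl_epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.rl_learning_rate = rl_learning_rate
        self.use_contractive = use_contractive
        self.use_margin = use_margin
        self.negative_threshold = negative_threshold
        self.reward_config = reward_config
        self.k = k
        self.seed = seed

    # ------------------------------------------------------------------
    def _as_pairs(self, X) -> list[MoleculePair]:
        pairs = []
        for row in X:
            if isinstance(row, MoleculePair):
                pairs.append(row)
            elif isinstance(row, Triplet):
                pairs.append(MoleculePair(row.source, row.target))
            else:
                s, t = row
                pairs.append(MoleculePair(str(s), str(t)))
        if not pairs:
            raise ValueError("X must contain at least one molecule pair")
        return pairs

    def fit(self, X: Sequence, y=None) -> "MolecularTranslator":
        """Train on (source, target) pairs (or ready-made triplets).

        ``X`` is a sequence of 2-tuples / :class:`MoleculePair` (negatives
        are then sampled from the pool of all molecules in ``X``) or of
        :class:`Triplet`.
        """
        if len(X) > 0 and isinstance(X[0], Triplet):
            triplets = list(X)
            corpus = sorted(
                {m for t in triplets for m in (t.source, t.target, t.negative)}
            )
        else:
            pairs = self._as_pairs(X)
            triplets = build_triplets(
                pairs, negative_threshold=self.negative_threshold, seed=self.seed
            )
            corpus = sorted({m for p in pairs for m in (p.source, p.target)})

        self.vocab_ = build_vocab(corpus)
        self.model_ = SmilesVae(
            self.vocab_,
            VaeConfig(
                latent_dim=self.latent_dim,
                hidden_size=self.hidden_size,
                embed_size=self.embed_size,
                max_len=self.max_len,
                seed=self.seed,
            ),
        )
        self.loss_history_ = train_metric_phase(
            triplets,
            self.model_,
            MetricTrainConfig(
                epochs=self.metric_epochs,
                batch_size=self.batch_size,
                learning_rate=self.learning_rate,
                seed=self.seed,
                use_contractive=self.use_contractive,
                use_margin=self.use_margin,
            ),
        )
        self.reward_history_: list[float] = []
        if self.rl_epochs > 0:
            if self.reward_config is None:
                raise ValueError("rl_epochs > 0 requires reward_config")
            sources = sorted({t.source for t in triplets})
            self.reward_history_ = train_rl_phase(
                sources,
                self.model_,
                self.reward_config,
                RlTrainConfig(
                    epochs=self.rl_epochs,
                    batch_size=self.batch_size,
                    learning_rate=self.rl_learning_rate,
                    seed=self.seed,
                ),
            )
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("this MolecularTranslator instance is not fitted yet")

    def predict(self, X: Sequence[str], seed: int | None = None) -> list[list[str]]:
        """Generate ``k`` candidate translations for each source SMILES."""
        self._check_fitted()
        rng = np.random.default_rng(self.seed if seed is None else seed)
        return [self.model_.translate(src, rng, k=self.k) for src in X]

    def score(self, X: Sequence[str], y=None, oracle=None, delta: float = 0.0,
              epsilon: float = 0.3, train_set: Sequence[str] = ()) -> float:
        """Success rate of the generated sets over source molecules ``X``."""
        self._check_fitted()
        oracle = oracle or (self.reward_config.oracle if self.reward_config else None)
        if oracle is None:
            oracle = chem.make_oracle("qed")
        sets = [
            make_generation_set(src, outs)
            for src, outs in zip(X, self.predict(X))
        ]
        return compute_metrics(sets, list(train_set), oracle, delta, epsilon).success_rate
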