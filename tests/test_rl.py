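"""Reward functions, task configurations, and the policy-gradient step."""

import numpy as np
import pytest

from simvae import chem
from simvae.autograd import Tensor
from simvae.codec import build_vocab
from simvae.model import SmilesVae, VaeConfig
from simvae.rl import (
    RewardConfig,
    RlTrainConfig,
    reinforce_step,
    reward,
    task_reward_config,
    train_rl_phase,
)

SRC = "CCCCCCCC"
NEAR = "CCCCCCCCO"   # same alkane family, T ~ 0.6
FAR = "COCOCOCOC"    # different family, T < 0.4


def const_oracle(value: float) -> chem.PropertyOracle:
    return chem.PropertyOracle("const", lambda s: value)


class TestReward:
    def test_increase_scaling(self):
        cfg = RewardConfig("increase", 0.75, 0.3, const_oracle(0.90))
        assert reward(NEAR, SRC, cfg) == pytest.approx((0.90 - 0.75) / 0.25)

    def test_similarity_gate_is_strict(self):
        t = chem.tanimoto_smiles(NEAR, SRC)
        cfg = RewardConfig("increase", 0.0, t, const_oracle(0.9))  # T == epsilon
        assert reward(NEAR, SRC, cfg) == 0.0
        below = RewardConfig("increase", 0.0, 0.99, const_oracle(0.9))
        assert reward(NEAR, SRC, below) == 0.0

    def test_decrease_zero_at_threshold_and_full_scale(self):
        cfg = RewardConfig("decrease", 4.989, 0.4, const_oracle(4.989))
        assert reward(NEAR, SRC, cfg) == 0.0
        cfg0 = RewardConfig("decrease", 4.989, 0.4, const_oracle(0.0))
        assert reward(NEAR, SRC, cfg0) == 1.0

    def test_improvement_can_exceed_one(self):
        oracle = chem.PropertyOracle("len", lambda s: float(len(chem.canonicalize(s))))
        cfg = RewardConfig("improvement", 0.0, 0.3, oracle)
        expected = len(chem.canonicalize(NEAR)) - len(chem.canonicalize(SRC))
        assert reward(NEAR, SRC, cfg) == pytest.approx(float(expected))

    def test_invalid_generated_text_scores_zero(self):
        cfg = RewardConfig("increase", 0.0, 0.3, const_oracle(0.9))
        assert reward("C(C", SRC, cfg) == 0.0

    def test_aux_constraint_gates_reward(self):
        cfg = RewardConfig(
            "decrease", 4.989, 0.4, const_oracle(1.0),
            aux_oracle=const_oracle(6.0), aux_min=6.235,
        )
        assert reward(NEAR, SRC, cfg) == 0.0
        cfg_ok = RewardConfig(
            "decrease", 4.989, 0.4, const_oracle(1.0),
            aux_oracle=const_oracle(7.0), aux_min=6.235,
        )
        assert reward(NEAR, SRC, cfg_ok) > 0.0

    def test_reward_bounded_for_increase_decrease_randomized(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            phi = float(rng.uniform(-2, 3))
            cfg = RewardConfig("increase", 0.5, 0.3, const_oracle(phi))
            assert 0.0 <= reward(NEAR, SRC, cfg) <= (3 - 0.5) / 0.5 + 1e-9
            cfgd = RewardConfig("decrease", 2.0, 0.3, const_oracle(abs(phi)))
            assert 0.0 <= reward(NEAR, SRC, cfgd) <= 1.0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            RewardConfig("sideways", 0.0, 0.3, const_oracle(1))
        with pytest.raises(ValueError):
            RewardConfig("increase", 0.0, 1.5, const_oracle(1))
        with pytest.raises(ValueError):
            RewardConfig("decrease", 0.0, 0.3, const_oracle(1))
        with pytest.raises(ValueError):
            RewardConfig("increase", 1.0, 0.3, const_oracle(1))


class TestTaskConfigs:
    def test_qed_task_thresholds(self):
        cfg = task_reward_config("qed")
        assert (cfg.direction, cfg.delta, cfg.epsilon) == ("increase", 0.75, 0.3)

    def test_plogp_dialects(self):
        assert task_reward_config("plogp04").epsilon == 0.3
        assert task_reward_config("plogp06").epsilon == 0.5
        assert task_reward_config("plogp04").direction == "improvement"

    def test_drd2_requires_external_oracle(self):
        with pytest.raises(ValueError):
            task_reward_config("drd2")
        cfg = task_reward_config("drd2", oracle=const_oracle(0.5))
        assert (cfg.direction, cfg.delta, cfg.epsilon) == ("increase", 0.0, 0.3)

    def test_abcg2_aux_threshold(self):
        cfg = task_reward_config(
            "abcg2", oracle=const_oracle(4.0), aux_oracle=const_oracle(7.0)
        )
        assert cfg.delta == 4.989 and cfg.epsilon == 0.4 and cfg.aux_min == 6.235

    def test_unknown_task_rejected(self):
        with pytest.raises(ValueError):
            task_reward_config("logd")


class TestReinforceStep:
    def _model(self, small_vocab):
        return SmilesVae(
            small_vocab, VaeConfig(latent_dim=8, hidden_size=16, embed_size=8, seed=2)
        )

    def test_zero_rewards_leave_parameters_bit_identical(self, small_vocab):
        model = self._model(small_vocab)
        before = {k: v.data.copy() for k, v in model.parameters().items()}
        cfg = RewardConfig("increase", 0.0, 0.3, const_oracle(0.0))
        reinforce_step([SRC, NEAR], model, cfg, np.random.default_rng(0), lr=0.1)
        for k, v in model.parameters().items():
            assert np.array_equal(before[k], v.data)

    def test_encoder_frozen_through_updates(self, small_vocab):
        model = self._model(small_vocab)
        enc_before = model.encoder_checksum()
        cfg = RewardConfig("increase", 0.0, 0.0, const_oracle(0.9))
        rng = np.random.default_rng(0)
        for _ in range(10):
            reinforce_step([SRC, NEAR, FAR], model, cfg, rng, lr=0.05)
        assert model.encoder_checksum() == enc_before

    def test_policy_gradient_increases_rewarded_token_probability(self):
        # enumerable categorical policy: reward 1 for token A, else 0
        theta = Tensor(np.zeros(3), requires_grad=True)
        rng = np.random.default_rng(0)
        rewards = np.array([1.0, 0.0, 0.0])

        def prob():
            e = np.exp(theta.data - theta.data.max())
            return e / e.sum()

        p0 = prob()[0]
        # one REINFORCE step from a modest sample of episodes
        grad_sum = np.zeros(3)
        n = 200
        for _ in range(n):
            theta.zero_grad()
            logp = theta.log_softmax()
            a = int(rng.choice(3, p=prob()))
            loss = -rewards[a] * (logp * Tensor(np.eye(3)[a])).sum()
            loss.backward()
            grad_sum += theta.grad
        theta.data = theta.data - 0.1 * grad_sum / n
        assert prob()[0] > p0


class TestTrainRlPhase:
    def test_zero_epochs_unchanged(self, small_vocab):
        model = SmilesVae(small_vocab, VaeConfig(latent_dim=8, hidden_size=16, embed_size=8, seed=2))
        before = model.checksum()
        cfg = RewardConfig("increase", 0.0, 0.3, const_oracle(0.5))
        history = train_rl_phase([SRC], model, cfg, RlTrainConfig(epochs=0))
        assert history == [] and model.checksum() == before

    def test_fixed_seed_identical_history(self, small_vocab):
        cfg = RewardConfig("increase", 0.0, 0.0, const_oracle(0.7))
        runs = []
        for _ in range(2):
            model = SmilesVae(
                small_vocab, VaeConfig(latent_dim=8, hidden_size=16, embed_size=8, seed=2)
            )
            runs.append(
                train_rl_phase([SRC, NEAR], model, cfg, RlTrainConfig(epochs=3, seed=4))
            )
        assert runs[0] == runs[1]

    def test_empty_sources_rejected(self, small_vocab):
        model = SmilesVae(small_vocab, VaeConfig(seed=0))
        with pytest.raises(ValueError):
            train_rl_phase([], model, RewardConfig("increase", 0.0, 0.3, const_oracle(1)))
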