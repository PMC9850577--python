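"""Generation metrics against an independent brute-force enumeration,
threshold sweeps, and latent-embedding geometry analytics."""

import itertools

import numpy as np
import pytest
from scipy.stats import kruskal

from simvae import chem
from simvae.metrics import (
    DEFAULT_SWEEP_THRESHOLDS,
    MetricsReport,
    compute_metrics,
    embedding_analysis,
    make_generation_set,
    split_pairs_by_similarity,
    success_rate_sweep,
)

VALID_POOL = [
    "CCO", "CCN", "CCC", "CCCC", "CCCCC", "c1ccccc1", "c1ccccc1C", "CCOC",
    "CC(C)C", "CCS", "CCCO", "CCCN", "OCCO", "CCOCC", "c1ccncc1", "CC=O",
]
INVALID_POOL = ["xx", "C(C", "1CC1(", ")(", "Cl)("]


def random_sets(rng, n_sources=8, k=6):
    sets, train = [], list(rng.choice(VALID_POOL, size=6, replace=False))
    for _ in range(n_sources):
        src = str(rng.choice(VALID_POOL))
        outs = [
            str(rng.choice(VALID_POOL)) if rng.random() > 0.3 else str(rng.choice(INVALID_POOL))
            for _ in range(k)
        ]
        sets.append(make_generation_set(src, outs))
    return sets, train


def toy_oracle(rng):
    scores = {chem.canonicalize(s): float(rng.uniform(0, 1)) for s in VALID_POOL}
    return chem.PropertyOracle("toy", lambda s: scores[chem.canonicalize(s)], (0, 1))


def brute_force_metrics(sets, train, oracle, delta, epsilon):
    """Direct enumeration of the seven metric definitions (test oracle)."""
    train_canon = {chem.canonicalize(s) for s in train}
    n = len(sets)
    valid = novel = success = 0
    prop, impr, sim, div = [], [], [], []
    for gs in sets:
        phi_x = oracle.score(gs.source)
        distinct = []
        for raw in gs.outputs:
            c = chem.canonicalize(raw)
            if c is not None and c not in distinct:
                distinct.append(c)
        if distinct:
            valid += 1
        out_ids = [chem.canonicalize(o) if chem.is_valid(o) else o for o in gs.outputs]
        if any(o not in train_canon for o in out_ids):
            novel += 1
        if distinct:
            prop.append(sum(oracle.score(y) for y in distinct) / len(distinct))
            impr.append(sum(oracle.score(y) - phi_x for y in distinct) / len(distinct))
            sim.append(
                sum(chem.tanimoto_smiles(y, gs.source) for y in distinct) / len(distinct)
            )
            pairs = [
                chem.tanimoto_smiles(y, z)
                for y, z in itertools.permutations(distinct, 2)
            ]
            if pairs:
                div.append(1 - sum(pairs) / len(pairs))
        for y in distinct:
            if (
                y not in train_canon
                and oracle.score(y) - phi_x >= delta
                and chem.tanimoto_smiles(y, gs.source) >= epsilon
            ):
                success += 1
                break
    mean = lambda xs: sum(xs) / len(xs) if xs else 0.0
    return MetricsReport(
        validity=valid / n, novelty=novel / n, property=mean(prop),
        improvement=mean(impr), similarity=mean(sim), diversity=mean(div),
        success_rate=success / n,
    )


class TestComputeMetrics:
    def test_validity_counts_sources_with_any_valid_output(self):
        s1 = make_generation_set("CCO", ["CCN"] * 20)
        s2 = make_generation_set("CCC", ["xx"] * 20)
        rep = compute_metrics([s1, s2], [], chem.make_oracle("qed"))
        assert rep.validity == 0.5

    def test_identity_outputs_edge_case(self):
        # every output equals the source, source known to training
        src = "c1ccccc1"
        gs = make_generation_set(src, [src] * 20)
        rep = compute_metrics([gs], [src], chem.make_oracle("qed"), delta=0.1)
        assert rep.similarity == 1.0
        assert rep.diversity == 0.0
        assert rep.success_rate == 0.0
        assert rep.novelty == 0.0

    def test_two_molecule_diversity_term(self):
        # outputs alternate between two molecules; diversity = 1 - T(a,b)
        a, b = "CCO", "CCOC"
        t = chem.tanimoto_smiles(a, b)
        gs = make_generation_set("CCO", [a, b] * 10)
        rep = compute_metrics([gs], [], chem.make_oracle("qed"))
        assert rep.diversity == pytest.approx(1 - t)

    def test_matches_brute_force_randomized(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            sets, train = random_sets(rng)
            oracle = toy_oracle(rng)
            delta, eps = float(rng.uniform(0, 0.3)), float(rng.uniform(0.1, 0.6))
            ours = compute_metrics(sets, train, oracle, delta, eps)
            ref = brute_force_metrics(sets, train, oracle, delta, eps)
            for f in ("validity", "novelty", "property", "improvement",
                      "similarity", "diversity", "success_rate"):
                assert getattr(ours, f) == pytest.approx(getattr(ref, f), abs=1e-12), f

    def test_success_rate_bounded_by_validity_and_novelty(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            sets, train = random_sets(rng)
            rep = compute_metrics(sets, train, toy_oracle(rng), 0.0, 0.3)
            assert rep.success_rate <= rep.validity + 1e-12
            assert rep.success_rate <= rep.novelty + 1e-12

    def test_total_is_sum_of_six(self):
        rng = np.random.default_rng(5)
        sets, train = random_sets(rng)
        rep = compute_metrics(sets, train, toy_oracle(rng))
        assert rep.total == pytest.approx(
            rep.validity + rep.novelty + rep.property + rep.improvement
            + rep.similarity + rep.diversity
        )

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([], [], chem.make_oracle("qed"))


class TestSweep:
    def test_grid_size_and_monotonicity(self):
        rng = np.random.default_rng(11)
        sets, train = random_sets(rng, n_sources=6)
        curve, mean_sr = success_rate_sweep(sets, train, toy_oracle(rng))
        assert len(curve) == 7
        srs = [sr for _, sr in curve]
        assert all(x >= y for x, y in zip(srs, srs[1:]))
        assert mean_sr == pytest.approx(np.mean(srs))

    def test_single_threshold_mean_is_that_value(self):
        rng = np.random.default_rng(12)
        sets, train = random_sets(rng, n_sources=4)
        curve, mean_sr = success_rate_sweep(sets, train, toy_oracle(rng), thresholds=[0.5])
        assert mean_sr == curve[0][1]

    def test_empty_thresholds_rejected(self):
        with pytest.raises(ValueError):
            success_rate_sweep([make_generation_set("CCO", ["CCO"])], [],
                               chem.make_oracle("qed"), thresholds=[])

    def test_default_grid_is_040_to_070(self):
        assert DEFAULT_SWEEP_THRESHOLDS[0] == 0.40
        assert DEFAULT_SWEEP_THRESHOLDS[-1] == 0.70


class TestEmbeddingAnalysis:
    def test_split_pairs_by_similarity_partitions_all(self, small_dataset):
        mols = small_dataset.pool[:12]
        sim, dis = split_pairs_by_similarity(mols)
        assert len(sim) + len(dis) == len(mols) * (len(mols) - 1) // 2

    def test_full_separation_matches_rank_closed_form(self):
        # distances fully separated, 5 vs 5: H = 12/(10*11)*(5*2.5^2*2) = 75/11
        d_sim = [0.1, 0.2, 0.3, 0.4, 0.5]
        d_dis = [1.1, 1.2, 1.3, 1.4, 1.5]
        h, p = kruskal(d_sim, d_dis)
        assert h == pytest.approx(75 / 11)

    def test_h_matches_hand_rank_formula_on_random_inputs(self, tiny_model, small_dataset):
        mols = small_dataset.pool[::6][:10]  # spread across scaffold families
        sim, dis = split_pairs_by_similarity(mols)
        coords, h, p = embedding_analysis(mols, sim, dis, tiny_model)
        assert coords.shape == (10, 2)
        # independent H computation from ranks (no ties for continuous data)
        d = {
            (i, j): float(np.linalg.norm(coords[i] - coords[j]))
            for i, j in sim | dis
        }
        all_d = sorted(d.values())
        ranks = {v: r + 1 for r, v in enumerate(all_d)}
        n = len(all_d)
        groups = [[ranks[d[p_]] for p_ in sorted(sim)], [ranks[d[p_]] for p_ in sorted(dis)]]
        h_ref = 12 / (n * (n + 1)) * sum(
            len(g) * (np.mean(g) - (n + 1) / 2) ** 2 for g in groups
        )
        assert h == pytest.approx(h_ref, abs=1e-8)

    def test_null_distributions_give_small_h(self, tiny_model):
        # pair sets drawn from the same distance distribution: p typically > 0.05
        rng = np.random.default_rng(0)
        mols = ["CCO", "CCN", "CCC", "CCCC", "CCOC", "CCS", "CCCO", "CCCN"]
        pairs = list(itertools.combinations(range(len(mols)), 2))
        rng.shuffle(pairs)
        half = len(pairs) // 2
        _, h, p = embedding_analysis(mols, set(pairs[:half]), set(pairs[half:]), tiny_model)
        assert p > 0.05

    def test_empty_pair_set_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            embedding_analysis(["CCO", "CCN"], set(), {(0, 1)}, tiny_model)
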