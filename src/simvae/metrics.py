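"""Structure-constrained generation metrics, the similarity-threshold sweep,
and latent-embedding geometry analytics.

A model is evaluated on a test set of source molecules; for each source it
emits k (default 20) candidate translations. Seven quantities summarise the
run — validity, novelty, mean property, mean improvement, mean similarity,
internal diversity, and success rate — plus a total score (the sum of the
six non-success metrics) for cross-model comparison. The success rate is
the strictest: a source succeeds only if at least one output is
simultaneously valid, novel with respect to the training set, improved by
at least delta, and at least epsilon-similar to its source.

Degenerate denominators are resolved by exclusion: a source with no valid
output contributes nothing to the property/improvement/similarity/diversity
means (each is a 0/0 there), but still counts in the validity, novelty and
success-rate denominators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import kruskal
from sklearn.decomposition import PCA

from . import chem
from .chem import PropertyOracle

__all__ = [
    "GenerationSet",
    "MetricsReport",
    "make_generation_set",
    "compute_metrics",
    "success_rate_sweep",
    "embedding_analysis",
    "split_pairs_by_similarity",
    "DEFAULT_SWEEP_THRESHOLDS",
]

DEFAULT_SWEEP_THRESHOLDS = tuple(np.round(np.arange(0.40, 0.701, 0.05), 2))


@dataclass(frozen=True)
class GenerationSet:
    """One source molecule with its k generated outputs and validity flags."""

    source: str
    outputs: tuple[str, ...]
    valid_flags: tuple[bool, ...]
    canonical_outputs: tuple[str | None, ...]

    def __post_init__(self):
        if not (len(self.outputs) == len(self.valid_flags) == len(self.canonical_outputs)):
            raise ValueError("outputs, valid_flags, canonical_outputs must align")


def make_generation_set(source: str, outputs: Sequence[str]) -> GenerationSet:
    canon = tuple(chem.canonicalize(o) for o in outputs)
    return GenerationSet(
        source=source,
        outputs=tuple(outputs),
        valid_flags=tuple(c is not chem.INVALID for c in canon),
        canonical_outputs=canon,
    )


@dataclass(frozen=True)
class MetricsReport:
    validity: float
    novelty: float
    property: float
    improvement: float
    similarity: float
    diversity: float
    success_rate: float

    @property
    def total(self) -> float:
        """Sum of the six non-success metrics (the benchmark total score)."""
        return (
            self.validity
            + self.novelty
            + self.property
            + self.improvement
            + self.similarity
            + self.diversity
        )

    def to_dict(self) -> dict[str, float]:
        return {
            "validity": self.validity,
            "novelty": self.novelty,
            "property": self.property,
            "improvement": self.improvement,
            "similarity": self.similarity,
            "diversity": self.diversity,
            "success_rate": self.success_rate,
            "total": self.total,
        }


def _success_indicator(
    gs: GenerationSet,
    train_canon: frozenset,
    oracle: PropertyOracle,
    delta: float,
    epsilon: float,
    src_fp: np.ndarray,
    phi_x: float,
) -> bool:
    for ok, y in zip(gs.valid_flags, gs.canonical_outputs):
        if not ok or y in train_canon:
            continue
        if oracle.score(y) - phi_x < delta:
            continue
        if chem.tanimoto(chem.morgan_fingerprint(y), src_fp) >= epsilon:
            return True
    return False


def compute_metrics(
    sets: Sequence[GenerationSet],
    train_set: Sequence[str],
    oracle: PropertyOracle,
    delta: float = 0.0,
    epsilon: float = 0.3,
) -> MetricsReport:
    """The seven generation metrics over a list of per-source output sets.

    ``train_set`` is canonicalized internally; novelty and the success
    rate's novelty condition compare canonical SMILES, not raw strings.
    Improvement/success use non-strict thresholds (>= delta, >= epsilon).
    Each generated collection is read as a set: duplicate outputs collapse
    to a single member (so a source whose k samples are all one molecule
    has no diversity term at all rather than diversity 0 from self-pairs).
    """
    if not sets:
        raise ValueError("no generation sets")
    train_canon = frozenset(
        c for c in (chem.canonicalize(s) for s in train_set) if c is not chem.INVALID
    )
    n = len(sets)
    valid_ind = novel_ind = success_ind = 0
    prop_terms: list[float] = []
    impr_terms: list[float] = []
    sim_terms: list[float] = []
    div_terms: list[float] = []

    for gs in sets:
        src_fp = chem.morgan_fingerprint(gs.source)
        phi_x = oracle.score(gs.source)
        # the generated set is a set: duplicate outputs collapse to one member
        valid_out = list(
            dict.fromkeys(
                y for ok, y in zip(gs.valid_flags, gs.canonical_outputs) if ok
            )
        )
        if valid_out:
            valid_ind += 1
        # Novelty reads the generated set literally: an output is outside the
        # training set if its canonical form (or the raw text, when invalid)
        # is not a training molecule. Validity is not required here.
        if any(
            (y if ok else raw) not in train_canon
            for ok, y, raw in zip(gs.valid_flags, gs.canonical_outputs, gs.outputs)
        ):
            novel_ind += 1
        if valid_out:
            fps = [chem.morgan_fingerprint(y) for y in valid_out]
            scores = [oracle.score(y) for y in valid_out]
            prop_terms.append(float(np.mean(scores)))
            impr_terms.append(float(np.mean([s - phi_x for s in scores])))
            sim_terms.append(
                float(np.mean([chem.tanimoto(f, src_fp) for f in fps]))
            )
            if len(valid_out) >= 2:
                pair_sims = [
                    chem.tanimoto(fps[i], fps[j])
                    for i in range(len(fps))
                    for j in range(len(fps))
                    if i != j
                ]
                div_terms.append(1.0 - float(np.mean(pair_sims)))
        if _success_indicator(
            gs, train_canon, oracle, delta, epsilon, src_fp, phi_x
        ):
            success_ind += 1

    def _mean(xs: list[float]) -> float:
        return float(np.mean(xs)) if xs else 0.0

    return MetricsReport(
        validity=valid_ind / n,
        novelty=novel_ind / n,
        property=_mean(prop_terms),
        improvement=_mean(impr_terms),
        similarity=_mean(sim_terms),
        diversity=_mean(div_terms),
        success_rate=success_ind / n,
    )


def success_rate_sweep(
    sets: Sequence[GenerationSet],
    train_set: Sequence[str],
    oracle: PropertyOracle,
    delta: float = 0.0,
    thresholds: Sequence[float] = DEFAULT_SWEEP_THRESHOLDS,
) -> tuple[list[tuple[float, float]], float]:
    """Success rate at each similarity threshold, plus the mean over them.

    The default grid spans 0.40-0.70 in steps of 0.05; the mean over the
    grid is the single-number summary used for cross-model ranking.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("empty threshold list")
    if sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be sorted ascending")
    curve = []
    for eps in thresholds:
        rep = compute_metrics(sets, train_set, oracle, delta=delta, epsilon=eps)
        curve.append((float(eps), rep.success_rate))
    mean_sr = float(np.mean([sr for _, sr in curve]))
    return curve, mean_sr


def split_pairs_by_similarity(
    molecules: Sequence[str], threshold: float = 0.4
) -> tuple[set[tuple[int, int]], set[tuple[int, int]]]:
    """Partition all unordered index pairs into similar (T >= thr) / dissimilar."""
    fps = [chem.morgan_fingerprint(s) for s in molecules]
    similar, dissimilar = set(), set()
    for i in range(len(molecules)):
        for j in range(i + 1, len(molecules)):
            t = chem.tanimoto(fps[i], fps[j])
            (similar if t >= threshold else dissimilar).add((i, j))
    return similar, dissimilar


def embedding_analysis(
    molecules: Sequence[str],
    similar_pairs: set[tuple[int, int]],
    dissimilar_pairs: set[tuple[int, int]],
    model,
) -> tuple[np.ndarray, float, float]:
    """Latent-geometry check of the metric-learning objective.

    Encodes the molecules, projects the latent mean vectors to two
    dimensions with PCA, computes Euclidean distances within the similar
    and dissimilar pair sets, and compares the two distance samples with a
    Kruskal-Wallis H test. A large H means similar molecules sit close
    while dissimilar ones sit far — the geometry the contractive and margin
    losses are meant to create.

    Returns (2-D coordinates, H statistic, p-value).
    """
    if not similar_pairs or not dissimilar_pairs:
        raise ValueError("both pair sets must be non-empty")
    mus = np.stack(
        [model.encode_smiles(s).mean_np.reshape(-1) for s in molecules]
    )
    coords = PCA(n_components=2, random_state=0).fit_transform(mus)
    d_sim = [float(np.linalg.norm(coords[i] - coords[j])) for i, j in sorted(similar_pairs)]
    d_dis = [
        float(np.linalg.norm(coords[i] - coords[j])) for i, j in sorted(dissimilar_pairs)
    ]
    h, p = kruskal(d_sim, d_dis)
    return coords, float(h), float(p)


def write_sweep_csv(path, curve: Sequence[tuple[float, float]]) -> None:
    with open(path, "w") as fh:
        fh.write("threshold,success_rate\n")
        for eps, sr in curve:
            fh.write(f"{eps},{sr}\n")
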