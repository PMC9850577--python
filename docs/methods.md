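# Methods

## Problem setting

Given a source molecule, produce candidates that improve a scalar property
φ while keeping Tanimoto similarity to the source above a threshold.
Supervision comes as molecule pairs (source, target) that are structurally
similar (T ≥ 0.4 on 2048-bit radius-2 Morgan fingerprints) and
property-ordered, the standard format of matched-pair translation
benchmarks (DRD2, QED, penalized-logP dialects).

## Model and objectives

The generator is a GRU sequence VAE over atom-level SMILES tokens
(brackets, two-letter elements and `%NN` ring closures are single tokens;
inputs are kekulized on ingest, which keeps the vocabulary small and makes
round-tripping exact). The encoder's final hidden state is mapped to a
latent mean and, through a softplus (+1e−6 floor), a strictly positive
diagonal variance. The decoder receives the latent both as its initial
hidden state (through a tanh projection) and concatenated to every input
embedding — the strong-conditioning choice, since nothing forces a
recurrent decoder to keep consulting a weakly injected latent.

Metric learning minimises, per (source, target, negative) triplet:
teacher-forced reconstruction NLL of all three strings from single
reparameterized samples of their own posteriors (summed over tokens,
averaged over the batch), the Fréchet distance between the pair's
posterior Gaussians, and softplus margin terms pushing the negative's mean
away from both pair members. Design points:

- **No N(0, I) KL term.** The contractive term replaces the prior
  matching entirely; the final objective contains no standard-normal KL,
  and none is added.
- **Diagonal covariance.** The Fréchet trace term is then the closed form
  `Σᵢ (√σ_a,i − √σ_b,i)²`, verified in the tests against the general
  matrix-square-root formula on random Gaussians to 1e−8. Σ is treated as
  a covariance (variance semantics), not a standard deviation.
- **Margin constant 1.** Fixed inside `softplus(1 − d²)`, not exposed as a
  knob; the softplus caps each margin term at softplus(1) ≈ 1.313 and
  prevents unbounded latent spread.
- **Negatives** are drawn uniformly (seeded) from the training pool among
  molecules with T < 0.4 to both pair members. A similarity-weighted
  sampler would also be defensible; uniform is the assumption made here
  and is isolated in `build_triplets`.

Fine-tuning is plain REINFORCE: one sampled output per source per step, no
baseline subtraction (an optional moving-average baseline exists but is
off by default — fidelity first, variance reduction as an escape hatch).
Rewards are similarity-gated property scores with a *strict* gate
(T exactly at ε scores 0); invalid outputs score 0 because they can be
neither scored nor compared. Only decoder parameters are updated; encoder
and decoder have separate embedding tables precisely so the frozen-encoder
contract can be enforced structurally and audited by checksum. Estimator
correctness is checked two ways: the Monte-Carlo mean of sampled gradients
matches the exact gradient of expected reward on an enumerable categorical
policy, and zero-reward batches leave parameters bit-identical.

## Numerical backend

The networks run on a purpose-built reverse-mode autodiff over NumPy
float64 (`autograd.py`): dense matmuls, elementwise nonlinearities, row
gather, log-softmax. Everything is single-threaded and seeded, so every
phase is bit-reproducible from its config — an explicit design goal that a
GPU framework would make harder to guarantee. Gradients are validated by
central differences in the test suite. Optimisation uses Adam
(lr 3e−3 metric phase, 1e−3 RL) over parameters in sorted-name order.

## Evaluation suite

Seven metrics over k = 20 generated candidates per test source: validity,
novelty, mean property, mean improvement, mean similarity, internal
diversity, success rate; plus the success-rate sweep over similarity
thresholds 0.40–0.70 (step 0.05, the grid matching seven tick positions)
and the total score (sum of the six non-success metrics). Conventions that
the equations leave open:

- A generated collection is treated as a **set**: duplicates collapse by
  canonical SMILES before the property/improvement/similarity/diversity
  means. (Forced by the diversity definition's set-minus notation: k
  copies of two molecules with pairwise T = 1/3 must give diversity 2/3,
  not a value inflated by self-pairs.)
- Sources with no valid output are **excluded** from the
  property/improvement/similarity/diversity means (each is 0/0 there) but
  count in the validity, novelty and success-rate denominators.
- Novelty is literal: any output — compared by canonical form when valid,
  raw text otherwise — outside the training set counts; validity is not
  required by that metric's definition. The success rate, by contrast,
  requires validity, novelty, improvement ≥ δ and similarity ≥ ε
  simultaneously (non-strict bounds, unlike the strict reward gates).
- Outputs identical to the source pass the success filter only if the
  source is absent from the training set (the literal reading).

The ablation analytic mirrors the published protocol: sample 10 training
pairs, embed the ~20 molecules' latent means with PCA to 2-D, split all
molecule pairs into similar (T ≥ 0.4) and dissimilar (< 0.4), and compare
the two Euclidean-distance samples with a Kruskal–Wallis H test. High H
means similar molecules sit close and dissimilar ones far.

## Synthetic data: what it emulates and what it does not

`generate_synthetic_dataset` emits pairs from six hand-designed scaffold
families: positional secondary alcohols (hydroxyl walking along C10–C13
chains), oxymethylene ethers, ethylamine chains, thioethers, fluoroalkanes
and alkyl-cyclohexanes. The grammar is built so that

- every emitted pair has T ≥ 0.4 and a strictly positive property gap;
- any two molecules from different families have T < 0.4 (verified
  exhaustively at generation time, with deterministic pruning of
  violators, not assumed);
- the task property is a deterministic size score (heavy atoms / 25,
  capped at 1) — monotone, bounded like a bioactivity probability, and
  computable on any valid molecule including novel ones, which keeps the
  reward oracle and the evaluation oracle identical, as the method
  requires.

The alcohol family exists specifically to make the ablation measurement
informative: its members are structurally similar but their SMILES differ
mid-string, so collocating similar pairs in latent space is something the
contractive/margin losses must *achieve*, not a by-product of token
statistics. An earlier all-suffix grammar saturated the rank-based H
statistic for the reconstruction-only arm too, making the comparison
insensitive.

What passing on this fixture does **not** show: coverage of drug-like
chemistry (ZINC/ChEMBL-scale vocabulary, stereochemistry, charged and
aromatic systems), oracle noise (real activity predictors are imperfect),
or benchmark-scale training dynamics. The published benchmark success
rates require the original ZINC-derived pair sets, externally trained
DRD2/affinity predictors and GPU-scale training, and are explicitly out of
scope; the desk-scale study checks directions and invariants, not
absolute benchmark numbers.

## Study conditions (the desk-scale protocol)

300 synthetic pairs, 10% held-out pair split (evaluation sources are
held-out pairs' sources; X_train is the training pairs' molecules), ~12
token vocabulary, latent 32 / hidden 64 / embedding 32, 30 metric epochs,
20 REINFORCE epochs, batch 32, k = 20, evaluation δ = 0 and ε = 0.3.
These sizes were chosen as the smallest at which the phenomena of interest
(latent reorganisation, reward lift, success-rate lift) are comfortably
measurable on a single CPU. RL improvement is measured
checkpoint-vs-checkpoint with fresh fixed-seed episodes rather than by
comparing noisy per-epoch training rewards.

## Known limitations

- Atom-level tokenizer only; no SELFIES or graph decoding, so validity of
  samples is never guaranteed (by design — validity is a metric).
- Penalized logP follows the unnormalized convention
  `logP − SA − max(0, largest_ring − 6)`; a z-scored variant is available
  behind a flag since both circulate in the literature.
- Fingerprints default to achiral; chirality is a flag.
- The recurrent stack is one GRU layer each side; desk-scale by intent.
- The DRD2 / binding-affinity oracles are integration points (tabulated or
  external-command), never re-trained here; their published thresholds
  (4.989, 6.235) are treated as given constants.
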