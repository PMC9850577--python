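"""Molecular structure utilities: canonical SMILES, Morgan fingerprints,
Tanimoto similarity, and pluggable property oracles.

All similarity computations in this package run on 2048-bit radius-2 Morgan
(ECFP4-like) fingerprints. Property oracles are deterministic maps from a
SMILES string to a real score; invalid input always raises rather than
returning a silent default.
"""

from __future__ import annotations

import os
import shlex
import subprocess
import sys
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
from rdkit import Chem, RDConfig, RDLogger
from rdkit.Chem import Crippen, QED, rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib synthetic-accessibility scorer)

#: Sentinel returned by :func:`canonicalize` for unparsable input.
INVALID = None

FP_BITS = 2048
FP_RADIUS = 2

__all__ = [
    "INVALID",
    "FP_BITS",
    "FP_RADIUS",
    "canonicalize",
    "is_valid",
    "morgan_fingerprint",
    "tanimoto",
    "tanimoto_smiles",
    "qed_score",
    "penalized_logp",
    "PropertyOracle",
    "make_oracle",
    "read_smiles_file",
    "write_smiles_file",
    "read_score_table",
    "write_score_table",
]


def _mol(smiles: str) -> Chem.Mol | None:
    if not isinstance(smiles, str) or not smiles.strip():
        return None
    return Chem.MolFromSmiles(smiles)


def canonicalize(smiles: str, kekulize: bool = False) -> str | None:
    """Return the canonical SMILES for ``smiles``, or ``INVALID`` (None).

    Invalidity is a value, not an exception: any unparsable text maps to
    ``INVALID``. With ``kekulize=True`` aromatic rings are written with
    explicit alternating bonds.
    """
    mol = _mol(smiles)
    if mol is None:
        return INVALID
    if kekulize:
        try:
            Chem.Kekulize(mol, clearAromaticFlags=True)
        except Chem.KekulizeException:
            return INVALID
        return Chem.MolToSmiles(mol, kekuleSmiles=True)
    return Chem.MolToSmiles(mol)


def is_valid(smiles: str) -> bool:
    """Validity indicator (the ζ flag used by all evaluation metrics)."""
    return canonicalize(smiles) is not INVALID


def morgan_fingerprint(
    smiles: str, n_bits: int = FP_BITS, radius: int = FP_RADIUS, chiral: bool = False
) -> np.ndarray:
    """Radius-2 Morgan fingerprint folded to ``n_bits`` as a uint8 0/1 vector.

    Chirality flags default off; raises ``ValueError`` on invalid SMILES.
    """
    mol = _mol(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius, fpSize=n_bits, includeChirality=chiral
    )
    bv = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in bv.GetOnBits():
        arr[bit] = 1
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |a∩b| / |a∪b| of two binary fingerprints.

    The all-zero/all-zero pair (a 0/0 expression) is defined as 0.0:
    two empty bit sets carry no evidence of shared structure.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    inter = int(np.sum((a != 0) & (b != 0)))
    union = int(np.sum((a != 0) | (b != 0)))
    if union == 0:
        return 0.0
    return inter / union


def tanimoto_smiles(x: str, y: str) -> float:
    """Tanimoto similarity between two SMILES strings (both must be valid)."""
    return tanimoto(morgan_fingerprint(x), morgan_fingerprint(y))


def qed_score(smiles: str) -> float:
    """Quantitative estimate of drug-likeness, in [0, 1]."""
    mol = _mol(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    return float(QED.qed(mol))


def _largest_ring_size(mol: Chem.Mol) -> int:
    rings = mol.GetRingInfo().AtomRings()
    return max((len(r) for r in rings), default=0)


def penalized_logp(smiles: str, normalized: bool = False) -> float:
    """Octanol-water logP penalized by synthetic accessibility and large rings.

    Unnormalized convention (default)::

        logP(m) - SA(m) - max(0, largest_ring_size(m) - 6)

    With ``normalized=True`` each of the three terms is z-scored with the
    moments conventionally estimated on the ZINC250k set, a variant that also
    circulates in the molecular-optimisation literature.
    """
    mol = _mol(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    logp = Crippen.MolLogP(mol)
    sa = sascorer.calculateScore(mol)
    cycle = max(0, _largest_ring_size(mol) - 6)
    if not normalized:
        return float(logp - sa - cycle)
    # ZINC250k moments (logP, SA, cycle penalty), the usual normalisation.
    return float(
        (logp - 2.4570953396190123) / 1.434324401111988
        - (sa - 3.0525811293166134) / 0.8335207024513095
        - (cycle - 0.0485696876403053) / 0.2860212110245455
    )


@dataclass(frozen=True)
class PropertyOracle:
    """A deterministic SMILES -> score map with a declared range.

    ``score`` raises ``ValueError`` on invalid SMILES (never a silent
    default) and ``KeyError`` when a tabulated oracle is missing an entry.
    """

    name: str
    func: Callable[[str], float] = field(repr=False)
    declared_range: tuple[float, float] = (-np.inf, np.inf)

    def score(self, smiles: str) -> float:
        if not is_valid(smiles):
            raise ValueError(f"invalid SMILES: {smiles!r}")
        return float(self.func(smiles))

    def __call__(self, smiles: str) -> float:
        return self.score(smiles)


def _tabulated(table: Mapping[str, float], default: float | None) -> Callable[[str], float]:
    canon = {}
    for smi, val in table.items():
        c = canonicalize(smi)
        if c is INVALID:
            raise ValueError(f"invalid SMILES in score table: {smi!r}")
        canon[c] = float(val)

    def score(smiles: str) -> float:
        c = canonicalize(smiles)
        if c in canon:
            return canon[c]
        if default is not None:
            return float(default)
        raise KeyError(f"no tabulated score for {smiles!r}")

    return score


def make_oracle(
    kind: str,
    table: Mapping[str, float] | None = None,
    command: str | None = None,
    default: float | None = None,
    **kwargs,
) -> PropertyOracle:
    """Build a :class:`PropertyOracle`.

    kind:
        ``qed`` | ``plogp`` | ``tabulated`` | ``external-command``.
    table:
        required for ``tabulated``; SMILES -> score.
    default:
        optional fallback score for tabulated oracles; absent keys raise
        ``KeyError`` when it is None.
    command:
        required for ``external-command``; invoked as ``<command> <smiles>``
        and expected to print one float.

    The tabulated / external-command kinds are the integration points for
    externally trained activity and affinity predictors (e.g. receptor
    bioactivity models), which this package deliberately does not re-train.
    """
    if kind == "qed":
        return PropertyOracle("qed", qed_score, (0.0, 1.0))
    if kind == "plogp":
        normalized = bool(kwargs.pop("normalized", False))
        return PropertyOracle(
            "plogp", lambda s: penalized_logp(s, normalized=normalized)
        )
    if kind == "tabulated":
        if table is None:
            raise ValueError("tabulated oracle requires a score table")
        return PropertyOracle("tabulated", _tabulated(table, default))
    if kind == "external-command":
        if not command:
            raise ValueError("external-command oracle requires a command")

        def run(smiles: str) -> float:
            out = subprocess.run(
                [*shlex.split(command), smiles],
                check=True,
                capture_output=True,
                text=True,
            )
            return float(out.stdout.strip())

        return PropertyOracle(f"external:{command}", run)
    raise ValueError(f"unknown oracle kind: {kind!r}")


def read_smiles_file(path) -> list[str]:
    """Read a SMILES list file (one SMILES per line, blank lines skipped)."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_smiles_file(path, smiles: Iterable[str]) -> None:
    with open(path, "w") as fh:
        for s in smiles:
            fh.write(s + "\n")


def read_score_table(path, sep: str = "\t") -> dict[str, float]:
    """Read a two-column (SMILES, score) table."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(sep)
            if len(parts) != 2:
                raise ValueError(f"{path}:{i}: expected 2 columns, got {len(parts)}")
            out[parts[0]] = float(parts[1])
    return out


def write_score_table(path, table: Mapping[str, float], sep: str = "\t") -> None:
    with open(path, "w") as fh:
        for smi, val in table.items():
            fh.write(f"{smi}{sep}{val}\n")
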