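"""SMILES tokenization and integer encoding for the sequence model.

Atom-level tokenizer: bracket atoms (``[nH]``, ``[O-]``), two-letter
elements (``Cl``, ``Br``) and two-digit ring closures (``%12``) are single
tokens; every other character is its own token. The rule table is ordered
(brackets > two-letter elements > %NN > single characters) so tokenization
is deterministic and ``detokenize(tokenize(s)) == s`` for any text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = ["Vocabulary", "tokenize", "detokenize", "build_vocab"]

_TOKEN_RE = re.compile(r"(\[[^\]]*\]|Br|Cl|%\d{2}|.)")

BOS, EOS, PAD, UNK = "<bos>", "<eos>", "<pad>", "<unk>"
SPECIALS = (PAD, BOS, EOS, UNK)  # PAD=0 so padded batches are zero-filled


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into atom-level tokens (lossless)."""
    return _TOKEN_RE.findall(smiles)


def detokenize(tokens: Iterable[str]) -> str:
    return "".join(tokens)


@dataclass(frozen=True)
class Vocabulary:
    """Bijective token <-> index map with reserved special tokens.

    Index layout: PAD=0, BOS=1, EOS=2, UNK=3, then corpus tokens in sorted
    order, so the same corpus always yields the same vocabulary.
    """

    tokens: tuple[str, ...]

    def __post_init__(self):
        if tuple(self.tokens[: len(SPECIALS)]) != SPECIALS:
            raise ValueError("vocabulary must start with the special tokens")
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        object.__setattr__(
            self, "_index", {tok: i for i, tok in enumerate(self.tokens)}
        )

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad(self) -> int:
        return 0

    @property
    def bos(self) -> int:
        return 1

    @property
    def eos(self) -> int:
        return 2

    @property
    def unk(self) -> int:
        return 3

    def index(self, token: str) -> int:
        return self._index.get(token, self.unk)

    def encode(self, smiles: str, max_len: int = 120) -> list[int]:
        """BOS + token indices + EOS; raises if the result exceeds max_len."""
        toks = tokenize(smiles)
        if len(toks) + 2 > max_len:
            raise ValueError(
                f"SMILES of {len(toks)} tokens exceeds max_len={max_len}: {smiles!r}"
            )
        return [self.bos, *(self.index(t) for t in toks), self.eos]

    def decode(self, indices: Sequence[int]) -> str:
        """Inverse of :meth:`encode`; stops at EOS, skips BOS/PAD."""
        toks = []
        for i in indices:
            if i == self.eos:
                break
            if i in (self.bos, self.pad):
                continue
            toks.append(self.tokens[i])
        return detokenize(toks)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for tok in self.tokens:
                fh.write(tok + "\n")

    @classmethod
    def load(cls, path) -> "Vocabulary":
        with open(path) as fh:
            return cls(tuple(line.rstrip("\n") for line in fh if line.rstrip("\n")))


def build_vocab(corpus: Iterable[str]) -> Vocabulary:
    """Vocabulary covering every token in ``corpus`` (order-independent)."""
    seen: set[str] = set()
    n = 0
    for smiles in corpus:
        n += 1
        seen.update(tokenize(smiles))
    if n == 0:
        raise ValueError("empty corpus")
    return Vocabulary((*SPECIALS, *sorted(seen)))
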