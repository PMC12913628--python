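"""SMILES tokenization, task sequence construction, and data augmentation.

Molecule tokens follow the community reaction-tokenizer grammar: bracket atoms
(``[O-]``, ``[nH]``), two-letter halogens (``Cl``, ``Br``), ``%nn`` ring
closures, bond/stereo/charge symbols and single characters are each one token,
and concatenating the tokens reproduces the input string exactly.

Condition tokens (``P3``, ``B31``, ...) are atomic: they are appended to the
token list as-is and never pass through the SMILES tokenizer. For the forward
task they follow the reactant tokens in the fixed category order
photocatalyst, base-or-acid, additive, wavelength, solvent — truncated to the
first ``n_conditions`` categories, so the 5-condition input is a prefix-wise
superset of the 4-condition input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem

from .records import (
    CATEGORIES,
    ChemistryParseError,
    ConditionSet,
    ConditionVocabulary,
    ReactionRecord,
    canonicalize,
    encode_conditions,
)

__all__ = [
    "SMILES_TOKEN_PATTERN",
    "TokenizationError",
    "MissingConditionsError",
    "SourceTarget",
    "AugmentationParams",
    "TokenVocab",
    "tokenize_smiles",
    "detokenize",
    "tokenize_components",
    "build_forward_source",
    "build_retro_source",
    "build_condition_target",
    "randomize_smiles",
    "span_mask",
    "augment_pair",
]

SMILES_TOKEN_PATTERN = (
    r"(\[[^\]]+]|Br?|Cl?|N|O|S|P|F|I|b|c|n|o|s|p|\(|\)|\."
    r"|=|#|-|\+|\\|\/|:|~|@|\?|>>?|\*|\$|%[0-9]{2}|[0-9])"
)
_TOKEN_RE = re.compile(SMILES_TOKEN_PATTERN)

# tokens the SMILES grammar does not cover but that appear in model streams
MASK_TOKEN = "<MASK>"
PAD_TOKEN = "<PAD>"
BOS_TOKEN = "<BOS>"
EOS_TOKEN = "<EOS>"
SPECIAL_TOKENS = (MASK_TOKEN, PAD_TOKEN, BOS_TOKEN, EOS_TOKEN)


class TokenizationError(ValueError):
    """Input contains a character outside the token grammar."""


class MissingConditionsError(ValueError):
    """A task needing condition tokens was given a record without conditions."""


def tokenize_smiles(smiles: str) -> list[str]:
    """Tokenize one SMILES string; concatenation of tokens equals the input."""
    tokens: list[str] = []
    pos = 0
    for m in _TOKEN_RE.finditer(smiles):
        if m.start() != pos:
            raise TokenizationError(
                f"untokenizable character {smiles[pos]!r} at position {pos} in {smiles!r}"
            )
        tokens.append(m.group())
        pos = m.end()
    if pos != len(smiles):
        raise TokenizationError(
            f"untokenizable character {smiles[pos]!r} at position {pos} in {smiles!r}"
        )
    return tokens


def detokenize(tokens: Sequence[str]) -> str:
    """Plain concatenation; inverse of :func:`tokenize_smiles`."""
    return "".join(tokens)


def tokenize_components(components: Sequence[str]) -> list[str]:
    """Tokenize several molecules, joined by ``.`` tokens."""
    out: list[str] = []
    for i, smi in enumerate(components):
        if i:
            out.append(".")
        out.extend(tokenize_smiles(smi))
    return out


# ---------------------------------------------------------------------------
# task sequences
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SourceTarget:
    """A tokenized (source, target) pair for one task."""

    source: tuple[str, ...]
    target: tuple[str, ...]
    task: str  # forward | retro | condition


def _condition_tokens(record: ReactionRecord, vocab: ConditionVocabulary) -> list[str]:
    if record.conditions is None:
        raise MissingConditionsError(
            "record has no condition annotation but condition tokens were requested"
        )
    cs: ConditionSet = encode_conditions(record.conditions, vocab)
    return cs.token_strings()


def build_forward_source(
    record: ReactionRecord,
    vocab: ConditionVocabulary | None = None,
    n_conditions: int = 5,
) -> SourceTarget:
    """Forward-prediction pair: reactants (+ first ``n_conditions`` condition
    tokens in P,B,A,W,S order) -> products."""
    if not 0 <= n_conditions <= 5:
        raise ValueError("n_conditions must be in 0..5")
    src = tokenize_components([m.smiles for m in record.reactants])
    if n_conditions > 0:
        if vocab is None:
            raise ValueError("a ConditionVocabulary is required when n_conditions > 0")
        src.extend(_condition_tokens(record, vocab)[:n_conditions])
    tgt = tokenize_components([m.smiles for m in record.products])
    return SourceTarget(tuple(src), tuple(tgt), "forward")


def build_retro_source(record: ReactionRecord) -> SourceTarget:
    """Retrosynthesis pair: main product -> reactants.

    Conditions never appear in the retro source; they are recommended by a
    separate model downstream. Multi-product records use the first (main)
    product.
    """
    if len(record.products) > 1:
        import warnings

        warnings.warn(
            "multi-product record: retro task uses the first (main) product",
            stacklevel=2,
        )
    src = tokenize_smiles(record.products[0].smiles)
    tgt = tokenize_components([m.smiles for m in record.reactants])
    return SourceTarget(tuple(src), tuple(tgt), "retro")


def build_condition_target(
    record: ReactionRecord, vocab: ConditionVocabulary
) -> SourceTarget:
    """Condition-recommendation pair: full reaction -> five condition tokens."""
    src = (
        tokenize_components([m.smiles for m in record.reactants])
        + [">>"]
        + tokenize_components([m.smiles for m in record.products])
    )
    tgt = _condition_tokens(record, vocab)
    return SourceTarget(tuple(src), tuple(tgt), "condition")


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AugmentationParams:
    """Stochastic augmentation settings, applied independently per sample."""

    apply_probability: float = 0.5
    mask_token: str = MASK_TOKEN
    span_length_range: tuple[int, int] = (2, 4)
    randomize_atom_order: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.apply_probability <= 1.0:
            raise ValueError("apply_probability must be in [0, 1]")
        lo, hi = self.span_length_range
        if lo < 1 or hi < lo:
            raise ValueError("span lengths must be >= 1 and ordered")


def randomize_smiles(smiles: str, rng: np.random.Generator) -> str:
    """A random non-canonical rendering of the same molecular graph.

    Atom indices are permuted with ``rng`` before writing, so the output
    distribution depends only on the generator state, and
    ``canonicalize(out) == canonicalize(in)`` always holds.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemistryParseError(f"unparsable SMILES: {smiles!r}")
    order = [int(i) for i in rng.permutation(mol.GetNumAtoms())]
    mol = Chem.RenumberAtoms(mol, order)
    return Chem.MolToSmiles(mol, canonical=False)


def span_mask(
    tokens: Sequence[str],
    rng: np.random.Generator,
    params: AugmentationParams = AugmentationParams(),
) -> list[str]:
    """Replace one contiguous token span by a single mask token.

    Applied with ``params.apply_probability`` per call; span length is drawn
    uniformly from ``span_length_range`` and clamped at the sequence end. With
    ``apply_probability = 0`` the input is returned unchanged.
    """
    if not tokens:
        raise ValueError("cannot mask an empty token list")
    toks = list(tokens)
    if rng.random() >= params.apply_probability:
        return toks
    lo, hi = params.span_length_range
    length = int(rng.integers(lo, hi + 1))
    start = int(rng.integers(0, len(toks)))
    end = min(start + length, len(toks))
    return toks[:start] + [params.mask_token] + toks[end:]


def augment_pair(
    pair: SourceTarget,
    rng: np.random.Generator,
    params: AugmentationParams = AugmentationParams(),
) -> SourceTarget:
    """Randomized-SMILES + span-mask augmentation of a source sequence.

    Molecule spans in the source are re-rendered with random atom order
    (probability ``apply_probability``, per molecule); condition tokens and
    the ``>>`` separator are left untouched. Span masking is then applied to
    the source. Targets are never augmented.
    """
    src = list(pair.source)
    # split the source into molecule spans and passthrough tokens
    out: list[str] = []
    buf: list[str] = []

    def flush() -> None:
        if not buf:
            return
        smi = detokenize(buf)
        if params.randomize_atom_order and rng.random() < params.apply_probability:
            try:
                smi = randomize_smiles(smi, rng)
            except ChemistryParseError:
                pass
        out.extend(tokenize_smiles(smi))
        buf.clear()

    for tok in src:
        if tok == ">>" or _is_condition_token(tok):
            flush()
            out.append(tok)
        elif tok == ".":
            flush()
            out.append(".")
        else:
            buf.append(tok)
    flush()
    out = span_mask(out, rng, params)
    return SourceTarget(tuple(out), pair.target, pair.task)


def _is_condition_token(tok: str) -> bool:
    return (
        len(tok) >= 2
        and tok[0] in "PBAWS"
        and tok[1:].isdigit()
    )


# ---------------------------------------------------------------------------
# integer token vocabulary
# ---------------------------------------------------------------------------


class TokenVocab:
    """Token <-> integer-id table with reserved specials at ids 0-3.

    ``<MASK>``, ``<PAD>``, ``<BOS>``, ``<EOS>`` occupy ids 0, 1, 2, 3; all
    other tokens follow in insertion order. Serialized as plain text, one
    token per line.
    """

    def __init__(self, tokens: Sequence[str] = ()) -> None:
        self._tokens: list[str] = list(SPECIAL_TOKENS)
        self._ids: dict[str, int] = {t: i for i, t in enumerate(self._tokens)}
        for t in tokens:
            self.add(t)

    def add(self, token: str) -> int:
        if token not in self._ids:
            self._ids[token] = len(self._tokens)
            self._tokens.append(token)
        return self._ids[token]

    def __len__(self) -> int:
        return len(self._tokens)

    def __contains__(self, token: str) -> bool:
        return token in self._ids

    @property
    def mask_id(self) -> int:
        return 0

    @property
    def pad_id(self) -> int:
        return 1

    @property
    def bos_id(self) -> int:
        return 2

    @property
    def eos_id(self) -> int:
        return 3

    def id_of(self, token: str) -> int:
        try:
            return self._ids[token]
        except KeyError:
            raise KeyError(f"token {token!r} not in vocabulary") from None

    def token_of(self, idx: int) -> str:
        return self._tokens[idx]

    def encode(self, tokens: Sequence[str]) -> list[int]:
        return [self.id_of(t) for t in tokens]

    def decode(self, ids: Sequence[int], strip_special: bool = True) -> list[str]:
        toks = [self._tokens[i] for i in ids]
        if strip_special:
            toks = [t for t in toks if t not in (PAD_TOKEN, BOS_TOKEN, EOS_TOKEN)]
        return toks

    def content_hash(self) -> str:
        import hashlib

        return hashlib.sha256("\n".join(self._tokens).encode()).hexdigest()[:16]

    @classmethod
    def from_pairs(cls, pairs: Sequence[SourceTarget]) -> "TokenVocab":
        vocab = cls()
        for p in pairs:
            for tok in (*p.source, *p.target):
                vocab.add(tok)
        return vocab

    def save(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self._tokens) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "TokenVocab":
        lines = Path(path).read_text().splitlines()
        if tuple(lines[:4]) != SPECIAL_TOKENS:
            raise ValueError("vocabulary file must begin with the four reserved tokens")
        return cls(lines[4:])
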