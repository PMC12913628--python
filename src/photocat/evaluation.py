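"""Evaluation: top-k accuracy, invalid-SMILES rate, condition accuracy,
cross-validation folds, and the condition-ablation driver.

Accuracy is canonical-SMILES equality: a candidate hits a reference iff its
canonical component multiset equals the reference's (order-insensitive for
multi-component targets, as in retrosynthesis). Invalid candidates can never
hit. The invalid fraction is measured on rank-1 candidates only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .grammar import SyntheticDataset, grammar_vocabulary
from .model import (
    ModelConfig,
    ModelState,
    PredictionResult,
    greedy_decode_batch,
    init_model,
    train,
)
from .records import ChemistryParseError, ConditionSet, canonical_components
from .tokenization import TokenVocab, build_forward_source

__all__ = [
    "FoldSplit",
    "EvalReport",
    "ConditionEvalReport",
    "AblationResult",
    "make_folds",
    "matches_reference",
    "topk_accuracy",
    "invalid_fraction",
    "evaluate_topk",
    "condition_accuracy",
    "run_ablation",
]


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoldSplit:
    """k disjoint index sets covering 0..n-1 with sizes differing by <= 1."""

    folds: tuple[tuple[int, ...], ...]

    @property
    def k(self) -> int:
        return len(self.folds)

    def train_indices(self, fold: int) -> tuple[int, ...]:
        return tuple(i for j, f in enumerate(self.folds) if j != fold for i in f)


def make_folds(n: int, k: int, seed: int) -> FoldSplit:
    """Uniform-shuffle k-fold split (deterministic for a fixed seed)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot split {n} items into {k} folds")
    perm = np.random.default_rng(seed).permutation(n)
    return FoldSplit(tuple(
        tuple(int(i) for i in chunk) for chunk in np.array_split(perm, k)
    ))


# ---------------------------------------------------------------------------
# top-k / validity metrics
# ---------------------------------------------------------------------------


def _canon_or_none(text: str) -> tuple[str, ...] | None:
    try:
        return canonical_components(text)
    except ChemistryParseError:
        return None


def matches_reference(candidate: str, reference: str) -> bool:
    """Canonical equality, order-insensitive over '.'-separated components."""
    cand = _canon_or_none(candidate)
    if cand is None:
        return False
    return cand == canonical_components(reference)


def topk_accuracy(
    predictions: Sequence[PredictionResult],
    references: Sequence[str],
    k: int,
) -> float:
    """Fraction of cases whose reference appears among the first k candidates.

    References must canonicalize; invalid candidates never hit. If a beam is
    narrower than k the available candidates are used (with a warning).
    """
    if len(predictions) != len(references):
        raise ValueError("predictions and references must have equal length")
    if any(p.k < k for p in predictions):
        warnings.warn(
            f"some beams are narrower than k={k}; evaluating available candidates",
            stacklevel=2,
        )
    hits = 0
    for pred, ref in zip(predictions, references):
        ref_canon = canonical_components(ref)
        for cand in pred.candidates[:k]:
            if cand.is_valid and _canon_or_none(cand.text) == ref_canon:
                hits += 1
                break
    return hits / len(predictions) if predictions else float("nan")


def invalid_fraction(predictions: Sequence[PredictionResult]) -> float:
    """Fraction of rank-1 candidates that fail canonicalization."""
    if not predictions:
        return 0.0
    bad = 0
    for pred in predictions:
        top = pred.top1
        if top is None or not top.is_valid:
            bad += 1
    return bad / len(predictions)


@dataclass(frozen=True)
class EvalReport:
    """Top-1..5 accuracies plus the invalid-SMILES fraction."""

    top_k_accuracy: dict[int, float]
    invalid_fraction: float
    n_eval: int

    def __post_init__(self) -> None:
        ks = sorted(self.top_k_accuracy)
        vals = [self.top_k_accuracy[k] for k in ks]
        if any(b < a - 1e-12 for a, b in zip(vals, vals[1:])):
            raise ValueError("top-k accuracy must be non-decreasing in k")


def evaluate_topk(
    predictions: Sequence[PredictionResult],
    references: Sequence[str],
    max_k: int = 5,
) -> EvalReport:
    return EvalReport(
        top_k_accuracy={k: topk_accuracy(predictions, references, k) for k in range(1, max_k + 1)},
        invalid_fraction=invalid_fraction(predictions),
        n_eval=len(predictions),
    )


# ---------------------------------------------------------------------------
# condition accuracy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConditionEvalReport:
    """Per-category exact-token accuracy and the all-five-correct fraction."""

    per_category: dict[str, float]
    all_five_fraction: float
    n_eval: int


def condition_accuracy(
    predicted: Sequence[ConditionSet], reference: Sequence[ConditionSet]
) -> ConditionEvalReport:
    if len(predicted) != len(reference):
        raise ValueError("predicted and reference lists must have equal length")
    if not predicted:
        raise ValueError("empty evaluation set")
    from .records import CATEGORIES

    per = {}
    all_five = 0
    for cat in CATEGORIES:
        per[cat] = float(np.mean([
            p.get(cat) == r.get(cat) for p, r in zip(predicted, reference)
        ]))
    for p, r in zip(predicted, reference):
        if all(p.get(c) == r.get(c) for c in CATEGORIES):
            all_five += 1
    return ConditionEvalReport(per, all_five / len(predicted), len(predicted))


# ---------------------------------------------------------------------------
# condition ablation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AblationResult:
    """Mean held-out top-1 accuracy per number of input condition categories.

    ``per_seed[n]`` holds the raw accuracies (one per seed); ``curve[n]`` is
    their mean. The curve is reported as measured, with no smoothing.
    """

    curve: dict[int, float]
    per_seed: dict[int, tuple[float, ...]] = field(default_factory=dict)

    def standard_error(self, n: int) -> float:
        vals = np.asarray(self.per_seed[n])
        if len(vals) < 2:
            return float("nan")
        return float(vals.std(ddof=1) / np.sqrt(len(vals)))


def greedy_top1_accuracy(
    state: ModelState, sources: Sequence[Sequence[str]], references: Sequence[str]
) -> float:
    """Batched greedy decode, scored by canonical equality."""
    outs = greedy_decode_batch(state, sources)
    return float(np.mean([
        matches_reference("".join(o), ref) for o, ref in zip(outs, references)
    ]))


def run_ablation(
    train_ds: SyntheticDataset,
    test_ds: SyntheticDataset,
    config: ModelConfig,
    seeds: Sequence[int],
    steps: int,
    n_conditions: Sequence[int] = (0, 1, 2, 3, 4, 5),
) -> AblationResult:
    """Condition-count ablation at matched training budgets.

    For each ``n`` in ``n_conditions`` and each seed, a fresh model is trained
    for the same number of steps on forward pairs carrying the first ``n``
    condition tokens, then scored by held-out greedy top-1; only the amount of
    condition information varies between arms.
    """
    if not train_ds.records or not test_ds.records:
        raise ValueError("ablation needs non-empty train and test datasets")
    vocab_cond = grammar_vocabulary(train_ds.spec)
    curve: dict[int, float] = {}
    per_seed: dict[int, tuple[float, ...]] = {}
    for n in n_conditions:
        ptr = [build_forward_source(r, vocab_cond, n) for r in train_ds.records]
        pte = [build_forward_source(r, vocab_cond, n) for r in test_ds.records]
        token_vocab = TokenVocab.from_pairs(ptr + pte)
        accs = []
        for seed in seeds:
            state = init_model(config, token_vocab, int(seed))
            train(state, ptr, steps, np.random.default_rng(int(seed) + 1))
            accs.append(greedy_top1_accuracy(
                state, [p.source for p in pte], ["".join(p.target) for p in pte]
            ))
        per_seed[n] = tuple(accs)
        curve[n] = float(np.mean(accs))
    return AblationResult(curve, per_seed)
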