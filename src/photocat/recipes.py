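"""Desk-scale training recipes over the synthetic grammar.

These helpers bundle the configurations and budgets used throughout the test
suite and the reproduction script: a tiny transformer (2+2 layers, dim 64)
trained at a constant rate of 1.5e-3 with a final tenfold rate drop for the
last fifth of the run — on one CPU a forward model converges on a
2,500-record grammar dataset in about three minutes.

All three task models trained from one dataset share a single token
vocabulary so they can be composed into the planning loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grammar import SyntheticDataset, grammar_vocabulary
from .model import ModelConfig, ModelState, init_model, train
from .records import ConditionVocabulary
from .tokenization import (
    SourceTarget,
    TokenVocab,
    build_condition_target,
    build_forward_source,
    build_retro_source,
)

__all__ = [
    "FORWARD_STEPS",
    "TRANSFER_STEPS",
    "COND_STEPS",
    "grammar_model_config",
    "build_task_pairs",
    "shared_token_vocab",
    "fit_task_model",
]

#: optimizer updates for a converged forward/retro model on ~2.5k records
FORWARD_STEPS = 2500
#: per-stage updates for the transfer-ordering experiment (matched budgets)
TRANSFER_STEPS = 1000
#: updates for the condition-recommendation model (5-token targets)
COND_STEPS = 1500


def grammar_model_config(steps: int = FORWARD_STEPS, **overrides) -> ModelConfig:
    """Tiny-preset config with the constant-rate + polish-decay schedule."""
    return ModelConfig.tiny(
        schedule="constant",
        learning_rate=1.5e-3,
        lr_decay_step=int(steps * 0.8),
        **overrides,
    )


def build_task_pairs(
    ds: SyntheticDataset,
    task: str,
    vocab: ConditionVocabulary | None = None,
    n_conditions: int = 5,
) -> list[SourceTarget]:
    """Tokenized pairs for one task over a generated dataset."""
    vocab = vocab or grammar_vocabulary(ds.spec)
    if task == "forward":
        return [build_forward_source(r, vocab, n_conditions) for r in ds.records]
    if task == "retro":
        return [build_retro_source(r) for r in ds.records]
    if task == "condition":
        return [build_condition_target(r, vocab) for r in ds.records]
    raise ValueError(f"unknown task {task!r}")


def shared_token_vocab(*pair_lists: Sequence[SourceTarget]) -> TokenVocab:
    """One vocabulary over several task streams (planner models must agree)."""
    return TokenVocab.from_pairs([p for pairs in pair_lists for p in pairs])


def fit_task_model(
    pairs: Sequence[SourceTarget],
    vocab: TokenVocab,
    seed: int,
    steps: int = FORWARD_STEPS,
    config: ModelConfig | None = None,
) -> ModelState:
    """Initialize and train one task model with the standard recipe."""
    config = config or grammar_model_config(steps)
    state = init_model(config, vocab, int(seed))
    return train(state, pairs, steps, np.random.default_rng(int(seed) + 1))
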