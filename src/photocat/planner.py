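"""Integrated single-step synthesis planning.

The three-step loop mirrors how the platform designs new photocatalytic
reactions: (1) retrosynthesis proposes candidate reactant sets for a target,
(2) the condition model recommends a full five-token condition set for each
proposed reaction, and (3) the forward model re-predicts the product under
those conditions — a route is accepted only when the forward top-1 prediction
canonically equals the target. Acceptance is re-checked by an independent
canonical-equality predicate, never taken from a model's own report.

Novelty is flagged against a user-supplied index of known canonical reaction
strings (an exact-lookup stand-in for a literature search; a hook accepts any
external checker).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence
import warnings

import numpy as np

from .model import ModelState, beam_decode
from .records import (
    CATEGORIES,
    ChemistryParseError,
    ConditionSet,
    ConditionVocabulary,
    Molecule,
    canonical_components,
    canonicalize,
    parse_condition_token,
    render_reaction,
)
from .tokenization import tokenize_components, tokenize_smiles

__all__ = [
    "RouteCandidate",
    "PlannerModels",
    "ConditionDecodeError",
    "propose_retro",
    "recommend_conditions",
    "forward_validate",
    "plan",
    "build_training_index",
]


class ConditionDecodeError(RuntimeError):
    """The condition model emitted something other than five condition tokens."""


@dataclass(frozen=True)
class RouteCandidate:
    """One proposed route: reactants + conditions + forward check result."""

    target: Molecule
    reactants: tuple[Molecule, ...]
    conditions: ConditionSet
    forward_top1: Molecule | None
    accepted: bool
    novelty_flag: str  # "known" | "unseen"

    def reaction_smiles(self) -> str:
        return render_reaction(
            [m.smiles for m in self.reactants],
            [self.target.smiles],
        )


@dataclass
class PlannerModels:
    """The three checkpoints driving the loop; vocabularies must agree."""

    retro: ModelState
    cond: ModelState
    forward: ModelState

    def __post_init__(self) -> None:
        h = {s.vocab.content_hash() for s in (self.retro, self.cond, self.forward)}
        if len(h) != 1:
            raise ValueError(
                "retro/cond/forward models carry different vocabularies"
            )


def propose_retro(
    target: str, retro_model: ModelState, k: int
) -> list[tuple[str, ...]]:
    """Up to k candidate reactant sets for a target, all-valid and
    deduplicated as canonical multisets; invalid beam entries are dropped."""
    canonicalize(target)  # fail fast on an unparsable target
    result = beam_decode(retro_model, tokenize_smiles(target), k)
    seen: set[tuple[str, ...]] = set()
    out: list[tuple[str, ...]] = []
    for cand in result.candidates:
        if not cand.is_valid:
            continue
        key = canonical_components(cand.text)
        if key in seen:
            continue
        seen.add(key)
        out.append(tuple(cand.text.split(".")))
    if not out:
        warnings.warn(f"no valid retrosynthesis candidate for {target!r}", stacklevel=2)
    return out


def recommend_conditions(
    reactants: Sequence[str], target: str, cond_model: ModelState
) -> ConditionSet:
    """Decode the five-token condition set for reactants >> target."""
    for s in (*reactants, target):
        canonicalize(s)
    source = tokenize_components(list(reactants)) + [">>"] + tokenize_smiles(target)
    result = beam_decode(cond_model, source, k=1, max_len=6)
    if not result.candidates:
        raise ConditionDecodeError("condition model produced no output")
    tokens = result.candidates[0].tokens
    try:
        cs = ConditionSet(tuple(parse_condition_token(t) for t in tokens))
    except ValueError as exc:
        raise ConditionDecodeError(
            f"condition model emitted non-condition output {tokens!r}"
        ) from exc
    return cs


def forward_validate(
    reactants: Sequence[str],
    conditions: ConditionSet,
    fwd_model: ModelState,
    target: str,
) -> tuple[bool, Molecule | None]:
    """Forward top-1 check: accepted iff the top-1 prediction canonically
    equals the target. Only the top-1 prediction is considered."""
    target_canon = canonical_components(target)
    source = tokenize_components(list(reactants)) + conditions.token_strings()
    result = beam_decode(fwd_model, source, k=1)
    top = result.top1
    if top is None or not top.is_valid:
        return False, None
    predicted = Molecule(top.text)
    try:
        accepted = canonical_components(top.text) == target_canon
    except ChemistryParseError:
        return False, None
    return accepted, predicted


def build_training_index(records: Iterable) -> set[str]:
    """Canonical reaction strings of a training set, for novelty flagging."""
    return {rec.canonical_reaction() for rec in records}


def _canonical_reaction_key(reactants: Sequence[str], target: str) -> str:
    r = sorted(canonicalize(s).smiles for s in reactants)
    p = [canonicalize(target).smiles]
    return render_reaction(r, p)


def plan(
    target: str,
    models: PlannerModels,
    k: int = 10,
    training_index: set[str] | None = None,
    novelty_checker: Callable[[str], bool] | None = None,
    reagent_allowlist: set[str] | None = None,
) -> list[RouteCandidate]:
    """Retro -> condition -> forward pipeline for one target.

    Returns routes sorted accepted-first (stable within groups). A route is
    "known" when its canonical reaction string occurs in ``training_index``
    (or ``novelty_checker`` returns True). ``reagent_allowlist`` optionally
    drops proposals using reactants outside the allowed canonical set.
    """
    proposals = propose_retro(target, models.retro, k)
    routes: list[RouteCandidate] = []
    for reactants in proposals:
        if reagent_allowlist is not None:
            canon = [canonicalize(s).smiles for s in reactants]
            if any(c not in reagent_allowlist for c in canon):
                continue
        try:
            conditions = recommend_conditions(reactants, target, models.cond)
        except ConditionDecodeError:
            continue
        accepted, forward_top1 = forward_validate(
            reactants, conditions, models.forward, target
        )
        if accepted and forward_top1 is not None:
            # independent re-check of the acceptance predicate
            assert canonical_components(forward_top1.smiles) == canonical_components(target)
        key = _canonical_reaction_key(reactants, target)
        if novelty_checker is not None:
            known = novelty_checker(key)
        else:
            known = key in (training_index or set())
        routes.append(
            RouteCandidate(
                target=canonicalize(target),
                reactants=tuple(Molecule(s) for s in reactants),
                conditions=conditions,
                forward_top1=forward_top1,
                accepted=accepted,
                novelty_flag="known" if known else "unseen",
            )
        )
    routes.sort(key=lambda r: (not r.accepted,))
    return routes
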