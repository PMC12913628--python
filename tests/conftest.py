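"""Shared fixtures.

Heavy fixtures (trained models) are session-scoped and built lazily: a
2,500-record condition-dependent grammar dataset with a 300-record held-out
split over unseen reactant combinations, plus forward/retro/condition models
trained with the standard desk-scale recipe. Unit tests use much smaller
datasets and models.
"""

from __future__ import annotations

import numpy as np
import pytest

from photocat import grammar as G
from photocat import recipes as R
from photocat.grammar import grammar_vocabulary
from photocat.model import staged_fit


@pytest.fixture(scope="session")
def spec():
    return G.default_spec()


@pytest.fixture(scope="session")
def small_dataset(spec):
    return G.generate_dataset(spec, 200, seed=1)


@pytest.fixture(scope="session")
def datasets(spec):
    """(train, test) with disjoint reactant-set instantiations."""
    return G.generate_train_test(spec, 2500, 300, seed=7)


@pytest.fixture(scope="session")
def cond_vocab(spec):
    return grammar_vocabulary(spec)


@pytest.fixture(scope="session")
def pretrain_corpus(spec):
    return G.generate_pretrain_corpus(spec, 4000, seed=8)


@pytest.fixture(scope="session")
def task_pairs(datasets, cond_vocab, pretrain_corpus):
    tr, te = datasets
    return {
        "fwd5": R.build_task_pairs(tr, "forward", cond_vocab, 5),
        "fwd5_test": R.build_task_pairs(te, "forward", cond_vocab, 5),
        "fwd1": R.build_task_pairs(tr, "forward", cond_vocab, 1),
        "fwd1_test": R.build_task_pairs(te, "forward", cond_vocab, 1),
        "fwd0": R.build_task_pairs(tr, "forward", cond_vocab, 0),
        "fwd0_test": R.build_task_pairs(te, "forward", cond_vocab, 0),
        "retro": R.build_task_pairs(tr, "retro"),
        "retro_test": R.build_task_pairs(te, "retro"),
        "cond": R.build_task_pairs(tr, "condition", cond_vocab),
        "cond_test": R.build_task_pairs(te, "condition", cond_vocab),
        "pre_retro": R.build_task_pairs(pretrain_corpus, "retro"),
    }


@pytest.fixture(scope="session")
def token_vocab(task_pairs):
    return R.shared_token_vocab(*task_pairs.values())


@pytest.fixture(scope="session")
def forward_model(task_pairs, token_vocab):
    """Condition-aware forward model (all five condition tokens)."""
    return R.fit_task_model(task_pairs["fwd5"], token_vocab, seed=5)


@pytest.fixture(scope="session")
def forward_model_n1(task_pairs, token_vocab):
    return R.fit_task_model(task_pairs["fwd1"], token_vocab, seed=5)


@pytest.fixture(scope="session")
def forward_model_blind(task_pairs, token_vocab):
    """Forward model trained without condition tokens."""
    return R.fit_task_model(task_pairs["fwd0"], token_vocab, seed=5)


@pytest.fixture(scope="session")
def transfer_models(task_pairs, token_vocab):
    """(pretrain->finetune, finetune-only, pretrain-only) retro models at
    matched per-stage budgets."""
    cfg = R.grammar_model_config(R.TRANSFER_STEPS)
    seq = staged_fit(
        task_pairs["pre_retro"], task_pairs["retro"], cfg, "sequential", rng=1,
        pretrain_steps=R.TRANSFER_STEPS, finetune_steps=R.TRANSFER_STEPS,
        vocab=token_vocab,
    )
    ft = staged_fit(
        None, task_pairs["retro"], cfg, "sequential", rng=1,
        finetune_steps=R.TRANSFER_STEPS, vocab=token_vocab,
    )
    po = staged_fit(
        task_pairs["pre_retro"], None, cfg, "sequential", rng=1,
        pretrain_steps=R.TRANSFER_STEPS, vocab=token_vocab,
    )
    return seq, ft, po


@pytest.fixture(scope="session")
def condition_model(task_pairs, token_vocab):
    return R.fit_task_model(
        task_pairs["cond"], token_vocab, seed=3, steps=R.COND_STEPS,
        config=R.grammar_model_config(R.COND_STEPS),
    )


# -- tiny memorized models for planner unit tests ---------------------------


@pytest.fixture(scope="session")
def memorized(spec, cond_vocab):
    """A 40-record dataset and three models that have memorized it."""
    ds = G.generate_dataset(spec, 40, seed=21)
    fwd_pairs = R.build_task_pairs(ds, "forward", cond_vocab)
    retro_pairs = R.build_task_pairs(ds, "retro")
    cond_pairs = R.build_task_pairs(ds, "condition", cond_vocab)
    vocab = R.shared_token_vocab(fwd_pairs, retro_pairs, cond_pairs)
    cfg = R.grammar_model_config(600)
    models = {
        "dataset": ds,
        "fwd": R.fit_task_model(fwd_pairs, vocab, seed=1, steps=600, config=cfg),
        "retro": R.fit_task_model(retro_pairs, vocab, seed=2, steps=600, config=cfg),
        "cond": R.fit_task_model(cond_pairs, vocab, seed=3, steps=600, config=cfg),
    }
    return models


def branch_records(ds):
    """Records of the condition-branched two-component template."""
    out = []
    for rec in ds.records:
        r = [m.smiles for m in rec.reactants]
        if len(r) == 2 and r[0].endswith("C(=O)O") and r[1].endswith("Br"):
            out.append(rec)
    return out
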