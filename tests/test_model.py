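"""Encoder-decoder model: gradients, training contracts, decoding, transfer."""

import numpy as np
import pytest

from photocat._transformer import Transformer, label_smoothed_loss
from photocat.model import (
    ModelConfig,
    TrainingMixture,
    beam_decode,
    extract_attention,
    greedy_decode_batch,
    init_model,
    load_checkpoint,
    noam_learning_rate,
    sample_mixture,
    save_checkpoint,
    staged_fit,
    train,
    train_mixture,
    CheckpointError,
)
from photocat.tokenization import SourceTarget, TokenVocab


def toy_pairs(n=50, seed=2, lo=5, hi=15):
    rng = np.random.default_rng(seed)
    alpha = list("CNOS") + ["Cl", "Br", "(", ")", "=", "1", "2"]
    pairs = []
    for _ in range(n):
        ln = int(rng.integers(lo, hi))
        src = tuple(rng.choice(alpha, ln))
        tgt = tuple(rng.choice(alpha, ln))
        pairs.append(SourceTarget(src, tgt, "forward"))
    return pairs


@pytest.fixture(scope="module")
def memorizing_state():
    """Tiny model trained to memorize 50 random pairs (the sanity contract)."""
    pairs = toy_pairs()
    vocab = TokenVocab.from_pairs(pairs)
    state = init_model(ModelConfig.tiny(), vocab, 0)
    train(state, pairs, 500, 1)
    return state, pairs


class TestGradients:
    @pytest.mark.parametrize("pre_norm,tie", [(True, True), (False, False)])
    def test_backward_matches_finite_differences(self, pre_norm, tie):
        rng = np.random.default_rng(0)
        net = Transformer(
            rng, vocab_size=11, dim=8, n_heads=2, n_encoder_layers=1,
            n_decoder_layers=1, ffn_dim=16, dropout=0.0, max_len=16,
            pre_norm=pre_norm, tie_embedding=tie,
        )
        src = np.array([[4, 5, 6, 1], [7, 8, 1, 1]])
        tgt_in = np.array([[2, 4, 5], [2, 6, 1]])
        tgt_out = np.array([[4, 5, 3], [6, 3, 1]])

        def loss_fn():
            logits = net.forward(src, tgt_in, pad_id=1, train=False)
            return label_smoothed_loss(logits, tgt_out, 1, 0.1)

        _, d = loss_fn()
        net.zero_grads()
        net.backward(d)
        rs = np.random.default_rng(1)
        for p in net.params():
            flat = p.v.ravel()
            for i in rs.choice(flat.size, size=min(3, flat.size), replace=False):
                eps, old = 1e-3, flat[i]
                flat[i] = old + eps
                lp, _ = loss_fn()
                flat[i] = old - eps
                lm, _ = loss_fn()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                ana = p.g.ravel()[i]
                assert abs(num - ana) <= 2e-3 * max(1.0, abs(num), abs(ana))


class TestLoss:
    def test_label_smoothing_zero_reduces_to_cross_entropy(self):
        # hand-computed 3-class case: logits (1, 2, 0.5), gold class 1
        logits = np.array([[[1.0, 2.0, 0.5]]])
        tgt = np.array([[1]])
        loss0, _ = label_smoothed_loss(logits, tgt, pad_id=-1, epsilon=0.0)
        assert loss0 == pytest.approx(0.46443, abs=1e-4)
        loss1, _ = label_smoothed_loss(logits, tgt, pad_id=-1, epsilon=0.1)
        assert loss1 == pytest.approx(0.54776, abs=1e-4)

    def test_pad_positions_excluded(self):
        logits = np.zeros((1, 2, 4))
        tgt = np.array([[2, 1]])  # second position is pad
        loss, grad = label_smoothed_loss(logits, tgt, pad_id=1, epsilon=0.0)
        assert loss == pytest.approx(np.log(4.0))
        assert np.all(grad[0, 1] == 0.0)


class TestNoamSchedule:
    def test_peak_at_warmup_where_branches_meet(self):
        dim, warmup, factor = 64, 300, 1.0
        peak = noam_learning_rate(warmup, dim, warmup, factor)
        closed_form = factor * dim ** -0.5 * warmup ** -0.5
        assert peak == pytest.approx(closed_form)
        # both min() branches agree exactly at the peak
        assert warmup * warmup ** -1.5 == pytest.approx(warmup ** -0.5)

    def test_increases_before_and_decays_after_warmup(self):
        rates = [noam_learning_rate(s, 64, 100, 1.0) for s in range(1, 301)]
        assert all(a < b for a, b in zip(rates[:99], rates[1:100]))
        assert all(a > b for a, b in zip(rates[100:-1], rates[101:]))
        assert noam_learning_rate(10_000_000, 64, 100, 1.0) < 1e-4

    def test_step_zero_is_a_domain_error(self):
        with pytest.raises(ValueError):
            noam_learning_rate(0, 64, 100, 1.0)


class TestMixture:
    def test_nine_to_one_frequency_within_three_sigma(self):
        mix = TrainingMixture((("a",), ("b",)), (9.0, 1.0))
        rng = np.random.default_rng(0)
        n = 10_000
        draws = sum(sample_mixture(mix, rng) == 0 for _ in range(n))
        sigma = np.sqrt(0.9 * 0.1 / n)
        assert abs(draws / n - 0.9) <= 3 * sigma

    def test_single_dataset_always_selected(self):
        mix = TrainingMixture((("a",),), (3.0,))
        rng = np.random.default_rng(1)
        assert all(sample_mixture(mix, rng) == 0 for _ in range(100))

    def test_equal_weights_are_symmetric(self):
        mix = TrainingMixture((("a",), ("b",)), (1.0, 1.0))
        rng = np.random.default_rng(2)
        n = 10_000
        frac = sum(sample_mixture(mix, rng) == 0 for _ in range(n)) / n
        assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / n)

    def test_non_positive_weight_rejected(self):
        with pytest.raises(ValueError):
            TrainingMixture((("a",), ("b",)), (9.0, 0.0))


class TestInit:
    def test_same_seed_gives_identical_parameters(self):
        vocab = TokenVocab(["C", "O"])
        cfg = ModelConfig.tiny()
        a = init_model(cfg, vocab, 7)
        b = init_model(cfg, vocab, 7)
        for pa, pb in zip(a.net.params(), b.net.params()):
            assert np.array_equal(pa.v, pb.v)

    def test_full_scale_config_accepted(self):
        cfg = ModelConfig.full_scale()
        assert cfg.model_dim == 512
        assert cfg.n_encoder_layers == cfg.n_decoder_layers == 6
        assert cfg.adam_beta2 == 0.998 and cfg.label_smoothing == 0.1
        assert cfg.batch_tokens == 4096 and cfg.grad_accumulation == 8
        assert cfg.max_grad_norm == 0.0 and cfg.lr_factor == 2.0

    def test_heads_must_divide_dim(self):
        with pytest.raises(ValueError):
            ModelConfig(model_dim=512, n_heads=7)


class TestTraining:
    def test_memorization_contract(self, memorizing_state):
        state, pairs = memorizing_state
        # loss halves well within 200 steps
        assert min(state.loss_history[:200]) < 0.5 * state.loss_history[0]
        outs = greedy_decode_batch(state, [p.source for p in pairs])
        acc = np.mean([tuple(o) == p.target for o, p in zip(outs, pairs)])
        assert acc >= 0.98

    def test_zero_steps_leaves_state_unchanged(self):
        pairs = toy_pairs(5)
        vocab = TokenVocab.from_pairs(pairs)
        state = init_model(ModelConfig.tiny(), vocab, 0)
        before = [p.v.copy() for p in state.net.params()]
        train(state, pairs, 0, 1)
        for b, p in zip(before, state.net.params()):
            assert np.array_equal(b, p.v)

    def test_fixed_seed_reproduces_loss_trace(self):
        pairs = toy_pairs(20)
        vocab = TokenVocab.from_pairs(pairs)
        runs = []
        for _ in range(2):
            state = init_model(ModelConfig.tiny(), vocab, 3)
            train(state, pairs, 30, 11)
            runs.append(state.loss_history)
        assert runs[0] == runs[1]

    def test_out_of_vocabulary_token_rejected(self):
        pairs = toy_pairs(5)
        vocab = TokenVocab.from_pairs(pairs[:1])
        state = init_model(ModelConfig.tiny(), vocab, 0)
        with pytest.raises(ValueError):
            train(state, [SourceTarget(("Zz",), ("Zz",), "forward")], 1, 1)

    def test_empty_stream_rejected(self):
        vocab = TokenVocab(["C"])
        state = init_model(ModelConfig.tiny(), vocab, 0)
        with pytest.raises(ValueError):
            train(state, [], 5, 1)


class TestStagedFit:
    def test_single_stream_baselines_are_valid_degenerate_calls(self):
        pairs = toy_pairs(10)
        vocab = TokenVocab.from_pairs(pairs)
        ft_only = staged_fit(None, pairs, ModelConfig.tiny(), "sequential",
                             rng=0, finetune_steps=5, vocab=vocab)
        pre_only = staged_fit(pairs, None, ModelConfig.tiny(), "sequential",
                              rng=0, pretrain_steps=5, vocab=vocab)
        assert ft_only.step == 5 and pre_only.step == 5

    def test_convex_mixture_consumes_streams_in_proportion(self):
        a, b = toy_pairs(30, seed=1), toy_pairs(30, seed=2)
        vocab = TokenVocab.from_pairs(a + b)
        state = staged_fit(a, b, ModelConfig.tiny(), "convex_mixture", rng=0,
                           pretrain_steps=150, finetune_steps=50, vocab=vocab)
        counts = state.meta["mixture_counts"]
        frac = counts[0] / sum(counts)
        sigma = np.sqrt(0.9 * 0.1 / sum(counts))
        assert abs(frac - 0.9) <= 4 * sigma

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            staged_fit(toy_pairs(3), None, ModelConfig.tiny(), "interleave", rng=0)


class TestDecoding:
    def test_beam_is_deterministic_and_unique(self, memorizing_state):
        state, pairs = memorizing_state
        r1 = beam_decode(state, pairs[0].source, 5)
        r2 = beam_decode(state, pairs[0].source, 5)
        assert [c.text for c in r1.candidates] == [c.text for c in r2.candidates]
        texts = [c.text for c in r1.candidates]
        assert len(texts) == len(set(texts))
        lps = [c.log_prob for c in r1.candidates]
        assert lps == sorted(lps, reverse=True)

    def test_beam_one_equals_greedy(self, memorizing_state):
        state, pairs = memorizing_state
        for p in pairs[:10]:
            beam = beam_decode(state, p.source, 1)
            greedy = greedy_decode_batch(state, [p.source])[0]
            assert beam.candidates[0].tokens == tuple(greedy)

    def test_memorized_pair_ranks_first(self, memorizing_state):
        state, pairs = memorizing_state
        hits = 0
        for p in pairs[:20]:
            r = beam_decode(state, p.source, 3)
            hits += r.candidates[0].tokens == p.target
        assert hits >= 19

    def test_validity_flag_reflects_canonicalizability(self, memorizing_state):
        state, _ = memorizing_state
        r = beam_decode(state, ("C", "C", "O"), 3)
        for c in r.candidates:
            from photocat.records import canonical_components, ChemistryParseError

            try:
                canonical_components(c.text)
                valid = True
            except ChemistryParseError:
                valid = False
            assert c.is_valid == valid

    def test_empty_source_rejected(self, memorizing_state):
        state, _ = memorizing_state
        with pytest.raises(ValueError):
            beam_decode(state, (), 3)


class TestAttention:
    def test_rows_sum_to_one_and_shape(self, memorizing_state):
        state, pairs = memorizing_state
        p = pairs[0]
        att = extract_attention(state, p.source, p.target)
        assert att.shape == (len(p.target), len(p.source))
        assert np.allclose(att.sum(axis=1), 1.0, atol=1e-6)

    def test_random_model_rows_also_normalized(self):
        vocab = TokenVocab(["C", "O", "N"])
        state = init_model(ModelConfig.tiny(), vocab, 9)
        att = extract_attention(state, ("C", "O", "N", "C"), ("O", "C"))
        assert att.shape == (2, 4)
        assert np.allclose(att.sum(axis=1), 1.0, atol=1e-6)


class TestCheckpoints:
    def test_round_trip_preserves_predictions(self, memorizing_state, tmp_path):
        state, pairs = memorizing_state
        path = tmp_path / "model.npz"
        save_checkpoint(state, path)
        back = load_checkpoint(path, expected_vocab=state.vocab)
        a = beam_decode(state, pairs[0].source, 2)
        b = beam_decode(back, pairs[0].source, 2)
        assert [c.text for c in a.candidates] == [c.text for c in b.candidates]
        assert back.step == state.step

    def test_vocabulary_hash_mismatch_refused(self, memorizing_state, tmp_path):
        state, _ = memorizing_state
        path = tmp_path / "model.npz"
        save_checkpoint(state, path)
        other = TokenVocab(["C", "O", "completely", "different"])
        with pytest.raises(CheckpointError):
            load_checkpoint(path, expected_vocab=other)
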