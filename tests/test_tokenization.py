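"""SMILES tokenization, task sequence construction, and augmentation."""

import re

import numpy as np
import pytest

from photocat import grammar as G
from photocat.records import canonicalize
from photocat.tokenization import (
    AugmentationParams,
    MissingConditionsError,
    SourceTarget,
    TokenVocab,
    TokenizationError,
    augment_pair,
    build_condition_target,
    build_forward_source,
    build_retro_source,
    detokenize,
    randomize_smiles,
    span_mask,
    tokenize_smiles,
)

# independent oracle: the community reaction-tokenizer regex, restated here
ORACLE_RE = re.compile(
    r"(\[[^\]]+]|Br?|Cl?|N|O|S|P|F|I|b|c|n|o|s|p|\(|\)|\.|=|#|-|\+|\\|\/|:"
    r"|~|@|\?|>>?|\*|\$|%[0-9]{2}|[0-9])"
)


def oracle_tokens(s):
    return [t for t in ORACLE_RE.findall(s)]


def sample_molecules(n, seed=0):
    spec = G.default_spec()
    rng = np.random.default_rng(seed)
    return [G.sample_molecule(spec, rng).smiles for _ in range(n)]


class TestTokenizer:
    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("C", ["C"]),
            ("Brc1ccccc1", ["Br", "c", "1", "c", "c", "c", "c", "c", "1"]),
            ("C[O-]", ["C", "[O-]"]),
            ("CCl", ["C", "Cl"]),
            ("C%12CC%12", ["C", "%12", "C", "C", "%12"]),
            ("F/C=C/F", ["F", "/", "C", "=", "C", "/", "F"]),
            ("C[C@H](N)O", ["C", "[C@H]", "(", "N", ")", "O"]),
        ],
    )
    def test_token_examples(self, smiles, expected):
        assert tokenize_smiles(smiles) == expected

    def test_error_reports_position(self):
        with pytest.raises(TokenizationError) as exc:
            tokenize_smiles("CC&O")
        assert "position 2" in str(exc.value)

    def test_detokenize_examples(self):
        assert detokenize(["C", "C", "O"]) == "CCO"
        assert detokenize([]) == ""

    def test_round_trip_and_oracle_agreement_on_fuzz(self):
        mols = sample_molecules(300, seed=3)
        for smi in mols:
            toks = tokenize_smiles(smi)
            assert detokenize(toks) == smi
            assert toks == oracle_tokens(smi)
            canonical = canonicalize(smi).smiles
            assert detokenize(tokenize_smiles(canonical)) == canonical


class TestTaskSequences:
    def test_forward_source_without_conditions(self, small_dataset, cond_vocab):
        rec = small_dataset.records[0]
        st = build_forward_source(rec, cond_vocab, 0)
        assert st.task == "forward"
        assert not any(t[0] in "PBAWS" and t[1:].isdigit() for t in st.source)

    def test_forward_condition_order_and_prefix_superset(self, small_dataset, cond_vocab):
        rec = small_dataset.records[0]
        seqs = [build_forward_source(rec, cond_vocab, n).source for n in range(6)]
        for n in range(5):
            assert seqs[n] == seqs[n + 1][: len(seqs[n])]  # prefix-wise superset
        tail = seqs[5][-5:]
        assert [t[0] for t in tail] == ["P", "B", "A", "W", "S"]

    def test_forward_needs_conditions_when_requested(self, spec, cond_vocab):
        pre = G.generate_pretrain_corpus(spec, 3, seed=0)
        with pytest.raises(MissingConditionsError):
            build_forward_source(pre.records[0], cond_vocab, 2)

    def test_condition_tokens_are_atomic(self, small_dataset, cond_vocab):
        st = build_forward_source(small_dataset.records[1], cond_vocab, 5)
        cond_tokens = st.source[-5:]
        assert all(len(t) >= 2 and t[1:].isdigit() for t in cond_tokens)

    def test_retro_inverts_forward_and_carries_no_conditions(
        self, small_dataset
    ):
        rec = small_dataset.records[2]
        st = build_retro_source(rec)
        assert detokenize(st.source) == rec.products[0].smiles
        assert detokenize(st.target) == ".".join(m.smiles for m in rec.reactants)
        assert not any(t[0] in "PBAWS" and t[1:].isdigit() for t in st.source)

    def test_condition_target_is_five_tokens(self, small_dataset, cond_vocab):
        for rec in small_dataset.records[:20]:
            st = build_condition_target(rec, cond_vocab)
            assert len(st.target) == 5
            assert ">>" in st.source

    def test_solvent_swap_changes_only_last_position(self, small_dataset, cond_vocab):
        from dataclasses import replace as drep

        rec = small_dataset.records[0]
        other = "DMSO" if rec.conditions.solvent != "DMSO" else "MeCN"
        rec2 = drep(rec, conditions=drep(rec.conditions, solvent=other))
        t1 = build_condition_target(rec, cond_vocab).target
        t2 = build_condition_target(rec2, cond_vocab).target
        assert t1[:4] == t2[:4] and t1[4] != t2[4]


class TestAugmentation:
    def test_randomize_preserves_canonical_identity(self):
        rng = np.random.default_rng(0)
        for smi in sample_molecules(200, seed=5):
            out = randomize_smiles(smi, rng)
            assert canonicalize(out).smiles == canonicalize(smi).smiles

    def test_randomize_single_atom_and_determinism(self):
        assert randomize_smiles("C", np.random.default_rng(0)) == "C"
        a = randomize_smiles("CCOCC(C)C", np.random.default_rng(42))
        b = randomize_smiles("CCOCC(C)C", np.random.default_rng(42))
        assert a == b

    def test_span_mask_identity_at_zero_probability(self):
        params = AugmentationParams(apply_probability=0.0)
        toks = ["C", "C", "O"]
        assert span_mask(toks, np.random.default_rng(0), params) == toks

    def test_span_mask_replaces_contiguous_span(self):
        params = AugmentationParams(apply_probability=1.0, span_length_range=(2, 2))
        rng = np.random.default_rng(1)
        out = span_mask(list("CCOCC"), rng, params)
        assert out.count("<MASK>") == 1
        assert len(out) == 4  # two tokens collapsed into one mask

    def test_span_mask_clamps_at_sequence_end(self):
        params = AugmentationParams(apply_probability=1.0, span_length_range=(10, 10))
        out = span_mask(["C", "C"], np.random.default_rng(0), params)
        assert "<MASK>" in out and len(out) <= 2

    def test_masked_fraction_matches_expectation(self):
        # Monte-Carlo: with p=0.5 and span 2 on length-10 inputs, the expected
        # number of masked-out tokens per sample is p * E[span | clamped]
        params = AugmentationParams(apply_probability=0.5, span_length_range=(2, 2))
        rng = np.random.default_rng(7)
        n, length, removed = 10_000, 10, 0
        for _ in range(n):
            out = span_mask(["C"] * length, rng, params)
            removed += length - (len(out) - out.count("<MASK>"))
        # spans starting at the last position clamp to 1 token: E = .5*(2*9+1)/10
        expected = 0.5 * (2 * 9 + 1) / 10
        assert abs(removed / n - expected) < 0.05

    def test_augment_pair_leaves_conditions_and_target_alone(
        self, small_dataset, cond_vocab
    ):
        pair = build_forward_source(small_dataset.records[0], cond_vocab, 5)
        rng = np.random.default_rng(3)
        params = AugmentationParams(apply_probability=1.0, span_length_range=(1, 1))
        out = augment_pair(pair, rng, params)
        assert out.target == pair.target
        assert out.source[-5:] == pair.source[-5:] or "<MASK>" in out.source


class TestTokenVocab:
    def test_reserved_ids(self):
        vocab = TokenVocab(["C", "O"])
        assert vocab.mask_id == 0 and vocab.pad_id == 1
        assert vocab.bos_id == 2 and vocab.eos_id == 3
        assert vocab.id_of("C") == 4

    def test_save_load_round_trip(self, tmp_path):
        vocab = TokenVocab(["C", "O", "B31"])
        path = tmp_path / "vocab.txt"
        vocab.save(path)
        back = TokenVocab.load(path)
        assert back.content_hash() == vocab.content_hash()
        assert back.id_of("B31") == vocab.id_of("B31")

    def test_load_rejects_missing_specials(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("C\nO\n")
        with pytest.raises(ValueError):
            TokenVocab.load(path)

    def test_encode_decode(self):
        vocab = TokenVocab(["C", "O"])
        ids = vocab.encode(["C", "O", "C"])
        assert vocab.decode(ids) == ["C", "O", "C"]
        with pytest.raises(KeyError):
            vocab.id_of("N")
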