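"""Reaction record model, condition vocabulary, and dataset I/O."""

import math

import numpy as np
import pytest

from photocat import records as R
from photocat.records import (
    CATEGORIES,
    ChemistryParseError,
    ConditionNames,
    ConditionSet,
    ConditionToken,
    ConditionVocabulary,
    DatasetFormatError,
    Molecule,
    ReactionRecord,
    ReactionFormatError,
    UnknownReagentError,
    build_vocabulary,
    canonicalize,
    dataset_stats,
    decode_conditions,
    encode_conditions,
    normalize_condition_name,
    parse_condition_token,
    parse_reaction,
    read_dataset,
    render_reaction,
    write_dataset,
)


class TestCanonicalize:
    def test_single_atom_already_canonical(self):
        assert canonicalize("C").smiles == "C"

    def test_matches_toolkit_canonical_form(self):
        # independent oracle: RDKit called directly
        from rdkit import Chem

        expected = Chem.MolToSmiles(Chem.MolFromSmiles("OCC"))
        assert canonicalize("OCC").smiles == expected == "CCO"

    @pytest.mark.parametrize("smiles", ["C(", "X@@Y", "c1ccccc"])
    def test_unparsable_raises_naming_input(self, smiles):
        with pytest.raises(ChemistryParseError) as exc:
            canonicalize(smiles)
        assert smiles in str(exc.value)

    def test_empty_input_rejected(self):
        with pytest.raises(ChemistryParseError):
            canonicalize("")

    def test_idempotent_on_grammar_fuzz(self, small_dataset):
        for rec in small_dataset.records[:100]:
            for mol in (*rec.reactants, *rec.products):
                once = canonicalize(mol.smiles).smiles
                assert canonicalize(once).smiles == once


class TestParseReaction:
    def test_splits_components_in_order(self):
        assert parse_reaction("CC(=O)O.OCC>>CC(=O)OCC") == (
            ["CC(=O)O", "OCC"],
            ["CC(=O)OCC"],
        )

    def test_guillemet_separator_dialect(self):
        assert parse_reaction("A»B") == (["A"], ["B"])

    @pytest.mark.parametrize(
        "bad", ["CCO", "A>>B>>C", "A»B»C", ">>B", "A>>", "A..B>>C"]
    )
    def test_format_errors(self, bad):
        with pytest.raises(ReactionFormatError):
            parse_reaction(bad)

    def test_render_parse_round_trip(self, small_dataset):
        for rec in small_dataset.records[:50]:
            reactants = [m.smiles for m in rec.reactants]
            products = [m.smiles for m in rec.products]
            assert parse_reaction(render_reaction(reactants, products)) == (
                reactants,
                products,
            )


class TestConditionTokens:
    def test_rendering_round_trip(self):
        tok = ConditionToken("base_or_acid", 31)
        assert tok.token == "B31"
        assert parse_condition_token("B31") == tok

    def test_all_prefixes_unique_and_mapped(self):
        prefixes = [R.CATEGORY_PREFIXES[c] for c in CATEGORIES]
        assert prefixes == ["P", "B", "A", "W", "S"]
        assert len(set(prefixes)) == 5

    @pytest.mark.parametrize("bad", ["", "X3", "B", "B3x", "31"])
    def test_parse_rejects_non_tokens(self, bad):
        with pytest.raises(ValueError):
            parse_condition_token(bad)

    def test_index_zero_means_none_when_decoded(self):
        vocab = ConditionVocabulary()
        tok = ConditionToken("base_or_acid", 0)
        assert vocab.decode_token(tok) is None


class TestVocabulary:
    def test_empty_records_give_none_only_entries(self):
        vocab = build_vocabulary([])
        for cat in CATEGORIES:
            assert vocab.names(cat) == ["None"]

    def test_first_appearance_indexing(self):
        recs = [
            ReactionRecord.from_smiles(
                "CC>>CC", ConditionNames(base_or_acid=None), validate=False
            ),
            ReactionRecord.from_smiles(
                "CC>>CC", ConditionNames(base_or_acid="TfOH"), validate=False
            ),
        ]
        vocab = build_vocabulary(recs)
        assert vocab.names("base_or_acid") == ["None", "TfOH"]
        assert vocab.index_of("base_or_acid", "TfOH") == 1

    def test_photocatalyst_corpus_count_includes_none(self):
        # a 59-name photocatalyst corpus yields 60 entries with "None"
        recs = [
            ReactionRecord.from_smiles(
                "CC>>CC", ConditionNames(photocatalyst=f"PC-{i}"), validate=False
            )
            for i in range(59)
        ]
        vocab = build_vocabulary(recs)
        assert vocab.size("photocatalyst") == 60

    def test_autocatalysis_is_a_valid_photocatalyst_label(self):
        vocab = ConditionVocabulary()
        tok = vocab.add("photocatalyst", "autocatalysis")
        assert vocab.name_of("photocatalyst", tok.index) == "autocatalysis"

    def test_large_vocabulary_indexing_gives_b31_for_tfoh(self):
        # with 30 other names registered first, TfOH lands at B31
        vocab = ConditionVocabulary()
        for i in range(30):
            vocab.add("base_or_acid", f"base-{i}")
        tok = vocab.add("base_or_acid", "TfOH")
        assert tok.token == "B31"


class TestNormalization:
    @pytest.fixture()
    def vocab(self):
        vocab = ConditionVocabulary(R.default_synonyms())
        vocab.add("base_or_acid", "TfOH")
        return vocab

    def test_synonym_dictionary_resolution(self, vocab):
        assert normalize_condition_name("trifluoromethanesulfonic acid", vocab) == "TfOH"

    def test_case_and_whitespace_insensitive(self, vocab):
        assert normalize_condition_name("tfoh", vocab) == "TfOH"
        assert normalize_condition_name("  Tf OH ", vocab) == "TfOH"

    def test_unknown_name_lists_categories(self, vocab):
        with pytest.raises(UnknownReagentError) as exc:
            normalize_condition_name("unobtainium chloride", vocab, "base_or_acid")
        assert "base_or_acid" in str(exc.value)


class TestEncodeDecode:
    def test_tfoh_token_and_none_token(self):
        vocab = ConditionVocabulary()
        for i in range(30):
            vocab.add("base_or_acid", f"base-{i}")
        vocab.add("base_or_acid", "TfOH")
        cs = encode_conditions(ConditionNames(base_or_acid="TfOH"), vocab)
        assert cs.get("base_or_acid").token == "B31"
        cs0 = encode_conditions(ConditionNames(), vocab)
        assert cs0.token_strings() == ["P0", "B0", "A0", "W0", "S0"]

    def test_round_trip_on_generated_vocabulary(self, small_dataset, cond_vocab):
        for rec in small_dataset.records[:60]:
            cs = encode_conditions(rec.conditions, cond_vocab)
            assert decode_conditions(cs, cond_vocab) == rec.conditions

    def test_out_of_vocabulary_name_rejected(self):
        vocab = ConditionVocabulary()
        with pytest.raises(UnknownReagentError):
            encode_conditions(ConditionNames(solvent="xenon ice"), vocab)

    def test_condition_set_requires_all_five_categories(self):
        with pytest.raises(ValueError):
            ConditionSet((ConditionToken("photocatalyst", 1),))


class TestDatasetIO:
    def test_write_read_identity_jsonl_and_tsv(self, tmp_path, small_dataset):
        recs = small_dataset.records[:10]
        for fmt, name in (("jsonl", "d.jsonl"), ("delimited", "d.tsv")):
            path = tmp_path / name
            write_dataset(recs, path, format=fmt)
            back = read_dataset(path, format=fmt)
            assert back == recs

    def test_condition_free_records_round_trip_as_null(self, tmp_path):
        rec = ReactionRecord.from_smiles("CC.OCC>>CCOCC", conditions=None)
        path = tmp_path / "x.jsonl"
        write_dataset([rec], path)
        assert read_dataset(path)[0].conditions is None

    def test_bad_smiles_reports_line_number(self, tmp_path, small_dataset):
        path = tmp_path / "d.jsonl"
        write_dataset(small_dataset.records[:5], path)
        lines = path.read_text().splitlines()
        import json

        row = json.loads(lines[2])
        row["reaction"] = "C(.X>>CC"
        lines[2] = json.dumps(row)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(DatasetFormatError) as exc:
            read_dataset(path)
        assert "line 3" in str(exc.value)

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "e.jsonl"
        path.write_text("")
        assert read_dataset(path) == []

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_dataset([], tmp_path / "x", format="parquet")


class TestDatasetStats:
    def test_component_counts(self):
        recs = [
            ReactionRecord.from_smiles("CC.CC>>CCCC", validate=False),
            ReactionRecord.from_smiles("C.C.C>>CCC", validate=False),
        ]
        st = dataset_stats(recs)
        assert st.n_total == 2
        assert st.n_multicomponent == 1
        assert st.n_three_component == 1
        assert st.n_four_component == 0

    def test_distinct_names_exclude_none(self):
        recs = [
            ReactionRecord.from_smiles(
                "CC>>CC",
                ConditionNames(photocatalyst="Eosin Y", solvent="DMSO"),
                validate=False,
            ),
            ReactionRecord.from_smiles(
                "CC>>CC", ConditionNames(photocatalyst="Eosin Y"), validate=False
            ),
        ]
        st = dataset_stats(recs)
        assert st.distinct_names["photocatalyst"] == 1
        assert st.distinct_names["additive"] == 0
        assert st.n_with_conditions == 2

    def test_count_identities_on_random_dataset(self, small_dataset):
        st = dataset_stats(small_dataset.records)
        assert st.n_three_component + st.n_four_component <= st.n_multicomponent
        assert st.n_multicomponent <= st.n_total
        assert st.n_with_conditions == st.n_total
        assert 0.0 <= st.multicomponent_fraction <= 1.0
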