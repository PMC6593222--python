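import numpy as np
import pytest
from hypothesis import given, strategies as st

from biomdex import metadata as md
from biomdex.kvstore import MemoryStore
from biomdex.metadata import MetadataError
from biomdex.where import (
    And,
    Comparison,
    Or,
    WhereEvaluationError,
    WhereSyntaxError,
    parse_where,
)

from oracles import (
    bf_stem_index,
    bf_stored_metadata,
    bf_where,
    random_clause,
    random_dataset,
    random_fulltext,
    render_clause,
    dataset_to_inputs,
)

TOY = [
    "#SampleID\tph\tempo_3\tdescription",
    "S1\t6.5\tSoil (non-saline)\tagricultural soil with antibiotics",
    "S2\t\tAnimal distal gut\tmouse fecal sample",
    "S3\t8.1\tSoil (saline)\tsaline soil crust",
    "S4\t7.0\tSoil (non-saline)\tantibiotic treatment study",
]


class TestIngest:
    def test_missing_values_dropped_and_counted(self, store):
        summary = md.ingest_metadata(store, TOY)
        assert summary.samples == 4
        assert summary.variables == 3
        assert summary.values_dropped_missing == 1
        assert md.get_record(store, "S2", ["ph"]) == {"ph": None}
        assert md.get_record(store, "S1", ["ph"]) == {"ph": "6.5"}

    def test_reingest_identical_table_is_idempotent(self, store, tmp_path):
        md.ingest_metadata(store, TOY)
        before = tmp_path / "before.db"
        store.save(before)
        md.ingest_metadata(store, TOY)
        after = tmp_path / "after.db"
        store.save(after)
        assert before.read_bytes() == after.read_bytes()

    def test_duplicate_sample_rejected(self, store):
        with pytest.raises(MetadataError, match="duplicate"):
            md.ingest_metadata(store, ["#SampleID\tph", "S1\t1", "S1\t2"])

    def test_ragged_row_rejected_with_line_number(self, store):
        with pytest.raises(MetadataError, match="line 3"):
            md.ingest_metadata(store, ["#SampleID\tph", "S1\t1", "S2"])

    @pytest.mark.parametrize("marker", [
        "NA", "n/a", "NaN", "None", "unknown", "Not Applicable",
        "Missing: not provided", "",
    ])
    def test_missing_marker_vocabulary(self, marker):
        assert md.is_missing(marker)

    def test_stem_index_matches_brute_force_rebuild(self, rng):
        _, metadata, _ = random_dataset(rng, n_contexts=1)
        _, lines, _ = dataset_to_inputs({}, metadata, {})
        store = MemoryStore()
        md.ingest_metadata(store, lines)
        expected = bf_stem_index(metadata)
        for stem, samples in expected.items():
            assert md.stem_samples(store, stem) == samples
        # per-variable sub-indices union to the global index
        for stem in expected:
            union = set()
            for variable in md.metadata_variables(store):
                union |= md.stem_samples(store, stem, variable)
            assert union == expected[stem]


class TestStemText:
    @pytest.mark.parametrize("value,expected", [
        ("Antibiotics", ["antibiot"]),
        ("Soil (non-saline)", ["soil", "non", "salin"]),
        ("pH 7", ["ph"]),
        ("", []),
        ("42 13", []),
        ("a I x", []),  # single-letter tokens dropped
        ("soil soil SOIL", ["soil"]),
    ])
    def test_tokenizer_and_stemming_rules(self, value, expected):
        assert md.stem_text(value) == expected


class TestFulltext:
    @pytest.fixture
    def indexed(self, store):
        md.ingest_metadata(store, TOY)
        return store

    def test_single_term_matches_any_inflection(self, indexed):
        # S1 says "antibiotics", S4 says "antibiotic": same stem
        assert md.search_fulltext(indexed, "antibiotics") == {"S1", "S4"}
        assert md.search_fulltext(indexed, "antibiotic") == {"S1", "S4"}

    def test_difference_and_intersection(self, indexed):
        # note "Soil (non-saline)" itself carries the salin stem, so the
        # discriminating terms here are crust/antibiotics
        assert md.search_fulltext(indexed, "soil - antibiotics") == {"S3"}
        assert md.search_fulltext(indexed, "soil & crust") == {"S3"}
        assert md.search_fulltext(indexed, "soil & (crust | antibiotics)") \
            == {"S1", "S3", "S4"}

    def test_phrase_intersects_all_stems(self, indexed):
        assert md.search_fulltext(indexed, "'saline soil crust'") == {"S3"}

    def test_variable_restriction(self, indexed):
        assert md.search_fulltext(indexed, "saline",
                                  variable="description") == {"S3"}
        # empo_3 values also contain the stem
        assert "S1" in md.search_fulltext(indexed, "saline",
                                          variable="empo_3")

    def test_unknown_stem_is_empty(self, indexed):
        assert md.search_fulltext(indexed, "zebrafish") == set()

    def test_syntax_error_carries_position(self, indexed):
        with pytest.raises(MetadataError, match="position"):
            md.search_fulltext(indexed, "soil & ")
        with pytest.raises(MetadataError, match="position"):
            md.search_fulltext(indexed, "soil )")

    def test_random_expressions_match_brute_force(self, rng):
        _, metadata, _ = random_dataset(rng)
        _, lines, _ = dataset_to_inputs({}, metadata, {})
        store = MemoryStore()
        md.ingest_metadata(store, lines)
        index = bf_stem_index(metadata)
        for _ in range(200):
            text, evaluate = random_fulltext(rng)
            assert md.search_fulltext(store, text) == evaluate(index), text


class TestWhereClause:
    def test_numeric_filter_excludes_missing(self, store):
        md.ingest_metadata(store, TOY)
        assert md.evaluate_where(store, "ph < 7") == {"S1"}
        assert md.evaluate_where(store, "ph >= 7") == {"S3", "S4"}

    def test_fig_style_conjunction(self, store):
        md.ingest_metadata(store, TOY)
        got = md.evaluate_where(
            store, "empo_3=='Soil (non-saline)' and ph > 0")
        assert got == {"S1", "S4"}

    def test_contradiction_is_empty(self, store):
        md.ingest_metadata(store, TOY)
        assert md.evaluate_where(store, "ph < 7 and ph > 7") == set()

    def test_universe_restriction(self, store):
        md.ingest_metadata(store, TOY)
        assert md.evaluate_where(store, "ph > 0", universe={"S3"}) == {"S3"}

    def test_numeric_equality_across_formats(self, store):
        md.ingest_metadata(store, ["#SampleID\tph", "A\t7.0", "B\t7",
                                   "C\tseven"])
        assert md.evaluate_where(store, "ph == 7") == {"A", "B"}
        assert md.evaluate_where(store, "ph != 7") == {"C"}

    def test_in_and_notin(self, store):
        md.ingest_metadata(store, TOY)
        got = md.evaluate_where(
            store, "empo_3 in ('Soil (non-saline)', 'Soil (saline)')")
        assert got == {"S1", "S3", "S4"}
        got = md.evaluate_where(store, "empo_3 notin ('Soil (saline)')")
        assert got == {"S1", "S2", "S4"}

    @pytest.mark.parametrize("bad", [
        "ph <", "== 5", "ph >> 3", "ph < 7 and", "(ph < 7", "ph ~ 3",
    ])
    def test_syntax_errors_rejected_with_position(self, bad):
        with pytest.raises(WhereSyntaxError):
            parse_where(bad)

    def test_ordering_against_text_literal_is_an_error(self, store):
        md.ingest_metadata(store, TOY)
        with pytest.raises(WhereEvaluationError):
            md.evaluate_where(store, "ph < 'acidic'")

    def test_random_clauses_match_brute_force(self, rng):
        _, metadata, _ = random_dataset(rng)
        _, lines, _ = dataset_to_inputs({}, metadata, {})
        store = MemoryStore()
        md.ingest_metadata(store, lines)
        for _ in range(200):
            tree = random_clause(rng)
            text = render_clause(tree)
            assert md.evaluate_where(store, text) == bf_where(metadata, tree), \
                text

    def test_monotonicity_in_universe_and_conjuncts(self, rng):
        _, metadata, _ = random_dataset(rng)
        _, lines, _ = dataset_to_inputs({}, metadata, {})
        store = MemoryStore()
        md.ingest_metadata(store, lines)
        samples = sorted(md.metadata_samples(store))
        for _ in range(50):
            tree = random_clause(rng)
            small = set(samples[: len(samples) // 2])
            r_small = md.evaluate_where(store, tree, universe=small)
            r_full = md.evaluate_where(store, tree)
            assert r_small <= r_full
            conjunct = And(tree, random_clause(rng))
            assert md.evaluate_where(store, conjunct) <= r_full


@given(st.text(max_size=40))
def test_stem_text_total_and_lowercase(value):
    """stem_text never raises and yields deduplicated lowercase tokens."""
    stems = md.stem_text(value)
    assert len(set(stems)) == len(stems)
    for s in stems:
        assert s == s.lower()
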