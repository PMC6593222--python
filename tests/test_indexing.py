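import numpy as np
import pytest

from biomdex import indexing
from biomdex.indexing import IngestError
from biomdex.kvstore import MemoryStore

from conftest import make_table
from oracles import dataset_to_inputs, random_dataset


class TestContextLifecycle:
    def test_create_and_list(self, store):
        indexing.create_context(store, "deblur-90nt", "deblur V4 90nt")
        names = [c.name for c in indexing.list_contexts(store)]
        assert names == ["deblur-90nt"]

    def test_duplicate_and_invalid_names_rejected(self, store):
        indexing.create_context(store, "deblur-90nt")
        with pytest.raises(IngestError):
            indexing.create_context(store, "deblur-90nt")
        with pytest.raises(IngestError):
            indexing.create_context(store, "bad:name")
        with pytest.raises(IngestError):
            indexing.create_context(store, "")
        with pytest.raises(IngestError):
            indexing.create_context(store, "metadata")

    def test_protocol_partitions_coexist_independently(self, store, toy_table):
        # a denoised exact-variant context and a closed-reference context
        # hold their own data; loading one never alters the other
        indexing.create_context(store, "deblur-90nt")
        indexing.create_context(store, "closedref-97")
        indexing.load_table(store, "deblur-90nt", toy_table)
        before = indexing.feature_samples(store, "deblur-90nt", "f_a")
        other = make_table([[7]], ["OTU_1"], ["S9"])
        indexing.load_table(store, "closedref-97", other)
        assert indexing.feature_samples(store, "deblur-90nt", "f_a") == before
        assert indexing.get_context(store, "closedref-97").n_samples == 1
        assert indexing.get_context(store, "deblur-90nt").n_samples == 2


class TestIdentifierMap:
    def test_dense_first_seen_assignment(self, store):
        indexing.create_context(store, "c")
        assert indexing.map_identifiers(store, "c", ["f1", "f2", "f1"]) == \
            [0, 1, 0]

    def test_stability_across_calls_and_reverse(self, store):
        indexing.create_context(store, "c")
        indexing.map_identifiers(store, "c", ["f1", "f2"])
        assert indexing.map_identifiers(store, "c", ["f3", "f2"]) == [2, 1]
        assert indexing.resolve_identifiers(store, "c", [1]) == ["f2"]

    def test_feature_and_sample_spaces_independent(self, store):
        indexing.create_context(store, "c")
        indexing.map_identifiers(store, "c", ["x"], "feature")
        assert indexing.map_identifiers(store, "c", ["x"], "sample") == [0]

    def test_bijection_holds_after_many_interleaved_calls(self, store, rng):
        indexing.create_context(store, "c")
        seen = {}
        for _ in range(50):
            ids = [f"f{rng.integers(0, 30)}" for _ in range(5)]
            out = indexing.map_identifiers(store, "c", ids)
            for i, v in zip(ids, out):
                assert seen.setdefault(i, v) == v
        back = indexing.resolve_identifiers(store, "c", list(seen.values()))
        assert back == list(seen.keys())


class TestLoadTable:
    def test_toy_transcription_zeros_dropped(self, store, toy_table):
        indexing.create_context(store, "c")
        summary = indexing.load_table(store, "c", toy_table)
        assert (summary.samples_loaded, summary.samples_skipped) == (2, 0)
        f = dict(zip(["f_a", "f_b", "f_c"],
                     indexing.map_identifiers(store, "c",
                                              ["f_a", "f_b", "f_c"])))
        assert indexing.get_vector(store, "c", "S1") == \
            sorted([(f["f_a"], 1), (f["f_c"], 2)])
        assert indexing.get_vector(store, "c", "S2") == [(f["f_b"], 5)]
        assert indexing.feature_samples(store, "c", "f_a") == {"S1"}
        assert indexing.feature_samples(store, "c", "f_b") == {"S2"}
        assert indexing.feature_samples(store, "c", "f_c") == {"S1"}
        assert indexing.sample_features(store, "c", "S1") == {"f_a", "f_c"}

    def test_reload_is_skipped_in_full(self, store, toy_table):
        indexing.create_context(store, "c")
        indexing.load_table(store, "c", toy_table)
        snap_before = indexing.get_vector(store, "c", "S1")
        summary = indexing.load_table(store, "c", toy_table)
        assert (summary.samples_loaded, summary.samples_skipped) == (0, 2)
        assert indexing.get_vector(store, "c", "S1") == snap_before

    def test_sample_id_with_separator_rejected(self, store):
        indexing.create_context(store, "c")
        bad = make_table([[1]], ["f"], ["bad:sample"])
        with pytest.raises(IngestError):
            indexing.load_table(store, "c", bad)

    def test_unknown_context_and_bad_file_rejected(self, store, tmp_path):
        with pytest.raises(IngestError):
            indexing.load_table(store, "ghost", make_table([[1]], ["f"], ["s"]))
        indexing.create_context(store, "c")
        bogus = tmp_path / "bogus.biom"
        bogus.write_text("this is not a table")
        with pytest.raises(IngestError):
            indexing.load_table(store, "c", bogus)

    def test_negative_counts_rejected(self, store):
        indexing.create_context(store, "c")
        with pytest.raises(IngestError):
            indexing.load_table(store, "c",
                                make_table([[-1]], ["f"], ["s"]))

    def test_biom_json_file_round_trips_through_loader(self, store, toy_table,
                                                       tmp_path):
        path = tmp_path / "toy.biom"
        path.write_text(toy_table.to_json("tests"))
        indexing.create_context(store, "c")
        summary = indexing.load_table(store, "c", path)
        assert summary.samples_loaded == 2
        assert indexing.feature_samples(store, "c", "f_b") == {"S2"}


class TestIndexConsistency:
    def test_inverted_index_matches_brute_force_rebuild(self, rng):
        """50x200-scale fixture: rebuild the index by scanning vectors."""
        contexts, _, _ = random_dataset(rng, n_contexts=1, max_samples=50,
                                        max_features=200)
        raw = contexts["ctx0"]
        tables, _, _ = dataset_to_inputs(contexts, {}, {})
        store = MemoryStore()
        indexing.create_context(store, "ctx0")
        indexing.load_table(store, "ctx0", tables["ctx0"])

        rebuilt: dict[str, set[str]] = {}
        for sample in indexing.samples_represented(store, "ctx0"):
            pairs = indexing.get_vector(store, "ctx0", sample)
            feats = indexing.resolve_identifiers(
                store, "ctx0", [f for f, _ in pairs])
            assert all(c > 0 for _, c in pairs)
            for f in feats:
                rebuilt.setdefault(f, set()).add(sample)
            assert indexing.sample_features(store, "ctx0", sample) == \
                set(feats)
        for f in indexing.features_represented(store, "ctx0"):
            assert indexing.feature_samples(store, "ctx0", f) == rebuilt[f]
        # and the store agrees with the generating dicts
        expected = {}
        for s, row in raw.items():
            for f in row:
                expected.setdefault(f, set()).add(s)
        assert rebuilt == expected

    def test_conservation_of_total_counts(self, rng):
        contexts, _, _ = random_dataset(rng)
        raw = contexts["ctx0"]
        tables, _, _ = dataset_to_inputs(contexts, {}, {})
        store = MemoryStore()
        indexing.create_context(store, "ctx0")
        indexing.load_table(store, "ctx0", tables["ctx0"])
        total_stored = sum(
            c for s in indexing.samples_represented(store, "ctx0")
            for _, c in indexing.get_vector(store, "ctx0", s))
        total_raw = sum(c for row in raw.values() for c in row.values())
        assert total_stored == pytest.approx(total_raw)

    def test_load_order_invariance_of_string_level_answers(self, rng):
        contexts, _, _ = random_dataset(rng)
        tables, _, _ = dataset_to_inputs(contexts, {}, {})
        table = tables["ctx0"]
        samples = list(table.ids("sample"))
        stores = []
        for order in (samples, samples[::-1]):
            st = MemoryStore()
            indexing.create_context(st, "c")
            for sid in order:
                indexing.load_table(store=st, context="c",
                                    table=table.filter([sid], axis="sample",
                                                       inplace=False))
            stores.append(st)
        a, b = stores
        assert indexing.samples_represented(a, "c") == \
            indexing.samples_represented(b, "c")
        for f in indexing.features_represented(a, "c"):
            assert indexing.feature_samples(a, "c", f) == \
                indexing.feature_samples(b, "c", f)


class TestTaxonomy:
    def test_rank_fanout_and_sharing(self, store):
        indexing.create_context(store, "c")
        lines = [
            "f_a\tk__Bacteria; p__Firmicutes; g__Clostridium",
            "f_b\tk__Bacteria; p__Firmicutes; g__Bacillus",
        ]
        assert indexing.load_taxonomy(store, "c", lines) == 2
        assert indexing.taxon_features(store, "c", "g__Clostridium") == {"f_a"}
        assert indexing.taxon_features(store, "c", "p__Firmicutes") == \
            {"f_a", "f_b"}
        assert indexing.taxon_features(store, "c", "g__Nothing") == set()
        assert indexing.feature_lineage(store, "c", "f_a") == \
            "k__Bacteria; p__Firmicutes; g__Clostridium"

    def test_malformed_line_reports_line_number(self, store):
        indexing.create_context(store, "c")
        with pytest.raises(IngestError, match="line 2"):
            indexing.load_taxonomy(store, "c", ["f_a\tk__Bacteria",
                                                "f_b only one column"])

    def test_features_absent_from_context_still_indexed(self, store):
        indexing.create_context(store, "c")
        indexing.load_taxonomy(store, "c", ["ghost\tk__Bacteria; g__X"])
        assert indexing.taxon_features(store, "c", "g__X") == {"ghost"}
        assert indexing.feature_samples(store, "c", "ghost") == set()
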