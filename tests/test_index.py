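import numpy as np
import pytest

import fpbrowser as fb
from conftest import linear_scan


def make_query(record, space=fb.Space.MQN, mode=fb.SearchMode.MAX_COUNT,
               limit=10, **kwargs):
    return fb.SearchQuery(query_record=record, space=fb.Space(space),
                          mode=mode, limit=limit, **kwargs)


class TestBuildIndex:
    def test_distinct_sums_distinct_buckets(self):
        records = [fb.annotate(s, f"m{i}") for i, s in enumerate(["C", "CC", "CCC"])]
        idx = fb.build_index(records, fb.Space.MQN)
        assert len(idx.buckets) == 3
        assert all(len(b) == 1 for b in idx.buckets.values())

    def test_equal_sums_share_a_bucket(self):
        # constitutional isomers: identical MQN total sums are not required,
        # so use two copies of the same structure under different ids
        records = [fb.annotate("CCO", "a"), fb.annotate("CCO", "b")]
        idx = fb.build_index(records, fb.Space.MQN)
        assert len(idx.buckets) == 1
        assert idx.size == 2

    def test_size_conserved(self, library300):
        idx = fb.build_index(library300, fb.Space.SMIFP)
        assert idx.size == len(library300)

    def test_bucket_key_equals_total_sum(self, library300):
        idx = fb.build_index(library300, fb.Space.MQN)
        for key, bucket in idx.buckets.items():
            assert all(fp.total_sum == key for _, fp in bucket)

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fb.build_index([], fb.Space.MQN)


class TestBucketRange:
    @pytest.mark.parametrize(
        "qsum, max_cbd, expected",
        [(100, 10, (90, 110)), (5, 10, (0, 15)), (42, 0, (42, 42))],
    )
    def test_ranges(self, qsum, max_cbd, expected):
        assert fb.bucket_range(qsum, max_cbd) == expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            fb.bucket_range(-1, 5)
        with pytest.raises(ValueError):
            fb.bucket_range(5, -1)


class TestFilters:
    def test_all_vendors_mask_passes_everything(self, library300):
        q = make_query(library300[0], wanted_vendor_mask=511)
        assert all(
            fb.passes_filters(r, q) or r.vendor_mask & 511 == 0 for r in library300
        )

    def test_vendor_intersection_rule(self):
        record = fb.annotate("CCO", "x", vendor_mask=0b000000101)
        q = make_query(record, wanted_vendor_mask=0b000000100)
        assert fb.passes_filters(record, q)
        q2 = make_query(record, wanted_vendor_mask=0b000000010)
        assert not fb.passes_filters(record, q2)

    def test_formula_lock_rejects_non_isomer(self):
        adrenaline = fb.annotate("CNC[C@H](O)c1ccc(O)c(O)c1", "q")  # C9H13NO3
        other = fb.annotate("NCCNc1ccc(C(N)=O)cc1", "c")  # C9H13N3O
        q = make_query(adrenaline, filters=fb.QueryFilters(lock_formula=True))
        assert not fb.passes_filters(other, q)
        assert fb.passes_filters(adrenaline, q)

    def test_oxygen_nitrogen_requirements(self):
        record = fb.annotate("CCO", "x")
        q = make_query(record, filters=fb.QueryFilters(required_oxygen=1))
        assert fb.passes_filters(record, q)
        q2 = make_query(record, filters=fb.QueryFilters(required_oxygen=2))
        assert not fb.passes_filters(record, q2)


class TestSearch:
    def test_identity_hit_at_distance_zero(self):
        record = fb.annotate("CCO", "only")
        idx = fb.build_index([record], fb.Space.MQN)
        q = make_query(record, mode=fb.SearchMode.MAX_DISTANCE, limit=0)
        result = fb.search(idx, q)
        assert [(r.id, d) for r, d in result.hits] == [("only", 0)]

    def test_space_mismatch_rejected(self, library300):
        idx = fb.build_index(library300[:10], fb.Space.MQN)
        q = make_query(library300[0], space=fb.Space.SMIFP)
        with pytest.raises(ValueError, match="space"):
            fb.search(idx, q)

    def test_no_passing_records_gives_empty_result(self):
        record = fb.annotate("CCO", "x", vendor_mask=0b1)
        idx = fb.build_index([record], fb.Space.MQN)
        q = make_query(record, wanted_vendor_mask=0b10,
                       mode=fb.SearchMode.MAX_DISTANCE, limit=100)
        result = fb.search(idx, q)
        assert len(result) == 0 and result.histogram == {}

    def test_max_count_limit_clamped_to_1000(self):
        record = fb.annotate("CCO", "x")
        q = make_query(record, limit=5000)
        assert q.limit == 1000

    def test_max_count_monotonic_in_limit(self, library300):
        idx = fb.build_index(library300, fb.Space.MQN)
        query = library300[42]
        previous_ids: set[str] = set()
        for limit in (5, 15, 40):
            hits = fb.search(idx, make_query(query, limit=limit)).hits
            ids = {r.id for r, _ in hits}
            assert previous_ids <= ids
            previous_ids = ids

    def test_hits_sorted_by_cbd_then_id(self, library300):
        idx = fb.build_index(library300, fb.Space.MQN)
        result = fb.search(idx, make_query(library300[0], limit=50))
        keys = [(d, r.id) for r, d in result.hits]
        assert keys == sorted(keys)

    @pytest.mark.parametrize("mode", list(fb.SearchMode))
    def test_matches_linear_scan_on_small_library(self, library300, mode):
        fps = [fb.fingerprint(r, fb.Space.MQN) for r in library300]
        idx = fb.build_index(library300, fb.Space.MQN, fingerprints=fps)
        for query_rec in library300[::60]:
            q = make_query(query_rec, mode=mode, limit=20)
            got = [(r.id, d) for r, d in fb.search(idx, q).hits]
            assert got == linear_scan(library300, fps, q)


class TestHistogram:
    def test_empty_result(self):
        assert fb.cbd_histogram(fb.SearchResult(hits=[], histogram={})) == {}

    def test_hand_tally(self):
        recs = [fb.annotate("CCO", f"m{i}") for i in range(4)]
        result = fb.SearchResult(
            hits=list(zip(recs, [0, 2, 2, 3])), histogram={}
        )
        assert fb.cbd_histogram(result) == {0: 1, 2: 2, 3: 1}

    def test_totals_match_hit_count(self, library300):
        idx = fb.build_index(library300, fb.Space.MQN)
        result = fb.search(idx, make_query(library300[3], limit=30))
        assert sum(result.histogram.values()) == len(result)
        assert result.histogram == fb.cbd_histogram(result)


class TestPersistence:
    @pytest.mark.parametrize("space", [fb.Space.MQN, fb.Space.SFP])
    def test_round_trip(self, tmp_path, library300, space):
        idx = fb.build_index(library300[:40], space)
        fb.save_index(idx, tmp_path)
        loaded = fb.load_index(tmp_path, space)
        assert loaded.size == idx.size
        assert sorted(loaded.buckets) == sorted(idx.buckets)
        for key in idx.buckets:
            original = {r.id: fp.values for r, fp in idx.buckets[key]}
            restored = {r.id: fp.values for r, fp in loaded.buckets[key]}
            assert original.keys() == restored.keys()
            for mol_id in original:
                assert np.array_equal(original[mol_id], restored[mol_id])

    def test_loaded_index_searches_identically(self, tmp_path, library300):
        idx = fb.build_index(library300, fb.Space.SMIFP)
        fb.save_index(idx, tmp_path)
        loaded = fb.load_index(tmp_path, fb.Space.SMIFP)
        q = make_query(library300[7], space=fb.Space.SMIFP, limit=25)
        assert [
            (r.id, d) for r, d in fb.search(idx, q).hits
        ] == [(r.id, d) for r, d in fb.search(loaded, q).hits]
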