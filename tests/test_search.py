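import io

import numpy as np
import pytest

from kmerank.database import build_index, read_header, write_index
from kmerank.kmer_core import DNA, UNRESTRICTED, extract_unique_kmers
from kmerank.search import (
    SearchParams,
    QueryResult,
    rank_hits,
    read_hits_tsv,
    score_query,
    search_batch,
    write_hits_tsv,
)
from kmerank.sequence_io import SequenceRecord
from kmerank.synthetic_fixtures import (
    FixtureSpec,
    expand_homopolymer,
    institute_records,
    random_sequences,
)

from conftest import naive_search


def make_view(records, k, alphabet, tmp_path, name="db.srdb"):
    index = build_index(records, k, alphabet)
    path = str(tmp_path / name)
    write_index(index, path)
    return read_header(path)


class TestScoreQuery:
    def test_toy_counts_by_hand(self, toy_view):
        profile = extract_unique_kmers("ACGT", 3, DNA)
        assert score_query(profile, toy_view).tolist() == [2, 1]

    def test_query_with_no_indexed_kmers_scores_zero(self, toy_view):
        profile = extract_unique_kmers("TTTT", 3, DNA)
        assert score_query(profile, toy_view).tolist() == [0, 0]

    def test_k_mismatch_is_hard_error(self, toy_view):
        profile = extract_unique_kmers("ACGT", 4, DNA)
        with pytest.raises(ValueError, match="4.*3"):
            score_query(profile, toy_view)

    def test_empty_profile_rejected(self, toy_view):
        with pytest.raises(ValueError):
            score_query(extract_unique_kmers("A", 3, DNA), toy_view)

    def test_cache_does_not_change_scores(self, toy_view):
        profile = extract_unique_kmers("ACGTACGG", 3, DNA)
        cached = {}
        s1 = score_query(profile, toy_view, cache=cached)
        s2 = score_query(profile, toy_view, cache=None)
        s3 = score_query(profile, toy_view, cache=cached)  # warm cache
        assert s1.tolist() == s2.tolist() == s3.tolist()

    def test_counts_bounded_by_unique_counts(self, tmp_path):
        records = random_sequences(FixtureSpec(15, 40, DNA, 5))
        view = make_view(records, 4, DNA, tmp_path)
        with view:
            for rec in records[:5]:
                profile = extract_unique_kmers(rec.sequence, 4, DNA)
                scores = score_query(profile, view)
                assert np.all(scores <= profile.unique_count)
                assert np.all(scores <= view.unique_per_string)


class TestRankHits:
    def test_self_search_ranks_self_first_at_100(self, toy_records, toy_view):
        profile = extract_unique_kmers(toy_records[0].sequence, 3, DNA)
        scores = score_query(profile, toy_view)
        hits = rank_hits(scores, profile, toy_view, SearchParams(min_percent=0),
                         query_id="s0")
        assert hits[0].subject_id == "s0"
        assert hits[0].percent == 100.0

    def test_institute_fixture_hit_at_96_47(self, tmp_path):
        records = institute_records()
        view = make_view(records, 4, UNRESTRICTED, tmp_path)
        with view:
            profile = extract_unique_kmers(records[0].sequence, 4, UNRESTRICTED)
            scores = score_query(profile, view)
            hits = rank_hits(scores, profile, view,
                             SearchParams(min_percent=90), query_id="inst_short")
        other = [h for h in hits if h.subject_id == "inst_long"]
        assert len(other) == 1
        assert f"{other[0].percent:.2f}" == "96.47"

    def test_min_percent_filters(self, toy_view):
        profile = extract_unique_kmers("ACGT", 3, DNA)
        scores = score_query(profile, toy_view)
        strict = rank_hits(scores, profile, toy_view, SearchParams(min_percent=90))
        loose = rank_hits(scores, profile, toy_view, SearchParams(min_percent=0))
        assert {h.subject_id for h in strict} == {"s0"}
        assert {h.subject_id for h in loose} == {"s0", "s1"}

    def test_tie_break_is_database_order(self, tmp_path):
        records = [
            SequenceRecord("dup_b", "dup_b", "ACGTACGT"),
            SequenceRecord("dup_a", "dup_a", "ACGTACGT"),
        ]
        view = make_view(records, 3, DNA, tmp_path)
        with view:
            profile = extract_unique_kmers("ACGTACGT", 3, DNA)
            hits = rank_hits(score_query(profile, view), profile, view,
                             SearchParams(min_percent=0))
        assert [h.subject_id for h in hits] == ["dup_b", "dup_a"]

    def test_top_n_truncates(self, tmp_path):
        records = random_sequences(FixtureSpec(20, 30, DNA, 6))
        view = make_view(records, 3, DNA, tmp_path)
        with view:
            profile = extract_unique_kmers(records[0].sequence, 3, DNA)
            scores = score_query(profile, view)
            assert len(rank_hits(scores, profile, view,
                                 SearchParams(top_n=5, min_percent=0))) == 5


class TestSearchBatch:
    def test_short_query_skipped_with_row(self, toy_records, toy_view):
        queries = [toy_records[0], SequenceRecord("shorty", "shorty", "AC")]
        results = list(search_batch(queries, toy_view, SearchParams(min_percent=0)))
        assert len(results) == 2
        assert results[0].hits
        assert results[1].skipped_reason == "no valid k-mers"
        assert results[1].hits == []

    def test_min_length_guard(self, toy_records, toy_view):
        results = list(search_batch(
            toy_records, toy_view, SearchParams(min_percent=0, min_length=100)))
        assert all(r.skipped_reason == "below min_length" for r in results)

    def test_self_batch_every_query_tops_itself(self, tmp_path):
        records = random_sequences(FixtureSpec(25, 60, DNA, 7))
        view = make_view(records, 5, DNA, tmp_path)
        with view:
            results = list(search_batch(records, view, SearchParams(min_percent=0)))
        for rec, result in zip(records, results):
            assert result.hits[0].subject_id == rec.identifier
            assert result.hits[0].percent == 100.0

    def test_serial_equals_split_batches(self, tmp_path):
        records = random_sequences(FixtureSpec(30, 50, DNA, 8))
        queries = random_sequences(FixtureSpec(10, 50, DNA, 9))
        view = make_view(records, 4, DNA, tmp_path)
        params = SearchParams(min_percent=0)
        with view:
            whole = list(search_batch(queries, view, params))
            split = list(search_batch(queries[:5], view, params)) + \
                list(search_batch(queries[5:], view, params))
        assert whole == split

    def test_cache_on_off_identical(self, tmp_path):
        records = random_sequences(FixtureSpec(30, 50, DNA, 10))
        queries = random_sequences(FixtureSpec(8, 50, DNA, 11))
        view = make_view(records, 4, DNA, tmp_path)
        with view:
            on = list(search_batch(queries, view, SearchParams(min_percent=0), use_cache=True))
            off = list(search_batch(queries, view, SearchParams(min_percent=0), use_cache=False))
        assert on == off

    def test_fold_case_option(self, tmp_path):
        records = [SequenceRecord("up", "up", "ACGTACGT")]
        view = make_view(records, 3, DNA, tmp_path)
        lower = [SequenceRecord("q", "q", "acgtacgt")]
        with view:
            plain = list(search_batch(lower, view, SearchParams(min_percent=0), alphabet=DNA))
            folded = list(search_batch(lower, view, SearchParams(min_percent=0),
                                       alphabet=DNA, fold_case=True))
        assert plain[0].skipped_reason == "no valid k-mers"
        assert folded[0].hits[0].percent == 100.0


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(6))
    def test_pipeline_matches_brute_force(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        length = int(rng.integers(20, 80))
        k = int(rng.integers(3, 7))
        records = random_sequences(FixtureSpec(n, length, DNA, seed))
        queries = random_sequences(FixtureSpec(5, length, DNA, seed + 1000), prefix="qry")
        min_percent = float(rng.choice([0.0, 25.0, 50.0, 90.0]))
        top_n = int(rng.choice([3, 10, 1000]))
        params = SearchParams(top_n=top_n, min_percent=min_percent)
        view = make_view(records, k, DNA, tmp_path, name=f"o{seed}.srdb")
        with view:
            results = list(search_batch(queries + records[:3], view, params, alphabet=DNA))
        for query, result in zip(queries + records[:3], results):
            expected = naive_search(query, records, k, set("ACGT"), top_n, min_percent)
            got = [(h.subject_id, round(h.percent, 9), h.shared,
                    h.query_unique, h.subject_unique) for h in result.hits]
            want = [(h.subject_id, round(h.percent, 9), h.shared,
                     h.query_unique, h.subject_unique) for h in expected]
            assert got == want


class TestDiscussionProperties:
    def test_homopolymer_expanded_query_has_identical_hit_table(self, tmp_path):
        records = random_sequences(FixtureSpec(30, 60, DNA, 12))
        base = records[3].sequence  # query related to a database string
        # plant a run of 5 A's (>= k = 4), then expand it by 4 more
        seq_with_run = base[:10] + "AAAAA" + base[10:]
        longer_run = expand_homopolymer(seq_with_run, 10, 4)
        view = make_view(records, 4, DNA, tmp_path)
        params = SearchParams(top_n=1000, min_percent=0)
        q1 = [SequenceRecord("q1", "q1", seq_with_run)]
        q2 = [SequenceRecord("q2", "q2", longer_run)]
        with view:
            h1 = [h for r in search_batch(q1, view, params, alphabet=DNA) for h in r.hits]
            h2 = [h for r in search_batch(q2, view, params, alphabet=DNA) for h in r.hits]
        assert [(h.subject_id, h.percent, h.shared) for h in h1] == \
               [(h.subject_id, h.percent, h.shared) for h in h2]

    def test_periodic_mutant_never_hits_original(self, tmp_path):
        from kmerank.synthetic_fixtures import periodic_disjoint_pair

        seq, mutant = periodic_disjoint_pair(700, m=7, seed=3, phase=2)
        records = [SequenceRecord("orig", "orig", seq)]
        view = make_view(records, 7, DNA, tmp_path)
        with view:
            results = list(search_batch(
                [SequenceRecord("mut", "mut", mutant)], view,
                SearchParams(min_percent=1e-9), alphabet=DNA))
        assert results[0].hits == []

    def test_threshold_monotonicity(self, tmp_path):
        records = random_sequences(FixtureSpec(40, 40, DNA, 13))
        query = records[0]
        view = make_view(records, 3, DNA, tmp_path)
        with view:
            profile = extract_unique_kmers(query.sequence, 3, DNA)
            scores = score_query(profile, view)
            prev_ids = None
            for min_percent in [0.0, 20.0, 40.0, 60.0, 80.0, 100.0]:
                hits = rank_hits(scores, profile, view,
                                 SearchParams(top_n=10 ** 6, min_percent=min_percent))
                ids = {h.subject_id for h in hits}
                if prev_ids is not None:
                    assert ids <= prev_ids  # raising threshold never adds hits
                prev_ids = ids
            small = rank_hits(scores, profile, view, SearchParams(top_n=5, min_percent=0))
            large = rank_hits(scores, profile, view, SearchParams(top_n=50, min_percent=0))
            assert [h.subject_id for h in large[:len(small)]] == [h.subject_id for h in small]


class TestHitTsv:
    def test_roundtrip_and_no_hit_placeholder(self, toy_view, toy_records):
        queries = toy_records + [SequenceRecord("zz", "zz", "TTTTTT")]
        results = list(search_batch(queries, toy_view, SearchParams(min_percent=0)))
        buf = io.StringIO()
        write_hits_tsv(results, buf, provenance={"k": 3})
        text = buf.getvalue()
        assert text.startswith("# k=3\n#query_id\tsubject_id\t")
        assert "zz\t-\t-\t-\t" in text
        hits = read_hits_tsv(io.StringIO(text))
        flat = [h for r in results for h in r.hits]
        assert [(h.query_id, h.subject_id, h.shared) for h in hits] == \
               [(h.query_id, h.subject_id, h.shared) for h in flat]

    def test_percent_rendered_two_decimals(self, tmp_path):
        records = institute_records()
        view = make_view(records, 4, UNRESTRICTED, tmp_path)
        with view:
            results = list(search_batch(records[:1], view, SearchParams(min_percent=90)))
        buf = io.StringIO()
        write_hits_tsv(results, buf)
        assert "\t96.47\t" in buf.getvalue()
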