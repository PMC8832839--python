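"""The seven query modes: worked examples on TOY5, oracle equivalence,
cross-mode consistency, and BED/BEDPE parsing."""

import pytest

from hicquery import (
    PairQueryRecord,
    ParseError,
    QueryError,
    QueryRecord,
    generate_map,
    query_bait,
    query_local,
    query_loop,
    query_pair,
    query_sites,
    query_submap,
    query_tad,
    read_bed,
    read_bedpe,
    read_classified_bed,
    read_bins,
    read_contacts_text,
    write_fixture,
)
from conftest import small_map_spec
from reference import (
    load_dense,
    ref_bait,
    ref_local,
    ref_loop,
    ref_pair,
    ref_sites,
    ref_submap,
    ref_tad,
)


def q(start, end, name="q", chrom="chrT"):
    return QueryRecord(chrom, start, end, name)


class TestBait:
    def test_central_bait_window_one(self, toy):
        _, cmap = toy
        res = query_bait(cmap, q(20, 30), near_bin=1)
        assert res.frequency == pytest.approx((9 + 10 + 9) / 3)
        assert res.n_pairs == 3

    def test_window_zero_is_diagonal_only(self, toy):
        _, cmap = toy
        res = query_bait(cmap, q(20, 30), near_bin=0)
        assert res.frequency == 10.0
        assert res.n_pairs == 1

    def test_window_clipped_at_chromosome_start(self, toy):
        _, cmap = toy
        res = query_bait(cmap, q(0, 10), near_bin=2)
        assert res.frequency == pytest.approx((10 + 9 + 8) / 3)
        assert res.n_pairs == 3

    def test_negative_window_rejected(self, toy):
        _, cmap = toy
        with pytest.raises(QueryError, match="near_bin"):
            query_bait(cmap, q(0, 10), near_bin=-1)


class TestLocal:
    def test_three_bin_interval_lists_six_pairs(self, toy):
        _, cmap = toy
        res = query_local(cmap, q(0, 30))
        assert res.rows == (
            (0, 0, 10.0), (0, 1, 9.0), (0, 2, 8.0),
            (1, 1, 10.0), (1, 2, 9.0), (2, 2, 10.0),
        )

    def test_single_bin_interval(self, toy):
        _, cmap = toy
        assert query_local(cmap, q(0, 10)).rows == ((0, 0, 10.0),)

    def test_unstored_pairs_listed_as_zero(self, tmp_path):
        bins_path = tmp_path / "t.bins"
        bins_path.write_text("0\tchrT\t0\t10\n1\tchrT\t10\t20\n")
        contacts = tmp_path / "c.tsv"
        contacts.write_text("0\t0\t4\n")
        bins = read_bins(bins_path)
        cmap = read_contacts_text(contacts, bins)
        res = query_local(cmap, q(0, 20))
        assert res.rows == ((0, 0, 4.0), (0, 1, 0.0), (1, 1, 0.0))


class TestLoop:
    def test_whole_chromosome_loop(self, toy):
        _, cmap = toy
        assert query_loop(cmap, q(0, 50)).frequency == 6.0

    def test_degenerate_loop_is_diagonal(self, toy):
        _, cmap = toy
        assert query_loop(cmap, q(0, 10)).frequency == 10.0

    def test_partial_bin_ends_snap_to_containing_bins(self, toy):
        _, cmap = toy
        assert query_loop(cmap, q(5, 45)).frequency == 6.0


class TestPair:
    def test_two_by_two_region_pair(self, toy):
        _, cmap = toy
        res = query_pair(cmap, PairQueryRecord("chrT", 0, 20, "chrT", 30, 50, "p"))
        assert res.total == 28.0
        assert res.frequency == 7.0
        assert res.n_pairs == 4

    def test_single_bin_regions(self, toy):
        _, cmap = toy
        res = query_pair(cmap, PairQueryRecord("chrT", 0, 10, "chrT", 40, 50, "p"))
        assert res.total == 6.0
        assert res.frequency == 6.0

    def test_self_pair_allowed(self, toy):
        _, cmap = toy
        res = query_pair(cmap, PairQueryRecord("chrT", 0, 10, "chrT", 0, 10, "p"))
        assert res.frequency == 10.0

    def test_inter_chromosomal_pair(self, noisy_map):
        bins, cmap, _ = noisy_map
        res = query_pair(
            cmap, PairQueryRecord("chr2L", 0, 3000, "chr2R", 0, 2000, "x")
        )
        assert res.n_pairs == 6
        assert res.frequency >= 0.0


class TestSites:
    def test_three_sites_give_six_rows(self, toy):
        _, cmap = toy
        sites = [q(0, 10, "a"), q(20, 30, "b"), q(40, 50, "c")]
        res = query_sites(cmap, sites)
        assert res.rows == (
            (0, 0, 10.0), (0, 2, 8.0), (0, 4, 6.0),
            (2, 2, 10.0), (2, 4, 8.0), (4, 4, 10.0),
        )

    def test_single_site_yields_diagonal(self, toy):
        _, cmap = toy
        assert query_sites(cmap, [q(0, 10)]).rows == ((0, 0, 10.0),)

    def test_cobinned_sites_deduplicated(self, toy):
        _, cmap = toy
        res = query_sites(cmap, [q(0, 4, "a"), q(4, 8, "b")])
        assert res.rows == ((0, 0, 10.0),)

    def test_empty_site_list_rejected(self, toy):
        _, cmap = toy
        with pytest.raises(QueryError):
            query_sites(cmap, [])


class TestSubmap:
    def test_single_region_matches_local(self, toy):
        _, cmap = toy
        sub = query_submap(cmap, [q(0, 30)])
        expected = {(i, j): 10.0 - (j - i) for i in range(3) for j in range(i, 3)}
        assert sub.entries == expected

    def test_whole_map_region_is_identity(self, toy):
        _, cmap = toy
        assert query_submap(cmap, [q(0, 50)]).entries == cmap.entries

    def test_disjoint_regions_keep_cross_pairs(self, toy):
        _, cmap = toy
        sub = query_submap(cmap, [q(0, 10), q(40, 50)])
        assert sub.entries == {(0, 0): 10.0, (0, 4): 6.0, (4, 4): 10.0}

    def test_queries_inside_submap_match_full_map(self, noisy_map):
        bins, cmap, _ = noisy_map
        sub = query_submap(cmap, [QueryRecord("chr2L", 5000, 30_000, "r")])
        inner = QueryRecord("chr2L", 8000, 24_000, "t")
        assert query_tad(sub, inner) == query_tad(cmap, inner)

    def test_written_submap_reloads_identically(self, toy, tmp_path):
        bins, cmap = toy
        out_c, out_b = tmp_path / "s.contacts", tmp_path / "s.bins"
        sub = query_submap(cmap, [q(0, 30)], out_contacts=out_c, out_bins=out_b)
        back = read_contacts_text(out_c, read_bins(out_b))
        assert back.entries == sub.entries


class TestTad:
    def test_three_bin_domain_sum_and_average(self, toy):
        _, cmap = toy
        res = query_tad(cmap, q(10, 40))
        assert res.total == 56.0
        assert res.frequency == pytest.approx(56 / 6)
        assert res.n_pairs == 6

    def test_single_bin_domain(self, toy):
        _, cmap = toy
        res = query_tad(cmap, q(0, 10))
        assert res.total == res.frequency == 10.0

    def test_zero_map(self, tmp_path):
        bins_path = tmp_path / "t.bins"
        bins_path.write_text("0\tchrT\t0\t10\n1\tchrT\t10\t20\n")
        contacts = tmp_path / "c.tsv"
        contacts.write_text("")
        bins = read_bins(bins_path)
        from hicquery import ContactMap

        res = query_tad(ContactMap(bins=bins), q(0, 20))
        assert res.total == 0.0
        assert res.frequency == 0.0


class TestCrossModeConsistency:
    def test_tad_sum_equals_local_sum(self, noisy_map):
        _, cmap, _ = noisy_map
        interval = QueryRecord("chr2L", 3000, 27_000, "t")
        tad = query_tad(cmap, interval)
        local_sum = sum(v for _, _, v in query_local(cmap, interval).rows)
        assert tad.total == pytest.approx(local_sum)
        assert tad.frequency * tad.n_pairs == pytest.approx(tad.total)

    def test_loop_equals_pair_of_terminal_bins(self, noisy_map):
        bins, cmap, _ = noisy_map
        interval = QueryRecord("chr2L", 2000, 41_000, "l")
        loop = query_loop(cmap, interval)
        pair = query_pair(
            cmap,
            PairQueryRecord("chr2L", 2000, 3000, "chr2L", 40_000, 41_000, "p"),
        )
        assert loop.frequency == pair.frequency


@pytest.mark.parametrize("seed", [11, 12, 13])
class TestOracleEquivalence:
    """Every mode against the dense brute-force reference on noisy maps."""

    @pytest.fixture
    def loaded(self, seed, tmp_path):
        bins, cmap = generate_map(small_map_spec(seed=seed))
        paths = write_fixture(bins, cmap, tmp_path, "m")
        rows, M = load_dense(*paths)
        return bins, cmap, rows, M

    def test_all_modes_match_reference(self, loaded):
        bins, cmap, rows, M = loaded
        rq = QueryRecord("chr2L", 4500, 18_200, "r")

        freq, n = ref_bait(rows, M, "chr2L", 4500, 18_200, 5)
        bait = query_bait(cmap, rq, 5)
        assert (bait.frequency, bait.n_pairs) == (pytest.approx(freq), n)

        assert [tuple(r) for r in query_local(cmap, rq).rows] == [
            (i, j, pytest.approx(v))
            for i, j, v in ref_local(rows, M, rq.chrom, rq.start, rq.end)
        ]

        assert query_loop(cmap, rq).frequency == pytest.approx(
            ref_loop(rows, M, "chr2L", 4500, 18_200)
        )

        pq = PairQueryRecord("chr2L", 1000, 9000, "chr2R", 5000, 12_000, "p")
        s, m, n = ref_pair(
            rows, M, pq.chrom1, pq.start1, pq.end1, pq.chrom2, pq.start2, pq.end2
        )
        pair = query_pair(cmap, pq)
        assert (pair.total, pair.frequency, pair.n_pairs) == (
            pytest.approx(s), pytest.approx(m), n,
        )

        sites = [
            QueryRecord("chr2L", 500, 600, "a"),
            QueryRecord("chr2L", 20_000, 20_100, "b"),
            QueryRecord("chr2R", 7000, 7100, "c"),
        ]
        assert [tuple(r) for r in query_sites(cmap, sites).rows] == [
            (i, j, pytest.approx(v))
            for i, j, v in ref_sites(rows, M, [(s.chrom, s.start, s.end) for s in sites])
        ]

        regions = [QueryRecord("chr2L", 0, 12_000, "r1"),
                   QueryRecord("chr2R", 20_000, 33_000, "r2")]
        sub = query_submap(cmap, regions)
        assert sub.entries == pytest.approx(
            ref_submap(rows, M, [(r.chrom, r.start, r.end) for r in regions])
        )

        s, avg, n = ref_tad(rows, M, "chr2L", 4500, 18_200)
        tad = query_tad(cmap, rq)
        assert (tad.total, tad.frequency, tad.n_pairs) == (
            pytest.approx(s), pytest.approx(avg), n,
        )


class TestBedParsing:
    def test_bed3_gets_autogenerated_names(self, tmp_path):
        p = tmp_path / "q.bed"
        p.write_text("chrT\t0\t30\nchrT\t10\t40\n")
        recs = read_bed(p)
        assert [r.name for r in recs] == ["query_1", "query_2"]

    def test_bed4_keeps_names_and_ignores_strand(self, tmp_path):
        p = tmp_path / "q.bed"
        p.write_text("chrT\t0\t30\tUbx\t0\t-\n")
        (rec,) = read_bed(p)
        assert rec == QueryRecord("chrT", 0, 30, "Ubx")

    def test_malformed_bed_names_line(self, tmp_path):
        p = tmp_path / "q.bed"
        p.write_text("chrT\t0\t30\nchrT\tstart\t40\n")
        with pytest.raises(ParseError, match=":2"):
            read_bed(p)

    def test_inverted_interval_rejected(self, tmp_path):
        p = tmp_path / "q.bed"
        p.write_text("chrT\t30\t10\n")
        with pytest.raises(ParseError, match="start >= end"):
            read_bed(p)

    def test_bedpe_seven_columns(self, tmp_path):
        p = tmp_path / "q.bedpe"
        p.write_text("chrT\t0\t10\tchrT\t30\t50\tXY\n")
        (rec,) = read_bedpe(p)
        assert rec == PairQueryRecord("chrT", 0, 10, "chrT", 30, 50, "XY")

    def test_classified_bed_counts_labels(self, tmp_path):
        # synthetic stand-in for a class-labelled domain list
        p = tmp_path / "domains.bed"
        p.write_text(
            "chrT\t0\t10\tactive\nchrT\t10\t20\tPcG\n"
            "chrT\t20\t30\tPcG\nchrT\t30\t40\tnull\n"
        )
        recs = read_classified_bed(p)
        assert len(recs) == 4
        assert sum(1 for _, label in recs if label == "PcG") == 2
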