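"""Proximal-gene assignment, catalog overlap, marker series, gene lists."""

import numpy as np
import pandas as pd
import pytest

from sernacall.annotation import (
    ProximalAssignment,
    _endpoint_distance,
    compare_to_catalog,
    export_state_gene_lists,
    extract_marker_series,
    map_enhancers_to_genes,
    map_sernas_to_genes,
)
from sernacall.caller import StitchedLocus, stitch_enhancers
from sernacall.intervals import GenomicInterval, interval_gap
from sernacall.matrix import ExpressionMatrix

from conftest import make_enhancer, make_gene, random_enhancers, random_genes


class TestEnhancerGeneMapping:
    def test_window_assignment(self):
        enh = make_enhancer("chr1", 9_900, 10_100)  # midpoint 10,000
        genes = [make_gene("NEAR", "chr1", 12_000, 13_000), make_gene("FAR", "chr1", 40_000, 41_000)]
        (a,) = map_enhancers_to_genes([enh], genes)
        assert a.rule_used == "window" and a.gene_symbols == ("NEAR",)

    def test_nearest_fallback_when_window_empty(self):
        enh = make_enhancer("chr1", 9_900, 10_100)
        genes = [make_gene("ONLY", "chr1", 40_000, 41_000)]
        (a,) = map_enhancers_to_genes([enh], genes)
        assert a.rule_used == "nearest" and a.gene_symbols == ("ONLY",)

    def test_window_collects_all_genes_inside(self):
        enh = make_enhancer("chr1", 9_900, 10_100)
        genes = [
            make_gene("B", "chr1", 11_000, 12_000),
            make_gene("A", "chr1", 6_000, 7_000),
            make_gene("OUT", "chr1", 40_000, 41_000),
        ]
        (a,) = map_enhancers_to_genes([enh], genes)
        assert a.gene_symbols == ("A", "B")

    def test_equidistant_tie_breaks_by_smaller_start(self):
        enh = make_enhancer("chr1", 29_900, 30_100)  # interval 29,900-30,100
        left = make_gene("LEFT", "chr1", 9_000, 10_000)   # gap 19,900
        right = make_gene("RIGHT", "chr1", 50_000, 51_000)  # gap 19,900
        assert interval_gap(enh.interval, left.interval) == interval_gap(
            enh.interval, right.interval
        )
        (a,) = map_enhancers_to_genes([enh], [right, left])
        assert a.gene_symbols == ("LEFT",)

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError):
            map_enhancers_to_genes([make_enhancer("chr1", 0, 100)], [])

    def test_gene_order_invariance(self, rng):
        enh = random_enhancers(rng, 30)
        genes = random_genes(rng, 15)
        a1 = map_enhancers_to_genes(enh, genes)
        a2 = map_enhancers_to_genes(enh, list(reversed(genes)))
        assert a1 == a2


class TestSernaGeneMapping:
    def _locus(self, chrom, start, end):
        return StitchedLocus((make_enhancer(chrom, start, end),))

    def test_overlapping_gene_wins_with_distance_zero(self):
        locus = self._locus("chr1", 1_000, 10_000)
        inside = make_gene("IN", "chr1", 4_000, 5_000)
        out = make_gene("OUT", "chr1", 10_500, 11_500)
        (a,) = map_sernas_to_genes([locus], [out, inside])
        assert a.gene_symbols == ("IN",)
        assert _endpoint_distance(locus.span, inside.interval) == 0

    def test_smaller_endpoint_distance_wins(self):
        locus = self._locus("chr1", 10_000, 20_000)
        near_start = make_gene("NS", "chr1", 8_000, 9_000)  # 1,000 from start
        near_end = make_gene("NE", "chr1", 22_000, 23_000)  # 2,000+ from end
        (a,) = map_sernas_to_genes([locus], [near_end, near_start])
        assert a.gene_symbols == ("NS",)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        enh = random_enhancers(rng, 30, chroms=("chr1",))
        genes = random_genes(rng, 20, chroms=("chr1",))
        stitched = stitch_enhancers(enh, [])
        assignments = map_sernas_to_genes(stitched, genes)
        for locus, a in zip(stitched, assignments):
            dists = [
                (_endpoint_distance(locus.span, g.interval), g.interval.start, g.symbol)
                for g in genes
            ]
            assert a.gene_symbols[0] == min(dists)[2]


class TestCatalogComparison:
    def test_identical_loci_fully_overlap(self):
        loci = [make_gene("x", "chr1", 0, 1_000)]
        rep = compare_to_catalog(loci, loci)
        assert rep.fraction_query == rep.fraction_reference == 1.0
        assert rep.pairs[0][2:] == (1.0, 1.0)

    def test_exactly_half_is_not_overlapped(self):
        query = [make_gene("q", "chr1", 0, 1_000)]
        reference = [make_gene("r", "chr1", 500, 1_000)]
        rep = compare_to_catalog(query, reference)
        assert rep.n_query_overlapped == 0  # 0.5 is not > 0.5
        assert rep.n_reference_overlapped == 1  # fraction 1.0

    def test_duplicates_removed_before_counting(self):
        q = [make_gene("a", "chr1", 0, 100), make_gene("b", "chr1", 0, 100)]
        rep = compare_to_catalog(q, [make_gene("r", "chr1", 0, 100)])
        assert rep.n_query == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_counts_match_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)

        def random_intervals(n, tag):
            out = []
            for i in range(n):
                start = int(rng.integers(0, 50_000))
                out.append(
                    make_gene(
                        f"{tag}{i}",
                        f"chr{rng.integers(1, 3)}",
                        start,
                        start + int(rng.integers(1, 5_000)),
                    )
                )
            return out

        query = random_intervals(100, "q")
        reference = random_intervals(100, "r")
        rep = compare_to_catalog(query, reference)

        def dedupe(loci):
            seen = {}
            for l in loci:
                seen.setdefault((l.interval.chrom, l.interval.start, l.interval.end), l)
            return list(seen.values())

        q, r = dedupe(query), dedupe(reference)
        q_hit = sum(
            any(
                qi.interval.overlap_length(ri.interval) / qi.interval.length > 0.5
                for ri in r
            )
            for qi in q
        )
        r_hit = sum(
            any(
                ri.interval.overlap_length(qi.interval) / ri.interval.length > 0.5
                for qi in q
            )
            for ri in r
        )
        assert (rep.n_query_overlapped, rep.n_reference_overlapped) == (q_hit, r_hit)
        assert rep.n_query == len(q) and rep.n_reference == len(r)

    def test_min_fraction_boundaries(self, rng):
        query = [make_gene("q", "chr1", 0, 1_000)]
        reference = [make_gene("r", "chr1", 900, 2_000)]  # overlap 100
        assert compare_to_catalog(query, reference, min_fraction=0).n_query_overlapped == 1
        # only exact containment of the full locus passes min_fraction just below 1
        assert compare_to_catalog(query, reference, min_fraction=0.999).n_query_overlapped == 0
        same = [make_gene("r", "chr1", 0, 1_000)]
        assert compare_to_catalog(query, same, min_fraction=0.999).n_query_overlapped == 1

    def test_report_counts_regenerate_from_pairs(self, rng):
        q = [make_gene(f"q{i}", "chr1", i * 100, i * 100 + 150) for i in range(20)]
        r = [make_gene(f"r{i}", "chr1", i * 130, i * 130 + 120) for i in range(20)]
        rep = compare_to_catalog(q, r)
        q_from_pairs = {p[0] for p in rep.pairs if p[2] > rep.min_fraction}
        r_from_pairs = {p[1] for p in rep.pairs if p[3] > rep.min_fraction}
        assert len(q_from_pairs) == rep.n_query_overlapped
        assert len(r_from_pairs) == rep.n_reference_overlapped


class TestMarkerSeries:
    @pytest.fixture
    def gene_expr(self):
        meta = pd.DataFrame(
            {"cell_type": "tc", "time": [0.0, 6.0, 12.0, 18.0]},
            index=pd.Index([f"s{i}" for i in range(4)], name="sample_id"),
        )
        df = pd.DataFrame(
            [[1.0, 10.0, 100.0, 1000.0], [5.0, 5.0, 5.0, 5.0]],
            index=["SOX2", "NANOG"],
            columns=meta.index,
        )
        return ExpressionMatrix(df, meta)

    def test_one_row_per_marker_per_sample(self, gene_expr):
        res = extract_marker_series(gene_expr, ["SOX2"])
        assert len(res.table) == 4
        assert res.table["log_expression"].tolist() == pytest.approx([0.0, 1.0, 2.0, 3.0])

    def test_missing_marker_reported_not_fatal(self, gene_expr):
        res = extract_marker_series(gene_expr, ["SOX2", "PAX6"])
        assert res.missing == ["PAX6"]
        assert set(res.table["gene"]) == {"SOX2"}

    def test_all_missing_is_error(self, gene_expr):
        with pytest.raises(ValueError, match="none of the requested markers"):
            extract_marker_series(gene_expr, ["KLF4"])


class TestStateGeneLists:
    def test_deduplication_and_union(self, tmp_path):
        assignments = [
            ProximalAssignment("se1", ("GENEA",), "nearest"),
            ProximalAssignment("se2", ("GENEA",), "nearest"),
            ProximalAssignment("se3", ("GENEB",), "nearest"),
        ]
        lists = export_state_gene_lists(
            {0: ["se1", "se2"], 1: ["se3"]}, assignments, out_dir=tmp_path
        )
        assert lists == {0: ["GENEA"], 1: ["GENEB"]}
        assert (tmp_path / "state_0.txt").read_text() == "GENEA\n"

    def test_empty_state_warns(self, tmp_path):
        with pytest.warns(UserWarning, match="no assigned genes"):
            lists = export_state_gene_lists({0: []}, [], out_dir=tmp_path)
        assert lists[0] == [] and (tmp_path / "state_0.txt").read_text() == ""
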