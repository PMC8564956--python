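"""Stitching, signal summation and reflection-point calling."""

import numpy as np
import pandas as pd
import pytest

from sernacall.caller import (
    call_sernas,
    find_reflection_point,
    stitch_enhancers,
    sum_member_expression,
)
from sernacall.matrix import ExpressionMatrix
from sernacall.simulate import SimulationConfig, simulate_dataset

from conftest import make_enhancer, make_gene, random_enhancers, random_genes


def enh_at_midpoint(chrom, mid, width=200):
    return make_enhancer(chrom, mid - width // 2, mid + width - width // 2)


def brute_force_partition(enhancers, genes, stitch_distance=12_500):
    """Oracle: connected components of the consecutive-pair join relation."""
    from collections import defaultdict

    comps = []
    by_chrom = defaultdict(list)
    for e in enhancers:
        by_chrom[e.interval.chrom].append(e)
    for chrom, group in by_chrom.items():
        group = sorted(group, key=lambda e: (e.midpoint, e.interval.start, e.id))
        # adjacency between consecutive-in-order pairs only
        edges = set()
        for i in range(len(group) - 1):
            a, b = group[i], group[i + 1]
            if b.midpoint - a.midpoint > stitch_distance:
                continue
            lo, hi = a.midpoint, b.midpoint
            blocked = any(
                g.interval.chrom == chrom
                and g.interval.start < hi
                and g.interval.end > lo + 1
                and hi > lo + 1
                for g in genes
            )
            if not blocked:
                edges.add((i, i + 1))
        # transitive closure over chain edges
        comp = [0] * len(group)
        c = 0
        for i in range(1, len(group)):
            if (i - 1, i) not in edges:
                c += 1
            comp[i] = c
        groups = defaultdict(set)
        for i, ci in enumerate(comp):
            groups[ci].add(group[i].id)
        comps.extend(frozenset(s) for s in groups.values())
    return set(comps)


class TestStitching:
    def test_within_distance_joins(self):
        enh = [enh_at_midpoint("chr1", 1_000), enh_at_midpoint("chr1", 13_000)]
        loci = stitch_enhancers(enh, [])
        assert len(loci) == 1 and loci[0].n_members == 2

    def test_beyond_distance_separates(self):
        enh = [enh_at_midpoint("chr1", 1_000), enh_at_midpoint("chr1", 14_000)]
        loci = stitch_enhancers(enh, [])
        assert [l.n_members for l in loci] == [1, 1]

    def test_boundary_distance_exactly_12500_joins(self):
        enh = [enh_at_midpoint("chr1", 1_000), enh_at_midpoint("chr1", 13_500)]
        assert len(stitch_enhancers(enh, [])) == 1

    def test_gene_between_midpoints_interrupts(self):
        enh = [enh_at_midpoint("chr1", 1_000), enh_at_midpoint("chr1", 11_000)]
        gene = make_gene("G", "chr1", 5_000, 6_000)
        loci = stitch_enhancers(enh, [gene])
        assert [l.n_members for l in loci] == [1, 1]

    def test_gene_outside_gap_does_not_interrupt(self):
        enh = [enh_at_midpoint("chr1", 1_000), enh_at_midpoint("chr1", 11_000)]
        gene = make_gene("G", "chr1", 20_000, 21_000)
        assert len(stitch_enhancers(enh, [gene])) == 1

    def test_gene_on_other_chromosome_ignored(self):
        enh = [enh_at_midpoint("chr1", 1_000), enh_at_midpoint("chr1", 11_000)]
        gene = make_gene("G", "chr2", 5_000, 6_000)
        assert len(stitch_enhancers(enh, [gene])) == 1

    def test_transitive_chaining_spans_beyond_stitch_distance(self):
        enh = [enh_at_midpoint("chr1", m) for m in (1_000, 11_000, 21_000)]
        loci = stitch_enhancers(enh, [])
        assert len(loci) == 1 and loci[0].n_members == 3

    def test_identical_midpoints_join(self):
        enh = [make_enhancer("chr1", 900, 1100), make_enhancer("chr1", 950, 1050)]
        assert len(stitch_enhancers(enh, [])) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        enh = random_enhancers(rng, int(rng.integers(10, 200)))
        genes = random_genes(rng, int(rng.integers(0, 20)))
        loci = stitch_enhancers(enh, genes)
        got = {frozenset(l.member_ids) for l in loci}
        assert got == brute_force_partition(enh, genes)
        assert sum(l.n_members for l in loci) == len(enh)

    def test_monotone_in_stitch_distance(self, rng):
        enh = random_enhancers(rng, 120)
        counts = [len(stitch_enhancers(enh, [], d)) for d in (0, 5_000, 12_500, 50_000)]
        assert counts == sorted(counts, reverse=True)


class TestSumMemberExpression:
    def test_additivity_and_identity(self):
        enh = [enh_at_midpoint("chr1", 1_000), enh_at_midpoint("chr1", 5_000),
               enh_at_midpoint("chr1", 100_000)]
        expr = ExpressionMatrix(
            pd.DataFrame(
                [[1.0, 2.0], [3.0, 4.0], [7.0, 8.0]],
                index=[e.id for e in enh],
                columns=["s1", "s2"],
            )
        )
        loci = stitch_enhancers(enh, [])
        summed = sum_member_expression(loci, expr)
        assert summed.values.tolist() == [[4.0, 6.0], [7.0, 8.0]]

    def test_mass_conservation_random(self, rng):
        enh = random_enhancers(rng, 20)
        values = rng.uniform(size=(20, 5))
        expr = ExpressionMatrix(
            pd.DataFrame(values, index=[e.id for e in enh], columns=[f"s{i}" for i in range(5)])
        )
        loci = stitch_enhancers(enh, [])
        summed = sum_member_expression(loci, expr)
        np.testing.assert_allclose(
            summed.values.sum(axis=0), values.sum(axis=0), rtol=1e-12
        )

    def test_missing_member_named_in_error(self, tiny_expr):
        enh = [enh_at_midpoint("chr9", 1_000)]
        loci = stitch_enhancers(enh, [])
        with pytest.raises(KeyError, match="chr9"):
            sum_member_expression(loci, tiny_expr)


class TestReflectionPoint:
    def test_linear_ramp_calls_nothing(self):
        idx, thr = find_reflection_point(np.arange(1.0, 101.0))
        assert idx == 99 and thr == 100.0  # strict threshold at max -> zero calls

    def test_single_outlier(self):
        idx, thr = find_reflection_point([0.0, 0.0, 0.0, 10.0])
        assert thr == 0.0
        assert sum(v > thr for v in [0, 0, 0, 10]) == 1

    def test_hockey_stick_recovers_planted_top(self, rng):
        background = rng.uniform(0, 1, size=90)
        planted = rng.uniform(50, 100, size=10)
        signal = np.concatenate([background, planted])
        _, thr = find_reflection_point(signal)
        called = signal > thr
        assert called[90:].all() and not called[:90].any()

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            find_reflection_point([1.0, 2.0])
        with pytest.raises(ValueError, match="no reflection point"):
            find_reflection_point([5.0, 5.0, 5.0])

    def test_scale_invariance(self, rng):
        signal = np.concatenate([rng.uniform(0, 1, 50), rng.uniform(30, 60, 5)])
        i1, t1 = find_reflection_point(signal)
        i2, t2 = find_reflection_point(signal * 37.5)
        assert i1 == i2 and np.isclose(t2, t1 * 37.5)


@pytest.fixture(scope="module")
def dataset():
    return simulate_dataset(SimulationConfig(seed=11))


class TestCallSernas:

    def test_planted_clusters_recovered(self, dataset):
        res = call_sernas(dataset.enhancers, dataset.genes, dataset.expression)
        called = {s.id for s in res.called_loci}
        assert called == {iv.id for iv in dataset.truth.planted_cluster_spans}

    def test_signal_conservation(self, dataset):
        res = call_sernas(dataset.enhancers, dataset.genes, dataset.expression)
        assert np.isclose(res.total_signal.sum(), dataset.expression.values.sum())

    def test_row_order_invariance(self, dataset):
        res = call_sernas(dataset.enhancers, dataset.genes, dataset.expression)
        perm_enh = list(reversed(dataset.enhancers))
        res2 = call_sernas(perm_enh, dataset.genes, dataset.expression)
        assert {s.id for s in res.called_loci} == {s.id for s in res2.called_loci}
        assert res.threshold == res2.threshold

    def test_uniform_scaling_invariance(self, dataset):
        res = call_sernas(dataset.enhancers, dataset.genes, dataset.expression)
        scaled = ExpressionMatrix(
            dataset.expression.data * 4.2, dataset.expression.sample_meta
        )
        res2 = call_sernas(dataset.enhancers, dataset.genes, scaled)
        assert list(res.calls) == list(res2.calls)

    def test_empty_gene_list_equivalent_to_nonblocking_genes(self, dataset):
        res = call_sernas(dataset.enhancers, [], dataset.expression)
        far_gene = [make_gene("FAR", "chr99", 0, 100)]
        res2 = call_sernas(dataset.enhancers, far_gene, dataset.expression)
        assert {s.id for s in res.stitched} == {s.id for s in res2.stitched}

    def test_per_sample_mode_produces_call_table(self, dataset):
        res = call_sernas(dataset.enhancers, dataset.genes, dataset.expression, per_sample=True)
        assert res.per_sample_calls is not None
        assert res.per_sample_calls.shape == (
            len(res.stitched),
            dataset.expression.n_samples,
        )
        # the planted cluster for a cell type must be called in that type's samples
        truth_ids = [iv.id for iv in dataset.truth.planted_cluster_spans]
        for cid, ctype in zip(truth_ids, dataset.truth.cluster_celltype_map):
            cols = [s for s in dataset.expression.sample_ids if s.startswith(ctype)]
            assert res.per_sample_calls.loc[cid, cols].all()
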