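"""Support partitions, pairwise agreement, distributions and coverage."""

import random

import pytest

from metanno.consensus import (
    aggregate_pairwise,
    gene_coverage,
    mean_region_counts,
    pairwise_gene_agreement,
    support_distribution,
    support_partition,
)
from metanno.model import AnnotationSet

from conftest import brute_force_regions, make_ec, random_annotation_sets

E = [make_ec(i) for i in range(10)]


def aset(tool, pairs, genome="G"):
    return AnnotationSet(genome, tool, frozenset(pairs))


class TestSupportPartition:
    def test_full_agreement(self):
        sets = {
            "a": aset("a", {("g1", E[1])}),
            "b": aset("b", {("g1", E[1])}),
        }
        part = support_partition(sets)
        assert part.counts == {1: 0, 2: 1}
        assert part.per_tool_unique == {"a": 0, "b": 0}

    def test_hand_venn(self):
        sets = {
            "a": aset("a", {("g1", E[1]), ("g2", E[2])}),
            "b": aset("b", {("g1", E[1]), ("g3", E[3])}),
        }
        part = support_partition(sets)
        assert part.counts == {1: 2, 2: 1}
        assert part.per_tool_unique == {"a": 1, "b": 1}

    def test_ec_unit_projects_before_venn(self):
        sets = {
            "a": aset("a", {("g1", E[1]), ("g2", E[1])}),
            "b": aset("b", {("g3", E[1])}),
        }
        part = support_partition(sets, unit="ec")
        assert part.counts == {1: 0, 2: 1}

    def test_genome_mismatch_rejected(self):
        sets = {
            "a": aset("a", {("g1", E[1])}, genome="G1"),
            "b": aset("b", {("g1", E[1])}, genome="G2"),
        }
        with pytest.raises(ValueError, match="genome"):
            support_partition(sets)

    @pytest.mark.parametrize("unit", ["gene_ec_pair", "ec", "gene"])
    def test_matches_brute_force_oracle(self, unit, rng):
        for _ in range(60):
            sets = random_annotation_sets(rng)
            part = support_partition(sets, unit)
            projected = {
                t: (s.pairs if unit == "gene_ec_pair" else s.ec_set if unit == "ec" else s.gene_set)
                for t, s in sets.items()
            }
            oracle = brute_force_regions(projected)
            assert part.regions == oracle
            assert sum(part.counts.values()) == len(set().union(*projected.values()))
            assert sum(part.per_tool_unique.values()) == part.counts[1]


class TestPairwiseAgreement:
    def test_printed_pooled_pair_formats_exactly(self):
        from metanno.consensus import PairwiseAgreement

        assert PairwiseAgreement("kegg", "rast", 16697, 20915).pct == 79.8

    def test_hand_enumeration(self):
        a = aset("a", {("g1", E[1]), ("g2", E[2])})
        b = aset("b", {("g1", E[1]), ("g1", E[3]), ("g2", E[4]), ("g3", E[5])})
        agr = pairwise_gene_agreement(a, b)
        assert (agr.numerator, agr.denominator, agr.pct) == (1, 2, 50.0)

    def test_identical_sets_agree_fully(self):
        a = aset("a", {("g1", E[1]), ("g2", E[2])})
        b = aset("b", set(a.pairs))
        agr = pairwise_gene_agreement(a, b)
        assert agr.numerator == agr.denominator and agr.pct == 100.0

    def test_zero_denominator_reports_absent(self):
        agr = pairwise_gene_agreement(aset("a", {("g1", E[1])}), aset("b", {("g2", E[2])}))
        assert agr.denominator == 0 and agr.pct is None

    def test_symmetric(self, rng):
        for _ in range(30):
            sets = random_annotation_sets(rng, n_tools=2)
            a, b = sets["tool0"], sets["tool1"]
            fwd, rev = pairwise_gene_agreement(a, b), pairwise_gene_agreement(b, a)
            assert (fwd.numerator, fwd.denominator) == (rev.numerator, rev.denominator)

    def test_adding_records_never_shrinks_denominator(self, rng):
        for _ in range(20):
            sets = random_annotation_sets(rng, n_tools=2)
            a, b = sets["tool0"], sets["tool1"]
            before = pairwise_gene_agreement(a, b).denominator
            grown = AnnotationSet(a.genome_id, a.tool, a.pairs | {("gNEW", E[0]), ("g0", E[9])})
            assert pairwise_gene_agreement(grown, b).denominator >= before

    def test_pooling_sums_numerators_and_denominators(self):
        by_genome = {
            "G1": {
                "a": aset("a", {("g1", E[1])}, "G1"),
                "b": aset("b", {("g1", E[1])}, "G1"),
            },
            "G2": {
                "a": aset("a", {("g1", E[1]), ("g2", E[2])}, "G2"),
                "b": aset("b", {("g1", E[3]), ("g2", E[2])}, "G2"),
            },
        }
        pooled = aggregate_pairwise(by_genome)[("a", "b")]
        assert (pooled.numerator, pooled.denominator) == (2, 3)


class TestSupportDistribution:
    def test_uniform_counts(self):
        # one unit at each support level 1..4
        sets = {
            "t0": aset("t0", {("g1", E[1]), ("g2", E[2]), ("g3", E[3]), ("g4", E[4])}),
            "t1": aset("t1", {("g2", E[2]), ("g3", E[3]), ("g4", E[4])}),
            "t2": aset("t2", {("g3", E[3]), ("g4", E[4])}),
            "t3": aset("t3", {("g4", E[4])}),
        }
        dist = support_distribution(sets, unit="ec")
        assert dist.fractions == {1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25}
        assert dist.ge3_fraction == 0.5

    def test_all_tools_full_support(self):
        pairs = {("g1", E[1]), ("g2", E[2])}
        sets = {t: aset(t, pairs) for t in ["t0", "t1", "t2", "t3"]}
        assert support_distribution(sets, unit="ec").ge3_fraction == 1.0

    def test_single_tool_fraction_arithmetic(self):
        # counts {1:48, 2:19, 3:20, 4:13} → single-tool fraction 0.48
        sets = {t: set() for t in ["t0", "t1", "t2", "t3"]}
        i = 0
        for level, n in [(1, 48), (2, 19), (3, 20), (4, 13)]:
            for _ in range(n):
                unit = (f"g{i}", make_ec(i))
                for t in list(sets)[:level]:
                    sets[t].add(unit)
                i += 1
        sets = {t: aset(t, p) for t, p in sets.items()}
        dist = support_distribution(sets, unit="gene_ec_pair")
        assert dist.fractions[1] == pytest.approx(0.48)
        assert dist.ge3_fraction == pytest.approx(0.33)

    def test_fractions_sum_to_one(self, rng):
        for _ in range(30):
            sets = random_annotation_sets(rng)
            dist = support_distribution(sets, unit="ec")
            assert abs(sum(dist.fractions.values()) - 1.0) < 1e-12

    def test_empty_union_rejected(self):
        sets = {"a": aset("a", set()), "b": aset("b", set())}
        with pytest.raises(ValueError, match="empty union"):
            support_distribution(sets)


class TestGeneCoverage:
    def test_disjoint_sets_no_multitool(self):
        cov = gene_coverage({"a": aset("a", {("g1", E[1])}), "b": aset("b", {("g2", E[2])})})
        assert cov.multi_tool_fraction == 0.0

    def test_identical_sets_full_multitool(self):
        pairs = {("g1", E[1]), ("g2", E[2])}
        cov = gene_coverage({"a": aset("a", pairs), "b": aset("b", pairs)})
        assert cov.multi_tool_fraction == 1.0

    def test_hand_enumeration(self):
        cov = gene_coverage(
            {
                "a": aset("a", {("g1", E[1]), ("g2", E[2])}),
                "b": aset("b", {("g2", E[3]), ("g3", E[4])}),
            }
        )
        assert cov.union_size == 3
        assert cov.multi_tool_fraction == pytest.approx(1 / 3)
        assert cov.per_tool == {"a": 2, "b": 2}


def test_mean_region_counts_one_decimal():
    by_genome = {
        "G1": {
            "a": aset("a", {("g1", E[1]), ("g2", E[2])}, "G1"),
            "b": aset("b", {("g1", E[1])}, "G1"),
        },
        "G2": {
            "a": aset("a", {("g1", E[1])}, "G2"),
            "b": aset("b", {("g1", E[1])}, "G2"),
        },
    }
    means = mean_region_counts(by_genome, unit="ec")
    assert means[frozenset({"a", "b"})] == 1.0
    assert means[frozenset({"a"})] == 0.5
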