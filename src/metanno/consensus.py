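"""Cross-tool overlap and agreement statistics.

Given per-tool :class:`~metanno.model.AnnotationSet`s for a genome, this
module computes:

* **Support partitions** — how many annotation units (gene-EC pairs,
  distinct ECs, or genes) are supported by exactly k of the T tools,
  including the full 2^T − 1 Venn region table and per-tool-unique counts.
* **Pairwise gene-level agreement** — among genes covered by both tools of
  a pair, the fraction for which the tools share at least one identical
  gene-EC annotation.  Cross-genome aggregation pools numerators and
  denominators; per-genome means are reported alongside.
* **Support distributions** (fractions by support level and the ≥3-tool
  fraction used to order genomes by annotation consistency).
* **Gene coverage** — genes with at least one complete EC per tool, and
  the fraction of the union covered by more than one tool.

Units are compared exactly; there is no hierarchy-aware EC matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

from ._fmt import agreement_pct, round_half_away
from .model import AnnotationSet

__all__ = [
    "UNIT_KINDS",
    "SupportPartition",
    "PairwiseAgreement",
    "SupportDistribution",
    "GeneCoverage",
    "support_partition",
    "pairwise_gene_agreement",
    "aggregate_pairwise",
    "support_distribution",
    "gene_coverage",
    "mean_region_counts",
]

UNIT_KINDS = ("gene_ec_pair", "ec", "gene")


def _units(aset: AnnotationSet, unit: str) -> frozenset:
    if unit == "gene_ec_pair":
        return aset.pairs
    if unit == "ec":
        return aset.ec_set
    if unit == "gene":
        return aset.gene_set
    raise ValueError(f"unknown unit kind {unit!r}; expected one of {UNIT_KINDS}")


def _check_sets(sets: Mapping[str, AnnotationSet], min_tools: int = 2) -> None:
    if len(sets) < min_tools:
        raise ValueError(f"need at least {min_tools} tools, got {len(sets)}")
    genomes = {s.genome_id for s in sets.values()}
    if len(genomes) > 1:
        raise ValueError(f"annotation sets span multiple genomes: {sorted(genomes)}")
    for tool, s in sets.items():
        if s.tool != tool:
            raise ValueError(f"set keyed {tool!r} carries tool label {s.tool!r}")


@dataclass
class SupportPartition:
    """Venn decomposition of annotation units across tools for one genome."""

    genome_id: str
    unit: str
    tools: tuple[str, ...]
    #: support level k (number of tools carrying the unit) → unit count
    counts: dict[int, int]
    #: tool → units carried by that tool and no other
    per_tool_unique: dict[str, int]
    #: frozenset of tool labels (non-empty) → exclusive Venn region count
    regions: dict[frozenset, int]

    @property
    def union_size(self) -> int:
        return sum(self.counts.values())


def support_partition(sets: Mapping[str, AnnotationSet], unit: str = "gene_ec_pair") -> SupportPartition:
    """Partition the union of units by the exact set of tools supporting each.

    ``counts[k]`` sums to the union cardinality over k; ``per_tool_unique``
    sums to ``counts[1]``.
    """
    _check_sets(sets)
    tools = tuple(sorted(sets))
    per_tool = {t: _units(sets[t], unit) for t in tools}
    union = frozenset().union(*per_tool.values())
    regions: dict[frozenset, int] = {}
    for u in union:
        supporters = frozenset(t for t in tools if u in per_tool[t])
        regions[supporters] = regions.get(supporters, 0) + 1
    counts: dict[int, int] = {k: 0 for k in range(1, len(tools) + 1)}
    for supporters, n in regions.items():
        counts[len(supporters)] += n
    unique = {t: regions.get(frozenset({t}), 0) for t in tools}
    genome = next(iter(sets.values())).genome_id
    return SupportPartition(genome, unit, tools, counts, unique, regions)


@dataclass
class PairwiseAgreement:
    """Gene-level agreement between two tools.

    The denominator counts genes with at least one EC from *both* tools;
    the numerator counts those genes for which the tools share at least one
    identical gene-EC annotation.
    """

    tool_a: str
    tool_b: str
    numerator: int
    denominator: int

    @property
    def pct(self) -> Optional[float]:
        return agreement_pct(self.numerator, self.denominator)


def pairwise_gene_agreement(a: AnnotationSet, b: AnnotationSet) -> PairwiseAgreement:
    """Agreement between two tools over the genes both cover; symmetric."""
    if a.genome_id != b.genome_id:
        raise ValueError(f"genome mismatch: {a.genome_id!r} vs {b.genome_id!r}")
    ecs_a: dict[str, set] = {}
    ecs_b: dict[str, set] = {}
    for g, ec in a.pairs:
        ecs_a.setdefault(g, set()).add(ec)
    for g, ec in b.pairs:
        ecs_b.setdefault(g, set()).add(ec)
    shared_genes = ecs_a.keys() & ecs_b.keys()
    numerator = sum(1 for g in shared_genes if ecs_a[g] & ecs_b[g])
    return PairwiseAgreement(a.tool, b.tool, numerator, len(shared_genes))


def aggregate_pairwise(
    sets_by_genome: Mapping[str, Mapping[str, AnnotationSet]]
) -> dict[tuple[str, str], PairwiseAgreement]:
    """Pool pairwise agreements over genomes.

    Numerators and denominators are summed across genomes (the pooled
    convention of multi-genome agreement tables); pairs are keyed by sorted
    tool labels.  A pair appears whenever both tools are present in at
    least one genome.
    """
    pooled: dict[tuple[str, str], list[int]] = {}
    for genome_sets in sets_by_genome.values():
        for ta, tb in combinations(sorted(genome_sets), 2):
            agr = pairwise_gene_agreement(genome_sets[ta], genome_sets[tb])
            acc = pooled.setdefault((ta, tb), [0, 0])
            acc[0] += agr.numerator
            acc[1] += agr.denominator
    return {
        pair: PairwiseAgreement(pair[0], pair[1], num, den)
        for pair, (num, den) in sorted(pooled.items())
    }


@dataclass
class SupportDistribution:
    """Fractions of units at each support level for one genome."""

    genome_id: str
    unit: str
    fractions: dict[int, float]
    #: fraction of units supported by ≥3 tools — the genome ordering key
    ge3_fraction: float
    union_size: int


def support_distribution(sets: Mapping[str, AnnotationSet], unit: str = "ec") -> SupportDistribution:
    """Fraction of units at each support level; fractions sum to 1."""
    part = support_partition(sets, unit)
    total = part.union_size
    if total == 0:
        raise ValueError("empty union across tools; support distribution undefined")
    fractions = {k: n / total for k, n in part.counts.items()}
    ge3 = sum(n for k, n in part.counts.items() if k >= 3) / total
    return SupportDistribution(part.genome_id, unit, fractions, ge3, total)


@dataclass
class GeneCoverage:
    """Per-tool counts of genes with ≥1 complete EC, and multi-tool overlap."""

    genome_id: str
    per_tool: dict[str, int]
    union_size: int
    #: fraction of the union annotated by at least two tools
    multi_tool_fraction: float


def gene_coverage(sets: Mapping[str, AnnotationSet]) -> GeneCoverage:
    _check_sets(sets)
    per_tool_genes = {t: s.gene_set for t, s in sets.items()}
    union = set().union(*per_tool_genes.values())
    multi = sum(1 for g in union if sum(g in gs for gs in per_tool_genes.values()) >= 2)
    frac = multi / len(union) if union else 0.0
    genome = next(iter(sets.values())).genome_id
    return GeneCoverage(genome, {t: len(gs) for t, gs in sorted(per_tool_genes.items())}, len(union), frac)


def mean_region_counts(
    sets_by_genome: Mapping[str, Mapping[str, AnnotationSet]], unit: str = "ec"
) -> dict[frozenset, float]:
    """Arithmetic mean of per-genome Venn region counts, one decimal.

    Regions absent in a genome count as zero there, so means are comparable
    across genomes with different tool coverage of the same tool panel.
    """
    genomes = list(sets_by_genome)
    if not genomes:
        raise ValueError("no genomes")
    totals: dict[frozenset, int] = {}
    for genome_sets in sets_by_genome.values():
        part = support_partition(genome_sets, unit)
        for region, n in part.regions.items():
            totals[region] = totals.get(region, 0) + n
    return {region: round_half_away(n / len(genomes), 1) for region, n in totals.items()}
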