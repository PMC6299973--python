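"""Gold-standard evaluation of tool combinations.

A curated reference (an EcoCyc-like set of gene-EC pairs, or its projected
EC set) defines true positives.  For any subset S of tools one can predict
with the *union* (ECs produced by at least one tool in S — higher coverage)
or the *intersection* (ECs produced by every tool in S — higher
confidence), and score each combination by

    precision = TP / (TP + FP)        recall = TP / (TP + FN)

where TP are predicted ECs found in the reference, FP predicted ECs absent
from it, and FN reference ECs not predicted.  ``pr_sweep`` scores every
non-empty subset under both modes; singletons are emitted once since their
union and intersection coincide.  Benchmarking here is at the EC-set level;
the gene-EC-pair-level three-way comparison against the gold standard is a
separate operation (:func:`gene_ec_confusion`).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import AbstractSet, Mapping, Optional, Sequence

from .model import AnnotationSet, GoldStandard

__all__ = [
    "ToolCombination",
    "PRResult",
    "combine",
    "precision_recall",
    "pr_sweep",
    "gene_ec_confusion",
]

MODES = ("union", "intersection")


@dataclass(frozen=True)
class ToolCombination:
    """A non-empty subset of tools plus a combination mode."""

    tools: tuple[str, ...]
    mode: str

    def __post_init__(self) -> None:
        if not self.tools:
            raise ValueError("tool combination must be non-empty")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        object.__setattr__(self, "tools", tuple(sorted(self.tools)))

    def label(self, initials: Optional[Mapping[str, str]] = None) -> str:
        """Compact label like ``K+R∩`` (initials upper-cased, singleton unmarked)."""
        if initials is None:
            firsts = [t[0].upper() for t in self.tools]
            initials = (
                {t: t[0].upper() for t in self.tools}
                if len(set(firsts)) == len(self.tools)
                else {t: t for t in self.tools}
            )
        base = "+".join(initials[t] for t in self.tools)
        if len(self.tools) == 1:
            return base
        return base + ("∪" if self.mode == "union" else "∩")


@dataclass
class PRResult:
    """TP/FP/FN and precision/recall for one tool combination.

    ``precision`` is absent (``None``) when nothing was predicted — an
    undefined ratio, reported as such rather than as 0 or 1.
    """

    combination: ToolCombination
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> Optional[float]:
        predicted = self.tp + self.fp
        return self.tp / predicted if predicted else None

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn)


def combine(sets: Mapping[str, AbstractSet], combo: ToolCombination) -> frozenset:
    """Union or intersection of the named tools' sets, exact."""
    missing = [t for t in combo.tools if t not in sets]
    if missing:
        raise KeyError(f"unknown tool(s) {missing}; have {sorted(sets)}")
    members = [frozenset(sets[t]) for t in combo.tools]
    if combo.mode == "union":
        return frozenset().union(*members)
    return frozenset.intersection(*members)


def precision_recall(predicted: AbstractSet, gold: AbstractSet,
                     combination: Optional[ToolCombination] = None) -> PRResult:
    """Score a predicted set against a non-empty gold set; exact counts.

    Works for any hashable unit — EC numbers for set-level benchmarking,
    (gene, EC) pairs for pair-level checks.
    """
    if not gold:
        raise ValueError("gold set is empty; recall undefined")
    predicted = frozenset(predicted)
    gold = frozenset(gold)
    tp = len(predicted & gold)
    combo = combination or ToolCombination(("predicted",), "union")
    return PRResult(combo, tp=tp, fp=len(predicted) - tp, fn=len(gold) - tp)


def pr_sweep(sets: Mapping[str, AbstractSet], gold: AbstractSet) -> list[PRResult]:
    """PRResult for every non-empty tool subset × {union, intersection}.

    Singletons appear once (their two modes coincide), so T tools yield
    (2^T − 1) × 2 − T rows: 26 for the four-tool panel.  Output order is
    deterministic — subset size, then lexicographic tool labels, union
    before intersection.
    """
    if not sets:
        raise ValueError("need at least one tool")
    tools = sorted(sets)
    results: list[PRResult] = []
    for size in range(1, len(tools) + 1):
        for subset in combinations(tools, size):
            for mode in MODES:
                if size == 1 and mode == "intersection":
                    continue
                combo = ToolCombination(subset, mode)
                results.append(precision_recall(combine(sets, combo), gold, combo))
    return results


def gene_ec_confusion(
    a: AnnotationSet, b: AnnotationSet, gold: GoldStandard
) -> dict[frozenset, int]:
    """Seven-region Venn counts over gene-EC pairs for two tools plus gold.

    Keys are non-empty frozensets over {tool_a label, tool_b label,
    "gold"}; values are exclusive region counts.  Regions with no pairs are
    present with count 0.
    """
    if a.genome_id != b.genome_id or a.genome_id != gold.genome_id:
        raise ValueError(
            f"genome mismatch: {a.genome_id!r}, {b.genome_id!r}, {gold.genome_id!r}"
        )
    labeled = {a.tool: a.pairs, b.tool: b.pairs, "gold": gold.pairs}
    labels = tuple(labeled)
    regions: dict[frozenset, int] = {}
    for size in (1, 2, 3):
        for subset in combinations(labels, size):
            regions[frozenset(subset)] = 0
    for pair in frozenset().union(*labeled.values()):
        members = frozenset(lab for lab, s in labeled.items() if pair in s)
        regions[members] += 1
    return regions
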