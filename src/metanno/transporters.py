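"""Transporter substrate-specificity ranking and cross-tool agreement.

Substrate predictions attached to membrane-transporter genes vary from
model-ready metabolites down to vague classes or nothing at all.  The
five-level ranking used here runs from most to least specific:

* rank 1 — a metabolite usable directly as a transport reaction in a
  metabolic model (``Fe``, ``lysine``);
* rank 2 — substrate(s) mapping to a small number of possible transport
  reactions (``Mg/Co/Ni``, ``aromatic amino acid``);
* rank 3 — a broader substrate class, not directly usable (``dipeptide``,
  ``sugar``);
* rank 4 — a very broad class (``multidrug efflux``, ``protein``);
* rank 5 — no substrate annotated (never stored in the vocabulary).

A :class:`SubstrateVocabulary` assigns ranks 1–4 to normalized substrate
strings and groups near-synonymous terms ("leucine/valine", "leucine",
"branched-chain amino acid") into flat equivalence classes used when
judging whether tools agree on a substrate.  Substrates that are present
but unknown to the vocabulary map to rank 5 with a separate "unranked"
tally, so curation gaps remain visible instead of inflating ranks 3–4.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

from ._fmt import agreement_pct
from .model import FormatError, GeneAnnotation

__all__ = [
    "SubstrateVocabulary",
    "TransporterAnnotation",
    "RankDistribution",
    "OverlapReport",
    "AgreementReport",
    "normalize_substrate",
    "rank_substrate",
    "assign_ranks",
    "rank_distribution",
    "three_tool_overlap",
    "substrate_agreement",
    "load_vocabulary",
    "bundled_vocabulary",
]

_STRIP_CHARS = " \t\r\n.,;:!?\"'()[]"


def normalize_substrate(text: Optional[str]) -> Optional[str]:
    """Lowercase, trim, collapse internal whitespace, strip surrounding punctuation.

    Empty input (or input that is empty after stripping) is absent: ``None``.
    """
    if text is None:
        return None
    cleaned = " ".join(text.strip(_STRIP_CHARS).lower().split())
    return cleaned or None


@dataclass(frozen=True)
class SubstrateVocabulary:
    """Normalized substrate → rank (1–4) plus flat synonym classes."""

    entries: Mapping[str, int]
    #: substrate → synonym group id; every keyed substrate is in ``entries``
    synonym_groups: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for substrate, rank in self.entries.items():
            if rank not in (1, 2, 3, 4):
                raise ValueError(f"vocabulary rank must be 1..4, got {rank} for {substrate!r}")
            if substrate != normalize_substrate(substrate):
                raise ValueError(f"vocabulary substrate not normalized: {substrate!r}")
        for substrate in self.synonym_groups:
            if substrate not in self.entries:
                raise ValueError(f"synonym-class member {substrate!r} missing from entries")

    def rank(self, substrate: Optional[str]) -> int:
        return rank_substrate(substrate, self)

    def group_of(self, substrate: str) -> str:
        """Synonym class id; ungrouped substrates form singleton classes."""
        return self.synonym_groups.get(substrate, f"~{substrate}")

    def same_class(self, a: str, b: str) -> bool:
        return self.group_of(a) == self.group_of(b)


def rank_substrate(substrate: Optional[str], vocab: SubstrateVocabulary) -> int:
    """Rank of a normalized substrate: vocabulary rank, else 5.

    Absent substrates and substrates unknown to the vocabulary both rank 5;
    the caller distinguishes the two cases via :func:`assign_ranks` tallies.
    """
    if substrate is None:
        return 5
    return vocab.entries.get(substrate, 5)


@dataclass(frozen=True)
class TransporterAnnotation:
    """One tool's transporter call for one gene, with its specificity rank."""

    genome_id: str
    gene_id: str
    tool: str
    substrate: Optional[str]
    rank: int

    def __post_init__(self) -> None:
        if self.rank not in (1, 2, 3, 4, 5):
            raise ValueError(f"rank must be in 1..5, got {self.rank}")
        if self.rank < 5 and self.substrate is None:
            raise ValueError("rank < 5 requires a substrate")


def assign_ranks(
    records: Iterable[GeneAnnotation], vocab: SubstrateVocabulary
) -> tuple[list[TransporterAnnotation], dict[str, int]]:
    """Normalize and rank TRANSPORT records; tally unranked substrates.

    Returns the ranked annotations plus tallies: ``absent`` (no substrate
    text) and ``unranked`` (substrate present but unknown to the
    vocabulary — a curation gap, ranked 5 but counted separately).
    """
    out: list[TransporterAnnotation] = []
    tallies = {"absent": 0, "unranked": 0}
    for r in records:
        if r.feature_type != "TRANSPORT":
            continue
        substrate = normalize_substrate(r.substrate)
        rank = rank_substrate(substrate, vocab)
        if substrate is None:
            tallies["absent"] += 1
        elif rank == 5:
            tallies["unranked"] += 1
        out.append(TransporterAnnotation(r.genome_id, r.gene_id, r.tool, substrate, rank))
    return out, tallies


@dataclass
class RankDistribution:
    """Per-tool transporter counts and fractions by specificity rank."""

    tool: str
    #: distinct (genome, gene) transporter calls by this tool
    total_genes: int
    counts: dict[int, int]
    fractions: dict[int, float]
    #: fraction of calls specific enough for a metabolic model (rank 1–2)
    specific_fraction: float


def _best_rank_per_gene(
    annotations: Iterable[TransporterAnnotation],
) -> dict[str, dict[tuple[str, str], int]]:
    """tool → (genome, gene) → best (lowest) rank among that tool's records."""
    best: dict[str, dict[tuple[str, str], int]] = {}
    for a in annotations:
        per_tool = best.setdefault(a.tool, {})
        key = (a.genome_id, a.gene_id)
        per_tool[key] = min(per_tool.get(key, 5), a.rank)
    return best


def rank_distribution(annotations: Iterable[TransporterAnnotation]) -> dict[str, RankDistribution]:
    """Per-tool rank profile over distinct transporter genes.

    A gene annotated by one tool with several substrates contributes its
    best (most specific) rank once.  Fractions sum to 1 per tool; an empty
    input yields an empty mapping.
    """
    best = _best_rank_per_gene(annotations)
    out: dict[str, RankDistribution] = {}
    for tool in sorted(best):
        ranks = list(best[tool].values())
        total = len(ranks)
        counts = {k: ranks.count(k) for k in range(1, 6)}
        fractions = {k: (counts[k] / total if total else 0.0) for k in range(1, 6)}
        specific = fractions[1] + fractions[2]
        out[tool] = RankDistribution(tool, total, counts, fractions, specific)
    return out


@dataclass
class OverlapReport:
    """Cross-tool transporter-gene overlap pooled over genomes."""

    tools: tuple[str, ...]
    #: Σ over tools of distinct (genome, gene) calls — the pooled denominator
    pooled_annotations: int
    #: distinct (genome, gene) annotated by every tool
    all_tools_genes: int
    #: of those, genes receiving rank ≤ 2 from every tool
    all_tools_specific: int
    per_tool_genes: dict[str, int]
    #: genes annotated by all tools, exported for alternative accountings
    shared_gene_ids: frozenset[tuple[str, str]]

    @property
    def agreement_pct(self) -> Optional[float]:
        return agreement_pct(self.all_tools_genes, self.pooled_annotations)


def three_tool_overlap(annotations: Iterable[TransporterAnnotation]) -> OverlapReport:
    """Overlap of transporter gene calls across the tool panel.

    The denominator pools distinct (genome, gene, tool) annotation
    instances across all genomes; the numerator counts distinct genes
    annotated by *all* tools, regardless of substrate.  Both underlying
    sets are exported so alternative accountings can be recomputed.
    """
    best = _best_rank_per_gene(annotations)
    if len(best) < 2:
        raise ValueError(f"need at least 2 transporter tools, got {len(best)}")
    tools = tuple(sorted(best))
    pooled = sum(len(best[t]) for t in tools)
    shared = frozenset.intersection(*(frozenset(best[t]) for t in tools))
    specific = sum(1 for key in shared if all(best[t][key] <= 2 for t in tools))
    return OverlapReport(
        tools=tools,
        pooled_annotations=pooled,
        all_tools_genes=len(shared),
        all_tools_specific=specific,
        per_tool_genes={t: len(best[t]) for t in tools},
        shared_gene_ids=shared,
    )


@dataclass
class AgreementReport:
    """Substrate agreement among tools giving specific (rank ≤ 2) predictions."""

    qualifying_genes: int
    agreeing_genes: int
    #: (tool_a, tool_b) → (agreeing, qualifying) over genes where both are specific
    per_pair: dict[tuple[str, str], tuple[int, int]]

    @property
    def fraction(self) -> Optional[float]:
        if self.qualifying_genes == 0:
            return None
        return self.agreeing_genes / self.qualifying_genes


def substrate_agreement(
    annotations: Iterable[TransporterAnnotation], vocab: SubstrateVocabulary
) -> AgreementReport:
    """Do tools that make specific predictions name the same substrate?

    Over genes where ≥2 tools assign a rank ≤ 2 substrate, a gene counts as
    agreeing when *all* those substrates fall into a single synonym class
    ("leucine/valine", "leucine" and "branched-chain amino acid" agree when
    the vocabulary groups them).  Invariant to annotation order and to
    internal relabeling of synonym classes.
    """
    specific: dict[tuple[str, str], dict[str, set[str]]] = {}
    for a in annotations:
        if a.rank <= 2 and a.substrate is not None:
            specific.setdefault((a.genome_id, a.gene_id), {}).setdefault(a.tool, set()).add(a.substrate)
    qualifying = agreeing = 0
    per_pair: dict[tuple[str, str], list[int]] = {}
    for by_tool in specific.values():
        if len(by_tool) < 2:
            continue
        qualifying += 1
        all_substrates = set().union(*by_tool.values())
        classes = {vocab.group_of(s) for s in all_substrates}
        if len(classes) == 1:
            agreeing += 1
        tools = sorted(by_tool)
        for i, ta in enumerate(tools):
            for tb in tools[i + 1 :]:
                pair_classes = {vocab.group_of(s) for s in by_tool[ta] | by_tool[tb]}
                acc = per_pair.setdefault((ta, tb), [0, 0])
                acc[1] += 1
                if len(pair_classes) == 1:
                    acc[0] += 1
    return AgreementReport(
        qualifying,
        agreeing,
        {pair: (a, q) for pair, (a, q) in sorted(per_pair.items())},
    )


# ---------------------------------------------------------------------------
# Vocabulary I/O
# ---------------------------------------------------------------------------

def load_vocabulary(path: Union[str, Path]) -> SubstrateVocabulary:
    """Load a vocabulary TSV with columns substrate, rank, synonym_group_id."""
    entries: dict[str, int] = {}
    groups: dict[str, str] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header: Optional[dict[str, int]] = None
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if header is None:
                header = {name: i for i, name in enumerate(row)}
                missing = [c for c in ("substrate", "rank") if c not in header]
                if missing:
                    raise FormatError(f"{path}:{lineno}: missing column(s) {missing}")
                continue
            substrate = normalize_substrate(row[header["substrate"]])
            if substrate is None:
                raise FormatError(f"{path}:{lineno}: empty substrate")
            try:
                entries[substrate] = int(row[header["rank"]])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer rank") from None
            gi = header.get("synonym_group_id")
            if gi is not None and gi < len(row) and row[gi].strip():
                groups[substrate] = row[gi].strip()
    return SubstrateVocabulary(entries, groups)


def bundled_vocabulary() -> SubstrateVocabulary:
    """The small starter vocabulary shipped with the package.

    Covers the canonical rank examples plus a few synonym classes; real
    analyses should supply a fuller curated table.
    """
    ref = resources.files("metanno").joinpath("data/substrate_ranks.tsv")
    with resources.as_file(ref) as path:
        return load_vocabulary(path)
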