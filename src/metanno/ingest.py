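"""Tool-specific converters to the normalized annotation format.

Each annotation tool family ships results in its own shape; the ingesters
here apply the normalization rules that make the outputs comparable:

* RAST-style function strings with embedded ``(EC x.x.x.x)`` tokens are
  split into one record per extracted EC.
* KAAS-style gene→KO assignments are expanded through a KO→EC mapping
  table (one record per mapped EC; KOs without an EC are tallied).
* BLAST tabular hits against an EC-labeled reference transfer the
  subject's EC(s) to the query when percent identity exceeds the
  threshold (strictly greater than 60% by default).
* Transporter tables become TRANSPORT records, keeping absent substrates
  absent (they become rank 5 downstream).

All ingesters are deterministic and order-independent: permuting input
rows yields identical record sets.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

from .ec import ECNumber, ECParseError, extract_ecs_from_function, parse_ec
from .model import (
    DEFAULT_TRANSPORT_TOOLS,
    FormatError,
    GeneAnnotation,
)

__all__ = [
    "KoEcMap",
    "BlastHit",
    "IngestResult",
    "ingest_rast",
    "ingest_kaas",
    "ingest_blast",
    "ingest_eficaz",
    "ingest_transporters",
    "load_ko_ec_map",
    "load_subject_ec_index",
    "read_blast_tabular",
    "read_two_column_table",
]

_KO_RE = re.compile(r"^K\d{5}$")


@dataclass(frozen=True)
class KoEcMap:
    """Mapping from KEGG Orthology id (``Kddddd``) to a set of ECs.

    One KO may map to zero, one, or many EC numbers; multi-mapped KOs are
    fully expanded during ingest.
    """

    entries: Mapping[str, frozenset[ECNumber]]

    def __post_init__(self) -> None:
        for ko in self.entries:
            if not _KO_RE.match(ko):
                raise ValueError(f"malformed KO id in map: {ko!r}")

    def get(self, ko: str) -> Optional[frozenset[ECNumber]]:
        return self.entries.get(ko)


@dataclass(frozen=True)
class BlastHit:
    """One row of 12-column BLAST tabular output (outfmt 6)."""

    query_gene: str
    subject_id: str
    identity_pct: float
    align_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError(f"identity_pct outside [0, 100]: {self.identity_pct}")
        if self.evalue < 0:
            raise ValueError(f"negative e-value: {self.evalue}")


@dataclass
class IngestResult:
    """Normalized records plus ingest tallies (unmapped KOs, skipped hits...)."""

    records: list[GeneAnnotation]
    tallies: dict[str, int] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _dedup(records: Iterable[GeneAnnotation]) -> list[GeneAnnotation]:
    seen: dict[GeneAnnotation, None] = {}
    for r in records:
        seen.setdefault(r, None)
    return sorted(
        seen,
        key=lambda r: (r.genome_id, r.gene_id, r.tool, r.feature_type, r.value),
    )


def ingest_rast(
    rows: Iterable[tuple[str, str]], genome_id: str, tool: str = "rast"
) -> IngestResult:
    """Split (gene_id, function_text) rows into one EC record per extracted EC.

    Genes whose function text carries no ``(EC ...)`` token produce no
    records; they are tallied under ``no_ec_function``.
    """
    records: list[GeneAnnotation] = []
    no_ec = 0
    for gene_id, function_text in rows:
        ecs = extract_ecs_from_function(function_text)
        if not ecs:
            no_ec += 1
            continue
        for ec in ecs:
            records.append(
                GeneAnnotation(genome_id, gene_id, tool, "EC", ec=ec, raw_function=function_text)
            )
    return IngestResult(_dedup(records), {"no_ec_function": no_ec})


def ingest_kaas(
    rows: Iterable[tuple[str, str]], ko_map: KoEcMap, genome_id: str, tool: str = "kegg"
) -> IngestResult:
    """Expand (gene_id, ko_id) rows through the KO→EC map.

    Each (gene, KO) yields one record per mapped EC.  KOs absent from the
    map are tallied under ``unmapped_ko``; KOs mapping to an empty EC set
    under ``ko_without_ec``.  Both yield no EC records.
    """
    records: list[GeneAnnotation] = []
    unmapped = no_ec = 0
    for gene_id, ko in rows:
        ko = ko.strip()
        if not _KO_RE.match(ko):
            raise FormatError(f"malformed KO id {ko!r} for gene {gene_id!r}")
        ecs = ko_map.get(ko)
        if ecs is None:
            unmapped += 1
            continue
        if not ecs:
            no_ec += 1
            continue
        for ec in ecs:
            records.append(GeneAnnotation(genome_id, gene_id, tool, "EC", ec=ec, ko=None))
    return IngestResult(_dedup(records), {"unmapped_ko": unmapped, "ko_without_ec": no_ec})


def ingest_blast(
    hits: Iterable[BlastHit],
    subject_ec_index: Mapping[str, frozenset[ECNumber]],
    genome_id: str,
    tool: str = "brenda",
    min_identity: float = 60.0,
    best_hit_only: bool = False,
    max_evalue: Optional[float] = None,
) -> IngestResult:
    """Transfer subject ECs to query genes for hits above the identity threshold.

    A hit qualifies when ``identity_pct`` is *strictly* greater than
    ``min_identity`` (a hit at exactly the threshold is discarded).  All
    qualifying hits transfer by default; with ``best_hit_only`` only each
    query's best hit (highest bit score, ties broken by lowest e-value then
    lexicographic subject id) is used.  Resulting (gene, EC) pairs are
    deduplicated per gene, and each record carries the maximum identity
    among its supporting hits.

    Subjects missing from ``subject_ec_index`` are tallied under
    ``uncovered_subject``, not fatal.
    """
    hits = list(hits)
    kept = [h for h in hits if h.identity_pct > min_identity]
    if max_evalue is not None:
        kept = [h for h in kept if h.evalue <= max_evalue]
    if best_hit_only:
        best: dict[str, BlastHit] = {}
        for h in sorted(kept, key=lambda h: (h.query_gene, -h.bit_score, h.evalue, h.subject_id)):
            best.setdefault(h.query_gene, h)
        kept = list(best.values())

    uncovered = 0
    support: dict[tuple[str, ECNumber], float] = {}
    for h in kept:
        ecs = subject_ec_index.get(h.subject_id)
        if ecs is None:
            uncovered += 1
            continue
        for ec in ecs:
            key = (h.query_gene, ec)
            support[key] = max(support.get(key, 0.0), h.identity_pct)
    records = [
        GeneAnnotation(genome_id, gene, tool, "EC", ec=ec, identity_pct=ident)
        for (gene, ec), ident in support.items()
    ]
    return IngestResult(
        _dedup(records),
        {"uncovered_subject": uncovered, "below_threshold": len(hits) - len(kept)},
    )


def ingest_eficaz(
    rows: Iterable[tuple[str, str]], genome_id: str, tool: str = "eficaz"
) -> IngestResult:
    """Normalize (gene_id, ec_string) rows; ECs are parsed and deduplicated.

    EFICAz-style output already pairs genes with EC strings (complete or
    three-digit partial), so ingest is parse + dedup only.
    """
    records: list[GeneAnnotation] = []
    for gene_id, ec_text in rows:
        records.append(GeneAnnotation(genome_id, gene_id, tool, "EC", ec=parse_ec(ec_text)))
    return IngestResult(_dedup(records))


def ingest_transporters(
    rows: Iterable[tuple[str, str, str]],
    genome_id: str,
    tools: frozenset[str] = DEFAULT_TRANSPORT_TOOLS,
) -> IngestResult:
    """Turn (gene_id, tool, substrate_text) rows into TRANSPORT records.

    Empty substrate text is preserved as absent (it becomes rank 5 in the
    substrate-specificity analysis).  Duplicate identical rows collapse to
    one record.
    """
    records: list[GeneAnnotation] = []
    for gene_id, tool, substrate_text in rows:
        if tool not in tools:
            raise FormatError(f"unregistered transporter tool {tool!r}")
        substrate = substrate_text.strip() or None
        records.append(GeneAnnotation(genome_id, gene_id, tool, "TRANSPORT", substrate=substrate))
    return IngestResult(_dedup(records))


# ---------------------------------------------------------------------------
# File readers for the native-ish shapes
# ---------------------------------------------------------------------------

def read_two_column_table(path: Union[str, Path]) -> list[tuple[str, str]]:
    """Read a headerless two-column TSV (gene_id, payload); ``#`` comments allowed."""
    out: list[tuple[str, str]] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(row)}")
            out.append((row[0].strip(), row[1].strip()))
    return out


def load_ko_ec_map(path: Union[str, Path]) -> KoEcMap:
    """Load a KO→EC map TSV: one ``ko_id<TAB>ec`` pair per line, empty ec allowed."""
    entries: dict[str, set[ECNumber]] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#") or row[0] == "ko_id":
                continue
            ko = row[0].strip()
            entries.setdefault(ko, set())
            ec_text = row[1].strip() if len(row) > 1 else ""
            if ec_text:
                try:
                    entries[ko].add(parse_ec(ec_text))
                except ECParseError as exc:
                    raise FormatError(f"{path}:{lineno}: {exc}") from None
    return KoEcMap({ko: frozenset(ecs) for ko, ecs in entries.items()})


def load_subject_ec_index(path: Union[str, Path]) -> dict[str, frozenset[ECNumber]]:
    """Load a subject→EC index TSV (``subject_id<TAB>ec``, one pair per line)."""
    index: dict[str, set[ECNumber]] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#") or row[0] == "subject_id":
                continue
            if len(row) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            try:
                index.setdefault(row[0].strip(), set()).add(parse_ec(row[1].strip()))
            except ECParseError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return {s: frozenset(e) for s, e in index.items()}


def read_blast_tabular(path: Union[str, Path]) -> list[BlastHit]:
    """Read 12-column BLAST tabular (outfmt 6) into :class:`BlastHit` rows."""
    hits: list[BlastHit] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 columns, got {len(row)}")
            try:
                hits.append(
                    BlastHit(
                        query_gene=row[0].strip(),
                        subject_id=row[1].strip(),
                        identity_pct=float(row[2]),
                        align_length=int(row[3]),
                        mismatches=int(row[4]),
                        gap_opens=int(row[5]),
                        q_start=int(row[6]),
                        q_end=int(row[7]),
                        s_start=int(row[8]),
                        s_end=int(row[9]),
                        evalue=float(row[10]),
                        bit_score=float(row[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return hits
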