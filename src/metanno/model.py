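"""Core annotation records, per-tool sets, gold standards, and TSV exchange.

The atomic unit throughout is the *gene-EC annotation*: "tool T assigns EC
number e to gene g in genome G".  Genes are identified by their locus tag,
the one identifier shared verbatim across tool outputs; ingesters never
re-call genes.  A gene may carry several ECs (multifunctional enzymes) and
an EC may appear on several genes (isozymes), so records form sets of
(gene, EC) pairs rather than a mapping.

All modules exchange data through one normalized TSV format (UTF-8,
tab-separated, single header row, ``#`` comments allowed, empty field =
absent) with columns::

    genome_id  gene_id  tool  feature_type  value  raw_function  identity_pct

where ``feature_type`` is ``EC``, ``KO`` or ``TRANSPORT`` and ``value`` holds
the canonical EC string, the KO id (``Kddddd``) or the substrate string.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from .ec import ECNumber, ECParseError, parse_ec

__all__ = [
    "FEATURE_TYPES",
    "DEFAULT_EC_TOOLS",
    "DEFAULT_TRANSPORT_TOOLS",
    "FormatError",
    "GeneAnnotation",
    "AnnotationSet",
    "GoldStandard",
    "filter_complete",
    "read_annotation_table",
    "write_annotation_table",
    "read_gold_standard",
    "write_gold_standard",
    "group_into_sets",
]

FEATURE_TYPES = ("EC", "KO", "TRANSPORT")

#: Registered enzyme-annotation tool labels (extensible per call site).
DEFAULT_EC_TOOLS = frozenset({"rast", "kegg", "eficaz", "brenda"})
#: Registered transporter-annotation tool labels.
DEFAULT_TRANSPORT_TOOLS = frozenset({"transportdb", "rast", "kegg"})

_KO_RE = re.compile(r"^K\d{5}$")

COLUMNS = ("genome_id", "gene_id", "tool", "feature_type", "value", "raw_function", "identity_pct")
MANDATORY = ("genome_id", "gene_id", "tool", "feature_type", "value")


class FormatError(ValueError):
    """Malformed input table; message carries the offending line number."""


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotation record: a tool's claim about one gene in one genome."""

    genome_id: str
    gene_id: str
    tool: str
    feature_type: str = "EC"
    ec: Optional[ECNumber] = None
    ko: Optional[str] = None
    substrate: Optional[str] = None
    raw_function: Optional[str] = None
    identity_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature_type {self.feature_type!r}")
        if self.ko is not None and not _KO_RE.match(self.ko):
            raise ValueError(f"malformed KO id {self.ko!r}")
        if self.identity_pct is not None and not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError(f"identity_pct outside [0, 100]: {self.identity_pct}")

    @property
    def value(self) -> str:
        if self.feature_type == "EC":
            return "" if self.ec is None else str(self.ec)
        if self.feature_type == "KO":
            return self.ko or ""
        return self.substrate or ""


@dataclass(frozen=True)
class AnnotationSet:
    """Distinct (gene, EC) pairs produced by one tool for one genome."""

    genome_id: str
    tool: str
    pairs: frozenset[tuple[str, ECNumber]]

    @classmethod
    def from_records(cls, records: Iterable[GeneAnnotation]) -> "AnnotationSet":
        records = [r for r in records if r.feature_type == "EC" and r.ec is not None]
        if not records:
            raise ValueError("no EC records to build an AnnotationSet from")
        genomes = {r.genome_id for r in records}
        tools = {r.tool for r in records}
        if len(genomes) != 1 or len(tools) != 1:
            raise ValueError(f"records span genomes {genomes} and tools {tools}; expected one each")
        return cls(genomes.pop(), tools.pop(), frozenset((r.gene_id, r.ec) for r in records))

    @property
    def ec_set(self) -> frozenset[ECNumber]:
        return frozenset(ec for _, ec in self.pairs)

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.pairs)

    def ecs_of(self, gene_id: str) -> frozenset[ECNumber]:
        return frozenset(ec for g, ec in self.pairs if g == gene_id)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class GoldStandard:
    """Curated reference gene-EC pairs defining true positives for one genome."""

    genome_id: str
    pairs: frozenset[tuple[str, ECNumber]]

    @property
    def ec_set(self) -> frozenset[ECNumber]:
        return frozenset(ec for _, ec in self.pairs)

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


def filter_complete(annotations: AnnotationSet) -> AnnotationSet:
    """Copy of ``annotations`` with all partial-EC pairs removed.

    Incomplete "three-digit" ECs (and two-digit ones) identify families, not
    single activities, so they are excluded from all set-level analyses.
    Idempotent; never increases set size.
    """
    return AnnotationSet(
        annotations.genome_id,
        annotations.tool,
        frozenset(p for p in annotations.pairs if not p[1].is_partial),
    )


def group_into_sets(
    records: Iterable[GeneAnnotation], complete_only: bool = True
) -> dict[str, dict[str, AnnotationSet]]:
    """Group EC records into ``{genome_id: {tool: AnnotationSet}}``."""
    buckets: dict[tuple[str, str], set[tuple[str, ECNumber]]] = {}
    for r in records:
        if r.feature_type != "EC" or r.ec is None:
            continue
        if complete_only and r.ec.is_partial:
            continue
        buckets.setdefault((r.genome_id, r.tool), set()).add((r.gene_id, r.ec))
    out: dict[str, dict[str, AnnotationSet]] = {}
    for (genome, tool), pairs in sorted(buckets.items()):
        out.setdefault(genome, {})[tool] = AnnotationSet(genome, tool, frozenset(pairs))
    return out


# ---------------------------------------------------------------------------
# Normalized TSV reader/writer
# ---------------------------------------------------------------------------

def _open_rows(path: Union[str, Path]):
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (row[0].startswith("#")):
                continue
            yield lineno, row


def read_annotation_table(
    path: Union[str, Path],
    tools: Optional[frozenset[str]] = None,
    locus_tags: Optional[set[str]] = None,
) -> list[GeneAnnotation]:
    """Read a normalized annotation TSV into records.

    Parameters
    ----------
    path:
        TSV file in the normalized format (see module docstring).
    tools:
        Registered tool labels; unknown labels are rejected.  Defaults to
        the union of the EC and transport registries.
    locus_tags:
        Declared locus-tag set of the genome(s).  Records whose gene is not
        in the set are kept but flagged in the raised-on-demand report; they
        are never silently dropped.  (Flagging is exposed via
        :func:`unknown_locus_tags`.)
    """
    if tools is None:
        tools = DEFAULT_EC_TOOLS | DEFAULT_TRANSPORT_TOOLS
    rows = _open_rows(path)
    try:
        header_lineno, header = next(rows)
    except StopIteration:
        raise FormatError(f"{path}: empty file") from None
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise FormatError(f"{path}:{header_lineno}: duplicate header column(s) {dupes}")
    missing = [c for c in MANDATORY if c not in header]
    if missing:
        raise FormatError(f"{path}:{header_lineno}: missing mandatory column(s) {missing}")
    idx = {name: header.index(name) for name in header}

    def cell(row: list[str], name: str) -> str:
        i = idx.get(name)
        return row[i].strip() if i is not None and i < len(row) else ""

    records: list[GeneAnnotation] = []
    for lineno, row in rows:
        tool = cell(row, "tool")
        if tool not in tools:
            raise FormatError(f"{path}:{lineno}: unregistered tool label {tool!r}")
        ftype = cell(row, "feature_type")
        if ftype not in FEATURE_TYPES:
            raise FormatError(f"{path}:{lineno}: unknown feature_type {ftype!r}")
        value = cell(row, "value")
        ec = ko = substrate = None
        if ftype == "EC":
            try:
                ec = parse_ec(value)
            except ECParseError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
        elif ftype == "KO":
            ko = value or None
        else:
            substrate = value or None
        ident = cell(row, "identity_pct")
        try:
            records.append(
                GeneAnnotation(
                    genome_id=cell(row, "genome_id"),
                    gene_id=cell(row, "gene_id"),
                    tool=tool,
                    feature_type=ftype,
                    ec=ec,
                    ko=ko,
                    substrate=substrate,
                    raw_function=cell(row, "raw_function") or None,
                    identity_pct=float(ident) if ident else None,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    return records


def unknown_locus_tags(records: Iterable[GeneAnnotation], locus_tags: set[str]) -> list[GeneAnnotation]:
    """Records whose gene_id is absent from the declared locus-tag set."""
    return [r for r in records if r.gene_id not in locus_tags]


def write_annotation_table(records: Iterable[GeneAnnotation], path: Union[str, Path]) -> None:
    """Write records to the normalized TSV; write∘read is the identity on record sets."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.genome_id,
                    r.gene_id,
                    r.tool,
                    r.feature_type,
                    r.value,
                    r.raw_function or "",
                    "" if r.identity_pct is None else repr(r.identity_pct),
                ]
            )


def read_gold_standard(path: Union[str, Path]) -> dict[str, GoldStandard]:
    """Read a gold-standard TSV (columns genome_id, gene_id, ec) keyed by genome."""
    rows = _open_rows(path)
    try:
        header_lineno, header = next(rows)
    except StopIteration:
        raise FormatError(f"{path}: empty file") from None
    missing = [c for c in ("genome_id", "gene_id", "ec") if c not in header]
    if missing:
        raise FormatError(f"{path}:{header_lineno}: missing mandatory column(s) {missing}")
    idx = {name: header.index(name) for name in ("genome_id", "gene_id", "ec")}
    pairs: dict[str, set[tuple[str, ECNumber]]] = {}
    for lineno, row in rows:
        try:
            ec = parse_ec(row[idx["ec"]].strip())
        except (ECParseError, IndexError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
        pairs.setdefault(row[idx["genome_id"]].strip(), set()).add((row[idx["gene_id"]].strip(), ec))
    return {g: GoldStandard(g, frozenset(p)) for g, p in sorted(pairs.items())}


def write_gold_standard(gold: Iterable[GoldStandard], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["genome_id", "gene_id", "ec"])
        for gs in gold:
            for gene, ec in sorted(gs.pairs, key=lambda p: (p[0], str(p[1]))):
                writer.writerow([gs.genome_id, gene, str(ec)])
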