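"""End-to-end report assembly: one summary tying all analysis stages together.

Takes normalized annotation records (real or simulated), groups them by
genome and tool, and produces the study-shaped tables: the pooled support
partition of gene-EC annotations, the pairwise agreement matrix, mean EC
Venn regions, per-genome support distributions and gene coverage, the
precision/recall sweep against a gold standard where one is available, and
the transporter overlap/agreement tables.  Everything is deterministic and
seed-free; all randomness lives in the simulator.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from ._fmt import agreement_pct, round_half_away
from .benchmark import PRResult, pr_sweep
from .consensus import (
    aggregate_pairwise,
    gene_coverage,
    mean_region_counts,
    support_distribution,
    support_partition,
)
from .model import AnnotationSet, GeneAnnotation, GoldStandard, group_into_sets
from .transporters import (
    SubstrateVocabulary,
    assign_ranks,
    rank_distribution,
    substrate_agreement,
    three_tool_overlap,
)

__all__ = ["assemble_summary", "write_summary", "pr_table", "partition_table"]


def _region_key(region: frozenset) -> str:
    return "+".join(sorted(region))


def assemble_summary(
    records: Iterable[GeneAnnotation],
    gold_by_genome: Optional[Mapping[str, GoldStandard]] = None,
    vocabulary: Optional[SubstrateVocabulary] = None,
) -> dict:
    """Compute every analysis section available for the given inputs."""
    records = list(records)
    sets_by_genome = group_into_sets(records, complete_only=True)
    summary: dict = {"n_genomes": len(sets_by_genome)}

    # Total and per-genome gene-EC annotation counts (complete ECs only).
    total_pairs = sum(
        len(s) for genome_sets in sets_by_genome.values() for s in genome_sets.values()
    )
    summary["total_gene_ec_annotations"] = total_pairs
    if sets_by_genome:
        summary["mean_gene_ec_annotations_per_genome"] = round(total_pairs / len(sets_by_genome))

    # Pooled support partition of gene-EC pairs across genomes.
    pooled_counts: dict[int, int] = {}
    pooled_unique: dict[str, int] = {}
    union_total = 0
    distributions = {}
    coverage = {}
    for genome, genome_sets in sets_by_genome.items():
        if len(genome_sets) < 2:
            continue
        part = support_partition(genome_sets, "gene_ec_pair")
        union_total += part.union_size
        for k, n in part.counts.items():
            pooled_counts[k] = pooled_counts.get(k, 0) + n
        for t, n in part.per_tool_unique.items():
            pooled_unique[t] = pooled_unique.get(t, 0) + n
        distributions[genome] = support_distribution(genome_sets, "ec")
        coverage[genome] = gene_coverage(genome_sets)
    if pooled_counts:
        summary["support_partition"] = {
            "unit": "gene_ec_pair",
            "counts": pooled_counts,
            "pct": {k: agreement_pct(n, union_total) for k, n in pooled_counts.items()},
            "per_tool_unique_pct": {
                t: agreement_pct(n, union_total) for t, n in sorted(pooled_unique.items())
            },
            "union_size": union_total,
        }
        summary["ge3_fraction_pooled_pct"] = agreement_pct(
            sum(n for k, n in pooled_counts.items() if k >= 3), union_total
        )

    pairwise = aggregate_pairwise(sets_by_genome)
    summary["pairwise_agreement"] = {
        f"{a}-{b}": {"numerator": agr.numerator, "denominator": agr.denominator, "pct": agr.pct}
        for (a, b), agr in pairwise.items()
    }

    multi = {g: s for g, s in sets_by_genome.items() if len(s) >= 2}
    if multi:
        summary["mean_ec_regions"] = {
            _region_key(r): v for r, v in sorted(mean_region_counts(multi, "ec").items(), key=lambda kv: _region_key(kv[0]))
        }
        summary["support_distribution_by_genome"] = {
            g: {"fractions": d.fractions, "ge3_fraction": d.ge3_fraction, "union_size": d.union_size}
            for g, d in sorted(distributions.items())
        }
        summary["gene_coverage_by_genome"] = {
            g: {
                "per_tool": c.per_tool,
                "union": c.union_size,
                "multi_tool_fraction": c.multi_tool_fraction,
            }
            for g, c in sorted(coverage.items())
        }

    # Gold-standard benchmark where a gold standard covers a genome.
    if gold_by_genome:
        bench: dict[str, list[dict]] = {}
        for genome, gold in gold_by_genome.items():
            genome_sets = sets_by_genome.get(genome)
            if not genome_sets or not gold.pairs:
                continue
            ec_sets = {t: s.ec_set for t, s in genome_sets.items()}
            bench[genome] = [_pr_row(r) for r in pr_sweep(ec_sets, gold.ec_set)]
        if bench:
            summary["precision_recall"] = bench

    # Transporter analyses.
    transport_records = [r for r in records if r.feature_type == "TRANSPORT"]
    if transport_records and vocabulary is not None:
        ranked, tallies = assign_ranks(transport_records, vocabulary)
        dists = rank_distribution(ranked)
        summary["transporter_rank_distribution"] = {
            t: {
                "total_genes": d.total_genes,
                "fractions": d.fractions,
                "specific_fraction": d.specific_fraction,
            }
            for t, d in dists.items()
        }
        summary["transporter_rank_tallies"] = tallies
        if len(dists) >= 2:
            overlap = three_tool_overlap(ranked)
            summary["transporter_overlap"] = {
                "pooled_annotations": overlap.pooled_annotations,
                "all_tools_genes": overlap.all_tools_genes,
                "all_tools_specific": overlap.all_tools_specific,
                "agreement_pct": overlap.agreement_pct,
                "per_tool_genes": overlap.per_tool_genes,
            }
            agr = substrate_agreement(ranked, vocabulary)
            summary["substrate_agreement"] = {
                "qualifying_genes": agr.qualifying_genes,
                "agreeing_genes": agr.agreeing_genes,
                "fraction": agr.fraction,
                "per_pair": {f"{a}-{b}": v for (a, b), v in agr.per_pair.items()},
            }
    return summary


def _pr_row(r: PRResult) -> dict:
    return {
        "label": r.combination.label(),
        "tools": list(r.combination.tools),
        "mode": r.combination.mode,
        "tp": r.tp,
        "fp": r.fp,
        "fn": r.fn,
        "precision": r.precision,
        "recall": r.recall,
    }


def pr_table(results: Iterable[PRResult]) -> pd.DataFrame:
    """Tidy PR-sweep table (one row per combination × mode)."""
    return pd.DataFrame([_pr_row(r) for r in results])


def partition_table(sets_by_genome: Mapping[str, Mapping[str, AnnotationSet]], unit: str) -> pd.DataFrame:
    """Tidy per-genome Venn region table (one row per genome × region)."""
    rows = []
    for genome, genome_sets in sorted(sets_by_genome.items()):
        part = support_partition(genome_sets, unit)
        for region, n in sorted(part.regions.items(), key=lambda kv: _region_key(kv[0])):
            rows.append(
                {
                    "genome_id": genome,
                    "unit": unit,
                    "region": _region_key(region),
                    "support": len(region),
                    "count": n,
                }
            )
    return pd.DataFrame(rows)


def write_summary(summary: dict, outdir: Union[str, Path]) -> Path:
    """Write the JSON summary (and flat TSV twins of its main tables)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "summary.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, ensure_ascii=False)
        fh.write("\n")
    if "pairwise_agreement" in summary:
        pd.DataFrame(
            [
                {"pair": pair, **vals}
                for pair, vals in summary["pairwise_agreement"].items()
            ]
        ).to_csv(outdir / "pairwise_agreement.tsv", sep="\t", index=False)
    if "precision_recall" in summary:
        frames = []
        for genome, rows in summary["precision_recall"].items():
            frame = pd.DataFrame(rows)
            frame.insert(0, "genome_id", genome)
            frames.append(frame)
        pd.concat(frames).to_csv(outdir / "precision_recall.tsv", sep="\t", index=False)
    return path
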