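# Methods

This note documents the statistical conventions, the synthetic-data
generative model, and the design choices behind `metanno`.

## Annotation model and normalization

The atomic unit is the gene-EC annotation: *tool T assigns EC number e to
gene g in genome G*. Genes are identified by locus tag — the one stable
identifier shared across tool outputs — and are never re-called; records
whose gene is outside a declared locus-tag set can be flagged
(`unknown_locus_tags`) but are never silently dropped.

EC numbers are compared as exact four-position strings. Partial
("three-digit") ECs such as `1.2.3.-` identify families rather than single
activities and are removed by `filter_complete` before any set-level
analysis; two-digit partials (`1.2.-.-`) are parsed, flagged partial, and
removed the same way. Deprecated or transferred EC numbers are *not*
remapped — they compare as literal strings, because remapping would hide
exactly the tool-vintage differences the comparison is meant to expose. The
top-level class accepts 1..7 (class 7, translocases, was added to the
nomenclature in 2018); `strict_classes=True` restores the older 1..6 range.

Normalization rules per tool family:

- **Function strings** (RAST-style): every embedded `(EC x.x.x.x)` token is
  extracted; a multi-EC function string is split into one record per EC,
  which matches how gene-EC pairs are counted everywhere else.
- **KO lists** (KAAS-style): each (gene, KO) is expanded through a
  user-supplied KO→EC table; a KO mapping to several ECs yields all of them
  (the conservative alternative — dropping multi-mapped KOs — would bias
  the KO-based tool's apparent coverage downward). KOs without an EC are
  tallied, not errors.
- **BLAST transfer**: hits with percent identity *strictly greater* than
  the threshold (default 60) transfer all of the subject's ECs to the
  query; all qualifying hits are used, then (gene, EC) pairs are
  deduplicated keeping the maximum supporting identity. A
  `best_hit_only` mode (highest bit score, ties by lowest e-value then
  subject id) exists for sensitivity analysis. No e-value or coverage
  filter is applied by default; both are optional.

## Consensus statistics

Support partitions classify each unit of the cross-tool union (gene-EC
pair, distinct EC, or gene) by the exact set of tools supporting it; the
per-level counts, per-tool-unique counts, and the full 2^T − 1 Venn region
table are all exposed, and `counts[k]` always sums to the union size.

Pairwise agreement follows the "both tools cover the gene" convention: the
denominator is the number of genes with at least one EC from *both* tools,
the numerator the subset where the tools' EC sets for that gene intersect.
Cross-genome aggregation pools numerators and denominators (grand totals,
not averages of percentages), since per-genome percentages weight small
genomes disproportionately; per-genome values remain available. A zero
denominator reports the percentage as absent, never 0. All printed
percentages use one decimal with ties rounded away from zero, centralized
in `metanno._fmt`.

## Benchmarking conventions

Benchmarking is at the EC-set level: the predicted EC set of a tool
combination is compared against the reference EC set, ignoring which gene
carried the EC (isozymes collapse; a gene-EC-pair-level three-way
comparison is provided separately as `gene_ec_confusion`). Precision for an
empty prediction is reported absent — not 0 and not 1 — and the convention
is stated in output metadata. Partial ECs are filtered before benchmarking.
For a subset S, recall(union(S)) ≥ recall({t}) ≥ recall(intersection(S))
for every t ∈ S holds set-theoretically; the test suite asserts it on
randomized instances as a regression guard.

## Synthetic-data generative model

The generator exists so every statistic can be checked against known
truth. One genome is drawn as follows:

- `n_genes` genes; a fraction `frac_metabolic` are metabolic and receive
  one true EC drawn uniformly from a universe of `ec_universe_size`
  distinct complete ECs, plus a second distinct EC with probability
  `multi_ec_prob` (multifunctional enzymes). Isozymes arise naturally from
  uniform reuse of the universe.
- Each gene g has a difficulty d_g = |Normal(0, `difficulty_sd`)|, shared
  by all tools. Tool t detects a true pair of gene g with probability
  `sensitivity_t · 2·logistic(−d_g)`, which equals `sensitivity_t` exactly
  when `difficulty_sd = 0` and decays toward 0 for hard genes. Difficulty
  is deliberately one-sided (half-normal): it can only *hurt* detection.
  This is the minimal mechanism that (a) preserves the noiseless limit
  (sensitivity 1, sd 0 ⇒ every tool reproduces the gold standard exactly),
  (b) correlates misses across tools, and (c) makes a larger spread
  strictly lower both per-tool detection and the fraction of ECs supported
  by ≥3 tools — the qualitative pattern separating well-annotated model
  organisms from phylogenetically remote genomes. A mean-zero symmetric
  difficulty would violate (a) and, because the ≥3-support probability is
  convex in the detection probability over the relevant range, would
  *raise* the high-support fraction as the spread grows — the wrong
  direction.
- False annotations: a Poisson(`false_rate · n_genes`) number of false
  pairs per tool, each placing a uniformly drawn wrong EC on a uniformly
  drawn gene (metabolic or not — both error types occur in real tool
  output).
- Partial-EC injection: each emitted record is, with probability
  `partial_ec_prob`, accompanied by a truncated duplicate (`1.2.3.-`),
  exercising the partial-EC filtering path.
- Every emitted record is labeled TP/FP/PARTIAL (and every miss MISS) in a
  provenance log.

Randomness uses one global seed with a documented stream-splitting scheme:
each (stage, tool label) pair gets its own numpy `SeedSequence` child keyed
by CRC32 of the stage and tool names, so adding a tool to the panel leaves
every other tool's draws byte-identical.

Default study conditions (chosen once as a realistic mid-size bacterial
genome and panel): 2000 genes, 35% metabolic, EC universe 1500,
multi-EC probability 0.15, difficulty spread 1.0, and four tools with
(sensitivity, false rate): rast (0.72, 0.05), kegg (0.76, 0.06), eficaz
(0.58, 0.012, 10% partial injection), brenda (0.38, 0.08). These produce
roughly 1700 gene-EC annotations per genome, pairwise agreements in the
55–90% band, and a minority of ECs supported by ≥3 tools — the regime the
consensus statistics are designed for. `simulate_study` varies the
difficulty spread linearly across genomes to emulate a panel running from
model organisms to remote lineages.

Transporter side: a pool of `n_transporter_genes` genes each carries a true
substrate class. Each tool covers an independent subset (default coverages
0.85 / 0.41 / 0.23 for transportdb / kegg / rast, mirroring the relative
call volumes of TransAAP-style, KO-mapped and subsystem-based pipelines)
and draws a specificity rank from its configured distribution (defaults
give rank-1–2 masses of 0.59 / 0.48 / 0.28 respectively). A specific
(rank ≤ 2) call names the true class with probability
`substrate_fidelity` (default 0.92), else a uniform other class; two
independent specific calls on the same gene then agree at roughly
fidelity² ≈ 0.85, the scale of cross-tool substrate agreement seen in
practice. Synonym classes are flat equivalence classes — a broad term
agreeing with a specific member must be expressed by co-membership; there
is no hierarchy.

### What the generator does not emulate

Real EC frequency distributions (core pathways are shared far more than
uniform sampling implies), sequence-level causes of error (annotation
transfer through homology makes tool errors *positively correlated on the
same wrong EC*, whereas simulated false positives are independent),
genome-specific gene counts, and curated substrate vocabularies. Passing
tests therefore demonstrate the correctness and calibration of the
*statistics* on data with known structure — not that any particular real
tool achieves the configured sensitivities.

## Numerical and degenerate-input conventions

- Percentages: one decimal, half away from zero; ratios with zero
  denominator are absent, never 0.
- Mean per-genome Venn regions: arithmetic mean of per-genome counts, one
  decimal; regions absent in a genome count 0.
- `support_distribution` refuses an empty union; fractions sum to 1 within
  1e-12.
- Empty transporter input yields an empty rank-distribution mapping;
  substrate agreement with no qualifying genes is absent.
- A gene annotated by one tool with several substrates contributes its
  best (lowest) rank once to that tool's rank distribution.
- Transporter overlap: the denominator pools distinct (genome, gene, tool)
  annotation instances; the numerator counts distinct genes annotated by
  all tools. Both underlying sets are exported so alternative accountings
  can be recomputed.

## Problem sizes

The test suite and the acceptance script run entirely on simulated data:
randomized property checks use ≤ 6 tools and ≤ 50 units per instance
(500+ instances against brute-force membership oracles); calibration
checks use 1000 true pairs over 10–20 seeds; shape checks use 100
replicates of a 400-gene genome and 30 replicates per point of a
three-point difficulty grid; the acceptance run simulates an eight-genome
study at the default conditions. These sizes give stable Monte-Carlo
bounds (3 SD) while keeping any single run in seconds.

## Known limitations

Exact string matching of ECs means nomenclature drift between tool
vintages appears as disagreement (an optional alias table can merge
deprecated numbers; off by default). Gene-level agreement uses "at least
one identical EC", so a gene where tools share one EC but disagree on a
second still counts as agreeing. The synonym-class rule for substrate
agreement is one formalization of "the same substrate, differently
phrased"; outputs label it as such, and the vocabulary shipped with the
package is a starter table, not a curated resource.
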