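# Methods

## Confidence model

A pair's confidence is the probability that at least one of the evidence
claims about it is correct, assuming claims from *different platforms* are
independent: P_new = 1 − ∏(1 − Sᵢ). Two deliberate consequences:

- **Per-platform deduplication.** The product runs over platforms, not
  rows. Repeated claims from the same platform for the same pair collapse
  to their maximum Sᵢ before combination, so a source that lists one
  experiment many times cannot inflate the score. Claims from different
  *sources* that used the same platform also collapse — they are typically
  re-exports of the same underlying experiments, and treating them as
  independent would double-count.
- **Monotonicity.** Adding evidence can never lower a score, and the
  combined score dominates every individual input. This is the property
  the scoring acceptance sweep checks.

Release fusion P = 1 − (1 − P_prev)(1 − P_new) is the same noisy-OR with
the previous release treated as one more independent "platform". Pairs
absent from the prior use P_prev = 0; pairs with a prior but no current
evidence keep their prior score. Scores are clamped to [0, 1] after
arithmetic to absorb floating-point drift at the 1e-15 level.

Star tiers are fixed thresholds on P (1★ < 0.25 ≤ 2★ < 0.45 ≤ 3★ < 0.75 ≤
4★ < 0.90 ≤ 5★ ≤ 1): lower bounds inclusive, so the tiers partition
[0, 1] exactly.

**Reliability indices are configuration, not estimates.** The shipped
defaults (curated-literature 0.9, affinity-purification 0.7,
yeast-two-hybrid 0.5, co-expression 0.3, text-mining 0.2, fallback 0.2)
are illustrative orderings of how much each platform class is usually
trusted for *direct physical* interaction claims; any downstream result
that depends on their absolute values is configuration-dependent, and the
CLI accepts a reliability file to override them.

## Identifier handling

Mapping raw tokens to canonical accessions is one-to-one after filtering
to reviewed rows; raw tokens mapping to several accessions are dropped
(and counted) rather than guessed. Gene symbols match case-insensitively,
accessions exactly. Unmapped tokens are tallied, never fatal. Self-pairs
are retained but flagged, so callers can filter them; graph-based
operations (components, diameter, degree) drop self-loops.

## Evaluation battery

**Gold-pair enrichment sampling.** Draw `n_samples` samples of
`sample_size` pairs uniformly without replacement within a sample,
independently across samples, from one seeded generator; count each
sample's overlap with the gold pair set. Under the null the overlap is
hypergeometric with mean `sample_size · |db ∩ gold| / |db|`, which is the
reference the acceptance check uses. Histogram bins are width 1 when the
expected overlap is below 50, otherwise Sturges' rule. The *normalized
sample size* `round(base · size_ratio)` scales the draw with database
size when comparing databases of different sizes against a fixed-size
reference set. Overlap is counted on pairs, not on genes.

**False positives and AUC.** E = O/N over exact set intersections. The
AUC is the Mann–Whitney statistic computed from average ranks of the
final scores, so ties contribute ½; it equals the brute-force fraction of
correctly ordered (positive, negative) pairs, which is how it is tested.

**Functional similarity.** Term information content is
IC(t) = −log(f(t)) with f(t) the fraction of annotated genes in the
namespace carrying t after propagation to ancestors (propagation happens
at corpus load). Term pairs use Lin's measure 2·IC(MICA)/(IC(t₁)+IC(t₂)),
with the MICA the shared ancestor of maximal IC; the degenerate root-only
case scores 0. Gene pairs use the best-match average over the genes'
*direct* term sets — ancestors enter only through the MICA — so
self-similarity is exactly 1 for informatively annotated genes. The
cross-namespace score averages BP and MF when both are defined, else uses
the defined one (a max-combination variant is a one-line change in
`gene_pair_gosim`; the reported variant is recorded in the result
metadata). Per-tier comparisons sample equal numbers of annotated pairs
per tier and of random annotated gene pairs, and use Welch's
unequal-variance t-test, since tier variances differ by construction.

**Term enrichment** is a one-sided hypergeometric upper tail per
propagated term with Benjamini–Hochberg adjustment across all tested
terms. This is an in-house engine by design: it replaces an external web
service whose internals are unversioned, and its p-values are verified
against exact combinatorial tail sums.

**Systematic-bias sets.** Absent proteins = reviewed proteome minus
proteins in any database pair; missing-overlap proteins = proteins of
gold pairs not covered by the database∩gold overlap; hubs = top-k
(default 100) proteins by number of distinct partners, ties broken
lexicographically for determinism.

## Network statistics

The largest connected component breaks size ties toward the component
containing the lexicographically smallest node. Degree fits regress
log₁₀(count) on log₁₀(degree) over raw degree counts (log-binning is an
option, off by default), excluding zero-degree nodes, and need at least
three distinct degrees.

Effective diameter is the interpolated 90th percentile of the
shortest-path-length distribution over distinct node pairs: find the
smallest integer distance D whose CDF reaches the percentile and
interpolate linearly between D−1 and D, clamping at 1.0 since distinct
connected nodes are never closer than one hop (so a complete graph has
effective diameter exactly 1). Graphs up to 2,000 nodes are computed
exactly by all-pairs BFS; larger graphs are estimated from BFS over a
seeded uniform sample of source nodes, which empirically stays within 0.5
of the exact value on the fixtures tested.

Spearman's ρ uses the rank-difference closed form 1 − 6Σd²/(n(n²−1))
whenever both rankings are tie-free, and average ranks with the
product-moment formula otherwise; the result records which path was
taken. Hub-rank comparisons condition on the *row* database's top-k hub
list (the construction is deliberately asymmetric), re-rank the shared
hubs by degree within each database, and return an undefined marker when
fewer than two hubs are shared.

## Rediscovery benchmark

Each gene set splits into seeded (S) and hidden (H) halves —
`hidden_fraction` defaults to 0.5 since no canonical split ratio exists;
it is recorded in every result row. The one-step expansion G excludes S
members: rediscovery is only meaningful for genes not given away.
Sensitivity is |H∩G|/|H|; the rediscovery factor α = |H∩G|/|G| · f with
f = |G_db|/|G_reference| penalises databases that inflate G
indiscriminately — uniform inflation cancels exactly, which the
acceptance check exercises. The benchmark is *paired*: within a replicate
every database sees the same partition, which is what licenses the paired
t-test between database sensitivities. Gene sets below the minimum size
(default 10) are dropped before partitioning.

## Synthetic data: what it emulates, and what it does not

The generators model the structural features the evaluation battery is
sensitive to: a connected preferential-attachment truth network (so
degree fits and hub statistics behave like a real interactome;
Erdős–Rényi attachment is available via `topology`), sources that cover
overlapping random slices of the truth with platform-specific noise
rates, scores jittered around the platform reliability (σ = 0.03), a
gold standard embedded in the truth, negatives drawn partly from
observed-but-false pairs so they are scoreable, annotations in which
interacting genes share informative leaf terms with probability 0.7, and
gene sets grown from network neighborhoods so expansion can plausibly
recover hidden members.

Default conditions: 1,000 proteins, 5,000 truth edges, five sources
spanning the reliability spectrum — litdb (curated-literature, coverage
0.12, noise 0.05), apdb (affinity-purification, 0.35/0.15), y2hdb
(yeast-two-hybrid, 0.40/0.30), coexdb (co-expression, 0.50/0.50), textdb
(text-mining, 0.60/1.00) — chosen so that small/clean vs. large/noisy
sources coexist and all five tiers are populated; gold covers 20% of the
truth; 1,000 negatives with 2% contamination (curated negative sets are
imperfect) and half drawn from observed non-truth pairs; a
two-namespace ontology of depth 3 and branching 3; 30 gene sets of sizes
10–20. This yields a scored network of roughly 10,000 pairs.

What the generator does **not** emulate: ascertainment bias toward
well-studied proteins, correlated errors between sources (noise is
independent per source; real text-mining noise is correlated with
literature volume), isoforms and identifier churn, directionality or
interaction types, and realistic GO DAG shape (real ontologies are deep
and irregular). Passing tests therefore demonstrate correctness of the
computations and the *qualitative* behaviour of the protocols — score
tiers enriching for truth, α penalising inflation — not quantitative
performance on real databases.

## Seeds and problem sizes

One global seed drives everything; each stage derives a 31-bit sub-seed
as CRC32 of `"<seed>:<stage>"`, so stages are independently reproducible
and reordering stages does not shift downstream streams. Statistical
checks run at deliberately moderate sizes — 10,000-pair databases for the
sampling-enrichment check, 300 pairs per tier for the per-tier similarity
comparison, 300-protein networks with 20 replicates for the rediscovery
quantities — sizes at which the expected effects exceed their standard
errors severalfold while a full run stays interactive.

## Known limitations

- The independence assumption behind noisy-OR is optimistic for platforms
  with shared failure modes; the per-platform max-collapse mitigates but
  does not remove this.
- IC-based similarity depends on the annotation corpus: scores are not
  comparable across corpora, and shallow synthetic DAGs compress the
  similarity range.
- The sampled effective diameter is a point estimate without an error
  bar; for publication-grade comparisons use the exact mode.
- Reliability indices are unvalidated configuration; AUC-style results
  should be read as orderings, not calibrated probabilities.
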