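# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the design choices made where several readings were possible.

## Expression, gene-pair correlation, coherence

Expression arrives at probeset resolution with a partial probeset→gene map
(unmapped probesets are kept but invisible to gene-level computation). The
correlation of two genes is the **maximum** Pearson correlation over all of
their probeset pairs; pairs in which either probeset has zero variance are
skipped, and a gene pair is *undefined* only when every probeset pair is
degenerate. The coherence of a gene set is the mean correlation over all
unordered distinct pairs, excluding undefined pairs.

Two readings were open and resolved as follows: undefined pairs are
*excluded* from the mean rather than scored 0 (scoring 0 would bias
coherence toward zero for flat probesets), and "all gene pairs" is read as
unordered pairs without self-pairs. `CoherenceEngine` centres and
L2-normalises every probeset row once, so each correlation is a dot
product; gene-level results are memoized, which is what makes
permutation testing over thousands of overlapping random sets cheap.

## Module construction

A CRM–miRNA module is the exact intersection of the two target sets;
intersections with fewer than `min_size = 2` genes are discarded (one gene
cannot carry a pairwise statistic). Genes in the module but missing from
the expression matrix stay in the module and are skipped by coherence, so
set sizes remain auditable against the input maps.

## Randomization significance

* **Background 1** redraws the module's genes, preserving size, uniformly
  without replacement from the CRM's target pool. The pool defaults to that
  CRM's own target set, with a `bg1_pool="union"` option for the union of
  all CRM targets — both readings are defensible and they differ by one
  flag.
* **Background 2** draws an artificial miRNA: the real miRNA's target
  *count* is preserved and its targets are redrawn from the union of all
  miRNA target genes, then intersected with the CRM's targets. The
  intersection may have any size; draws whose intersection has fewer than
  two usable genes are redrawn (up to 1000 times, then scored −∞ so they
  can never reach the observed coherence). This keeps the compared sets
  non-degenerate without distorting the size distribution noticeably.
* **Whole-gene-set** redraw serves as the null for plain CRM/miRNA
  coherence baselines.

The empirical p-value over `n_reps = 100` draws is the proportion of
random sets with coherence **at least** the observed value — ties count
toward the numerator, so a constant matrix yields p = 1, never p = 0.
`n_reps = 5` is supported for plotting background distributions. p-values
therefore live on the grid {0, 1/n, …, 1} and are mildly anti-conservative
(P(p ≤ α) = (⌊αn⌋+1)/(n+1) under exchangeability), which the calibration
test accounts for via a binomial interval rather than an exact match.

Multiple testing uses Benjamini–Hochberg step-up q-values, implemented
directly (sorted p·m/rank with a tail cumulative minimum) so that the
output is bit-reproducible against a definitional oracle; statsmodels'
`multipletests` is used as an independent cross-check in the tests.

RNG discipline: one seed per run; each module gets its own generator
spawned by module index, so p-values do not depend on evaluation order.

## PWM scanning and CRM→miRNA edges

Scores are natural-log likelihood ratios with a pseudocount blend
p′ = (1−w)·p + w·q toward the background q (default w = 0.01, uniform q);
an `N` base contributes exactly 0. Both strands are scanned; reverse-strand
hits are reported in forward coordinates (start = leftmost forward base),
which makes the scan strand-symmetric under reverse complementation.

The per-motif cutoff is the empirical `quantile = 0.9999` of window scores
on one shared seeded random sequence of `calibration_length = 1e6` bases
(both strands pooled), with linear-interpolation quantiles; a calibration
shorter than 100/(1−quantile) windows raises an error in strict mode. A
window is a *site* only when its score is strictly above the cutoff.

A CRM→miRNA edge requires a choice of one site per CRM motif such that
max(end) − min(start) ≤ `cluster_window = 200` bases — i.e. all required
sites inside one 200 bp span, the usual motif-cluster reading, evaluated by
sliding an anchor over hit starts rather than enumerating combinations.
Edge calling is monotone in the window and anti-monotone in the cutoff.
Internally coordinates are 0-based half-open; TSV output is 1-based.

## Network pattern census and edge-swap nulls

Nodes are typed (CRM, miRNA, gene) and edges are typed accordingly (C→G,
M→G, C→M, M→C). The pattern catalog is generated, not hand-listed: all
weakly connected typed digraphs on 2–3 nodes over the allowed edge types,
deduplicated by type-preserving isomorphism — 31 patterns, with the
familiar ones annotated by name (both FFL variants, the co-regulation
fork, both regulator chains, the CRM↔miRNA mutual pair). Counting is
*subgraph-occurrence* counting (injective node assignments with all
template edges present, divided by the pattern's automorphism count), so a
triangle also contributes to its sub-fork and sub-chains.

Null networks preserve each node's per-type in/out degrees and all
edge-type counts by repeated double-edge swaps within each edge type
((a→b, c→d) → (a→d, c→b)), rejecting duplicates; every edge type joins two
distinct node types, so self-edges cannot arise. `swaps_per_edge = 10`
attempted swaps per edge is the standard mixing heuristic. The z-score of
a pattern is (observed − null mean)/null sd over `n_random = 100` null
networks (sample sd, ddof = 1, reported to 4 decimals); sd = 0 yields an
explicitly undefined z.

A caveat the tests respect: for patterns whose null mean count is far
below 1, the count distribution is so skewed that z is not usefully
calibrated — a single occurrence can give z > 5 on a perfectly null
network. Calibration checks therefore use networks dense enough that
pattern counts have means well above 1, and judge rare patterns pooled
rather than individually.

## Knockdown linear model

g\_k = c + a\_TF·b\_TF,k + Σᵢ a\_mirᵢ·b\_mirᵢ,k + ε, with effects shared
across genes and 0/1 indicators per gene. Per-gene effect coefficients
would be unidentifiable with one observation per gene, so the shared-effect
form is the only estimable reading. Replicate expression measurements are
expected to be averaged upstream.

Selection is two-stage: each candidate miRNA is prescreened in a model
with intercept + TF + that miRNA (two-sided t-test on the miRNA
coefficient; default α = 0.05; rank-deficient designs — a miRNA targeting
no gene or every gene — are excluded with a warning), then survivors enter
a bidirectional stepwise search starting from the TF-only model,
minimising AIC = n·ln(RSS/n) + 2k with k the number of mean parameters
(constants omitted consistently, so only AIC differences matter). Ties are
broken by candidate order, making selection deterministic and invariant to
gene row order; a duplicated indicator column can never join its twin
because it leaves RSS unchanged while paying +2 in AIC. The final model is
refit by OLS (statsmodels) for coefficients, standard errors and p-values.

## Host genes and clustering

A hosted miRNA "shares" a CRM when that CRM both regulates the miRNA
(C→M edge) and contains the miRNA's host gene among its targets; the
summary statistic is the count of hosted miRNAs with at least one shared
CRM. Clustering of module genes uses d = 1 − r on the max-over-probesets
correlation, average linkage by default (the robust choice for correlation
distances; complete/single available), with undefined correlations
assigned the maximal distance 2 under a warning. Dendrograms serialize to
Newick; the planted-block recovery check asks whether a block appears as
the exact leaf set of some merge.

## Synthetic data: what it emulates, what it does not

* **Expression**: equicorrelated Gaussian blocks (pairwise correlation ρ
  via a shared latent factor), independent unit-variance genes elsewhere,
  optional noisy extra probesets per gene (profile + N(0, noise_sd),
  default sd 0.5) to exercise the max-over-probesets rule. This is the
  minimal structure the pipeline's pairwise-Pearson view can detect; it
  does not emulate microarray normalization artifacts, heavy-tailed
  expression noise, or time-series autocorrelation, so passing tests show
  correctness of the statistics, not robustness to array artifacts.
* **Target maps**: uniform CRM out-degrees (default 20–60) and a
  discretized power law for miRNA out-degrees (default exponent 2 on
  [10, 80]) — a non-trivial degree distribution is needed because
  background 2 preserves it. `overlap_spec` forces chosen CRM–miRNA pairs
  to share a planted co-expression block, giving truly coherent modules
  with known membership.
* **Sequences**: i.i.d. background bases; planted sites are sampled from
  the PWM (consensus optional) so scores vary realistically around the
  cutoff, placed without overlap inside one cluster window on random
  strands. Default generator PWMs are length 12 with a 0.95-probability
  dominant base and Dirichlet-split minor mass: informative enough that a
  PWM-sampled site is detected at the 99.99% cutoff with probability
  ≈ 0.98, and with continuous-valued scores so empirical quantiles are
  well behaved. Genomic composition (GC skew, repeats, CpG islands) is not
  modelled.
* **Networks**: independent per-type edge probabilities plus planted FFLs
  on fresh node triples, so the planted count is exactly recoverable.
* **Knockdown**: log-ratios generated exactly from the linear model with
  Gaussian noise (default sd 0.3).

All generators are deterministic given their seed, and every generated
object passes the corresponding reader's validators after a write/read
cycle.

## Problem sizes and numerical choices

The bundled fixture (`generate_fixture` / `coregnet simulate`) uses 120
genes × 30 samples with two planted blocks, 3 CRMs over 4 PWMs, 6 miRNAs
with 2 kb upstream sequences, and a 120-gene knockdown vector — small
enough that the full pipeline runs in seconds while every stage has signal
to find. Validation simulations use 300–3000 observations per stage
(500-module calibration runs, 10⁶-window scan calibration, 20-seed
selection studies), sizes at which the binomial/recovery bounds they check
are statistically meaningful. Numerical tolerances: PWM columns must sum
to 1 within 1e-9 after normalization; oracle-equality checks are asserted
at 1e-12 (correlation/coherence) or 1e-8 (OLS); coherence of sets with no
defined pair, z with zero null sd, and p for undefined coherence are all
reported as explicitly undefined rather than coerced to numbers.

## Known limitations

* Coherence caching holds the full probeset-correlation workspace in
  memory; it is sized for desk-scale matrices (10⁴ probesets), not for
  whole-compendium runs.
* The census enumerates patterns up to 3 nodes only; larger motifs
  (bi-fans, multi-input modules) are out of scope.
* The edge-swap sampler is the standard switching chain; uniformity over
  the degree-constrained graph space is asymptotic in the number of swaps,
  and `swaps_per_edge` trades mixing for time.
* Empirical p-values cannot go below 1/n_reps; with 100 replicates the
  q-value resolution is correspondingly coarse.
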