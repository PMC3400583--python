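# Methods

This note documents the models, estimators and design choices behind
`fflnet`: what each stage computes, the parameters that matter, what the
synthetic generators do and do not emulate, and the known limits of the
approach.

## The FFL model

A 3-node feed-forward loop is a triple (TF, miRNA, gene) with TF→gene
(transcriptional regulation at the promoter) and miRNA→gene
(post-transcriptional repression at the 3′ UTR), plus at least one relation
between the two regulators. The regulator relation pattern defines three
mutually exclusive classes:

| class         | TF→miRNA | miRNA→TF |
|---------------|----------|----------|
| TF-FFL        | yes      | no       |
| miRNA-FFL     | no       | yes      |
| composite-FFL | yes      | yes      |

Neither relation present means no FFL. Composite FFLs contain, by
definition, a TF↔miRNA feedback loop.

The 4-node FFL replaces the single target with a coexpressed gene pair
(g1, g2): the gene–gene edge plus, under some labeling of the pair,
TF→g1 and miRNA→g2 are required, and at least one of TF→g2 / miRNA→g1
must also hold. Both labelings are tried; a pair satisfying the template
either way is reported once per (TF, miRNA). The same (TF, miRNA, gene)
relation can appear inside both a 3-node and a 4-node loop; deduplication
happens at network construction, where edges are keyed by
(source, target, relation).

Enumeration is exact: it indexes regulator pairs with at least one
inter-regulator edge and intersects their target sets, which equals
exhaustive search over all node triples/quadruples (asserted against
brute-force oracles in the tests).

## Co-targeting significance

Random (TF, miRNA) pairings are filtered with a one-sided cumulative
hypergeometric test. With a target universe of `Total` genes — by default
the intersection of all miRNA-targeted genes and all TF-regulated genes in
the supplied background edge maps (the analysis edge set when no separate
background is given; overridable) — a miRNA targeting `m` of them, a TF
regulating `n`, and `x` joint targets:

    P = P(X >= x),  X ~ Hypergeometric(Total, m, n)

For `Total <= 100` the tail is evaluated in exact rational arithmetic;
larger problems use `scipy.stats.hypergeom.sf`. P-values are BH-adjusted
and pairs with q < 0.05 (strict) are kept. Filtering is applied to pairs
*before* FFL assembly, so failing pairs contribute no loops. The test is
run once per (TF, miRNA) pair over gene-class targets only; TF genes
repressed by the miRNA do not enter the overlap count.

## Promoter scanning

PWMs are column count matrices (TRANSFAC flat-file or simple TSV input).
Column frequencies are computed after adding a pseudocount (default 0.25
per cell; the exact smoothing used by the commercial Match implementation
is unpublished, so it is configurable). The per-position information
weight is

    I(i) = Σ_b f(i,b) · ln(4 · f(i,b))

and window similarity is `(Current − Min)/(Max − Min)` with
`Current = Σ_i I(i)·f(i, b_i)` and Min/Max the same sums over per-position
minimum/maximum frequencies. The core score restricts the sum to the five
consecutive positions with maximal ΣI(i) (leftmost on ties; the whole
matrix if shorter than five). Scores are exactly invariant to positive
rescaling of counts (when the pseudocount is scaled along) and span [0, 1]
over all windows of matching length. Matrices whose smoothed columns are
all uniform carry no information; every window scores 1.0 by convention.

Scanning slides over every window position on both strands (reverse
complement scored for the − strand; positions always refer to the forward
sequence, 0-based half-open). Windows containing N are skipped, not
scored. Defaults follow the stringent published practice: core ≥ 1.00,
matrix ≥ 0.95 (a 1e-12 floating-point slack keeps exact-consensus windows
at a 1.0 cutoff). A predicted (TF, node) pair becomes an edge only when it
has at least one hit in every required species (default human, mouse,
rat); positional alignment across species is *not* required — only
pair-level presence, since orthologous promoter coordinates rarely align
base-for-base. Promoter windows default to −1500/+500 around the TSS, with
the −1000/+500 variant available.

## Coexpression inference

Mutual information is estimated on the copula transform: average ranks
mapped to (0,1), cut into `b` equal-frequency bins
(`b = round(n^(1/3))` for "auto"), MI in nats from the joint histogram.
This makes the estimate exactly symmetric and invariant to strictly
monotone transforms of either input; a constant vector yields MI = 0. The
estimator is a documented substitute for ARACNE's Gaussian-kernel
estimator (whose bandwidth tables are implementation-specific) and is
validated against the closed-form Gaussian value
`MI = −½·ln(1−ρ²)` (within 0.1 nats at ρ = 0.9, n = 10,000).

The significance threshold is the MI value with null exceedance
probability `p` (default 10⁻⁷, the stringent published setting) under a
permutation null of independently shuffled sequences. Calibrating a 10⁻⁷
tail empirically needs ≥10⁷ permutations, so by default an exponential
right tail is fitted to the top 1% of the permutation null and
extrapolated:

    P(MI > t) ≈ q₀ · exp(−(t − t₀)/β),  t₀ = 99th percentile, q₀ = 0.01

with `β` the mean tail excess; full empirical calibration is available
when the permutation budget covers the tail. Thresholds are deterministic
given the seed and non-increasing in `p`.

DPI pruning removes, for every MI triangle (i, j, k), the weakest edge
(i, k) iff `MI_ik < min(MI_ij, MI_jk)·(1 − tolerance)` (default tolerance
0.15). Marks are evaluated against pre-pruning weights in a two-pass
mark-then-delete, so the result is order-independent and idempotent —
unlike in-place variants, which can depend on edge order.

## Target-prediction filtering

TargetScan-style records are kept when conserved in all required species
(default human, mouse, rat, dog) and passing the total-context-score
cutoff. Context scores are negative with more-negative meaning stronger
predicted repression; the filter therefore keeps scores ≤ −0.30 (boundary
inclusive — the boundary convention is not externally pinned down, so the
comparator and cutoff are exposed in the API). Kept records become
miRNA-gene or miRNA-TF edges according to the target's catalog class, both
for dual-role targets.

## Network construction and topology

Merged FFLs (one record per (TF, miRNA) regulation, carrying the list of
joint targets) expand back into typed edges and union into one network;
every edge records the set of contributing merged-FFL keys (provenance).
Re-importing a merged record from a 4-node table connects both regulators
to both pair members — the merged representation no longer distinguishes
which optional cross edge was observed; building directly from enumerated
FFL instances (`build_network_from_ffls`) preserves the observed edges.

Degrees are computed on the undirected simple projection: direction
ignored, parallel relations between the same endpoints collapsed to one
adjacency. Dual-role nodes (gene + TF) are stored once under the gene
class with the TF role retained as a secondary label.

Hub calling uses a per-class top-quantile rule: the cutoff is the smallest
degree among the top ⌈q·n⌉ nodes (default q = 0.20), and hubs must also
strictly exceed the class median degree, so degree-uniform classes yield
no hubs. The rule is scale-consistent (a disjoint copy of the network
leaves cutoffs unchanged). Published hub analyses of this kind do not
specify their cutoff algorithm precisely, so this package makes no claim
of reproducing any particular published cutoff values; the quantile is
configurable. Classes with fewer than five nodes are skipped.

Communities are k-clique percolation (default k = 3) on the undirected
projection, delegated to `networkx.community.k_clique_communities` and
verified against a brute-force clique-enumeration oracle; k = 2 reduces to
connected components of non-isolated nodes.

## Supporting statistics

* Permutation target enrichment: observed = |targets ∩ candidates|; the
  null redraws |candidates| genes uniformly without replacement from the
  universe (default 10,000 permutations). Empirical p uses the add-one
  correction (r+1)/(N+1), never exactly zero. The summary adds a paired
  t-test across miRNAs of observed counts vs per-miRNA null means — one
  plausible population-level reading; the per-miRNA empirical p-values are
  the primary output.
* One-sided KS: D⁺ = sup(F_b − F_a) over right-continuous ECDFs for the
  alternative "a stochastically greater than b", asymptotic p
  `exp(−2·D²·mn/(m+n))`; identical samples give exactly (0, 1).
* Fisher's exact test via `scipy.stats.fisher_exact`, verified to 1e-12
  against margin-constrained enumeration.
* Shared annotation: a pair shares iff its term sets intersect (exact-match
  mode available); unannotated pairs are dropped with a logged count, and
  the shared/unshared × observed/null table goes to the right-tailed
  Fisher test. GO semantic-similarity scores are consumed as precomputed
  tables; computing them from the ontology is out of scope.
* BH FDR is the step-up adjustment, order-preserving and clipped to 1,
  cross-checked against statsmodels.

## Synthetic data

The generators produce every input the pipeline reads, as pure functions
of spec + seed (PCG64, recorded in output sidecars):

* `gen_regulome` plants FFLs on disjoint regulator pairs (optionally with
  several joint targets per pair, which is what makes planted pairs
  detectable by the co-targeting filter) and then adds background edges
  per-relation at the configured density (default 0.05 — sparse enough
  that planted structure dominates, dense enough for incidental motifs to
  occur, as in prediction-derived edge sets). Background may create
  incidental FFLs; the truth object records planted ones only.
* `gen_expression` builds forests of Gaussian parent→child chains,
  children standardised to unit variance so `noise_sd` is a per-edge
  relative noise level (parent–child correlation 1/√(1+σ²) at every
  depth); the conditional-independence structure is exactly what DPI
  should recover.
* `gen_promoters` plants PWM consensus sites in i.i.d. uniform sequence;
  `gen_annotations` controls the fraction of designated pairs sharing a
  term.

What they do not emulate: realistic expression covariance of tumor
cohorts, TargetScan site biology, promoter base composition, or symbol
aliasing. Passing tests therefore demonstrate algorithmic correctness
(recovery of known structure under the stated noise model), not predictive
accuracy on real regulomes.

## Numerical and scale choices

* Exact hypergeometric tails (rational arithmetic) for universes ≤ 100;
  scipy beyond.
* Oracle-equivalence tests run on 100 seeded random stores of ≤ 12 nodes;
  clique-percolation oracles on 15-node graphs; these sizes make
  brute-force enumeration instantaneous while covering all motif
  configurations.
* The end-to-end recovery experiment uses 25–30 TFs/miRNAs, 120–160
  genes, 20–25 planted FFLs, four joint targets per pair, background
  density 0.05 — a scale at which the co-targeting filter separates
  planted from incidental pairs and a full run takes seconds.
* Permutation budgets: 10,000 for target enrichment (matching the
  published protocol), 2,000–10,000 elsewhere in tests with the
  exponential tail extrapolation bridging smaller budgets to extreme
  p-value thresholds.

## Limitations

* Identifier matching is exact and case-sensitive; symbol aliasing and
  orthology mapping are the caller's responsibility.
* The Match-style scanner reproduces the published scoring *formula*, not
  the proprietary per-matrix minFP cutoff profiles; per-matrix cutoff
  overrides can be supplied instead.
* The MI estimator is not bit-compatible with ARACNE; thresholds
  calibrated by extrapolation inherit exponential-tail error beyond the
  permutation budget.
* Externally curated merged-FFL tables are imported as-is; the package
  validates structure (classes, arity, deduplication), not biological
  provenance.
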