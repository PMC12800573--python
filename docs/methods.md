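# Methods

## Problem and model

`phylolink` links **gene cluster families** (GCFs — groups of similar
biosynthetic gene clusters across bacterial genomes) to **metabolite
families** (MFs — groups of LC-MS features attributed to structurally
related natural products) observed in the same strains.  Naive
co-occurrence screens over strains suffer from phylogenetic
pseudo-replication: closely related strains share both their gene clusters
and their metabolites by descent, so a contingency test over strains counts
each inheritance event many times and produces large numbers of spurious
links.

The phylogeny-aware screen instead models each binary trait (presence of a
GCF, presence of an MF) as a continuous-time Markov chain on the rooted
strain phylogeny and asks whether the two traits of a pair evolve
*dependently*:

* **Independent model** (4 parameters): trait A evolves with gain rate
  `q01^A` and loss rate `q10^A`, trait B likewise, irrespective of each
  other.
* **Dependent model** (8 parameters): the pair occupies states
  {(0,0), (0,1), (1,0), (1,1)}; each trait's gain and loss rate may differ
  according to the partner's current state (`alpha1 = q(00→10)` vs
  `alpha2 = q(01→11)` etc.).  Simultaneous changes of both traits have rate
  0 — a standard identifiability restriction, since a dual change over an
  edge can always be realised as two single changes in sequence.

Likelihoods are computed with the pruning algorithm (postorder dynamic
program over partial likelihoods) with per-node rescaling against
underflow.  Transition matrices come from the closed-form 2-state solution
or an eigendecomposition of the 4-state generator (with a scipy `expm`
fallback for near-defective generators).  The hot path is JIT-compiled
with numba; the numpy fallback path is retained and the two are asserted
equal in the tests.

Dependence is assessed by a likelihood-ratio test, `D = 2(lnL_dep −
lnL_indep)` referred to chi-square with 4 degrees of freedom, at
`alpha = 0.01`.

### Direction statistic RQ

A significant LRT detects any dependence, including anti-correlation
(traits avoiding each other).  To keep positive associations only, each
dependent fit is summarised by **RQ**, defined here as the stationary
probability mass of the fitted 4-state chain on the concordant states:

    RQ = pi(0,0) + pi(1,1)

RQ = 0.5 for a symmetric independent chain, →1 under strong positive
coupling, <0.5 under anti-coupling.  A pair is called **linked** iff it is
eligible, `p < alpha` and `RQ ≥ 0.65`.  This stationary-concordance
definition is this package's declared operationalization of the direction
criterion; the threshold 0.65 is the default decision value.  (For a
reducible fitted generator — some rate at its bound making states
unreachable — RQ is computed on the restricted recurrent chain and the
result is flagged.)

### Eligibility

A pair is tested only if **each** trait shows at least 2 parsimony state
changes (unit-cost Sankoff) on the tree.  A trait gained once in a single
clade carries no repeated evolutionary signal; its likelihood surface
cannot distinguish dependence from shared ancestry.  The change count is
observable and deterministic, which makes the filter reproducible.

### Comparator

The conventional screen is Pearson's chi-square on the per-pair 2×2
presence/absence table over strains, continuity-corrected (the default of
standard contingency routines; verified against `scipy.stats.
chi2_contingency`), at the same `alpha`, with a direction filter requiring
observed co-presence above its independence expectation — the positive-
association analogue of the RQ rule.

### Known-pair evaluation and permutation control

Given a catalog of compounds with known cognate (GCF, MF) pairs, a method
scores **correct** for a compound when it links exactly the cognate pair,
and one **false positive** for every other GCF linked to that compound's
MF.  The fold reduction in false positives versus the comparator is
computed over the compounds the phylogeny-aware method *assessed* (at
least one eligible pair for that MF): a compound on which the method could
make no prediction cannot fairly inflate the comparator's baseline.  The
permutation control shuffles which strain carries which MF row (a
bijection preserving column sums), destroying genuine signal while keeping
both margins; correct calls on permuted data estimate the chance level.

## Fitting

* Rates are optimised on the log scale with L-BFGS-B, bounds
  `[1e-6, 1e3]` per rate on the rescaled tree, convergence tolerance
  ~1e-8 in log-likelihood, 5 restarts by default (first start
  deterministic, the rest log-uniform in `[1e-3, 1e2]`, seeded).  Ties
  between restarts break by higher lnL, then smaller parameter norm.
* The tree is rescaled internally to mean root-to-tip depth 1; rate
  *ratios* are scale-invariant and absolute rates are reported in scaled
  units.
* The independent pair model factorises (with a product root prior) into
  two single-trait problems, which are fitted separately and recombined;
  the recombined optimum also seeds the dependent optimisation, which both
  accelerates it and guarantees the nesting property
  `lnL_dep ≥ lnL_indep` up to noise (`D` is clipped at 0).
* Root prior: uniform over states by default, configurable.  Empirically
  (see Limitations) the uniform prior recovers the *median* gain/loss
  ratio without bias in the sparse regime this pipeline targets.
* Degenerate fits (any rate at a bound, e.g. for a constant trait) are
  flagged and excluded from rate summaries.
* Zero-length branches get identity transition matrices; multifurcations
  are handled by all tree code (likelihood, parsimony, pruning of tips).

## Gain/loss summary

`gain_loss_summary` fits the 2-state model to every trait and reports the
median and median absolute deviation of `q01/q10` over converged,
non-degenerate fits.  For gene-cluster traits evolving like the data this
package targets, the median ratio is far below 1 (clusters are rarely
gained, often lost).

## BGC curation

Predicted BGC regions are curated before clustering:

1. **Supercluster splitting.** A region's core genes are compared against
   every shorter region from other genomes in the same family
   (`match_blocks`: maximal collinear runs of genes sharing a domain
   family, gaps ≤ 2 unmatched genes bridged, blocks must be anchored by a
   shared core-gene domain).  When the core genes partition into ≥ 2
   disjoint contiguous groups, each exactly matching some shorter region
   from another genome, and the gaps between groups are core-free, the
   region is split at the midpoint of each gap.  Children keep the
   interleaved non-core genes (the gene multiset is conserved), inherit
   the product class, and the split is logged with its evidence regions.
   Ambiguous evidence (overlapping or interleaved coverage) never splits —
   the design prefers missed splits over spurious ones.
2. **Core-gene reduction.** Regions are reduced to their core biosynthetic
   genes; regions with no core genes are excluded from clustering and
   logged.
3. **Re-clustering.** Families are re-computed after curation.

The clustering distance is a declared **stand-in**, not a
re-implementation of the external BiG-SCAPE tool: `d = 1 − (0.7·J_dom +
0.3·J_bigram)` with `J_dom` the Jaccard index of domain-family sets and
`J_bigram` the Jaccard index of adjacent domain pairs (order sensitivity);
single-linkage components at `d ≤ 0.4` (default) form the families.  It
preserves the qualitative behaviour that matters downstream (identical
regions cluster, disjoint ones do not, a looser cutoff never increases
the family count) and keeps the pipeline runnable end to end on synthetic
data.

## MF calling

An MF is present in a strain iff at least 3% of the MF's features were
detected there **and** at least one detected feature carries the
protonated molecular ion `[M+H]+` (evidence the compound itself, not only
an adduct or in-source fragment, was seen).  The 3% boundary is evaluated
with exact rational arithmetic, so "exactly 3%" is reproducibly present.
A feature is detected in a strain if detected in ≥ 1 replicate
(configurable to majority).  Distinct features are counted (not feature ×
adduct combinations) — the alternative reading exists and is deliberately
not the default.  Adduct strings are matched exactly after whitespace
stripping, with a configurable synonym map for dialects.

## Rarefaction

Incidence-based (sample-based) rarefaction of trait richness over strains
uses the hypergeometric expectation; extrapolation uses the Chao2
estimator `S_obs + ((T−1)/T)·Q1²/(2·Q2)` (bias-corrected form
`((T−1)/T)·Q1(Q1−1)/2` when there are no duplicates), with the standard
incidence extrapolation curve approaching the Chao2 asymptote.  Only
richness (Hill order 0) is computed.  Optional confidence bands
(`n_bootstrap > 0`) resample strains with replacement; because such
resampling duplicates strains and so biases richness low, the bootstrap
is used for spread only and the percentile band is centered on the
analytic estimate.

## Synthetic data

The generator produces the statistical structure the analysis assumes,
plus ground truth:

* **Tree**: Yule (pure-birth) with 72 tips by default, rescaled to mean
  root-to-tip depth 1 (branch lengths in arbitrary units; only relative
  rates matter).
* **Bulk traits**: 265 GCF and 99 MF traits by default.  Per-trait rates
  are drawn log-normally: gain/loss ratio around median 0.016 (σ = 0.4
  log units) — the sparse-gain regime typical of gene-cluster evolution —
  and loss rate around 1.0 (σ = 0.5).  With these values the simulated
  incidence matrices reproduce the descriptive statistics of real
  cluster-family data at this scale: ~37% of observed traits are
  singletons and the median observed trait occurs in ~4 of 72 strains.
  Traits are conditioned on being non-empty, since only observed families
  enter real incidence matrices; the root state is drawn from the
  stationary distribution.
* **Linked pairs** evolve under the dependent 4-state model with one
  coupling factor κ: gain-with-partner rates are multiplied by κ and
  loss-with-partner rates divided by κ.  Defaults: κ = 16 and linked-pair
  loss rates around 4.0 — a near-deterministic metabolite-on-cluster
  dependence with enough evolutionary turnover that planted pairs are
  recoverable at roughly the rate real studies report for known
  compound/cluster pairs; pairs are resimulated (rates redrawn each try,
  bounded retries) until both traits show at least `min_events` (default 2)
  parsimony changes, so every truth pair passes the eligibility filter by
  construction.
* **MF dropout** (default 0.1) zeroes each present metabolite call with
  that probability, emulating condition-dependent non-production under a
  single laboratory cultivation condition.
* **Curation fixtures**: gene tables containing fused superclusters of
  2–3 core blocks, partner genomes carrying the single blocks (the
  cross-strain evidence), and distractor regions, together with the
  expected split log.
* **Feature-table fixtures**: per-strain feature detections with adduct
  labels consistent with a given MF matrix (≥ 3% of features including
  one `[M+H]+` where present).

What the generator does **not** emulate: real domain-content distances
between cluster variants (the clustering stand-in is exercised on
synthetic domain vocabularies), correlated detection noise across related
metabolites, within-family feature-intensity structure, horizontal
transfer of clusters between *lineages of different datasets*, and any
sequence-level realism.  Passing tests therefore demonstrate the
statistical machinery is correct and calibrated under the model's own
assumptions, not that the biological model is true of any particular
dataset.

## Numerical and design choices

* Likelihood engine kernel falls back from eigendecomposition to `expm`
  when the eigenvector matrix has condition number > 1e10 or row sums
  deviate by > 1e-8.
* `lnL = −1e308` is the guarded sentinel for zero-likelihood
  configurations (e.g. all rates 0 with discordant tips).
* Stationary distributions solve `πQ = 0, Σπ = 1` by least squares;
  communicating-class analysis handles reducible generators.
* Strain matching is exact string equality after trimming whitespace;
  mismatches either raise (strict mode) or prune both sides to the
  intersection (prune mode), never silently.
* Per-pair optimiser seeds derive from a seed-sequence keyed by pair
  position, so batch results are independent of iteration order and
  bit-reproducible for a given seed.
* No multiple-testing correction by default (the decision rule is the
  plain `alpha = 0.01` threshold); a Benjamini–Hochberg option exists.

## Problem sizes

The test-suite and the acceptance script use reduced sizes chosen as the
package's own trade-off between statistical resolution and convenience:
null calibration on 24-tip trees (2000 pairs in the suite, 600 in the
script), power on 100 (suite) / 60 (script) replicates of 72-tip trees,
association screens on 60×30 trait matrices with 9 planted known pairs,
permutation controls restricted to catalog MFs (sufficient for the
correct/false-positive accounting and far cheaper).

## Known limitations

* **The LRT is conservative at these tree sizes.**  Under the null, the
  observed `D` is stochastically smaller than chi-square(4) (mean ≈ 3.3
  vs 4 at 24 tips; fitted rates frequently sit at bounds, reducing the
  effective degrees of freedom).  The empirical type-I error at
  `alpha = 0.01` is ~0.1–0.5%, not 1%.  The test never over-rejects —
  errors are in the protective direction — but nominal and actual size
  differ, a well-known property of this class of tests away from the
  asymptotic regime.
* **Per-trait rate ratios are extremely noisy.**  The 2-rate MLE from a
  single binary character on ~70 tips has very high sampling variance
  (fitted ratios commonly off by 3× either way); only aggregates (the
  median over many traits) are reliable, and that is what the gain/loss
  summary reports.  Relatedly, the uniform root prior is empirically
  unbiased for the median ratio in the sparse (ratio ≈ 0.016) regime but
  biases individual ratios low at richer ratios (≈ 0.1); the stationary
  prior behaves oppositely.  Neither dominates; uniform is the default.
* **Power falls near the coupling boundary.**  At κ = 8 (half the default
  coupling) with ≥ 4 events per trait, power at `alpha = 0.01` is ~0.6–0.7
  — pairs in that regime sit at the detectability edge of a 4-df test.
* The clustering stand-in is not BiG-SCAPE and its distances are not
  comparable to BiG-SCAPE's; only the downstream pipeline logic should be
  interpreted on real data after substituting real GCF calls.
* Supercluster splitting requires cross-strain evidence by design;
  superclusters present in *every* genome of a family full-length are
  never split.
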