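# Methods

## Problem setting

Somatic alterations that hit the same signaling pathway tend to be mutually
exclusive across tumors, while the pathway as a whole is altered in a large
fraction of samples. `mexmod` frames module discovery as maximum-weight
submatrix search over binary sample × gene incidence matrices, in two
designs:

* **common**: one group of positive cohorts A_1..A_R (R ≥ 2); the module
  should show coverage + exclusivity in *every* A_r;
* **specific**: positives A_1..A_R versus controls B_1..B_T; the module
  should show the structure in the A side and *lack* it in the B side.

## Input processing

Cohorts arrive as binary matrices or MAF-like long tables. For MAF input,
variant classes outside the configured non-silent set (default: missense,
nonsense, frameshift ins/del, in-frame ins/del, splice site, translation
start, nonstop) are dropped before binarization; duplicate (sample, gene)
records collapse to a single 1. Copy-number input is accepted only as a
pre-binarized second matrix OR'd in — no segmentation logic is attempted.
Samples with no remaining alteration are removed by an explicit step, never
implicitly. Clinical stratification uses threshold predicates (adult = age
≥ 18, pediatric = age < 18, obese = BMI > 25, boundary conventions exactly
as stated); samples with a missing value in the rule's column are excluded
from both strata and reported, not imputed.

Before scoring, all matrices of a comparison are **harmonized**: every
matrix is reindexed to the lexicographically sorted union of gene lists,
absent genes becoming all-zero columns. Harmonization is idempotent and
preserves the column sums of genes already present.

## Objectives

With Γ_A(g) the altered-sample set of gene g, coverage
|Γ_A(M)| = |∪_{g∈M} Γ_A(g)| and the Dendrix weight
W(M) = 2|Γ_A(M)| − Σ_g |Γ_A(g)|:

* common score: C_m(M) = ω · Σ_r W_r(M), with ω the Shannon entropy of the
  normalized coverage rates CR_r = |Γ_{A_r}(M)|/m_r. ω ∈ [0, ln R],
  maximal iff all rates are equal and positive, so the score prefers
  modules whose coverage is *balanced* across cohorts.
* specific score: S_m(M) = (1/R)Σ_r W_r(M) −
  (1/T)Σ_t [K|Γ_{B_t}(M)| − Σ_g|Γ_{B_t}(g)|]/(K−1). The control-side term
  equals the coverage c for a perfectly exclusive set covering c samples,
  so a module "specific" to the A side must be both weighty in A and
  unremarkable in B. K = 1 is rejected outright (the K−1 divisor; sweeps
  start at K = 2).

Numerical conventions: the entropy uses the **natural log** — the base
rescales C_m monotonically and cannot change the argmax — with 0·log 0 := 0
and ω := 0 when every coverage rate is zero. Counts and weights are exact
integers; floats enter only in the final ω multiplication and averaging,
so score comparisons are reproducible to 1e-12.

## Optimization

* **Exhaustive** enumeration of K-subsets up to a configurable cap
  (default 5×10⁶ combinations), visiting subsets in lexicographic order of
  sorted gene labels and replacing the incumbent only on strict
  improvement — ties therefore resolve to the lexicographically smallest
  tuple, totally and deterministically.
* **Genetic algorithm** over K-subsets: tournament selection (size 3),
  uniform crossover drawing the child without replacement from the two
  parents' gene union, per-child mutation (rate 0.1) swapping one member
  for a random non-member, elitism (2), population 100, ≤ 500 generations.
  Early stop after 200 stagnant generations: the single-swap mutation
  escapes local optima on a timescale of tens-to-hundreds of generations
  for a few-hundred-gene search space, and a short stagnation window (we
  initially used 50) demonstrably causes premature convergence on
  200-gene instances while saving little runtime. All hyperparameters are
  configurable; the defaults are justified by the oracle-equivalence tests
  (GA vs exhaustive optimum on enumerable instances), not by any claim
  about external GA implementations. Identical (instance, K, params, seed)
  gives bit-identical results.
* **Exact MILP** for S_m (HiGHS backend through `scipy.optimize.milp`):
  gene indicators x_j with Σx_j = K; per positive-side sample a continuous
  z ∈ [0,1] with z ≤ Σ_j a_ij x_j and objective coefficient +2/R (pushed up
  to the coverage indicator); per control-side sample z ∈ [0,1] with
  z ≥ x_j for each mutated gene and coefficient −K/(T(K−1)) (pushed down to
  the indicator); per-gene frequency sums enter linearly. For every
  feasible 0/1 assignment the linear objective equals S_m of the selected
  set, so the MILP optimum is a certified global maximizer; this is
  cross-checked against exhaustive enumeration in the test suite. C_m has
  **no** MILP route — ω is non-linear — so exact common-mode answers come
  from exhaustive search only, and large common instances use the GA.
  The dispatcher never downgrades an exact method to the GA silently; the
  result object records the method used.

## Permutation significance

The null model permutes each gene column independently, re-assigning its
1-entries to a uniformly random sample subset of the same size: gene
mutation frequencies are preserved exactly while co-occurrence structure is
destroyed. p-values use the add-one estimator
p = (1 + #{null ≥ observed})/(N+1) — never zero at finite N, ties counted
conservatively toward the null. Defaults: N = 1,000 permutations
(tests and examples use scaled-down N, flagged where they do), α = 0.05.

Two significance notions are computed: *individual* (the Dendrix weight of
the fixed set within one matrix) and *overall* (C_m or S_m across the
group). The overall null either re-scores the same fixed set
(`fixed_set`, default — cheap, and it is the reported set that is under
test) or re-optimizes the best K-set per permutation (`reoptimized`, the
conservative max-weight null, available when an optimizer is supplied).

Decision rules: a common-mode set is accepted iff overall p < α **and**
every positive individual p < α; a specific-mode set additionally requires
individual p ≥ α in **every** control matrix. Inequalities are strict at α
for "significant" and non-strict for the control-side requirement. No
multiple-testing correction is applied across the K = 2..10 sweep, matching
the stated procedure; the sweep table reports every K so users can apply
their own.

A practical caveat established during calibration: on sparse instances
(e.g. ≤ 100 samples at ~5% background), the test statistic saturates at its
fully-exclusive maximum, which carries a large probability atom; a
tie-conservative permutation test is then *degenerate* (rejection rate ≈ 0
at any α), not miscalibrated. Calibration claims in the test suite
therefore use instances large and dense enough (400 samples, K = 6) for
the score support to be effectively continuous, where the measured null
rejection rate at α = 0.05 is 0.05 ± 0.01.

## Validation and prioritization

* **Reference overlap**: identified genes are compared with per-cohort
  reference driver lists via the upper-tail hypergeometric test
  (population = the analysis gene universe; configurable to the union of
  cohort genes). The "common reference" of a cohort selection is the
  intersection of its lists (the union minus the intersection being the
  "partial" tier); the "specific reference" of A-cohorts versus B-cohorts
  is (union of A references) − (union of B references). Cohorts with empty
  reference lists are rejected explicitly rather than silently skipped.
  Identified genes are categorized with precedence
  all_cohorts > partial > literature > novel.
* **Enrichment**: hypergeometric upper-tail test of each candidate set
  against a user-supplied GMT collection at threshold 0.05, with the
  analysis universe (not the genome) as background. This replaces an
  external web-service step with a reproducible offline equivalent; no
  multiple-testing correction by default (Benjamini–Hochberg behind a
  flag). The *enrichment ratio* of a candidate is the largest fraction of
  its genes inside any single enriched pathway; across the accepted rows
  of a K sweep, the candidate with the highest ratio is the final module,
  ties breaking to smaller K, then lexicographic genes.

## Synthetic data

The generator emulates exactly the structure the objectives assume. Per
positive matrix: round(γ_r · m_r) samples are covered (an exact count, not
Bernoulli, so recovery experiments have deterministic signal strength);
each covered sample gets one module gene uniformly at random; with
probability ε it gets a second distinct module gene (exclusivity
violation). Independent Bernoulli background at rate p_bg is OR'd over
every cell — including module genes in negative matrices — so impurity can
also arise from background, as in real cohorts; realized violations are
recorded in the ground truth. Per-gene heterogeneous rates
(Uniform(0.001, 0.05)) are available to emulate the inter-cohort rate
variation that motivates the entropy weight. Generation is a pure function
of the config including the seed.

Default scenario parameters (3 positive cohorts of 100 samples, 200 genes,
K* = 4, γ = 0.7, ε = 0, p_bg = 0.02) describe a strong, clean module on
realistic sparse background. What a green recovery test establishes is that
the search + testing machinery finds a module *of the kind the model
assumes*; the generator deliberately does not emulate mutational
signatures, gene-length or expression covariates, subclonal structure, or
inter-gene correlation beyond the planted module, so green tests say
nothing about robustness to those.

## Known limitations

* EntCDP-style common scoring has no exact solver at scale (non-linear ω);
  GA results are stochastic lower bounds, certified only on instances small
  enough to enumerate.
* The fixed-set permutation test is conservative under heavy score ties
  (sparse matrices, small K); see the calibration caveat above.
* The MAF reader requires only (sample, gene, classification) and applies
  no variant-level filtering beyond the classification set.
* Reference catalogs and literature-verified gene lists are user input;
  the package does not curate them.
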