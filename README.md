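# mexmod

Cross-cohort discovery of **mutually exclusive cancer driver gene modules**
from binary somatic-mutation matrices.

Driver alterations within one signaling pathway tend to be *mutually
exclusive* across tumors: one hit per pathway per patient is usually enough.
Given several cohorts (binary sample × gene matrices), `mexmod` searches for
gene sets that jointly show **high coverage** (many samples altered in at
least one member) and **high exclusivity** (few samples altered in more than
one member) — either *common* to all cohorts in a group, or *specific* to
target cohorts relative to control cohorts. It is aimed at researchers
comparing mutation profiles across regions, tumor subtypes, age groups or
risk-factor strata.

## The objectives

For a gene set *M* of size *K* and cohort matrix *A_r* (m_r samples), let
Γ_{A_r}(g) be the samples altered in gene *g* and
Γ_{A_r}(M) = ∪_{g∈M} Γ_{A_r}(g). The per-cohort Dendrix weight

    W_r(M) = 2·|Γ_{A_r}(M)| − Σ_{g∈M} |Γ_{A_r}(g)|

rewards coverage and penalizes overlap (W_r = coverage exactly when *M* is
perfectly exclusive).

**Common modules** (positive cohorts A_1..A_R, R ≥ 2) maximize the
entropy-weighted objective

    C_m(M) = ω · Σ_r W_r(M),    ω = −Σ_r q_r ln q_r,   q_r = CR_r / Σ CR_r,

where CR_r = |Γ_{A_r}(M)|/m_r is the coverage rate. ω peaks at ln R when
coverage is balanced across cohorts, so lopsided sets are demoted.

**Specific modules** (targets A_1..A_R vs controls B_1..B_T) maximize

    S_m(M) = (1/R) Σ_r W_r(M) − (1/T) Σ_t [K·|Γ_{B_t}(M)| − Σ_g |Γ_{B_t}(g)|]/(K−1),

penalizing sets that show the same coverage/exclusivity structure in the
controls.

Candidates are screened over K = 2..10 with frequency-preserving permutation
tests (overall + per-cohort individual significance, with the control-side
*non*-significance requirement for specific modules), validated against
reference driver catalogs by hypergeometric overlap, and prioritized by
pathway **enrichment ratio** (the largest fraction of the set inside any
significantly enriched pathway).

Optimizers: exhaustive enumeration (certified, capped), a seeded genetic
algorithm (either objective, any scale), and an exact mixed-integer linear
program for S_m (HiGHS via `scipy.optimize.milp`).

## Worked example

Simulate three cohorts of 100 samples over 200 genes with a planted 4-gene
module (70% coverage, perfectly exclusive) on 2% background noise, then
recover it:

```python
import numpy as np
from mexmod import (MatrixSpec, ScenarioConfig, generate_group,
                    ga_maximize, GAParams, assess_candidate)

cfg = ScenarioConfig(
    n_genes=200,
    matrices=[MatrixSpec(f"A{r+1}", 100) for r in range(3)],
    module_size=4, coverage=0.7, background_rate=0.02, seed=1,
)
group, truth = generate_group(cfg)
print(truth.module_genes)            # ('g094', 'g102', 'g151', 'g191')

res = ga_maximize(group, K=4, model="entcdp", params=GAParams(seed=1))
print(res.best_set.sorted(), round(res.best_score, 2))
#  ('g094', 'g102', 'g151', 'g191') 227.38

report = assess_candidate(group, res.best_set, "entcdp",
                          n_perm=200, rng=np.random.default_rng(1))
print(report.overall_p, report.decision)
#  0.004975124378109453 accept
```

The GA recovers exactly the planted module; its score 227.38 is
ω · Σ_r W_r at near-balanced ~72% coverage per cohort (ω ≈ ln 3), and the
permutation p-value 1/201 says no frequency-preserving shuffle of the
cohorts reached that score in 200 tries, so the set is accepted.

The same workflow runs from the shell:

```bash
mexmod simulate --out-dir sim --n-genes 200 --n-positive 3 --module-size 4 --seed 1
mexmod run comparison.yaml        # sweep K, test, validate, prioritize
```

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from scratch
on seeded synthetic data: the common-module scenario above (GA + permutation
test + reference overlap + enrichment prioritization), a specific-module
scenario with two control cohorts solved exactly by the MILP, and a small
K-sweep. It writes its results JSON to `--out`:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `mexmod.cohort_io` — matrix/clinical/universe IO, silent-mutation
  filtering, sample stratification (adult/pediatric, obesity), gene-column
  harmonization across cohorts.
- `mexmod.objectives` — coverage/exclusivity primitives, C_m and S_m.
- `mexmod.optimizers` — exhaustive search, genetic algorithm, exact MILP.
- `mexmod.significance` — permutation null, individual/overall p-values,
  decision rules, K sweep.
- `mexmod.reference_overlap` — hypergeometric overlap against reference
  driver catalogs; gene categorization.
- `mexmod.enrichment` — GMT parsing, hypergeometric pathway enrichment,
  enrichment-ratio prioritization.
- `mexmod.synthetic` — planted-module cohort simulator with ground truth.
- `mexmod.pipeline` / `mexmod.cli` — config-driven end-to-end runs.

See `docs/methods.md` for the statistical model, parameter defaults and
their rationale, and known limitations.
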