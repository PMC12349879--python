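"""Maximizers for the common (EntCDP) and specific (ModSDP) objectives.

Three routes:

* :func:`exhaustive_search` — certified global optimum by enumerating every
  K-subset; refuses above a combination cap.  Ties break to the
  lexicographically smallest sorted gene tuple.
* :func:`ga_maximize` — seeded genetic algorithm over K-subsets
  (tournament selection, union crossover, member-swap mutation, elitism);
  the paper-scale route for either objective.
* :func:`ilp_maximize_modsdp` — exact mixed-integer linear program for the
  specific objective, solved with HiGHS via ``scipy.optimize.milp``.  The
  common objective has no ILP route (the entropy weight is non-linear).

MILP formulation (Dendrix-style binary program adapted to the two-group sign
structure of S_m): gene variables x_j in {0,1} with sum x_j = K; for every
sample i of a positive matrix A_r a continuous z_i^r in [0,1] with
z_i^r <= sum_j a_ij x_j and objective coefficient +2/R, so the maximizer
drives z to min(1, #selected mutated genes) — the coverage indicator; for
every sample i of a negative matrix B_t a continuous z_i^t in [0,1] with
z_i^t >= x_j for every gene j mutated in that sample, and coefficient
-K/(T(K-1)), driving z down to the coverage indicator.  Per-gene frequency
terms enter linearly as sum_j freq_j x_j.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .cohort_io import CohortGroup, ConfigError
from .objectives import CandidateSet, GroupArrays, modsdp_score

__all__ = [
    "OptimizerResult",
    "GAParams",
    "exhaustive_search",
    "ga_maximize",
    "ilp_maximize_modsdp",
    "optimize",
]


class CapabilityError(RuntimeError):
    """A requested backend or search mode is unavailable for this instance."""


@dataclass
class OptimizerResult:
    best_set: CandidateSet
    best_score: float
    method: str  # exhaustive | ga | ilp
    seed: int | None
    evaluations: int
    converged: bool


@dataclass
class GAParams:
    """Genetic-algorithm hyperparameters (all configurable; defaults below).

    population_size=100, tournament_size=3, per-child mutation_rate=0.1
    (swap one member for a random non-member), elite_count=2, at most
    generations=500 with early stop after stagnation_limit=200 generations
    without improvement.  The stagnation window is deliberately wide: the
    single-gene-swap mutation escapes local optima on a timescale of tens of
    generations for a few-hundred-gene search space, and a short window cuts
    that escape off (premature convergence) while saving little time.
    """

    population_size: int = 100
    generations: int = 500
    tournament_size: int = 3
    mutation_rate: float = 0.1
    elite_count: int = 2
    stagnation_limit: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.population_size, self.generations, self.tournament_size,
               self.elite_count, self.stagnation_limit) <= 0:
            raise ConfigError("GA parameters must be positive")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ConfigError("mutation_rate must be in [0, 1]")


def _sorted_gene_order(group: CohortGroup) -> tuple[list[str], np.ndarray]:
    """Genes in lexicographic order plus their column indices (for tie-breaking)."""
    genes = group.gene_ids
    order = np.argsort(np.asarray(genes, dtype=object))
    return [genes[i] for i in order], order


def exhaustive_search(
    group: CohortGroup,
    K: int,
    model: str,
    max_combinations: int = 5_000_000,
    batch: int = 4096,
) -> OptimizerResult:
    """Enumerate all K-subsets; certified global optimum.

    Subsets are visited in lexicographic order of the sorted gene labels and
    only strictly better scores replace the incumbent, so score ties resolve
    to the lexicographically smallest gene tuple.
    """
    G = len(group.gene_ids)
    if K < 2:
        raise ConfigError("K must be >= 2")
    if K > G:
        raise ConfigError(f"K={K} exceeds the {G} genes in the group")
    n_comb = comb(G, K)
    if n_comb > max_combinations:
        raise CapabilityError(
            f"C({G},{K}) = {n_comb} exceeds the exhaustive cap {max_combinations}"
        )
    genes_sorted, col_order = _sorted_gene_order(group)
    arrays = GroupArrays(group)
    best_score = -np.inf
    best_combo: tuple[int, ...] | None = None
    evaluations = 0
    buf: list[tuple[int, ...]] = []

    def flush(buf: list[tuple[int, ...]]) -> None:
        nonlocal best_score, best_combo
        pop = col_order[np.array(buf, dtype=np.intp)]
        scores = arrays.score_population(pop, model)
        j = int(np.argmax(scores))  # argmax takes the first max: lexicographic tie-break
        if scores[j] > best_score:
            best_score = float(scores[j])
            best_combo = buf[j]

    for combo in combinations(range(G), K):
        buf.append(combo)
        evaluations += 1
        if len(buf) == batch:
            flush(buf)
            buf = []
    if buf:
        flush(buf)
    assert best_combo is not None
    best = CandidateSet(tuple(genes_sorted[i] for i in best_combo))
    return OptimizerResult(best, best_score, "exhaustive", None, evaluations, True)


def ga_maximize(group: CohortGroup, K: int, model: str, params: GAParams | None = None) -> OptimizerResult:
    """Seeded GA over K-subsets of the group's genes.

    Chromosome = K distinct gene indices; fitness = objective score.  The
    best-ever individual is tracked outside the population (elitism), so a
    population that contains the optimum can never return less.  Identical
    (group, K, model, params, seed) gives bit-identical results.
    """
    params = params or GAParams()
    G = len(group.gene_ids)
    if K < 2:
        raise ConfigError("K must be >= 2")
    if K > G:
        raise ConfigError(f"K={K} exceeds the {G} genes in the group")
    rng = np.random.default_rng(params.seed)
    arrays = GroupArrays(group)
    P = params.population_size

    pop = np.empty((P, K), dtype=np.intp)
    for i in range(P):
        pop[i] = rng.choice(G, size=K, replace=False)
    fitness = arrays.score_population(pop, model)
    evaluations = P

    def best_of(pop: np.ndarray, fitness: np.ndarray) -> tuple[np.ndarray, float]:
        j = int(np.argmax(fitness))
        return pop[j].copy(), float(fitness[j])

    best_ind, best_fit = best_of(pop, fitness)
    stagnant = 0
    converged = False
    for _ in range(params.generations):
        elite_idx = np.argsort(fitness)[::-1][: params.elite_count]
        children = [pop[i].copy() for i in elite_idx]
        while len(children) < P:
            # tournament selection of two parents
            parents = []
            for _p in range(2):
                contenders = rng.integers(0, P, size=params.tournament_size)
                parents.append(pop[contenders[np.argmax(fitness[contenders])]])
            union = np.union1d(parents[0], parents[1])
            child = rng.choice(union, size=K, replace=False)
            if rng.random() < params.mutation_rate:
                # swap one member for a random non-member
                out = rng.integers(0, K)
                member = set(child.tolist())
                while True:
                    g = int(rng.integers(0, G))
                    if g not in member:
                        break
                child = child.copy()
                child[out] = g
            children.append(child)
        pop = np.array(children, dtype=np.intp)
        fitness = arrays.score_population(pop, model)
        evaluations += P
        gen_best, gen_fit = best_of(pop, fitness)
        if gen_fit > best_fit:
            best_ind, best_fit = gen_best, gen_fit
            stagnant = 0
        else:
            stagnant += 1
            if stagnant >= params.stagnation_limit:
                converged = True
                break
    genes = tuple(sorted(group.gene_ids[i] for i in best_ind))
    return OptimizerResult(CandidateSet(genes), best_fit, "ga", params.seed, evaluations, converged)


def ilp_maximize_modsdp(group: CohortGroup, K: int, solver: str = "highs") -> OptimizerResult:
    """Certified global maximizer of S_m via mixed-integer linear programming."""
    if group.mode != "specific":
        raise ConfigError("ilp_maximize_modsdp requires a specific-mode group")
    if solver != "highs":
        raise CapabilityError(f"unknown solver backend {solver!r}; available: 'highs'")
    G = len(group.gene_ids)
    if K < 2:
        raise ConfigError("K must be >= 2")
    if K > G:
        raise ConfigError(f"K={K} exceeds the {G} genes in the group")
    R, T = group.R, group.T
    mA = [a.n_samples for a in group.positives]
    mB = [b.n_samples for b in group.negatives]
    n_x = G
    n_zA = sum(mA)
    n_zB = sum(mB)
    n = n_x + n_zA + n_zB

    # milp minimizes; the objective to MAXIMIZE is
    #   sum_r (2/R) z^r - (1/R) freqA.x - sum_t K/(T(K-1)) z^t + (1/(T(K-1))) freqB.x
    # so the minimization vector is its negation:
    c_min = np.zeros(n)
    for a in group.positives:
        c_min[:G] += a.data.sum(axis=0) / R
    for b in group.negatives:
        c_min[:G] -= b.data.sum(axis=0) / (T * (K - 1))
    c_min[n_x : n_x + n_zA] = -2.0 / R
    c_min[n_x + n_zA :] = K / (T * (K - 1))

    rows, cols, vals = [], [], []
    lb_con, ub_con = [], []
    row = 0
    # cardinality: sum x_j = K
    for j in range(G):
        rows.append(row); cols.append(j); vals.append(1.0)
    lb_con.append(K); ub_con.append(K)
    row += 1
    # A-side: z_i^r - sum_j a_ij x_j <= 0
    offset = n_x
    for a in group.positives:
        data = a.data
        for i in range(a.n_samples):
            mut = np.flatnonzero(data[i])
            rows.append(row); cols.append(offset + i); vals.append(1.0)
            for j in mut:
                rows.append(row); cols.append(int(j)); vals.append(-1.0)
            lb_con.append(-np.inf); ub_con.append(0.0)
            row += 1
        offset += a.n_samples
    # B-side: x_j - z_i^t <= 0 for every mutated gene j of sample i
    for b in group.negatives:
        data = b.data
        for i in range(b.n_samples):
            for j in np.flatnonzero(data[i]):
                rows.append(row); cols.append(int(j)); vals.append(1.0)
                rows.append(row); cols.append(offset + i); vals.append(-1.0)
                lb_con.append(-np.inf); ub_con.append(0.0)
                row += 1
        offset += b.n_samples

    A = sparse.csr_matrix((vals, (rows, cols)), shape=(row, n))
    constraints = LinearConstraint(A, lb_con, ub_con)
    integrality = np.zeros(n)
    integrality[:G] = 1
    res = milp(
        c=c_min,
        constraints=constraints,
        integrality=integrality,
        bounds=Bounds(np.zeros(n), np.ones(n)),
    )
    if res.status != 0 or res.x is None:
        raise CapabilityError(f"MILP solver failed: {res.message}")
    x = np.round(res.x[:G]).astype(bool)
    genes = tuple(sorted(g for g, sel in zip(group.gene_ids, x) if sel))
    best = CandidateSet(genes)
    # certify by recomputing the objective on the selected set
    score, _ = modsdp_score(group, best)
    return OptimizerResult(best, float(score), "ilp", None, 1, True)


def optimize(
    group: CohortGroup,
    K: int,
    model: str,
    method: str = "auto",
    ga_params: GAParams | None = None,
    max_combinations: int = 5_000_000,
) -> OptimizerResult:
    """Dispatch: 'exhaustive', 'ga', 'ilp', or 'auto'.

    'auto' prefers the exact route (exhaustive when the instance fits under
    the cap, else ILP for the specific model) and falls back to the GA
    explicitly — never silently: the returned result records the method used.
    """
    if method == "exhaustive":
        return exhaustive_search(group, K, model, max_combinations=max_combinations)
    if method == "ga":
        return ga_maximize(group, K, model, ga_params)
    if method == "ilp":
        if model != "modsdp":
            raise CapabilityError("ILP route exists only for the specific (modsdp) objective")
        return ilp_maximize_modsdp(group, K)
    if method == "auto":
        if comb(len(group.gene_ids), K) <= max_combinations:
            return exhaustive_search(group, K, model, max_combinations=max_combinations)
        if model == "modsdp":
            return ilp_maximize_modsdp(group, K)
        return ga_maximize(group, K, model, ga_params)
    raise ConfigError(f"unknown optimizer method {method!r}")
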