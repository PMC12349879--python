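"""Permutation significance testing and the K-sweep decision procedure.

Null model: each permutation preserves every gene's mutation frequency but
re-assigns its 1-entries to a uniformly random sample subset, independently
per gene — coverage/exclusivity structure is destroyed while per-gene
marginals are kept exactly.

Two notions of significance:

* *individual* — the Dendrix weight 2|Gamma(M)| - sum_g |Gamma(g)| of a fixed
  set M within a single matrix, against its permutation null;
* *overall* — the group-level objective (C_m for common mode, S_m for
  specific mode), against permutations of every member matrix.  The null
  statistic either re-scores the same fixed set (``fixed_set``, the default)
  or re-optimizes the best set at the same K per permutation
  (``reoptimized``, the conservative max-weight null).

p-values use the add-one estimator p = (1 + #{null >= observed}) / (N + 1),
so p is never 0 and ties count conservatively toward the null.

Decision rules at level alpha (default 0.05): a common-mode set is accepted
iff the overall p and every positive matrix's individual p are < alpha; a
specific-mode set additionally requires individual p >= alpha in every
negative matrix (the set must NOT be significant in the controls).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cohort_io import CohortGroup, ConfigError, MutationMatrix
from .objectives import CandidateSet, GroupArrays, dendrix_weight
from .optimizers import GAParams, optimize

__all__ = [
    "SignificanceReport",
    "SweepRow",
    "SweepTable",
    "permute_matrix",
    "permutation_pvalue",
    "individual_significance",
    "overall_significance",
    "decide",
    "assess_candidate",
    "sweep_K",
]


@dataclass
class SignificanceReport:
    overall_p: float
    individual_p_positive: dict[str, float]
    individual_p_negative: dict[str, float]
    n_permutations: int
    null_mode: str  # fixed_set | reoptimized
    alpha: float = 0.05
    decision: str | None = None  # accept | reject


def permute_matrix(matrix: MutationMatrix, rng: np.random.Generator) -> MutationMatrix:
    """Frequency-preserving column permutation.

    Every column's 1-entries are re-assigned to a uniformly random sample
    subset of the same size, independently per column.  Column sums are
    preserved exactly; row sums generally change.
    """
    m, G = matrix.data.shape
    if m == 0 or G == 0:
        return MutationMatrix(matrix.cohort_id, list(matrix.sample_ids),
                              list(matrix.gene_ids), matrix.data.copy())
    colsums = matrix.data.sum(axis=0)
    # rank the rows of one uniform draw per column: the first f ranks form a
    # uniformly random f-subset for that column
    keys = rng.random((m, G))
    order = np.argsort(keys, axis=0, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(m)[:, None] * np.ones(G, dtype=np.intp), axis=0)
    new = (ranks < colsums[None, :]).astype(np.uint8)
    return MutationMatrix(matrix.cohort_id, list(matrix.sample_ids), list(matrix.gene_ids), new)


def permutation_pvalue(observed: float, null_values: Sequence[float]) -> float:
    """Add-one permutation p-value: (1 + #{null >= observed}) / (N + 1)."""
    nulls = np.asarray(null_values, dtype=float)
    if nulls.size == 0:
        raise ConfigError("permutation_pvalue needs at least one null value")
    return float((1 + (nulls >= observed).sum()) / (nulls.size + 1))


def individual_significance(
    matrix: MutationMatrix,
    M: CandidateSet,
    n_perm: int,
    rng: np.random.Generator,
) -> float:
    """Permutation p-value for M's Dendrix weight within one matrix."""
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    observed = dendrix_weight(matrix, M)
    nulls = np.empty(n_perm)
    for b in range(n_perm):
        nulls[b] = dendrix_weight(permute_matrix(matrix, rng), M)
    return permutation_pvalue(observed, nulls)


def overall_significance(
    group: CohortGroup,
    M: CandidateSet,
    model: str,
    n_perm: int,
    rng: np.random.Generator,
    null_mode: str = "fixed_set",
    optimizer: Callable[[CohortGroup], float] | None = None,
) -> float:
    """Permutation p-value for the group-level objective score of M.

    In ``fixed_set`` mode the null statistic is the score of the same M on
    the permuted group; in ``reoptimized`` mode it is the score of the best
    set at |M| genes found on each permuted group (pass *optimizer*, a
    callable group -> best score; required for this mode).
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    if (model == "entcdp") != (group.mode == "common"):
        raise ConfigError(f"model {model!r} does not match group mode {group.mode!r}")
    if null_mode not in ("fixed_set", "reoptimized"):
        raise ConfigError(f"unknown null_mode {null_mode!r}")
    if null_mode == "reoptimized" and optimizer is None:
        raise ConfigError("reoptimized null_mode requires an optimizer callable")
    arrays = GroupArrays(group)
    gene_index = {g: j for j, g in enumerate(group.gene_ids)}
    idx = np.array([gene_index[g] for g in M.genes], dtype=np.intp)
    observed = arrays.score_indices(idx, model)
    nulls = np.empty(n_perm)
    for b in range(n_perm):
        perm_group = CohortGroup(
            positives=[permute_matrix(a, rng) for a in group.positives],
            negatives=[permute_matrix(bm, rng) for bm in group.negatives],
            mode=group.mode,
        )
        if null_mode == "fixed_set":
            nulls[b] = GroupArrays(perm_group).score_indices(idx, model)
        else:
            nulls[b] = optimizer(perm_group)
    return permutation_pvalue(observed, nulls)


def decide(report: SignificanceReport, model: str) -> bool:
    """Apply the acceptance rule; stores and returns the decision.

    Common mode (entcdp): overall p < alpha and every positive individual
    p < alpha.  Specific mode (modsdp): additionally every negative
    individual p >= alpha.  Inequalities are strict at alpha for
    "significant" and non-strict for the negative-side requirement.
    """
    if not report.individual_p_positive:
        raise ConfigError("report lacks positive-matrix individual p-values")
    a = report.alpha
    ok = report.overall_p < a and all(p < a for p in report.individual_p_positive.values())
    if model == "modsdp":
        if not report.individual_p_negative:
            raise ConfigError("modsdp decision requires negative-matrix individual p-values")
        ok = ok and all(p >= a for p in report.individual_p_negative.values())
    elif model != "entcdp":
        raise ConfigError(f"unknown model {model!r}")
    report.decision = "accept" if ok else "reject"
    return ok


def assess_candidate(
    group: CohortGroup,
    M: CandidateSet,
    model: str,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    null_mode: str = "fixed_set",
    alpha: float = 0.05,
    optimizer: Callable[[CohortGroup], float] | None = None,
) -> SignificanceReport:
    """Full individual+overall permutation assessment of one candidate set."""
    rng = rng if rng is not None else np.random.default_rng(0)
    report = SignificanceReport(
        overall_p=overall_significance(group, M, model, n_perm, rng, null_mode, optimizer),
        individual_p_positive={
            a.cohort_id: individual_significance(a, M, n_perm, rng) for a in group.positives
        },
        individual_p_negative={
            b.cohort_id: individual_significance(b, M, n_perm, rng) for b in group.negatives
        },
        n_permutations=n_perm,
        null_mode=null_mode,
        alpha=alpha,
    )
    decide(report, model)
    return report


@dataclass
class SweepRow:
    K: int
    best_set: CandidateSet
    score: float
    report: SignificanceReport
    method: str


@dataclass
class SweepTable:
    rows: list[SweepRow] = field(default_factory=list)

    def accepted(self) -> list[SweepRow]:
        return [r for r in self.rows if r.report.decision == "accept"]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            rec = {
                "K": r.K,
                "genes": ",".join(sorted(r.best_set.genes)),
                "score": r.score,
                "method": r.method,
                "overall_p": r.report.overall_p,
                "decision": r.report.decision,
            }
            for cid, p in r.report.individual_p_positive.items():
                rec[f"p_A[{cid}]"] = p
            for cid, p in r.report.individual_p_negative.items():
                rec[f"p_B[{cid}]"] = p
            recs.append(rec)
        return pd.DataFrame(recs)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_frame().to_dict(orient="records"), fh, indent=2)


def sweep_K(
    group: CohortGroup,
    model: str,
    Kmin: int = 2,
    Kmax: int = 10,
    method: str = "auto",
    ga_params: GAParams | None = None,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    null_mode: str = "fixed_set",
    alpha: float = 0.05,
) -> SweepTable:
    """Optimize and permutation-test the best set at every K in [Kmin, Kmax]."""
    if Kmin < 2:
        raise ConfigError("Kmin must be >= 2")
    if Kmax < Kmin:
        raise ConfigError("Kmax must be >= Kmin")
    rng = rng if rng is not None else np.random.default_rng(0)
    table = SweepTable()
    for K in range(Kmin, Kmax + 1):
        result = optimize(group, K, model, method=method, ga_params=ga_params)
        report = assess_candidate(
            group, result.best_set, model, n_perm=n_perm, rng=rng,
            null_mode=null_mode, alpha=alpha,
        )
        table.rows.append(SweepRow(K, result.best_set, result.best_score, report, result.method))
    return table
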