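"""Coverage/exclusivity primitives and the EntCDP / ModSDP objective functions.

For a gene set M of size K and a cohort matrix A_r:

* coverage   |Gamma_Ar(M)| — number of samples altered in at least one gene
  of M;
* Dendrix weight W_r(M) = 2|Gamma_Ar(M)| - sum_g |Gamma_Ar(g)| — rewards
  coverage, penalizes overlap; W_r = |Gamma_Ar(M)| exactly when M's columns
  are pairwise disjoint (perfect mutual exclusivity).

The common-driver objective (EntCDP) is

    C_m(M) = omega * sum_r W_r(M),

where omega is the Shannon entropy of the normalized per-cohort coverage
rates CR_r = |Gamma_Ar(M)| / m_r: omega is maximal (ln R) when coverage is
balanced across cohorts and shrinks when one cohort dominates.

The specific-driver objective (ModSDP), for positive matrices A_1..A_R and
negative (control) matrices B_1..B_T, is

    S_m(M) = (1/R) sum_r W_r(M)
           - (1/T) sum_t [K|Gamma_Bt(M)| - sum_g |Gamma_Bt(g)|] / (K-1),

so a set is rewarded for coverage+exclusivity in the A side and penalized for
showing the same structure in the B side.  K=1 is rejected (the K-1 divisor).

Counts are accumulated in exact integer arithmetic; floats enter only in the
final entropy weighting / averaging.  The entropy uses the natural log (the
base only rescales C_m monotonically and cannot change the argmax).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .cohort_io import CohortGroup, ConfigError, MutationMatrix

__all__ = [
    "CandidateSet",
    "ObjectiveReport",
    "gene_coverage",
    "set_coverage",
    "dendrix_weight",
    "coverage_and_weight",
    "entropy_weight",
    "entcdp_score",
    "modsdp_score",
    "score_group",
]


@dataclass(frozen=True)
class CandidateSet:
    """A candidate driver gene set M of K >= 2 distinct genes."""

    genes: tuple[str, ...]

    def __init__(self, genes: Iterable[str]):
        genes = tuple(genes)
        if len(set(genes)) != len(genes):
            raise ConfigError(f"duplicate genes in candidate set: {genes}")
        if len(genes) < 2:
            raise ConfigError(f"candidate set needs K>=2 genes, got {len(genes)}")
        object.__setattr__(self, "genes", genes)

    @property
    def K(self) -> int:
        return len(self.genes)

    def sorted(self) -> tuple[str, ...]:
        return tuple(sorted(self.genes))


@dataclass
class ObjectiveReport:
    """All intermediates behind one C_m or S_m evaluation."""

    model: str  # entcdp | modsdp
    genes: tuple[str, ...]
    coverage_counts: dict[str, int]       # positive matrices: |Gamma_Ar(M)|
    coverage_rates: dict[str, float]      # CR_r(M) = |Gamma_Ar(M)| / m_r
    dendrix_weights: dict[str, int]       # positive matrices: W_r(M)
    score: float
    omega: float | None = None            # common mode only
    penalties: dict[str, float] = field(default_factory=dict)  # per-B_t, specific mode


def gene_coverage(matrix: MutationMatrix, gene: str) -> set[str]:
    """Gamma_Ar(g): the set of sample IDs in which *gene* is altered."""
    col = matrix.gene_column(gene)
    return {matrix.sample_ids[i] for i in np.flatnonzero(col)}


def set_coverage(matrix: MutationMatrix, M: CandidateSet) -> int:
    """|Gamma_Ar(M)|: number of samples altered in at least one gene of M."""
    idx = matrix.gene_indices(M.genes)
    return int(matrix.data[:, idx].any(axis=1).sum())


def coverage_and_weight(matrix: MutationMatrix, M: CandidateSet) -> tuple[int, int]:
    """(|Gamma(M)|, W(M)) computed in one pass over M's columns."""
    idx = matrix.gene_indices(M.genes)
    sub = matrix.data[:, idx]
    cov = int(sub.any(axis=1).sum())
    return cov, 2 * cov - int(sub.sum())


def dendrix_weight(matrix: MutationMatrix, M: CandidateSet) -> int:
    """W(M) = 2|Gamma(M)| - sum_g |Gamma(g)|; may be negative for heavy overlap."""
    return coverage_and_weight(matrix, M)[1]


def entropy_weight(coverage_rates: Sequence[float]) -> float:
    """Shannon entropy omega of the normalized coverage rates (natural log).

    Terms with zero rate contribute 0 (the 0*log 0 := 0 convention); if every
    rate is zero, omega := 0.  0 <= omega <= ln R, with equality at ln R iff
    all rates are equal and nonzero.
    """
    rates = np.asarray(coverage_rates, dtype=float)
    total = rates.sum()
    if total <= 0:
        return 0.0
    q = rates[rates > 0] / total
    return float(-(q * np.log(q)).sum())


def entcdp_score(group: CohortGroup, M: CandidateSet) -> tuple[float, ObjectiveReport]:
    """C_m(M) = omega * sum_r W_r(M) on a common-mode group."""
    if group.mode != "common":
        raise ConfigError("entcdp_score requires a common-mode group")
    counts, rates, weights = {}, {}, {}
    for a in group.positives:
        cov, w = coverage_and_weight(a, M)
        counts[a.cohort_id] = cov
        rates[a.cohort_id] = cov / a.n_samples
        weights[a.cohort_id] = w
    omega = entropy_weight(list(rates.values()))
    score = omega * sum(weights.values())
    return score, ObjectiveReport(
        model="entcdp", genes=M.genes, coverage_counts=counts,
        coverage_rates=rates, dendrix_weights=weights, omega=omega, score=score,
    )


def modsdp_score(group: CohortGroup, M: CandidateSet) -> tuple[float, ObjectiveReport]:
    """S_m(M) on a specific-mode group; requires K >= 2 (K-1 divisor)."""
    if group.mode != "specific":
        raise ConfigError("modsdp_score requires a specific-mode group")
    K = M.K
    if K < 2:  # unreachable through CandidateSet, kept as an explicit contract
        raise ConfigError("modsdp requires K >= 2")
    counts, rates, weights, penalties = {}, {}, {}, {}
    w_sum = 0
    for a in group.positives:
        cov, w = coverage_and_weight(a, M)
        counts[a.cohort_id] = cov
        rates[a.cohort_id] = cov / a.n_samples
        weights[a.cohort_id] = w
        w_sum += w
    pen_sum = 0.0
    for b in group.negatives:
        idx = b.gene_indices(M.genes)
        sub = b.data[:, idx]
        cov_b = int(sub.any(axis=1).sum())
        pen = (K * cov_b - int(sub.sum())) / (K - 1)
        penalties[b.cohort_id] = pen
        pen_sum += pen
    score = w_sum / group.R - pen_sum / group.T
    return score, ObjectiveReport(
        model="modsdp", genes=M.genes, coverage_counts=counts,
        coverage_rates=rates, dendrix_weights=weights,
        penalties=penalties, score=score,
    )


def score_group(group: CohortGroup, M: CandidateSet, model: str) -> tuple[float, ObjectiveReport]:
    """Dispatch to :func:`entcdp_score` or :func:`modsdp_score` by model name."""
    if model == "entcdp":
        return entcdp_score(group, M)
    if model == "modsdp":
        return modsdp_score(group, M)
    raise ConfigError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# Index-based fast paths used by the optimizers.  These operate on raw column
# index arrays against precomputed per-matrix data and avoid label lookups.
# ---------------------------------------------------------------------------


class GroupArrays:
    """Precomputed dense views of a group for repeated objective evaluation."""

    def __init__(self, group: CohortGroup):
        self.mode = group.mode
        self.R = group.R
        self.T = group.T
        self.pos_data = [a.data.astype(bool) for a in group.positives]
        self.neg_data = [b.data.astype(bool) for b in group.negatives]
        self.pos_freq = [a.data.sum(axis=0).astype(np.int64) for a in group.positives]
        self.neg_freq = [b.data.sum(axis=0).astype(np.int64) for b in group.negatives]
        self.pos_m = [a.n_samples for a in group.positives]
        self.gene_ids = list(group.gene_ids)

    def score_population(self, pop: np.ndarray, model: str) -> np.ndarray:
        """Objective value for each row of *pop* (a P x K array of gene indices)."""
        pop = np.atleast_2d(pop)
        P, K = pop.shape
        if model == "entcdp":
            w_total = np.zeros(P)
            cr = np.empty((self.R, P))
            for r, (data, freq, m) in enumerate(zip(self.pos_data, self.pos_freq, self.pos_m)):
                cov = data[:, pop].any(axis=2).sum(axis=0)  # (P,)
                w_total += 2 * cov - freq[pop].sum(axis=1)
                cr[r] = cov / m
            total = cr.sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                q = np.where(total > 0, cr / total, 0.0)
                omega = np.where(q > 0, -q * np.log(np.where(q > 0, q, 1.0)), 0.0).sum(axis=0)
            return omega * w_total
        if model == "modsdp":
            score = np.zeros(P)
            for data, freq in zip(self.pos_data, self.pos_freq):
                cov = data[:, pop].any(axis=2).sum(axis=0)
                score += (2 * cov - freq[pop].sum(axis=1)) / self.R
            for data, freq in zip(self.neg_data, self.neg_freq):
                cov = data[:, pop].any(axis=2).sum(axis=0)
                score -= (K * cov - freq[pop].sum(axis=1)) / ((K - 1) * self.T)
            return score
        raise ConfigError(f"unknown model {model!r}")

    def score_indices(self, idx: Sequence[int], model: str) -> float:
        return float(self.score_population(np.asarray(idx, dtype=np.intp)[None, :], model)[0])
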