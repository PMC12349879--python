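"""Definition-literal oracle implementations used to cross-check the package.

Everything here is written straight from the mathematical definitions using
Python sets and loops, deliberately independent of the package's vectorized
code paths.
"""

from __future__ import annotations

import math
from itertools import combinations


def gamma(matrix, gene) -> set:
    """Sample set in which *gene* is altered, by row-wise loop."""
    j = matrix.gene_ids.index(gene)
    return {s for i, s in enumerate(matrix.sample_ids) if matrix.data[i, j] == 1}


def coverage(matrix, genes) -> int:
    covered = set()
    for g in genes:
        covered |= gamma(matrix, g)
    return len(covered)


def dendrix_weight(matrix, genes) -> int:
    return 2 * coverage(matrix, genes) - sum(len(gamma(matrix, g)) for g in genes)


def entropy(rates) -> float:
    total = sum(rates)
    if total == 0:
        return 0.0
    h = 0.0
    for r in rates:
        if r > 0:
            q = r / total
            h -= q * math.log(q)
    return h


def entcdp(group, genes) -> float:
    """Eq-literal C_m: entropy of normalized coverage rates times summed weights."""
    rates = [coverage(a, genes) / len(a.sample_ids) for a in group.positives]
    return entropy(rates) * sum(dendrix_weight(a, genes) for a in group.positives)


def modsdp(group, genes) -> float:
    """Eq-literal S_m with the K/(K-1)-scaled control-side penalty."""
    K = len(genes)
    R, T = len(group.positives), len(group.negatives)
    a_part = sum(dendrix_weight(a, genes) for a in group.positives) / R
    b_part = sum(
        (K * coverage(b, genes) - sum(len(gamma(b, g)) for g in genes)) / (K - 1)
        for b in group.negatives
    ) / T
    return a_part - b_part


def best_subset(group, K, model) -> tuple[tuple, float]:
    """Brute-force argmax over all K-subsets (lexicographic tie-break)."""
    fn = entcdp if model == "entcdp" else modsdp
    best, best_score = None, -math.inf
    for combo in combinations(sorted(group.gene_ids), K):
        s = fn(group, combo)
        if s > best_score:
            best, best_score = combo, s
    return best, best_score


def hypergeom_tail(k, N, K, n) -> float:
    """P(X >= k) by direct pmf summation for X ~ Hypergeom(N, K, n)."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
    return min(total, 1.0)
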