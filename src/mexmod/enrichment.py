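"""Offline hypergeometric pathway enrichment over GMT collections.

Each candidate gene set is tested against every pathway of a user-supplied
GMT collection (KEGG/GO-style) with the upper-tail hypergeometric test at a
0.05 threshold, against the analysis gene universe as background (not the
whole genome).  The *enrichment ratio* of a candidate is the maximum
proportion of its genes mapped to any single enriched pathway; among a list
of candidates (typically the accepted rows of a K sweep) the one with the
highest ratio is the final prioritized set.

No multiple-testing correction is applied by default; Benjamini-Hochberg is
available behind the ``correction="bh"`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom

from .cohort_io import ConfigError, FormatError, GeneUniverse
from .objectives import CandidateSet

__all__ = [
    "GeneSetCollection",
    "PathwayResult",
    "EnrichmentReport",
    "read_gmt",
    "enrich",
    "prioritize",
]


@dataclass
class GeneSetCollection:
    """Named pathways with descriptions and member gene sets (GMT contents)."""

    pathways: list[tuple[str, str, frozenset[str]]]

    def names(self) -> list[str]:
        return [name for name, _, _ in self.pathways]


@dataclass
class PathwayResult:
    name: str
    size_in_universe: int
    overlap: int
    p: float | None  # None = untestable (no members in the universe)

    @property
    def testable(self) -> bool:
        return self.p is not None


@dataclass
class EnrichmentReport:
    genes: tuple[str, ...]
    results: list[PathwayResult]
    alpha: float
    correction: str | None
    enriched: list[str] = field(default_factory=list)
    enrichment_ratio: float = 0.0
    best_pathway: str | None = None


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one pathway per line, 'name<TAB>description<TAB>genes...'.

    Duplicate member genes within a line collapse; a duplicate pathway name
    or a line with fewer than three fields is a format error.  An empty file
    yields an empty collection.
    """
    pathways: list[tuple[str, str, frozenset[str]]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno} has {len(fields)} fields, need >= 3")
            name, desc = fields[0], fields[1]
            if name in seen:
                raise FormatError(f"{path}: line {lineno}: duplicate pathway name {name!r}")
            seen.add(name)
            members = frozenset(g for g in fields[2:] if g)
            pathways.append((name, desc, members))
    return GeneSetCollection(pathways)


def enrich(
    M: CandidateSet,
    collection: GeneSetCollection,
    universe: GeneUniverse,
    alpha: float = 0.05,
    correction: str | None = None,
) -> EnrichmentReport:
    """Hypergeometric enrichment of M against every pathway in the collection.

    Pathway members are intersected with the universe before testing; a
    pathway disjoint from the universe is reported as untestable.  A pathway
    is enriched iff its (optionally BH-corrected) p < alpha.
    """
    uni = universe.as_set()
    if not uni:
        raise ConfigError("empty universe")
    genes = set(M.genes) & uni
    N, n_draw = len(uni), len(genes)
    results: list[PathwayResult] = []
    for name, _, members in collection.pathways:
        members_u = members & uni
        if not members_u:
            results.append(PathwayResult(name, 0, 0, None))
            continue
        k = len(genes & members_u)
        p = float(hypergeom.sf(k - 1, N, len(members_u), n_draw))
        results.append(PathwayResult(name, len(members_u), k, p))

    testable = [r for r in results if r.testable]
    pvals = {r.name: r.p for r in testable}
    if correction == "bh" and testable:
        order = sorted(testable, key=lambda r: r.p)
        n = len(order)
        adj = np.minimum.accumulate(
            [order[i].p * n / (i + 1) for i in range(n - 1, -1, -1)]
        )[::-1]
        pvals = {r.name: float(min(a, 1.0)) for r, a in zip(order, adj)}
    elif correction not in (None, "bh"):
        raise ConfigError(f"unknown correction {correction!r}")

    enriched = [r.name for r in testable if pvals[r.name] < alpha]
    ratio, best = 0.0, None
    for r in testable:
        if r.name in enriched and M.K:
            frac = r.overlap / M.K
            if frac > ratio:
                ratio, best = frac, r.name
    return EnrichmentReport(
        genes=M.genes, results=results, alpha=alpha, correction=correction,
        enriched=enriched, enrichment_ratio=ratio, best_pathway=best,
    )


def prioritize(
    candidates: Sequence[tuple[CandidateSet, EnrichmentReport]],
) -> tuple[CandidateSet, EnrichmentReport]:
    """The candidate with the highest enrichment ratio.

    Ties break to the smaller K, then to the lexicographically smallest
    sorted gene tuple.  If no candidate has any enriched pathway (all ratios
    zero) the same tie-break applies and the returned report carries
    ``enrichment_ratio == 0`` — callers should flag "no enrichment".
    """
    if not candidates:
        raise ConfigError("prioritize needs at least one candidate")
    return min(
        candidates,
        key=lambda cr: (-cr[1].enrichment_ratio, cr[0].K, cr[0].sorted()),
    )
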