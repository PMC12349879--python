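"""Reliability checks against per-cohort reference driver-gene catalogs.

Identified gene sets are compared with curated per-cohort driver lists (an
IntOGen-style compendium supplied by the user) via the upper-tail
hypergeometric overlap test, and each identified gene is categorized by how
broadly the references support it: found in the reference list of *every*
compared cohort, of only *part* of them, verified in the literature only, or
novel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .cohort_io import ConfigError, GeneUniverse

__all__ = [
    "ReferenceCatalog",
    "load_catalog",
    "common_reference",
    "specific_reference",
    "hypergeom_overlap_test",
    "categorize_genes",
]


@dataclass
class ReferenceCatalog:
    """Per-cohort reference driver-gene lists plus an optional literature-verified set."""

    cohort_genes: dict[str, set[str]]
    literature: set[str] = field(default_factory=set)

    def genes_of(self, cohort_id: str) -> set[str]:
        try:
            return self.cohort_genes[cohort_id]
        except KeyError:
            raise ConfigError(f"cohort {cohort_id!r} not in reference catalog") from None


def load_catalog(path, literature_path=None) -> ReferenceCatalog:
    """Read a (cohort_id, gene) TSV and an optional plain-text literature gene list."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"cohort_id", "gene"}.issubset(df.columns):
        raise ConfigError(f"{path}: catalog needs columns 'cohort_id' and 'gene'")
    cohort_genes: dict[str, set[str]] = {}
    for cid, sub in df.groupby("cohort_id"):
        cohort_genes[str(cid)] = set(sub["gene"])
    literature: set[str] = set()
    if literature_path is not None:
        with open(literature_path) as fh:
            literature = {line.strip() for line in fh if line.strip()}
    return ReferenceCatalog(cohort_genes, literature)


def common_reference(
    catalog: ReferenceCatalog, cohort_ids: Sequence[str]
) -> tuple[set[str], set[str]]:
    """(all-cohorts genes, partial genes) across the selected cohorts.

    ``all`` is the intersection of the cohorts' reference lists, ``partial``
    the union minus the intersection.  Cohorts with an empty reference list
    cannot participate (the overlap test is restricted to cohorts that have
    reference genes) and raise an explicit error.
    """
    if not cohort_ids:
        raise ConfigError("no cohorts selected")
    lists = []
    for cid in cohort_ids:
        genes = catalog.genes_of(cid)
        if not genes:
            raise ConfigError(
                f"cohort {cid!r} has an empty reference list; "
                "exclude it from the overlap comparison"
            )
        lists.append(genes)
    inter = set.intersection(*lists)
    union = set.union(*lists)
    return inter, union - inter


def specific_reference(
    catalog: ReferenceCatalog,
    positive_ids: Sequence[str],
    negative_ids: Sequence[str],
) -> set[str]:
    """Reference genes specific to the positive cohorts: (union of positive
    references) minus (union of negative references)."""
    pos = set().union(*(catalog.genes_of(c) for c in positive_ids)) if positive_ids else set()
    neg = set().union(*(catalog.genes_of(c) for c in negative_ids)) if negative_ids else set()
    return pos - neg


def hypergeom_overlap_test(
    identified: Iterable[str], reference: Iterable[str], universe: GeneUniverse
) -> float:
    """Upper-tail hypergeometric p-value for the overlap of two gene sets.

    Population = the search universe, successes = reference genes inside the
    universe, draws = the identified set, observed = |identified & reference|;
    p = P(X >= k).
    """
    uni = universe.as_set()
    if not uni:
        raise ConfigError("empty universe")
    identified = set(identified) & uni
    reference = set(reference) & uni
    k = len(identified & reference)
    N, Kref, nn = len(uni), len(reference), len(identified)
    return float(hypergeom.sf(k - 1, N, Kref, nn))


def categorize_genes(
    identified: Iterable[str],
    catalog: ReferenceCatalog,
    cohort_ids: Sequence[str],
) -> dict[str, str]:
    """Label each identified gene: all_cohorts > partial > literature > novel.

    ``all_cohorts``: in every selected cohort's reference list; ``partial``:
    in at least one but not all; ``literature``: in no reference list but in
    the literature-verified set; ``novel``: none of the above.
    """
    lists = [catalog.genes_of(c) for c in cohort_ids]
    inter = set.intersection(*lists) if lists else set()
    union = set.union(*lists) if lists else set()
    labels = {}
    for g in identified:
        if g in inter:
            labels[g] = "all_cohorts"
        elif g in union:
            labels[g] = "partial"
        elif g in catalog.literature:
            labels[g] = "literature"
        else:
            labels[g] = "novel"
    return labels
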