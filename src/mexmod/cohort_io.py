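"""Reading, filtering, stratifying and harmonizing cohort mutation data.

A cohort is represented by a binary sample-by-gene alteration matrix
(:class:`MutationMatrix`).  Matrices from several cohorts are compared after
*harmonization*: every matrix is expanded to the union of all gene columns,
with genes absent from a cohort encoded as all-zero columns.  A harmonized
comparison of positive cohorts (and, for specific-driver analysis, negative
control cohorts) is a :class:`CohortGroup`.

Two input dialects are supported:

* ``binary-matrix-tsv`` — header row of gene symbols, first column sample
  IDs, cells 0/1;
* ``maf-like-tsv`` — long-format mutation table with sample, gene and
  variant-classification columns; silent classes are dropped and surviving
  (sample, gene) pairs are collapsed into binary incidence.

Clinical attributes (age, BMI, region, smoking, drinking, ...) live in a
plain :class:`pandas.DataFrame` keyed by sample ID and drive sample
stratification (e.g. adult = age >= 18, obese = BMI > 25).  Samples with a
missing value in a rule's column are excluded from both strata rather than
imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MutationMatrix",
    "GeneUniverse",
    "CohortGroup",
    "StratificationRule",
    "StratificationResult",
    "FormatError",
    "ConfigError",
    "DEFAULT_NONSILENT_CLASSES",
    "load_mutation_table",
    "load_clinical_table",
    "load_gene_universe",
    "drop_empty_samples",
    "restrict_to_universe",
    "stratify_samples",
    "harmonize",
    "build_group",
]

#: Variant classes counted as non-silent alterations in MAF-like input.
#: Configurable per call; silent/intronic/UTR classes are excluded by default.
DEFAULT_NONSILENT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
        "Nonstop_Mutation",
    }
)


class FormatError(ValueError):
    """Malformed input file (non-binary cell, missing column, bad GMT line...)."""


class ConfigError(ValueError):
    """Invalid configuration or contract violation (mode/count mismatch...)."""


def _check_unique(labels: Sequence[str], what: str) -> None:
    if len(set(labels)) != len(labels):
        seen: set[str] = set()
        dupes = sorted({x for x in labels if x in seen or seen.add(x)})
        raise FormatError(f"duplicate {what} labels: {dupes[:5]}")


@dataclass
class MutationMatrix:
    """One cohort's binary sample x gene alteration incidence matrix.

    Entries ``data[i, j] == 1`` mean gene ``gene_ids[j]`` is altered in sample
    ``sample_ids[i]``.  Rows and columns carry unique ordered labels.
    """

    cohort_id: str
    sample_ids: list[str]
    gene_ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise FormatError(
                f"matrix shape {self.data.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if self.data.size and not np.isin(self.data, (0, 1)).all():
            bad = self.data[~np.isin(self.data, (0, 1))].flat[0]
            raise FormatError(f"non-binary entry {bad!r} in matrix {self.cohort_id!r}")
        self.data = self.data.astype(np.uint8, copy=False)
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.gene_ids, "gene")
        self._gene_index = {g: j for j, g in enumerate(self.gene_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_column(self, gene: str) -> np.ndarray:
        """The 0/1 incidence column for *gene* (KeyError if absent)."""
        try:
            j = self._gene_index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in matrix {self.cohort_id!r}") from None
        return self.data[:, j]

    def gene_indices(self, genes: Iterable[str]) -> np.ndarray:
        return np.array([self._gene_index[g] if g in self._gene_index else self._missing(g) for g in genes], dtype=np.intp)

    def _missing(self, gene: str) -> int:
        raise KeyError(f"gene {gene!r} not in matrix {self.cohort_id!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.sample_ids, columns=self.gene_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, cohort_id: str) -> "MutationMatrix":
        return cls(
            cohort_id=cohort_id,
            sample_ids=[str(s) for s in df.index],
            gene_ids=[str(g) for g in df.columns],
            data=df.to_numpy(),
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id")


@dataclass(frozen=True)
class GeneUniverse:
    """Ordered, duplicate-free driver-gene search universe (e.g. an IntOGen-style compendium)."""

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ConfigError("gene universe is empty")
        _check_unique(self.genes, "universe gene")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.genes)


@dataclass
class CohortGroup:
    """A harmonized comparison: positive matrices A_1..A_R, optional negatives B_1..B_T.

    ``mode`` is ``"common"`` (R >= 2, no negatives; EntCDP) or ``"specific"``
    (R >= 1 and T >= 1; ModSDP).  All member matrices share one ordered gene
    list after harmonization.
    """

    positives: list[MutationMatrix]
    negatives: list[MutationMatrix] = field(default_factory=list)
    mode: str = "common"

    @property
    def R(self) -> int:
        return len(self.positives)

    @property
    def T(self) -> int:
        return len(self.negatives)

    @property
    def gene_ids(self) -> list[str]:
        return self.positives[0].gene_ids

    @property
    def matrices(self) -> list[MutationMatrix]:
        return self.positives + self.negatives


def load_mutation_table(
    path,
    dialect: str = "binary-matrix-tsv",
    nonsilent_classes: Iterable[str] = DEFAULT_NONSILENT_CLASSES,
    cohort_id: str | None = None,
    sample_col: str = "Tumor_Sample_Barcode",
    gene_col: str = "Hugo_Symbol",
    class_col: str = "Variant_Classification",
) -> MutationMatrix:
    """Read a cohort mutation file into a binary :class:`MutationMatrix`.

    For the MAF-like dialect, rows whose variant classification is not in
    *nonsilent_classes* are dropped (silent-mutation exclusion) and surviving
    (sample, gene) pairs collapse to a single 1 entry.  Samples whose only
    mutations are silent end up as all-zero rows; dropping them is a separate,
    explicit step (:func:`drop_empty_samples`).
    """
    cohort_id = cohort_id or str(path)
    if dialect == "binary-matrix-tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if df.size and not df.isin((0, 1)).to_numpy().all():
            bad = df.to_numpy()[~df.isin((0, 1)).to_numpy()].flat[0]
            raise FormatError(f"non-binary cell {bad!r} in {path}")
        return MutationMatrix.from_frame(df, cohort_id)
    if dialect == "maf-like-tsv":
        table = pd.read_csv(path, sep="\t", dtype=str)
        missing = [c for c in (sample_col, gene_col, class_col) if c not in table.columns]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        keep = table[table[class_col].isin(set(nonsilent_classes))]
        samples = list(dict.fromkeys(table[sample_col]))  # keep silent-only samples as zero rows
        genes = sorted(set(keep[gene_col]))
        data = np.zeros((len(samples), len(genes)), dtype=np.uint8)
        srow = {s: i for i, s in enumerate(samples)}
        gcol = {g: j for j, g in enumerate(genes)}
        for s, g in zip(keep[sample_col], keep[gene_col]):
            data[srow[s], gcol[g]] = 1
        return MutationMatrix(cohort_id, samples, genes, data)
    raise ConfigError(f"unknown dialect {dialect!r}")


def load_clinical_table(path, sample_col: str = "sample_id") -> pd.DataFrame:
    """Read a clinical TSV into a DataFrame indexed by unique sample ID.

    Missing values stay as NaN so they remain distinguishable from any
    category; stratification excludes them explicitly.
    """
    df = pd.read_csv(path, sep="\t")
    if sample_col not in df.columns:
        raise FormatError(f"{path}: missing sample column {sample_col!r}")
    df[sample_col] = df[sample_col].astype(str)
    if df[sample_col].duplicated().any():
        raise FormatError(f"{path}: duplicate sample IDs in clinical table")
    return df.set_index(sample_col)


def load_gene_universe(path) -> GeneUniverse:
    """Read a plain-text gene list (one symbol per line) into a :class:`GeneUniverse`."""
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    return GeneUniverse(tuple(genes))


def drop_empty_samples(matrix: MutationMatrix) -> MutationMatrix:
    """Remove samples with no alteration in any gene (row sum zero)."""
    keep = matrix.data.sum(axis=1) > 0
    return MutationMatrix(
        matrix.cohort_id,
        [s for s, k in zip(matrix.sample_ids, keep) if k],
        list(matrix.gene_ids),
        matrix.data[keep],
    )


def restrict_to_universe(matrix: MutationMatrix, universe: GeneUniverse) -> MutationMatrix:
    """Keep only universe genes, in universe order; samples are untouched.

    Samples left all-zero by the restriction are *not* dropped here — the
    caller decides whether to re-apply :func:`drop_empty_samples`.
    """
    present = set(matrix.gene_ids)
    kept = [g for g in universe.genes if g in present]
    if not kept:
        raise ConfigError(
            f"no universe genes present in matrix {matrix.cohort_id!r} "
            f"({matrix.n_genes} genes checked)"
        )
    idx = matrix.gene_indices(kept)
    return MutationMatrix(matrix.cohort_id, list(matrix.sample_ids), kept, matrix.data[:, idx])


@dataclass(frozen=True)
class StratificationRule:
    """Threshold predicate over one clinical column, e.g. age >= 18.

    Named shortcuts mirror the stratified comparisons: ``adult`` (age >= 18),
    ``pediatric`` (age < 18), ``obese`` (BMI > 25, WHO-style cutoff as used
    here).
    """

    column: str
    op: str  # ge | gt | lt | le | eq
    value: float

    _OPS = {
        "ge": np.greater_equal,
        "gt": np.greater,
        "lt": np.less,
        "le": np.less_equal,
        "eq": np.equal,
    }

    @classmethod
    def named(cls, name: str) -> "StratificationRule":
        rules = {
            "adult": cls("age", "ge", 18),
            "pediatric": cls("age", "lt", 18),
            "obese": cls("BMI", "gt", 25),
        }
        try:
            return rules[name]
        except KeyError:
            raise ConfigError(f"unknown named rule {name!r}; known: {sorted(rules)}") from None

    def evaluate(self, values: pd.Series) -> pd.Series:
        if self.op not in self._OPS:
            raise ConfigError(f"unknown rule operator {self.op!r}")
        return pd.Series(self._OPS[self.op](values.astype(float), self.value), index=values.index)


class StratificationResult(NamedTuple):
    true_matrix: MutationMatrix
    false_matrix: MutationMatrix
    excluded_samples: list[str]


def stratify_samples(
    matrix: MutationMatrix,
    clinical: pd.DataFrame,
    rule: StratificationRule | str,
) -> StratificationResult:
    """Split a cohort by a clinical predicate into (rule-true, rule-false) matrices.

    Samples missing from the clinical table, or with a missing value in the
    rule's column, appear in neither stratum; they are returned in
    ``excluded_samples`` and logged.
    """
    if isinstance(rule, str):
        rule = StratificationRule.named(rule)
    if rule.column not in clinical.columns:
        raise ConfigError(f"clinical table has no column {rule.column!r}")
    values = clinical[rule.column].reindex(matrix.sample_ids)
    known = values.notna().to_numpy()
    verdict = np.zeros(len(values), dtype=bool)
    verdict[known] = rule.evaluate(values[known]).to_numpy(dtype=bool)

    def _subset(keep: np.ndarray, tag: str) -> MutationMatrix:
        return MutationMatrix(
            f"{matrix.cohort_id}|{tag}",
            [s for s, k in zip(matrix.sample_ids, keep) if k],
            list(matrix.gene_ids),
            matrix.data[keep],
        )

    excluded = [s for s, k in zip(matrix.sample_ids, known) if not k]
    if excluded:
        logger.info(
            "stratify %s on %s: excluded %d sample(s) with missing %r",
            matrix.cohort_id, rule, len(excluded), rule.column,
        )
    return StratificationResult(
        _subset(known & verdict, f"{rule.column}-true"),
        _subset(known & ~verdict, f"{rule.column}-false"),
        excluded,
    )


def harmonize(matrices: Sequence[MutationMatrix]) -> list[MutationMatrix]:
    """Expand every matrix to the sorted union of all gene lists.

    Genes absent from a cohort become all-zero columns, so the same column
    index refers to the same gene in every matrix.  Idempotent; preserves
    column sums of genes already present.
    """
    if len(matrices) < 2:
        raise ConfigError("harmonize needs at least 2 matrices")
    union = sorted(set().union(*(m.gene_ids for m in matrices)))
    out = []
    for m in matrices:
        df = m.to_frame().reindex(columns=union, fill_value=0)
        out.append(MutationMatrix.from_frame(df, m.cohort_id))
    return out


def build_group(
    positives: Sequence[MutationMatrix],
    negatives: Sequence[MutationMatrix] = (),
    mode: str = "common",
) -> CohortGroup:
    """Harmonize positives (and negatives) together into a :class:`CohortGroup`.

    ``common`` mode needs >= 2 positive matrices and no negatives (EntCDP);
    ``specific`` mode needs >= 1 positive and >= 1 negative (ModSDP).
    """
    positives, negatives = list(positives), list(negatives)
    if mode == "common":
        if negatives:
            raise ConfigError("common mode takes no negative matrices")
        if len(positives) < 2:
            raise ConfigError(f"common mode requires R>=2 positive matrices, got {len(positives)}")
    elif mode == "specific":
        if not positives or not negatives:
            raise ConfigError(
                f"specific mode requires >=1 positive and >=1 negative matrix, "
                f"got R={len(positives)}, T={len(negatives)}"
            )
    else:
        raise ConfigError(f"unknown group mode {mode!r}")
    harmonized = harmonize(positives + negatives)
    return CohortGroup(
        positives=harmonized[: len(positives)],
        negatives=harmonized[len(positives):],
        mode=mode,
    )
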