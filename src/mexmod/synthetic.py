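"""Synthetic cohort generator with planted mutually exclusive driver modules.

Emulates the statistical structure the cross-cohort analysis assumes: a
group of binary mutation matrices with heterogeneous sample sizes and
background mutation rates, carrying (in designated *positive* matrices) a
planted module of K* genes with high coverage and near-perfect mutual
exclusivity, and lacking that structure in designated *negative* control
matrices.

Construction per positive matrix: exactly ``round(gamma_r * m_r)`` samples
are covered; each covered sample receives one module gene uniformly at
random; with probability epsilon a covered sample additionally receives a
second distinct module gene (an exclusivity violation).  Independent
Bernoulli background noise at rate p_bg is then OR'd over every cell of
every matrix — including module genes in negative matrices — so background
can create additional impurity, as in real cohorts.  Per-gene background
rates may instead be drawn Uniform(0.001, 0.05) to emulate inter-cohort rate
heterogeneity.

Coverage is planted as an exact count rather than Bernoulli so recovery
experiments have deterministic signal strength.  Generation is a pure
function of the config (seed included); :class:`PlantedTruth` records the
module, assignments, and realized counts for ground-truth checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort_io import CohortGroup, ConfigError, MutationMatrix, build_group

__all__ = ["MatrixSpec", "ScenarioConfig", "PlantedTruth", "generate_group", "null_group"]


@dataclass(frozen=True)
class MatrixSpec:
    cohort_id: str
    n_samples: int
    role: str = "positive"  # positive | negative

    def __post_init__(self) -> None:
        if self.role not in ("positive", "negative"):
            raise ConfigError(f"unknown matrix role {self.role!r}")
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")


@dataclass
class ScenarioConfig:
    """Stated world of one synthetic scenario.

    ``coverage`` is a scalar applied to every positive matrix or a sequence
    with one value per positive matrix; ``background_rate`` is a scalar, a
    per-gene vector, or the string ``"heterogeneous"`` for per-gene rates
    drawn Uniform(0.001, 0.05).
    """

    n_genes: int
    matrices: Sequence[MatrixSpec]
    module_size: int
    coverage: float | Sequence[float] = 0.7
    exclusivity_violation_rate: float = 0.0
    background_rate: float | Sequence[float] | str = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_size > self.n_genes:
            raise ConfigError("module_size exceeds n_genes")
        if self.module_size < 2:
            raise ConfigError("module_size must be >= 2")
        if not self.matrices:
            raise ConfigError("at least one matrix spec required")
        eps = self.exclusivity_violation_rate
        if not 0.0 <= eps <= 1.0:
            raise ConfigError("exclusivity_violation_rate must be in [0, 1]")
        for g in self._coverages():
            if not 0.0 <= g <= 1.0:
                raise ConfigError("coverage must be in [0, 1]")
        bg = self.background_rate
        if not isinstance(bg, str):
            arr = np.atleast_1d(np.asarray(bg, dtype=float))
            if ((arr < 0) | (arr > 1)).any():
                raise ConfigError("background_rate must be in [0, 1]")
        elif bg != "heterogeneous":
            raise ConfigError(f"unknown background_rate spec {bg!r}")

    def positive_specs(self) -> list[MatrixSpec]:
        return [s for s in self.matrices if s.role == "positive"]

    def negative_specs(self) -> list[MatrixSpec]:
        return [s for s in self.matrices if s.role == "negative"]

    def _coverages(self) -> list[float]:
        n_pos = len([s for s in self.matrices if s.role == "positive"])
        if np.isscalar(self.coverage):
            return [float(self.coverage)] * n_pos
        cov = [float(g) for g in self.coverage]
        if len(cov) != n_pos:
            raise ConfigError(f"need one coverage per positive matrix ({n_pos}), got {len(cov)}")
        return cov


@dataclass
class PlantedTruth:
    """Ground truth of one generated scenario."""

    module_genes: tuple[str, ...]
    planted_coverage: dict[str, int]                 # per positive matrix
    assignments: dict[str, dict[str, str]] = field(default_factory=dict)
    realized_violations: dict[str, int] = field(default_factory=dict)


def _gene_labels(n: int) -> list[str]:
    width = len(str(n))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def generate_group(config: ScenarioConfig) -> tuple[CohortGroup, PlantedTruth]:
    """Generate a cohort group with a planted module; returns group + truth.

    Group mode is ``common`` when the config has no negative matrices, else
    ``specific``.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_labels(config.n_genes)
    module_idx = np.sort(rng.choice(config.n_genes, size=config.module_size, replace=False))
    module = tuple(genes[i] for i in module_idx)

    if isinstance(config.background_rate, str):  # heterogeneous per-gene rates
        bg = rng.uniform(0.001, 0.05, size=config.n_genes)
    else:
        bg = np.broadcast_to(
            np.asarray(config.background_rate, dtype=float), (config.n_genes,)
        ).copy()

    coverages = config._coverages()
    eps = config.exclusivity_violation_rate
    positives: list[MutationMatrix] = []
    negatives: list[MutationMatrix] = []
    truth = PlantedTruth(module_genes=module, planted_coverage={})

    pos_i = 0
    for spec in config.matrices:
        m = spec.n_samples
        samples = [f"{spec.cohort_id}-s{i:04d}" for i in range(1, m + 1)]
        planted = np.zeros((m, config.n_genes), dtype=np.uint8)
        if spec.role == "positive":
            gamma = coverages[pos_i]
            pos_i += 1
            n_cov = round(gamma * m)
            if gamma > 0 and n_cov < 1:
                warnings.warn(
                    f"{spec.cohort_id}: coverage {gamma} on {m} samples rounds to 0 covered",
                    stacklevel=2,
                )
            covered = rng.choice(m, size=n_cov, replace=False)
            assign = rng.choice(module_idx, size=n_cov)
            planted[covered, assign] = 1
            truth.assignments[spec.cohort_id] = {
                samples[s]: genes[g] for s, g in zip(covered, assign)
            }
            violate = rng.random(n_cov) < eps
            for s, g, v in zip(covered, assign, violate):
                if v and config.module_size > 1:
                    others = module_idx[module_idx != g]
                    planted[s, rng.choice(others)] = 1
            truth.planted_coverage[spec.cohort_id] = int(n_cov)
        noise = (rng.random((m, config.n_genes)) < bg[None, :]).astype(np.uint8)
        data = planted | noise
        matrix = MutationMatrix(spec.cohort_id, samples, list(genes), data)
        if spec.role == "positive":
            # impurity bookkeeping: covered samples ending up with >1 module gene
            sub = data[:, module_idx]
            truth.realized_violations[spec.cohort_id] = int((sub.sum(axis=1) > 1).sum())
            positives.append(matrix)
        else:
            negatives.append(matrix)

    mode = "specific" if negatives else "common"
    group = build_group(positives, negatives, mode=mode)
    return group, truth


def null_group(config: ScenarioConfig) -> tuple[CohortGroup, PlantedTruth]:
    """Pure-background calibration null: same world with zero planted coverage."""
    null_cfg = ScenarioConfig(
        n_genes=config.n_genes,
        matrices=config.matrices,
        module_size=config.module_size,
        coverage=0.0,
        exclusivity_violation_rate=0.0,
        background_rate=config.background_rate,
        seed=config.seed,
    )
    group, truth = generate_group(null_cfg)
    truth.module_genes = ()
    truth.assignments = {}
    return group, truth
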