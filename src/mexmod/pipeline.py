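"""Config-driven orchestration of one full cross-cohort comparison.

Stages: load -> filter -> (optional) stratify -> harmonize -> optimize over
K -> permutation-test -> (optional) reference-overlap validation ->
(optional) pathway enrichment + final-candidate prioritization -> report.

Outputs land in the configured directory: ``sweep.tsv``/``sweep.json`` (one
row per K), ``overlap.json`` (if a reference catalog is given),
``enrichment.tsv`` and ``final_candidate.json`` (if a GMT is given), and a
``manifest.json`` echoing every parameter and the seed so a rerun is
bit-identical.  Any stage error aborts with the stage name; partial outputs
are flagged incomplete in the manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from . import __version__
from .cohort_io import (
    CohortGroup,
    ConfigError,
    GeneUniverse,
    build_group,
    drop_empty_samples,
    load_clinical_table,
    load_gene_universe,
    load_mutation_table,
    restrict_to_universe,
    stratify_samples,
)
from .enrichment import enrich, prioritize, read_gmt
from .objectives import CandidateSet
from .optimizers import GAParams
from .reference_overlap import categorize_genes, common_reference, hypergeom_overlap_test, load_catalog
from .significance import SweepTable, sweep_K

logger = logging.getLogger(__name__)

__all__ = ["CohortSpec", "ComparisonConfig", "run_comparison", "load_config"]


@dataclass(frozen=True)
class CohortSpec:
    path: str
    cohort_id: str
    role: str = "positive"  # positive | negative
    dialect: str = "binary-matrix-tsv"


@dataclass
class ComparisonConfig:
    cohorts: Sequence[CohortSpec]
    mode: str  # common | specific
    out_dir: str
    universe_path: str | None = None
    clinical_path: str | None = None
    stratify_rule: str | None = None          # named rule; keeps the rule-true stratum
    Kmin: int = 2
    Kmax: int = 10
    optimizer: str = "auto"                   # auto | exhaustive | ga | ilp
    ga: dict[str, Any] = field(default_factory=dict)
    n_perm: int = 1000
    null_mode: str = "fixed_set"
    alpha: float = 0.05
    seed: int = 0
    catalog_path: str | None = None
    literature_path: str | None = None
    gmt_path: str | None = None

    def __post_init__(self) -> None:
        if self.mode == "common" and any(c.role == "negative" for c in self.cohorts):
            raise ConfigError("common mode takes no negative cohorts")
        if self.mode == "specific" and not any(c.role == "negative" for c in self.cohorts):
            raise ConfigError("specific mode needs at least one negative cohort")


def load_config(path) -> ComparisonConfig:
    """Read a ComparisonConfig from YAML or JSON."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cohorts = [CohortSpec(**c) for c in raw.pop("cohorts")]
    return ComparisonConfig(cohorts=cohorts, **raw)


def _load_group(config: ComparisonConfig) -> tuple[CohortGroup, GeneUniverse | None]:
    universe = load_gene_universe(config.universe_path) if config.universe_path else None
    clinical = load_clinical_table(config.clinical_path) if config.clinical_path else None
    positives, negatives = [], []
    for spec in config.cohorts:
        m = load_mutation_table(spec.path, dialect=spec.dialect, cohort_id=spec.cohort_id)
        if universe is not None:
            m = restrict_to_universe(m, universe)
        if clinical is not None and config.stratify_rule:
            m = stratify_samples(m, clinical, config.stratify_rule).true_matrix
        m = drop_empty_samples(m)
        (positives if spec.role == "positive" else negatives).append(m)
    return build_group(positives, negatives, mode=config.mode), universe


def run_comparison(config: ComparisonConfig) -> dict[str, Any]:
    """Run one comparison end to end; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = "entcdp" if config.mode == "common" else "modsdp"
    manifest: dict[str, Any] = {
        "package": "mexmod",
        "version": __version__,
        "model": model,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "null_mode": config.null_mode,
        "alpha": config.alpha,
        "K_range": [config.Kmin, config.Kmax],
        "optimizer": config.optimizer,
        "cohorts": [vars(c) | {} for c in config.cohorts],
        "complete": False,
        "stages": {},
    }
    stage = "load"
    try:
        t0 = time.perf_counter()
        group, universe = _load_group(config)
        manifest["stages"][stage] = round(time.perf_counter() - t0, 3)
        logger.info("loaded group: R=%d T=%d genes=%d", group.R, group.T, len(group.gene_ids))

        stage = "sweep"
        t0 = time.perf_counter()
        rng = np.random.default_rng(config.seed)
        ga_params = GAParams(**({"seed": config.seed} | config.ga)) if config.ga or config.optimizer in ("ga", "auto") else None
        table: SweepTable = sweep_K(
            group, model, Kmin=config.Kmin, Kmax=config.Kmax,
            method=config.optimizer, ga_params=ga_params,
            n_perm=config.n_perm, rng=rng, null_mode=config.null_mode,
            alpha=config.alpha,
        )
        table.to_tsv(out / "sweep.tsv")
        table.to_json(out / "sweep.json")
        manifest["stages"][stage] = round(time.perf_counter() - t0, 3)

        accepted = table.accepted()
        manifest["accepted_K"] = [r.K for r in accepted]

        if config.catalog_path:
            stage = "overlap"
            t0 = time.perf_counter()
            catalog = load_catalog(config.catalog_path, config.literature_path)
            uni = universe or GeneUniverse(tuple(group.gene_ids))
            pos_ids = [a.cohort_id for a in group.positives]
            identified = sorted({g for r in accepted for g in r.best_set.genes})
            ref_all, _ = common_reference(catalog, pos_ids)
            overlap = {
                "identified": identified,
                "p_overlap": hypergeom_overlap_test(identified, ref_all, uni) if identified else None,
                "categories": categorize_genes(identified, catalog, pos_ids),
            }
            with open(out / "overlap.json", "w") as fh:
                json.dump(overlap, fh, indent=2)
            manifest["stages"][stage] = round(time.perf_counter() - t0, 3)

        if config.gmt_path:
            stage = "enrichment"
            t0 = time.perf_counter()
            collection = read_gmt(config.gmt_path)
            uni = universe or GeneUniverse(tuple(group.gene_ids))
            candidates = [
                (r.best_set, enrich(r.best_set, collection, uni, alpha=config.alpha))
                for r in accepted
            ]
            if candidates:
                final_set, final_report = prioritize(candidates)
                rows = []
                for cs, rep in candidates:
                    rows.append(
                        "\t".join([
                            ",".join(cs.sorted()),
                            f"{rep.enrichment_ratio:.4f}",
                            rep.best_pathway or "-",
                        ])
                    )
                (out / "enrichment.tsv").write_text(
                    "genes\tenrichment_ratio\tbest_pathway\n" + "\n".join(rows) + "\n"
                )
                with open(out / "final_candidate.json", "w") as fh:
                    json.dump(
                        {
                            "genes": sorted(final_set.genes),
                            "K": final_set.K,
                            "enrichment_ratio": final_report.enrichment_ratio,
                            "best_pathway": final_report.best_pathway,
                            "no_enrichment": final_report.enrichment_ratio == 0.0,
                        },
                        fh, indent=2,
                    )
            manifest["stages"][stage] = round(time.perf_counter() - t0, 3)

        manifest["complete"] = True
    except Exception:
        logger.exception("comparison failed at stage %r", stage)
        manifest["failed_stage"] = stage
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
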