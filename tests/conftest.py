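import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from mexmod import MatrixSpec, MutationMatrix, ScenarioConfig, build_group, generate_group


def random_matrix(rng, cohort_id, m, genes, p=0.15) -> MutationMatrix:
    data = (rng.random((m, len(genes))) < p).astype(np.uint8)
    samples = [f"{cohort_id}-s{i}" for i in range(m)]
    return MutationMatrix(cohort_id, samples, list(genes), data)


def random_common_group(rng, R=3, genes=30, ms=(40, 50, 60), p=0.15):
    labels = [f"g{j:03d}" for j in range(genes)]
    mats = [random_matrix(rng, f"A{r}", ms[r % len(ms)], labels, p) for r in range(R)]
    return build_group(mats, mode="common")


def random_specific_group(rng, R=2, T=2, genes=25, m=40, p=0.15):
    labels = [f"g{j:03d}" for j in range(genes)]
    pos = [random_matrix(rng, f"A{r}", m, labels, p) for r in range(R)]
    neg = [random_matrix(rng, f"B{t}", m, labels, p) for t in range(T)]
    return build_group(pos, neg, mode="specific")


@pytest.fixture
def rng():
    return np.random.default_rng(20260917)


@pytest.fixture
def tiny_matrix():
    # 5 samples x 4 genes, hand-checkable
    data = np.array(
        [
            [1, 0, 0, 1],
            [0, 1, 0, 0],
            [1, 0, 0, 0],
            [0, 0, 0, 0],
            [0, 1, 1, 0],
        ],
        dtype=np.uint8,
    )
    return MutationMatrix("toy", [f"s{i}" for i in range(1, 6)], ["gA", "gB", "gC", "gD"], data)


@pytest.fixture
def planted_common():
    """Small common scenario with a clean planted module (no noise)."""
    cfg = ScenarioConfig(
        n_genes=15,
        matrices=[MatrixSpec("A1", 40), MatrixSpec("A2", 40)],
        module_size=3,
        coverage=0.8,
        exclusivity_violation_rate=0.0,
        background_rate=0.0,
        seed=7,
    )
    return generate_group(cfg)


@pytest.fixture
def planted_specific():
    cfg = ScenarioConfig(
        n_genes=15,
        matrices=[
            MatrixSpec("A1", 40),
            MatrixSpec("A2", 40),
            MatrixSpec("B1", 40, "negative"),
        ],
        module_size=3,
        coverage=0.8,
        exclusivity_violation_rate=0.0,
        background_rate=0.0,
        seed=11,
    )
    return generate_group(cfg)
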