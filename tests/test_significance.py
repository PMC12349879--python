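import numpy as np
import pytest

from conftest import random_common_group
from mexmod import (
    CandidateSet,
    MatrixSpec,
    MutationMatrix,
    ScenarioConfig,
    build_group,
    decide,
    generate_group,
    individual_significance,
    null_group,
    overall_significance,
    permutation_pvalue,
    permute_matrix,
    sweep_K,
)
from mexmod.cohort_io import ConfigError
from mexmod.significance import SignificanceReport


class TestPermuteMatrix:
    def test_column_sums_preserved_exactly(self, rng):
        for _ in range(10):
            m = MutationMatrix(
                "c", [f"s{i}" for i in range(30)], [f"g{j}" for j in range(12)],
                (rng.random((30, 12)) < 0.3).astype(np.uint8),
            )
            perm = permute_matrix(m, rng)
            assert (perm.data.sum(axis=0) == m.data.sum(axis=0)).all()
            assert perm.sample_ids == m.sample_ids and perm.gene_ids == m.gene_ids

    def test_all_zero_matrix_unchanged(self, rng):
        m = MutationMatrix("c", ["s1", "s2"], ["g1"], np.zeros((2, 1)))
        assert (permute_matrix(m, rng).data == 0).all()

    def test_marginal_uniformity(self):
        """A column with f ones over m samples hits each sample with
        probability f/m across permutations (chi-square sanity check)."""
        from scipy.stats import chisquare

        m, f, n_rep = 20, 6, 2000
        mat = MutationMatrix(
            "c", [f"s{i}" for i in range(m)], ["g"],
            np.array([[1]] * f + [[0]] * (m - f), dtype=np.uint8),
        )
        rng = np.random.default_rng(123)
        counts = np.zeros(m)
        for _ in range(n_rep):
            counts += permute_matrix(mat, rng).data[:, 0]
        stat, p = chisquare(counts, f_exp=np.full(m, f * n_rep / m))
        assert p > 0.001  # no sample is systematically favored

    def test_determinism_same_seed(self, tiny_matrix):
        p1 = permute_matrix(tiny_matrix, np.random.default_rng(9)).data
        p2 = permute_matrix(tiny_matrix, np.random.default_rng(9)).data
        assert (p1 == p2).all()


class TestPermutationPvalue:
    @pytest.mark.parametrize(
        "observed,nulls,expected",
        [
            (10.0, [1.0] * 199, 1 / 200),       # above every null
            (0.0, [1.0] * 50, 1.0),              # below every null
            (5.0, [5.0] * 10 + [0.0] * 89, 11 / 100),  # ties count toward >=
        ],
    )
    def test_add_one_estimator(self, observed, nulls, expected):
        assert permutation_pvalue(observed, nulls) == pytest.approx(expected, abs=1e-12)

    def test_never_zero(self, rng):
        assert permutation_pvalue(1e9, rng.random(500).tolist()) > 0

    def test_empty_nulls_error(self):
        with pytest.raises(ConfigError):
            permutation_pvalue(1.0, [])


class TestIndividualSignificance:
    def test_planted_exclusive_module_is_significant(self):
        cfg = ScenarioConfig(
            n_genes=50, matrices=[MatrixSpec("A1", 100), MatrixSpec("A2", 100)],
            module_size=3, coverage=0.6, background_rate=0.0, seed=5,
        )
        group, truth = generate_group(cfg)
        p = individual_significance(
            group.positives[0], CandidateSet(truth.module_genes), 200,
            np.random.default_rng(1),
        )
        assert p <= 0.01

    def test_saturating_disjoint_set_attains_minimal_p(self):
        """When sum|Gamma(g)| is permutation-invariant and the observed set is
        disjoint and saturating, no permutation can beat it but any can tie:
        the observed sits at the supremum of the null support."""
        data = np.array([[1, 0], [0, 1], [1, 0], [0, 1]], dtype=np.uint8)
        m = MutationMatrix("c", [f"s{i}" for i in range(4)], ["g1", "g2"], data)
        p = individual_significance(m, CandidateSet(("g1", "g2")), 50, np.random.default_rng(0))
        assert p <= 1.0  # well-defined
        # observed weight is the maximum achievable: 2*4 - 4 = 4
        from mexmod import dendrix_weight

        assert dendrix_weight(m, CandidateSet(("g1", "g2"))) == 4


class TestOverallSignificance:
    def test_planted_common_module_significant(self):
        cfg = ScenarioConfig(
            n_genes=50, matrices=[MatrixSpec("A1", 100), MatrixSpec("A2", 100)],
            module_size=3, coverage=0.6, background_rate=0.02, seed=6,
        )
        group, truth = generate_group(cfg)
        p = overall_significance(
            group, CandidateSet(truth.module_genes), "entcdp", 200,
            np.random.default_rng(2),
        )
        assert p <= 0.01

    def test_model_group_mismatch(self, planted_common):
        group, truth = planted_common
        with pytest.raises(ConfigError, match="does not match"):
            overall_significance(group, CandidateSet(truth.module_genes), "modsdp",
                                 10, np.random.default_rng(0))

    def test_zero_permutations_error(self, planted_common):
        group, truth = planted_common
        with pytest.raises(ConfigError, match="n_perm"):
            overall_significance(group, CandidateSet(truth.module_genes), "entcdp",
                                 0, np.random.default_rng(0))

    def test_reoptimized_mode_requires_optimizer(self, planted_common):
        group, truth = planted_common
        with pytest.raises(ConfigError, match="optimizer"):
            overall_significance(group, CandidateSet(truth.module_genes), "entcdp",
                                 10, np.random.default_rng(0), null_mode="reoptimized")

    def test_reoptimized_null_is_more_conservative(self, planted_common):
        """Re-optimizing per permutation can only raise the null statistics,
        so the re-optimized p is >= the fixed-set p on the same instance."""
        from mexmod import exhaustive_search

        group, truth = planted_common
        M = CandidateSet(truth.module_genes)
        p_fixed = overall_significance(group, M, "entcdp", 30, np.random.default_rng(4))
        p_reopt = overall_significance(
            group, M, "entcdp", 30, np.random.default_rng(4),
            null_mode="reoptimized",
            optimizer=lambda g: exhaustive_search(g, M.K, "entcdp").best_score,
        )
        assert p_reopt >= p_fixed

    def test_determinism(self, planted_common):
        group, truth = planted_common
        M = CandidateSet(truth.module_genes)
        p1 = overall_significance(group, M, "entcdp", 50, np.random.default_rng(7))
        p2 = overall_significance(group, M, "entcdp", 50, np.random.default_rng(7))
        assert p1 == p2


class TestDecide:
    def make_report(self, overall, pos, neg=()):
        return SignificanceReport(
            overall_p=overall,
            individual_p_positive={f"A{i}": p for i, p in enumerate(pos)},
            individual_p_negative={f"B{i}": p for i, p in enumerate(neg)},
            n_permutations=100, null_mode="fixed_set",
        )

    def test_entcdp_accept(self):
        r = self.make_report(0.001, (0.01, 0.03))
        assert decide(r, "entcdp") and r.decision == "accept"

    def test_entcdp_boundary_strict(self):
        r = self.make_report(0.049, (0.05,))
        assert not decide(r, "entcdp")  # individual p == alpha is not significant

    def test_modsdp_rejects_significant_control(self):
        r = self.make_report(0.001, (0.01,), neg=(0.02,))
        assert not decide(r, "modsdp")  # B-side must be NON-significant

    def test_modsdp_accepts_nonsignificant_control_at_boundary(self):
        r = self.make_report(0.001, (0.01,), neg=(0.05,))
        assert decide(r, "modsdp")  # p >= alpha on B side is allowed (non-strict)

    def test_missing_negative_ps_contract_error(self):
        r = self.make_report(0.001, (0.01,))
        with pytest.raises(ConfigError, match="negative"):
            decide(r, "modsdp")


class TestSweep:
    def test_kmin_below_two_errors(self, planted_common):
        group, _ = planted_common
        with pytest.raises(ConfigError, match="Kmin"):
            sweep_K(group, "entcdp", Kmin=1, Kmax=3)

    def test_planted_k_row_accepted_and_recovered(self):
        cfg = ScenarioConfig(
            n_genes=20, matrices=[MatrixSpec("A1", 80), MatrixSpec("A2", 80)],
            module_size=3, coverage=0.7, background_rate=0.02, seed=13,
        )
        group, truth = generate_group(cfg)
        table = sweep_K(group, "entcdp", Kmin=2, Kmax=4, method="exhaustive",
                        n_perm=100, rng=np.random.default_rng(3))
        row = next(r for r in table.rows if r.K == 3)
        assert row.best_set.sorted() == tuple(sorted(truth.module_genes))
        assert row.report.decision == "accept"
        df = table.to_frame()
        assert set(df["K"]) == {2, 3, 4}

    def test_serialization_roundtrip(self, tmp_path, planted_common):
        group, _ = planted_common
        table = sweep_K(group, "entcdp", Kmin=2, Kmax=3, method="exhaustive",
                        n_perm=20, rng=np.random.default_rng(0))
        table.to_tsv(tmp_path / "s.tsv")
        table.to_json(tmp_path / "s.json")
        assert (tmp_path / "s.tsv").read_text().startswith("K\t")


class TestNullCalibrationSmoke:
    def test_null_rejection_rate_near_alpha(self):
        """Small-scale calibration: under pure background, the fixed-set
        overall test should reject about alpha of the time (wide band here;
        the full-size check lives in the acceptance suite)."""
        rng = np.random.default_rng(99)
        rejections = 0
        n_rep = 60
        for i in range(n_rep):
            cfg = ScenarioConfig(
                n_genes=10, matrices=[MatrixSpec("A1", 40), MatrixSpec("A2", 40)],
                module_size=2, coverage=0.0, background_rate=0.08,
                seed=1000 + i,
            )
            group, _ = null_group(cfg)
            genes = tuple(rng.choice(group.gene_ids, size=3, replace=False))
            p = overall_significance(group, CandidateSet(genes), "entcdp", 60, rng)
            rejections += p < 0.05
        assert rejections / n_rep < 0.2
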