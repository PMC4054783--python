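import numpy as np
import pandas as pd
import pytest
from scipy import stats

from esekit.association_tests import (
    class_comparison,
    covariates_table,
    expression_summaries,
    intron_length_correlation,
    partial_spearman,
    strength_density_correlation,
)
from esekit.motif_sets import HexamerSet
from esekit.synthetic_data import SyntheticSpec, gen_expression, gen_genome


@pytest.fixture(scope="module")
def correlated_covariates():
    spec = SyntheticSpec(
        seed=202, n_exons=3000, rho_score_density=-0.1, rho_intron_density=0.1
    )
    exons, truth = gen_genome(spec)
    pool = HexamerSet.from_iterable("pool", truth["params"]["pool"])
    return covariates_table(exons, pool)


class TestStrengthDensity:
    def test_negative_dependence_recovered(self, correlated_covariates):
        for end in (5, 3):
            rho, p = strength_density_correlation(correlated_covariates, end)
            assert rho == pytest.approx(-0.1, abs=0.06)
            assert p < 0.05

    def test_independent_score_is_null(self):
        spec = SyntheticSpec(seed=203, n_exons=1500, rho_score_density=0.0)
        exons, truth = gen_genome(spec)
        pool = HexamerSet.from_iterable("pool", truth["params"]["pool"])
        cov = covariates_table(exons, pool)
        rho, _ = strength_density_correlation(cov, 5)
        assert abs(rho) < 3 / np.sqrt(len(cov))

    def test_constant_density_warns(self):
        cov = pd.DataFrame(
            {"splice5_score": np.arange(20.0), "density5": np.zeros(20)}
        )
        with pytest.warns(UserWarning, match="constant"):
            rho, p = strength_density_correlation(cov, 5)
        assert np.isnan(rho)

    def test_too_few_exons_rejected(self):
        cov = pd.DataFrame({"splice5_score": [1.0, 2.0], "density5": [0.1, 0.2]})
        with pytest.raises(ValueError):
            strength_density_correlation(cov, 5)


class TestClassComparison:
    def test_constitutive_density_excess_detected(self):
        spec = SyntheticSpec(
            seed=204, n_exons=1200, pool_size=30,
            embed_floor=0.02, embed_plateau=0.05,
            constitutive_embed_multiplier=1.5, p_alternative=0.5,
        )
        exons, truth = gen_genome(spec)
        pool = HexamerSet.from_iterable("pool", truth["params"]["pool"])
        cov = covariates_table(exons, pool)
        res = class_comparison(cov, "inclusion")
        assert (res["p_alternative_less"] < 0.05).all()

    def test_random_labels_are_null(self):
        spec = SyntheticSpec(seed=205, n_exons=600, p_conserved=0.5)
        exons, truth = gen_genome(spec)
        pool = HexamerSet.from_iterable("pool", truth["params"]["pool"])
        cov = covariates_table(exons, pool)
        res = class_comparison(cov, "conservation")
        # conservation labels are independent of density in the generator
        assert (res["p_two_sided"] > 0.001).all()

    def test_identical_vectors_give_p_one(self):
        cov = pd.DataFrame(
            {
                "inclusion": ["alternative"] * 10 + ["constitutive"] * 10,
                "density100_5": [0.3] * 20,
                "density100_3": [0.3] * 20,
            }
        )
        res = class_comparison(cov, "inclusion")
        assert (res["p_two_sided"] == 1.0).all()

    def test_empty_class_rejected(self):
        cov = pd.DataFrame(
            {
                "inclusion": ["constitutive"] * 10,
                "density100_5": np.linspace(0, 1, 10),
                "density100_3": np.linspace(0, 1, 10),
            }
        )
        with pytest.raises(ValueError):
            class_comparison(cov, "inclusion")


class TestIntronLength:
    def test_positive_dependence_recovered(self, correlated_covariates):
        r, p = intron_length_correlation(correlated_covariates)
        assert r == pytest.approx(0.1, abs=0.04)
        assert p < 1e-4

    def test_short_intron_filter_applies(self, correlated_covariates):
        r_all, _ = intron_length_correlation(correlated_covariates)
        r_short, _ = intron_length_correlation(
            correlated_covariates, max_intron=1501
        )
        assert not np.isnan(r_short)

    def test_empty_filter_rejected(self, correlated_covariates):
        with pytest.raises(ValueError):
            intron_length_correlation(correlated_covariates, max_intron=1)

    def test_rank_invariance_to_monotone_transform(self, correlated_covariates):
        cov = correlated_covariates.copy()
        r1, _ = intron_length_correlation(cov)
        cov["intron5_len"] = np.log(cov["intron5_len"].astype(float))
        cov["intron3_len"] = np.log(cov["intron3_len"].astype(float))
        r2, _ = intron_length_correlation(cov)
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestPartialSpearman:
    def test_no_covariates_equals_plain_spearman(self, correlated_covariates):
        rho_plain, _ = strength_density_correlation(correlated_covariates, 5)
        rho_partial, _ = partial_spearman(
            correlated_covariates, "splice5_score", "density5"
        )
        assert rho_partial == pytest.approx(rho_plain, abs=1e-10)

    def test_predictor_among_covariates_gives_zero(self, correlated_covariates):
        rho, _ = partial_spearman(
            correlated_covariates, "splice5_score", "density5", ["density5"]
        )
        assert rho == pytest.approx(0.0, abs=1e-10)

    def test_known_trivariate_partial_correlation(self, rng):
        # X,Y,Z jointly normal; partial corr of X,Y given Z fixed at 0.2
        n = 5000
        rho_xy, rho_xz, rho_yz = 0.34, 0.5, 0.5
        # partial = (rho_xy - rho_xz*rho_yz)/sqrt((1-rho_xz^2)(1-rho_yz^2))
        target = (rho_xy - rho_xz * rho_yz) / (1 - rho_xz ** 2)
        cov = np.array(
            [[1, rho_xy, rho_xz], [rho_xy, 1, rho_yz], [rho_xz, rho_yz, 1]]
        )
        data = rng.multivariate_normal(np.zeros(3), cov, size=n)
        df = pd.DataFrame(data, columns=["x", "y", "z"])
        rho, p = partial_spearman(df, "x", "y", ["z"])
        assert rho == pytest.approx(target, abs=0.05)

    def test_collinear_covariates_named(self, correlated_covariates):
        cov = correlated_covariates.copy()
        cov["dup"] = cov["intron5_len"]
        with pytest.raises(ValueError, match="collinear"):
            partial_spearman(
                cov, "splice5_score", "density5", ["intron5_len", "dup"]
            )


class TestExpressionSummaries:
    def test_uniform_gene_limits(self):
        # uniform genes in a balanced matrix: breadth 1, tau 0
        expr = pd.DataFrame(
            {"t1": [5.0, 2.0], "t2": [5.0, 2.0], "t3": [5.0, 2.0]},
            index=["a", "b"],
        )
        controls = pd.Series(0.5, index=["t1", "t2", "t3"])
        out = expression_summaries(expr, controls)
        assert (out["breadth"] == 1.0).all()
        assert np.allclose(out["tau"], 0.0)

    def test_single_tissue_gene_limits(self):
        expr = pd.DataFrame(
            {"t1": [9.0, 1.0], "t2": [0.4, 1.0], "t3": [0.4, 1.0]},
            index=["specific", "broad"],
        )
        controls = pd.Series(0.5, index=["t1", "t2", "t3"])
        out = expression_summaries(expr, controls)
        assert out.loc["specific", "breadth"] == pytest.approx(1 / 3)
        assert out.loc["specific", "tau"] == pytest.approx(1.0)

    def test_hand_computed_toy_matrix(self):
        # 3 genes x 4 tissues; one value below control masks to zero
        expr = pd.DataFrame(
            [[2.0, 4.0, 0.4, 2.0],
             [2.0, 4.0, 4.0, 2.0],
             [4.0, 4.0, 4.0, 4.0]],
            index=["a", "b", "c"],
            columns=["t1", "t2", "t3", "t4"],
        )
        controls = pd.Series([1.0, 1.0, 1.0, 1.0], index=expr.columns)
        out = expression_summaries(expr, controls)
        # masked matrix: a = (2,4,0,2); totals per tissue: (8,12,8,8)
        a_norm = np.array([2 / 8, 4 / 12, 0.0, 2 / 8])
        assert out.loc["a", "breadth"] == pytest.approx(3 / 4)
        assert out.loc["a", "mean"] == pytest.approx(a_norm.mean())
        assert out.loc["a", "median"] == pytest.approx(np.median(a_norm))
        tau_a = (1 - a_norm / a_norm.max()).sum() / 3
        assert out.loc["a", "tau"] == pytest.approx(tau_a)

    def test_masking_is_idempotent(self):
        expr, controls = gen_expression(200, seed=9)
        once = expression_summaries(expr, controls)
        masked = expr.where(expr.ge(controls, axis=1), 0.0)
        twice = expression_summaries(masked, controls)
        pd.testing.assert_frame_equal(once, twice)

    def test_tau_and_breadth_bounds(self):
        expr, controls = gen_expression(300, seed=10)
        out = expression_summaries(expr, controls)
        assert out["tau"].between(0, 1).all()
        assert (out["breadth"] > 0).all() and (out["breadth"] <= 1).all()

    def test_all_zero_tissue_rejected(self):
        expr = pd.DataFrame({"t1": [1.0, 2.0], "t2": [0.1, 0.2]}, index=["a", "b"])
        controls = pd.Series([0.5, 5.0], index=["t1", "t2"])
        with pytest.raises(ValueError, match="zero total"):
            expression_summaries(expr, controls)
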