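import shutil
import subprocess
import textwrap

import numpy as np
import pytest

from mlrpower import (
    DegenerateDataError,
    FixedEffects,
    ModelStructure,
    PredictorSpec,
    RandomEffectsCov,
    ScenarioSpec,
    case_preset,
    fit,
    lrt_random_effect,
    marginal_loglik,
    simulate_dataset,
    wald_pvalue,
)
from mlrpower.glmm_inference import FitResult, lrt_pvalue

from .oracles import dense_loglik_1d, dense_loglik_2d, laplace_loglik_1d


class TestModelStructure:
    def test_hierarchy_enforced(self):
        with pytest.raises(ValueError):
            ModelStructure(random_intercept=False, random_slope=True)
        with pytest.raises(ValueError):
            ModelStructure(random_intercept=True, random_slope=False,
                           free_covariance=True)

    def test_dimensions(self):
        assert ModelStructure(False, False).n_random_dims == 0
        assert ModelStructure(True, False).n_random_dims == 1
        assert ModelStructure(True, True).n_random_dims == 2


class TestMarginalLoglik:
    def test_matches_dense_grid_1d(self, toy_dataset, toy_params):
        st = ModelStructure(random_intercept=True, random_slope=False)
        ours = marginal_loglik(toy_params, toy_dataset, st, n_quadrature=7)
        oracle = dense_loglik_1d(toy_params, toy_dataset)
        assert ours == pytest.approx(oracle, abs=1e-4)

    def test_matches_dense_grid_2d(self, toy_dataset, toy_params):
        st = ModelStructure(random_intercept=True, random_slope=True)
        ours = marginal_loglik(toy_params, toy_dataset, st, n_quadrature=9)
        oracle = dense_loglik_2d(toy_params, toy_dataset)
        assert ours == pytest.approx(oracle, abs=1e-3)

    def test_no_random_effects_equals_plain_logistic(self, toy_dataset, toy_params):
        st = ModelStructure(random_intercept=False, random_slope=False)
        ours = marginal_loglik(toy_params, toy_dataset, st)
        z = toy_dataset.z
        eta = (
            toy_params["gamma00"]
            + toy_params["gamma01"] * z
            + (toy_params["gamma10"] + toy_params["gamma11"] * z) * toy_dataset.x
        )
        plain = np.sum(toy_dataset.y * eta - np.logaddexp(0.0, eta))
        assert ours == pytest.approx(plain, abs=1e-10)

    def test_one_node_is_laplace(self, toy_dataset, toy_params):
        st = ModelStructure(random_intercept=True, random_slope=False)
        agq1 = marginal_loglik(toy_params, toy_dataset, st, n_quadrature=1)
        laplace = laplace_loglik_1d(toy_params, toy_dataset)
        assert agq1 == pytest.approx(laplace, abs=1e-8)

    def test_invariant_under_row_and_cluster_permutation(
        self, toy_dataset, toy_params
    ):
        st = ModelStructure(random_intercept=True, random_slope=True)
        base = marginal_loglik(toy_params, toy_dataset, st)
        rng = np.random.default_rng(3)
        perm = rng.permutation(toy_dataset.n_rows)
        from mlrpower.simulate import SimulatedDataset

        shuffled = SimulatedDataset(
            cluster_id=toy_dataset.cluster_id[perm],
            x=toy_dataset.x[perm],
            z=toy_dataset.z[perm],
            y=toy_dataset.y[perm],
            n_level1=toy_dataset.n_level1,
            n_level2=toy_dataset.n_level2,
        )
        assert marginal_loglik(toy_params, shuffled, st) == pytest.approx(
            base, abs=1e-10
        )

    def test_rejects_bad_quadrature_and_variances(self, toy_dataset, toy_params):
        with pytest.raises(ValueError):
            marginal_loglik(toy_params, toy_dataset, n_quadrature=0)
        bad = dict(toy_params, sigma0_sq=0.0)
        with pytest.raises(ValueError):
            marginal_loglik(bad, toy_dataset, ModelStructure(True, False))


@pytest.fixture(scope="module")
def bench_data():
    scn = case_preset("benchmark", "medium")
    rng = np.random.default_rng(2024)
    return simulate_dataset(scn, 30, 40, rng)


@pytest.fixture(scope="module")
def bench_fit(bench_data):
    return fit(bench_data)


class TestFit:
    def test_converges_with_ses(self, bench_fit):
        assert bench_fit.converged
        for name in ("gamma00", "gamma10", "gamma01", "gamma11"):
            assert bench_fit.std_errors[name] > 0
        assert bench_fit.estimates["sigma0_sq"] >= 0
        assert bench_fit.estimates["sigma1_sq"] >= 0

    def test_quadrature_refinement_stable(self, bench_data):
        f7 = fit(bench_data, n_quadrature=7, compute_se=False)
        f15 = fit(bench_data, n_quadrature=15, compute_se=False)
        assert abs(f7.loglik - f15.loglik) < 1e-3

    def test_fixed_effects_recovered_without_random_effects(self, rng):
        # sigma = 0 data, large n: plain-logistic consistency
        scn = ScenarioSpec(
            fixed=FixedEffects(gamma00=0.0, gamma10=0.5, gamma01=0.3, gamma11=0.3),
            random_cov=RandomEffectsCov(sigma0_sq=0.0, sigma1_sq=0.0),
            level1_predictor=PredictorSpec("binary", incidence=0.5),
            level2_predictor=PredictorSpec("normal"),
        )
        d = simulate_dataset(scn, 500, 100, rng)
        f = fit(d, ModelStructure(random_intercept=False, random_slope=False))
        truth = dict(gamma00=0.0, gamma10=0.5, gamma01=0.3, gamma11=0.3)
        assert f.converged
        for k, v in truth.items():
            assert abs(f.estimates[k] - v) < 3 * f.std_errors[k]

    def test_plain_logistic_matches_statsmodels(self, bench_data):
        import statsmodels.api as sm
        ours = fit(bench_data, ModelStructure(False, False))
        X = np.column_stack(
            [
                np.ones(bench_data.n_rows),
                bench_data.x,
                bench_data.z,
                bench_data.x * bench_data.z,
            ]
        )
        ref = sm.Logit(bench_data.y, X).fit(disp=0)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-6)
        est = [ours.estimates[k] for k in ("gamma00", "gamma10", "gamma01", "gamma11")]
        np.testing.assert_allclose(est, ref.params, atol=1e-5)
        se = [ours.std_errors[k] for k in ("gamma00", "gamma10", "gamma01", "gamma11")]
        np.testing.assert_allclose(se, ref.bse, rtol=1e-3)

    def test_random_intercept_fit_matches_lme4(self, tmp_path):
        # independent engine: lme4::glmer with nAGQ=7 on the same CSV
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; cannot run the lme4 cross-check")
        scn = case_preset("benchmark", "medium")
        d = simulate_dataset(scn, 20, 30, np.random.default_rng(55))
        csv = tmp_path / "d.csv"
        d.to_csv(csv)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(y ~ x*z + (1 | cluster_id), data=d, family=binomial, nAGQ=7)
            co <- fixef(m)
            cat(sprintf("%.8f %.8f %.8f %.8f %.8f %.8f\\n", as.numeric(logLik(m)),
                co[1], co[2], co[3], co[4],
                as.numeric(VarCorr(m)$cluster_id[1,1])))
        """))
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        ll, g00, g10, g01, g11, s0 = map(float, out.stdout.split())
        ours = fit(d, ModelStructure(random_intercept=True, random_slope=False))
        assert ours.converged
        assert ours.loglik == pytest.approx(ll, abs=5e-3)
        assert ours.estimates["gamma00"] == pytest.approx(g00, abs=0.02)
        assert ours.estimates["gamma10"] == pytest.approx(g10, abs=0.02)
        assert ours.estimates["gamma01"] == pytest.approx(g01, abs=0.02)
        assert ours.estimates["gamma11"] == pytest.approx(g11, abs=0.02)
        assert ours.estimates["sigma0_sq"] == pytest.approx(s0, abs=0.05)

    def test_constant_outcome_is_degenerate(self, benchmark_scenario, rng):
        d = simulate_dataset(benchmark_scenario, 5, 4, rng)
        d.y[:] = 1
        with pytest.raises(DegenerateDataError):
            fit(d)

    def test_report_lists_parameters(self, bench_fit):
        text = bench_fit.report()
        for name in ("gamma10", "gamma01", "gamma11", "sigma0_sq", "sigma1_sq"):
            assert name in text


class TestWaldPvalue:
    def _fake_fit(self, estimate, se):
        return FitResult(
            estimates={"gamma10": estimate, "gamma00": 0, "gamma01": 0, "gamma11": 0},
            std_errors={"gamma10": se, "gamma00": 1, "gamma01": 1, "gamma11": 1},
            loglik=0.0,
            converged=True,
            n_quadrature=7,
            structure=ModelStructure(),
        )

    @pytest.mark.parametrize(
        "estimate, se, expected",
        [(0.0, 1.0, 1.0), (1.959964, 1.0, 0.05), (-1.959964, 1.0, 0.05)],
    )
    def test_reference_values(self, estimate, se, expected):
        assert wald_pvalue(self._fake_fit(estimate, se), "gamma10") == pytest.approx(
            expected, abs=1e-6
        )

    def test_unknown_coefficient(self):
        with pytest.raises(ValueError):
            wald_pvalue(self._fake_fit(0, 1), "sigma0_sq")

    def test_requires_convergence(self):
        bad = self._fake_fit(0, 1)
        bad.converged = False
        with pytest.raises(ValueError):
            wald_pvalue(bad, "gamma10")


class TestLikelihoodRatio:
    def test_chi_square_reference_values(self):
        assert lrt_pvalue(0.0) == 1.0
        assert lrt_pvalue(3.841459) == pytest.approx(0.05, abs=1e-6)
        assert lrt_pvalue(-2.0) == 1.0  # floored

    def test_intercept_variance_detected(self):
        scn = case_preset("benchmark", "medium")
        d = simulate_dataset(scn, 50, 60, np.random.default_rng(8))
        res = lrt_random_effect(d, "intercept_variance")
        assert res.converged
        assert res.df == 1
        assert res.statistic > 3.84  # sigma0_sq = pi^2/7 is a big signal
        assert res.p_value < 0.05

    def test_unknown_target(self, toy_dataset):
        with pytest.raises(ValueError):
            lrt_random_effect(toy_dataset, "slope_mean")
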