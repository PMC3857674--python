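import numpy as np
import pytest

from mixselect import scenario, solve_lognormal_params
from mixselect.simulate import (
    ExposureModelCS,
    ExposureModelTS,
    OffsetModel,
    OutcomeModelLinear,
    OutcomeModelPoisson,
    build_offset,
    generate_counts_ts,
    generate_exposures_cs,
    generate_exposures_ts,
    generate_outcome_linear,
)


class TestLognormalInversion:
    def test_unit_mean_unit_variance(self):
        # mu=1, sigma^2=1 component: log variance ln 2, log mean -ln2/2
        m, C = solve_lognormal_params([1.0], [[1.0]])
        assert C[0, 0] == pytest.approx(np.log(2.0), abs=1e-12)
        assert m[0] == pytest.approx(-np.log(2.0) / 2, abs=1e-12)

    def test_two_pollutant_cross_term(self):
        # mu=(1.20, 2.30), cov12=0.52 -> log cov12 = ln(1 + 0.52/2.76)
        m, C = solve_lognormal_params(
            [1.20, 2.30], [[1.0, 0.52], [0.52, 1.0]]
        )
        assert C[0, 1] == pytest.approx(np.log(1 + 0.52 / (1.2 * 2.3)), rel=1e-12)
        assert C[0, 1] == pytest.approx(0.1726, abs=2e-4)

    def test_independence_preserved(self):
        _, C = solve_lognormal_params([1.0, 2.0], [[1.0, 0.0], [0.0, 4.0]])
        assert C[0, 1] == 0.0

    def test_moment_recovery_monte_carlo(self, rng):
        mu = np.array([1.2, 2.3])
        cov = np.array([[1.0, 0.52], [0.52, 1.0]])
        m, C = solve_lognormal_params(mu, cov)
        X = np.exp(rng.multivariate_normal(m, C, size=400_000))
        np.testing.assert_allclose(X.mean(axis=0), mu, rtol=0.01)
        np.testing.assert_allclose(np.cov(X.T), cov, atol=0.03)

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            solve_lognormal_params([-1.0], [[1.0]])
        with pytest.raises(ValueError):
            solve_lognormal_params([1.0, 1.0], [[1.0, -1.5], [-1.5, 1.0]])
        with pytest.raises(ValueError):
            solve_lognormal_params([1.0], [[1.0, 0.0], [0.0, 1.0]])


class TestCrossSectionalExposures:
    def test_scenario1_moments(self):
        model = scenario("s1").exposure_model
        X = generate_exposures_cs(model, 300_000, seed=4)
        np.testing.assert_allclose(
            X.mean(axis=0), [1.20, 2.30, 1.89, 1.00], rtol=0.01
        )
        C = np.cov(X.T)
        np.testing.assert_allclose(np.diag(C), np.ones(4), rtol=0.03)
        assert C[1, 2] == pytest.approx(0.57, abs=0.03)

    def test_near_degenerate_covariance(self):
        model = ExposureModelCS([2.0, 3.0], 1e-8 * np.eye(2))
        X = model.sample(500, np.random.default_rng(0))
        np.testing.assert_allclose(X.mean(axis=0), [2.0, 3.0], atol=1e-3)
        assert X.std(axis=0).max() < 1e-3

    def test_determinism_and_positivity(self):
        model = scenario("s1").exposure_model
        a = generate_exposures_cs(model, 100, seed=9)
        b = generate_exposures_cs(model, 100, seed=9)
        np.testing.assert_array_equal(a, b)
        assert (a > 0).all()
        with pytest.raises(ValueError):
            model.sample(0, np.random.default_rng(0))


class TestTimeSeriesExposures:
    def test_iid_limit(self):
        model = ExposureModelTS(
            ar_coef=np.zeros((2, 1)), seasonal_const=np.zeros(2),
            innov_cov=np.eye(2),
        )
        X = generate_exposures_ts(model, 20_000, seed=3)
        r1 = np.corrcoef(X[:-1, 0], X[1:, 0])[0, 1]
        assert abs(r1) < 0.03
        np.testing.assert_allclose(X.std(axis=0), 1.0, rtol=0.03)

    def test_ar1_closed_form(self):
        model = ExposureModelTS(
            ar_coef=np.array([[0.5]]), seasonal_const=np.zeros(1),
            innov_cov=np.eye(1),
        )
        X = generate_exposures_ts(model, 60_000, seed=3)[:, 0]
        assert np.corrcoef(X[:-1], X[1:])[0, 1] == pytest.approx(0.5, abs=0.03)
        assert X.var() == pytest.approx(1 / (1 - 0.25), rel=0.05)

    def test_nonstationary_rejected(self):
        with pytest.raises(ValueError, match="non-stationary"):
            ExposureModelTS(
                ar_coef=np.array([[1.05]]), seasonal_const=np.zeros(1),
                innov_cov=np.eye(1),
            )

    def test_marginal_moment_matching(self):
        model = scenario("s3").exposure_model
        X = generate_exposures_ts(model, 200_000, seed=5)
        np.testing.assert_allclose(
            X.mean(axis=0), [1.20, 2.30, 1.89, 1.00], atol=0.05
        )
        np.testing.assert_allclose(np.diag(np.cov(X.T)), 1.0, atol=0.06)

    def test_determinism_and_length(self):
        model = scenario("s4").exposure_model
        a = generate_exposures_ts(model, 123, seed=8)
        b = generate_exposures_ts(model, 123, seed=8)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (123, 10)

    def test_positive_variant(self):
        model = ExposureModelTS(
            ar_coef=np.array([[0.4]]), seasonal_const=np.zeros(1),
            innov_cov=np.eye(1), positive=True,
        )
        assert (generate_exposures_ts(model, 500, seed=1) > 0).all()


class TestLinearOutcome:
    def test_known_row_arithmetic(self):
        # Scenario-1 coefficients at X=(1,1,1,1), no noise:
        # 0.1 + 0.5 + 0.5 + 0.2 = 1.3
        model = OutcomeModelLinear(0.1, [0, 0.5, 0.5, 0], {(2, 3): 0.2}, 3.0)
        assert model.mean(np.ones((1, 4)))[0] == pytest.approx(1.3)

    def test_intercept_only_limit(self):
        model = OutcomeModelLinear(0.1, np.zeros(2), {}, 1e-12)
        y = generate_outcome_linear(np.ones((50, 2)), model, seed=0)
        np.testing.assert_allclose(y, 0.1, atol=1e-9)

    def test_noise_scale_and_determinism(self, rng):
        model = OutcomeModelLinear(0.0, np.zeros(2), {}, 3.0)
        X = rng.lognormal(size=(40_000, 2))
        y = generate_outcome_linear(X, model, seed=2)
        assert y.std() == pytest.approx(3.0, rel=0.02)
        np.testing.assert_array_equal(
            y, generate_outcome_linear(X, model, seed=2)
        )

    def test_gamma_index_validation(self):
        with pytest.raises(ValueError):
            OutcomeModelLinear(0.0, np.zeros(3), {(3, 2): 0.1}, 1.0)


class TestOffsetAndCounts:
    def test_flat_offset(self):
        model = OffsetModel(
            season_amp=0, dow_effects=(0,) * 7, rh_coef=0,
            temp_coef=(0, 0), trend_coef=(0, 0), calibration_rate=13.3,
        )
        omega = build_offset(400, model, seed=1)
        np.testing.assert_allclose(omega, 13.3, atol=1e-9)

    def test_calibration_and_periodicity(self):
        model = OffsetModel(calibration_rate=13.3)
        omega = build_offset(730, model, seed=1)
        assert (omega > 0).all()
        assert omega.mean() == pytest.approx(13.3, rel=1e-6)
        np.testing.assert_array_equal(omega, build_offset(730, model, seed=1))

    def test_counts_mean_tracks_offset_under_null(self):
        model = OutcomeModelPoisson(
            beta=np.zeros(2), offset_model=OffsetModel(calibration_rate=10.0)
        )
        X = np.ones((20_000, 2))
        y = generate_counts_ts(X, model, seed=7)
        assert y.mean() == pytest.approx(10.0, rel=0.02)

    def test_poisson_conditional_mean_closed_form(self, rng):
        # omega=1, beta1=0.3, X1=1 everywhere -> E[y] = e^0.3
        model = OutcomeModelPoisson(beta=np.array([0.3]))
        X = np.ones((50_000, 1))
        y = model.sample(X, np.ones(50_000), rng)
        assert y.mean() == pytest.approx(np.exp(0.3), rel=0.02)

    def test_conditional_mean_at_fixed_design_row(self):
        cfg = scenario("s3")
        X = cfg.exposure_model.sample(5, np.random.default_rng(0))
        offset = np.full(5, 13.3)
        psi = cfg.outcome_model.mean(X, offset)
        draws = np.array([
            cfg.outcome_model.sample(X, offset, np.random.default_rng(s))
            for s in range(4000)
        ])
        np.testing.assert_allclose(draws.mean(axis=0), psi, rtol=0.05)

    def test_overflow_rejected(self):
        model = OutcomeModelPoisson(beta=np.array([10.0]))
        with pytest.raises(FloatingPointError, match="overflow"):
            model.mean(np.full((5, 1), 50.0), np.ones(5))


class TestScenarioPresets:
    @pytest.mark.parametrize("sid,K,n,family", [
        ("s1", 4, 250, "gaussian"), ("s2", 20, 250, "gaussian"),
        ("s3", 4, 400, "poisson"), ("s4", 10, 800, "poisson"),
    ])
    def test_preset_shapes(self, sid, K, n, family):
        cfg = scenario(sid)
        data = cfg.simulate(0)
        assert data.X.shape == (n, K)
        assert data.family == family
        if family == "poisson":
            assert data.offset is not None and (data.offset > 0).all()

    def test_preset_true_models(self):
        assert scenario("s1").true_coef() == {
            "X2": 0.5, "X3": 0.5, "X2*X3": 0.2
        }
        assert scenario("s4").true_coef() == {
            "X1": 0.2, "X3": 0.2, "X6": 0.2, "X9": 0.2,
            "X1*X3": 0.1, "X1*X6": 0.1,
        }

    def test_unknown_id(self):
        with pytest.raises(ValueError):
            scenario("s9")

    def test_bit_identical_replicates(self):
        cfg = scenario("s3")
        a, b = cfg.simulate(42), cfg.simulate(42)
        np.testing.assert_array_equal(a.X.to_numpy(), b.X.to_numpy())
        np.testing.assert_array_equal(a.y, b.y)
        np.testing.assert_array_equal(a.offset, b.offset)
        c = cfg.simulate(43)
        assert not np.array_equal(a.y, c.y)
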