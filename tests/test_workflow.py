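import numpy as np
import pandas as pd
import pytest

from mixselect import (
    WorkflowConfig,
    collinearity_prefilter,
    omnibus_and_prune,
    residualize,
    run_workflow,
)


@pytest.fixture
def table(rng):
    n = 400
    C1 = rng.lognormal(size=n)
    C2 = rng.normal(size=n)
    E1 = rng.lognormal(size=n)
    E2 = E1 * np.exp(rng.normal(scale=0.1, size=n))  # r > 0.9 with E1
    E3 = rng.lognormal(size=n)
    E4 = rng.lognormal(size=n)
    y = 0.5 * C1 + 1.0 * E1 + 0.8 * E3 + rng.normal(size=n)
    return pd.DataFrame(
        {"y": y, "C1": C1, "C2": C2, "E1": E1, "E2": E2, "E3": E3, "E4": E4}
    )


@pytest.fixture
def config():
    return WorkflowConfig(
        outcome="y", exposures=["E1", "E2", "E3", "E4"], covariates=["C1", "C2"],
        methods=["lasso", "bma"], seed=3,
    )


class TestResidualize:
    def test_no_covariates_returns_centered_response(self, table):
        cfg = WorkflowConfig(outcome="y", exposures=["E1"])
        r = residualize(table, cfg)
        np.testing.assert_allclose(r, table["y"] - table["y"].mean())

    def test_exact_linear_response_gives_zero_residuals(self, rng):
        C = rng.normal(size=(50, 2))
        t = pd.DataFrame({"y": 2 * C[:, 0] - C[:, 1] + 3, "C1": C[:, 0], "C2": C[:, 1]})
        cfg = WorkflowConfig(outcome="y", exposures=[], covariates=["C1", "C2"])
        np.testing.assert_allclose(residualize(t, cfg), 0.0, atol=1e-10)

    def test_matches_hat_matrix_arithmetic(self, rng):
        C = rng.normal(size=(10, 2))
        y = rng.normal(size=10)
        t = pd.DataFrame({"y": y, "C1": C[:, 0], "C2": C[:, 1]})
        cfg = WorkflowConfig(outcome="y", exposures=[], covariates=["C1", "C2"])
        X = np.column_stack([np.ones(10), C])
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        np.testing.assert_allclose(residualize(t, cfg), (np.eye(10) - H) @ y, atol=1e-10)

    def test_rank_deficiency_rejected(self, rng):
        C = rng.normal(size=30)
        t = pd.DataFrame({"y": rng.normal(size=30), "C1": C, "C2": 2 * C})
        cfg = WorkflowConfig(outcome="y", exposures=[], covariates=["C1", "C2"])
        with pytest.raises(ValueError, match="rank"):
            residualize(t, cfg)

    def test_poisson_first_stage_returns_offset(self, rng):
        n = 200
        C = rng.normal(size=n)
        y = rng.poisson(np.exp(1.0 + 0.3 * C))
        t = pd.DataFrame({"y": y, "C1": C, "E1": rng.lognormal(size=n)})
        cfg = WorkflowConfig(outcome="y", exposures=["E1"], covariates=["C1"],
                             family="poisson")
        counts, offset = residualize(t, cfg)
        assert (offset > 0).all()
        assert offset.sum() == pytest.approx(y.sum(), rel=1e-6)


class TestPrefilter:
    def test_identical_columns_keep_one(self, rng):
        E = rng.lognormal(size=60)
        t = pd.DataFrame({"y": rng.normal(size=60), "E1": E, "E2": E})
        cfg = WorkflowConfig(outcome="y", exposures=["E1", "E2"])
        kept = collinearity_prefilter(t, residualize(t, cfg), cfg)
        assert len(kept) == 1

    def test_uncorrelated_all_kept(self, table, config):
        cfg = WorkflowConfig(outcome="y", exposures=["E1", "E3", "E4"])
        kept = collinearity_prefilter(table, residualize(table, cfg), cfg)
        assert kept == ["E1", "E3", "E4"]

    def test_correlated_pair_keeps_smaller_p(self, table, config):
        resp = residualize(table, config)
        kept = collinearity_prefilter(table, resp, config)
        # E1/E2 form one cluster; E1 drives the outcome so it has smaller p
        assert "E1" in kept and "E2" not in kept
        assert set(kept) == {"E1", "E3", "E4"}

    def test_idempotent(self, table, config):
        resp = residualize(table, config)
        kept = collinearity_prefilter(table, resp, config)
        cfg2 = WorkflowConfig(
            outcome="y", exposures=kept, covariates=config.covariates
        )
        assert collinearity_prefilter(table, resp, cfg2) == kept

    def test_groups_are_filtered_separately(self, table):
        # E1 and E2 in different groups: both survive despite r > 0.9
        cfg = WorkflowConfig(
            outcome="y", exposures=["E1", "E2"],
            groups={"E1": "a", "E2": "b"},
        )
        kept = collinearity_prefilter(table, residualize(table, cfg), cfg)
        assert set(kept) == {"E1", "E2"}


class TestOmnibusPrune:
    def test_all_significant_model_unchanged(self, table, config):
        resp = residualize(table, config)
        final, steps = omnibus_and_prune(["E1", "E3"], table, resp, config)
        assert steps == []
        assert set(final.index) == {"E1", "E3"}
        assert (final["pvalue"] <= 0.05).all()

    def test_noise_term_eliminated(self, table, config):
        resp = residualize(table, config)
        final, steps = omnibus_and_prune(["E1", "E3", "E4"], table, resp, config)
        assert "E4" not in final.index
        assert steps[0]["removed"] == "E4"

    def test_elimination_order_matches_hand_rule(self, rng):
        # constructed dataset with graded signal: weakest terms drop first
        n = 300
        X = rng.normal(size=(n, 3))
        y = 1.0 * X[:, 0] + 0.02 * X[:, 1] + 0.005 * X[:, 2] + rng.normal(size=n)
        t = pd.DataFrame({"y": y, "A": X[:, 0], "B": X[:, 1], "D": X[:, 2]})
        cfg = WorkflowConfig(outcome="y", exposures=["A", "B", "D"])
        resp = residualize(t, cfg)
        import statsmodels.api as sm

        # hand-run of the rule: iteratively drop the largest p > 0.05
        terms = ["A", "B", "D"]
        expected_steps = []
        while True:
            Xm = sm.add_constant(t[terms].to_numpy())
            pv = pd.Series(sm.OLS(resp, Xm).fit().pvalues[1:], index=terms)
            if pv.max() <= 0.05 or len(terms) == 1:
                break
            expected_steps.append(pv.idxmax())
            terms = [x for x in terms if x != pv.idxmax()]
        final, steps = omnibus_and_prune(["A", "B", "D"], t, resp, cfg)
        assert [s["removed"] for s in steps][: len(expected_steps)] == expected_steps

    def test_empty_union_rejected(self, table, config):
        with pytest.raises(ValueError, match="empty"):
            omnibus_and_prune([], table, table["y"], config)


class TestFullPipeline:
    def test_end_to_end_deterministic(self, table, config):
        r1 = run_workflow(table, config)
        r2 = run_workflow(table, config)
        pd.testing.assert_frame_equal(r1.final_model, r2.final_model)
        assert r1.screened_exposures == r2.screened_exposures
        assert "optimistic" in r1.log["caveat"]

    def test_recovers_true_drivers(self, table, config):
        res = run_workflow(table, config)
        assert "E1" in res.final_model.index or "E2" in res.final_model.index
        assert "E3" in res.final_model.index

    def test_config_loads_from_yaml(self, tmp_path):
        p = tmp_path / "wf.yaml"
        p.write_text(
            "outcome: y\nexposures: [E1, E2]\ncovariates: [C1]\n"
            "correlation_cutoff: 0.7\nmethods: [lasso]\n"
        )
        cfg = WorkflowConfig.from_yaml(p)
        assert cfg.exposures == ["E1", "E2"]
        assert cfg.correlation_cutoff == 0.7

    def test_config_validation(self):
        with pytest.raises(ValueError, match="cutoff"):
            WorkflowConfig(outcome="y", exposures=["E1"], correlation_cutoff=1.5)
        with pytest.raises(ValueError, match="role"):
            WorkflowConfig(outcome="y", exposures=["y"])
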