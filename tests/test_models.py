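"""Affect multilevel models and the life-satisfaction OLS.

The synthetic generator's ground truth is the oracle for parameter
recovery; hand-rolled normal equations are the oracle for the OLS path;
pivot rotations are checked as exact linear reparameterisations.
"""

import numpy as np
import pandas as pd
import pytest

from timeuse_coda import coda, models, preprocess, simulate, pipeline

from conftest import random_compositions


def normal_equations(X, y):
    """Independent OLS oracle: solve X'X b = X'y directly."""
    return np.linalg.solve(X.T @ X, X.T @ y)


@pytest.fixture(scope="module")
def happiness_fit(small_table):
    spec = models.ModelSpec(outcome="happiness", pivot="sb", seed=11)
    return models.fit_affect_model(small_table, spec)


class TestAffectModel:
    def test_recovers_true_between_coefficients(self, small_cohort, small_table, happiness_fit):
        cfg, _, _ = small_cohort
        truth = np.asarray(cfg.true_beta_between["happiness"])
        s = happiness_fit.summary
        for k, name in enumerate(preprocess.ILR_B_COLS):
            z = abs(s.loc[name, "mean"] - truth[k]) / s.loc[name, "sd"]
            assert z < 2.0, f"{name}: posterior mean {s.loc[name, 'mean']:.2f} vs truth {truth[k]}"

    def test_within_null_intervals_cover_zero(self, happiness_fit):
        """Generator sets all within effects to 0; intervals should say so."""
        s = happiness_fit.summary
        covered = sum(
            s.loc[n, "ci_low"] <= 0 <= s.loc[n, "ci_high"]
            for n in preprocess.ILR_W_COLS
        )
        assert covered >= 2

    def test_convergence_diagnostics_recorded(self, happiness_fit):
        d = happiness_fit.diagnostics
        assert (d["rhat"] <= models.RHAT_LIMIT).all()
        assert (d["ess_bulk"] >= 400).all()
        n_draws = happiness_fit.draws["intercept"].size
        assert n_draws == happiness_fit.spec.chains * happiness_fit.spec.draws

    def test_row_permutation_invariance(self, small_table):
        spec = models.ModelSpec(
            outcome="anxiousness", seed=3, chains=2, draws=200, warmup=200,
            check_convergence=False,  # short chains: equality is the point
        )
        a = models.fit_affect_model(small_table, spec)
        shuffled = small_table.sample(frac=1.0, random_state=9).reset_index(drop=True)
        b = models.fit_affect_model(shuffled, spec)
        pd.testing.assert_frame_equal(a.summary, b.summary)

    def test_degenerate_predictor_named(self, small_table):
        df = small_table.copy()
        df["deprivation_decile"] = 5
        spec = models.ModelSpec(outcome="happiness", seed=0)
        with pytest.raises(ValueError, match="deprivation_decile"):
            models.fit_affect_model(df, spec)

    def test_noise_monotonicity_of_posterior_sd(self):
        """More residual noise in the generator never shrinks posterior SDs."""
        sds = []
        for noise in (0.5, 1.5, 3.0):
            cfg = simulate.GeneratorConfig(
                n_participants=40, residual_sd=noise, seed=5
            )
            tables, _ = simulate.generate_cohort(cfg)
            table = pipeline.preprocess_tables(tables)
            spec = models.ModelSpec(
                outcome="happiness", adjusted=False, seed=1,
                chains=2, draws=400, warmup=400, check_convergence=False,
            )
            fit = models.fit_affect_model(table, spec)
            sds.append(fit.summary.loc["ilr_b1", "sd"])
        assert sds[0] < sds[1] < sds[2]


class TestLifeSatisfaction:
    @staticmethod
    def _person_table(rng, n=200, beta=(2.0, 0.0, 0.0), noise=0.0, seed_offset=0):
        comps = random_compositions(rng, n)
        z = coda.ilr_transform(comps)
        y = 5.0 + z @ np.asarray(beta) + noise * rng.standard_normal(n)
        return pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(n)],
                "ilr_b1": z[:, 0],
                "ilr_b2": z[:, 1],
                "ilr_b3": z[:, 2],
                "life_satisfaction": y,
            }
        )

    def test_noiseless_linear_outcome_recovered_exactly(self, rng):
        df = self._person_table(rng)
        spec = models.ModelSpec(outcome="life_satisfaction", adjusted=False)
        fit = models.fit_life_satisfaction(df, spec)
        assert fit.params["ilr_b1"] == pytest.approx(2.0, abs=1e-8)
        assert fit.rsquared == pytest.approx(1.0, abs=1e-10)

    def test_null_model_r2_near_zero(self, rng):
        df = self._person_table(rng, beta=(0, 0, 0), noise=1.0)
        spec = models.ModelSpec(outcome="life_satisfaction", adjusted=False)
        fit = models.fit_life_satisfaction(df, spec)
        assert fit.rsquared < 0.1
        assert ((fit.pvalues >= 0) & (fit.pvalues <= 1)).all()

    def test_matches_normal_equations_oracle(self, rng):
        df = self._person_table(rng, beta=(1.2, -0.4, 0.3), noise=0.8)
        spec = models.ModelSpec(outcome="life_satisfaction", adjusted=False)
        fit = models.fit_life_satisfaction(df, spec)
        X = np.column_stack(
            [np.ones(len(df)), df[["ilr_b1", "ilr_b2", "ilr_b3"]].to_numpy()]
        )
        oracle = normal_equations(X, df["life_satisfaction"].to_numpy())
        np.testing.assert_allclose(fit.params.to_numpy(), oracle, atol=1e-8)

    def test_underdetermined_fit_rejected(self, rng):
        df = self._person_table(rng, n=4)
        spec = models.ModelSpec(outcome="life_satisfaction", adjusted=False)
        with pytest.raises(ValueError, match="identify"):
            models.fit_life_satisfaction(df, spec)


class TestPivots:
    def test_pivot_fits_are_reparameterisations_ols(self, small_table):
        """Fitted values of the four pivot OLS fits agree exactly: the
        rotated bases span the same column space."""
        person = preprocess.person_level_table(small_table)
        fitted = {}
        for pivot in coda.PARTS:
            basis = coda.default_basis(pivot)
            df = preprocess.decompose_between_within(
                preprocess.add_ilr_coordinates(
                    small_table, basis
                )
            )
            p = preprocess.person_level_table(df)
            X = np.column_stack(
                [np.ones(len(p)), p[["ilr_b1", "ilr_b2", "ilr_b3"]].to_numpy()]
            )
            y = p["life_satisfaction"].to_numpy(dtype=float)
            fitted[pivot] = X @ normal_equations(X, y)
        base = fitted["sb"]
        for pivot in ("lpa", "mvpa", "sleep"):
            np.testing.assert_allclose(fitted[pivot], base, atol=1e-8)
        assert len(person) == len(base)

    def test_pivot_posterior_predictions_agree(self, small_table):
        """Bayesian pivot fits agree on fitted day-level means within MCMC
        error (the likelihood is identical up to rotation)."""
        preds = {}
        for pivot in ("sb", "mvpa"):
            basis = coda.default_basis(pivot)
            df = preprocess.decompose_between_within(
                preprocess.add_ilr_coordinates(small_table, basis)
            )
            spec = models.ModelSpec(
                outcome="happiness", adjusted=False, pivot=pivot, seed=4
            )
            fit = models.fit_affect_model(df, spec)
            rows = df.loc[df["has_affect"]].sort_values(["participant_id", "date"])
            X = rows[[*preprocess.ILR_B_COLS, *preprocess.ILR_W_COLS]].to_numpy()
            coefs = fit.summary.loc[
                [*preprocess.ILR_B_COLS, *preprocess.ILR_W_COLS], "mean"
            ].to_numpy()
            preds[pivot] = fit.summary.loc["intercept", "mean"] + X @ coefs
        diff = np.abs(preds["sb"] - preds["mvpa"]).mean()
        assert diff < 0.05

    def test_summary_table_counts(self, small_table):
        fits = {
            o: models.fit_all_pivots(
                small_table, o, adjusted=False, chains=2, draws=250, warmup=250, seed=6
            )
            for o in ("happiness",)
        }
        tbl = models.summarize_fits(fits)
        assert len(tbl) == 2 * 4  # levels x pivots for one outcome
        assert set(tbl["level"]) == {"between", "within"}

    def test_equal_composition_dataset_errors_on_degenerate_ilr(self):
        df = pd.DataFrame(
            {
                "participant_id": np.repeat([f"P{i}" for i in range(6)], 4),
                "date": list(pd.date_range("2023-06-05", periods=4)) * 6,
                "sb": 600.0, "lpa": 300.0, "mvpa": 60.0, "sleep": 480.0,
                "happiness": np.tile([5.0, 6, 7, 5], 6),
                "has_affect": True,
            }
        )
        df = preprocess.decompose_between_within(preprocess.add_ilr_coordinates(df))
        spec = models.ModelSpec(outcome="happiness", adjusted=False)
        with pytest.raises(ValueError, match="degenerate"):
            models.fit_affect_model(df, spec)


class TestSignificanceFlag:
    def test_interval_excluding_zero_flagged(self):
        draws = {"x": np.array([[-3.0, -2.0, -1.0, -0.5, -2.5] * 100])}
        summary, _ = models._summaries(draws)
        assert summary.loc["x", "significant"]

    def test_interval_containing_zero_not_flagged(self, rng):
        draws = {"x": rng.standard_normal((2, 500))}
        summary, _ = models._summaries(draws)
        assert not summary.loc["x", "significant"]
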