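"""Model inversion: likelihood oracle, MAP behavior, evidence sanity,
and the validating behavioral GLM."""

import numpy as np
import pandas as pd
import pytest

from effortpath.design import TaskConfig, generate_session
from effortpath.fitting import (ChoiceData, Priors, behavioral_glm, fit_map,
                                neg_log_posterior, theta_to_k)
from effortpath.model import PARAM_NAMES, ModelParams, simulate_choices

_LOG_2PI = np.log(2 * np.pi)


def prior_term(theta, sd=1.0):
    theta = np.asarray(theta, float)
    return float(0.5 * np.sum((theta / sd) ** 2)
                 + len(theta) * (0.5 * _LOG_2PI + np.log(sd)))


def empty_data():
    df = pd.DataFrame({
        "block_index": pd.Series(dtype=int),
        "trial_index": pd.Series(dtype=int),
        "domain": pd.Series(dtype=str),
        "valence": pd.Series(dtype=str),
        "he_incentive": pd.Series(dtype=float),
        "he_effort": pd.Series(dtype=float),
        "choice": pd.Series(dtype=int),
    })
    return ChoiceData.from_frame(df)


class TestNegLogPosterior:
    def test_no_data_reduces_to_prior(self):
        theta = np.zeros(len(PARAM_NAMES))
        assert neg_log_posterior(theta, empty_data()) == \
            pytest.approx(prior_term(theta))

    def test_single_indifferent_trial_adds_log2(self):
        df = pd.DataFrame([{
            "block_index": 0, "trial_index": 0, "domain": "physical",
            "valence": "reward", "he_incentive": 1, "he_effort": 1,
            "choice": 1,
        }])
        data = ChoiceData.from_frame(df)
        # theta chosen so every parameter is 0 except exp-transformed
        # ones at tiny values: use kR=kEp with equal push/pull -> dsv=0
        theta = np.array([0.0] * 7)
        k = theta_to_k(theta, np.ones(7, bool), np.zeros(7))
        # kR=kEp=1 etc: dsv = 1*1 - 1*1 + 0 = 0 -> p = 0.5
        assert neg_log_posterior(theta, data) == \
            pytest.approx(np.log(2) + prior_term(theta))

    def test_matches_hand_expanded_sum(self):
        """Ten-trial fixture against an independent scalar summation."""
        cfg = TaskConfig()
        session = generate_session(cfg, "physical", seed=5)
        rng = np.random.default_rng(8)
        df = simulate_choices(
            session, ModelParams(kR=1, kEp=0.7, kBias=0.2), rng).head(10)
        data = ChoiceData.from_frame(df)
        theta = np.array([0.1, -0.3, 0.2, -0.1, 0.05, -0.2, 0.3])
        k = dict(zip(PARAM_NAMES, theta_to_k(theta, np.ones(7, bool),
                                             np.zeros(7))))
        # independent oracle: per-trial scalar loop with running fatigue
        total, F = 0.0, 0.0
        for _, row in df.iterrows():
            gain = k["kR"] * row.he_incentive if row.valence == "reward" \
                else k["kP"] * row.he_incentive
            cost = (k["kEp"] + k["kFp"] * F) * row.he_effort
            dsv = k["kBias"] + gain - cost
            p = 1 / (1 + np.exp(-dsv))
            total += -np.log(p if row.choice == 1 else 1 - p)
            F += row.Ech / (3 * 10)  # block length inferred from data
        assert neg_log_posterior(theta, data) == \
            pytest.approx(total + prior_term(theta), abs=1e-9)

    def test_nonfinite_theta_rejected(self):
        with pytest.raises(ValueError):
            neg_log_posterior(np.full(7, np.inf), empty_data())


class TestFitMap:
    def test_pure_bias_agent_reproduced(self):
        cfg = TaskConfig()
        session = generate_session(cfg, "physical", seed=1)
        rng = np.random.default_rng(3)
        df = simulate_choices(session, ModelParams(kBias=5.0), rng)
        fit = fit_map(df, seed=0)
        k = fit.estimates.to_array()
        dsv = (np.where(df["valence"] == "reward", k[0], k[1])
               * df["he_incentive"].to_numpy())
        # predicted choice from the fitted rule (state terms tiny here)
        pred = (fit.estimates.kBias + dsv
                - np.where(df["domain"] == "physical",
                           k[2], k[3]) * df["he_effort"].to_numpy()) > 0
        assert (pred == df["choice"].astype(bool).to_numpy()).mean() >= 0.95

    def test_duplicating_data_keeps_mode_moves_evidence(self,
                                                        simulated_choices):
        # a weak prior makes the mode likelihood-dominated, so
        # duplicating every trial leaves it (nearly) unchanged while
        # the evidence's data term doubles
        weak = Priors(sd=5.0)
        fit1 = fit_map(simulated_choices, priors=weak, seed=0, n_restarts=3)
        doubled = pd.concat([
            simulated_choices,
            simulated_choices.assign(
                block_index=simulated_choices["block_index"] + 4),
        ], ignore_index=True)
        fit2 = fit_map(doubled, priors=weak, seed=0, n_restarts=3)
        assert np.allclose(fit1.theta_mode, fit2.theta_mode, atol=0.05)
        assert fit2.laplace_evidence < fit1.laplace_evidence  # data doubled
        assert fit2.n_trials_used == 2 * fit1.n_trials_used

    def test_reduced_model_matches_grid_oracle(self):
        """Two-parameter MAP vs exhaustive grid search (independent
        optimizer) on one simulated session."""
        cfg = TaskConfig()
        session = generate_session(cfg, "physical", seed=21)
        rng = np.random.default_rng(22)
        truth = ModelParams(kR=0.9, kEp=0.7)
        df = simulate_choices(session, truth, rng)
        fit = fit_map(df, free_params=("kR", "kEp"), seed=0)
        data = ChoiceData.from_frame(df)
        A = np.where(data.is_reward, data.d_inc, 0.0)
        B = np.where(data.is_physical, data.d_eff, 0.0)
        y = data.choice
        ks = np.arange(0.05, 3.0, 0.005)
        best = (np.inf, None, None)
        for kr in ks:
            dsv = kr * A[None, :] - ks[:, None] * B[None, :]
            nll = np.where(y == 1, np.logaddexp(0, -dsv),
                           np.logaddexp(0, dsv)).sum(axis=1)
            nlp = nll + 0.5 * (np.log(kr) ** 2 + np.log(ks) ** 2)
            j = int(np.argmin(nlp))
            if nlp[j] < best[0]:
                best = (float(nlp[j]), float(kr), float(ks[j]))
        assert fit.estimates.kR == pytest.approx(best[1], abs=1e-2)
        assert fit.estimates.kEp == pytest.approx(best[2], abs=1e-2)

    def test_occam_penalty_on_irrelevant_parameter(self):
        """A nested model without the (generatively absent) punishment
        sensitivity achieves at least as high Laplace evidence."""
        cfg = TaskConfig()
        session = generate_session(cfg, "physical", seed=31)
        rng = np.random.default_rng(32)
        df = simulate_choices(session, ModelParams(kR=1.2, kEp=0.8), rng)
        reduced = fit_map(df, free_params=("kR", "kEp"), seed=0)
        full = fit_map(df, free_params=("kR", "kEp", "kP", "kEm"), seed=0)
        assert reduced.laplace_evidence > full.laplace_evidence

    def test_no_free_parameters_rejected(self, simulated_choices):
        with pytest.raises(ValueError):
            fit_map(simulated_choices, free_params=())


class TestBehavioralGLM:
    def test_effort_and_incentive_drive_choices(self):
        cfg = TaskConfig()
        session = generate_session(cfg, "physical", seed=41)
        rng = np.random.default_rng(42)
        df = simulate_choices(session, ModelParams(kR=1.0, kEp=1.2), rng)
        phys = df[df["domain"] == "physical"]
        tab = behavioral_glm(phys)["choice"]
        assert tab.loc["he_effort", "coef"] < 0
        assert tab.loc["he_effort", "p"] < 0.05
        assert tab.loc["he_incentive", "coef"] > 0

    def test_type_one_error_controlled(self):
        """Pure-noise choices rarely yield a significant effort term."""
        cfg = TaskConfig()
        session = generate_session(cfg, "physical", seed=51)
        rng = np.random.default_rng(52)
        n_sig = 0
        n_rep = 200
        for _ in range(n_rep):
            df = simulate_choices(session, ModelParams(), rng)
            tab = behavioral_glm(df)["choice"]
            n_sig += tab.loc["he_effort", "p"] < 0.05
        # binomial(200, 0.05) 99.9% upper bound ~ 0.10
        assert n_sig / n_rep <= 0.10

    def test_dt_regression_tracks_value_difference(self):
        from effortpath.cohort import DTParams, simulate_dt
        cfg = TaskConfig()
        session = generate_session(cfg, "physical", seed=61)
        rng = np.random.default_rng(62)
        dt_model = lambda dsv, r: simulate_dt(dsv, DTParams(b1=0.4), r)
        df = simulate_choices(session, ModelParams(kR=1.0, kEp=0.8), rng,
                              dt_model=dt_model)
        tab = behavioral_glm(df)["log_dt"]
        # higher incentive -> larger |dSV| on average -> faster choices
        assert tab.loc["he_incentive", "coef"] < 0
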