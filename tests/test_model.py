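"""Choice-model semantics: value differences, softmax, internal-state
dynamics, forward simulation, and modulator z-scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from effortpath.design import TaskConfig, Trial, generate_block, \
    generate_session
from effortpath.model import (InternalState, ModelParams, delta_sv,
                              p_high_effort, parametric_modulators,
                              simulate_choices, update_state)


def make_trial(domain="physical", valence="reward", inc=2, eff=2):
    return Trial(block_index=0, trial_index=0, domain=domain,
                 valence=valence, he_incentive=inc, he_effort=eff,
                 le_incentive=0, le_effort=0, side_of_he="left")


class TestDeltaSV:
    def test_zero_parameters_give_zero(self):
        assert delta_sv(make_trial(), ModelParams(), InternalState()) == 0.0

    def test_reward_benefit(self):
        p = ModelParams(kR=1.0)
        assert delta_sv(make_trial(inc=2, eff=1), p, InternalState()) == 2.0

    def test_fatigue_inflates_physical_cost(self):
        p = ModelParams(kEp=1.0, kFp=0.5)
        out = delta_sv(make_trial(valence="punishment", inc=1, eff=2), p,
                       InternalState(F=2.0))
        assert out == pytest.approx(-(1.0 + 0.5 * 2.0) * 2.0)

    def test_learning_deflates_mental_cost_with_floor(self):
        p = ModelParams(kEm=0.4, kLm=1.0)
        t = make_trial(domain="mental", eff=2)
        assert delta_sv(t, p, InternalState(L=0.2)) == \
            pytest.approx(-(0.4 - 0.2) * 2)
        # large learning cannot turn effort into a benefit
        assert delta_sv(t, p, InternalState(L=1.0)) == 0.0

    def test_monotone_in_incentive_and_effort(self):
        p = ModelParams(kR=0.7, kEp=0.9)
        s = InternalState()
        vals_inc = [delta_sv(make_trial(inc=i, eff=2), p, s) for i in (1, 2, 3)]
        vals_eff = [delta_sv(make_trial(inc=2, eff=e), p, s) for e in (1, 2, 3)]
        assert vals_inc == sorted(vals_inc)
        assert vals_eff == sorted(vals_eff, reverse=True)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(kR=-0.1)
        with pytest.raises(ValueError):
            ModelParams(kBias=float("nan"))


class TestSoftmax:
    def test_indifference(self):
        assert p_high_effort(0.0) == 0.5

    def test_closed_form_value(self):
        assert p_high_effort(2.0) == pytest.approx(0.8808, abs=5e-5)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-700, 700))
    def test_symmetry_and_bounds(self, x):
        p = float(p_high_effort(x))
        q = float(p_high_effort(-x))
        assert 0.0 <= p <= 1.0
        assert p + q == pytest.approx(1.0, abs=1e-12)


class TestInternalState:
    def test_le_choice_leaves_fatigue(self):
        s = update_state(InternalState(), make_trial(), "LE",
                         he_effort_max=3, trials_per_block=54)
        assert s.F == 0.0

    def test_full_block_of_maximal_effort_saturates_fatigue(self):
        s = InternalState()
        t = make_trial(eff=3)
        for _ in range(54):
            s = update_state(s, t, "HE", he_effort_max=3, trials_per_block=54)
        assert s.F == pytest.approx(1.0)

    def test_mental_block_learning_reaches_one(self):
        s = InternalState()
        t = make_trial(domain="mental")
        for _ in range(54):
            s = update_state(s, t, "LE", he_effort_max=3, trials_per_block=54)
        assert s.L == pytest.approx(1.0)
        assert s.F == 0.0


class TestSimulation:
    def test_strong_bias_saturates(self, session_blocks):
        rng = np.random.default_rng(0)
        df = simulate_choices(session_blocks, ModelParams(kBias=10.0), rng)
        assert df["choice"].mean() >= 0.99

    def test_indifferent_agent_near_half(self, session_blocks):
        rng = np.random.default_rng(1)
        df = simulate_choices(session_blocks, ModelParams(), rng)
        # binomial 99% CI half-width for n=216 at p=0.5 is ~0.088
        assert abs(df["choice"].mean() - 0.5) < 0.09
        assert np.allclose(df["p_he"], 0.5)

    def test_effort_sensitivity_coupling_monotone(self):
        """With a shared uniform stream, raising kEp can only flip HE
        choices to LE in the physical blocks, never the reverse."""
        cfg = TaskConfig()
        session = generate_session(cfg, "physical", seed=11)
        counts = []
        for kep in (0.2, 0.6, 1.0, 1.6):
            rng = np.random.default_rng(42)
            df = simulate_choices(
                session, ModelParams(kR=1.0, kEp=kep), rng)
            counts.append(
                int(df.loc[df["domain"] == "physical", "choice"].sum()))
        assert counts == sorted(counts, reverse=True)

    def test_state_free_model_order_invariant(self):
        """With kFp = 0, physical choice probabilities depend only on
        the trial's own attributes, not its position."""
        cfg = TaskConfig()
        block = generate_block("physical", cfg, seed=3)
        rng = np.random.default_rng(0)
        df = simulate_choices([block], ModelParams(kR=0.8, kEp=0.5), rng)
        by_cell = df.groupby(["valence", "he_incentive", "he_effort"])[
            "p_he"].nunique()
        assert (by_cell == 1).all()

    def test_simulation_frequency_matches_probability(self):
        """Repeating one trial many times, the HE frequency converges
        to the model probability."""
        cfg = TaskConfig()
        block = generate_block("physical", cfg, seed=9)
        params = ModelParams(kR=0.9, kEp=0.6)
        rng = np.random.default_rng(7)
        reps = [simulate_choices([block], params, rng) for _ in range(60)]
        df = reps[0]
        freq = np.mean([r["choice"].to_numpy() for r in reps], axis=0)
        # pooled Monte-Carlo tolerance: SE <= 0.5/sqrt(60) ~ 0.065
        assert np.abs(freq - df["p_he"].to_numpy()).mean() < 0.06

    def test_ech_consistent_with_choice(self, simulated_choices):
        df = simulated_choices
        he = df["chosen"] == "HE"
        assert (df.loc[he, "Ech"] == df.loc[he, "he_effort"]).all()
        assert (df.loc[~he, "Ech"] == 0).all()


class TestModulators:
    def test_zscore_identity_per_block(self, simulated_choices):
        df = simulated_choices.copy()
        df["DT"] = np.random.default_rng(0).lognormal(size=len(df))
        mods = parametric_modulators(df)
        for _, grp in mods.groupby("block_index"):
            for col in ("Ech", "DT"):
                assert abs(grp[col].mean()) < 1e-12
                assert abs(grp[col].std(ddof=1) - 1) < 1e-12

    def test_constant_column_becomes_zero_with_warning(self, simulated_choices):
        df = simulated_choices.copy()
        df["Ech"] = 2.0
        with pytest.warns(UserWarning, match="constant"):
            mods = parametric_modulators(df, columns=("Ech",))
        assert (mods["Ech"] == 0).all()

    def test_per_block_differs_from_global(self):
        import pandas as pd
        df = pd.DataFrame({
            "block_index": [0, 0, 1, 1],
            "trial_index": [0, 1, 0, 1],
            "Ech": [1.0, 2.0, 5.0, 9.0],
            "SVch": [0.0, 1.0, 0.0, 1.0],
            "DT": [1.0, 2.0, 3.0, 4.0],
        })
        per_block = parametric_modulators(df)
        global_z = parametric_modulators(df, by_block=False)
        assert not np.allclose(per_block["Ech"], global_z["Ech"])
        # two-point blocks z-score to -1/sqrt(2), +1/sqrt(2) regardless
        # of the block mean
        s = 1 / np.sqrt(2)
        assert np.allclose(per_block["Ech"], [-s, s, -s, s])

    def test_missed_trials_excluded(self, simulated_choices):
        df = simulated_choices.copy()
        df.loc[df.index[:5], "missed"] = True
        mods = parametric_modulators(df)
        assert len(mods) == len(df) - 5
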