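import numpy as np
import pandas as pd
import pytest

import speechmf as smf


class TestCascade:
    def test_uniform_weight_gives_flat_measure(self):
        flat = smf.binomial_cascade(smf.CascadeSpec(p=0.5, levels=8, seed=0))
        assert np.allclose(flat, 2.0**-8)

    @pytest.mark.parametrize("p, levels", [(0.7, 10), (0.3, 6), (0.91, 14)])
    def test_mass_conserved_and_positive(self, p, levels):
        cas = smf.binomial_cascade(smf.CascadeSpec(p=p, levels=levels, seed=4))
        assert cas.size == 2**levels
        assert np.all(cas > 0)
        assert cas.sum() == pytest.approx(1.0, abs=1e-12)

    def test_branch_order_seeded_but_mass_multiset_fixed(self):
        a = smf.binomial_cascade(smf.CascadeSpec(p=0.7, levels=8, seed=1))
        b = smf.binomial_cascade(smf.CascadeSpec(p=0.7, levels=8, seed=2))
        assert not np.array_equal(a, b)
        assert np.allclose(np.sort(a), np.sort(b))

    def test_degenerate_weight_rejected(self):
        with pytest.raises(ValueError):
            smf.CascadeSpec(p=1.0, levels=8)


class TestARControl:
    def test_white_noise_lag1_within_sampling_error(self):
        x = smf.linear_gaussian_control(4096, phi=0.0, seed=5)
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r1) < 3 / np.sqrt(4096)

    def test_ar08_lag1_in_band(self):
        x = smf.linear_gaussian_control(4096, phi=0.8, seed=6)
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert 0.7 < r1 < 0.9

    def test_deterministic(self):
        a = smf.linear_gaussian_control(128, phi=0.5, seed=7)
        b = smf.linear_gaussian_control(128, phi=0.5, seed=7)
        assert np.array_equal(a, b)

    def test_nonstationary_rejected(self):
        with pytest.raises(ValueError, match="stationarity"):
            smf.linear_gaussian_control(64, phi=1.0)


@pytest.fixture(scope="module")
def schedule():
    return smf.generate_trial_schedule(smf.BehaviorSimSpec(n_participants=6, seed=2))


class TestSchedule:
    def test_design_counts(self, schedule):
        per = schedule.groupby("participant")
        assert (per.size() == 176).all()
        assert (schedule.groupby(["participant", "step"]).size() == 16).all()
        assert (schedule.groupby(["participant", "precursor"]).size() == 88).all()

    def test_block_structure(self, schedule):
        blocks = schedule.groupby(["participant", "block"]).size()
        assert (blocks == 22).all()
        assert schedule["block"].max() == 8

    def test_counterbalancing_constant_within_participant(self, schedule):
        assert (schedule.groupby("participant")["cb"].nunique() == 1).all()
        assert set(schedule["cb"]) == {0, 1}

    def test_variant_only_for_simulated_speech(self, schedule):
        ss = schedule[schedule["context"] == "simulated_speech"]
        other = schedule[schedule["context"] != "simulated_speech"]
        assert ss["variant"].between(1, 8).all()
        assert (other["variant"] == 0).all()


class TestResponses:
    def test_null_model_gives_half_ga(self):
        spec = smf.BehaviorSimSpec(n_participants=10, seed=8)
        spec.coefficients = {k: 0.0 for k in spec.coefficients}
        trials = smf.simulate_responses(
            smf.generate_trial_schedule(spec), spec, smf.reference_token_covariates()
        )
        assert trials["ga_response"].mean() == pytest.approx(0.5, abs=0.05)

    def test_negative_step_slope_decreases_ga_across_continuum(self):
        spec = smf.BehaviorSimSpec(n_participants=42, seed=9)
        trials = smf.simulate_responses(
            smf.generate_trial_schedule(spec), spec, smf.reference_token_covariates()
        )
        by_step = trials.groupby("step")["ga_response"].mean()
        assert by_step.loc[0] > by_step.loc[10]

    def test_deterministic_given_spec_and_seed(self):
        spec = smf.BehaviorSimSpec(n_participants=3, seed=10)
        cov = smf.reference_token_covariates()
        a = smf.simulate_responses(smf.generate_trial_schedule(spec), spec, cov)
        b = smf.simulate_responses(smf.generate_trial_schedule(spec), spec, cov)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_covariates_reported(self):
        spec = smf.BehaviorSimSpec(n_participants=3, seed=10)
        cov = smf.reference_token_covariates().query("context != 'tone'")
        with pytest.raises(ValueError, match="missing covariates"):
            smf.simulate_responses(smf.generate_trial_schedule(spec), spec, cov)

    def test_rt_distribution_plausible(self):
        spec = smf.BehaviorSimSpec(n_participants=20, seed=11)
        trials = smf.simulate_responses(
            smf.generate_trial_schedule(spec), spec, smf.reference_token_covariates()
        )
        assert trials["rt"].mean() == pytest.approx(650, rel=0.05)
        lo, hi = np.percentile(trials["rt"], [5, 95])
        assert 350 < lo < 500
        assert 950 < hi < 1250


class TestTrajectories:
    def test_650ms_response_yields_38_samples(self):
        traj, _ = smf.simulate_trajectory({"rt": 650.0, "step": 0}, seed=0)
        assert len(traj) == 38  # round(0.650 * 58)

    def test_noise_free_straight_path(self):
        params = smf.TrajectoryParams(jitter_px=0.0)
        traj, k = smf.simulate_trajectory({"rt": 650.0, "step": 0}, params, seed=1)
        assert k == 0
        assert smf.x_position_flips(traj) == 0
        assert smf.max_displacement(traj) <= 1e-9

    @pytest.mark.parametrize("step, expected_k", [(5, 4), (3, 3), (0, 0)])
    def test_injected_reversals_equal_measured_flips(self, step, expected_k):
        params = smf.TrajectoryParams(jitter_px=0.0)
        traj, k = smf.simulate_trajectory({"rt": 650.0, "step": step}, params, seed=2)
        assert k == expected_k
        assert smf.x_position_flips(traj) == k

    def test_goal_follows_response_and_counterbalancing(self):
        params = smf.TrajectoryParams(jitter_px=0.0)
        ga_left, _ = smf.simulate_trajectory(
            {"rt": 650.0, "step": 0, "ga_response": 1, "cb": 0}, params, seed=3)
        ga_right, _ = smf.simulate_trajectory(
            {"rt": 650.0, "step": 0, "ga_response": 1, "cb": 1}, params, seed=3)
        assert ga_left.goal == params.goal_left
        assert ga_right.goal == params.goal_right

    def test_too_short_rt_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            smf.simulate_trajectory({"rt": 10.0, "step": 0}, seed=0)
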