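"""Tests of the session generator: trial statistics, spikes, LFP, hazard stops."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bartstop import synthetic_data as sd
from bartstop.hazard_model import normal_hazard


class TestGenerateTrials:
    def test_pop_time_moments_match_configured_distribution(self):
        cfg = sd.TaskConfig(
            risk_levels=[("red", 3.0, 0.9)],
            frac_forced=0.0,
            include_gray=False,
            n_trials=10_000,
            seed=1,
        )
        pop = sd.generate_trials(cfg)["t_pop_s"].to_numpy()
        # Monte-Carlo error of the mean is sd/sqrt(n) ~ 0.009
        assert abs(pop.mean() - 3.0) < 4 * 0.9 / np.sqrt(10_000)
        assert abs(pop.std() - 0.9) < 0.05

    def test_degenerate_sd_yields_constant_pop_times(self):
        cfg = sd.TaskConfig(
            risk_levels=[("red", 3.0, 1e-12)],
            frac_forced=0.0,
            include_gray=False,
            n_trials=50,
            seed=2,
        )
        pop = sd.generate_trials(cfg)["t_pop_s"].to_numpy()
        assert np.allclose(pop, 3.0, atol=1e-9)

    def test_forced_quota_is_exact(self):
        cfg = sd.TaskConfig(n_trials=1000, frac_forced=0.25, include_gray=False, seed=3)
        trials = sd.generate_trials(cfg)
        assert (trials["type"] == "forced").sum() == 250

    def test_gray_rings_drawn_from_source_distribution(self):
        cfg = sd.TaskConfig(n_trials=2000, frac_forced=0.0, frac_gray=0.5, seed=4)
        trials = sd.generate_trials(cfg)
        gray = trials.loc[trials["type"] == "gray"]
        assert (gray["risk"] == "orange").all()
        assert abs(gray["t_pop_s"].mean() - 6.5) < 0.2

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sd.generate_trials(sd.TaskConfig(n_trials=0))
        with pytest.raises(KeyError):
            sd.generate_trials(sd.TaskConfig(gray_ring_source="purple", n_trials=10))
        with pytest.raises(ValueError):
            sd.TaskConfig(risk_levels=[("red", -1.0, 0.9)])
        with pytest.raises(ValueError):
            sd.TaskConfig(frac_forced=1.5)

    def test_start_times_strictly_increasing_with_gaps(self):
        cfg = sd.TaskConfig(n_trials=50, seed=5, iti_s=2.0)
        trials = sd.generate_trials(cfg)
        starts = trials["t_start_s"].to_numpy()
        ends = starts + trials["t_pop_s"].to_numpy()
        assert np.all(starts[1:] >= ends[:-1] + 2.0 - 1e-9)


class TestAgentStops:
    def test_banked_and_popped_rules(self, small_config):
        trials = sd.generate_trials(small_config)
        done = sd.simulate_agent_stops(trials, sd.AgentPolicy(), small_config, seed=6)
        free = done[done["type"] == "free"]
        banked = free[free["outcome"] == "banked"]
        popped = free[free["outcome"] == "popped"]
        assert np.allclose(
            banked["points"], small_config.reward_rate * banked["t_stop_s"]
        )
        assert (popped["points"] == 0).all()
        assert popped["t_stop_s"].isna().all()
        # banked stops precede the pop
        assert (banked["t_stop_s"] < banked["t_pop_s"]).all()

    def test_control_trial_outcomes(self, small_config):
        trials = sd.generate_trials(small_config)
        done = sd.simulate_agent_stops(trials, sd.AgentPolicy(), small_config, seed=7)
        forced = done[done["type"] == "forced"]
        gray = done[done["type"] == "gray"]
        assert (forced["outcome"] == "banked").all()
        assert np.allclose(
            forced["points"], small_config.reward_rate * forced["t_pop_s"]
        )
        assert (gray["points"] == 0).all()

    def test_cautious_policy_rarely_pops(self):
        # stopping at 1.0 +/- 0.1 s against a pop at 3.0 +/- 0.9 s: the pop
        # probability is the normal tail P(pop < stop) ~ Phi(-2.2) ~ 0.014
        cfg = sd.TaskConfig(
            risk_levels=[("red", 3.0, 0.9)],
            frac_forced=0.0,
            include_gray=False,
            n_trials=2000,
            seed=8,
        )
        policy = sd.AgentPolicy(targets={"red": (1.0, 0.1)}, reaction_jitter_s=0.0)
        done = sd.simulate_agent_stops(sd.generate_trials(cfg), policy, cfg, seed=9)
        frac_pop = (done["outcome"] == "popped").mean()
        assert frac_pop < 0.03

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_points_identity_property(self, seed):
        cfg = sd.TaskConfig(n_trials=30, seed=seed % 100)
        done = sd.simulate_agent_stops(
            sd.generate_trials(cfg), sd.AgentPolicy(), cfg, seed=seed
        )
        banked = done[done["outcome"] == "banked"]
        assert np.allclose(banked["points"], cfg.reward_rate * banked["t_stop_s"])
        assert (done.loc[done["outcome"] != "banked", "points"] == 0).all()


class TestSimulateSpikes:
    def test_constant_rate_unit(self, small_config):
        trials = sd.simulate_agent_stops(
            sd.generate_trials(small_config), sd.AgentPolicy(), small_config, seed=10
        )
        params = sd.NeuralGenParams(glm_truth=sd.GlmTruth(beta0=np.log(10.0)))
        spikes = sd.simulate_spikes(trials, params, seed=11)
        rate = list(spikes.rates().values())[0]
        assert abs(rate - 10.0) < 0.5

    def test_positive_gamma_raises_late_trial_rate(self):
        cfg = sd.TaskConfig(n_trials=300, frac_forced=0.0, include_gray=False, seed=12)
        trials = sd.simulate_agent_stops(sd.generate_trials(cfg), sd.AgentPolicy(), cfg, seed=13)
        params = sd.NeuralGenParams(
            glm_truth=sd.GlmTruth(beta0=np.log(10.0), gamma=0.5)
        )
        spikes = sd.simulate_spikes(trials, params, bin_s=0.05, seed=14)
        ts = list(spikes.timestamps.values())[0]
        early = late = 0.0
        n_early = n_late = 0
        for row in trials.itertuples(index=False):
            if row.outcome != "banked" or row.t_stop_s < 2.0:
                continue
            t0 = row.t_start_s
            early += np.sum((ts >= t0) & (ts < t0 + 1.0))
            late += np.sum((ts >= t0 + row.t_stop_s - 1.0) & (ts < t0 + row.t_stop_s))
            n_early += 1
            n_late += 1
        assert late / n_late > early / n_early

    def test_rate_overflow_reported(self, small_config):
        trials = sd.simulate_agent_stops(
            sd.generate_trials(small_config), sd.AgentPolicy(), small_config, seed=15
        )
        params = sd.NeuralGenParams(glm_truth=sd.GlmTruth(beta0=20.0))
        with pytest.raises(FloatingPointError):
            sd.simulate_spikes(trials, params, seed=16)


class TestSimulateLfp:
    def test_deterministic_given_seed(self, small_session):
        params = small_session["params"]
        a = sd.simulate_lfp(small_session["trials"], params, seed=20)
        b = sd.simulate_lfp(small_session["trials"], params, seed=20)
        assert np.array_equal(a.data, b.data)

    def test_band_center_above_nyquist_rejected(self, small_session):
        params = sd.NeuralGenParams(
            lfp_bands=[sd.LfpBandTruth("hf", 90.0)], fs_hz=1000.0
        )
        params.fs_hz = 150.0  # post-validation tweak to hit the runtime check
        with pytest.raises(ValueError):
            sd.simulate_lfp(small_session["trials"], params, seed=21)


class TestSimulateHazardStops:
    @staticmethod
    def _discrete_law_cdf(m, s, dt, n_bins):
        """Implied event-time CDF of the discrete-time thinning generator."""
        t = (np.arange(n_bins) + 0.5) * dt
        p = np.clip(normal_hazard(t, m, s) * dt, 0, 1)
        surv = np.cumprod(1 - p)
        pmf = p * np.concatenate([[1.0], surv[:-1]])
        return t, np.cumsum(pmf)

    def test_stop_times_follow_implied_event_law(self):
        cfg = sd.TaskConfig(
            risk_levels=[("red", 3.0, 0.9)],
            frac_forced=0.0,
            include_gray=False,
            n_trials=5000,
            seed=30,
        )
        trials = sd.generate_trials(cfg)
        trials["t_pop_s"] = 8.0  # effectively never pops (z = 5.6)
        truth = sd.HazardTruth(m_s={"red": 3.0}, s_s={"red": 0.9})
        done = sd.simulate_hazard_stops(trials, truth, cfg, fs_hz=40, seed=31)
        st_ = done.loc[done["outcome"] == "banked", "t_stop_s"].to_numpy()
        assert len(st_) == 5000
        t, cdf = self._discrete_law_cdf(3.0, 0.9, 1 / 40, 320)
        emp = np.searchsorted(np.sort(st_), t, side="right") / len(st_)
        # Kolmogorov-Smirnov distance against the exact discrete oracle
        assert np.max(np.abs(emp - cdf)) < 1.5 * 1.36 / np.sqrt(len(st_))

    def test_halving_dt_leaves_distribution_stable(self):
        cfg = sd.TaskConfig(
            risk_levels=[("red", 3.0, 0.9)],
            frac_forced=0.0,
            include_gray=False,
            n_trials=3000,
            seed=32,
        )
        trials = sd.generate_trials(cfg)
        trials["t_pop_s"] = 8.0
        truth = sd.HazardTruth(m_s={"red": 3.0}, s_s={"red": 0.9})
        a = sd.simulate_hazard_stops(trials, truth, cfg, fs_hz=40, seed=33)
        b = sd.simulate_hazard_stops(trials, truth, cfg, fs_hz=80, seed=34)
        sa = a.loc[a["outcome"] == "banked", "t_stop_s"]
        sb = b.loc[b["outcome"] == "banked", "t_stop_s"]
        assert abs(sa.mean() - sb.mean()) < 0.06
        assert abs(sa.std() - sb.std()) < 0.06

    def test_regressor_spike_concentrates_stops(self):
        cfg = sd.TaskConfig(
            risk_levels=[("yellow", 10.0, 3.0)],
            frac_forced=0.0,
            include_gray=False,
            n_trials=500,
            seed=35,
        )
        trials = sd.generate_trials(cfg)
        trials["t_pop_s"] = 12.0
        fs = 40.0
        n_bins = int(12.0 * fs) + 2
        x = np.zeros((n_bins, 1))
        # regressor pulse just after 2 s
        x[int(2.0 * fs) : int(2.4 * fs)] = 1.0
        regs = {int(tid): x for tid in trials["trial_id"]}
        truth = sd.HazardTruth(
            m_s={"yellow": 10.0}, s_s={"yellow": 3.0}, beta=np.array([4.0])
        )
        done = sd.simulate_hazard_stops(
            trials, truth, cfg, regressors=regs, fs_hz=fs, seed=36
        )
        st_ = done.loc[done["outcome"] == "banked", "t_stop_s"]
        in_pulse = ((st_ >= 2.0) & (st_ < 2.5)).mean()
        null = sd.simulate_hazard_stops(
            trials, sd.HazardTruth(m_s={"yellow": 10.0}, s_s={"yellow": 3.0}),
            cfg, fs_hz=fs, seed=36,
        )
        st0 = null.loc[null["outcome"] == "banked", "t_stop_s"]
        in_pulse_null = ((st0 >= 2.0) & (st0 < 2.5)).mean()
        # stops concentrate just after 2 s relative to the no-covariate model
        assert in_pulse > 10 * max(in_pulse_null, 1e-3)

    def test_unstable_discretization_aborts_with_guidance(self):
        cfg = sd.TaskConfig(
            risk_levels=[("red", 0.5, 0.05)],
            frac_forced=0.0,
            include_gray=False,
            n_trials=50,
            seed=37,
        )
        trials = sd.generate_trials(cfg)
        trials["t_pop_s"] = 3.0
        truth = sd.HazardTruth(m_s={"red": 0.5}, s_s={"red": 0.05})
        with pytest.raises(ValueError, match="reduce dt"):
            sd.simulate_hazard_stops(trials, truth, cfg, fs_hz=40, seed=38)
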