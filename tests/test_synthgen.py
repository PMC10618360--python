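"""Generator-level tests: fixation-preference map, race, rate profile,
spike sampling, eye kinematics and session assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

import scchoice as sc
from scchoice.config import (
    FixationMapConfig,
    GeometryConfig,
    NeuronProfile,
    RaceConfig,
    SaccadeKinematics,
    TaskConfig,
)
from scchoice.errors import (
    InvalidConfigError,
    InvalidProfileError,
    InvalidTargetError,
    MalformedTrialError,
    NoChoiceError,
)
from scchoice.synthgen import (
    fixation_preference_map,
    make_session,
    rate_profile,
    sample_spikes,
    simulate_race,
    simulate_trial_eyes,
)


# ---------------------------------------------------------------------------
# fixation-preference map
# ---------------------------------------------------------------------------

class TestFixationPreferenceMap:
    def test_sharp_border_saturates(self):
        geom = GeometryConfig(h_deviation=30.0)
        cfg = FixationMapConfig(border_slope=float("inf"))
        df = fixation_preference_map(geom, cfg, TaskConfig())
        at = lambda h, v: df[(df.h == h) & (df.v == v)].p_right.iloc[0]
        # left of the left eye's line of sight: always the left eye
        assert at(-20.0, 0.0) == 0.0
        assert at(-30.0, 10.0) == 0.0
        # right of the right eye's line of sight: always the right eye
        assert at(30.0, 0.0) == 1.0

    def test_midpoint_is_even_odds(self):
        geom = GeometryConfig(h_deviation=30.0)
        task = TaskConfig(grid_h=(0.0, 15.0, 30.0), grid_v=(0.0,))
        df = fixation_preference_map(geom, FixationMapConfig(), task)
        assert df[(df.h == 15.0)].p_right.iloc[0] == pytest.approx(0.5)

    def test_matches_pointwise_sigmoid_oracle(self):
        geom = GeometryConfig(h_deviation=20.0)
        cfg = FixationMapConfig(border_slope=0.5)
        task = TaskConfig()
        df = fixation_preference_map(geom, cfg, task)
        for _, row in df.iterrows():
            assert row.p_right == pytest.approx(
                expit(0.5 * (row.h - 10.0)), abs=1e-12
            )

    def test_saturation_beyond_lines_of_sight(self):
        geom = GeometryConfig(h_deviation=30.0)
        df = fixation_preference_map(geom, FixationMapConfig(), TaskConfig())
        assert (df[df.h <= 0.0].p_right <= 0.05).all()
        assert (df[df.h >= 30.0].p_right >= 0.95).all()

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        h_dev=st.floats(5.0, 40.0),
        slope=st.floats(0.05, 5.0),
        offset=st.floats(-5.0, 5.0),
    )
    def test_monotone_in_horizontal_position(self, h_dev, slope, offset):
        geom = GeometryConfig(h_deviation=h_dev)
        cfg = FixationMapConfig(border_slope=slope, border_offset=offset)
        df = fixation_preference_map(geom, cfg, TaskConfig())
        for v, sub in df.groupby("v"):
            p = sub.sort_values("h").p_right.to_numpy()
            assert (np.diff(p) >= -1e-12).all()

    def test_empty_grid_rejected(self):
        with pytest.raises(InvalidConfigError):
            TaskConfig(grid_h=(), grid_v=(0.0,))


# ---------------------------------------------------------------------------
# race model
# ---------------------------------------------------------------------------

class TestRace:
    def test_equal_drives_are_even(self, rng):
        race = RaceConfig()
        wins = sum(
            simulate_race(race, 1.0, 1.0, rng)[0] == "A" for _ in range(400)
        )
        assert abs(wins / 400 - 0.5) < 0.09  # ~3.5 sigma binomial band

    def test_total_suppression_is_deterministic(self, rng):
        race = RaceConfig(suppression=1.0)
        drive_b = 1.0 * (1.0 - race.suppression)
        for _ in range(25):
            winner, _ = simulate_race(race, 1.0, drive_b, rng)
            assert winner == "A"

    def test_matches_independent_monte_carlo_oracle(self, rng):
        """Win probability agrees with a plain two-accumulator simulation."""
        race = RaceConfig()
        n = 1000
        wins = sum(
            simulate_race(race, 1.0, 0.85, rng)[0] == "A" for _ in range(n)
        )

        # independent oracle: naive per-step loop, separate generator
        orng = np.random.default_rng(987)
        oracle_wins = 0
        for _ in range(n):
            xa = xb = 0.0
            for _step in range(450):
                xa += 1.0 / race.latency_scale_ms + orng.normal(
                    0, race.drift_noise_sd
                )
                xb += 0.85 / race.latency_scale_ms + orng.normal(
                    0, race.drift_noise_sd
                )
                if xa >= race.threshold or xb >= race.threshold:
                    oracle_wins += xa >= xb
                    break
            else:
                oracle_wins += xa >= xb
        # binomial SE of the difference ~ 0.02; allow ~4 sigma
        assert abs(wins / n - oracle_wins / n) < 0.08

    def test_latency_is_plausible(self, rng):
        race = RaceConfig()
        lats = [simulate_race(race, 1.0, 1.0, rng)[1] for _ in range(200)]
        assert 120 < np.median(lats) < 240

    def test_zero_drives_rejected(self, rng):
        with pytest.raises(NoChoiceError):
            simulate_race(RaceConfig(), 0.0, 0.0, rng)


# ---------------------------------------------------------------------------
# rate profile
# ---------------------------------------------------------------------------

EVENTS = {"target_on": 500.0, "go": 1500.0, "saccade_onset": 1680.0}


class TestRateProfile:
    def test_baseline_before_target_onset(self):
        neuron = NeuronProfile()
        fn = rate_profile(neuron, EVENTS, won=True, gain=1.0, race=RaceConfig())
        t = np.arange(0.0, 400.0)
        assert np.allclose(fn(t), neuron.baseline_hz, atol=1e-6)

    def test_lost_trials_have_no_burst(self):
        neuron = NeuronProfile()
        race = RaceConfig()
        fn = rate_profile(neuron, EVENTS, won=False, gain=1.0, race=race)
        t_sac = EVENTS["saccade_onset"]
        peri = fn(np.arange(t_sac - 50, t_sac + 50))
        buildup_level = (
            neuron.baseline_hz
            + neuron.buildup_slope_hz_per_s
            / 1000.0
            * (t_sac - race.divergence_ms - EVENTS["target_on"]
               - neuron.buildup_onset_ms)
        )
        assert peri.max() <= buildup_level + 1e-9

    def test_visual_peak_closed_form(self):
        """Peak of the suppressed transient = baseline + (1-s) * amplitude."""
        neuron = NeuronProfile()
        race = RaceConfig(suppression=0.15)
        fn = rate_profile(
            neuron, EVENTS, won=True, gain=1.0, race=race, suppressed=True
        )
        t_vis = EVENTS["target_on"] + neuron.visual_latency_ms
        expected = neuron.baseline_hz + 0.85 * neuron.visual_amp_hz
        assert fn(np.array([t_vis]))[0] == pytest.approx(expected, rel=1e-9)

    def test_missing_event_rejected(self):
        with pytest.raises(MalformedTrialError):
            rate_profile(
                NeuronProfile(), {"target_on": 500.0}, True, 1.0, RaceConfig()
            )

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        baseline=st.floats(0.0, 50.0),
        vamp=st.floats(0.0, 400.0),
        slope=st.floats(0.0, 400.0),
        mamp=st.floats(0.0, 800.0),
        coupling=st.floats(0.0, 3.0),
        gain=st.floats(0.2, 3.0),
        won=st.booleans(),
        suppressed=st.booleans(),
        latency=st.floats(80.0, 280.0),
    )
    def test_rate_never_negative(
        self, baseline, vamp, slope, mamp, coupling, gain, won, suppressed,
        latency,
    ):
        neuron = NeuronProfile(
            baseline_hz=baseline,
            visual_amp_hz=vamp,
            buildup_slope_hz_per_s=slope,
            motor_amp_hz=mamp,
            race_coupling=coupling,
        )
        events = dict(EVENTS, saccade_onset=1500.0 + latency)
        fn = rate_profile(neuron, events, won, gain, RaceConfig(), suppressed)
        rates = fn(np.arange(0.0, 2000.0, 0.5))
        assert np.all(rates >= 0.0)
        assert np.all(np.isfinite(rates))


# ---------------------------------------------------------------------------
# spike sampling
# ---------------------------------------------------------------------------

class TestSampleSpikes:
    def test_zero_rate_gives_empty_train(self, rng):
        out = sample_spikes(lambda t: np.zeros_like(t), (0.0, 1000.0), rng)
        assert out.size == 0

    def test_poisson_moments_at_constant_rate(self):
        counts = [
            sample_spikes(
                lambda t: np.full_like(t, 100.0),
                (0.0, 1000.0),
                np.random.default_rng(seed),
            ).size
            for seed in range(300)
        ]
        assert np.mean(counts) == pytest.approx(100.0, abs=3.0)
        assert np.var(counts) == pytest.approx(100.0, rel=0.35)

    def test_sorted_within_range(self, rng):
        out = sample_spikes(
            lambda t: np.full_like(t, 80.0), (200.0, 1400.0), rng
        )
        assert np.all(np.diff(out) >= 0)
        assert out.min() >= 200.0 and out.max() <= 1400.0

    def test_piecewise_counts_match_direct_poisson_draws(self):
        """Thinning counts per piece are distributed as direct Poisson draws."""
        from scipy.stats import ks_2samp

        def fn(t):
            return np.where(np.asarray(t) < 500.0, 50.0, 150.0)

        lo, hi = [], []
        for seed in range(200):
            train = sample_spikes(fn, (0.0, 1000.0), np.random.default_rng(seed))
            lo.append(np.sum(train < 500.0))
            hi.append(np.sum(train >= 500.0))
        orng = np.random.default_rng(123)
        ks_lo = ks_2samp(lo, orng.poisson(25.0, 200))
        ks_hi = ks_2samp(hi, orng.poisson(75.0, 200))
        assert ks_lo.pvalue > 1e-3
        assert ks_hi.pvalue > 1e-3

    def test_unbounded_rate_rejected(self, rng):
        with pytest.raises(InvalidProfileError):
            sample_spikes(
                lambda t: 1.0 / np.maximum(np.asarray(t), 1e-12),
                (0.0, 1000.0),
                rng,
            )


# ---------------------------------------------------------------------------
# eye kinematics
# ---------------------------------------------------------------------------

class TestTrialEyes:
    def _clean(self):
        geom = GeometryConfig(noise_sd=0.0, drift_sd=0.0)
        kin = SaccadeKinematics(endpoint_noise_frac=0.0)
        return geom, TaskConfig(), kin

    def test_no_switch_landing_geometry(self, rng):
        geom, task, kin = self._clean()
        time_ms, eyes, _ = simulate_trial_eyes(
            geom, task, kin, "L", "L", (0.0, 10.0), 150.0, rng
        )
        assert np.allclose(eyes[-1, 0:2], [0.0, 10.0], atol=1e-6)
        assert np.allclose(
            eyes[-1, 2:4],
            [0.0 + geom.h_deviation, 10.0 + geom.v_deviation],
            atol=1e-6,
        )

    def test_conjugacy_with_zero_noise(self, rng):
        geom, task, kin = self._clean()
        _, eyes, _ = simulate_trial_eyes(
            geom, task, kin, "L", "R", (20.0, 10.0), 200.0, rng
        )
        diff = eyes[:, 0:2] - eyes[:, 2:4]
        assert np.allclose(diff, diff[0], atol=1e-9)

    def test_detector_recovers_injected_onset(self, rng):
        from scchoice.eyemoves import detect_saccades

        geom, task, kin = self._clean()
        time_ms, eyes, _ = simulate_trial_eyes(
            geom, task, kin, "L", "L", (0.0, 10.0), 150.0, rng
        )
        sacs = detect_saccades(time_ms, eyes[:, 0], eyes[:, 1])
        assert len(sacs) == 1
        assert abs(sacs[0].onset_ms - 1650.0) <= 5.0
        assert sacs[0].amplitude_deg == pytest.approx(10.0, abs=0.1)

    def test_off_grid_target_rejected(self, rng):
        geom, task, kin = self._clean()
        with pytest.raises(InvalidTargetError):
            simulate_trial_eyes(
                geom, task, kin, "L", "L", (15.0, 10.0), 150.0, rng
            )


# ---------------------------------------------------------------------------
# session assembly
# ---------------------------------------------------------------------------

class TestMakeSession:
    def test_two_target_locations(self):
        cfg = sc.RunConfig.defaults_for(
            "two-target", seed=2, n_cells=1, trials_per_cell=10
        )
        session = make_session(cfg)
        targets = {t.target for t in session.all_trials()}
        # fixating-eye RF (0,10) and the equivalent deviated-eye LED,
        # offset horizontally by the 30 deg deviation
        assert targets == {(0.0, 10.0), (30.0, 10.0)}

    def test_seeded_determinism(self):
        cfg = sc.RunConfig.defaults_for(
            "one-target", seed=9, n_cells=2, trials_per_cell=6
        )
        s1, s2 = make_session(cfg), make_session(cfg)
        for t1, t2 in zip(s1.all_trials(), s2.all_trials()):
            assert np.array_equal(t1.eyes, t2.eyes)
            assert np.array_equal(t1.spikes, t2.spikes)
            assert t1.truth.to_dict() == t2.truth.to_dict()

    def test_symmetric_race_switches_half_the_time(self):
        cfg = sc.RunConfig.defaults_for(
            "one-target", seed=4, n_cells=1, trials_per_cell=240
        )
        cfg = cfg.model_copy(
            update={"race": cfg.race.model_copy(update={"suppression": 0.0})}
        )
        session = make_session(cfg)
        frac = np.mean([t.truth.switch for t in session.all_trials()])
        assert abs(frac - 0.5) < 0.12  # ~3.5 sigma binomial band at n=240

    def test_selection_effect_on_sensory_drive(self):
        """Won trials carry higher neuron-side sensory drive than lost trials."""
        cfg = sc.RunConfig.defaults_for(
            "one-target", seed=6, n_cells=1, trials_per_cell=200
        )
        session = make_session(cfg)
        drives = {True: [], False: []}
        for t in session.all_trials():
            d = t.truth.gain_a * (
                1.0 - cfg.race.suppression * (t.truth.suppressed_side == "A")
            )
            drives[t.truth.winner == "neuron"].append(d)
        assert np.mean(drives[True]) > np.mean(drives[False])
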