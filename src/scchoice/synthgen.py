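"""Generative model of strabismic delayed-saccade sessions.

The generator composes four ingredients with known ground truth:

* binocular geometry — a fixating eye on the central LED and a deviated
  fellow eye offset by the ocular deviation, moving conjugately;
* a spatial fixation-preference map — a sigmoid in horizontal target
  position across a border midway between the two lines of sight;
* a two-accumulator race that decides, trial by trial, which saccade
  vector (and hence which eye) acquires the target, with interocular
  suppression attenuating the sensory drive of one side per trial;
* a visuomotor rate profile (baseline, visual transient, buildup ramp,
  motor burst) whose trial-to-trial amplitude covaries with the race
  outcome, sampled into spikes by thinning.

All times are in ms from trial start; rates in spikes/s; positions in
degrees (positive rightward / upward).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import (
    FixationMapConfig,
    GeometryConfig,
    NeuronProfile,
    PopulationSpec,
    RaceConfig,
    RunConfig,
    SaccadeKinematics,
    TaskConfig,
)
from .errors import (
    InfeasibleGeometryError,
    InvalidConfigError,
    InvalidProfileError,
    InvalidTargetError,
    MalformedTrialError,
    NoChoiceError,
)
from .session import Cell, GroundTruth, Session, Trial

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# fixation-preference map
# ---------------------------------------------------------------------------

def fixation_preference_map(
    geometry: GeometryConfig,
    map_cfg: FixationMapConfig,
    task: TaskConfig,
) -> pd.DataFrame:
    """Probability that the deviated (right) eye acquires each grid target.

    The left eye is assumed fixating at the grid center, so its line of
    sight is at 0 deg and the deviated right eye's is at ``+h_deviation``.
    Preference follows a sigmoid across a vertical border at the midpoint
    of the two lines of sight (plus ``border_offset``): targets well left
    of the left eye's line of sight are always acquired by the left eye
    and targets well right of the right eye's by the right eye.

    Returns a tidy frame with columns ``h``, ``v``, ``p_right``.
    """
    if len(task.grid_h) == 0 or len(task.grid_v) == 0:
        raise InvalidConfigError("target grid is empty")
    border = geometry.h_deviation / 2.0 + map_cfg.border_offset
    rows = []
    for v in task.grid_v:
        for h in task.grid_h:
            if math.isinf(map_cfg.border_slope):
                p = 0.5 if h == border else float(h > border)
            else:
                p = float(expit(map_cfg.border_slope * (h - border)))
            rows.append({"h": h, "v": v, "p_right": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# race model
# ---------------------------------------------------------------------------

@dataclass
class RaceOutcome:
    winner: str  # 'A' or 'B'
    latency_ms: float
    gain_a: float
    gain_b: float


def simulate_race(
    race: RaceConfig,
    sensory_drive_a: float,
    sensory_drive_b: float,
    rng: np.random.Generator,
    max_ms: int = 450,
) -> Tuple[str, float]:
    """Race two noisy accumulators to threshold.

    Each accumulator integrates ``drive / latency_scale_ms`` per ms plus
    zero-mean Gaussian noise of standard deviation ``drift_noise_sd`` per
    sqrt(ms).  The first to reach ``threshold`` wins; its crossing time is
    the saccade latency.  If neither crosses within ``max_ms`` the larger
    accumulator wins with latency ``max_ms`` (the response-window deadline).
    """
    if sensory_drive_a < 0 or sensory_drive_b < 0:
        raise NoChoiceError("sensory drives must be >= 0")
    if sensory_drive_a == 0 and sensory_drive_b == 0:
        raise NoChoiceError("both sensory drives are zero; trial is invalid")
    drives = np.array([sensory_drive_a, sensory_drive_b]) / race.latency_scale_ms
    steps = rng.standard_normal((max_ms, 2)) * race.drift_noise_sd + drives
    paths = np.cumsum(steps, axis=0)
    crossed = paths >= race.threshold
    first = np.where(crossed.any(axis=0), crossed.argmax(axis=0), max_ms)
    if first[0] == first[1]:
        if first[0] >= max_ms:  # deadline: larger accumulator wins
            winner = 0 if paths[-1, 0] >= paths[-1, 1] else 1
            return ("A" if winner == 0 else "B"), float(max_ms)
        winner = 0 if paths[first[0], 0] >= paths[first[1], 1] else 1
    else:
        winner = int(np.argmin(first))
    return ("A" if winner == 0 else "B"), float(first[winner] + 1)


# ---------------------------------------------------------------------------
# visuomotor rate profile
# ---------------------------------------------------------------------------

def rate_profile(
    neuron: NeuronProfile,
    events: Dict[str, float],
    won: bool,
    gain: float,
    race: RaceConfig,
    suppressed: bool = False,
) -> Callable[[np.ndarray], np.ndarray]:
    """Closed-form firing-rate profile (spikes/s) for one trial.

    Baseline before target onset; a Gaussian visual transient peaking
    ``visual_latency_ms`` after target onset, scaled by ``gain`` and by
    ``(1 - suppression)`` when the trial's sensory drive was the
    suppressed one; a linear buildup ramp from ``buildup_onset_ms`` after
    target onset toward saccade onset; then either a motor burst centered
    at saccade onset (won trials) or an exponential decay of buildup
    starting ``divergence_ms`` before saccade onset with no burst (lost
    trials).  The burst's rising flank broadens with the cell's
    ``race_coupling`` — strongly race-coupled cells accelerate into the
    burst earlier — while the losing-side decay rate scales with the same
    coupling.  The returned callable is vectorized over time and
    everywhere >= 0.
    """
    if gain <= 0:
        raise MalformedTrialError("gain must be > 0")
    for key in ("target_on", "saccade_onset"):
        if key not in events:
            raise MalformedTrialError(f"missing event {key!r}")
    t_target = events["target_on"]
    t_sac = events["saccade_onset"]
    s = race.suppression if suppressed else 0.0
    c = neuron.race_coupling
    t_vis = t_target + neuron.visual_latency_ms
    t_bu = t_target + neuron.buildup_onset_ms
    t_div = t_sac - race.divergence_ms
    slope = neuron.buildup_slope_hz_per_s / 1000.0  # Hz per ms
    tau = race.decay_tau_ms
    sigma_rise = neuron.motor_sigma_ms * (1.0 + race.rise_widening * c)
    post_tau = 20.0  # ms, post-saccade collapse of buildup on won trials

    def rate(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, neuron.baseline_hz)
        # visual transient
        out += (
            neuron.visual_amp_hz
            * gain
            * (1.0 - s)
            * np.exp(-0.5 * ((t - t_vis) / neuron.visual_sigma_ms) ** 2)
        )
        # buildup ramp
        ramp = np.clip(t - t_bu, 0.0, None) * slope * gain
        if won:
            # winning-side prelude accelerates from the divergence time
            boost = 1.0 + race.winner_boost * c * (
                1.0 - np.exp(-np.clip(t - t_div, 0.0, None) / tau)
            )
            boost_at_sac = 1.0 + race.winner_boost * c * (
                1.0 - math.exp(-max(t_sac - t_div, 0.0) / tau)
            )
            bu = np.where(
                t <= t_sac,
                ramp * boost,
                slope * gain * max(t_sac - t_bu, 0.0) * boost_at_sac
                * np.exp(-np.clip(t - t_sac, 0.0, None) / post_tau),
            )
            # motor burst peaking mid-saccade: broadened rising flank,
            # standard falling flank
            t_burst = t_sac + neuron.burst_peak_offset_ms
            sig = np.where(t < t_burst, sigma_rise, neuron.motor_sigma_ms)
            out += neuron.motor_amp_hz * gain * np.exp(
                -0.5 * ((t - t_burst) / sig) ** 2
            )
        else:
            frozen = slope * gain * max(t_div - t_bu, 0.0)
            bu = np.where(
                t < t_div,
                ramp,
                frozen * np.exp(-c * np.clip(t - t_div, 0.0, None) / tau),
            )
        out += bu
        return np.clip(out, 0.0, None)

    return rate


# ---------------------------------------------------------------------------
# inhomogeneous Poisson sampling by thinning
# ---------------------------------------------------------------------------

def sample_spikes(
    rate_fn: Callable[[np.ndarray], np.ndarray],
    t_range: Tuple[float, float],
    rng: np.random.Generator,
    rate_max: Optional[float] = None,
) -> np.ndarray:
    """Sample an inhomogeneous Poisson spike train by thinning.

    Candidates are drawn homogeneously at ``rate_max`` and accepted with
    probability ``rate(t)/rate_max``, so the expected count equals the
    integral of the rate.  ``rate_max`` defaults to a fine-grid maximum of
    the profile with a small safety margin.
    """
    t0, t1 = t_range
    if t1 <= t0:
        raise InvalidProfileError("empty time range")
    if rate_max is None:
        grid = np.arange(t0, t1 + 0.25, 0.5)
        vals = np.asarray(rate_fn(grid), dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise InvalidProfileError("rate must be finite and >= 0")
        rate_max = float(vals.max()) * 1.02 + 1e-9
    if not np.isfinite(rate_max) or rate_max > 1e5:
        raise InvalidProfileError("rate profile is unbounded")
    if rate_max <= 0:
        return np.empty(0)
    duration_s = (t1 - t0) / 1000.0
    n_cand = rng.poisson(rate_max * duration_s)
    if n_cand == 0:
        return np.empty(0)
    times = rng.uniform(t0, t1, size=n_cand)
    accept = rng.uniform(0.0, rate_max, size=n_cand) < np.asarray(
        rate_fn(times), dtype=float
    )
    return np.sort(times[accept])


# ---------------------------------------------------------------------------
# eye kinematics
# ---------------------------------------------------------------------------

def minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile on tau in [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def simulate_trial_eyes(
    geometry: GeometryConfig,
    task: TaskConfig,
    kin: SaccadeKinematics,
    fixating_eye: str,
    acquiring_eye: str,
    target: Tuple[float, float],
    latency_ms: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray, Dict[str, float]]:
    """Binocular position traces for one trial.

    The fixating eye starts on the central LED; the deviated eye is offset
    temporally by the ocular deviation (plus a slow random-walk drift).
    At ``go + latency`` both eyes make a conjugate minimum-jerk saccade
    whose vector brings the acquiring eye onto the target; the fellow eye
    makes the same-amplitude movement, preserving conjugacy.

    Returns ``(time_ms, eyes, events)`` where ``eyes`` has columns
    lh, lv, rh, rv.
    """
    if not task.on_grid(*target):
        raise InvalidTargetError(f"target {target} not on the LED grid")
    dt = 1000.0 / task.sample_rate_hz
    n = int(round(task.trial_len_ms / dt)) + 1
    time_ms = np.arange(n) * dt

    dev_sign = 1.0 if fixating_eye == "L" else -1.0
    deviation = np.array([dev_sign * geometry.h_deviation,
                          dev_sign * geometry.v_deviation])
    start = {"L": np.zeros(2), "R": np.zeros(2)}
    deviated_eye = "R" if fixating_eye == "L" else "L"
    start[deviated_eye] = deviation.copy()

    onset = task.go_ms + latency_ms
    vector = np.asarray(target, float) - start[acquiring_eye]
    nominal_amp = float(np.hypot(*vector))
    if kin.endpoint_noise_frac > 0:
        scatter = max(
            kin.endpoint_noise_frac * nominal_amp, kin.endpoint_noise_min_deg
        )
        vector = vector + rng.standard_normal(2) * scatter
    amp = float(np.hypot(*vector))
    duration = kin.duration_intercept_ms + kin.duration_slope_ms_per_deg * amp
    profile = minimum_jerk((time_ms - onset) / duration)
    displacement = np.outer(profile, vector)

    pos = {eye: start[eye][None, :] + displacement for eye in ("L", "R")}
    # slow positional instability of the deviated eye (random walk)
    if geometry.drift_sd > 0:
        drift = np.cumsum(
            rng.standard_normal((n, 2)) * geometry.drift_sd, axis=0
        )
        pos[deviated_eye] = pos[deviated_eye] + drift
    eyes = np.column_stack([pos["L"], pos["R"]])
    if geometry.noise_sd > 0:
        eyes = eyes + rng.standard_normal(eyes.shape) * geometry.noise_sd

    events = {
        "fixation_on": 0.0,
        "target_on": task.fixation_ms,
        "go": task.go_ms,
        "trial_end": task.trial_len_ms,
    }
    return time_ms, eyes, events


# ---------------------------------------------------------------------------
# session assembly
# ---------------------------------------------------------------------------

def _trial_rng(seed: int, cell: int, trial: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(cell, trial))
    )


def _draw_profile(
    pop: PopulationSpec, rf: Tuple[float, float], rng: np.random.Generator
) -> NeuronProfile:
    u = lambda lo_hi: float(rng.uniform(*lo_hi))
    return NeuronProfile(
        rf_center=rf,
        baseline_hz=u(pop.baseline_range),
        visual_latency_ms=u(pop.visual_latency_range),
        visual_amp_hz=u(pop.visual_amp_range),
        buildup_slope_hz_per_s=u(pop.buildup_slope_range),
        motor_amp_hz=u(pop.motor_amp_range),
        motor_sigma_ms=u(pop.motor_sigma_range),
        race_coupling=u(pop.coupling_range),
    )


# receptive-field locations (w.r.t. the fixating eye) cycled across cells
TWO_TARGET_RFS = ((0.0, 10.0), (-10.0, 10.0), (0.0, -10.0), (-10.0, -10.0))
ONE_TARGET_RFS = ((10.0, 10.0), (10.0, 0.0), (10.0, -10.0))


def deviated_rf_location(
    rf: Tuple[float, float],
    geometry: GeometryConfig,
    task: TaskConfig,
    dev_sign: float = 1.0,
) -> Tuple[float, float]:
    """Equivalent receptive-field LED for the deviated eye.

    The deviated-eye location is the fixating-eye RF offset horizontally by
    the ocular deviation.  The vertical deviation is added only when the
    resulting LED exists on the grid; otherwise it is dropped (the discrete
    LED array imposes the same constraint on a real experiment).
    """
    h = rf[0] + dev_sign * geometry.h_deviation
    v = rf[1] + dev_sign * geometry.v_deviation
    if task.on_grid(h, v):
        return (h, v)
    if task.on_grid(h, rf[1]):
        if geometry.v_deviation:
            logger.debug(
                "vertical deviation %.1f dropped: (%g, %g) off grid",
                geometry.v_deviation, h, v,
            )
        return (h, rf[1])
    raise InfeasibleGeometryError(
        f"deviated-eye RF location ({h:g}, {v:g}) is off the LED grid"
    )


def make_session(config: RunConfig) -> Session:
    """Generate a complete synthetic session with ground truth.

    Two-target sessions alternate the eccentric target between the
    fixating-eye RF location and the equivalent deviated-eye location;
    the zone determines the acquiring eye deterministically.  One-target
    sessions place a single target at the RF location in the bistable
    zone; each trial the interocular suppression state is drawn, the two
    sensory drives race, and the winner determines the acquiring eye.
    """
    if config.n_cells < 1:
        raise InvalidConfigError("n_cells must be >= 1")
    if config.trials_per_cell < 2:
        raise InvalidConfigError("trials_per_cell must be >= 2")
    geom, task, race = config.geometry, config.task, config.race
    cells = []
    trial_counter = 0
    for ci in range(config.n_cells):
        cell_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(ci,))
        )
        if config.paradigm == "two-target":
            rf = TWO_TARGET_RFS[ci % len(TWO_TARGET_RFS)]
        else:
            rf = ONE_TARGET_RFS[ci % len(ONE_TARGET_RFS)]
        profile = _draw_profile(config.population, rf, cell_rng)
        cell = Cell(index=ci, profile_dict=profile.model_dump())

        # balanced, shuffled two-target schedule
        if config.paradigm == "two-target":
            sched = np.array([0, 1] * (config.trials_per_cell // 2)
                             + [0] * (config.trials_per_cell % 2))
            cell_rng.shuffle(sched)
        for ti in range(config.trials_per_cell):
            rng = _trial_rng(config.seed, ci, ti)
            fixating = "L" if rng.uniform() < geom.p_left_fixating else "R"
            deviated = "R" if fixating == "L" else "L"
            dev_sign = 1.0 if fixating == "L" else -1.0
            gain_a = float(rng.lognormal(0.0, race.gain_sd))
            gain_b = float(rng.lognormal(0.0, race.gain_sd))

            if config.paradigm == "two-target":
                use_deviated = bool(sched[ti])
                if use_deviated:
                    target = deviated_rf_location(rf, geom, task, dev_sign)
                    acquiring, switch, suppressed = deviated, True, True
                else:
                    target = (rf[0], rf[1])
                    acquiring, switch, suppressed = fixating, False, False
                    if not task.on_grid(*target):
                        raise InfeasibleGeometryError(
                            f"RF location {target} off the LED grid"
                        )
                # latency from a solo accumulator at the trial's gain
                _, latency = simulate_race(race, gain_a, 0.0, rng)
                winner, supp_side = "neuron", ("B" if use_deviated else None)
                won = True
            else:
                target = (rf[0], rf[1])
                if not task.on_grid(*target):
                    raise InfeasibleGeometryError(
                        f"RF location {target} off the LED grid"
                    )
                # dynamic interocular suppression state: at border targets
                # either side is suppressed with equal probability
                supp_side = "A" if rng.uniform() < 0.5 else "B"
                drive_a = gain_a * (1.0 - race.suppression * (supp_side == "A"))
                drive_b = gain_b * (1.0 - race.suppression * (supp_side == "B"))
                winner_ab, latency = simulate_race(race, drive_a, drive_b, rng)
                won = winner_ab == "A"
                winner = "neuron" if won else "opposite"
                switch = not won
                acquiring = fixating if won else deviated

            latency = float(np.clip(latency, config.kinematics.latency_min_ms,
                                    task.response_window_ms - 220.0))
            time_ms, eyes, events = simulate_trial_eyes(
                geom, task, config.kinematics, fixating, acquiring, target,
                latency, rng,
            )
            saccade_onset = task.go_ms + latency
            profile_events = dict(events, saccade_onset=saccade_onset)
            suppressed_flag = supp_side == "A"
            fn = rate_profile(
                profile, profile_events, won, gain_a, race,
                suppressed=suppressed_flag if config.paradigm == "one-target"
                else bool(supp_side == "B" and switch),
            )
            spikes = sample_spikes(fn, (0.0, task.trial_len_ms), rng)
            truth = GroundTruth(
                fixating_eye=fixating,
                acquiring_eye=acquiring,
                winner=winner,
                switch=switch,
                saccade_onset_ms=saccade_onset,
                latency_ms=latency,
                gain_a=gain_a,
                gain_b=gain_b,
                suppressed_side=supp_side,
            )
            cell.trials.append(
                Trial(
                    index=trial_counter,
                    cell_index=ci,
                    paradigm=config.paradigm,
                    target=target,
                    events=events,
                    time_ms=time_ms,
                    eyes=eyes,
                    spikes=spikes,
                    truth=truth,
                )
            )
            trial_counter += 1
        cells.append(cell)
    return Session(config=config, cells=cells)
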