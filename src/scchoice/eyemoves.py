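"""Saccade detection, trial labeling and trial selection.

Works on binocular 1 kHz position traces.  The detector is a standard
velocity-threshold scheme: boxcar smoothing, central-difference velocity,
a high threshold to find candidate saccades and a lower threshold to
refine their onsets/offsets.  Trial labels name the eye fixating at
baseline and the eye acquiring the eccentric target; a trial is a
fixation switch when the two differ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import stats

from .config import DetectionParams, TaskConfig
from .errors import (
    AmbiguousTrialError,
    FailedTrialError,
    InvalidFixationError,
    RankError,
    SamplingError,
    UnmatchableError,
)


@dataclass
class Saccade:
    onset_ms: float
    offset_ms: float
    dh_deg: float
    dv_deg: float
    amplitude_deg: float
    peak_velocity_deg_s: float

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass
class TrialLabel:
    fixating_eye: str  # 'L' or 'R'
    acquiring_eye: str
    label: str  # 'LL', 'LR', 'RL', 'RR'
    switch: bool


def _boxcar(x: np.ndarray, halfwidth: int) -> np.ndarray:
    if halfwidth <= 0:
        return x
    w = 2 * halfwidth + 1
    kernel = np.ones(w) / w
    pad = np.pad(x, halfwidth, mode="edge")
    return np.convolve(pad, kernel, mode="valid")


def detect_saccades(
    time_ms: np.ndarray,
    h_deg: np.ndarray,
    v_deg: np.ndarray,
    params: DetectionParams | None = None,
) -> List[Saccade]:
    """Detect saccades in one eye's H/V position trace.

    Velocity is computed by central difference after boxcar smoothing;
    samples whose speed exceeds ``velocity_threshold`` seed candidate
    saccades whose onset and offset are refined outward to the
    ``onset_refine_threshold`` crossing.  Overlapping candidates merge;
    candidates shorter than ``min_duration_ms`` are discarded.
    """
    params = params or DetectionParams()
    time_ms = np.asarray(time_ms, float)
    dt = np.diff(time_ms)
    if len(dt) == 0 or not np.allclose(dt, dt[0], atol=1e-6):
        raise SamplingError("trace is not uniformly sampled")
    step = dt[0]
    h = _boxcar(np.asarray(h_deg, float), params.smooth_halfwidth)
    v = _boxcar(np.asarray(v_deg, float), params.smooth_halfwidth)
    vh = np.gradient(h, step) * 1000.0  # deg/s
    vv = np.gradient(v, step) * 1000.0
    speed = np.hypot(vh, vv)

    above = speed >= params.velocity_threshold
    if not above.any():
        return []
    # contiguous runs above the high threshold
    starts = list(np.flatnonzero(np.diff(above.astype(int)) == 1) + 1)
    ends = list(np.flatnonzero(np.diff(above.astype(int)) == -1))
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above) - 1)

    low = speed >= params.onset_refine_threshold
    saccades: List[Saccade] = []
    last_end = -1
    for s0, s1 in zip(starts, ends):
        # refine outward to the low-threshold crossing
        i = s0
        while i > 0 and low[i - 1]:
            i -= 1
        j = s1
        while j < len(low) - 1 and low[j + 1]:
            j += 1
        if saccades and i <= last_end:
            # merge with previous refined interval
            prev = saccades.pop()
            i = int(round((prev.onset_ms - time_ms[0]) / step))
        if (time_ms[j] - time_ms[i]) < params.min_duration_ms:
            last_end = j
            continue
        dh = h[j] - h[i]
        dv = v[j] - v[i]
        saccades.append(
            Saccade(
                onset_ms=float(time_ms[i]),
                offset_ms=float(time_ms[j]),
                dh_deg=float(dh),
                dv_deg=float(dv),
                amplitude_deg=float(np.hypot(dh, dv)),
                peak_velocity_deg_s=float(speed[i : j + 1].max()),
            )
        )
        last_end = j
    return saccades


def classify_trial(
    time_ms: np.ndarray,
    eyes: np.ndarray,
    events: dict,
    target: Tuple[float, float],
    task: TaskConfig | None = None,
    baseline_ms: float = 200.0,
    end_ms: float = 150.0,
    fixation_point: Tuple[float, float] = (0.0, 0.0),
) -> TrialLabel:
    """Label the fixating and acquiring eye of one trial.

    The fixating eye is the one whose mean position over the last
    ``baseline_ms`` before target onset lies within the fixation window of
    the central target; the acquiring eye is the one whose mean position
    over the last ``end_ms`` of the trial lies within the acquisition
    window of the eccentric target.
    """
    task = task or TaskConfig()
    t_target = events["target_on"]
    base_mask = (time_ms >= t_target - baseline_ms) & (time_ms < t_target)
    end_mask = time_ms >= time_ms[-1] - end_ms
    fix = np.asarray(fixation_point, float)
    tgt = np.asarray(target, float)

    def _dist(cols, mask, ref):
        mean_pos = eyes[mask][:, cols].mean(axis=0)
        return float(np.linalg.norm(mean_pos - ref))

    d_base = {"L": _dist([0, 1], base_mask, fix), "R": _dist([2, 3], base_mask, fix)}
    within_base = [e for e in "LR" if d_base[e] <= task.fixation_window_deg]
    if not within_base:
        raise InvalidFixationError(
            f"neither eye within {task.fixation_window_deg} deg of fixation "
            f"at baseline (L: {d_base['L']:.2f}, R: {d_base['R']:.2f})"
        )
    if len(within_base) == 2:
        raise AmbiguousTrialError("both eyes within the fixation window")
    fixating = within_base[0]

    d_end = {"L": _dist([0, 1], end_mask, tgt), "R": _dist([2, 3], end_mask, tgt)}
    within_end = [e for e in "LR" if d_end[e] <= task.acquisition_window_deg]
    if not within_end:
        raise FailedTrialError(
            f"neither eye within {task.acquisition_window_deg} deg of target "
            f"{tuple(tgt)} at trial end (L: {d_end['L']:.2f}, R: {d_end['R']:.2f})"
        )
    if len(within_end) == 2:
        raise AmbiguousTrialError("both eyes within the acquisition window")
    acquiring = within_end[0]
    return TrialLabel(
        fixating_eye=fixating,
        acquiring_eye=acquiring,
        label=fixating + acquiring,
        switch=acquiring != fixating,
    )


def match_amplitudes(
    amps_no_switch: Sequence[float],
    amps_switch: Sequence[float],
    alpha: float = 0.05,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Greedily prune trials until the groups' amplitudes are matched.

    A Welch two-sample t-test compares the two groups.  While p <= alpha,
    one trial is removed from the group whose mean is farther from the
    pooled mean — the single trial whose removal maximizes the resulting
    p — until p > alpha or a group would drop below 3 trials (then the
    cell is unmatchable).  Returns the retained indices of each group and
    the achieved p.
    """
    a = np.asarray(amps_no_switch, float)
    b = np.asarray(amps_switch, float)
    if len(a) < 3 or len(b) < 3:
        raise UnmatchableError("need at least 3 trials per group")
    keep_a = list(range(len(a)))
    keep_b = list(range(len(b)))

    def _p(xa, xb):
        if np.ptp(xa) == 0 and np.ptp(xb) == 0:
            return 1.0 if xa.mean() == xb.mean() else 0.0
        return float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)

    p = _p(a[keep_a], b[keep_b])
    while p <= alpha:
        pooled = np.concatenate([a[keep_a], b[keep_b]]).mean()
        dist_a = abs(a[keep_a].mean() - pooled)
        dist_b = abs(b[keep_b].mean() - pooled)
        donor_is_a = dist_a >= dist_b
        keep, other, vals, ovals = (
            (keep_a, keep_b, a, b) if donor_is_a else (keep_b, keep_a, b, a)
        )
        if len(keep) <= 3:
            raise UnmatchableError(
                f"cannot match amplitudes with >= 3 trials per group "
                f"(p = {p:.3g})"
            )
        best_p, best_i = -1.0, None
        for pos in range(len(keep)):
            trial = keep[:pos] + keep[pos + 1 :]
            xa = vals[trial]
            xb = ovals[other]
            cand = _p(xa, xb) if donor_is_a else _p(xb, xa)
            if cand > best_p:
                best_p, best_i = cand, pos
        del keep[best_i]
        p = best_p
    assert p > alpha  # postcondition self-check
    return np.array(keep_a), np.array(keep_b), p


def calibrate(
    raw: np.ndarray, true_positions: np.ndarray
) -> Tuple[float, float]:
    """Least-squares affine map from raw coil units to degrees.

    Fits ``raw = gain * position + offset`` over calibration fixations and
    returns ``(gain, offset)``; apply with :func:`apply_calibration`.
    """
    raw = np.asarray(raw, float)
    true_positions = np.asarray(true_positions, float)
    if len(np.unique(true_positions)) < 2:
        raise RankError("need at least 2 distinct calibration targets per axis")
    A = np.column_stack([true_positions, np.ones_like(true_positions)])
    (gain, offset), *_ = np.linalg.lstsq(A, raw, rcond=None)
    return float(gain), float(offset)


def apply_calibration(raw: np.ndarray, gain: float, offset: float) -> np.ndarray:
    return (np.asarray(raw, float) - offset) / gain
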