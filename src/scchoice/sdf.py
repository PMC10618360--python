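"""Spike-density estimation, condition averaging and normalization.

The spike density function (SDF) convolves spike timestamps with a
unit-area Gaussian kernel (default sigma 15 ms, truncated at +/-5 sigma,
no renormalization), expressed in spikes/s on a uniform 1 ms grid, so the
integral over an isolated spike's support is one spike.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .config import SDFParams
from .errors import (
    AlignmentError,
    DegenerateCellError,
    InvalidParamsError,
    MalformedTrialError,
)


@dataclass
class SDFTrace:
    """A smoothed firing-rate trace on a uniform time grid.

    ``time_ms`` is relative to the alignment event (``'trial_start'``,
    ``'target_onset'`` or ``'saccade_onset'``).
    """

    time_ms: np.ndarray
    rate_hz: np.ndarray
    alignment: str = "trial_start"
    n_trials: int = 1

    def __post_init__(self):
        self.time_ms = np.asarray(self.time_ms, float)
        self.rate_hz = np.asarray(self.rate_hz, float)
        if self.time_ms.shape != self.rate_hz.shape:
            raise InvalidParamsError("time and rate grids differ in length")

    @property
    def step_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])

    def copy_with(self, rate_hz: np.ndarray) -> "SDFTrace":
        return SDFTrace(self.time_ms.copy(), rate_hz, self.alignment, self.n_trials)


def _kernel(params: SDFParams) -> np.ndarray:
    """Sampled unit-area Gaussian in spikes/s per spike, truncated +/-5 sigma."""
    sigma = params.kernel_sigma_ms
    step = params.grid_step_ms
    half = int(np.ceil(params.support_sigmas * sigma / step))
    x = np.arange(-half, half + 1) * step
    return 1000.0 * np.exp(-0.5 * (x / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))


def spike_density(
    timestamps: Sequence[float],
    params: SDFParams | None = None,
    t_range: tuple[float, float] = (0.0, 2000.0),
    alignment: str = "trial_start",
) -> SDFTrace:
    """Gaussian-kernel spike density function on a uniform grid.

    rate(t) = sum_i G_sigma(t - t_i) in spikes/s; the integral of the
    trace over an interior spike's support equals one spike.  Timestamps
    are sorted if needed; duplicates are allowed; spikes outside
    ``t_range`` are ignored.
    """
    params = params or SDFParams()
    if params.kernel_sigma_ms <= 0:
        raise InvalidParamsError("kernel sigma must be > 0")
    t0, t1 = t_range
    step = params.grid_step_ms
    grid = np.arange(t0, t1 + step / 2, step)
    ts = np.sort(np.asarray(timestamps, float))
    ts = ts[(ts >= t0) & (ts <= t1)]
    counts = np.zeros(len(grid))
    if len(ts):
        idx = np.clip(np.round((ts - t0) / step).astype(int), 0, len(grid) - 1)
        np.add.at(counts, idx, 1.0)
    rate = np.convolve(counts, _kernel(params), mode="same")
    return SDFTrace(grid, rate, alignment=alignment, n_trials=1)


def align_and_average(
    spike_trains: List[np.ndarray],
    event_times: Sequence[float],
    params: SDFParams | None = None,
    window: tuple[float, float] = (-300.0, 300.0),
    alignment: str = "event",
) -> SDFTrace:
    """Condition-mean SDF of trials re-aligned to a per-trial event.

    Each trial's timestamps are shifted so its event is time zero, the SDF
    is computed on a grid extended by the kernel support (so spikes just
    outside the window still contribute), cropped to ``window`` and
    averaged pointwise across trials.
    """
    params = params or SDFParams()
    if len(spike_trains) == 0:
        raise MalformedTrialError("no trials to average")
    if len(spike_trains) != len(event_times):
        raise MalformedTrialError("one alignment event required per trial")
    for i, ev in enumerate(event_times):
        if ev is None or not np.isfinite(ev):
            raise MalformedTrialError(f"trial {i}: missing alignment event")
    pad = params.support_sigmas * params.kernel_sigma_ms
    w0, w1 = window
    acc = None
    for train, ev in zip(spike_trains, event_times):
        shifted = np.asarray(train, float) - ev
        tr = spike_density(shifted, params, (w0 - pad, w1 + pad))
        mask = (tr.time_ms >= w0 - params.grid_step_ms / 2) & (
            tr.time_ms <= w1 + params.grid_step_ms / 2
        )
        rate = tr.rate_hz[mask]
        grid = tr.time_ms[mask]
        acc = rate if acc is None else acc + rate
    mean = acc / len(spike_trains)
    return SDFTrace(grid, mean, alignment=alignment, n_trials=len(spike_trains))


def normalize_cell(cond_traces: Dict[str, SDFTrace]) -> Dict[str, SDFTrace]:
    """Normalize a cell's condition traces by its single maximal response.

    The divisor is the maximum over both conditions for one alignment, so
    the normalized set has global maximum exactly 1.
    """
    if not cond_traces:
        raise DegenerateCellError("no traces to normalize")
    peak = max(float(tr.rate_hz.max()) for tr in cond_traces.values())
    if peak <= 0:
        raise DegenerateCellError("all condition traces are zero")
    return {
        cond: tr.copy_with(tr.rate_hz / peak) for cond, tr in cond_traces.items()
    }


@dataclass
class PopulationResponse:
    """Population mean +/- SE of per-cell normalized condition traces."""

    time_ms: np.ndarray
    mean: Dict[str, np.ndarray]
    se: Dict[str, np.ndarray]
    n_cells: int
    alignment: str = "event"
    per_cell: Dict[str, np.ndarray] = field(default_factory=dict)  # (cells, t)


def population_mean(
    cells: List[Dict[str, SDFTrace]], alignment: str = "event"
) -> PopulationResponse:
    """Pointwise mean and SE (sd/sqrt(n)) across cells' normalized traces.

    All cells must share the same time grid and condition set.  Because
    each cell is normalized individually and peaks at its own time, the
    population mean's peak is <= 1, with equality only if every cell peaks
    at the same sample.
    """
    if len(cells) < 2:
        raise AlignmentError("population mean needs >= 2 cells")
    conditions = sorted(cells[0].keys())
    ref = cells[0][conditions[0]].time_ms
    for cdict in cells:
        if sorted(cdict.keys()) != conditions:
            raise AlignmentError("cells have differing condition sets")
        for tr in cdict.values():
            if len(tr.time_ms) != len(ref) or not np.allclose(tr.time_ms, ref):
                raise AlignmentError("cells are on different time grids")
    mean, se, per_cell = {}, {}, {}
    n = len(cells)
    for cond in conditions:
        mat = np.vstack([c[cond].rate_hz for c in cells])
        mean[cond] = mat.mean(axis=0)
        se[cond] = mat.std(axis=0, ddof=1) / np.sqrt(n)
        per_cell[cond] = mat
    return PopulationResponse(
        time_ms=ref.copy(), mean=mean, se=se, n_cells=n,
        alignment=alignment, per_cell=per_cell,
    )
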