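"""Configuration objects for the simulator and the analysis chain.

All durations are in milliseconds from trial start, all positions in degrees
of visual angle (positive rightward / upward), all rates in spikes/s.  The
defaults encode the study conditions the analysis assumes: an exotropic
subject with ~30 deg horizontal deviation performing a delayed saccade task
(500 ms fixation, 1,000 ms sensory overlap, <=500 ms response window) on a
7x3 LED grid spaced 10 deg apart and sampled at 1 kHz.
"""

from __future__ import annotations

from typing import Literal, Optional, Tuple

from pydantic import BaseModel, Field, model_validator

from .errors import InvalidConfigError


class GeometryConfig(BaseModel):
    """Binocular geometry of an exotropic subject.

    ``h_deviation`` is the horizontal angle of the deviated eye relative to
    the fixating eye (positive = temporal-ward, i.e. a right exotropic eye
    sits to the right of the target the left eye foveates).  ``drift_sd`` is
    the per-sample random-walk step of the deviated eye's slow positional
    instability; ``noise_sd`` is white measurement noise added to every
    channel sample.
    """

    h_deviation: float = 30.0
    v_deviation: float = 1.0
    p_left_fixating: float = 1.0
    drift_sd: float = 0.01
    noise_sd: float = 0.05

    @model_validator(mode="after")
    def _check(self) -> "GeometryConfig":
        if self.h_deviation < 0:
            raise InvalidConfigError("h_deviation must be >= 0 (exotropia)")
        if not 0.0 <= self.p_left_fixating <= 1.0:
            raise InvalidConfigError("p_left_fixating must be in [0, 1]")
        if self.drift_sd < 0 or self.noise_sd < 0:
            raise InvalidConfigError("noise parameters must be >= 0")
        return self


class TaskConfig(BaseModel):
    """Delayed-saccade task timing, reward windows and LED grid."""

    fixation_ms: float = 500.0
    overlap_ms: float = 1000.0
    response_window_ms: float = 500.0
    fixation_window_deg: float = 2.0
    acquisition_window_deg: float = 5.0
    grid_h: Tuple[float, ...] = (-30.0, -20.0, -10.0, 0.0, 10.0, 20.0, 30.0)
    grid_v: Tuple[float, ...] = (-10.0, 0.0, 10.0)
    sample_rate_hz: float = 1000.0

    @model_validator(mode="after")
    def _check(self) -> "TaskConfig":
        for name in ("fixation_ms", "overlap_ms", "response_window_ms"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be > 0")
        if self.sample_rate_hz <= 0:
            raise InvalidConfigError("sample_rate_hz must be > 0")
        if len(self.grid_h) == 0 or len(self.grid_v) == 0:
            raise InvalidConfigError("LED grid must be non-empty")
        for axis in (self.grid_h, self.grid_v):
            if len(axis) > 1:
                import numpy as np

                d = np.diff(sorted(axis))
                if not np.allclose(d, d[0]):
                    raise InvalidConfigError("LED grid spacing must be uniform")
        return self

    @property
    def go_ms(self) -> float:
        """Time of fixation offset (the go signal) from trial start."""
        return self.fixation_ms + self.overlap_ms

    @property
    def trial_len_ms(self) -> float:
        return self.fixation_ms + self.overlap_ms + self.response_window_ms

    def on_grid(self, h: float, v: float) -> bool:
        return any(abs(h - g) < 1e-9 for g in self.grid_h) and any(
            abs(v - g) < 1e-9 for g in self.grid_v
        )


class NeuronProfile(BaseModel):
    """Visuomotor response profile of one SC neuron.

    The profile is the classic SC visuomotor triad: a transient visual
    response ``visual_latency_ms`` after target onset, a linear buildup ramp
    during the delay period, and a motor burst at saccade onset for saccades
    into the movement field.  ``race_coupling`` scales how strongly the last
    ~125 ms of the cell's buildup reflects the outcome of the saccade-vector
    race: strongly coupled cells accelerate earlier into the burst on won
    trials and shed buildup faster on lost trials.
    """

    rf_center: Tuple[float, float] = (10.0, 10.0)
    rf_sigma: float = 10.0
    baseline_hz: float = 12.0
    visual_latency_ms: float = 50.0
    visual_amp_hz: float = 150.0
    visual_sigma_ms: float = 15.0
    buildup_onset_ms: float = 150.0
    buildup_slope_hz_per_s: float = 120.0
    motor_amp_hz: float = 300.0
    motor_sigma_ms: float = 25.0
    burst_peak_offset_ms: float = 15.0
    race_coupling: float = 1.0

    @model_validator(mode="after")
    def _check(self) -> "NeuronProfile":
        for name in (
            "rf_sigma",
            "baseline_hz",
            "visual_amp_hz",
            "visual_sigma_ms",
            "buildup_slope_hz_per_s",
            "motor_amp_hz",
            "motor_sigma_ms",
            "race_coupling",
        ):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        if self.visual_latency_ms < 0 or self.visual_latency_ms >= 100.0:
            raise InvalidConfigError(
                "visual_latency_ms must lie in [0, 100) so the transient peak "
                "is observable inside the visual analysis window"
            )
        return self


class RaceConfig(BaseModel):
    """Two-accumulator race between the neuron-side and opposite-side
    saccade-vector populations.

    ``suppression`` is the fractional attenuation applied to the sensory
    drive of the population representing the currently suppressed retinal
    error; ``divergence_ms`` is the time before saccade onset at which the
    losing population's buildup starts to decay (time constant
    ``decay_tau_ms``).  Accumulators integrate drive/latency_scale_ms per ms
    plus Gaussian noise until one reaches ``threshold``; the winner's
    crossing time is the saccade latency.
    """

    suppression: float = 0.15
    divergence_ms: float = 125.0
    gain_sd: float = 0.12
    threshold: float = 1.0
    drift_noise_sd: float = 0.005
    latency_scale_ms: float = 180.0
    decay_tau_ms: float = 15.0
    winner_boost: float = 0.4
    rise_widening: float = 1.2

    @model_validator(mode="after")
    def _check(self) -> "RaceConfig":
        if not 0.0 <= self.suppression <= 1.0:
            raise InvalidConfigError("suppression must be in [0, 1]")
        if not 0.0 < self.divergence_ms <= 200.0:
            raise InvalidConfigError("divergence_ms must be in (0, 200]")
        if self.gain_sd < 0 or self.drift_noise_sd < 0:
            raise InvalidConfigError("dispersion parameters must be >= 0")
        if self.threshold <= 0 or self.latency_scale_ms <= 0:
            raise InvalidConfigError("threshold and latency scale must be > 0")
        if self.decay_tau_ms <= 0:
            raise InvalidConfigError("decay_tau_ms must be > 0")
        return self


class FixationMapConfig(BaseModel):
    """Spatial fixation-preference map across the target grid.

    The probability that the deviated (right) eye acquires a target follows
    a sigmoid across a vertical border located ``border_offset`` degrees
    from the midpoint of the two lines of sight; ``border_slope`` (1/deg)
    sets how sharply preference transitions across the border.
    """

    border_offset: float = 0.0
    border_slope: float = 0.3

    @model_validator(mode="after")
    def _check(self) -> "FixationMapConfig":
        if self.border_slope <= 0:
            raise InvalidConfigError("border_slope must be > 0")
        return self


class PopulationSpec(BaseModel):
    """Ranges from which per-cell response profiles are drawn.

    Cells share the canonical visuomotor shape but differ in amplitude
    ratios, burst width and race coupling; the coupling spread is what lets
    the across-cell correlation analysis see the race outcome.
    """

    baseline_range: Tuple[float, float] = (8.0, 16.0)
    visual_amp_range: Tuple[float, float] = (240.0, 360.0)
    visual_latency_range: Tuple[float, float] = (45.0, 55.0)
    buildup_slope_range: Tuple[float, float] = (170.0, 270.0)
    motor_amp_range: Tuple[float, float] = (520.0, 760.0)
    motor_sigma_range: Tuple[float, float] = (20.0, 30.0)
    coupling_range: Tuple[float, float] = (0.1, 1.9)

    @model_validator(mode="after")
    def _check(self) -> "PopulationSpec":
        for name in type(self).model_fields:
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise InvalidConfigError(f"{name} must satisfy 0 <= lo <= hi")
        return self


class SaccadeKinematics(BaseModel):
    """Minimum-jerk saccade with amplitude-dependent duration.

    Duration = ``duration_intercept_ms`` + ``duration_slope_ms_per_deg`` x
    amplitude, the standard main-sequence relation for primate saccades.
    Endpoints scatter around the target with a per-component standard
    deviation of ``endpoint_noise_frac`` x amplitude (floored at
    ``endpoint_noise_min_deg``); the scatter is conjugate — both eyes
    share the same perturbed saccade vector.
    """

    duration_slope_ms_per_deg: float = 2.2
    duration_intercept_ms: float = 25.0
    latency_min_ms: float = 80.0
    endpoint_noise_frac: float = 0.08
    endpoint_noise_min_deg: float = 0.25


class DetectionParams(BaseModel):
    """Velocity-threshold saccade detector settings."""

    velocity_threshold: float = 50.0
    onset_refine_threshold: float = 20.0
    min_duration_ms: float = 10.0
    smooth_halfwidth: int = 2

    @model_validator(mode="after")
    def _check(self) -> "DetectionParams":
        if self.onset_refine_threshold >= self.velocity_threshold:
            raise InvalidConfigError(
                "onset_refine_threshold must be below velocity_threshold"
            )
        if self.min_duration_ms <= 0:
            raise InvalidConfigError("min_duration_ms must be > 0")
        return self


class SDFParams(BaseModel):
    """Spike-density-function kernel: a 15 ms Gaussian truncated at +/-5 sigma."""

    kernel_sigma_ms: float = 15.0
    grid_step_ms: float = 1.0
    support_sigmas: float = 5.0

    @model_validator(mode="after")
    def _check(self) -> "SDFParams":
        if self.kernel_sigma_ms <= 0 or self.grid_step_ms <= 0:
            raise InvalidConfigError("kernel sigma and grid step must be > 0")
        return self


class WindowSpec(BaseModel):
    """Analysis windows for peak and buildup measures.

    visual: (0, +100] ms after target onset; motor: [-50, +50] ms around
    saccade onset; buildup: [-200, 0) ms before saccade onset, divided into
    25 ms bins with an early/late split at the midpoint.
    """

    visual_window: Tuple[float, float] = (0.0, 100.0)
    motor_window: Tuple[float, float] = (-50.0, 50.0)
    buildup_window: Tuple[float, float] = (-200.0, 0.0)
    bin_ms: float = 25.0
    early_late_split_ms: float = 100.0

    @model_validator(mode="after")
    def _check(self) -> "WindowSpec":
        for name in ("visual_window", "motor_window", "buildup_window"):
            lo, hi = getattr(self, name)
            if hi <= lo:
                raise InvalidConfigError(f"{name} must be non-empty")
        lo, hi = self.buildup_window
        n = (hi - lo) / self.bin_ms
        if abs(n - round(n)) > 1e-9:
            raise InvalidConfigError("bin_ms must divide the buildup window")
        return self

    def bin_edges(self):
        import numpy as np

        lo, hi = self.buildup_window
        return np.arange(lo, hi + self.bin_ms / 2, self.bin_ms)

    def bin_centers(self):
        e = self.bin_edges()
        return (e[:-1] + e[1:]) / 2.0


Paradigm = Literal["one-target", "two-target"]


class RunConfig(BaseModel):
    """Everything needed to reproduce a simulate -> analyze -> report run."""

    paradigm: Paradigm = "one-target"
    seed: int = 0
    n_cells: int = 32
    trials_per_cell: int = 60
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    task: TaskConfig = Field(default_factory=TaskConfig)
    race: RaceConfig = Field(default_factory=RaceConfig)
    fixmap: FixationMapConfig = Field(default_factory=FixationMapConfig)
    population: PopulationSpec = Field(default_factory=PopulationSpec)
    kinematics: SaccadeKinematics = Field(default_factory=SaccadeKinematics)
    detection: DetectionParams = Field(default_factory=DetectionParams)
    sdf: SDFParams = Field(default_factory=SDFParams)
    windows: WindowSpec = Field(default_factory=WindowSpec)
    out_dir: Optional[str] = None
    write_figures: bool = True

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.n_cells < 1:
            raise InvalidConfigError("n_cells must be >= 1")
        if self.trials_per_cell < 2:
            raise InvalidConfigError("trials_per_cell must be >= 2")
        return self

    @classmethod
    def defaults_for(cls, paradigm: Paradigm, seed: int = 0, **kw) -> "RunConfig":
        """Study-condition defaults: 32 cells x 60 trials for one-target
        sessions, 40 cells x 40 trials for two-target sessions."""
        if paradigm == "one-target":
            base = dict(n_cells=32, trials_per_cell=60)
        else:
            base = dict(n_cells=40, trials_per_cell=40)
        base.update(kw)
        return cls(paradigm=paradigm, seed=seed, **base)
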