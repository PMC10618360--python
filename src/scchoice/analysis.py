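"""Windowed peak measures, paired comparisons and the binned pre-saccadic
correlation used to time the eye-choice decision.

Peaks are maxima of condition-mean spike density functions inside fixed
windows: the visual peak within 100 ms after target onset, the motor peak
within the 100 ms surrounding saccade onset.  The buildup analysis takes
the 200 ms before saccade onset in 25 ms bins; in each bin a Pearson
correlation is computed across cells between the fixation-switch and
no-switch mean normalized activities, and per-bin two-sided significance
(uncorrected, alpha 0.05) is flagged with its sign.  The earliest
significantly negative bin marks the putative time of eye choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .config import WindowSpec
from .errors import InvalidParamsError, WindowError
from .sdf import SDFTrace


@dataclass
class PeakMeasure:
    peak_hz: float
    time_ms: float


@dataclass
class ComparisonResult:
    test: str  # 'paired-t' or 'wilcoxon'
    statistic: float
    p: float
    n: int


@dataclass
class BuildupCorrelation:
    bin_centers_ms: np.ndarray
    r: np.ndarray
    p: np.ndarray
    flags: List[str]  # '+', '-', 'none'
    reasons: List[str]


def peak_in_window(
    trace: SDFTrace,
    window: Tuple[float, float],
    closed_left: bool = True,
    closed_right: bool = True,
) -> PeakMeasure:
    """Maximum of a condition-mean SDF restricted to a time window.

    Ties resolve to the earliest time; the peak time is reported for
    auditability.
    """
    lo, hi = window
    t = trace.time_ms
    mask = (t >= lo if closed_left else t > lo) & (
        t <= hi if closed_right else t < hi
    )
    if not mask.any():
        raise WindowError(f"window {window} is outside the trace grid")
    rates = trace.rate_hz[mask]
    times = t[mask]
    i = int(np.argmax(rates))  # argmax returns the first (earliest) maximum
    return PeakMeasure(peak_hz=float(rates[i]), time_ms=float(times[i]))


def paired_compare(
    x: Sequence[float], y: Sequence[float], method: str = "paired-t"
) -> ComparisonResult:
    """Two-sided paired comparison of per-cell values.

    ``paired-t``: Student t on the differences, df = n - 1.  ``wilcoxon``:
    signed-rank dropping zero differences, exact null distribution for
    n <= 25, otherwise the normal approximation with continuity correction
    (the reported statistic is then the Z value).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise InvalidParamsError("paired samples must have equal length")
    n = len(x)
    if n < 5:
        raise InvalidParamsError("need at least 5 pairs")
    d = x - y
    if np.all(d == 0):
        return ComparisonResult(method, 0.0, 1.0, n)
    if method == "paired-t":
        if np.ptp(d) == 0:  # constant nonzero difference: infinite t
            return ComparisonResult("paired-t", float(np.sign(d[0]) * np.inf), 0.0, n)
        res = stats.ttest_rel(x, y)
        return ComparisonResult("paired-t", float(res.statistic), float(res.pvalue), n)
    if method == "wilcoxon":
        nz = d[d != 0]
        if len(nz) == 0:
            return ComparisonResult("wilcoxon", 0.0, 1.0, n)
        if len(nz) <= 25:
            res = stats.wilcoxon(nz, alternative="two-sided", method="exact")
            return ComparisonResult(
                "wilcoxon", float(res.statistic), float(res.pvalue), len(nz)
            )
        res = stats.wilcoxon(
            nz, alternative="two-sided", method="approx", correction=True
        )
        return ComparisonResult(
            "wilcoxon", float(res.zstatistic), float(res.pvalue), len(nz)
        )
    raise InvalidParamsError(f"unknown method {method!r}")


def bin_activity(trace: SDFTrace, spec: WindowSpec) -> np.ndarray:
    """Mean activity of a saccade-aligned trace in each buildup bin.

    Bins tile ``buildup_window`` ([-200, 0) by default) in ``bin_ms``
    steps; each bin averages the samples with bin_lo <= t < bin_hi.
    """
    edges = spec.bin_edges()
    out = np.empty(len(edges) - 1)
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        mask = (trace.time_ms >= lo) & (trace.time_ms < hi)
        if not mask.any():
            raise WindowError(f"buildup bin [{lo}, {hi}) outside trace grid")
        out[i] = float(trace.rate_hz[mask].mean())
    return out


def binned_correlation(
    pop_switch: np.ndarray,
    pop_noswitch: np.ndarray,
    spec: WindowSpec | None = None,
    alpha: float = 0.05,
) -> BuildupCorrelation:
    """Across-cell Pearson correlation per 25 ms pre-saccadic bin.

    ``pop_switch`` and ``pop_noswitch`` are (cells x bins) matrices of
    mean normalized activity for the same cells.  For each bin, r
    correlates the two condition vectors across cells; the flag is '+'
    or '-' when the two-sided p is below alpha (no multiple-comparison
    correction), else 'none'.  A bin with zero variance in either vector
    has undefined r and is flagged 'none' with the reason recorded.
    """
    spec = spec or WindowSpec()
    a = np.asarray(pop_switch, float)
    b = np.asarray(pop_noswitch, float)
    if a.shape != b.shape:
        raise InvalidParamsError("condition matrices must have the same shape")
    if a.shape[0] < 3:
        raise InvalidParamsError("need >= 3 cells for the correlation")
    centers = spec.bin_centers()
    if a.shape[1] != len(centers):
        raise InvalidParamsError(
            f"expected {len(centers)} bins, got {a.shape[1]}"
        )
    r = np.full(len(centers), np.nan)
    p = np.full(len(centers), np.nan)
    flags, reasons = [], []
    for j in range(len(centers)):
        xa, xb = a[:, j], b[:, j]
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            flags.append("none")
            reasons.append("zero variance across cells")
            continue
        res = stats.pearsonr(xa, xb)
        r[j], p[j] = float(res.statistic), float(res.pvalue)
        if p[j] < alpha:
            flags.append("+" if r[j] > 0 else "-")
        else:
            flags.append("none")
        reasons.append("")
    return BuildupCorrelation(centers, r, p, flags, reasons)


def divergence_onset(bc: BuildupCorrelation) -> Optional[float]:
    """Earliest pre-saccadic bin center with a significant negative
    correlation, scanning from -200 ms toward saccade onset; None if no
    bin qualifies."""
    for center, flag in zip(bc.bin_centers_ms, bc.flags):
        if flag == "-":
            return float(center)
    return None
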