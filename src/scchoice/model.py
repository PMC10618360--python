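"""Model/Results interface for the eye-choice analysis.

:class:`EyeChoiceModel` wraps one recorded (or simulated) session;
``fit()`` runs the full chain — trial labeling from the binocular traces,
saccade detection, amplitude matching (two-target), spike-density
estimation, windowed peaks, per-cell normalization, population averaging,
paired statistics and the binned pre-saccadic correlation — and returns an
:class:`EyeChoiceResults` carrying the estimates, their uncertainties and
a ``summary()`` table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import analysis as an
from . import eyemoves, sdf
from .config import DetectionParams, RunConfig, SDFParams, WindowSpec
from .errors import SCChoiceError
from .session import Session

logger = logging.getLogger(__name__)

TARGET_WINDOW = (-200.0, 400.0)  # ms around target onset
SACCADE_WINDOW = (-300.0, 150.0)  # ms around saccade onset
MIN_TRIALS_PER_CONDITION = 3


@dataclass
class CellFit:
    """Per-cell intermediate results retained for auditability."""

    cell: int
    n_trials_in: int
    n_switch: int
    n_noswitch: int
    match_p: Optional[float]
    target_aligned: Dict[str, sdf.SDFTrace]
    saccade_aligned: Dict[str, sdf.SDFTrace]
    norm_target: Dict[str, sdf.SDFTrace]
    norm_saccade: Dict[str, sdf.SDFTrace]
    peaks: Dict[str, Dict[str, an.PeakMeasure]]  # condition -> epoch -> peak


class EyeChoiceModel:
    """Eye-choice analysis of one delayed-saccade session.

    Parameters
    ----------
    session
        A :class:`~scchoice.session.Session` (simulated or read from disk).
    detection, sdf_params, windows
        Override the detector, SDF kernel or analysis windows; defaults
        come from the session's own run configuration.
    use_ground_truth_labels
        Bypass the behavioral classifier and use generator truth (only
        meaningful on synthetic sessions; used for validation).
    """

    def __init__(
        self,
        session: Session,
        detection: DetectionParams | None = None,
        sdf_params: SDFParams | None = None,
        windows: WindowSpec | None = None,
        use_ground_truth_labels: bool = False,
    ):
        self.session = session
        cfg = session.config
        self.detection = detection or cfg.detection
        self.sdf_params = sdf_params or cfg.sdf
        self.windows = windows or cfg.windows
        self.use_ground_truth_labels = use_ground_truth_labels

    # ------------------------------------------------------------------
    def _label_and_detect(self, exclusions: list) -> pd.DataFrame:
        """Label every trial and detect its saccade onset."""
        rows = []
        task = self.session.config.task
        for trial in self.session.all_trials():
            try:
                if self.use_ground_truth_labels and trial.truth is not None:
                    fixating = trial.truth.fixating_eye
                    acquiring = trial.truth.acquiring_eye
                    switch = trial.truth.switch
                else:
                    lab = eyemoves.classify_trial(
                        trial.time_ms, trial.eyes, trial.events, trial.target,
                        task,
                    )
                    fixating, acquiring, switch = (
                        lab.fixating_eye, lab.acquiring_eye, lab.switch,
                    )
            except SCChoiceError as exc:
                exclusions.append(
                    dict(stage="classify", cell=trial.cell_index,
                         trial=trial.index, reason=str(exc))
                )
                continue
            # detect the target-acquiring saccade on the initially fixating eye
            mask = trial.time_ms >= task.go_ms - 100.0
            eye = trial.eye(fixating)[mask]
            saccades = [
                s
                for s in eyemoves.detect_saccades(
                    trial.time_ms[mask], eye[:, 0], eye[:, 1], self.detection
                )
                if s.amplitude_deg >= 2.0 and s.onset_ms >= task.go_ms - 20.0
            ]
            if not saccades:
                exclusions.append(
                    dict(stage="detect", cell=trial.cell_index,
                         trial=trial.index, reason="no saccade after go")
                )
                continue
            s = saccades[0]
            rows.append(
                dict(
                    trial=trial.index,
                    cell=trial.cell_index,
                    fixating_eye=fixating,
                    acquiring_eye=acquiring,
                    label=fixating + acquiring,
                    switch=switch,
                    saccade_onset_ms=s.onset_ms,
                    saccade_offset_ms=s.offset_ms,
                    amplitude_deg=s.amplitude_deg,
                    peak_velocity_deg_s=s.peak_velocity_deg_s,
                    retained=True,
                )
            )
        return pd.DataFrame(rows)

    # ------------------------------------------------------------------
    def fit(self) -> "EyeChoiceResults":
        cfg = self.session.config
        paradigm = cfg.paradigm
        exclusions: list = []
        labels = self._label_and_detect(exclusions)
        if labels.empty:
            raise SCChoiceError("no labelable trials in session")

        trials_by_index = {t.index: t for t in self.session.all_trials()}
        cell_fits: List[CellFit] = []
        for cell in self.session.cells:
            sub = labels[labels.cell == cell.index]
            n_in = len(sub)
            sw = sub[sub.switch]
            ns = sub[~sub.switch]
            if len(sw) < MIN_TRIALS_PER_CONDITION or len(ns) < MIN_TRIALS_PER_CONDITION:
                exclusions.append(
                    dict(stage="condition-count", cell=cell.index, trial=-1,
                         reason=f"{len(ns)} no-switch / {len(sw)} switch trials")
                )
                logger.info(
                    "cell %d: excluded (%d no-switch, %d switch)",
                    cell.index, len(ns), len(sw),
                )
                continue
            match_p = None
            if paradigm == "two-target":
                try:
                    keep_ns, keep_sw, match_p = eyemoves.match_amplitudes(
                        ns.amplitude_deg.to_numpy(), sw.amplitude_deg.to_numpy()
                    )
                except SCChoiceError as exc:
                    exclusions.append(
                        dict(stage="match", cell=cell.index, trial=-1,
                             reason=str(exc))
                    )
                    continue
                dropped = set(ns.trial.to_numpy()) - set(
                    ns.trial.to_numpy()[keep_ns]
                ) | set(sw.trial.to_numpy()) - set(sw.trial.to_numpy()[keep_sw])
                if dropped:
                    labels.loc[labels.trial.isin(dropped), "retained"] = False
                ns = ns.iloc[keep_ns]
                sw = sw.iloc[keep_sw]

            conds = {"no_switch": ns, "switch": sw}
            target_al, saccade_al = {}, {}
            for cond, rows in conds.items():
                trains = [trials_by_index[i].spikes for i in rows.trial]
                t_on = [trials_by_index[i].events["target_on"] for i in rows.trial]
                s_on = rows.saccade_onset_ms.to_list()
                target_al[cond] = sdf.align_and_average(
                    trains, t_on, self.sdf_params, TARGET_WINDOW, "target_onset"
                )
                saccade_al[cond] = sdf.align_and_average(
                    trains, s_on, self.sdf_params, SACCADE_WINDOW, "saccade_onset"
                )
            norm_t = sdf.normalize_cell(target_al)
            norm_s = sdf.normalize_cell(saccade_al)
            peaks = {}
            for cond in conds:
                peaks[cond] = {
                    "visual": an.peak_in_window(
                        target_al[cond], self.windows.visual_window,
                        closed_left=False,
                    ),
                    "motor": an.peak_in_window(
                        saccade_al[cond], self.windows.motor_window
                    ),
                }
            logger.info(
                "cell %d: %d trials in, %d no-switch + %d switch analyzed",
                cell.index, n_in, len(ns), len(sw),
            )
            cell_fits.append(
                CellFit(
                    cell=cell.index,
                    n_trials_in=n_in,
                    n_switch=len(sw),
                    n_noswitch=len(ns),
                    match_p=match_p,
                    target_aligned=target_al,
                    saccade_aligned=saccade_al,
                    norm_target=norm_t,
                    norm_saccade=norm_s,
                    peaks=peaks,
                )
            )

        if len(cell_fits) < 3:
            raise SCChoiceError(
                f"only {len(cell_fits)} analyzable cells; need >= 3"
            )

        return EyeChoiceResults(
            model=self, cell_fits=cell_fits, labels=labels,
            exclusions=pd.DataFrame(
                exclusions, columns=["stage", "cell", "trial", "reason"]
            ),
        )


class EyeChoiceResults:
    """Fitted eye-choice analysis: estimates, uncertainties, diagnostics."""

    def __init__(self, model, cell_fits, labels, exclusions):
        self.model = model
        self.session = model.session
        self.config = model.session.config
        self.paradigm = self.config.paradigm
        self.cell_fits = cell_fits
        self.labels = labels
        self.exclusions = exclusions
        self._compute()

    # ------------------------------------------------------------------
    def _compute(self):
        spec = self.model.windows
        fits = self.cell_fits

        rows = []
        for f in fits:
            for cond in ("no_switch", "switch"):
                pk = f.peaks[cond]
                rows.append(
                    dict(
                        cell=f.cell, condition=cond,
                        visual_peak_hz=pk["visual"].peak_hz,
                        visual_peak_t_ms=pk["visual"].time_ms,
                        motor_peak_hz=pk["motor"].peak_hz,
                        motor_peak_t_ms=pk["motor"].time_ms,
                        n_trials=(f.n_noswitch if cond == "no_switch"
                                  else f.n_switch),
                        match_p=f.match_p,
                    )
                )
        self.peaks = pd.DataFrame(rows)

        vis_ns = np.array(
            [f.peaks["no_switch"]["visual"].peak_hz for f in fits]
        )
        vis_sw = np.array([f.peaks["switch"]["visual"].peak_hz for f in fits])
        mot_ns = np.array([f.peaks["no_switch"]["motor"].peak_hz for f in fits])
        mot_sw = np.array([f.peaks["switch"]["motor"].peak_hz for f in fits])
        self.visual_peaks_ns, self.visual_peaks_sw = vis_ns, vis_sw
        self.motor_peaks_ns, self.motor_peaks_sw = mot_ns, mot_sw

        comp_rows = []
        for epoch, a, b in (("visual", vis_ns, vis_sw), ("motor", mot_ns, mot_sw)):
            for method in ("wilcoxon", "paired-t"):
                if len(a) >= 5:
                    res = an.paired_compare(a, b, method)
                    comp_rows.append(
                        dict(epoch=epoch, test=res.test,
                             statistic=res.statistic, p=res.p, n=res.n)
                    )
                else:  # too few cells for paired statistics
                    comp_rows.append(
                        dict(epoch=epoch, test=method, statistic=np.nan,
                             p=np.nan, n=len(a))
                    )
        self.comparisons = pd.DataFrame(comp_rows)

        # population normalized traces per alignment
        self.population = {
            "target_onset": sdf.population_mean(
                [f.norm_target for f in fits], "target_onset"
            ),
            "saccade_onset": sdf.population_mean(
                [f.norm_saccade for f in fits], "saccade_onset"
            ),
        }

        # binned pre-saccadic correlation on saccade-aligned normalized data
        mat_sw = np.vstack(
            [an.bin_activity(f.norm_saccade["switch"], spec) for f in fits]
        )
        mat_ns = np.vstack(
            [an.bin_activity(f.norm_saccade["no_switch"], spec) for f in fits]
        )
        self.buildup_bins_switch = mat_sw
        self.buildup_bins_noswitch = mat_ns
        self.buildup_correlation = an.binned_correlation(mat_sw, mat_ns, spec)
        self.divergence_onset_ms = an.divergence_onset(self.buildup_correlation)

        mean_ns = float(vis_ns.mean())
        mean_sw = float(vis_sw.mean())
        self.suppression_percent = 100.0 * (mean_ns - mean_sw) / mean_ns
        self.switch_fraction = float(self.labels.switch.mean())
        self.switch_fraction_per_cell = (
            self.labels.groupby("cell").switch.mean()
        )
        self.n_cells = len(fits)

    # ------------------------------------------------------------------
    @property
    def config_hash(self) -> str:
        """Hash of the scientific configuration (output plumbing excluded)."""
        payload = self.config.model_dump(
            mode="json", exclude={"out_dir", "write_figures"}
        )
        blob = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def comparison(self, epoch: str, test: str) -> an.ComparisonResult:
        row = self.comparisons[
            (self.comparisons.epoch == epoch) & (self.comparisons.test == test)
        ].iloc[0]
        return an.ComparisonResult(row.test, row.statistic, row.p, int(row.n))

    def summary(self) -> str:
        bc = self.buildup_correlation
        lines = [
            "Eye-choice session analysis",
            "=" * 64,
            f"paradigm:            {self.paradigm}",
            f"config hash:         {self.config_hash}",
            f"cells analyzed:      {self.n_cells}",
            f"trials labeled:      {len(self.labels)}"
            f"  (switch fraction {self.switch_fraction:.3f})",
            "",
            "Peak firing rates (population mean +/- SE, spikes/s)",
            "-" * 64,
        ]
        for epoch, a, b in (
            ("visual", self.visual_peaks_ns, self.visual_peaks_sw),
            ("motor", self.motor_peaks_ns, self.motor_peaks_sw),
        ):
            lines.append(
                f"  {epoch:<7} no-switch {a.mean():8.1f} +/- "
                f"{a.std(ddof=1)/np.sqrt(len(a)):5.1f}   "
                f"switch {b.mean():8.1f} +/- "
                f"{b.std(ddof=1)/np.sqrt(len(b)):5.1f}"
            )
        lines += [
            f"  visual-peak reduction on switch trials: "
            f"{self.suppression_percent:.1f}%",
            "",
            "Paired comparisons (two-sided)",
            "-" * 64,
        ]
        for _, row in self.comparisons.iterrows():
            lines.append(
                f"  {row.epoch:<7} {row.test:<9} stat = {row.statistic:8.3f}  "
                f"p = {row.p:.3g}  (n = {int(row.n)})"
            )
        lines += [
            "",
            "Pre-saccadic buildup correlation (25 ms bins, across cells)",
            "-" * 64,
        ]
        for c, r, p, fl in zip(bc.bin_centers_ms, bc.r, bc.p, bc.flags):
            lines.append(
                f"  bin {c:8.1f} ms   r = {r: .3f}   p = {p:.3g}   [{fl}]"
            )
        onset = (
            f"{-self.divergence_onset_ms:.1f} ms before saccade onset"
            if self.divergence_onset_ms is not None
            else "none detected"
        )
        lines.append(f"  divergence onset: {onset}")
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def save(self, out_dir: str | Path) -> Path:
        """Emit the tabular result surfaces as CSV files."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tag = self.paradigm.replace("-", "_")
        header = f"# config_hash: {self.config_hash}\n"

        def _write(df: pd.DataFrame, name: str):
            path = out / name
            with open(path, "w") as fh:
                fh.write(header)
                df.to_csv(fh, index=False)

        _write(self.labels, "labels.csv")
        _write(self.peaks, f"peaks_{tag}.csv")
        _write(self.comparisons, "comparisons.csv")
        bc = self.buildup_correlation
        _write(
            pd.DataFrame(
                dict(bin_center_ms=bc.bin_centers_ms, r=bc.r, p=bc.p,
                     flag=bc.flags)
            ),
            f"buildup_corr_{tag}.csv",
        )
        for align, pop in self.population.items():
            cols = {"time_ms": pop.time_ms}
            for cond in pop.mean:
                cols[f"mean_{cond}"] = pop.mean[cond]
                cols[f"se_{cond}"] = pop.se[cond]
            df = pd.DataFrame(cols)
            df["n_cells"] = pop.n_cells
            _write(df, f"population_{tag}_{align}.csv")
        sdf_dir = out / "sdf"
        sdf_dir.mkdir(exist_ok=True)
        for f in self.cell_fits:
            for align, traces in (
                ("target_onset", f.target_aligned),
                ("saccade_onset", f.saccade_aligned),
            ):
                for cond, tr in traces.items():
                    pd.DataFrame(
                        dict(time_ms=tr.time_ms, rate_hz=tr.rate_hz,
                             n_trials=tr.n_trials)
                    ).to_csv(
                        sdf_dir / f"cell_{f.cell:02d}_{align}_{cond}.csv",
                        index=False,
                    )
        if not self.exclusions.empty:
            _write(self.exclusions, "exclusions.csv")
        summary_rows = dict(
            paradigm=self.paradigm,
            config_hash=self.config_hash,
            n_cells=self.n_cells,
            switch_fraction=self.switch_fraction,
            suppression_percent=self.suppression_percent,
            divergence_onset_ms=self.divergence_onset_ms,
        )
        (out / "run_summary.json").write_text(
            json.dumps(summary_rows, indent=1)
        )
        return out
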