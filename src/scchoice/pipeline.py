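"""End-to-end experiment drivers: simulate -> label -> SDF -> analyze ->
report, for the two-target and one-target paradigms."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

from .config import RunConfig
from .model import EyeChoiceModel, EyeChoiceResults
from .session import Session, read_session, write_session
from .synthgen import make_session

logger = logging.getLogger(__name__)

__all__ = [
    "run_one_target",
    "run_two_target",
    "run_paradigm",
    "Report",
    "read_session",
    "write_session",
]


@dataclass
class Report:
    """Results plus the files emitted for one pipeline run."""

    results: EyeChoiceResults
    out_dir: Optional[Path] = None
    tables: Dict[str, Path] = field(default_factory=dict)
    figures: Dict[str, Path] = field(default_factory=dict)

    def summary(self) -> str:
        return self.results.summary()


def _emit(results: EyeChoiceResults, config: RunConfig) -> Report:
    report = Report(results=results)
    if config.out_dir is None:
        return report
    out = Path(config.out_dir)
    results.save(out)
    tag = config.paradigm.replace("-", "_")
    report.out_dir = out
    for name in (
        "labels.csv",
        f"peaks_{tag}.csv",
        "comparisons.csv",
        f"buildup_corr_{tag}.csv",
        f"population_{tag}_target_onset.csv",
        f"population_{tag}_saccade_onset.csv",
    ):
        report.tables[name] = out / name
    if config.write_figures:
        from . import plotting

        figs = out / "figures"
        figs.mkdir(exist_ok=True)
        for align in ("target_onset", "saccade_onset"):
            report.figures[f"population_{align}"] = plotting.plot_population(
                out / f"population_{tag}_{align}.csv",
                figs / f"population_{tag}_{align}.svg",
            )
        report.figures["peaks"] = plotting.plot_peak_scatter(
            out / f"peaks_{tag}.csv", figs / f"peaks_{tag}.svg"
        )
        report.figures["buildup"] = plotting.plot_buildup_correlation(
            out / f"buildup_corr_{tag}.csv", figs / f"buildup_corr_{tag}.svg"
        )
    return report


def run_paradigm(
    config: RunConfig, session: Session | None = None
) -> Report:
    """Run the full chain for ``config``'s paradigm.

    If ``session`` is None a synthetic session is generated from the
    config (and written to ``out_dir/session`` when an output directory is
    set); otherwise the provided session is analyzed.
    """
    if session is None:
        logger.info(
            "simulating %s session: %d cells x %d trials (seed %d)",
            config.paradigm, config.n_cells, config.trials_per_cell,
            config.seed,
        )
        session = make_session(config)
    results = EyeChoiceModel(session).fit()
    return _emit(results, config)


def run_one_target(config: RunConfig | None = None, **kw) -> Report:
    """One-target paradigm: a single bistable-zone target; the race decides
    the acquiring eye trial by trial."""
    config = config or RunConfig.defaults_for("one-target", **kw)
    if config.paradigm != "one-target":
        raise ValueError("config.paradigm must be 'one-target'")
    return run_paradigm(config)


def run_two_target(config: RunConfig | None = None, **kw) -> Report:
    """Two-target paradigm: the target alternates between the fixating-eye
    and deviated-eye receptive-field locations."""
    config = config or RunConfig.defaults_for("two-target", **kw)
    if config.paradigm != "two-target":
        raise ValueError("config.paradigm must be 'two-target'")
    return run_paradigm(config)
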