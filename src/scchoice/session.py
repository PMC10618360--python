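"""In-memory session containers and the on-disk session format.

A session directory holds::

    session.json            all configs, the seed, and per-trial ground truth
    trials.csv              one row per trial (ids, paradigm, target, labels)
    eyes/trial_NNNN.csv     time_ms, lh_deg, lv_deg, rh_deg, rv_deg
    spikes/trial_NNNN.txt   one spike timestamp (ms) per line

Reading validates the schema (columns, monotone time, sorted spikes) and
raises :class:`~scchoice.errors.SchemaError` naming the offending file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import SchemaError

EYE_COLUMNS = ["time_ms", "lh_deg", "lv_deg", "rh_deg", "rv_deg"]


@dataclass
class GroundTruth:
    """Generator-side truth for one trial (not visible to the analysis)."""

    fixating_eye: str  # 'L' or 'R'
    acquiring_eye: str
    winner: str  # 'neuron' or 'opposite'
    switch: bool
    saccade_onset_ms: float
    latency_ms: float
    gain_a: float
    gain_b: float
    suppressed_side: Optional[str]  # 'A', 'B' or None

    def to_dict(self) -> dict:
        return {
            "fixating_eye": self.fixating_eye,
            "acquiring_eye": self.acquiring_eye,
            "winner": self.winner,
            "switch": self.switch,
            "saccade_onset_ms": self.saccade_onset_ms,
            "latency_ms": self.latency_ms,
            "gain_a": self.gain_a,
            "gain_b": self.gain_b,
            "suppressed_side": self.suppressed_side,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(**d)


@dataclass
class Trial:
    """One delayed-saccade trial: binocular traces, events and spikes."""

    index: int
    cell_index: int
    paradigm: str
    target: Tuple[float, float]
    events: Dict[str, float]
    time_ms: np.ndarray
    eyes: np.ndarray  # (n_samples, 4): lh, lv, rh, rv in degrees
    spikes: np.ndarray  # sorted timestamps in ms from trial start
    truth: Optional[GroundTruth] = None

    def eye(self, which: str) -> np.ndarray:
        """Return the (n, 2) H/V trace of eye 'L' or 'R'."""
        if which == "L":
            return self.eyes[:, 0:2]
        if which == "R":
            return self.eyes[:, 2:4]
        raise ValueError(f"unknown eye {which!r}")


@dataclass
class Cell:
    index: int
    profile_dict: dict
    trials: List[Trial] = field(default_factory=list)


@dataclass
class Session:
    """A full recording session: one or more cells with their trials."""

    config: RunConfig
    cells: List[Cell] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return sum(len(c.trials) for c in self.cells)

    def all_trials(self):
        for cell in self.cells:
            yield from cell.trials

    def approx_equal(self, other: "Session", tol: float = 1e-4) -> bool:
        """Structural equality within the on-disk numeric precision."""
        if self.config.model_dump() != other.config.model_dump():
            return False
        if len(self.cells) != len(other.cells):
            return False
        for ca, cb in zip(self.cells, other.cells):
            if len(ca.trials) != len(cb.trials):
                return False
            for ta, tb in zip(ca.trials, cb.trials):
                if ta.target != tb.target or ta.events.keys() != tb.events.keys():
                    return False
                if any(
                    abs(ta.events[k] - tb.events[k]) > tol for k in ta.events
                ):
                    return False
                if not np.allclose(ta.eyes, tb.eyes, atol=tol):
                    return False
                if len(ta.spikes) != len(tb.spikes) or not np.allclose(
                    ta.spikes, tb.spikes, atol=tol
                ):
                    return False
        return True


def write_session(session: Session, directory: str | Path) -> Path:
    """Write a session to ``directory`` in the plain-text layout."""
    root = Path(directory)
    (root / "eyes").mkdir(parents=True, exist_ok=True)
    (root / "spikes").mkdir(parents=True, exist_ok=True)

    meta = {
        "config": session.config.model_dump(mode="json"),
        "cells": [
            {
                "index": c.index,
                "profile": c.profile_dict,
                "trial_indices": [t.index for t in c.trials],
            }
            for c in session.cells
        ],
        "truth": {
            str(t.index): (t.truth.to_dict() if t.truth is not None else None)
            for t in session.all_trials()
        },
        "events": {
            str(t.index): t.events for t in session.all_trials()
        },
    }
    (root / "session.json").write_text(json.dumps(meta, indent=1, sort_keys=True))

    rows = []
    for t in session.all_trials():
        rows.append(
            {
                "trial": t.index,
                "cell": t.cell_index,
                "paradigm": t.paradigm,
                "target_h": t.target[0],
                "target_v": t.target[1],
                "fixating_eye": t.truth.fixating_eye if t.truth else "",
                "acquiring_eye": t.truth.acquiring_eye if t.truth else "",
                "switch": t.truth.switch if t.truth else "",
            }
        )
        eye_df = pd.DataFrame(
            np.column_stack([t.time_ms, t.eyes]), columns=EYE_COLUMNS
        )
        eye_df.to_csv(
            root / "eyes" / f"trial_{t.index:04d}.csv", index=False,
            float_format="%.4f",
        )
        np.savetxt(
            root / "spikes" / f"trial_{t.index:04d}.txt",
            t.spikes,
            fmt="%.4f",
        )
    pd.DataFrame(rows).to_csv(root / "trials.csv", index=False)
    return root


def read_session(directory: str | Path) -> Session:
    """Read and schema-validate a session directory."""
    root = Path(directory)
    meta_path = root / "session.json"
    if not meta_path.exists():
        raise SchemaError(f"missing {meta_path}")
    meta = json.loads(meta_path.read_text())
    config = RunConfig(**meta["config"])

    trials_path = root / "trials.csv"
    if not trials_path.exists():
        raise SchemaError(f"missing {trials_path}")
    trials_df = pd.read_csv(trials_path)
    required = {"trial", "cell", "paradigm", "target_h", "target_v"}
    missing = required - set(trials_df.columns)
    if missing:
        raise SchemaError(f"trials.csv missing columns {sorted(missing)}")

    cells: Dict[int, Cell] = {}
    for cell_meta in meta["cells"]:
        cells[cell_meta["index"]] = Cell(
            index=cell_meta["index"], profile_dict=cell_meta["profile"]
        )

    for _, row in trials_df.iterrows():
        idx = int(row["trial"])
        eye_path = root / "eyes" / f"trial_{idx:04d}.csv"
        spk_path = root / "spikes" / f"trial_{idx:04d}.txt"
        if not eye_path.exists():
            raise SchemaError(f"trial {idx}: missing {eye_path}")
        eye_df = pd.read_csv(eye_path)
        if list(eye_df.columns) != EYE_COLUMNS:
            raise SchemaError(
                f"trial {idx}: {eye_path} columns {list(eye_df.columns)} != "
                f"{EYE_COLUMNS}"
            )
        time_ms = eye_df["time_ms"].to_numpy(float)
        if len(time_ms) < 2 or np.any(np.diff(time_ms) <= 0):
            raise SchemaError(f"trial {idx}: non-monotone time base in {eye_path}")
        events = meta["events"].get(str(idx))
        if events is None:
            raise SchemaError(f"trial {idx}: no events recorded in session.json")
        expected_len = int(
            round(
                (config.task.trial_len_ms) * config.task.sample_rate_hz / 1000.0
            )
        ) + 1
        if len(time_ms) != expected_len:
            raise SchemaError(
                f"trial {idx}: {eye_path} truncated "
                f"({len(time_ms)} samples, expected {expected_len})"
            )
        if spk_path.exists() and spk_path.stat().st_size > 0:
            spikes = np.atleast_1d(np.loadtxt(spk_path, dtype=float))
        else:
            spikes = np.empty(0)
        if spikes.size > 1 and np.any(np.diff(spikes) < 0):
            raise SchemaError(f"trial {idx}: unsorted spikes in {spk_path}")
        truth_d = meta["truth"].get(str(idx))
        truth = GroundTruth.from_dict(truth_d) if truth_d else None
        cell_idx = int(row["cell"])
        if cell_idx not in cells:
            raise SchemaError(f"trial {idx}: unknown cell {cell_idx}")
        cells[cell_idx].trials.append(
            Trial(
                index=idx,
                cell_index=cell_idx,
                paradigm=str(row["paradigm"]),
                target=(float(row["target_h"]), float(row["target_v"])),
                events={k: float(v) for k, v in events.items()},
                time_ms=time_ms,
                eyes=eye_df[EYE_COLUMNS[1:]].to_numpy(float),
                spikes=np.sort(spikes.astype(float)),
                truth=truth,
            )
        )
    return Session(config=config, cells=[cells[k] for k in sorted(cells)])
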