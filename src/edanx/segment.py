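"""Event-locked windowing and dataset assembly.

Each rated stimulus (a coin pickup in the motivating VR task) defines one
5-second analysis window taken immediately *before* the stimulus time — the
interval of maximal exposure to the phobic stimulus, ending just before the
self-report panel appears.  Windows carry synchronized slices of all signal
streams (raw conductance, tonic, phasic, heart rate), the SCR events whose
onsets fall inside the interval, and the 0-10 subjective distress rating
(SUD) that serves as the regression target (ANX).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decompose import DecompositionResult, ScrEvent
from .preprocess import RawRecording

__all__ = [
    "StimulusEvent",
    "LabeledWindow",
    "FeatureDataset",
    "extract_windows",
    "assemble_dataset",
    "read_events_csv",
    "write_events_csv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StimulusEvent:
    """A rated stimulus: time (s, recording clock) and SUD rating (0-10)."""

    time: float
    sud: int

    def __post_init__(self) -> None:
        if not (0 <= self.sud <= 10) or int(self.sud) != self.sud:
            raise ValueError(f"SUD must be an integer in 0..10, got {self.sud}")


@dataclass
class LabeledWindow:
    """One pre-stimulus analysis window with its anxiety rating."""

    subject_id: str
    window_index: int
    gsr: np.ndarray
    scl: np.ndarray
    scr: np.ndarray
    hr: np.ndarray
    events_in_window: list[ScrEvent]
    anx: int
    fs: float
    start_time: float = 0.0


@dataclass
class FeatureDataset:
    """Tabular layout: one row per window, 32 feature columns plus the rating."""

    frame: pd.DataFrame
    feature_names: list[str] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def features(self) -> np.ndarray:
        return self.frame[self.feature_names].to_numpy(dtype=float)

    def targets(self) -> np.ndarray:
        return self.frame["anx"].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, feature_names: list[str] | None = None) -> "FeatureDataset":
        from .features import FEATURE_NAMES

        frame = pd.read_csv(path)
        names = feature_names or [c for c in FEATURE_NAMES if c in frame.columns]
        missing = set(names) - set(frame.columns)
        if missing:
            raise ValueError(f"dataset CSV missing feature columns {sorted(missing)}")
        return cls(frame=frame, feature_names=list(names))


def extract_windows(
    recording: RawRecording,
    decomposition: DecompositionResult,
    events: list[StimulusEvent],
    window_len: float = 5.0,
) -> list[LabeledWindow]:
    """Cut one half-open window ``[t - window_len, t)`` per stimulus event.

    The stimulus sample itself is excluded (strictly pre-stimulus).  Events
    whose window would start before the recording does are skipped with a
    logged warning.  Windows of events less than ``window_len`` apart overlap;
    this is permitted and logged.
    """
    fs = recording.fs
    n_win = int(round(window_len * fs))
    windows: list[LabeledWindow] = []
    prev_end = -np.inf
    for idx, event in enumerate(sorted(events, key=lambda e: e.time), start=1):
        t_rel = event.time - recording.start_time
        stop = int(round(t_rel * fs))
        start = stop - n_win
        if start < 0 or stop > recording.n_samples:
            logger.warning(
                "skipping event at t=%.2f s: window outside recording", event.time
            )
            continue
        if event.time - window_len < prev_end:
            logger.info("window at t=%.2f s overlaps the previous one", event.time)
        prev_end = event.time
        t0 = recording.start_time + start / fs
        t1 = recording.start_time + stop / fs
        in_window = [
            e
            for e in decomposition.events
            if t0 <= recording.start_time + e.onset_time < t1
        ]
        windows.append(
            LabeledWindow(
                subject_id=recording.subject_id,
                window_index=len(windows) + 1,
                gsr=recording.gsr[start:stop].copy(),
                scl=decomposition.scl[start:stop].copy(),
                scr=decomposition.scr[start:stop].copy(),
                hr=recording.hr[start:stop].copy(),
                events_in_window=in_window,
                anx=event.sud,
                fs=fs,
                start_time=t0,
            )
        )
    return windows


def assemble_dataset(
    windows: list[LabeledWindow], features_per_window: list[pd.Series]
) -> FeatureDataset:
    """Stack per-window feature vectors into the canonical tabular layout.

    Rows are ordered by (subject, window index); duplicate keys are an error.
    """
    if len(windows) != len(features_per_window):
        raise ValueError(
            f"{len(windows)} windows but {len(features_per_window)} feature vectors"
        )
    if not windows:
        from .features import FEATURE_NAMES

        empty = pd.DataFrame(columns=["subject", "window", "anx", *FEATURE_NAMES])
        return FeatureDataset(frame=empty, feature_names=list(FEATURE_NAMES))

    feature_names = list(features_per_window[0].index)
    keys = [(w.subject_id, w.window_index) for w in windows]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (subject, window) pair in dataset assembly")
    rows = []
    for w, fv in zip(windows, features_per_window):
        if list(fv.index) != feature_names:
            raise ValueError("inconsistent feature naming across windows")
        rows.append({"subject": w.subject_id, "window": w.window_index, "anx": w.anx, **fv})
    frame = (
        pd.DataFrame(rows)
        .sort_values(["subject", "window"], kind="mergesort")
        .reset_index(drop=True)
    )
    return FeatureDataset(frame=frame, feature_names=feature_names)


def read_events_csv(path) -> list[StimulusEvent]:
    """Read a ``time_s,sud`` CSV of rated stimulus timestamps."""
    df = pd.read_csv(path)
    if not {"time_s", "sud"}.issubset(df.columns):
        raise ValueError("events CSV must have columns ['time_s', 'sud']")
    return [
        StimulusEvent(time=float(r.time_s), sud=int(r.sud)) for r in df.itertuples()
    ]


def write_events_csv(events: list[StimulusEvent], path) -> None:
    pd.DataFrame(
        {"time_s": [e.time for e in events], "sud": [e.sud for e in events]}
    ).to_csv(path, index=False)
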