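"""End-to-end orchestration: signals -> features -> estimator -> report.

``run_pipeline`` executes the full chain (preprocess, decompose, segment,
extract features, stratified split, exhaustive subset search, threshold
classification) either on synthetic sessions or on CSV inputs, and returns a
serializable :class:`RunReport`.  ``StreamingEstimator`` applies a fitted
model to a live sample stream with a sliding 5-s window.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import model as est
from .decompose import DecompositionConfig, continuous_decomposition
from .preprocess import PreprocessConfig, RawRecording, preprocess_recording
from .segment import (
    FeatureDataset,
    StimulusEvent,
    assemble_dataset,
    extract_windows,
    read_events_csv,
)
from .synth import SessionConfig, SubjectSession, gen_cohort

__all__ = [
    "PipelineConfig",
    "RunReport",
    "run_pipeline",
    "sessions_to_dataset",
    "StreamingEstimator",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run."""

    seed: int = 0
    synth: bool = True
    input_csv: str | None = None
    events_csv: str | None = None
    baseline_csv: str | None = None
    out_dir: str | None = None
    max_p: int = 3
    scheme: int = 2
    window_len: float = 5.0
    train_fraction: float = 6 / 7
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    cda: DecompositionConfig = field(default_factory=DecompositionConfig)
    session: SessionConfig = field(default_factory=SessionConfig)

    def __post_init__(self) -> None:
        if self.max_p < 1:
            raise ValueError("max_p must be >= 1")
        if self.scheme not in (2, 3):
            raise ValueError("scheme must be 2 or 3")
        if not self.synth and (self.input_csv is None or self.events_csv is None):
            raise ValueError("non-synthetic runs require input and events CSVs")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key, sub_cls in (
            ("preprocess", PreprocessConfig),
            ("cda", DecompositionConfig),
            ("session", SessionConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub_known = {f.name for f in dataclasses.fields(sub_cls)}
                sub_unknown = set(kwargs[key]) - sub_known
                if sub_unknown:
                    raise ValueError(
                        f"unknown keys under {key!r}: {sorted(sub_unknown)}"
                    )
                kwargs[key] = sub_cls(**kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


@dataclass
class RunReport:
    """Everything a run produced, traceable to pipeline artifacts."""

    seed: int
    n_rows: int
    n_identification: int
    n_validation: int
    per_p: list[dict]  # subset, SSR on IS/VS/all per subset size
    best_subset: list[str]
    best_model_json: str
    confusion_2: dict
    confusion_3: dict
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _decompose_session(
    recording: RawRecording, baseline: RawRecording | None, config: PipelineConfig
):
    dec = continuous_decomposition(recording.gsr, recording.fs, config=config.cda)
    if baseline is not None:
        bdec = continuous_decomposition(baseline.gsr, baseline.fs, config=config.cda)
        stats = feat.BaselineStats.from_baseline(baseline.gsr, bdec.scl, bdec.scr)
    else:
        # fall back to the session's own opening segment
        n = min(recording.n_samples, int(60 * recording.fs))
        stats = feat.BaselineStats.from_baseline(
            recording.gsr[:n], dec.scl[:n], dec.scr[:n]
        )
    return dec, stats


def sessions_to_dataset(
    sessions: list[SubjectSession], config: PipelineConfig | None = None
) -> FeatureDataset:
    """Run decomposition, segmentation and feature extraction on a cohort."""
    config = config or PipelineConfig()
    windows = []
    vectors = []
    for session in sessions:
        rec = preprocess_recording(session.recording, config.preprocess)
        dec, stats = _decompose_session(rec, session.baseline, config)
        for w in extract_windows(rec, dec, session.events, config.window_len):
            windows.append(w)
            vectors.append(feat.extract_all(w, stats))
    return assemble_dataset(windows, vectors)


def _search_tables(
    dataset: FeatureDataset, split: est.SplitPlan, max_p: int
) -> tuple[list[dict], est.SearchResult]:
    X = dataset.features()
    y = dataset.targets()
    per_p = []
    last = None
    for p in range(1, max_p + 1):
        result = est.exhaustive_search(
            X, y, split, p, feature_names=dataset.feature_names
        )
        per_p.append(
            {
                "p": p,
                "subset": list(result.best_subset),
                "ssr_identification": result.ssr_identification,
                "ssr_validation": result.ssr_validation,
                "ssr_total": result.ssr_total,
                "ssr_total_per_point": result.ssr_total / len(y),
                "evaluated_count": result.evaluated_count,
            }
        )
        last = result
    assert last is not None
    return per_p, last


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full chain and assemble the run report.

    In synthetic mode a seeded cohort is generated; otherwise the input,
    events and optional baseline CSVs are loaded.  Intermediate artifacts
    (feature dataset, best model, report) are written to ``out_dir`` when
    one is configured.
    """
    captured: list[str] = []
    if config.synth:
        session_cfg = dataclasses.replace(config.session, seed=config.seed)
        sessions = gen_cohort(session_cfg)
    else:
        from .preprocess import read_recording_csv

        rec = read_recording_csv(config.input_csv)
        events = read_events_csv(config.events_csv)
        baseline = (
            read_recording_csv(config.baseline_csv) if config.baseline_csv else None
        )
        sessions = [
            SubjectSession(
                recording=rec, baseline=baseline, events=events, ground_truth=None
            )
        ]

    dataset = sessions_to_dataset(sessions, config)
    if dataset.n_rows == 0:
        raise RuntimeError("segmentation produced no analysis windows")

    ratings = dataset.targets().astype(int)
    split = est.stratified_split(ratings, config.train_fraction, seed=config.seed)
    per_p, best = _search_tables(dataset, split, config.max_p)

    X = dataset.features()
    names = dataset.feature_names
    subset_idx = [names.index(f) for f in best.best_subset]
    # round to 9 decimals so float jitter cannot flip an estimate sitting
    # numerically on a class boundary (ratings are integers, bounds too)
    estimates = np.round(est.predict(best.best_model, X[:, subset_idx]), 9)

    reports = {}
    for k in (2, 3):
        scheme = est.ClassScheme.from_level_count(k)
        truths = [est.classify(v, scheme) for v in dataset.targets()]
        preds = [est.classify(v, scheme) for v in estimates]
        rep = est.confusion(truths, preds, scheme)
        reports[k] = {
            "labels": list(rep.labels),
            "counts": rep.counts.tolist(),
            "matrix": np.nan_to_num(rep.matrix).tolist(),
            "overall_accuracy": rep.overall_accuracy,
            "empty_classes": list(rep.empty_classes),
        }

    report = RunReport(
        seed=config.seed,
        n_rows=dataset.n_rows,
        n_identification=split.n_identification,
        n_validation=split.n_validation,
        per_p=per_p,
        best_subset=list(best.best_subset),
        best_model_json=best.best_model.to_json(),
        confusion_2=reports[2],
        confusion_3=reports[3],
        warnings=captured,
    )

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        dataset.to_csv(out / "features.csv")
        best.best_model.to_json(out / "model.json")
        report.to_json(out / "report.json")
    return report


class StreamingEstimator:
    """Sliding-window anxiety estimates from a live GSR/HR sample stream.

    Keeps a rolling context buffer (default 30 s) so the tonic/phasic
    decomposition has enough history, then evaluates the fitted model on the
    most recent 5-s window every ``stride`` seconds.  Until the buffer holds
    one full context the estimator reports "not ready" (returns None).
    """

    def __init__(
        self,
        model: est.PolyModel,
        baseline: feat.BaselineStats,
        fs: float = 51.2,
        window_len: float = 5.0,
        stride: float = 1.0,
        context_len: float = 30.0,
        cda: DecompositionConfig | None = None,
    ):
        self.model = model
        self.baseline = baseline
        self.fs = fs
        self.window_len = window_len
        self.stride = stride
        self.n_context = int(round(context_len * fs))
        self.n_window = int(round(window_len * fs))
        self.n_stride = max(1, int(round(stride * fs)))
        self.cda = cda or DecompositionConfig()
        self._gsr: list[float] = []
        self._hr: list[float] = []
        self._since_last = 0
        self.estimates: list[tuple[float, float]] = []  # (time, estimate)

    def update(self, gsr_chunk, hr_chunk) -> float | None:
        """Feed new samples; return the latest estimate or None if not ready."""
        gsr_chunk = np.atleast_1d(np.asarray(gsr_chunk, dtype=float))
        hr_chunk = np.atleast_1d(np.asarray(hr_chunk, dtype=float))
        if gsr_chunk.size != hr_chunk.size:
            raise ValueError("GSR and HR chunks must have the same length")
        self._gsr.extend(gsr_chunk.tolist())
        self._hr.extend(hr_chunk.tolist())
        self._since_last += gsr_chunk.size
        keep = self.n_context
        if len(self._gsr) > keep:
            self._gsr = self._gsr[-keep:]
            self._hr = self._hr[-keep:]
        if len(self._gsr) < keep or self._since_last < self.n_stride:
            return self.estimates[-1][1] if self.estimates else None
        self._since_last = 0
        return self._evaluate()

    def _evaluate(self) -> float:
        from .segment import LabeledWindow

        gsr = np.array(self._gsr)
        hr = np.array(self._hr)
        dec = continuous_decomposition(gsr, self.fs, config=self.cda)
        sl = slice(gsr.size - self.n_window, gsr.size)
        t0 = (gsr.size - self.n_window) / self.fs
        in_window = [e for e in dec.events if e.onset_time >= t0]
        window = LabeledWindow(
            subject_id="stream",
            window_index=len(self.estimates) + 1,
            gsr=gsr[sl],
            scl=dec.scl[sl],
            scr=dec.scr[sl],
            hr=hr[sl],
            events_in_window=in_window,
            anx=0,
            fs=self.fs,
        )
        vec = feat.extract_all(window, self.baseline)
        x = vec[list(self.model.feature_names)].to_numpy(dtype=float)
        value = float(est.predict(self.model, x[None, :])[0])
        self.estimates.append((len(self._gsr) / self.fs, value))
        return value
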