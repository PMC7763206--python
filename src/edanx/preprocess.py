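"""Conditioning of raw biosignals before decomposition and feature extraction.

Skin conductance is typically acquired at a rate high enough to keep mains
interference (50 Hz and its harmonics) below Nyquist, low-pass filtered with a
linear-phase FIR filter, and then decimated down to a working rate whose
Nyquist still covers the EDA bandwidth.  The working rate used throughout this
package is 51.2 Hz, which makes the feature-stage PSD grid (0-25.6 Hz in
0.05 Hz steps) span Nyquist exactly.

Recordings already sampled at 51.2 Hz (the wearable used in the motivating
protocol reports GSR at that rate) bypass filtering and decimation, but then a
50.032 Hz mains component folds to 1.168 Hz and may contaminate the phasic
band; :func:`alias_frequency` quantifies that folding and
:func:`preprocess_recording` warns when the bypass path is taken.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "RawRecording",
    "FilterSpec",
    "PreprocessConfig",
    "alias_frequency",
    "design_lowpass",
    "apply_fir",
    "fir_edge_mask",
    "decimate",
    "normalize",
    "check_reference_response",
    "read_recording_csv",
    "write_recording_csv",
    "preprocess_recording",
]

#: Working sampling rate after decimation (Hz).
TARGET_FS = 51.2


@dataclass
class RawRecording:
    """Synchronized skin-conductance and heart-rate sample streams.

    Parameters
    ----------
    gsr : ndarray
        Skin conductance samples in microsiemens (µS); must be finite and
        non-negative.
    hr : ndarray
        Heart-rate samples in beats per minute, same length as ``gsr``.
    fs : float
        Sampling rate in Hz.
    start_time : float
        Time of the first sample in seconds.
    subject_id : str
        Optional identifier used when assembling multi-subject datasets.
    """

    gsr: np.ndarray
    hr: np.ndarray
    fs: float
    start_time: float = 0.0
    subject_id: str = "S1"

    def __post_init__(self) -> None:
        self.gsr = np.asarray(self.gsr, dtype=float)
        self.hr = np.asarray(self.hr, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.fs}")
        if self.gsr.shape != self.hr.shape:
            raise ValueError("gsr and hr streams must have the same length")
        if not np.all(np.isfinite(self.gsr)) or not np.all(np.isfinite(self.hr)):
            raise ValueError("all samples must be finite")
        if np.any(self.gsr < 0):
            raise ValueError("skin conductance cannot be negative")

    @property
    def n_samples(self) -> int:
        return self.gsr.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def time(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.fs


@dataclass
class FilterSpec:
    """Linear-phase FIR low-pass design parameters.

    ``n_taps`` must be odd so the group delay ``(n_taps - 1) / 2`` is an
    integer number of samples and can be compensated exactly.
    """

    cutoff: float = 25.0
    n_taps: int = 257
    design_window: str = "hamming"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.n_taps < 3 or self.n_taps % 2 == 0:
            raise ValueError("n_taps must be an odd integer >= 3")
        if self.design_window not in ("hamming", "blackman"):
            raise ValueError("design_window must be 'hamming' or 'blackman'")


@dataclass
class PreprocessConfig:
    fs_raw: float = 512.0
    fs_target: float = TARGET_FS
    fir: FilterSpec = field(default_factory=FilterSpec)
    qc_min_spike_uS: float = 0.05


def alias_frequency(f: float, fs: float) -> float:
    """Fold a frequency into the first Nyquist zone of a sampling rate.

    A component at ``f`` Hz sampled at ``fs`` Hz appears at
    ``|f - fs * round(f / fs)|``, always within ``[0, fs / 2]``.  A 50.032 Hz
    mains tone sampled at 51.2 Hz folds to 1.168 Hz — squarely inside the
    phasic EDA band.
    """
    if fs <= 0:
        raise ValueError(f"sampling rate must be positive, got {fs}")
    if f < 0:
        raise ValueError(f"frequency must be non-negative, got {f}")
    return float(abs(f - fs * np.round(f / fs)))


def design_lowpass(spec: FilterSpec, fs: float) -> np.ndarray:
    """Design linear-phase FIR low-pass coefficients with unit DC gain."""
    if spec.cutoff >= fs / 2:
        raise ValueError(
            f"cutoff {spec.cutoff} Hz must be below Nyquist {fs / 2} Hz"
        )
    return sps.firwin(spec.n_taps, spec.cutoff, window=spec.design_window, fs=fs)


def apply_fir(x: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Filter and compensate the integer group delay of a linear-phase FIR.

    The output has the same length as the input and is aligned to the input
    timeline.  The first and last ``(n_taps - 1) / 2`` samples are transient
    (the convolution has not fully overlapped the data there); use
    :func:`fir_edge_mask` to identify them.
    """
    x = np.asarray(x, dtype=float)
    coeffs = np.asarray(coeffs, dtype=float)
    n_taps = coeffs.size
    if x.size <= n_taps:
        raise ValueError(
            f"signal length {x.size} must exceed filter length {n_taps}"
        )
    delay = (n_taps - 1) // 2
    full = np.convolve(x, coeffs, mode="full")
    return full[delay : delay + x.size]


def fir_edge_mask(n_samples: int, n_taps: int) -> np.ndarray:
    """Boolean mask of samples free of FIR start/end transients."""
    delay = (n_taps - 1) // 2
    mask = np.zeros(n_samples, dtype=bool)
    if n_samples > 2 * delay:
        mask[delay : n_samples - delay] = True
    return mask


def decimate(x: np.ndarray, factor: int) -> np.ndarray:
    """Keep every ``factor``-th sample starting at index 0.

    The caller is responsible for low-pass filtering first so that the reduced
    Nyquist rate still covers the signal bandwidth.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError(f"decimation factor must be a positive integer, got {factor}")
    return np.asarray(x)[:: int(factor)]


def normalize(x: np.ndarray, method: str = "minmax") -> np.ndarray:
    """Rescale a signal to [0, 1] (``minmax``) or to zero mean / unit sample
    standard deviation (``zscore``, N-1 denominator).

    A constant signal has no scale; it maps to all zeros and a
    ``UserWarning`` is emitted instead of dividing by zero.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot normalize an empty signal")
    if method == "minmax":
        lo, hi = x.min(), x.max()
        if hi == lo:
            warnings.warn("constant signal: min-max normalization returns zeros")
            return np.zeros_like(x)
        return (x - lo) / (hi - lo)
    if method == "zscore":
        if x.size < 2:
            raise ValueError("zscore requires at least 2 samples")
        sd = x.std(ddof=1)
        if sd == 0:
            warnings.warn("constant signal: z-score normalization returns zeros")
            return np.zeros_like(x)
        return (x - x.mean()) / sd
    raise ValueError(f"unknown normalization method {method!r}")


def check_reference_response(
    gsr: np.ndarray,
    fs: float,
    breath_time: float,
    min_spike_uS: float = 0.05,
    response_window: float = 3.0,
) -> tuple[bool, float | None]:
    """Sensor quality check: a deep breath should evoke a conductance spike.

    Electrode contact is judged adequate when skin conductance rises by at
    least ``min_spike_uS`` within ``response_window`` seconds of the breath.

    Returns
    -------
    (ok, latency)
        ``ok`` is True when the rise criterion is met; ``latency`` is the time
        from ``breath_time`` to the first sample reaching the criterion, or
        None when the check fails.
    """
    gsr = np.asarray(gsr, dtype=float)
    i0 = int(round(breath_time * fs))
    i1 = int(round((breath_time + response_window) * fs))
    if breath_time < 0 or int(round((breath_time + 5.0) * fs)) > gsr.size:
        raise ValueError("reference-response window extends outside the recording")
    seg = gsr[i0 : i1 + 1]
    rise = seg - seg[0]
    hits = np.nonzero(rise >= min_spike_uS)[0]
    if hits.size == 0:
        return False, None
    return True, float(hits[0] / fs)


def read_recording_csv(path, subject_id: str = "S1") -> RawRecording:
    """Read a ``time_s,gsr_uS,hr_bpm`` CSV into a :class:`RawRecording`.

    The HR column may contain gaps (wearables report HR at a lower rate than
    conductance); gaps are forward-filled, and leading gaps back-filled.
    """
    df = pd.read_csv(path)
    required = {"time_s", "gsr_uS", "hr_bpm"}
    if not required.issubset(df.columns):
        raise ValueError(f"recording CSV must have columns {sorted(required)}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("recording must contain at least 2 samples")
    dt = np.diff(t)
    fs = 1.0 / np.median(dt)
    hr = df["hr_bpm"].ffill().bfill().to_numpy(dtype=float)
    return RawRecording(
        gsr=df["gsr_uS"].to_numpy(dtype=float),
        hr=hr,
        fs=float(fs),
        start_time=float(t[0]),
        subject_id=subject_id,
    )


def write_recording_csv(recording: RawRecording, path) -> None:
    pd.DataFrame(
        {
            "time_s": recording.time,
            "gsr_uS": recording.gsr,
            "hr_bpm": recording.hr,
        }
    ).to_csv(path, index=False)


def preprocess_recording(
    recording: RawRecording, config: PreprocessConfig | None = None
) -> RawRecording:
    """Condition a raw recording down to the 51.2 Hz working rate.

    Recordings acquired above the target rate are FIR low-pass filtered
    (mains rejection) and decimated by the integer ratio ``fs / fs_target``.
    Recordings already at the target rate are passed through unchanged with a
    warning: mains interference, if present at acquisition, has already
    folded into the EDA band (e.g. 50.032 Hz -> 1.168 Hz at 51.2 Hz) and
    cannot be removed by filtering after the fact.

    HR streams come pre-filtered from the acquisition device (they are derived
    from PPG/ECG processing), so only the conductance channel is filtered; HR
    is decimated on the same sample grid to stay synchronized.
    """
    config = config or PreprocessConfig()
    fs_target = config.fs_target
    if abs(recording.fs - fs_target) < 1e-9:
        warnings.warn(
            "recording already at the target rate; mains aliases "
            f"(e.g. {alias_frequency(50.032, fs_target):.3f} Hz) may be present"
        )
        return recording
    ratio = recording.fs / fs_target
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-6 or factor < 1:
        raise ValueError(
            f"sampling rate {recording.fs} Hz is not an integer multiple of "
            f"the target rate {fs_target} Hz"
        )
    taps = design_lowpass(config.fir, recording.fs)
    gsr_f = apply_fir(recording.gsr, taps)
    gsr_f = np.clip(gsr_f, 0.0, None)  # filter ripple can dip below zero
    return RawRecording(
        gsr=decimate(gsr_f, factor),
        hr=decimate(recording.hr, factor),
        fs=fs_target,
        start_time=recording.start_time,
        subject_id=recording.subject_id,
    )
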