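"""The 32 physiological features computed on each 5-s analysis window.

Three signal streams derived from skin conductance (the raw trace GSR, the
tonic level SCL, the phasic component SCR) each contribute six time-domain
statistics (MAV, MAR, STD, WL, SSC, WAMP) and two spectral statistics
(median and mean frequency of the power spectral density), the phasic event
stream contributes three event statistics (NR, AVRA, MAXRA), and the heart
rate stream contributes two time-domain (MAV, STD) and three band-power
statistics (LFI, HFI, HLR) — 18 + 6 + 3 + 2 + 3 = 32 features in a fixed
canonical order (:data:`FEATURE_NAMES`).

Definitions follow the conventions of surface-signal feature engineering:

- MAV: mean absolute value, ``(1/N) sum |x_k|``.
- MAR: MAV relative to the session's baseline MAV (dimensionless).
- STD: sample standard deviation (N-1 denominator).
- WL: waveform length, here the sum of *squared* first differences
  ``sum (x_k - x_{k-1})^2`` (set ``wl_absolute=True`` for the conventional
  sum of absolute differences).
- SSC: slope-sign changes, counting turns whose adjacent slopes both exceed
  a noise deadband of 0.001 µS.
- WAMP: Willison amplitude, counting first differences of at least 0.5 µS.
- LFI/HFI: mean squared value of the heart-rate signal band-passed to
  0.04-0.15 Hz / 0.15-0.4 Hz by 3rd-order Butterworth filters; HLR = HFI/LFI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .decompose import ScrEvent
from .segment import LabeledWindow

__all__ = [
    "FEATURE_NAMES",
    "BaselineStats",
    "PsdEstimate",
    "mav",
    "mar",
    "std",
    "wl",
    "ssc",
    "wamp",
    "event_features",
    "psd",
    "fmd",
    "fmn",
    "hr_time_features",
    "hr_band_decompose",
    "hr_freq_features",
    "extract_all",
]

#: Canonical ordering of the 32 features; dataset columns, model subsets and
#: exported CSVs all follow this order.
FEATURE_NAMES: tuple[str, ...] = (
    "GSR_mav", "SCL_mav", "SCR_mav",
    "GSR_mar", "SCL_mar", "SCR_mar",
    "GSR_std", "SCL_std", "SCR_std",
    "GSR_wl", "SCL_wl", "SCR_wl",
    "GSR_ssc", "SCL_ssc", "SCR_ssc",
    "GSR_wamp", "SCL_wamp", "SCR_wamp",
    "GSR_nr", "GSR_avra", "GSR_maxra",
    "GSR_fmd", "SCL_fmd", "SCR_fmd",
    "GSR_fmn", "SCL_fmn", "SCR_fmn",
    "HR_mav", "HR_std",
    "HR_lfi", "HR_hfi", "HR_hlr",
)

#: Deadband for slope-sign-change counting (µS).
SSC_EPS = 0.001
#: Willison amplitude threshold (µS).
WAMP_EPS = 0.5
#: Canonical PSD grid: 0 to 25.6 Hz in 0.05 Hz steps at fs = 51.2 Hz.
PSD_STEP = 0.05

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)


@dataclass(frozen=True)
class BaselineStats:
    """Per-session baseline MAVs (X_B) of the three conductance streams.

    Computed once per subject over the 60-s resting baseline recording and
    used to express window-level MAVs relative to the individual's resting
    conductance (the MAR features), removing inter-individual offsets.
    """

    xb_gsr: float
    xb_scl: float
    xb_scr: float

    def __post_init__(self) -> None:
        if self.xb_gsr < 0 or self.xb_scl < 0 or self.xb_scr < 0:
            raise ValueError("baseline statistics must be non-negative")

    @classmethod
    def from_baseline(
        cls, gsr: np.ndarray, scl: np.ndarray, scr: np.ndarray
    ) -> "BaselineStats":
        return cls(
            xb_gsr=mav(gsr), xb_scl=mav(scl), xb_scr=max(mav(scr), 1e-12)
        )


@dataclass
class PsdEstimate:
    """One-sided power spectral density on a fixed uniform frequency grid."""

    frequencies: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        if self.frequencies.shape != self.power.shape:
            raise ValueError("frequency grid and power must have equal length")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    @property
    def total_power(self) -> float:
        return float(self.power.sum())


def _as1d(x) -> np.ndarray:
    return np.asarray(x, dtype=float).ravel()


def mav(x) -> float:
    """Mean absolute value."""
    x = _as1d(x)
    if x.size == 0:
        raise ValueError("mav requires a non-empty signal")
    return float(np.mean(np.abs(x)))


def mar(x, xb: float) -> float:
    """Mean absolute value relative to the session baseline MAV."""
    if xb <= 0:
        raise ValueError(f"baseline statistic must be positive, got {xb}")
    return mav(x) / xb


def std(x) -> float:
    """Sample standard deviation (N-1 denominator)."""
    x = _as1d(x)
    if x.size < 2:
        raise ValueError("std requires at least 2 samples")
    return float(np.std(x, ddof=1))


def wl(x, absolute: bool = False) -> float:
    """Waveform length: sum of squared (default) or absolute first differences."""
    x = _as1d(x)
    if x.size < 2:
        raise ValueError("wl requires at least 2 samples")
    d = np.diff(x)
    return float(np.sum(np.abs(d)) if absolute else np.sum(d * d))


def ssc(x, eps: float = SSC_EPS) -> int:
    """Slope sign changes exceeding a deadband on both adjacent slopes."""
    x = _as1d(x)
    if x.size < 3:
        raise ValueError("ssc requires at least 3 samples")
    d1 = x[1:-1] - x[:-2]
    d2 = x[2:] - x[1:-1]
    return int(np.sum((d1 * d2 < 0) & (np.abs(d1) >= eps) & (np.abs(d2) >= eps)))


def wamp(x, eps_w: float = WAMP_EPS) -> int:
    """Willison amplitude: count of first differences of magnitude >= eps_w."""
    x = _as1d(x)
    if x.size < 2:
        raise ValueError("wamp requires at least 2 samples")
    return int(np.sum(np.abs(np.diff(x)) >= eps_w))


def event_features(events_in_window: list[ScrEvent]) -> tuple[int, float, float]:
    """(NR, AVRA, MAXRA) of the SCR events inside a window.

    With no events both amplitude statistics are 0 ("no response" is treated
    as minimal response, keeping feature vectors finite).
    """
    nr = len(events_in_window)
    if nr == 0:
        return 0, 0.0, 0.0
    amps = np.array([e.amplitude for e in events_in_window], dtype=float)
    return nr, float(amps.mean()), float(amps.max())


def psd(x, fs: float = 51.2) -> PsdEstimate:
    """Zero-padded periodogram on the canonical 0.05 Hz grid.

    At the 51.2 Hz working rate a 1024-point transform places bins at exactly
    0, 0.05, ..., 25.6 Hz (513 points).  The scaling satisfies Parseval: the
    one-sided powers sum to the mean squared value of the signal.  For other
    sampling rates the grid is recomputed to span [0, fs/2] at the same step,
    with a warning.
    """
    x = _as1d(x)
    if x.size == 0:
        raise ValueError("psd requires a non-empty signal")
    n_bins = round(fs / 2 / PSD_STEP)
    if abs(n_bins * PSD_STEP - fs / 2) > 1e-9:
        warnings.warn(
            f"fs={fs} Hz does not put Nyquist on the {PSD_STEP} Hz grid; "
            "grid recomputed to the nearest bin"
        )
    if fs != 51.2:
        warnings.warn(
            f"canonical PSD grid assumes fs=51.2 Hz; got {fs} Hz, "
            "recomputing grid to [0, fs/2]"
        )
    nfft = 2 * n_bins
    while nfft < x.size:  # never truncate the data
        nfft *= 2
    X = np.fft.rfft(x, nfft)
    power = np.abs(X) ** 2 / (x.size * nfft)
    power[1:-1] *= 2.0  # one-sided fold of the interior bins
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return PsdEstimate(frequencies=freqs, power=power)


def fmd(p: PsdEstimate) -> float:
    """Median frequency: the grid split equalizing spectral power.

    Returns the frequency at the index ``M`` minimizing
    ``|sum_{k<M} P_k - sum_{k>=M} P_k|``.  Ties are resolved to the largest
    ``M`` whose left mass does not exceed half the total, so that a spectrum
    concentrated in a single bin reports that bin's frequency.
    """
    total = p.total_power
    if total <= 0:
        raise ValueError("median frequency undefined for zero total power")
    left = np.concatenate([[0.0], np.cumsum(p.power)[:-1]])  # sum_{k<M}
    diffs = np.abs(2.0 * left - total)
    ties = np.flatnonzero(diffs == diffs.min())
    balanced = ties[left[ties] <= total / 2.0]
    m = int(balanced[-1]) if balanced.size else int(ties[0])
    return float(p.frequencies[m])


def fmn(p: PsdEstimate) -> float:
    """Mean frequency: the power-weighted centroid of the grid."""
    total = p.total_power
    if total <= 0:
        raise ValueError("mean frequency undefined for zero total power")
    return float(np.sum(p.frequencies * p.power) / total)


def hr_time_features(h) -> tuple[float, float]:
    """(MAV, STD) of the window's heart-rate vector."""
    h = _as1d(h)
    if h.size < 2:
        raise ValueError("heart-rate features require at least 2 samples")
    return mav(h), std(h)


def _butter_band(band: tuple[float, float], fs: float):
    return sps.butter(3, band, btype="bandpass", fs=fs, output="sos")


def hr_band_decompose(h, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Split heart rate into LF (0.04-0.15 Hz) and HF (0.15-0.4 Hz) signals.

    Two 3rd-order Butterworth band-pass filters, applied causally (single
    pass, real-time compatible) with initial conditions matched to the first
    sample to shorten the start-up transient.  Second-order-section form is
    used because the corner frequencies sit ~3 decades below Nyquist at the
    51.2 Hz working rate.
    """
    h = _as1d(h)
    if fs <= 2 * HF_BAND[1]:
        raise ValueError(
            f"sampling rate {fs} Hz cannot resolve the {HF_BAND[1]} Hz band edge"
        )
    out = []
    for band in (LF_BAND, HF_BAND):
        sos = _butter_band(band, fs)
        zi = sps.sosfilt_zi(sos) * h[0]
        y, _ = sps.sosfilt(sos, h, zi=zi)
        out.append(y)
    return out[0], out[1]


def hr_freq_features(h_low, h_high) -> tuple[float, float, float]:
    """(LFI, HFI, HLR): band intensities and their ratio HFI / LFI."""
    h_low = _as1d(h_low)
    h_high = _as1d(h_high)
    lfi = float(np.mean(h_low**2))
    hfi = float(np.mean(h_high**2))
    if lfi == 0:
        raise ValueError("HLR undefined: zero low-frequency intensity")
    return lfi, hfi, hfi / lfi


def extract_all(
    window: LabeledWindow,
    baseline: BaselineStats,
    fs: float | None = None,
    wl_absolute: bool = False,
) -> pd.Series:
    """Compute the full 32-feature vector of one window, in canonical order.

    Degenerate windows are kept finite: a phasic stream that is identically
    zero has no spectrum, so its FMD/FMN are reported as 0 Hz, and a window
    with zero LF intensity reports HLR = 0.  These guards only matter for
    pathological (e.g. perfectly constant) synthetic inputs.
    """
    fs = fs or window.fs
    values: dict[str, float] = {}
    streams = {"GSR": window.gsr, "SCL": window.scl, "SCR": window.scr}
    baselines = {"GSR": baseline.xb_gsr, "SCL": baseline.xb_scl, "SCR": baseline.xb_scr}
    for name, x in streams.items():
        values[f"{name}_mav"] = mav(x)
        values[f"{name}_mar"] = mar(x, baselines[name])
        values[f"{name}_std"] = std(x)
        values[f"{name}_wl"] = wl(x, absolute=wl_absolute)
        values[f"{name}_ssc"] = float(ssc(x))
        values[f"{name}_wamp"] = float(wamp(x))
    nr, avra, maxra = event_features(window.events_in_window)
    values["GSR_nr"] = float(nr)
    values["GSR_avra"] = avra
    values["GSR_maxra"] = maxra
    for name, x in streams.items():
        spectrum = psd(x, fs)
        if spectrum.total_power > 0:
            values[f"{name}_fmd"] = fmd(spectrum)
            values[f"{name}_fmn"] = fmn(spectrum)
        else:
            values[f"{name}_fmd"] = 0.0
            values[f"{name}_fmn"] = 0.0
    hr_mav, hr_std = hr_time_features(window.hr)
    values["HR_mav"] = hr_mav
    values["HR_std"] = hr_std
    h_low, h_high = hr_band_decompose(window.hr, fs)
    lfi = float(np.mean(h_low**2))
    hfi = float(np.mean(h_high**2))
    values["HR_lfi"] = lfi
    values["HR_hfi"] = hfi
    values["HR_hlr"] = hfi / lfi if lfi > 0 else 0.0
    vec = pd.Series([values[k] for k in FEATURE_NAMES], index=list(FEATURE_NAMES))
    if not np.all(np.isfinite(vec.to_numpy())):
        raise ValueError("non-finite feature value produced")
    return vec
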