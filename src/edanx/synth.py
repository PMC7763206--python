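"""Seeded generator of synthetic VR-exposure sessions with ground truth.

No public dataset exists for the motivating acrophobia study, so this module
emulates its acquisition conditions end to end: a latent 0-10 anxiety
trajectory drives both skin conductance (tonic level drifting inside the
physiological 2-20 µS range, Bateman-shaped phasic responses from an
inhomogeneous Poisson process whose rate climbs from a resting 2/min to
20/min under high arousal, amplitudes within 0.1-3 µS, optional mains
interference at 50.032 Hz and harmonics) and heart rate (resting ~65 bpm
rising with anxiety, LF and HF variability with the HF component shrinking
as vagal tone withdraws).  Each subject collects 15 rated events; the
default 7 x 15 cohort reproduces the study's marginal distribution of
reported anxiety levels.

The anxiety -> physiology link is generative while the estimator learns the
inverse map from features computed on the signals alone, so pipeline
recovery tests are not circular.  All randomness flows from a single seed
via spawned child generators; identical seeds give bit-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .decompose import BatemanParams, bateman_kernel
from .model import PolyModel
from .preprocess import RawRecording
from .segment import StimulusEvent

__all__ = [
    "SessionConfig",
    "SessionGroundTruth",
    "SubjectSession",
    "STUDY_SUD_HISTOGRAM",
    "make_trajectory",
    "gen_mains_noise",
    "gen_eda",
    "gen_hr",
    "gen_session",
    "gen_cohort",
]

#: Marginal distribution of reported anxiety levels (levels 0..10) in the
#: motivating 7-subject study; used as the default cohort histogram.
STUDY_SUD_HISTOGRAM: tuple[int, ...] = (41, 16, 12, 9, 7, 4, 4, 2, 5, 2, 3)


@dataclass
class SessionConfig:
    """Generator settings; defaults emulate the study acquisition conditions."""

    fs: float = 51.2
    n_events: int = 15
    n_subjects: int = 7
    event_spacing: float = 20.0  # s between rated events
    lead_in: float = 20.0  # s of rest before the first episode
    baseline_duration: float = 60.0  # s of resting baseline per subject

    scl_base: float = 6.0  # µS, within the physiological 2-20 µS range
    scl_drift_sd: float = 0.05  # µS per sqrt(s), slow tonic random walk
    scl_range: tuple[float, float] = (2.0, 20.0)
    scr_amp_range: tuple[float, float] = (0.1, 3.0)
    nsscr_rate_rest: float = 2.0  # per minute at anxiety 0
    nsscr_rate_arousal: float = 20.0  # per minute at anxiety 10
    bateman: BatemanParams = field(default_factory=BatemanParams)
    gsr_noise_sd: float = 0.01  # µS measurement noise

    mains_freq: float = 50.032
    mains_harmonics: int = 3
    mains_amp: float = 0.02  # µS; folds to 1.168 Hz when sampled at 51.2 Hz

    hr_base: float = 65.0  # bpm resting heart rate
    hr_gain: float = 3.0  # bpm per anxiety unit
    lf_freq: float = 0.1  # Hz, inside the 0.04-0.15 band
    hf_freq: float = 0.25  # Hz, inside the 0.15-0.4 band
    lf_amp: float = 1.5  # bpm
    hf_amp: float = 2.0  # bpm at rest; shrinks with anxiety (vagal withdrawal)
    hr_noise_sd: float = 0.3  # bpm

    sud_noise: float = 1.0  # scale of the uniform(-0.5, 0.5) reporting noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.n_events < 1 or self.n_subjects < 1:
            raise ValueError("invalid session configuration")
        if not (self.scl_range[0] <= self.scl_base <= self.scl_range[1]):
            raise ValueError("scl_base must lie inside scl_range")
        if self.scr_amp_range[0] <= 0 or self.scr_amp_range[1] < self.scr_amp_range[0]:
            raise ValueError("invalid SCR amplitude range")

    @property
    def event_times(self) -> np.ndarray:
        return self.lead_in + self.event_spacing * np.arange(1, self.n_events + 1)

    @property
    def duration(self) -> float:
        return float(self.event_times[-1] + 5.0)

    def noiseless(self) -> "SessionConfig":
        """A copy with every noise source silenced (for recovery tests)."""
        return replace(
            self,
            gsr_noise_sd=0.0,
            mains_amp=0.0,
            lf_amp=0.0,
            hf_amp=0.0,
            hr_noise_sd=0.0,
            sud_noise=0.0,
        )


@dataclass
class SessionGroundTruth:
    """Latent state behind one generated session."""

    trajectory_knots: list[tuple[float, float]]  # (time, level) steps
    scr_schedule: list[tuple[float, float]]  # (onset s, amplitude µS)
    sud_per_event: list[int]
    hr_base: float
    hr_gain: float

    def anxiety_at(self, t: float) -> float:
        return make_trajectory(self.trajectory_knots)(t)

    @property
    def true_model(self) -> PolyModel:
        """The exact inverse of the anxiety -> mean-HR link as a PolyModel.

        ``anx = (HR_mav - hr_base) / hr_gain`` is linear in the single
        feature HR_mav, representable with one beta coefficient and an
        intercept (quadratic terms zero).
        """
        coef = np.array([0.0, 1.0 / self.hr_gain, -self.hr_base / self.hr_gain])
        return PolyModel(feature_names=["HR_mav"], coef=coef)

    def to_dict(self) -> dict:
        return {
            "trajectory_knots": [list(k) for k in self.trajectory_knots],
            "scr_schedule": [list(s) for s in self.scr_schedule],
            "sud_per_event": self.sud_per_event,
            "hr_base": self.hr_base,
            "hr_gain": self.hr_gain,
        }


@dataclass
class SubjectSession:
    """One synthetic subject: session recording, baseline, rated events, truth."""

    recording: RawRecording
    baseline: RawRecording
    events: list[StimulusEvent]
    ground_truth: SessionGroundTruth


def make_trajectory(knots: list[tuple[float, float]]):
    """Piecewise-constant anxiety trajectory from (time, level) step knots."""
    if not knots:
        return lambda t: np.zeros_like(np.asarray(t, dtype=float))
    times = np.array([k[0] for k in knots])
    levels = np.array([k[1] for k in knots])
    order = np.argsort(times, kind="mergesort")
    times, levels = times[order], levels[order]

    def anx(t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(times, t, side="right") - 1
        out = np.where(idx >= 0, levels[np.clip(idx, 0, None)], 0.0)
        return out if out.ndim else float(out)

    return anx


def gen_mains_noise(
    fs: float,
    duration: float,
    fundamental: float = 50.032,
    n_harmonics: int = 3,
    amplitude: float = 0.02,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Mains interference: harmonics at k*fundamental with 1/k amplitudes.

    Sampled below Nyquist the fundamental appears at its true frequency; at
    the 51.2 Hz working rate it folds to 1.168 Hz (and the second harmonic to
    2.336 Hz), mimicking the contamination seen on under-sampled recordings.
    Harmonic phases are drawn from ``rng`` for reproducibility.
    """
    rng = rng or np.random.default_rng(0)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    out = np.zeros(n)
    if amplitude == 0:
        return out
    for k in range(1, n_harmonics + 1):
        phase = rng.uniform(0, 2 * np.pi)
        out += (amplitude / k) * np.sin(2 * np.pi * k * fundamental * t + phase)
    return out


def gen_eda(
    config: SessionConfig,
    anxiety,
    rng: np.random.Generator,
    duration: float | None = None,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Synthesize a conductance trace driven by the anxiety trajectory.

    Tonic level: mean-reverting random walk around ``scl_base`` clipped to
    the physiological range.  Phasic responses: an inhomogeneous Poisson
    process (thinning) whose per-minute rate interpolates linearly between
    the resting and high-arousal NS-SCR rates with anxiety, each response a
    Bateman kernel with an amplitude that scales with the anxiety level
    inside ``scr_amp_range``.
    """
    fs = config.fs
    duration = duration if duration is not None else config.duration
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    # tonic: mean-reverting random walk, smoothed to the minutes-scale
    # wander of a real skin-conductance level, clipped to physiological range
    dt = 1.0 / fs
    steps = rng.normal(0.0, config.scl_drift_sd * np.sqrt(dt), n)
    theta = 0.01  # 1/s mean reversion
    decay = 1.0 - theta * dt
    walk = np.empty(n)
    level = 0.0
    for k in range(n):
        level = decay * level + steps[k]
        walk[k] = level
    walk = ndimage.gaussian_filter1d(walk, sigma=5.0 * fs, mode="nearest")
    tonic = np.clip(config.scl_base + walk, *config.scl_range)

    # phasic: inhomogeneous Poisson by thinning
    anx_t = np.asarray(anxiety(t), dtype=float)
    rate_per_s = (
        config.nsscr_rate_rest
        + (config.nsscr_rate_arousal - config.nsscr_rate_rest) * anx_t / 10.0
    ) / 60.0
    lam_max = max(config.nsscr_rate_rest, config.nsscr_rate_arousal) / 60.0
    schedule: list[tuple[float, float]] = []
    gsr = tonic.copy()
    if lam_max > 0:
        n_cand = rng.poisson(lam_max * duration)
        cand_times = np.sort(rng.uniform(0.0, duration, n_cand))
        accept_u = rng.uniform(0.0, 1.0, n_cand)
        amp_u = rng.uniform(0.2, 1.0, n_cand)
        kernel = bateman_kernel(config.bateman, fs)
        amin, amax = config.scr_amp_range
        for onset, u, au in zip(cand_times, accept_u, amp_u):
            idx = min(int(onset * fs), n - 1)
            if u * lam_max > rate_per_s[idx]:
                continue
            anx_here = anx_t[idx]
            amp = amin + (amax - amin) * (0.15 + 0.85 * anx_here / 10.0) * au
            amp = float(np.clip(amp, amin, amax))
            schedule.append((float(onset), amp))
            span = min(kernel.size, n - idx)
            gsr[idx : idx + span] += amp * kernel[:span]

    gsr += gen_mains_noise(
        fs,
        duration,
        fundamental=config.mains_freq,
        n_harmonics=config.mains_harmonics,
        amplitude=config.mains_amp,
        rng=rng,
    )
    if config.gsr_noise_sd > 0:
        gsr += rng.normal(0.0, config.gsr_noise_sd, n)
    return np.clip(gsr, 0.0, None), schedule


def gen_hr(
    config: SessionConfig,
    anxiety,
    rng: np.random.Generator,
    duration: float | None = None,
) -> np.ndarray:
    """Synthesize heart rate: baseline + anxiety gain + LF/HF variability.

    The HF (respiratory-band) amplitude shrinks linearly with anxiety,
    emulating vagal withdrawal under threat, so high-anxiety windows show
    both a higher mean HR and a lower HF intensity.
    """
    fs = config.fs
    duration = duration if duration is not None else config.duration
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    anx_t = np.asarray(anxiety(t), dtype=float)
    phase_lf = rng.uniform(0, 2 * np.pi)
    phase_hf = rng.uniform(0, 2 * np.pi)
    hr = (
        config.hr_base
        + config.hr_gain * anx_t
        + config.lf_amp * np.sin(2 * np.pi * config.lf_freq * t + phase_lf)
        + config.hf_amp
        * (1.0 - 0.8 * anx_t / 10.0)
        * np.sin(2 * np.pi * config.hf_freq * t + phase_hf)
    )
    if config.hr_noise_sd > 0:
        hr += rng.normal(0.0, config.hr_noise_sd, n)
    return hr


def gen_session(
    config: SessionConfig,
    levels: list[int],
    rng: np.random.Generator,
    subject_id: str = "S1",
) -> SubjectSession:
    """Generate one subject's session for a given sequence of event levels."""
    if len(levels) != config.n_events:
        raise ValueError("need one anxiety level per event")
    event_times = config.event_times
    knots: list[tuple[float, float]] = [(0.0, 0.0)]
    for time, level in zip(event_times, levels):
        knots.append((float(time - config.event_spacing), float(level)))
    anx = make_trajectory(knots)

    gsr, schedule = gen_eda(config, anx, rng)
    hr = gen_hr(config, anx, rng)
    recording = RawRecording(gsr=gsr, hr=hr, fs=config.fs, subject_id=subject_id)

    rest = make_trajectory([(0.0, 0.0)])
    b_gsr, _ = gen_eda(config, rest, rng, duration=config.baseline_duration)
    b_hr = gen_hr(config, rest, rng, duration=config.baseline_duration)
    baseline = RawRecording(gsr=b_gsr, hr=b_hr, fs=config.fs, subject_id=subject_id)

    suds: list[int] = []
    for level in levels:
        noise = config.sud_noise * rng.uniform(-0.5, 0.5)
        rated = int(np.floor(level + noise + 0.5))  # round half up
        suds.append(int(np.clip(rated, 0, 10)))
    events = [
        StimulusEvent(time=float(t_), sud=s) for t_, s in zip(event_times, suds)
    ]
    truth = SessionGroundTruth(
        trajectory_knots=knots,
        scr_schedule=schedule,
        sud_per_event=suds,
        hr_base=config.hr_base,
        hr_gain=config.hr_gain,
    )
    return SubjectSession(
        recording=recording, baseline=baseline, events=events, ground_truth=truth
    )


def gen_cohort(
    config: SessionConfig | None = None,
    sud_histogram: tuple[int, ...] | None = None,
) -> list[SubjectSession]:
    """Generate the full cohort with a prescribed rating histogram.

    ``sud_histogram`` gives the target number of events per anxiety level
    (0..10) over the whole cohort; it must sum to ``n_subjects * n_events``.
    With the default 7 x 15 layout the study's marginal distribution is used.
    Levels are shuffled across subjects under the configured seed.
    """
    config = config or SessionConfig()
    total = config.n_subjects * config.n_events
    if sud_histogram is None:
        if total == sum(STUDY_SUD_HISTOGRAM):
            sud_histogram = STUDY_SUD_HISTOGRAM
        else:
            # draw levels from the study's marginal proportions
            probs = np.array(STUDY_SUD_HISTOGRAM, dtype=float)
            probs /= probs.sum()
            rng0 = np.random.default_rng(config.seed)
            counts = rng0.multinomial(total, probs)
            sud_histogram = tuple(int(c) for c in counts)
    if len(sud_histogram) != 11:
        raise ValueError("sud_histogram must give counts for levels 0..10")
    if sum(sud_histogram) != total:
        raise ValueError(
            f"sud_histogram sums to {sum(sud_histogram)}; cohort needs {total}"
        )
    levels = [lvl for lvl, c in enumerate(sud_histogram) for _ in range(c)]
    ss = np.random.SeedSequence(config.seed)
    shuffle_rng = np.random.default_rng(ss.spawn(1)[0])
    levels = list(np.array(levels)[shuffle_rng.permutation(total)])
    subject_seeds = ss.spawn(config.n_subjects)
    sessions = []
    for s in range(config.n_subjects):
        rng = np.random.default_rng(subject_seeds[s])
        chunk = [int(v) for v in levels[s * config.n_events : (s + 1) * config.n_events]]
        sessions.append(
            gen_session(config, chunk, rng, subject_id=f"S{s + 1}")
        )
    return sessions
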