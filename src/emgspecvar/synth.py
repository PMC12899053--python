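"""Synthetic two-channel surface-EMG cohort generator.

Emulates a protocol of repeated near-maximal isometric elbow-flexion bursts
recorded from biceps brachii (BB) and brachioradialis (BR) under two forearm
postures (supinated open hand, SP; neutral grip, NT).  Each recording is a
sequence of ~5 s contraction bursts separated by rest, sampled at 2 kHz in
microvolts.  Bursts are colored Gaussian noise whose expected periodogram
follows a rational band-pass spectral model with per-muscle corner
frequencies; participant-level random effects and repetition-level jitter
perturb those corners, with larger jitter in NT than SP.  Ground-truth burst
intervals and realized corner frequencies are returned alongside the signal
so segmentation and spectral recovery can be validated exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "MUSCLES",
    "TASKS",
    "CohortParams",
    "Recording",
    "GroundTruth",
    "Cohort",
    "shape_psd",
    "generate_burst",
    "generate_recording",
    "generate_cohort",
    "write_recording_csv",
]

MUSCLES = ("BB", "BR")
TASKS = ("SP", "NT")


def _default_shape_means() -> dict:
    # (f_l, f_h) corner frequencies in Hz per muscle x posture; NT shifted +5 Hz
    return {
        ("BB", "SP"): (60.0, 120.0),
        ("BB", "NT"): (65.0, 125.0),
        ("BR", "SP"): (70.0, 140.0),
        ("BR", "NT"): (75.0, 145.0),
    }


@dataclass
class CohortParams:
    """Parameters of a synthetic cohort.

    Defaults mirror the emulated acquisition protocol: 33 participants,
    10 repetitions per task, 2 kHz sampling, ~5 s bursts, rest baseline
    below 5 uV, and NT repetition jitter twice that of SP.
    """

    n_participants: int = 33
    n_repetitions: int = 10
    fs: float = 2000.0
    burst_duration_s: float = 5.0
    rest_duration_s: float = 2.0
    shape_means: dict = field(default_factory=_default_shape_means)
    subject_sd: float = 15.0
    rep_jitter_sd: dict = field(default_factory=lambda: {"SP": 5.0, "NT": 10.0})
    burst_rms_uv: float = 400.0
    baseline_amp_uv: float = 5.0
    line_amp_uv: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.baseline_amp_uv < 0:
            raise ValueError("baseline_amp_uv must be >= 0")
        if self.burst_duration_s <= 0 or self.rest_duration_s < 0:
            raise ValueError("durations must be positive")
        for (muscle, task), (f_l, f_h) in self.shape_means.items():
            if not (0 < f_l < f_h < self.fs / 2):
                raise ValueError(
                    f"corner frequencies for {muscle}/{task} must satisfy "
                    f"0 < f_l < f_h < fs/2, got ({f_l}, {f_h})"
                )
        for task in TASKS:
            if task not in self.rep_jitter_sd:
                raise ValueError(f"rep_jitter_sd missing task {task}")

    def with_updates(self, **kwargs) -> "CohortParams":
        return replace(self, **kwargs)


@dataclass
class Recording:
    """One participant x task recording: time vector, (n, 2) sample matrix in uV."""

    t: np.ndarray
    x: np.ndarray
    fs: float
    participant_id: str
    task: str
    channel_muscles: tuple = MUSCLES

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 2 or self.x.shape[0] != self.t.shape[0]:
            raise ValueError("x must be (n_samples, n_channels) matching t")
        if self.t.size > 1:
            dt = np.diff(self.t)
            if np.any(np.abs(dt - 1.0 / self.fs) > 1e-9):
                raise ValueError("time vector spacing inconsistent with fs")

    @property
    def n_samples(self) -> int:
        return self.t.shape[0]


@dataclass
class GroundTruth:
    """Burst annotations for one recording: intervals in seconds and the
    realized (f_l, f_h) corner pair per repetition per muscle."""

    burst_intervals: list  # [(start_s, end_s), ...] sorted, non-overlapping
    corners: dict  # muscle -> list of (f_l, f_h) per repetition

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for s, e in self.burst_intervals:
            if s >= e or s < prev_end:
                raise ValueError("burst intervals must be sorted, non-overlapping")
            prev_end = e


@dataclass
class Cohort:
    params: CohortParams
    recordings: list
    ground_truths: dict  # (participant_id, task) -> GroundTruth

    def recording(self, participant_id: str, task: str) -> Recording:
        for rec in self.recordings:
            if rec.participant_id == participant_id and rec.task == task:
                return rec
        raise KeyError((participant_id, task))


def shape_psd(f, f_l: float, f_h: float):
    """Band-limited rational spectral model for contraction-level sEMG.

    G(f) = f_h^2 f^2 / ((f^2 + f_l^2)(f^2 + f_h^2)^2): zero at DC, unimodal,
    decaying at high frequency, with the passband set by the corners.
    """
    if f_l <= 0 or f_h <= 0:
        raise ValueError("corner frequencies must be positive")
    if f_l >= f_h:
        raise ValueError("f_l must be below f_h")
    f = np.asarray(f, dtype=float)
    return (f_h**2 * f**2) / ((f**2 + f_l**2) * (f**2 + f_h**2) ** 2)


def _trapezoid_envelope(n: int, rise_frac: float = 0.1, fall_frac: float = 0.1):
    n_rise = max(1, int(round(rise_frac * n)))
    n_fall = max(1, int(round(fall_frac * n)))
    env = np.ones(n)
    env[:n_rise] = np.linspace(0.0, 1.0, n_rise, endpoint=False)
    env[n - n_fall:] = np.linspace(1.0, 0.0, n_fall + 1)[1:]
    return env, n_rise, n - n_fall


def _as_rng(rng_state) -> np.random.Generator:
    if isinstance(rng_state, np.random.Generator):
        return rng_state
    return np.random.default_rng(rng_state)


def generate_burst(duration_s: float, fs: float, f_l: float, f_h: float,
                   target_rms_uv: float, rng_state) -> np.ndarray:
    """One contraction burst: spectrally-shaped Gaussian noise under a
    trapezoidal envelope (10% rise, 80% plateau, 10% fall), with the plateau
    RMS scaled to ``target_rms_uv``.
    """
    n = int(round(duration_s * fs))
    if n < 10:
        raise ValueError("burst must span at least 10 samples")
    if target_rms_uv == 0.0:
        return np.zeros(n)
    rng = _as_rng(rng_state)
    white = rng.standard_normal(n)
    # color in the frequency domain: multiply the transform by sqrt(G(f))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.sqrt(shape_psd(freqs, f_l, f_h))
    colored = np.fft.irfft(np.fft.rfft(white) * gain, n=n)
    env, p0, p1 = _trapezoid_envelope(n)
    y = colored * env
    plateau_rms = np.sqrt(np.mean(y[p0:p1] ** 2))
    if plateau_rms > 0:
        y *= target_rms_uv / plateau_rms
    return y


def _participant_effects(params: CohortParams, index: int) -> dict:
    """Between-participant corner-frequency offsets, drawn once per
    participant (shared across tasks and repetitions)."""
    rng = np.random.default_rng(np.random.SeedSequence((params.seed, index, 2)))
    return {m: rng.normal(0.0, params.subject_sd, size=2) for m in MUSCLES}


def _clip_corners(f_l: float, f_h: float, fs: float):
    f_l = float(np.clip(f_l, 5.0, fs / 2 - 20.0))
    f_h = float(np.clip(f_h, f_l + 10.0, fs / 2 - 5.0))
    return f_l, f_h


def generate_recording(params: CohortParams, participant_effects: dict,
                       task: str, rng_state,
                       participant_id: str = "P01"):
    """Assemble one recording: rest / burst / rest / ... / rest, plus a
    burst-gated 50 Hz line-interference component common to both channels.

    The interference is modulated by the contraction envelope so rest
    intervals keep the baseline-amplitude guarantee (max |x| <= baseline_amp_uv),
    matching the emulated system's quality criterion.
    """
    if task not in TASKS:
        raise ValueError(f"task must be one of {TASKS}")
    rng = _as_rng(rng_state)
    fs = params.fs
    n_burst = int(round(params.burst_duration_s * fs))
    n_rest = int(round(params.rest_duration_s * fs))
    n_reps = params.n_repetitions
    total = n_reps * n_burst + (n_reps + 1) * n_rest
    t = np.arange(total) / fs
    x = np.zeros((total, len(MUSCLES)))

    env_full = np.zeros(total)
    intervals = []
    corners: dict = {m: [] for m in MUSCLES}

    # per-repetition corner jitter, per muscle and corner
    jit_sd = params.rep_jitter_sd[task]
    jitter = {m: rng.normal(0.0, jit_sd, size=(n_reps, 2)) for m in MUSCLES}

    pos = n_rest
    burst_env, _, _ = _trapezoid_envelope(n_burst)
    for rep in range(n_reps):
        intervals.append((pos / fs, (pos + n_burst) / fs))
        for ci, muscle in enumerate(MUSCLES):
            mf_l, mf_h = params.shape_means[(muscle, task)]
            eff = participant_effects[muscle]
            f_l = mf_l + eff[0] + jitter[muscle][rep, 0]
            f_h = mf_h + eff[1] + jitter[muscle][rep, 1]
            f_l, f_h = _clip_corners(f_l, f_h, fs)
            corners[muscle].append((f_l, f_h))
            x[pos:pos + n_burst, ci] = generate_burst(
                params.burst_duration_s, fs, f_l, f_h, params.burst_rms_uv, rng)
        env_full[pos:pos + n_burst] = burst_env
        pos += n_burst + n_rest

    # rest-interval baseline: uniform noise bounded by baseline_amp_uv
    if params.baseline_amp_uv > 0:
        rest_mask = env_full == 0.0
        for ci in range(len(MUSCLES)):
            x[rest_mask, ci] = rng.uniform(
                -params.baseline_amp_uv, params.baseline_amp_uv,
                size=int(rest_mask.sum()))

    # common-mode 50 Hz line interference, gated by the contraction envelope
    if params.line_amp_uv > 0:
        phase = rng.uniform(0.0, 2 * np.pi)
        line = params.line_amp_uv * env_full * np.sin(2 * np.pi * 50.0 * t + phase)
        x += line[:, None]

    rec = Recording(t=t, x=x, fs=fs, participant_id=participant_id,
                    task=task, channel_muscles=MUSCLES)
    gt = GroundTruth(burst_intervals=intervals, corners=corners)
    return rec, gt


def generate_cohort(params: CohortParams) -> Cohort:
    """Full cohort: n_participants x 2 tasks, reproducible from params.seed.

    Per-recording RNG substreams are keyed by (seed, participant index, task
    index), so enlarging the cohort leaves existing recordings untouched.
    """
    recordings = []
    gts = {}
    width = max(2, len(str(params.n_participants)))
    for i in range(params.n_participants):
        pid = f"P{i + 1:0{width}d}"
        effects = _participant_effects(params, i)
        for ti, task in enumerate(TASKS):
            rng = np.random.default_rng(
                np.random.SeedSequence((params.seed, i, ti)))
            rec, gt = generate_recording(params, effects, task, rng,
                                         participant_id=pid)
            recordings.append(rec)
            gts[(pid, task)] = gt
    return Cohort(params=params, recordings=recordings, ground_truths=gts)


def write_recording_csv(rec: Recording, path, ground_truth: GroundTruth | None = None):
    """Write a recording as `time_s,<m1>_uv,<m2>_uv` CSV (full precision so
    the round trip is exact), with an optional JSON ground-truth sidecar."""
    path = Path(path)
    header = "time_s," + ",".join(f"{m}_uv" for m in rec.channel_muscles)
    data = np.column_stack([rec.t, rec.x])
    np.savetxt(path, data, delimiter=",", header=header, comments="",
               fmt="%.17g")
    if ground_truth is not None:
        side = path.with_suffix(".json")
        side.write_text(json.dumps({
            "burst_intervals": ground_truth.burst_intervals,
            "corners": {m: [list(c) for c in cs]
                        for m, cs in ground_truth.corners.items()},
        }, indent=1))


def write_cohort(cohort: Cohort, out_dir) -> list:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in cohort.recordings:
        p = out_dir / f"{rec.participant_id}_{rec.task}.csv"
        write_recording_csv(rec, p,
                            cohort.ground_truths[(rec.participant_id, rec.task)])
        paths.append(p)
    return paths
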