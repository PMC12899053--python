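"""Contraction segmentation for two-channel sEMG recordings.

A reference trace is formed by summing the two channels (approximate phase
synchrony makes contractions add), candidate peaks are detected on the raw
summed trace under three constraints (minimum topographic prominence,
minimum inter-peak spacing, and a minimum rise of the RMS envelope at the
peak above the envelope minima toward both neighbours), and segment
boundaries are then placed at the RMS-envelope minimum between consecutive
retained peaks.  The boundaries partition the recording, so every sample
belongs to exactly one segment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .synth import Recording

__all__ = [
    "SegmenterConfig",
    "Segment",
    "SegmentationWarning",
    "build_reference_trace",
    "detect_peaks",
    "rms_envelope",
    "refine_boundaries",
    "segment_recording",
]


class SegmentationWarning(UserWarning):
    pass


@dataclass
class SegmenterConfig:
    """Peak-detection and boundary-refinement thresholds (all in uV / s)."""

    min_prominence_uv: float = 500.0
    min_peak_distance_s: float = 0.35
    neighbor_delta_uv: float = 250.0
    rms_window_s: float = 0.1
    expected_count: int | None = None

    def __post_init__(self) -> None:
        if min(self.min_prominence_uv, self.min_peak_distance_s,
               self.neighbor_delta_uv, self.rms_window_s) <= 0:
            raise ValueError("all segmenter thresholds must be positive")


@dataclass
class Segment:
    participant_id: str
    task: str
    repetition_index: int
    start: int  # inclusive sample index
    end: int    # exclusive sample index
    data: np.ndarray  # (end - start, n_channels) uV
    fs: float
    channel_muscles: tuple

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("segment bounds must satisfy 0 <= start < end")

    @property
    def n_samples(self) -> int:
        return self.end - self.start


def build_reference_trace(rec: Recording) -> np.ndarray:
    """Sum the two channels into a single reference trace."""
    if rec.x.shape[1] != 2:
        raise ValueError(f"expected exactly 2 channels, got {rec.x.shape[1]}")
    return rec.x[:, 0] + rec.x[:, 1]


def rms_envelope(trace: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    """Centered moving RMS with the window shrunk at the boundaries."""
    trace = np.asarray(trace, dtype=float)
    n_w = int(round(window_s * fs))
    if n_w < 1:
        raise ValueError("window must span at least one sample")
    n = trace.shape[0]
    left = (n_w - 1) // 2
    right = n_w // 2  # window covers [i - left, i + right]
    sq = np.concatenate(([0.0], np.cumsum(trace**2)))
    i = np.arange(n)
    lo = np.maximum(i - left, 0)
    hi = np.minimum(i + right, n - 1)
    return np.sqrt((sq[hi + 1] - sq[lo]) / (hi - lo + 1))


def detect_peaks(trace: np.ndarray, fs: float, cfg: SegmenterConfig) -> np.ndarray:
    """Contraction-peak candidates on the raw summed trace.

    Constraints: prominence >= min_prominence_uv; spacing >=
    min_peak_distance_s (taller peak wins a conflict); and each retained
    peak must stand out from its neighbours on the RMS envelope.  Two
    adjacent candidates count as distinct contractions only when the
    envelope valley between them both sinks to <= neighbor_delta_uv (the
    inter-contraction rest level) and lies >= neighbor_delta_uv below the
    envelope at each peak; otherwise they belong to one contraction and the
    lower-amplitude candidate is merged away.  First/last peaks must also
    rise >= neighbor_delta_uv above the envelope minimum toward the
    recording edge.  Every returned peak therefore exceeds both adjacent
    inter-peak envelope minima by at least neighbor_delta_uv.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 2:
        raise ValueError("trace must contain at least 2 samples")
    distance = max(1, int(round(cfg.min_peak_distance_s * fs)))
    peaks, _ = find_peaks(trace, prominence=cfg.min_prominence_uv,
                          distance=distance)
    if peaks.size == 0:
        return peaks
    env = rms_envelope(trace, fs, cfg.rms_window_s)
    delta = cfg.neighbor_delta_uv
    kept = list(peaks)

    def separated(a: int, b: int) -> bool:
        valley = env[a:b + 1].min()
        return (valley <= delta and env[a] - valley >= delta
                and env[b] - valley >= delta)

    merging = True
    while merging and len(kept) > 1:
        merging = False
        for i in range(len(kept) - 1):
            if not separated(kept[i], kept[i + 1]):
                drop = i if trace[kept[i]] < trace[kept[i + 1]] else i + 1
                kept.pop(drop)
                merging = True
                break
    # edge rule: first/last peak must rise above the envelope toward the edge
    while kept and env[kept[0]] - env[:kept[0] + 1].min() < delta:
        kept.pop(0)
    while kept and env[kept[-1]] - env[kept[-1]:].min() < delta:
        kept.pop()
    return np.asarray(kept, dtype=int)


def refine_boundaries(trace: np.ndarray, fs: float, peaks: np.ndarray,
                      cfg: SegmenterConfig) -> list:
    """Partition [0, len(trace)) at the RMS-envelope minimum strictly
    between each pair of consecutive peaks (first index on ties)."""
    trace = np.asarray(trace, dtype=float)
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size == 0:
        raise ValueError("refine_boundaries requires at least one peak")
    env = rms_envelope(trace, fs, cfg.rms_window_s)
    cuts = [0]
    for p0, p1 in zip(peaks[:-1], peaks[1:]):
        inner = env[p0 + 1:p1]
        if inner.size == 0:
            raise ValueError("adjacent peaks with no samples between them")
        cuts.append(p0 + 1 + int(np.argmin(inner)))
    cuts.append(trace.size)
    return [(cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1)]


def segment_recording(rec: Recording, cfg: SegmenterConfig | None = None) -> list:
    """Cut a recording into per-contraction segments (both channels share the
    boundaries derived from the summed trace).  Returns [] with a warning if
    no peaks satisfy the constraints; warns on an expected-count mismatch."""
    cfg = cfg or SegmenterConfig()
    trace = build_reference_trace(rec)
    peaks = detect_peaks(trace, rec.fs, cfg)
    if peaks.size == 0:
        warnings.warn("no contraction peaks detected; returning no segments",
                      SegmentationWarning)
        return []
    windows = refine_boundaries(trace, rec.fs, peaks, cfg)
    if cfg.expected_count is not None and len(windows) != cfg.expected_count:
        warnings.warn(
            f"expected {cfg.expected_count} segments, found {len(windows)} "
            f"for {rec.participant_id}/{rec.task}", SegmentationWarning)
    return [
        Segment(participant_id=rec.participant_id, task=rec.task,
                repetition_index=i, start=s, end=e, data=rec.x[s:e],
                fs=rec.fs, channel_muscles=rec.channel_muscles)
        for i, (s, e) in enumerate(windows)
    ]
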