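"""Per-segment power spectra: notch, zero-padding, Hann taper, FFT,
moving-trend-filter smoothing, normalization, and regridding.

The processing order is fixed: 50 Hz notch on the raw segment, zero-pad to
the longest segment of the recording, Hann taper, FFT power spectrum
restricted to the analysis band, moving-trend-filter (MTF) smoothing,
normalization (by peak power or total energy), and finally linear
interpolation onto the shared frequency grid used for distance computation.

The MTF fits an order-p polynomial by least squares inside every sliding
window of M = 2K+1 bins that covers a given bin, evaluates each fit at that
bin, and averages the evaluations.  Because the fit/evaluate step is a fixed
linear projection, the averaged smoother reduces to a convolution at
interior bins; edge bins average over the (fewer) admissible full windows.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import filtfilt, iirnotch
from scipy.signal.windows import hann

__all__ = [
    "SpectralConfig",
    "Spectrum",
    "notch_filter",
    "pad_to_reference",
    "apply_window",
    "power_spectrum",
    "mtf_smooth",
    "normalize",
    "regrid",
]


@dataclass
class SpectralConfig:
    notch_freq_hz: float = 50.0
    notch_q: float = 35.0
    window: str = "hann"
    mtf_order: int = 3
    mtf_span_bins: int = 180
    analysis_band_hz: tuple = (0.0, 500.0)
    common_grid_df_hz: float = 0.5

    def __post_init__(self) -> None:
        if self.notch_freq_hz <= 0 or self.notch_q <= 0:
            raise ValueError("notch frequency and Q must be positive")
        if self.mtf_order < 1:
            raise ValueError("mtf_order must be >= 1")
        if self.mtf_span_bins < 2 * self.mtf_order + 2:
            raise ValueError("mtf_span_bins must be >= 2*order + 2")
        f_min, f_max = self.analysis_band_hz
        if not f_min < f_max:
            raise ValueError("analysis band must satisfy f_min < f_max")
        if self.window != "hann":
            raise ValueError("only the Hann taper is supported")


@dataclass
class Spectrum:
    """One-sided power spectrum on a uniform frequency grid."""

    f: np.ndarray
    p: np.ndarray
    n_fft: int
    normalization: str = "none"  # none | max | energy
    smoothing: str = "raw"       # raw | mtf

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.f.shape != self.p.shape or self.f.ndim != 1:
            raise ValueError("f and p must be 1-D arrays of equal length")
        if self.f.size > 1 and np.any(np.diff(self.f) <= 0):
            raise ValueError("frequency grid must be strictly increasing")

    @property
    def df(self) -> float:
        return float(self.f[1] - self.f[0]) if self.f.size > 1 else np.nan

    def copy_with(self, **kwargs) -> "Spectrum":
        out = replace(self, **kwargs)
        return out


def notch_filter(series: np.ndarray, fs: float, f0: float = 50.0,
                 q: float = 35.0) -> np.ndarray:
    """Second-order IIR notch at f0 (bandwidth f0/q), applied
    forward-backward for zero phase."""
    if not 0 < f0 < fs / 2:
        raise ValueError("notch frequency must lie in (0, fs/2)")
    b, a = iirnotch(f0, q, fs=fs)
    return filtfilt(b, a, np.asarray(series, dtype=float))


def pad_to_reference(segments: list) -> tuple:
    """Zero-pad every segment (trailing zeros) to the longest length in the
    recording; returns (padded list, N)."""
    if not segments:
        raise ValueError("need at least one segment")
    arrays = [np.asarray(s, dtype=float) for s in segments]
    n_ref = max(a.shape[0] for a in arrays)
    padded = [np.pad(a, (0, n_ref - a.shape[0])) for a in arrays]
    return padded, n_ref


def apply_window(segment: np.ndarray) -> np.ndarray:
    """Symmetric Hann taper (zero endpoints)."""
    segment = np.asarray(segment, dtype=float)
    if segment.shape[0] < 2:
        raise ValueError("segment must have at least 2 samples")
    return segment * hann(segment.shape[0], sym=True)


def power_spectrum(segment: np.ndarray, fs: float,
                   analysis_band_hz: tuple = (0.0, 500.0)) -> Spectrum:
    """P[f_m] = |X[m]|^2 on the one-sided grid f_m = m fs / N, truncated to
    the analysis band."""
    segment = np.asarray(segment, dtype=float)
    n = segment.shape[0]
    if n < 2:
        raise ValueError("segment must have at least 2 samples")
    x = np.fft.rfft(segment)
    p = np.abs(x) ** 2
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    f_min, f_max = analysis_band_hz
    keep = (f >= f_min) & (f <= f_max)
    return Spectrum(f=f[keep], p=p[keep], n_fft=n)


def _mtf_window_length(span_bins: int) -> int:
    # "span of 180 bins" read as M = 2K+1 with K = span/2
    k = span_bins // 2
    return 2 * k + 1


def _projection_matrix(m: int, order: int) -> np.ndarray:
    u = np.linspace(-1.0, 1.0, m)
    v = np.vander(u, order + 1, increasing=True)
    return v @ np.linalg.pinv(v)  # H: fitted values = H @ window samples


def mtf_values(s: np.ndarray, span_bins: int, order: int) -> np.ndarray:
    """Moving-trend-filter smoothing of a 1-D series (no clipping).

    At bin n the result is the mean, over every length-M window containing
    n, of the order-p least-squares polynomial fit to that window evaluated
    at n.  Interior bins (covered by all M window positions) are computed by
    the equivalent convolution kernel; the M-1 bins at each edge average
    over their admissible windows explicitly.
    """
    s = np.asarray(s, dtype=float)
    m = _mtf_window_length(span_bins)
    L = s.shape[0]
    if L <= m:
        raise ValueError("spectrum must be longer than the smoothing window")
    h = _projection_matrix(m, order)
    n_pos = L - m + 1  # admissible window start positions

    acc = np.zeros(L)
    count = np.zeros(L)

    # interior: all M positions admissible -> convolution with the
    # diagonal-averaged kernel c[d] = mean_j H[j, j+d]
    lo, hi = m - 1, L - m  # inclusive interior range
    if hi >= lo:
        kernel = np.array([np.trace(h, offset=d) for d in range(-(m - 1), m)])
        kernel /= m
        conv = np.convolve(s, kernel[::-1], mode="same")
        acc[lo:hi + 1] = conv[lo:hi + 1] * m
        count[lo:hi + 1] = m

    # edges: evaluate each admissible window explicitly
    windows = np.lib.stride_tricks.sliding_window_view(s, m)
    edge_n = [n for n in range(L) if not (lo <= n <= hi)]
    if edge_n:
        top = min(m - 1, n_pos)
        bot_start = max(0, n_pos - (m - 1))
        pos_idx = sorted(set(range(top)) | set(range(bot_start, n_pos)))
        pos_idx = np.asarray(pos_idx, dtype=int)
        e = windows[pos_idx] @ h.T  # e[i, j] = fit from window pos_idx[i] at bin pos_idx[i]+j
        target = pos_idx[:, None] + np.arange(m)[None, :]
        mask = (target < lo) | (target > hi)
        np.add.at(acc, target[mask], e[mask])
        np.add.at(count, target[mask], 1.0)
    return acc / count


def mtf_smooth(spectrum: Spectrum, cfg: SpectralConfig,
               clip: bool = True) -> Spectrum:
    """MTF-smoothed spectrum (order cfg.mtf_order, span cfg.mtf_span_bins);
    negative fitted values are clipped to 0 unless ``clip`` is False."""
    out = mtf_values(spectrum.p, cfg.mtf_span_bins, cfg.mtf_order)
    if clip:
        out = np.maximum(out, 0.0)
    return spectrum.copy_with(p=out, smoothing="mtf")


def normalize(spectrum: Spectrum, mode: str) -> Spectrum:
    """Scale so the peak equals 1 (mode='max') or the bin sum equals 1
    (mode='energy')."""
    if mode not in ("max", "energy"):
        raise ValueError("mode must be 'max' or 'energy'")
    p = spectrum.p
    if not np.any(p > 0):
        raise ValueError("cannot normalize an all-zero spectrum")
    denom = p.max() if mode == "max" else p.sum()
    return spectrum.copy_with(p=p / denom, normalization=mode)


def regrid(spectrum: Spectrum, target_f: np.ndarray) -> Spectrum:
    """Linear interpolation onto a new uniform grid; the spectrum's
    normalization mode is re-applied so its invariant holds on the new grid."""
    target_f = np.asarray(target_f, dtype=float)
    if target_f[0] < spectrum.f[0] - 1e-12 or target_f[-1] > spectrum.f[-1] + 1e-12:
        raise ValueError("target grid extends beyond the source grid")
    p = np.interp(target_f, spectrum.f, spectrum.p)
    out = spectrum.copy_with(f=target_f, p=p)
    if spectrum.normalization != "none":
        out = normalize(out, spectrum.normalization)
    return out


def common_grid(max_freqs, cfg: SpectralConfig) -> np.ndarray:
    """Shared uniform grid at cfg.common_grid_df_hz covering the analysis
    band but never extending past the shortest source grid."""
    f_min, f_max = cfg.analysis_band_hz
    df = cfg.common_grid_df_hz
    top = min(float(np.min(max_freqs)), f_max)
    n = int(np.floor((top - f_min) / df + 1e-9))
    return f_min + df * np.arange(n + 1)
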