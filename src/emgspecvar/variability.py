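"""Spectral variability quantification via Minkowski distances.

For each participant and condition (muscle x posture x normalization) the
repetition spectra are averaged into a subject reference spectrum.  Intra-
subject variability is the distance of each repetition from that reference;
inter-subject variability is the pairwise distance between participants'
references.  Distances use the Minkowski family of order 1 (Manhattan),
2 (Euclidean) or infinity (Chebyshev), computed binwise on the shared grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import Spectrum

__all__ = [
    "ORDERS",
    "SummaryStats",
    "reference_spectrum",
    "minkowski_distance",
    "intra_distances",
    "inter_distances",
    "summarize",
]

ORDERS = (1, 2, "inf")


@dataclass
class SummaryStats:
    mean: float
    std: float   # sample (n-1) standard deviation
    cv: float    # std / mean; NaN when mean == 0
    min: float
    max: float
    n: int


def _check_same_grid(spectra: list) -> None:
    f0 = spectra[0].f
    norm0 = spectra[0].normalization
    for s in spectra[1:]:
        if s.f.shape != f0.shape or not np.allclose(s.f, f0):
            raise ValueError("spectra are not on a common frequency grid")
        if s.normalization != norm0:
            raise ValueError("spectra mix normalization modes")


def reference_spectrum(spectra: list) -> Spectrum:
    """Binwise arithmetic mean of the repetition spectra of one participant
    and condition."""
    if not spectra:
        raise ValueError("need at least one spectrum")
    _check_same_grid(spectra)
    mean_p = np.mean([s.p for s in spectra], axis=0)
    return spectra[0].copy_with(p=mean_p)


def _norm_order(order):
    if order in (1, 2):
        return order
    if order in ("inf", np.inf, float("inf")):
        return np.inf
    raise ValueError(f"order must be 1, 2 or 'inf', got {order!r}")


def minkowski_distance(x: np.ndarray, y: np.ndarray, order) -> float:
    """(sum |x_k - y_k|^l)^(1/l); order 'inf' gives the Chebyshev maximum."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    ell = _norm_order(order)
    d = np.abs(x - y)
    if ell is np.inf or ell == np.inf:
        return float(d.max())
    if ell == 1:
        return float(d.sum())
    return float(np.sqrt(np.sum(d * d)))


def intra_distances(spectra: list, reference: Spectrum, order) -> np.ndarray:
    """Distance of each repetition spectrum from the subject reference."""
    _check_same_grid(list(spectra) + [reference])
    return np.array([minkowski_distance(s.p, reference.p, order)
                     for s in spectra])


def inter_distances(references: dict, order) -> list:
    """All unordered participant pairs for one condition.

    ``references`` maps participant_id -> reference Spectrum; returns a list
    of (id1, id2, distance) over the n(n-1)/2 pairs, ids in sorted order.
    """
    if len(references) < 2:
        raise ValueError("need at least 2 participants")
    ids = sorted(references)
    _check_same_grid([references[i] for i in ids])
    out = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            d = minkowski_distance(references[ids[a]].p,
                                   references[ids[b]].p, order)
            out.append((ids[a], ids[b], d))
    return out


def summarize(values) -> SummaryStats:
    """Mean / sample STD / CV / min / max of a distance sample."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values to summarize")
    mean = float(values.mean())
    std = float(values.std(ddof=1))
    cv = std / mean if mean != 0 else float("nan")
    return SummaryStats(mean=mean, std=std, cv=cv,
                        min=float(values.min()), max=float(values.max()),
                        n=int(values.size))
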