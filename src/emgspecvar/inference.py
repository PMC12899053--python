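"""Posture comparisons and distance-distribution modelling.

SP vs NT distance samples are compared per muscle x order x normalization
with the Wilcoxon signed-rank test (paired design; zero differences are
discarded, exact null when feasible, otherwise the tie/continuity-corrected
normal approximation).  Inter-subject distance samples are additionally
fitted with Normal, Laplace (double exponential) and Maxwell-Boltzmann
distributions by maximum likelihood, and the fits assessed with a
chi-square goodness-of-fit test on equal-probability bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FAMILIES",
    "TestResult",
    "FitResult",
    "wilcoxon_signed_rank",
    "compare_postures",
    "fit_distribution",
    "chi_square_gof",
]

FAMILIES = ("normal", "laplace", "maxwell")
_N_PARAMS = {"normal": 2, "laplace": 2, "maxwell": 1}


@dataclass
class TestResult:
    statistic: float  # signed-rank sum W+ of the positive differences
    p_value: float
    n_pairs: int      # pairs contributing after zero-difference removal
    method: str       # exact | approx | degenerate


@dataclass
class FitResult:
    family: str
    params: dict
    chi2: float | None = None
    df: int | None = None
    p_value: float | None = None
    n_bins: int | None = None


def wilcoxon_signed_rank(x, y) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are discarded; the exact null distribution is used for
    n <= 25 without tied |differences|, otherwise the normal approximation
    with continuity and tie corrections.  All differences zero yields the
    degenerate result p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(statistic=0.0, p_value=1.0, n_pairs=0,
                          method="degenerate")
    if n < 5:
        raise ValueError("need at least 5 nonzero differences")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    has_ties = np.unique(np.abs(d)).size < n
    if n <= 25 and not has_ties:
        method = "exact"
        res = stats.wilcoxon(d, zero_method="wilcox", correction=False,
                             alternative="two-sided", method="exact")
    else:
        method = "approx"
        res = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                             alternative="two-sided", method="approx")
    return TestResult(statistic=w_plus, p_value=float(res.pvalue),
                      n_pairs=n, method=method)


def compare_postures(distances: pd.DataFrame, level: str,
                     aggregation: str = "mean") -> pd.DataFrame:
    """Paired SP vs NT tests per muscle x order x normalization.

    ``distances`` is a tidy table with columns muscle, posture, norm, order,
    value and the pairing keys: intra level pairs by participant (default
    aggregation: each participant's mean repetition distance; 'pooled' pairs
    individual repetitions by participant x rep); inter level pairs by the
    participant pair.  Units missing one posture are dropped with a warning.
    """
    if level not in ("intra", "inter"):
        raise ValueError("level must be 'intra' or 'inter'")
    if level == "intra":
        if aggregation == "mean":
            unit_cols = ["participant"]
        elif aggregation == "pooled":
            unit_cols = ["participant", "rep"]
        else:
            raise ValueError("aggregation must be 'mean' or 'pooled'")
    else:
        unit_cols = ["id1", "id2"]

    rows = []
    for (muscle, order, norm), grp in distances.groupby(
            ["muscle", "order", "norm"], sort=True):
        agg = (grp.groupby(unit_cols + ["posture"])["value"]
               .mean().unstack("posture"))
        missing = agg.isna().any(axis=1)
        if missing.any():
            warnings.warn(f"{int(missing.sum())} pairing units missing a "
                          f"posture dropped for {muscle}/{order}/{norm}")
            agg = agg[~missing]
        res = wilcoxon_signed_rank(agg["SP"].to_numpy(), agg["NT"].to_numpy())
        rows.append({"level": level, "muscle": muscle, "order": order,
                     "norm": norm, "statistic": res.statistic,
                     "p_value": res.p_value, "n_pairs": res.n_pairs,
                     "method": res.method})
    return pd.DataFrame(rows)


def fit_distribution(sample, family: str) -> FitResult:
    """Maximum-likelihood fit of one distribution family.

    normal: (mean, sd) with the n-denominator sd; laplace: (median, mean
    absolute deviation from the median); maxwell: scale a = sqrt(mean(x^2)/3)
    (density proportional to x^2 exp(-x^2 / 2 a^2), support x >= 0).
    """
    sample = np.asarray(sample, dtype=float)
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    if sample.size < 20:
        raise ValueError("need at least 20 observations to fit")
    if family == "normal":
        params = {"mean": float(sample.mean()),
                  "sd": float(sample.std(ddof=0))}
    elif family == "laplace":
        loc = float(np.median(sample))
        params = {"location": loc,
                  "scale": float(np.mean(np.abs(sample - loc)))}
    else:
        if np.any(sample < 0):
            raise ValueError("maxwell family requires nonnegative values")
        params = {"a": float(np.sqrt(np.mean(sample**2) / 3.0))}
    return FitResult(family=family, params=params)


def _frozen(fit: FitResult):
    if fit.family == "normal":
        return stats.norm(fit.params["mean"], fit.params["sd"])
    if fit.family == "laplace":
        return stats.laplace(fit.params["location"], fit.params["scale"])
    return stats.maxwell(scale=fit.params["a"])


def chi_square_gof(sample, fit: FitResult) -> FitResult:
    """Chi-square goodness of fit on equal-probability bins.

    n_bins = max(5, floor(n/10)), reduced if needed so every expected count
    is >= 5; df = n_bins - 1 - n_params.  A fit is conventionally deemed
    consistent with the data when p >= 0.05.
    """
    sample = np.asarray(sample, dtype=float)
    n = sample.size
    n_params = _N_PARAMS[fit.family]
    n_bins = max(5, n // 10)
    n_bins = min(n_bins, n // 5)  # keep expected counts >= 5
    if n_bins < n_params + 2:
        raise ValueError("sample too small for a chi-square test with "
                         ">= 5 expected observations per bin")
    dist = _frozen(fit)
    edges = dist.ppf(np.linspace(0.0, 1.0, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    observed = np.histogram(sample, bins=edges)[0]
    expected = n / n_bins
    chi2 = float(np.sum((observed - expected) ** 2) / expected)
    df = n_bins - 1 - n_params
    p = float(stats.chi2.sf(chi2, df))
    return replace(fit, chi2=chi2, df=df, p_value=p, n_bins=n_bins)
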