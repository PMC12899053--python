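"""Diagnostic plots for fitted results (matplotlib)."""

from __future__ import annotations

import numpy as np

from .inference import _frozen

__all__ = ["plot_reference_spectra", "plot_intra_boxplots",
           "plot_inter_histogram"]


def plot_reference_spectra(results, participant, norm="max", ax=None):
    """Per-condition reference spectra of one participant."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    for (pid, muscle, task, n), ref in sorted(results.references.items()):
        if pid == participant and n == norm:
            ax.plot(ref.f, ref.p, label=f"{muscle}/{task}")
    ax.set_xlabel("frequency [Hz]")
    ax.set_ylabel(f"normalized power ({norm})")
    ax.set_title(f"reference spectra, {participant}")
    ax.legend()
    return ax


def plot_intra_boxplots(results, order="2", norm="max", ax=None):
    """Intra-subject distance distributions by muscle and posture."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    sub = results.intra.query("order == @order and norm == @norm")
    groups, labels = [], []
    for muscle in sorted(sub["muscle"].unique()):
        for posture in ("SP", "NT"):
            vals = sub.query("muscle == @muscle and posture == @posture")["value"]
            if len(vals):
                groups.append(vals.to_numpy())
                labels.append(f"{muscle}/{posture}")
    ax.boxplot(groups, tick_labels=labels)
    ax.set_ylabel(f"L{order} distance ({norm} norm)")
    ax.set_title("intra-subject spectral distances")
    return ax


def plot_inter_histogram(results, muscle, posture, order="2", norm="max",
                         ax=None, bins=20):
    """Histogram of pairwise inter-subject distances with fitted models."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    vals = results.inter.query(
        "muscle == @muscle and posture == @posture and order == @order "
        "and norm == @norm")["value"].to_numpy()
    ax.hist(vals, bins=bins, density=True, alpha=0.5, label="empirical")
    if len(results.gof):
        import json
        from .inference import FitResult
        sub = results.gof.query(
            "muscle == @muscle and posture == @posture and order == @order "
            "and norm == @norm")
        xs = np.linspace(0, vals.max() * 1.2, 300)
        for _, row in sub.iterrows():
            fit = FitResult(family=row["family"],
                            params=json.loads(row["params"]))
            ax.plot(xs, _frozen(fit).pdf(xs),
                    label=f"{row['family']} (p={row['p_value']:.3f})")
    ax.set_xlabel(f"L{order} distance ({norm} norm)")
    ax.set_ylabel("density")
    ax.set_title(f"inter-subject distances, {muscle}/{posture}")
    ax.legend()
    return ax
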