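"""Model / Results interface tying the pipeline together.

``SpectralVariability`` is built from a set of two-channel recordings
(synthetic or loaded from disk); ``fit()`` runs segmentation, spectral
estimation, distance computation and inference, returning a
``SpectralVariabilityResults`` object that carries the distance tables,
descriptive summaries, posture tests, distribution fits and a ``summary()``
report, and can serialize everything to CSV + a JSON manifest.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .inference import FAMILIES, chi_square_gof, compare_postures, fit_distribution
from .segment import SegmenterConfig, segment_recording
from .spectral import (SpectralConfig, apply_window, common_grid, mtf_smooth,
                       normalize, notch_filter, pad_to_reference,
                       power_spectrum, regrid)
from .synth import TASKS, CohortParams, generate_cohort
from .variability import (ORDERS, inter_distances, intra_distances,
                          reference_spectrum, summarize)

__all__ = ["SpectralVariability", "SpectralVariabilityResults"]

NORMALIZATIONS = ("max", "energy")


class SpectralVariability:
    """Spectral-variability model for a cohort of two-channel sEMG recordings.

    Parameters
    ----------
    recordings : list of Recording
        One recording per participant x task.
    ground_truths : dict, optional
        (participant_id, task) -> GroundTruth, available for synthetic data.
    segmenter, spectral : stage configurations (defaults as documented).
    orders : Minkowski orders to compute (subset of 1, 2, 'inf').
    normalizations : subset of ('max', 'energy').
    """

    def __init__(self, recordings, ground_truths=None,
                 segmenter: SegmenterConfig | None = None,
                 spectral: SpectralConfig | None = None,
                 orders=ORDERS, normalizations=NORMALIZATIONS):
        if not recordings:
            raise ValueError("no recordings")
        self.recordings = list(recordings)
        self.ground_truths = ground_truths or {}
        self.segmenter = segmenter or SegmenterConfig()
        self.spectral = spectral or SpectralConfig()
        self.orders = tuple(orders)
        self.normalizations = tuple(normalizations)
        for n in self.normalizations:
            if n not in NORMALIZATIONS:
                raise ValueError(f"unknown normalization {n!r}")

    # ------------------------------------------------------------------
    @classmethod
    def from_synthetic(cls, params: CohortParams | None = None, **kwargs):
        """Build the model on a generated synthetic cohort."""
        model_kw = {k: kwargs.pop(k) for k in
                    ("segmenter", "spectral", "orders", "normalizations")
                    if k in kwargs}
        params = params or CohortParams(**kwargs)
        cohort = generate_cohort(params)
        obj = cls(cohort.recordings, cohort.ground_truths, **model_kw)
        obj.cohort_params = params
        return obj

    @classmethod
    def from_directory(cls, path, **kwargs):
        """Build the model from `P<id>_<task>.csv` recordings in a directory."""
        from .io import read_recording
        path = Path(path)
        files = sorted(path.glob("P*_*.csv"))
        if not files:
            raise ValueError(f"no recordings found in {path}")
        return cls([read_recording(f) for f in files], **kwargs)

    # ------------------------------------------------------------------
    def fit(self) -> "SpectralVariabilityResults":
        stages = {}
        caught: list = []

        t0 = time.perf_counter()
        seg_rows, segments_by_rec = [], []
        cfg = self.segmenter
        if cfg.expected_count is None and hasattr(self, "cohort_params"):
            cfg = SegmenterConfig(**{**asdict(cfg),
                                     "expected_count":
                                     self.cohort_params.n_repetitions})
        for rec in self.recordings:
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                segs = segment_recording(rec, cfg)
            caught.extend(str(w.message) for w in wlist)
            segments_by_rec.append((rec, segs))
            for s in segs:
                seg_rows.append({"participant": s.participant_id,
                                 "task": s.task, "rep": s.repetition_index,
                                 "start_sample": s.start, "end_sample": s.end})
        segments = pd.DataFrame(seg_rows)
        stages["segment"] = {"seconds": time.perf_counter() - t0,
                             "n_segments": len(segments)}

        # ---- spectra: notch -> pad -> Hann -> FFT -> MTF ----------------
        t0 = time.perf_counter()
        scfg = self.spectral
        smoothed = []  # records with raw (un-normalized) smoothed spectra
        for rec, segs in segments_by_rec:
            if not segs:
                continue
            per_channel = {
                m: [notch_filter(s.data[:, ci], rec.fs,
                                 scfg.notch_freq_hz, scfg.notch_q)
                    for s in segs]
                for ci, m in enumerate(rec.channel_muscles)}
            all_series = [a for lst in per_channel.values() for a in lst]
            padded, n_ref = pad_to_reference(all_series)
            it = iter(padded)
            for m in rec.channel_muscles:
                for s in segs:
                    spec = power_spectrum(apply_window(next(it)), rec.fs,
                                          scfg.analysis_band_hz)
                    spec = mtf_smooth(spec, scfg)
                    smoothed.append({"participant": rec.participant_id,
                                     "task": rec.task, "muscle": m,
                                     "rep": s.repetition_index,
                                     "spectrum": spec})
        if not smoothed:
            raise RuntimeError("no segments found in any recording")
        grid = common_grid([r["spectrum"].f[-1] for r in smoothed], scfg)
        spectra = []
        for r in smoothed:
            for norm in self.normalizations:
                spec = regrid(normalize(r["spectrum"], norm), grid)
                spectra.append({**{k: r[k] for k in
                                   ("participant", "task", "muscle", "rep")},
                                "norm": norm, "spectrum": spec})
        stages["spectra"] = {"seconds": time.perf_counter() - t0,
                             "n_spectra": len(spectra),
                             "grid_bins": int(grid.size)}

        # ---- distances ---------------------------------------------------
        t0 = time.perf_counter()
        by_cond: dict = {}
        for r in spectra:
            key = (r["participant"], r["muscle"], r["task"], r["norm"])
            by_cond.setdefault(key, []).append(r)
        references = {}
        for key, rows in by_cond.items():
            rows.sort(key=lambda r: r["rep"])
            references[key] = reference_spectrum([r["spectrum"] for r in rows])

        intra_rows = []
        for (pid, muscle, task, norm), rows in by_cond.items():
            ref = references[(pid, muscle, task, norm)]
            for order in self.orders:
                dists = intra_distances([r["spectrum"] for r in rows],
                                        ref, order)
                for r, d in zip(rows, dists):
                    intra_rows.append({"participant": pid, "muscle": muscle,
                                       "posture": task, "norm": norm,
                                       "order": str(order), "rep": r["rep"],
                                       "value": d})
        intra = pd.DataFrame(intra_rows)

        inter_rows = []
        participants = sorted({r["participant"] for r in spectra})
        muscles = sorted({r["muscle"] for r in spectra})
        if len(participants) >= 2:
            for muscle in muscles:
                for task in TASKS:
                    for norm in self.normalizations:
                        refs = {p: references[(p, muscle, task, norm)]
                                for p in participants
                                if (p, muscle, task, norm) in references}
                        if len(refs) < 2:
                            continue
                        for order in self.orders:
                            for i1, i2, d in inter_distances(refs, order):
                                inter_rows.append(
                                    {"id1": i1, "id2": i2, "muscle": muscle,
                                     "posture": task, "norm": norm,
                                     "order": str(order), "value": d})
        inter = pd.DataFrame(inter_rows)
        stages["distances"] = {"seconds": time.perf_counter() - t0,
                               "n_intra": len(intra), "n_inter": len(inter)}

        # ---- summaries, tests, distribution fits ------------------------
        t0 = time.perf_counter()
        intra_summary = _summary_table(intra)
        inter_summary = _summary_table(inter) if len(inter) else pd.DataFrame()

        tests = []
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            for level, table in (("intra", intra), ("inter", inter)):
                if not len(table):
                    continue
                if not {"SP", "NT"} <= set(table["posture"].unique()):
                    continue
                try:
                    tests.append(compare_postures(table, level))
                except ValueError as exc:  # e.g. too few pairs for the test
                    caught.append(f"{level} posture test skipped: {exc}")
        caught.extend(str(w.message) for w in wlist)
        posture_tests = (pd.concat(tests, ignore_index=True)
                         if tests else pd.DataFrame())

        gof_rows = []
        if len(inter):
            for (muscle, posture, norm, order), grp in inter.groupby(
                    ["muscle", "posture", "norm", "order"], sort=True):
                values = grp["value"].to_numpy()
                for family in FAMILIES:
                    if values.size < 25:
                        caught.append(
                            f"too few inter distances ({values.size}) to fit "
                            f"{family} for {muscle}/{posture}/{norm}/{order}")
                        continue
                    fit = chi_square_gof(values,
                                         fit_distribution(values, family))
                    gof_rows.append({"muscle": muscle, "posture": posture,
                                     "norm": norm, "order": order,
                                     "family": family,
                                     "params": json.dumps(fit.params),
                                     "chi2": fit.chi2, "df": fit.df,
                                     "p_value": fit.p_value,
                                     "n_bins": fit.n_bins})
        gof = pd.DataFrame(gof_rows)
        stages["inference"] = {"seconds": time.perf_counter() - t0,
                               "n_tests": len(posture_tests),
                               "n_fits": len(gof)}

        manifest = {
            "version": __version__,
            "n_recordings": len(self.recordings),
            "orders": [str(o) for o in self.orders],
            "normalizations": list(self.normalizations),
            "segmenter": asdict(cfg),
            "spectral": {**asdict(scfg),
                         "analysis_band_hz": list(scfg.analysis_band_hz)},
            "stages": stages,
            "warnings": caught,
        }
        if hasattr(self, "cohort_params"):
            p = asdict(self.cohort_params)
            p["shape_means"] = {f"{m}/{t}": list(v)
                                for (m, t), v in p["shape_means"].items()}
            manifest["cohort_params"] = p

        return SpectralVariabilityResults(
            model=self, segments=segments, spectra=spectra,
            references=references, grid=grid, intra=intra, inter=inter,
            intra_summary=intra_summary, inter_summary=inter_summary,
            posture_tests=posture_tests, gof=gof, manifest=manifest)


def _summary_table(distances: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (order, muscle, posture, norm), grp in distances.groupby(
            ["order", "muscle", "posture", "norm"], sort=True):
        if len(grp) < 2:
            continue
        s = summarize(grp["value"].to_numpy())
        rows.append({"order": order, "muscle": muscle, "posture": posture,
                     "norm": norm, "mean": s.mean, "std": s.std, "cv": s.cv,
                     "min": s.min, "max": s.max, "n": s.n})
    return pd.DataFrame(rows)


class SpectralVariabilityResults:
    """Fitted results: distance tables, summaries, tests and fits."""

    def __init__(self, model, segments, spectra, references, grid, intra,
                 inter, intra_summary, inter_summary, posture_tests, gof,
                 manifest):
        self.model = model
        self.segments = segments
        self.spectra = spectra
        self.references = references
        self.grid = grid
        self.intra = intra
        self.inter = inter
        self.intra_summary = intra_summary
        self.inter_summary = inter_summary
        self.posture_tests = posture_tests
        self.gof = gof
        self.manifest = manifest

    # ------------------------------------------------------------------
    def summary(self) -> str:
        lines = ["Spectral variability analysis"
                 f" (emgspecvar {self.manifest['version']})",
                 f"recordings: {self.manifest['n_recordings']}  "
                 f"segments: {len(self.segments)}  "
                 f"grid bins: {self.manifest['stages']['spectra']['grid_bins']}",
                 ""]
        with pd.option_context("display.width", 120,
                               "display.float_format", "{:.6g}".format):
            lines += ["Intra-subject distance summary "
                      "(pooled repetitions; mean/STD/CV/min/max):",
                      self.intra_summary.to_string(index=False), ""]
            if len(self.inter_summary):
                lines += ["Inter-subject distance summary (participant pairs):",
                          self.inter_summary.to_string(index=False), ""]
            if len(self.posture_tests):
                lines += ["Wilcoxon signed-rank SP vs NT:",
                          self.posture_tests.to_string(index=False), ""]
            if len(self.gof):
                piv = self.gof.pivot_table(
                    index=["order", "muscle", "posture", "norm"],
                    columns="family", values="p_value")
                lines += ["Chi-square GOF p-values for inter-subject "
                          "distance distributions:", piv.to_string(), ""]
        if self.manifest["warnings"]:
            lines.append(f"warnings: {len(self.manifest['warnings'])} "
                         "(see manifest)")
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def save(self, out_dir, write_spectra: str = "reference") -> dict:
        """Write result tables as CSV plus a JSON manifest.

        write_spectra: 'none' | 'reference' | 'all' — how much of the
        spectral intermediates to serialize.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.segments.to_csv(out / "segments.csv", index=False)
        self.intra.to_csv(out / "intra_distances.csv", index=False)
        if len(self.inter):
            self.inter.to_csv(out / "inter_distances.csv", index=False)
        self.intra_summary.to_csv(out / "intra_summary.csv", index=False)
        if len(self.inter_summary):
            self.inter_summary.to_csv(out / "inter_summary.csv", index=False)
        if len(self.posture_tests):
            self.posture_tests.to_csv(out / "posture_tests.csv", index=False)
        if len(self.gof):
            self.gof.to_csv(out / "distribution_fits.csv", index=False)
        if write_spectra in ("reference", "all"):
            rows = []
            for (pid, muscle, task, norm), ref in sorted(self.references.items()):
                for f, p in zip(ref.f, ref.p):
                    rows.append((pid, task, muscle, norm, f, p))
            pd.DataFrame(rows, columns=["participant", "task", "muscle",
                                        "norm", "freq_hz", "power"]
                         ).to_csv(out / "reference_spectra.csv", index=False)
        if write_spectra == "all":
            rows = []
            for r in self.spectra:
                for f, p in zip(r["spectrum"].f, r["spectrum"].p):
                    rows.append((r["participant"], r["task"], r["muscle"],
                                 r["rep"], r["norm"], f, p))
            pd.DataFrame(rows, columns=["participant", "task", "muscle",
                                        "rep", "norm", "freq_hz", "power"]
                         ).to_csv(out / "segment_spectra.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=1))
        return self.manifest
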