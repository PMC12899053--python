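"""Reading recording CSV files (`time_s,<m1>_uv,<m2>_uv`)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synth import Recording

__all__ = ["read_recording"]


def read_recording(path) -> Recording:
    """Parse a two-channel recording CSV written by the generator.

    Validates the header (a time column plus exactly two `<muscle>_uv`
    channels), uniform sampling (every timestamp within 1e-6 s of the
    uniform grid), and derives participant/task from the `P<id>_<task>`
    file-name convention when present.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in df.columns:
        raise ValueError(f"{path.name}: missing required column 'time_s'")
    chan_cols = [c for c in df.columns if c.endswith("_uv")]
    if len(chan_cols) != 2:
        raise ValueError(
            f"{path.name}: expected exactly two '<muscle>_uv' channel "
            f"columns, found {chan_cols or 'none'}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path.name}: fewer than 2 samples")
    fs = (t.size - 1) / (t[-1] - t[0])
    ideal = t[0] + np.arange(t.size) / fs
    dev = np.abs(t - ideal)
    if np.any(dev > 1e-6):
        k = int(np.argmax(dev))
        raise ValueError(
            f"{path.name}: non-uniform sampling at row {k} "
            f"(deviation {dev[k]:.3g} s from a uniform {fs:.6g} Hz grid)")
    muscles = tuple(c[:-3] for c in chan_cols)
    stem = path.stem
    pid, task = (stem.split("_", 1) + ["?"])[:2] if "_" in stem else (stem, "?")
    return Recording(t=t, x=df[chan_cols].to_numpy(dtype=float), fs=fs,
                     participant_id=pid, task=task, channel_muscles=muscles)
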