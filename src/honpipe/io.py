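"""Plain-file readers and writers (CSV, JSON, multi-page TIFF)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import SpeedTrace, TraceMatrix, validate_bouts, make_stimulus_schedule
from .traces import RoiSet


def write_traces_csv(path, tm: TraceMatrix) -> None:
    """Traces as CSV: rows = cells, columns = frames; metadata in header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# rate={tm.rate} t0={tm.t0} kind={tm.kind}\n")
        tm.to_frame().to_csv(fh, index=False)


def read_traces_csv(path) -> TraceMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
        df = pd.read_csv(fh)
    return TraceMatrix(df.to_numpy(), rate=float(meta["rate"]), t0=float(meta["t0"]), kind=meta["kind"])


def write_speed_csv(path, speed: SpeedTrace) -> None:
    pd.DataFrame({"time": speed.times, "speed": speed.values}).to_csv(path, index=False)


def read_speed_csv(path) -> SpeedTrace:
    df = pd.read_csv(path)
    t = df["time"].to_numpy()
    rate = 1.0 / np.median(np.diff(t)) if t.size > 1 else 1.0
    return SpeedTrace(df["speed"].to_numpy(), rate=rate, t0=float(t[0]) if t.size else 0.0)


def write_bouts_csv(path, bouts: pd.DataFrame) -> None:
    bouts.to_csv(path, index=False)


def read_bouts_csv(path) -> pd.DataFrame:
    # keep_default_na: class labels like "null" must stay strings
    return validate_bouts(pd.read_csv(path, keep_default_na=False, na_values=[""]))


def write_stimuli_csv(path, stimuli: pd.DataFrame) -> None:
    stimuli.to_csv(path, index=False)


def read_stimuli_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    return make_stimulus_schedule(df["time"], df["modality"], df["duration"])


def write_stack_tiff(path, stack: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(stack, np.float32))


def read_stack_tiff(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), float)


def write_roi_labels_tiff(path, rois: RoiSet) -> None:
    """ROI masks as a labelled image (0 = background, i+1 = cell i)."""
    lab = np.zeros(rois.frame_shape, np.uint16)
    for i, m in enumerate(rois.masks):
        lab[m] = i + 1
    tifffile.imwrite(path, lab)


def read_roi_labels_tiff(path) -> RoiSet:
    lab = tifffile.imread(path)
    n = int(lab.max())
    return RoiSet(masks=np.stack([lab == i + 1 for i in range(n)]))


def write_json(path, obj) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default))
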