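"""Locomotion epoch detection, bout statistics and peri-event alignment."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import ParameterError, PeriEventTensor, SpeedTrace, TraceMatrix, make_bout_table


def detect_bouts(
    speed: SpeedTrace,
    threshold: float = 1.0,
    min_duration: float = 0.5,
    merge_gap: float = 0.5,
) -> pd.DataFrame:
    """Detect locomotion bouts as maximal runs of speed above threshold.

    A locomotion epoch is any time the animal moves faster than
    ``threshold`` (1 cm/s by default). Sub-threshold gaps shorter than
    ``merge_gap`` are bridged and runs shorter than ``min_duration`` are
    dropped, which prevents sensor noise from fragmenting bouts. The
    onset is the time of the first supra-threshold sample; the offset is
    one sample past the last (half-open span).
    """
    v = speed.values
    above = v > threshold
    if not above.any():
        return make_bout_table([], [])
    d = np.diff(above.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(v.size)
    # merge runs separated by short gaps
    merged = [[starts[0], ends[0]]]
    gap_n = merge_gap * speed.rate
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] < gap_n:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    rows = [(s, e) for s, e in merged if (e - s) / speed.rate >= min_duration]
    onsets = [speed.t0 + s / speed.rate for s, _ in rows]
    offsets = [speed.t0 + e / speed.rate for _, e in rows]
    dist = [float(v[s:e].sum() / speed.rate) for s, e in rows]
    mspeed = [float(v[s:e].mean()) for s, e in rows]
    return make_bout_table(onsets, offsets, distance=dist, mean_speed=mspeed)


def bout_stats(bouts: pd.DataFrame, recording_span: tuple) -> dict:
    """Bout counts, durations, inter-bout intervals and mean speeds.

    Intervals run from each bout's offset to the next bout's onset.
    Summaries are returned both raw and averaged.
    """
    durations = bouts["duration"].to_numpy() if len(bouts) else np.array([])
    intervals = (
        bouts["onset"].to_numpy()[1:] - bouts["offset"].to_numpy()[:-1]
        if len(bouts) > 1
        else np.array([])
    )
    speeds = bouts["mean_speed"].to_numpy() if len(bouts) else np.array([])
    return {
        "n_bouts": int(len(bouts)),
        "durations": durations,
        "inter_bout_intervals": intervals,
        "mean_speeds": speeds,
        "mean_duration": float(durations.mean()) if durations.size else np.nan,
        "mean_interval": float(intervals.mean()) if intervals.size else np.nan,
        "mean_speed": float(np.nanmean(speeds)) if speeds.size else np.nan,
        "recording_span": tuple(recording_span),
    }


def align(
    traces: TraceMatrix,
    events: np.ndarray,
    window: tuple,
    alignment: str = "bout_onset",
    require_z: bool = True,
) -> PeriEventTensor:
    """Nearest-frame alignment of traces around event times.

    Events whose window extends beyond the recording are kept but
    flagged truncated (NaN-padded) and excluded from averages by
    default.
    """
    if require_z and traces.kind != "z":
        raise ParameterError("align expects z-scored traces")
    events = np.atleast_1d(np.asarray(events, float))
    if events.size == 0:
        raise ParameterError("no events to align")
    n_rel = int(round((window[1] - window[0]) * traces.rate))
    off0 = int(round(window[0] * traces.rate))
    vals = np.full((traces.n_cells, events.size, n_rel), np.nan)
    truncated = np.zeros(events.size, dtype=bool)
    for j, ev in enumerate(events):
        c = traces.time_to_index(ev)
        lo, hi = c + off0, c + off0 + n_rel
        src_lo, src_hi = max(lo, 0), min(hi, traces.n_frames)
        if src_lo >= src_hi:
            truncated[j] = True
            continue
        vals[:, j, src_lo - lo : src_hi - lo] = traces.values[:, src_lo:src_hi]
        truncated[j] = lo < 0 or hi > traces.n_frames
    if truncated.all():
        raise ParameterError("every event window is truncated; nothing usable to align")
    return PeriEventTensor(vals, rate=traces.rate, window=tuple(window), alignment=alignment, truncated=truncated)


def normalize_to_baseline(stats_pre: dict, stats_post: dict) -> dict:
    """Each statistic of ``stats_post`` as a percentage of ``stats_pre``.

    Zero-valued baselines are flagged ``None`` rather than divided.
    """
    keys = ("n_bouts", "mean_duration", "mean_interval", "mean_speed")
    out = {}
    for k in keys:
        pre, post = stats_pre.get(k), stats_post.get(k)
        if pre is None or post is None or not np.isfinite(pre) or pre == 0:
            out[k] = None
        else:
            out[k] = 100.0 * post / pre
    return out
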