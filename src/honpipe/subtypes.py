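"""Five-way peri-locomotor subtype classification of individual cells.

Cells are classified from their bout-averaged z-scored trace aligned to
locomotion onset.  Baseline mean and a 2σ threshold come from 10-6 s
before onset; extrema are searched 6 s before to 16 s after onset and
summarised as 1 s means around the extremum.  A cell with only a
maximum above baseline + 2σ is an ON cell, only a minimum below
baseline - 2σ an OFF cell, both in max-then-min order an up-down cell,
the reverse order a down-up cell, and otherwise it is not modulated.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .core import ParameterError, TraceMatrix
from .locomotion import align
from .traces import moving_average, sustained_crossing

BASELINE_WINDOW = (-10.0, -6.0)
EXTREMA_WINDOW = (-6.0, 16.0)


@dataclass
class SubtypeResult:
    """Per-cell classification and its derived statistics."""

    subtype: str
    baseline_mean: float
    baseline_sd: float
    max_resp: float
    min_resp: float
    t_max: float
    t_min: float
    onset_time: float | None = None
    active_move_fraction: float | None = None


def classify_cell(
    mean_peri_trace: np.ndarray,
    rate: float,
    t0: float,
    baseline_window: tuple = BASELINE_WINDOW,
    extrema_window: tuple = EXTREMA_WINDOW,
    k: float = 2.0,
    resp_avg: float = 1.0,
) -> SubtypeResult:
    """Classify one cell from its bout-averaged peri-onset trace.

    ``t0`` is the time of the first sample relative to locomotion onset.
    ``max_resp``/``min_resp`` are means over a centred ``resp_avg``-second
    window around the extrema, truncated at the extrema-window edges.
    """
    x = np.asarray(mean_peri_trace, float)
    times = t0 + np.arange(x.size) / rate
    bsel = (times >= baseline_window[0]) & (times < baseline_window[1])
    esel = (times >= extrema_window[0]) & (times < extrema_window[1])
    if bsel.sum() < 2 or not esel.any():
        raise ParameterError("trace does not cover the baseline/extrema windows")
    base = x[bsel].mean()
    sd = x[bsel].std()
    eidx = np.flatnonzero(esel)
    half = max(int(round(resp_avg * rate / 2)), 0)

    def _resp(i):
        lo = max(i - half, eidx[0])
        hi = min(i + half + 1, eidx[-1] + 1)
        return float(x[lo:hi].mean())

    imax = eidx[np.argmax(x[eidx])]
    imin = eidx[np.argmin(x[eidx])]
    max_resp, min_resp = _resp(imax), _resp(imin)
    t_max, t_min = float(times[imax]), float(times[imin])
    has_max = max_resp > base + k * sd
    has_min = min_resp < base - k * sd
    if has_max and has_min:
        label = "up_down" if t_max < t_min else "down_up"
    elif has_max:
        label = "ON"
    elif has_min:
        label = "OFF"
    else:
        label = "non_mod"
    return SubtypeResult(
        subtype=label,
        baseline_mean=float(base),
        baseline_sd=float(sd),
        max_resp=max_resp,
        min_resp=min_resp,
        t_max=t_max,
        t_min=t_min,
    )


#: initial deviation direction of each modulated subtype
_ONSET_DIRECTION = {"ON": "above", "up_down": "above", "OFF": "below", "down_up": "below"}


def onset_time(
    mean_peri_trace: np.ndarray,
    rate: float,
    t0: float,
    subtype: str,
    baseline_window: tuple = BASELINE_WINDOW,
    search_window: tuple = EXTREMA_WINDOW,
    k_sd: float = 1.0,
    min_hold: float = 2.0,
) -> float | None:
    """Response onset: first 1σ deviation from baseline held for 2 s.

    The deviation direction follows the subtype's initial phase (upward
    for ON/up-down, downward for OFF/down-up).  Not defined for
    non-modulated cells.
    """
    if subtype not in _ONSET_DIRECTION:
        raise ParameterError(f"onset time undefined for subtype {subtype!r}")
    return sustained_crossing(
        mean_peri_trace,
        rate,
        baseline_window=baseline_window,
        k_sd=k_sd,
        min_hold=min_hold,
        direction=_ONSET_DIRECTION[subtype],
        search_window=search_window,
        t0=t0,
    )


def active_move_fraction(
    z_trace: np.ndarray,
    rate: float,
    bouts: pd.DataFrame,
    pad: float = 3.0,
    t0: float = 0.0,
) -> float | None:
    """Fraction of a cell's active frames that fall during movement.

    Active frames exceed mean + 2 s.d. of the whole recording; movement
    frames are bout spans padded ±``pad`` seconds (union). Returns
    ``None`` when the cell has no active frames.
    """
    x = np.asarray(z_trace, float)
    times = t0 + np.arange(x.size) / rate
    active = x > x.mean() + 2 * x.std()
    if not active.any():
        return None
    move = np.zeros(x.size, dtype=bool)
    for _, b in bouts.iterrows():
        move |= (times >= b.onset - pad) & (times < b.offset + pad)
    return float((active & move).sum() / active.sum())


def classify_ensemble(
    traces: TraceMatrix,
    bouts: pd.DataFrame,
    baseline_window: tuple = BASELINE_WINDOW,
    extrema_window: tuple = EXTREMA_WINDOW,
    smooth_frames: int = 3,
    min_bouts: int = 3,
    pad: float = 3.0,
) -> pd.DataFrame:
    """Classify every cell of a z-scored recording against its bouts.

    Aligns each cell to all bout onsets over the union of the baseline
    and extrema windows, averages across non-truncated bouts (3-frame
    smoothed), then applies :func:`classify_cell`, :func:`onset_time`
    and :func:`active_move_fraction`. Cells with fewer than ``min_bouts``
    usable bouts are reported ``unclassifiable``.
    """
    if traces.kind != "z":
        raise ParameterError("classification expects z-scored traces")
    window = (baseline_window[0], extrema_window[1])
    tensor = align(traces, bouts["onset"].to_numpy(), window)
    usable = int((~tensor.truncated).sum())
    rows = []
    if usable < min_bouts:
        for _ in range(traces.n_cells):
            rows.append({"subtype": "unclassifiable", "n_bouts": usable})
        return pd.DataFrame(rows)
    mean_traces = tensor.event_mean()
    mean_traces = moving_average(mean_traces, smooth_frames)
    for i in range(traces.n_cells):
        res = classify_cell(
            mean_traces[i], traces.rate, t0=window[0],
            baseline_window=baseline_window, extrema_window=extrema_window,
        )
        if res.subtype != "non_mod":
            res.onset_time = onset_time(
                mean_traces[i], traces.rate, t0=window[0], subtype=res.subtype,
                baseline_window=baseline_window, search_window=extrema_window,
            )
        res.active_move_fraction = active_move_fraction(
            traces.values[i], traces.rate, bouts, pad=pad, t0=traces.t0
        )
        row = asdict(res)
        row["n_bouts"] = usable
        rows.append(row)
    return pd.DataFrame(rows)
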