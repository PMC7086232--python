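"""ROI trace extraction and fluorescence preprocessing.

Implements the standard miniscope/two-photon processing chain: mean-ROI
extraction with a ring-shaped neuropil mask, raw neuropil subtraction
(``F_raw - F_np``, no scaling coefficient), ΔF/F₀ with several baseline
estimators, z-scoring (optionally across concatenated sessions), boxcar
smoothing, and a sustained threshold-crossing onset detector used both
for per-cell onset times and photometry latencies.

All moving windows are centred and truncated at the edges, which avoids
introducing phase lag into onset estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import ParameterError, TraceMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ROI sets and extraction
# ---------------------------------------------------------------------------

@dataclass
class RoiSet:
    """Boolean pixel masks per cell, with derived neuropil ring masks.

    The neuropil mask of a cell is the ring of pixels at Chebyshev
    (square) distance 3-6 from the ROI outline, excluding pixels that
    belong to any ROI.
    """

    masks: np.ndarray  # (n_cells, H, W) bool
    ring_inner: int = 3
    ring_outer: int = 6

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.masks.ndim != 3:
            raise ParameterError("RoiSet masks must be (n_cells, H, W)")

    @property
    def n_cells(self) -> int:
        return self.masks.shape[0]

    @property
    def frame_shape(self) -> tuple:
        return self.masks.shape[1:]

    def neuropil_masks(self) -> np.ndarray:
        """Ring masks at Chebyshev distance ``ring_inner``..``ring_outer``."""
        any_roi = self.masks.any(axis=0)
        out = np.zeros_like(self.masks)
        for i, m in enumerate(self.masks):
            # square dilation of half-width k covers Chebyshev distance <= k
            outer = ndimage.binary_dilation(m, structure=np.ones((2 * self.ring_outer + 1,) * 2))
            inner = ndimage.binary_dilation(m, structure=np.ones((2 * (self.ring_inner - 1) + 1,) * 2))
            out[i] = outer & ~inner & ~any_roi
        return out


def extract_traces(stack: np.ndarray, rois: RoiSet, rate: float = 1.0) -> tuple[TraceMatrix, np.ndarray]:
    """Mean-ROI fluorescence and neuropil traces from an image stack.

    Returns ``(F_raw, F_np)`` where ``F_raw`` is a raw :class:`TraceMatrix`
    and ``F_np`` the per-cell neuropil trace array. A cell whose neuropil
    ring is empty (crowded field) falls back to the frame background mean
    and is logged.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[1:] != rois.frame_shape:
        raise ParameterError(
            f"stack frames {stack.shape[1:]} do not match RoiSet {rois.frame_shape}"
        )
    flat = stack.reshape(stack.shape[0], -1)
    np_masks = rois.neuropil_masks()
    any_roi = rois.masks.any(axis=0).ravel()
    f_raw = np.empty((rois.n_cells, stack.shape[0]))
    f_np = np.empty_like(f_raw)
    for i in range(rois.n_cells):
        f_raw[i] = flat[:, rois.masks[i].ravel()].mean(axis=1)
        ring = np_masks[i].ravel()
        if ring.any():
            f_np[i] = flat[:, ring].mean(axis=1)
        else:
            logger.warning("cell %d has an empty neuropil ring; using frame background mean", i)
            f_np[i] = flat[:, ~any_roi].mean(axis=1)
    return TraceMatrix(f_raw, rate=rate, kind="raw"), f_np


def neuropil_correct(f_raw: np.ndarray, f_np: np.ndarray) -> np.ndarray:
    """Raw neuropil subtraction, ``F_raw - F_np`` elementwise."""
    f_raw = np.asarray(f_raw, float)
    f_np = np.asarray(f_np, float)
    if f_raw.shape[-1] != f_np.shape[-1]:
        raise ParameterError("F_raw and F_np lengths differ")
    return f_raw - f_np


# ---------------------------------------------------------------------------
# smoothing / normalisation
# ---------------------------------------------------------------------------

def moving_average(x: np.ndarray, n_samples: int) -> np.ndarray:
    """Centred boxcar of length ``n_samples``, truncated at the edges."""
    if n_samples < 1:
        raise ParameterError("moving-average length must be >= 1")
    x = np.asarray(x, float)
    return (
        pd.DataFrame(np.atleast_2d(x).T)
        .rolling(int(n_samples), center=True, min_periods=1)
        .mean()
        .to_numpy()
        .T.reshape(x.shape)
    )


def _moving_stat(x: np.ndarray, n: int, stat: str) -> np.ndarray:
    roll = pd.DataFrame(np.atleast_2d(x).T).rolling(int(n), center=True, min_periods=1)
    out = roll.median() if stat == "median" else roll.mean()
    return out.to_numpy().T.reshape(np.asarray(x).shape)


def dff(
    trace: np.ndarray,
    rate: float,
    mode: str = "moving_median",
    window_s: float = 100.0,
    event_time: float | None = None,
    pre_window_s: float = 2.0,
) -> np.ndarray:
    """ΔF/F₀ with a selectable baseline estimator.

    ``moving_median`` (default window 100 s) corrects slow photobleaching
    in miniscope data; ``moving_mean`` (e.g. 240 s) is the photometry
    variant; ``pre_event_mean`` uses the mean over ``pre_window_s``
    seconds before ``event_time`` as a constant F₀.
    """
    x = np.asarray(trace, float)
    if mode in ("moving_median", "moving_mean"):
        if window_s <= 0:
            raise ParameterError("window_s must be positive")
        n = max(int(round(window_s * rate)), 1)
        f0 = _moving_stat(x, n, "median" if mode == "moving_median" else "mean")
    elif mode == "pre_event_mean":
        if event_time is None:
            raise ParameterError("pre_event_mean mode requires event_time")
        i1 = int(round(event_time * rate))
        i0 = max(i1 - int(round(pre_window_s * rate)), 0)
        if i1 <= i0:
            raise ParameterError("pre-event baseline window is empty")
        f0 = np.broadcast_to(x[..., i0:i1].mean(axis=-1, keepdims=True), x.shape)
    else:
        raise ParameterError(f"unknown dff mode {mode!r}")
    bad = f0 <= 0
    if np.any(bad):
        raise ParameterError(f"F0 <= 0 at sample {int(np.argmax(bad.ravel()))}; cannot form dF/F")
    return (x - f0) / f0


def zscore(x: np.ndarray, concat: list | None = None) -> np.ndarray | list:
    """Z-score per cell over the full record.

    ``concat`` may hold several session arrays sharing cells; they are
    z-scored jointly (mean/sd over the concatenation) and returned split,
    which makes amplitudes comparable across sessions.
    """
    if concat is not None:
        arrs = [np.atleast_2d(np.asarray(a, float)) for a in concat]
        joint = np.concatenate(arrs, axis=1)
        mu = joint.mean(axis=1, keepdims=True)
        sd = joint.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise ParameterError("zero variance; cannot z-score")
        out, i = [], 0
        for a in arrs:
            out.append(((joint[:, i : i + a.shape[1]] - mu) / sd))
            i += a.shape[1]
        return out
    x = np.asarray(x, float)
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    if np.any(sd == 0):
        raise ParameterError("zero variance; cannot z-score")
    return (x - mu) / sd


def zscore_matrix(tm: TraceMatrix) -> TraceMatrix:
    """Z-scored copy of a trace matrix (kind advances to ``'z'``)."""
    return tm.with_values(zscore(tm.values), kind="z")


# ---------------------------------------------------------------------------
# sustained threshold crossing
# ---------------------------------------------------------------------------

def sustained_crossing(
    trace: np.ndarray,
    rate: float,
    baseline_window: tuple,
    k_sd: float = 1.0,
    min_hold: float = 2.0,
    direction: str = "above",
    search_window: tuple | None = None,
    t0: float = 0.0,
) -> float | None:
    """First time the trace deviates ``k_sd``·σ from baseline and holds.

    Baseline mean and σ come from ``baseline_window`` (population s.d.,
    denominator *n*). The onset is the first sample in ``search_window``
    whose deviation is at least ``k_sd``·σ in the requested direction for
    every sample over the following ``min_hold`` seconds. Windows are in
    the same time coordinates as the trace (``t0`` + sample/rate),
    half-open. Returns ``None`` if no qualifying sample exists.
    """
    x = np.asarray(trace, float)
    times = t0 + np.arange(x.size) / rate
    bsel = (times >= baseline_window[0]) & (times < baseline_window[1])
    if bsel.sum() < 2:
        raise ParameterError("baseline window must contain at least 2 samples")
    mu = x[bsel].mean()
    sd = x[bsel].std()
    dev = x - mu
    # a (numerically) zero-variance baseline degenerates the threshold to
    # the baseline level itself; require a strict deviation then
    scale = float(np.max(np.abs(dev))) or 1.0
    tiny = 1e-9 * scale
    degenerate = sd <= tiny
    thr = tiny if degenerate else k_sd * sd
    if direction == "above":
        ok = dev > thr if degenerate else dev >= thr
    elif direction == "below":
        ok = dev < -thr if degenerate else dev <= -thr
    elif direction == "either":
        ok = np.abs(dev) > thr if degenerate else np.abs(dev) >= thr
    else:
        raise ParameterError(f"unknown direction {direction!r}")
    if search_window is None:
        search_window = (times[0], times[-1] + 1 / rate)
    hold = max(int(round(min_hold * rate)), 1)
    # run length of consecutive qualifying samples starting at each index
    run = np.zeros(x.size, dtype=int)
    acc = 0
    for i in range(x.size - 1, -1, -1):
        acc = acc + 1 if ok[i] else 0
        run[i] = acc
    candidates = np.flatnonzero(
        (times >= search_window[0]) & (times < search_window[1]) & (run >= hold)
    )
    if candidates.size == 0:
        return None
    return float(times[candidates[0]])
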