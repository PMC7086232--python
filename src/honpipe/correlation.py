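"""Behavior-bout correlation analyses and speed cross-correlograms.

Per-bout mean activity is correlated across bouts with bout speed,
distance and duration per cell; a population regression relates the
across-cell bout average to bout speed; and frame-wise
fluorescence-speed cross-correlograms quantify the lag structure of the
coupling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ParameterError, TraceMatrix


@dataclass
class BoutActivity:
    """Cell x bout mean activity plus per-bout movement metrics."""

    activity: np.ndarray  # (n_cells, n_bouts)
    bouts: pd.DataFrame
    valid: np.ndarray  # per-bout flag; False where the bout fell outside the trace


def bout_activity(traces: TraceMatrix, bouts: pd.DataFrame) -> BoutActivity:
    """Per-cell mean z activity during each behavior bout."""
    if traces.kind != "z":
        raise ParameterError("bout_activity expects z-scored traces")
    act = np.full((traces.n_cells, len(bouts)), np.nan)
    valid = np.zeros(len(bouts), dtype=bool)
    for j, (_, b) in enumerate(bouts.iterrows()):
        i0 = max(traces.time_to_index(b.onset), 0)
        i1 = min(traces.time_to_index(b.offset), traces.n_frames)
        if i1 <= i0 or b.onset < traces.t0 or b.offset > traces.t0 + traces.n_frames / traces.rate:
            continue
        act[:, j] = traces.values[:, i0:i1].mean(axis=1)
        valid[j] = True
    return BoutActivity(activity=act, bouts=bouts.reset_index(drop=True), valid=valid)


def metric_correlations(ba: BoutActivity, strong_r: float = 0.6) -> dict:
    """Pearson r of each cell's bout activity with speed/distance/duration.

    Also reports, per metric, the fraction of cells strongly correlated
    (r > ``strong_r``) and the cross-metric regression of each cell's
    speed-r against its distance-r.
    """
    keep = ba.valid
    if keep.sum() < 3:
        raise ParameterError("need at least 3 valid bouts")
    act = ba.activity[:, keep]
    table = {}
    for metric, col in (("speed", "mean_speed"), ("distance", "distance"), ("duration", "duration")):
        m = ba.bouts.loc[keep, col].to_numpy(float)
        if np.all(np.isnan(m)) or np.nanstd(m) == 0:
            table[metric] = np.full(act.shape[0], np.nan)
            continue
        table[metric] = np.array([stats.pearsonr(a, m)[0] for a in act])
    frac = {
        m: float(np.mean(r > strong_r)) if not np.all(np.isnan(r)) else np.nan
        for m, r in table.items()
    }
    cross = None
    rs, rd = table["speed"], table["distance"]
    good = ~(np.isnan(rs) | np.isnan(rd))
    if good.sum() >= 3 and np.std(rd[good]) > 0:
        fit = stats.linregress(rd[good], rs[good])
        cross = {"slope": fit.slope, "r_squared": fit.rvalue**2, "p": fit.pvalue}
    return {"r": pd.DataFrame(table), "fraction_strong": frac, "speed_vs_distance": cross}


def pop_regression(ba: BoutActivity) -> dict:
    """OLS of the across-cell bout-mean activity on bout mean speed."""
    keep = ba.valid
    if keep.sum() < 2:
        raise ParameterError("need at least 2 valid bouts")
    y = np.nanmean(ba.activity[:, keep], axis=0)
    x = ba.bouts.loc[keep, "mean_speed"].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ParameterError("degenerate variance in regression inputs")
    fit = stats.linregress(x, y)
    return {
        "slope": fit.slope,
        "intercept": fit.intercept,
        "r_squared": fit.rvalue**2,
        "p": fit.pvalue,
        "n_bouts": int(keep.sum()),
        "underdetermined": bool(keep.sum() < 3),
    }


def resample_to_rate(values: np.ndarray, rate_in: float, rate_out: float) -> np.ndarray:
    """Mean-binned resampling onto a slower sample grid."""
    if rate_in == rate_out:
        return np.asarray(values, float)
    factor = rate_in / rate_out
    n_out = int(np.floor(values.size / factor))
    idx = np.floor(np.arange(values.size) / factor).astype(int)
    sums = np.bincount(idx, weights=values, minlength=n_out + 1)
    cnts = np.bincount(idx, minlength=n_out + 1)
    return (sums / np.maximum(cnts, 1))[:n_out]


def speed_xcorr(z_trace: np.ndarray, speed_values: np.ndarray, rate: float, speed_rate: float, max_lag: float = 10.0):
    """Fluorescence-speed cross-correlogram (Pearson r per frame lag).

    Positive lags mean fluorescence follows speed. Returns
    ``(lags_seconds, r_values, zero_lag_r)``; ``None`` r where either
    segment is constant.
    """
    x = np.asarray(z_trace, float)
    s = resample_to_rate(np.asarray(speed_values, float), speed_rate, rate)
    n = min(x.size, s.size)
    x, s = x[:n], s[:n]
    if np.std(x) == 0 or np.std(s) == 0:
        return None
    max_k = int(round(max_lag * rate))
    lags = np.arange(-max_k, max_k + 1)
    rvals = np.full(lags.size, np.nan)
    for i, k in enumerate(lags):
        if k >= 0:
            a, b = x[k:], s[: n - k]
        else:
            a, b = x[: n + k], s[-k:]
        if a.size > 2 and np.std(a) > 0 and np.std(b) > 0:
            rvals[i] = stats.pearsonr(a, b)[0]
    return lags / rate, rvals, float(rvals[max_k])
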