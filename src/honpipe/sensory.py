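"""Sensory response scoring, null-stimulus calibration and contrasts.

Response amplitude is the mean z-scored signal 1-4 s after stimulus
onset, averaged over trials in which the animal stayed stationary.
The interleaved null stimulus (a tone that evokes no response) sets the
bounds of meaningful responses: only amplitudes outside the global
null-response extrema count as responsive, with the side recording
excitatory vs inhibitory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core import NULL_MODALITY, ParameterError, TraceMatrix
from .locomotion import align
from .traces import sustained_crossing

RESPONSE_WINDOW = (1.0, 4.0)
#: a trial counts as stationary when no locomotion occurs in this
#: post-stimulus span (covers the scoring window with margin)
TRIAL_WINDOW = 5.0
#: and none in this pre-stimulus span, whose reporter decay tail would
#: otherwise contaminate the scoring window
TRIAL_PRE_WINDOW = 10.0


@dataclass
class ResponseTable:
    """Cell x modality response amplitudes and responsiveness flags."""

    amplitudes: pd.DataFrame  # cell x modality, z-units
    n_trials: dict  # modality -> trials used
    null_low: float | None = None
    null_high: float | None = None
    responsive: pd.DataFrame | None = None  # 'none'|'excitatory'|'inhibitory'
    flagged: list = field(default_factory=list)  # modalities with no eligible trial


def _stationary_trials(
    stimuli: pd.DataFrame,
    bouts: pd.DataFrame,
    trial_window: float,
    pre_window: float = TRIAL_PRE_WINDOW,
) -> np.ndarray:
    """True where no bout overlaps [stim - pre_window, stim + trial_window)."""
    ok = np.ones(len(stimuli), dtype=bool)
    if bouts is None or not len(bouts):
        return ok
    on = bouts["onset"].to_numpy()
    off = bouts["offset"].to_numpy()
    for i, t in enumerate(stimuli["time"].to_numpy()):
        ok[i] = not np.any((on < t + trial_window) & (off > t - pre_window))
    return ok


def response_amplitudes(
    traces: TraceMatrix,
    stimuli: pd.DataFrame,
    bouts: pd.DataFrame | None = None,
    stationary_only: bool = True,
    window: tuple = RESPONSE_WINDOW,
    trial_window: float = TRIAL_WINDOW,
) -> ResponseTable:
    """Per-cell per-modality response amplitudes from stationary trials."""
    if traces.kind != "z":
        raise ParameterError("response amplitudes expect z-scored traces")
    eligible = (
        _stationary_trials(stimuli, bouts, trial_window)
        if stationary_only
        else np.ones(len(stimuli), dtype=bool)
    )
    amps, n_trials, flagged = {}, {}, []
    for mod in pd.unique(stimuli["modality"]):
        times = stimuli.loc[(stimuli["modality"] == mod) & eligible, "time"].to_numpy()
        span = (traces.t0, traces.t0 + traces.n_frames / traces.rate)
        times = times[(times + window[0] >= span[0]) & (times + window[1] <= span[1])]
        if times.size == 0:
            flagged.append(mod)
            amps[mod] = np.full(traces.n_cells, np.nan)
            n_trials[mod] = 0
            continue
        tensor = align(traces, times, window, alignment="stimulus")
        amps[mod] = tensor.event_mean(include_truncated=True).mean(axis=1)
        n_trials[mod] = int(times.size)
    return ResponseTable(amplitudes=pd.DataFrame(amps), n_trials=n_trials, flagged=flagged)


def null_box(rt: ResponseTable) -> ResponseTable:
    """Set the null-response box and flag responsiveness against it.

    The box is the global min/max of all cells' null-stimulus
    amplitudes; responses falling inside it are indistinguishable from
    noise. Modifies and returns ``rt``.
    """
    if NULL_MODALITY not in rt.amplitudes.columns or rt.amplitudes[NULL_MODALITY].isna().all():
        raise ParameterError("no null-stimulus amplitudes; cannot calibrate the response box")
    nulls = rt.amplitudes[NULL_MODALITY].dropna()
    rt.null_low = float(nulls.min())
    rt.null_high = float(nulls.max())
    flags = {}
    for mod in rt.amplitudes.columns:
        if mod == NULL_MODALITY:
            continue
        a = rt.amplitudes[mod]
        flags[mod] = np.where(
            a > rt.null_high, "excitatory", np.where(a < rt.null_low, "inhibitory", "none")
        )
    rt.responsive = pd.DataFrame(flags)
    return rt


def modality_overlap(rt: ResponseTable) -> dict:
    """Observed vs chance-expected multimodal responder counts.

    Per-modality marginals are reported among responsive cells (cells
    responsive to at least one modality) — the form the published
    percentages take — and among all cells. The chance expectation
    assumes independent responsiveness across modalities: the
    responsive-cell marginals are inverted to unconditional
    probabilities by fixed point (conditioning on responding to at
    least one modality induces negative dependence, so the naive
    product of conditional marginals overstates multimodal overlap),
    and expected exactly-k counts are conditioned on >= 1. The
    top-modality overlap gets an exact binomial consistency check.
    """
    if rt.responsive is None:
        raise ParameterError("call null_box before modality_overlap")
    resp = rt.responsive != "none"
    mods = list(resp.columns)
    n_resp_mod = resp.sum(axis=1)
    responders = n_resp_mod > 0
    n_responders = int(responders.sum())
    if n_responders == 0:
        return None
    p_resp = {m: float(resp.loc[responders, m].mean()) for m in mods}
    p_all = {m: float(resp[m].mean()) for m in mods}

    # unconditional marginals p with p_m / (1 - prod(1-p)) = conditional
    p = dict(p_resp)
    for _ in range(200):
        p_none = float(np.prod([1.0 - p[m] for m in mods]))
        p = {m: min(p_resp[m] * (1.0 - p_none), 1.0) for m in mods}
    p_none = float(np.prod([1.0 - p[m] for m in mods]))

    def _exact_k(k: int) -> float:
        tot = 0.0
        for sub in combinations(mods, k):
            q = 1.0
            for m in mods:
                q *= p[m] if m in sub else 1.0 - p[m]
            tot += q
        return tot

    denom = max(1.0 - p_none, 1e-300)
    observed = {k: int((n_resp_mod == k).sum()) for k in range(1, len(mods) + 1)}
    expected = {k: _exact_k(k) / denom * n_responders for k in range(1, len(mods) + 1)}
    k_top = len(mods)
    p_top = min(max(_exact_k(k_top) / denom, 0.0), 1.0)
    btest = stats.binomtest(observed[k_top], n_responders, p_top)
    return {
        "n_responders": n_responders,
        "marginals_responsive": p_resp,
        "marginals_all": p_all,
        "observed": observed,
        "expected": expected,
        "binomial_p": float(btest.pvalue),
    }


def evoked_vs_stationary(
    traces: TraceMatrix,
    stimuli: pd.DataFrame,
    bouts: pd.DataFrame,
    subtype_table: pd.DataFrame,
    window: tuple = RESPONSE_WINDOW,
    evoke_window: float = 5.0,
) -> dict:
    """Per-subtype amplitudes for stationary, evoked-movement and
    self-paced conditions, plus the activity-to-locomotion latency.

    A trial is *evoked* when a bout onset falls within ``evoke_window``
    seconds after the stimulus; *stationary* when no bout overlaps the
    trial. Self-paced amplitudes come from bouts outside any trial,
    scored 1-4 s after locomotion onset. The latency summary applies the
    sustained-crossing onset rule to the mean ON/up-down-cell trace of
    evoked trials.
    """
    if traces.kind != "z":
        raise ParameterError("expects z-scored traces")
    st = stimuli[stimuli["modality"] != NULL_MODALITY].reset_index(drop=True)
    times = st["time"].to_numpy()
    bout_on = bouts["onset"].to_numpy() if len(bouts) else np.array([])
    stationary = _stationary_trials(st, bouts, TRIAL_WINDOW)
    evoked = np.array([np.any((bout_on > t) & (bout_on <= t + evoke_window)) for t in times])
    self_paced = (
        np.array([not np.any((times > o - evoke_window) & (times <= o)) for o in bout_on])
        if bout_on.size
        else np.array([], bool)
    )

    labels = subtype_table["subtype"].to_numpy()
    out = {}
    conditions = {}
    if stationary.any():
        conditions["stationary"] = ("stimulus", times[stationary])
    if evoked.any():
        conditions["evoked_move"] = ("stimulus", times[evoked])
    if self_paced.any():
        conditions["self_paced"] = ("bout_onset", bout_on[self_paced])
    for lab in pd.unique(labels):
        cells = np.flatnonzero(labels == lab)
        row = {}
        for cond, (alignment, evs) in conditions.items():
            try:
                tensor = align(traces, evs, window, alignment=alignment)
                row[cond] = float(np.nanmean(tensor.event_mean(include_truncated=True)[cells]))
            except ParameterError:
                row[cond] = None
        out[lab] = row

    latency = None
    if evoked.any():
        cells = np.flatnonzero(np.isin(labels, ("ON", "up_down")))
        if cells.size:
            tensor = align(traces, times[evoked], (-2.5, evoke_window), alignment="stimulus")
            pop = tensor.event_mean(include_truncated=True)[cells].mean(axis=0)
            onset = sustained_crossing(
                pop, traces.rate, baseline_window=(-2.5, 0.0), k_sd=1.0,
                min_hold=0.2, direction="above", search_window=(0.0, evoke_window),
                t0=-2.5,
            )
            if onset is not None:
                first_bouts = np.array(
                    [bout_on[(bout_on > t) & (bout_on <= t + evoke_window)][0] - t for t in times[evoked]]
                )
                latency = float(first_bouts.mean() - onset)
    return {"amplitudes": out, "activity_to_locomotion_latency": latency}


def movement_likelihood(stimuli: pd.DataFrame, bouts: pd.DataFrame, evoke_window: float = 5.0) -> dict:
    """Per-modality fraction of trials followed by locomotion."""
    bout_on = bouts["onset"].to_numpy() if len(bouts) else np.array([])
    out = {}
    for mod in pd.unique(stimuli["modality"]):
        times = stimuli.loc[stimuli["modality"] == mod, "time"].to_numpy()
        moved = [np.any((bout_on > t) & (bout_on <= t + evoke_window)) for t in times]
        out[mod] = float(np.mean(moved)) if times.size else np.nan
    return out


def state_contrast(
    rt_hungry: ResponseTable,
    rt_refed: ResponseTable,
    subtypes: np.ndarray | None = None,
    alpha: float = 0.0125,
) -> pd.DataFrame:
    """Paired per-cell comparison of amplitudes between hunger states.

    Both tables must come from jointly z-scored (concatenated) sessions
    of the same cells. The significance threshold defaults to the
    Bonferroni-style 0.05/4 = 0.0125 used for four modalities.
    """
    a, b = rt_hungry.amplitudes, rt_refed.amplitudes
    if a.shape[0] != b.shape[0] or set(a.columns) != set(b.columns):
        raise ParameterError("state tables must share cells and modalities")
    rows = []
    groups = [("all", np.ones(a.shape[0], bool))]
    if subtypes is not None:
        subtypes = np.asarray(subtypes)
        groups += [(lab, subtypes == lab) for lab in pd.unique(subtypes)]
    for mod in a.columns:
        if mod == NULL_MODALITY:
            continue
        for gname, sel in groups:
            x, y = a.loc[sel, mod].to_numpy(), b.loc[sel, mod].to_numpy()
            keep = ~(np.isnan(x) | np.isnan(y))
            x, y = x[keep], y[keep]
            if x.size < 2 or np.all(x == y):
                t = p = np.nan
            else:
                t, p = stats.ttest_rel(x, y)
            rows.append(
                {
                    "modality": mod,
                    "group": gname,
                    "mean_hungry": float(np.mean(x)) if x.size else np.nan,
                    "mean_refed": float(np.mean(y)) if y.size else np.nan,
                    "delta": float(np.mean(x - y)) if x.size else np.nan,
                    "t": float(t) if np.isfinite(t) else np.nan,
                    "p": float(p) if np.isfinite(p) else np.nan,
                    "significant": bool(np.isfinite(p) and p < alpha),
                    "n": int(x.size),
                }
            )
    return pd.DataFrame(rows)
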