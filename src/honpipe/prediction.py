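"""Movement prediction and population decoding.

Covers the online prediction variable built from early-leading ON
cells, its frame/bout detection metrics, cross-validated linear
support-vector decoding of movement vs stationary epochs with an
empirical permutation chance, and ROC-AUC time courses per subtype
(ideal-observer analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import ParameterError, PeriEventTensor, TraceMatrix
from .locomotion import align


@dataclass
class DecoderConfig:
    """Decoding protocol parameters.

    The defaults mirror the published protocol: a linear SVM with fixed
    C = 1, 8-fold cross-validation repeated 10 times with re-drawn
    folds (80 analyses total), 800 ms feature windows, 20 s epochs, and
    stationary epochs required to be at least 5 s away from any
    locomotion.
    """

    C: float = 1.0
    n_folds: int = 8
    n_repeats: int = 10
    window: float = 0.8
    epoch_length: float = 20.0
    stationary_margin: float = 5.0

    def __post_init__(self) -> None:
        if self.n_folds < 2 or self.n_repeats < 1:
            raise ParameterError("need n_folds >= 2 and n_repeats >= 1")


@dataclass
class PredictionResult:
    """Decoding accuracies per evaluation window."""

    window_starts: np.ndarray  # seconds relative to epoch alignment
    accuracy: np.ndarray  # mean over folds x repeats
    accuracy_sd: np.ndarray  # spread over the individual analyses
    permuted: bool
    n_epochs: int


# ---------------------------------------------------------------------------
# online prediction variable
# ---------------------------------------------------------------------------

def select_predictor_cells(
    results: pd.DataFrame,
    lead_threshold: float = 0.0,
    move_fraction_min: float = 0.9,
    include_up_down: bool = False,
) -> np.ndarray:
    """ON cells with early onsets that are active solely during movement.

    Selects cells with ``onset_time < lead_threshold`` and
    ``active_move_fraction >= move_fraction_min``.
    """
    labels = ("ON", "up_down") if include_up_down else ("ON",)
    sel = (
        results["subtype"].isin(labels)
        & (results["onset_time"] < lead_threshold)
        & (results["active_move_fraction"] >= move_fraction_min)
    )
    idx = np.flatnonzero(sel.fillna(False).to_numpy())
    return idx


def prediction_variable(
    traces: TraceMatrix,
    cells: np.ndarray,
    n_frames: int = 3,
    k_sd: float = 2.0,
):
    """Online movement-prediction variable and its threshold crossings.

    The variable is the mean over the selected cells of each frame and
    the ``n_frames - 1`` preceding frames (trailing window, so it is
    computable online). A crossing is the first sample of each excursion
    at or above ``k_sd`` standard deviations of the variable.
    Returns ``(variable, crossing_times, threshold)``.
    """
    if traces.kind != "z":
        raise ParameterError("prediction variable expects z-scored traces")
    cells = np.asarray(cells, int)
    if cells.size == 0:
        raise ParameterError("empty predictor cell set")
    pop = traces.values[cells].mean(axis=0)
    kernel = np.ones(n_frames) / n_frames
    var = np.convolve(pop, kernel)[: pop.size]  # trailing mean
    sd = var.std()
    thr = var.mean() + k_sd * sd
    supra = var >= thr if sd > 0 else np.zeros(var.size, dtype=bool)
    rising = np.flatnonzero(np.diff(supra.astype(int)) == 1) + 1
    if supra[0]:
        rising = np.insert(rising, 0, 0)
    times = traces.t0 + rising / traces.rate
    return var, times, float(thr)


def detection_metrics(
    supra: np.ndarray,
    rate: float,
    bouts: pd.DataFrame,
    pad: float = 3.0,
    predict_window: tuple = (-5.0, 0.0),
    t0: float = 0.0,
) -> dict:
    """Frame- and bout-level detection performance of a binary variable.

    ``supra`` is the per-frame indicator that the prediction variable is
    above threshold. Movement frames are bout spans padded ±``pad`` s.
    A bout counts as predicted when a crossing occurs within
    ``predict_window`` of its onset with no intervening movement; lead
    times are onset minus crossing time.
    """
    if not len(bouts):
        return None
    supra = np.asarray(supra, bool)
    times = t0 + np.arange(supra.size) / rate
    move = np.zeros(supra.size, dtype=bool)
    raw_move = np.zeros(supra.size, dtype=bool)
    for _, b in bouts.iterrows():
        move |= (times >= b.onset - pad) & (times < b.offset + pad)
        raw_move |= (times >= b.onset) & (times < b.offset)
    detection = float(supra[move].mean()) if move.any() else np.nan
    fpr = float(supra[~move].mean()) if (~move).any() else np.nan
    crossings = np.flatnonzero(np.diff(supra.astype(int)) == 1) + 1
    if supra[0]:
        crossings = np.insert(crossings, 0, 0)
    cross_t = times[crossings]
    leads = []
    predicted = 0
    for _, b in bouts.iterrows():
        cand = cross_t[(cross_t >= b.onset + predict_window[0]) & (cross_t < b.onset + predict_window[1])]
        for c in cand:
            between = (times >= c) & (times < b.onset)
            if not raw_move[between].any():
                predicted += 1
                leads.append(float(b.onset - c))
                break
    return {
        "frame_detection_rate": detection,
        "false_positive_rate": fpr,
        "n_bouts_predicted": predicted,
        "n_bouts": int(len(bouts)),
        "bout_lead_times": np.array(leads),
    }


# ---------------------------------------------------------------------------
# epoch construction
# ---------------------------------------------------------------------------

def draw_epochs(
    traces: TraceMatrix,
    bouts: pd.DataFrame,
    cfg: DecoderConfig | None = None,
    seed: int = 0,
    n_max: int | None = None,
) -> tuple[PeriEventTensor, PeriEventTensor]:
    """Movement and matched stationary epochs for decoding.

    Movement epochs are centred on bout onsets. Stationary epochs are
    drawn at random from times with no locomotion during the epoch nor
    within ``cfg.stationary_margin`` seconds of it, in equal number to
    the movement epochs.
    """
    cfg = cfg or DecoderConfig()
    rng = np.random.default_rng(seed)
    half = cfg.epoch_length / 2
    window = (-half, half)
    onsets = bouts["onset"].to_numpy()
    span = (traces.t0, traces.t0 + traces.n_frames / traces.rate)
    onsets = onsets[(onsets + window[0] >= span[0]) & (onsets + window[1] <= span[1])]
    if n_max is not None:
        onsets = onsets[:n_max]
    if onsets.size == 0:
        raise ParameterError("no bouts with a full epoch window")
    move = align(traces, onsets, window, alignment="bout_onset")

    # candidate stationary centres on the frame grid
    times = traces.times
    forbidden = np.zeros(times.size, dtype=bool)
    guard = half + cfg.stationary_margin
    for _, b in bouts.iterrows():
        forbidden |= (times >= b.onset - guard) & (times < b.offset + guard)
    forbidden |= (times < span[0] + half) | (times > span[1] - half)
    cand = times[~forbidden]
    if cand.size == 0:
        raise ParameterError("no stationary time satisfies the margin constraints")
    centers = []
    pool = cand.copy()
    rng.shuffle(pool)
    for c in pool:
        if all(abs(c - c0) >= half for c0 in centers):
            centers.append(c)
        if len(centers) == onsets.size:
            break
    if len(centers) < onsets.size:
        raise ParameterError(
            f"only {len(centers)} stationary epochs available for {onsets.size} movement epochs"
        )
    stat = align(traces, np.sort(centers), window, alignment="stationary")
    return move, stat


# ---------------------------------------------------------------------------
# SVM decoding
# ---------------------------------------------------------------------------

def _window_features(tensor: PeriEventTensor, start: float, length: float) -> np.ndarray:
    """(n_epochs, n_cells) per-cell means within [start, start+length)."""
    t = tensor.rel_times
    sel = (t >= start) & (t < start + length)
    if not sel.any():
        raise ParameterError(f"evaluation window {start} outside the epoch")
    return np.nanmean(tensor.values[:, :, sel], axis=2).T


def svm_decode(
    movement: PeriEventTensor,
    stationary: PeriEventTensor,
    cfg: DecoderConfig | None = None,
    permute: bool = False,
    seed: int = 0,
    eval_windows: list | None = None,
) -> PredictionResult:
    """Cross-validated linear SVM decoding of movement vs stationary.

    For each evaluation window the features are per-cell window means.
    Accuracy is averaged over ``n_folds`` stratified folds x
    ``n_repeats`` re-drawn repeats (80 analyses at the defaults).
    Features are standardised within training folds only. With
    ``permute=True`` the epoch labels are freshly shuffled before every
    repeat, yielding the empirical chance distribution.
    """
    cfg = cfg or DecoderConfig()
    n_mov, n_stat = movement.values.shape[1], stationary.values.shape[1]
    if n_mov != n_stat:
        raise ParameterError(f"class imbalance: {n_mov} movement vs {n_stat} stationary epochs")
    if n_mov < cfg.n_folds:
        raise ParameterError(f"{n_mov} epochs per class < {cfg.n_folds} folds")
    rng = np.random.default_rng(seed)
    if eval_windows is None:
        t = movement.rel_times
        starts = t[t <= t[-1] - cfg.window + 1e-9]
        eval_windows = [(float(s), cfg.window) for s in starts]
    else:
        eval_windows = [(float(s), float(l)) for s, l in eval_windows]

    y_base = np.concatenate([np.ones(n_mov, int), np.zeros(n_stat, int)])
    feats = [
        np.vstack(
            [_window_features(movement, s, l), _window_features(stationary, s, l)]
        )
        for s, l in eval_windows
    ]
    acc = np.zeros(len(eval_windows))
    acc_sq = np.zeros(len(eval_windows))
    n_analyses = cfg.n_folds * cfg.n_repeats
    for _ in range(cfg.n_repeats):
        y = rng.permutation(y_base) if permute else y_base
        skf = StratifiedKFold(cfg.n_folds, shuffle=True, random_state=int(rng.integers(2**31)))
        for train, test in skf.split(feats[0], y):
            for w, X in enumerate(feats):
                scaler = StandardScaler().fit(X[train])
                clf = SVC(kernel="linear", C=cfg.C)
                clf.fit(scaler.transform(X[train]), y[train])
                a = clf.score(scaler.transform(X[test]), y[test])
                acc[w] += a
                acc_sq[w] += a * a
    acc /= n_analyses
    sd = np.sqrt(np.maximum(acc_sq / n_analyses - acc**2, 0.0))
    return PredictionResult(
        window_starts=np.array([s for s, _ in eval_windows]),
        accuracy=acc,
        accuracy_sd=sd,
        permuted=permute,
        n_epochs=n_mov + n_stat,
    )


# ---------------------------------------------------------------------------
# ROC AUC time courses
# ---------------------------------------------------------------------------

def roc_auc_timecourse(
    tensor: PeriEventTensor,
    moved: np.ndarray,
    cell_subtypes: list | np.ndarray,
    censor_times: np.ndarray | None = None,
    censor_post_onset: bool = False,
) -> pd.DataFrame:
    """AUC(t) of subtype-mean activity for discriminating trial outcome.

    Per time sample, the predictor is the mean activity of the cells of
    each subtype on each trial; AUC is the Mann-Whitney probability that
    a movement trial exceeds a stationary trial. When
    ``censor_post_onset`` is set (stimulus-aligned analysis), each
    moving trial is excluded from bins at or after its locomotion onset
    so the AUC reflects activity before movement has started.
    Bins with only one outcome present yield NaN.
    """
    moved = np.asarray(moved, bool)
    if moved.sum() < 2 or (~moved).sum() < 2:
        raise ParameterError("need at least 2 trials per outcome")
    subtypes = np.asarray(cell_subtypes)
    t = tensor.rel_times
    out = {}
    for lab in pd.unique(subtypes):
        cells = np.flatnonzero(subtypes == lab)
        pred = np.nanmean(tensor.values[cells], axis=0)  # (trials, time)
        auc = np.full(t.size, np.nan)
        for k in range(t.size):
            vals = pred[:, k]
            keep = ~np.isnan(vals)
            if censor_post_onset and censor_times is not None:
                keep &= ~(moved & (np.nan_to_num(censor_times, nan=np.inf) <= t[k]))
            y = moved[keep]
            if y.sum() == 0 or (~y).sum() == 0:
                continue
            auc[k] = roc_auc_score(y, vals[keep])
        out[lab] = auc
    df = pd.DataFrame(out)
    df.insert(0, "time", t)
    return df
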