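"""Synthetic recording generator with full ground truth.

Forward-simulates the kind of data the rest of the pipeline analyses:
trapezoidal treadmill locomotion bouts, randomised sensory stimulus
blocks (with a response-free null stimulus), subtype-specific
peri-locomotor firing profiles in the 0-15 Hz instantaneous range,
inhomogeneous-Poisson spike trains, spike-to-fluorescence convolution
with a delayed GCaMP6s-like kernel, photobleaching, a shared neuropil
background, additive noise, and optional rendering to an image stack
with ROI masks.  Every stochastic step is driven by an explicit seed and
the generator records all per-cell ground truth so recovery can be
scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import (
    NULL_MODALITY,
    GcampKernel,
    GroundTruth,
    ParameterError,
    SpeedTrace,
    SubtypeTemplate,
    TraceMatrix,
    make_bout_table,
    make_stimulus_schedule,
)

# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

#: subtype mixture observed across the recorded ensemble
DEFAULT_PROPORTIONS = {
    "ON": 0.31,
    "OFF": 0.10,
    "up_down": 0.33,
    "down_up": 0.20,
    "non_mod": 0.06,
}


def default_templates(
    on_lead: float = -1.0,
    off_baseline: float = 5.0,
) -> dict:
    """Firing-rate templates per subtype, peak rates within 0-15 Hz.

    ``off_baseline`` is exposed because the resting rate of suppressed
    cells is a free parameter of the simulation rather than a measured
    quantity.
    """
    return {
        "ON": SubtypeTemplate("ON", baseline_rate=1.0, peak_rate=10.0, onset_lead=on_lead),
        "OFF": SubtypeTemplate("OFF", baseline_rate=off_baseline, peak_rate=0.3, onset_lead=0.0),
        "up_down": SubtypeTemplate(
            "up_down", baseline_rate=3.0, peak_rate=10.0, onset_lead=-0.5, phase_durations=(2.0,)
        ),
        "down_up": SubtypeTemplate(
            "down_up", baseline_rate=5.0, peak_rate=10.0, onset_lead=0.0, phase_durations=(2.0,)
        ),
        "non_mod": SubtypeTemplate("non_mod", baseline_rate=2.0, peak_rate=2.0),
    }


#: suppressed firing level (Hz) used for the low phase of OFF/up_down/down_up
TROUGH_RATE = 0.3


# ---------------------------------------------------------------------------
# locomotion
# ---------------------------------------------------------------------------

def gen_locomotion(
    duration: float,
    rate: float,
    bout_rate: float,
    plateau_speed_median: float = 5.0,
    plateau_speed_sigma: float = 0.35,
    duration_median: float = 5.0,
    duration_sigma: float = 0.45,
    ramp: float = 0.5,
    refractory: float = 20.0,
    threshold: float = 1.0,
    seed: int = 0,
) -> tuple[SpeedTrace, pd.DataFrame]:
    """Generate a treadmill speed trace with trapezoidal locomotion bouts.

    Bouts are ramp-plateau-ramp with lognormal plateau speed (median
    ``plateau_speed_median`` cm/s) and lognormal plateau duration (median
    ``duration_median`` s), separated by at least ``refractory`` seconds
    of stillness so that stationary decoding epochs exist.  The returned
    bout table is the generator's own event log: onsets/offsets are the
    sample times where the rendered speed first/last exceeds
    ``threshold``.
    """
    if duration <= 0 or rate <= 0:
        raise ParameterError("duration and rate must be positive")
    if bout_rate < 0:
        raise ParameterError("bout_rate cannot be negative")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    speed = np.zeros(n)
    onsets, offsets, distances, mean_speeds = [], [], [], []
    if bout_rate > 0:
        t = rng.exponential(60.0 / bout_rate)
        while t < duration:
            v = float(np.clip(rng.lognormal(np.log(plateau_speed_median), plateau_speed_sigma), 1.5, 40.0))
            plateau = float(rng.lognormal(np.log(duration_median), duration_sigma))
            total = 2 * ramp + plateau
            if t + total >= duration:
                break
            i0 = int(round(t * rate))
            tt = np.arange(i0, min(n, int(round((t + total) * rate)) + 1)) / rate - t
            prof = np.where(
                tt < ramp,
                v * tt / ramp,
                np.where(tt < ramp + plateau, v, np.maximum(v * (total - tt) / ramp, 0.0)),
            )
            speed[i0 : i0 + prof.size] = np.maximum(speed[i0 : i0 + prof.size], prof)
            # event log from the rendered samples, matching threshold detection
            seg = speed[i0 : i0 + prof.size]
            above = np.flatnonzero(seg > threshold)
            if above.size:
                onsets.append((i0 + above[0]) / rate)
                offsets.append((i0 + above[-1] + 1) / rate)
                distances.append(float(seg[above].sum() / rate))
                mean_speeds.append(float(seg[above].mean()))
            t += total + refractory + rng.exponential(60.0 / bout_rate)
    bouts = make_bout_table(onsets, offsets, distance=distances or None, mean_speed=mean_speeds or None)
    return SpeedTrace(speed, rate=rate), bouts


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------

def gen_stimuli(
    n_blocks: int,
    modalities: tuple = ("visual", "tactile", "olfactory_food", NULL_MODALITY),
    base_interval: float = 15.0,
    jitter_max: float = 15.0,
    stim_duration: float = 0.2,
    t_start: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Randomised stimulus blocks.

    Each block presents each modality exactly once in random order; the
    interval before every stimulus is ``base_interval`` plus a uniform
    draw from ``(0.1, jitter_max)``, re-randomised per stimulus.
    """
    if base_interval <= 0:
        raise ParameterError("base_interval must be positive")
    rng = np.random.default_rng(seed)
    times, mods = [], []
    t = t_start
    for _ in range(int(n_blocks)):
        order = rng.permutation(len(modalities))
        for j in order:
            t += base_interval + rng.uniform(0.1, jitter_max)
            times.append(t)
            mods.append(modalities[j])
    return make_stimulus_schedule(times, mods, np.full(len(times), stim_duration))


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

def _template_segments(tpl: SubtypeTemplate, bouts: pd.DataFrame) -> list:
    """Per-bout (start, end, rate) overrides of the baseline rate."""
    segs = []
    for _, b in bouts.iterrows():
        start = b.onset + tpl.onset_lead
        if tpl.label == "ON":
            segs.append((start, b.offset, tpl.peak_rate))
        elif tpl.label == "OFF":
            segs.append((start, b.offset, tpl.peak_rate))
        elif tpl.label == "up_down":
            # suppression outlasts the bout: the reporter needs time to
            # decay off the initial transient before the dip is visible
            d1 = tpl.phase_durations[0] if tpl.phase_durations else 2.0
            segs.append((start, start + d1, tpl.peak_rate))
            segs.append((start + d1, max(b.offset, start + d1) + 4.0, TROUGH_RATE))
        elif tpl.label == "down_up":
            d1 = tpl.phase_durations[0] if tpl.phase_durations else 2.0
            segs.append((start, start + d1, TROUGH_RATE))
            segs.append((start + d1, b.offset + 2.0, tpl.peak_rate))
    return segs


def _rate_profile(base: float, overrides: list, additive: list, duration: float):
    """Piecewise-constant rate as (breakpoints, rates-per-interval)."""
    pts = {0.0, duration}
    for a, b, _ in overrides:
        pts.update((min(max(a, 0.0), duration), min(max(b, 0.0), duration)))
    for a, b, _ in additive:
        pts.update((min(max(a, 0.0), duration), min(max(b, 0.0), duration)))
    bp = np.array(sorted(pts))
    mid = (bp[:-1] + bp[1:]) / 2
    rates = np.full(mid.size, float(base))
    for a, b, r in overrides:
        rates[(mid >= a) & (mid < b)] = r
    for a, b, g in additive:
        rates[(mid >= a) & (mid < b)] += g
    return bp, np.maximum(rates, 0.0)


def gen_spikes(
    bouts: pd.DataFrame,
    stimuli: pd.DataFrame | None,
    duration: float,
    n_cells: int,
    proportions: dict | None = None,
    templates: dict | None = None,
    sensory_gain: dict | None = None,
    p_responsive: dict | float = 0.4,
    response_duration: float = 2.0,
    kernel: GcampKernel | None = None,
    noise_sd: float = 25.0,
    bleach_tau: float = np.inf,
    neuropil_gain: float = 0.3,
    movement_coupled_gain: float = 0.0,
    evoke_window: float = 5.0,
    seed: int = 0,
) -> GroundTruth:
    """Inhomogeneous-Poisson spike trains following subtype templates.

    The firing rate of each cell follows its subtype template around
    every locomotion bout; cells flagged sensory-responsive additionally
    step their rate up by ``sensory_gain[modality]`` Hz for
    ``response_duration`` seconds after each stimulus of that modality.
    The null stimulus never modulates any cell.  Spikes are drawn exactly
    per constant-rate segment (Poisson count, uniform times), so rate
    steps are sharp to machine precision.
    """
    proportions = dict(DEFAULT_PROPORTIONS if proportions is None else proportions)
    if abs(sum(proportions.values()) - 1.0) > 1e-9:
        raise ParameterError("mixture proportions must sum to 1")
    templates = default_templates() if templates is None else templates
    kernel = GcampKernel() if kernel is None else kernel
    rng = np.random.default_rng(seed)

    # deterministic label counts closest to the requested mixture
    labels_sorted = list(proportions)
    counts = np.floor(np.array([proportions[l] for l in labels_sorted]) * n_cells).astype(int)
    rem = n_cells - counts.sum()
    frac = np.array([proportions[l] for l in labels_sorted]) * n_cells - counts
    for i in np.argsort(-frac)[:rem]:
        counts[i] += 1
    labels = [l for l, c in zip(labels_sorted, counts) for _ in range(c)]
    rng.shuffle(labels)

    modalities = []
    if stimuli is not None and len(stimuli):
        modalities = [m for m in pd.unique(stimuli["modality"]) if m != NULL_MODALITY]
    if sensory_gain is None:
        sensory_gain = {m: 5.0 for m in modalities}
    if not isinstance(p_responsive, dict):
        p_responsive = {m: float(p_responsive) for m in modalities}
    responsive = pd.DataFrame(
        {m: rng.random(n_cells) < p_responsive.get(m, 0.0) for m in modalities},
        index=range(n_cells),
    )

    # stimuli that evoke movement: a bout onset within evoke_window after onset
    evoked = np.zeros(0, dtype=bool)
    if stimuli is not None and len(stimuli):
        st = stimuli["time"].to_numpy()
        bo = bouts["onset"].to_numpy() if len(bouts) else np.array([])
        evoked = np.array([np.any((bo > t) & (bo <= t + evoke_window)) for t in st])

    seg_cache = {lab: _template_segments(templates[lab], bouts) for lab in set(labels)}
    spike_trains, onset_rows = [], []
    for i, lab in enumerate(labels):
        overrides = seg_cache[lab]
        additive = []
        if stimuli is not None and len(stimuli):
            for k, (_, s) in enumerate(stimuli.iterrows()):
                if s.modality == NULL_MODALITY or not responsive.loc[i].get(s.modality, False):
                    continue
                g = sensory_gain.get(s.modality, 0.0)
                if movement_coupled_gain and evoked[k]:
                    g += movement_coupled_gain
                if g:
                    additive.append((s.time, s.time + response_duration, g))
        bp, rates = _rate_profile(templates[lab].baseline_rate, overrides, additive, duration)
        widths = np.diff(bp)
        ns = rng.poisson(rates * widths)
        spikes = np.concatenate(
            [rng.uniform(a, b, k) for a, b, k in zip(bp[:-1], bp[1:], ns) if k > 0]
            or [np.empty(0)]
        )
        spike_trains.append(np.sort(spikes))
        if lab == "non_mod":
            onset_rows.append(np.full(len(bouts), np.nan))
        else:
            onset_rows.append(bouts["onset"].to_numpy() + templates[lab].onset_lead)

    return GroundTruth(
        cell_labels=labels,
        spike_trains=spike_trains,
        true_onsets=np.array(onset_rows).reshape(n_cells, len(bouts)),
        kernel=kernel,
        noise_sd=noise_sd,
        bleach_tau=bleach_tau,
        neuropil_gain=neuropil_gain,
        duration=duration,
        sensory_responsive=responsive,
        templates=templates,
    )


# ---------------------------------------------------------------------------
# fluorescence
# ---------------------------------------------------------------------------

def gen_common_signal(n: int, rate: float, sd: float = 1.0, cutoff: float = 0.5, seed: int = 0) -> np.ndarray:
    """Shared neuropil background: low-pass-filtered Gaussian noise."""
    rng = np.random.default_rng(seed)
    w = rng.standard_normal(n)
    if n > 20 and cutoff < rate / 2:
        b, a = sps.butter(2, cutoff / (rate / 2))
        w = sps.filtfilt(b, a, w)
    s = w.std()
    return w / s * sd if s > 0 else w


@dataclass
class FluorResult:
    """Output of the spike-to-fluorescence forward model."""

    traces: TraceMatrix
    neuropil: np.ndarray  # what a neuropil mask would measure
    common: np.ndarray  # the underlying shared background


def spikes_to_fluor(
    gt: GroundTruth,
    rate: float,
    duration: float | None = None,
    f_base: float = 100.0,
    common: np.ndarray | None = None,
    common_sd: float = 2.0,
    seed: int = 0,
) -> FluorResult:
    """Render spike trains to raw fluorescence traces.

    ``F_i(t) = f_base * exp(-t / bleach_tau) * (1 + sum_k h(t - t_k))
    + neuropil_gain * common(t) + noise`` where ``h`` is the delayed
    double-exponential reporter kernel.  Spikes are binned at the output
    rate before convolution, so timing is exact to one sample.
    """
    if rate <= 0:
        raise ParameterError("rate must be positive")
    duration = gt.duration if duration is None else duration
    n = int(round(duration * rate))
    rng = np.random.default_rng(seed)
    if common is None:
        common = gen_common_signal(n, rate, sd=common_sd, seed=seed + 1)
    t = np.arange(n) / rate
    bleach = np.exp(-t / gt.bleach_tau) if np.isfinite(gt.bleach_tau) else np.ones(n)
    h = gt.kernel.sample(rate)
    values = np.empty((len(gt.spike_trains), n))
    for i, spikes in enumerate(gt.spike_trains):
        cnt = np.zeros(n)
        if spikes.size:
            idx = np.floor(spikes * rate).astype(int)
            idx = idx[(idx >= 0) & (idx < n)]
            np.add.at(cnt, idx, 1.0)
        conv = sps.fftconvolve(cnt, h)[:n] if spikes.size else cnt
        values[i] = f_base * bleach * (1.0 + conv)
    values += gt.neuropil_gain * common
    if gt.noise_sd > 0:
        values += rng.normal(0.0, gt.noise_sd, values.shape)
    return FluorResult(
        traces=TraceMatrix(values, rate=rate, kind="raw"),
        neuropil=gt.neuropil_gain * common,
        common=common,
    )


# ---------------------------------------------------------------------------
# image-stack rendering
# ---------------------------------------------------------------------------

class LayoutError(ValueError):
    """ROIs do not fit in the requested frame."""


def render_stack(
    traces: TraceMatrix,
    frame_shape: tuple = (128, 128),
    roi_radius: int = 4,
    spacing: int | None = None,
    neuropil_level: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Render traces to a movie with disk ROIs on a common background.

    Each ROI's pixels carry its trace value exactly (plus rendering
    noise); background pixels carry ``neuropil_level`` (e.g. the
    generator's ``neuropil_gain * common``).  Returns ``(stack, RoiSet)``.
    """
    from .traces import RoiSet

    h, w = frame_shape
    n_cells, n_frames = traces.values.shape
    spacing = spacing if spacing is not None else 4 * roi_radius + 10
    centers = []
    y = spacing // 2 + roi_radius
    x = spacing // 2 + roi_radius
    for _ in range(n_cells):
        if x + roi_radius >= w:
            x = spacing // 2 + roi_radius
            y += spacing
        if y + roi_radius >= h:
            raise LayoutError(f"{n_cells} ROIs of radius {roi_radius} do not fit in {frame_shape}")
        centers.append((y, x))
        x += spacing
    yy, xx = np.mgrid[0:h, 0:w]
    masks = np.zeros((n_cells, h, w), dtype=bool)
    for i, (cy, cx) in enumerate(centers):
        masks[i] = (yy - cy) ** 2 + (xx - cx) ** 2 <= roi_radius**2
    if masks.sum(0).max() > 1:
        raise LayoutError("ROIs overlap under the requested layout")

    bg = np.zeros(n_frames) if neuropil_level is None else np.asarray(neuropil_level, float)
    stack = np.broadcast_to(bg[:, None, None], (n_frames, h, w)).copy()
    for i in range(n_cells):
        stack[:, masks[i]] = traces.values[i][:, None]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        stack += rng.normal(0.0, noise_sd, stack.shape)
    return stack, RoiSet(masks=masks)


# ---------------------------------------------------------------------------
# convenience: one full synthetic session
# ---------------------------------------------------------------------------

@dataclass
class Session:
    """A complete synthetic recording plus its ground truth."""

    speed: SpeedTrace
    bouts: pd.DataFrame
    stimuli: pd.DataFrame
    ground_truth: GroundTruth
    fluor: FluorResult

    @property
    def traces(self) -> TraceMatrix:
        return self.fluor.traces


def simulate_session(
    duration: float = 1200.0,
    rate: float = 10.0,
    n_cells: int = 60,
    bout_rate: float = 1.0,
    n_stim_blocks: int = 0,
    seed: int = 0,
    **spike_kwargs,
) -> Session:
    """Generate locomotion, stimuli, spikes and fluorescence in one call."""
    speed, bouts = gen_locomotion(duration, rate=rate, bout_rate=bout_rate, seed=seed)
    if n_stim_blocks > 0:
        stimuli = gen_stimuli(n_stim_blocks, seed=seed + 10)
        stimuli = stimuli[stimuli["time"] < duration - 10].reset_index(drop=True)
    else:
        stimuli = make_stimulus_schedule([], [], [])
    gt = gen_spikes(bouts, stimuli, duration=duration, n_cells=n_cells, seed=seed + 20, **spike_kwargs)
    fluor = spikes_to_fluor(gt, rate=rate, duration=duration, seed=seed + 30)
    return Session(speed=speed, bouts=bouts, stimuli=stimuli, ground_truth=gt, fluor=fluor)
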