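"""Ground-truth synthetic extracellular recordings.

Emulates ~30 kHz multichannel data: each unit is a biphasic
(difference-of-Gaussians) temporal kernel placed on a peak channel with
exponentially decaying spatial spread, firing as an inhomogeneous Poisson
process with refractory deletion. Direction tuning follows a von Mises
rate modulation during 0.25 s stimulus presentations (twelve directions
in 30 degree steps). Fast-spiking (FS) vs regular-spiking (RS) classes
are produced by controlling the trough-to-peak width around the 200 us
boundary. A state session adds a slow two-state multiplicative gain
shared by the FS subpopulation, for closed-loop trigger benchmarks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_probe import ProbeGeometry, RawRecording

__all__ = [
    "GroundTruthUnit",
    "GroundTruth",
    "StateParams",
    "ClippingError",
    "make_probe",
    "make_templates",
    "make_units",
    "make_trials",
    "simulate_trains",
    "render_recording",
    "simulate_state_session",
    "add_evoked_spikes",
    "DIRECTIONS_DEG",
    "STIM_DUR_S",
    "ISI_S",
]

logger = logging.getLogger(__name__)

DIRECTIONS_DEG = np.arange(0, 360, 30)  # twelve directions, 0-330
STIM_DUR_S = 0.25  # stimulus duration
ISI_S = 0.15  # interstimulus interval within a trial
STIMS_PER_TRIAL = 3


class ClippingError(ValueError):
    """int16 quantization would clip the rendered signal."""


@dataclass
class GroundTruthUnit:
    """A simulated unit: waveform template plus firing statistics."""

    unit_id: int
    template: np.ndarray  # M x C, microvolts
    peak_channel: int
    rate_hz: float
    refractory_ms: float
    tuning: tuple  # (preferred_direction_deg, kappa, modulation_depth)
    waveform_width_us: float  # trough-to-peak on the peak channel

    def __post_init__(self):
        self.template = np.asarray(self.template, float)
        if self.template.ndim != 2:
            raise ValueError("template must be M x C")
        if self.template.shape[0] % 2 != 1:
            raise ValueError("M must be odd (symmetric alignment window)")
        if not np.isfinite(self.template).all():
            raise ValueError("template must be finite")
        if not self.refractory_ms > 0:
            raise ValueError("refractory_ms must be positive")
        if self.tuning[1] < 0:
            raise ValueError("tuning concentration must be >= 0")


@dataclass
class GroundTruth:
    """Simulator-known identities, spike times and trial structure."""

    units: list
    spikes: list  # per-unit sorted spike times in samples
    trials: pd.DataFrame  # onset_sample, direction_deg, condition
    fs: float
    duration_samples: int
    state: dict | None = None  # latent gain trace: {"edges_s", "gains"}
    geometry: ProbeGeometry | None = None

    def __post_init__(self):
        self.spikes = [np.asarray(s, dtype=np.int64) for s in self.spikes]
        for u, s in zip(self.units, self.spikes):
            ref = int(round(u.refractory_ms * 1e-3 * self.fs))
            if len(s) > 1 and np.any(np.diff(s) < ref):
                raise ValueError(f"unit {u.unit_id}: refractory violated")
        ons = self.trials["onset_sample"].to_numpy()
        if len(ons) > 1 and np.any(np.diff(ons) < 0):
            raise ValueError("trial onsets must be nondecreasing")

    def trains(self) -> dict[int, np.ndarray]:
        return {u.unit_id: s for u, s in zip(self.units, self.spikes)}


@dataclass
class StateParams:
    """Slow two-state multiplicative gain applied to the FS subpopulation."""

    gain_low: float = 1.0
    gain_high: float = 2.5
    mean_dwell_s: float = 0.4
    fs_width_cut_us: float = 200.0  # units narrower than this share the gain


def make_probe(n_channels: int, pitch_um: float = 20.0, n_cols: int = 2) -> ProbeGeometry:
    """A dense two-column probe layout (checkerboard-free, Neuropixels-like)."""
    idx = np.arange(n_channels)
    x = (idx % n_cols) * pitch_um
    y = (idx // n_cols) * pitch_um
    return ProbeGeometry(x=x, y=y)


def _biphasic_kernel(M: int, width_samples: float) -> np.ndarray:
    """Unit-amplitude biphasic kernel: trough at the center sample, positive
    peak ``width_samples`` later (difference of Gaussians)."""
    c = (M - 1) // 2
    t = np.arange(M, dtype=float)
    s1 = max(width_samples / 3.0, 0.8)
    s2 = 1.5 * s1
    w = -np.exp(-((t - c) ** 2) / (2 * s1**2)) + 0.55 * np.exp(
        -((t - c - width_samples) ** 2) / (2 * s2**2)
    )
    return w / np.abs(w.min())


def make_templates(
    geometry: ProbeGeometry,
    K: int,
    seed: int,
    amp_range_uv: tuple = (60.0, 150.0),
    decay_um: float = 25.0,
    width_range_us: tuple = (150.0, 500.0),
    M: int = 61,
    fs: float = 30000.0,
    widths_us: np.ndarray | None = None,
    peak_channels: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw K biphasic templates on random peak channels.

    Returns ``(templates, peak_channels, widths_us)`` with templates of
    shape (K, M, C) in microvolts. Deterministic for a fixed seed.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    C = geometry.n_channels
    if K > C:
        raise ValueError(f"K={K} exceeds allowed density of one unit per channel (C={C})")
    rng = np.random.default_rng(seed)
    if peak_channels is None:
        peak_channels = rng.choice(C, size=K, replace=False)
    peak_channels = np.asarray(peak_channels, int)
    if widths_us is None:
        widths_us = rng.uniform(*width_range_us, size=K)
    widths_us = np.asarray(widths_us, float)
    amps = rng.uniform(*amp_range_uv, size=K)
    templates = np.zeros((K, M, C))
    for k in range(K):
        kernel = _biphasic_kernel(M, widths_us[k] * fs / 1e6)
        spatial = amps[k] * np.exp(-geometry.distances_from(peak_channels[k]) / decay_um)
        templates[k] = kernel[:, None] * spatial[None, :]
    return templates, peak_channels, widths_us


def trough_to_peak_us(template: np.ndarray, fs: float) -> float:
    """Trough-to-peak time (us) on the maximum-amplitude channel."""
    ch = int(np.argmax(np.abs(template).max(axis=0)))
    w = template[:, ch]
    trough = int(np.argmin(w))
    after = w[trough + 1 :]
    if len(after) == 0 or after.max() <= 0:
        return float("nan")  # monophasic
    peak = trough + 1 + int(np.argmax(after))
    return (peak - trough) / fs * 1e6


def make_units(
    geometry: ProbeGeometry,
    K: int,
    seed: int,
    rate_range_hz: tuple = (5.0, 15.0),
    refractory_ms: float = 2.0,
    kappa: float = 2.0,
    depth: float = 2.0,
    **template_kwargs,
) -> list[GroundTruthUnit]:
    """Convenience constructor: templates plus firing/tuning parameters."""
    fs = template_kwargs.get("fs", 30000.0)
    templates, peaks, widths = make_templates(geometry, K, seed, **template_kwargs)
    rng = np.random.default_rng(seed + 1)
    rates = rng.uniform(*rate_range_hz, size=K)
    prefs = rng.choice(DIRECTIONS_DEG, size=K)
    return [
        GroundTruthUnit(
            unit_id=k,
            template=templates[k],
            peak_channel=int(peaks[k]),
            rate_hz=float(rates[k]),
            refractory_ms=refractory_ms,
            tuning=(float(prefs[k]), kappa, depth),
            waveform_width_us=float(widths[k]),
        )
        for k in range(K)
    ]


def make_trials(
    n_trials: int,
    seed: int,
    fs: float = 30000.0,
    start_s: float = 1.0,
    gap_s: float = 0.5,
    condition: str = "stim",
) -> pd.DataFrame:
    """Trial structure: 3 stimuli per trial, 0.25 s each, 0.15 s apart.

    Directions are balanced across the session and shuffled.
    """
    n_stim = n_trials * STIMS_PER_TRIAL
    rng = np.random.default_rng(seed)
    dirs = np.tile(DIRECTIONS_DEG, int(np.ceil(n_stim / len(DIRECTIONS_DEG))))[:n_stim]
    rng.shuffle(dirs)
    onsets = []
    t = start_s
    for _ in range(n_trials):
        for s in range(STIMS_PER_TRIAL):
            onsets.append(t)
            t += STIM_DUR_S + ISI_S
        t += gap_s
    return pd.DataFrame(
        {
            "onset_sample": (np.asarray(onsets) * fs).round().astype(np.int64),
            "direction_deg": dirs.astype(float),
            "condition": condition,
        }
    )


def von_mises_rate(direction_deg, pref_deg, kappa, depth) -> np.ndarray:
    """Multiplicative stimulus modulation 1 + depth*exp(kappa*(cos(d-pref)-1))."""
    delta = np.deg2rad(np.asarray(direction_deg, float) - pref_deg)
    return 1.0 + depth * np.exp(kappa * (np.cos(delta) - 1.0))


def _thin_poisson(rate_fn, rmax: float, duration_s: float, rng) -> np.ndarray:
    """Inhomogeneous Poisson times (s) by thinning a rate-``rmax`` process."""
    if rmax <= 0:
        return np.empty(0)
    n = rng.poisson(rmax * duration_s)
    t = np.sort(rng.uniform(0.0, duration_s, size=n))
    keep = rng.uniform(0.0, 1.0, size=n) < rate_fn(t) / rmax
    return t[keep]


def _apply_refractory(times_s: np.ndarray, refractory_s: float) -> np.ndarray:
    """Greedy earliest-first deletion of refractory violations."""
    kept = []
    last = -np.inf
    for t in times_s:
        if t - last >= refractory_s:
            kept.append(t)
            last = t
    return np.asarray(kept)


def _stim_modulation(t_s: np.ndarray, trials: pd.DataFrame, fs: float, unit) -> np.ndarray:
    """Per-time multiplicative factor from the tuned stimulus windows."""
    mod = np.ones_like(t_s)
    if len(trials) == 0:
        return mod
    onsets_s = trials["onset_sample"].to_numpy() / fs
    dirs = trials["direction_deg"].to_numpy()
    idx = np.searchsorted(onsets_s, t_s, side="right") - 1
    valid = idx >= 0
    in_stim = valid & (t_s - onsets_s[np.clip(idx, 0, None)] < STIM_DUR_S)
    pref, kappa, depth = unit.tuning
    mod[in_stim] = von_mises_rate(dirs[idx[in_stim]], pref, kappa, depth)
    return mod


def simulate_trains(
    units: list,
    duration_s: float,
    trials: pd.DataFrame | None = None,
    fs: float = 30000.0,
    seed: int = 0,
    edge_margin_samples: int | None = None,
    geometry: ProbeGeometry | None = None,
) -> GroundTruth:
    """Inhomogeneous Poisson trains with refractory deletion.

    During each 0.25 s stimulus window the rate is
    ``baseline * (1 + depth * exp(kappa * (cos(theta - pref) - 1)))``.
    Spikes too close to the recording edge for a full template are dropped.
    """
    if trials is None:
        trials = pd.DataFrame(columns=["onset_sample", "direction_deg", "condition"])
    if len(trials) and trials["onset_sample"].max() / fs + STIM_DUR_S > duration_s:
        raise ValueError("duration does not cover all trials")
    n_samples = int(round(duration_s * fs))
    if edge_margin_samples is None:
        M = max(u.template.shape[0] for u in units)
        edge_margin_samples = (M - 1) // 2 + 1
    rng = np.random.default_rng(seed)
    spikes = []
    for u in units:
        if u.rate_hz < 0:
            raise ValueError("rates must be >= 0")
        depth = u.tuning[2]
        rmax = u.rate_hz * (1.0 + depth)
        t = _thin_poisson(
            lambda ts: u.rate_hz * _stim_modulation(ts, trials, fs, u),
            rmax,
            duration_s,
            rng,
        )
        t = _apply_refractory(t, u.refractory_ms * 1e-3)
        samp = np.round(t * fs).astype(np.int64)
        # rounding can re-introduce sub-refractory gaps at the sample level
        ref_samp = int(round(u.refractory_ms * 1e-3 * fs))
        if len(samp) > 1:
            keep = np.ones(len(samp), bool)
            last = samp[0]
            for i in range(1, len(samp)):
                if samp[i] - last < ref_samp:
                    keep[i] = False
                else:
                    last = samp[i]
            samp = samp[keep]
        samp = samp[(samp >= edge_margin_samples) & (samp < n_samples - edge_margin_samples)]
        spikes.append(samp)
    return GroundTruth(
        units=units,
        spikes=spikes,
        trials=trials,
        fs=fs,
        duration_samples=n_samples,
        geometry=geometry,
    )


def render_recording(
    ground_truth: GroundTruth,
    noise_sd_uv: float = 10.0,
    amp_jitter: float = 0.1,
    seed: int = 0,
    gain_uv: float | None = None,
    quantize: bool = True,
) -> RawRecording:
    """Template superposition plus i.i.d. Gaussian channel noise.

    With ``quantize`` the signal is stored as int16 counts at ``gain_uv``
    microvolts per count (default: the largest template amplitude uses
    ~25% of the int16 range); clipping raises :class:`ClippingError`.
    With ``quantize=False`` the float microvolt signal is returned at
    gain 1, which makes zero-noise rendering exactly the superposition.
    """
    if noise_sd_uv < 0:
        raise ValueError("noise_sd_uv must be >= 0")
    if not 0 <= amp_jitter < 1:
        raise ValueError("amp_jitter must be in [0, 1)")
    gt = ground_truth
    C = gt.units[0].template.shape[1]
    n = gt.duration_samples
    rng = np.random.default_rng(seed)
    signal = np.zeros((n, C))
    dropped = 0
    for u, times in zip(gt.units, gt.spikes):
        M = u.template.shape[0]
        h = (M - 1) // 2
        jit = 1.0 + rng.uniform(-amp_jitter, amp_jitter, size=len(times))
        for t, j in zip(times, jit):
            if t - h < 0 or t + h + 1 > n:
                dropped += 1
                continue
            signal[t - h : t + h + 1] += j * u.template
    if dropped:
        logger.warning("render_recording: dropped %d edge spikes", dropped)
    if noise_sd_uv > 0:
        signal = signal + rng.normal(0.0, noise_sd_uv, size=signal.shape)
    geometry = _geometry_for(gt, C)
    if not quantize:
        return RawRecording(data=signal, fs=gt.fs, gain=1.0, geometry=geometry)
    if gain_uv is None:
        max_amp = max(np.abs(u.template).max() for u in gt.units)
        gain_uv = max_amp / (0.25 * 32767)
    counts = np.round(signal / gain_uv)
    if np.abs(counts).max() > 32767:
        raise ClippingError(
            f"signal exceeds int16 range at gain {gain_uv:g} uV/count"
        )
    return RawRecording(
        data=counts.astype(np.int16), fs=gt.fs, gain=gain_uv, geometry=geometry
    )


def _geometry_for(gt: GroundTruth, C: int) -> ProbeGeometry:
    geom = getattr(gt, "geometry", None)
    if geom is not None:
        return geom
    return make_probe(C)


def simulate_state_session(
    units: list,
    state_params: StateParams,
    seed: int,
    duration_s: float = 120.0,
    fs: float = 30000.0,
    trials: pd.DataFrame | None = None,
    geometry: ProbeGeometry | None = None,
) -> GroundTruth:
    """Spontaneous session whose FS subpopulation shares a slow gain state.

    The latent gain is a two-state telegraph process (exponential dwell
    times, mean ``mean_dwell_s``) multiplying the baseline rate of every
    unit with trough-to-peak width below ``fs_width_cut_us``. The latent
    trace is recorded in ``GroundTruth.state``.
    """
    rng = np.random.default_rng(seed)
    edges = [0.0]
    states = [int(rng.integers(2))]
    t = 0.0
    while t < duration_s:
        t += rng.exponential(state_params.mean_dwell_s)
        edges.append(min(t, duration_s))
        states.append(1 - states[-1])
    edges = np.asarray(edges)
    gains = np.where(np.asarray(states[:-1]) == 1, state_params.gain_high, state_params.gain_low)

    def gain_at(ts: np.ndarray) -> np.ndarray:
        idx = np.clip(np.searchsorted(edges, ts, side="right") - 1, 0, len(gains) - 1)
        return gains[idx]

    if trials is None:
        trials = pd.DataFrame(columns=["onset_sample", "direction_deg", "condition"])
    n_samples = int(round(duration_s * fs))
    M = max(u.template.shape[0] for u in units)
    margin = (M - 1) // 2 + 1
    spikes = []
    gmax = max(state_params.gain_low, state_params.gain_high)
    for u in units:
        targeted = u.waveform_width_us < state_params.fs_width_cut_us
        depth = u.tuning[2]
        rmax = u.rate_hz * (1.0 + depth) * (gmax if targeted else 1.0)

        def rate_fn(ts, u=u, targeted=targeted):
            r = u.rate_hz * _stim_modulation(ts, trials, fs, u)
            return r * gain_at(ts) if targeted else r

        t_s = _thin_poisson(rate_fn, rmax, duration_s, rng)
        t_s = _apply_refractory(t_s, u.refractory_ms * 1e-3)
        samp = np.round(t_s * fs).astype(np.int64)
        samp = samp[(samp >= margin) & (samp < n_samples - margin)]
        spikes.append(samp)
    return GroundTruth(
        units=units,
        spikes=spikes,
        trials=trials,
        fs=fs,
        duration_samples=n_samples,
        state={"edges_s": edges[:-1], "gains": gains},
        geometry=geometry,
    )


def add_evoked_spikes(
    gt: GroundTruth,
    trial_table: pd.DataFrame,
    seed: int,
    stim_dur_s: float = STIM_DUR_S,
) -> GroundTruth:
    """Append tuned evoked spikes at decided stimulus onsets.

    Used by the closed-loop simulation after the trigger rule has fixed
    the onset times: for each unit the extra evoked rate is
    ``rate * depth * exp(kappa * (cos(theta - pref) - 1))`` during the
    stimulus, merged with the existing spontaneous train under the
    refractory constraint (earlier spike wins).
    """
    rng = np.random.default_rng(seed)
    onsets_s = trial_table["onset_sample"].to_numpy() / gt.fs
    dirs = trial_table["direction_deg"].to_numpy()
    new_spikes = []
    for u, samp in zip(gt.units, gt.spikes):
        pref, kappa, depth = u.tuning
        extra = []
        for onset, d in zip(onsets_s, dirs):
            rate = u.rate_hz * depth * float(np.exp(kappa * (np.cos(np.deg2rad(d - pref)) - 1.0)))
            n = rng.poisson(rate * stim_dur_s)
            extra.append(onset + rng.uniform(0.0, stim_dur_s, size=n))
        merged_s = np.sort(np.concatenate([samp / gt.fs] + extra))
        merged_s = _apply_refractory(merged_s, u.refractory_ms * 1e-3)
        merged = np.unique(np.round(merged_s * gt.fs).astype(np.int64))
        ref = int(round(u.refractory_ms * 1e-3 * gt.fs))
        if len(merged) > 1:
            keep = np.ones(len(merged), bool)
            last = merged[0]
            for i in range(1, len(merged)):
                if merged[i] - last < ref:
                    keep[i] = False
                else:
                    last = merged[i]
            merged = merged[keep]
        M = u.template.shape[0]
        margin = (M - 1) // 2 + 1
        merged = merged[(merged >= margin) & (merged < gt.duration_samples - margin)]
        new_spikes.append(merged)
    return GroundTruth(
        units=gt.units,
        spikes=new_spikes,
        trials=trial_table,
        fs=gt.fs,
        duration_samples=gt.duration_samples,
        state=gt.state,
        geometry=gt.geometry,
    )
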