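"""Streaming matching-pursuit sorter.

The recording is processed in overlapping windows (overlap = twice the
template duration) so no spike is lost at a boundary; each window owns a
disjoint emit range, making emission exactly-once. Within a window, an
iterative matching-pursuit loop detects template instances on the
convolution traces, estimates least-squares amplitudes, and subtracts
each accepted spike from both the residual and every template's
convolution trace via the precomputed pairwise cross-correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_probe import RawRecording, SortedOutput
from .preprocess import preprocess_batch

__all__ = [
    "BatchPlan",
    "SpikeEvent",
    "plan_batches",
    "run_matching_pursuit",
    "localize_and_assign",
    "dedup",
    "sort_stream",
]

logger = logging.getLogger(__name__)

MAX_PASSES = 50


@dataclass
class BatchPlan:
    """Overlapping processing windows with disjoint emit ranges."""

    windows: list  # [(start, end)]
    emit_ranges: list  # [(emit_start, emit_end)] partitioning [0, n)
    overlap_samples: int

    def __len__(self):
        return len(self.windows)


@dataclass
class SpikeEvent:
    """A detected spike: alignment point = template trough, center sample."""

    time: int
    template_id: int
    cluster_id: int
    amplitude: float
    x: float
    y: float


def plan_batches(n_samples: int, batch_len: int, M: int) -> BatchPlan:
    """Window k starts at ``k * (batch_len - 2M)``; adjacent windows overlap
    by exactly 2M samples; emit ranges ``[start+M, end-M)`` (extended to the
    recording edges for the first/last window) partition ``[0, n)``."""
    if batch_len <= 4 * M:
        raise ValueError(f"batch_len ({batch_len}) must exceed 4M ({4 * M})")
    stride = batch_len - 2 * M
    windows, emits = [], []
    start, k = 0, 0
    while True:
        end = min(start + batch_len, n_samples)
        es = 0 if k == 0 else start + M
        ee = n_samples if end >= n_samples else end - M
        windows.append((start, end))
        emits.append((es, ee))
        if ee >= n_samples:
            break
        start += stride
        k += 1
    return BatchPlan(windows=windows, emit_ranges=emits, overlap_samples=2 * M)


def _correlate_all(x: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Template correlation traces B[k, t] = <T_k, x centered at t>.

    Implemented as a batched FFT convolution (the matrix-product
    formulation of the detection step).
    """
    from scipy import fft as sp_fft

    K, M, C = templates.shape
    n = x.shape[0]
    h = (M - 1) // 2
    n_fft = sp_fft.next_fast_len(n + M - 1)
    Xf = sp_fft.rfft(x, n_fft, axis=0)  # (n_fft//2+1) x C
    B = np.empty((K, n))
    for k in range(K):
        Tf = sp_fft.rfft(templates[k, ::-1, :], n_fft, axis=0)
        full = sp_fft.irfft((Xf * Tf).sum(axis=1), n_fft)
        B[k] = full[h : h + n]
    return B


def run_matching_pursuit(
    prebatch: np.ndarray,
    bank,
    max_passes: int = MAX_PASSES,
    return_debug: bool = False,
    record_history: bool = False,
):
    """Iterative template deconvolution of one preprocessed batch.

    Each pass: squared-ReLU normalized detection statistic with M border
    samples zeroed per end -> temporal local maxima via max-pooling
    (window 2M+1) per template -> accept candidates above the learned
    threshold (strongest first, re-validated against the updated traces)
    -> least-squares amplitude -> subtract ``a * T_k`` from the residual
    and ``a * pair_cc[:, k]`` from every convolution trace. Stops when a
    pass accepts nothing, or after ``max_passes``.

    Returns a list of ``(time, template_id, amplitude)``; with
    ``return_debug`` also a dict holding the residual and convolution
    traces after every pass.
    """
    # The matcher works in the common-mode-rejected subspace: the median
    # reference is nonlinear, so superposed spikes leave a residual ghost
    # that is equal on every channel; projecting it out restores exact
    # linear superposition of templates (which live in the same subspace).
    X = np.asarray(prebatch, float)
    X = X - X.mean(axis=1, keepdims=True)
    n = X.shape[0]
    templates = bank.templates
    K, M, C = templates.shape
    h = (M - 1) // 2
    norms2 = bank.template_norms2
    norms = np.sqrt(norms2)
    thr = bank.detect_threshold
    min_amp = getattr(bank, "min_amplitude", 0.0)
    # zero detections only where the template lacks full support: any spike
    # owned by a neighboring window's emit range is then still detectable
    # here and gets subtracted, keeping this window's emit range clean
    border = h

    residual = X.copy()
    B = _correlate_all(residual, templates)
    pair_cc = bank.pair_cc  # K x K x (2M-1)

    events: list[tuple[int, int, float]] = []
    debug = {"conv_after_pass": [], "residual_after_pass": []} if record_history else None

    for p in range(max_passes):
        if not np.isfinite(B).all():
            raise FloatingPointError(f"non-finite convolution trace in pass {p + 1}")
        stat = np.square(np.maximum(B, 0.0) / norms[:, None])
        if n > 2 * border:
            stat[:, :border] = 0.0
            stat[:, n - border :] = 0.0
        else:
            stat[:] = 0.0
        pooled = ndimage.maximum_filter1d(stat, size=2 * M + 1, axis=1, mode="constant")
        kk, tt = np.nonzero((stat >= pooled) & (stat > thr))
        if len(kk) == 0:
            break
        order = np.argsort(stat[kk, tt])[::-1]
        accepted_this_pass = 0
        for idx in order:
            k, t = int(kk[idx]), int(tt[idx])
            a = B[k, t] / norms2[k]
            cur = (max(B[k, t], 0.0) / norms[k]) ** 2
            if cur <= thr or a < min_amp:
                continue
            events.append((t, k, float(a)))
            accepted_this_pass += 1
            lo = max(t - h, 0)
            hi = min(t + h + 1, n)
            residual[lo:hi] -= a * templates[k, lo - (t - h) : hi - (t - h)]
            clo = max(t - (M - 1), 0)
            chi = min(t + M, n)
            B[:, clo:chi] -= a * pair_cc[:, k, clo - (t - (M - 1)) : chi - (t - (M - 1))]
        if record_history:
            debug["conv_after_pass"].append(B.copy())
            debug["residual_after_pass"].append(residual.copy())
        if accepted_this_pass == 0:
            break
    # when detection is saturated (e.g., noise far above the threshold's
    # calibration), the quadratic pileup polish is pointless and slow;
    # degrade to a single refinement sweep
    full_polish = len(events) <= max(n // 50, 200)
    events = _polish_events(
        events, residual, B, bank, min_amp,
        threshold=thr if full_polish else None,
        n_sweeps=3 if full_polish else 1,
        refine_pairs=full_polish,
    )
    events.sort()
    if return_debug or record_history:
        debug = debug if debug is not None else {}
        debug["residual"] = residual
        debug["conv"] = B
        return events, debug
    return events


def _polish_events(
    events: list,
    residual: np.ndarray,
    B: np.ndarray,
    bank,
    min_amp: float,
    threshold: float | None = None,
    n_sweeps: int = 3,
    max_shift: int = 2,
    refine_pairs: bool = True,
) -> list:
    """Refine accepted events by coordinate descent plus backward elimination.

    Greedy matching pursuit biases amplitudes and times when spikes
    overlap, and can leave small spurious events inside pileups. Phase 1
    sweeps: each event is removed (its contribution restored to the
    residual and convolution traces), re-placed at the best time within
    ``max_shift`` samples with the exact least-squares amplitude against
    the remaining residual, and dropped if the refit amplitude falls
    below the floor. Phase 2 elimination: each event, weakest first, is
    tentatively deleted and its neighbors refit; the deletion sticks when
    it raises local residual energy by less than the detection threshold
    (i.e. the event explained less than a detectable spike). Residual and
    traces stay exactly consistent throughout.
    """
    if not events:
        return events
    templates = bank.templates
    pair_cc = bank.pair_cc
    norms2 = bank.template_norms2
    K, M, C = templates.shape
    h = (M - 1) // 2
    n = residual.shape[0]

    def _apply(t, k, a, sign):
        lo = max(t - h, 0)
        hi = min(t + h + 1, n)
        residual[lo:hi] += sign * a * templates[k, lo - (t - h) : hi - (t - h)]
        clo = max(t - (M - 1), 0)
        chi = min(t + M, n)
        B[:, clo:chi] += sign * a * pair_cc[:, k, clo - (t - (M - 1)) : chi - (t - (M - 1))]

    def _replace(t, k):
        """Re-place a removed event at its best nearby time; None if dropped."""
        lo = max(t - max_shift, h)
        hi = min(t + max_shift, n - h - 1)
        t_new = int(lo + np.argmax(B[k, lo : hi + 1]))
        a_new = B[k, t_new] / norms2[k]
        if a_new < min_amp:
            return None
        _apply(t_new, k, a_new, -1)
        return (t_new, k, float(a_new))

    def _sweep(evs):
        changed = False
        out = []
        for t, k, a in sorted(evs):
            _apply(t, k, a, +1)
            new = _replace(t, k)
            if new is None:
                changed = True
                continue
            if new[0] != t or abs(new[2] - a) > 1e-12:
                changed = True
            out.append(new)
        return sorted(out), changed

    current = sorted(events)
    for _ in range(n_sweeps):
        current, changed = _sweep(current)
        if not changed:
            break

    if refine_pairs:
        # joint refinement of overlapping pairs: two close events can lock
        # each other into a compensating local minimum that single-event
        # moves cannot leave; search a small grid of joint time offsets
        # with the exact 2x2 least-squares amplitudes
        current = _refine_pairs(current, residual, B, bank, min_amp, max_shift=8)
        for _ in range(2):
            current, changed = _sweep(current)
            if not changed:
                break

    if threshold is None or not current:
        return current

    def _energy_cmfree(x):
        # energy outside the cross-channel common mode: superposed spikes
        # shift the common median reference nonlinearly, leaving a ghost
        # that is equal on every channel and that no template combination
        # can explain; it must not count as evidence for an event
        return float(np.sum((x - x.mean(axis=1, keepdims=True)) ** 2))

    # backward elimination, weakest events first, iterated to a fixed point
    # (an accepted elimination refits its neighbors, which must then be
    # re-tested themselves)
    for _ in range(4):
        any_change = False
        for t0, k0, a0 in sorted(current, key=lambda e: e[2]):
            if (t0, k0, a0) not in current:
                continue  # already altered by a previous elimination
            neighbors = [
                e for e in current if e != (t0, k0, a0) and abs(e[0] - t0) < 2 * M
            ]
            rlo, rhi = max(t0 - 3 * M, 0), min(t0 + 3 * M, n)
            blo, bhi = max(t0 - 4 * M, 0), min(t0 + 4 * M, n)
            saved_res = residual[rlo:rhi].copy()
            saved_B = B[:, blo:bhi].copy()
            e_before = _energy_cmfree(residual[rlo:rhi])
            _apply(t0, k0, a0, +1)
            new_neighbors = list(neighbors)
            for _ in range(4):
                new_neighbors, ch = _sweep(new_neighbors)
                if not ch:
                    break
            e_after = _energy_cmfree(residual[rlo:rhi])
            if e_after - e_before < threshold:
                current = [
                    e for e in current if e != (t0, k0, a0) and e not in neighbors
                ]
                current.extend(new_neighbors)
                current.sort()
                any_change = True
            else:
                residual[rlo:rhi] = saved_res
                B[:, blo:bhi] = saved_B
        if not any_change:
            break
    return sorted(current)


def _refine_pairs(events, residual, B, bank, min_amp, max_shift=2):
    """Jointly re-place each overlapping event pair on a small offset grid.

    For every pair closer than one template length, both events are
    removed, every joint offset within ``max_shift`` is scored by the
    explained energy of the exact two-template least-squares fit (read off
    the convolution traces and pair_cc), and the best placement is
    re-applied. Template correlations are blind to the common-mode ghost
    by construction, so this scoring is unaffected by the median
    reference's nonlinearity.
    """
    if len(events) < 2:
        return events
    templates = bank.templates
    pair_cc = bank.pair_cc
    norms2 = bank.template_norms2
    K, M, C = templates.shape
    h = (M - 1) // 2
    n = residual.shape[0]

    def _apply(t, k, a, sign):
        lo = max(t - h, 0)
        hi = min(t + h + 1, n)
        residual[lo:hi] += sign * a * templates[k, lo - (t - h) : hi - (t - h)]
        clo = max(t - (M - 1), 0)
        chi = min(t + M, n)
        B[:, clo:chi] += sign * a * pair_cc[:, k, clo - (t - (M - 1)) : chi - (t - (M - 1))]

    current = sorted(events)
    out = list(current)
    i = 0
    while i < len(out) - 1:
        t1, k1, a1 = out[i]
        t2, k2, a2 = out[i + 1]
        if t2 - t1 >= M:
            i += 1
            continue
        _apply(t1, k1, a1, +1)
        _apply(t2, k2, a2, +1)
        best = None
        for d1 in range(-max_shift, max_shift + 1):
            for d2 in range(-max_shift, max_shift + 1):
                u1, u2 = t1 + d1, t2 + d2
                if not (h <= u1 < n - h and h <= u2 < n - h):
                    continue
                tau = u1 - u2
                g12 = pair_cc[k1, k2, tau + M - 1] if abs(tau) < M else 0.0
                det = norms2[k1] * norms2[k2] - g12 * g12
                if det <= 1e-12 * norms2[k1] * norms2[k2]:
                    continue
                b1, b2 = B[k1, u1], B[k2, u2]
                x1 = (norms2[k2] * b1 - g12 * b2) / det
                x2 = (norms2[k1] * b2 - g12 * b1) / det
                if x1 < min_amp or x2 < min_amp:
                    continue
                explained = x1 * b1 + x2 * b2
                if best is None or explained > best[0]:
                    best = (explained, u1, x1, u2, x2)
        if best is None:
            _apply(t1, k1, a1, -1)
            _apply(t2, k2, a2, -1)
            i += 1
            continue
        _, u1, x1, u2, x2 = best
        _apply(u1, k1, x1, -1)
        _apply(u2, k2, x2, -1)
        out[i] = (u1, k1, float(x1))
        out[i + 1] = (u2, k2, float(x2))
        out.sort()
        i += 1
    return sorted(out)


def _event_features(residual: np.ndarray, events, bank) -> np.ndarray:
    """PCA features of each event's waveform (residual plus the subtracted
    spike) on all channels: (n_events, n_pcs, C)."""
    K, M, C = bank.templates.shape
    h = (M - 1) // 2
    basis = bank.pca_basis
    feats = np.zeros((len(events), basis.shape[0], C))
    for i, (t, k, a) in enumerate(events):
        lo, hi = t - h, t + h + 1
        snip = np.zeros((M, C))
        slo, shi = max(lo, 0), min(hi, residual.shape[0])
        snip[slo - lo : shi - lo] = residual[slo:shi]
        snip += a * bank.templates[k]
        feats[i] = basis @ snip
    return feats


def localize_and_assign(event, features: np.ndarray, bank) -> SpikeEvent:
    """Mass-weighted spike position and nearest-centroid cluster assignment.

    ``features`` is the event's n_pcs x C PCA feature matrix. The position
    mass on channel c is the feature energy there, restricted to channels
    within ``bank.local_radius_um`` of the template's peak channel;
    all-zero mass falls back to the peak-channel position. Cluster = index
    of the nearest centroid (Euclidean, ties to the lowest id).
    """
    t, k, a = event
    geom = bank.geometry
    peak = int(bank.peak_channels[k])
    nearby = geom.distances_from(peak) <= getattr(bank, "local_radius_um", 100.0)
    mass = np.einsum("pc,pc->c", features, features) * nearby
    total = mass.sum()
    if total > 0:
        x = float(mass @ geom.x / total)
        y = float(mass @ geom.y / total)
    else:
        logger.warning("event at %d: zero feature mass; using peak channel", t)
        x, y = float(geom.x[peak]), float(geom.y[peak])
    d2 = np.einsum("ij,ij->i", bank.centroids - features.ravel(), bank.centroids - features.ravel())
    cluster = int(np.argmin(d2))  # argmin takes the lowest index on ties
    return SpikeEvent(time=int(t), template_id=int(k), cluster_id=cluster,
                      amplitude=float(a), x=x, y=y)


def dedup(events: list, min_isi_samples: int) -> list:
    """Suppress duplicates per template: of any same-template pair closer
    than ``min_isi_samples`` (strict), the larger-amplitude event survives;
    applied greedily in descending amplitude order. Events are
    ``(time, template_id, amplitude)`` or SpikeEvent, time-sorted."""

    def fields(e):
        if isinstance(e, SpikeEvent):
            return e.time, e.template_id, e.amplitude
        return e[0], e[1], e[2]

    order = sorted(range(len(events)), key=lambda i: -fields(events[i])[2])
    kept_times: dict[int, list] = {}
    keep = [False] * len(events)
    for i in order:
        t, k, a = fields(events[i])
        ok = all(abs(t - t2) >= min_isi_samples for t2 in kept_times.get(k, ()))
        if ok:
            keep[i] = True
            kept_times.setdefault(k, []).append(t)
    return [e for i, e in enumerate(events) if keep[i]]


def sort_stream(
    recording: RawRecording,
    bank,
    batch_len: int = 30000,
    realtime_budget: float | None = None,
) -> SortedOutput:
    """Sort a recording through the batched streaming pipeline.

    ``realtime_budget`` simulates a processing-speed ratio (seconds of
    data processed per second of wall time). When the simulated clock
    falls more than one window behind acquisition, pending windows are
    skipped oldest-first; skipped emit spans are reported in
    ``SortedOutput.skipped_spans``, never silently lost. ``None`` disables
    the budget.
    """
    M = bank.n_samples_template
    n = recording.n_samples
    plan = plan_batches(n, min(batch_len, max(n, 4 * M + 1)), M)
    fs = recording.fs
    uv = recording.to_uv()

    all_events: list[SpikeEvent] = []
    skipped: list[tuple[int, int]] = []
    clock = 0.0
    for (start, end), (es, ee) in zip(plan.windows, plan.emit_ranges):
        if realtime_budget is not None:
            available_at = end / fs
            window_dur = (end - start) / fs
            if realtime_budget <= 0:
                skipped.append((es, ee))
                continue
            start_proc = max(clock, available_at)
            if start_proc - available_at > window_dur:
                skipped.append((es, ee))
                continue
            clock = start_proc + window_dur / realtime_budget
        try:
            # preprocess with context so filter edge transients stay outside
            # the window regardless of how the recording was batched
            ctx = 256
            lo = max(start - ctx, 0)
            hi = min(end + ctx, n)
            pre = preprocess_batch(uv[lo:hi], bank.preproc)[start - lo : end - lo]
            raw_events, dbg = run_matching_pursuit(pre, bank, return_debug=True)
        except Exception as exc:
            raise RuntimeError(
                f"sorting failed in window [{start}, {end})"
            ) from exc
        raw_events = dedup(raw_events, bank.min_isi_samples)
        feats = _event_features(dbg["residual"], raw_events, bank)
        for ev, f in zip(raw_events, feats):
            t_abs = ev[0] + start
            if es <= t_abs < ee:
                se = localize_and_assign(ev, f, bank)
                se.time = t_abs
                all_events.append(se)

    all_events.sort(key=lambda e: e.time)
    return SortedOutput(
        times=[e.time for e in all_events],
        clusters=[e.cluster_id for e in all_events],
        templates=[e.template_id for e in all_events],
        amplitudes=[e.amplitude for e in all_events],
        positions=np.asarray([[e.x, e.y] for e in all_events]).reshape(-1, 2),
        fs=fs,
        skipped_spans=skipped,
    )
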