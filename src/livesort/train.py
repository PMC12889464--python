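"""Offline template learning: build the TemplateBank the online sorter loads.

This is a deliberately simple learner (threshold detection, temporal PCA,
seeded k-means with silhouette-based cluster-count selection, duplicate
merging) standing in for a full offline sorter; only the bank's interface
matters downstream. It is documented as non-canonical in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .io_probe import ProbeGeometry, RawRecording
from .preprocess import PreprocSpec, compute_whitening, preprocess_batch

__all__ = [
    "TemplateBank",
    "TrainParams",
    "NoUnitsLearnedError",
    "learn_templates",
    "import_bank",
    "compute_pair_cc",
]


class NoUnitsLearnedError(RuntimeError):
    """Raised when the training segment yields no usable units."""


@dataclass
class TrainParams:
    """Knobs of the simplified template learner."""

    M: int = 61  # template length, samples (odd)
    n_pcs: int = 6  # temporal PCA dimensions
    detect_mad_mult: float = 5.0  # robust-SD multiplier for detection
    detect_floor_frac: float = 0.02  # detection floor vs 99.99th |signal| percentile
    min_cluster_size: int = 30  # events needed to keep a cluster
    max_units: int = 24
    merge_cos: float = 0.95  # merge templates above this cosine similarity
    dust_adjacency_max: float = 0.75  # drop clusters mostly adjacent to bigger events
    threshold_quantile: float = 0.999  # noise quantile for the online threshold
    min_amplitude: float = 0.2  # template-normalized amplitude floor online
    min_isi_samples: int = 15  # 0.5 ms at 30 kHz
    refine_passes: int = 1  # matching-pursuit template refinement rounds
    refine_min_amplitude: float = 0.6  # confident-event floor for template refits
    min_train_s: float = 60.0
    local_radius_um: float = 100.0  # feature/localization channel neighborhood
    whiten_radius_um: float | None = None
    split_silhouette: float = 0.6  # split a channel group only above this
    threshold_max_samples: int = 600_000  # signal subsample for threshold learning
    stat_floor_frac: float = 0.05  # threshold floor as fraction of min template energy
    seed: int = 0


@dataclass
class TemplateBank:
    """Everything the online sorter loads.

    ``templates`` are whitened K x M x C waveforms; ``pair_cc[i, j, tau]``
    (tau from -(M-1) to M-1) is the full spatiotemporal cross-correlation
    used to update the convolution traces after each subtraction;
    ``detect_threshold`` applies to the squared ReLU of the l2-normalized
    template correlation; ``centroids`` live in flattened (n_pcs * C) PCA
    feature space.
    """

    templates: np.ndarray
    pca_basis: np.ndarray  # n_pcs x M
    template_features: np.ndarray  # K x n_pcs x C
    pair_cc: np.ndarray  # K x K x (2M-1)
    detect_threshold: float
    centroids: np.ndarray  # n_clusters x (n_pcs * C)
    template_to_cluster: np.ndarray  # K
    min_isi_samples: int
    preproc: PreprocSpec
    geometry: ProbeGeometry
    min_amplitude: float = 0.2
    local_radius_um: float = 100.0

    def __post_init__(self):
        self.templates = np.asarray(self.templates, float)
        K, M, C = self.templates.shape
        if K < 1:
            raise ValueError("bank must contain at least one template")
        if M % 2 != 1:
            raise ValueError("template length M must be odd")
        if self.pair_cc.shape != (K, K, 2 * M - 1):
            raise ValueError("pair_cc must be K x K x (2M-1)")
        norms2 = np.einsum("kmc,kmc->k", self.templates, self.templates)
        if not np.allclose(self.pair_cc[np.arange(K), np.arange(K), M - 1], norms2, rtol=1e-6):
            raise ValueError("pair_cc self zero-lag must equal template energy")
        self.template_to_cluster = np.asarray(self.template_to_cluster, int)
        if self.template_to_cluster.shape != (K,):
            raise ValueError("template_to_cluster must map every template")
        if not self.detect_threshold > 0:
            raise ValueError("detect_threshold must be positive")

    @property
    def n_templates(self) -> int:
        return self.templates.shape[0]

    @property
    def n_samples_template(self) -> int:
        return self.templates.shape[1]

    @property
    def template_norms2(self) -> np.ndarray:
        return np.einsum("kmc,kmc->k", self.templates, self.templates)

    @property
    def peak_channels(self) -> np.ndarray:
        return np.argmax(np.abs(self.templates).max(axis=1), axis=1)


def compute_pair_cc(templates: np.ndarray) -> np.ndarray:
    """Pairwise spatiotemporal cross-correlations.

    ``cc[i, j, tau + M - 1] = sum_{m, c} T_i[m, c] * T_j[m + tau, c]``,
    so ``cc[i, j, t] == cc[j, i, -t]`` and the self zero-lag is the
    template energy.
    """
    K, M, C = templates.shape
    cc = np.zeros((K, K, 2 * M - 1))
    for i in range(K):
        for j in range(K):
            acc = np.zeros(2 * M - 1)
            for c in range(C):
                # correlate(Tj, Ti)[k] = sum_m Ti[m] * Tj[m + k - (M-1)]
                acc += np.correlate(templates[j, :, c], templates[i, :, c], mode="full")
            cc[i, j] = acc
    return cc


def _detect_events(x: np.ndarray, thresholds: np.ndarray, M: int) -> np.ndarray:
    """Negative-threshold crossing events, consolidated across channels.

    Returns trough sample times, at least M//2 apart, strongest-first
    greedy within a +/- M//2 exclusion window.
    """
    from scipy import ndimage

    half = (M - 1) // 2
    n, C = x.shape
    minf = ndimage.minimum_filter1d(x, size=2 * half + 1, axis=0, mode="nearest")
    ts, cs = np.nonzero((x < -thresholds[None, :]) & (x == minf))
    if len(ts) == 0:
        return np.empty(0, dtype=np.int64)
    order = np.argsort(x[ts, cs])  # most negative (strongest) first
    accepted: list[int] = []
    taken = np.zeros(n, bool)
    for i in order:
        t = int(ts[i])
        if taken[t]:
            continue
        accepted.append(t)
        taken[max(t - half, 0) : min(t + half + 1, n)] = True
    return np.sort(np.asarray(accepted, dtype=np.int64))


def _temporal_basis(snippets: np.ndarray, n_pcs: int) -> np.ndarray:
    """Orthonormal temporal basis (n_pcs x M) from uncentered SVD of all
    single-channel waveforms. Rank-deficient inputs are completed with the
    remaining orthonormal right singular vectors."""
    E, M, C = snippets.shape
    rows = snippets.transpose(0, 2, 1).reshape(E * C, M)
    # weight by row energy implicitly (SVD does); drop all-zero rows for speed
    keep = np.einsum("ij,ij->i", rows, rows) > 0
    if keep.sum() == 0:
        raise NoUnitsLearnedError("no units learned: snippets have zero energy")
    _, _, Vt = np.linalg.svd(rows[keep], full_matrices=False)
    if Vt.shape[0] < n_pcs:  # pragma: no cover - E*C >= M in practice
        Vt = np.vstack([Vt, np.eye(M)[: n_pcs - Vt.shape[0]]])
    return Vt[:n_pcs]


def _select_clusters(features: np.ndarray, peak_channels: np.ndarray, params: TrainParams):
    """Cluster events within peak-channel groups (dense-probe practice).

    Each channel group is split by seeded k-means only when the best
    silhouette over k = 2..4 clears ``params.split_silhouette``; channel
    groups below the minimum size stay unlabeled (-1). Cross-channel
    duplicates are merged later by template similarity.
    """
    n = len(features)
    labels = np.full(n, -1, int)
    next_id = 0
    rng = np.random.default_rng(params.seed)
    for c in np.unique(peak_channels):
        idx = np.flatnonzero(peak_channels == c)
        if len(idx) < params.min_cluster_size:
            continue
        f = features[idx]
        kmax = min(4, len(idx) // params.min_cluster_size)
        best_s, best_lab, best_k = -np.inf, None, 1
        sub = (
            rng.choice(len(idx), size=1500, replace=False)
            if len(idx) > 1500
            else np.arange(len(idx))
        )
        for k in range(2, kmax + 1):
            lab = KMeans(n_clusters=k, n_init=5, random_state=params.seed).fit_predict(f)
            if len(np.unique(lab[sub])) < 2:
                continue
            s = silhouette_score(f[sub], lab[sub])
            if s > best_s:
                best_s, best_lab, best_k = s, lab, k
        if best_s >= params.split_silhouette:
            labels[idx] = next_id + best_lab
            next_id += best_k
        else:
            labels[idx] = next_id
            next_id += 1
    return labels


def _merge_and_filter(
    labels: np.ndarray,
    snippets: np.ndarray,
    event_times: np.ndarray,
    params: TrainParams,
):
    """Merge near-duplicate clusters (cosine of mean waveforms) and drop
    clusters below the minimum size. Returns relabeled events."""
    uniq = np.unique(labels[labels >= 0])
    if len(uniq) == 0:
        return np.full(len(labels), -1, int)
    means = {u: snippets[labels == u].mean(axis=0).ravel() for u in uniq}
    parent = {u: u for u in uniq}

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for i, a in enumerate(uniq):
        for b in uniq[i + 1 :]:
            va, vb = means[a], means[b]
            denom = np.linalg.norm(va) * np.linalg.norm(vb)
            if denom > 0 and va @ vb / denom > params.merge_cos:
                parent[find(b)] = find(a)
    merged = np.asarray([find(u) if u >= 0 else -1 for u in labels])
    # drop undersized and weak-energy clusters, plus "dust" clusters formed
    # from subtraction leftovers: leftover events sit, by construction, next
    # to a much larger parent event, so a cluster whose members are almost
    # all adjacent to bigger events is not a unit
    M = snippets.shape[1]
    e_event = np.einsum("emc,emc->e", snippets, snippets)
    order = np.argsort(event_times)
    st = event_times[order]
    se = e_event[order]
    adjacent = np.zeros(len(event_times), bool)
    for pos, t in enumerate(st):
        lo = np.searchsorted(st, t - M, side="left")
        hi = np.searchsorted(st, t + M, side="right")
        nb = np.r_[se[lo:pos], se[pos + 1 : hi]]
        if len(nb) and nb.max() > 1.5 * se[pos]:
            adjacent[order[pos]] = True
    energies = {}
    for u in np.unique(merged):
        if u < 0:
            continue
        med = np.median(snippets[merged == u], axis=0)
        energies[u] = float(np.sum(med * med))
    e_max = max(energies.values(), default=0.0)
    out = np.full(len(labels), -1, int)
    next_id = 0
    for u in np.unique(merged):
        if u < 0:
            continue
        mask = merged == u
        if (
            mask.sum() >= params.min_cluster_size
            and energies[u] >= 0.01 * e_max
            and adjacent[mask].mean() <= params.dust_adjacency_max
        ):
            out[mask] = next_id
            next_id += 1
    return out


def learn_templates(
    training: RawRecording, params: TrainParams | None = None, seed: int | None = None
) -> TemplateBank:
    """Learn a TemplateBank from a training recording segment.

    Pipeline: preprocess (high-pass, CMR) -> robust-threshold event
    detection -> noise-masked whitening -> aligned snippet extraction ->
    temporal PCA -> seeded k-means with silhouette model selection ->
    merge/size-filter -> cluster means become whitened templates. The
    online detection threshold is the ``threshold_quantile`` of the
    normalized detection statistic on spike-free stretches.
    """
    params = params or TrainParams()
    if seed is not None:
        params = TrainParams(**{**params.__dict__, "seed": seed})
    if training.duration_s < params.min_train_s:
        raise ValueError(
            f"training segment is {training.duration_s:.1f} s; "
            f"need at least {params.min_train_s:.1f} s (params.min_train_s)"
        )
    M = params.M
    half = (M - 1) // 2
    fs = training.fs
    geom = training.geometry

    base_spec = PreprocSpec(fs=fs)
    filtered = preprocess_batch(training.to_uv(), base_spec)

    # rough detection on the filtered signal, for noise masking; the floor
    # keeps filter ringing around large spikes out of the event set
    mad = np.median(np.abs(filtered - np.median(filtered, axis=0)), axis=0) / 0.6745
    floor = params.detect_floor_frac * max(
        float(np.quantile(np.abs(filtered), 0.9999)), 1e-12
    )
    thr = np.maximum(params.detect_mad_mult * mad, floor)
    rough = _detect_events(filtered, thr, M)

    noise_mask = np.ones(len(filtered), bool)
    for t in rough:
        noise_mask[max(t - M, 0) : t + M] = False
    noise_sd = float(np.median(np.abs(filtered[noise_mask]))) / 0.6745 if noise_mask.any() else 0.0
    # a noise floor at the quantization scale means there is no channel noise
    # to whiten: fitting W to quantization residue would wildly amplify
    # silent channels, so fall back to identity
    quant_sd = training.gain / np.sqrt(12.0)
    if noise_mask.sum() >= 4 * geom.n_channels and noise_sd > 5.0 * quant_sd:
        W = compute_whitening(
            filtered[noise_mask], geometry=geom,
            neighborhood_radius_um=params.whiten_radius_um,
        )
    else:
        # essentially noiseless training data: unit whitening
        W = np.eye(geom.n_channels)
    spec = PreprocSpec(
        fs=fs, whitening_matrix=W, drift_matrix=np.eye(geom.n_channels)
    )
    # work in the matcher's common-mode-rejected subspace (see sortengine):
    # snippets, templates, features and the detection threshold must all
    # live in the same space the online matcher operates in
    white = filtered @ W.T
    white = white - white.mean(axis=1, keepdims=True)

    mad_w = np.median(np.abs(white - np.median(white, axis=0)), axis=0) / 0.6745
    floor_w = params.detect_floor_frac * max(
        float(np.quantile(np.abs(white), 0.9999)), 1e-12
    )
    thr_w = np.maximum(params.detect_mad_mult * mad_w, floor_w)
    events = _detect_events(white, thr_w, M)
    events = events[(events >= half) & (events < len(white) - half)]
    if len(events) == 0:
        raise NoUnitsLearnedError("no units learned: no events above threshold")

    snippets = np.stack([white[t - half : t + half + 1] for t in events])
    bank = _assemble_bank(snippets, white, events, geom, spec, params)

    # refinement: re-extract collision-cleaned snippets with the engine
    for _ in range(params.refine_passes):
        ev2, snip2 = _mp_snippets(white, bank, params)
        if len(ev2) < params.min_cluster_size:
            break
        times2 = np.asarray([t for t, _, _ in ev2], dtype=np.int64)
        bank = _assemble_bank(snip2, white, times2, geom, spec, params)
    return bank


def _assemble_bank(snippets, white, event_times, geom, spec, params) -> TemplateBank:
    """Cluster snippets and build every bank field from the result.

    Clustering features use snippets masked to each event's local channel
    neighborhood (so coincident distant spikes do not contaminate them);
    the templates themselves are means of the raw snippets, masked once by
    the cluster's own peak-channel neighborhood.
    """
    dist = np.stack([geom.distances_from(c) for c in range(geom.n_channels)])
    local_mask = dist <= params.local_radius_um
    half = (snippets.shape[1] - 1) // 2
    peak_ch = np.argmin(snippets[:, half, :], axis=1)
    masked = snippets * local_mask[peak_ch][:, None, :]

    basis = _temporal_basis(masked, params.n_pcs)
    feats = np.einsum("pm,emc->epc", basis, masked)
    flat = feats.reshape(len(snippets), -1)

    labels = _select_clusters(flat, peak_ch, params)
    labels = _merge_and_filter(labels, masked, np.asarray(event_times), params)
    if (labels >= 0).sum() == 0:
        raise NoUnitsLearnedError(
            "no units learned: all clusters below min_cluster_size"
        )
    ids = np.unique(labels[labels >= 0])
    # element-wise median: robust to the minority of collision-contaminated
    # snippets, and exactly the clean waveform on noiseless data. Templates
    # keep all channels: common-median referencing leaves a small inverted
    # copy of each spike on every channel, which subtraction must include.
    templates = np.stack([np.median(snippets[labels == i], axis=0) for i in ids])
    centroids = np.stack([flat[labels == i].mean(axis=0) for i in ids])
    K = len(ids)

    return TemplateBank(
        templates=templates,
        pca_basis=basis,
        template_features=np.einsum("pm,kmc->kpc", basis, templates),
        pair_cc=compute_pair_cc(templates),
        detect_threshold=_learn_threshold(white, templates, event_times, params),
        centroids=centroids,
        template_to_cluster=np.arange(K),
        min_isi_samples=params.min_isi_samples,
        preproc=spec,
        geometry=geom,
        min_amplitude=params.min_amplitude,
        local_radius_um=params.local_radius_um,
    )


def _mp_snippets(white, bank, params):
    """Matching-pursuit pass over the (already preprocessed) training signal,
    returning confident events and their collision-cleaned waveforms.

    A cleaned waveform is the final residual plus the event's own template
    contribution, with every low-amplitude event's contribution restored
    as well: low-amplitude detections frequently explain the residual
    shape error of an adjacent real spike, and subtracting them would pull
    the refined templates toward the previous generation's bias. Only
    events with amplitude >= ``refine_min_amplitude`` seed templates.
    """
    from .sortengine import dedup, plan_batches, run_matching_pursuit

    M = bank.n_samples_template
    half = (M - 1) // 2
    n = len(white)
    plan = plan_batches(n, min(90000, max(n, 4 * M + 1)), M)
    events = []
    snippets = []
    for (start, end), (es, ee) in zip(plan.windows, plan.emit_ranges):
        evs, dbg = run_matching_pursuit(white[start:end], bank, return_debug=True)
        evs = dedup(evs, bank.min_isi_samples)
        res = dbg["residual"].copy()
        weak = [e for e in evs if e[2] < params.refine_min_amplitude]
        strong = [e for e in evs if e[2] >= params.refine_min_amplitude]
        for t, k, a in weak:  # restore weak contributions into the residual
            lo = max(t - half, 0)
            hi = min(t + half + 1, end - start)
            res[lo:hi] += a * bank.templates[k, lo - (t - half) : hi - (t - half)]
        for t, k, a in strong:
            t_abs = t + start
            if not (es <= t_abs < ee):
                continue
            if t - half < 0 or t + half + 1 > end - start:
                continue
            snippets.append(res[t - half : t + half + 1] + a * bank.templates[k])
            events.append((t_abs, k, a))
    if not events:
        return [], np.empty((0, M, white.shape[1]))
    if len(events) > 50_000:  # memory guard: clustering needs no more
        rng = np.random.default_rng(params.seed)
        keep = np.sort(rng.choice(len(events), size=50_000, replace=False))
        events = [events[i] for i in keep]
        snippets = [snippets[i] for i in keep]
    return events, np.stack(snippets)


def _learn_threshold(
    white: np.ndarray, templates: np.ndarray, events: np.ndarray, params: TrainParams
) -> float:
    """Quantile of the normalized detection statistic on spike-free stretches."""
    from .sortengine import _correlate_all  # shared kernel

    K, M, C = templates.shape
    n = min(len(white), params.threshold_max_samples)
    white = white[:n]
    events = events[events < n]
    B = _correlate_all(white, templates)
    norms = np.sqrt(np.einsum("kmc,kmc->k", templates, templates))
    stat = np.square(np.maximum(B, 0.0) / norms[:, None])
    mask = np.ones(n, bool)
    for t in events:
        mask[max(t - 2 * M, 0) : t + 2 * M] = False
    mask[: M] = False
    mask[-M:] = False
    norms2 = np.einsum("kmc,kmc->k", templates, templates)
    floor = params.stat_floor_frac * float(norms2.min())
    if mask.sum() == 0:
        return floor  # no spike-free stretch (noiseless data): energy floor
    q = float(np.quantile(stat[:, mask], params.threshold_quantile))
    return max(q, floor)


def import_bank(
    kilosort_dir,
    fs: float = 30000.0,
    detect_threshold: float = 10.0,
    min_isi_samples: int = 15,
) -> TemplateBank:
    """Adapter for a phy-layout directory of offline sorter output.

    Requires ``templates.npy`` (K x M x C), ``channel_map.npy`` and
    ``channel_positions.npy``; reads ``whitening_mat.npy`` when present.
    pair_cc, the PCA basis, features and centroids are recomputed from the
    imported templates.
    """
    from pathlib import Path

    d = Path(kilosort_dir)
    required = ["templates.npy", "channel_map.npy", "channel_positions.npy"]
    missing = [f for f in required if not (d / f).exists()]
    if missing:
        raise FileNotFoundError(f"phy directory missing arrays: {missing}")
    templates = np.load(d / "templates.npy").astype(float)
    chan_map = np.load(d / "channel_map.npy").ravel()
    positions = np.load(d / "channel_positions.npy")
    if len(chan_map) != len(positions):
        raise ValueError(
            f"channel_map has {len(chan_map)} channels but channel_positions "
            f"has {len(positions)}"
        )
    if templates.shape[2] != len(chan_map):
        raise ValueError(
            f"templates cover {templates.shape[2]} channels but channel map "
            f"lists {len(chan_map)}"
        )
    K, M, C = templates.shape
    if M % 2 == 0:  # pad to odd alignment window
        templates = np.concatenate([templates, np.zeros((K, 1, C))], axis=1)
        M += 1
    # bank templates live in the matcher's common-mode-rejected subspace
    templates = templates - templates.mean(axis=2, keepdims=True)
    geom = ProbeGeometry(x=positions[:, 0], y=positions[:, 1])
    wfile = d / "whitening_mat.npy"
    W = np.load(wfile) if wfile.exists() else np.eye(C)
    spec = PreprocSpec(fs=fs, whitening_matrix=W, drift_matrix=np.eye(C))

    n_pcs = min(6, M)
    rows = templates.transpose(0, 2, 1).reshape(K * C, M)
    keep = np.einsum("ij,ij->i", rows, rows) > 0
    _, _, Vt = np.linalg.svd(rows[keep], full_matrices=False)
    basis = Vt[:n_pcs]
    if basis.shape[0] < n_pcs:
        basis = np.vstack([basis, np.zeros((n_pcs - basis.shape[0], M))])
    template_features = np.einsum("pm,kmc->kpc", basis, templates)
    centroids = template_features.reshape(K, -1)
    return TemplateBank(
        templates=templates,
        pca_basis=basis,
        template_features=template_features,
        pair_cc=compute_pair_cc(templates),
        detect_threshold=detect_threshold,
        centroids=centroids,
        template_to_cluster=np.arange(K),
        min_isi_samples=min_isi_samples,
        preproc=spec,
        geometry=geom,
    )
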