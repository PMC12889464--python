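"""The 5-step online preprocessing chain applied to every batch.

Order is fixed: (1) per-channel mean subtraction, (2) common median
referencing across channels, (3) FFT-domain high-pass at ``highpass_hz``,
(4) spatial whitening, (5) drift correction. Steps 4-5 are left
multiplications by precomputed channel x channel matrices; the drift
matrix defaults to identity (no live drift estimation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft

__all__ = ["PreprocSpec", "preprocess_batch", "compute_whitening"]


@dataclass
class PreprocSpec:
    """Parameters of the online preprocessing chain.

    The high-pass is applied in the FFT domain with a raised-cosine
    transition band of ``highpass_hz`` +/- ``transition_hz`` (fully
    blocked below the lower edge, fully passed above the upper edge).
    """

    fs: float
    highpass_hz: float = 300.0
    transition_hz: float = 75.0
    whitening_matrix: np.ndarray | None = None
    drift_matrix: np.ndarray | None = None
    n_channels: int | None = field(default=None)

    def __post_init__(self):
        if self.whitening_matrix is not None:
            self.whitening_matrix = np.asarray(self.whitening_matrix, float)
            w = self.whitening_matrix
            if w.ndim != 2 or w.shape[0] != w.shape[1]:
                raise ValueError("whitening matrix must be square")
            if not np.isfinite(w).all():
                raise ValueError("whitening matrix must be finite")
            self.n_channels = w.shape[0]
        if self.drift_matrix is not None:
            self.drift_matrix = np.asarray(self.drift_matrix, float)
            d = self.drift_matrix
            if d.ndim != 2 or d.shape[0] != d.shape[1]:
                raise ValueError("drift matrix must be square")
            if not np.isfinite(d).all():
                raise ValueError("drift matrix must be finite")
            if self.n_channels is not None and d.shape[0] != self.n_channels:
                raise ValueError("drift matrix channel count mismatch")
            self.n_channels = d.shape[0]


def _highpass_fft(batch: np.ndarray, fs: float, cutoff: float, transition: float) -> np.ndarray:
    """Zero-phase FFT high-pass with a raised-cosine edge around ``cutoff``.

    The batch is reflect-padded by one filter support on each side so batch
    boundaries do not ring through the circular FFT.
    """
    n = batch.shape[0]
    pad = min(n, max(64, int(round(fs / max(cutoff - transition, 1.0)))))
    x = np.pad(batch, ((pad, pad), (0, 0)), mode="reflect")
    n_fft = sp_fft.next_fast_len(x.shape[0])
    x = np.pad(x, ((0, n_fft - x.shape[0]), (0, 0)))
    freqs = np.abs(sp_fft.rfftfreq(n_fft, d=1.0 / fs))
    lo, hi = cutoff - transition, cutoff + transition
    gain = np.ones_like(freqs)
    gain[freqs <= lo] = 0.0
    band = (freqs > lo) & (freqs < hi)
    gain[band] = 0.5 * (1.0 - np.cos(np.pi * (freqs[band] - lo) / (hi - lo)))
    spec = sp_fft.rfft(x, axis=0)
    out = sp_fft.irfft(spec * gain[:, None], n=n_fft, axis=0)
    return out[pad : pad + n]


def preprocess_batch(batch: np.ndarray, spec: PreprocSpec) -> np.ndarray:
    """Apply the 5-step chain to a samples x channels float batch."""
    batch = np.asarray(batch, dtype=np.float64)
    if batch.ndim != 2:
        raise ValueError("batch must be samples x channels")
    if not np.isfinite(batch).all():
        raise ValueError("batch contains non-finite samples")
    if spec.n_channels is not None and batch.shape[1] != spec.n_channels:
        raise ValueError(
            f"batch has {batch.shape[1]} channels, spec expects {spec.n_channels}"
        )
    # (1) per-channel mean subtraction
    out = batch - batch.mean(axis=0, keepdims=True)
    # (2) common median reference across channels, per sample
    out = out - np.median(out, axis=1, keepdims=True)
    # (3) FFT-based high-pass
    out = _highpass_fft(out, spec.fs, spec.highpass_hz, spec.transition_hz)
    # (4) spatial whitening
    if spec.whitening_matrix is not None:
        out = out @ spec.whitening_matrix.T
    # (5) drift correction
    if spec.drift_matrix is not None:
        out = out @ spec.drift_matrix.T
    return out


def compute_whitening(
    noise_segment: np.ndarray,
    geometry=None,
    neighborhood_radius_um: float | None = None,
    eps: float | None = None,
) -> np.ndarray:
    """Symmetric (ZCA) whitening matrix from a noise segment.

    Computed channel-block-wise: each output channel's whitening row is
    taken from a ZCA solve restricted to channels within
    ``neighborhood_radius_um`` of it (all channels when no geometry or
    radius is given). ``eps`` regularizes the covariance eigenvalues;
    default ``1e-6 *`` mean diagonal. For i.i.d. noise the result is a
    scaled identity.
    """
    seg = np.asarray(noise_segment, float)
    if seg.ndim != 2 or seg.shape[0] < seg.shape[1]:
        raise ValueError("noise segment must be samples x channels, samples >= channels")
    seg = seg - seg.mean(axis=0, keepdims=True)
    cov = seg.T @ seg / seg.shape[0]
    nc = cov.shape[0]
    if eps is None:
        eps = 1e-6 * float(np.mean(np.diag(cov)))

    def _zca(c: np.ndarray) -> np.ndarray:
        vals, vecs = np.linalg.eigh(c)
        if eps == 0 and np.min(vals) <= np.finfo(float).eps * np.max(np.abs(vals)) * len(vals):
            raise np.linalg.LinAlgError(
                "noise covariance is singular; pass eps > 0 to regularize"
            )
        return vecs @ np.diag(1.0 / np.sqrt(vals + eps)) @ vecs.T

    if geometry is None or neighborhood_radius_um is None:
        return _zca(cov)
    W = np.zeros((nc, nc))
    for c in range(nc):
        nbr = np.flatnonzero(geometry.distances_from(c) <= neighborhood_radius_um)
        sub = _zca(cov[np.ix_(nbr, nbr)])
        W[c, nbr] = sub[np.flatnonzero(nbr == c)[0]]
    return W
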