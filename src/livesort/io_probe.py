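"""On-disk artifacts: raw binaries, probe geometry, sorted outputs, template banks.

Raw recordings follow the SpikeGLX dialect: frame-interleaved (sample-major)
little-endian int16 ``.bin`` next to a flat ``key=value`` ``.meta`` sidecar.
Probe geometry is a 3-column TSV (channel, x, y in micrometres). Sorted
outputs use phy-style columnar NPY arrays plus a JSON manifest. Template
banks are a single NPZ archive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ProbeGeometry",
    "RawRecording",
    "SortedOutput",
    "FormatError",
    "read_raw",
    "write_raw",
    "read_geometry",
    "write_geometry",
    "read_sorted",
    "write_sorted",
    "save_bank",
    "load_bank",
]


class FormatError(ValueError):
    """Raised when an on-disk artifact violates its declared layout."""


@dataclass(frozen=True)
class ProbeGeometry:
    """Per-channel positions on the probe, in micrometres."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if len(x) < 1:
            raise ValueError("need at least one channel")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("channel positions must be finite")

    @property
    def n_channels(self) -> int:
        return len(self.x)

    @property
    def positions(self) -> np.ndarray:
        """(n_channels, 2) array of (x, y)."""
        return np.column_stack([self.x, self.y])

    def distances_from(self, channel: int) -> np.ndarray:
        """Euclidean distance of every channel from ``channel``, in um."""
        return np.hypot(self.x - self.x[channel], self.y - self.y[channel])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ProbeGeometry)
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
        )


@dataclass
class RawRecording:
    """A samples x channels int16 signal tied to a probe geometry.

    ``gain`` converts counts to microvolts: ``signal_uV = data * gain``.
    """

    data: np.ndarray
    fs: float
    gain: float
    geometry: ProbeGeometry

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (samples x channels)")
        if self.data.shape[0] < 1:
            raise ValueError("recording must contain at least one sample")
        if self.data.shape[1] != self.geometry.n_channels:
            raise ValueError(
                f"data has {self.data.shape[1]} channels but geometry has "
                f"{self.geometry.n_channels}"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def to_uv(self) -> np.ndarray:
        """Signal in microvolts as float64."""
        return self.data.astype(np.float64) * self.gain


@dataclass
class SortedOutput:
    """Sorted spikes: one row per event, plus per-cluster train access."""

    times: np.ndarray  # sample indices, nondecreasing
    clusters: np.ndarray
    templates: np.ndarray
    amplitudes: np.ndarray
    positions: np.ndarray  # (n, 2) um
    fs: float
    skipped_spans: list = field(default_factory=list)  # [(start, end)] samples

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.int64)
        self.clusters = np.asarray(self.clusters, dtype=np.int64)
        self.templates = np.asarray(self.templates, dtype=np.int64)
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64)
        self.positions = np.asarray(self.positions, dtype=np.float64).reshape(-1, 2)
        n = len(self.times)
        for name in ("clusters", "templates", "amplitudes"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != times length")
        if self.positions.shape[0] != n:
            raise ValueError("positions length != times length")
        if n and np.any(np.diff(self.times) < 0):
            raise ValueError("spike times must be nondecreasing")

    @property
    def n_spikes(self) -> int:
        return len(self.times)

    @property
    def n_clusters(self) -> int:
        return int(len(np.unique(self.clusters))) if self.n_spikes else 0

    def train(self, cluster: int) -> np.ndarray:
        """Spike times (samples) of one cluster."""
        return self.times[self.clusters == cluster]

    def trains(self) -> dict[int, np.ndarray]:
        return {int(c): self.train(int(c)) for c in np.unique(self.clusters)}


# ---------------------------------------------------------------------------
# raw binary + meta + geometry


def _parse_meta(meta_path) -> dict[str, str]:
    meta = {}
    for line in Path(meta_path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FormatError(f"meta line without '=': {line!r}")
        key, _, val = line.partition("=")
        meta[key.strip()] = val.strip()
    return meta


def write_raw(rec: RawRecording, binary_path, meta_path, geometry_path=None) -> None:
    """Write ``rec`` as int16 .bin plus key=value .meta (and optional probe TSV)."""
    data = np.ascontiguousarray(rec.data, dtype="<i2")
    Path(binary_path).write_bytes(data.tobytes())
    lines = [
        f"imSampRate={rec.fs:g}",
        f"nSavedChans={rec.n_channels}",
        f"uVPerBit={float(rec.gain):.12g}",
    ]
    Path(meta_path).write_text("\n".join(lines) + "\n")
    if geometry_path is not None:
        write_geometry(rec.geometry, geometry_path)


def read_raw(binary_path, meta_path, geometry_path) -> RawRecording:
    """Read a raw int16 recording and its sidecars.

    The binary must be an exact multiple of ``2 * n_channels`` bytes; any
    mismatch raises :class:`FormatError` naming expected vs actual counts.
    """
    meta = _parse_meta(meta_path)
    for key in ("imSampRate", "nSavedChans"):
        if key not in meta:
            raise FormatError(f"meta file missing required key {key!r}")
    fs = float(meta["imSampRate"])
    n_channels = int(meta["nSavedChans"])
    gain = float(meta.get("uVPerBit", 1.0))
    raw = Path(binary_path).read_bytes()
    frame_bytes = 2 * n_channels
    if len(raw) % frame_bytes != 0:
        raise FormatError(
            f"binary size {len(raw)} bytes is not a multiple of "
            f"{frame_bytes} bytes ({n_channels} int16 channels per frame); "
            f"nearest frame count {len(raw) // frame_bytes} would need "
            f"{(len(raw) // frame_bytes) * frame_bytes} bytes"
        )
    data = np.frombuffer(raw, dtype="<i2").reshape(-1, n_channels)
    geometry = read_geometry(geometry_path)
    if geometry.n_channels != n_channels:
        raise FormatError(
            f"meta declares {n_channels} channels but geometry file has "
            f"{geometry.n_channels}"
        )
    return RawRecording(data=data.copy(), fs=fs, gain=gain, geometry=geometry)


def write_geometry(geom: ProbeGeometry, path) -> None:
    df = pd.DataFrame(
        {"channel": np.arange(geom.n_channels), "x": geom.x, "y": geom.y}
    )
    df.to_csv(path, sep="\t", index=False)


def read_geometry(path) -> ProbeGeometry:
    df = pd.read_csv(path, sep="\t")
    for col in ("channel", "x", "y"):
        if col not in df.columns:
            raise FormatError(f"geometry table missing column {col!r}")
    df = df.sort_values("channel")
    chans = df["channel"].to_numpy()
    if not np.array_equal(chans, np.arange(len(chans))):
        raise FormatError("channel indices must be unique and contiguous from 0")
    return ProbeGeometry(x=df["x"].to_numpy(float), y=df["y"].to_numpy(float))


# ---------------------------------------------------------------------------
# phy-style sorted output


def write_sorted(output: SortedOutput, dir_path) -> dict:
    """Write phy-style columnar arrays plus manifest.json; returns the manifest."""
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    np.save(d / "spike_times.npy", output.times)
    np.save(d / "spike_clusters.npy", output.clusters)
    np.save(d / "spike_templates.npy", output.templates)
    np.save(d / "amplitudes.npy", output.amplitudes)
    np.save(d / "spike_positions.npy", output.positions)
    manifest = {
        "n_spikes": int(output.n_spikes),
        "n_clusters": int(output.n_clusters),
        "fs": float(output.fs),
        "skipped_spans": [[int(a), int(b)] for a, b in output.skipped_spans],
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_sorted(dir_path) -> SortedOutput:
    d = Path(dir_path)
    manifest = json.loads((d / "manifest.json").read_text())
    return SortedOutput(
        times=np.load(d / "spike_times.npy"),
        clusters=np.load(d / "spike_clusters.npy"),
        templates=np.load(d / "spike_templates.npy"),
        amplitudes=np.load(d / "amplitudes.npy"),
        positions=np.load(d / "spike_positions.npy"),
        fs=manifest["fs"],
        skipped_spans=[tuple(s) for s in manifest.get("skipped_spans", [])],
    )


# ---------------------------------------------------------------------------
# template bank archive (NPZ)

_BANK_VERSION = 1
_BANK_REQUIRED = (
    "templates",
    "pca_basis",
    "template_features",
    "pair_cc",
    "detect_threshold",
    "centroids",
    "template_to_cluster",
    "min_isi_samples",
    "whitening_matrix",
    "drift_matrix",
    "highpass_hz",
    "fs",
    "geom_x",
    "geom_y",
)


def save_bank(bank, path) -> None:
    """Serialize a TemplateBank to a single NPZ archive."""
    C = bank.geometry.n_channels
    W = bank.preproc.whitening_matrix
    D = bank.preproc.drift_matrix
    np.savez_compressed(
        path,
        version=np.int64(_BANK_VERSION),
        templates=bank.templates,
        pca_basis=bank.pca_basis,
        template_features=bank.template_features,
        pair_cc=bank.pair_cc,
        detect_threshold=np.float64(bank.detect_threshold),
        centroids=bank.centroids,
        template_to_cluster=bank.template_to_cluster,
        min_isi_samples=np.int64(bank.min_isi_samples),
        whitening_matrix=W if W is not None else np.eye(C),
        drift_matrix=D if D is not None else np.eye(C),
        highpass_hz=np.float64(bank.preproc.highpass_hz),
        fs=np.float64(bank.preproc.fs),
        geom_x=bank.geometry.x,
        geom_y=bank.geometry.y,
    )


def load_bank(path):
    """Load a TemplateBank archive, checking version and required fields."""
    from .preprocess import PreprocSpec
    from .train import TemplateBank

    with np.load(path) as arc:
        version = int(arc["version"]) if "version" in arc else None
        if version != _BANK_VERSION:
            raise FormatError(
                f"incompatible bank archive version {version} "
                f"(expected {_BANK_VERSION})"
            )
        missing = [k for k in _BANK_REQUIRED if k not in arc]
        if missing:
            raise FormatError(f"bank archive missing fields: {missing}")
        geometry = ProbeGeometry(x=arc["geom_x"], y=arc["geom_y"])
        preproc = PreprocSpec(
            highpass_hz=float(arc["highpass_hz"]),
            fs=float(arc["fs"]),
            whitening_matrix=arc["whitening_matrix"],
            drift_matrix=arc["drift_matrix"],
        )
        return TemplateBank(
            templates=arc["templates"],
            pca_basis=arc["pca_basis"],
            template_features=arc["template_features"],
            pair_cc=arc["pair_cc"],
            detect_threshold=float(arc["detect_threshold"]),
            centroids=arc["centroids"],
            template_to_cluster=arc["template_to_cluster"],
            min_isi_samples=int(arc["min_isi_samples"]),
            preproc=preproc,
            geometry=geometry,
        )
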