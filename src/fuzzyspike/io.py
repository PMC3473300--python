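"""Data containers and plain-text readers/writers.

Voltage traces travel as raw little-endian float32 samples next to a JSON
sidecar (``<stem>.json``) holding the sampling rate; event lists are CSV;
the sorter prototype (the frozen projection + cluster model used for online
classification) is a JSON document of full-precision floats so that it can
be inspected and diffed by hand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RawRecording",
    "SpikeEvent",
    "GroundTruthEvent",
    "SorterModel",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "save_model",
    "load_model",
]


@dataclass
class RawRecording:
    """A single-channel sampled voltage trace.

    Parameters
    ----------
    samples : ndarray
        Amplitudes in arbitrary (but consistent) signal units; must be finite.
    fs : float
        Sampling rate in Hz, strictly positive.
    t0 : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("recording must hold at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")
        if not (self.fs > 0):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration


@dataclass(frozen=True)
class SpikeEvent:
    """A detected spike: sub-sample peak time and quadratic-fit amplitude."""

    time_s: float
    amplitude: float


@dataclass(frozen=True)
class GroundTruthEvent:
    """A simulated true spike with its generating unit.

    ``is_overlapping`` is true iff the nearest other true spike (any unit)
    is closer than 0.7 ms, the regime where superimposed waveforms make
    shape-based sorting hardest.
    """

    time_s: float
    unit_id: int
    is_overlapping: bool = False


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: RawRecording, path: str | Path) -> None:
    """Write float32 little-endian samples plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = rec.samples.astype("<f4")
    data.tofile(path)
    sidecar = {
        "fs": rec.fs,
        "t0": rec.t0,
        "units": "arbitrary",
        "n_samples": int(rec.samples.size),
        "dtype": "float32-le",
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_recording(path: str | Path) -> RawRecording:
    """Read a float32 binary trace described by its JSON sidecar."""
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    samples = np.fromfile(path, dtype="<f4").astype(np.float64)
    if "n_samples" in meta and samples.size != int(meta["n_samples"]):
        raise ValueError(
            f"sidecar announces {meta['n_samples']} samples, file holds {samples.size}"
        )
    return RawRecording(samples=samples, fs=float(meta["fs"]), t0=float(meta.get("t0", 0.0)))


def _check_sorted(times: np.ndarray) -> None:
    if np.any(np.diff(times) < 0):
        raise ValueError("event list must be sorted by time")


def write_events(events, path: str | Path) -> None:
    """Write a time-sorted list of spike or ground-truth events as CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if len(events) == 0:
        # header-only file; default to the detection schema
        pd.DataFrame(columns=["time_s", "amplitude"]).to_csv(path, index=False)
        return
    times = np.array([e.time_s for e in events])
    _check_sorted(times)
    if isinstance(events[0], GroundTruthEvent):
        df = pd.DataFrame(
            {
                "time_s": times,
                "unit_id": [e.unit_id for e in events],
                "is_overlapping": [int(e.is_overlapping) for e in events],
            }
        )
    else:
        df = pd.DataFrame({"time_s": times, "amplitude": [e.amplitude for e in events]})
    df.to_csv(path, index=False, float_format="%.12g")


def read_events(path: str | Path):
    """Read back an event CSV; the schema decides the event type."""
    df = pd.read_csv(path)
    if "unit_id" in df.columns:
        events = [
            GroundTruthEvent(float(t), int(u), bool(o))
            for t, u, o in zip(df["time_s"], df["unit_id"], df["is_overlapping"])
        ]
    else:
        events = [SpikeEvent(float(t), float(a)) for t, a in zip(df["time_s"], df["amplitude"])]
    _check_sorted(np.array([e.time_s for e in events]))
    return events


@dataclass
class SorterModel:
    """The persisted prototype for supervised online classification.

    Holds everything the streaming classifier needs: the truncated
    right-singular basis ``V_k`` and inverse singular values ``S_k_inv``
    for low-rank projection of new waveforms, the frozen fuzzy C-means
    centroids, per-cluster covariances for the Mahalanobis noise gate and
    the L-ratio monitor, and the detection scale/threshold estimated
    during the training acquisition.
    """

    V_k: np.ndarray                  # 24 x k, orthonormal columns
    S_k_inv: np.ndarray              # k positive values
    k: int
    centroids: np.ndarray            # c x k
    covariances: np.ndarray          # c x k x k
    m: float                         # FCM fuzziness exponent
    c: int
    sigma_noise: float
    threshold: float
    fs: float
    dead_time_ms: float = 1.0
    polarity: str = "positive"
    pre_ms: float = 0.8
    post_ms: float = 1.0
    band: tuple | None = None        # None = detection ran unfiltered
    noise_quantile: float = 0.999
    l_ratio_threshold: float = 5.0
    row_centering: str = "per-spike"

    def __post_init__(self) -> None:
        self.V_k = np.asarray(self.V_k, dtype=np.float64)
        self.S_k_inv = np.asarray(self.S_k_inv, dtype=np.float64)
        self.centroids = np.asarray(self.centroids, dtype=np.float64)
        self.covariances = np.asarray(self.covariances, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        if self.V_k.shape != (24, self.k):
            raise ValueError(f"V_k must be 24x{self.k}, got {self.V_k.shape}")
        gram = self.V_k.T @ self.V_k
        if not np.allclose(gram, np.eye(self.k), atol=1e-8):
            raise ValueError("columns of V_k are not orthonormal")
        if self.S_k_inv.shape != (self.k,) or np.any(self.S_k_inv <= 0):
            raise ValueError("S_k_inv must hold k positive values")
        if self.centroids.shape != (self.c, self.k):
            raise ValueError(
                f"centroids must be {self.c}x{self.k}, got {self.centroids.shape}"
            )
        if self.covariances.shape != (self.c, self.k, self.k):
            raise ValueError("covariances must be c x k x k")
        if not (self.m > 1):
            raise ValueError("fuzziness m must exceed 1")
        if not (self.l_ratio_threshold > 0):
            raise ValueError("l_ratio_threshold must be positive")


_ARRAY_FIELDS = ("V_k", "S_k_inv", "centroids", "covariances")


def save_model(model: SorterModel, path: str | Path) -> None:
    """Serialize a SorterModel to human-readable JSON (full float precision)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {"format": "fuzzyspike-sorter-model", "version": 1}
    for f in fields(model):
        val = getattr(model, f.name)
        if f.name in _ARRAY_FIELDS:
            val = np.asarray(val).tolist()
        elif isinstance(val, tuple):
            val = list(val)
        doc[f.name] = val
    path.write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path) -> SorterModel:
    """Load and validate a persisted SorterModel."""
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "fuzzyspike-sorter-model":
        raise ValueError("not a fuzzyspike sorter model file")
    kwargs = {}
    for f in fields(SorterModel):
        if f.name not in doc:
            raise ValueError(f"model file missing field {f.name!r}")
        val = doc[f.name]
        if f.name in _ARRAY_FIELDS:
            val = np.asarray(val, dtype=np.float64)
        elif isinstance(val, list):
            val = tuple(val)
        kwargs[f.name] = val
    return SorterModel(**kwargs)  # __post_init__ re-validates invariants
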