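"""Unsupervised training and supervised streaming classification.

``sort_recording`` runs the full offline pipeline on a recording —
detect, extract/align, row-centre, SVD, automatic choice of the number of
components, l1-norm histogram cluster count, fuzzy C-means — and packs
the frozen projection operators, centroids and covariances into a
:class:`~fuzzyspike.io.SorterModel`.  ``classify_spike`` then labels a
single new 24-sample waveform with one small matrix product (no
refactorization), and ``stream_classify`` replays a recording through the
frozen model while monitoring per-class L-ratio over a sliding buffer,
raising an alert record whenever isolation degrades past the threshold
(the sign that the SVD/FCM prototype should be retrained).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from . import cluster as _cluster
from . import features as _features
from .detect import DetectionConfig, WaveformMatrix, bandpass_filter, compute_threshold, \
    detect_peaks, estimate_noise_sigma, extract_waveforms
from .io import RawRecording, SorterModel
from .quality import compute_quality_report, l_ratio

__all__ = [
    "SortConfig",
    "SortResult",
    "NOISE_LABEL",
    "TooFewSpikesError",
    "sort_recording",
    "train_prototype",
    "classify_spike",
    "stream_classify",
]

NOISE_LABEL = -1


class TooFewSpikesError(RuntimeError):
    """Raised when a recording yields too few spikes to train on."""


@dataclass
class SortConfig:
    """Settings of the full unsupervised pipeline."""

    detection: DetectionConfig = field(default_factory=DetectionConfig)
    m: float = 1.1
    tol: float = 1e-5
    max_iter: int = 300
    n_clusters: int | None = None     # manual override of the automatic count
    min_spikes: int = 50
    noise_quantile: float = 0.999
    l_ratio_threshold: float = 5.0
    seed: int = 0


@dataclass
class SortResult:
    """Everything the offline pipeline produced, plus the packed model."""

    waveforms: WaveformMatrix
    svd: _features.SVDModel
    scores: np.ndarray
    histogram: _cluster.L1Histogram
    fcm: _cluster.FCMResult
    quality: object
    model: SorterModel
    sigma_noise: float
    threshold: float

    @property
    def labels(self) -> np.ndarray:
        return self.fcm.labels

    @property
    def times(self) -> np.ndarray:
        return self.waveforms.times


def _detect_and_extract(rec: RawRecording, det: DetectionConfig, threshold: float | None = None):
    x = bandpass_filter(rec, det.band) if det.filter_signal else rec
    sigma = estimate_noise_sigma(x.samples)
    if threshold is None:
        threshold = compute_threshold(sigma, det.threshold_multiplier)
    events = detect_peaks(x, threshold, det)
    wm = extract_waveforms(x, events, det)
    return x, sigma, threshold, events, wm


def sort_recording(rec: RawRecording, cfg: SortConfig | None = None) -> SortResult:
    """Run the full unsupervised sorting pipeline on one recording."""
    if cfg is None:
        cfg = SortConfig()
    _, sigma, thr, _, wm = _detect_and_extract(rec, cfg.detection)
    if wm.n < cfg.min_spikes:
        raise TooFewSpikesError(
            f"only {wm.n} spikes above threshold (need {cfg.min_spikes}); "
            "recording too short or too quiet to train on"
        )
    X, _ = _features.center_rows(wm.A)
    svd = _features.fit_svd(X)
    svd.k = _features.select_noc(svd.S)
    scores = svd.U[:, : svd.k]

    # the cluster-count histogram needs the radial (energy) structure of
    # the data, so it sees the unwhitened projections X V_k = U_k S_k;
    # FCM then clusters the whitened scores U_k, where the background
    # noise is closest to isotropic
    norms = _cluster.l1_norms(scores * svd.S[: svd.k])
    c_auto, hist = _cluster.estimate_cluster_count(norms)
    c = cfg.n_clusters if cfg.n_clusters is not None else c_auto
    if c < 1 or c > wm.n:
        raise ValueError(f"cannot cluster {wm.n} spikes into {c} clusters")

    candidates = [
        _cluster.fcm(
            scores, c, m=cfg.m, tol=cfg.tol, max_iter=cfg.max_iter,
            seed=cfg.seed, n_init=5,
        )
    ]
    if hist.peak_count == c:
        init = _cluster.init_from_histogram(scores, hist)
        if init.shape[0] == c:
            candidates.append(
                _cluster.fcm(
                    scores, c, m=cfg.m, tol=cfg.tol, max_iter=cfg.max_iter,
                    init_centroids=init,
                )
            )
    result = min(candidates, key=lambda r: r.objective)
    _cluster.mark_outliers(scores, result, cfg.noise_quantile)
    quality = compute_quality_report(scores, result, cfg.l_ratio_threshold)

    covs = np.stack(
        [
            _cluster.regularized_covariance(
                scores[result.labels == j], result.centroids[j]
            )
            if np.any(result.labels == j)
            else np.eye(svd.k)
            for j in range(c)
        ]
    )
    det = cfg.detection
    model = SorterModel(
        V_k=svd.V_k, S_k_inv=svd.S_k_inv, k=svd.k,
        centroids=result.centroids, covariances=covs,
        m=cfg.m, c=c, sigma_noise=sigma, threshold=thr, fs=rec.fs,
        dead_time_ms=det.dead_time_ms, polarity=det.polarity,
        pre_ms=det.pre_ms, post_ms=det.post_ms,
        band=det.band if det.filter_signal else None,
        noise_quantile=cfg.noise_quantile,
        l_ratio_threshold=cfg.l_ratio_threshold,
    )
    return SortResult(
        waveforms=wm, svd=svd, scores=scores, histogram=hist, fcm=result,
        quality=quality, model=model, sigma_noise=sigma, threshold=thr,
    )


def train_prototype(rec: RawRecording, cfg: SortConfig | None = None) -> SorterModel:
    """Train the online prototype on a test-acquisition recording."""
    return sort_recording(rec, cfg).model


def _project(waveform24: np.ndarray, model: SorterModel) -> np.ndarray:
    w = np.asarray(waveform24, dtype=np.float64)
    if w.shape != (24,):
        raise ValueError(f"expected a 24-sample waveform, got shape {w.shape}")
    xc = w - w.mean()
    return xc @ model.V_k * model.S_k_inv


def classify_spike(waveform24: np.ndarray, model: SorterModel):
    """Label one aligned waveform against the frozen prototype.

    Returns ``(label, memberships)``; ``label`` is ``NOISE_LABEL`` when the
    Mahalanobis distance to the winning cluster exceeds the model's noise
    quantile (the spike does not statistically belong anywhere).
    """
    u_row = _project(waveform24, model)
    memberships = _cluster.fcm_memberships(u_row[None, :], model.centroids, model.m)[0]
    label = int(np.argmax(memberships))
    cut = chi2.ppf(model.noise_quantile, df=model.k)
    d2 = _cluster.mahalanobis_sq(
        u_row[None, :], model.centroids[label], model.covariances[label]
    )[0]
    if d2 > cut:
        label = NOISE_LABEL
    return label, memberships


def stream_classify(
    rec: RawRecording,
    model: SorterModel,
    buffer_size: int = 1000,
    recompute_every: int = 100,
):
    """Classify a recording spike-by-spike with drift monitoring.

    Detection reuses the model's frozen threshold.  Classified score
    vectors accumulate in a sliding buffer; every ``recompute_every``
    spikes the per-class L-ratio is recomputed over the buffer (with
    buffer-estimated means and covariances) and an alert record is logged
    for every class above the model's L-ratio threshold.  Returns
    ``(labeled, monitor)`` where ``labeled`` is a list of
    ``(time_s, label, membership_vector)`` and ``monitor`` a list of dict
    records.
    """
    if rec.fs != model.fs:
        raise ValueError(f"recording fs={rec.fs} does not match model fs={model.fs}")
    det = DetectionConfig(
        band=model.band if model.band is not None else (300.0, 5000.0),
        dead_time_ms=model.dead_time_ms,
        polarity=model.polarity,
        filter_signal=model.band is not None,
        pre_ms=model.pre_ms,
        post_ms=model.post_ms,
    )
    _, _, _, _, wm = _detect_and_extract(rec, det, threshold=model.threshold)

    labeled = []
    buf_scores: list = []
    buf_labels: list = []
    monitor = []
    for i in range(wm.n):
        label, memb = classify_spike(wm.A[i], model)
        t = float(wm.times[i])
        labeled.append((t, label, memb))
        buf_scores.append(_project(wm.A[i], model))
        buf_labels.append(label)
        if len(buf_scores) > buffer_size:
            buf_scores.pop(0)
            buf_labels.pop(0)
        if (i + 1) % recompute_every == 0:
            scores = np.array(buf_scores)
            labels = np.array(buf_labels)
            for j in range(model.c):
                n_j = int(np.sum(labels == j))
                if n_j <= model.k:  # covariance not estimable yet
                    continue
                lr = l_ratio(scores, labels, j, df=model.k)
                monitor.append(
                    {
                        "spike_index": i,
                        "time_s": t,
                        "cluster": j,
                        "l_ratio": lr,
                        "alarm": bool(lr > model.l_ratio_threshold),
                    }
                )
    return labeled, monitor
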