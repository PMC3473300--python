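"""Synthetic extracellular recordings with ground truth.

Emulates the classic simulated spike-sorting benchmark: a small set of
spike templates, each peak-normalized to 1, fired at random times on top of
background noise that is itself built from many superimposed, randomly
scaled and randomly timed spike waveforms (colored, spike-shaped noise —
not white Gaussian).  The noise amplitude is quoted as its standard
deviation relative to the unit spike peak, on the standard grid
0.05 / 0.1 / 0.15 / 0.2.  Two true spikes closer than 0.7 ms are flagged
as overlapping; those are the hardest cases for shape-based sorting and
are scored separately downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GroundTruthEvent, RawRecording

__all__ = [
    "TemplateSet",
    "SimConfig",
    "make_templates",
    "generate_background_noise",
    "generate_recording",
    "OVERLAP_LATENCY_S",
]

# two spikes closer than this are considered overlapping
OVERLAP_LATENCY_S = 0.7e-3


@dataclass
class TemplateSet:
    """Peak-normalized spike templates sampled at ``fs``."""

    templates: list  # list of 1-D ndarrays
    fs: float

    def __post_init__(self) -> None:
        self.templates = [np.asarray(t, dtype=np.float64) for t in self.templates]
        for i, t in enumerate(self.templates):
            peak = np.max(np.abs(t))
            if abs(peak - 1.0) > 1e-9:
                raise ValueError(f"template {i} peak is {peak}, expected 1")
        for i in range(len(self.templates)):
            for j in range(i + 1, len(self.templates)):
                d = normalized_rms_difference(self.templates[i], self.templates[j])
                if d <= 0.05:
                    raise ValueError(
                        f"templates {i} and {j} are near-duplicates (nRMSd={d:.3f})"
                    )

    @property
    def n_units(self) -> int:
        return len(self.templates)

    def peak_offset(self, unit: int) -> int:
        """Sample index of the template's (positive) peak."""
        return int(np.argmax(self.templates[unit]))


def normalized_rms_difference(a: np.ndarray, b: np.ndarray) -> float:
    """RMS of the pointwise difference, scaled by the templates' own RMS."""
    n = max(len(a), len(b))
    a = np.pad(a, (0, n - len(a)))
    b = np.pad(b, (0, n - len(b)))
    scale = np.sqrt(0.5 * (np.mean(a**2) + np.mean(b**2)))
    return float(np.sqrt(np.mean((a - b) ** 2)) / scale)


@dataclass
class SimConfig:
    """Conditions of one simulated recording.

    ``noise_level`` is the background standard deviation relative to the
    unit spike peak (which is fixed at 1).  ``amp_drift`` optionally scales
    unit spike amplitudes linearly from 1 at the start to ``1 + amp_drift``
    at the end of the recording (0 = stationary), for drift-monitor tests.
    """

    fs: float = 10_000.0
    duration: float = 60.0
    noise_level: float = 0.1
    firing_rate: float | tuple = 20.0   # scalar, or one rate per unit
    n_units: int = 3
    min_isi: float = 2.5e-3
    difficulty: str = "easy"
    template_ms: float = 1.5
    background_rate: float = 5000.0
    background_amp: tuple = (0.2, 1.0)
    background_shapes: int = 100
    amp_drift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_units < 2 or self.n_units > 6:
            raise ValueError("n_units must be between 2 and 6")
        for r in self.unit_rates():
            if r > 0 and 1.0 / r <= self.min_isi:
                raise ValueError("firing rate incompatible with the minimum same-unit ISI")

    def unit_rates(self) -> tuple:
        """Per-unit firing rates (a scalar rate applies to every unit)."""
        if np.isscalar(self.firing_rate):
            return (float(self.firing_rate),) * self.n_units
        rates = tuple(float(r) for r in self.firing_rate)
        if len(rates) != self.n_units:
            raise ValueError("need one firing rate per unit")
        return rates


def _gamma_lobe(t: np.ndarray, t_peak: float, p: float) -> np.ndarray:
    """Gamma-shaped lobe with unit peak at t = t_peak (t in ms, t >= 0)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (t / t_peak) ** p * np.exp(p * (1.0 - t / t_peak))
    return np.where(t > 0, out, 0.0)


# per-unit (t_peak1, p1, ahp_amp, t_peak2, p2) in ms; a sharp depolarizing
# lobe minus a slower after-wave.  "easy" shapes differ strongly in width
# and after-hyperpolarization (and span a ladder of total waveform energy,
# which is what radial cluster-count histograms can see); "hard" shapes are
# deliberately similar.
_EASY_PARAMS = [
    (0.12, 8.0, 0.15, 0.45, 10.0),
    (0.60, 3.0, 0.60, 1.20, 12.0),
    (0.30, 2.0, 1.00, 0.75, 2.5),
    (0.65, 3.0, 0.55, 1.30, 12.0),
    (0.15, 4.0, 0.75, 0.45, 6.0),
    (0.42, 1.5, 0.25, 0.90, 5.0),
]
_HARD_PARAMS = [
    (0.30, 3.0, 0.50, 0.80, 5.0),
    (0.34, 3.4, 0.55, 0.85, 5.5),
    (0.28, 2.8, 0.47, 0.77, 4.8),
    (0.31, 3.1, 0.60, 0.90, 5.2),
    (0.36, 3.6, 0.48, 0.78, 5.8),
    (0.25, 2.5, 0.52, 0.84, 4.4),
]


def make_templates(
    fs: float = 10_000.0,
    n_units: int = 3,
    difficulty: str = "easy",
    duration_ms: float = 1.5,
    params: list | None = None,
) -> TemplateSet:
    """Build ``n_units`` peak-normalized spike templates.

    ``difficulty`` selects parameter banks: "easy" shapes are clearly
    distinct (pairwise normalized RMS difference > 0.5), "hard" shapes are
    similar (< 0.3) and emulate the benchmark's difficult examples.
    Explicit ``params`` (list of 5-tuples) override the banks; requesting
    near-duplicate shapes raises.
    """
    n_samp = int(round(duration_ms * 1e-3 * fs))
    if n_samp < 6:
        raise ValueError(f"fs={fs} Hz too low to represent a {duration_ms} ms template")
    if params is None:
        bank = {"easy": _EASY_PARAMS, "hard": _HARD_PARAMS}.get(difficulty)
        if bank is None:
            raise ValueError(f"difficulty must be 'easy' or 'hard', got {difficulty!r}")
        if n_units > len(bank):
            raise ValueError(f"at most {len(bank)} units supported")
        params = bank[:n_units]
    t = np.arange(n_samp) / fs * 1e3  # ms
    templates = []
    for (tp1, p1, a2, tp2, p2) in params:
        w = _gamma_lobe(t, tp1, p1) - a2 * _gamma_lobe(t, tp2, p2)
        w = w / np.max(np.abs(w))
        templates.append(w)
    return TemplateSet(templates=templates, fs=fs)


def _random_shape_bank(
    rng: np.random.Generator, fs: float, n_shapes: int, duration_ms: float
) -> list:
    """A diverse 'database' of peak-normalized spike shapes for the noise.

    Parameters of the gamma-lobe family are drawn at random so that the
    background emulates spikes of many distant neurons, not copies of the
    signal units (which would concentrate noise variance exactly along the
    inter-class directions and make the benchmark unrealistically hard).
    """
    t = np.arange(int(round(duration_ms * 1e-3 * fs))) / fs * 1e3
    shapes = []
    for _ in range(n_shapes):
        tp1 = rng.uniform(0.1, 0.7)
        p1 = rng.uniform(1.0, 8.0)
        a2 = rng.uniform(0.05, 1.0)
        tp2 = rng.uniform(tp1 + 0.15, 1.3)
        p2 = rng.uniform(2.0, 12.0)
        w = _gamma_lobe(t, tp1, p1) - a2 * _gamma_lobe(t, tp2, p2)
        shapes.append(w / np.max(np.abs(w)))
    return shapes


def generate_background_noise(
    templates: TemplateSet, config: SimConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Colored background noise from superimposed random spikes.

    Draws ~``background_rate`` spikes per second at uniform random times,
    each a random shape from a seeded 100-shape database scaled by a
    uniform random amplitude, sums them, removes the mean, and rescales so
    the empirical standard deviation equals ``config.noise_level`` exactly.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = int(round(config.duration * config.fs))
    if n == 0:
        raise ValueError("zero-duration noise requested")
    if config.noise_level == 0:
        return np.zeros(n)
    bank = _random_shape_bank(rng, config.fs, config.background_shapes, config.template_ms)
    count = rng.poisson(config.background_rate * config.duration)
    pad = max(len(t) for t in bank)
    noise = np.zeros(n + pad)
    starts = rng.integers(0, n, size=count)
    which = rng.integers(0, len(bank), size=count)
    lo, hi = config.background_amp
    amps = rng.uniform(lo, hi, size=count)
    for s, w, a in zip(starts, which, amps):
        tpl = bank[w]
        noise[s : s + len(tpl)] += a * tpl
    noise = noise[:n]
    noise -= noise.mean()
    sd = noise.std()
    if sd > 0:
        noise *= config.noise_level / sd
    return noise


def _spike_train(
    rng: np.random.Generator, rate: float, min_isi: float, duration: float
) -> np.ndarray:
    """Poisson-like train with a hard minimum ISI, mean rate ≈ ``rate``."""
    if rate <= 0:
        return np.array([])
    mean_gap = 1.0 / rate - min_isi
    times = []
    t = rng.exponential(1.0 / rate)
    while t < duration:
        times.append(t)
        t += min_isi + rng.exponential(mean_gap)
    return np.array(times)


def generate_recording(config: SimConfig):
    """Simulate one recording; returns ``(RawRecording, truth_events)``.

    Each unit fires an independent train (hard refractory ``min_isi``);
    its template is added with the peak on an integer sample, so a truth
    event's time is exactly a sample time.  Overlap flags follow the
    0.7 ms nearest-other-spike rule.  Fully reproducible from the seed.
    """
    rng = np.random.default_rng(config.seed)
    templates = make_templates(config.fs, config.n_units, config.difficulty, config.template_ms)
    n = int(round(config.duration * config.fs))
    trace = generate_background_noise(templates, config, rng)

    events = []  # (peak_sample, unit)
    for unit, rate in enumerate(config.unit_rates()):
        for t in _spike_train(rng, rate, config.min_isi, config.duration):
            events.append((int(round(t * config.fs)), unit))
    events.sort()

    truth = []
    kept_times = []
    for peak_idx, unit in events:
        tpl = templates.templates[unit]
        off = templates.peak_offset(unit)
        start = peak_idx - off
        if start < 0 or start + len(tpl) > n:
            continue  # template would clip the trace edge
        t_s = peak_idx / config.fs
        amp = 1.0 + config.amp_drift * (t_s / config.duration)
        trace[start : start + len(tpl)] += amp * tpl
        truth.append((t_s, unit + 1))
        kept_times.append(t_s)

    kept_times = np.asarray(kept_times)
    out = []
    for i, (t_s, unit_id) in enumerate(truth):
        others = np.delete(kept_times, i)
        overlapping = bool(others.size and np.min(np.abs(others - t_s)) < OVERLAP_LATENCY_S)
        out.append(GroundTruthEvent(time_s=t_s, unit_id=unit_id, is_overlapping=overlapping))
    return RawRecording(samples=trace, fs=config.fs), out
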