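"""Synthetic multichannel EEG with known microstate ground truth.

The generator produces cohorts of recordings built as sequences of
quasi-stable topographies: a semi-Markov state sequence (gamma-distributed
dwell times, no self-transitions) selects one of K smooth unit-norm
templates at each sample; the template is amplitude-modulated by a rectified
band-limited carrier and embedded in spatially white noise at a prescribed
signal-to-noise power ratio. Condition effects (dwell-time multipliers,
extra carrier power in chosen bands) and between-subject jitter are applied
per recording, and the realized state sequence and its statistics are
emitted alongside every recording so downstream stages can be validated by
parameter recovery.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so identical specs give identical
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import signal as _signal

from .core import CONDITIONS, ElectrodeLayout, Recording


# --------------------------------------------------------------------------
# layout and templates
# --------------------------------------------------------------------------

def make_layout(n_channels: int, seed: int) -> ElectrodeLayout:
    """Quasi-uniform electrode positions on the unit disk (sunflower spiral
    plus a small seeded jitter), labeled E001..E{n}."""
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    rng = np.random.default_rng(seed)
    k = np.arange(1, n_channels + 1)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    r = 0.95 * np.sqrt((k - 0.5) / n_channels)
    theta = k * golden
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    pos += rng.normal(scale=0.01, size=pos.shape)
    radii = np.hypot(pos[:, 0], pos[:, 1])
    over = radii > 0.999
    if np.any(over):
        pos[over] *= (0.999 / radii[over])[:, None]
    labels = tuple(f"E{i:03d}" for i in k)
    return ElectrodeLayout(labels, pos)


def _poly_basis(pos: np.ndarray) -> np.ndarray:
    """Smooth spatial basis: polynomial terms of (x, y) up to degree 3."""
    x, y = pos[:, 0], pos[:, 1]
    cols = [x, y, x * y, x**2 - y**2, x**2 + y**2,
            x**3, y**3, x**2 * y, x * y**2]
    return np.column_stack(cols)


def _center_normalize(m: np.ndarray) -> np.ndarray:
    m = m - m.mean()
    n = np.linalg.norm(m)
    if n == 0:
        raise ValueError("degenerate (constant) topography")
    return m / n


def spatial_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation across channels of two topographies."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(a @ b / denom)


def make_templates(K: int, layout: ElectrodeLayout, seed: int,
                   max_abs_corr: float = 0.7) -> np.ndarray:
    """K zero-mean unit-norm topographies built from smooth low-order
    polynomials of electrode position, pairwise |r| < ``max_abs_corr``."""
    if K > layout.n_channels:
        raise ValueError("K cannot exceed the number of channels")
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    basis = _poly_basis(layout.positions)
    accepted: list[np.ndarray] = []
    attempts = 0
    while len(accepted) < K:
        attempts += 1
        if attempts > 200 * K:
            raise RuntimeError("could not generate sufficiently distinct templates")
        coef = rng.normal(size=basis.shape[1])
        cand = basis @ coef
        if np.allclose(cand, cand.mean()):
            continue
        cand = _center_normalize(cand)
        if attempts > 50 * K and accepted:
            # fall back to partial Gram-Schmidt to guarantee progress
            for a in accepted:
                cand = cand - (cand @ a) * a
            if np.linalg.norm(cand) < 1e-6:
                continue
            cand = _center_normalize(cand)
        if all(abs(spatial_correlation(cand, a)) < max_abs_corr for a in accepted):
            accepted.append(cand)
    return np.array(accepted)


# --------------------------------------------------------------------------
# spec and ground truth
# --------------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    """Parameters of a synthetic cohort.

    ``dwell_mean_ms`` maps condition -> per-class mean dwell (scalar or
    length-K sequence, ms). ``carrier_bands`` maps condition -> list of
    (low Hz, high Hz, relative amplitude) band-limited carriers.
    """

    n_subjects: int = 8
    conditions: tuple[str, ...] = CONDITIONS
    n_templates: int = 4
    n_channels: int = 60
    rate: float = 250.0
    duration_s: float = 180.0
    dwell_mean_ms: Mapping[str, object] = field(
        default_factory=lambda: {"wake": 80.0, "LOC": 120.0, "ROC": 90.0})
    dwell_shape: float = 2.0
    carrier_bands: Mapping[str, Sequence[tuple[float, float, float]]] = field(
        default_factory=lambda: {
            # high-band component keeps GFP peaks dense enough that
            # back-fitted durations track the true dwell times
            "wake": [(8.0, 15.0, 1.0), (1.0, 4.0, 0.5), (30.0, 45.0, 0.7)],
            "LOC": [(8.0, 15.0, 1.5), (1.0, 4.0, 2.0), (30.0, 45.0, 0.7)],
            "ROC": [(8.0, 15.0, 1.2), (1.0, 4.0, 1.0), (30.0, 45.0, 0.7)],
        })
    snr: float = 4.0
    between_subject_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_templates < 2:
            raise ValueError("need at least 2 templates")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.n_subjects < 1 or self.duration_s <= 0:
            raise ValueError("invalid cohort size or duration")
        for cond in self.conditions:
            if cond not in self.dwell_mean_ms:
                raise ValueError(f"no dwell mean for condition {cond!r}")
            means = np.atleast_1d(np.asarray(self.dwell_mean_ms[cond], dtype=float))
            if np.any(means <= 0):
                raise ValueError("dwell means must be positive")
            for low, high, amp in self.carrier_bands.get(cond, []):
                if not (0 < low < high):
                    raise ValueError("invalid carrier band")
                if self.rate <= 2 * high:
                    raise ValueError(
                        f"rate {self.rate} violates Nyquist for carrier ({low}, {high})")

    def dwell_means(self, condition: str) -> np.ndarray:
        means = np.atleast_1d(np.asarray(self.dwell_mean_ms[condition], dtype=float))
        if means.size == 1:
            means = np.full(self.n_templates, means[0])
        if means.size != self.n_templates:
            raise ValueError("dwell mean vector length must equal K")
        return means


@dataclass
class GroundTruth:
    """Realized generative state of one recording."""

    templates: np.ndarray          # (K, C) unit-norm
    state_sequence: np.ndarray     # (T,) int class indices
    dwell_mean_ms: np.ndarray      # (K,) realized mean dwell
    occurrence_per_s: np.ndarray   # (K,) realized segments per second
    coverage: np.ndarray           # (K,) realized fraction of samples


def _sequence_stats(labels: np.ndarray, rate: float, K: int):
    """Realized per-class dwell / occurrence / coverage of a label sequence."""
    boundaries = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [labels.size]])
    seg_labels = labels[starts]
    seg_lens = ends - starts
    dwell = np.full(K, np.nan)
    occ = np.zeros(K)
    cov = np.zeros(K)
    total_s = labels.size / rate
    for k in range(K):
        mask = seg_labels == k
        if mask.any():
            dwell[k] = seg_lens[mask].mean() / rate * 1000.0
            occ[k] = mask.sum() / total_s
            cov[k] = seg_lens[mask].sum() / labels.size
    return dwell, occ, cov


def sample_state_sequence(spec: SyntheticSpec, condition: str,
                          seed: int,
                          dwell_means_ms: Optional[np.ndarray] = None) -> np.ndarray:
    """Semi-Markov label sequence: gamma dwell times (shape ``dwell_shape``,
    per-class means), uniform next-state law without self-transitions."""
    rng = np.random.default_rng(seed)
    K = spec.n_templates
    means = (np.asarray(dwell_means_ms, dtype=float)
             if dwell_means_ms is not None else spec.dwell_means(condition))
    n_total = int(round(spec.duration_s * spec.rate))
    labels = np.empty(n_total, dtype=np.int64)
    pos = 0
    state = int(rng.integers(K))
    while pos < n_total:
        scale = means[state] / spec.dwell_shape
        dwell_ms = rng.gamma(spec.dwell_shape, scale)
        n = max(1, int(round(dwell_ms / 1000.0 * spec.rate)))
        n = min(n, n_total - pos)
        labels[pos:pos + n] = state
        pos += n
        if K == 2:
            state = 1 - state
        else:
            step = int(rng.integers(K - 1))
            state = step if step < state else step + 1
    return labels


def _band_carrier(n: int, rate: float, low: float, high: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Rectified envelope of band-filtered Gaussian noise, unit mean power."""
    if rate <= 2 * high:
        raise ValueError(f"rate {rate} violates Nyquist for band ({low}, {high})")
    white = rng.standard_normal(n)
    sos = _signal.butter(4, [low / (rate / 2), high / (rate / 2)],
                         btype="bandpass", output="sos")
    carrier = np.abs(_signal.sosfiltfilt(sos, white))
    rms = np.sqrt(np.mean(carrier**2))
    return carrier / rms if rms > 0 else carrier


def synthesize_recording(spec: SyntheticSpec, labels: np.ndarray,
                         templates: np.ndarray, seed: int,
                         condition: str = "wake",
                         layout: Optional[ElectrodeLayout] = None,
                         subject: str = "") -> Recording:
    """Forward model: signal(t) = a(t) * template[label(t)] + white noise.

    ``a(t)`` sums the condition's rectified band-limited carriers; noise
    power is set from ``spec.snr``; the output is average-referenced.
    """
    rng = np.random.default_rng(seed)
    n = labels.size
    if layout is None:
        layout = make_layout(templates.shape[1], spec.seed)
    bands = spec.carrier_bands.get(condition, [(8.0, 15.0, 1.0)])
    envelope = np.zeros(n)
    for low, high, amp in bands:
        envelope += amp * _band_carrier(n, spec.rate, low, high, rng)
    source = templates[labels] * envelope[:, None]   # (T, C)
    sig_power = float(np.mean(source**2))
    data = source.T.copy()
    if np.isfinite(spec.snr):
        noise_sd = np.sqrt(sig_power / spec.snr)
        data = data + rng.normal(scale=noise_sd, size=data.shape)
    data -= data.mean(axis=0, keepdims=True)
    return Recording(data=data, rate=spec.rate, layout=layout,
                     subject=subject, condition=condition)


def generate_cohort(spec: SyntheticSpec,
                    layout: Optional[ElectrodeLayout] = None,
                    templates: Optional[np.ndarray] = None):
    """Generate all subject x condition recordings plus per-recording ground
    truth. Returns (recordings, truths) keyed by ``(subject, condition)``."""
    root = np.random.SeedSequence(spec.seed)
    layout_seed, template_seed, *subject_seeds = [
        s.generate_state(1)[0] for s in root.spawn(2 + spec.n_subjects)]
    if layout is None:
        layout = make_layout(spec.n_channels, int(layout_seed))
    if templates is None:
        templates = make_templates(spec.n_templates, layout, int(template_seed))
    elif templates.shape != (spec.n_templates, layout.n_channels):
        raise ValueError("templates shape must be (K, n_channels)")
    recordings: dict[tuple[str, str], Recording] = {}
    truths: dict[tuple[str, str], GroundTruth] = {}
    for si in range(spec.n_subjects):
        subject = f"S{si + 1:02d}"
        srng = np.random.default_rng(int(subject_seeds[si]))
        jitter = srng.normal(1.0, spec.between_subject_sd, size=spec.n_templates)
        jitter = np.clip(jitter, 0.2, None)
        for ci, cond in enumerate(spec.conditions):
            means = spec.dwell_means(cond) * jitter
            seq_seed = int(srng.integers(2**63))
            rec_seed = int(srng.integers(2**63))
            labels = sample_state_sequence(spec, cond, seq_seed, means)
            rec = synthesize_recording(spec, labels, templates, rec_seed,
                                       condition=cond, layout=layout,
                                       subject=subject)
            dwell, occ, cov = _sequence_stats(labels, spec.rate, spec.n_templates)
            recordings[(subject, cond)] = rec
            truths[(subject, cond)] = GroundTruth(
                templates=templates, state_sequence=labels,
                dwell_mean_ms=dwell, occurrence_per_s=occ, coverage=cov)
    return recordings, truths
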