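"""Map averaging, template sorting, back-fitting, and temporal metrics.

Individual models are averaged into condition-level and grand-mean models
with polarity alignment, sorted against a canonical labeled template set by
optimal assignment, and back-fitted to continuous data: GFP peaks get the
label of the best-|correlation| map and labels switch halfway between
successive peaks. Segments truncated at epoch edges are excluded from
duration, occurrence, and coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .core import ElectrodeLayout, Recording
from .microstates import (MicrostateModel, _assign, _demean, _unit,
                          compute_gfp, detect_peaks_from_values)
from .synthetic import spatial_correlation

UNASSIGNED = -1

CANONICAL_LABELS = ("A", "B", "C", "D", "E", "F", "G")


@dataclass
class CanonicalTemplateSet:
    """Labeled reference topographies on a given layout.

    The maps are analytic stand-ins constructed from the usual verbal
    descriptions of the seven canonical classes (diagonal gradients A/B,
    anterior-posterior C, fronto-central maximum D, left-right E,
    occipito-central maximum F, central-posterior maximum G).
    """

    labels: tuple[str, ...]
    maps: np.ndarray  # (n_templates, C) zero-mean unit-norm
    layout: ElectrodeLayout


def canonical_templates(layout: ElectrodeLayout) -> CanonicalTemplateSet:
    pos = layout.positions
    x, y = pos[:, 0], pos[:, 1]

    def bump(cx: float, cy: float, s: float) -> np.ndarray:
        return np.exp(-(((x - cx)**2 + (y - cy)**2) / (2 * s**2)))

    raw = np.array([
        x + y,                    # A: left-posterior -> right-frontal
        -x + y,                   # B: right-posterior -> left-frontal
        y,                        # C: anterior-posterior
        bump(0.0, 0.45, 0.40),    # D: fronto-central maximum
        x,                        # E: left-right
        bump(0.0, -0.60, 0.35),   # F: occipito-central maximum
        bump(0.0, -0.10, 0.65),   # G: central-posterior maximum
    ])
    maps = _unit(_demean(raw))
    return CanonicalTemplateSet(labels=CANONICAL_LABELS, maps=maps,
                                layout=layout)


@dataclass
class LabelSequence:
    labels: np.ndarray           # (T,) class index or UNASSIGNED
    rate: float
    band: Optional[str] = None
    class_names: tuple[str, ...] = ()
    segments: list = field(default_factory=list)  # (class, start, end, truncated)


@dataclass
class MicrostateMetrics:
    """Per-class temporal statistics of a label sequence."""

    class_names: tuple[str, ...]
    duration_ms: np.ndarray      # NaN when the class never occurs
    occurrence_per_s: np.ndarray
    coverage: np.ndarray
    iev: Optional[np.ndarray] = None

    def to_frame(self, subject: str = "", condition: str = "",
                 band: str = "") -> pd.DataFrame:
        rows = []
        for i, name in enumerate(self.class_names):
            rows.append({
                "subject": subject, "condition": condition, "band": band,
                "class": name, "duration_ms": self.duration_ms[i],
                "occurrence": self.occurrence_per_s[i],
                "coverage": self.coverage[i],
                "iev": (self.iev[i] if self.iev is not None else np.nan),
            })
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# map averaging and sorting
# --------------------------------------------------------------------------

def mean_maps(models: Sequence[MicrostateModel], level: str = "condition") -> MicrostateModel:
    """Polarity-aligned per-class average of sorted models.

    Each contributing map is sign-flipped to correlate positively with the
    running average before accumulation; the result is re-normalized.
    Requires all models to share K and channel count (classes must already
    correspond by prior sorting).
    """
    if not models:
        raise ValueError("no models to average")
    K = models[0].K
    C = models[0].n_channels
    for m in models:
        if m.K != K or m.n_channels != C:
            raise ValueError("models disagree in K or channel count")
    out = np.zeros((K, C))
    for k in range(K):
        ref = models[0].maps[k]
        acc = np.zeros(C)
        for m in models:
            v = m.maps[k]
            acc += v if v @ ref >= 0 else -v
        out[k] = acc
    out = _unit(_demean(out))
    return MicrostateModel(maps=out, level=level, band=models[0].band,
                           labels=models[0].labels)


def sort_by_template(model: MicrostateModel,
                     templates: CanonicalTemplateSet) -> tuple[MicrostateModel, np.ndarray]:
    """Optimal one-to-one relabeling of model classes to template labels.

    Maximizes the summed |spatial correlation| (Hungarian algorithm); each
    map's sign is set so its correlation with the assigned template is
    positive. Returns the relabeled model and the per-class correlations
    (in output class order).
    """
    if model.K > templates.maps.shape[0]:
        raise ValueError("model has more classes than the template set")
    if model.n_channels != templates.maps.shape[1]:
        raise ValueError("model and template layouts differ in channel count")
    corr = model.maps @ templates.maps.T  # unit-norm zero-mean both sides
    rows, cols = linear_sum_assignment(-np.abs(corr))
    order = np.argsort(cols)
    new_maps = np.empty_like(model.maps)
    new_corr = np.empty(model.K)
    new_labels = []
    for out_idx, (r, c) in enumerate(zip(rows[order], cols[order])):
        sign = 1.0 if corr[r, c] >= 0 else -1.0
        new_maps[out_idx] = sign * model.maps[r]
        new_corr[out_idx] = abs(corr[r, c])
        new_labels.append(templates.labels[c])
    sorted_model = MicrostateModel(
        maps=new_maps, gev_total=model.gev_total,
        ev_per_class=model.ev_per_class, cv_value=model.cv_value,
        band=model.band, level=model.level, labels=tuple(new_labels))
    return sorted_model, new_corr


def sort_to_model(model: MicrostateModel,
                  reference: MicrostateModel) -> tuple[MicrostateModel, np.ndarray]:
    """Sort a model against another model's maps (e.g. the grand mean)."""
    ref_set = CanonicalTemplateSet(
        labels=reference.labels or tuple(str(i) for i in range(reference.K)),
        maps=reference.maps, layout=None)
    return sort_by_template(model, ref_set)


# --------------------------------------------------------------------------
# back-fitting
# --------------------------------------------------------------------------

def backfit(recording: Recording, model: MicrostateModel) -> LabelSequence:
    """Label continuous data from GFP-peak assignments with midpoint
    interpolation.

    Each GFP peak gets the class with maximal |spatial correlation|; between
    consecutive peaks the label switches after the midpoint sample (the
    earlier half, midpoint included, keeps the left peak's label). Samples
    before the first and after the last peak are UNASSIGNED; the first and
    last remaining segments are flagged truncated.
    """
    data = recording.data - recording.data.mean(axis=0, keepdims=True)
    gfp = data.std(axis=0, ddof=0)
    peaks = detect_peaks_from_values(gfp)
    T = data.shape[1]
    labels = np.full(T, UNASSIGNED, dtype=np.int64)
    if peaks.size == 0:
        import warnings
        warnings.warn("no GFP peaks found; empty label sequence")
        return LabelSequence(labels=labels, rate=recording.rate,
                             band=recording.band,
                             class_names=model.labels, segments=[])
    peak_maps = _unit(_demean(data[:, peaks].T))
    peak_labels = _assign(peak_maps, model.maps)
    # midpoint interpolation: boundary sample (p_i + p_{i+1}) // 2 belongs
    # to the left peak's segment
    starts = np.empty(peaks.size, dtype=np.int64)
    ends = np.empty(peaks.size, dtype=np.int64)
    starts[0] = peaks[0]
    for i in range(peaks.size - 1):
        mid = (peaks[i] + peaks[i + 1]) // 2
        ends[i] = mid + 1          # exclusive
        starts[i + 1] = mid + 1
    ends[-1] = peaks[-1] + 1
    for s, e, lab in zip(starts, ends, peak_labels):
        labels[s:e] = lab
    segments = _segment_runs(labels, recording.rate)
    return LabelSequence(labels=labels, rate=recording.rate,
                         band=recording.band, class_names=model.labels,
                         segments=segments)


def _segment_runs(labels: np.ndarray, rate: float) -> list:
    """Run-length encode the labeled span; first/last runs are truncated."""
    assigned = labels != UNASSIGNED
    if not assigned.any():
        return []
    first = int(np.argmax(assigned))
    last = int(len(labels) - np.argmax(assigned[::-1]))  # exclusive
    span = labels[first:last]
    boundaries = np.flatnonzero(np.diff(span)) + 1
    starts = np.concatenate([[0], boundaries]) + first
    ends = np.concatenate([boundaries, [span.size]]) + first
    segs = []
    for i, (s, e) in enumerate(zip(starts, ends)):
        truncated = (i == 0) or (i == len(starts) - 1)
        segs.append((int(labels[s]), int(s), int(e), truncated))
    return segs


def compute_metrics(seq: LabelSequence, n_classes: Optional[int] = None) -> MicrostateMetrics:
    """Duration / occurrence / coverage with truncated segments excluded
    from all three statistics (numerator and denominator)."""
    if n_classes is None:
        n_classes = len(seq.class_names) if seq.class_names else int(seq.labels.max()) + 1
    kept = [(c, e - s) for c, s, e, trunc in seq.segments if not trunc]
    names = seq.class_names or tuple(str(i) for i in range(n_classes))
    duration = np.full(n_classes, np.nan)
    occurrence = np.zeros(n_classes)
    coverage = np.zeros(n_classes)
    if kept:
        total_samples = sum(n for _, n in kept)
        total_s = total_samples / seq.rate
        for k in range(n_classes):
            lens = [n for c, n in kept if c == k]
            if lens:
                duration[k] = np.mean(lens) / seq.rate * 1000.0
                occurrence[k] = len(lens) / total_s
                coverage[k] = sum(lens) / total_samples
    return MicrostateMetrics(class_names=names, duration_ms=duration,
                             occurrence_per_s=occurrence, coverage=coverage)


def compute_iev(recording: Recording, model: MicrostateModel,
                seq: Optional[LabelSequence] = None) -> np.ndarray:
    """Per-class partition of GEV over GFP-peak samples.

    IEV_k = sum over class-k peaks of GFP² r² / sum over all peaks of GFP²,
    so the classes partition the total GEV exactly.
    """
    data = recording.data - recording.data.mean(axis=0, keepdims=True)
    gfp = data.std(axis=0, ddof=0)
    peaks = detect_peaks_from_values(gfp)
    if peaks.size == 0:
        raise ValueError("no GFP peaks")
    v = _demean(data[:, peaks].T)
    vu = _unit(v)
    if seq is not None and seq.labels.size == recording.n_samples:
        assignment = seq.labels[peaks]
    else:
        assignment = _assign(vu, model.maps)
    g2 = gfp[peaks]**2
    denom = g2.sum()
    if denom == 0:
        raise FloatingPointError("all-zero GFP at peaks")
    r = np.einsum("tc,tc->t", vu, model.maps[np.clip(assignment, 0, None)])
    contrib = g2 * r**2
    iev = np.array([contrib[assignment == k].sum() for k in range(model.K)])
    return iev / denom


def metrics_with_iev(recording: Recording, model: MicrostateModel,
                     seq: LabelSequence) -> MicrostateMetrics:
    m = compute_metrics(seq, n_classes=model.K)
    m.iev = compute_iev(recording, model, seq)
    return m
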