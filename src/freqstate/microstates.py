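"""Polarity-invariant topographic clustering of GFP-peak maps.

GFP is the spatial (population) standard deviation of the average-referenced
potential at each sample. Topographies at GFP local maxima are clustered
with a modified k-means in which assignment maximizes squared spatial
correlation (so map polarity is ignored) and each centroid update takes the
dominant eigenvector of the assigned maps' outer-product sum. Model quality
is summarized by the GFP²-weighted global explained variance (GEV) and a
predictive-residual cross-validation criterion that penalizes model size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import Recording


@dataclass
class GfpSeries:
    values: np.ndarray
    peak_indices: np.ndarray


@dataclass
class MicrostateModel:
    """K unit-norm, zero-mean, polarity-free topographies with fit stats."""

    maps: np.ndarray                 # (K, C)
    gev_total: float = np.nan
    ev_per_class: np.ndarray = field(default_factory=lambda: np.array([]))
    cv_value: float = np.nan
    band: Optional[str] = None
    level: str = "individual"
    labels: tuple[str, ...] = ()     # class names after template sorting

    @property
    def K(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


@dataclass
class KScanResult:
    ks: np.ndarray
    gev: np.ndarray
    cv: np.ndarray
    chosen_k: int
    models: dict


def compute_gfp(recording: Recording) -> GfpSeries:
    """GFP(t): population SD (divisor C) over channels at each sample."""
    if recording.n_channels < 2:
        raise ValueError("GFP needs at least 2 channels")
    values = recording.data.std(axis=0, ddof=0)
    peaks = detect_peaks_from_values(values)
    return GfpSeries(values=values, peak_indices=peaks)


def detect_peaks_from_values(values: np.ndarray) -> np.ndarray:
    """Strict-rise local maxima; plateaus yield their first sample. No
    height or minimum-distance thresholds."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        return np.array([], dtype=np.int64)
    rising = v[1:-1] > v[:-2]
    not_falling = v[1:-1] >= v[2:]
    return np.flatnonzero(rising & not_falling) + 1


def detect_peaks(gfp: GfpSeries) -> np.ndarray:
    return detect_peaks_from_values(gfp.values)


def _demean(maps: np.ndarray) -> np.ndarray:
    return maps - maps.mean(axis=1, keepdims=True)


def _unit(maps: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(maps, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return maps / norms


def _assign(maps_unit: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Class index per map by maximum squared correlation; ties -> lowest
    class index (argmax convention)."""
    corr = maps_unit @ centroids.T
    return np.argmax(corr**2, axis=1)


def _dominant_eigvec(maps: np.ndarray) -> np.ndarray:
    s = maps.T @ maps
    w, v = np.linalg.eigh(s)
    vec = v[:, -1]
    vec = vec - vec.mean()
    n = np.linalg.norm(vec)
    return vec / n if n > 0 else vec


def gev_for_assignment(peak_maps: np.ndarray, centroids: np.ndarray,
                       assignment: np.ndarray) -> float:
    """GFP²-weighted explained variance of an explicit assignment.

    For average-referenced maps this reduces to
    sum_t (a_{L(t)} · v_t)² / sum_t ||v_t||².
    """
    v = _demean(np.asarray(peak_maps, dtype=float))
    proj = np.einsum("tc,tc->t", v, centroids[assignment])
    denom = np.sum(v**2)
    if denom == 0:
        raise FloatingPointError("all-zero peak maps")
    return float(np.sum(proj**2) / denom)


def _polish_assignment(raw: np.ndarray, assignment: np.ndarray, K: int,
                       max_passes: int = 20) -> tuple[np.ndarray, np.ndarray, float]:
    """Greedy single-move refinement: move one map to another class whenever
    that raises GEV, until no single move improves. Quadratic in the number
    of maps, so only used on small instances."""
    a = assignment.copy()
    T = raw.shape[0]

    def centroids_of(a):
        cents = np.zeros((K, raw.shape[1]))
        for k in range(K):
            members = raw[a == k]
            if members.shape[0]:
                cents[k] = _dominant_eigvec(members)
        return cents

    cents = centroids_of(a)
    best = gev_for_assignment(raw, cents, a)
    for _ in range(max_passes):
        improved = False
        for t in range(T):
            old = a[t]
            if np.sum(a == old) == 1:
                continue  # never empty a class
            for k in range(K):
                if k == old:
                    continue
                a[t] = k
                cand_cents = centroids_of(a)
                cand = gev_for_assignment(raw, cand_cents, a)
                if cand > best + 1e-15:
                    best, cents = cand, cand_cents
                    old = k
                    improved = True
                else:
                    a[t] = old
        if not improved:
            break
    return a, cents, best


def modified_kmeans(peak_maps: np.ndarray, K: int, n_restarts: int = 20,
                    max_iter: int = 300, tol: float = 1e-7,
                    seed: int = 0, polish: Optional[bool] = None) -> MicrostateModel:
    """Best-of-restarts polarity-invariant k-means on GFP-peak maps.

    Assignment uses the maximum squared spatial correlation (polarity-free;
    identical whether maps are normalized or not); the centroid update takes
    the dominant eigenvector of the assigned raw maps' outer-product sum, so
    each sweep monotonically increases the GFP²-weighted explained variance
    and the converged solution is a local GEV optimum. Returned centroids
    are zero-mean unit-norm topographies. Empty clusters are re-seeded from
    the worst-fit map.
    """
    raw = _demean(np.asarray(peak_maps, dtype=float))
    T = raw.shape[0]
    if K > T:
        raise ValueError(f"K={K} exceeds number of peak maps ({T})")
    if K < 1:
        raise ValueError("K must be >= 1")
    maps_unit = _unit(raw)

    if K == 1:
        centroid = _dominant_eigvec(raw)[None, :]
        assignment = np.zeros(T, dtype=np.int64)
        gev = gev_for_assignment(raw, centroid, assignment)
        model = MicrostateModel(maps=centroid, gev_total=gev,
                                ev_per_class=np.array([gev]))
        model.cv_value = cv_criterion(model, raw, assignment)
        return model

    best_gev = -np.inf
    best: Optional[tuple[np.ndarray, np.ndarray]] = None
    for restart in range(n_restarts):
        rng = np.random.default_rng(seed + restart)
        # ++-style seeding: residual-weighted draws reach small basins far
        # more reliably than uniform K-subsets
        idx = [int(rng.integers(T))]
        while len(idx) < K:
            corr2 = (maps_unit @ maps_unit[idx].T)**2
            resid = np.clip(1.0 - corr2.max(axis=1), 0.0, None) * np.sum(raw**2, axis=1)
            resid[idx] = 0.0
            total = resid.sum()
            if total <= 0:
                choices = [t for t in range(T) if t not in idx]
                idx.append(int(rng.choice(choices)))
            else:
                idx.append(int(rng.choice(T, p=resid / total)))
        centroids = maps_unit[idx].copy()
        prev_gev = -np.inf
        assignment = _assign(maps_unit, centroids)
        for _ in range(max_iter):
            for k in range(K):
                members = raw[assignment == k]
                if members.shape[0] == 0:
                    # re-seed from the worst-fit map
                    fit = np.max((maps_unit @ centroids.T)**2, axis=1)
                    centroids[k] = maps_unit[np.argmin(fit)]
                else:
                    centroids[k] = _dominant_eigvec(members)
            new_assignment = _assign(maps_unit, centroids)
            gev = gev_for_assignment(raw, centroids, new_assignment)
            converged = (np.array_equal(new_assignment, assignment)
                         or (prev_gev > -np.inf
                             and abs(gev - prev_gev) <= tol * max(prev_gev, 1e-300)))
            assignment = new_assignment
            if converged:
                break
            prev_gev = gev
        gev = gev_for_assignment(raw, centroids, assignment)
        if polish or (polish is None and T <= 32):
            assignment, centroids, gev = _polish_assignment(raw, assignment, K)
        if gev > best_gev:
            best_gev = gev
            best = (centroids.copy(), assignment.copy())

    centroids, assignment = best
    model = MicrostateModel(maps=centroids, gev_total=best_gev)
    _, ev = compute_gev(model, raw, assignment=assignment)
    model.ev_per_class = ev
    model.gev_total = float(ev.sum())
    model.cv_value = cv_criterion(model, raw, assignment)
    return model


def compute_gev(model: MicrostateModel, peak_maps: np.ndarray,
                gfp_at_peaks: Optional[np.ndarray] = None,
                assignment: Optional[np.ndarray] = None):
    """(gev_total, ev_per_class): GFP²-weighted r² under the assigned class.

    GEV = sum_t GFP_t² r²(a_{L(t)}, v_t) / sum_t GFP_t², with r the spatial
    Pearson correlation and L(t) the max-|r| assignment unless given.
    """
    v = _demean(np.asarray(peak_maps, dtype=float))
    C = v.shape[1]
    vu = _unit(v)
    if assignment is None:
        assignment = _assign(vu, model.maps)
    if gfp_at_peaks is None:
        gfp = np.linalg.norm(v, axis=1) / np.sqrt(C)
    else:
        gfp = np.asarray(gfp_at_peaks, dtype=float)
    denom = np.sum(gfp**2)
    if denom == 0:
        raise FloatingPointError("all-zero GFP at peaks")
    r = np.einsum("tc,tc->t", vu, model.maps[assignment])
    contrib = gfp**2 * r**2
    ev = np.array([contrib[assignment == k].sum() for k in range(model.K)]) / denom
    return float(ev.sum()), ev


def cv_criterion(model: MicrostateModel, peak_maps: np.ndarray,
                 assignment: Optional[np.ndarray] = None) -> float:
    """Predictive-residual criterion:

    CV = sigma² * ((C-1)/(C-1-K))², with
    sigma² = sum_t (v_t'v_t - (a_{L(t)}'v_t)²) / (T (C-1)).
    """
    v = _demean(np.asarray(peak_maps, dtype=float))
    T, C = v.shape
    if model.K >= C - 1:
        raise ValueError(f"CV criterion requires K < C-1 (K={model.K}, C={C})")
    if assignment is None:
        assignment = _assign(_unit(v), model.maps)
    proj = np.einsum("tc,tc->t", v, model.maps[assignment])
    resid = np.sum(v**2) - np.sum(proj**2)
    sigma2 = resid / (T * (C - 1))
    factor = ((C - 1) / (C - 1 - model.K))**2
    return float(sigma2 * factor)


def scan_k(peak_maps: np.ndarray, k_range=range(2, 9), n_restarts: int = 20,
           max_iter: int = 300, tol: float = 1e-7, seed: int = 0,
           fixed_k: Optional[int] = 7, select: str = "fixed") -> KScanResult:
    """Fit models for each k and choose one: ``select='fixed'`` returns
    ``fixed_k``; ``'elbow'`` maximizes the second difference of GEV."""
    ks = np.array(list(k_range))
    models = {}
    gev = np.empty(ks.size)
    cv = np.empty(ks.size)
    for i, k in enumerate(ks):
        m = modified_kmeans(peak_maps, int(k), n_restarts=n_restarts,
                            max_iter=max_iter, tol=tol, seed=seed)
        models[int(k)] = m
        gev[i] = m.gev_total
        cv[i] = m.cv_value
    if select == "fixed":
        if fixed_k is None or int(fixed_k) not in models:
            raise ValueError("fixed_k must lie inside k_range")
        chosen = int(fixed_k)
    elif select == "elbow":
        if ks.size < 3:
            chosen = int(ks[-1])
        else:
            second_diff = gev[:-2] - 2 * gev[1:-1] + gev[2:]
            chosen = int(ks[1:-1][np.argmin(second_diff)])
    else:
        raise ValueError("select must be 'fixed' or 'elbow'")
    return KScanResult(ks=ks, gev=gev, cv=cv, chosen_k=chosen, models=models)
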