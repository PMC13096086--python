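"""Consciousness-state classification from microstate feature tables.

Features are per subject x condition rows named ``band.class.param`` with
param in {duration, occurrence, coverage, ev}. A hybrid selector combines
diagonal neighborhood component analysis (NCA) weights with greedy
minimum-redundancy-maximum-relevance (MRMR) scores: both are min-max
normalized, summed, and the top-10 composite features feed a linear SVM or
a 100-tree random forest evaluated by leave-one-out or stratified 5-fold
cross-validation with per-fold standardization (and, by default, per-fold
feature selection).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (accuracy_score, confusion_matrix, f1_score,
                             roc_auc_score)
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.svm import SVC

PARAMS = ("duration", "occurrence", "coverage", "ev")


# --------------------------------------------------------------------------
# feature assembly
# --------------------------------------------------------------------------

def build_features(metrics: pd.DataFrame, bands: Sequence[str]) -> pd.DataFrame:
    """Wide table: one row per subject x condition, columns band.class.param.

    ``metrics`` is tidy with columns subject, condition, band, class,
    duration_ms, occurrence, coverage, iev. Missing classes are imputed as
    0 for occurrence/coverage/ev; an absent duration (class never seen)
    also becomes 0.
    """
    df = metrics[metrics["band"].isin(bands)].copy()
    if df.empty:
        raise ValueError(f"no rows for bands {list(bands)}")
    col_of = {"duration": "duration_ms", "occurrence": "occurrence",
              "coverage": "coverage", "ev": "iev"}
    classes = sorted(df["class"].unique())
    rows = {}
    for (subject, condition), grp in df.groupby(["subject", "condition"]):
        feats = {}
        grp = grp.set_index(["band", "class"])
        for band in bands:
            for cls in classes:
                for param in PARAMS:
                    key = f"{band}.{cls}.{param}"
                    try:
                        val = grp.loc[(band, cls), col_of[param]]
                    except KeyError:
                        val = 0.0
                    feats[key] = 0.0 if pd.isna(val) else float(val)
        rows[(subject, condition)] = feats
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index = pd.MultiIndex.from_tuples(out.index, names=["subject", "condition"])
    expected = [f"{b}.{c}.{p}" for b in bands for c in classes for p in PARAMS]
    return out[expected]


@dataclass
class Standardizer:
    """Column-wise z-scoring fit on training rows only; zero-SD columns are
    centered and left unscaled."""

    mean_: Optional[np.ndarray] = None
    scale_: Optional[np.ndarray] = None
    degenerate_: Optional[np.ndarray] = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self.degenerate_ = sd == 0
        sd = np.where(self.degenerate_, 1.0, sd)
        self.scale_ = sd
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) * self.scale_ + self.mean_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


# --------------------------------------------------------------------------
# NCA
# --------------------------------------------------------------------------

def nca_weights(X: np.ndarray, y: np.ndarray, regularization: float = 1.0,
                seed: int = 0, max_iter: int = 200) -> np.ndarray:
    """Diagonal NCA feature importances (squared learned weights).

    Maximizes the expected leave-one-out accuracy of a softmax
    nearest-neighbor classifier under a per-feature weighted squared
    distance, minus an L2 penalty on the weights. The default penalty of 1
    on the summed objective matches the usual 1/n default on the per-sample
    mean objective at n around 60. Deterministic: starts from w = 1 (the
    seed only matters if an optimizer restart is needed).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    diff2 = (X[:, None, :] - X[None, :, :])**2      # (n, n, p)
    same = (y[:, None] == y[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)
    eye = np.eye(n, dtype=bool)

    def neg_obj_grad(w):
        w2 = w**2
        d = diff2 @ w2                               # (n, n)
        d[eye] = np.inf
        dmin = d.min(axis=1, keepdims=True)
        dmin[~np.isfinite(dmin)] = 0.0
        ex = np.exp(-(d - dmin))
        ex[eye] = 0.0
        z = ex.sum(axis=1, keepdims=True)
        z[z == 0] = 1.0
        pij = ex / z                                  # (n, n)
        pi = (pij * same).sum(axis=1)                 # (n,)
        # gradient wrt w_f of sum_i p_i
        g = 2.0 * w * (
            np.einsum("i,ij,ijf->f", pi, pij, diff2)
            - np.einsum("ij,ijf->f", pij * same, diff2)
        )
        obj = pi.sum() - regularization * np.sum(w2)
        grad = g - 2.0 * regularization * w
        return -obj, -grad

    w0 = np.ones(p)
    res = minimize(neg_obj_grad, w0, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter})
    w = res.x
    return w**2


# --------------------------------------------------------------------------
# MRMR
# --------------------------------------------------------------------------

def _discretize(col: np.ndarray, n_bins: int = 10) -> np.ndarray:
    qs = np.quantile(col, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.digitize(col, np.unique(qs))


def _mi(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information (nats) of two small integer arrays via a
    bincount contingency table; equivalent to sklearn's mutual_info_score
    but much faster in the greedy MRMR loop."""
    na, nb = a.max() + 1, b.max() + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb)
    joint = joint / joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])))


def mrmr_scores(X: np.ndarray, y: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Greedy MID-scheme MRMR: per-feature score at selection time.

    Features are discretized into equal-frequency bins; the first pick
    maximizes MI(f; y), later picks maximize MI(f; y) minus the mean MI
    with already-selected features. Every feature receives the score it had
    when selected, so the ranking is recoverable from the scores.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    disc = np.column_stack([_discretize(X[:, f], n_bins) for f in range(p)])
    _, y_codes = np.unique(y, return_inverse=True)
    relevance = np.array([_mi(disc[:, f], y_codes) for f in range(p)])
    scores = np.full(p, np.nan)
    selected: list[int] = []
    remaining = list(range(p))
    red_cache = np.zeros(p)
    while remaining:
        if not selected:
            cand_scores = relevance[remaining]
        else:
            cand_scores = np.array([
                relevance[f] - red_cache[f] / len(selected) for f in remaining])
        best_pos = int(np.argmax(cand_scores))
        f = remaining.pop(best_pos)
        scores[f] = float(cand_scores[best_pos])
        selected.append(f)
        for g in remaining:
            red_cache[g] += _mi(disc[:, f], disc[:, g])
    return scores


# --------------------------------------------------------------------------
# composite selection
# --------------------------------------------------------------------------

@dataclass
class SelectionResult:
    feature_names: tuple[str, ...]
    nca_weight: np.ndarray
    mrmr_score: np.ndarray
    composite: np.ndarray
    selected: tuple[str, ...]


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def composite_select(nca: np.ndarray, mrmr: np.ndarray,
                     feature_names: Sequence[str],
                     top_n: int = 10) -> SelectionResult:
    """Min-max normalize both score vectors, sum, take the top-n composite.

    Ties at the boundary are broken by raw NCA weight, then by feature name
    (lexicographic), making selection deterministic.
    """
    nca = np.asarray(nca, dtype=float)
    mrmr = np.asarray(mrmr, dtype=float)
    if nca.shape != mrmr.shape or len(feature_names) != nca.size:
        raise ValueError("score vectors and names must align")
    composite = _minmax(nca) + _minmax(mrmr)
    order = sorted(range(nca.size),
                   key=lambda i: (-composite[i], -nca[i], feature_names[i]))
    top = min(top_n, nca.size)
    selected = tuple(feature_names[i] for i in order[:top])
    return SelectionResult(feature_names=tuple(feature_names),
                           nca_weight=nca, mrmr_score=mrmr,
                           composite=composite, selected=selected)


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------

@dataclass
class ClassificationReport:
    model: str
    cv_scheme: str
    classes: tuple[str, ...]
    accuracy: float
    macro_f1: float
    per_class_f1: dict
    confusion: np.ndarray
    auc: dict
    predictions: pd.DataFrame      # row index, true, predicted, fold
    selection: Optional[SelectionResult] = None
    nested_selection: bool = True

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "cv_scheme": self.cv_scheme,
            "classes": list(self.classes),
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "per_class_f1": {k: float(v) for k, v in self.per_class_f1.items()},
            "confusion": self.confusion.tolist(),
            "auc": {k: float(v) for k, v in self.auc.items()},
            "nested_selection": self.nested_selection,
            "selected_features": (list(self.selection.selected)
                                  if self.selection else None),
        }


def _make_estimator(model: str, seed: int):
    if model == "linear_svm":
        return SVC(kernel="linear", C=1.0, decision_function_shape="ovr")
    if model == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    raise ValueError(f"unknown model {model!r}")


def _select_features(Xs: np.ndarray, y: np.ndarray, names, top_n: int,
                     seed: int) -> SelectionResult:
    nca = nca_weights(Xs, y, seed=seed)
    mrmr = mrmr_scores(Xs, y)
    return composite_select(nca, mrmr, names, top_n=top_n)


def evaluate(table: pd.DataFrame, labels: Sequence[str],
             model: str = "linear_svm", cv: str = "loocv",
             nested_selection: bool = True, top_n: int = 10,
             select_features: bool = True, seed: int = 0) -> ClassificationReport:
    """Cross-validated classification with per-fold standardization and
    (optionally nested) hybrid feature selection.

    ``nested_selection=False`` runs one global selection on the full table
    before CV (the optimistic single-pass variant).
    """
    X = table.to_numpy(dtype=float)
    y = np.asarray(labels)
    names = list(table.columns)
    classes = tuple(sorted(np.unique(y)))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if cv == "loocv":
        splitter = LeaveOneOut()
    elif cv == "stratified_5fold":
        splitter = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    else:
        raise ValueError(f"unknown cv scheme {cv!r}")

    global_selection = None
    if select_features and not nested_selection:
        Xs = Standardizer().fit_transform(X)
        global_selection = _select_features(Xs, y, names, top_n, seed)

    preds = np.empty(len(y), dtype=object)
    fold_of = np.empty(len(y), dtype=int)
    scores = np.full((len(y), len(classes)), np.nan)
    last_selection = global_selection
    for fold, (tr, te) in enumerate(splitter.split(X, y)):
        std = Standardizer().fit(X[tr])
        Xtr, Xte = std.transform(X[tr]), std.transform(X[te])
        if select_features:
            sel = (global_selection if global_selection is not None
                   else _select_features(Xtr, y[tr], names, top_n, seed))
            idx = [names.index(f) for f in sel.selected]
            Xtr, Xte = Xtr[:, idx], Xte[:, idx]
            last_selection = sel
        est = _make_estimator(model, seed)
        est.fit(Xtr, y[tr])
        preds[te] = est.predict(Xte)
        fold_of[te] = fold
        if hasattr(est, "decision_function") and len(classes) > 2:
            sc = est.decision_function(Xte)
        elif hasattr(est, "predict_proba"):
            sc = est.predict_proba(Xte)
        else:
            sc = est.decision_function(Xte)
            if sc.ndim == 1:
                sc = np.column_stack([-sc, sc])
        order = [list(est.classes_).index(c) for c in classes]
        scores[te] = np.asarray(sc)[:, order]

    y_pred = preds.astype(str)
    acc = accuracy_score(y, y_pred)
    per_f1 = f1_score(y, y_pred, labels=list(classes), average=None)
    macro = f1_score(y, y_pred, labels=list(classes), average="macro")
    conf = confusion_matrix(y, y_pred, labels=list(classes))
    auc = {}
    for i, c in enumerate(classes):
        binary = (y == c).astype(int)
        if binary.sum() in (0, len(binary)):
            auc[c] = np.nan
        else:
            auc[c] = roc_auc_score(binary, scores[:, i])
    pred_df = pd.DataFrame({
        "index": np.arange(len(y)), "true": y, "predicted": y_pred,
        "fold": fold_of,
    })
    return ClassificationReport(
        model=model, cv_scheme=cv, classes=classes, accuracy=float(acc),
        macro_f1=float(macro),
        per_class_f1={c: float(v) for c, v in zip(classes, per_f1)},
        confusion=conf, auc=auc, predictions=pred_df,
        selection=last_selection, nested_selection=nested_selection)
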