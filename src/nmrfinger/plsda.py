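"""Partial least-squares discriminant analysis with VIP ranking.

The engine is a NIPALS PLS1: components are extracted iteratively to
maximize covariance between X scores and the response, deflating X after
each component. For discrimination the response is the class coded +/-1 and
held-out samples are classified by the sign of their predicted response.
Cross-validation uses Venetian blinds (deterministic interleaved fold
assignment), with centering computed on training folds only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import FeatureMatrix

_EPS = 1e-12


def _as_array(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def _bin_centers(X) -> np.ndarray | None:
    if isinstance(X, FeatureMatrix):
        return X.bin_centers
    return None


@dataclass
class PlsModel:
    """A fitted PLS1 decomposition.

    ``x_weights`` (p x A) are the unit-norm component weights, ``x_loadings``
    the deflation loadings, ``scores`` (n x A) the sample scores, and
    ``y_loadings`` the per-component response loadings.
    ``explained_variance_fraction`` is the fraction of (centered) X variance
    captured by each component.
    """

    n_components: int
    x_weights: np.ndarray
    x_loadings: np.ndarray
    scores: np.ndarray
    y_loadings: np.ndarray
    x_center: np.ndarray
    y_center: float
    explained_variance_fraction: np.ndarray
    bin_centers: np.ndarray | None = None

    @property
    def coefficients(self) -> np.ndarray:
        """Regression vector B with prediction y_center + (x - x_center) B."""
        W, P, q = self.x_weights, self.x_loadings, self.y_loadings
        ptw = P.T @ W
        return W @ np.linalg.solve(ptw, q)

    def predict(self, X) -> np.ndarray:
        Xc = _as_array(X) - self.x_center
        return self.y_center + Xc @ self.coefficients


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_components: int):
    """Core NIPALS loop on centered data. Returns (W, P, T, q, n_used)."""
    n, p = Xc.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    X = Xc.copy()
    used = 0
    for a in range(n_components):
        w = X.T @ yc
        nw = np.linalg.norm(w)
        if nw < _EPS:
            break  # residual carries no covariance with y
        w /= nw
        t = X @ w
        tt = t @ t
        if tt < _EPS:
            break
        p_a = X.T @ t / tt
        q_a = (yc @ t) / tt
        X -= np.outer(t, p_a)
        W[:, a], P[:, a], T[:, a], q[a] = w, p_a, t, q_a
        used += 1
    return W[:, :used], P[:, :used], T[:, :used], q[:used], used


def fit_pls(X, y, n_components: int = 2) -> PlsModel:
    """Fit a PLS1 model of the (class-coded or continuous) response on X."""
    Xa = _as_array(X)
    ya = np.asarray(y, dtype=float)
    n, p = Xa.shape
    if ya.shape != (n,):
        raise ValueError("y length must match the number of samples")
    if n_components < 1 or n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} must be in [1, min(n-1, p)] = "
            f"[1, {min(n - 1, p)}]"
        )
    if np.std(ya) < _EPS:
        raise ValueError("response has zero variance")
    x_center = Xa.mean(axis=0)
    y_center = float(ya.mean())
    Xc = Xa - x_center
    yc = ya - y_center
    W, P, T, q, used = _nipals_pls1(Xc, yc, n_components)
    if used == 0:
        raise ValueError("could not extract any PLS component")
    total_ssx = float(np.sum(Xc * Xc))
    if total_ssx < _EPS:
        evf = np.zeros(used)
    else:
        evf = np.sum(T * T, axis=0) * np.sum(P * P, axis=0) / total_ssx
    return PlsModel(
        n_components=used,
        x_weights=W,
        x_loadings=P,
        scores=T,
        y_loadings=q,
        x_center=x_center,
        y_center=y_center,
        explained_variance_fraction=evf,
        bin_centers=_bin_centers(X),
    )


def vip_scores(model: PlsModel) -> np.ndarray:
    """Variable importance in projection for every bin.

    VIP_j = sqrt( p * sum_a SS_a (w_ja / ||w_a||)^2 / sum_a SS_a ), with
    SS_a = q_a^2 t_a' t_a the response variance captured by component a.
    The mean squared VIP over bins is exactly 1.
    """
    W = model.x_weights
    p = W.shape[0]
    ss = model.y_loadings**2 * np.sum(model.scores**2, axis=0)
    wnorm2 = np.sum(W * W, axis=0)
    wnorm2 = np.where(wnorm2 < _EPS, 1.0, wnorm2)
    return np.sqrt(p * (W * W / wnorm2) @ ss / ss.sum())


def venetian_blinds_split(n: int, k: int, block_size: int = 1) -> np.ndarray:
    """Interleaved fold assignment: sample i -> fold (i // block_size) mod k."""
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    return (np.arange(n) // block_size) % k


@dataclass
class CvReport:
    """Confusion counts and sensitivity/specificity from cross-validation."""

    true_positive: int
    false_positive: int
    true_negative: int
    false_negative: int
    sensitivity: float
    specificity: float
    positive_class: object
    fold_assignments: np.ndarray
    params: dict = field(default_factory=dict)
    #: raw held-out predicted responses (sign decides the class); not
    #: serialized
    decision_values: np.ndarray | None = None

    @property
    def n(self) -> int:
        return (self.true_positive + self.false_positive
                + self.true_negative + self.false_negative)

    @property
    def accuracy(self) -> float:
        return (self.true_positive + self.true_negative) / self.n

    def to_dict(self) -> dict:
        return {
            "true_positive": int(self.true_positive),
            "false_positive": int(self.false_positive),
            "true_negative": int(self.true_negative),
            "false_negative": int(self.false_negative),
            "sensitivity": float(self.sensitivity),
            "specificity": float(self.specificity),
            "positive_class": str(self.positive_class),
            "fold_assignments": [int(f) for f in self.fold_assignments],
            **{k: v for k, v in self.params.items()},
        }


def _confusion(y_true_pos: np.ndarray, y_pred_pos: np.ndarray):
    tp = int(np.sum(y_true_pos & y_pred_pos))
    fn = int(np.sum(y_true_pos & ~y_pred_pos))
    tn = int(np.sum(~y_true_pos & ~y_pred_pos))
    fp = int(np.sum(~y_true_pos & y_pred_pos))
    return tp, fp, tn, fn


def encode_labels(y, positive_class=None):
    """Code a two-class label vector as +/-1. Returns (codes, positive_class)."""
    y = np.asarray(y)
    classes = sorted(np.unique(y).tolist())
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 classes, got {classes}")
    if positive_class is None:
        positive_class = classes[0]
    if positive_class not in classes:
        raise ValueError(f"positive_class {positive_class!r} not among {classes}")
    return np.where(y == positive_class, 1.0, -1.0), positive_class


def cross_validate_plsda(
    X,
    y,
    k: int = 7,
    n_components: int = 2,
    positive_class=None,
    block_size: int = 1,
) -> CvReport:
    """Venetian-blinds cross-validated PLS-DA sensitivity/specificity.

    Each fold's model is centered and fitted on training rows only; held-out
    rows are classified by the sign of the predicted (+/-1 coded) response.
    """
    Xa = _as_array(X)
    coded, positive_class = encode_labels(y, positive_class)
    n = Xa.shape[0]
    folds = venetian_blinds_split(n, k, block_size)
    decision = np.zeros(n)
    for f in range(k):
        test = folds == f
        train = ~test
        ytr = coded[train]
        if len(np.unique(ytr)) < 2:
            raise ValueError(
                f"training fold {f} lost a class; use fewer folds (k={k})"
            )
        a = min(n_components, int(train.sum()) - 1, Xa.shape[1])
        model = fit_pls(Xa[train], ytr, a)
        decision[test] = model.predict(Xa[test])
    pred_pos = decision >= 0.0
    true_pos = coded > 0
    tp, fp, tn, fn = _confusion(true_pos, pred_pos)
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return CvReport(
        tp, fp, tn, fn, sens, spec, positive_class, folds,
        params={"k": k, "n_components": n_components, "block_size": block_size,
                "scheme": "venetian_blinds"},
        decision_values=decision,
    )


def top_weighted_peaks(
    model: PlsModel,
    n_top: int = 20,
    bin_centers: np.ndarray | None = None,
    component: int = 0,
) -> pd.DataFrame:
    """Bins ranked by |weighting| on one component (default the first).

    A positive weighting means the bin is elevated in the positive class
    (up-regulation); negative means depressed. Ties break to the lower bin
    index.
    """
    W = model.x_weights
    if component >= W.shape[1]:
        raise ValueError(f"model has only {W.shape[1]} components")
    w = W[:, component]
    if n_top > w.size:
        raise ValueError(f"n_top={n_top} exceeds the {w.size} bins")
    order = np.lexsort((np.arange(w.size), -np.abs(w)))[:n_top]
    centers = bin_centers if bin_centers is not None else model.bin_centers
    if centers is None:
        centers = np.arange(w.size, dtype=float)
    return pd.DataFrame(
        {
            "bin_index": order,
            "bin_center": np.asarray(centers)[order],
            "weighting": w[order],
            "direction": np.where(w[order] >= 0, "up", "down"),
        }
    )


def aggregate_weighted_peaks(model: PlsModel, n_top: int = 20,
                             bin_centers: np.ndarray | None = None) -> pd.DataFrame:
    """Multi-component variant: rank bins by the norm of their weight row."""
    W = model.x_weights
    mag = np.sqrt(np.sum(W * W, axis=1))
    if n_top > mag.size:
        raise ValueError(f"n_top={n_top} exceeds the {mag.size} bins")
    order = np.lexsort((np.arange(mag.size), -mag))[:n_top]
    centers = bin_centers if bin_centers is not None else model.bin_centers
    if centers is None:
        centers = np.arange(mag.size, dtype=float)
    return pd.DataFrame(
        {
            "bin_index": order,
            "bin_center": np.asarray(centers)[order],
            "weighting": mag[order],
            "direction": np.where(W[order, 0] >= 0, "up", "down"),
        }
    )
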