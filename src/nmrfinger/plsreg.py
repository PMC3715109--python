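"""PLS regression of bins on a continuous clinical outcome.

Greedy forward selection grows a bin set (budget 90 by default) by
maximizing cross-validated r-squared of the PLS regression, and the fit's
significance is assessed by permutation: the whole pipeline — forward
selection included — is rerun on outcome-permuted data to build the null
r-squared distribution, so selection bias cannot manufacture significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .plsda import _EPS, _as_array, fit_pls, venetian_blinds_split

LOO_THRESHOLD = 40  # leave-one-out below this cohort size, else 7-fold


@dataclass
class RegressionResult:
    """Observed fit plus its permutation null distribution."""

    selected_bins: list[int]
    r_squared: float
    null_r_squared: np.ndarray
    p_value: float
    n_permutations: int
    outcome_name: str = "outcome"
    step_cv_r2: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "selected_bins": [int(b) for b in self.selected_bins],
            "r_squared": float(self.r_squared),
            "null_r_squared": [float(v) for v in self.null_r_squared],
            "p_value": float(self.p_value),
            "n_permutations": int(self.n_permutations),
            "outcome_name": self.outcome_name,
            "step_cv_r2": [float(v) for v in self.step_cv_r2],
        }


def default_folds(n: int, cv_folds: int | None = None) -> list[np.ndarray]:
    """Deterministic CV folds: leave-one-out at small n, else interleaved."""
    if cv_folds is None:
        cv_folds = n if n <= LOO_THRESHOLD else 7
    cv_folds = min(cv_folds, n)
    assignment = venetian_blinds_split(n, cv_folds)
    return [np.flatnonzero(assignment == f) for f in range(cv_folds)]


def _batched_press(X: np.ndarray, y: np.ndarray, folds: list[np.ndarray],
                   n_components: int) -> float:
    """Pooled squared prediction error over folds, NIPALS vectorized.

    Folds are grouped by test-set size so each group batches into one 3-D
    NIPALS sweep (training center, component extraction, held-out
    prediction all einsum-vectorized over folds).
    """
    n, p = X.shape
    all_idx = np.arange(n)
    press = 0.0
    sizes: dict[int, list[np.ndarray]] = {}
    for t in folds:
        sizes.setdefault(t.size, []).append(t)
    for group in sizes.values():
        test = np.stack(group)                      # (F, n_te)
        train = np.stack([np.setdiff1d(all_idx, t, assume_unique=True)
                          for t in group])          # (F, n_tr)
        F, n_tr = train.shape
        A = max(1, min(n_components, n_tr - 1, p))
        Xtr = X[train]                              # (F, n_tr, p)
        ytr = y[train]
        xm = Xtr.mean(axis=1, keepdims=True)
        ym = ytr.mean(axis=1, keepdims=True)
        Xc = Xtr - xm
        yc = ytr - ym
        W = np.zeros((F, p, A))
        P = np.zeros((F, p, A))
        q = np.zeros((F, A))
        for a in range(A):
            w = np.einsum("fij,fi->fj", Xc, yc)
            nw = np.linalg.norm(w, axis=1, keepdims=True)
            w = np.where(nw > _EPS, w / np.where(nw > _EPS, nw, 1.0), 0.0)
            t = np.einsum("fij,fj->fi", Xc, w)
            tt = np.maximum(np.sum(t * t, axis=1), _EPS)
            pa = np.einsum("fij,fi->fj", Xc, t) / tt[:, None]
            qa = np.sum(yc * t, axis=1) / tt
            Xc = Xc - t[:, :, None] * pa[:, None, :]
            W[:, :, a], P[:, :, a], q[:, a] = w, pa, qa
        ptw = np.einsum("fpa,fpb->fab", P, W)
        ptw = ptw + 1e-12 * np.eye(A)
        beta = np.linalg.solve(ptw, q[:, :, None])[:, :, 0]
        B = np.einsum("fpa,fa->fp", W, beta)
        Xte = X[test] - xm                          # (F, n_te, p)
        pred = ym + np.einsum("fij,fj->fi", Xte, B)
        press += float(np.sum((y[test] - pred) ** 2))
    return press


def cv_r2(X, y, bins, n_components: int = 2,
          folds: list[np.ndarray] | None = None) -> float:
    """Cross-validated r-squared (Q2) of PLS regression on selected bins."""
    Xa = _as_array(X)[:, list(bins)]
    ya = np.asarray(y, dtype=float)
    if folds is None:
        folds = default_folds(ya.size)
    tss = float(np.sum((ya - ya.mean()) ** 2))
    if tss < _EPS:
        raise ValueError("outcome has zero variance")
    press = _batched_press(Xa, ya, folds, n_components)
    return 1.0 - press / tss


def forward_select_bins(
    X,
    y,
    max_bins: int = 90,
    n_components: int = 2,
    cv_folds: int | None = None,
) -> tuple[list[int], list[float]]:
    """Greedy forward selection of bins maximizing cross-validated r-squared.

    At each step the bin whose addition gives the highest CV r-squared is
    added (ties break to the lower bin index); selection stops at
    ``max_bins`` or as soon as CV r-squared stops improving. Returns the
    ordered bin list and the per-step CV r-squared trace.
    """
    Xa = _as_array(X)
    ya = np.asarray(y, dtype=float)
    n, p = Xa.shape
    if max_bins > p:
        raise ValueError(f"max_bins={max_bins} exceeds the {p} available bins")
    if np.std(ya) < _EPS:
        raise ValueError("outcome has zero variance")
    folds = default_folds(n, cv_folds)
    tss = float(np.sum((ya - ya.mean()) ** 2))
    selected: list[int] = []
    trace: list[float] = []
    best_so_far = -np.inf
    remaining = list(range(p))
    while len(selected) < max_bins and remaining:
        best_j, best_r2 = None, -np.inf
        for j in remaining:
            cols = selected + [j]
            press = _batched_press(Xa[:, cols], ya, folds, n_components)
            r2 = 1.0 - press / tss
            if r2 > best_r2 + 1e-12:
                best_j, best_r2 = j, r2
        if best_j is None or best_r2 <= best_so_far + 1e-12:
            break
        selected.append(best_j)
        trace.append(best_r2)
        best_so_far = best_r2
        remaining.remove(best_j)
    return selected, trace


def pls_regress_r2(X, y, bins, n_components: int = 2) -> float:
    """Training r-squared of the PLS regression on the selected bins."""
    if len(bins) == 0:
        raise ValueError("bins must be nonempty")
    Xa = _as_array(X)[:, list(bins)]
    ya = np.asarray(y, dtype=float)
    a = min(n_components, Xa.shape[0] - 1, Xa.shape[1])
    if a < n_components:
        warnings.warn(
            f"n_components reduced from {n_components} to {a} (rank limit)",
            stacklevel=2,
        )
    model = fit_pls(Xa, ya, a)
    resid = ya - model.predict(Xa)
    tss = float(np.sum((ya - ya.mean()) ** 2))
    return 1.0 - float(np.sum(resid**2)) / tss


def permutation_test(
    X,
    y,
    max_bins: int = 90,
    n_components: int = 2,
    cv_folds: int | None = None,
    n_permutations: int = 100,
    seed: int = 0,
    outcome_name: str = "outcome",
    freeze_selection: bool = False,
    permute_x_rows: bool = False,
) -> RegressionResult:
    """Permutation-tested PLS regression of bins on a continuous outcome.

    The observed r-squared comes from forward selection followed by the PLS
    fit on the intact outcome. Each permutation breaks the X-outcome link
    (shuffling the outcome, or the rows of X when ``permute_x_rows``) and
    reruns the *entire* pipeline, selection included, unless
    ``freeze_selection`` fixes the observed bin set (a demonstrably
    anti-conservative shortcut, provided for comparison only).
    p = (1 + #{null >= observed}) / (1 + n_valid) so p is never zero.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    Xa = _as_array(X)
    ya = np.asarray(y, dtype=float)
    selected, trace = forward_select_bins(Xa, ya, max_bins, n_components, cv_folds)
    if not selected:
        selected, trace = [int(np.argmax(np.abs(np.corrcoef(Xa.T, ya)[-1, :-1])))], []
    r2_obs = pls_regress_r2(Xa, ya, selected, n_components)
    rng = np.random.default_rng(seed)
    null: list[float] = []
    failures = 0
    for _ in range(n_permutations):
        perm = rng.permutation(ya.size)
        Xp, yp = (Xa[perm], ya) if permute_x_rows else (Xa, ya[perm])
        try:
            if freeze_selection:
                bins_p = selected
            else:
                bins_p, _ = forward_select_bins(Xp, yp, max_bins, n_components,
                                                cv_folds)
                if not bins_p:
                    bins_p = [int(np.argmax(np.abs(
                        np.corrcoef(Xp.T, yp)[-1, :-1])))]
            null.append(pls_regress_r2(Xp, yp, bins_p, n_components))
        except (ValueError, np.linalg.LinAlgError):
            failures += 1
    if failures:
        if failures > 0.05 * n_permutations:
            raise RuntimeError(
                f"{failures}/{n_permutations} permutations failed"
            )
        warnings.warn(f"excluded {failures} failed permutation(s)", stacklevel=2)
    null_arr = np.asarray(null)
    p = (1 + int(np.sum(null_arr >= r2_obs - 1e-12))) / (1 + null_arr.size)
    return RegressionResult(
        selected_bins=selected,
        r_squared=r2_obs,
        null_r_squared=null_arr,
        p_value=p,
        n_permutations=null_arr.size,
        outcome_name=outcome_name,
        step_cv_r2=trace,
    )
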