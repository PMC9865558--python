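"""Alternating linear-SVM optimization of lighting weights.

The baseline scheme treats the classifier weights ``w`` (one per camera
channel) and the lighting weights ``x`` (one per sub-light) as two blocks
and alternates exact soft-margin SVM solves:

* **w-step** - fix ``x``, render features ``o_i = A_i x`` and fit a linear
  SVM over the channels: ``min ||w||`` s.t. ``y_i (w^T A_i x + b) >= 1``
  (soft-margin form in practice).
* **x-step** - fix ``w``, project features ``z_i = A_i^T w`` and fit the
  *same kind* of SVM over the sub-lights, whose "classifier weights" are
  the new lighting weights: ``min ||x||`` s.t. ``y_i (w^T A_i x + b) >= 1``.

Both subproblems are ordinary linear SVMs because the decision value
``w^T A_i x + b`` is bilinear in (w, x).  Real data is not separable, so
both steps use the hinge-loss soft margin with a shared penalty; the
hard-margin problem is recovered as the penalty grows.  The bias is refit
in whichever subproblem is being solved.

Ten random restarts (x0 uniform in [-1, 1]^NL) guard against the
nonconvexity of the joint problem; the best trial is kept by F1 score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .evaluation import binary_metrics

__all__ = [
    "AltOptState",
    "fit_w_given_x",
    "fit_x_given_w",
    "alternate",
    "restarts",
    "predict",
    "hinge_objective",
    "AlternatingSVMClassifier",
]

_SVC_TOL = 1e-8


def _as_pixel_features(A: np.ndarray) -> np.ndarray:
    """Accept (N, Nch, NL) or patch-shaped (N, 1, 1, Nch, NL) A arrays."""
    A = np.asarray(A, dtype=float)
    if A.ndim == 5:
        if A.shape[1] != 1 or A.shape[2] != 1:
            raise ValueError(
                "alternating optimization operates on 1x1 pixels; got "
                f"patch shape {A.shape[1:3]}"
            )
        A = A[:, 0, 0]
    if A.ndim != 3:
        raise ValueError(f"A must be (N, Nch, NL); got shape {A.shape}")
    return A


def _check_two_classes(y: np.ndarray):
    if np.unique(y).size < 2:
        raise ValueError("need samples from both classes")


def _fit_linear_svm(features: np.ndarray, y: np.ndarray, c: float):
    svm = SVC(kernel="linear", C=c, tol=_SVC_TOL)
    svm.fit(features, y)
    # libsvm orders classes ascending; flip so weights predict y=+1 positive
    w = svm.coef_.ravel().copy()
    b = float(svm.intercept_[0])
    return w, b


@dataclass
class AltOptState:
    """State of one alternating-optimization run.

    ``history`` rows are per full sweep: dicts with the joint hinge loss,
    each subproblem objective, and the direction changes of x and w.
    """

    w: np.ndarray
    b: float
    x: np.ndarray
    soft_margin_c: float
    history: list = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0

    def decision_values(self, A: np.ndarray) -> np.ndarray:
        A = _as_pixel_features(A)
        return A @ self.x @ self.w + self.b


def fit_w_given_x(A, y, x, soft_margin_c: float = 1.0):
    """Solve the w-step: soft-margin linear SVM on rendered pixels A_i x.

    Returns ``(w, b)`` with ``w`` of length n_channels.
    """
    A = _as_pixel_features(A)
    y = np.asarray(y)
    _check_two_classes(y)
    feats = A @ np.asarray(x, dtype=float)  # (N, Nch)
    return _fit_linear_svm(feats, y, soft_margin_c)


def fit_x_given_w(A, y, w, soft_margin_c: float = 1.0):
    """Solve the x-step: the equivalent SVM on projected features A_i^T w.

    The lighting weights are the classifier weights of a linear SVM trained
    on ``z_i = A_i^T w``; the bias is refit here too.  Returns ``(x, b)``.
    """
    A = _as_pixel_features(A)
    y = np.asarray(y)
    _check_two_classes(y)
    w = np.asarray(w, dtype=float)
    if not np.any(w):
        raise ValueError("w = 0 makes all projected features vanish")
    feats = np.einsum("ncl,c->nl", A, w)  # (N, NL)
    return _fit_linear_svm(feats, y, soft_margin_c)


def predict(A, w, b, x) -> np.ndarray:
    """Labels sign(w^T A x + b) in {-1, +1}; a value of exactly 0 -> +1."""
    A = _as_pixel_features(A)
    scores = A @ np.asarray(x, dtype=float) @ np.asarray(w, dtype=float) + b
    return np.where(scores >= 0, 1, -1)


def hinge_objective(A, y, w, b, x, soft_margin_c: float) -> dict:
    """Joint diagnostics: total hinge loss and both subproblem objectives."""
    A = _as_pixel_features(A)
    margins = np.asarray(y) * (A @ x @ w + b)
    hinge = float(np.maximum(0.0, 1.0 - margins).sum())
    return {
        "hinge_total": hinge,
        "j_w": 0.5 * float(w @ w) + soft_margin_c * hinge,
        "j_x": 0.5 * float(x @ x) + soft_margin_c * hinge,
    }


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def alternate(
    A,
    y,
    x0,
    soft_margin_c: float = 1.0,
    max_iter: int = 50,
    tol: float = 1e-3,
) -> AltOptState:
    """Alternate w-step and x-step to convergence.

    The decision value ``w^T A x + b`` is bilinear in (w, x), so the pair
    carries a scale indeterminacy (w -> a w, x -> x / a) along which the
    raw iterates can slide without the classifier changing.  Convergence
    is therefore measured on the *normalized directions* of w and x:
    stop when both unit vectors move less than ``tol`` between sweeps
    (euclidean norm), or after ``max_iter`` sweeps.  Per-sweep diagnostics
    are kept in ``history``.
    """
    A = _as_pixel_features(A)
    y = np.asarray(y)
    x = np.asarray(x0, dtype=float).copy()
    if x.shape != (A.shape[2],):
        raise ValueError(f"x0 length {x.size} != n_lights {A.shape[2]}")
    state = AltOptState(
        w=np.zeros(A.shape[1]), b=0.0, x=x, soft_margin_c=soft_margin_c
    )
    w_dir_prev = None
    x_dir_prev = _unit(x)
    for it in range(max_iter):
        w, b = fit_w_given_x(A, y, state.x, soft_margin_c)
        x_new, b = fit_x_given_w(A, y, w, soft_margin_c)
        w_dir, x_dir = _unit(w), _unit(x_new)
        dx = float(np.linalg.norm(x_dir - x_dir_prev))
        dw = (
            np.inf
            if w_dir_prev is None
            else float(np.linalg.norm(w_dir - w_dir_prev))
        )
        state.w, state.b, state.x = w, b, x_new
        rec = hinge_objective(A, y, w, b, x_new, soft_margin_c)
        rec.update({"dx": dx, "dw": dw})
        state.history.append(rec)
        state.n_iter = it + 1
        if w_dir_prev is not None and max(dx, dw) < tol:
            state.converged = True
            break
        w_dir_prev, x_dir_prev = w_dir, x_dir
    return state


def restarts(
    A,
    y,
    n_trials: int = 10,
    seed: int = 0,
    soft_margin_c: float = 1.0,
    max_iter: int = 50,
    tol: float = 1e-3,
    A_val=None,
    y_val=None,
) -> AltOptState:
    """Run :func:`alternate` from ``n_trials`` random starts, keep the best.

    Initial weights are drawn uniformly from [-1, 1]^NL; trials are ranked
    by F1 score on the validation set (training set if none is given), as
    trials in the underlying scheme are selected by F1.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    A = _as_pixel_features(A)
    if A_val is None:
        A_val, y_val = A, y
    rng = np.random.default_rng(seed)
    best, best_f1 = None, -1.0
    for _ in range(n_trials):
        x0 = rng.uniform(-1.0, 1.0, size=A.shape[2])
        state = alternate(A, y, x0, soft_margin_c, max_iter, tol)
        y_hat = predict(A_val, state.w, state.b, state.x)
        f1, _, _ = binary_metrics(y_val, y_hat)
        if f1 > best_f1:
            best, best_f1 = state, f1
    return best


class AlternatingSVMClassifier(BaseEstimator, ClassifierMixin):
    """One-vs-rest classifier with jointly optimized lighting weights.

    Scikit-learn estimator wrapping the alternating scheme.  ``X`` may be
    the native A array of shape (N, n_channels, n_lights), a patch array
    (N, 1, 1, n_channels, n_lights), or a flat 2-D array of shape
    (N, n_channels * n_lights) if both dimensions are passed to the
    constructor (the 2-D form composes with sklearn model selection).

    Parameters
    ----------
    soft_margin_c : float
        Shared soft-margin penalty of both SVM subproblems.
    n_trials : int
        Random restarts of the alternating loop (best kept by F1).
    optimize_lighting : bool
        If False, skip the alternation and keep ``fixed_x`` (or all-ones),
        fitting only the w-step once - the fixed-illuminant baseline.
    fixed_x : array-like or None
        Lighting weights used when ``optimize_lighting`` is False.
    n_channels, n_lights : int or None
        Needed only to unflatten 2-D ``X``.

    Attributes
    ----------
    w_ : ndarray of shape (n_channels,)
        Channel classifier weights.
    b_ : float
        Bias.
    x_ : ndarray of shape (n_lights,)
        Learned (or fixed) lighting weights.
    state_ : AltOptState
        Full optimizer state of the winning trial.
    """

    def __init__(
        self,
        soft_margin_c: float = 1.0,
        n_trials: int = 10,
        max_iter: int = 50,
        tol: float = 1e-3,
        optimize_lighting: bool = True,
        fixed_x=None,
        n_channels: int | None = None,
        n_lights: int | None = None,
        random_state: int = 0,
    ):
        self.soft_margin_c = soft_margin_c
        self.n_trials = n_trials
        self.max_iter = max_iter
        self.tol = tol
        self.optimize_lighting = optimize_lighting
        self.fixed_x = fixed_x
        self.n_channels = n_channels
        self.n_lights = n_lights
        self.random_state = random_state

    def _coerce(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if self.n_channels is None or self.n_lights is None:
                raise ValueError(
                    "2-D X requires n_channels and n_lights to unflatten"
                )
            X = X.reshape(len(X), self.n_channels, self.n_lights)
        return _as_pixel_features(X)

    def fit(self, X, y):
        A = self._coerce(X)
        y = np.asarray(y)
        _check_two_classes(y)
        y = np.where(y > 0, 1, -1)
        if self.optimize_lighting:
            state = restarts(
                A,
                y,
                n_trials=self.n_trials,
                seed=self.random_state,
                soft_margin_c=self.soft_margin_c,
                max_iter=self.max_iter,
                tol=self.tol,
            )
        else:
            x = (
                np.ones(A.shape[2])
                if self.fixed_x is None
                else np.asarray(self.fixed_x, dtype=float)
            )
            w, b = fit_w_given_x(A, y, x, self.soft_margin_c)
            state = AltOptState(
                w=w, b=b, x=x, soft_margin_c=self.soft_margin_c, n_iter=1
            )
        self.state_ = state
        self.w_, self.b_, self.x_ = state.w, state.b, state.x
        self.classes_ = np.array([-1, 1])
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "w_")
        return self._coerce(X) @ self.x_ @ self.w_ + self.b_

    def predict(self, X) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0, 1, -1)
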