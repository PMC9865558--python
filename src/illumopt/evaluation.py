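"""Evaluation: F1/accuracy, cross-validation, SPD reconstruction, and
Mahalanobis interclass-distance analysis.

The one-vs-rest task is scored with the F1 of the target ("one") class;
all model selection elsewhere in the package ranks by this score.  The
Mahalanobis analysis quantifies how far "rest" samples sit from the target
class distribution in rendered-feature space: larger distances under an
optimized illuminant than under the fixed reference indicate the lighting
genuinely spreads the classes, not just the classifier boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .spectral import SPD, SubLightSet, approximate_illuminant
from .synthetic import PatchDataset, assign_folds

__all__ = [
    "FoldResult",
    "MahalanobisReport",
    "ReconstructedSPD",
    "binary_metrics",
    "cross_validate",
    "reconstruct_optimal_spd",
    "mahalanobis_report",
    "compare_lighting",
]


def binary_metrics(truth, predicted):
    """F1 score, accuracy and confusion counts of a binary labeling.

    Labels > 0 count as the positive (target) class.  F1 =
    2TP / (2TP + FP + FN); when that denominator is zero (no positives
    anywhere) F1 is 0 by convention.

    Returns
    -------
    (f1, accuracy, confusion) with confusion = dict(tp, fp, fn, tn).
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.size == 0:
        raise ValueError("empty input")
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted lengths differ")
    t = truth > 0
    p = predicted > 0
    tp = int(np.sum(t & p))
    fp = int(np.sum(~t & p))
    fn = int(np.sum(t & ~p))
    tn = int(np.sum(~t & ~p))
    denom = 2 * tp + fp + fn
    f1 = 2 * tp / denom if denom else 0.0
    accuracy = (tp + tn) / truth.size
    return f1, accuracy, {"tp": tp, "fp": fp, "fn": fn, "tn": tn}


@dataclass(frozen=True)
class FoldResult:
    """Held-out metrics and learned lighting weights of one CV fold."""

    fold_id: int
    f1: float
    accuracy: float
    confusion: dict
    learned_x: np.ndarray


def _make_estimator(method: str, dataset: PatchDataset, seed: int, kwargs):
    # local imports: alternating/network themselves import this module
    from .alternating import AlternatingSVMClassifier
    from .network import NeuralLightingClassifier

    if method == "alt":
        return AlternatingSVMClassifier(random_state=seed, **kwargs)
    if method in ("fcl", "cnn"):
        return NeuralLightingClassifier(
            model_kind=method,
            patch_size=dataset.patch_size,
            random_state=seed,
            **kwargs,
        )
    raise ValueError(f"unknown method {method!r}")


def cross_validate(
    method: str,
    dataset: PatchDataset,
    k: int = 5,
    seed: int = 0,
    **method_kwargs,
) -> list:
    """k-fold CV of one method ('alt', 'fcl' or 'cnn') on a patch dataset.

    Folds come from ``dataset.fold_ids`` when present (else a stratified
    split seeded by ``seed``); each fold trains on the other k-1 and is
    scored on the held-out fold.  The learned lighting weights are stored
    per fold - across folds they generally differ, as the joint problem is
    nonconvex.
    """
    ds = dataset if dataset.fold_ids is not None else assign_folds(dataset, k, seed)
    results = []
    for fold in range(int(ds.fold_ids.max()) + 1):
        tr = ds.subset(ds.fold_ids != fold)
        te = ds.subset(ds.fold_ids == fold)
        est = _make_estimator(method, ds, seed, method_kwargs)
        est.fit(tr.A, tr.y)
        f1, acc, conf = binary_metrics(te.y, est.predict(te.A))
        results.append(FoldResult(fold, f1, acc, conf, est.x_.copy()))
    return results


@dataclass(frozen=True)
class ReconstructedSPD:
    """An optimized illuminant rebuilt from lighting weights.

    Negative lobes are preserved (the weights may be negative) and flagged
    via ``has_negative_lobes``; such an SPD is a post-capture linear
    combination, not a physical lamp.
    """

    spd: SPD
    has_negative_lobes: bool
    normalization: str


def reconstruct_optimal_spd(
    sublights: SubLightSet, x, normalization: str = "none"
) -> ReconstructedSPD:
    """Rebuild the optimized illuminant ``Q x``, optionally normalized.

    ``normalization``: 'none', 'unit_max' (peak |value| scaled to 1) or
    'unit_l2' (unit euclidean norm).
    """
    x = np.asarray(x, dtype=float)
    intensity = sublights.Q @ x
    if normalization not in ("none", "unit_max", "unit_l2"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if normalization != "none":
        scale = (
            np.abs(intensity).max()
            if normalization == "unit_max"
            else np.linalg.norm(intensity)
        )
        if scale == 0:
            raise ValueError(
                f"cannot {normalization}-normalize an all-zero SPD"
            )
        intensity = intensity / scale
    return ReconstructedSPD(
        SPD(sublights.grid, intensity),
        bool(np.any(intensity < 0)),
        normalization,
    )


@dataclass(frozen=True)
class MahalanobisReport:
    """Squared Mahalanobis distances of 'rest' samples from the target class.

    ``mu_c`` and ``sigma_c`` describe the target-class distribution in the
    ``n_dim``-dimensional feature space; ``distances`` holds the squared
    form (no square root) for every rest sample, in input order.
    """

    target_class: int
    mu_c: np.ndarray
    sigma_c: np.ndarray
    distances: np.ndarray
    n_dim: int
    sqrt_applied: bool = False


def mahalanobis_report(
    features,
    labels,
    target_class,
    ridge: float | str = "auto",
    centered: bool = True,
    sqrt: bool = False,
    eval_features=None,
    eval_labels=None,
) -> MahalanobisReport:
    """Distance of every non-target sample from the target distribution.

    The target class's mean ``mu_c`` and covariance ``sigma_c`` are
    estimated from its samples; each rest sample's squared distance is
    ``(f - mu_c)^T sigma_c^{-1} (f - mu_c)``.

    Parameters
    ----------
    eval_features, eval_labels : optional
        Score the rest samples of this set instead of the fitting set
        (e.g. held-out samples against a training-set distribution).
    ridge : float or 'auto'
        Tikhonov term added to the covariance diagonal;
        'auto' uses 1e-6 * trace(sigma) / n_dim.  With ridge = 0 a
        singular covariance raises.
    centered : bool
        True (default): standard covariance, mean-centered with
        1/(Nc - 1) scaling.  False: the literal uncentered, unscaled
        second-moment matrix Y_c^T Y_c.
    sqrt : bool
        Report plain (square-rooted) distances instead of squared ones.
    """
    F = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if F.ndim != 2 or F.shape[0] != labels.size:
        raise ValueError("features must be (N, n_dim) matching labels")
    tgt = labels == target_class
    if tgt.sum() < 2:
        raise ValueError("need at least two target-class samples")
    Yc = F[tgt]
    n_dim = F.shape[1]
    mu = Yc.mean(axis=0)
    if centered:
        Z = Yc - mu
        sigma = Z.T @ Z / (len(Yc) - 1)
    else:
        sigma = Yc.T @ Yc
    if ridge == "auto":
        ridge = 1e-6 * np.trace(sigma) / n_dim
    if ridge < 0:
        raise ValueError("ridge must be nonnegative")
    sigma = sigma + ridge * np.eye(n_dim)
    try:
        chol = cho_factor(sigma)
    except LinAlgError as exc:
        raise ValueError(
            "covariance is singular; pass a positive ridge"
        ) from exc
    if eval_features is not None:
        Fe = np.asarray(eval_features, dtype=float)
        rest = np.asarray(eval_labels) != target_class
        diffs = Fe[rest] - mu
    else:
        diffs = F[~tgt] - mu
    d2 = np.einsum("nd,nd->n", diffs, cho_solve(chol, diffs.T).T)
    d2 = np.maximum(d2, 0.0)
    return MahalanobisReport(
        target_class=int(target_class),
        mu_c=mu,
        sigma_c=sigma,
        distances=np.sqrt(d2) if sqrt else d2,
        n_dim=n_dim,
        sqrt_applied=sqrt,
    )


def compare_lighting(
    datasets,
    methods,
    sublights: SubLightSet,
    fixed_spd: SPD,
    k: int = 5,
    seed: int = 0,
    **method_kwargs,
) -> list:
    """Optimized vs fixed-illuminant arms, per method and target class.

    For every (method, target class): run k-fold CV (a) with trainable /
    optimized lighting weights and (b) with weights frozen at the
    pseudo-inverse approximation of ``fixed_spd`` (the reference-light
    baseline), on identical folds and seeds.  Returns one row per
    method x class with per-fold F1s of both arms and their paired
    differences.
    """
    if isinstance(datasets, PatchDataset):
        datasets = {datasets.target_class: datasets}
    x_fixed = approximate_illuminant(sublights, fixed_spd).x_approx
    rows = []
    for method in methods:
        for cls, ds in datasets.items():
            if ds.fold_ids is None:
                ds = assign_folds(ds, k, seed)
            frozen_kwargs = dict(method_kwargs)
            if method == "alt":
                frozen_kwargs.update(
                    optimize_lighting=False, fixed_x=x_fixed
                )
            else:
                frozen_kwargs.update(train_lighting=False, x0=x_fixed)
            opt = cross_validate(method, ds, k, seed, **method_kwargs)
            fixed = cross_validate(method, ds, k, seed, **frozen_kwargs)
            f1_opt = [r.f1 for r in opt]
            f1_fixed = [r.f1 for r in fixed]
            rows.append(
                {
                    "method": method,
                    "target_class": cls,
                    "f1_optimized": f1_opt,
                    "f1_fixed": f1_fixed,
                    "paired_diff": [
                        a - b for a, b in zip(f1_opt, f1_fixed)
                    ],
                    "acc_optimized": [r.accuracy for r in opt],
                    "acc_fixed": [r.accuracy for r in fixed],
                    "learned_x": [r.learned_x for r in opt],
                }
            )
    return rows
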