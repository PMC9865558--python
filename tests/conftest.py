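"""Shared fixtures: small spectral setups and the band-separable task.

The "band task" is the package's canonical recovery problem: two classes
whose reflectances are identical except inside one ~50 nm band (620-670
nm), observed through the synthetic RGB camera under the 24 simulated
sub-lights.  Only the sub-lights overlapping that band carry any class
information, so it exercises whether an optimizer allocates lighting
weight where the signal is.
"""

import numpy as np
import pytest
from scipy.optimize import minimize

import illumopt as il

BAND = (620.0, 670.0)
#: indices of simulated sub-lights whose peak lies within BAND +- fwhm/2
COVERING = (8, 9, 10, 11)  # peaks 612, 637, 662, 687 nm


@pytest.fixture(scope="session")
def grid_full():
    return il.make_grid(400, 1000, 5)


@pytest.fixture(scope="session")
def grid_vis():
    return il.make_grid(400, 830, 5)


@pytest.fixture(scope="session")
def sublights(grid_full):
    return il.simulated_sublights(grid_full)


@pytest.fixture(scope="session")
def camera(grid_full):
    return il.synthetic_rgb_camera(grid_full)


@pytest.fixture(scope="session")
def band_models(grid_full):
    return il.make_class_spectra(2, grid_full, seed=0, band_range=BAND)


@pytest.fixture(scope="session")
def band_scene(band_models, grid_full):
    layout = il.block_layout(24, 24, 2, tile=6)
    return il.generate_scene(band_models, 24, 24, layout, seed=1)


@pytest.fixture(scope="session")
def pixel_ds(band_scene, camera, sublights):
    """1x1-pixel A-matrix dataset of the band task, 5 stratified folds."""
    return il.make_patch_dataset(
        band_scene, camera, sublights, 1, 1, k_folds=5, seed=0
    )


@pytest.fixture(scope="session")
def patch_ds(band_scene, camera, sublights):
    """5x5-patch dataset of the band task, 5 stratified folds."""
    return il.make_patch_dataset(
        band_scene, camera, sublights, 5, 1, k_folds=5, seed=0
    )


def svm_qp_oracle(Z, y, c):
    """Soft-margin linear SVM by direct solution of the dual QP (SLSQP).

    Independent of the package's SVM path; only suitable for small n.
    Returns (w, b).
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    G = Z * y[:, None]
    K = G @ G.T
    res = minimize(
        lambda a: 0.5 * a @ K @ a - a.sum(),
        np.full(n, min(c, 1.0) / 2),
        jac=lambda a: K @ a - np.ones(n),
        bounds=[(0.0, c)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    alpha = res.x
    w = (alpha * y) @ Z
    margin_sv = (alpha > 1e-6 * c) & (alpha < c * (1 - 1e-6))
    if not margin_sv.any():
        margin_sv = alpha > 1e-6 * c
    b = float(np.mean(y[margin_sv] - Z[margin_sv] @ w))
    return w, b
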