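"""Synthetic labeled reflectance scenes for light-source optimization.

Emulates the structure of oral/dental spectral image databases: a scene is
an H x W grid of pixels, each carrying a full reflectance spectrum in
[0, 1], with an integer class mask (healthy enamel plus several lesion
classes; -1 marks unlabeled pixels).  Classes share a smooth baseline
reflectance and differ by small Gaussian "bumps" confined to narrow
wavelength bands, so they overlap heavily under broadband illumination but
become separable when the illuminant weights the right band - exactly the
regime light-source optimization is meant to exploit.

The scene is converted to per-pixel A-matrices (channel response under each
sub-light) and cut into odd-sized square patches whose binary one-vs-rest
label comes from the central pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .spectral import (
    CameraSensitivity,
    SubLightSet,
    WavelengthGrid,
    build_A_cube,
)

__all__ = [
    "ClassSpectrumModel",
    "LabeledReflectanceCube",
    "PatchDataset",
    "make_class_spectra",
    "block_layout",
    "generate_scene",
    "extract_patches",
    "assign_folds",
    "make_patch_dataset",
]


@dataclass(frozen=True)
class ClassSpectrumModel:
    """Generative model of one class's reflectance spectrum.

    ``spectrum = clip(base + sum of Gaussian bumps, 0, 1)``; individual
    pixels add iid Gaussian noise with standard deviation ``noise_sd``.
    """

    class_id: int
    base: np.ndarray
    bumps: tuple  # of (center_nm, width_nm, amplitude)
    noise_sd: float
    grid: WavelengthGrid = field(repr=False)

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def spectrum(self) -> np.ndarray:
        """Noise-free class reflectance on the model grid, in [0, 1]."""
        lam = self.grid.values
        r = np.asarray(self.base, dtype=float).copy()
        for center, width, amp in self.bumps:
            r += amp * np.exp(-((lam - center) ** 2) / (2.0 * width**2))
        return np.clip(r, 0.0, 1.0)


@dataclass(frozen=True)
class LabeledReflectanceCube:
    """H x W x n_wavelengths reflectance cube plus integer class mask.

    Mask values are class ids 0..K-1, or -1 for unlabeled pixels.
    """

    cube: np.ndarray
    mask: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self):
        cube = np.asarray(self.cube, dtype=float)
        mask = np.asarray(self.mask)
        if cube.ndim != 3 or cube.shape[2] != len(self.grid):
            raise ValueError("cube must be H x W x n_wavelengths")
        if mask.shape != cube.shape[:2]:
            raise ValueError("mask shape must match cube spatial shape")
        if cube.min() < 0 or cube.max() > 1:
            raise ValueError("reflectances must lie in [0, 1]")
        object.__setattr__(self, "cube", cube)
        object.__setattr__(self, "mask", mask.astype(int))


@dataclass(frozen=True)
class PatchDataset:
    """Patch samples of A-matrices with one-vs-rest labels.

    ``A`` has shape (N, p, p, n_channels, n_lights); ``y`` is +1 where the
    central pixel of the patch belongs to ``target_class``, else -1.
    ``fold_ids`` (0..k-1, stratified) are attached by :func:`assign_folds`.
    """

    A: np.ndarray
    y: np.ndarray
    patch_size: int
    target_class: int
    fold_ids: np.ndarray | None = None

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float)
        y = np.asarray(self.y, dtype=int)
        if A.ndim != 5 or A.shape[0] != y.size:
            raise ValueError("A must be (N, p, p, Nch, NL) matching y")
        if not set(np.unique(y)) <= {-1, 1}:
            raise ValueError("labels must be in {-1, +1}")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "y", y)
        if self.fold_ids is not None:
            fid = np.asarray(self.fold_ids, dtype=int)
            if fid.shape != y.shape:
                raise ValueError("fold_ids must match y")
            object.__setattr__(self, "fold_ids", fid)

    @property
    def n_samples(self) -> int:
        return self.y.size

    @property
    def n_channels(self) -> int:
        return self.A.shape[3]

    @property
    def n_lights(self) -> int:
        return self.A.shape[4]

    @property
    def y01(self) -> np.ndarray:
        """Labels recoded {0, 1} (1 = target class), for NN training."""
        return (self.y > 0).astype(int)

    def one_hot(self) -> np.ndarray:
        """N x 2 one-hot targets; column 1 is the target class."""
        out = np.zeros((self.n_samples, 2))
        out[np.arange(self.n_samples), self.y01] = 1.0
        return out

    def subset(self, idx) -> "PatchDataset":
        idx = np.asarray(idx)
        return PatchDataset(
            self.A[idx],
            self.y[idx],
            self.patch_size,
            self.target_class,
            None if self.fold_ids is None else self.fold_ids[idx],
        )


def _smooth_base(grid: WavelengthGrid) -> np.ndarray:
    """Shared baseline reflectance: smooth sigmoidal rise typical of
    bright biological hard tissue (about 0.35 at 400 nm to 0.65 in NIR)."""
    lam = grid.values
    return 0.35 + 0.30 / (1.0 + np.exp(-(lam - 580.0) / 80.0))


def make_class_spectra(
    n_classes: int,
    grid: WavelengthGrid,
    seed: int,
    *,
    band_range: tuple = (430.0, 760.0),
    bump_width: float = 12.0,
    bump_amplitude: float = 0.12,
    noise_sd: float = 0.02,
) -> list:
    """Build ``n_classes`` spectrum models with disjoint discriminative bands.

    Class 0 is the bare baseline; each further class adds one Gaussian bump
    (alternating sign) centred in its own slot of ``band_range``, with a
    small seeded jitter.  Slots do not overlap, so any two classes differ
    only inside their respective bands.

    Deterministic given ``seed``.
    """
    if n_classes < 2:
        raise ValueError("need at least two classes")
    rng = np.random.default_rng(seed)
    base = _smooth_base(grid)
    lo, hi = band_range
    n_bumped = n_classes - 1
    slot = (hi - lo) / n_bumped
    models = [
        ClassSpectrumModel(0, base, (), noise_sd, grid)
    ]
    for k in range(n_bumped):
        center = lo + (k + 0.5) * slot + rng.uniform(-0.1, 0.1) * slot
        amp = bump_amplitude * (1 if k % 2 == 0 else -1)
        models.append(
            ClassSpectrumModel(
                k + 1, base, ((float(center), bump_width, amp),), noise_sd, grid
            )
        )
    return models


def block_layout(h: int, w: int, n_classes: int, tile: int = 8) -> np.ndarray:
    """Deterministic region map: ``tile`` x ``tile`` blocks cycling class ids.

    Every class appears in contiguous regions, mimicking annotated tissue
    areas; all pixels are labeled.
    """
    rows = np.arange(h) // tile
    cols = np.arange(w) // tile
    return ((rows[:, None] * (w // tile + 1) + cols[None, :]) % n_classes).astype(int)


def generate_scene(
    models: list, h: int, w: int, layout: np.ndarray, seed: int
) -> LabeledReflectanceCube:
    """Render a labeled reflectance cube from class models and a region map.

    Each pixel gets its class's spectrum plus iid Gaussian noise
    (sd = the class's ``noise_sd``), clipped to [0, 1]; ``layout`` entries
    of -1 produce unlabeled pixels carrying the class-0 baseline.
    """
    layout = np.asarray(layout, dtype=int)
    if layout.shape != (h, w):
        raise ValueError(f"layout shape {layout.shape} != ({h}, {w})")
    grid = models[0].grid
    n_lam = len(grid)
    rng = np.random.default_rng(seed)
    cube = np.empty((h, w, n_lam))
    spectra = {m.class_id: m.spectrum() for m in models}
    noise_sds = {m.class_id: m.noise_sd for m in models}
    for cid in np.unique(layout):
        sel = layout == cid
        key = 0 if cid < 0 else int(cid)
        if key not in spectra:
            raise ValueError(f"layout references unknown class {cid}")
        n_pix = int(sel.sum())
        block = spectra[key][None, :] + rng.normal(
            0.0, noise_sds[key], size=(n_pix, n_lam)
        )
        cube[sel] = block
    cube = np.clip(cube, 0.0, 1.0)
    return LabeledReflectanceCube(cube, layout.copy(), grid)


def extract_patches(
    A_cube: np.ndarray, mask: np.ndarray, patch_size: int, target_class: int
) -> PatchDataset:
    """Cut a per-pixel A-matrix cube into labeled square patches.

    One sample per labeled pixel whose ``p x p`` window lies fully inside
    the image (no padding; border windows are discarded).  The binary label
    is +1 iff the *central* pixel belongs to ``target_class``; patches may
    straddle class boundaries and may overlap each other.
    """
    if patch_size % 2 == 0 or patch_size < 1:
        raise ValueError(f"patch_size must be odd and >= 1, got {patch_size}")
    A_cube = np.asarray(A_cube, dtype=float)
    mask = np.asarray(mask, dtype=int)
    if A_cube.ndim != 4 or mask.shape != A_cube.shape[:2]:
        raise ValueError("A_cube must be (H, W, Nch, NL) with matching mask")
    h, w = mask.shape
    half = patch_size // 2
    centers = [
        (r, c)
        for r in range(half, h - half)
        for c in range(half, w - half)
        if mask[r, c] >= 0
    ]
    if not centers:
        raise ValueError("no labeled pixels with a fully interior window")
    A = np.stack(
        [
            A_cube[r - half : r + half + 1, c - half : c + half + 1]
            for r, c in centers
        ]
    )
    y = np.array(
        [1 if mask[r, c] == target_class else -1 for r, c in centers]
    )
    return PatchDataset(A, y, patch_size, target_class)


def assign_folds(dataset: PatchDataset, k: int, seed: int) -> PatchDataset:
    """Attach a stratified k-fold partition (deterministic given seed)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > dataset.n_samples:
        raise ValueError(f"k={k} exceeds sample count {dataset.n_samples}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_ids = np.empty(dataset.n_samples, dtype=int)
    for fid, (_, test_idx) in enumerate(
        skf.split(np.zeros(dataset.n_samples), dataset.y)
    ):
        fold_ids[test_idx] = fid
    return replace(dataset, fold_ids=fold_ids)


def make_patch_dataset(
    scene: LabeledReflectanceCube,
    camera: CameraSensitivity,
    sublights: SubLightSet,
    patch_size: int,
    target_class: int,
    *,
    k_folds: int | None = None,
    seed: int = 0,
) -> PatchDataset:
    """Scene -> A-cube -> patches (-> folds) in one call."""
    A_cube = build_A_cube(camera, scene.cube, sublights)
    ds = extract_patches(A_cube, scene.mask, patch_size, target_class)
    if k_folds is not None:
        ds = assign_folds(ds, k_folds, seed)
    return ds
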