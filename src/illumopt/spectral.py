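"""Spectral observation model: wavelength grids, SPDs, camera sensitivities.

The color observation model treats a camera measurement as the wavelength
integral of (channel sensitivity) x (illuminant) x (surface reflectance).
When the illuminant is a weighted mixture of ``NL`` elementary "sub-lights"
with spectra stacked in a matrix ``Q`` (one column per sub-light) and mixing
weights ``x``, the channel responses of a single pixel factor as

    o = C^T R Q x = A x,

where ``C`` holds the per-channel sensitivities, ``R = diag(r)`` the pixel
reflectance, and ``A = C^T R Q`` is an ``Nch x NL`` matrix that can be
precomputed once per pixel.  Everything downstream (the alternating SVM
scheme and the trainable rendering layer) operates on ``A`` and optimizes
``x``.

The integral is discretized as a rectangle-rule sum with the grid step
folded into ``A``, so the identity ``o = A x`` is exact in floating point:
rendering an image from ``A`` and observing it under the accumulated SPD
``Q x`` give the same numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "WavelengthGrid",
    "SPD",
    "SubLightSet",
    "CameraSensitivity",
    "IlluminantApproximation",
    "make_grid",
    "resample_spd",
    "gaussian_sublights",
    "simulated_sublights",
    "measured_led_peaks",
    "accumulate_spd",
    "observe",
    "build_A",
    "build_A_cube",
    "render",
    "approximate_illuminant",
    "load_d65",
    "synthetic_rgb_camera",
    "SIMULATED_PEAKS_NM",
    "MEASURED_LED_PEAKS_NM",
]

#: Nominal peak wavelengths (nm) of the 24 simulated Gaussian sub-lights:
#: 412..987 nm at an even 25 nm spacing.
SIMULATED_PEAKS_NM = tuple(range(412, 988, 25))

#: Nominal peak wavelengths (nm) of the 24-LED bank the simulated set
#: stands in for (visible band, uneven spacing).
MEASURED_LED_PEAKS_NM = (
    405, 420, 435, 450, 470, 490, 505, 525, 535, 555, 565, 570,
    590, 600, 610, 625, 630, 645, 660, 670, 680, 690, 700, 780,
)


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength axis in nanometres.

    Attributes
    ----------
    start, stop, step : float
        Inclusive range bounds and spacing, nm.
    values : ndarray of shape (n_wavelengths,)
        The wavelengths themselves, strictly increasing.
    """

    start: float
    stop: float
    step: float
    values: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return (
            self.values.size == other.values.size
            and np.allclose(self.values, other.values, rtol=0, atol=1e-9)
        )

    def __hash__(self):
        return hash((self.start, self.stop, self.step))


def make_grid(start: float, stop: float, step: float) -> WavelengthGrid:
    """Build a uniform wavelength grid from ``start`` to ``stop`` inclusive.

    Raises
    ------
    ValueError
        If ``start >= stop``, ``step <= 0`` or the range is not an integer
        multiple of ``step`` (within 1e-9 relative tolerance).
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    if start >= stop:
        raise ValueError(f"start ({start}) must be below stop ({stop})")
    n_steps = (stop - start) / step
    if abs(n_steps - round(n_steps)) > 1e-9 * max(1.0, abs(n_steps)):
        raise ValueError(
            f"range {stop}-{start}={stop - start} nm is not divisible by "
            f"step {step} nm"
        )
    n = int(round(n_steps)) + 1
    values = start + step * np.arange(n)
    return WavelengthGrid(float(start), float(stop), float(step), values)


@dataclass(frozen=True)
class SPD:
    """A spectral power distribution on a wavelength grid.

    ``intensity`` is relative radiant power (unitless).  Physical source
    SPDs are nonnegative; mixed or optimized SPDs may have negative lobes,
    in which case they are interpretable only as post-capture linear
    combinations, not physical lamps.
    """

    grid: WavelengthGrid
    intensity: np.ndarray

    def __post_init__(self):
        intensity = np.asarray(self.intensity, dtype=float)
        if intensity.shape != (len(self.grid),):
            raise ValueError(
                f"intensity shape {intensity.shape} does not match grid "
                f"length {len(self.grid)}"
            )
        if not np.all(np.isfinite(intensity)):
            raise ValueError("SPD intensity must be finite")
        object.__setattr__(self, "intensity", intensity)


@dataclass(frozen=True)
class SubLightSet:
    """A bank of ``NL`` sub-light SPDs sharing one wavelength grid.

    ``Q`` has shape (n_wavelengths, NL); column ``i`` is the SPD of
    sub-light ``i`` whose nominal peak is ``peak_nm[i]``.
    """

    grid: WavelengthGrid
    Q: np.ndarray
    peak_nm: np.ndarray

    def __post_init__(self):
        Q = np.asarray(self.Q, dtype=float)
        peaks = np.asarray(self.peak_nm, dtype=float)
        if Q.ndim != 2 or Q.shape[0] != len(self.grid):
            raise ValueError(f"Q shape {Q.shape} incompatible with grid")
        if Q.shape[1] < 1:
            raise ValueError("need at least one sub-light")
        if peaks.shape != (Q.shape[1],):
            raise ValueError("peak_nm length must equal number of sub-lights")
        if np.any(Q < 0):
            raise ValueError("sub-light SPDs must be nonnegative")
        object.__setattr__(self, "Q", Q)
        object.__setattr__(self, "peak_nm", peaks)

    @property
    def n_lights(self) -> int:
        return self.Q.shape[1]

    def spd(self, i: int) -> SPD:
        return SPD(self.grid, self.Q[:, i])


@dataclass(frozen=True)
class CameraSensitivity:
    """Per-channel spectral response (quantum efficiency, unitless).

    ``C`` has shape (n_wavelengths, n_channels).
    """

    grid: WavelengthGrid
    C: np.ndarray
    channel_names: tuple = ("R", "G", "B")

    def __post_init__(self):
        C = np.asarray(self.C, dtype=float)
        if C.ndim != 2 or C.shape[0] != len(self.grid):
            raise ValueError(f"C shape {C.shape} incompatible with grid")
        if C.shape[1] < 1:
            raise ValueError("need at least one channel")
        if np.any(C < 0):
            raise ValueError("sensitivities must be nonnegative")
        if len(self.channel_names) != C.shape[1]:
            raise ValueError("channel_names length must equal n_channels")
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))

    @property
    def n_channels(self) -> int:
        return self.C.shape[1]


@dataclass(frozen=True)
class IlluminantApproximation:
    """Least-squares mixture of sub-lights approximating a target SPD."""

    x_approx: np.ndarray
    reconstructed: SPD
    residual_l2: float


def resample_spd(spd: SPD, target: WavelengthGrid) -> SPD:
    """Linearly interpolate an SPD onto ``target``; out of range -> 0.

    SPDs vanish outside their measured band, so wavelengths beyond the
    source range get zero intensity rather than an extrapolated value.
    """
    src = spd.grid.values
    if target.values[0] > src[-1] or target.values[-1] < src[0]:
        raise ValueError(
            f"no overlap between source range [{src[0]}, {src[-1]}] and "
            f"target range [{target.values[0]}, {target.values[-1]}]"
        )
    out = np.interp(target.values, src, spd.intensity, left=0.0, right=0.0)
    return SPD(target, out)


def gaussian_sublights(
    peaks, fwhm: float, grid: WavelengthGrid
) -> SubLightSet:
    """Generate Gaussian sub-light SPDs with unit peak height.

    Column ``i`` is ``exp(-(lam - mu_i)^2 / (2 sigma^2))`` with
    ``sigma = fwhm / (2 sqrt(2 ln 2))``, i.e. the stated full width at
    half maximum is exact for the continuous curve.

    Parameters
    ----------
    peaks : array-like of float
        Nominal peak wavelengths (nm), one per sub-light.
    fwhm : float
        Full width at half maximum (nm), shared by all sub-lights.
    """
    if fwhm <= 0:
        raise ValueError(f"fwhm must be positive, got {fwhm}")
    peaks = np.atleast_1d(np.asarray(peaks, dtype=float))
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    lam = grid.values[:, None]
    Q = np.exp(-((lam - peaks[None, :]) ** 2) / (2.0 * sigma**2))
    return SubLightSet(grid, Q, peaks)


def simulated_sublights(grid: WavelengthGrid | None = None) -> SubLightSet:
    """The 24 simulated Gaussian sub-lights spanning 400-1000 nm.

    Peaks at 412..987 nm (25 nm spacing), FWHM 40 nm.  Default grid is
    400-1000 nm at 5 nm.
    """
    if grid is None:
        grid = make_grid(400, 1000, 5)
    return gaussian_sublights(SIMULATED_PEAKS_NM, 40.0, grid)


def measured_led_peaks() -> np.ndarray:
    """Nominal peak wavelengths of the 24-LED visible-band bank (nm)."""
    return np.asarray(MEASURED_LED_PEAKS_NM, dtype=float)


def accumulate_spd(sublights: SubLightSet, x) -> SPD:
    """Mix sub-lights into one illuminant: ``l = Q x`` on the shared grid."""
    x = np.asarray(x, dtype=float)
    if x.shape != (sublights.n_lights,):
        raise ValueError(
            f"x has length {x.size}, expected {sublights.n_lights}"
        )
    return SPD(sublights.grid, sublights.Q @ x)


def _check_same_grid(*grids: WavelengthGrid):
    first = grids[0]
    for g in grids[1:]:
        if g != first:
            raise ValueError("wavelength grids do not match")


def observe(camera: CameraSensitivity, refl, illuminant: SPD) -> np.ndarray:
    """Channel responses of one surface patch under one illuminant.

    Rectangle-rule discretization of the observation integral:
    ``o_j = sum_lam c_j(lam) l(lam) r(lam) dlam``.

    Parameters
    ----------
    refl : array-like of shape (n_wavelengths,)
        Surface spectral reflectance in [0, 1] on the camera's grid.
    """
    _check_same_grid(camera.grid, illuminant.grid)
    refl = np.asarray(refl, dtype=float)
    if refl.shape != (len(camera.grid),):
        raise ValueError("reflectance length does not match grid")
    dlam = camera.grid.step
    return camera.C.T @ (illuminant.intensity * refl) * dlam


def build_A(camera: CameraSensitivity, refl, sublights: SubLightSet) -> np.ndarray:
    """Per-pixel feature matrix ``A = C^T R Q`` (grid step folded in).

    ``A[j, i]`` is channel ``j``'s response to this pixel under sub-light
    ``i`` alone, so ``A @ x`` equals ``observe`` under the accumulated
    illuminant ``Q x`` exactly.
    """
    _check_same_grid(camera.grid, sublights.grid)
    refl = np.asarray(refl, dtype=float)
    if refl.shape != (len(camera.grid),):
        raise ValueError("reflectance length does not match grid")
    dlam = camera.grid.step
    return camera.C.T @ (refl[:, None] * sublights.Q) * dlam


def build_A_cube(
    camera: CameraSensitivity, cube: np.ndarray, sublights: SubLightSet
) -> np.ndarray:
    """Vectorized :func:`build_A` over an H x W x n_wavelengths cube.

    Returns an array of shape (H, W, n_channels, n_lights).
    """
    _check_same_grid(camera.grid, sublights.grid)
    cube = np.asarray(cube, dtype=float)
    if cube.ndim != 3 or cube.shape[2] != len(camera.grid):
        raise ValueError(
            f"cube shape {cube.shape} incompatible with grid length "
            f"{len(camera.grid)}"
        )
    dlam = camera.grid.step
    # (H, W, lam) x (lam, ch) x (lam, NL) -> (H, W, ch, NL)
    A = np.einsum("hwl,lc,ln->hwcn", cube, camera.C, sublights.Q) * dlam
    return A


def render(A: np.ndarray, x) -> np.ndarray:
    """Contract the trailing sub-light axis of an A array with weights x.

    Works for a single pixel (Nch, NL), a cube (H, W, Nch, NL) or a batch
    of patches (N, p, p, Nch, NL); the result drops the last axis.
    """
    A = np.asarray(A, dtype=float)
    x = np.asarray(x, dtype=float)
    if A.shape[-1] != x.size:
        raise ValueError(
            f"trailing axis {A.shape[-1]} does not match len(x)={x.size}"
        )
    return A @ x


def approximate_illuminant(
    sublights: SubLightSet, target: SPD
) -> IlluminantApproximation:
    """Best mixture of sub-lights matching a target SPD, by pseudo-inverse.

    Returns the minimum-norm least-squares weights ``x = Q^+ t``, the
    reconstruction ``Q x`` and the l2 residual.  Sub-light coverage gaps
    (bands where no column of Q has power) dominate the residual.
    """
    _check_same_grid(sublights.grid, target.grid)
    x = np.linalg.pinv(sublights.Q) @ target.intensity
    recon = sublights.Q @ x
    residual = float(np.linalg.norm(recon - target.intensity))
    return IlluminantApproximation(x, SPD(sublights.grid, recon), residual)


def load_d65(grid: WavelengthGrid | None = None) -> SPD:
    """The CIE D65 daylight illuminant, resampled to ``grid``.

    The packaged table holds the standard relative SPD (normalized to 100
    at 560 nm) at 10 nm anchors over 380-830 nm; loading interpolates
    linearly to the requested grid (default 400-830 nm at 5 nm) and sets
    wavelengths outside the tabulated band to zero.
    """
    path = resources.files("illumopt.data") / "cie_d65.csv"
    rows = np.loadtxt(str(path), delimiter=",", skiprows=1)
    src_grid = make_grid(rows[0, 0], rows[-1, 0], rows[1, 0] - rows[0, 0])
    d65 = SPD(src_grid, rows[:, 1])
    if grid is None:
        grid = make_grid(400, 830, 5)
    return resample_spd(d65, grid)


def synthetic_rgb_camera(
    grid: WavelengthGrid | None = None, nir_tail: bool = False
) -> CameraSensitivity:
    """A synthetic RGB quantum-efficiency model (three Gaussian bands).

    Stand-in for a CMOS RGB sensor: channels peak near 600 (R), 540 (G)
    and 460 nm (B) with ~90 nm FWHM.  With ``nir_tail=True`` all three
    channels additionally share an identical flat tail beyond 830 nm,
    emulating sensors whose channels become indistinct in the
    near-infrared (the NIR then carries no chromatic information).
    """
    if grid is None:
        grid = make_grid(400, 830, 5)
    lam = grid.values
    centers = (600.0, 540.0, 460.0)  # R, G, B
    sigma = 38.0
    C = np.stack(
        [np.exp(-((lam - mu) ** 2) / (2 * sigma**2)) for mu in centers],
        axis=1,
    )
    if nir_tail:
        tail = 0.25 * (1.0 / (1.0 + np.exp(-(lam - 840.0) / 10.0)))
        C = C + tail[:, None]
    return CameraSensitivity(grid, C, ("R", "G", "B"))
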