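"""File formats: two-column SPD CSVs, wide sub-light CSVs, camera
sensitivity CSVs, and labeled reflectance cubes as ENVI-style BSQ binaries
(with a JSON header) or multi-page TIFFs (with a sidecar JSON of band
wavelengths).  Masks travel as integer CSVs next to the cube.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .spectral import (
    SPD,
    CameraSensitivity,
    SubLightSet,
    WavelengthGrid,
    make_grid,
)
from .synthetic import LabeledReflectanceCube

__all__ = [
    "read_spd_csv",
    "write_spd_csv",
    "read_sublights_csv",
    "write_sublights_csv",
    "read_camera_csv",
    "write_camera_csv",
    "write_scene_envi",
    "read_scene_envi",
    "write_scene_tiff",
    "read_scene_tiff",
]


def _grid_from_wavelengths(wl: np.ndarray) -> WavelengthGrid:
    wl = np.asarray(wl, dtype=float)
    if wl.size < 2:
        raise ValueError("need at least two wavelengths")
    steps = np.diff(wl)
    if steps.min() <= 0 or not np.allclose(steps, steps[0], atol=1e-6):
        raise ValueError("wavelength axis must be uniform and increasing")
    return make_grid(wl[0], wl[-1], steps[0])


def read_spd_csv(path) -> SPD:
    """Read a two-column ``wavelength_nm,value`` CSV (header required)."""
    df = pd.read_csv(path)
    if "wavelength_nm" not in df.columns or df.shape[1] < 2:
        raise ValueError(
            f"{path}: expected columns 'wavelength_nm,value'"
        )
    value_col = [c for c in df.columns if c != "wavelength_nm"][0]
    grid = _grid_from_wavelengths(df["wavelength_nm"].to_numpy())
    return SPD(grid, df[value_col].to_numpy(dtype=float))


def write_spd_csv(spd: SPD, path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spd.grid.values, "value": spd.intensity}
    ).to_csv(path, index=False)


def read_sublights_csv(path) -> SubLightSet:
    """Read a wide sub-light CSV: ``wavelength_nm,light_01,light_02,...``.

    Nominal peaks are recovered as the argmax of each column.
    """
    df = pd.read_csv(path)
    if "wavelength_nm" not in df.columns or df.shape[1] < 2:
        raise ValueError(f"{path}: expected 'wavelength_nm' plus light columns")
    grid = _grid_from_wavelengths(df["wavelength_nm"].to_numpy())
    cols = [c for c in df.columns if c != "wavelength_nm"]
    Q = df[cols].to_numpy(dtype=float)
    peaks = grid.values[np.argmax(Q, axis=0)]
    return SubLightSet(grid, Q, peaks)


def write_sublights_csv(sublights: SubLightSet, path) -> None:
    data = {"wavelength_nm": sublights.grid.values}
    for i in range(sublights.n_lights):
        data[f"light_{i + 1:02d}"] = sublights.Q[:, i]
    pd.DataFrame(data).to_csv(path, index=False)


def read_camera_csv(path) -> CameraSensitivity:
    """Read sensitivities: ``wavelength_nm`` plus one column per channel."""
    df = pd.read_csv(path)
    if "wavelength_nm" not in df.columns or df.shape[1] < 2:
        raise ValueError(f"{path}: expected 'wavelength_nm' plus channels")
    grid = _grid_from_wavelengths(df["wavelength_nm"].to_numpy())
    cols = [c for c in df.columns if c != "wavelength_nm"]
    return CameraSensitivity(
        grid, df[cols].to_numpy(dtype=float), tuple(cols)
    )


def write_camera_csv(camera: CameraSensitivity, path) -> None:
    data = {"wavelength_nm": camera.grid.values}
    for name, col in zip(camera.channel_names, camera.C.T):
        data[name] = col
    pd.DataFrame(data).to_csv(path, index=False)


# --------------------------------------------------------------------------
# reflectance cubes
# --------------------------------------------------------------------------

def write_scene_envi(scene: LabeledReflectanceCube, path_base) -> None:
    """Write cube as band-sequential float32 + JSON header + mask CSV.

    Produces ``<base>.bsq``, ``<base>.hdr.json`` and ``<base>.mask.csv``.
    """
    base = Path(path_base)
    h, w, nb = scene.cube.shape
    bsq = np.ascontiguousarray(
        np.moveaxis(scene.cube, 2, 0), dtype="<f4"
    )  # (bands, lines, samples)
    bsq.tofile(base.with_suffix(".bsq"))
    header = {
        "samples": w,
        "lines": h,
        "bands": nb,
        "interleave": "bsq",
        "data type": "float32",
        "byte order": "little",
        "wavelength": scene.grid.values.tolist(),
        "wavelength units": "nm",
    }
    base.with_suffix(".hdr.json").write_text(json.dumps(header, indent=1))
    np.savetxt(base.with_suffix(".mask.csv"), scene.mask, fmt="%d", delimiter=",")


def read_scene_envi(path_base) -> LabeledReflectanceCube:
    base = Path(path_base)
    hdr_path = base.with_suffix(".hdr.json")
    if not hdr_path.exists():
        raise FileNotFoundError(f"missing header {hdr_path}")
    header = json.loads(hdr_path.read_text())
    if header.get("interleave", "bsq").lower() != "bsq":
        raise ValueError("only BSQ interleave is supported")
    shape = (header["bands"], header["lines"], header["samples"])
    cube = np.fromfile(base.with_suffix(".bsq"), dtype="<f4").reshape(shape)
    cube = np.moveaxis(cube, 0, 2).astype(float)
    grid = _grid_from_wavelengths(np.asarray(header["wavelength"]))
    mask = np.loadtxt(
        base.with_suffix(".mask.csv"), dtype=int, delimiter=","
    ).reshape(header["lines"], header["samples"])
    return LabeledReflectanceCube(np.clip(cube, 0, 1), mask, grid)


def write_scene_tiff(scene: LabeledReflectanceCube, path_base) -> None:
    """Write cube as a multi-page TIFF (page = band) + sidecar JSON + mask."""
    import tifffile

    base = Path(path_base)
    pages = np.moveaxis(scene.cube, 2, 0).astype(np.float32)
    tifffile.imwrite(base.with_suffix(".tiff"), pages)
    sidecar = {
        "wavelength": scene.grid.values.tolist(),
        "wavelength units": "nm",
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    np.savetxt(base.with_suffix(".mask.csv"), scene.mask, fmt="%d", delimiter=",")


def read_scene_tiff(path_base) -> LabeledReflectanceCube:
    import tifffile

    base = Path(path_base)
    pages = tifffile.imread(base.with_suffix(".tiff"))
    sidecar = json.loads(base.with_suffix(".json").read_text())
    grid = _grid_from_wavelengths(np.asarray(sidecar["wavelength"]))
    cube = np.moveaxis(np.asarray(pages, dtype=float), 0, 2)
    mask = np.loadtxt(
        base.with_suffix(".mask.csv"), dtype=int, delimiter=","
    ).reshape(cube.shape[0], cube.shape[1])
    return LabeledReflectanceCube(np.clip(cube, 0, 1), mask, grid)
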