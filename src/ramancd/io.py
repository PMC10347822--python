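"""Readers and writers for the formats the workflow touches.

Hyperspectral cubes travel as self-describing HDF5 (datasets ``wavenumbers``
and ``cube`` with a ``pixel_size_um`` attribute) or as long-format CSV with
columns ``row, col, wavenumber_cm1, counts`` (a ``# pixel_size_um=`` comment
line preserves the pixel size).  Micrographs, masks and heat maps are
grayscale TIFF or PNG; landmark pairs are CSV with columns ``moving_x,
moving_y, target_x, target_y``.
"""

from __future__ import annotations

import os
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .exceptions import (
    ColorImageError,
    LandmarkFormatError,
    NonMonotonicAxisError,
    SharedAxisError,
    ValidationError,
)
from .types import HyperspectralMap

__all__ = [
    "read_cube",
    "write_cube",
    "read_image",
    "write_image",
    "read_landmarks",
    "write_landmarks",
]

_CSV_COLUMNS = ["row", "col", "wavenumber_cm1", "counts"]


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("hdf5", "long-csv"):
            raise ValidationError(f"format must be 'hdf5' or 'long-csv', got {fmt!r}")
        return fmt
    if path.suffix.lower() in (".h5", ".hdf5"):
        return "hdf5"
    if path.suffix.lower() == ".csv":
        return "long-csv"
    raise ValidationError(f"cannot infer cube format from suffix {path.suffix!r}")


def read_cube(path, format: str | None = None) -> HyperspectralMap:
    """Read a hyperspectral cube; validates the shared-axis invariant."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            w = np.asarray(f["wavenumbers"], dtype=float)
            cube = np.asarray(f["cube"], dtype=float)
            pixel_size = float(f["cube"].attrs.get("pixel_size_um", 1.0))
        return HyperspectralMap(w, cube, pixel_size)

    pixel_size = 1.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "pixel_size_um=" in first:
                pixel_size = float(first.split("pixel_size_um=")[1])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"long CSV lacks columns {missing}")
    rows = int(df["row"].max()) + 1
    cols = int(df["col"].max()) + 1
    axes = df.groupby(["row", "col"])["wavenumber_cm1"].apply(np.asarray)
    ref = None
    for (r, c), ax in axes.items():
        if ref is None:
            ref = ax
        elif ax.shape != ref.shape or not np.allclose(ax, ref):
            raise SharedAxisError(
                f"pixel ({r}, {c}) has a different wavenumber axis"
            )
    if ref is None or len(axes) != rows * cols:
        raise ValidationError("long CSV does not cover a full rectangular grid")
    if not np.all(np.diff(ref) > 0):
        raise NonMonotonicAxisError("wavenumber axis must be strictly increasing")
    df = df.sort_values(["row", "col", "wavenumber_cm1"])
    cube = df["counts"].to_numpy(dtype=float).reshape(rows, cols, ref.size)
    return HyperspectralMap(ref, cube, pixel_size)


def write_cube(hsmap: HyperspectralMap, path, format: str | None = None) -> Path:
    """Write a cube losslessly; missing parent directories are created."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fmt = _infer_format(path, format)
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("wavenumbers", data=hsmap.wavenumbers)
            dset = f.create_dataset("cube", data=hsmap.cube)
            dset.attrs["pixel_size_um"] = hsmap.pixel_size_um
        return path
    rows, cols = hsmap.shape
    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    n = hsmap.n_channels
    df = pd.DataFrame(
        {
            "row": np.repeat(r.ravel(), n),
            "col": np.repeat(c.ravel(), n),
            "wavenumber_cm1": np.tile(hsmap.wavenumbers, rows * cols),
            "counts": hsmap.cube.reshape(-1),
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# pixel_size_um={hsmap.pixel_size_um}\n")
        df.to_csv(fh, index=False)
    return path


def read_image(path) -> np.ndarray:
    """Read a grayscale TIFF/PNG; color images are rejected."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        img = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        img = iio.imread(path)
    img = np.asarray(img)
    if img.ndim != 2:
        raise ColorImageError(
            f"{path.name} is not single-channel grayscale (shape {img.shape})"
        )
    return img


def write_image(image: np.ndarray, path) -> Path:
    """Write a 2-D grayscale image; dtype is preserved (use TIFF for floats)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = np.asarray(image)
    if img.ndim != 2:
        raise ColorImageError("only 2-D grayscale images are written")
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, img)
    else:
        import imageio.v3 as iio

        if img.dtype not in (np.uint8, np.uint16):
            raise ValidationError("PNG output requires uint8 or uint16 data")
        iio.imwrite(path, img)
    return path


def read_landmarks(path) -> np.ndarray:
    """Read landmark pairs: (N, 4) array (moving_x, moving_y, target_x, target_y).

    Malformed rows raise :class:`LandmarkFormatError` carrying the 1-based
    line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split(",")]
            if lineno == 1 and not _all_numeric(fields):
                continue  # header
            if len(fields) != 4:
                raise LandmarkFormatError(
                    f"line {lineno}: expected 4 fields, got {len(fields)}", line=lineno
                )
            try:
                pairs.append([float(f) for f in fields])
            except ValueError as err:
                raise LandmarkFormatError(
                    f"line {lineno}: non-numeric field ({err})", line=lineno
                ) from err
    return np.asarray(pairs, dtype=float).reshape(-1, 4)


def _all_numeric(fields) -> bool:
    try:
        [float(f) for f in fields]
        return True
    except ValueError:
        return False


def write_landmarks(pairs: np.ndarray, path) -> Path:
    """Write landmark pairs with the standard header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValidationError("landmarks must form an (N, 4) array")
    df = pd.DataFrame(arr, columns=["moving_x", "moving_y", "target_x", "target_y"])
    df.to_csv(path, index=False)
    return path
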