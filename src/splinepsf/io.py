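"""File I/O: movies (TIFF), PSF stacks, localization tables.

Movies are multi-page grayscale TIFFs holding photon counts; PSF stacks
are TIFF + a YAML sidecar carrying z positions, pixel size and wavelength;
splines live in HDF5 (see :meth:`splinepsf.splines.SplinePSF.save`);
localizations are written as CSV (human readable) and HDF5 (lossless).
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd
import tifffile
import yaml

from .fit import Localization
from .stack import PSFStack

__all__ = [
    "read_movie",
    "write_movie",
    "read_psf_stack",
    "write_psf_stack",
    "localizations_to_frame",
    "write_localizations",
    "read_localizations",
]

LOC_COLUMNS = ["frame", "x_px", "y_px", "x_nm", "y_nm", "z_nm", "photons",
               "background", "chi2", "iterations", "status"]


def read_movie(path) -> np.ndarray:
    """Load a multi-page grayscale TIFF as a (frames, h, w) float array."""
    path = pathlib.Path(path)
    if not path.exists():
        raise IOError(f"movie file not found: {path}")
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # corrupt file
        raise IOError(f"could not read movie {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    # channel-last arrays (h, w, 3|4) are RGB(A) images, not frame stacks
    if data.ndim == 3 and data.shape[-1] in (3, 4) and data.shape[0] > 4:
        raise ValueError(f"unsupported format in {path}: RGB input is not "
                         "supported, expected grayscale frames")
    if data.ndim != 3:
        raise ValueError(f"unsupported format in {path}: expected grayscale "
                         f"frames, got shape {data.shape}")
    if data.shape[0] == 0:
        raise ValueError(f"movie {path} has no frames")
    return data.astype(float)


def write_movie(path, movie: np.ndarray, dtype=np.float32) -> None:
    movie = np.asarray(movie)
    if movie.ndim == 2:
        movie = movie[None]
    # explicit grayscale: short stacks would otherwise be guessed as RGB
    tifffile.imwrite(path, movie.astype(dtype), photometric="minisblack")


def write_psf_stack(path, stack: PSFStack) -> None:
    """TIFF stack plus a ``<path>.yaml`` sidecar with the metadata."""
    path = pathlib.Path(path)
    tifffile.imwrite(path, stack.data.astype(np.float32),
                     photometric="minisblack")
    meta = {
        "z_positions_nm": [float(z) for z in stack.z_positions],
        "pixel_size_nm": float(stack.pixel_size),
        "wavelength_nm": float(stack.wavelength),
    }
    with open(path.with_suffix(path.suffix + ".yaml"), "w") as fh:
        yaml.safe_dump(meta, fh)


def read_psf_stack(path) -> PSFStack:
    path = pathlib.Path(path)
    sidecar = path.with_suffix(path.suffix + ".yaml")
    if not sidecar.exists():
        raise IOError(f"metadata sidecar not found: {sidecar}")
    data = tifffile.imread(path).astype(float)
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    return PSFStack(data, np.asarray(meta["z_positions_nm"], dtype=float),
                    meta["pixel_size_nm"], meta.get("wavelength_nm", 600.0))


# --------------------------------------------------------------------------
# Localization tables
# --------------------------------------------------------------------------

def localizations_to_frame(locs: list[Localization],
                           pixel_size: float) -> pd.DataFrame:
    """Tabulate localization records (positions in both px and nm)."""
    rows = [{
        "frame": loc.frame,
        "x_px": loc.x, "y_px": loc.y,
        "x_nm": loc.x * pixel_size, "y_nm": loc.y * pixel_size,
        "z_nm": loc.z,
        "photons": loc.photons, "background": loc.background,
        "chi2": loc.chi2, "iterations": loc.iterations, "status": loc.status,
    } for loc in locs]
    return pd.DataFrame(rows, columns=LOC_COLUMNS)


def write_localizations(records, path, fmt: str = "csv",
                        pixel_size: float = 160.0) -> None:
    """Write localizations as CSV or HDF5.

    ``records`` is a list of :class:`~splinepsf.fit.Localization` or an
    already-tabulated DataFrame.  An empty record list produces a
    header-only file.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = localizations_to_frame(records, pixel_size)
    path = pathlib.Path(path)
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "hdf5":
        import h5py

        with h5py.File(path, "w") as fh:
            for col in df.columns:
                values = df[col].to_numpy()
                if values.dtype == object:
                    values = values.astype("S")
                fh.create_dataset(col, data=values)
            fh.attrs["n_records"] = len(df)
    else:
        raise ValueError(f"unknown format {fmt!r} (use 'csv' or 'hdf5')")


def read_localizations(path) -> pd.DataFrame:
    path = pathlib.Path(path)
    if not path.exists():
        raise IOError(f"localization file not found: {path}")
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as fh:
            data = {}
            for col in LOC_COLUMNS:
                if col in fh:
                    values = fh[col][...]
                    if values.dtype.kind == "S":
                        values = values.astype(str)
                    data[col] = values
        return pd.DataFrame(data)
    return pd.read_csv(path)
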