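"""Image and grid IO: PNG/TIFF images, CSV grids, map serialization."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from neutrodent.membership import NeutrosophicMap

__all__ = [
    "load_grid_csv",
    "read_image",
    "save_grid_csv",
    "save_map_csv",
    "save_map_tiff",
    "load_map_tiff",
    "write_image",
]


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale PNG/TIFF and normalize intensities to [0, 1].

    8- and 16-bit integer images divide by their type maximum; float
    images are validated to lie in [0, 1].  Multi-channel images are
    averaged to one channel.
    """
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(float)
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise ValueError("float image intensities must lie in [0, 1]")
    return arr


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a [0, 1] float grid as an 8-bit grayscale image."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(path, (arr * 255.0).round().astype(np.uint8))


def save_map_tiff(path: str | Path, nmap: NeutrosophicMap) -> None:
    """Serialize a neutrosophic map as a 3-channel float TIFF (T, I, F)."""
    stack = np.stack([nmap.t_grid, nmap.i_grid, nmap.f_grid]).astype(np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack")


def load_map_tiff(path: str | Path) -> NeutrosophicMap:
    stack = tifffile.imread(path)
    return NeutrosophicMap(*(stack[k].astype(float) for k in range(3)))


def save_map_csv(prefix: str | Path, nmap: NeutrosophicMap) -> list[Path]:
    """Serialize a map as three CSV grids ``<prefix>_{t,i,f}.csv``."""
    prefix = Path(prefix)
    paths = []
    for name, grid in (("t", nmap.t_grid), ("i", nmap.i_grid), ("f", nmap.f_grid)):
        p = prefix.with_name(f"{prefix.name}_{name}.csv")
        np.savetxt(p, grid, delimiter=",")
        paths.append(p)
    return paths


def save_grid_csv(path: str | Path, grid: np.ndarray) -> None:
    np.savetxt(path, np.asarray(grid, dtype=float), delimiter=",")


def load_grid_csv(path: str | Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))
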