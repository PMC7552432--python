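"""Reading and writing phase rasters for the command-line tools.

TIFF is the working format (32-bit float, via tifffile); ``.npy`` arrays
and plain-text grids are accepted for convenience.
"""

from __future__ import annotations

import os

import numpy as np
import tifffile


def read_phase(path) -> np.ndarray:
    """Load a 2D floating-point raster from TIFF, .npy or text."""
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif ext == ".npy":
        arr = np.load(path)
    else:
        arr = np.loadtxt(path)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single 2D image, got shape {arr.shape}")
    return arr


def write_phase(path, arr) -> None:
    """Save a 2D raster as 32-bit float TIFF, .npy or text by extension."""
    ext = os.path.splitext(str(path))[1].lower()
    arr = np.asarray(arr)
    if ext in (".tif", ".tiff"):
        tifffile.imwrite(path, arr.astype(np.float32))
    elif ext == ".npy":
        np.save(path, arr)
    else:
        np.savetxt(path, arr)
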