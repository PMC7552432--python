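"""Wrapped-phase arithmetic: wrapping, wrapped differences and residue detection.

A wrapped phase is stored as a plain 2D float array with every value in the
half-open interval (-pi, pi].  Phase residues are the integer topological
charges obtained by summing wrapped differences around each 2x2 pixel loop;
a nonzero charge is the obstruction that makes path-following unwrapping
ambiguous.

Conventions (fixed throughout the package):

* wrapping interval (-pi, pi]; the boundary value -pi maps to +pi.
* residue loops are traversed (i,j) -> (i,j+1) -> (i+1,j+1) -> (i+1,j) ->
  (i,j) in (row, col) image coordinates, and the charge is anchored at the
  top-left pixel (i, j) of its loop.  With this orientation a phase vortex
  ``atan2(row - r0, col - c0)`` carries charge +1.  Reversing the
  orientation only flips every charge sign.
* arrays are 0-based and row-major; plaquette (i, j) spans pixels
  {i, i+1} x {j, j+1}.
"""

from __future__ import annotations

import csv

import numpy as np

__all__ = [
    "TWO_PI",
    "wrap",
    "wrapped_diff",
    "residue_map",
    "residue_mask",
    "count_residues",
    "residues_to_csv",
    "residue_overlay",
]

TWO_PI = 2.0 * np.pi

#: tolerance used when rounding a loop sum to an integer multiple of 2*pi
_CHARGE_TOL = 1e-6


def _as_float_array(phase, name: str = "phase") -> np.ndarray:
    arr = np.asarray(phase, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite (no NaN/Inf)")
    return arr


def _check_2d(arr: np.ndarray, name: str = "phase") -> None:
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError(f"{name} must be a 2D grid of at least 2x2 pixels")


def wrap(phase) -> np.ndarray:
    """Wrap angles into the half-open interval (-pi, pi].

    Values already inside the interval are returned bit-identical, which
    makes ``wrap`` exactly idempotent.  The boundary is tie-broken toward
    +pi: ``wrap(-pi) == pi``.
    """
    arr = _as_float_array(phase)
    # k = ceil((x - pi) / 2pi) is the unique integer with x - 2*pi*k in
    # (-pi, pi]; k == 0 whenever x is already wrapped, so those values pass
    # through untouched.
    k = np.ceil((arr - np.pi) / TWO_PI)
    return arr - TWO_PI * k


def wrapped_diff(a, b) -> np.ndarray:
    """Shortest signed arc from ``b`` to ``a``: ``wrap(a - b)``.

    This is the modulo-2*pi gradient used in residue detection; the result
    lies in (-pi, pi] with the exact-pi tie broken toward +pi.
    """
    a = _as_float_array(a, "a")
    b = _as_float_array(b, "b")
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return wrap(a - b)


def residue_map(phase) -> np.ndarray:
    """Integer residue charges on all 2x2 loops of a wrapped phase.

    Parameters
    ----------
    phase
        2D wrapped phase (radians), at least 2x2.

    Returns
    -------
    charges : int ndarray, shape (H-1, W-1)
        ``charges[i, j]`` is the winding number of the loop whose top-left
        pixel is (i, j).  Smooth phases (all neighbour differences below pi
        in magnitude) give all-zero charges.
    """
    arr = _as_float_array(phase)
    _check_2d(arr)
    # wrapped differences along rows (axis 1) and columns (axis 0)
    dx = wrapped_diff(arr[:, 1:], arr[:, :-1])  # (i,j) -> (i,j+1)
    dy = wrapped_diff(arr[1:, :], arr[:-1, :])  # (i,j) -> (i+1,j)
    # loop (i,j) -> (i,j+1) -> (i+1,j+1) -> (i+1,j) -> (i,j)
    loop = dx[:-1, :] + dy[:, 1:] - dx[1:, :] - dy[:, :-1]
    charges = loop / TWO_PI
    rounded = np.rint(charges)
    if not np.allclose(charges, rounded, atol=_CHARGE_TOL):
        raise ValueError("loop sums are not integer multiples of 2*pi")
    return rounded.astype(np.int64)


def residue_mask(charges) -> np.ndarray:
    """Binary mask (phase-shaped) marking the first pixel of each residue loop.

    The anchor (``FPR``) of the loop with charge at plaquette (i, j) is
    pixel (i, j).  The returned mask has the phase's shape
    ``(H, W) = charges.shape + (1, 1)``; its ones count equals the number of
    nonzero charges.
    """
    charges = np.asarray(charges)
    if charges.ndim != 2:
        raise ValueError("charges must be a 2D integer grid")
    mask = np.zeros((charges.shape[0] + 1, charges.shape[1] + 1), dtype=bool)
    mask[:-1, :-1] = charges != 0
    return mask


def count_residues(phase) -> int:
    """Number of nonzero residue charges in a wrapped phase."""
    return int(np.count_nonzero(residue_map(phase)))


def residues_to_csv(charges, path) -> None:
    """Write nonzero residues as ``row,col,charge`` rows."""
    charges = np.asarray(charges)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row", "col", "charge"])
        for i, j in zip(*np.nonzero(charges)):
            writer.writerow([int(i), int(j), int(charges[i, j])])


def residue_overlay(phase, charges) -> np.ndarray:
    """RGB uint8 image of the phase with residues marked for inspection.

    Positive charges are painted red, negative blue, on a grayscale
    rendering of the wrapped phase.  Intended for quick visual QC (save
    with ``imageio.imwrite``).
    """
    arr = _as_float_array(phase)
    charges = np.asarray(charges)
    gray = ((arr + np.pi) / TWO_PI * 255.0).astype(np.uint8)
    rgb = np.stack([gray, gray, gray], axis=-1)
    pos = charges > 0
    neg = charges < 0
    for mask, color in ((pos, (255, 0, 0)), (neg, (0, 0, 255))):
        for i, j in zip(*np.nonzero(mask)):
            rgb[i : i + 2, j : j + 2] = color
    return rgb
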