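"""Simple 1D (Itoh) phase unwrapping, applied line-by-line to 2D maps.

Itoh's method integrates wrapped neighbour differences along a line:

    out[0] = in[0];   out[k] = out[k-1] + wrap(in[k] - in[k-1])

which is exact whenever the true phase changes by less than pi per sample.
The implementation tracks the integer number of 2*pi offsets per pixel, so
every output value is the input plus an exact integer multiple of 2*pi
(up to one floating-point rounding in the final addition).

On a 2D map the 1D routine is applied along one axis, then the first line
of the transverse axis is unwrapped and its offsets propagated; the default
order (columns first) matches the behaviour of unwrapping a 2D array along
its first dimension.  The result is path-dependent in the presence of
residues — a warning is emitted in that case.
"""

from __future__ import annotations

import warnings

import numpy as np

from .phase_core import TWO_PI, residue_map, _as_float_array, _check_2d

__all__ = ["unwrap_1d_line", "unwrap_2d_by_1d", "ResidueWarning"]

_ORDERS = ("cols-then-rows", "rows-then-cols")


class ResidueWarning(UserWarning):
    """Raised when unwrapping a phase whose result is path-dependent."""


def _jump_integers(diffs: np.ndarray, axis: int = -1) -> np.ndarray:
    """Integer k per difference such that d - 2*pi*k lies in (-pi, pi]."""
    return np.ceil((diffs - np.pi) / TWO_PI).astype(np.int64)


def unwrap_1d_line(line) -> np.ndarray:
    """Itoh unwrapping of a 1D sequence of wrapped phases (radians)."""
    arr = _as_float_array(line, "line")
    if arr.ndim != 1:
        raise ValueError("unwrap_1d_line expects a 1D sequence")
    if arr.size == 0:
        return arr.copy()
    k = _jump_integers(np.diff(arr))
    offsets = np.concatenate([[0], -np.cumsum(k)])
    return arr + TWO_PI * offsets


def unwrap_2d_by_1d(phase, order: str = "cols-then-rows") -> np.ndarray:
    """Unwrap a 2D wrapped phase with successive 1D passes.

    ``"cols-then-rows"`` (default): every column is unwrapped independently,
    then the first row is unwrapped and each column is shifted by its row
    offset.  ``"rows-then-cols"`` transposes the roles.

    Each output pixel equals the input plus an integer multiple of 2*pi,
    so re-wrapping recovers the input.  If the input contains residues a
    :class:`ResidueWarning` is emitted: the result then depends on the
    traversal order.
    """
    arr = _as_float_array(phase)
    _check_2d(arr)
    if order not in _ORDERS:
        raise ValueError(f"order must be one of {_ORDERS}, got {order!r}")
    if np.count_nonzero(residue_map(arr)):
        warnings.warn(
            "phase contains residues: 1D unwrapping is path-dependent",
            ResidueWarning,
            stacklevel=2,
        )
    if order == "rows-then-cols":
        return unwrap_2d_by_1d(arr.T, "cols-then-rows").T

    # integer 2*pi offsets per pixel, accumulated exactly
    offsets = np.zeros(arr.shape, dtype=np.int64)
    k_col = _jump_integers(np.diff(arr, axis=0))
    offsets[1:, :] = -np.cumsum(k_col, axis=0)
    # first row of the column-unwrapped result is the original first row
    k_row = _jump_integers(np.diff(arr[0]))
    offsets[:, 1:] += -np.cumsum(k_row)[np.newaxis, :]
    return arr + TWO_PI * offsets
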