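"""Windowed phasor filtering of wrapped phases.

A wrapped phase cannot be smoothed directly: its sawtooth jumps are signal,
not noise, and a linear filter blurs them into unusable intermediate values.
The phasor exp(i*phi) is continuous across the jumps, so filtering is done
on the complex phasor field and the argument is taken afterwards:

    psi = arg{ L[ exp(i*phi) ] }

where ``L`` is a windowed mean or a component-wise (marginal) median.
Applied to every pixel this is plain phasor average filtering (PAF), the
non-adaptive baseline; the iterative residue-guided scheme lives in
:mod:`spaf.engine`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phase_core import count_residues, wrap, _as_float_array

__all__ = ["FilterSpec", "phasor_filter", "global_paf", "min_residue_free_window"]

logger = logging.getLogger(__name__)

_MODES = ("mean", "median")


@dataclass(frozen=True)
class FilterSpec:
    """Window geometry and statistic of a phasor filter.

    Window extents must be odd so the window is centred on the output pixel;
    anisotropic windows (different row/column extents) are allowed.
    ``mode`` selects the window statistic applied to the phasor field:
    ``"mean"`` (arithmetic mean of complex phasors) or ``"median"``
    (component-wise median of real and imaginary parts).
    """

    wf_rows: int = 3
    wf_cols: int = 3
    mode: str = "mean"

    def __post_init__(self) -> None:
        for name in ("wf_rows", "wf_cols"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1 or v % 2 == 0:
                raise ValueError(f"{name} must be an odd integer >= 1, got {v!r}")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")

    @property
    def size(self) -> tuple[int, int]:
        return (int(self.wf_rows), int(self.wf_cols))


def phasor_filter(phase, spec: FilterSpec) -> np.ndarray:
    """Filter a wrapped phase through its phasor representation.

    The phasor field exp(i*phi) is smoothed component-wise with the window
    statistic from ``spec`` (reflect padding at the borders) and the
    argument of the result is wrapped back into (-pi, pi].

    Where the windowed phasor sum vanishes (antipodal phasors cancelling)
    the argument is undefined; those pixels keep their input value and the
    occurrence is logged at DEBUG level.
    """
    arr = _as_float_array(phase)
    z = np.exp(1j * arr)
    if spec.mode == "mean":
        re = ndimage.uniform_filter(z.real, size=spec.size, mode="reflect")
        im = ndimage.uniform_filter(z.imag, size=spec.size, mode="reflect")
    else:
        re = ndimage.median_filter(z.real, size=spec.size, mode="reflect")
        im = ndimage.median_filter(z.imag, size=spec.size, mode="reflect")
    out = wrap(np.arctan2(im, re))
    degenerate = np.hypot(re, im) < 1e-12
    if np.any(degenerate):
        logger.debug(
            "phasor_filter: %d pixel(s) with vanishing phasor sum kept their "
            "input value",
            int(np.count_nonzero(degenerate)),
        )
        out = np.where(degenerate, arr, out)
    return out


def global_paf(phase, spec: FilterSpec) -> np.ndarray:
    """Phasor average filtering applied to every pixel (the PAF baseline)."""
    return phasor_filter(phase, spec)


def min_residue_free_window(
    phase,
    mode: str = "mean",
    wf_start: int = 3,
    wf_max: int = 61,
) -> tuple[int, np.ndarray]:
    """Smallest square PAF window that leaves the phase residue-free.

    Escalates odd window sizes from ``wf_start`` to ``wf_max`` and returns
    ``(wf, filtered)`` for the first window whose globally filtered output
    has zero residues.  Raises ``RuntimeError`` if no window up to
    ``wf_max`` succeeds.  This is the operating point a non-adaptive PAF
    user would have to accept, and the comparison baseline for resolution-
    preservation measurements.
    """
    for wf in range(wf_start, wf_max + 1, 2):
        filtered = global_paf(phase, FilterSpec(wf, wf, mode))
        if count_residues(filtered) == 0:
            return wf, filtered
    raise RuntimeError(
        f"global PAF did not reach zero residues for any window <= {wf_max}"
    )
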