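"""The iterative SPAF engine.

Smart phasor average filtering (SPAF) removes phase residues from a noisy
wrapped phase while touching as few pixels as possible.  Each iteration

1. locates the residues (2x2 loop charges) of the current phase,
2. stops if the count is at or below the target (normally zero),
3. phasor-filters the full phase with the current window ``wf``,
4. builds a binary patch mask: the union of ``wp x wp`` squares around the
   first pixel (FPR) of every residue loop,
5. substitutes the filtered values only inside the mask,

    phi_m = (1 - P_wp) * phi_{m-1} + P_wp * filter_wf[phi_{m-1}]

6. recomputes the residues (they can shift between neighbouring pixels
   under filtering) and repeats.

When the residue count stalls, the filter window grows first and only once
the window is exhausted does the patch grow — growing patches first would
spread filtering artifacts further than necessary.  Escalation on every
iteration (rather than on stall) is available through
``SpafConfig.escalate_on``.

Pixels outside the patch mask are bit-identical before and after each
iteration; this locality contract is what preserves high-spatial-frequency
content that global filtering would destroy.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .filters import FilterSpec, phasor_filter
from .phase_core import residue_map, residue_mask, _as_float_array, _check_2d

__all__ = [
    "SpafConfig",
    "SpafIteration",
    "SpafTrace",
    "patch_mask",
    "spaf_step",
    "run_spaf",
]


@dataclass(frozen=True)
class SpafConfig:
    """Schedule parameters of the SPAF loop.

    Attributes
    ----------
    wf_start, wf_max : int
        Odd phasor-filter window extents; the window grows by +2 per
        escalation.
    wp_start, wp_max : int
        Patch extents; the patch grows by +1 once the window is exhausted
        (the window then restarts from ``wf_start``).  ``wp = 2`` covers
        exactly the 2x2 residue loop.  The default cap of 15 px reflects
        a patch a few times the optical resolution.
    filter_mode : str
        ``"mean"`` or ``"median"`` phasor statistic.
    max_iterations : int
        Hard iteration cap; hitting it is reported, not raised.
    target_residues : int
        Stop once the residue count is at or below this (default 0).
    escalate_on : str
        ``"stall"`` (grow only when the count stops improving) or
        ``"always"`` (grow every iteration).
    """

    wf_start: int = 3
    wf_max: int = 15
    wp_start: int = 2
    wp_max: int = 15
    filter_mode: str = "mean"
    max_iterations: int = 500
    target_residues: int = 0
    escalate_on: str = "stall"

    def __post_init__(self) -> None:
        if self.wf_start > self.wf_max:
            raise ValueError("wf_start must not exceed wf_max")
        if self.wp_start > self.wp_max:
            raise ValueError("wp_start must not exceed wp_max")
        if self.wf_start < 1 or self.wf_start % 2 == 0 or self.wf_max % 2 == 0:
            raise ValueError("filter windows must be odd and >= 1")
        if self.wp_start < 1:
            raise ValueError("wp_start must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.escalate_on not in ("stall", "always"):
            raise ValueError("escalate_on must be 'stall' or 'always'")
        FilterSpec(self.wf_start, self.wf_start, self.filter_mode)  # validates mode


@dataclass(frozen=True)
class SpafIteration:
    """One row of the SPAF trace."""

    iteration: int
    wf_rows: int
    wf_cols: int
    wp: int
    n_residues: int


@dataclass
class SpafTrace:
    """Per-iteration diagnostics of a SPAF run.

    ``records[0]`` describes the input phase (iteration 0); the terminal
    ``status`` is one of ``"residue-free"``, ``"cap-reached"`` or
    ``"max-iter"``.
    """

    records: list[SpafIteration] = field(default_factory=list)
    status: str = ""

    @property
    def n_iterations(self) -> int:
        return self.records[-1].iteration

    @property
    def final_residues(self) -> int:
        return self.records[-1].n_residues

    @property
    def residue_counts(self) -> np.ndarray:
        """Residue count per iteration (the curve of the diagnostics plot)."""
        return np.array([r.n_residues for r in self.records])

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["iteration", "wf_rows", "wf_cols", "wp", "n_residues"])
            for r in self.records:
                writer.writerow([r.iteration, r.wf_rows, r.wf_cols, r.wp, r.n_residues])


def patch_mask(fpr, wp: int) -> np.ndarray:
    """Union of ``wp x wp`` squares around each marked FPR pixel.

    Squares are centred on the FPR; for even ``wp`` the extra row/column
    extends right/down, so ``wp = 2`` covers exactly the four pixels of the
    residue loop.  Squares are clipped at the image border, and overlapping
    squares merge into a single region.
    """
    fpr = np.asarray(fpr, dtype=bool)
    if wp < 1:
        raise ValueError("wp must be >= 1")
    mask = np.zeros_like(fpr)
    top = (wp - 1) // 2  # extent above/left of the anchor
    h, w = fpr.shape
    for i, j in zip(*np.nonzero(fpr)):
        r0 = max(i - top, 0)
        c0 = max(j - top, 0)
        mask[r0 : min(i - top + wp, h), c0 : min(j - top + wp, w)] = True
    return mask


def spaf_step(phase, fpr, spec: FilterSpec, wp: int) -> np.ndarray:
    """One masked substitution step.

    The phasor filter is evaluated from the full input phase (windows may
    read outside the patch); its values replace the input only inside the
    patch mask.  Pixels outside the mask are returned bit-identical.
    """
    arr = _as_float_array(phase)
    mask = patch_mask(fpr, wp)
    if not mask.any():
        return arr.copy()
    filtered = phasor_filter(arr, spec)
    return np.where(mask, filtered, arr)


def run_spaf(
    phase,
    config: SpafConfig = SpafConfig(),
    on_iteration: Optional[Callable[[int, np.ndarray, np.ndarray, np.ndarray], None]] = None,
) -> tuple[np.ndarray, SpafTrace]:
    """Run the full SPAF schedule on a wrapped phase.

    Parameters
    ----------
    phase
        2D wrapped phase in (-pi, pi].
    config
        Schedule parameters; the run is deterministic given (phase, config).
    on_iteration
        Optional callback ``f(m, phase_before, phase_after, mask)`` invoked
        after each substitution step, for diagnostics.

    Returns
    -------
    filtered, trace
        The final wrapped phase and the per-iteration trace.
        Non-convergence is not an error: the trace's ``status`` reports
        whether the run ended residue-free, exhausted the window/patch caps,
        or hit ``max_iterations``.
    """
    arr = _as_float_array(phase).copy()
    _check_2d(arr)
    wf, wp = config.wf_start, config.wp_start
    charges = residue_map(arr)
    count = int(np.count_nonzero(charges))
    trace = SpafTrace(records=[SpafIteration(0, wf, wf, wp, count)])
    if count <= config.target_residues:
        trace.status = "residue-free"
        return arr, trace

    best = count
    trace.status = "max-iter"
    for m in range(1, config.max_iterations + 1):
        fpr = residue_mask(charges)
        spec = FilterSpec(wf, wf, config.filter_mode)
        mask = patch_mask(fpr, wp)
        filtered = phasor_filter(arr, spec)
        new = np.where(mask, filtered, arr)
        charges = residue_map(new)
        count = int(np.count_nonzero(charges))
        trace.records.append(SpafIteration(m, wf, wf, wp, count))
        if on_iteration is not None:
            on_iteration(m, arr, new, mask)
        arr = new
        if count <= config.target_residues:
            trace.status = "residue-free"
            break
        if config.escalate_on == "always" or count >= best:
            if wf + 2 <= config.wf_max:
                wf += 2
            elif wp + 1 <= config.wp_max:
                wp += 1
                wf = config.wf_start
            else:
                trace.status = "cap-reached"
                break
        best = min(best, count)
    return arr, trace
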