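"""Synthetic wrapped phases and the noise model used throughout the tests.

The reference simulation condition is a centred 2D Gaussian bump of peak
height 30 rad on a 400 x 600 px grid, corrupted in the phasor domain by
multiplicative speckle of variance 2 and additive white Gaussian noise at a
signal-to-noise ratio of 6 (linear power ratio by default).  Noise acts on
the complex field exp(i*phi), not on the raw phase values: that is where
speckle and sensor noise physically live, and it is what creates phase
residues.

Additional fixtures: ideal phase vortices with prescribed integer charges
(the canonical residue test object) and a band-limited textured phase whose
energy spans low and high spatial frequencies, used for resolution-
preservation measurements in place of a natural test image.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .phase_core import wrap, count_residues

__all__ = [
    "SimSpec",
    "gaussian_phase",
    "add_noise",
    "noisy_gaussian_phase",
    "vortex_phase",
    "textured_phase",
]


@dataclass(frozen=True)
class SimSpec:
    """Parameters of the simulated noisy Gaussian phase.

    ``bump_sigma`` defaults to 60 px so the bump spans roughly half of the
    shorter image dimension and its wrap produces several fringe rings.
    ``awgn_snr`` is a linear power ratio unless ``snr_in_db`` is set.
    """

    shape: tuple[int, int] = (400, 600)
    bump_height: float = 30.0
    bump_sigma: float = 60.0
    speckle_variance: float = 2.0
    awgn_snr: float = 6.0
    snr_in_db: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bump_height <= 0:
            raise ValueError("bump_height must be > 0")
        if self.speckle_variance < 0:
            raise ValueError("speckle_variance must be >= 0")
        if self.awgn_snr <= 0:
            raise ValueError("awgn_snr must be > 0")

    @property
    def snr_linear(self) -> float:
        return 10.0 ** (self.awgn_snr / 10.0) if self.snr_in_db else self.awgn_snr

    @property
    def bump_center(self) -> tuple[int, int]:
        """Grid pixel at which the Gaussian bump attains its peak."""
        return (self.shape[0] // 2, self.shape[1] // 2)


def gaussian_phase(spec: SimSpec = SimSpec()) -> tuple[np.ndarray, np.ndarray]:
    """Centred Gaussian bump: ground truth and its wrap.

    Returns ``(truth, wrapped)`` where ``truth`` peaks at exactly
    ``bump_height`` radians and ``wrapped == wrap(truth)``.  The bump is
    smooth, so the wrapped version is residue-free.  The centre sits on the
    grid pixel ``(rows // 2, cols // 2)`` so the peak value is attained
    exactly.
    """
    h, w = spec.shape
    rows = np.arange(h) - h // 2
    cols = np.arange(w) - w // 2
    r2 = rows[:, None] ** 2 + cols[None, :] ** 2
    truth = spec.bump_height * np.exp(-r2 / (2.0 * spec.bump_sigma**2))
    return truth, wrap(truth)


def add_noise(
    phase,
    spec: SimSpec = SimSpec(),
    rng: Optional[np.random.Generator] = None,
    return_fields: bool = False,
):
    """Corrupt a wrapped phase in the phasor domain.

    The phasor field ``z = exp(i*phase)`` receives multiplicative speckle
    ``z * (1 + u)`` with ``u`` zero-mean uniform of variance
    ``speckle_variance``, followed by additive complex white Gaussian noise
    scaled so that (speckled) signal power over noise power equals
    ``snr_linear``.  The returned phase is the wrapped argument of the
    noisy field.

    With ``return_fields=True`` also returns the noise-free speckled field
    and the realised additive noise, for empirical SNR checks.
    """
    arr = np.asarray(phase, dtype=float)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    z = np.exp(1j * arr)
    if spec.speckle_variance > 0:
        half_width = np.sqrt(3.0 * spec.speckle_variance)
        u = rng.uniform(-half_width, half_width, size=arr.shape)
        z = z * (1.0 + u)
    signal_power = float(np.mean(np.abs(z) ** 2))
    noise_power = signal_power / spec.snr_linear
    noise = np.sqrt(noise_power / 2.0) * (
        rng.standard_normal(arr.shape) + 1j * rng.standard_normal(arr.shape)
    )
    noisy = wrap(np.angle(z + noise))
    if return_fields:
        return noisy, z, noise
    return noisy


def noisy_gaussian_phase(spec: SimSpec = SimSpec()) -> tuple[np.ndarray, np.ndarray]:
    """Convenience: ``(truth, noisy wrapped phase)`` for the default study."""
    truth, wrapped = gaussian_phase(spec)
    return truth, add_noise(wrapped, spec)


def vortex_phase(
    shape: tuple[int, int],
    charges: Sequence[tuple[float, float, int]],
) -> np.ndarray:
    """Wrapped superposition of ideal phase vortices.

    Each ``(row, col, q)`` places a vortex of integer charge ``q`` at
    sub-pixel centre ``(row, col)``; the residue map of the result carries
    exactly those charges, at the plaquettes containing the centres.
    Centres must lie strictly inside the grid, off pixel centres, and must
    not coincide.
    """
    h, w = shape
    seen = set()
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    total = np.zeros(shape, dtype=float)
    for r0, c0, q in charges:
        if not (0 < r0 < h - 1 and 0 < c0 < w - 1):
            raise ValueError(f"vortex centre ({r0}, {c0}) outside the grid interior")
        if (r0, c0) in seen:
            raise ValueError(f"coincident vortex centres at ({r0}, {c0})")
        seen.add((r0, c0))
        total += q * np.arctan2(rows - r0, cols - c0)
    return wrap(total)


def textured_phase(
    shape: tuple[int, int] = (256, 256),
    seed: int = 0,
    peak: float = 2.5,
    knee: float = 0.08,
    floor: float = 0.05,
) -> np.ndarray:
    """Band-limited random phase with broadband spatial-frequency content.

    White complex noise is shaped in the Fourier domain by an isotropic
    amplitude profile ``1 / (1 + (k / knee)^2) + floor`` (``k`` in cycles
    per pixel) whose flat floor keeps energy up to Nyquist, then scaled to
    a peak magnitude of ``peak`` radians — low enough that the map wraps
    nowhere and is residue-free, so it can serve as its own ground truth in
    resolution-preservation experiments.  If the initial scaling still
    produces residues (possible for aggressive ``peak``), the amplitude is
    reduced until the map is clean; the procedure is deterministic given
    the seed.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    noise = rng.standard_normal((h, w)) + 1j * rng.standard_normal((h, w))
    ky = np.fft.fftfreq(h)[:, None]
    kx = np.fft.fftfreq(w)[None, :]
    k = np.hypot(ky, kx)
    profile = 1.0 / (1.0 + (k / knee) ** 2) + floor
    field = np.fft.ifft2(noise * profile).real
    field -= field.mean()
    field *= peak / np.max(np.abs(field))
    while count_residues(field) > 0:
        field *= 0.8
    return wrap(field)
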