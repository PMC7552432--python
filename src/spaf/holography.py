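"""Off-axis hologram forward model and first-order Fourier demodulation.

An off-axis interferogram records the sample field against a tilted
reference beam, producing a carrier fringe of spatial frequency ``q``
(cycles/pixel, along x):

    I = |E_R|^2 + |E_S|^2 + 2 |E_R| |E_S| cos(2*pi*q*x + phi_S - phi_R)

The cosine term places a copy of the object spectrum at +/-q in the
Fourier plane.  Demodulation crops a disk of radius ``f_NA`` (sized to the
imaging system's numerical aperture) around the +q order, recentres it and
inverse-transforms, recovering the complex object field whose argument is
the wrapped phase difference — the input to residue filtering and
unwrapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .phase_core import wrap

__all__ = ["CarrierSpec", "simulate_hologram", "demodulate", "demodulated_phase"]

_NYQUIST = 0.5  # cycles/pixel


@dataclass(frozen=True)
class CarrierSpec:
    """Carrier frequency and first-order crop radius, in cycles/pixel.

    Separability of the first order from the DC term requires
    ``0 < f_na < q/2`` and ``q/2 < 0.25`` (so the order plus its sidelobe
    support stays below Nyquist).
    """

    q: float
    f_na: float

    def __post_init__(self) -> None:
        if not (0.0 < self.f_na < self.q / 2.0 < _NYQUIST / 2.0):
            raise ValueError(
                "carrier must satisfy 0 < f_na < q/2 < 0.25 cycles/pixel, "
                f"got q={self.q}, f_na={self.f_na}"
            )


def simulate_hologram(sample, reference, carrier: CarrierSpec) -> np.ndarray:
    """Intensity recorded by an off-axis interferometer.

    ``sample`` and ``reference`` are complex 2D fields of matching shape;
    the returned intensity is real and non-negative.
    """
    s = np.asarray(sample, dtype=complex)
    r = np.asarray(reference, dtype=complex)
    if s.shape != r.shape:
        raise ValueError(f"shape mismatch: {s.shape} vs {r.shape}")
    if not (np.all(np.isfinite(s.view(float))) and np.all(np.isfinite(r.view(float)))):
        raise ValueError("fields must be finite")
    x = np.arange(s.shape[1])[None, :]
    fringe = np.cos(2.0 * np.pi * carrier.q * x + np.angle(s) - np.angle(r))
    intensity = np.abs(r) ** 2 + np.abs(s) ** 2 + 2.0 * np.abs(r) * np.abs(s) * fringe
    # clamp tiny negative round-off; analytically I >= (|R| - |S|)^2 >= 0
    return np.maximum(intensity, 0.0)


def demodulate(
    intensity,
    carrier: CarrierSpec,
    background=None,
    soft_edge: bool = False,
) -> np.ndarray:
    """Recover the complex object field from an off-axis hologram.

    The intensity spectrum is cropped with a disk of radius ``f_na``
    centred on the brightest bin near the +q carrier peak, shifted to DC
    and inverse-transformed.  ``background`` (an amplitude map, e.g. from a
    sample-free hologram) optionally normalises the recovered amplitude.
    ``soft_edge=True`` replaces the hard-edged disk with a Gaussian
    roll-off at the rim to reduce ringing.

    Returns the complex field; its wrapped phase is
    :func:`demodulated_phase`.
    """
    arr = np.asarray(intensity, dtype=float)
    h, w = arr.shape
    spectrum = np.fft.fftshift(np.fft.fft2(arr))
    fy = np.fft.fftshift(np.fft.fftfreq(h))[:, None]
    fx = np.fft.fftshift(np.fft.fftfreq(w))[None, :]

    # locate the +q order: brightest bin within f_na of (fx=q, fy=0)
    near = np.hypot(fy, fx - carrier.q) <= max(carrier.f_na, 2.0 / min(h, w))
    if not near.any():
        raise ValueError("no spectral bins near the requested carrier frequency")
    masked = np.where(near, np.abs(spectrum), -np.inf)
    pk_r, pk_c = np.unravel_index(int(np.argmax(masked)), arr.shape)
    if np.hypot(fy[pk_r, 0], fx[0, pk_c]) <= 2.0 * carrier.f_na:
        warnings.warn(
            "first order overlaps the DC term; demodulation may be corrupted",
            stacklevel=2,
        )

    dist = np.hypot(fy - fy[pk_r, 0], fx - fx[0, pk_c])
    if soft_edge:
        sigma = 0.1 * carrier.f_na
        window = np.where(
            dist <= carrier.f_na,
            1.0,
            np.exp(-0.5 * ((dist - carrier.f_na) / sigma) ** 2),
        )
    else:
        window = (dist <= carrier.f_na).astype(float)
    cropped = spectrum * window
    # shift the order to DC (circular roll preserves the cropped energy)
    cropped = np.roll(cropped, (h // 2 - pk_r, w // 2 - pk_c), axis=(0, 1))
    field = np.fft.ifft2(np.fft.ifftshift(cropped))
    if background is not None:
        field = field / np.asarray(background, dtype=float)
    return field


def demodulated_phase(intensity, carrier: CarrierSpec, **kwargs) -> np.ndarray:
    """Wrapped phase of the demodulated object field, in (-pi, pi]."""
    return wrap(np.angle(demodulate(intensity, carrier, **kwargs)))
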