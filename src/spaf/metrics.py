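"""Quantitative error metrics: pixel-domain RSE and radial spectral analysis.

Two complementary views of filtering damage:

* the relative square error RSE = ||phi - phi_GT||^2 / ||phi_GT||^2
  measures average per-pixel error against a ground truth;
* the radially averaged log-spectrum of the phasor field exp(i*phi)
  measures how much energy survives at each absolute spatial frequency —
  the quantity that distinguishes a filter that blurs everywhere from one
  that acts only around residues.  Curves are compared with an RSE on the
  max-normalised radial profiles ("spectral RSE").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RadialSpectrum",
    "rse",
    "phasor_spectrum",
    "radial_average",
    "spectral_rse",
]


@dataclass(frozen=True)
class RadialSpectrum:
    """Radially averaged log-intensity of a DC-centred 2D spectrum.

    ``k`` holds annulus centres as absolute spatial frequency normalised to
    Nyquist (1.0 = Nyquist); ``log_intensity`` the mean natural log of the
    intensity over each annulus; ``delta`` the uniform annulus thickness.
    ``merged`` flags annuli that were empty and inherited a neighbour's
    value (only possible for very small images / many bins).
    """

    k: np.ndarray
    log_intensity: np.ndarray
    delta: float
    merged: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.merged is None:
            object.__setattr__(self, "merged", np.zeros(len(self.k), dtype=bool))

    def normalized(self) -> np.ndarray:
        """Log of the max-normalised intensity: ``logI - max(logI)``.

        Equivalent to dividing the intensity curve by its maximum before
        the log, so a global rescaling of the spectrum cancels exactly.
        """
        return self.log_intensity - np.max(self.log_intensity)


def rse(phase, truth) -> float:
    """Relative square error ||phi - phi_GT||^2 / ||phi_GT||^2.

    Returned as a fraction (multiply by 100 for the conventional percent
    form).  Raises for mismatched shapes or an all-zero ground truth.
    """
    a = np.asarray(phase, dtype=float)
    t = np.asarray(truth, dtype=float)
    if a.shape != t.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {t.shape}")
    denom = float(np.sum(t * t))
    if denom == 0.0:
        raise ValueError("ground truth has zero norm")
    return float(np.sum((a - t) ** 2)) / denom


def phasor_spectrum(phase) -> np.ndarray:
    """Magnitude of the DC-centred 2D Fourier transform of exp(i*phi)."""
    arr = np.asarray(phase, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("phase must be finite")
    return np.abs(np.fft.fftshift(np.fft.fft2(np.exp(1j * arr))))


def radial_average(spectrum, n_bins: int = 64) -> RadialSpectrum:
    """Mean log-intensity over concentric annuli of a DC-centred spectrum.

    Frequencies are normalised to Nyquist; ``n_bins`` uniform annuli tile
    [0, 1] (corner frequencies beyond Nyquist are discarded so every
    annulus is a full circle).  Zero bins are floored at machine epsilon
    times the spectral maximum before the log.  An empty annulus inherits
    its inner neighbour's value and is flagged in ``merged``.
    """
    spec = np.asarray(spectrum, dtype=float)
    if spec.ndim != 2:
        raise ValueError("spectrum must be 2D")
    h, w = spec.shape
    ky = np.fft.fftshift(np.fft.fftfreq(h))[:, None] / 0.5
    kx = np.fft.fftshift(np.fft.fftfreq(w))[None, :] / 0.5
    kr = np.hypot(ky, kx)

    floor = np.finfo(float).eps * np.max(spec)
    logs = np.log(np.maximum(spec, floor))

    delta = 1.0 / n_bins
    idx = np.floor(kr / delta).astype(int)
    valid = (kr <= 1.0) & (idx < n_bins)
    sums = np.bincount(idx[valid], weights=logs[valid], minlength=n_bins)
    counts = np.bincount(idx[valid], minlength=n_bins)

    log_i = np.empty(n_bins)
    merged = np.zeros(n_bins, dtype=bool)
    last = 0.0
    for i in range(n_bins):
        if counts[i] > 0:
            log_i[i] = sums[i] / counts[i]
            last = log_i[i]
        else:
            log_i[i] = last
            merged[i] = True
    k_centres = (np.arange(n_bins) + 0.5) * delta
    return RadialSpectrum(k=k_centres, log_intensity=log_i, delta=delta, merged=merged)


def spectral_rse(measured: RadialSpectrum, reference: RadialSpectrum) -> float:
    """RSE between two max-normalised radial log-intensity curves.

    Normalisation to each curve's own maximum removes overall intensity
    scale, so the metric responds only to the *shape* of the frequency
    falloff — i.e. to lost high-frequency content.  Returned as a
    fraction, relative to ``reference``.
    """
    if len(measured.k) != len(reference.k) or not np.allclose(measured.k, reference.k):
        raise ValueError("radial spectra use different binnings")
    a = measured.normalized()
    b = reference.normalized()
    return float(np.sum((a - b) ** 2) / np.sum(b * b))
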