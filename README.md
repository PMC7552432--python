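# spaf — smart phasor average filtering of noisy wrapped phases

Quantitative phase imaging (digital holographic microscopy, interferometry,
InSAR-style fringe analysis) measures phase modulo 2π.  Recovering the
continuous phase — *unwrapping* — fails in the presence of **phase
residues**: pixels where speckle and sensor noise have corrupted the
wrapped phase so badly that summing wrapped differences around a 2×2 pixel
loop yields a nonzero winding number

> Σ<sub>p∈loop</sub> ∇φ<sub>p</sub> = 2πn,  n ≠ 0.

Classical fixes filter *every* pixel of the phasor field exp(iφ)
(sine/cosine or windowed-Fourier filtering), which removes the residues but
also destroys the high-spatial-frequency content that a high-NA microscope
objective exists to deliver.

**SPAF** (smart phasor average filtering) removes residues while leaving
almost the whole image untouched.  Each iteration locates the residues,
phasor-filters the phase with window *wf*, and substitutes the filtered
values only inside *wp*×*wp* patches around each residue:

> φ<sup>m</sup> = [1 − P<sub>wp</sub>(U<sub>R</sub>)]·φ<sup>m−1</sup> + P<sub>wp</sub>(U<sub>R</sub>)·ℓ<sub>wf</sub>[φ<sup>m−1</sup>],  ℓ<sub>wf</sub>[φ] = arg{L<sub>wf</sub>[e<sup>iφ</sup>]}

When the residue count stalls, the filter window grows first, then the
patch, until the phase is residue-free and a simple 1D (Itoh) unwrapper
suffices.

The package ships the complete pipeline: wrapped-phase arithmetic and
residue detection, phasor mean/median filters, the SPAF engine with
per-iteration trace, 1D/2D Itoh unwrapping, an off-axis hologram
simulator + Fourier demodulator, synthetic data generators (noisy Gaussian
bump, vortices, textured phases), and spectral resolution metrics (RSE and
radially averaged log-spectra).

## Worked example

```python
from spaf import SimSpec, SpafConfig, count_residues, noisy_gaussian_phase, \
    run_spaf, unwrap_2d_by_1d

spec = SimSpec(seed=1)                 # 400x600 px, 30 rad bump,
truth, noisy = noisy_gaussian_phase(spec)  # speckle var 2 + AWGN snr 6
print(count_residues(noisy))           # 58054

filtered, trace = run_spaf(noisy, SpafConfig())
print(trace.status, trace.n_iterations)  # residue-free 41

unwrapped = unwrap_2d_by_1d(filtered)
```

Running `python examples/01_filter_noisy_gaussian.py` prints:

```
noisy wrapped phase: 400x600 px, 58054 residues
SPAF: status=residue-free after 41 iterations, final window wf=11, patch wp=2
residue counts over the first iterations: [58054  9026  2058   965   576   420   330   257]
recovered bump height: 30.06 rad (generated height: 30.0 rad)
```

The residue count collapses in the first few iterations and reaches zero,
after which the simple 1D unwrapper recovers the generating 30 rad bump to
within the noise floor.  `examples/04_resolution_preservation.py` shows the
point of being *smart* about where to filter: on a broadband textured phase
with the same noise, SPAF's radial-spectrum error versus ground truth is
5.4 % where the smallest residue-free global PAF costs 66 % — a 12×
resolution-preservation gap.

The other examples demonstrate residue detection on vortex fixtures
(`02_residue_detection.py`) and the off-axis hologram round trip
(`03_hologram_to_phase.py`).

## Command line

```sh
spaf simulate --preset paper --seed 3 --out-truth truth.tif --out-wrapped noisy.tif
spaf run --input noisy.tif --out filtered.tif --trace trace.csv --unwrap
spaf unwrap --input filtered.tif --out unwrapped.tif --order cols-rows
spaf demodulate --input hologram.tif --q 0.25 --fna 0.08 --out wrapped.tif
spaf metrics --phase a.tif --truth b.tif --out report.json
```

`trace.csv` holds the per-iteration schedule and residue counts
(`iteration, wf_rows, wf_cols, wp, n_residues`).

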