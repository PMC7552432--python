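# Methods

## Problem and model

A wrapped phase map φ ∈ (−π, π] carries the true phase modulo 2π.  Noise
splits the map into pixels with ordinary (amplitude-like) noise and pixels
carrying **residues**: 2×2 pixel loops around which the sum of wrapped
neighbour differences is 2πn with integer n ≠ 0.  Any path-following
unwrapper becomes path-dependent in their presence, so the practical goal
is to drive the residue count to zero with the least possible damage to
the image.

Filtering is done on the phasor field exp(iφ), which is continuous across
the sawtooth jumps of the wrapped map; the filtered phase is
ψ = arg{L[exp(iφ)]}, with L a windowed mean or marginal median.  SPAF
applies this filter **only inside patches around residues** and escalates
window then patch size until the map is residue-free:

    φ_m = (1 − P_wp(U_R)) · φ_{m−1} + P_wp(U_R) · ℓ_wf[φ_{m−1}]

where U_R marks the first pixel of each residue loop (FPR) and P_wp dilates
those marks into wp×wp squares.  Residues are re-detected every iteration
because filtering can shift them between neighbouring pixels.

## Conventions and numerical choices

* **Wrapping interval** (−π, π]; the tie at ±π is broken toward +π.  The
  implementation (`x − 2π·ceil((x−π)/2π)`) returns in-range values
  bit-identical, so `wrap` is exactly idempotent.
* **Loop orientation**: right along the top edge, down, left, up, with the
  charge anchored at the loop's top-left pixel.  Under this convention a
  vortex `atan2(row−r0, col−c0)` carries charge +1.  Reversing orientation
  flips all signs globally and changes nothing else.
* **Charge rounding**: loop sums are divided by 2π and rounded with a
  1e−6 tolerance guard; violations raise rather than silently truncate.
* **Filter borders**: reflect padding.  Zero padding would fabricate
  spurious edge residues; reflection is neutral for the window sizes used.
* **Complex median**: marginal (median of real and imaginary parts
  separately).  The geometric median would be rotation-equivariant but
  costs an iterative solve per pixel; the marginal median is the standard
  cheap surrogate.  Consequence: the exact gauge-equivariance property
  ψ(φ+c) = ψ(φ)+c holds for the phasor **mean** only — with the median it
  holds only approximately.  The mean is the default mode.
* **Degenerate windows**: where the windowed phasor statistic vanishes
  (antipodal cancellation) the argument is undefined; such pixels keep
  their input value and the event is logged at DEBUG level.
* **Patch geometry**: squares centred on the FPR, extended right/down for
  even wp, so wp = 2 covers exactly the 2×2 residue loop.  Overlapping
  patches merge; the union is filtered once.
* **Escalation**: window +2 (odd sizes), patch +1, window before patch;
  by default escalation happens only when the residue count fails to
  improve on the best count so far ("stall"), since filtering at a fixed
  (wf, wp) often keeps making progress for several iterations.
  `escalate_on="always"` grows every iteration instead.  The (wp, wf)
  schedule is lexicographically non-decreasing either way.  Termination:
  residue count ≤ target (default 0), both caps exhausted while stalled,
  or `max_iterations` (default 500) — non-convergence is a reported
  status, never an exception.
* **Unwrapping** is Itoh integration implemented with explicit integer
  2π-offset arrays: `out = φ + 2π·N` with N ∈ ℤ computed from wrapped
  neighbour differences.  The integer bookkeeping makes the "output minus
  input is an integer multiple of 2π" invariant exact by construction; the
  floating-point *values* of `wrap(out)` can still differ from φ by a few
  ulp of 2π·N, which is the best any binary floating-point representation
  allows (the low bits of φ are lost in the addition).  Default traversal
  is columns-then-rows, matching unwrapping a 2D array along its first
  dimension.
* **Spectral metrics**: the radial average bins ln I over uniform annuli
  of |k| normalised to Nyquist (64 bins by default; corner frequencies
  beyond Nyquist are discarded so annuli stay complete circles).  Zero
  intensities are floored at machine epsilon times the spectral maximum
  before the log; empty annuli (only possible for tiny images) inherit
  their inner neighbour and are flagged.  Curves are compared after
  subtracting each one's maximum — i.e. on the log of the max-normalised
  intensity — so the spectral RSE is exactly invariant to intensity
  rescaling.

## Synthetic data: what it emulates, what it does not

The reference condition is a centred Gaussian bump of peak 30 rad on a
400×600 px grid (σ = 60 px, chosen so the bump spans about half the short
image dimension and wraps into several fringe rings; the peak sits on a
grid pixel so the ground-truth maximum is attained exactly).  Noise acts
on the phasor field: multiplicative speckle `z·(1+u)` with u zero-mean
uniform of variance 2 (the convention of MATLAB-style speckle noise),
then additive complex white Gaussian noise at a linear power SNR of 6
measured against the speckled field.  A dB reading of the SNR is
selectable (`SimSpec.snr_in_db`).  Under these defaults a realisation
carries ≈58 000 residues, and the default SPAF schedule clears them in
roughly 25–40 iterations, under a second of CPU time.

Vortex fixtures give exact, analytically known residue charges; the
textured phase is band-limited random texture (Lorentzian-squared spectral
knee at 0.08 cycles/px plus a 5 % flat floor to Nyquist) normalised below
the wrap threshold, so it is residue-free and serves as its own ground
truth in resolution-preservation experiments.

What the generators do **not** emulate: spatially correlated speckle with
realistic grain size, shot-noise statistics, optical aberrations,
non-uniform background amplitude, and the morphology of real specimens.
Passing tests show the algorithm's contracts (residue elimination,
locality, spectral ordering) under idealised noise; absolute error values
on real holograms will differ.

## Problem sizes used by the test suite

Acceptance-level checks run the full 400×600 reference condition (ten
noise seeds for residue elimination, one for peak recovery).  The
resolution-preservation ordering uses a 256×256 textured phase — the
property being checked is an ordering and a ratio, not an absolute value,
and is stable across sizes.  Unit tests use 16–160 px grids so the whole
suite stays interactive (≈10 s).

## Known limitations

* A single isolated vortex of nonzero total charge cannot always be
  removed by local filtering (total charge is conserved until a residue
  reaches the image boundary); heavy noise with tiny caps ends with
  status `cap-reached` and a positive residue count, by design.
* Global phasor-mean PAF can fail to reach zero residues at *any* window
  on steep-fringed phases (fringe period approaching the window size) —
  the adaptive schedule is not just cheaper but strictly more capable.
* Anisotropic filter windows are supported in `FilterSpec` but never
  chosen automatically.
* The demodulator's hard-edged crop disk rings slightly on broadband
  inputs; a Gaussian-edged window is available (`soft_edge=True`).
* Combining SPAF with 2D quality-guided or network-flow unwrappers is out
  of scope; the output is a standard wrapped phase, so any external
  unwrapper can consume it.
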