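"""Independent brute-force reference implementations used as test oracles.

Deliberately scalar, loop-based and free of any code from the package's own
vectorized paths.
"""

import numpy as np

TWO_PI = 2.0 * np.pi


def brute_wrap(x: float) -> float:
    """Scalar wrap into (-pi, pi] by repeated shifting."""
    while x <= -np.pi:
        x += TWO_PI
    while x > np.pi:
        x -= TWO_PI
    return x


def brute_wrapped_diff(a: float, b: float) -> float:
    return brute_wrap(a - b)


def brute_residue_map(phase: np.ndarray) -> np.ndarray:
    """Explicit 4-edge loop sum per plaquette, one plaquette at a time."""
    h, w = phase.shape
    out = np.zeros((h - 1, w - 1), dtype=np.int64)
    for i in range(h - 1):
        for j in range(w - 1):
            s = (
                brute_wrapped_diff(phase[i, j + 1], phase[i, j])
                + brute_wrapped_diff(phase[i + 1, j + 1], phase[i, j + 1])
                + brute_wrapped_diff(phase[i + 1, j], phase[i + 1, j + 1])
                + brute_wrapped_diff(phase[i, j], phase[i + 1, j])
            )
            out[i, j] = round(s / TWO_PI)
    return out


def boundary_loop_charge(phase: np.ndarray) -> int:
    """Winding number of the image-boundary loop, same orientation as the
    per-plaquette loops (right along the top row, down the last column,
    left along the bottom row, up the first column)."""
    h, w = phase.shape
    path = (
        [phase[0, j] for j in range(w)]
        + [phase[i, w - 1] for i in range(1, h)]
        + [phase[h - 1, j] for j in range(w - 2, -1, -1)]
        + [phase[i, 0] for i in range(h - 2, -1, -1)]
    )
    s = sum(
        brute_wrapped_diff(path[k + 1], path[k]) for k in range(len(path) - 1)
    )
    s += brute_wrapped_diff(path[0], path[-1])
    return round(s / TWO_PI)


def brute_patch_union(fprs, wp: int, shape) -> set:
    """Set of pixels covered by wp x wp squares around each FPR."""
    h, w = shape
    top = (wp - 1) // 2
    covered = set()
    for r, c in fprs:
        for i in range(r - top, r - top + wp):
            for j in range(c - top, c - top + wp):
                if 0 <= i < h and 0 <= j < w:
                    covered.add((i, j))
    return covered


def brute_radial_average(spectrum: np.ndarray, n_bins: int):
    """Per-pixel annulus assignment with explicit loops."""
    h, w = spectrum.shape
    floor = np.finfo(float).eps * spectrum.max()
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for i in range(h):
        for j in range(w):
            ky = (i - h // 2) / h / 0.5
            kx = (j - w // 2) / w / 0.5
            kr = np.hypot(ky, kx)
            b = int(kr * n_bins)
            if kr <= 1.0 and b < n_bins:
                sums[b] += np.log(max(spectrum[i, j], floor))
                counts[b] += 1
    out = np.full(n_bins, np.nan)
    last = 0.0
    for b in range(n_bins):
        if counts[b]:
            last = sums[b] / counts[b]
        out[b] = last
    return out
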