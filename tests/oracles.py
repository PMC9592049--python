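"""Independent brute-force oracles used to validate the implementation.

Each oracle recomputes a quantity by the most direct method available
(scalar simulation, dense convolution, per-pixel enumeration, exhaustive
search) without sharing code with the package's vectorized paths.
"""

import numpy as np


def scalar_acquire_draws(S: float, T: float, sigma: float, gain: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """n i.i.d. draws of the scalar thresholded-acquisition model."""
    out = np.empty(n)
    for i in range(n):
        v = 0.0
        if gain > 0:
            v += rng.poisson(gain * S) / gain - S
        if sigma > 0:
            v += rng.normal(0.0, sigma)
        total = S + v
        out[i] = total - T if total > T else 0.0
    return out


def dense_gaussian_convolve(image: np.ndarray, sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Direct dense convolution with the sampled, normalized Gaussian kernel.

    Uses symmetric (reflect) padding matching scipy.ndimage's 'reflect'.
    """
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    g1 = np.exp(-0.5 * (x / sigma) ** 2)
    g1 /= g1.sum()
    kernel = np.outer(g1, g1)
    padded = np.pad(image, radius, mode="symmetric")
    h, w = image.shape
    out = np.empty_like(image, dtype=float)
    for i in range(h):
        for j in range(w):
            out[i, j] = np.sum(padded[i : i + 2 * radius + 1, j : j + 2 * radius + 1] * kernel)
    return out


def per_pixel_median(image: np.ndarray, window: int) -> np.ndarray:
    """Per-pixel sorted-window median with symmetric padding."""
    r = window // 2
    padded = np.pad(image, r, mode="symmetric")
    h, w = image.shape
    out = np.empty_like(image, dtype=float)
    for i in range(h):
        for j in range(w):
            block = padded[i : i + window, j : j + window]
            out[i, j] = float(np.sort(block.ravel())[block.size // 2])
    return out


def truth_table_confusion(o: np.ndarray, a: np.ndarray) -> dict:
    """Pixel-by-pixel enumeration of the four confusion cases."""
    counts = {"AND": 0, "NOR": 0, "FP": 0, "FN": 0, "O": 0, "Ans": 0}
    for oi, ai in zip(o.ravel(), a.ravel()):
        counts["O"] += bool(oi)
        counts["Ans"] += bool(ai)
        if oi and ai:
            counts["AND"] += 1
        elif oi and not ai:
            counts["FP"] += 1
        elif not oi and ai:
            counts["FN"] += 1
        else:
            counts["NOR"] += 1
    return counts


def brute_force_isodata(image: np.ndarray, n_bins: int = 256) -> float:
    """Exhaustive search for the IsoData fixed point over candidate bins.

    Scans the bin-centre candidates and returns the one minimizing the
    fixed-point residual |t - (mean_low + mean_high)/2|.
    """
    v = np.asarray(image, dtype=float).ravel()
    lo, hi = v.min(), v.max()
    centres = lo + (np.arange(n_bins) + 0.5) * (hi - lo) / n_bins
    best_t, best_res = None, np.inf
    for t in centres:
        low = v[v <= t]
        high = v[v > t]
        if low.size == 0 or high.size == 0:
            continue
        res = abs(t - 0.5 * (low.mean() + high.mean()))
        if res < best_res:
            best_res, best_t = res, t
    return float(best_t)


def harmonic_mean(p: float, r: float) -> float:
    return 2.0 / (1.0 / p + 1.0 / r)
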