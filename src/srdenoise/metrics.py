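"""Image-quality metrics: PSNR and SSIM against the low-noise answer.

Both follow the standard definitions: PSNR = 10*log10(data_range^2 / MSE)
and the mean local structural-similarity index with a Gaussian-weighted
11-pixel window (sigma 1.5), K1 = 0.01, K2 = 0.03 and population
(co)variances — the reference convention of Wang et al.

Because answer images are float frame-means with no canonical full scale,
``data_range`` defaults to the reference image's max - min for each
comparison and is recorded in the returned :class:`QualityScore`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class QualityScore:
    psnr_db: float  # may be math.inf for identical images
    ssim: float
    data_range: float

    def to_json_dict(self) -> dict:
        identical = math.isinf(self.psnr_db)
        return {
            "psnr_db": None if identical else self.psnr_db,
            "identical": identical,
            "ssim": self.ssim,
            "data_range": self.data_range,
        }


def _check_pair(test: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    test = np.asarray(test, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if test.shape != ref.shape:
        raise ValueError(f"shape mismatch: {test.shape} vs {ref.shape}")
    return test, ref


def _default_range(ref: np.ndarray) -> float:
    dr = float(ref.max() - ref.min())
    if dr <= 0:
        raise ValueError("reference image is constant; pass data_range explicitly")
    return dr


def psnr(test: np.ndarray, ref: np.ndarray, data_range: Optional[float] = None) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` for identical images."""
    test, ref = _check_pair(test, ref)
    if data_range is None:
        data_range = _default_range(ref)
    elif data_range <= 0:
        raise ValueError("data_range must be positive")
    mse = float(np.mean((test - ref) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(data_range**2 / mse)


def ssim(
    test: np.ndarray,
    ref: np.ndarray,
    data_range: Optional[float] = None,
    sigma: float = 1.5,
    truncate: float = 3.5,
    k1: float = 0.01,
    k2: float = 0.03,
) -> float:
    """Mean structural similarity with a Gaussian-weighted window.

    The window radius is ``int(truncate * sigma + 0.5)`` (11 pixels at the
    defaults); a border of one radius is excluded from the mean to avoid
    edge effects, as in the reference implementation.
    """
    test, ref = _check_pair(test, ref)
    if data_range is None:
        data_range = _default_range(ref)
    elif data_range <= 0:
        raise ValueError("data_range must be positive")
    radius = int(truncate * sigma + 0.5)
    win = 2 * radius + 1
    if win > min(test.shape):
        raise ValueError(f"window {win} exceeds image extent {test.shape}")

    def g(a: np.ndarray) -> np.ndarray:
        return ndimage.gaussian_filter(a, sigma=sigma, truncate=truncate, mode="reflect")

    ux, uy = g(test), g(ref)
    vx = g(test * test) - ux * ux
    vy = g(ref * ref) - uy * uy
    vxy = g(test * ref) - ux * uy
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / ((ux**2 + uy**2 + c1) * (vx + vy + c2))
    return float(s[radius:-radius, radius:-radius].mean())


def quality(test: np.ndarray, ref: np.ndarray, data_range: Optional[float] = None) -> QualityScore:
    """PSNR and SSIM of ``test`` against the answer ``ref`` in one record."""
    test, ref = _check_pair(test, ref)
    dr = _default_range(ref) if data_range is None else float(data_range)
    return QualityScore(psnr_db=psnr(test, ref, dr), ssim=ssim(test, ref, dr), data_range=dr)
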