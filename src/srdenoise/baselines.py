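"""Classical denoising baselines: Gaussian, median, and (pluggable) BM3D.

The Gaussian and median filters wrap ``scipy.ndimage`` with reflective
boundaries, swept over the standard sigma lists (1, 3, 5, 10). Following
the field's loose convention, the median filter's parameter is also called
``sigma`` even though it is the square window size in pixels.

BM3D (block-matching collaborative filtering) is delegated to a pluggable
backend registered via :func:`set_bm3d_backend`; the algorithm itself is
third-party and not re-implemented here. Without a registered backend,
:func:`bm3d_denoise` raises :class:`BM3DUnavailableError` — never a silent
fallback to another filter. Its sigma is interpreted on the image's native
intensity scale (the conventional sweep is 120..240 on photomultiplier
counts) and rescaled to the backend's [0, 1] convention internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .metrics import psnr, ssim

GAUSSIAN_SIGMAS: tuple = (1, 3, 5, 10)
MEDIAN_SIGMAS: tuple = (1, 3, 5, 10)
BM3D_SIGMAS: tuple = (120, 140, 160, 180, 200, 220, 240)


class BM3DUnavailableError(RuntimeError):
    """No BM3D backend has been registered."""


@dataclass(frozen=True)
class BaselineSpec:
    method: str  # gaussian | median | bm3d
    sigma: float

    def __post_init__(self) -> None:
        if self.method not in ("gaussian", "median", "bm3d"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def default_specs() -> list[BaselineSpec]:
    specs = [BaselineSpec("gaussian", s) for s in GAUSSIAN_SIGMAS]
    specs += [BaselineSpec("median", s) for s in MEDIAN_SIGMAS]
    if _BM3D_BACKEND is not None:
        specs += [BaselineSpec("bm3d", s) for s in BM3D_SIGMAS]
    return specs


def gaussian_denoise(image: np.ndarray, sigma: float) -> np.ndarray:
    """Isotropic Gaussian smoothing, reflective boundaries."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return ndimage.gaussian_filter(np.asarray(image, dtype=np.float64), sigma=sigma, mode="reflect")


def median_denoise(image: np.ndarray, sigma: float) -> np.ndarray:
    """Square-window median filter; ``sigma`` is the window size in pixels."""
    window = int(round(sigma))
    if window < 1:
        raise ValueError("median window must be >= 1")
    return ndimage.median_filter(np.asarray(image, dtype=np.float64), size=window, mode="reflect")


_BM3D_BACKEND: Optional[Callable[[np.ndarray, float], np.ndarray]] = None


def set_bm3d_backend(backend: Optional[Callable[[np.ndarray, float], np.ndarray]]) -> None:
    """Register a BM3D implementation ``backend(image01, sigma01) -> image01``.

    The backend receives the image rescaled to [0, 1] and the noise standard
    deviation on that scale. Pass ``None`` to unregister.
    """
    global _BM3D_BACKEND
    _BM3D_BACKEND = backend


def bm3d_denoise(image: np.ndarray, sigma: float) -> np.ndarray:
    """Collaborative-filtering denoising through the registered backend.

    ``sigma`` is on the image's native intensity scale; the image is scaled
    to [0, 1] for the backend and inverse-scaled on return.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if _BM3D_BACKEND is None:
        raise BM3DUnavailableError(
            "no BM3D backend registered; install one and call set_bm3d_backend()"
        )
    image = np.asarray(image, dtype=np.float64)
    lo, hi = float(image.min()), float(image.max())
    scale = hi - lo if hi > lo else 1.0
    out01 = _BM3D_BACKEND((image - lo) / scale, sigma / scale)
    return np.asarray(out01, dtype=np.float64) * scale + lo


_DISPATCH = {"gaussian": gaussian_denoise, "median": median_denoise, "bm3d": bm3d_denoise}


def apply_baseline(image: np.ndarray, spec: BaselineSpec) -> np.ndarray:
    return _DISPATCH[spec.method](image, spec.sigma)


def sweep(
    images: Sequence[np.ndarray],
    answers: Sequence[np.ndarray],
    specs: Optional[Iterable[BaselineSpec]] = None,
) -> pd.DataFrame:
    """Score every spec on every image pair; flag the best sigma per method.

    Returns one row per spec with average PSNR/SSIM over the image list and
    an ``optimal`` flag marking, per method, the spec with the highest
    average PSNR (ties go to the smaller sigma; among equal sigmas, the
    first row listed).
    """
    images = list(images)
    answers = list(answers)
    if not images or len(images) != len(answers):
        raise ValueError("need equal, non-empty image and answer lists")
    if specs is None:
        specs = default_specs()
    rows = []
    for spec in specs:
        ps, ss = [], []
        for img, ans in zip(images, answers):
            out = apply_baseline(img, spec)
            ps.append(psnr(out, ans))
            ss.append(ssim(out, ans))
        rows.append(
            {"method": spec.method, "sigma": spec.sigma, "psnr_db": float(np.mean(ps)), "ssim": float(np.mean(ss))}
        )
    table = pd.DataFrame(rows)
    table["optimal"] = False
    for method, group in table.groupby("method"):
        best = group.sort_values(["psnr_db", "sigma"], ascending=[False, True], kind="stable").index[0]
        table.loc[best, "optimal"] = True
    return table
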