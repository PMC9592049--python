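"""Synthetic clean-image phantoms for the two multiphoton modalities.

Two generators emulate the qualitative appearance of the imaging targets:

* three-photon fluorescence (3PF) of Hoechst-stained nuclei — bright
  elliptical blobs with smooth intra-nuclear texture on a dim background;
* third-harmonic generation (THG) of inflammatory macrophages — dim
  cytoplasmic disks studded with small bright lipid granules that delineate
  the cell outline.

Both return a :class:`CleanImage` whose ``pixels`` field is the true signal
``S`` fed to the acquisition simulator, together with the ground-truth cell
mask used by the boundary-evaluation pipeline.

Default geometry targets roughly half of the field of view covered by
foreground, matching confluent culture fields; the boundary pipeline
(equalize + IsoData) resolves the true boundary most faithfully in that
regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Tuple

import numpy as np
from scipy import ndimage

Modality = Literal["3PF", "THG"]


class PhantomConfigError(ValueError):
    """Raised when phantom parameters are inconsistent or unplaceable."""


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and intensity parameters for a synthetic phantom.

    Parameters
    ----------
    image_size : int
        Pixels per side of the square field (>= 32).
    n_objects : int
        Number of nuclei (3PF) or cells (THG).
    radius_range : (float, float)
        Min/max object semi-axis in pixels.
    intensity_fg : float
        Mean foreground signal (arbitrary linear units).
    intensity_bg : float
        Background signal level; must be below ``intensity_fg``.
    texture_scale : float
        Gaussian smoothing length (pixels) of the multiplicative
        intra-object texture field.
    seed : int
        Seed for all random placement and texture draws.
    """

    image_size: int = 512
    n_objects: int = 24
    radius_range: Tuple[float, float] = (35.0, 52.0)
    intensity_fg: float = 100.0
    intensity_bg: float = 2.0
    texture_scale: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise PhantomConfigError(f"image_size must be >= 32, got {self.image_size}")
        if self.n_objects < 1:
            raise PhantomConfigError(f"n_objects must be >= 1, got {self.n_objects}")
        lo, hi = self.radius_range
        if not (0 < lo <= hi):
            raise PhantomConfigError(f"invalid radius_range {self.radius_range}")
        if not (self.intensity_fg > self.intensity_bg >= 0):
            raise PhantomConfigError(
                f"need intensity_fg > intensity_bg >= 0, got fg={self.intensity_fg} bg={self.intensity_bg}"
            )
        if self.texture_scale <= 0:
            raise PhantomConfigError("texture_scale must be positive")

    def scaled_to(self, image_size: int) -> "PhantomParams":
        """Return a copy with geometry rescaled to another field size."""
        f = image_size / self.image_size
        return PhantomParams(
            image_size=image_size,
            n_objects=self.n_objects,
            radius_range=(self.radius_range[0] * f, self.radius_range[1] * f),
            intensity_fg=self.intensity_fg,
            intensity_bg=self.intensity_bg,
            texture_scale=max(1.0, self.texture_scale * f),
            seed=self.seed,
        )


@dataclass
class CleanImage:
    """Noiseless ground-truth intensity field with its object mask."""

    pixels: np.ndarray
    modality: Modality
    cell_masks: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        self.cell_masks = np.asarray(self.cell_masks, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2-D")
        if self.cell_masks.shape != self.pixels.shape:
            raise ValueError("cell_masks shape must match pixels")
        if np.any(self.pixels < 0):
            raise ValueError("clean pixel intensities must be non-negative")


def _place_centres(rng: np.random.Generator, params: PhantomParams) -> np.ndarray:
    """Rejection-sample object centres with minimum pairwise separation.

    Separation is one mean radius: neighbouring objects may touch or
    partially overlap (confluent fields), but centres never coincide.
    """
    n = params.n_objects
    size = params.image_size
    r_mean = 0.5 * (params.radius_range[0] + params.radius_range[1])
    min_sep = r_mean
    margin = params.radius_range[0] * 0.5
    centres: list[np.ndarray] = []
    attempts = 0
    max_attempts = 2000 * n
    while len(centres) < n:
        if attempts > max_attempts:
            raise PhantomConfigError(
                f"could not place {n} objects of mean radius {r_mean:.1f} "
                f"in a {size}x{size} field (min separation {min_sep:.1f})"
            )
        attempts += 1
        c = rng.uniform(margin, size - margin, size=2)
        if all(np.hypot(*(c - p)) >= min_sep for p in centres):
            centres.append(c)
    return np.array(centres)


def _ellipse_mask(shape: tuple, centre: np.ndarray, a: float, b: float, theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = yy - centre[0]
    dx = xx - centre[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = dy * ct + dx * st
    v = -dy * st + dx * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _texture_field(rng: np.random.Generator, shape: tuple, scale: float, amplitude: float) -> np.ndarray:
    """Smooth multiplicative texture with mean ~1, clipped away from zero."""
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=scale, mode="reflect")
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    return np.clip(1.0 + amplitude * smooth, 0.2, None)


def make_nuclei_phantom(params: PhantomParams) -> CleanImage:
    """Generate a 3PF-like phantom: textured elliptical nuclei.

    ``cell_masks`` marks nucleus interiors. Deterministic given
    ``params.seed``. Background pixels carry exactly ``intensity_bg``.
    """
    rng = np.random.default_rng(params.seed)
    centres = _place_centres(rng, params)
    shape = (params.image_size, params.image_size)
    mask = np.zeros(shape, dtype=bool)
    lo, hi = params.radius_range
    for c in centres:
        a = rng.uniform(lo, hi)
        b = rng.uniform(lo, hi)
        theta = rng.uniform(0, np.pi)
        mask |= _ellipse_mask(shape, c, a, b, theta)
    texture = _texture_field(rng, shape, params.texture_scale, amplitude=0.2)
    pixels = np.full(shape, float(params.intensity_bg))
    pixels[mask] = params.intensity_fg * texture[mask]
    return CleanImage(
        pixels=pixels,
        modality="3PF",
        cell_masks=mask,
        meta={"kind": "nuclei", "params": params, "n_placed": len(centres)},
    )


def make_granule_phantom(
    params: PhantomParams,
    granule_fraction: float = 0.12,
    granule_radius: float = 1.5,
    cytoplasm_level: float = 0.5,
) -> CleanImage:
    """Generate a THG-like phantom: granule clusters in cytoplasmic disks.

    Each cell is a dim cytoplasmic disk (``cytoplasm_level * intensity_fg``)
    containing bright puncta at ``intensity_fg``; ``cell_masks`` marks the
    cytoplasmic disks (the scored cell region). ``granule_fraction`` is the
    target fraction of the disk area occupied by puncta.
    """
    if not (0 < granule_fraction < 0.5):
        raise PhantomConfigError("granule_fraction must lie in (0, 0.5)")
    rng = np.random.default_rng(params.seed)
    centres = _place_centres(rng, params)
    shape = (params.image_size, params.image_size)
    cell_mask = np.zeros(shape, dtype=bool)
    granule_mask = np.zeros(shape, dtype=bool)
    lo, hi = params.radius_range
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for c in centres:
        r = rng.uniform(lo, hi)
        disk = (yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= r**2
        cell_mask |= disk
        # granule count to hit the target area fraction of this disk
        disk_area = np.pi * r**2
        g_area = np.pi * granule_radius**2
        n_gran = max(3, int(round(granule_fraction * disk_area / g_area)))
        for _ in range(n_gran):
            rho = r * np.sqrt(rng.uniform(0, 0.85))
            ang = rng.uniform(0, 2 * np.pi)
            gc = c + rho * np.array([np.sin(ang), np.cos(ang)])
            gr = rng.uniform(0.8, 1.2) * granule_radius
            granule_mask |= (yy - gc[0]) ** 2 + (xx - gc[1]) ** 2 <= gr**2
    granule_mask &= cell_mask
    texture = _texture_field(rng, shape, params.texture_scale, amplitude=0.15)
    pixels = np.full(shape, float(params.intensity_bg))
    cyto = cell_mask & ~granule_mask
    pixels[cyto] = cytoplasm_level * params.intensity_fg * texture[cyto]
    pixels[granule_mask] = params.intensity_fg * texture[granule_mask]
    return CleanImage(
        pixels=pixels,
        modality="THG",
        cell_masks=cell_mask,
        meta={
            "kind": "granules",
            "params": params,
            "granule_fraction": granule_fraction,
            "granule_mask_count": int(granule_mask.sum()),
            "n_placed": len(centres),
        },
    )
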