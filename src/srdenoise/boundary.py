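"""Boundary-preservation analysis.

Pipeline: histogram-equalize the denoised image and the low-noise answer,
binarize each with the IsoData auto-threshold, form the AND (true positive)
and NOR (true negative) masks, and score

    precision   = count_AND / count_O
    recall      = count_AND / count_Ans
    specificity = count_NOR / count_IAns
    F           = 2 * precision * recall / (precision + recall)

where count_O / count_Ans are the foreground pixel counts of the two binary
masks and count_IAns = total - count_Ans. A pseudo-colour overlay paints
true positives blue, false positives magenta and false negatives green so
boundary mismatches are visible at a glance.

IsoData here is the Ridler–Calvard fixed point iterated on intensities:
starting from the mid-range, T <- (mean(pixels <= T) + mean(pixels > T))/2
until the update falls below half of a 256-bin width. Means are computed
inclusively on the <= side. Each image is thresholded independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np


@dataclass
class BinaryMask:
    pixels: np.ndarray
    origin: Literal["denoised", "answer", "derived"] = "derived"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def count(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class ConfusionCounts:
    count_O: int
    count_Ans: int
    count_AND: int
    count_NOR: int
    total_pixels: int

    def __post_init__(self) -> None:
        if self.count_AND > min(self.count_O, self.count_Ans):
            raise ValueError("count_AND cannot exceed either mask count")
        expected_nor = self.total_pixels - (self.count_O + self.count_Ans - self.count_AND)
        if self.count_NOR != expected_nor:
            raise ValueError(f"count_NOR={self.count_NOR} inconsistent, expected {expected_nor}")

    @property
    def count_IAns(self) -> int:
        return self.total_pixels - self.count_Ans


@dataclass(frozen=True)
class BoundaryScores:
    precision: float
    recall: float
    specificity: float
    f_measure: float
    undefined_reason: Optional[str] = None


def equalize(image: np.ndarray, n_bins: int = 256) -> np.ndarray:
    """Classical cumulative-histogram equalization onto [0, 255].

    The image is linearly rescaled to [0, 255], binned into ``n_bins``
    levels and mapped through 255 * CDF. A constant image is returned
    unchanged (degenerate case: no contrast to redistribute).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("empty image")
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        return image.copy()
    scaled = (image - lo) / (hi - lo) * 255.0
    bins = np.clip((scaled / 256.0 * n_bins).astype(int), 0, n_bins - 1)
    hist = np.bincount(bins.ravel(), minlength=n_bins)
    cdf = np.cumsum(hist) / image.size
    return 255.0 * cdf[bins]


def isodata_threshold(image: np.ndarray, n_bins: int = 256, max_iter: int = 500) -> float:
    """Iterative mean-of-means (IsoData / Ridler–Calvard) threshold.

    Starts at the midpoint of the data range and iterates
    ``T <- (mean(v <= T) + mean(v > T)) / 2`` until the change is below
    half a bin width (range / n_bins / 2). Raises on constant images.
    """
    v = np.asarray(image, dtype=np.float64).ravel()
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        raise ValueError("constant image has no threshold")
    half_bin = (hi - lo) / n_bins / 2.0
    t = 0.5 * (lo + hi)
    for _ in range(max_iter):
        low = v[v <= t]
        high = v[v > t]
        # at the extremes one side may empty out; clamp to the data edge
        m_low = low.mean() if low.size else lo
        m_high = high.mean() if high.size else hi
        t_new = 0.5 * (m_low + m_high)
        if abs(t_new - t) < half_bin:
            return t_new
        t = t_new
    return t


def binarize(image: np.ndarray, threshold: float, origin: str = "derived") -> BinaryMask:
    """Pixels strictly above ``threshold`` become foreground."""
    return BinaryMask(pixels=np.asarray(image) > threshold, origin=origin)  # type: ignore[arg-type]


def confusion(b_o: BinaryMask, b_ans: BinaryMask) -> tuple[ConfusionCounts, dict]:
    """Logical masks and pixel counts comparing denoised vs answer masks.

    Returns the counts plus a dict of masks: ``AND`` (true positive),
    ``NOR`` (true negative), ``FP`` (in denoised only), ``FN`` (in answer
    only).
    """
    o = b_o.pixels
    a = b_ans.pixels
    if o.shape != a.shape:
        raise ValueError(f"shape mismatch: {o.shape} vs {a.shape}")
    and_mask = o & a
    nor_mask = ~(o | a)
    fp = o & ~and_mask
    fn = a & ~and_mask
    counts = ConfusionCounts(
        count_O=int(o.sum()),
        count_Ans=int(a.sum()),
        count_AND=int(and_mask.sum()),
        count_NOR=int(nor_mask.sum()),
        total_pixels=o.size,
    )
    masks = {
        "AND": BinaryMask(and_mask),
        "NOR": BinaryMask(nor_mask),
        "FP": BinaryMask(fp),
        "FN": BinaryMask(fn),
    }
    return counts, masks


def boundary_scores(c: ConfusionCounts) -> BoundaryScores:
    """Precision / recall / specificity / F from confusion counts.

    Degenerate denominators yield NaN with an explicit reason rather than a
    silent zero.
    """
    reason = None
    if c.count_O == 0:
        precision = math.nan
        reason = "count_O = 0: denoised mask empty, precision undefined"
    else:
        precision = c.count_AND / c.count_O
    if c.count_Ans == 0:
        recall = math.nan
        reason = "count_Ans = 0: answer mask empty, recall undefined"
    else:
        recall = c.count_AND / c.count_Ans
    if c.count_IAns == 0:
        specificity = math.nan
        reason = "count_IAns = 0: answer mask covers image, specificity undefined"
    else:
        specificity = c.count_NOR / c.count_IAns
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f = math.nan
        if reason is None:
            reason = "precision + recall = 0: F-measure undefined"
    else:
        f = 2.0 * precision * recall / (precision + recall)
    return BoundaryScores(precision=precision, recall=recall, specificity=specificity, f_measure=f, undefined_reason=reason)


# overlay colour code: blue TP, magenta FP, green FN, black elsewhere
_COLORS = {"AND": (0, 0, 255), "FP": (255, 0, 255), "FN": (0, 255, 0)}


def overlay(masks: dict) -> np.ndarray:
    """Pseudo-colour RGB (uint8) superposition of the confusion masks."""
    shape = masks["AND"].pixels.shape
    rgb = np.zeros(shape + (3,), dtype=np.uint8)
    for key, color in _COLORS.items():
        rgb[masks[key].pixels] = color
    return rgb


def evaluate_boundary(
    denoised_image: np.ndarray, answer_image: np.ndarray
) -> tuple[BoundaryScores, np.ndarray, ConfusionCounts]:
    """Full boundary pipeline: equalize, IsoData-binarize, score, overlay.

    Both images are equalized and thresholded independently; returns the
    scores, the RGB overlay and the raw counts.
    """
    denoised_image = np.asarray(denoised_image, dtype=np.float64)
    answer_image = np.asarray(answer_image, dtype=np.float64)
    if denoised_image.shape != answer_image.shape:
        raise ValueError(f"shape mismatch: {denoised_image.shape} vs {answer_image.shape}")
    eq_o = equalize(denoised_image)
    eq_ans = equalize(answer_image)
    b_o = binarize(eq_o, isodata_threshold(eq_o), origin="denoised")
    b_ans = binarize(eq_ans, isodata_threshold(eq_ans), origin="answer")
    counts, masks = confusion(b_o, b_ans)
    return boundary_scores(counts), overlay(masks), counts
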