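"""Stochastic-resonance acquisition model.

A detected pixel value is a hard-thresholded superposition of true signal
and noise::

    y = S + V - T   if S + V > T
    y = 0           otherwise

where ``S`` is the clean signal, ``T`` the detection threshold, and the
noise ``V`` decomposes additively into a signal-dependent shot-noise term
and a detector Gaussian term::

    V = (Poisson(g * S) / g - S) + Normal(0, sigma)

with photon gain ``g`` (photons per intensity unit; ``g = 0`` disables the
Poisson component). The Poisson term is re-centred to zero mean so that the
additive-then-threshold algebra holds exactly.

In the stochastic-resonance regime (``T > S`` over much of the field,
noise comparable to signal) sub-threshold structures are detectable only
because noise occasionally boosts them across ``T``; frame averaging over a
location then yields a low-noise "answer" image used as the training and
evaluation target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .phantom import CleanImage


@dataclass(frozen=True)
class AcquisitionParams:
    """Forward-model parameters for one acquisition.

    Defaults realize a low-photon-budget regime: detector noise comparable
    to the signal, a threshold exceeding the dimmer signal levels, and 200
    frames per location.
    """

    threshold_T: float = 60.0
    gaussian_sigma: float = 40.0
    poisson_gain: float = 0.25
    n_frames: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold_T < 0:
            raise ValueError("threshold_T must be >= 0")
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        if self.poisson_gain < 0:
            raise ValueError("poisson_gain must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


@dataclass
class FrameStack:
    """``n_frames`` independently acquired noisy frames of one location."""

    frames: np.ndarray
    params: AcquisitionParams
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be 3-D (n_frames, H, W)")
        if self.frames.shape[0] != self.params.n_frames:
            raise ValueError(
                f"frames.shape[0]={self.frames.shape[0]} != n_frames={self.params.n_frames}"
            )
        if np.any(self.frames < 0):
            raise ValueError("thresholded frames must be non-negative")


@dataclass
class AnswerImage:
    """Per-pixel mean over a frame stack — the low-noise target."""

    pixels: np.ndarray
    n_averaged: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("answer pixels must be 2-D")


def acquire_frame(
    clean: CleanImage | np.ndarray,
    params: AcquisitionParams,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Simulate one thresholded noisy frame of ``clean``.

    Per pixel: draw the re-centred Poisson + Gaussian noise ``V``, then
    return ``S + V - T`` where ``S + V > T`` and 0 elsewhere. Draws are
    independent per pixel.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    S = clean.pixels if isinstance(clean, CleanImage) else np.asarray(clean, dtype=np.float64)
    total = S.astype(np.float64, copy=True)
    g = params.poisson_gain
    if g > 0:
        total += rng.poisson(g * S) / g - S
    if params.gaussian_sigma > 0:
        total += rng.normal(0.0, params.gaussian_sigma, size=S.shape)
    return np.where(total > params.threshold_T, total - params.threshold_T, 0.0)


def acquire_stack(clean: CleanImage, params: AcquisitionParams) -> FrameStack:
    """Acquire ``n_frames`` independent frames of one location.

    Each frame uses its own substream spawned from ``params.seed`` via
    ``SeedSequence(seed).spawn``, so stacks are reproducible and a frame's
    draw does not depend on how many frames precede it.
    """
    children = np.random.SeedSequence(params.seed).spawn(params.n_frames)
    frames = np.empty((params.n_frames,) + clean.pixels.shape, dtype=np.float64)
    for i, child in enumerate(children):
        frames[i] = acquire_frame(clean, params, np.random.default_rng(child))
    return FrameStack(frames=frames, params=params, source=dict(clean.meta, modality=clean.modality))


def make_answer(stack: FrameStack) -> AnswerImage:
    """Average the stack along the frame axis into the low-noise answer."""
    return AnswerImage(pixels=stack.frames.mean(axis=0), n_averaged=stack.frames.shape[0])
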