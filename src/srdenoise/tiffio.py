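"""TIFF I/O for frame stacks, answers and denoised outputs.

Stacks are written as uncompressed multi-page grayscale TIFF, one page per
frame, with generation metadata serialized as JSON in the image-description
tag. Canonical depths: 16-bit for simulated acquisitions, float32 for
answers and denoised outputs (frame means are non-integer). Integer writes
never rescale silently: values outside the representable range raise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import tifffile

from .noise import FrameStack

_DTYPES = {"8": np.uint8, "16": np.uint16, "float32": np.float32}
_MAX = {"8": 255, "16": 65535}


@dataclass(frozen=True)
class StackFile:
    path: Path
    bit_depth: str
    n_pages: int


def write_stack(
    stack: Union[FrameStack, np.ndarray],
    path: Union[str, Path],
    bit_depth: str = "float32",
    metadata: Optional[dict] = None,
) -> StackFile:
    """Write a stack (or single image) as a multi-page TIFF.

    ``bit_depth`` is one of ``"8"``, ``"16"``, ``"float32"``. For integer
    depths values must already lie in the representable range (after any
    caller-side scaling); out-of-range values raise rather than clip.
    """
    if bit_depth not in _DTYPES:
        raise ValueError(f"bit_depth must be one of {sorted(_DTYPES)}, got {bit_depth!r}")
    if isinstance(stack, FrameStack):
        data = stack.frames
        meta = dict(metadata or {})
        meta.setdefault("acquisition", _params_dict(stack))
    else:
        data = np.asarray(stack)
        meta = dict(metadata or {})
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError("expected a 2-D image or 3-D stack")
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite values cannot be written")
    if bit_depth in _MAX:
        if data.min() < 0 or data.max() > _MAX[bit_depth]:
            raise ValueError(
                f"values [{data.min():g}, {data.max():g}] out of range for "
                f"{bit_depth}-bit TIFF (0..{_MAX[bit_depth]}); rescale explicitly"
            )
        out = np.round(data).astype(_DTYPES[bit_depth])
    else:
        out = data.astype(np.float32)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    description = json.dumps({"bit_depth": bit_depth, **meta}, sort_keys=True, default=str)
    tifffile.imwrite(path, out, photometric="minisblack", description=description, compression=None)
    return StackFile(path=path, bit_depth=bit_depth, n_pages=out.shape[0])


def read_stack(path: Union[str, Path]) -> tuple[np.ndarray, dict]:
    """Read a TIFF written by :func:`write_stack`.

    Returns ``(array, metadata)``; one-page files come back as 2-D arrays,
    multi-page files as (n_pages, H, W). Metadata is parsed from the
    description tag when present (empty dict otherwise).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description
    except tifffile.TiffFileError as exc:
        raise ValueError(f"malformed TIFF at {path}: {exc}") from exc
    if data.ndim == 3 and data.shape[0] == 1:
        data = data[0]
    meta: dict = {}
    if desc:
        try:
            parsed = json.loads(desc)
            if isinstance(parsed, dict):
                meta = parsed
        except json.JSONDecodeError:
            meta = {"description": desc}
    return data, meta


def write_report(report: dict, path: Union[str, Path]) -> Path:
    """Persist a metric report as indented JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    return path


def _params_dict(stack: FrameStack) -> dict:
    p = stack.params
    return {
        "threshold_T": p.threshold_T,
        "gaussian_sigma": p.gaussian_sigma,
        "poisson_gain": p.poisson_gain,
        "n_frames": p.n_frames,
        "seed": p.seed,
    }
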