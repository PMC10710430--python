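"""Normalization, crop/resize into the 128x128 model space, the inverse
mapping of masks back to full size, and sequence chunking.

Images are interpolated bilinearly; masks use nearest-neighbour (on the
way down) or bilinear-then-threshold-at-0.5 (on the way back up) so
they stay strictly binary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .dataset import CropParams, VideoStack


class DegenerateVideoError(ValueError):
    """The video has zero intensity variance and cannot be normalized."""


def normalize_video(frames: np.ndarray | VideoStack) -> np.ndarray:
    """Centre a video to mean 0 and standard deviation 1.

    One mean and one standard deviation are computed over the whole
    stack, so relative frame-to-frame brightness is preserved. The
    result is invariant to any positive affine rescaling of the input.
    """
    if isinstance(frames, VideoStack):
        frames = frames.frames
    x = np.asarray(frames, dtype=np.float32)
    if x.size == 0:
        raise DegenerateVideoError("empty video")
    mu = float(x.mean())
    sd = float(x.std())
    if sd == 0.0:
        raise DegenerateVideoError("constant-intensity video has no contrast")
    return (x - mu) / sd


def _crop(frames: np.ndarray, p: CropParams) -> np.ndarray:
    if not p.in_bounds(frames.shape):
        raise ValueError(f"crop box {p} out of bounds for frames {frames.shape}")
    return frames[:, p.min_y : p.max_y, p.min_x : p.max_x]


def crop_resize(
    frames: np.ndarray | VideoStack,
    p: CropParams,
    out: int = 128,
    mask: bool = False,
) -> np.ndarray:
    """Crop every frame to the box of ``p`` and resize to ``out x out``.

    ``mask=True`` switches to nearest-neighbour interpolation so binary
    values are preserved exactly.
    """
    if isinstance(frames, VideoStack):
        frames = frames.frames
    cropped = _crop(np.asarray(frames), p)
    t = cropped.shape[0]
    if cropped.shape[1:] == (out, out):
        return cropped.astype(np.uint8) if mask else cropped.astype(np.float32)
    order = 0 if mask else 1
    dtype = np.uint8 if mask else np.float32
    resized = _sk_resize(
        cropped.astype(np.float32),
        (t, out, out),
        order=order,
        preserve_range=True,
        anti_aliasing=False,
    )
    return resized.astype(dtype)


def mask_to_fullsize(
    m: np.ndarray, p: CropParams, full_shape: tuple[int, int]
) -> np.ndarray:
    """Map a resized-space mask back onto the full-size frame.

    The mask is bilinearly resized to the crop-box extent, thresholded
    at 0.5 back to {0, 1}, and pasted at the box position; everything
    outside the box is background.
    """
    m = np.asarray(m)
    squeeze = m.ndim == 2
    if squeeze:
        m = m[None]
    t = m.shape[0]
    h, w = full_shape
    if not p.in_bounds((h, w)):
        raise ValueError(f"crop box {p} out of bounds for full shape {full_shape}")
    dy, dx = p.max_y - p.min_y, p.max_x - p.min_x
    box = _sk_resize(
        m.astype(np.float32), (t, dy, dx), order=1, preserve_range=True,
        anti_aliasing=False,
    )
    full = np.zeros((t, h, w), dtype=np.uint8)
    full[:, p.min_y : p.max_y, p.min_x : p.max_x] = box > 0.5
    return full[0] if squeeze else full


def bbox_from_mask(m: np.ndarray, margin: int = 0, square: bool = True) -> CropParams:
    """Bounding box of the foreground union across all frames.

    The tight box is dilated by ``margin`` pixels, optionally expanded
    to a square by padding the shorter side symmetrically (shifting
    inward at frame edges), and clipped to the frame. Using the union
    over time keeps the heart inside the box through the whole beat.
    """
    m = np.asarray(m)
    if m.ndim == 2:
        m = m[None]
    h, w = m.shape[1], m.shape[2]
    union = m.any(axis=0)
    ys, xs = np.nonzero(union)
    if ys.size == 0:
        raise ValueError("mask has no foreground pixels in any frame")
    min_y = max(int(ys.min()) - margin, 0)
    max_y = min(int(ys.max()) + 1 + margin, h)
    min_x = max(int(xs.min()) - margin, 0)
    max_x = min(int(xs.max()) + 1 + margin, w)
    if square:
        side = min(max(max_y - min_y, max_x - min_x), h, w)
        min_y, max_y = _grow_to(min_y, max_y, side, h)
        min_x, max_x = _grow_to(min_x, max_x, side, w)
    return CropParams.from_box(min_y, max_y, min_x, max_x)


def _grow_to(lo: int, hi: int, side: int, limit: int) -> tuple[int, int]:
    """Symmetrically widen [lo, hi) to ``side`` pixels within [0, limit)."""
    extra = side - (hi - lo)
    if extra <= 0:
        return lo, hi
    lo -= extra // 2
    hi += extra - extra // 2
    if lo < 0:
        hi -= lo
        lo = 0
    if hi > limit:
        lo -= hi - limit
        hi = limit
    return max(lo, 0), hi


@dataclass(frozen=True)
class ChunkRange:
    """A half-open frame range; ``pad`` frames of last-frame repetition
    are appended when the tail is shorter than the sequence length."""

    start: int
    stop: int
    pad: int = 0


def chunk_sequences(t: int, seq_len: int = 32, stride: int | None = None) -> list[ChunkRange]:
    """Cover [0, T) with contiguous ``seq_len``-frame ranges.

    The final range may be short; it is flagged with the number of
    padding frames needed so predictions can be trimmed afterwards.
    """
    if t < 1 or seq_len < 1:
        raise ValueError("t and seq_len must be positive")
    stride = stride or seq_len
    chunks = []
    for start in range(0, t, stride):
        stop = min(start + seq_len, t)
        chunks.append(ChunkRange(start, stop, pad=seq_len - (stop - start)))
        if stop == t:
            break
    return chunks
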