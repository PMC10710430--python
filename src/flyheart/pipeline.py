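"""Two-network segmentation cascade.

A coarse localization network (a spatial U-Net run on aspect-distorted
downsampled full frames) finds the heart region; its thresholded
prediction gives one bounding box for the whole video. The video is
cropped to that box, resized to the model space, and segmented by the
fine spatiotemporal FlyNet. Predicted masks are cleaned per frame —
keep the largest 4-connected component, fill enclosed holes — and
mapped back to the full-size frame, yielding both mask spaces of the
dataset convention.

``TruthOracle`` stands in for either network slot when a known mask
should be injected instead of a prediction (for plumbing tests and
ceiling measurements).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from . import nn
from .dataset import CropParams, VideoStack
from .model import FlyNet, SamplePair, TrainConfig, _log_cosh_dice_grad, log_cosh_dice_loss
from .preprocess import (
    bbox_from_mask,
    chunk_sequences,
    crop_resize,
    mask_to_fullsize,
    normalize_video,
)

#: 4-connectivity structuring element used for components and holes.
STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


class PipelineError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class LocalizationError(PipelineError):
    def __init__(self, message: str):
        super().__init__("localize", message)


@dataclass
class TruthOracle:
    """Injects a known full-size mask in place of a network prediction."""

    full_mask: np.ndarray

    def __post_init__(self):
        self.full_mask = np.asarray(self.full_mask)


@dataclass
class PipelineBundle:
    coarse_model: object  # FlyNet, TruthOracle, or a raw coarse mask array
    fine_model: object  # FlyNet or TruthOracle
    margin: int = 8
    threshold: float = 0.5

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, m in (("coarse", self.coarse_model), ("fine", self.fine_model)):
            if not isinstance(m, FlyNet):
                raise TypeError(f"cannot serialize a {type(m).__name__} {name} model")
            m.save(out_dir / name)

    @classmethod
    def load(cls, weights_dir, margin: int = 8, threshold: float = 0.5):
        weights_dir = Path(weights_dir)
        return cls(
            coarse_model=FlyNet.load(weights_dir / "coarse"),
            fine_model=FlyNet.load(weights_dir / "fine"),
            margin=margin,
            threshold=threshold,
        )


def localize_heart(
    video: np.ndarray | VideoStack,
    coarse_model,
    margin: int = 8,
    threshold: float = 0.5,
) -> CropParams:
    """Find the heart's bounding box on the full-size video.

    Full frames are downsampled to the coarse model's input size,
    segmented, and the probability maps are upsampled back before
    thresholding; the box is the (squared, margin-dilated) bounding box
    of the foreground union over all frames.

    Oracle modes: passing a mask array (or a :class:`TruthOracle`) skips
    the network and the resize round trip entirely, so the result equals
    ``bbox_from_mask`` on that mask.
    """
    frames = video.frames if isinstance(video, VideoStack) else np.asarray(video)
    t, h, w = frames.shape
    if isinstance(coarse_model, TruthOracle):
        coarse_model = coarse_model.full_mask
    if isinstance(coarse_model, np.ndarray):
        mask = coarse_model > 0
    else:
        size = coarse_model.in_size
        small = _sk_resize(
            frames.astype(np.float32), (t, size, size), order=1,
            preserve_range=True, anti_aliasing=False,
        )
        probs = coarse_model.predict_probs(normalize_video(small))
        big = _sk_resize(
            probs, (t, h, w), order=1, preserve_range=True, anti_aliasing=False
        )
        mask = big > threshold
    if not mask.any():
        raise LocalizationError("coarse network found no heart pixels in any frame")
    return bbox_from_mask(mask.astype(np.uint8), margin=margin, square=True)


def clean_mask(m: np.ndarray) -> np.ndarray:
    """Per-frame cleanup: drop all but the largest 4-connected component
    and fill enclosed holes. Empty frames pass through unchanged."""
    m = np.asarray(m)
    squeeze = m.ndim == 2
    if squeeze:
        m = m[None]
    out = np.zeros_like(m, dtype=np.uint8)
    for i in range(m.shape[0]):
        frame = m[i] > 0
        if not frame.any():
            continue
        labels, n = ndimage.label(frame, structure=STRUCTURE_4)
        if n > 1:
            sizes = ndimage.sum_labels(frame, labels, index=np.arange(1, n + 1))
            frame = labels == (1 + int(np.argmax(sizes)))
        out[i] = ndimage.binary_fill_holes(frame, structure=STRUCTURE_4)
    return out[0] if squeeze else out


def train_localizer(model: FlyNet, tc: TrainConfig, samples) -> dict:
    """Train the coarse localization network on whole full-size frames.

    Frames and masks are resized (aspect-distorted) to the model's input
    size — no cropping, since this network's job is to find the crop.
    Only a rough, fully contained segmentation is needed, so a short
    schedule suffices.
    """
    tc.validate()
    samples = [s if isinstance(s, SamplePair) else SamplePair(*s) for s in samples]
    if not samples:
        raise ValueError("empty training set")
    rng = np.random.default_rng(tc.seed)
    size, seq_len = model.in_size, model.cfg.seq_len
    clips = []
    for s in samples:
        t = s.full_img.shape[0]
        img = _sk_resize(s.full_img.astype(np.float32), (t, size, size), order=1,
                         preserve_range=True, anti_aliasing=False)
        img = normalize_video(img)
        msk = _sk_resize(s.full_mask.astype(np.float32), (t, size, size), order=0,
                         preserve_range=True, anti_aliasing=False).astype(np.uint8)
        for ch in chunk_sequences(t, seq_len):
            xi = img[ch.start : ch.stop]
            yi = msk[ch.start : ch.stop]
            if ch.pad:
                xi = np.concatenate([xi, np.repeat(xi[-1:], ch.pad, axis=0)])
                yi = np.concatenate([yi, np.repeat(yi[-1:], ch.pad, axis=0)])
            clips.append((xi, yi))
    opt = nn.Adam(model.params(), lr=tc.lr)
    history = {"train_loss": []}
    for _epoch in range(tc.epochs):
        losses = []
        for ci in rng.permutation(len(clips)):
            xi, yi = clips[ci]
            xb = xi[None, :, None].astype(np.float32)
            yb = yi[None, :, None].astype(np.float32)
            probs, state = model.forward(xb, training=True)
            losses.append(log_cosh_dice_loss(probs, yb, tc.dice_epsilon))
            nn.zero_grads(model.params())
            model.backward(_log_cosh_dice_grad(probs, yb, tc.dice_epsilon), state)
            opt.step()
        history["train_loss"].append(float(np.mean(losses)))
    return history


def segment_video(
    video: np.ndarray | VideoStack,
    bundle: PipelineBundle,
    clean: bool = True,
):
    """Run the full cascade on a full-size video.

    Returns ``(full_mask, resized_mask, crop)`` — the segmentation in
    both the full-size and the model (128x128) space, plus the crop
    parameters used, matching the dataset's two-mask convention.
    """
    frames = video.frames if isinstance(video, VideoStack) else np.asarray(video)
    crop = localize_heart(frames, bundle.coarse_model, bundle.margin, bundle.threshold)
    fine = bundle.fine_model
    if isinstance(fine, TruthOracle):
        probs = crop_resize(fine.full_mask, crop, out=128, mask=True).astype(np.float32)
    else:
        try:
            small = crop_resize(frames, crop, out=fine.in_size)
            norm = normalize_video(small)
        except ValueError as exc:
            raise PipelineError("crop_resize", str(exc)) from exc
        probs = fine.predict_probs(norm)
    mask_small = (probs > bundle.threshold).astype(np.uint8)
    if clean:
        mask_small = clean_mask(mask_small)
    full = mask_to_fullsize(mask_small, crop, frames.shape[1:])
    return full, mask_small, crop
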