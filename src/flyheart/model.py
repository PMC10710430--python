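"""FlyNet 2.0+ — a convolutional-LSTM U-Net for heart segmentation in
OCM video, with its Log-Cosh Dice training loss.

The network is U-shaped. The first ``n_spatiotemporal`` encoder blocks
open with a convolutional LSTM that propagates feature maps through
time, so the prediction for one frame can draw on the frames before it
(heart walls blur and vanish near end-systole in single frames; the
recurrence carries them across). Every other layer is applied
identically to each frame. Encoder block: temporal (or plain) conv ->
batch norm -> per-frame conv -> batch norm -> leaky ReLU -> 2x2 max
pool, with a skip connection taken before pooling. Decoder block:
2x transposed conv -> skip concatenation -> conv -> batch norm -> leaky
ReLU. A 1x1 convolution plus sigmoid yields a per-pixel heart
probability for every frame.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .dataset import MaskStack, VideoStack
from .preprocess import bbox_from_mask, chunk_sequences, crop_resize, normalize_video


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``n_spatiotemporal`` counts the leading encoder blocks that use a
    ConvLSTM; set it to 0 for a purely spatial (frame-independent)
    network of the same shape, as used for coarse heart localization.
    """

    seq_len: int = 32
    in_size: int = 128
    n_levels: int = 4
    n_spatiotemporal: int = 2
    base_filters: int = 16
    kernel: int = 3
    leaky_slope: float = 0.2

    def validate(self) -> None:
        if self.in_size % (2**self.n_levels) != 0:
            raise ValueError(
                f"in_size {self.in_size} not divisible by 2^{self.n_levels}"
            )
        if not 0 <= self.n_spatiotemporal <= self.n_levels:
            raise ValueError("n_spatiotemporal must be in [0, n_levels]")
        if self.seq_len < 1 or self.base_filters < 1:
            raise ValueError("seq_len and base_filters must be positive")


@dataclass
class TrainConfig:
    lr: float = 0.001
    batch_size: int = 1
    epochs: int = 15
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    dice_epsilon: float = 1.0
    jitter: int = 4
    margin: int = 4

    def validate(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def log_cosh_dice_loss(pred, truth, eps: float = 1.0):
    """``ln(cosh(1 - Dice))`` averaged over the batch.

    Dice pools every frame of a sample's sequence:
    ``(2 * sum(p*t) + eps) / (sum(p) + sum(t) + eps)``. The loss is 0
    exactly when Dice is 1 and increases monotonically as Dice falls.

    Parameters
    ----------
    pred, truth : arrays of matching shape; the leading axis is the
        batch, everything else is pooled per sample.
    eps : Dice smoothing constant; keeps empty-vs-empty well defined.
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    b = pred.shape[0]
    p = pred.reshape(b, -1)
    t = truth.reshape(b, -1)
    inter = (p * t).sum(axis=1)
    dice = (2.0 * inter + eps) / (p.sum(axis=1) + t.sum(axis=1) + eps)
    # log(cosh(x)) computed stably
    x = 1.0 - dice
    return float(np.mean(np.logaddexp(x, -x) - np.log(2.0)))


def _log_cosh_dice_grad(pred, truth, eps: float = 1.0):
    """Gradient of the loss w.r.t. the predicted probabilities."""
    b = pred.shape[0]
    p = pred.reshape(b, -1).astype(np.float64)
    t = truth.reshape(b, -1).astype(np.float64)
    inter = (p * t).sum(axis=1)
    denom = p.sum(axis=1) + t.sum(axis=1) + eps
    dice = (2.0 * inter + eps) / denom
    # dL/dDice = -tanh(1 - Dice); dDice/dp = (2t*denom - (2*inter+eps)) / denom^2
    dl_ddice = -np.tanh(1.0 - dice) / b
    ddice_dp = (2.0 * t * denom[:, None] - (2.0 * inter + eps)[:, None]) / (
        denom[:, None] ** 2
    )
    return (dl_ddice[:, None] * ddice_dp).reshape(pred.shape).astype(pred.dtype)


class FlyNet:
    """The segmentation network; weights live in plain numpy arrays."""

    def __init__(self, cfg: ModelConfig, seed: int = 0, dtype=nn.DEFAULT_DTYPE):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        k, slope = cfg.kernel, cfg.leaky_slope
        filters = [cfg.base_filters * 2**i for i in range(cfg.n_levels)]
        self.enc = []
        c_in = 1
        for i, f in enumerate(filters):
            if i < cfg.n_spatiotemporal:
                temporal = nn.ConvLSTM2d(c_in, f, k, rng=rng, dtype=dtype)
            else:
                temporal = nn.Conv2d(c_in, f, k, rng=rng, dtype=dtype)
            block = {
                "temporal": temporal,
                "bn1": nn.BatchNorm2d(f, dtype=dtype),
                "conv": nn.Conv2d(f, f, k, rng=rng, dtype=dtype),
                "bn2": nn.BatchNorm2d(f, dtype=dtype),
                "act": nn.LeakyReLU(slope),
                "pool": nn.MaxPool2d(),
            }
            self.enc.append(block)
            c_in = f
        self.dec = []
        for f in reversed(filters):
            block = {
                "up": nn.ConvTranspose2d(c_in, f, rng=rng, dtype=dtype),
                "conv": nn.Conv2d(2 * f, f, k, rng=rng, dtype=dtype),
                "bn": nn.BatchNorm2d(f, dtype=dtype),
                "act": nn.LeakyReLU(slope),
            }
            self.dec.append(block)
            c_in = f
        self.out_conv = nn.Conv2d(filters[0], 1, 1, rng=rng, init="glorot", dtype=dtype)
        self.out_act = nn.Sigmoid()

    # -- parameters ----------------------------------------------------
    def params(self) -> list[nn.Param]:
        ps = []
        for block in self.enc + self.dec:
            for layer in block.values():
                ps.extend(layer.params())
        ps.extend(self.out_conv.params())
        return ps

    # -- forward / backward --------------------------------------------
    def forward(self, x: np.ndarray, training: bool = True):
        """x: (B, T, 1, H, W) -> probabilities of the same shape."""
        b, t, c, h, w = x.shape
        if h != self.cfg.in_size or w != self.cfg.in_size:
            raise ValueError(f"expected {self.cfg.in_size}^2 input, got {h}x{w}")
        caches = []
        cur = x.reshape(b * t, c, h, w)
        skips = []
        for i, blk in enumerate(self.enc):
            cache = {}
            if isinstance(blk["temporal"], nn.ConvLSTM2d):
                seq = cur.reshape(b, t, *cur.shape[1:])
                cur, cache["temporal"] = blk["temporal"].forward(seq, training)
                cur = cur.reshape(b * t, *cur.shape[2:])
            else:
                cur, cache["temporal"] = blk["temporal"].forward(cur, training)
            cur, cache["bn1"] = blk["bn1"].forward(cur, training)
            cur, cache["conv"] = blk["conv"].forward(cur, training)
            cur, cache["bn2"] = blk["bn2"].forward(cur, training)
            cur, cache["act"] = blk["act"].forward(cur, training)
            skips.append(cur)
            cur, cache["pool"] = blk["pool"].forward(cur, training)
            caches.append(cache)
        dec_caches = []
        for blk, skip in zip(self.dec, reversed(skips)):
            cache = {}
            cur, cache["up"] = blk["up"].forward(cur, training)
            cur = np.concatenate([cur, skip], axis=1)
            cache["split"] = cur.shape[1] // 2
            cur, cache["conv"] = blk["conv"].forward(cur, training)
            cur, cache["bn"] = blk["bn"].forward(cur, training)
            cur, cache["act"] = blk["act"].forward(cur, training)
            dec_caches.append(cache)
        cur, out_cache = self.out_conv.forward(cur, training)
        probs, act_cache = self.out_act.forward(cur, training)
        state = (caches, dec_caches, out_cache, act_cache, (b, t))
        return probs.reshape(b, t, 1, h, w), state

    def backward(self, dprobs: np.ndarray, state) -> None:
        caches, dec_caches, out_cache, act_cache, (b, t) = state
        d = dprobs.reshape(b * t, *dprobs.shape[2:])
        d = self.out_act.backward(d, act_cache)
        d = self.out_conv.backward(d, out_cache)
        dskips = []
        for blk, cache in zip(reversed(self.dec), reversed(dec_caches)):
            d = blk["act"].backward(d, cache["act"])
            d = blk["bn"].backward(d, cache["bn"])
            d = blk["conv"].backward(d, cache["conv"])
            split = cache["split"]
            dskips.append(d[:, split:])
            d = blk["up"].backward(np.ascontiguousarray(d[:, :split]), cache["up"])
        for blk, cache, dskip in zip(reversed(self.enc), reversed(caches), reversed(dskips)):
            d = blk["pool"].backward(d, cache["pool"])
            d = d + dskip
            d = blk["act"].backward(d, cache["act"])
            d = blk["bn2"].backward(d, cache["bn2"])
            d = blk["conv"].backward(d, cache["conv"])
            d = blk["bn1"].backward(d, cache["bn1"])
            if isinstance(blk["temporal"], nn.ConvLSTM2d):
                dseq = d.reshape(b, t, *d.shape[1:])
                dseq = blk["temporal"].backward(dseq, cache["temporal"])
                d = dseq.reshape(b * t, *dseq.shape[2:])
            else:
                d = blk["temporal"].backward(d, cache["temporal"])

    # -- persistence ----------------------------------------------------
    def save(self, path) -> None:
        """Write weights (.npz) plus the architecture config (.json)."""
        path = Path(path)
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        for bi, blk in enumerate(self.enc + self.dec):
            for name, layer in blk.items():
                if isinstance(layer, nn.BatchNorm2d):
                    arrays[f"rm{bi}_{name}"] = layer.running_mean
                    arrays[f"rv{bi}_{name}"] = layer.running_var
        np.savez(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(
            json.dumps(dataclasses.asdict(self.cfg), indent=1)
        )

    @classmethod
    def load(cls, path) -> "FlyNet":
        path = Path(path)
        cfg = ModelConfig(**json.loads(path.with_suffix(".json").read_text()))
        model = cls(cfg)
        data = np.load(path.with_suffix(".npz"))
        for i, p in enumerate(model.params()):
            p.value[...] = data[f"p{i}"]
        for bi, blk in enumerate(model.enc + model.dec):
            for name, layer in blk.items():
                if isinstance(layer, nn.BatchNorm2d):
                    layer.running_mean[...] = data[f"rm{bi}_{name}"]
                    layer.running_var[...] = data[f"rv{bi}_{name}"]
        return model

    # -- inference -------------------------------------------------------
    @property
    def in_size(self) -> int:
        return self.cfg.in_size

    def predict_probs(self, video: np.ndarray, batch: int = 4) -> np.ndarray:
        """Segment a normalized (T, H, W) video into per-pixel probabilities.

        The video is chunked into ``seq_len``-frame sequences; a short
        tail is padded by repeating the last frame and trimmed again
        afterwards, so the output has exactly T frames.
        """
        t = video.shape[0]
        probs = np.empty_like(video, dtype=np.float32)
        for ch in chunk_sequences(t, self.cfg.seq_len):
            clip = video[ch.start : ch.stop]
            if ch.pad:
                clip = np.concatenate([clip, np.repeat(clip[-1:], ch.pad, axis=0)])
            x = clip[None, :, None].astype(np.float32)
            p, _ = self.forward(x, training=False)
            probs[ch.start : ch.stop] = p[0, : ch.stop - ch.start, 0]
        return probs


def build_flynet(cfg: ModelConfig | None = None, seed: int = 0) -> FlyNet:
    """Construct an untrained FlyNet from the given configuration."""
    return FlyNet(cfg or ModelConfig(), seed=seed)


def predict_masks(
    model: FlyNet, video: np.ndarray, threshold: float = 0.5, batch: int = 4
) -> np.ndarray:
    """Threshold the model's probabilities into a {0,1} mask stack."""
    if video.shape[1] != model.in_size or video.shape[2] != model.in_size:
        raise ValueError(
            f"video is {video.shape[1]}x{video.shape[2]}, model wants "
            f"{model.in_size}x{model.in_size}"
        )
    probs = model.predict_probs(video, batch=batch)
    return (probs > threshold).astype(np.uint8)


# ---------------------------------------------------------------------------
# training


@dataclass
class SamplePair:
    """One training sample: full-size video and its full-size mask."""

    full_img: np.ndarray
    full_mask: np.ndarray

    def __post_init__(self):
        if isinstance(self.full_img, VideoStack):
            self.full_img = self.full_img.frames
        if isinstance(self.full_mask, MaskStack):
            self.full_mask = self.full_mask.frames
        if self.full_img.shape != self.full_mask.shape:
            raise ValueError(
                f"image {self.full_img.shape} and mask {self.full_mask.shape} disagree"
            )


def _make_clip(sample: SamplePair, ch, seq_len: int):
    img = sample.full_img[ch.start : ch.stop]
    msk = sample.full_mask[ch.start : ch.stop]
    if ch.pad:
        img = np.concatenate([img, np.repeat(img[-1:], ch.pad, axis=0)])
        msk = np.concatenate([msk, np.repeat(msk[-1:], ch.pad, axis=0)])
    return img, msk


def _augmented_crop(img, msk, in_size, margin, jitter, rng):
    """Random crop around the heart, with the heart guaranteed inside.

    The box is the (squared, margin-dilated) bounding box of the mask
    union over the clip, shifted by a uniform jitter no larger than the
    margin, then clipped to the frame. The full-size mask makes the
    guarantee checkable: the tight heart box always stays inside.
    """
    h, w = img.shape[1:]
    box = bbox_from_mask(msk, margin=margin, square=True)
    if jitter > 0 and rng is not None:
        j = min(jitter, margin)
        dy = int(rng.integers(-j, j + 1))
        dx = int(rng.integers(-j, j + 1))
        dy = int(np.clip(dy, -box.min_y, h - box.max_y))
        dx = int(np.clip(dx, -box.min_x, w - box.max_x))
        from .dataset import CropParams

        box = CropParams.from_box(
            box.min_y + dy, box.max_y + dy, box.min_x + dx, box.max_x + dx
        )
    x = crop_resize(img, box, out=in_size)
    y = crop_resize(msk, box, out=in_size, mask=True)
    return normalize_video(x), y


def split_samples(samples, split, rng):
    """Shuffle and partition samples into train / validation / test."""
    idx = rng.permutation(len(samples))
    n = len(samples)
    n_train = max(int(round(split[0] * n)), 1)
    n_val = int(round(split[1] * n))
    train = [samples[i] for i in idx[:n_train]]
    val = [samples[i] for i in idx[n_train : n_train + n_val]]
    test = [samples[i] for i in idx[n_train + n_val :]]
    return train, val, test


def evaluate_model(model: FlyNet, samples, margin: int = 4, threshold: float = 0.5):
    """Mean loss and IOU over samples with a deterministic centred crop."""
    from .analysis import iou as _iou

    losses, ious = [], []
    for sample in samples:
        x, y = _augmented_crop(
            sample.full_img, sample.full_mask, model.in_size, margin, 0, None
        )
        probs = model.predict_probs(x)
        losses.append(log_cosh_dice_loss(probs[None], y[None].astype(np.float32)))
        ious.append(_iou((probs > threshold).astype(np.uint8), y))
    return float(np.mean(losses)), float(np.mean(ious))


def train_model(
    model: FlyNet,
    tc: TrainConfig,
    samples,
    val_samples=None,
    verbose: bool = False,
):
    """Train FlyNet on full-size sample pairs with crop augmentation.

    Every epoch, each ``seq_len``-frame sequence of each training sample
    receives a fresh random crop (jittered around the heart's bounding
    box, heart always inside), is resized to the model space, normalized
    and fed to Adam minimizing the Log-Cosh Dice loss. When
    ``val_samples`` is not given, ``tc.split`` partitions ``samples``
    into train/validation/test subsets first.

    Returns the training history: per-epoch train loss/IOU and, when a
    validation set exists, validation loss/IOU.
    """
    from .analysis import iou as _iou

    tc.validate()
    samples = [s if isinstance(s, SamplePair) else SamplePair(*s) for s in samples]
    if not samples:
        raise ValueError("empty training set")
    rng = np.random.default_rng(tc.seed)
    if val_samples is None:
        train, val, _test = split_samples(samples, tc.split, rng)
    else:
        train = samples
        val = [s if isinstance(s, SamplePair) else SamplePair(*s) for s in val_samples]
    if not train:
        raise ValueError("empty training set after split")

    opt = nn.Adam(model.params(), lr=tc.lr)
    seq_len = model.cfg.seq_len
    units = [
        (si, ch)
        for si, s in enumerate(train)
        for ch in chunk_sequences(s.full_img.shape[0], seq_len)
    ]
    history = {"train_loss": [], "train_iou": [], "val_loss": [], "val_iou": []}
    for epoch in range(tc.epochs):
        order = rng.permutation(len(units))
        ep_loss, ep_iou = [], []
        for bstart in range(0, len(order), tc.batch_size):
            xs, ys = [], []
            for ui in order[bstart : bstart + tc.batch_size]:
                si, ch = units[ui]
                img, msk = _make_clip(train[si], ch, seq_len)
                x, y = _augmented_crop(
                    img, msk, model.cfg.in_size, tc.margin, tc.jitter, rng
                )
                xs.append(x)
                ys.append(y)
            xb = np.stack(xs)[:, :, None].astype(np.float32)
            yb = np.stack(ys)[:, :, None].astype(np.float32)
            probs, state = model.forward(xb, training=True)
            ep_loss.append(log_cosh_dice_loss(probs, yb, tc.dice_epsilon))
            ep_iou.append(_iou((probs[:, :, 0] > 0.5).reshape(-1, *probs.shape[-2:]).astype(np.uint8),
                               yb[:, :, 0].reshape(-1, *yb.shape[-2:])))
            nn.zero_grads(model.params())
            model.backward(_log_cosh_dice_grad(probs, yb, tc.dice_epsilon), state)
            opt.step()
        history["train_loss"].append(float(np.mean(ep_loss)))
        history["train_iou"].append(float(np.mean(ep_iou)))
        if val:
            vl, vi = evaluate_model(model, val, margin=tc.margin)
            history["val_loss"].append(vl)
            history["val_iou"].append(vi)
        if verbose:  # pragma: no cover - logging only
            msg = (
                f"epoch {epoch + 1}/{tc.epochs} "
                f"loss {history['train_loss'][-1]:.4f} iou {history['train_iou'][-1]:.3f}"
            )
            if val:
                msg += f" val_iou {history['val_iou'][-1]:.3f}"
            print(msg)
    return history
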