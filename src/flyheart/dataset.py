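"""Reading, writing and validating the OCM heart-video dataset layout.

Each sample lives in a folder named ``<ID>_<stage>`` with stage one of
``LA`` (larva), ``EP`` (early pupa) or ``AD`` (adult), and holds five
files::

    <ID>_full_img.tiff     full-size video, typically T x 600 x 128
    <ID>_full_mask.tiff    heart mask on the full-size frames, 0/255
    <ID>_resize_img.tiff   heart-centred crop resized to T x 128 x 128
    <ID>_resize_mask.tiff  mask in the resized space, 0/255
    resize_parameters.txt  six integers: delta y, delta x, min y, max y,
                           min x, max x (the crop box, half-open)

Masks are stored 0/255 on disk and decoded to 0/1 in memory.
Coordinates are 0-based with row = axial depth (y), column = lateral
position (x); crop boxes are half-open ``[min, max)`` so that
``delta == max - min``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

STAGES = ("LA", "EP", "AD")

#: On-disk mask encoding: admissible pixel values.
MASK_DISK_VALUES = frozenset({0, 255})


class FormatError(ValueError):
    """The file exists but is not in the documented format."""


@dataclass
class VideoStack:
    """A T x H x W grayscale video plus acquisition metadata."""

    frames: np.ndarray
    fps: float = 125.0
    sample_id: str = ""
    stage: str = ""

    def __post_init__(self):
        if self.frames.ndim != 3:
            raise FormatError(f"expected T x H x W frames, got shape {self.frames.shape}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self):
        return self.frames.shape


@dataclass
class MaskStack:
    """A binary heart-segmentation stack; values 0/1 in memory."""

    frames: np.ndarray
    sample_id: str = ""

    def __post_init__(self):
        if self.frames.ndim != 3:
            raise FormatError(f"expected T x H x W frames, got shape {self.frames.shape}")
        vals = np.unique(self.frames)
        if not set(vals.tolist()) <= {0, 1}:
            raise FormatError(f"mask values must be 0/1, found {vals[:10]}")

    @property
    def shape(self):
        return self.frames.shape


@dataclass
class CropParams:
    """The six integers of ``resize_parameters.txt``.

    ``min``/``max`` bound the heart box on the full-size frame,
    half-open, and ``delta`` is the box size per axis.
    """

    delta_y: int
    delta_x: int
    min_y: int
    max_y: int
    min_x: int
    max_x: int

    def __post_init__(self):
        if self.min_y >= self.max_y or self.min_x >= self.max_x:
            raise ValueError(f"degenerate crop box {self}")
        if self.min_y < 0 or self.min_x < 0:
            raise ValueError(f"negative crop coordinates {self}")
        if self.delta_y != self.max_y - self.min_y or self.delta_x != self.max_x - self.min_x:
            warnings.warn(
                f"crop deltas ({self.delta_y}, {self.delta_x}) disagree with "
                f"box extents ({self.max_y - self.min_y}, {self.max_x - self.min_x})",
                stacklevel=2,
            )

    @classmethod
    def from_box(cls, min_y, max_y, min_x, max_x) -> "CropParams":
        return cls(max_y - min_y, max_x - min_x, min_y, max_y, min_x, max_x)

    def in_bounds(self, shape) -> bool:
        h, w = shape[-2], shape[-1]
        return 0 <= self.min_y < self.max_y <= h and 0 <= self.min_x < self.max_x <= w


@dataclass
class SampleRecord:
    sample_id: str
    stage: str
    folder: Path
    full_img: Path
    full_mask: Path
    resize_img: Path
    resize_mask: Path
    crop_file: Path


@dataclass
class ValidationReport:
    sample_id: str
    checks: list[tuple[str, bool, str]] = field(default_factory=list)

    def add(self, name: str, ok: bool, detail: str = "") -> None:
        self.checks.append((name, bool(ok), detail))

    @property
    def passed(self) -> bool:
        return all(ok for _, ok, _ in self.checks)

    def failed_checks(self) -> list[str]:
        return [name for name, ok, _ in self.checks if not ok]

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "passed": self.passed,
            "checks": [
                {"name": n, "passed": ok, "detail": d} for n, ok, d in self.checks
            ],
        }


# ---------------------------------------------------------------------------
# stack I/O


def _looks_like_mask(frames: np.ndarray) -> bool:
    return set(np.unique(frames).tolist()) <= MASK_DISK_VALUES


def read_stack(path, kind: str = "auto", fps: float = 125.0):
    """Read a multi-frame grayscale TIFF as a VideoStack or MaskStack.

    ``kind`` may be ``"auto"`` (detect a mask by its value set being a
    subset of {0, 255}), ``"video"`` or ``"mask"``. An all-zero stack is
    ambiguous under auto-detection and is returned as a mask; pass
    ``kind="video"`` to override.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise FormatError(
            f"{path.name}: expected single-channel frames, got shape {frames.shape}"
        )
    sample_id, stage = _parse_sample_name(path.parent.name)
    if kind == "auto":
        kind = "mask" if _looks_like_mask(frames) else "video"
    if kind == "mask":
        if not _looks_like_mask(frames):
            raise FormatError(f"{path.name}: mask values outside {{0, 255}}")
        return MaskStack((frames > 0).astype(np.uint8), sample_id=sample_id)
    return VideoStack(frames, fps=fps, sample_id=sample_id, stage=stage)


def write_stack(stack, path) -> None:
    """Write a stack in the dataset's on-disk encoding.

    Masks are encoded 0/255. Float-valued videos are min-max scaled to
    [0, 255] and cast to uint8; integer videos already within uint8
    range are written untouched so a read/write cycle is lossless.
    """
    path = Path(path)
    if isinstance(stack, MaskStack):
        data = (stack.frames.astype(np.uint8) * 255)
    elif isinstance(stack, VideoStack):
        frames = stack.frames
        if np.issubdtype(frames.dtype, np.integer):
            if frames.min() < 0 or frames.max() > 255:
                raise ValueError("integer video values must lie in [0, 255]")
            data = frames.astype(np.uint8)
        else:
            lo, hi = float(frames.min()), float(frames.max())
            scale = 255.0 / (hi - lo) if hi > lo else 0.0
            data = np.clip((frames - lo) * scale, 0, 255).astype(np.uint8)
    else:
        raise TypeError(f"cannot write {type(stack).__name__}")
    tifffile.imwrite(path, data, photometric="minisblack")


# ---------------------------------------------------------------------------
# crop parameters


def parse_crop_params(text: str) -> CropParams:
    """Parse the six whitespace-separated integers of resize_parameters.txt."""
    tokens = text.split()
    if len(tokens) != 6:
        raise ValueError(f"expected 6 numbers, got {len(tokens)}: {text!r}")
    try:
        nums = [int(tok) for tok in tokens]
    except ValueError as exc:
        raise ValueError(f"non-integer crop parameter in {text!r}") from exc
    return CropParams(*nums)


def format_crop_params(p: CropParams) -> str:
    return f"{p.delta_y} {p.delta_x} {p.min_y} {p.max_y} {p.min_x} {p.max_x}\n"


# ---------------------------------------------------------------------------
# dataset scanning / validation


def _parse_sample_name(name: str):
    if "_" in name:
        sample_id, _, stage = name.rpartition("_")
        if stage in STAGES and sample_id:
            return sample_id, stage
    return "", ""


def scan_dataset(root) -> list[SampleRecord]:
    """Enumerate conforming ``<ID>_<stage>`` sample folders under root."""
    root = Path(root)
    if not root.exists():
        raise FileNotFoundError(root)
    records = []
    folders = sorted(p for p in root.iterdir() if p.is_dir())
    if not folders:
        warnings.warn(f"no sample folders under {root}", stacklevel=2)
    for folder in folders:
        sample_id, stage = _parse_sample_name(folder.name)
        if not stage:
            warnings.warn(f"skipping non-conforming folder {folder.name}", stacklevel=2)
            continue
        records.append(
            SampleRecord(
                sample_id=sample_id,
                stage=stage,
                folder=folder,
                full_img=folder / f"{sample_id}_full_img.tiff",
                full_mask=folder / f"{sample_id}_full_mask.tiff",
                resize_img=folder / f"{sample_id}_resize_img.tiff",
                resize_mask=folder / f"{sample_id}_resize_mask.tiff",
                crop_file=folder / "resize_parameters.txt",
            )
        )
    return records


def validate_sample(rec: SampleRecord, resized_size: int = 128) -> ValidationReport:
    """Check one sample folder against the documented layout.

    Findings are reported, never raised: a partially broken sample still
    yields a full report listing which checks failed.
    """
    rep = ValidationReport(rec.sample_id)
    paths = [rec.full_img, rec.full_mask, rec.resize_img, rec.resize_mask, rec.crop_file]
    missing = [p.name for p in paths if not p.exists()]
    rep.add("files_present", not missing, f"missing: {missing}" if missing else "")
    if missing:
        return rep

    full_img = tifffile.imread(rec.full_img)
    full_mask = tifffile.imread(rec.full_mask)
    rsz_img = tifffile.imread(rec.resize_img)
    rsz_mask = tifffile.imread(rec.resize_mask)

    rep.add(
        "full_shapes_agree",
        full_img.shape == full_mask.shape,
        f"img {full_img.shape} vs mask {full_mask.shape}",
    )
    rep.add(
        "resized_shapes_agree",
        rsz_img.shape == rsz_mask.shape,
        f"img {rsz_img.shape} vs mask {rsz_mask.shape}",
    )
    rep.add(
        "frame_counts_agree",
        full_img.shape[0] == rsz_img.shape[0],
        f"full T={full_img.shape[0]} resized T={rsz_img.shape[0]}",
    )
    ok_rs = rsz_img.shape[1:] == (resized_size, resized_size)
    rep.add("resized_is_square", ok_rs, f"resized frames are {rsz_img.shape[1:]}")
    for name, m in (("full_mask_values", full_mask), ("resize_mask_values", rsz_mask)):
        vals = set(np.unique(m).tolist())
        rep.add(name, vals <= MASK_DISK_VALUES, f"values {sorted(vals)[:8]}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            crop = parse_crop_params(rec.crop_file.read_text())
        rep.add("crop_parse", True)
        rep.add(
            "crop_in_bounds",
            crop.in_bounds(full_img.shape),
            f"box y[{crop.min_y},{crop.max_y}) x[{crop.min_x},{crop.max_x}) "
            f"on {full_img.shape[1:]}",
        )
        rep.add(
            "crop_deltas_consistent",
            crop.delta_y == crop.max_y - crop.min_y
            and crop.delta_x == crop.max_x - crop.min_x,
        )
    except ValueError as exc:
        rep.add("crop_parse", False, str(exc))
    return rep
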