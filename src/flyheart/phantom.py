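"""Synthetic beating-heart phantoms with exact ground truth.

An OCM cross-section of the fly heart shows a bright muscular wall
around a darker lumen, embedded in speckled tissue. The phantom
emulates that appearance with an elliptical lumen whose area follows a
configurable beat schedule: periodic raised-cosine contractions,
optional beat-interval jitter (arrhythmia), heart-stop pauses, and
pacing segments that override the base rate. Because the geometry is
analytic, every phantom carries a pixel-exact mask and the true heart
rate, fractional shortening and arrhythmia index, so the whole
segmentation + analysis pipeline can be validated without real
recordings.

Speckle is modelled as multiplicative exponential noise followed by a
Gaussian blur — a first-order approximation of fully developed OCT
speckle — and intensity decays exponentially with depth (row index).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .dataset import CropParams, MaskStack, VideoStack, format_crop_params, write_stack


@dataclass
class PhantomConfig:
    """All knobs of the synthetic heart video.

    Geometry is in pixels on an ``height x width`` frame; rates in Hz;
    times in seconds. ``systolic_fraction`` is the end-systolic /
    end-diastolic area ratio, so the true fractional shortening is
    ``100 * (1 - systolic_fraction)`` percent.
    """

    n_frames: int = 500
    height: int = 128
    width: int = 128
    fps: float = 125.0
    base_hr: float = 3.0
    hr_jitter_cv: float = 0.0
    pause_windows: tuple[tuple[float, float], ...] = ()
    pacing_segments: tuple[tuple[float, float, float], ...] = ()
    systolic_fraction: float = 0.5
    contraction_fraction: float = 0.4
    center: tuple[float, float] | None = None
    semi_axes: tuple[float, float] = (22.0, 30.0)
    wall_thickness: float = 5.0
    speckle_scale: float = 0.35
    blur_sigma: float = 1.0
    depth_attenuation: float = 0.002
    lumen_intensity: float = 0.05
    wall_intensity: float = 0.9
    background_intensity: float = 0.35
    axial_um_per_px: float = 3.3
    lateral_um_per_px: float = 2.3
    seed: int = 0

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def resolved_center(self) -> tuple[float, float]:
        return self.center if self.center is not None else (
            self.height / 2.0,
            self.width / 2.0,
        )

    def validate(self) -> None:
        if not 0.0 < self.systolic_fraction <= 1.0:
            raise ValueError("systolic_fraction must be in (0, 1]")
        if self.base_hr <= 0 or self.fps <= 0 or self.n_frames < 1:
            raise ValueError("base_hr, fps and n_frames must be positive")
        if not 0.0 < self.contraction_fraction < 1.0:
            raise ValueError("contraction_fraction must be in (0, 1)")
        for lo, hi in self.pause_windows:
            if not (0.0 <= lo < hi <= self.duration_s + 1e-9):
                raise ValueError(f"pause window ({lo}, {hi}) outside recording")
        for lo, hi, rate in self.pacing_segments:
            if not (0.0 <= lo < hi <= self.duration_s + 1e-9) or rate <= 0:
                raise ValueError(f"invalid pacing segment ({lo}, {hi}, {rate})")
        cy, cx = self.resolved_center()
        ay, ax = self.semi_axes
        if (
            cy - ay - self.wall_thickness < 0
            or cy + ay + self.wall_thickness > self.height
            or cx - ax - self.wall_thickness < 0
            or cx + ax + self.wall_thickness > self.width
        ):
            raise ValueError("heart ellipse plus wall does not fit in the frame")


@dataclass
class BeatSchedule:
    """End-diastole times and the rate in force for each beat."""

    beat_times: np.ndarray
    per_beat_rate: np.ndarray
    pause_mask: np.ndarray  # boolean, per frame


@dataclass
class GroundTruth:
    schedule: BeatSchedule
    area_truth: np.ndarray  # µm² per frame, from the exact mask
    hr_truth: float
    fs_truth: float
    ai_truth: float

    def to_dict(self) -> dict:
        return {
            "hr_truth_hz": self.hr_truth,
            "fs_truth_percent": self.fs_truth,
            "ai_truth": self.ai_truth,
            "beat_times_s": self.schedule.beat_times.tolist(),
            "area_truth_um2": self.area_truth.tolist(),
        }


def _in_window(t: float, windows) -> float | None:
    """Return the window end if t falls inside one, else None."""
    for win in windows:
        if win[0] <= t < win[1]:
            return win[1]
    return None


def make_beat_schedule(cfg: PhantomConfig) -> BeatSchedule:
    """Draw end-diastole times for the configured rhythm.

    Beat intervals are ``1/rate * (1 + jitter)`` with jitter normal with
    standard deviation ``hr_jitter_cv``, truncated at three sigma. No
    beat falls inside a pause window; the beat after a pause starts at
    the pause end. Pacing segments override the base rate while the
    beat onset lies inside them. Deterministic for a fixed seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    duration = cfg.duration_s
    times, rates = [], []
    t = 0.0
    while t < duration:
        pause_end = _in_window(t, cfg.pause_windows)
        if pause_end is not None:
            t = pause_end
            continue
        rate = cfg.base_hr
        for lo, hi, r in cfg.pacing_segments:
            if lo <= t < hi:
                rate = r
                break
        times.append(t)
        rates.append(rate)
        jitter = 0.0
        if cfg.hr_jitter_cv > 0:
            jitter = float(
                np.clip(
                    rng.normal(0.0, cfg.hr_jitter_cv),
                    -3 * cfg.hr_jitter_cv,
                    3 * cfg.hr_jitter_cv,
                )
            )
            jitter = max(jitter, -0.9)  # keep intervals positive
        t += (1.0 / rate) * (1.0 + jitter)
    frame_t = np.arange(cfg.n_frames) / cfg.fps
    pause_mask = np.zeros(cfg.n_frames, dtype=bool)
    for lo, hi in cfg.pause_windows:
        pause_mask |= (frame_t >= lo) & (frame_t < hi)
    return BeatSchedule(
        beat_times=np.asarray(times, dtype=float),
        per_beat_rate=np.asarray(rates, dtype=float),
        pause_mask=pause_mask,
    )


def area_waveform(schedule: BeatSchedule, cfg: PhantomConfig) -> np.ndarray:
    """Relative lumen area per frame: 1.0 at diastole, dipping to
    ``systolic_fraction`` mid-contraction.

    Each beat opens with a raised-cosine contraction-relaxation pulse
    spanning ``contraction_fraction`` of the beat interval; the area
    then holds at the diastolic level, including through pauses.
    """
    sf = cfg.systolic_fraction
    frame_t = np.arange(cfg.n_frames) / cfg.fps
    area = np.ones(cfg.n_frames, dtype=float)
    beats = schedule.beat_times
    if sf >= 1.0 or beats.size == 0:
        return area
    # interval after the last beat extends at that beat's rate
    ends = np.append(beats[1:], beats[-1] + 1.0 / schedule.per_beat_rate[-1])
    idx = np.searchsorted(beats, frame_t, side="right") - 1
    valid = idx >= 0
    iv = idx[valid]
    phase = (frame_t[valid] - beats[iv]) / (ends[iv] - beats[iv])
    in_pulse = phase < cfg.contraction_fraction
    u = phase[in_pulse] / cfg.contraction_fraction  # 0..1 across the pulse
    dip = 0.5 * (1.0 - np.cos(2.0 * np.pi * u))  # 0 -> 1 -> 0
    vals = np.ones(phase.shape)
    vals[in_pulse] = 1.0 - (1.0 - sf) * dip
    area[valid] = vals
    area[schedule.pause_mask] = 1.0
    return area


def _ellipse_mask(h, w, cy, cx, ay, ax):
    yy = (np.arange(h)[:, None] - cy) / ay
    xx = (np.arange(w)[None, :] - cx) / ax
    return (yy * yy + xx * xx) <= 1.0


def render_phantom(
    cfg: PhantomConfig, images: bool = True
) -> tuple[VideoStack | None, MaskStack, GroundTruth]:
    """Render the phantom video, its exact lumen mask, and ground truth.

    Per frame both ellipse semi-axes are scaled by the square root of
    the relative area, so lumen area tracks :func:`area_waveform`
    exactly (up to pixelation). ``images=False`` skips the intensity
    rendering when only masks and ground truth are needed.

    The ground-truth heart region is the lumen only (not the wall);
    users comparing against datasets whose labels include the wall
    should account for that convention.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    schedule = make_beat_schedule(cfg)
    rel_area = area_waveform(schedule, cfg)
    cy, cx = cfg.resolved_center()
    ay0, ax0 = cfg.semi_axes
    h, w = cfg.height, cfg.width
    masks = np.empty((cfg.n_frames, h, w), dtype=np.uint8)
    vids = np.empty((cfg.n_frames, h, w), dtype=np.float32) if images else None
    depth_decay = np.exp(-cfg.depth_attenuation * np.arange(h, dtype=np.float32))
    for i in range(cfg.n_frames):
        s = np.sqrt(rel_area[i])
        lumen = _ellipse_mask(h, w, cy, cx, ay0 * s, ax0 * s)
        masks[i] = lumen
        if not images:
            continue
        outer = _ellipse_mask(
            h, w, cy, cx, ay0 * s + cfg.wall_thickness, ax0 * s + cfg.wall_thickness
        )
        frame = np.full((h, w), cfg.background_intensity, dtype=np.float32)
        frame[outer] = cfg.wall_intensity
        frame[lumen] = cfg.lumen_intensity
        if cfg.speckle_scale > 0:
            speckle = rng.exponential(1.0, size=(h, w)).astype(np.float32)
            frame = frame * ((1.0 - cfg.speckle_scale) + cfg.speckle_scale * speckle)
        if cfg.blur_sigma > 0:
            frame = gaussian_filter(frame, cfg.blur_sigma)
        frame *= depth_decay[:, None]
        vids[i] = frame
    px_area = cfg.axial_um_per_px * cfg.lateral_um_per_px
    area_truth = masks.sum(axis=(1, 2)).astype(float) * px_area
    truth = GroundTruth(
        schedule=schedule,
        area_truth=area_truth,
        hr_truth=_hr_truth(schedule, cfg),
        fs_truth=100.0 * (1.0 - cfg.systolic_fraction),
        ai_truth=_ai_truth(schedule, cfg),
    )
    video = (
        VideoStack(vids, fps=cfg.fps, sample_id="phantom") if images else None
    )
    return video, MaskStack(masks, sample_id="phantom"), truth


def _clean_intervals(schedule: BeatSchedule, cfg: PhantomConfig) -> np.ndarray:
    """Diastole-to-diastole intervals that do not span a pause."""
    beats = schedule.beat_times
    if beats.size < 2:
        return np.empty(0)
    iv = np.diff(beats)
    keep = np.ones(iv.shape, dtype=bool)
    for lo, hi in cfg.pause_windows:
        keep &= ~((beats[:-1] < hi) & (beats[1:] > lo))
    return iv[keep]


def _hr_truth(schedule: BeatSchedule, cfg: PhantomConfig) -> float:
    iv = _clean_intervals(schedule, cfg)
    return float(np.median(1.0 / iv)) if iv.size else float("nan")


def _ai_truth(schedule: BeatSchedule, cfg: PhantomConfig) -> float:
    iv = _clean_intervals(schedule, cfg)
    if iv.size < 2:
        return float("nan")
    rates = 1.0 / iv
    return float(np.std(rates, ddof=1) / np.median(rates))


def render_fullsize_phantom(
    cfg: PhantomConfig,
    full_height: int = 600,
    full_width: int | None = None,
    rng: np.random.Generator | None = None,
):
    """Embed a phantom into a taller full-size frame at a random depth
    offset, mirroring how the heart sits inside the raw recording.

    Returns ``(full_video, full_mask, crop, video128, mask128, truth)``
    where ``crop`` records the embedding box in ``resize_parameters.txt``
    convention.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    video, mask, truth = render_phantom(cfg, images=True)
    h, w = cfg.height, cfg.width
    full_width = full_width or w
    if full_height < h or full_width < w:
        raise ValueError("full frame smaller than the phantom region")
    off_y = int(rng.integers(0, full_height - h + 1))
    off_x = int(rng.integers(0, full_width - w + 1))
    t = cfg.n_frames
    bg = np.full((t, full_height, full_width), cfg.background_intensity, np.float32)
    if cfg.speckle_scale > 0:
        speckle = rng.exponential(1.0, size=bg.shape).astype(np.float32)
        bg *= (1.0 - cfg.speckle_scale) + cfg.speckle_scale * speckle
    if cfg.blur_sigma > 0:
        bg = gaussian_filter(bg, (0, cfg.blur_sigma, cfg.blur_sigma))
    bg *= np.exp(-cfg.depth_attenuation * np.arange(full_height, dtype=np.float32))[
        None, :, None
    ]
    bg[:, off_y : off_y + h, off_x : off_x + w] = video.frames
    full_mask = np.zeros((t, full_height, full_width), dtype=np.uint8)
    full_mask[:, off_y : off_y + h, off_x : off_x + w] = mask.frames
    crop = CropParams.from_box(off_y, off_y + h, off_x, off_x + w)
    full_video = VideoStack(bg, fps=cfg.fps, sample_id="phantom")
    return full_video, MaskStack(full_mask, sample_id="phantom"), crop, video, mask, truth


def write_phantom_sample(
    out_dir,
    sample_id: str,
    cfg: PhantomConfig,
    stage: str = "LA",
    full_height: int = 600,
) -> Path:
    """Write one phantom in the five-file dataset layout plus
    ``ground_truth.json``; returns the sample folder path."""
    full_video, full_mask, crop, video, mask, truth = render_fullsize_phantom(
        cfg, full_height=full_height
    )
    folder = Path(out_dir) / f"{sample_id}_{stage}"
    folder.mkdir(parents=True, exist_ok=True)
    write_stack(full_video, folder / f"{sample_id}_full_img.tiff")
    write_stack(full_mask, folder / f"{sample_id}_full_mask.tiff")
    write_stack(video, folder / f"{sample_id}_resize_img.tiff")
    write_stack(mask, folder / f"{sample_id}_resize_mask.tiff")
    (folder / "resize_parameters.txt").write_text(format_crop_params(crop))
    payload = truth.to_dict()
    payload["config"] = {
        k: v for k, v in dataclasses.asdict(cfg).items() if not isinstance(v, np.ndarray)
    }
    (folder / "ground_truth.json").write_text(json.dumps(payload, indent=1))
    return folder
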