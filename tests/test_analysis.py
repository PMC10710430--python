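"""Cardiac analysis: IOU/Dice metrics, area traces, beat detection,
heart rate, fractional shortening, arrhythmia index, M-mode."""

import numpy as np
import pytest
from scipy import ndimage

from flyheart import (
    BeatDetectConfig,
    Calibration,
    PhantomConfig,
    area_trace,
    area_waveform,
    arrhythmia_index,
    cardiac_report,
    detect_beats,
    dice,
    fractional_shortening,
    heart_rate,
    iou,
    iou_stack,
    make_beat_schedule,
    phase_iou,
    render_mmode,
    render_phantom,
)
from flyheart.analysis import AreaTrace, BeatEvents


def brute_force_iou(a, b):
    inter = union = 0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            pa, pb = bool(a[i, j]), bool(b[i, j])
            inter += pa and pb
            union += pa or pb
    return 1.0 if union == 0 else inter / union


class TestIou:
    def test_identical_masks(self):
        m = np.eye(4, dtype=np.uint8)
        assert iou(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), np.uint8)
        b = np.zeros((4, 4), np.uint8)
        a[0, 0] = 1
        b[3, 3] = 1
        assert iou(a, b) == 0.0

    def test_one_third_overlap(self):
        a = np.array([[1, 1], [0, 0]], np.uint8)
        b = np.array([[0, 1], [1, 0]], np.uint8)
        assert iou(a, b) == pytest.approx(1 / 3)

    def test_matches_bruteforce_and_symmetric(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a = (rng.random((6, 7)) > 0.5).astype(np.uint8)
            b = (rng.random((6, 7)) > 0.5).astype(np.uint8)
            assert iou(a, b) == pytest.approx(brute_force_iou(a, b), abs=1e-12)
            assert iou(a, b) == iou(b, a)

    def test_dice_iou_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a = (rng.random((5, 5)) > 0.4).astype(np.uint8)
            b = (rng.random((5, 5)) > 0.6).astype(np.uint8)
            d, i = dice(a, b), iou(a, b)
            assert d == pytest.approx(2 * i / (1 + i), abs=1e-12)
            assert i == pytest.approx(d / (2 - d), abs=1e-12)

    def test_both_empty_frames_flagged(self):
        a = np.zeros((3, 4, 4), np.uint8)
        b = np.zeros((3, 4, 4), np.uint8)
        a[0, 1, 1] = b[0, 1, 1] = 1
        per, mean, empty = iou_stack(a, b)
        assert list(empty) == [False, True, True]
        assert per[1] == 1.0 and mean == 1.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            iou(np.zeros((3, 3)), np.zeros((4, 4)))


class TestAreaTrace:
    def test_pixel_count_times_pixel_area(self):
        m = np.zeros((1, 20, 20), np.uint8)
        m[0, :10, :10] = 1  # 100 px
        tr = area_trace(m, Calibration(2.0, 3.0, 100.0))
        assert tr.area_um2[0] == pytest.approx(600.0)

    def test_empty_frame_is_zero(self):
        tr = area_trace(np.zeros((2, 8, 8), np.uint8), Calibration())
        assert tr.area_um2.tolist() == [0.0, 0.0]

    def test_phantom_trace_correlates_with_waveform(self):
        cfg = PhantomConfig(n_frames=250, fps=125.0, base_hr=2.0, seed=8)
        _, mask, _ = render_phantom(cfg, images=False)
        tr = area_trace(mask.frames, Calibration(fps=cfg.fps))
        wave = area_waveform(make_beat_schedule(cfg), cfg)
        r = np.corrcoef(tr.area_um2, wave)[0, 1]
        assert r > 0.99


class TestDetectBeats:
    def test_regular_one_hz_intervals(self):
        cfg = PhantomConfig(n_frames=1000, fps=125.0, base_hr=1.0, seed=0)
        _, mask, _ = render_phantom(cfg, images=False)
        ev = detect_beats(area_trace(mask.frames, Calibration(fps=125.0)))
        frames = np.diff(ev.diastole_frames)
        # 8 s of recording holds 8 beats; boundary beats cannot form
        # interior maxima, leaving >= 6 measurable intervals
        assert ev.n_beats >= 6
        assert np.all(np.abs(frames - 125) <= 1)

    def test_constant_trace_has_no_beats(self):
        tr = AreaTrace(np.full(300, 50.0), fps=125.0)
        ev = detect_beats(tr)
        assert ev.n_beats == 0 and ev.diastole_frames.size == 0

    def test_no_diastole_inside_pause(self):
        cfg = PhantomConfig(
            n_frames=1000, fps=125.0, base_hr=3.0, pause_windows=((3.0, 5.0),), seed=1
        )
        _, mask, _ = render_phantom(cfg, images=False)
        ev = detect_beats(area_trace(mask.frames, Calibration(fps=125.0)))
        times = ev.diastole_frames / 125.0
        assert not np.any((times >= 3.0) & (times < 5.0))
        assert ev.diastole_frames.size > 0

    def test_systole_lies_between_diastoles(self):
        cfg = PhantomConfig(n_frames=500, fps=125.0, base_hr=2.0, seed=2)
        _, mask, _ = render_phantom(cfg, images=False)
        ev = detect_beats(area_trace(mask.frames, Calibration(fps=125.0)))
        for s, d0, d1 in zip(ev.systole_frames, ev.diastole_frames, ev.diastole_frames[1:]):
            assert d0 < s < d1

    def test_too_short_trace_raises(self):
        with pytest.raises(ValueError):
            detect_beats(AreaTrace(np.array([1.0, 2.0]), fps=10.0))


class TestHeartRate:
    def test_unit_intervals_give_one_hz(self):
        ev = BeatEvents(np.array([0, 125, 250]), np.array([60, 190]),
                        np.array([1.0, 1.0]))
        rates, med = heart_rate(ev)
        assert med == 1.0 and rates.tolist() == [1.0, 1.0]

    def test_single_diastole_is_undefined(self):
        ev = BeatEvents(np.array([5]), np.array([], int), np.array([]))
        with pytest.raises(ValueError):
            heart_rate(ev)


class TestFractionalShortening:
    def test_half_area_is_fifty_percent(self):
        tr = AreaTrace(np.array([100.0, 50.0, 100.0, 50.0]), fps=10.0)
        ev = BeatEvents(np.array([0, 2]), np.array([1, 3]), np.array([0.2]))
        fs, eda, esa = fractional_shortening(tr, ev)
        assert fs == 50.0 and eda == 100.0 and esa == 50.0

    def test_no_contraction_is_zero_percent(self):
        tr = AreaTrace(np.array([80.0, 80.0, 80.0]), fps=10.0)
        ev = BeatEvents(np.array([0, 2]), np.array([1]), np.array([0.2]))
        assert fractional_shortening(tr, ev)[0] == 0.0

    def test_zero_eda_is_error(self):
        tr = AreaTrace(np.zeros(4), fps=10.0)
        ev = BeatEvents(np.array([0, 2]), np.array([1]), np.array([0.2]))
        with pytest.raises(ValueError):
            fractional_shortening(tr, ev)

    def test_scale_invariance_under_calibration(self):
        cfg = PhantomConfig(n_frames=500, fps=125.0, base_hr=2.0, seed=3)
        _, mask, _ = render_phantom(cfg, images=False)
        for c in (1.0, 3.7):
            cal = Calibration(3.3 * c, 2.3 * c, 125.0)
            tr = area_trace(mask.frames, cal)
            ev = detect_beats(tr)
            if c == 1.0:
                base = fractional_shortening(tr, ev)[0]
            else:
                assert fractional_shortening(tr, ev)[0] == pytest.approx(base)


class TestArrhythmiaIndex:
    def test_constant_rate_is_zero(self):
        assert arrhythmia_index([2.0, 2.0, 2.0]) == 0.0

    def test_sample_std_over_median(self):
        # std([1,2,3], ddof=1) = 1, median = 2
        assert arrhythmia_index([1.0, 2.0, 3.0]) == pytest.approx(0.5)

    def test_population_flavour_option(self):
        assert arrhythmia_index([1.0, 2.0, 3.0], ddof=0) == pytest.approx(
            np.sqrt(2 / 3) / 2
        )

    def test_fewer_than_two_rates_raises(self):
        with pytest.raises(ValueError):
            arrhythmia_index([1.0])


@pytest.fixture(scope="module")
def phantom_events():
    cfg = PhantomConfig(n_frames=500, fps=125.0, base_hr=2.0, seed=4)
    _, mask, _ = render_phantom(cfg, images=False)
    ev = detect_beats(area_trace(mask.frames, Calibration(fps=125.0)))
    return mask.frames, ev


class TestPhaseIou:

    def test_perfect_prediction(self, phantom_events):
        truth, ev = phantom_events
        assert phase_iou(truth, truth, ev) == (1.0, 1.0)

    def test_erosion_hurts_systole_more(self, phantom_events):
        """Smaller systolic areas are hit proportionally harder by a
        one-pixel boundary erosion."""
        truth, ev = phantom_events
        eroded = np.stack([ndimage.binary_erosion(f) for f in truth]).astype(np.uint8)
        es, ed = phase_iou(eroded, truth, ev)
        assert es <= ed

    def test_disjoint_prediction(self, phantom_events):
        truth, ev = phantom_events
        pred = np.zeros_like(truth)
        pred[:, 0, 0] = 1 - truth[:, 0, 0]
        es, ed = phase_iou(pred, truth, ev)
        assert es == 0.0 and ed == 0.0

    def test_no_events_is_error(self):
        empty = BeatEvents(np.array([], int), np.array([], int), np.array([]))
        with pytest.raises(ValueError):
            phase_iou(np.zeros((2, 4, 4)), np.zeros((2, 4, 4)), empty)


class TestMMode:
    def test_depth_by_time_shape(self):
        video = np.random.default_rng(0).random((100, 128, 64))
        mm = render_mmode(video, column=10)
        assert mm.shape == (128, 100)

    def test_constant_column_gives_constant_rows(self):
        video = np.zeros((10, 8, 8))
        video[:, 3, 2] = 7.0
        mm = render_mmode(video, column=2)
        assert np.all(mm[3] == 7.0) and mm.sum() == 70.0

    def test_out_of_range_column(self):
        with pytest.raises(ValueError):
            render_mmode(np.zeros((5, 8, 8)), column=8)

    def test_overlay_band_width_tracks_waveform(self):
        """The mask band at the heart centre column is wider at diastole
        than at systole."""
        cfg = PhantomConfig(n_frames=250, fps=125.0, base_hr=2.0, seed=5)
        _, mask, _ = render_phantom(cfg, images=False)
        _, overlay = render_mmode(mask.frames * 1.0, column=64, mask=mask.frames)
        widths = overlay.sum(axis=0)  # per-frame band height
        tr = area_trace(mask.frames, Calibration(fps=125.0))
        ev = detect_beats(tr)
        assert widths[ev.diastole_frames].mean() > widths[ev.systole_frames].mean()


def test_cardiac_report_end_to_end():
    cfg = PhantomConfig(n_frames=1000, fps=125.0, base_hr=3.0,
                        systolic_fraction=0.4, seed=6)
    _, mask, truth = render_phantom(cfg, images=False)
    rep = cardiac_report(mask.frames, Calibration(fps=125.0))
    assert rep.median_hr_hz == pytest.approx(3.0, rel=0.02)
    assert rep.fs_percent == pytest.approx(60.0, abs=3.0)
    assert rep.arrhythmia_index < 0.05
    assert rep.edd_um == pytest.approx(2 * np.sqrt(rep.eda_um2 / np.pi))
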