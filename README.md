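# flyheart

Automated segmentation and cardiac-function analysis of the beating
*Drosophila melanogaster* heart in optical coherence microscopy (OCM)
videos.

OCM records cross-sectional B-scans of the fly heart at ~125 frames per
second (4000-frame, ~32 s recordings). Quantifying cardiac function —
heart rate, end-diastolic/systolic area, fractional shortening,
arrhythmia — requires a per-frame segmentation of the heart lumen,
which is far too slow and irreproducible to do by hand. `flyheart`
provides:

- **FlyNet 2.0+**, a convolutional-LSTM U-Net that segments whole video
  sequences rather than independent frames. The first two encoder
  blocks open with a ConvLSTM so the prediction for one frame draws on
  the frames before it (heart walls blur or vanish near end-systole in
  single frames; the recurrence carries them across). Trained with the
  Log-Cosh Dice loss `ln cosh(1 − Dice)` and Adam (lr 0.001). The
  network, backpropagation and the optimizer are implemented directly
  on numpy, and verified by numeric gradient checks.
- A **two-network cascade**: a coarse spatial U-Net localizes the heart
  on full-size frames, the video is cropped and resized to the
  128×128 model space, the fine spatiotemporal network segments it, and
  masks are cleaned (largest 4-connected component, hole filling) and
  mapped back to full size.
- **Cardiac analysis**: heart area per frame from the mask pixel count
  and the µm-per-pixel calibration; end-diastoles as area maxima,
  end-systoles as the minima between them; HR = 1/interval (median
  over beats), FS = 100·(EDA − ESA)/EDA, arrhythmia index
  AI = sd(HR)/median(HR); overall and per-phase IOU; M-mode rendering.
- **Dataset I/O** for the published layout: per-sample folders
  `<ID>_<stage>` (stage ∈ LA/EP/AD) with full-size and resized
  image/mask TIFF stacks (masks 0/255 on disk, 0/1 in memory) and a
  six-integer `resize_parameters.txt` crop record, plus a validator.
- A **synthetic phantom generator** producing OCM-like beating-heart
  videos (bright wall annulus, dark elliptical lumen, multiplicative
  speckle, depth attenuation) with pixel-exact masks and known HR, FS
  and AI — including arrhythmic jitter, heart-stop pauses, and pacing
  segments — so the whole pipeline can be validated end to end without
  the real dataset.

## Worked example

```python
import numpy as np
from flyheart import (PhantomConfig, render_phantom, Calibration,
                      cardiac_report)

cfg = PhantomConfig(n_frames=1000, fps=125.0, base_hr=3.0,
                    systolic_fraction=0.4, hr_jitter_cv=0.0, seed=6)
_, mask, truth = render_phantom(cfg, images=False)
rep = cardiac_report(mask.frames, Calibration(3.3, 2.3, 125.0))
print(f"HR {rep.median_hr_hz:.3f} Hz  FS {rep.fs_percent:.2f}%  "
      f"AI {rep.arrhythmia_index:.4f}  beats {rep.n_beats}")
```

prints

```
HR 3.012 Hz  FS 60.44%  AI 0.0120  beats 23
```

The phantom was configured to beat at 3 Hz with an end-systolic area
40% of end-diastolic (true FS 60%): the analysis recovers the rate
within 0.5%, FS within half a point, and an arrhythmia index near zero
for this metronomic heart.

The same analysis applies to predicted masks from a trained cascade
(`segment_video`) or to any mask TIFF via the CLI:

```bash
flyheart synth --out data --id 001 --stage LA --seed 5
flyheart validate-dataset data --report report.json
flyheart analyze --mask data/001_LA/001_resize_mask.tiff --fps 125 \
    --out cardiac.json
flyheart evaluate --pred pred_mask.tiff --truth truth_mask.tiff
```

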