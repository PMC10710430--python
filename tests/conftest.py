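"""Shared fixtures: small phantom study conditions and trained models.

The scaled-down training conditions (64x64 model space, 8-frame
sequences, 8 base filters, six noiseless phantoms of 32 frames) are
chosen so a full training run fits on one desktop CPU core while still
exercising every stage of the pipeline.
"""

from __future__ import annotations

import numpy as np
import pytest

from flyheart import (
    ModelConfig,
    PhantomConfig,
    TrainConfig,
    build_flynet,
    render_fullsize_phantom,
    train_model,
)
from flyheart.model import SamplePair, evaluate_model

SMALL_MODEL_CFG = dict(
    seq_len=8, in_size=64, n_levels=4, n_spatiotemporal=2, base_filters=8
)

TRAIN_SF = [0.4, 0.5, 0.6, 0.45, 0.55, 0.5]
HELD_SF = [0.42, 0.58]


def small_phantom_cfg(seed: int, systolic_fraction: float = 0.5, **kw) -> PhantomConfig:
    """A 96x96 noiseless phantom sized for the 64x64 model space."""
    defaults = dict(
        n_frames=32,
        height=96,
        width=96,
        fps=25.0,
        base_hr=2.5,
        systolic_fraction=systolic_fraction,
        semi_axes=(16.0, 22.0),
        wall_thickness=4.0,
        speckle_scale=0.0,
        blur_sigma=0.8,
        seed=seed,
    )
    defaults.update(kw)
    return PhantomConfig(**defaults)


def make_fullsize_sample(seed: int, systolic_fraction: float = 0.5, **kw):
    cfg = small_phantom_cfg(seed, systolic_fraction, **kw)
    return render_fullsize_phantom(cfg, full_height=140, full_width=96)


@pytest.fixture(scope="session")
def phantom_training_set():
    """Six noiseless training phantoms and two held-out phantoms
    (full-size video + mask pairs, plus held-out render tuples)."""
    train = [
        SamplePair(r[0].frames, r[1].frames)
        for r in (make_fullsize_sample(s, sf) for s, sf in enumerate(TRAIN_SF))
    ]
    held = [make_fullsize_sample(100 + s, sf) for s, sf in enumerate(HELD_SF)]
    return train, held


@pytest.fixture(scope="session")
def trained_fine_models(phantom_training_set):
    """FlyNets trained for 15 epochs from three seeds, with their
    held-out IOUs. Shared across tests because training dominates the
    suite's runtime."""
    train, held = phantom_training_set
    held_pairs = [SamplePair(r[0].frames, r[1].frames) for r in held]
    results = []
    for seed in (0, 1, 2):
        model = build_flynet(ModelConfig(**SMALL_MODEL_CFG), seed=seed)
        tc = TrainConfig(epochs=15, seed=seed, split=(1.0, 0.0, 0.0))
        history = train_model(model, tc, train, val_samples=[])
        _, held_iou = evaluate_model(model, held_pairs)
        results.append({"seed": seed, "model": model, "history": history,
                        "held_iou": held_iou})
    return results
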