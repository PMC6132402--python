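"""Shared fixtures: small deterministic phantoms generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from usneedle.phantom import PhantomConfig, generate_phantom


def phantom_suite(seed0: int, n: int, shape=(64, 64, 64), **overrides):
    """n small phantoms with randomized needle pose, deterministic in seed0."""
    rng = np.random.default_rng(seed0)
    length = overrides.pop("needle_length_mm", 11.0)
    out = []
    for _ in range(n):
        cfg = PhantomConfig(
            shape=shape,
            voxel_size_mm=0.2,
            needle_length_mm=length,
            needle_intensity_gain=5.0,
            n_distractors=4,
            steepness_angle_deg=float(rng.uniform(10, 30)),
            horizontal_angle_deg=float(rng.uniform(-15, 15)),
            seed=int(rng.integers(2**31)),
            **overrides,
        )
        out.append(generate_phantom(cfg))
    return out


@pytest.fixture(scope="session")
def easy_phantom():
    """One bright, distractor-free phantom: the needle is trivially salient."""
    cfg = PhantomConfig(
        shape=(48, 48, 48), voxel_size_mm=0.2, needle_length_mm=8.0,
        needle_diameter_mm=1.47, needle_intensity_gain=10.0,
        n_distractors=0, shadow_enabled=False, steepness_angle_deg=15.0,
        seed=7,
    )
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def fcn_study():
    """Width-scaled ShareFCNs trained on the small-phantom study over 3 seeds.

    Eight training and two held-out phantoms (64³ voxels at 0.2 mm, 11 mm
    needle, intensity gain 5, four distractors).  Desk-scale training
    settings: width_scale 0.0625, dropout off (the 0.85 rate is calibrated
    for the full-width net), Adam step 1e-3, one rotation augmentation,
    slice gap 2.0 mm, three epochs with the better of two restarts kept by
    validation slice F1.  Returns per-seed trained models with held-out fused
    voxel F1 and geometric errors; shared by the learning smoke tests and
    the end-to-end pipeline tests.
    """
    from usneedle.axis import RansacConfig, designate_tip, needle_plane, ransac_fit
    from usneedle.evaluation import orientation_error, tip_error, voxel_metrics
    from usneedle.segmenter import (
        FCNConfig,
        FCNTrainConfig,
        binarize,
        segment_volume,
        train_fcn,
    )

    train_pairs = [(v, t.mask) for v, t in phantom_suite(1, 8)]
    heldout = phantom_suite(100, 2)
    cfg = FCNConfig(width_scale=0.0625, dropout_p=0.0)
    results = []
    for seed in (0, 1, 2):
        model, _ = train_fcn(
            train_pairs, cfg,
            FCNTrainConfig(seed=seed, epochs=3, n_rotations=1, lr=1e-3,
                           gap_d_mm=2.0, restarts=2),
        )
        f1s, tips, orients = [], [], []
        for vol, truth in heldout:
            pred = binarize(segment_volume(model, vol, gap_d_mm=2.0))
            m = voxel_metrics(pred, truth.mask)
            f1s.append(0.0 if m.f1 is None else m.f1)
            fit = ransac_fit(pred, RansacConfig(seed=seed))
            if fit is not None:
                fit = designate_tip(fit)
                tips.append(tip_error(truth.tip_mm, needle_plane(fit)))
                orients.append(orientation_error(fit.direction,
                                                 truth.axis_direction))
            else:
                tips.append(np.inf)
                orients.append(np.inf)
        results.append({"model": model, "f1": f1s, "tip": tips,
                        "orient": orients})
    return {"results": results, "heldout": heldout, "train_pairs": train_pairs}


@pytest.fixture(scope="session")
def small_phantom_pairs():
    """Three modest phantoms as (volume, mask) training pairs."""
    return [(v, t.mask) for v, t in phantom_suite(11, 3, shape=(48, 48, 48),
                                                  needle_length_mm=7.0)]
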