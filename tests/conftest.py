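"""Shared fixtures: phantoms, trained segmenters, registration trials.

The expensive artifacts (U-net training runs, the 10-seed registration
recovery experiment) are session-scoped so the unit, property, and
acceptance tests measure the same computation instead of repeating it.
"""

from __future__ import annotations

import numpy as np
import pytest

import spinereg as sr

# study conditions for the registration recovery experiment:
# 64x64 phantoms, ground-truth FFD with control displacements up to
# 3 voxels (1 mm spacing), 10 seeds
RECOVERY_SEEDS = list(range(10))
RECOVERY_MAX_DISPLACEMENT = 3.0

# phantom noise level for the noisy training condition: sd 10 on the
# 20-200 intensity scale is ~0.056 of the dynamic range
NOISY_SD = 10.0


@pytest.fixture(scope="session")
def phantom2d():
    """Default noise-free 64x64 five-vertebra phantom."""
    return sr.generate_phantom(sr.PhantomConfig(seed=0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def run_recovery_trial(seed: int, max_displacement: float = RECOVERY_MAX_DISPLACEMENT):
    """One seeded ground-truth recovery experiment.

    The floating image is the clean phantom; the reference is the
    phantom warped by a known random FFD, so the optimizer's target is
    the ground-truth transform itself.
    """
    cfg = sr.PhantomConfig(seed=seed)
    volume, mask, landmarks = sr.generate_phantom(cfg)
    truth = sr.random_deformation(cfg, max_displacement)
    reference = truth.warp_image(volume)
    reference_mask = truth.warp_mask(mask)
    paired = sr.LandmarkSet(landmarks.points,
                            truth.transform_points(landmarks.points))
    result = sr.register(reference, volume)
    vert = lambda m: (m.labels >= 1) & (m.labels <= cfg.n_vertebrae)
    warped_mask = result.transform.warp_mask(mask)
    return {
        "seed": seed,
        "volume": volume,
        "mask": mask,
        "reference": reference,
        "reference_mask": reference_mask,
        "truth": truth,
        "paired": paired,
        "result": result,
        "pre_mtre": sr.mean_tre(None, paired),
        "post_mtre": sr.mean_tre(result.transform, paired),
        "dice_before": sr.dice(vert(reference_mask), vert(mask)),
        "dice_after": sr.dice(vert(reference_mask), vert(warped_mask)),
    }


@pytest.fixture(scope="session")
def recovery_trials():
    """The 10-seed registration recovery experiment (shared)."""
    return [run_recovery_trial(seed) for seed in RECOVERY_SEEDS]


def make_training_data(noise_sd: float, n_train: int = 50, n_test: int = 10):
    train = sr.segmentation_dataset(
        n_train, sr.PhantomConfig(seed=1, noise_sd=noise_sd))
    test = sr.segmentation_dataset(
        n_test, sr.PhantomConfig(seed=9001, noise_sd=noise_sd))
    return train, test


@pytest.fixture(scope="session")
def segmenter_noisefree():
    """U-net trained on 50 noise-free phantom slices, with held-out set."""
    train, test = make_training_data(0.0)
    model = sr.train(train, sr.SegNetConfig(seed=0))
    return model, train, test


@pytest.fixture(scope="session")
def segmenter_noisy():
    """U-net trained at the noisy study condition, with held-out set."""
    train, test = make_training_data(NOISY_SD)
    model = sr.train(train, sr.SegNetConfig(seed=0))
    return model, train, test


def heldout_dice(model, test_pairs, label: int = 1) -> list[float]:
    return [sr.dice(mask.labels, sr.segment(model, vol).labels, label=label)
            for vol, mask in test_pairs]
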