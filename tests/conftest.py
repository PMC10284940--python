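"""Shared fixtures: seeded synthetic scenes and a trained classifier."""

from __future__ import annotations

import numpy as np
import pytest

import fragscan as fs
from fragscan.pipeline import characterize_objects


STANDARD_SCENE_SPEC = dict(seed=11, n_particles=30, n_fibers=3)


@pytest.fixture(scope="session")
def standard_scene():
    """The seeded standard scene: 30 particles + 3 fibers on a pore lattice."""
    spec = fs.SceneSpec(**STANDARD_SCENE_SPEC)
    img, truth = fs.generate_scene(spec)
    return img, truth


@pytest.fixture(scope="session")
def preprocessed_scene(standard_scene):
    img, truth = standard_scene
    return fs.preprocess(img), truth


@pytest.fixture(scope="session")
def detected_objects(preprocessed_scene):
    pre, truth = preprocessed_scene
    params = fs.DetectionParams(min_feret_um=1.0, max_feret_um=100.0)
    return fs.detect_objects(pre, params), pre, truth


@pytest.fixture(scope="session")
def labeled_set():
    """A small synthetic labelled set (fast); the full-size set is exercised separately."""
    return fs.generate_labeled_set(n_fibers=120, n_particles=280, seed=7)


@pytest.fixture(scope="session")
def trained_model(labeled_set):
    return fs.train_classifier(labeled_set, n_trees=100, seed=42)


@pytest.fixture(scope="session")
def characterized_objects(detected_objects, trained_model):
    objects, pre, truth = detected_objects
    objects = characterize_objects(list(objects), pre, trained_model)
    return objects, pre, truth


def mask_from_truth(truth, shape):
    gt = np.zeros(shape, dtype=bool)
    for o in truth.objects:
        r0, c0, r1, c1 = o.bbox
        gt[r0:r1, c0:c1] |= o.mask
    return gt
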