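"""Shared fixtures: small synthetic scenes and hand-built feature stacks."""

from __future__ import annotations

import numpy as np
import pytest

import frfseg


def make_stack(*planes: np.ndarray) -> frfseg.FeatureStack:
    """FeatureStack from explicit planes (bypasses the filter bank)."""
    data = np.stack([np.asarray(p, dtype=np.float64) for p in planes], axis=-1)
    return frfseg.FeatureStack(
        data=data, feature_names=[f"f{i}" for i in range(data.shape[-1])]
    )


@pytest.fixture(scope="session")
def separable():
    """Two-class fixture: left half near 0, right half near 1, 50 labels each.

    The single informative feature separates the classes by a wide margin,
    so any reasonable forest reaches training precision 1.
    """
    rng = np.random.default_rng(42)
    h, w = 40, 40
    plane = np.where(np.arange(w)[None, :] < w // 2, 0.0, 1.0) + rng.normal(0, 0.02, (h, w))
    noise = rng.random((h, w))  # uninformative second feature
    stack = make_stack(plane, noise)
    left = np.column_stack([rng.integers(0, h, 50), rng.integers(0, w // 2, 50)])
    right = np.column_stack([rng.integers(0, h, 50), rng.integers(w // 2, w, 50)])
    labels = frfseg.LabelSet(
        classes=["dark", "bright"],
        coords={"dark": np.unique(left, axis=0), "bright": np.unique(right, axis=0)},
    )
    return stack, labels


@pytest.fixture(scope="session")
def scene_small():
    """160x320 calibrated scene with exact-area defect blobs (5.3% and 4.1%)."""
    total = 160 * 320
    params = frfseg.SceneParams(
        height=160,
        width=320,
        classes=(
            frfseg.DefectClassSpec(
                name="C1", mean=0.35, sd=0.05, correlation_length=4.0,
                orientation_deg=30.0, blob_areas_px=(round(0.053 * total),),
            ),
            frfseg.DefectClassSpec(
                name="C2", mean=0.55, sd=0.05, correlation_length=8.0,
                orientation_deg=120.0, blob_areas_px=(round(0.041 * total),),
            ),
        ),
    )
    return frfseg.generate_scene(params, seed=11)


@pytest.fixture(scope="session")
def scene_pipeline(scene_small):
    """Stack, labels, trained model and probability map for the small scene."""
    labels = frfseg.sample_labels(scene_small, n_per_class=80, seed=5)
    stack = frfseg.build_stack(scene_small.image)
    model = frfseg.train(stack, labels, n_trees=100, seed=3)
    class_map, prob = frfseg.predict(model, stack)
    return {
        "scene": scene_small,
        "stack": stack,
        "labels": labels,
        "model": model,
        "class_map": class_map,
        "prob": prob,
    }
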