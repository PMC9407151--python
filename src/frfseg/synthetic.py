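"""Synthetic calibrated photomicrograph-like scenes with known truth masks.

No study images are redistributable, so every other module is exercised on
generated scenes: a stationary correlated-Gaussian background (emulating
the light, textured look of an H&E field at low power) into which
elliptical "defect" blobs are rasterized, each defect class with its own
intensity mean, noise level, correlation length and texture orientation.
Blob pixel areas are exact by construction — the requested number of
pixels nearest (in the ellipse metric) to the blob centre is selected — so
ground-truth coverage percentages are known without measurement error.

Defaults mirror the study conditions: a 1000 x 2000 px field at
1000 px/mm (1 mm x 2 mm) with two defect classes covering 5.3% and 4.1%
of the field, the coverages reported for the first two analyzed images.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, SamplingError
from .io import GrayImage, LabelSet, write_labels

_PALETTE = ("#e41a1c", "#377eb8", "#4daf4a", "#984ea3", "#ff7f00", "#a65628")


@dataclass
class DefectClassSpec:
    """Texture and geometry of one synthetic defect class."""

    name: str
    mean: float
    sd: float
    correlation_length: float
    orientation_deg: float = 0.0
    blob_areas_px: tuple[int, ...] = ()
    aspect_range: tuple[float, float] = (1.5, 3.0)


@dataclass
class SceneParams:
    """Full description of a synthetic scene (image + truth geometry)."""

    height: int = 1000
    width: int = 2000
    pixels_per_mm: float = 1000.0
    background_mean: float = 0.78
    background_sd: float = 0.05
    background_correlation: float = 2.0
    classes: tuple[DefectClassSpec, ...] = (
        DefectClassSpec(
            name="C1", mean=0.35, sd=0.05, correlation_length=4.0,
            orientation_deg=30.0, blob_areas_px=(106_000,),
        ),
        DefectClassSpec(
            name="C2", mean=0.55, sd=0.05, correlation_length=8.0,
            orientation_deg=120.0, blob_areas_px=(82_000,),
        ),
    )

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ConfigurationError("scene dimensions must be positive")
        sigs = [(c.mean, c.sd, c.correlation_length) for c in self.classes]
        if len(set(sigs)) != len(sigs):
            warnings.warn("two defect classes share identical texture parameters")


@dataclass
class SyntheticScene:
    image: GrayImage
    truth_masks: dict[str, np.ndarray]
    params: SceneParams
    seed: int

    def background_mask(self) -> np.ndarray:
        occupied = np.zeros(self.image.shape, dtype=bool)
        for m in self.truth_masks.values():
            occupied |= m
        return ~occupied

    def coverage_percent(self) -> dict[str, float]:
        total = self.image.pixels.size
        return {name: 100.0 * m.sum() / total for name, m in self.truth_masks.items()}


def _texture(
    shape: tuple[int, int],
    mean: float,
    sd: float,
    corr: float,
    orientation_deg: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stationary Gaussian field with the requested first/second moments."""
    white = rng.standard_normal(shape)
    if corr > 0:
        minor = max(corr / 3.0, 0.5)
        smooth = ndimage.gaussian_filter(white, (minor, corr), mode="wrap")
        if orientation_deg % 180.0:
            smooth = ndimage.rotate(
                smooth, orientation_deg, reshape=False, order=1, mode="reflect"
            )
        smooth = (smooth - smooth.mean()) / max(smooth.std(), 1e-12)
    else:
        smooth = white
    return mean + sd * smooth


def _rasterize_blob(
    shape: tuple[int, int],
    area_px: int,
    occupied: np.ndarray,
    orientation_deg: float,
    aspect_range: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Elliptical blob with an exact pixel count.

    All free pixels are ranked by the ellipse quadratic form around a
    random centre and the ``area_px`` closest are taken, so the mask has
    exactly the requested area even when clipped by the frame or by
    previously placed blobs.
    """
    h, w = shape
    if area_px > (~occupied).sum():
        raise ConfigurationError("not enough free pixels for requested blob area")
    cy = rng.uniform(0.15 * h, 0.85 * h)
    cx = rng.uniform(0.15 * w, 0.85 * w)
    aspect = rng.uniform(*aspect_range)
    a = np.sqrt(area_px * aspect / np.pi)  # semi-major (px)
    b = a / aspect
    theta = np.deg2rad(orientation_deg)
    yy, xx = np.mgrid[0:h, 0:w]
    u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    q = (u / a) ** 2 + (v / b) ** 2
    q[occupied] = np.inf
    chosen = np.argsort(q.ravel(), kind="stable")[:area_px]
    mask = np.zeros(h * w, dtype=bool)
    mask[chosen] = True
    return mask.reshape(h, w)


def generate_scene(params: SceneParams | None = None, seed: int = 0) -> SyntheticScene:
    """Generate a calibrated scene; identical (params, seed) is bit-identical."""
    params = params or SceneParams()
    rng = np.random.default_rng(seed)
    shape = (params.height, params.width)

    image = _texture(
        shape, params.background_mean, params.background_sd,
        params.background_correlation, 0.0, rng,
    )
    occupied = np.zeros(shape, dtype=bool)
    truth_masks: dict[str, np.ndarray] = {}
    for spec in params.classes:
        mask = np.zeros(shape, dtype=bool)
        for area in spec.blob_areas_px:
            blob = _rasterize_blob(
                shape, int(area), occupied, spec.orientation_deg, spec.aspect_range, rng
            )
            mask |= blob
            occupied |= blob
        truth_masks[spec.name] = mask
        tex = _texture(
            shape, spec.mean, spec.sd, spec.correlation_length, spec.orientation_deg, rng
        )
        image = np.where(mask, tex, image)

    gray = GrayImage(np.clip(image, 0.0, 1.0), pixels_per_mm=params.pixels_per_mm)
    return SyntheticScene(image=gray, truth_masks=truth_masks, params=params, seed=seed)


def sample_labels(
    scene: SyntheticScene,
    n_per_class: int,
    seed: int = 0,
    background_name: str = "background",
) -> LabelSet:
    """Sparse annotations: n pixels drawn uniformly inside each truth mask.

    Emulates the annotator circling a few clusters per class; the
    background counts as a class of its own (index 0) so the forest learns
    to reject normal tissue.
    """
    rng = np.random.default_rng(seed)
    masks = {background_name: scene.background_mask(), **scene.truth_masks}
    classes, coords, colors = [], {}, {}
    for i, (name, mask) in enumerate(masks.items()):
        flat = np.flatnonzero(mask)
        if len(flat) < n_per_class:
            raise SamplingError(
                f"class {name!r} has {len(flat)} pixels, {n_per_class} requested"
            )
        pick = rng.choice(flat, size=n_per_class, replace=False)
        coords[name] = np.column_stack(np.unravel_index(np.sort(pick), scene.image.shape)).astype(np.intp)
        classes.append(name)
        colors[name] = _PALETTE[i % len(_PALETTE)]
    return LabelSet(classes=classes, coords=coords, colors=colors)


def write_scene(scene: SyntheticScene, out_dir: str | Path) -> dict[str, Path]:
    """Write image (16-bit PNG), truth masks (indexed PNG + JSON) and params."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out_dir / "image.png",
        "truth_mask": out_dir / "truth_mask.png",
        "truth_classes": out_dir / "truth_classes.json",
        "params": out_dir / "params.json",
    }
    iio.imwrite(paths["image"], np.round(scene.image.pixels * 65535).astype(np.uint16))
    truth = LabelSet(
        classes=list(scene.truth_masks),
        coords={
            name: np.column_stack(np.nonzero(mask)).astype(np.intp)
            for name, mask in scene.truth_masks.items()
        },
        colors={name: _PALETTE[i % len(_PALETTE)] for i, name in enumerate(scene.truth_masks)},
    )
    write_labels(truth, scene.image.shape, paths["truth_mask"], paths["truth_classes"])
    payload = {"seed": scene.seed, "params": asdict(scene.params)}
    paths["params"].write_text(json.dumps(payload, indent=1))
    return paths
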