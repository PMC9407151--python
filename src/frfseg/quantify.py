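"""Defect quantification: probability thresholding and coverage reports.

A per-class probability plane is binarized at a threshold (>= comparison,
so the threshold value itself is included) and the resulting mask is
summarized as a coverage percentage of the whole field plus, when the
image carries a pixels-per-mm calibration, a physical extension in mm^2:

    coverage_percent = 100 * covered_pixels / total_pixels
    extension_mm2    = (coverage_percent / 100) * physical_area_mm2

Human-readable tables round to one decimal; JSON/CSV keep full precision.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .forest import ProbabilityMap
from .io import GrayImage

DEFAULT_THRESHOLD = 0.5


def threshold_probability(prob: ProbabilityMap, class_name: str, thr: float) -> np.ndarray:
    """Binary defect mask: probability >= thr for the given class."""
    if not 0.0 <= thr <= 1.0:
        raise ConfigurationError("threshold must lie in [0, 1]")
    return prob.plane(class_name) >= thr


@dataclass
class CoverageEntry:
    """Coverage of one defect class at one threshold."""

    class_name: str
    threshold: float
    covered_pixels: int
    total_pixels: int
    coverage_percent: float
    extension_mm2: float | None

    def rounded(self) -> dict:
        """Table-style values: percent and mm^2 to the printed precision."""
        return {
            "class": self.class_name,
            "percent": round(self.coverage_percent, 1),
            "extension_mm2": None if self.extension_mm2 is None else round(self.extension_mm2, 3),
        }


def coverage_report(mask: np.ndarray, img: GrayImage, class_name: str = "defect",
                    threshold: float = DEFAULT_THRESHOLD) -> CoverageEntry:
    """Summarize a binary defect mask over the calibrated field.

    Without calibration the physical extension is omitted (with a warning)
    and only the percentage is reported.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape:
        raise ConfigurationError(f"mask shape {mask.shape} != image shape {img.shape}")
    covered = int(mask.sum())
    total = mask.size
    percent = 100.0 * covered / total
    area = img.physical_area_mm2
    if area is None:
        warnings.warn("image has no pixels-per-mm calibration; extension omitted")
        extension = None
    else:
        extension = (percent / 100.0) * area
    return CoverageEntry(
        class_name=class_name,
        threshold=threshold,
        covered_pixels=covered,
        total_pixels=total,
        coverage_percent=percent,
        extension_mm2=extension,
    )


@dataclass
class DefectReport:
    """Per-class defect coverage of one analyzed image."""

    image_id: str
    entries: list[CoverageEntry]
    height_px: int
    width_px: int
    pixels_per_mm: float | None
    seed: int | None = None
    config_hash: str | None = None
    extra: dict = field(default_factory=dict)

    @property
    def physical_dims_mm(self) -> tuple[float, float] | None:
        if self.pixels_per_mm is None:
            return None
        return (self.height_px / self.pixels_per_mm, self.width_px / self.pixels_per_mm)

    def to_dict(self) -> dict:
        dims = self.physical_dims_mm
        return {
            "image_id": self.image_id,
            "height_px": self.height_px,
            "width_px": self.width_px,
            "pixels_per_mm": self.pixels_per_mm,
            "physical_dims_mm": list(dims) if dims else None,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "classes": [
                {
                    "class": e.class_name,
                    "threshold": e.threshold,
                    "covered_pixels": e.covered_pixels,
                    "total_pixels": e.total_pixels,
                    "coverage_percent": e.coverage_percent,
                    "extension_mm2": e.extension_mm2,
                }
                for e in self.entries
            ],
            **self.extra,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {
                "image_id": self.image_id,
                "class": e.class_name,
                "threshold": e.threshold,
                "coverage_percent": e.coverage_percent,
                "extension_mm2": e.extension_mm2,
            }
            for e in self.entries
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    def format_table(self) -> str:
        """Plain-text table with percentages at one decimal, mm^2 at three."""
        lines = [f"{'Class':<12}{'Coverage %':>12}{'Extension mm^2':>16}"]
        for e in self.entries:
            r = e.rounded()
            ext = "n/a" if r["extension_mm2"] is None else f"{r['extension_mm2']:.3f}"
            lines.append(f"{r['class']:<12}{r['percent']:>12.1f}{ext:>16}")
        return "\n".join(lines)


def quantify(
    prob: ProbabilityMap,
    img: GrayImage,
    thresholds: dict[str, float] | float | None = None,
    default_threshold: float = DEFAULT_THRESHOLD,
    image_id: str = "image",
    skip_classes: tuple[str, ...] = (),
) -> DefectReport:
    """Threshold every class plane and assemble the per-image report.

    ``thresholds`` may be a per-class dict (missing classes fall back to
    ``default_threshold``), a single float for all classes, or None.
    """
    entries = []
    for name in prob.class_names:
        if name in skip_classes:
            continue
        if isinstance(thresholds, dict):
            thr = thresholds.get(name, default_threshold)
        else:
            thr = default_threshold if thresholds is None else float(thresholds)
        mask = threshold_probability(prob, name, thr)
        entries.append(coverage_report(mask, img, class_name=name, threshold=thr))
    return DefectReport(
        image_id=image_id,
        entries=entries,
        height_px=img.height_px,
        width_px=img.width_px,
        pixels_per_mm=img.pixels_per_mm,
    )
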