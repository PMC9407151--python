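"""Raster and annotation I/O with physical calibration.

Photomicrographs come in as 8/16-bit PNG or TIFF, greyscale or RGB; they are
collapsed to a single luma channel in [0, 1] and carry an optional
pixels-per-mm calibration so that pixel counts convert to physical area.
Sparse class annotations travel as an indexed PNG mask (0 = unlabeled)
paired with a JSON class table; per-class probability maps are stored as
multi-page float32 TIFF with class names embedded in the page description.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import AnnotationError, FormatError, ImageIOError

#: BT.601 luma weights used to collapse RGB to a single intensity channel.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Default physical calibration: 1000 px/mm, i.e. a 1000x2000-px analysis
#: image spans 1 mm x 2 mm.
DEFAULT_PIXELS_PER_MM = 1000.0


@dataclass
class GrayImage:
    """Calibrated 2-D intensity grid with values in [0, 1].

    Parameters
    ----------
    pixels
        2-D float array of intensities in [0, 1].
    pixels_per_mm
        Physical calibration in pixels per millimetre, or None when the
        acquisition scale is unknown (areas in mm^2 are then unavailable).
    """

    pixels: np.ndarray
    pixels_per_mm: float | None = DEFAULT_PIXELS_PER_MM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise FormatError(f"expected a 2-D intensity grid, got ndim={self.pixels.ndim}")
        if not np.all(np.isfinite(self.pixels)):
            raise ImageIOError("image contains non-finite intensities")
        if self.pixels.size and (self.pixels.min() < 0.0 or self.pixels.max() > 1.0):
            raise ImageIOError("intensities must lie in [0, 1]")
        if self.pixels_per_mm is not None and self.pixels_per_mm <= 0:
            raise ImageIOError("pixels_per_mm must be positive")

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def physical_area_mm2(self) -> float | None:
        """Field area in mm^2, or None without calibration."""
        if self.pixels_per_mm is None:
            return None
        return self.height_px * self.width_px / self.pixels_per_mm**2


@dataclass
class LabelSet:
    """Sparse per-class pixel annotations.

    ``coords`` maps each class name to an (n, 2) int array of (row, col)
    coordinates, 0-based, origin top-left.  Classes are ordered; the order
    defines class indices everywhere downstream (maps, reports, models).
    """

    classes: list[str]
    coords: dict[str, np.ndarray]
    colors: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[int, int]] = set()
        for name in self.classes:
            c = np.asarray(self.coords.get(name, np.empty((0, 2), dtype=np.intp)), dtype=np.intp)
            c = c.reshape(-1, 2)
            self.coords[name] = c
            pts = set(map(tuple, c.tolist()))
            if pts & seen:
                raise AnnotationError(f"class {name!r} shares pixels with another class")
            seen |= pts

    @property
    def n_labels(self) -> int:
        return sum(len(c) for c in self.coords.values())

    def class_counts(self) -> dict[str, int]:
        return {name: len(self.coords[name]) for name in self.classes}

    def validate_bounds(self, shape: tuple[int, int]) -> None:
        for name in self.classes:
            c = self.coords[name]
            if len(c) and (
                c[:, 0].min() < 0
                or c[:, 1].min() < 0
                or c[:, 0].max() >= shape[0]
                or c[:, 1].max() >= shape[1]
            ):
                raise AnnotationError(f"class {name!r} has coordinates outside {shape}")

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """All coordinates and integer class targets, in class order."""
        coords = [self.coords[name] for name in self.classes]
        y = np.concatenate(
            [np.full(len(c), i, dtype=np.intp) for i, c in enumerate(coords)]
            or [np.empty(0, dtype=np.intp)]
        )
        xy = np.concatenate(coords or [np.empty((0, 2), dtype=np.intp)])
        return xy, y


def _rescale_to_unit(arr: np.ndarray) -> np.ndarray:
    """Map integer sample values onto [0, 1] by the dtype's full range."""
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        out = arr.astype(np.float64)
        if out.size and (out.min() < 0.0 or out.max() > 1.0):
            raise FormatError("float image values must already lie in [0, 1]")
        return out
    raise FormatError(f"unsupported sample dtype {arr.dtype}")


def read_image(path: str | Path, pixels_per_mm: float | None = DEFAULT_PIXELS_PER_MM) -> GrayImage:
    """Read a PNG/TIFF photomicrograph and convert it to calibrated luma.

    RGB images are collapsed with BT.601 weights (0.299 R + 0.587 G +
    0.114 B); greyscale images pass through the dtype rescale only, so a
    stored grey image round-trips to itself.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # undecodable raster
        raise ImageIOError(f"cannot decode {path}: {exc}") from exc

    if raw.ndim == 2:
        gray = _rescale_to_unit(raw)
    elif raw.ndim == 3 and raw.shape[2] == 3:
        gray = _rescale_to_unit(raw) @ LUMA_WEIGHTS
    else:
        raise FormatError(
            f"unsupported channel layout {raw.shape}: expected HxW or HxWx3"
        )
    return GrayImage(np.clip(gray, 0.0, 1.0), pixels_per_mm=pixels_per_mm)


def read_labels(mask_path: str | Path, class_table_path: str | Path) -> LabelSet:
    """Read sparse annotations: indexed mask (0 = unlabeled) + JSON table.

    The class table is a JSON object ``{"classes": [{"index": 1, "name":
    "C1", "color": "#e41a1c"}, ...]}``; table order defines class order.
    """
    try:
        mask = iio.imread(Path(mask_path))
    except Exception as exc:
        raise ImageIOError(f"cannot decode label mask {mask_path}: {exc}") from exc
    if mask.ndim != 2:
        raise AnnotationError("label mask must be a single-channel indexed image")
    with open(class_table_path) as fh:
        table = json.load(fh)

    entries = table["classes"]
    index_to_name: dict[int, str] = {}
    classes: list[str] = []
    colors: dict[str, str] = {}
    for entry in entries:
        idx, name = int(entry["index"]), str(entry["name"])
        if idx == 0:
            raise AnnotationError("class index 0 is reserved for unlabeled pixels")
        index_to_name[idx] = name
        classes.append(name)
        colors[name] = entry.get("color", "#000000")

    present = set(np.unique(mask).tolist()) - {0}
    missing = present - set(index_to_name)
    if missing:
        raise AnnotationError(f"mask indices {sorted(missing)} absent from class table")

    coords = {}
    for idx, name in index_to_name.items():
        rr, cc = np.nonzero(mask == idx)
        coords[name] = np.column_stack([rr, cc]).astype(np.intp)
    return LabelSet(classes=classes, coords=coords, colors=colors)


def write_labels(labels: LabelSet, shape: tuple[int, int], mask_path: str | Path, class_table_path: str | Path) -> None:
    """Serialize a LabelSet to the indexed-mask + JSON-table dialect."""
    mask = np.zeros(shape, dtype=np.uint8 if len(labels.classes) < 256 else np.uint16)
    table = {"classes": []}
    for i, name in enumerate(labels.classes, start=1):
        c = labels.coords[name]
        if len(c):
            mask[c[:, 0], c[:, 1]] = i
        table["classes"].append(
            {"index": i, "name": name, "color": labels.colors.get(name, "#000000")}
        )
    iio.imwrite(Path(mask_path), mask)
    with open(class_table_path, "w") as fh:
        json.dump(table, fh, indent=1)


def write_probability_map(
    planes: np.ndarray,
    class_names: list[str],
    path: str | Path,
    preview_path: str | Path | None = None,
) -> None:
    """Write per-class probability planes as a multi-page float32 TIFF.

    Pages follow class order; class names are embedded as JSON in the TIFF
    description so the file round-trips without side-car metadata.  An
    optional 8-bit PNG preview maps probability 1.0 to white.
    """
    planes = np.asarray(planes, dtype=np.float32)
    if planes.ndim == 2:
        planes = planes[None]
    if not np.all(np.isfinite(planes)):
        raise ImageIOError("probability map contains non-finite values")
    if planes.min() < 0.0 or planes.max() > 1.0:
        raise ImageIOError("probability values must lie in [0, 1]")
    if len(class_names) != planes.shape[0]:
        raise ImageIOError("one class name per probability plane required")
    tifffile.imwrite(
        Path(path),
        planes,
        description=json.dumps({"classes": list(class_names)}),
        photometric="minisblack",
    )
    if preview_path is not None:
        preview_path = Path(preview_path)
        for name, plane in zip(class_names, planes):
            out = preview_path if len(class_names) == 1 else preview_path.with_name(
                f"{preview_path.stem}_{name}{preview_path.suffix}"
            )
            iio.imwrite(out, np.round(plane * 255).astype(np.uint8))


def read_probability_map(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a multi-page float32 TIFF probability map; returns (planes, names)."""
    with tifffile.TiffFile(Path(path)) as tif:
        planes = tif.asarray()
        desc = tif.pages[0].description
    if planes.ndim == 2:
        planes = planes[None]
    try:
        names = json.loads(desc)["classes"]
    except (json.JSONDecodeError, KeyError, TypeError):
        names = [f"class_{i}" for i in range(planes.shape[0])]
    return planes, list(names)
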