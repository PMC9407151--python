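"""Full diagnostic protocol: stack -> train -> classify -> threshold -> report.

Mirrors the image-vision workflow: the annotated photomicrograph is
converted to features, the forest is trained on the sparse labels of the
same image, every pixel is classified, each defect class's probability
plane is thresholded, and the coverage/extension report is written together
with the probability maps, class map and performance indicators.  Every
artifact embeds the seed and a hash of the configuration for provenance;
no timestamps are written, so identical runs produce byte-identical
reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from . import forest, io
from .errors import AnnotationError, ImageIOError
from .quantify import DEFAULT_THRESHOLD, DefectReport
from .quantify import quantify as quantify_coverage
from .features import FilterConfig, build_stack

log = logging.getLogger("frfseg")


@dataclass
class RunConfig:
    """Everything one protocol run needs, serializable to JSON."""

    image: str
    labels_mask: str
    labels_table: str
    out_dir: str = "frfseg_out"
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    n_trees: int = 200
    features_per_split: int | None = None
    thresholds: dict[str, float] = field(default_factory=dict)
    default_threshold: float = DEFAULT_THRESHOLD
    pixels_per_mm: float | None = io.DEFAULT_PIXELS_PER_MM
    seed: int = 0
    background_class: str | None = "background"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["filter_config"] = asdict(self.filter_config)
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        data = json.loads(text)
        fc = data.pop("filter_config", None)
        cfg = cls(**data)
        if fc is not None:
            fc["enabled_filters"] = tuple(fc.get("enabled_filters", ()))
            cfg.filter_config = FilterConfig(**fc)
        return cfg

    def config_hash(self) -> str:
        """Hash of the scientifically relevant parameters.

        Output directory and log level are excluded so that re-running the
        same analysis elsewhere yields byte-identical reports.
        """
        d = {k: v for k, v in self.to_dict().items() if k not in ("out_dir", "log_level")}
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def run_protocol(cfg: RunConfig) -> DefectReport:
    """Execute the whole protocol and write all artifacts under ``out_dir``."""
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    log.info("protocol start: seed=%d config=%s", cfg.seed, chash)

    img = io.read_image(cfg.image, pixels_per_mm=cfg.pixels_per_mm)
    try:
        labels = io.read_labels(cfg.labels_mask, cfg.labels_table)
    except (FileNotFoundError, ImageIOError) as exc:
        raise AnnotationError(f"cannot load annotations: {exc}") from exc
    labels.validate_bounds(img.shape)
    log.info("image %dx%d px, %d labeled pixels in %d classes",
             img.height_px, img.width_px, labels.n_labels, len(labels.classes))

    stack = build_stack(img, cfg.filter_config)
    log.info("feature stack: %d features", stack.n_features)

    model = forest.train(
        stack, labels, n_trees=cfg.n_trees,
        features_per_split=cfg.features_per_split, seed=cfg.seed,
    )
    model_payload = json.loads(model.to_json())
    model_payload["config_hash"] = chash
    (out / "model.json").write_text(json.dumps(model_payload))

    class_map, prob = forest.predict(model, stack)
    io.write_probability_map(
        prob.planes, prob.class_names, out / "probability_maps.tif",
        preview_path=out / "probability.png",
    )
    iio.imwrite(out / "class_map.png", class_map.astype(np.uint8))

    metrics = forest.evaluate(model, stack, labels)
    log.info("training precision=%.3f recall=%.3f",
             metrics["micro_precision"], metrics["micro_recall"])
    perf = {"seed": cfg.seed, "config_hash": chash, **metrics}
    (out / "performance.json").write_text(json.dumps(perf, indent=1, sort_keys=True))

    report = quantify_coverage(
        prob, img,
        thresholds=cfg.thresholds or None,
        default_threshold=cfg.default_threshold,
        image_id=Path(cfg.image).stem,
        skip_classes=(cfg.background_class,) if cfg.background_class else (),
    )
    report.seed = cfg.seed
    report.config_hash = chash
    report.extra["training_performance"] = metrics
    report.to_json(out / "report.json")
    report.to_csv(out / "report.csv")
    cfg.to_json(out / "run_config.json")
    log.info("report written to %s", out / "report.json")
    return report
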