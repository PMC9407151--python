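"""Per-pixel filter bank: the classifier's feature space.

Each enabled filter is evaluated at a ladder of Gaussian scales (powers of
two between ``sigma_min`` and ``sigma_max``; the study defaults 1..16 give
{1, 2, 4, 8, 16}) and every response plane becomes one feature.  The bank
covers smoothing (Gaussian), gradients (Sobel), band-pass (difference of
Gaussians), second-order structure (the Hessian family below), oriented
ridge texture (membrane projections), neighbourhood statistics, two
edge-preserving smoothers (Perona-Malik diffusion, bilateral), Lipschitz
top-hats, Gabor texture energy, higher-order Gaussian derivatives, the
structure-tensor eigenvalues and axis shifts.  All convolutions reflect at
the border, so the stack is deterministic and translation-equivariant away
from the frame.

The Hessian family derives, from the smoothed second derivatives
h1 = I_xx, h2 = h3 = I_xy, h4 = I_yy:

* trace        = h1 + h4
* det_standard = h1*h4 - h2*h3           (algebraic determinant)
* det_printed  = h1^2 + h2*h3 + h4^2     (non-standard variant kept as a
  selectable stack feature; the eigenvalue identities below use the
  algebraic form)
* fe, se       = (h1+h4)/2 +- sqrt(4*h2^2 + (h1-h4)^2)/2   (eigenvalues)
* orientation  = 1/2 * arctan2(2*h2, h1-h4) by default; a legacy
  1/2 * arccos(4*h2^2 + (h1-h4)^2) form is selectable with its argument
  clamped to [-1, 1], since it is otherwise undefined
* gamma        = t^4 * (h1-h4)^2 * ((h1-h4)^2 + 4*h2^2)
* square_gamma = t^2 * ((h1-h4)^2 + 4*h2^2)            with t = 13/4
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage import feature as skfeature
from skimage import filters as skfilters
from skimage import morphology, restoration, transform

from .errors import ConfigurationError
from .io import GrayImage

ALL_FILTERS = (
    "gaussian",
    "sobel",
    "hessian",
    "dog",
    "membrane",
    "local_stats",
    "aniso_diffusion",
    "bilateral",
    "lipschitz",
    "gabor",
    "derivatives",
    "structure",
    "shift",
)

#: The study's optimized training configuration: Gaussian blur + Hessian
#: family + membrane projections, thickness 1, patch 19, sigma 1..16.
DEFAULT_FILTERS = ("gaussian", "hessian", "membrane")


@dataclass
class FilterConfig:
    """Filter-bank configuration.

    Defaults reproduce the protocol's optimized hyperparameters: membrane
    thickness 1 px, membrane patch size 19 px, sigma from 1 to 16 px
    (doubling ladder), with the Gaussian, Hessian and membrane-projection
    filters enabled.
    """

    membrane_thickness: int = 1
    membrane_patch_size: int = 19
    sigma_min: float = 1.0
    sigma_max: float = 16.0
    enabled_filters: tuple[str, ...] = DEFAULT_FILTERS
    hessian_t: float = 13 / 4
    use_printed_det: bool = True
    use_printed_orientation: bool = False
    gabor_orientations: int = 4
    diffusion_iterations: int = 20
    diffusion_kappa: float = 20 / 255
    diffusion_step: float = 0.2
    lipschitz_slope: float = 5 / 255

    def __post_init__(self) -> None:
        if self.sigma_min < 0.5:
            raise ConfigurationError("sigma_min must be >= 0.5")
        if self.sigma_max < self.sigma_min:
            raise ConfigurationError("sigma_max must be >= sigma_min")
        if self.membrane_patch_size % 2 == 0:
            raise ConfigurationError("membrane_patch_size must be odd")
        if self.membrane_patch_size < self.membrane_thickness:
            raise ConfigurationError("membrane_patch_size must be >= membrane_thickness")
        unknown = set(self.enabled_filters) - set(ALL_FILTERS)
        if unknown:
            raise ConfigurationError(f"unknown filter kinds: {sorted(unknown)}")
        self.enabled_filters = tuple(self.enabled_filters)

    def scales(self) -> list[float]:
        """Doubling sigma ladder from sigma_min up to sigma_max."""
        out, s = [], self.sigma_min
        while s <= self.sigma_max + 1e-12:
            out.append(float(s))
            s *= 2.0
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "FilterConfig":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        data = json.loads(text)
        data["enabled_filters"] = tuple(data.get("enabled_filters", DEFAULT_FILTERS))
        return cls(**data)


@dataclass
class HessianFeatures:
    """Second-order derivative planes and their derived quantities at one scale."""

    h1: np.ndarray
    h2: np.ndarray
    h3: np.ndarray
    h4: np.ndarray
    trace: np.ndarray
    det_printed: np.ndarray
    det_standard: np.ndarray
    fe: np.ndarray
    se: np.ndarray
    orientation: np.ndarray
    gamma: np.ndarray
    square_gamma: np.ndarray
    sigma: float
    t: float


@dataclass
class FeatureStack:
    """Named per-pixel feature planes stacked as (height, width, n_features)."""

    data: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ConfigurationError("feature stack must be (H, W, F)")
        if len(self.feature_names) != self.data.shape[2]:
            raise ConfigurationError("one name per feature plane required")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ConfigurationError("feature names must be unique")

    @property
    def n_features(self) -> int:
        return self.data.shape[2]

    @property
    def source_dims(self) -> tuple[int, int]:
        return self.data.shape[:2]  # type: ignore[return-value]

    def sample(self, coords: np.ndarray) -> np.ndarray:
        """Feature vectors at (row, col) coordinates -> (n, n_features)."""
        coords = np.asarray(coords, dtype=np.intp).reshape(-1, 2)
        return self.data[coords[:, 0], coords[:, 1], :]

    def flat(self) -> np.ndarray:
        """All pixels as a (H*W, n_features) design matrix."""
        return self.data.reshape(-1, self.n_features)

    def to_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(
            Path(path),
            np.moveaxis(self.data.astype(np.float32), -1, 0),
            description=json.dumps({"features": self.feature_names}),
            photometric="minisblack",
        )


def _as_array(img: GrayImage | np.ndarray) -> np.ndarray:
    return img.pixels if isinstance(img, GrayImage) else np.asarray(img, dtype=np.float64)


def _gauss(arr: np.ndarray, sigma: float, order=(0, 0)) -> np.ndarray:
    out = ndimage.gaussian_filter(arr, sigma, order=order, mode="reflect")
    if any(o > 0 and o % 2 == 0 for o in order):
        # Truncated even-order derivative kernels keep a small DC residual;
        # subtract it (times the identity) so constants are annihilated.
        dc = float(ndimage.gaussian_filter(np.ones((1, 1)), sigma, order=order, mode="reflect")[0, 0])
        out = out - dc * arr
    return out


def hessian_features(
    img: GrayImage | np.ndarray,
    sigma: float,
    t: float = 13 / 4,
    printed_orientation: bool = False,
) -> HessianFeatures:
    """Hessian-matrix features at Gaussian scale ``sigma``.

    ``h1..h4`` are the smoothed second partials (xx, xy, yx, yy; x runs
    along columns).  The derived planes follow the module docstring; the
    mixed partials commute, so h2 == h3 by construction.
    """
    if sigma <= 0:
        raise ConfigurationError("sigma must be positive")
    arr = _as_array(img)
    h1 = _gauss(arr, sigma, order=(0, 2))  # I_xx
    h2 = _gauss(arr, sigma, order=(1, 1))  # I_xy
    h3 = h2.copy()                         # I_yx == I_xy
    h4 = _gauss(arr, sigma, order=(2, 0))  # I_yy
    trace = h1 + h4
    det_printed = h1**2 + h2 * h3 + h4**2
    det_standard = h1 * h4 - h2 * h3
    disc = np.sqrt(4.0 * h2**2 + (h1 - h4) ** 2)
    fe = trace / 2.0 + disc / 2.0
    se = trace / 2.0 - disc / 2.0
    if printed_orientation:
        orientation = 0.5 * np.arccos(np.clip(4.0 * h2**2 + (h1 - h4) ** 2, -1.0, 1.0))
    else:
        orientation = 0.5 * np.arctan2(2.0 * h2, h1 - h4)
    module = (h1 - h4) ** 2 + 4.0 * h2**2
    gamma = t**4 * (h1 - h4) ** 2 * module
    square_gamma = t**2 * module
    return HessianFeatures(
        h1=h1, h2=h2, h3=h3, h4=h4, trace=trace,
        det_printed=det_printed, det_standard=det_standard,
        fe=fe, se=se, orientation=orientation,
        gamma=gamma, square_gamma=square_gamma, sigma=sigma, t=t,
    )


def _membrane_kernels(thickness: int, patch_size: int, n_rotations: int = 30) -> list[np.ndarray]:
    """Rotated line kernels: length patch_size, width thickness, unit sum.

    The base kernel is a vertical line through the patch centre; it is
    rotated in 180/n_rotations-degree steps (6 degrees for the default 30)
    and each rotation is renormalized to unit sum so that a constant image
    produces identical responses at every orientation.
    """
    base = np.zeros((patch_size, patch_size), dtype=np.float64)
    mid = patch_size // 2
    half = (thickness - 1) // 2
    base[:, mid - half : mid - half + thickness] = 1.0
    kernels = []
    for k in range(n_rotations):
        angle = k * (180.0 / n_rotations)
        rot = transform.rotate(base, angle, order=1, preserve_range=True)
        s = rot.sum()
        kernels.append(rot / s if s > 0 else rot)
    return kernels


MEMBRANE_AGGREGATES = ("sum", "mean", "std", "median", "max", "min")


def membrane_projections(
    img: GrayImage | np.ndarray,
    thickness: int = 1,
    patch_size: int = 19,
    n_rotations: int = 30,
) -> dict[str, np.ndarray]:
    """Oriented ridge-texture responses aggregated over kernel rotations.

    A thin line kernel is convolved with the image at ``n_rotations``
    orientations; the per-pixel response distribution over orientations is
    summarized by sum, mean, std, median, max and min -> 6 planes.
    """
    if patch_size % 2 == 0:
        raise ConfigurationError("patch_size must be odd")
    if thickness < 1:
        raise ConfigurationError("thickness must be >= 1")
    arr = _as_array(img)
    responses = np.stack(
        [ndimage.convolve(arr, k, mode="reflect") for k in _membrane_kernels(thickness, patch_size, n_rotations)]
    )
    return {
        "sum": responses.sum(axis=0),
        "mean": responses.mean(axis=0),
        "std": responses.std(axis=0),
        "median": np.median(responses, axis=0),
        "max": responses.max(axis=0),
        "min": responses.min(axis=0),
    }


def _perona_malik(arr: np.ndarray, iterations: int, kappa: float, step: float) -> np.ndarray:
    """Edge-preserving anisotropic diffusion with exponential conduction."""
    out = arr.copy()
    for _ in range(iterations):
        padded = np.pad(out, 1, mode="reflect")
        dn = padded[:-2, 1:-1] - out
        ds = padded[2:, 1:-1] - out
        de = padded[1:-1, 2:] - out
        dw = padded[1:-1, :-2] - out
        flux = sum(np.exp(-((d / kappa) ** 2)) * d for d in (dn, ds, de, dw))
        out = out + step * flux
    return out


def _lipschitz_covers(arr: np.ndarray, slope: float) -> tuple[np.ndarray, np.ndarray]:
    """Lower/upper Lipschitz envelopes by row/column chamfer relaxation.

    lower(x) = min_y I(y) + slope*d(x,y) <= I and upper(x) = max_y I(y) -
    slope*d(x,y) >= I under the city-block metric; the top-hats I - lower
    and upper - I vanish on constant images and grow where intensity varies
    faster than the slope.
    """

    def _relax(a: np.ndarray, sign: float) -> np.ndarray:
        better = np.minimum if sign > 0 else np.maximum
        for _ in range(2):
            for i in range(1, a.shape[0]):  # top -> bottom
                a[i] = better(a[i], a[i - 1] + sign * slope)
            for i in range(a.shape[0] - 2, -1, -1):  # bottom -> top
                a[i] = better(a[i], a[i + 1] + sign * slope)
            for j in range(1, a.shape[1]):  # left -> right
                a[:, j] = better(a[:, j], a[:, j - 1] + sign * slope)
            for j in range(a.shape[1] - 2, -1, -1):  # right -> left
                a[:, j] = better(a[:, j], a[:, j + 1] + sign * slope)
        return a

    return _relax(arr.copy(), +1.0), _relax(arr.copy(), -1.0)


def apply_filter(
    img: GrayImage | np.ndarray,
    kind: str,
    sigma: float = 1.0,
    cfg: FilterConfig | None = None,
    **params,
) -> dict[str, np.ndarray]:
    """Evaluate one filter kind at one scale; returns {name: plane}.

    All planes share the source dimensions and reflect-pad at the border.
    """
    cfg = cfg or FilterConfig()
    arr = _as_array(img)
    s_tag = f"s{sigma:g}"

    if kind == "gaussian":
        return {f"gaussian_{s_tag}": _gauss(arr, sigma)}
    if kind == "sobel":
        return {f"sobel_{s_tag}": skfilters.sobel(_gauss(arr, sigma))}
    if kind == "hessian":
        hf = hessian_features(arr, sigma, t=cfg.hessian_t, printed_orientation=cfg.use_printed_orientation)
        det = hf.det_printed if cfg.use_printed_det else hf.det_standard
        return {
            f"hessian_trace_{s_tag}": hf.trace,
            f"hessian_det_{s_tag}": det,
            f"hessian_fe_{s_tag}": hf.fe,
            f"hessian_se_{s_tag}": hf.se,
            f"hessian_orientation_{s_tag}": hf.orientation,
            f"hessian_gamma_{s_tag}": hf.gamma,
            f"hessian_square_gamma_{s_tag}": hf.square_gamma,
        }
    if kind == "dog":
        sigma_b = params.get("sigma_b", 2.0 * sigma)
        return {f"dog_{s_tag}_s{sigma_b:g}": _gauss(arr, sigma) - _gauss(arr, sigma_b)}
    if kind == "membrane":
        planes = membrane_projections(arr, cfg.membrane_thickness, cfg.membrane_patch_size)
        tag = f"t{cfg.membrane_thickness}_p{cfg.membrane_patch_size}"
        return {f"membrane_{agg}_{tag}": planes[agg] for agg in MEMBRANE_AGGREGATES}
    if kind == "local_stats":
        radius = max(1, int(round(sigma)))
        disc = morphology.disk(radius).astype(np.float64)
        mean = ndimage.correlate(arr, disc / disc.sum(), mode="reflect")
        mean_sq = ndimage.correlate(arr**2, disc / disc.sum(), mode="reflect")
        return {
            f"stat_mean_{s_tag}": mean,
            f"stat_var_{s_tag}": np.clip(mean_sq - mean**2, 0.0, None),
            f"stat_min_{s_tag}": ndimage.minimum_filter(arr, footprint=disc > 0, mode="reflect"),
            f"stat_max_{s_tag}": ndimage.maximum_filter(arr, footprint=disc > 0, mode="reflect"),
            f"stat_median_{s_tag}": ndimage.median_filter(arr, footprint=disc > 0, mode="reflect"),
        }
    if kind == "aniso_diffusion":
        return {
            f"aniso_{s_tag}": _perona_malik(
                arr, cfg.diffusion_iterations, cfg.diffusion_kappa, cfg.diffusion_step
            )
        }
    if kind == "bilateral":
        win = min(2 * int(np.ceil(1.5 * sigma)) + 1, 15)
        return {
            f"bilateral_{s_tag}": restoration.denoise_bilateral(
                arr, win_size=win, sigma_color=0.1, sigma_spatial=sigma, mode="edge"
            )
        }
    if kind == "lipschitz":
        lower, upper = _lipschitz_covers(arr, cfg.lipschitz_slope)
        return {"lipschitz_lower": arr - lower, "lipschitz_upper": upper - arr}
    if kind == "gabor":
        out = {}
        for freq in (0.5 / sigma, 0.25 / sigma):
            for k in range(cfg.gabor_orientations):
                theta = k * np.pi / cfg.gabor_orientations
                real, imag = skfilters.gabor(arr, frequency=freq, theta=theta)
                out[f"gabor_{s_tag}_f{freq:.3g}_o{k}"] = np.hypot(real, imag)
        return out
    if kind == "derivatives":
        out = {}
        for order in (2, 3, 4):
            dx = _gauss(arr, sigma, order=(0, order))
            dy = _gauss(arr, sigma, order=(order, 0))
            out[f"deriv{order}_{s_tag}"] = np.hypot(dx, dy)
        return out
    if kind == "structure":
        tensor = skfeature.structure_tensor(arr, sigma=sigma, mode="reflect", order="rc")
        big, small = skfeature.structure_tensor_eigenvalues(tensor)
        return {f"structure_e1_{s_tag}": big, f"structure_e2_{s_tag}": small}
    if kind == "shift":
        step = max(1, int(round(sigma)))
        out = {}
        for tag, (dr, dc) in {
            "up": (-step, 0), "down": (step, 0), "left": (0, -step), "right": (0, step),
        }.items():
            out[f"shift_{tag}_{s_tag}"] = ndimage.shift(arr, (dr, dc), order=1, mode="reflect")
        return out
    raise ConfigurationError(f"unknown filter kind {kind!r}")


#: Filters whose response does not depend on the scale ladder.
SCALE_FREE = {"membrane", "aniso_diffusion", "lipschitz"}


def build_stack(img: GrayImage | np.ndarray, cfg: FilterConfig | None = None) -> FeatureStack:
    """Evaluate the configured bank over the scale ladder.

    The raw intensity plane always comes first; then each enabled filter in
    canonical order, scale-free filters once, scaled filters at every sigma
    in ``cfg.scales()``.  Construction is pure: same image and config give
    bit-identical stacks.
    """
    cfg = cfg or FilterConfig()
    if not cfg.enabled_filters:
        raise ConfigurationError("at least one filter must be enabled")
    arr = _as_array(img)
    names: list[str] = ["raw"]
    planes: list[np.ndarray] = [arr]
    for kind in ALL_FILTERS:  # canonical order, independent of cfg tuple order
        if kind not in cfg.enabled_filters:
            continue
        sigmas = [cfg.sigma_min] if kind in SCALE_FREE else cfg.scales()
        for sigma in sigmas:
            for name, plane in apply_filter(arr, kind, sigma=sigma, cfg=cfg).items():
                names.append(name)
                planes.append(plane)
    data = np.stack(planes, axis=-1).astype(np.float32)
    if not np.all(np.isfinite(data)):
        raise ConfigurationError("feature stack contains non-finite values")
    return FeatureStack(data=data, feature_names=names)
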