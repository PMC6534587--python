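"""Seeded synthetic fluorescence-image cohorts with known ground truth.

No raw images from the 4NQO rat tongue carcinogenesis experiment are
publicly deposited, so every downstream stage of this package is exercised
against synthetic cohorts whose statistical structure matches the published
stage-level numbers: per-animal mean G-values drawn around the stage mean
(between-animal SD), independent per-pixel Gaussian noise (within-sample
SD), a linear apex-to-root intensity gradient, and dark-spot depressions
(fluorescence visualization loss) whose prevalence grows with tumor
progression.

The pixel model for one animal is

    pixel(x, y) = animal_mean
                  + realized_slope * (x - x_mid)
                  + Normal(0, within_sd^2)
                  - spot_field(x)

with ``animal_mean ~ Normal(mean_g, between_sd^2)`` and ``realized_slope ~
Normal(axial_slope, slope_sd^2)``.  The gradient is centred on the
measurement line midpoint so that ``animal_mean`` is the expected profile
mean — the quantity the stage tables summarize.  Fields are kept at full
float precision in memory; clipping to [0, 255] and 8-bit quantization
happen only when an image is rendered, so statistics tests can separate
quantization error.  Pixels are independent apart from the shared gradient
and spots; no further spatial autocorrelation is modelled.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile
from PIL import Image

from .measure import GValueImage

__all__ = [
    "StageParams",
    "GroundTruth",
    "generate_animal_field",
    "generate_cohort",
    "render_rgb",
    "quantize_g",
    "save_image",
    "load_truth",
]

#: Fixed low backdrop written to the red/blue channels of rendered images.
BACKDROP_RB = (8, 16)

#: Default image height in pixels (the measurement line runs horizontally
#: along the middle row; width equals the line length).
DEFAULT_HEIGHT = 64


@dataclass(frozen=True)
class StageParams:
    """Generator parameters for one histological stage.

    Parameters
    ----------
    stage_label:
        One of "Control", "LGD", "HGD/CIS", "Cancer" (or a human site name).
    mean_g:
        Stage population mean G-value (expected profile mean).
    between_sd:
        SD of per-animal mean G-values around ``mean_g``.
    within_sd:
        Per-pixel noise SD inside one sample, about the axial trend.
    axial_slope:
        Mean apex→root intensity gradient, G-value per pixel.
    slope_sd:
        SD of the per-animal realized gradient (stages mix positive and
        negative slopes).
    spot_rate:
        Expected dark spots per 100 px of line (fluorescence visualization
        loss); 0 for Control.
    spot_depth, spot_width:
        G-values subtracted inside a spot and spot width in pixels.
    n_animals:
        Cohort size for this stage.
    line_px:
        Measurement-line length in pixels (200 rat, 50 human).
    """

    stage_label: str
    mean_g: float
    between_sd: float
    within_sd: float
    axial_slope: float = 0.0
    slope_sd: float = 0.0
    spot_rate: float = 0.0
    spot_depth: float = 0.0
    spot_width: int = 1
    n_animals: int = 1
    line_px: int = 200

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean_g <= 255.0):
            raise ValueError(f"mean_g must lie in [0, 255], got {self.mean_g}")
        for name in ("between_sd", "within_sd", "slope_sd", "spot_rate", "spot_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.spot_width < 1:
            raise ValueError("spot_width must be >= 1")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.line_px < 2:
            raise ValueError("line_px must be >= 2")


@dataclass
class GroundTruth:
    """Latent draws behind one generated animal, for parameter-recovery tests."""

    animal_id: str
    stage_label: str
    animal_mean: float
    realized_slope: float
    spot_positions: list[int]
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


def _stage_key(label: str) -> int:
    # stable small integer per stage label for seed derivation
    return zlib.crc32(label.encode("utf8")) & 0x7FFFFFFF


def _animal_rng(params: StageParams, animal_index: int, seed: int) -> np.random.Generator:
    ss = np.random.SeedSequence([int(seed), _stage_key(params.stage_label), int(animal_index)])
    return np.random.default_rng(ss)


def generate_animal_field(
    params: StageParams,
    animal_index: int = 0,
    seed: int = 0,
    *,
    height: int = DEFAULT_HEIGHT,
    spot_profile: str = "tophat",
) -> tuple[GValueImage, GroundTruth]:
    """Generate one animal's full-precision G-value field.

    The image is ``height`` x ``params.line_px``; the measurement line spans
    any row left-to-right (apex at x = 0).  The same (params, seed,
    animal_index) triple reproduces the field bit-exactly.

    ``spot_profile`` selects rectangular ("tophat", default) or Gaussian
    ("gaussian") dark-spot depressions.
    """
    if height < 1:
        raise ValueError("image height must be positive")
    if spot_profile not in {"tophat", "gaussian"}:
        raise ValueError(f"unknown spot_profile {spot_profile!r}")
    rng = _animal_rng(params, animal_index, seed)
    w = params.line_px

    animal_mean = float(rng.normal(params.mean_g, params.between_sd))
    if not (0.0 <= animal_mean <= 255.0):
        raise ValueError(
            f"drawn animal mean {animal_mean:.2f} lies outside [0, 255]; "
            "stage parameters are too extreme"
        )
    realized_slope = float(rng.normal(params.axial_slope, params.slope_sd))

    x = np.arange(w, dtype=np.float64) - (w - 1) / 2.0
    field_arr = (
        animal_mean
        + realized_slope * x[None, :]
        + rng.normal(0.0, params.within_sd, size=(height, w))
    )

    n_spots = int(rng.poisson(params.spot_rate * w / 100.0))
    positions = sorted(int(p) for p in rng.integers(0, w, size=n_spots))
    cols = np.arange(w, dtype=np.float64)
    for p in positions:
        if spot_profile == "tophat":
            field_arr[:, p : p + params.spot_width] -= params.spot_depth
        else:
            sigma = max(params.spot_width / 2.0, 0.5)
            field_arr -= params.spot_depth * np.exp(
                -0.5 * ((cols - p) / sigma) ** 2
            )[None, :]

    safe = params.stage_label.replace("/", "_").replace(" ", "_")
    truth = GroundTruth(
        animal_id=f"{safe}_{animal_index:02d}",
        stage_label=params.stage_label,
        animal_mean=animal_mean,
        realized_slope=realized_slope,
        spot_positions=positions,
        seed=int(seed),
    )
    return GValueImage(pixels=field_arr), truth


def quantize_g(field_arr: np.ndarray) -> np.ndarray:
    """Clip to [0, 255] and quantize to 8 bits, as rendering does."""
    return np.clip(np.rint(field_arr), 0, 255).astype(np.uint8)


def render_rgb(field_arr: np.ndarray) -> np.ndarray:
    """Render a field as an 8-bit RGB array: signal in green, fixed backdrop."""
    g = quantize_g(np.asarray(field_arr, dtype=np.float64))
    rgb = np.empty(g.shape + (3,), dtype=np.uint8)
    rgb[..., 0] = BACKDROP_RB[0]
    rgb[..., 1] = g
    rgb[..., 2] = BACKDROP_RB[1]
    return rgb


def save_image(field_arr: np.ndarray, path: str | Path) -> None:
    """Write a field to PNG or TIFF (by extension) as 8-bit RGB."""
    path = Path(path)
    rgb = render_rgb(field_arr)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, rgb, photometric="rgb")
    else:
        Image.fromarray(rgb, mode="RGB").save(path)


def generate_cohort(
    config: Mapping[str, StageParams],
    seed: int,
    out_dir: str | Path,
    *,
    image_format: str = "png",
    height: int = DEFAULT_HEIGHT,
    force: bool = False,
) -> Path:
    """Generate one image file per animal plus a cohort truth JSON.

    Refuses to overwrite an existing non-empty directory unless ``force``.
    Regenerating with the same seed reproduces byte-identical truth
    metadata (and images).
    """
    if not config:
        raise ValueError("no stages configured")
    if image_format not in {"png", "tif", "tiff"}:
        raise ValueError(f"unsupported image format {image_format!r}")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(
            f"cohort directory {out_dir} exists; pass force=True to overwrite"
        )
    out_dir.mkdir(parents=True, exist_ok=True)

    animals = []
    for label, params in config.items():
        if params.stage_label != label:
            raise ValueError(
                f"config key {label!r} does not match stage_label {params.stage_label!r}"
            )
        for i in range(params.n_animals):
            img, truth = generate_animal_field(params, i, seed, height=height)
            fname = f"{truth.animal_id}.{image_format}"
            save_image(img.pixels, out_dir / fname)
            rec = truth.to_dict()
            rec["file"] = fname
            animals.append(rec)

    truth_doc = {
        "seed": int(seed),
        "image_format": image_format,
        "height": int(height),
        "stages": {label: asdict(p) for label, p in config.items()},
        "animals": animals,
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth_doc, fh, indent=2, sort_keys=True)
    return out_dir


def load_truth(cohort_dir: str | Path) -> dict:
    """Read the truth metadata written by :func:`generate_cohort`."""
    with open(Path(cohort_dir) / "truth.json") as fh:
        return json.load(fh)
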