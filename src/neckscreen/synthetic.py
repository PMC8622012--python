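"""Synthetic neck images and cohorts.

The patient photographs and tabular data behind the screening test are not
publicly available, so this module generates stand-ins with the statistical
structure the analysis assumes:

* **Images** — a smooth vertical luminance base whose overall level, number
  of dark curvilinear wrinkle strokes, and recessed patches (darkened
  ellipses with bright rims, mimicking the shadow-and-highlight pattern
  around a protruding clavicle) all grow with a latent ``severity`` in
  [0, 1].  By construction the affected class ends up with a higher pixel
  median, a higher pixel IQR and a higher FAST corner density — the
  direction reported for real sarcopenic-dysphagia necks.
* **Cohorts** — subjects with a Bernoulli outcome label and class-conditional
  covariates/features.  The default class parameters are the published
  development-cohort group means and SDs (n = 308, prevalence 133/308):
  age 82.57 (8.01) vs 86.22 (7.47) years, BMI 21.01 (3.38) vs 16.90 (2.79)
  kg/m^2, median pixel 0.40 (0.09) vs 0.45 (0.11), pixel IQR 0.09 (0.05)
  vs 0.12 (0.06), corner density 0.44 (0.56) vs 1.10 (1.28).

In *table mode* the three image features are drawn directly from
class-conditional distributions; in *image mode* each subject gets an image
whose parameters derive from a latent severity, and features are meant to be
extracted through the imaging/features pipeline.  Sampling distributions are
moment-matched so that sample means and SDs converge to the configured
values while respecting physiologic bounds (see
:func:`_bounded_sampler`).  All randomness flows from a single seeded
generator per call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .features import FASTConfig, extract_features
from .imaging import median_filter, save_image

__all__ = [
    "ImageSynthParams",
    "CohortConfig",
    "Cohort",
    "DEFAULT_CLASS_PARAMS",
    "generate_neck_image",
    "generate_cohort",
    "extract_cohort_features",
    "write_cohort",
    "cohort_config_from_file",
]

#: Published development-cohort group summaries used as default calibration:
#: per class, (mean, sd) for each continuous variable plus the probability
#: of female sex.
DEFAULT_CLASS_PARAMS: dict[str, dict] = {
    "non_dysphagic": {
        "age": (82.57, 8.01),
        "bmi": (21.01, 3.38),
        "median_pixel": (0.40, 0.09),
        "iqr_pixel": (0.09, 0.05),
        "fast_density": (0.44, 0.56),
        "sex_female_p": 108 / 175,
    },
    "dysphagic": {
        "age": (86.22, 7.47),
        "bmi": (16.90, 2.79),
        "median_pixel": (0.45, 0.11),
        "iqr_pixel": (0.12, 0.06),
        "fast_density": (1.10, 1.28),
        "sex_female_p": 72 / 133,
    },
}

#: Development-cohort prevalence of sarcopenic dysphagia (133 of 308).
DEFAULT_PREVALENCE = 133 / 308

#: Physiologic truncation bounds per variable.
VARIABLE_BOUNDS: dict[str, tuple[float, float]] = {
    "age": (65.0, 110.0),
    "bmi": (10.0, 45.0),
    "median_pixel": (0.0, 1.0),
    "iqr_pixel": (0.0, np.inf),
    "fast_density": (0.0, np.inf),
}


@dataclass(frozen=True)
class ImageSynthParams:
    """Knobs of one synthetic neck image.

    ``severity`` in [0, 1] drives everything: 0 renders a smooth
    non-dysphagic-like neck, 1 a maximally textured muscle-loss neck.
    Sizes default to 256 x 128 (width x height), a lower-half aspect.
    """

    height: int = 128
    width: int = 256
    severity: float = 0.0
    n_wrinkles_base: int = 3
    wrinkle_depth: float = 0.18
    recess_count: int = 3
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ValueError(
                f"image dimensions must be at least 32x32, got {self.height}x{self.width}"
            )
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError(f"severity must be in [0, 1], got {self.severity}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


def _base_field(params: ImageSynthParams) -> np.ndarray:
    """Smooth vertical luminance gradient; overall level rises with severity."""
    level = 0.40 + 0.05 * params.severity
    rows = np.linspace(0.03, -0.03, params.height)
    return level + np.repeat(rows[:, None], params.width, axis=1)


def generate_neck_image(params: ImageSynthParams) -> np.ndarray:
    """Render one synthetic neck image in [0, 1]; identical params -> identical image."""
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    image = _base_field(params)
    rows = np.arange(h, dtype=float)[:, None]  # (h, 1)
    cols = np.arange(w, dtype=float)[None, :]  # (1, w)

    # dark curvilinear wrinkle strokes, more of them at higher severity
    n_wrinkles = int(round(params.n_wrinkles_base * (1.0 + 3.0 * params.severity)))
    for _ in range(n_wrinkles):
        y0 = rng.uniform(0.1, 0.9) * h
        amp = rng.uniform(0.02, 0.08) * h
        freq = rng.uniform(1.0, 2.5)
        phase = rng.uniform(0, 2 * np.pi)
        sigma = rng.uniform(1.2, 2.0)
        depth = params.wrinkle_depth * rng.uniform(0.7, 1.3)
        centerline = y0 + amp * np.sin(2 * np.pi * freq * cols / w + phase)  # (1, w)
        image -= depth * np.exp(-((rows - centerline) ** 2) / (2 * sigma**2))

    # recessed patches: darkened ellipse interiors with bright rims
    n_recess = int(round(params.recess_count * params.severity))
    for _ in range(n_recess):
        cy = rng.uniform(0.2, 0.8) * h
        cx = rng.uniform(0.1, 0.9) * w
        ry = rng.uniform(0.10, 0.20) * h
        rx = rng.uniform(0.06, 0.14) * w
        d = np.sqrt(((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2)
        depth = params.wrinkle_depth * rng.uniform(0.8, 1.2)
        interior = np.clip(1.0 - d, 0.0, 1.0)
        image -= 0.6 * depth * interior
        rim = np.exp(-((d - 1.15) ** 2) / (2 * 0.12**2))
        image += 0.9 * depth * rim

    if params.noise_sd > 0:
        image = image + rng.normal(0.0, params.noise_sd, size=(h, w))
    return np.clip(image, 0.0, 1.0)


def _moment_matched_truncnorm(
    mean: float, sd: float, lower: float, upper: float
):
    """Parent (mu, sigma) of a truncated normal whose truncated mean/sd equal
    the targets; None when no such parent exists (e.g. sd >= mean above a
    zero lower bound)."""

    def residuals(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        a, b = (lower - mu) / sigma, (upper - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.root(residuals, x0=[mean, np.log(sd)], method="hybr")
    if not sol.success or np.abs(sol.fun).max() > 1e-6 * max(sd, 1e-12):
        return None
    mu, log_sigma = sol.x
    return float(mu), float(np.exp(log_sigma))


def _bounded_sampler(mean: float, sd: float, lower: float, upper: float):
    """Sampler with exact target moments on a bounded support.

    Uses a moment-matched truncated normal when one exists; otherwise (a
    nonnegative variable whose SD is as large as its mean, like the corner
    density) a moment-matched gamma, whose right skew matches the observed
    feature densities.
    """
    if sd == 0:
        return lambda rng, size: np.full(size, mean)
    # fast path: truncation negligible (> 6 sigma to either bound)
    if mean - 6 * sd > lower and mean + 6 * sd < upper:
        return lambda rng, size: rng.normal(mean, sd, size)
    fit = _moment_matched_truncnorm(mean, sd, lower, upper)
    if fit is not None:
        mu, sigma = fit
        a, b = (lower - mu) / sigma, (upper - mu) / sigma

        def sample_truncnorm(rng, size):
            return stats.truncnorm.rvs(
                a, b, loc=mu, scale=sigma, size=size, random_state=rng
            )

        return sample_truncnorm
    if lower == 0 and np.isinf(upper):
        shape = (mean / sd) ** 2
        scale = sd**2 / mean
        return lambda rng, size: rng.gamma(shape, scale, size)
    raise ValueError(
        f"cannot match mean {mean} / sd {sd} on support [{lower}, {upper}]"
    )


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of one synthetic cohort.

    ``mode="table"`` draws the image features directly from class-conditional
    distributions; ``mode="image"`` attaches a rendered image per subject
    (features are then extracted through the preprocessing pipeline).
    """

    n_subjects: int = 308
    prevalence: float = DEFAULT_PREVALENCE
    class_params: dict[str, dict] = field(
        default_factory=lambda: {
            g: dict(v) for g, v in DEFAULT_CLASS_PARAMS.items()
        }
    )
    mode: str = "table"
    seed: int = 0
    image_params: ImageSynthParams = ImageSynthParams()

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(
                f"prevalence must be strictly inside (0, 1), got {self.prevalence}"
            )
        if self.mode not in ("table", "image"):
            raise ValueError(f"mode must be 'table' or 'image', got {self.mode!r}")
        required = {"non_dysphagic", "dysphagic"}
        if set(self.class_params) != required:
            raise ValueError(f"class_params must have keys {sorted(required)}")
        needed = {"age", "bmi", "sex_female_p"}
        if self.mode == "table":
            needed |= {"median_pixel", "iqr_pixel", "fast_density"}
        for group, params in self.class_params.items():
            missing = needed - set(params)
            if missing:
                raise ValueError(f"class {group!r} missing parameters {sorted(missing)}")
            if not 0.0 <= params["sex_female_p"] <= 1.0:
                raise ValueError(f"sex probability out of [0, 1] for {group!r}")
            for name, value in params.items():
                if name == "sex_female_p":
                    continue
                _, sd = value
                if sd < 0:
                    raise ValueError(f"negative sd for {group!r}/{name}")


@dataclass
class Cohort:
    """Generated cohort: one row per subject, plus images in image mode."""

    table: pd.DataFrame
    images: list[np.ndarray] | None
    config: CohortConfig


def _draw_severity(group: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Latent severity: affected subjects Uniform(0.5, 1), unaffected
    Uniform(0, 0.5), blurred by N(0, 0.1) overlap noise and clipped —
    classes overlap, as the observed feature densities do."""
    base = np.where(
        group == 1, rng.uniform(0.5, 1.0, len(group)), rng.uniform(0.0, 0.5, len(group))
    )
    return np.clip(base + rng.normal(0.0, 0.1, len(group)), 0.0, 1.0)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a seeded cohort; equal (config, seed) gives identical output."""
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    group = (rng.random(n) < config.prevalence).astype(int)
    severity = _draw_severity(group, rng)

    class_of = np.where(group == 1, "dysphagic", "non_dysphagic")
    table_vars = ["age", "bmi"]
    if config.mode == "table":
        table_vars += ["median_pixel", "iqr_pixel", "fast_density"]

    data: dict[str, np.ndarray] = {
        "subject_id": np.array([f"s{i:05d}" for i in range(n)]),
        "group": group,
    }
    sex = np.empty(n, dtype=object)
    for name in table_vars:
        data[name] = np.empty(n)
    for label, params in config.class_params.items():
        mask = class_of == label
        if not mask.any():
            continue
        size = int(mask.sum())
        for name in table_vars:
            mean, sd = params[name]
            lower, upper = VARIABLE_BOUNDS[name]
            sampler = _bounded_sampler(mean, sd, lower, upper)
            data[name][mask] = sampler(rng, size)
        female = rng.random(size) < params["sex_female_p"]
        sex[mask] = np.where(female, "female", "male")
    data["sex"] = sex
    data["true_severity"] = severity

    images = None
    if config.mode == "image":
        images = []
        child_seeds = rng.integers(0, 2**31 - 1, size=n)
        for i in range(n):
            params = replace(
                config.image_params, severity=float(severity[i]), seed=int(child_seeds[i])
            )
            images.append(generate_neck_image(params))

    column_order = ["subject_id", "group", "age", "sex", "bmi", "true_severity"]
    if config.mode == "table":
        column_order += ["median_pixel", "iqr_pixel", "fast_density"]
    table = pd.DataFrame(data)[column_order]
    return Cohort(table=table, images=images, config=config)


def extract_cohort_features(
    cohort: Cohort,
    fast_config: FASTConfig = FASTConfig(),
    kernel: int = 5,
    scale: float = 1.0,
) -> pd.DataFrame:
    """Run the median filter + feature extraction over an image-mode cohort
    and return its table with the three feature columns appended."""
    if cohort.images is None:
        raise ValueError("cohort has no images; generate with mode='image'")
    rows = []
    for image in cohort.images:
        filtered = median_filter(image, kernel=kernel)
        rows.append(extract_features(filtered, fast_config, scale=scale).as_dict())
    features = pd.DataFrame(rows)
    return pd.concat([cohort.table.reset_index(drop=True), features], axis=1)


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write ``cohort.csv`` (+ ``images/*.png`` and an ``image_path`` column
    in image mode); returns the CSV path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = cohort.table.copy()
    if cohort.images is not None:
        image_dir = outdir / "images"
        image_dir.mkdir(exist_ok=True)
        paths = []
        for subject_id, image in zip(table["subject_id"], cohort.images):
            path = image_dir / f"{subject_id}.png"
            save_image(image, path)
            paths.append(str(path.relative_to(outdir)))
        table["image_path"] = paths
    csv_path = outdir / "cohort.csv"
    table.to_csv(csv_path, index=False)
    return csv_path


def cohort_config_from_file(path: str | Path) -> CohortConfig:
    """Load a CohortConfig from YAML or JSON mirroring its fields."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if "class_params" in raw:
        raw["class_params"] = {
            group: {
                k: (tuple(v) if isinstance(v, (list, tuple)) else v)
                for k, v in params.items()
            }
            for group, params in raw["class_params"].items()
        }
    if "image_params" in raw:
        raw["image_params"] = ImageSynthParams(**raw["image_params"])
    return CohortConfig(**raw)
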