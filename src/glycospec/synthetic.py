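"""Synthetic SWIR spectra, hypercubes and reference TGA values.

The generator emulates the statistical structure of a greening study on
Yukon Gold tubers: three day groups (control, 7 and 14 days of light
exposure) of 70 tubers each, a 169-band reflectance grid from 901.121 nm
at 9.527 nm spacing, matrix (water/starch/sugar) absorption peaks,
TGA-linked absorptions whose depth is linear in concentration (ppm),
multiplicative scatter, a random linear baseline and additive white
noise.  Ground truth is returned alongside every dataset so recovery
tests can compare against known coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GridConfig",
    "ImageConfig",
    "SyntheticConfig",
    "GroundTruth",
    "wavelength_grid",
    "generate_spectrum",
    "generate_dataset",
    "generate_hypercube",
    "generate_references",
    "make_band_recovery_benchmark",
]

#: reflectance values are clipped to this ceiling (above-white artifacts occur
#: on shiny tuber surfaces but never by much)
REFLECTANCE_CEILING = 1.2


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class GridConfig:
    """Uniform band-center grid: ``start_nm + k * step_nm`` for k = 0..n_bands-1."""

    start_nm: float = 901.121
    step_nm: float = 9.527
    n_bands: int = 169

    def validate(self) -> None:
        if self.n_bands < 2:
            raise ConfigError(f"n_bands must be >= 2, got {self.n_bands}")
        if self.step_nm <= 0:
            raise ConfigError(f"step_nm must be > 0, got {self.step_nm}")


@dataclass(frozen=True)
class ImageConfig:
    """Spatial layout of a synthetic tuber frame.

    An ellipse (the tuber) centered in the frame over a dark background.
    Axes are semi-axes in pixels.
    """

    rows: int = 64
    cols: int = 48
    ellipse_row_axis: float = 22.0
    ellipse_col_axis: float = 16.0
    background_reflectance: float = 0.02
    pixel_gain_jitter_sd: float = 0.01

    def validate(self) -> None:
        if self.ellipse_row_axis >= self.rows / 2 or self.ellipse_col_axis >= self.cols / 2:
            raise ConfigError(
                "ellipse semi-axes "
                f"({self.ellipse_row_axis}, {self.ellipse_col_axis}) do not fit "
                f"inside a {self.rows}x{self.cols} frame"
            )
        if self.ellipse_row_axis <= 0 or self.ellipse_col_axis <= 0:
            raise ConfigError("ellipse semi-axes must be positive")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-level generator settings.

    Day-group TGA means default to the measured group means of the greening
    study (ppm): 97.13 (day 0), 159.56 (day 7), 128.41 (day 14).  Matrix
    peaks sit at the O-H / C-H overtone bands seen in tuber spectra
    (976, 1214, 1431, 1781, 1905 nm); TGA-linked peaks sit at the
    carbohydrate/water bands consistently selected by wavelength selection
    (1166.3, 1649.3, 1791.4, 2047.1, 2085.0, 2378.5 nm plus the 1933.4 nm
    water region).  Peak shape is Gaussian in wavelength; matrix widths
    default to 30 nm, TGA widths to 20 nm.
    """

    n_per_day: int = 70
    day_means_ppm: tuple[float, float, float] = (97.13, 159.56, 128.41)
    day_labels: tuple[int, int, int] = (0, 7, 14)
    day_sd_ppm: float = 30.0
    grid: GridConfig = field(default_factory=GridConfig)
    #: (center nm, width nm, depth in reflectance units)
    matrix_peaks: tuple[tuple[float, float, float], ...] = (
        (976.0, 30.0, 0.08),
        (1214.0, 30.0, 0.10),
        (1431.0, 30.0, 0.18),
        (1781.0, 30.0, 0.08),
        (1905.0, 30.0, 0.30),
    )
    #: (center nm, width nm, depth per ppm)
    tga_peaks: tuple[tuple[float, float, float], ...] = (
        (1166.3, 20.0, 2.5e-4),
        (1649.3, 20.0, 2.5e-4),
        (1791.4, 20.0, 2.0e-4),
        (2047.1, 20.0, 2.0e-4),
        (2085.0, 20.0, 2.0e-4),
        (2378.5, 20.0, 1.5e-4),
        (1933.4, 20.0, 1.0e-4),
    )
    base_reflectance: float = 0.55
    #: sigma of the lognormal multiplicative gain
    scatter_sd: float = 0.05
    #: sd of the additive linear-baseline slope, per nm
    baseline_slope_sd: float = 5.0e-5
    #: sd of additive white noise, reflectance units; calibrated so the
    #: default full-spectrum PLSR model lands in the fair RPD band (1.4-1.8)
    noise_sd: float = 0.02
    #: optional quadratic term in the TGA -> depth map (0 = exactly linear)
    tga_nonlinearity: float = 0.0
    image: ImageConfig = field(default_factory=ImageConfig)
    seed: int = 0

    def validate(self) -> None:
        self.grid.validate()
        self.image.validate()
        if self.n_per_day < 1:
            raise ConfigError("n_per_day must be >= 1")
        if any(m < 0 for m in self.day_means_ppm):
            raise ConfigError("day_means_ppm must be nonnegative")
        lo = self.grid.start_nm
        hi = self.grid.start_nm + (self.grid.n_bands - 1) * self.grid.step_nm
        for center, _, _ in (*self.matrix_peaks, *self.tga_peaks):
            if not (lo <= center <= hi):
                raise ConfigError(
                    f"peak center {center} nm outside grid [{lo}, {hi}] nm"
                )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Everything needed to reconstruct each noiseless spectrum.

    ``tga_profile`` is the per-band depth-per-ppm curve (the derivative of
    reflectance with respect to TGA, negated); the noiseless spectrum of
    sample i is ``gains[i] * (matrix_curve - tga_ppm[i] * tga_profile
    + slopes[i] * (grid - grid_mean))``.
    """

    wavelengths_nm: np.ndarray
    matrix_curve: np.ndarray
    tga_profile: np.ndarray
    gains: np.ndarray
    slopes: np.ndarray
    tga_ppm: np.ndarray
    day: np.ndarray


def wavelength_grid(config: SyntheticConfig | GridConfig) -> np.ndarray:
    """Band-center wavelengths in nm, strictly increasing."""
    grid = config.grid if isinstance(config, SyntheticConfig) else config
    grid.validate()
    return grid.start_nm + grid.step_nm * np.arange(grid.n_bands, dtype=float)


def _gaussian(lam: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((lam - center) / width) ** 2)


def _matrix_curve(config: SyntheticConfig, lam: np.ndarray) -> np.ndarray:
    curve = np.full_like(lam, config.base_reflectance)
    for center, width, depth in config.matrix_peaks:
        curve -= depth * _gaussian(lam, center, width)
    return curve


def _tga_profile(config: SyntheticConfig, lam: np.ndarray) -> np.ndarray:
    prof = np.zeros_like(lam)
    for center, width, depth in config.tga_peaks:
        prof += depth * _gaussian(lam, center, width)
    return prof


def _tga_depth_scale(config: SyntheticConfig, tga_ppm: float) -> float:
    # linear in ppm by default; optional quadratic departure
    return tga_ppm + config.tga_nonlinearity * tga_ppm**2


def generate_spectrum(
    tga_ppm: float,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    *,
    clip: bool = True,
) -> np.ndarray:
    """One reflectance spectrum for a tuber at the given TGA concentration.

    Model: ``R(lam) = clip(g * [R0(lam) - tga * P(lam) + b*(lam - mean(lam))]
    + eps, 0, 1.2)`` with lognormal gain g, normal slope b and white noise
    eps.  With all noise scales zero the output is deterministic and affine
    in ``tga_ppm``.
    """
    if tga_ppm < 0:
        raise ValueError(f"tga_ppm must be >= 0, got {tga_ppm}")
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lam = wavelength_grid(config)
    clean = _matrix_curve(config, lam) - _tga_depth_scale(config, tga_ppm) * _tga_profile(config, lam)

    gain = float(np.exp(rng.normal(0.0, config.scatter_sd))) if config.scatter_sd > 0 else 1.0
    slope = float(rng.normal(0.0, config.baseline_slope_sd)) if config.baseline_slope_sd > 0 else 0.0
    spectrum = gain * (clean + slope * (lam - lam.mean()))
    if config.noise_sd > 0:
        spectrum = spectrum + rng.normal(0.0, config.noise_sd, size=lam.size)
    if clip:
        spectrum = np.clip(spectrum, 0.0, REFLECTANCE_CEILING)
    return spectrum


def _draw_tga(mean: float, sd: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Truncated-normal TGA draw (concentrations cannot be negative)."""
    if sd == 0:
        return np.full(size, mean)
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def generate_dataset(config: SyntheticConfig):
    """Full study dataset: (SpectralDataset, GroundTruth).

    3 * n_per_day samples; TGA drawn per day group from a truncated normal;
    spectra generated sample-by-sample from one shared rng seeded by
    ``config.seed`` (fixed seed => byte-identical output).
    """
    from .hypercube import SpectralDataset  # local import to avoid a cycle

    config.validate()
    rng = np.random.default_rng(config.seed)
    lam = wavelength_grid(config)

    tga, day = [], []
    for mean, label in zip(config.day_means_ppm, config.day_labels):
        tga.append(_draw_tga(mean, config.day_sd_ppm, config.n_per_day, rng))
        day.append(np.full(config.n_per_day, label))
    tga = np.concatenate(tga)
    day = np.concatenate(day)
    n = tga.size

    X = np.empty((n, lam.size))
    gains = np.empty(n)
    slopes = np.empty(n)
    for i in range(n):
        gains[i] = float(np.exp(rng.normal(0.0, config.scatter_sd))) if config.scatter_sd > 0 else 1.0
        slopes[i] = float(rng.normal(0.0, config.baseline_slope_sd)) if config.baseline_slope_sd > 0 else 0.0
        clean = _matrix_curve(config, lam) - _tga_depth_scale(config, float(tga[i])) * _tga_profile(config, lam)
        row = gains[i] * (clean + slopes[i] * (lam - lam.mean()))
        if config.noise_sd > 0:
            row = row + rng.normal(0.0, config.noise_sd, size=lam.size)
        X[i] = np.clip(row, 0.0, REFLECTANCE_CEILING)

    dataset = SpectralDataset(
        X=X,
        wavelengths_nm=lam,
        y=tga,
        sample_id=np.array([f"s{i:03d}" for i in range(n)]),
        day=day,
    )
    truth = GroundTruth(
        wavelengths_nm=lam,
        matrix_curve=_matrix_curve(config, lam),
        tga_profile=_tga_profile(config, lam),
        gains=gains,
        slopes=slopes,
        tga_ppm=tga,
        day=day,
    )
    return dataset, truth


def ellipse_mask(image: ImageConfig) -> np.ndarray:
    """Binary tuber mask: 1 inside the centered ellipse, 0 outside."""
    r = np.arange(image.rows)[:, None] - (image.rows - 1) / 2.0
    c = np.arange(image.cols)[None, :] - (image.cols - 1) / 2.0
    inside = (r / image.ellipse_row_axis) ** 2 + (c / image.ellipse_col_axis) ** 2 <= 1.0
    return inside.astype(np.uint8)


def generate_hypercube(
    tga_ppm: float,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
):
    """Synthetic tuber frame: (Hypercube, true Mask).

    Foreground pixels carry the sample spectrum times a small per-pixel
    multiplicative jitter; background pixels are flat low reflectance plus
    the additive noise level.  With noise and jitter off, every foreground
    pixel equals ``generate_spectrum(tga_ppm)`` exactly.
    """
    from .hypercube import Hypercube, Mask

    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    img = config.image
    lam = wavelength_grid(config)
    mask = ellipse_mask(img)

    base = generate_spectrum(tga_ppm, config, rng, clip=False)
    values = np.empty((img.rows, img.cols, lam.size))
    values[...] = img.background_reflectance
    if config.noise_sd > 0:
        values += rng.normal(0.0, config.noise_sd, size=values.shape)

    fg = mask.astype(bool)
    n_fg = int(fg.sum())
    if img.pixel_gain_jitter_sd > 0:
        jitter = rng.normal(1.0, img.pixel_gain_jitter_sd, size=n_fg)
    else:
        jitter = np.ones(n_fg)
    values[fg] = jitter[:, None] * base[None, :]
    if config.noise_sd > 0:
        values[fg] += rng.normal(0.0, config.noise_sd, size=(n_fg, lam.size))
    values = np.clip(values, 0.0, REFLECTANCE_CEILING)

    cube = Hypercube(values=values, wavelengths_nm=lam, meta={"tga_ppm": float(tga_ppm)})
    return cube, Mask(values=mask)


def generate_references(config: SyntheticConfig):
    """(white, dark) reference cubes matching the sample-frame shape.

    The white tile is 99% reflectance; the dark frame is the closed-shutter
    signal (zero plus noise, floored at zero).
    """
    from .hypercube import Hypercube

    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    img = config.image
    lam = wavelength_grid(config)
    shape = (img.rows, img.cols, lam.size)

    white = np.full(shape, 0.99)
    dark = np.zeros(shape)
    if config.noise_sd > 0:
        white = white + rng.normal(0.0, config.noise_sd, size=shape)
        dark = np.abs(rng.normal(0.0, config.noise_sd, size=shape))
    meta_w = {"reference": "white"}
    meta_d = {"reference": "dark"}
    return (
        Hypercube(values=white, wavelengths_nm=lam, meta=meta_w),
        Hypercube(values=dark, wavelengths_nm=lam, meta=meta_d),
    )


def make_band_recovery_benchmark(
    n_samples: int = 210,
    n_bands: int = 169,
    n_informative: int = 10,
    noise_sd: float = 0.5,
    seed: int = 0,
):
    """Selector-recovery benchmark with independently informative bands.

    Each informative band reflects one of ``n_informative`` independent
    latent factors; the response is the factor sum, so every informative
    band carries unique predictive information and dropping one genuinely
    hurts.  Non-informative bands are pure unit noise.  With band noise sd
    s, the population R^2 of the best linear predictor is 1/(1+s^2);
    the default s=0.5 puts the full-spectrum cross-validated R^2 near 0.8.

    Returns ``(X, y, informative_idx)`` with informative_idx sorted.
    """
    if n_informative >= n_bands:
        raise ValueError("n_informative must be < n_bands")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_samples, n_informative))
    y = z.sum(axis=1)
    X = rng.standard_normal((n_samples, n_bands))
    idx = np.sort(rng.choice(n_bands, size=n_informative, replace=False))
    X[:, idx] = z + noise_sd * rng.standard_normal((n_samples, n_informative))
    return X, y, idx
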