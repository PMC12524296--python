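"""Hypercube containers, ENVI I/O, reflectance calibration and ROI extraction.

A scan session produces, per tuber, a rows x cols x bands radiance cube
plus white-tile and closed-shutter (dark) reference cubes.  This module
calibrates cubes to reflectance, segments the tuber from the dark
background with Otsu's threshold on the band-averaged intensity image,
and averages the masked pixels into one spectrum per tuber, yielding the
n x p analysis matrix.

The ENVI dialect supported is deliberately narrow: BIL or BSQ interleave,
32-bit little-endian float, wavelengths (nm) listed in the header.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage import measure

__all__ = [
    "Hypercube",
    "Mask",
    "SpectralDataset",
    "FormatError",
    "CalibrationError",
    "DegenerateImageError",
    "read_envi",
    "write_envi",
    "calibrate_reflectance",
    "otsu_threshold",
    "build_mask",
    "mean_spectrum",
    "extract_dataset",
    "write_mask_png",
]


class FormatError(ValueError):
    """Malformed or unsupported ENVI header/data."""


class CalibrationError(ValueError):
    """White/dark references unusable for reflectance calibration."""


class DegenerateImageError(ValueError):
    """Image has no contrast to threshold."""


@dataclass
class Hypercube:
    """rows x cols x bands reflectance block with its wavelength grid."""

    values: np.ndarray
    wavelengths_nm: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"cube must be 3-D, got shape {self.values.shape}")
        if self.values.shape[2] != self.wavelengths_nm.size:
            raise ValueError(
                f"bands axis ({self.values.shape[2]}) does not match "
                f"wavelength count ({self.wavelengths_nm.size})"
            )
        if self.wavelengths_nm.size >= 2 and not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def band_average(self) -> np.ndarray:
        """Band-averaged intensity image (rows x cols)."""
        return self.values.mean(axis=2)


@dataclass
class Mask:
    """Binary rows x cols foreground mask (1 = tuber, 0 = background)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {values.shape}")
        uniq = np.unique(values)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be in {0, 1}")
        self.values = values.astype(np.uint8)

    @property
    def n_foreground(self) -> int:
        return int(self.values.sum())


@dataclass
class SpectralDataset:
    """n x p mean-spectrum matrix with aligned TGA references (ppm)."""

    X: np.ndarray
    wavelengths_nm: np.ndarray
    y: np.ndarray
    sample_id: np.ndarray
    day: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.sample_id = np.asarray(self.sample_id)
        self.day = np.asarray(self.day)
        n, p = self.X.shape
        if self.y.size != n or self.sample_id.size != n or self.day.size != n:
            raise ValueError("X rows, y, sample_id and day must have equal length")
        if self.wavelengths_nm.size != p:
            raise ValueError("wavelength count must equal X columns")
        if np.isnan(self.X).any() or np.isnan(self.y).any():
            raise ValueError("dataset must not contain missing values")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]

    def to_csv(self, path: str | Path) -> None:
        """Write columns sample_id, day, tga_ppm, then one column per band (nm)."""
        meta = pd.DataFrame(
            {"sample_id": self.sample_id, "day": self.day, "tga_ppm": self.y}
        )
        bands = pd.DataFrame(
            self.X, columns=[f"{nm:.3f}" for nm in self.wavelengths_nm]
        )
        pd.concat([meta, bands], axis=1).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectralDataset":
        frame = pd.read_csv(path)
        meta_cols = ["sample_id", "day", "tga_ppm"]
        band_cols = [c for c in frame.columns if c not in meta_cols]
        return cls(
            X=frame[band_cols].to_numpy(dtype=float),
            wavelengths_nm=np.array([float(c) for c in band_cols]),
            y=frame["tga_ppm"].to_numpy(dtype=float),
            sample_id=frame["sample_id"].to_numpy(),
            day=frame["day"].to_numpy(),
        )

    def select_bands(self, indices: Sequence[int]) -> "SpectralDataset":
        idx = np.asarray(indices, dtype=int)
        return SpectralDataset(
            X=self.X[:, idx],
            wavelengths_nm=self.wavelengths_nm[idx],
            y=self.y,
            sample_id=self.sample_id,
            day=self.day,
        )


# ---------------------------------------------------------------------------
# ENVI I/O

_SUPPORTED_INTERLEAVES = ("bil", "bsq")


def _parse_envi_header(text: str) -> dict:
    """Parse `key = value` pairs; `{...}` lists may span lines."""
    fields: dict[str, str] = {}
    # normalize: join braces across newlines
    body = text
    if not body.lstrip().lower().startswith("envi"):
        raise FormatError("missing ENVI magic line")
    for match in re.finditer(
        r"^\s*([a-zA-Z][a-zA-Z0-9 _]*?)\s*=\s*(\{[^}]*\}|[^\n{]*)\s*$",
        body,
        flags=re.MULTILINE | re.DOTALL,
    ):
        key = match.group(1).strip().lower()
        fields[key] = match.group(2).strip()
    return fields


def read_envi(header_path: str | Path) -> Hypercube:
    """Read a BIL/BSQ float32 little-endian ENVI cube via its .hdr file."""
    header_path = Path(header_path)
    fields = _parse_envi_header(header_path.read_text())

    for key in ("samples", "lines", "bands", "interleave", "data type"):
        if key not in fields:
            raise FormatError(f"header missing required field '{key}'")
    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    interleave = fields["interleave"].lower()
    data_type = int(fields["data type"])
    byte_order = int(fields.get("byte order", "0"))
    offset = int(fields.get("header offset", "0"))

    if interleave not in _SUPPORTED_INTERLEAVES:
        raise FormatError(
            f"unsupported interleave '{interleave}' (supported: bil, bsq)"
        )
    if data_type != 4:
        raise FormatError(f"unsupported data type {data_type} (only 4 = float32)")
    if byte_order != 0:
        raise FormatError("only little-endian (byte order = 0) is supported")
    if "wavelength" not in fields:
        raise FormatError("header missing wavelength list")
    wl_text = fields["wavelength"]
    if not (wl_text.startswith("{") and wl_text.endswith("}")):
        raise FormatError("wavelength list must be brace-delimited")
    wavelengths = np.array(
        [float(tok) for tok in wl_text[1:-1].replace("\n", " ").split(",") if tok.strip()]
    )
    if wavelengths.size != bands:
        raise FormatError(
            f"band count ({bands}) does not match wavelength count ({wavelengths.size})"
        )

    data_path = None
    for candidate in (
        header_path.with_suffix(".raw"),
        header_path.with_suffix(".img"),
        header_path.with_suffix(".dat"),
        header_path.with_suffix(""),
    ):
        if candidate.exists() and candidate != header_path:
            data_path = candidate
            break
    if data_path is None:
        raise FormatError(f"no data file found next to {header_path}")

    raw = np.fromfile(data_path, dtype="<f4", offset=offset)
    expected = samples * lines * bands
    if raw.size != expected:
        raise FormatError(
            f"data file holds {raw.size} values, header declares {expected}"
        )
    if interleave == "bil":
        values = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bsq
        values = raw.reshape(bands, lines, samples).transpose(1, 2, 0)

    meta = {k: v for k, v in fields.items()
            if k not in {"samples", "lines", "bands", "interleave", "data type",
                         "byte order", "header offset", "wavelength"}}
    return Hypercube(values=values.astype(float), wavelengths_nm=wavelengths, meta=meta)


def write_envi(cube: Hypercube, path: str | Path, interleave: str = "bil") -> Path:
    """Write `<path>.hdr` + `<path>.raw` (float32 LE); returns the header path."""
    interleave = interleave.lower()
    if interleave not in _SUPPORTED_INTERLEAVES:
        raise FormatError(
            f"unsupported interleave '{interleave}' (supported: bil, bsq)"
        )
    path = Path(path)
    if path.suffix in {".hdr", ".raw"}:
        path = path.with_suffix("")
    rows, cols, bands = cube.shape
    data = cube.values.astype("<f4")
    if interleave == "bil":
        ordered = data.transpose(0, 2, 1)  # lines, bands, samples
    else:
        ordered = data.transpose(2, 0, 1)  # bands, lines, samples

    raw_path = path.with_suffix(".raw")
    hdr_path = path.with_suffix(".hdr")
    ordered.tofile(raw_path)

    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths_nm)
    hdr_path.write_text(
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    return hdr_path


# ---------------------------------------------------------------------------
# Calibration and masking


def calibrate_reflectance(raw: Hypercube, white: Hypercube, dark: Hypercube) -> Hypercube:
    """Reflectance = (raw - dark) / (white - dark), clipped to [0, 1.2].

    White and dark are averaged over their spatial extent per band, so a
    reference tile scanned anywhere in the frame calibrates the whole
    image.  Scaling raw, white and dark by a common gain leaves the
    result unchanged.
    """
    if raw.shape[2] != white.shape[2] or raw.shape[2] != dark.shape[2]:
        raise CalibrationError("raw, white and dark must share the band axis")
    white_b = white.values.mean(axis=(0, 1))
    dark_b = dark.values.mean(axis=(0, 1))
    denom = white_b - dark_b
    if np.any(denom <= 0):
        bad = int(np.argmax(denom <= 0))
        raise CalibrationError(
            f"white reference does not exceed dark at band {bad} "
            f"({white_b[bad]:.4g} <= {dark_b[bad]:.4g})"
        )
    values = (raw.values - dark_b) / denom
    values = np.clip(values, 0.0, 1.2)
    meta = dict(raw.meta)
    meta["calibrated"] = True
    return Hypercube(values=values, wavelengths_nm=raw.wavelengths_nm, meta=meta)


def otsu_threshold(image: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold: maximize between-class variance over a histogram.

    Returns the bin-center threshold; pixels strictly above it are
    foreground.  Deterministic; raises on a constant image.
    """
    image = np.asarray(image, dtype=float)
    if image.max() == image.min():
        raise DegenerateImageError("image is constant; nothing to threshold")
    counts, edges = np.histogram(image.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    counts = counts.astype(float)

    w0 = np.cumsum(counts)
    w1 = w0[-1] - w0
    mu = np.cumsum(counts * centers)
    mu_total = mu[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        m0 = mu / w0
        m1 = (mu_total - mu) / w1
        between = w0 * w1 * (m0 - m1) ** 2
    between[~np.isfinite(between)] = -np.inf
    # argmax over thresholds placed after each bin; exclude the last (empty split)
    idx = int(np.argmax(between[:-1]))
    return float(centers[idx])


def build_mask(cube: Hypercube) -> Mask:
    """Foreground mask from the band-averaged intensity image.

    Otsu threshold, then retain the largest connected foreground
    component (a single tuber per frame).
    """
    intensity = cube.band_average()
    threshold = otsu_threshold(intensity)
    fg = intensity > threshold
    if not fg.any():
        raise DegenerateImageError("no foreground pixels above Otsu threshold")
    labels = measure.label(fg)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return Mask(values=(labels == largest).astype(np.uint8))


def mean_spectrum(cube: Hypercube, mask: Mask) -> np.ndarray:
    """Per-band mean over foreground pixels; the tuber's one spectrum."""
    if mask.values.shape != cube.shape[:2]:
        raise ValueError("mask shape does not match cube spatial shape")
    if mask.n_foreground == 0:
        raise ValueError("mask has no foreground pixels")
    fg = mask.values.astype(bool)
    return cube.values[fg].mean(axis=0)


def extract_dataset(
    cubes: Sequence[Hypercube],
    masks: Sequence[Mask],
    tga_ppm: Sequence[float],
    sample_id: Sequence[str] | None = None,
    day: Sequence[int] | None = None,
) -> SpectralDataset:
    """Mean spectra of all tubers stacked into the n x p analysis matrix."""
    if not (len(cubes) == len(masks) == len(tga_ppm)):
        raise ValueError("cubes, masks and tga_ppm must have equal length")
    if len(cubes) == 0:
        raise ValueError("no cubes supplied")
    wavelengths = cubes[0].wavelengths_nm
    for cube in cubes[1:]:
        if cube.wavelengths_nm.size != wavelengths.size or not np.allclose(
            cube.wavelengths_nm, wavelengths
        ):
            raise ValueError("wavelength grids differ across cubes")
    X = np.stack([mean_spectrum(c, m) for c, m in zip(cubes, masks)])
    n = len(cubes)
    return SpectralDataset(
        X=X,
        wavelengths_nm=wavelengths,
        y=np.asarray(tga_ppm, dtype=float),
        sample_id=np.asarray(sample_id if sample_id is not None
                             else [f"s{i:03d}" for i in range(n)]),
        day=np.asarray(day if day is not None else np.zeros(n, dtype=int)),
    )


def write_mask_png(mask: Mask, path: str | Path) -> None:
    """Export a mask as an 8-bit PNG (255 = foreground) for visual checks."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), (mask.values * 255).astype(np.uint8))
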