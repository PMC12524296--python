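"""From raw hypercubes to the n x 169 analysis matrix.

Simulates tuber frames plus white/dark reference cubes, writes and
re-reads them as ENVI files, calibrates to reflectance, masks each tuber
with Otsu's threshold on the band-averaged image, and averages the ROI
into one spectrum per tuber.
"""

import tempfile
from pathlib import Path

import numpy as np

import glycospec as gs
from glycospec.hypercube import (
    build_mask, calibrate_reflectance, extract_dataset, read_envi, write_envi,
)

config = gs.SyntheticConfig(seed=1)
rng = np.random.default_rng(0)
tga_values = [95.0, 150.0, 130.0]

with tempfile.TemporaryDirectory() as tmp:
    headers = []
    for i, tga in enumerate(tga_values):
        cube, _ = gs.generate_hypercube(tga, config, rng)
        headers.append(write_envi(cube, Path(tmp) / f"tuber{i}", interleave="bil"))

    white, dark = gs.generate_references(config)
    cubes, masks = [], []
    for header in headers:
        raw = read_envi(header)
        reflectance = calibrate_reflectance(raw, white, dark)
        mask = build_mask(reflectance)
        cubes.append(reflectance)
        masks.append(mask)
        print(f"{header.name}: {raw.shape[0]}x{raw.shape[1]} frame, "
              f"{mask.n_foreground} tuber pixels")

    dataset = extract_dataset(cubes, masks, tga_values)

print(f"analysis matrix: {dataset.X.shape[0]} x {dataset.X.shape[1]}")
band_1905 = int(np.argmin(np.abs(dataset.wavelengths_nm - 1905)))
print(f"reflectance at the 1905 nm water band: {dataset.X[:, band_1905].round(3)}")
# Each row is one tuber's mean reflectance spectrum; the deep value near
# 1905 nm is the O-H stretching/deformation water absorption.
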