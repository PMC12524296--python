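import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import glycospec as gs
from glycospec.hypercube import (
    CalibrationError,
    DegenerateImageError,
    FormatError,
    Hypercube,
    Mask,
    SpectralDataset,
    build_mask,
    calibrate_reflectance,
    extract_dataset,
    mean_spectrum,
    otsu_threshold,
    read_envi,
    write_envi,
)


def random_cube(rng, rows=8, cols=6, bands=5):
    return Hypercube(
        values=rng.random((rows, cols, bands)),
        wavelengths_nm=900.0 + 10.0 * np.arange(bands),
    )


class TestEnviIO:
    @pytest.mark.parametrize("interleave", ["bil", "bsq"])
    def test_roundtrip_bit_exact(self, rng, tmp_path, interleave):
        cube = random_cube(rng)
        header = write_envi(cube, tmp_path / "cube", interleave=interleave)
        back = read_envi(header)
        np.testing.assert_array_equal(back.values, cube.values.astype(np.float32))
        np.testing.assert_allclose(back.wavelengths_nm, cube.wavelengths_nm, atol=1e-6)

    def test_interleaves_agree(self, rng, tmp_path):
        cube = random_cube(rng)
        a = read_envi(write_envi(cube, tmp_path / "a", interleave="bil"))
        b = read_envi(write_envi(cube, tmp_path / "b", interleave="bsq"))
        np.testing.assert_array_equal(a.values, b.values)

    def test_bil_layout_matches_explicit_index_arithmetic(self, rng, tmp_path):
        # independent oracle: value (r, c, b) sits at offset r*(B*C) + b*C + c
        cube = random_cube(rng, rows=3, cols=4, bands=2)
        write_envi(cube, tmp_path / "c", interleave="bil")
        flat = np.fromfile(tmp_path / "c.raw", dtype="<f4")
        rows, cols, bands = cube.shape
        for r in range(rows):
            for c in range(cols):
                for b in range(bands):
                    assert flat[r * bands * cols + b * cols + c] == np.float32(
                        cube.values[r, c, b]
                    )

    def test_bsq_layout_matches_explicit_index_arithmetic(self, rng, tmp_path):
        # value (r, c, b) sits at offset b*(R*C) + r*C + c
        cube = random_cube(rng, rows=3, cols=4, bands=2)
        write_envi(cube, tmp_path / "c", interleave="bsq")
        flat = np.fromfile(tmp_path / "c.raw", dtype="<f4")
        rows, cols, bands = cube.shape
        for r in range(rows):
            for c in range(cols):
                for b in range(bands):
                    assert flat[b * rows * cols + r * cols + c] == np.float32(
                        cube.values[r, c, b]
                    )

    def test_band_count_mismatch_rejected(self, rng, tmp_path):
        cube = random_cube(rng)
        header = write_envi(cube, tmp_path / "c")
        text = header.read_text().replace("bands = 5", "bands = 4")
        # keep the data size consistent with the tampered band count
        text = text.replace("wavelength = {", "wavelength = { 1.0, ", 1)
        header.write_text(text)
        with pytest.raises(FormatError):
            read_envi(header)

    def test_missing_wavelength_list_rejected(self, rng, tmp_path):
        header = write_envi(random_cube(rng), tmp_path / "c")
        lines = [l for l in header.read_text().splitlines() if not l.startswith("wavelength =")]
        header.write_text("\n".join(lines) + "\n")
        with pytest.raises(FormatError, match="wavelength"):
            read_envi(header)

    def test_unsupported_interleave_named_in_error(self, rng, tmp_path):
        header = write_envi(random_cube(rng), tmp_path / "c")
        header.write_text(header.read_text().replace("interleave = bil", "interleave = bip"))
        with pytest.raises(FormatError, match="bip"):
            read_envi(header)


class TestCalibration:
    def make_refs(self, shape):
        white = Hypercube(np.full(shape, 0.9), 900 + 10.0 * np.arange(shape[2]))
        dark = Hypercube(np.full(shape, 0.1), 900 + 10.0 * np.arange(shape[2]))
        return white, dark

    @pytest.mark.parametrize("level,expected", [(0.9, 1.0), (0.1, 0.0), (0.5, 0.5)])
    def test_known_levels(self, level, expected):
        shape = (4, 3, 2)
        white, dark = self.make_refs(shape)
        raw = Hypercube(np.full(shape, level), white.wavelengths_nm)
        out = calibrate_reflectance(raw, white, dark)
        np.testing.assert_allclose(out.values, expected, atol=1e-12)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(gain=st.floats(min_value=0.1, max_value=10.0))
    def test_common_gain_invariance(self, gain):
        rng = np.random.default_rng(1)
        shape = (4, 3, 2)
        lam = 900 + 10.0 * np.arange(shape[2])
        raw = rng.random(shape) * 0.5 + 0.3
        white = np.full(shape, 0.9)
        dark = np.full(shape, 0.05)
        base = calibrate_reflectance(
            Hypercube(raw, lam), Hypercube(white, lam), Hypercube(dark, lam)
        )
        scaled = calibrate_reflectance(
            Hypercube(raw * gain, lam), Hypercube(white * gain, lam), Hypercube(dark * gain, lam)
        )
        np.testing.assert_allclose(scaled.values, base.values, atol=1e-9)

    def test_white_below_dark_rejected(self):
        shape = (2, 2, 2)
        lam = np.array([900.0, 910.0])
        with pytest.raises(CalibrationError):
            calibrate_reflectance(
                Hypercube(np.full(shape, 0.5), lam),
                Hypercube(np.full(shape, 0.1), lam),
                Hypercube(np.full(shape, 0.2), lam),
            )


def brute_force_otsu(image, nbins=256):
    """Independent oracle: exhaustive between-class variance over bin edges.

    Returns every threshold attaining the maximal variance (empty-bin
    plateaus make the argmax a tie set, not a single value).
    """
    counts, edges = np.histogram(np.asarray(image, float).ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    variances = np.full(nbins - 1, -np.inf)
    for split in range(1, nbins):
        w0, w1 = counts[:split].sum(), counts[split:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (counts[:split] * centers[:split]).sum() / w0
        m1 = (counts[split:] * centers[split:]).sum() / w1
        variances[split - 1] = w0 * w1 * (m0 - m1) ** 2
    best = variances.max()
    tied = variances >= best * (1 - 1e-10)
    return centers[:-1][tied]


class TestOtsu:
    def test_two_level_image_threshold_separates(self):
        img = np.concatenate([np.full(60, 0.02), np.full(40, 0.50)])
        t = otsu_threshold(img.reshape(10, 10))
        assert 0.02 < t < 0.50

    def test_matches_brute_force_on_random_images(self, rng):
        for _ in range(10):
            img = rng.random((20, 20)) ** 2
            tied = brute_force_otsu(img)
            assert np.abs(tied - otsu_threshold(img)).min() < 1e-12

    def test_matches_skimage(self, rng):
        from skimage.filters import threshold_otsu

        img = rng.random((30, 30))
        assert otsu_threshold(img) == pytest.approx(threshold_otsu(img, nbins=256), abs=1e-12)

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateImageError):
            otsu_threshold(np.ones((5, 5)))


class TestBuildMask:
    def test_recovers_generator_ellipse(self):
        cube, true_mask = gs.generate_hypercube(120.0, gs.SyntheticConfig(seed=4))
        mask = build_mask(cube)
        true_count = true_mask.values.sum()
        assert abs(mask.n_foreground - true_count) / true_count < 0.05
        inter = np.logical_and(mask.values, true_mask.values).sum()
        union = np.logical_or(mask.values, true_mask.values).sum()
        assert inter / union > 0.95

    def test_constant_cube_rejected(self):
        cube = Hypercube(np.full((6, 6, 3), 0.2), np.array([900.0, 910.0, 920.0]))
        with pytest.raises(DegenerateImageError):
            build_mask(cube)

    def test_mask_values_binary(self):
        cube, _ = gs.generate_hypercube(120.0, gs.SyntheticConfig(seed=4))
        mask = build_mask(cube)
        assert set(np.unique(mask.values)) <= {0, 1}


class TestMeanSpectrum:
    def test_single_pixel_mask(self, rng):
        cube = random_cube(rng)
        mask_values = np.zeros(cube.shape[:2], dtype=np.uint8)
        mask_values[2, 3] = 1
        np.testing.assert_array_equal(
            mean_spectrum(cube, Mask(mask_values)), cube.values[2, 3]
        )

    def test_all_ones_mask_is_global_mean(self, rng):
        cube = random_cube(rng)
        out = mean_spectrum(cube, Mask(np.ones(cube.shape[:2], dtype=np.uint8)))
        np.testing.assert_allclose(out, cube.values.mean(axis=(0, 1)))

    def test_two_pixel_mask_average(self, rng):
        cube = random_cube(rng)
        mask_values = np.zeros(cube.shape[:2], dtype=np.uint8)
        mask_values[0, 0] = mask_values[1, 1] = 1
        np.testing.assert_allclose(
            mean_spectrum(cube, Mask(mask_values)),
            (cube.values[0, 0] + cube.values[1, 1]) / 2,
        )

    def test_empty_mask_rejected(self, rng):
        cube = random_cube(rng)
        with pytest.raises(ValueError):
            mean_spectrum(cube, Mask(np.zeros(cube.shape[:2], dtype=np.uint8)))


class TestExtractDataset:
    def test_row_per_cube(self, rng):
        cubes = [random_cube(rng) for _ in range(3)]
        masks = [Mask(np.ones((8, 6), dtype=np.uint8))] * 3
        dataset = extract_dataset(cubes, masks, [10.0, 20.0, 30.0])
        assert dataset.X.shape == (3, 5)
        np.testing.assert_array_equal(dataset.y, [10.0, 20.0, 30.0])

    def test_wavelength_mismatch_rejected(self, rng):
        a = random_cube(rng)
        b = Hypercube(rng.random((8, 6, 5)), a.wavelengths_nm + 5.0)
        masks = [Mask(np.ones((8, 6), dtype=np.uint8))] * 2
        with pytest.raises(ValueError):
            extract_dataset([a, b], masks, [1.0, 2.0])

    def test_noiseless_cube_row_equals_generator_spectrum(self, noiseless_config):
        expected = gs.generate_spectrum(80.0, noiseless_config, np.random.default_rng(0))
        cube, mask = gs.generate_hypercube(80.0, noiseless_config, np.random.default_rng(0))
        dataset = extract_dataset([cube], [mask], [80.0])
        np.testing.assert_allclose(dataset.X[0], expected, atol=1e-12)


class TestSpectralDatasetCSV:
    def test_roundtrip(self, tmp_path, small_dataset):
        dataset, _, _ = small_dataset
        path = tmp_path / "data.csv"
        dataset.to_csv(path)
        back = SpectralDataset.from_csv(path)
        np.testing.assert_allclose(back.X, dataset.X, atol=1e-12)
        np.testing.assert_allclose(back.y, dataset.y)
        np.testing.assert_allclose(back.wavelengths_nm, dataset.wavelengths_nm, atol=1e-3)
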