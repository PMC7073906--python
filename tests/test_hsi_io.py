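"""ENVI round trips, reflectance calibration, band-math ROI masks."""

import numpy as np
import pytest

import meatspec as ms
from meatspec.hsi_io import EnviFormatError, CalibrationError


def _toy_cube(rows=4, cols=4, bands=5, dtype=np.float32, kind="reflectance"):
    rng = np.random.default_rng(0)
    data = rng.uniform(0, 100, size=(rows, cols, bands)).astype(dtype)
    wl = np.linspace(400.0, 1000.0, bands)
    return ms.Hypercube(data, wl, kind=kind)


class TestEnviRoundTrip:
    @pytest.mark.parametrize("interleave", ["bil", "bsq", "bip"])
    def test_write_read_identity(self, tmp_path, interleave):
        cube = _toy_cube()
        path = ms.write_cube(cube, tmp_path / "cube.raw", interleave=interleave)
        back = ms.read_cube(path)
        assert np.array_equal(back.data, cube.data)  # bit-exact raster
        assert np.allclose(back.wavelengths, cube.wavelengths, atol=1e-4)
        assert back.kind == cube.kind

    def test_interleave_dialects_agree(self, tmp_path):
        cube = _toy_cube(rows=3, cols=6, bands=4)
        a = ms.read_cube(ms.write_cube(cube, tmp_path / "a.raw", interleave="bil"))
        b = ms.read_cube(ms.write_cube(cube, tmp_path / "b.raw", interleave="bsq"))
        assert np.array_equal(a.data, b.data)

    def test_uint16_round_trip(self, tmp_path):
        cube = ms.Hypercube(
            np.arange(24, dtype=np.uint16).reshape(2, 3, 4),
            np.linspace(400, 700, 4),
            kind="raw",
        )
        back = ms.read_cube(ms.write_cube(cube, tmp_path / "c.raw"))
        assert back.data.dtype == np.uint16
        assert np.array_equal(back.data, cube.data)
        assert back.kind == "raw"

    def test_read_via_header_path(self, tmp_path):
        cube = _toy_cube()
        path = ms.write_cube(cube, tmp_path / "cube.raw")
        back = ms.read_cube(path.with_suffix(".raw.hdr"))
        assert np.array_equal(back.data, cube.data)

    def test_wavelength_count_mismatch_rejected(self, tmp_path):
        path = ms.write_cube(_toy_cube(bands=5), tmp_path / "bad.raw")
        hdr = path.with_suffix(".raw.hdr")
        text = hdr.read_text()
        wl_start = text.index("wavelength = {")
        trimmed = text[:wl_start] + "wavelength = {400.0, 500.0, 600.0, 700.0}\n"
        hdr.write_text(trimmed)
        with pytest.raises(EnviFormatError, match="4 wavelengths"):
            ms.read_cube(path)

    def test_missing_wavelengths_rejected(self, tmp_path):
        path = ms.write_cube(_toy_cube(), tmp_path / "nowl.raw")
        hdr = path.with_suffix(".raw.hdr")
        hdr.write_text(
            "\n".join(
                line for line in hdr.read_text().splitlines()
                if not line.startswith("wavelength =")
            )
            + "\n"
        )
        with pytest.raises(EnviFormatError, match="no wavelength list"):
            ms.read_cube(path)

    def test_size_mismatch_rejected(self, tmp_path):
        path = ms.write_cube(_toy_cube(), tmp_path / "short.raw")
        data = path.read_bytes()
        path.write_bytes(data[:-8])
        with pytest.raises(EnviFormatError, match="does not match header dimensions"):
            ms.read_cube(path)


def _flat_refs(bands, white=100.0, dark=0.0):
    wl = np.linspace(400.0, 1000.0, bands)
    shape = (2, 2, bands)
    return ms.ReferencePair(
        white=ms.Hypercube(np.full(shape, white), wl, kind="raw"),
        dark=ms.Hypercube(np.full(shape, dark), wl, kind="raw"),
    )


class TestCalibrate:
    def test_direct_value(self):
        refs = _flat_refs(3)
        raw = ms.Hypercube(np.full((1, 1, 3), 50.0), refs.white.wavelengths, kind="raw")
        out = ms.calibrate(raw, refs)
        assert out.kind == "reflectance"
        assert np.allclose(out.data, 50.0)

    def test_dark_limit_gives_zero(self):
        refs = _flat_refs(3, white=110.0, dark=10.0)
        raw = ms.Hypercube(np.full((2, 2, 3), 10.0), refs.white.wavelengths, kind="raw")
        assert np.allclose(ms.calibrate(raw, refs).data, 0.0)

    def test_offset_references(self):
        refs = _flat_refs(2, white=110.0, dark=10.0)
        raw = ms.Hypercube(np.full((1, 1, 2), 30.0), refs.white.wavelengths, kind="raw")
        assert np.allclose(ms.calibrate(raw, refs).data, 20.0)

    def test_affine_property(self, rng):
        """calibrate(a*W + (1-a)*D) = 100a % for any mixing fraction a."""
        bands = 6
        wl = np.linspace(400, 1000, bands)
        w_spec = rng.uniform(80, 120, bands)
        d_spec = rng.uniform(0, 10, bands)
        refs = ms.ReferencePair(
            white=ms.Hypercube(np.broadcast_to(w_spec, (3, 3, bands)).copy(), wl, kind="raw"),
            dark=ms.Hypercube(np.broadcast_to(d_spec, (3, 3, bands)).copy(), wl, kind="raw"),
        )
        for a in (0.0, 0.25, 0.9, 1.0):
            raw = ms.Hypercube(
                (a * w_spec + (1 - a) * d_spec)[None, None, :], wl, kind="raw"
            )
            assert np.allclose(ms.calibrate(raw, refs).data, 100.0 * a, atol=1e-9)

    def test_degenerate_band_identified(self):
        wl = np.linspace(400, 1000, 3)
        white = np.full((2, 2, 3), 100.0)
        white[:, :, 1] = 5.0  # equals dark at band 1
        refs = ms.ReferencePair(
            white=ms.Hypercube(white, wl, kind="raw"),
            dark=ms.Hypercube(np.full((2, 2, 3), 5.0), wl, kind="raw"),
        )
        raw = ms.Hypercube(np.full((1, 1, 3), 50.0), wl, kind="raw")
        with pytest.raises(CalibrationError, match="band 1"):
            ms.calibrate(raw, refs)

    def test_already_calibrated_rejected(self):
        refs = _flat_refs(3)
        cube = ms.Hypercube(np.full((1, 1, 3), 50.0), refs.white.wavelengths,
                            kind="reflectance")
        with pytest.raises(CalibrationError):
            ms.calibrate(cube, refs)


class TestMask:
    def _two_band_cube(self, diff_percent):
        """Cube whose 890-450 nm reflectance difference is given per pixel."""
        wl = np.array([450.0, 890.0])
        diff = np.asarray(diff_percent, dtype=float)
        data = np.zeros(diff.shape + (2,))
        data[..., 0] = 10.0
        data[..., 1] = 10.0 + diff
        return ms.Hypercube(data, wl, kind="reflectance")

    def test_threshold_rule(self):
        # 0.4 fractional difference passes the 0.2 threshold; 0.0 does not
        cube = self._two_band_cube([[40.0, 0.0]])
        mask = ms.build_mask(cube)
        assert mask.mask.tolist() == [[True, False]]
        assert mask.n_pixels == 1

    def test_exact_threshold_excluded(self):
        cube = self._two_band_cube([[20.0]])  # exactly 0.2: strict inequality
        assert ms.build_mask(cube).n_pixels == 0

    def test_scale_consistency(self, rng):
        """Doubling both the reflectance difference and the threshold leaves
        membership unchanged."""
        diff = rng.uniform(-10, 60, size=(8, 8))
        m1 = ms.build_mask(self._two_band_cube(diff), threshold=0.2)
        m2 = ms.build_mask(self._two_band_cube(2 * diff), threshold=0.4)
        assert np.array_equal(m1.mask, m2.mask)

    def test_out_of_range_wavelength_rejected(self):
        cube = self._two_band_cube([[30.0]])
        with pytest.raises(ValueError, match="outside cube range"):
            ms.build_mask(cube, low_nm=300.0)

    def test_matches_phantom_geometry(self, small_config):
        cube, true_map = ms.simulate_sample_cube(small_config, 30.0, seed=8)
        mask = ms.build_mask(cube)
        n_disk = int(np.isfinite(true_map).sum())
        assert abs(mask.n_pixels - n_disk) <= max(1, 0.01 * n_disk)


class TestNearestBand:
    def test_tie_breaks_toward_lower_index(self):
        wl = np.array([400.0, 500.0, 600.0])
        assert ms.nearest_band(wl, 450.0) == 0
        assert ms.nearest_band(wl, 451.0) == 1


class TestMeanSpectrum:
    def test_single_pixel(self):
        cube = ms.Hypercube(np.arange(12.0).reshape(2, 2, 3),
                            np.array([400.0, 500, 600]), kind="reflectance")
        mask = ms.RoiMask(np.array([[True, False], [False, False]]))
        assert np.array_equal(ms.mean_spectrum(cube, mask), cube.data[0, 0])

    def test_symmetric_pair_averages_to_ones(self):
        s = np.array([0.2, 0.7, 1.5])
        data = np.stack([s, -s + 2.0])[None, :, :]
        cube = ms.Hypercube(data, np.array([400.0, 500, 600]), kind="reflectance")
        mask = ms.RoiMask(np.ones((1, 2), bool))
        assert np.allclose(ms.mean_spectrum(cube, mask), 1.0)

    def test_empty_mask_rejected(self):
        cube = _toy_cube()
        with pytest.raises(ValueError, match="empty mask"):
            ms.mean_spectrum(cube, ms.RoiMask(np.zeros((4, 4), bool)))

    def test_zero_noise_phantom_midpoint(self, noise_free_config):
        em = ms.make_endmembers(noise_free_config.wavelengths(), noise_free_config.seed)
        cube, _ = ms.simulate_sample_cube(noise_free_config, 50.0, seed=1, endmembers=em)
        mask = ms.build_mask(cube)
        assert np.allclose(
            ms.mean_spectrum(cube, mask), 100 * 0.5 * (em.pork + em.jowl), atol=1e-9
        )
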