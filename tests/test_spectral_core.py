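"""Data model, container round-trips and pretreatment operations."""

import os

import numpy as np
import pytest
from hypothesis import given, strategies as st

from osteospec.errors import (
    DegenerateSpectrumError,
    IntegrityError,
    ParameterError,
    SpectralDomainError,
    SuspiciousSpectrumError,
)
from osteospec.spectral_core import (
    HyperspectralCube,
    SpectralMask,
    Spectrum,
    WavenumberAxis,
    apply_mask,
    crop_spectral,
    despike,
    mean_spectrum,
    read_cube,
    rubberband_baseline,
    smooth,
    spectrum_to_csv,
    vector_normalize,
    write_cube,
)
from osteospec.synthetic_data import synth_cube, make_tissue_template


def ftir_axis(step=2.0):
    return WavenumberAxis(np.arange(600.0, 4000.0 + step / 2, step))


def small_cube(seed=0, h=4, w=5, n=12):
    rng = np.random.default_rng(seed)
    axis = WavenumberAxis(np.linspace(700, 900, n))
    return HyperspectralCube(
        axis=axis,
        data=rng.normal(1.0, 0.1, (h, w, n)),
        modality="atr",
        pixel_pitch=10.0,
        sample_id="T1",
        pmi_days=42.5,
    )


class TestAxis:
    def test_descending_input_normalized_ascending(self):
        ax = WavenumberAxis(np.array([4000.0, 3000.0, 2000.0]))
        assert ax.values[0] == 2000.0 and ax.descending_input

    @pytest.mark.parametrize(
        "values",
        [np.array([1.0]), np.array([1.0, 2.0, 2.0]), np.array([1.0, np.nan, 3.0]),
         np.array([-5.0, 1.0, 2.0])],
    )
    def test_invalid_axes_rejected(self, values):
        with pytest.raises(ParameterError):
            WavenumberAxis(values)


class TestCubeIO:
    def test_round_trip_identity(self, tmp_path):
        cube = small_cube()
        p = tmp_path / "c.osc"
        write_cube(cube, p)
        back = read_cube(p)
        assert back.modality == cube.modality
        assert back.sample_id == cube.sample_id
        assert back.pixel_pitch == cube.pixel_pitch
        assert back.pmi_days == cube.pmi_days
        np.testing.assert_array_equal(back.axis.values, cube.axis.values)
        assert np.max(np.abs(back.data - cube.data)) < 1e-12

    def test_truncated_payload_is_integrity_error(self, tmp_path):
        cube = small_cube()
        p = tmp_path / "c.osc"
        write_cube(cube, p)
        raw = p.read_bytes()
        p.write_bytes(raw[:-8])  # drop one float
        with pytest.raises(IntegrityError):
            read_cube(p)

    def test_file_size_matches_declared_shape(self, tmp_path):
        cube = small_cube(h=10, w=10, n=50)
        p = tmp_path / "c.osc"
        write_cube(cube, p)
        payload = 8 * 10 * 10 * 50
        assert payload <= os.path.getsize(p) <= payload * 1.05 + 4096

    def test_invalid_pixel_pitch_rejected_before_write(self, tmp_path):
        with pytest.raises(ParameterError):
            HyperspectralCube(
                axis=WavenumberAxis(np.linspace(700, 900, 5)),
                data=np.zeros((2, 2, 5)),
                modality="atr",
                pixel_pitch=0.0,
            )
        assert list(tmp_path.iterdir()) == []

    def test_round_trip_preserves_chemimap(self, tmp_path):
        from osteospec.chemimaps import integrate_band
        from osteospec.synthetic_data import get_band

        tpl = make_tissue_template(24, 24, 1, seed=1)
        cube = synth_cube("atr", 3.0, tpl, seed=1)
        band = get_band("atr", "nu3 PO4")
        before = integrate_band(cube, band).values
        p = tmp_path / "c.osc"
        write_cube(cube, p)
        after = integrate_band(read_cube(p), band).values
        assert np.max(np.abs(before - after)) < 1e-9

    def test_spectrum_csv_round_trip(self, tmp_path):
        s = Spectrum(WavenumberAxis(np.array([1.0, 2.0, 3.0])), np.array([4.0, 5.0, 6.0]))
        p = tmp_path / "s.csv"
        spectrum_to_csv(s, p)
        lines = p.read_text().strip().splitlines()
        assert lines[0] == "wavenumber_cm-1,intensity"
        assert len(lines) == 4


class TestCrop:
    def test_crop_bounds_and_count(self):
        axis = ftir_axis()
        s = Spectrum(axis, np.ones(len(axis)))
        c = crop_spectral(s, 900.0, 1000.0)
        assert len(c.axis) == 51  # 900, 902, ..., 1000
        assert c.axis.lo >= 900 and c.axis.hi <= 1000

    def test_full_range_crop_is_identity(self):
        axis = ftir_axis()
        s = Spectrum(axis, np.linspace(0, 1, len(axis)))
        c = crop_spectral(s, axis.lo, axis.hi)
        np.testing.assert_array_equal(c.intensities, s.intensities)

    def test_nested_crops_equal_inner_crop(self):
        axis = ftir_axis()
        s = Spectrum(axis, np.linspace(0, 1, len(axis)))
        once = crop_spectral(s, 900.0, 1100.0)
        twice = crop_spectral(crop_spectral(s, 800.0, 1300.0), 900.0, 1100.0)
        np.testing.assert_array_equal(once.axis.values, twice.axis.values)
        np.testing.assert_array_equal(once.intensities, twice.intensities)

    def test_empty_overlap_raises(self):
        axis = WavenumberAxis(np.linspace(700, 900, 10))
        with pytest.raises(SpectralDomainError):
            crop_spectral(Spectrum(axis, np.ones(10)), 100.0, 200.0)


class TestVectorNormalize:
    def test_constant_spectrum_closed_form(self):
        axis = WavenumberAxis(np.linspace(600, 4000, 100))
        s = vector_normalize(Spectrum(axis, np.full(100, 7.3)))
        np.testing.assert_allclose(s.intensities, 1.0 / np.sqrt(100), atol=1e-12)

    def test_unit_norm_in_window(self):
        axis = ftir_axis(10.0)
        rng = np.random.default_rng(0)
        s = vector_normalize(Spectrum(axis, rng.normal(1, 0.3, len(axis))), 600, 4000)
        idx = axis.window_indices(600, 4000)
        assert abs(np.linalg.norm(s.intensities[idx]) - 1.0) < 1e-12

    @given(st.floats(min_value=0.01, max_value=1e6), st.integers(0, 10_000))
    def test_idempotent_and_scale_invariant(self, k, seed):
        axis = WavenumberAxis(np.linspace(600, 4000, 60))
        y = np.random.default_rng(seed).normal(1, 0.2, 60)
        a = vector_normalize(Spectrum(axis, y))
        b = vector_normalize(Spectrum(axis, k * y))
        c = vector_normalize(a)
        np.testing.assert_allclose(a.intensities, b.intensities, atol=1e-12)
        np.testing.assert_allclose(a.intensities, c.intensities, atol=1e-12)

    def test_zero_norm_raises(self):
        axis = WavenumberAxis(np.linspace(600, 700, 10))
        with pytest.raises(DegenerateSpectrumError):
            vector_normalize(Spectrum(axis, np.zeros(10)))


class TestRubberband:
    def test_straight_line_maps_to_zero(self):
        axis = WavenumberAxis(np.linspace(600, 4000, 200))
        s = rubberband_baseline(Spectrum(axis, 0.3 + 0.001 * axis.values))
        np.testing.assert_allclose(s.intensities, 0.0, atol=1e-9)

    def test_gaussian_band_height_recovered_from_slope(self):
        axis = ftir_axis()
        x = axis.values
        band = np.exp(-4 * np.log(2) * ((x - 1500.0) / 50.0) ** 2)
        sloped = band + 0.1 + 5e-4 * x
        out = rubberband_baseline(Spectrum(axis, sloped))
        assert abs(out.intensities.max() - 1.0) < 0.02

    @given(st.floats(-10, 10), st.floats(-0.01, 0.01), st.integers(0, 1000))
    def test_affine_invariance(self, a, b, seed):
        axis = WavenumberAxis(np.linspace(600, 1600, 150))
        rng = np.random.default_rng(seed)
        y = np.abs(rng.normal(1.0, 0.3, 150))
        base = rubberband_baseline(Spectrum(axis, y)).intensities
        shifted = rubberband_baseline(Spectrum(axis, y + a + b * axis.values)).intensities
        np.testing.assert_allclose(base, shifted, atol=1e-9)
        assert np.min(base) > -1e-9


class TestSmooth:
    def test_polynomial_reproduced_exactly(self):
        axis = WavenumberAxis(np.linspace(600, 1000, 101))
        u = np.linspace(-1, 1, 101)
        y = 2.0 - 3.0 * u + 0.5 * u**2
        out = smooth(Spectrum(axis, y), window_channels=11, polyorder=2)
        np.testing.assert_allclose(out.intensities, y, atol=1e-9)

    def test_noise_variance_reduced(self):
        axis = WavenumberAxis(np.linspace(0, 1700, 1000))
        y = np.random.default_rng(7).normal(0, 1.0, 1000)
        out = smooth(Spectrum(axis, y, "raman"), window_channels=11, polyorder=2)
        assert out.intensities.std() / y.std() < 0.6

    @pytest.mark.parametrize("window,order", [(4, 2), (9, 9), (2001, 2)])
    def test_bad_parameters_raise(self, window, order):
        axis = WavenumberAxis(np.linspace(600, 1000, 101))
        with pytest.raises(ParameterError):
            smooth(Spectrum(axis, np.ones(101)), window, order)


class TestMask:
    def test_masked_channels_removed(self):
        axis = ftir_axis()
        s = apply_mask(Spectrum(axis, np.ones(len(axis))), SpectralMask([(2300, 2400)]))
        assert not np.any((s.axis.values > 2300) & (s.axis.values < 2400))

    def test_empty_mask_is_identity(self):
        axis = ftir_axis(10.0)
        s = Spectrum(axis, np.ones(len(axis)))
        assert apply_mask(s, SpectralMask(())) is s

    def test_full_cover_mask_raises(self):
        axis = WavenumberAxis(np.linspace(700, 800, 10))
        with pytest.raises(DegenerateSpectrumError):
            apply_mask(Spectrum(axis, np.ones(10)), SpectralMask([(600, 900)]))

    def test_norm_over_remaining_channels(self):
        axis = ftir_axis(10.0)
        rng = np.random.default_rng(3)
        s = Spectrum(axis, rng.normal(1, 0.2, len(axis)))
        masked = apply_mask(s, SpectralMask([(2300, 2400), (1800, 1900)]))
        normed = vector_normalize(masked)
        assert abs(np.linalg.norm(normed.intensities) - 1.0) < 1e-12


class TestDespike:
    def _raman(self, y):
        axis = WavenumberAxis(np.arange(0.0, len(y) * 6.0, 6.0))
        return Spectrum(axis, y, "raman")

    def test_single_spike_removed_neighbors_intact(self):
        x = np.arange(300.0)
        y = 1.0 + 0.1 * np.sin(x / 40)
        y_spiked = y.copy()
        y_spiked[150] += 100.0
        out = despike(self._raman(y_spiked), z_threshold=8.0)
        assert abs(out.intensities[150] - y[150]) < 0.05
        np.testing.assert_allclose(out.intensities[:148], y[:148], atol=1e-12)

    def test_smooth_spectrum_unchanged(self):
        y = 1.0 + 0.1 * np.sin(np.arange(300.0) / 40)
        out = despike(self._raman(y))
        np.testing.assert_array_equal(out.intensities, y)

    def test_pathological_input_raises(self):
        y = np.zeros(100)
        y[::2] = 50.0  # half the channels are spikes
        with pytest.raises(SuspiciousSpectrumError):
            despike(self._raman(y), z_threshold=3.0)

    def test_non_raman_rejected(self):
        axis = WavenumberAxis(np.linspace(600, 700, 20))
        with pytest.raises(ParameterError):
            despike(Spectrum(axis, np.ones(20), "atr"))


class TestMeanSpectrum:
    def test_identical_pixels_give_that_spectrum(self):
        cube = small_cube()
        cube = HyperspectralCube(
            axis=cube.axis,
            data=np.broadcast_to(cube.data[0, 0], cube.data.shape).copy(),
            modality="atr",
            pixel_pitch=10.0,
        )
        np.testing.assert_allclose(
            mean_spectrum(cube).intensities, cube.data[0, 0], atol=1e-14
        )

    def test_two_pixel_average(self):
        cube = small_cube()
        mask = np.zeros((cube.height, cube.width), dtype=bool)
        mask[0, 0] = mask[1, 1] = True
        expect = (cube.data[0, 0] + cube.data[1, 1]) / 2
        np.testing.assert_allclose(mean_spectrum(cube, mask).intensities, expect)

    def test_mean_equals_mean_of_row_means(self):
        cube = small_cube(seed=9)
        rows = np.stack([cube.data[r].mean(axis=0) for r in range(cube.height)])
        np.testing.assert_allclose(
            mean_spectrum(cube).intensities, rows.mean(axis=0), atol=1e-12
        )

    def test_empty_mask_raises(self):
        cube = small_cube()
        with pytest.raises(SpectralDomainError):
            mean_spectrum(cube, np.zeros((cube.height, cube.width), dtype=bool))
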