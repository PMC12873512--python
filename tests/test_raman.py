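"""Hyperspectral preprocessing, band imaging, unmixing, layer measurement."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from cuticula import raman as rm
from cuticula import synthetic as syn


def _cosine(a, b):
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def _match_components(spectra, truth):
    """Hungarian matching of recovered spectra to true endmembers."""
    cos = np.array([[_cosine(s, t) for t in truth] for s in spectra])
    ri, cj = linear_sum_assignment(-cos)
    return ri, cj, cos[ri, cj]


@pytest.fixture
def clean_cube():
    return syn.generate_raman_cube(
        [(5.0, "flavonoids", 1.0), (10.0, "cutin", 1.0)],
        noise_sd=0.0, baseline_amplitude=0.0, seed=0,
    )


class TestCrop:
    def test_crop_endpoints(self, clean_cube):
        out = rm.crop_spectra(clean_cube)
        spacing = np.median(np.diff(clean_cube.wavenumbers))
        assert abs(out.wavenumbers[0] - 120.0) <= spacing
        assert abs(out.wavenumbers[-1] - 1810.0) <= spacing

    def test_idempotent(self, clean_cube):
        once = rm.crop_spectra(clean_cube)
        twice = rm.crop_spectra(once)
        np.testing.assert_array_equal(once.intensities, twice.intensities)
        np.testing.assert_array_equal(once.wavenumbers, twice.wavenumbers)

    def test_full_range_is_identity_on_pixels(self, clean_cube):
        out = rm.crop_spectra(clean_cube, low=0.0, high=1e4)
        np.testing.assert_array_equal(out.intensities, clean_cube.intensities)

    def test_empty_overlap_rejected(self, clean_cube):
        with pytest.raises(ValueError):
            rm.crop_spectra(clean_cube, low=5000.0, high=6000.0)


class TestCosmicRays:
    def test_spike_free_cube_unchanged(self):
        cube = syn.generate_raman_cube(
            [(3.0, "cutin", 1.0)], noise_sd=0.02, cosmic_ray_rate=0.0, seed=2
        )
        cropped = rm.crop_spectra(cube)
        out = rm.remove_cosmic_rays(cropped)
        np.testing.assert_array_equal(out.intensities, cropped.intensities)

    def test_injected_spike_removed(self):
        noise_sd = 0.02
        cube = syn.generate_raman_cube(
            [(3.0, "cutin", 1.0)], noise_sd=noise_sd, cosmic_ray_rate=0.0, seed=3
        )
        cube = rm.crop_spectra(cube)
        truth = cube.intensities.copy()
        spiked = truth.copy()
        spiked[2, 4, 300] += 50 * noise_sd
        cube2 = rm.RamanCube(cube.wavenumbers, spiked, cube.pixel_size,
                             stages=cube.stages)
        out = rm.remove_cosmic_rays(cube2)
        assert abs(out.intensities[2, 4, 300] - truth[2, 4, 300]) < 3 * noise_sd

    def test_broad_band_untouched(self):
        # FWHM 12 cm^-1 bands are wider than max_width and must survive
        cube = rm.crop_spectra(syn.generate_raman_cube(
            [(3.0, "triterpenoids", 1.0)], noise_sd=0.0, seed=0
        ))
        out = rm.remove_cosmic_rays(cube)
        np.testing.assert_array_equal(out.intensities, cube.intensities)


class TestBaseline:
    def test_zero_baseline_spectrum_minimally_changed(self):
        noise_sd = 0.02
        cube = rm.remove_cosmic_rays(rm.crop_spectra(syn.generate_raman_cube(
            [(3.0, "cutin", 1.0)], noise_sd=noise_sd, seed=4
        )))
        out = rm.baseline_correct(cube)
        assert np.max(np.abs(out.intensities - cube.intensities)) < 3 * noise_sd

    def test_quadratic_baseline_band_areas_recovered(self):
        cube = rm.remove_cosmic_rays(rm.crop_spectra(syn.generate_raman_cube(
            [(3.0, "cutin", 1.0)], noise_sd=0.0, baseline_amplitude=0.5, seed=5
        )))
        out = rm.baseline_correct(cube)
        img = rm.band_integral_image(out, center=1443.0, half_width=30.0)
        sigma = 12.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        true_area = 1.0 * sigma * np.sqrt(2.0 * np.pi)
        np.testing.assert_allclose(img, true_area, rtol=0.05)

    def test_flat_spectrum_residual_near_zero(self):
        wn = np.arange(120.0, 1810.0, 2.0)
        flat = np.full((2, 2, len(wn)), 3.0)
        cube = rm.RamanCube(wn, flat, 0.3, stages=("crop", "despike"))
        out = rm.baseline_correct(cube)
        assert np.max(np.abs(out.intensities)) < 1e-3


class TestPreprocessingOrder:
    def test_despike_before_crop_rejected(self, clean_cube):
        with pytest.raises(rm.PreprocessingOrderError):
            rm.remove_cosmic_rays(clean_cube)

    def test_baseline_before_despike_rejected(self, clean_cube):
        cropped = rm.crop_spectra(clean_cube)
        with pytest.raises(rm.PreprocessingOrderError):
            rm.baseline_correct(cropped)

    def test_unmix_requires_full_preprocessing(self, clean_cube):
        with pytest.raises(rm.PreprocessingOrderError):
            rm.unmix_components(rm.crop_spectra(clean_cube))


class TestBandIntegralImage:
    def test_all_zero_cube(self):
        wn = np.arange(120.0, 1810.0, 2.0)
        cube = rm.RamanCube(wn, np.zeros((3, 3, len(wn))), 0.3)
        assert (rm.band_integral_image(cube) == 0).all()

    def test_cutin_layer_positive_inside_zero_outside(self):
        cube = syn.generate_raman_cube(
            [(3.0, "cutin", 1.0), (3.0, "triterpenoids", 1.0)],
            noise_sd=0.0, seed=0,
        )
        img = rm.band_integral_image(cube)  # 1452 band sits on cutin's 1443
        rows = cube.metadata["layer_rows"]
        cutin_rows = slice(rows[0]["row_start"], rows[0]["row_end"])
        terp_rows = slice(rows[1]["row_start"], rows[1]["row_end"])
        assert img[cutin_rows].min() > 1.0
        assert np.abs(img[terp_rows]).max() < 1e-6

    def test_gaussian_band_integral_matches_closed_form(self):
        # single Gaussian of known analytic area centred at 1452
        wn = np.arange(1300.0, 1600.0, 1.0)
        amp, sigma = 2.0, 12.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        spec = amp * np.exp(-((wn - 1452.0) ** 2) / (2 * sigma**2))
        cube = rm.RamanCube(wn, np.tile(spec, (2, 2, 1)), 0.3)
        img = rm.band_integral_image(cube, center=1452.0, half_width=30.0)
        np.testing.assert_allclose(img, amp * sigma * np.sqrt(2 * np.pi), rtol=0.02)

    def test_window_outside_axis_rejected(self):
        wn = np.arange(120.0, 800.0, 2.0)
        cube = rm.RamanCube(wn, np.zeros((2, 2, len(wn))), 0.3)
        with pytest.raises(ValueError):
            rm.band_integral_image(cube, center=1452.0)


class TestAverageSpectrum:
    def test_single_pixel_mask(self, clean_cube):
        mask = np.zeros(clean_cube.shape[:2], dtype=bool)
        mask[0, 0] = True
        np.testing.assert_array_equal(
            rm.average_spectrum(clean_cube, mask), clean_cube.intensities[0, 0]
        )

    def test_random_mask_matches_brute_force(self):
        rng = np.random.default_rng(3)
        cube = syn.generate_raman_cube([(3.0, "cutin", 1.0)], noise_sd=0.05, seed=6)
        mask = rng.uniform(size=cube.shape[:2]) > 0.5
        out = rm.average_spectrum(cube, mask)
        expected = np.mean([cube.intensities[i, j] for i, j in zip(*np.nonzero(mask))],
                           axis=0)
        np.testing.assert_allclose(out, expected)

    def test_empty_mask_rejected(self, clean_cube):
        with pytest.raises(ValueError):
            rm.average_spectrum(clean_cube, np.zeros(clean_cube.shape[:2], dtype=bool))


def _preprocess(cube):
    return rm.baseline_correct(rm.remove_cosmic_rays(rm.crop_spectra(cube)))


class TestUnmixing:
    def test_noiseless_two_layer_endmember_recovery(self):
        cube = syn.generate_raman_cube(
            [(5.0, "flavonoids", 1.0), (10.0, "cutin", 1.0)],
            noise_sd=0.0, baseline_amplitude=0.0, seed=1,
        )
        pre = _preprocess(cube)
        comps = rm.unmix_components(pre, k_select=2)
        truth = [syn.endmember_spectrum(lbl, pre.wavenumbers)
                 for lbl in ("flavonoids", "cutin")]
        _, _, matched = _match_components(comps.selected_spectra, truth)
        assert (matched >= 0.99).all()

    def test_single_endmember_dominant_component(self):
        cube = syn.generate_raman_cube([(5.0, "cutin", 1.0)], noise_sd=0.01, seed=2)
        pre = _preprocess(cube)
        comps = rm.unmix_components(pre, k_select=1)
        amap = comps.selected_maps[0]
        # abundance approximately constant across the pure layer
        assert amap.std() / amap.mean() < 0.1

    def test_three_endmember_pixel_classification(self):
        layers = [(3.0, "flavonoids", 1.0), (5.0, "triterpenoids", 1.0),
                  (8.0, "cutin", 1.0)]
        cube = syn.generate_raman_cube(layers, noise_sd=0.05, seed=3)
        pre = _preprocess(cube)
        comps = rm.unmix_components(pre, k_select=3)
        truth = [syn.endmember_spectrum(lbl, pre.wavenumbers)
                 for lbl, in [(l[1],) for l in layers]]
        ri, cj, _ = _match_components(comps.selected_spectra, truth)
        comp_label = {int(r): layers[int(c)][1] for r, c in zip(ri, cj)}
        pred = np.vectorize(comp_label.get)(comps.classify_pixels())
        truth_grid = np.repeat(cube.metadata["row_labels"][:, None],
                               cube.shape[1], axis=1)
        assert (pred == truth_grid).mean() >= 0.95

    def test_reconstruction_error_monotone_in_k(self):
        cube = syn.generate_raman_cube(
            [(3.0, "flavonoids", 1.0), (4.0, "cutin", 1.0)], noise_sd=0.05, seed=4
        )
        comps = rm.unmix_components(_preprocess(cube), k_select=2)
        errs = [comps.reconstruction_errors[k] for k in sorted(comps.reconstruction_errors)]
        assert all(a >= b - 1e-9 for a, b in zip(errs, errs[1:]))

    def test_too_many_components_requested_rejected(self):
        cube = syn.generate_raman_cube([(5.0, "cutin", 1.0)],
                                       noise_sd=0.0, baseline_amplitude=0.0, seed=5)
        with pytest.raises(ValueError):
            rm.unmix_components(_preprocess(cube), k_select=4)


class TestLayerThickness:
    def test_synthetic_layer_within_one_pixel(self):
        cube = syn.generate_raman_cube(
            [(5.0, "flavonoids", 1.0), (10.0, "cutin", 1.0)], noise_sd=0.02, seed=6
        )
        pre = _preprocess(cube)
        comps = rm.unmix_components(pre, k_select=2)
        truth = [syn.endmember_spectrum(lbl, pre.wavenumbers)
                 for lbl in ("flavonoids", "cutin")]
        ri, cj, _ = _match_components(comps.selected_spectra, truth)
        flav_comp = [int(r) for r, c in zip(ri, cj) if c == 0][0]
        meas = rm.measure_layer_thickness(comps.selected_maps[flav_comp],
                                          cube.pixel_size)
        assert meas.mean == pytest.approx(5.0, abs=0.3 + 1e-9)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            rm.measure_layer_thickness(np.zeros((5, 5)), 0.3)

    def test_proportional_to_pixel_size(self):
        amap = np.zeros((10, 4))
        amap[2:7] = 1.0
        a = rm.measure_layer_thickness(amap, 0.3)
        b = rm.measure_layer_thickness(amap, 0.6)
        assert b.mean == pytest.approx(2.0 * a.mean)


class TestAssignBands:
    def test_flavonoid_endmember_scores_flavonoids_highest(self):
        wn = np.arange(120.0, 1810.0, 2.0)
        spec = syn.endmember_spectrum("flavonoids", wn)
        scores = rm.assign_bands(wn, spec)
        assert scores["flavonoids"]["fraction_matched"] == 1.0
        best = max(scores, key=lambda k: scores[k]["fraction_matched"])
        assert scores[best]["fraction_matched"] == scores["flavonoids"]["fraction_matched"]

    def test_flat_spectrum_no_matches(self):
        wn = np.arange(120.0, 1810.0, 2.0)
        scores = rm.assign_bands(wn, np.zeros_like(wn))
        assert all(v["fraction_matched"] == 0.0 for v in scores.values())

    def test_cutin_triterpenoid_mixture_matches_both(self):
        wn = np.arange(120.0, 1810.0, 2.0)
        spec = (syn.endmember_spectrum("cutin", wn)
                + syn.endmember_spectrum("triterpenoids", wn))
        scores = rm.assign_bands(wn, spec)
        assert scores["cutin"]["fraction_matched"] >= 0.8
        assert scores["triterpenoids"]["fraction_matched"] >= 0.8


def test_cube_io_round_trip(tmp_path):
    cube = syn.generate_raman_cube([(3.0, "cutin", 1.0)], noise_sd=0.02, seed=7)
    rm.write_cube(cube, tmp_path / "cube")
    back = rm.read_cube(tmp_path / "cube")
    np.testing.assert_array_equal(back.intensities, cube.intensities)
    np.testing.assert_array_equal(back.wavenumbers, cube.wavenumbers)
    assert back.pixel_size == cube.pixel_size
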