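"""NDI, NAOC and the exhaustive band-pair optimization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rededge import (
    BandLookupError,
    CoverageError,
    DegenerateDataError,
    NAOCConfig,
    ReflectanceCube,
    Spectrum,
    UsageError,
    naoc,
    naoc_bandset_variants,
    ndi,
    ndi_value,
    optimize_ndi,
)


def one_pixel_cube(wavelengths, reflectance):
    return ReflectanceCube(wavelengths, np.asarray(reflectance, float).reshape(1, 1, -1))


reflectances = st.lists(
    st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=2, max_size=8
)


class TestNDI:
    @pytest.mark.parametrize(
        "ra, rb, expected",
        [(0.2, 0.2, 0.0), (0.0, 0.4, 1.0), (0.05, 0.35, 0.75)],
    )
    def test_hand_values(self, ra, rb, expected):
        cube = one_pixel_cube([674.0, 712.0], [ra, rb])
        result = ndi(cube, 674, 712)
        assert result.values[0, 0] == pytest.approx(expected)

    def test_meta_records_actual_wavelengths(self):
        cube = one_pixel_cube([664.0, 706.0], [0.1, 0.3])
        result = ndi(cube, 665, 705)  # nearest-band matching within 5 nm
        assert result.meta["wl_a"] == 664.0 and result.meta["wl_b"] == 706.0

    def test_no_band_within_tolerance(self):
        cube = one_pixel_cube([500.0, 600.0], [0.1, 0.3])
        with pytest.raises(BandLookupError, match="712"):
            ndi(cube, 600, 712)

    def test_same_wavelength_rejected(self):
        cube = one_pixel_cube([500.0, 600.0], [0.1, 0.3])
        with pytest.raises(UsageError):
            ndi(cube, 600, 600)

    def test_zero_denominator_masked(self):
        cube = one_pixel_cube([674.0, 712.0], [0.0, 0.0])
        result = ndi(cube, 674, 712)
        assert result.mask[0, 0]

    @settings(derandomize=True, max_examples=50)
    @given(ra=st.floats(0, 1), rb=st.floats(0, 1))
    def test_antisymmetry_and_bound(self, ra, rb):
        if ra + rb == 0:
            return
        cube = one_pixel_cube([674.0, 712.0], [ra, rb])
        forward = ndi(cube, 674, 712).values[0, 0]
        backward = ndi(cube, 712, 674).values[0, 0]
        assert forward == pytest.approx(-backward)
        assert abs(forward) <= 1.0 + 1e-12


class TestNAOC:
    def test_flat_spectrum_is_zero(self):
        axis = np.arange(600.0, 851.0, 1.0)
        value = naoc(Spectrum(axis, np.full(axis.size, 0.3)))
        assert value == pytest.approx(0.0, abs=1e-12)

    def test_triangle_closed_form(self):
        """Linear ramp 0 at 643 nm to 0.4 at 795 nm: area is half the box."""
        axis = np.arange(643.0, 796.0, 1.0)
        refl = 0.4 * (axis - 643.0) / 152.0
        assert naoc(Spectrum(axis, refl)) == pytest.approx(0.5)

    def test_scale_invariance(self):
        axis = np.arange(600.0, 851.0, 1.0)
        refl = 0.1 + 0.3 * (axis - 600.0) / 250.0
        base = naoc(Spectrum(axis, refl))
        scaled = naoc(Spectrum(axis, np.clip(7.3 * refl, 0, None)))
        assert scaled == pytest.approx(base)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4))
    def test_never_exceeds_one(self, values):
        axis = np.array([660.0, 700.0, 745.0, 790.0])
        assert naoc(Spectrum(axis, np.array(values))) <= 1.0

    def test_quadrature_convergence(self, noiseless_scene):
        """1 nm and 0.1 nm trapezoid grids agree within 1e-3 on scene spectra."""
        cube, _ = noiseless_scene
        coarse = naoc(cube, NAOCConfig(sample_step=1.0))
        fine = naoc(cube, NAOCConfig(sample_step=0.1))
        assert np.nanmax(np.abs(coarse.values - fine.values)) < 1e-3

    def test_rb_nonpositive_masked(self):
        cube = one_pixel_cube([650.0, 790.0], [0.2, 0.0])
        result = naoc(cube)
        assert result.mask[0, 0]

    def test_too_few_bands_in_window(self):
        with pytest.raises(CoverageError):
            naoc(Spectrum(np.array([400.0, 500.0, 700.0]), np.array([0.1, 0.2, 0.3])))

    def test_config_validation(self):
        with pytest.raises(UsageError):
            NAOCConfig(a=700, b=650)
        with pytest.raises(UsageError):
            NAOCConfig(sample_step=50.0)

    def test_default_window_width(self):
        cfg = NAOCConfig()
        assert cfg.b - cfg.a == 152.0


class TestNAOCVariants:
    def s2_cube(self, refl_fn):
        centers = np.array([443.0, 490.0, 560.0, 665.0, 705.0, 740.0, 783.0, 842.0])
        return one_pixel_cube(centers, refl_fn(centers))

    def test_flat_spectrum_both_zero(self):
        with_re, without_re = naoc_bandset_variants(self.s2_cube(lambda wl: np.full_like(wl, 0.3)))
        assert with_re.values[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert without_re.values[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_linear_spectrum_variants_equal(self):
        with_re, without_re = naoc_bandset_variants(self.s2_cube(lambda wl: wl / 2000.0))
        assert with_re.values[0, 0] == pytest.approx(without_re.values[0, 0])

    def test_convex_red_edge_four_nodes_closer_to_reference(self, noiseless_scene):
        """On vegetated spectra the B4-B7 curve tracks the fine-grid NAOC
        better than the B4+B7 chord, which overestimates the red-edge area."""
        from rededge import covered_bands, resample_cube, s2_bandset

        cube, truth = noiseless_scene
        reference = naoc(cube)
        s2 = resample_cube(cube, covered_bands(s2_bandset(), cube.wavelengths))
        with_re, without_re = naoc_bandset_variants(s2)
        vegetated = truth.lai > 1.0
        err_with = np.abs(with_re.values - reference.values)[vegetated]
        err_without = np.abs(without_re.values - reference.values)[vegetated]
        assert np.mean(err_with) < np.mean(err_without)

    def test_missing_band_errors(self):
        cube = one_pixel_cube([665.0, 740.0, 783.0], [0.1, 0.3, 0.4])  # no B5
        with pytest.raises(CoverageError):
            naoc_bandset_variants(cube)


class TestOptimizeNDI:
    def scene_spectra(self, noiseless_scene):
        cube, truth = noiseless_scene
        spectra = [
            cube.spectrum(r, c)
            for r in range(cube.n_rows)
            for c in range(cube.n_cols)
        ]
        return spectra, truth.lai.ravel()

    def test_self_consistency_perfect_target(self, noiseless_scene):
        """A target equal to NDI(674, 712) itself is recovered with r = 1."""
        spectra, _ = self.scene_spectra(noiseless_scene)
        target = [ndi_value(s, 674, 712) for s in spectra]
        surface = optimize_ndi(spectra, target, 660, 720)
        assert surface.best_pair == (674.0, 712.0)
        assert surface.best_r == pytest.approx(1.0)

    def test_argmax_matches_brute_force_scan(self, small_scene):
        """best_r equals an independent full scan over all ordered pairs."""
        cube, truth = small_scene
        spectra = [cube.spectrum(r, c) for r in range(5) for c in range(20)]
        target = truth.lai[:5].ravel()
        surface = optimize_ndi(spectra, target, 640, 760)
        wl = surface.wavelengths
        R = np.stack([s.reflectance for s in spectra])
        cand = np.searchsorted(spectra[0].wavelengths, wl)
        best = 0.0
        for i in range(len(wl)):
            for j in range(len(wl)):
                if i == j:
                    continue
                x = (R[:, cand[j]] - R[:, cand[i]]) / (R[:, cand[j]] + R[:, cand[i]])
                if np.ptp(x) == 0:
                    continue
                r = np.corrcoef(x, target)[0, 1]
                best = max(best, abs(r))
        assert surface.best_r == pytest.approx(best)

    def test_surface_antisymmetry(self, small_scene):
        cube, truth = small_scene
        spectra = [cube.spectrum(0, c) for c in range(20)]
        surface = optimize_ndi(spectra, truth.lai[0], 660, 700)
        m = surface.r_matrix
        off_diag = ~np.isnan(m)
        assert np.allclose(m[off_diag], -m.T[off_diag])

    def test_absorption_band_in_best_pair(self, noiseless_scene):
        """The LAI-optimal pair anchors in the chlorophyll absorption region."""
        spectra, lai = self.scene_spectra(noiseless_scene)
        surface = optimize_ndi(spectra, lai, 600, 800)
        assert any(650 <= w <= 690 for w in surface.best_pair)
        assert surface.best_r >= 0.85

    def test_best_pair_reported_with_positive_r(self, noiseless_scene):
        spectra, lai = self.scene_spectra(noiseless_scene)
        surface = optimize_ndi(spectra, lai, 650, 720)
        wl = list(surface.wavelengths)
        i = wl.index(surface.best_pair[0])
        j = wl.index(surface.best_pair[1])
        assert surface.r_matrix[i, j] > 0

    def test_constant_target_rejected(self, small_scene):
        cube, _ = small_scene
        spectra = [cube.spectrum(0, c) for c in range(5)]
        with pytest.raises(DegenerateDataError):
            optimize_ndi(spectra, np.ones(5), 600, 800)


def test_indexmap_geotiff_export(tmp_path, small_scene):
    import json
    import tifffile

    cube, _ = small_scene
    m = ndi(cube, 674, 712)
    path = tmp_path / "ndi.tif"
    m.write_geotiff(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        assert page.asarray().shape == m.values.shape
        assert json.loads(page.description)["index"] == "NDI"
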