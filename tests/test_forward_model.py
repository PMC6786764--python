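import numpy as np
import pytest

import specmammo as sm
from specmammo.errors import ConfigurationError, CorrectionError


def slab_phantom(material, thickness_cm, n=12, pitch_um=100.0):
    maps = {material: np.full((n, n), float(thickness_cm))}
    return sm.PhantomModel(
        pixel_pitch_cm=pitch_um * 1e-4, thickness_maps=maps, features=[],
        background_material=material, slab_thickness_cm=thickness_cm,
    )


@pytest.fixture(scope="module")
def iodine_table():
    return {"iodine": sm.load_material("iodine")}


def open_beam_counts(flux, exposure, pitch_cm):
    return exposure * flux.fluence_rate_per_cm2_s * pitch_cm**2


def test_empty_phantom_gives_unattenuated_flux(flux):
    ph = slab_phantom("water", 0.0)
    r = sm.project(ph, sm.delta_spectrum(25.0), flux, 2.0, {"water": sm.load_material("water")})
    assert np.allclose(r.intensity, open_beam_counts(flux, 2.0, ph.pixel_pitch_cm))


def test_iodine_transmission_matches_basis_coefficient(flux, iodine_table):
    """0.1 cm of iodine at 25 keV transmits exp(-6.8796) of the open beam."""
    ph = slab_phantom("iodine", 0.1)
    r = sm.project(ph, sm.delta_spectrum(25.0), flux, 1.0, iodine_table)
    expected = open_beam_counts(flux, 1.0, ph.pixel_pitch_cm) * np.exp(-6.8796)
    assert np.allclose(r.intensity, expected, rtol=1e-12)


def test_noiseless_projection_is_bit_exact_repeatable(small_phantom, materials, flux):
    spec = sm.make_spectrum(25.0, 0.89, 9)
    a = sm.project(small_phantom, spec, flux, 1.0, materials)
    b = sm.project(small_phantom, spec, flux, 1.0, materials)
    np.testing.assert_array_equal(a.intensity, b.intensity)


def test_poisson_sampling_is_seeded(small_phantom, materials, flux):
    spec = sm.delta_spectrum(25.0)
    a = sm.project(small_phantom, spec, flux, 1.0, materials, seed=11)
    b = sm.project(small_phantom, spec, flux, 1.0, materials, seed=11)
    c = sm.project(small_phantom, spec, flux, 1.0, materials, seed=12)
    np.testing.assert_array_equal(a.intensity, b.intensity)
    assert not np.array_equal(a.intensity, c.intensity)
    assert a.seed == 11


def test_added_thickness_never_increases_expected_counts(small_phantom, materials, flux):
    spec = sm.make_spectrum(25.0, 0.89, 9)
    base = sm.expected_counts(small_phantom, spec, flux, 1.0, materials)
    thicker = sm.PhantomModel(
        pixel_pitch_cm=small_phantom.pixel_pitch_cm,
        thickness_maps={m: t + 0.01 for m, t in small_phantom.thickness_maps.items()},
        features=[], background_material=small_phantom.background_material,
        slab_thickness_cm=small_phantom.slab_thickness_cm,
    )
    more = sm.expected_counts(thicker, spec, flux, 1.0, materials)
    assert np.all(more <= base)


def test_quasi_monochromatic_close_to_monochromatic(small_phantom, materials, flux):
    """At few-percent FWHM, log-attenuation is within 0.5% of the central energy's."""
    for e, fwhm in [(25.0, 0.89), (35.0, 1.50)]:
        wide = sm.expected_counts(small_phantom, sm.make_spectrum(e, fwhm, 31), flux, 1.0, materials)
        mono = sm.expected_counts(small_phantom, sm.delta_spectrum(e), flux, 1.0, materials)
        n0 = open_beam_counts(flux, 1.0, small_phantom.pixel_pitch_cm)
        a_wide, a_mono = -np.log(wide / n0), -np.log(mono / n0)
        assert np.all(np.abs(a_wide - a_mono) / np.abs(a_mono) < 0.005)


def test_delta_spectrum_equals_monochromatic_beer_lambert(small_phantom, materials, flux):
    spec = sm.delta_spectrum(25.0)
    counts = sm.expected_counts(small_phantom, spec, flux, 1.0, materials)
    expo = np.zeros(small_phantom.shape)
    for name, t in small_phantom.thickness_maps.items():
        expo += sm.mu_at(materials[name], 25.0) * t
    n0 = open_beam_counts(flux, 1.0, small_phantom.pixel_pitch_cm)
    np.testing.assert_allclose(counts, n0 * np.exp(-expo), rtol=1e-12)


def test_missing_material_table_raises(small_phantom, flux):
    with pytest.raises(ConfigurationError, match="iodine"):
        sm.expected_counts(small_phantom, sm.delta_spectrum(25.0), flux, 1.0,
                           {"breast_50_50": sm.load_material("breast_50_50")})


class TestFlatDarkCorrection:
    def make(self, arr):
        return sm.Radiograph(np.asarray(arr, dtype=float), pixel_pitch_um=71.0)

    def test_raw_equals_flat_gives_unity(self):
        raw = self.make(np.full((4, 4), 7.0))
        out = sm.flat_dark_correct(raw, self.make(np.full((4, 4), 7.0)))
        assert np.allclose(out.intensity, 1.0)
        assert out.corrected

    def test_dark_subtraction_only(self):
        raw = self.make(np.arange(16.0).reshape(4, 4) + 5)
        flat = self.make(np.full((4, 4), 1.0 + 2.0))
        dark = self.make(np.full((4, 4), 2.0))
        out = sm.flat_dark_correct(raw, flat, dark)
        np.testing.assert_allclose(out.intensity, raw.intensity - 2.0)

    def test_matched_slab_cancels_in_ratio(self, flux):
        """A phantom attenuation-matched to the flat reference corrects to ~1."""
        water = {"water": sm.load_material("water"), "pmma": sm.load_material("pmma")}
        ph = slab_phantom("water", 3.0)
        spec = sm.make_spectrum(25.0, 0.89, 9)
        raw = sm.project(ph, spec, flux, 1.0, water)
        flat = sm.simulate_flat(ph, spec, flux, 1.0, material="water", thickness_cm=3.0,
                                materials=water)
        out = sm.flat_dark_correct(raw, flat)
        np.testing.assert_allclose(out.intensity, 1.0, rtol=1e-12)

    def test_non_positive_flat_minus_dark_reports_pixel_count(self):
        raw = self.make(np.ones((3, 3)))
        flat = self.make(np.ones((3, 3)))
        dark = self.make(np.eye(3) * 2.0)
        with pytest.raises(CorrectionError, match="3 pixel"):
            sm.flat_dark_correct(raw, flat, dark)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(CorrectionError):
            sm.flat_dark_correct(self.make(np.ones((3, 3))), self.make(np.ones((4, 4))))


class TestAttenuationImage:
    def test_inverse_of_exponential(self):
        r = sm.Radiograph(np.full((2, 2), np.exp(-3.0)), corrected=True)
        a = sm.attenuation_image(r)
        assert np.allclose(a, 3.0)
        r1 = sm.Radiograph(np.ones((2, 2)), corrected=True)
        assert np.allclose(sm.attenuation_image(r1), 0.0)

    def test_non_positive_pixels_masked_with_warning(self):
        img = np.ones((3, 3))
        img[1, 1] = 0.0
        with pytest.warns(UserWarning, match="1 non-positive"):
            a = sm.attenuation_image(sm.Radiograph(img, corrected=True))
        assert a.mask[1, 1] and a.mask.sum() == 1

    def test_matches_line_integral_for_noiseless_delta_projection(self, flux, iodine_table):
        ph = slab_phantom("iodine", 0.05)
        raw = sm.project(ph, sm.delta_spectrum(30.0), flux, 1.0, iodine_table)
        flat = sm.simulate_flat(ph, sm.delta_spectrum(30.0), flux, 1.0, thickness_cm=0.0)
        a = sm.attenuation_image(sm.flat_dark_correct(raw, flat))
        mu = sm.mu_at(iodine_table["iodine"], 30.0)
        np.testing.assert_allclose(np.asarray(a), mu * 0.05, rtol=1e-12)


def test_radiograph_tiff_roundtrip(tmp_path):
    img = np.random.default_rng(0).random((8, 8)).astype(np.float32)
    r = sm.Radiograph(img, pixel_pitch_um=71.0, exposure_s=1.5, corrected=True, seed=5)
    p = tmp_path / "r.tif"
    r.to_tiff(p)
    back = sm.Radiograph.from_tiff(p)
    np.testing.assert_allclose(back.intensity, img, rtol=1e-6)
    assert back.pixel_pitch_um == 71.0
    assert back.exposure_s == 1.5
    assert back.corrected and back.seed == 5
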