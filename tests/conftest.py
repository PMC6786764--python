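import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import specmammo as sm

settings.register_profile(
    "ci",
    max_examples=50,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_phantom_config() -> sm.PhantomConfig:
    """Coarse, small-extent phantom for fast simulation tests."""
    return sm.PhantomConfig(
        pixel_pitch_um=140.0,
        width_cm=3.4,
        height_cm=2.6,
        features=[
            sm.Feature("speck_group", 0.8, 0.7,
                       {"diameter_mm": 0.54, "thickness_mm": 0.20, "n": 6, "spread_mm": 2.5}),
            sm.Feature("mass", 1.5, 1.9, {"diameter_mm": 2.0, "height_mm": 1.0}),
            sm.Feature("iodine_tube", 2.7, 1.3,
                       {"width_cm": 0.8, "height_cm": 1.6, "path_cm": 1.0,
                        "concentration_mg_ml": 6.0}),
        ],
    )


@pytest.fixture(scope="session")
def small_config():
    return small_phantom_config()


@pytest.fixture(scope="session")
def small_phantom(small_config):
    return sm.build_phantom(small_config, seed=7)


@pytest.fixture(scope="session")
def materials(small_phantom):
    names = set(small_phantom.thickness_maps) | {"pmma"}
    return sm.forward_model.default_materials(names)


@pytest.fixture(scope="session")
def flux():
    return sm.BeamlineFlux()


@pytest.fixture(scope="session")
def basis():
    return sm.DecompositionBasis.default()


def simulate_pair_log_attenuation(phantom, materials, flux, exposure_s, seed,
                                  n_bins=9, flat_thickness_cm=6.0):
    """Noisy corrected log-attenuation pair on the phantom grid."""
    out = {}
    rng = np.random.default_rng(seed)
    slab = sm.forward_model.uniform_slab_phantom(phantom, "pmma", flat_thickness_cm)
    for key, (e, fwhm) in {"low": (25.0, 0.89), "high": (35.0, 1.50)}.items():
        spec = sm.make_spectrum(e, fwhm, n_bins)
        mu = sm.expected_counts(phantom, spec, flux, exposure_s, materials)
        flat = sm.expected_counts(slab, spec, flux, exposure_s, materials)
        out[key] = -np.log(rng.poisson(mu) / flat)
    return out["low"], out["high"]
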