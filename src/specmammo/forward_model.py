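"""Radiograph acquisition model.

Expected detector counts follow spectrum-weighted Beer-Lambert transmission,

    N(x, y) = t_exp * flux_per_pixel * eff * sum_E w(E) exp(-sum_m mu_m(E) d_m(x, y)),

optionally Poisson-sampled with an explicit seed.  The detector is an ideal
photon counter with pixel pitch 71 um by default; scintillator response and
optical blur are outside the model (resolution is probed empirically by the
image metrics).  Images are dark-current subtracted and flat-field corrected,
by default against a 6 cm PMMA reference as in the experimental protocol, so
log-attenuation is measured relative to that reference.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .attenuation import MaterialAttenuation, load_material, mu_at
from .errors import ConfigurationError, CorrectionError
from .phantom import PhantomModel
from .source_spectrum import BeamlineFlux, Spectrum

_MAX_EXPECTED_COUNTS = 1e15  # Poisson sampling overflow guard


@dataclass
class Radiograph:
    """A single 2-D intensity image with its acquisition metadata."""

    intensity: np.ndarray
    pixel_pitch_um: float = 71.0
    spectrum: Spectrum | None = None
    exposure_s: float | None = None
    corrected: bool = False
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    def to_tiff(self, path) -> None:
        import tifffile

        desc = {
            "pixel_pitch_um": self.pixel_pitch_um,
            "exposure_s": self.exposure_s,
            "corrected": self.corrected,
            "seed": self.seed,
            "e_central_kev": self.spectrum.e_central_kev if self.spectrum else None,
            **self.meta,
        }
        tifffile.imwrite(path, self.intensity.astype(np.float32), photometric="minisblack",
                         description=json.dumps(desc))

    @classmethod
    def from_tiff(cls, path) -> "Radiograph":
        import tifffile

        with tifffile.TiffFile(path) as tf:
            img = tf.asarray().astype(float)
            try:
                desc = json.loads(tf.pages[0].description or "{}")
            except json.JSONDecodeError:
                desc = {}
        return cls(
            intensity=img,
            pixel_pitch_um=desc.get("pixel_pitch_um", 71.0),
            exposure_s=desc.get("exposure_s"),
            corrected=bool(desc.get("corrected", False)),
            seed=desc.get("seed"),
            meta={k: v for k, v in desc.items() if k not in
                  {"pixel_pitch_um", "exposure_s", "corrected", "seed", "e_central_kev"}},
        )


@dataclass
class RadiographPair:
    """Registered low/high-energy images on one grid."""

    low: Radiograph
    high: Radiograph

    def __post_init__(self) -> None:
        if self.low.shape != self.high.shape or self.low.pixel_pitch_um != self.high.pixel_pitch_um:
            raise ValueError("pair images must share grid shape and pixel pitch")


def default_materials(names) -> dict[str, MaterialAttenuation]:
    """Load the packaged attenuation table for each requested material name."""
    return {n: load_material(n) for n in names}


def expected_counts(
    phantom: PhantomModel,
    spectrum: Spectrum,
    flux: BeamlineFlux,
    exposure_s: float,
    materials: dict[str, MaterialAttenuation] | None = None,
    efficiency: float = 1.0,
) -> np.ndarray:
    """Noiseless expected counts per pixel (the Poisson mean map)."""
    if exposure_s < 0:
        raise ValueError("exposure must be non-negative")
    if materials is None:
        materials = default_materials(phantom.thickness_maps.keys())
    missing = set(phantom.thickness_maps) - set(materials)
    if missing:
        raise ConfigurationError(f"no attenuation table for material(s): {sorted(missing)}")

    n0 = exposure_s * flux.fluence_rate_per_cm2_s * phantom.pixel_area_cm2 * efficiency
    trans = np.zeros(phantom.shape)
    for e, w in zip(spectrum.bin_energies_kev, spectrum.weights):
        expo = np.zeros(phantom.shape)
        for name, thick in phantom.thickness_maps.items():
            expo += mu_at(materials[name], float(e)) * thick
        trans += w * np.exp(-expo)
    counts = n0 * trans
    if np.any(counts > _MAX_EXPECTED_COUNTS):
        raise ValueError("expected counts exceed the overflow guard")
    return counts


def project(
    phantom: PhantomModel,
    spectrum: Spectrum,
    flux: BeamlineFlux,
    exposure_s: float,
    materials: dict[str, MaterialAttenuation] | None = None,
    seed: int | None = None,
    efficiency: float = 1.0,
) -> Radiograph:
    """Simulate one radiograph; ``seed=None`` returns the noiseless expectation."""
    counts = expected_counts(phantom, spectrum, flux, exposure_s, materials, efficiency)
    if seed is not None:
        counts = np.random.default_rng(seed).poisson(counts).astype(float)
    return Radiograph(
        intensity=counts,
        pixel_pitch_um=phantom.pixel_pitch_cm * 1e4,
        spectrum=spectrum,
        exposure_s=exposure_s,
        seed=seed,
    )


def uniform_slab_phantom(like: PhantomModel, material: str, thickness_cm: float) -> PhantomModel:
    """A featureless slab on the same grid as ``like`` (flat-field reference)."""
    return PhantomModel(
        pixel_pitch_cm=like.pixel_pitch_cm,
        thickness_maps={material: np.full(like.shape, thickness_cm)},
        features=[],
        background_material=material,
        slab_thickness_cm=thickness_cm,
    )


def simulate_flat(
    phantom: PhantomModel,
    spectrum: Spectrum,
    flux: BeamlineFlux,
    exposure_s: float,
    material: str = "pmma",
    thickness_cm: float = 6.0,
    materials: dict[str, MaterialAttenuation] | None = None,
    seed: int | None = None,
    efficiency: float = 1.0,
) -> Radiograph:
    """Flat-field reference through a uniform slab (default 6 cm PMMA).

    ``thickness_cm = 0`` gives an open-beam flat.
    """
    slab = uniform_slab_phantom(phantom, material, thickness_cm)
    if thickness_cm == 0:
        slab.thickness_maps[material][:] = 0.0
    if materials is None:
        materials = default_materials([material])
    return project(slab, spectrum, flux, exposure_s, materials, seed, efficiency)


def flat_dark_correct(raw: Radiograph, flat: Radiograph, dark: Radiograph | None = None) -> Radiograph:
    """Dark-current subtraction and flat-field normalisation.

    corrected = (raw - dark) / (flat - dark); all images must share one grid
    and the flat must exceed the dark everywhere.
    """
    if dark is None:
        dark = Radiograph(np.zeros(raw.shape), pixel_pitch_um=raw.pixel_pitch_um)
    for other in (flat, dark):
        if other.shape != raw.shape:
            raise CorrectionError("raw, flat and dark grids must match")
    denom = flat.intensity - dark.intensity
    bad = int(np.count_nonzero(denom <= 0))
    if bad:
        raise CorrectionError(f"flat - dark is non-positive at {bad} pixel(s)")
    corrected = (raw.intensity - dark.intensity) / denom
    out = replace(raw)
    out.intensity = corrected
    out.corrected = True
    out.meta = {**raw.meta, "flat_exposure_s": flat.exposure_s}
    return out


def attenuation_image(corrected: Radiograph) -> np.ma.MaskedArray:
    """Log-attenuation map A = -ln(I) of a corrected radiograph.

    Non-positive pixels (possible at extreme noise) are masked rather than
    silently propagated as NaN; a warning reports how many.
    """
    inten = corrected.intensity
    mask = inten <= 0
    n_bad = int(mask.sum())
    if n_bad:
        warnings.warn(f"attenuation_image: masked {n_bad} non-positive pixel(s)")
    safe = np.where(mask, 1.0, inten)
    return np.ma.MaskedArray(-np.log(safe), mask=mask)
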