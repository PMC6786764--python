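"""Quasi-monochromatic beam spectra and the inverse-Compton energy relation.

An inverse-Compton source back-scatters laser photons off relativistic
electrons; the emitted X-ray energy is approximately E_x = 4 * gamma^2 * E_L
with gamma the electron Lorentz factor.  The resulting beam is
quasi-monochromatic: here a few-percent-FWHM line, modelled as a Gaussian
truncated at +/-3 sigma (only the central energy and FWHM are constrained by
the source characterisation; the exact line shape matters little downstream
because attenuation varies slowly over the bandwidth).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import numpy as np

ELECTRON_REST_ENERGY_KEV = 511.0
_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def ics_xray_energy(e_electron_kev: float, e_laser_kev: float) -> float:
    """On-axis inverse-Compton X-ray energy, E_x = 4 (E_e/E_0)^2 E_L (keV)."""
    if e_electron_kev < ELECTRON_REST_ENERGY_KEV:
        raise ValueError("electron total energy must be at least the rest energy (511 keV)")
    if e_laser_kev <= 0:
        raise ValueError("laser photon energy must be positive")
    gamma = e_electron_kev / ELECTRON_REST_ENERGY_KEV
    return 4.0 * gamma**2 * e_laser_kev


@dataclass
class Spectrum:
    """Discretised photon-energy distribution of one beam setting."""

    bin_energies_kev: np.ndarray
    weights: np.ndarray
    e_central_kev: float
    fwhm_kev: float

    def __post_init__(self) -> None:
        self.bin_energies_kev = np.atleast_1d(np.asarray(self.bin_energies_kev, dtype=float))
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if self.bin_energies_kev.shape != self.weights.shape:
            raise ValueError("bin energies and weights must have matching shapes")
        if np.any(self.weights < 0):
            raise ValueError("spectrum weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("spectrum weights must sum to 1")

    @property
    def n_bins(self) -> int:
        return self.bin_energies_kev.size

    def mean_energy_kev(self) -> float:
        return float(np.sum(self.bin_energies_kev * self.weights))

    def empirical_fwhm_kev(self) -> float:
        """Full width at half maximum of the discretised shape.

        Half-maximum crossings are located by linear interpolation between
        bin centres; a delta spectrum has zero width.
        """
        if self.n_bins < 3:
            return 0.0
        e, w = self.bin_energies_kev, self.weights
        half = w.max() / 2.0
        above = np.nonzero(w >= half)[0]
        i0, i1 = above[0], above[-1]
        if i0 == 0:
            left = e[0]
        else:
            left = e[i0 - 1] + (half - w[i0 - 1]) / (w[i0] - w[i0 - 1]) * (e[i0] - e[i0 - 1])
        if i1 == self.n_bins - 1:
            right = e[-1]
        else:
            right = e[i1] + (w[i1] - half) / (w[i1] - w[i1 + 1]) * (e[i1 + 1] - e[i1])
        return float(right - left)

    def to_csv(self, path) -> None:
        header = f"# e_central_kev: {self.e_central_kev}\n# fwhm_kev: {self.fwhm_kev}\nenergy_keV,weight\n"
        rows = "\n".join(f"{e:.10g},{w:.12g}" for e, w in zip(self.bin_energies_kev, self.weights))
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header + rows + "\n")

    @classmethod
    def from_csv(cls, path) -> "Spectrum":
        meta = {}
        lines = []
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#") and ":" in line:
                    k, v = line.lstrip("#").split(":", 1)
                    meta[k.strip()] = float(v)
                elif line and not line.startswith("#") and not line.startswith("energy"):
                    lines.append(line)
        arr = np.loadtxt(io.StringIO("\n".join(lines)), delimiter=",", ndmin=2)
        return cls(arr[:, 0], arr[:, 1], meta.get("e_central_kev", float(np.nan)), meta.get("fwhm_kev", 0.0))


def make_spectrum(e_central_kev: float, fwhm_kev: float, n_bins: int = 51) -> Spectrum:
    """Gaussian line truncated at +/-3 sigma and renormalised.

    ``fwhm_kev = 0`` or ``n_bins = 1`` degenerates to a delta line at the
    central energy (exactly monochromatic Beer-Lambert downstream).
    """
    if e_central_kev <= 0:
        raise ValueError("central energy must be positive")
    if fwhm_kev < 0 or n_bins < 1:
        raise ValueError("fwhm must be non-negative and n_bins at least 1")
    if fwhm_kev == 0 or n_bins == 1:
        return Spectrum(np.array([e_central_kev]), np.array([1.0]), e_central_kev, 0.0)
    sigma = fwhm_kev / _FWHM_PER_SIGMA
    e = np.linspace(e_central_kev - 3 * sigma, e_central_kev + 3 * sigma, n_bins)
    w = np.exp(-0.5 * ((e - e_central_kev) / sigma) ** 2)
    w /= w.sum()
    return Spectrum(e, w, e_central_kev, fwhm_kev)


def delta_spectrum(e_kev: float) -> Spectrum:
    """Monochromatic line at ``e_kev``."""
    return make_spectrum(e_kev, 0.0, 1)


@dataclass(frozen=True)
class BeamlineFlux:
    """Photon flux at the sample plane.

    Defaults follow the source characterisation used in this study:
    3.0e10 photons/s into an elliptical 6.2 cm x 7.4 cm footprint 16 m from
    the interaction point.  The measured per-scan flux calibration chain is
    outside this model — its output (photons per second and footprint area)
    is the interface.
    """

    photons_per_second: float = 3.0e10
    beam_area_cm2: float = float(np.pi * 3.1 * 3.7)
    distance_from_ip_m: float = 16.0

    def __post_init__(self) -> None:
        if self.photons_per_second <= 0 or self.beam_area_cm2 <= 0 or self.distance_from_ip_m <= 0:
            raise ValueError("flux parameters must be positive")

    @property
    def fluence_rate_per_cm2_s(self) -> float:
        return self.photons_per_second / self.beam_area_cm2

    def at_distance(self, distance_m: float) -> "BeamlineFlux":
        """Inverse-square rescaling of the footprint to another plane."""
        if distance_m <= 0:
            raise ValueError("distance must be positive")
        scale = (distance_m / self.distance_from_ip_m) ** 2
        return replace(self, beam_area_cm2=self.beam_area_cm2 * scale, distance_from_ip_m=distance_m)
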