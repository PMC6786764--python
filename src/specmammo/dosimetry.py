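"""Air kerma and mean glandular dose (MGD) for one acquisition.

Per energy bin, the air kerma delivered by a fluence Phi(E) (photons/cm^2) is

    K(E) = E * Phi(E) * (mu_en/rho)_air(E),

converted from keV/g to mGy.  The MGD then follows from the monoenergetic
normalised glandular dose coefficients DgN(E) (mGy per roentgen of entrance
exposure) for the phantom's thickness and glandularity:

    MGD = sum_E K(E) [mGy] * 0.114 [R/mGy] * DgN(E) [mGy/R].

0.114 R/mGy converts air kerma to exposure; it is stored once below.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import RangeError
from .source_spectrum import BeamlineFlux, Spectrum

#: exposure per unit air kerma, R/mGy (reciprocal: ~8.77 mGy air kerma per R)
ROENTGEN_PER_MGY_AIR_KERMA = 0.114
#: 1 gray deposits 6.241509e12 keV per gram
KEV_PER_G_PER_GRAY = 6.241509e12


def _read_two_column_csv(path_or_buffer, value_col: str):
    if hasattr(path_or_buffer, "read"):
        text = path_or_buffer.read()
    else:
        with open(path_or_buffer, "r", encoding="utf-8") as fh:
            text = fh.read()
    meta: dict[str, str] = {}
    rows = []
    header: list[str] | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
            continue
        if header is None:
            header = [c.strip() for c in line.split(",")]
            continue
        rows.append(line)
    arr = np.loadtxt(io.StringIO("\n".join(rows)), delimiter=",", ndmin=2)
    cols = {name: arr[:, i] for i, name in enumerate(header)}
    return cols["energy_keV"], cols[value_col], meta


@dataclass
class AirEnergyAbsorption:
    """Mass energy-absorption coefficient of air, cm^2/g on a keV grid."""

    energies_kev: np.ndarray
    muen_rho_cm2_g: np.ndarray

    def __post_init__(self) -> None:
        self.energies_kev = np.asarray(self.energies_kev, dtype=float)
        self.muen_rho_cm2_g = np.asarray(self.muen_rho_cm2_g, dtype=float)
        if not np.all(np.diff(self.energies_kev) > 0) or np.any(self.muen_rho_cm2_g <= 0):
            raise ValueError("air table must have an increasing grid and positive values")

    @classmethod
    def from_csv(cls, path_or_buffer) -> "AirEnergyAbsorption":
        e, v, _ = _read_two_column_csv(path_or_buffer, "muen_per_rho_cm2_g")
        return cls(e, v)

    def at(self, e_kev):
        e = np.atleast_1d(np.asarray(e_kev, dtype=float))
        if np.any(e < self.energies_kev[0]) or np.any(e > self.energies_kev[-1]):
            raise RangeError(
                f"air mass energy-absorption table covers "
                f"[{self.energies_kev[0]:g}, {self.energies_kev[-1]:g}] keV"
            )
        # log-log interpolation: muen/rho is close to a power law here
        out = np.exp(np.interp(np.log(e), np.log(self.energies_kev), np.log(self.muen_rho_cm2_g)))
        return float(out[0]) if np.ndim(e_kev) == 0 else out


@dataclass
class DgnTable:
    """Monoenergetic normalised glandular dose coefficients, mGy/R."""

    energies_kev: np.ndarray
    dgn_mgy_per_r: np.ndarray
    breast_thickness_cm: float = 4.2
    glandularity: float = 0.5

    def __post_init__(self) -> None:
        self.energies_kev = np.asarray(self.energies_kev, dtype=float)
        self.dgn_mgy_per_r = np.asarray(self.dgn_mgy_per_r, dtype=float)
        if not np.all(np.diff(self.energies_kev) > 0) or np.any(self.dgn_mgy_per_r <= 0):
            raise ValueError("DgN table must have an increasing grid and positive values")

    @classmethod
    def from_csv(cls, path_or_buffer) -> "DgnTable":
        e, v, meta = _read_two_column_csv(path_or_buffer, "dgn_mgy_per_r")
        return cls(
            e, v,
            breast_thickness_cm=float(meta.get("breast_thickness_cm", 4.2)),
            glandularity=float(meta.get("glandularity", 0.5)),
        )

    def at(self, e_kev):
        e = np.atleast_1d(np.asarray(e_kev, dtype=float))
        if np.any(e < self.energies_kev[0]) or np.any(e > self.energies_kev[-1]):
            raise RangeError(
                f"DgN table covers [{self.energies_kev[0]:g}, {self.energies_kev[-1]:g}] keV"
            )
        out = np.interp(e, self.energies_kev, self.dgn_mgy_per_r)
        return float(out[0]) if np.ndim(e_kev) == 0 else out


def load_air_table() -> AirEnergyAbsorption:
    ref = resources.files("specmammo.data").joinpath("air_muen.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return AirEnergyAbsorption.from_csv(fh)


def load_dgn_table() -> DgnTable:
    ref = resources.files("specmammo.data").joinpath("dgn_50_50_4p2cm.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return DgnTable.from_csv(fh)


def air_kerma(
    spectrum: Spectrum,
    flux: BeamlineFlux,
    exposure_s: float,
    air_table: AirEnergyAbsorption | None = None,
) -> np.ndarray:
    """Air kerma per spectrum bin, mGy.

    The bin fluence is ``weights * photons_per_second * exposure / beam_area``.
    """
    if exposure_s < 0:
        raise ValueError("exposure must be non-negative")
    if air_table is None:
        air_table = load_air_table()
    fluence = spectrum.weights * flux.photons_per_second * exposure_s / flux.beam_area_cm2
    e = spectrum.bin_energies_kev
    muen = np.atleast_1d(air_table.at(e))
    kev_per_g = e * fluence * muen
    return kev_per_g / KEV_PER_G_PER_GRAY * 1e3  # Gy -> mGy


def mgd(kerma_per_bin_mgy: np.ndarray, bin_energies_kev: np.ndarray, dgn_table: DgnTable | None = None) -> float:
    """Mean glandular dose, mGy: sum_E K(E) * 0.114 * DgN(E)."""
    if dgn_table is None:
        dgn_table = load_dgn_table()
    k = np.atleast_1d(np.asarray(kerma_per_bin_mgy, dtype=float))
    e = np.atleast_1d(np.asarray(bin_energies_kev, dtype=float))
    nz = k > 0
    dgn = np.zeros_like(k)
    if np.any(nz):
        dgn[nz] = np.atleast_1d(dgn_table.at(e[nz]))
    return float(np.sum(k * ROENTGEN_PER_MGY_AIR_KERMA * dgn))


@dataclass
class DoseReport:
    """Kerma spectrum and MGD of one acquisition."""

    bin_energies_kev: np.ndarray
    kerma_per_bin_mgy: np.ndarray
    mgd_mgy: float
    e_central_kev: float
    exposure_s: float

    @property
    def total_kerma_mgy(self) -> float:
        return float(np.sum(self.kerma_per_bin_mgy))

    def to_json(self) -> str:
        return json.dumps({
            "e_central_kev": self.e_central_kev,
            "exposure_s": self.exposure_s,
            "total_kerma_mgy": self.total_kerma_mgy,
            "mgd_mgy": self.mgd_mgy,
        })


def compute_dose(
    spectrum: Spectrum,
    flux: BeamlineFlux,
    exposure_s: float,
    air_table: AirEnergyAbsorption | None = None,
    dgn_table: DgnTable | None = None,
) -> DoseReport:
    """Air kerma plus MGD for one acquisition, as a report object."""
    k = air_kerma(spectrum, flux, exposure_s, air_table)
    return DoseReport(
        bin_energies_kev=spectrum.bin_energies_kev.copy(),
        kerma_per_bin_mgy=k,
        mgd_mgy=mgd(k, spectrum.bin_energies_kev, dgn_table),
        e_central_kev=spectrum.e_central_kev,
        exposure_s=exposure_s,
    )
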