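"""Material attenuation tables and the two-material decomposition basis.

Linear attenuation coefficients mu(E) are tabulated on an energy grid and
interpolated log-log (attenuation is close to a power law between absorption
edges).  The iodine table carries its K edge at 33.17 keV; interpolation never
crosses the edge — queries on each side use only grid points from that side.

The decomposition basis holds the four linear attenuation coefficients of
elemental iodine and calcium at the low/high beam energies.  The defaults are
the literature values used throughout this study:

    mu_I(25 keV) = 68.796 /cm    mu_I(35 keV) = 154.109 /cm
    mu_C(25 keV) = 10.650 /cm    mu_C(35 keV) =   4.097 /cm

so the basis images d_I, d_C are pure-element-equivalent thicknesses in cm.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .errors import ConfigurationError, RangeError

IODINE_K_EDGE_KEV = 33.17
#: density of solid elemental iodine, used to convert dilute solutions to
#: pure-iodine-equivalent path length
IODINE_DENSITY_G_CM3 = 4.93


def _loglog_interp(e: np.ndarray, energies: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Piecewise-linear interpolation in (log E, log value) space.

    Queries outside the grid must be guarded by the caller; values at grid
    points are reproduced exactly.
    """
    le = np.log(energies)
    lv = np.log(values)
    idx = np.searchsorted(energies, e, side="left")
    exact = (idx < len(energies)) & (energies[np.minimum(idx, len(energies) - 1)] == e)
    hi = np.clip(idx, 1, len(energies) - 1)
    lo = hi - 1
    t = (np.log(e) - le[lo]) / (le[hi] - le[lo])
    out = np.exp(lv[lo] + t * (lv[hi] - lv[lo]))
    return np.where(exact, values[np.minimum(idx, len(energies) - 1)], out)


@dataclass
class MaterialAttenuation:
    """Tabulated linear attenuation of one material.

    Parameters
    ----------
    material_name
        Label used to match phantom thickness maps to tables.
    energies
        Strictly increasing photon-energy grid in keV.
    mu_linear
        Linear attenuation coefficient per grid point, 1/cm (all positive).
    density_g_cm3
        Bulk density; informative only once ``mu_linear`` is linear.
    k_edge_kev
        Energy of an absorption-edge discontinuity inside the grid span, if
        any.  Interpolation is restricted to one side of the edge.
    """

    material_name: str
    energies: np.ndarray
    mu_linear: np.ndarray
    density_g_cm3: float | None = None
    k_edge_kev: float | None = None

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        self.mu_linear = np.asarray(self.mu_linear, dtype=float)
        if self.energies.ndim != 1 or self.energies.shape != self.mu_linear.shape:
            raise ConfigurationError("energies and mu_linear must be matching 1-D arrays")
        if not np.all(np.diff(self.energies) > 0):
            raise ConfigurationError(f"{self.material_name}: energy grid must be strictly increasing")
        if not np.all(self.mu_linear > 0):
            raise ConfigurationError(f"{self.material_name}: attenuation values must be positive")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.energies[0]), float(self.energies[-1])

    @classmethod
    def from_csv(cls, path_or_buffer, material_name: str | None = None) -> "MaterialAttenuation":
        """Read a table from CSV with '#'-comment headers.

        Recognised headers: ``material``, ``density_g_cm3``, ``k_edge_kev``.
        Columns: ``energy_keV`` and either ``mu_per_cm`` or
        ``mass_atten_cm2_g`` (the latter requires a density header and is
        converted to linear attenuation).
        """
        if hasattr(path_or_buffer, "read"):
            text = path_or_buffer.read()
        else:
            with open(path_or_buffer, "r", encoding="utf-8") as fh:
                text = fh.read()
        meta: dict[str, str] = {}
        data_lines = []
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
            data_lines.append(line)
        header = [c.strip() for c in data_lines[0].split(",")]
        arr = np.loadtxt(io.StringIO("\n".join(data_lines[1:])), delimiter=",", ndmin=2)
        cols = {name: arr[:, i] for i, name in enumerate(header)}
        density = float(meta["density_g_cm3"]) if "density_g_cm3" in meta else None
        if "mu_per_cm" in cols:
            mu = cols["mu_per_cm"]
        elif "mass_atten_cm2_g" in cols:
            if density is None:
                raise ConfigurationError("mass attenuation table requires a density_g_cm3 header")
            mu = cols["mass_atten_cm2_g"] * density
        else:
            raise ConfigurationError("table needs a mu_per_cm or mass_atten_cm2_g column")
        return cls(
            material_name=material_name or meta.get("material", "unknown").split("(")[0].strip(),
            energies=cols["energy_keV"],
            mu_linear=mu,
            density_g_cm3=density,
            k_edge_kev=float(meta["k_edge_kev"]) if "k_edge_kev" in meta else None,
        )


def load_material(name: str) -> MaterialAttenuation:
    """Load one of the packaged material tables by file stem (e.g. ``iodine``)."""
    ref = resources.files("specmammo.data").joinpath(f"{name}.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return MaterialAttenuation.from_csv(fh, material_name=name)


def mu_at(material: MaterialAttenuation, e_kev):
    """Linear attenuation (1/cm) at energy ``e_kev`` by log-log interpolation.

    Grid points reproduce their stored values exactly.  For a material with a
    K edge, queries strictly below the edge use only grid points below it (and
    vice versa), extrapolating the edge-side segment across any gap up to the
    edge rather than blending across the discontinuity.
    """
    e = np.asarray(e_kev, dtype=float)
    lo, hi = material.span
    if np.any(e < lo) or np.any(e > hi):
        raise RangeError(
            f"energy query outside {material.material_name} table span "
            f"[{lo:g}, {hi:g}] keV"
        )
    scalar = e.ndim == 0
    e = np.atleast_1d(e)
    if material.k_edge_kev is None or not (lo < material.k_edge_kev < hi):
        out = _loglog_interp(e, material.energies, material.mu_linear)
    else:
        below = material.energies < material.k_edge_kev
        out = np.empty_like(e)
        qb = e < material.k_edge_kev
        if np.any(qb):
            out[qb] = _loglog_interp(e[qb], material.energies[below], material.mu_linear[below])
        if np.any(~qb):
            out[~qb] = _loglog_interp(e[~qb], material.energies[~below], material.mu_linear[~below])
    return float(out[0]) if scalar else out


def photoelectric_scale(mu_ref: float, e_ref_kev: float, e_kev: float) -> float:
    """Scale an attenuation value between energies with the mu ~ 1/E^3 law."""
    if mu_ref <= 0 or e_ref_kev <= 0 or e_kev <= 0:
        raise ValueError("photoelectric_scale requires positive inputs")
    return mu_ref * (e_ref_kev / e_kev) ** 3


def dilute_iodine(concentration_mg_ml: float, rho_iodine_g_cm3: float = IODINE_DENSITY_G_CM3) -> float:
    """Pure-iodine-equivalent path length per cm of solution path.

    A solution of ``c`` mg/ml carries ``c`` mg of iodine per cm^2 per cm of
    path, i.e. an elemental-iodine-equivalent thickness of
    ``c [g/cm^3] / rho_iodine`` cm per cm of solution.  The solvent (water)
    is modelled separately in the forward model.
    """
    if concentration_mg_ml < 0:
        raise ValueError("iodine concentration must be non-negative")
    if rho_iodine_g_cm3 <= 0:
        raise ValueError("iodine density must be positive")
    return (concentration_mg_ml * 1e-3) / rho_iodine_g_cm3


@dataclass(frozen=True)
class DecompositionBasis:
    """Fixed linear-attenuation coefficients defining the iodine/calcium basis."""

    mu_i_low: float = 68.796
    mu_i_high: float = 154.109
    mu_c_low: float = 10.650
    mu_c_high: float = 4.097
    e_low_kev: float = 25.0
    e_high_kev: float = 35.0

    def __post_init__(self) -> None:
        if self.determinant == 0:
            raise ConfigurationError("decomposition basis is singular")

    @property
    def determinant(self) -> float:
        """mu_I(low)*mu_C(high) - mu_I(high)*mu_C(low), in 1/cm^2."""
        return self.mu_i_low * self.mu_c_high - self.mu_i_high * self.mu_c_low

    @classmethod
    def default(cls) -> "DecompositionBasis":
        return cls()

    @classmethod
    def from_tables(
        cls,
        iodine: MaterialAttenuation,
        calcium: MaterialAttenuation,
        e_low_kev: float,
        e_high_kev: float,
    ) -> "DecompositionBasis":
        return cls(
            mu_i_low=mu_at(iodine, e_low_kev),
            mu_i_high=mu_at(iodine, e_high_kev),
            mu_c_low=mu_at(calcium, e_low_kev),
            mu_c_high=mu_at(calcium, e_high_kev),
            e_low_kev=e_low_kev,
            e_high_kev=e_high_kev,
        )
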