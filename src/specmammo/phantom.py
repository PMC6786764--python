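"""Digital twin of a mammographic accreditation phantom.

The phantom is a uniform 50/50 glandular/adipose slab (default 4.2 cm of
breast-equivalent material) carrying the accreditation feature set —
microcalcification speck groups, lens-shaped tumour masses, fibres — plus a
rectangular tube of dilute iodine solution (default 1 cm x 3 cm at 6 mg/ml)
standing in for the injected contrast agent.

Geometry is two-dimensional: each material is represented by a thickness map
(cm of material along the beam) on a lateral pixel grid.  The beam is treated
as parallel (the source sits metres away from a centimetre-thick object), so
a radiograph is fully determined by these line integrals.

Masses and fibres are rendered as *excess breast-tissue thickness*: their real
counterparts attenuate almost like glandular tissue, which is exactly why they
vanish from iodine images.  Specks add to a calcium map, the tube to iodine
and water maps.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

from .attenuation import DecompositionBasis, dilute_iodine
from .errors import PlacementError

_OVERSAMPLE = 4  # sub-pixel sampling factor for feature coverage fractions


@dataclass
class Feature:
    """One placed phantom feature.

    ``kind`` is one of ``speck_group``, ``mass``, ``fiber``, ``iodine_tube``;
    ``params`` holds the kind-specific dimensions (mm unless suffixed _cm).
    """

    kind: str
    x_cm: float
    y_cm: float
    params: dict = field(default_factory=dict)


def default_features() -> list[Feature]:
    """Accreditation-style feature ladder plus the contrast-agent tube.

    Speck diameters span 0.16-0.54 mm, masses 0.25-2.0 mm, fibres
    0.4-1.56 mm; the iodine tube is 1 cm x 3 cm at the clinical 6 mg/ml.
    """
    return [
        Feature("speck_group", 0.9, 0.9, {"diameter_mm": 0.54, "thickness_mm": 0.20, "n": 6, "spread_mm": 2.5}),
        Feature("speck_group", 2.1, 0.9, {"diameter_mm": 0.32, "thickness_mm": 0.16, "n": 6, "spread_mm": 2.0}),
        Feature("speck_group", 0.9, 1.9, {"diameter_mm": 0.16, "thickness_mm": 0.12, "n": 6, "spread_mm": 1.6}),
        Feature("mass", 2.1, 2.4, {"diameter_mm": 2.0, "height_mm": 1.0}),
        Feature("mass", 1.2, 2.9, {"diameter_mm": 1.0, "height_mm": 0.5}),
        Feature("fiber", 0.7, 2.45, {"length_mm": 10.0, "width_mm": 1.56, "thickness_mm": 0.8, "angle_deg": 25.0}),
        Feature("fiber", 2.6, 1.7, {"length_mm": 8.0, "width_mm": 0.4, "thickness_mm": 0.5, "angle_deg": -40.0}),
        Feature(
            "iodine_tube", 3.9, 1.8,
            {"width_cm": 1.0, "height_cm": 3.0, "path_cm": 1.0, "concentration_mg_ml": 6.0},
        ),
    ]


@dataclass
class PhantomConfig:
    """Parameters of the synthetic phantom."""

    pixel_pitch_um: float = 71.0
    width_cm: float = 4.8
    height_cm: float = 3.6
    slab_thickness_cm: float = 4.2
    background_material: str = "breast_50_50"
    features: list[Feature] = field(default_factory=default_features)
    speck_jitter_mm: float = 0.35  # random in-group displacement of specks

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        feats = [Feature(**f) if isinstance(f, dict) else f for f in d.pop("features", [])]
        cfg = cls(**{k: v for k, v in d.items() if k != "features"})
        if feats:
            cfg.features = feats
        return cfg


@dataclass
class PhantomModel:
    """Per-material thickness maps on a lateral grid plus the feature registry."""

    pixel_pitch_cm: float
    thickness_maps: dict[str, np.ndarray]
    features: list[Feature]
    background_material: str
    slab_thickness_cm: float

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.thickness_maps.values())).shape

    @property
    def pixel_area_cm2(self) -> float:
        return self.pixel_pitch_cm**2

    def material_volumes_cm3(self) -> dict[str, float]:
        """Integral of each thickness map times pixel area."""
        return {m: float(t.sum() * self.pixel_area_cm2) for m, t in self.thickness_maps.items()}

    def tube_rect_px(self) -> tuple[int, int, int, int] | None:
        """Half-open (x0, y0, x1, y1) pixel rectangle of the iodine tube, if placed."""
        for f in self.features:
            if f.kind == "iodine_tube":
                w = f.params["width_cm"] / self.pixel_pitch_cm
                h = f.params["height_cm"] / self.pixel_pitch_cm
                cx = f.x_cm / self.pixel_pitch_cm
                cy = f.y_cm / self.pixel_pitch_cm
                return (
                    int(round(cx - w / 2)), int(round(cy - h / 2)),
                    int(round(cx + w / 2)), int(round(cy + h / 2)),
                )
        return None

    def to_tiff(self, path) -> None:
        """Multi-page float32 TIFF, one page per material, pitch in metadata."""
        import tifffile

        names = sorted(self.thickness_maps)
        stack = np.stack([self.thickness_maps[m].astype(np.float32) for m in names])
        tifffile.imwrite(
            path, stack, photometric="minisblack",
            description=json.dumps({"materials": names, "pixel_pitch_cm": self.pixel_pitch_cm}),
        )

    def registry_to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["kind", "x_cm", "y_cm", "params_json"])
            for f in self.features:
                w.writerow([f.kind, f.x_cm, f.y_cm, json.dumps(f.params)])


def _coverage(nx: int, ny: int, inside) -> np.ndarray:
    """Fractional pixel coverage of the region ``inside(x_cm_grid, y_cm_grid)``.

    Evaluated on an oversampled sub-pixel lattice and block-averaged, so the
    rendered area converges at second order in the pitch.
    """
    s = _OVERSAMPLE
    xs = (np.arange(nx * s) + 0.5) / s
    ys = (np.arange(ny * s) + 0.5) / s
    mask = inside(xs[None, :], ys[:, None]).astype(float)
    return mask.reshape(ny, s, nx, s).mean(axis=(1, 3))


def build_phantom(config: PhantomConfig, seed: int = 0) -> PhantomModel:
    """Render the phantom's per-material thickness maps.

    Deterministic for a fixed seed (the seed only jitters speck positions
    within each group).  Raises :class:`PlacementError` for features outside
    the extent and ``ValueError`` for non-positive dimensions.
    """
    if config.pixel_pitch_um <= 0 or config.width_cm <= 0 or config.height_cm <= 0:
        raise ValueError("pixel pitch and extent must be positive")
    if config.slab_thickness_cm <= 0:
        raise ValueError("slab thickness must be positive")
    pitch = config.pixel_pitch_um * 1e-4  # cm
    nx = int(round(config.width_cm / pitch))
    ny = int(round(config.height_cm / pitch))
    rng = np.random.default_rng(seed)

    maps: dict[str, np.ndarray] = {
        config.background_material: np.full((ny, nx), config.slab_thickness_cm),
    }

    def get(material: str) -> np.ndarray:
        return maps.setdefault(material, np.zeros((ny, nx)))

    def check_inside(f: Feature, half_w_cm: float, half_h_cm: float) -> None:
        if (
            f.x_cm - half_w_cm < 0 or f.x_cm + half_w_cm > config.width_cm
            or f.y_cm - half_h_cm < 0 or f.y_cm + half_h_cm > config.height_cm
        ):
            raise PlacementError(f"{f.kind} at ({f.x_cm}, {f.y_cm}) cm exceeds the phantom extent")

    def add_disc(material: str, x0: float, y0: float, radius_cm: float, thick_cm: float) -> None:
        px, py, pr = x0 / pitch, y0 / pitch, radius_cm / pitch
        cov = _coverage(nx, ny, lambda X, Y: (X - px) ** 2 + (Y - py) ** 2 <= pr**2)
        get(material)[:] += thick_cm * cov

    for f in config.features:
        p = f.params
        if f.kind != "iodine_tube" and any(
            v <= 0 for k, v in p.items() if k.endswith(("_mm", "_cm"))
        ):
            raise ValueError(f"{f.kind}: feature dimensions must be positive")
        if f.kind == "speck_group":
            r = p["diameter_mm"] / 20.0  # mm diameter -> cm radius
            spread = p["spread_mm"] / 10.0
            check_inside(f, spread / 2 + r, spread / 2 + r)
            n = int(p.get("n", 6))
            ring = np.linspace(0, 2 * np.pi, n, endpoint=False)
            jit = config.speck_jitter_mm / 10.0
            for ang in ring:
                dx = spread / 2 * np.cos(ang) + rng.uniform(-jit, jit)
                dy = spread / 2 * np.sin(ang) + rng.uniform(-jit, jit)
                add_disc("calcium", f.x_cm + dx, f.y_cm + dy, r, p["thickness_mm"] / 10.0)
        elif f.kind == "mass":
            a = p["diameter_mm"] / 20.0  # cm, lateral radius
            h = p["height_mm"] / 10.0    # cm, cap height (excess thickness at centre)
            if h > config.slab_thickness_cm:
                raise PlacementError("mass thicker than the slab")
            check_inside(f, a, a)
            rs = (a**2 + h**2) / (2 * h)  # sphere radius of the cap
            px, py, pa = f.x_cm / pitch, f.y_cm / pitch, a / pitch
            s = _OVERSAMPLE
            xs = (np.arange(nx * s) + 0.5) / s
            ys = (np.arange(ny * s) + 0.5) / s
            r2 = ((xs[None, :] - px) ** 2 + (ys[:, None] - py) ** 2) * pitch**2
            cap = np.maximum(0.0, np.sqrt(np.maximum(rs**2 - r2, 0.0)) - (rs - h))
            cap[r2 > a**2] = 0.0
            get(config.background_material)[:] += cap.reshape(ny, s, nx, s).mean(axis=(1, 3))
        elif f.kind == "fiber":
            length = p["length_mm"] / 10.0
            width = p["width_mm"] / 10.0
            thick = p["thickness_mm"] / 10.0
            half = np.hypot(length, width) / 2
            check_inside(f, half, half)
            ang = np.deg2rad(p.get("angle_deg", 0.0))
            ca, sa = np.cos(ang), np.sin(ang)
            px, py = f.x_cm / pitch, f.y_cm / pitch
            lpx, wpx = length / pitch, width / pitch

            def in_rect(X, Y, _px=px, _py=py, _ca=ca, _sa=sa, _l=lpx, _w=wpx):
                u = (X - _px) * _ca + (Y - _py) * _sa
                v = -(X - _px) * _sa + (Y - _py) * _ca
                return (np.abs(u) <= _l / 2) & (np.abs(v) <= _w / 2)

            get(config.background_material)[:] += thick * _coverage(nx, ny, in_rect)
        elif f.kind == "iodine_tube":
            w, h = p["width_cm"], p["height_cm"]
            path = p["path_cm"]
            conc = p["concentration_mg_ml"]
            if w <= 0 or h <= 0 or path <= 0 or conc < 0:
                raise ValueError("iodine tube dimensions must be positive, concentration non-negative")
            check_inside(f, w / 2, h / 2)
            px, py = f.x_cm / pitch, f.y_cm / pitch
            wpx, hpx = w / pitch, h / pitch
            cov = _coverage(
                nx, ny,
                lambda X, Y: (np.abs(X - px) <= wpx / 2) & (np.abs(Y - py) <= hpx / 2),
            )
            d_i = dilute_iodine(conc) * path
            get("iodine")[:] += d_i * cov
            # solvent: the remaining solution path is modelled as water
            get("water")[:] += (path - d_i) * cov
        else:
            raise ValueError(f"unknown feature kind {f.kind!r}")

    for m, t in maps.items():
        if m != config.background_material and np.any(t > config.slab_thickness_cm):
            raise PlacementError(f"{m} feature thickness exceeds the slab thickness")

    return PhantomModel(
        pixel_pitch_cm=pitch,
        thickness_maps=maps,
        features=list(config.features),
        background_material=config.background_material,
        slab_thickness_cm=config.slab_thickness_cm,
    )


def line_integrals(phantom: PhantomModel, basis: DecompositionBasis | None = None):
    """Ground-truth iodine/calcium equivalent thickness maps (d_I, d_C) in cm.

    These are the recovery targets for the two-material decomposition; the
    basis argument only documents which element pair the maps refer to.
    """
    zeros = np.zeros(phantom.shape)
    d_i = phantom.thickness_maps.get("iodine", zeros)
    d_c = phantom.thickness_maps.get("calcium", zeros)
    return d_i.copy(), d_c.copy()
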