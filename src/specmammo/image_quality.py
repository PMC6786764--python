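"""Image-quality metrics: ROI-based CNR and power-spectrum spatial resolution.

CNR follows the three-ROI convention: the mean over a signal ROI minus the
mean over a reference ROI, divided by the sample standard deviation over a
feature-free background ROI,

    CNR = (S1_mean - S2_mean) / sigma_BG.

Spatial resolution is estimated from the radially averaged 2-D power
spectrum, lightly smoothed in the frequency plane: the reported resolution is
the highest spatial frequency (lp/mm) at which the spectral power still
reaches twice the noise baseline, the baseline being the median power over
the top decile of frequencies below Nyquist.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import NoSignalError, NoSignalWarning, UndefinedCnrError


@dataclass(frozen=True)
class Roi:
    """Half-open pixel rectangle [x0, x1) x [y0, y1), 0-based."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError("ROI must be non-empty")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("ROI coordinates must be non-negative")

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.y0, self.y1), slice(self.x0, self.x1)

    @property
    def n_pixels(self) -> int:
        return (self.x1 - self.x0) * (self.y1 - self.y0)

    def overlaps(self, other: "Roi") -> bool:
        return not (self.x1 <= other.x0 or other.x1 <= self.x0
                    or self.y1 <= other.y0 or other.y1 <= self.y0)

    @classmethod
    def from_dict(cls, d: dict) -> "Roi":
        return cls(int(d["x0"]), int(d["y0"]), int(d["x1"]), int(d["y1"]))


@dataclass(frozen=True)
class RoiSet:
    """Signal / reference / noise ROI triplet for one CNR measurement."""

    signal: Roi
    reference: Roi
    noise: Roi

    def __post_init__(self) -> None:
        if self.signal.overlaps(self.noise) or self.reference.overlaps(self.noise):
            raise ValueError("signal and reference ROIs must not overlap the noise ROI")

    def check_inside(self, shape: tuple[int, int]) -> None:
        ny, nx = shape
        for name, roi in (("signal", self.signal), ("reference", self.reference), ("noise", self.noise)):
            if roi.x1 > nx or roi.y1 > ny:
                raise ValueError(f"{name} ROI exceeds the image extent {nx}x{ny}")

    @classmethod
    def from_dict(cls, d: dict) -> "RoiSet":
        return cls(Roi.from_dict(d["signal"]), Roi.from_dict(d["reference"]), Roi.from_dict(d["noise"]))

    def to_dict(self) -> dict:
        return {name: vars(roi) for name, roi in
                (("signal", self.signal), ("reference", self.reference), ("noise", self.noise))}


def _values(image, roi: Roi) -> np.ndarray:
    arr = np.ma.asarray(image)[roi.slices]
    return np.ma.compressed(arr) if np.ma.is_masked(arr) else np.asarray(arr).ravel()


def cnr(image, rois: RoiSet) -> float:
    """Contrast-to-noise ratio of ``image`` for the given ROI triplet."""
    rois.check_inside(np.asarray(image).shape)
    noise_vals = _values(image, rois.noise)
    if noise_vals.size < 2:
        raise UndefinedCnrError("noise ROI needs at least 2 pixels")
    sigma = noise_vals.std(ddof=1)
    if sigma == 0:
        raise UndefinedCnrError("noise ROI is constant; CNR undefined")
    return float((_values(image, rois.signal).mean() - _values(image, rois.reference).mean()) / sigma)


def _split(roi: Roi, n: int) -> list[Roi]:
    """Split a ROI into ``n`` blocks along its longer axis."""
    w, h = roi.x1 - roi.x0, roi.y1 - roi.y0
    along_x = w >= h
    length = w if along_x else h
    if length < n:
        raise ValueError(f"ROI of extent {length} px cannot be split into {n} blocks")
    edges = np.linspace(0, length, n + 1).round().astype(int)
    out = []
    for a, b in zip(edges[:-1], edges[1:]):
        if along_x:
            out.append(Roi(roi.x0 + a, roi.y0, roi.x0 + b, roi.y1))
        else:
            out.append(Roi(roi.x0, roi.y0 + a, roi.x1, roi.y0 + b))
    return out


def cnr_uncertainty(image, rois: RoiSet, n_splits: int = 4) -> float:
    """Standard error of the CNR from sub-block resampling.

    Each ROI is cut into ``n_splits`` blocks along its longer axis; the CNR is
    recomputed per block triplet and the standard error across blocks is
    returned.  Deterministic for fixed inputs.
    """
    if n_splits < 2:
        raise ValueError("CNR uncertainty needs at least 2 sub-blocks")
    triplets = zip(_split(rois.signal, n_splits), _split(rois.reference, n_splits), _split(rois.noise, n_splits))
    sub = [cnr(image, RoiSet(s, r, n)) for s, r, n in triplets]
    return float(np.std(sub, ddof=1) / np.sqrt(n_splits))


def resolution_power_spectrum(image, pixel_pitch_um: float, smoothing: float = 0.9) -> float:
    """Spatial resolution in lp/mm from the radially averaged power spectrum.

    The 2-D power spectrum |FFT|^2 of the mean-subtracted image is smoothed
    with a Gaussian of ``smoothing`` frequency-grid pixels, radially averaged,
    and compared against a noise baseline (median power over the top decile of
    radial frequencies below Nyquist).  The resolution is the highest radial
    frequency whose power reaches twice the baseline, beyond which no bin does
    — isolated noisy bins above the cut do not extend the estimate.

    If no frequency clears the threshold (e.g. pure white noise), the lowest
    radial bin is returned with a :class:`NoSignalWarning`.
    """
    img = np.ma.filled(np.ma.asarray(image, dtype=float), np.nan)
    if img.ndim != 2 or min(img.shape) < 64:
        raise NoSignalError("resolution estimate needs a 2-D image of at least 64x64 pixels")
    if np.any(np.isnan(img)):
        img = np.where(np.isnan(img), np.nanmean(img), img)
    if pixel_pitch_um <= 0:
        raise ValueError("pixel pitch must be positive")
    if np.ptp(img) == 0:
        raise NoSignalError("constant image has no spectral content")

    power = np.abs(np.fft.fftshift(np.fft.fft2(img - img.mean()))) ** 2
    power = ndimage.gaussian_filter(power, sigma=smoothing, mode="wrap")

    ny, nx = img.shape
    fy = np.fft.fftshift(np.fft.fftfreq(ny))[:, None]
    fx = np.fft.fftshift(np.fft.fftfreq(nx))[None, :]
    fr = np.hypot(fy, fx)  # cycles per pixel

    n_bins = min(ny, nx) // 2
    bin_width = 0.5 / n_bins
    idx = np.minimum((fr / bin_width).astype(int), n_bins)  # last bin collects > Nyquist
    counts = np.bincount(idx.ravel(), minlength=n_bins + 1)[:n_bins]
    sums = np.bincount(idx.ravel(), weights=power.ravel(), minlength=n_bins + 1)[:n_bins]
    profile = sums / np.maximum(counts, 1)
    freqs = (np.arange(n_bins) + 0.5) * bin_width

    # skip the DC-adjacent bin: it holds residual mean/trend power
    valid = slice(1, n_bins)
    top = freqs >= 0.9 * 0.5
    baseline = float(np.median(profile[top]))
    above = profile[valid] >= 2.0 * baseline
    to_lpmm = 1000.0 / pixel_pitch_um  # cycles/px -> lp/mm

    if not np.any(above):
        warnings.warn("no frequency band exceeds twice the noise baseline", NoSignalWarning)
        return float(freqs[1] * to_lpmm)
    last = np.nonzero(above)[0][-1] + 1  # offset for skipped DC bin
    return float(freqs[last] * to_lpmm)


def nyquist_lp_mm(pixel_pitch_um: float) -> float:
    """Nyquist frequency for a given pixel pitch, lp/mm."""
    return 1000.0 / (2.0 * pixel_pitch_um)


@dataclass
class QualityReport:
    """CNR and resolution of one image."""

    cnr: float
    resolution_lp_mm: float
    pixel_pitch_um: float
    cnr_se: float | None = None
    label: str = ""
    mgd_mgy: float | None = None

    def to_json(self) -> str:
        return json.dumps({
            "label": self.label, "cnr": self.cnr, "cnr_se": self.cnr_se,
            "resolution_lp_mm": self.resolution_lp_mm,
            "pixel_pitch_um": self.pixel_pitch_um, "mgd_mgy": self.mgd_mgy,
        })

    def csv_row(self) -> str:
        se = "" if self.cnr_se is None else f"{self.cnr_se:.4g}"
        mgd = "" if self.mgd_mgy is None else f"{self.mgd_mgy:.6g}"
        return f"{self.label},{mgd},{self.cnr:.4f},{se},{self.resolution_lp_mm:.3f}"
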