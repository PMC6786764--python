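# Methods

This note documents the models behind `specmammo`, the defaults and why they
were chosen, the numerical conventions, and what the simulation does and does
not capture about real contrast-enhanced spectral mammography (CESM) data.

## Phantom model

The synthetic object is a two-dimensional field of per-material thickness
maps (cm of material along the beam) on a lateral grid — a parallel-beam
idealisation justified by the geometry it emulates (source–detector distance
of metres against a centimetre-thick object, so cone-beam magnification is
below the pixel scale).

Defaults:

| parameter | default | unit | rationale |
|---|---|---|---|
| pixel pitch | 71 | µm | effective pixel of the flat-panel detector modelled |
| extent | 4.8 × 3.6 | cm | covers the feature region plus the contrast tube |
| slab | 4.2 cm of 50/50 glandular/adipose | — | compressed-breast equivalent of the accreditation phantom; thickness is a configurable assumption, matched to the DgN table |
| specks | discs, ⌀ 0.16–0.54 mm, calcium | — | microcalcification ladder; exact commercial dimensions are not public, so a configurable ladder is used |
| masses | spherical caps, ⌀ 0.25–2.0 mm, excess tissue | — | tumour simulants attenuate nearly like glandular tissue, which is why they vanish from iodine images; modelling them as excess slab material encodes that directly |
| fibres | rotated rectangles, 0.4–1.56 mm wide, excess tissue | — | fibrous-structure ladder |
| iodine tube | 1 × 3 cm rectangle, 6 mg/ml over a 1 cm internal path | — | clinical contrast concentration; the tube contributes an elemental-iodine-equivalent column c/ρ_I (ρ_I = 4.93 g/cm³, configurable) plus water for the remaining solution path |

Features are rendered with 4× sub-pixel supersampling so that material
volume converges at second order in the pitch (the volume-conservation test
checks < 1 % drift between pitch h and h/2). The only randomness is a small
in-group jitter of speck positions, controlled by the build seed.

What the generator deliberately does **not** emulate: anatomical texture
(the background is uniform, so background ROIs contain pure counting noise),
scatter, compression mechanics, and 3-D structure. Consequences for
interpreting results are noted under Limitations.

## Source and forward model

Beam lines are Gaussian in energy, truncated at ±3σ and renormalised; only
the central energy and FWHM are physically constrained (25 keV / 0.89 keV
and 35 keV / 1.50 keV by default), and attenuation varies slowly over a
few-percent bandwidth, so the exact line shape is immaterial downstream (the
quasi-monochromatic log-attenuation differs from the monochromatic one by
< 0.5 % on the default phantom; a delta spectrum reproduces monochromatic
Beer–Lambert exactly). The published source bandwidth percentages are not
numerically consistent with FWHM/E; the FWHM values are taken as
authoritative. The inverse-Compton energy relation E_x = 4γ²E_L is provided
for tuning calculations; storage-ring physics is out of scope.

Expected counts per pixel are

    N = t · Φ · A_px · η · Σ_E w(E) · exp(−Σ_m μ_m(E) d_m),

with flux Φ = 3.0×10¹⁰ photons/s into an elliptical 6.2 × 7.4 cm footprint
by default, η an optional scalar detector efficiency, and Poisson sampling
behind an explicit seed. The detector is otherwise ideal: no scintillator
blur, glare, or electronic noise. Images are corrected as
(raw − dark)/(flat − dark); the default flat-field reference is 6 cm of
PMMA, matching the experimental protocol this emulates, so log-attenuation
maps are relative to that reference (a uniform offset that cancels in every
difference-based metric). Log-attenuation of non-positive pixels is masked
and reported, never silently NaN.

## Attenuation data

Material tables (CSV, 15–40 keV) are interpolated log-log, since attenuation
is near power-law between edges. The iodine table carries its K edge at
33.17 keV with grid points on each side; queries never interpolate across
the discontinuity — each side extrapolates its own segment up to the edge.
The four basis coefficients

    μ_I(25) = 68.796, μ_I(35) = 154.109, μ_C(25) = 10.650, μ_C(35) = 4.097 cm⁻¹

are exact grid entries (and the `DecompositionBasis` defaults), so basis
images are elemental-equivalent thicknesses in cm. The remaining table
values are generated from a two-term photoelectric-plus-Compton
parametrisation (a·E⁻³ + b, or anchored power laws for iodine) fitted to
reference-scale linear attenuation values; they are physically plausible
rather than certified reference data, which suffices because no result
depends on their magnitudes beyond the four anchored coefficients.

## Recombination

KES multiplies the *low*-energy log-attenuation by (E_low/E_high)³ before
subtracting it from the high-energy map. That direction is forced by the
physics: it is the only one for which a purely photoelectric (μ ∝ E⁻³)
background cancels identically. Tissue deviates from the cube law through
its Compton component and leaves a uniform residual; no additional empirical
flattening is applied. The decomposition solves the 2×2 system per pixel by
the closed-form inverse (determinant −1359.4 cm⁻²). Noise can drive basis
thicknesses negative; they are retained unclipped by default because
clipping would bias every downstream noise statistic (a clipped copy exists
for display).

## Dosimetry

Air kerma per bin is K(E) = E·Φ(E)·(μ_en/ρ)_air(E), converted via
6.241509×10¹² keV/g per gray; MGD = Σ K(E)·0.114·DgN(E), with the
0.114 R/mGy exposure conversion stored in exactly one place. The DgN fixture
(4.2 cm, 50 % glandularity) is a plausible monotone table; tests exercise
the arithmetic of the chain, not DgN magnitudes, and user tables are
accepted. Per-pair dose is booked as the sum of the two acquisitions' MGDs.

## Image metrics

CNR uses the three-ROI convention with the sample standard deviation
(ddof 1) of a feature-free background ROI; it is invariant under affine
intensity rescaling. Its uncertainty is estimated by cutting each ROI into
n sub-blocks along its longer axis and taking the standard error of the
per-block CNRs — this consistently estimates the replicate spread of the
full-ROI CNR and is approximately independent of n (the per-block spread
grows as √n and the 1/√n of the standard error cancels it).

The resolution estimator: 2-D power spectrum of the mean-subtracted image,
Gaussian-smoothed with σ = 0.9 frequency-grid pixels (exposed as a
parameter, since "kernel of 0.9" admits readings), radially averaged into
min(N)/2 bins; the noise baseline is the median power over the top decile of
frequencies below Nyquist (median for robustness against residual signal);
the resolution is the highest radial frequency whose smoothed power still
reaches twice that baseline, reported in lp/mm via the pixel pitch and
bounded by Nyquist (7.04 lp/mm at 71 µm) by construction. A flat spectrum
(no band-limited signal) returns the lowest bin with an explicit warning.
The DC-adjacent bin is excluded: it holds residual mean/trend power.

## Statistics

Spearman's r is the Pearson correlation of mean ranks (scipy); its
significance uses t = r√(n−2)/√(1−r²) against the two-sided α = 0.05
Student-t critical value (the tabulated values this reproduces — 2.262,
2.080, 2.447 — are two-sided at df 9/21/6). |r| = 1 yields an infinite
statistic by convention rather than an error. Kruskal–Wallis H is computed
from the printed rank-sum formula with mean ranks for ties and **no** tie
correction by default, matching that formula exactly; the tie-corrected
variant (which scipy applies unconditionally) is behind a flag and both are
cross-checked in tests. The dose–CNR model CNR = a√MGD has no intercept —
σ of log-attenuation is 1/√counts, so CNR grows with the root of exposure
and vanishes at zero dose; an intercept variant exists but is non-default.
Matched-CNR dose ratios between methods are (a₂/a₁)², independent of the
chosen CNR level.

## Noise analysis of the two recombinations

Both iodine images are fixed linear combinations w·(A_low, A_high) with
independent Poisson noise diag(1/I_low, 1/I_high). For the fixed basis
above, KES uses w = (−0.364, 1) and the decomposition's d_I uses
w ∝ (μ_C,high, −μ_C,low). Propagating both gives

    CNR_MD / CNR_KES = (s_MD/s_KES) · √((x + 0.1328)/(x + 0.1480)),
    x = σ²_high/σ²_low,

where the signal ratio s_MD/s_KES ≤ 0.96 for an iodine or iodine-plus-water
column. The ratio therefore lies in (0.90, 0.96) for *every* exposure split:
under pure Poisson noise, KES is marginally the better-matched filter for
this signal, and the simulation reproduces exactly that. An observed
advantage of the decomposition on real devices must come from effects this
model idealises away — structured backgrounds and flat-field residuals
(which inflate σ_BG for the incompletely-cancelling KES image), electronic
noise, and proprietary recombination processing. This is the main caveat
when transferring conclusions from the synthetic study to measured data, and
it is why the method-ordering acceptance check fails honestly under this
model.

## Problem sizes

The default phantom is 676 × 507 px (4.8 × 3.6 cm at 71 µm); the test suite
uses a coarser 243 × 186 px configuration (140 µm pitch) and 7–9 spectrum
bins, sizes chosen so the full chain (including the 8-rung ladder and the
Poisson-law replicates at 10³–10⁵ counts × 2×10⁴ samples) completes in
seconds while leaving every statistical tolerance comfortably resolved.
Expectation maps are computed once per energy and scaled linearly with
exposure before sampling, since the Poisson mean is linear in time.

## Known limitations

- No scatter, beam hardening, detector blur/MTF, glare or electronic noise;
  resolution estimates on simulated images reflect phantom structure and
  sampling, not detector physics.
- Uniform background: CNR and the KES/decomposition comparison exclude
  anatomical clutter, the regime where the two methods differ most on real
  data (see the noise analysis above).
- Attenuation and DgN tables are parametrised stand-ins anchored to the four
  mandated basis coefficients, not certified reference datasets.
- Absolute MGD depends on the per-scan flux calibration of the real
  beamline, which is not public; with the nominal source parameters the
  simulated dose rate is a factor of a few below the published dose ladder,
  and all dose comparisons here are ratio-based.
- Two-material decomposition only; a third basis material (e.g. water) or
  regularised decompositions are out of scope.
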