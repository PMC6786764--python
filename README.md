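# specmammo

Dual-energy spectral mammography simulation and analysis: K-edge subtraction
versus two-material decomposition for contrast-enhanced breast imaging with
quasi-monochromatic X-rays.

## The problem

Contrast-enhanced spectral mammography (CESM) images an iodinated contrast
agent by acquiring two radiographs — one with mean energy below and one above
the iodine K edge at 33.17 keV — and recombining them so that breast tissue
cancels and only the iodine signal remains. The clinical recombination is a
K-edge subtraction (KES); an alternative is a two-material basis
decomposition, which promises cleaner separation of iodine from
microcalcifications and a lower mean glandular dose (MGD) at equal image
quality. Comparing the two fairly requires controlling the beam spectrum, the
dose bookkeeping, and the noise statistics — which is exactly what a
simulation can hold fixed.

This package is a desk-scale digital twin of such a benchmarking study, for
medical-physics researchers who want to study the recombination algebra, its
noise propagation and its dose trade-offs without beam time. It provides:

- a **digital accreditation phantom**: a 4.2 cm 50/50 glandular/adipose slab
  with speck groups (calcium), lens-shaped masses, fibres, and a 1 cm x 3 cm
  tube of 6 mg/ml iodine solution, rendered as per-material thickness maps;
- a **quasi-monochromatic source model** (Gaussian lines at 25 keV,
  FWHM 0.89 keV, and 35 keV, FWHM 1.50 keV, plus the inverse-Compton energy
  relation `E_x = 4 γ² E_L`);
- a **forward model**: spectrum-weighted Beer–Lambert transmission onto a
  71 µm photon-counting detector with Poisson noise, dark-current subtraction
  and flat-field correction against a 6 cm PMMA reference;
- both **recombinations** on log-attenuation maps `A = −ln(I/I₀)`:

  KES with the empirical photoelectric correction,

      iodine_signal = A_high − (E_low/E_high)³ · A_low,

  and the per-pixel two-material solve

      A_low  = μ_I(25 keV)·d_I + μ_C(25 keV)·d_C
      A_high = μ_I(35 keV)·d_I + μ_C(35 keV)·d_C

  with the fixed elemental basis μ_I = 68.796 / 154.109 cm⁻¹ and
  μ_C = 10.650 / 4.097 cm⁻¹, yielding iodine- and calcium-equivalent
  thickness maps (d_I, d_C) in cm;
- **dosimetry**: air kerma per energy bin
  `K(E) = E · Φ(E) · (μ_en/ρ)_air(E)` and
  `MGD = Σ_E K(E) · 0.114 · DgN(E)` with monoenergetic normalised glandular
  dose coefficients;
- **image metrics**: three-ROI CNR `(S̄₁ − S̄₂)/σ_BG` and a power-spectrum
  resolution estimate in lp/mm;
- the **statistical layer**: Spearman rank correlation with its t test
  `t = r·√(n−2)/√(1−r²)`, Kruskal–Wallis H against χ² critical values, and
  zero-intercept root fits `CNR = a·√MGD` whose intersections give
  matched-CNR dose ratios between methods.

## Worked example

The analysis drivers under `analysis/` run the study in sequence. Building
the phantom and simulating the 8-rung exposure ladder
(`python analysis/01_build_phantom.py && python analysis/02_run_experiment.py`)
prints:

```
phantom grid: 676 x 507 px at 71 um (4.8 x 3.6 cm)
iodine-equivalent thickness inside the tube: 1.2170 x 10^-3 cm (6 mg/ml over a 1 cm path)
simulated 8 exposure rungs (25/35 keV pairs)
pair MGD range: 0.0532 - 0.532 mGy
  low        CNR   33.9 -  103.5
  kes_iodine CNR   19.3 -   61.3
  md_iodine  CNR   18.2 -   57.8
```

The tube's iodine column is the 6 mg/ml concentration divided by the density
of solid iodine (0.006/4.93 cm per cm of path); CNR values in the tens and a
pair dose of a few tenths of a mGy are the ranges one expects from a
compact-synchrotron acquisition at these exposures. The statistics driver
(`python analysis/03_dose_cnr_statistics.py`) then reports:

```
method       n   r      t_calc  t_crit  correlated  fit a
low           8   1.00     inf  2.447  yes         188.74
kes_iodine    8   1.00     inf  2.447  yes          84.34
md_iodine     8   1.00     inf  2.447  yes          79.56
Kruskal-Wallis across methods: H = 7.34 (df 2, chi2 crit 5.99) -> methods differ
dose needed for equal iodine-image CNR, decomposition vs KES: 1.124
```

CNR correlates perfectly with dose in this noise-controlled simulation
(Spearman r = 1, so the t statistic is unbounded), the three methods differ
as groups (H = 7.34 > 5.99), and each series is summarised by its root-fit
coefficient `a`. The matched-CNR dose ratio — `(a_KES/a_MD)²` — quantifies
the dose a method needs to reach a reference CNR: under pure Poisson noise
the decomposition needs ~12% *more* dose than KES, because with this fixed
basis KES is marginally the better-matched linear filter for an
iodine-plus-water signal; see `docs/methods.md` for the derivation and for
which real-detector effects this idealised model leaves out.
`analysis/04_dose_cnr_figure.py` draws the corresponding dose–CNR plot.

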