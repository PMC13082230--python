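# Methods

## Pipeline overview

`sipraman` operationalizes ¹³C stable-isotope probing with single-cell
Raman spectroscopy as a four-stage computational pipeline:

1. **Preprocessing** — resample each cell's spectrum to a uniform
   wavenumber grid, crop to the 500–1800 cm⁻¹ fingerprint region, subtract
   a slowly varying baseline, and normalize.
2. **Band fitting** — locate and refine the five biomarker bands
   (cytochrome c quartet plus phenylalanine ring breathing) inside
   per-band search windows.
3. **Shift quantification** — convert fitted centers into redshifts
   `delta = c12 − ĉ` and per-band labeling fractions.
4. **Classification** — apply the sorting rule that defines an active
   carbon fixer.

A synthetic-spectrum generator provides the test substrate, since no
instrument spectra are publicly available for this system.

## Preprocessing

*Grid.* 1 cm⁻¹ spacing, finer than the ~3 cm⁻¹ spectral resolution of the
emulated confocal system, so grid quantization never dominates shift
estimates. The working region is 500–1800 cm⁻¹; spectra acquired over the
wider 500–3200 cm⁻¹ range are cropped.

*Baseline.* Asymmetric least squares (AsLS): minimize
Σ wᵢ(yᵢ−zᵢ)² + λ Σ(Δ²z)² with w = p above the current baseline estimate
and 1−p below. Defaults λ = 1e5, p = 0.01, 10 reweighting iterations —
the de facto standard for fluorescence-dominated microbial Raman baselines
on a ~1 cm⁻¹ grid. The estimated baseline is retrievable
(`estimate_baseline`); non-convergence sets a warning flag on the output
rather than raising, because a slightly unconverged baseline is still
usable. The local linear term in the band-fit model absorbs any small
residual.

*Normalization.* ℓ2 (unit Euclidean norm) over the cropped region by
default, making downstream classification invariant to laser power,
focus, and integration time. `area` and `max` are available.

*Averaging.* Cohort mean spectra carry a pointwise population-SD envelope
(`MeanSpectrum`); with ~50 cells per group the population/sample SD
distinction is negligible, and population SD makes the n = 1 edge case
well defined.

*Despiking* (median filter) exists but is off by default: cosmic-ray
artifacts are instrument-specific and the synthetic substrate does not
produce them.

## Band fitting

Each band's search window is `[c13 − w, c12 + w]` with w = 10 cm⁻¹ —
wide enough to catch jittered peaks anywhere along the isotopic
trajectory, narrow enough to exclude the non-shifting cellular background
bands at 1240, 1450, and 1664 cm⁻¹.

Apex candidates are local maxima of a Savitzky–Golay-smoothed copy
(7 cm⁻¹ window, order 2) of the window signal. The fit **fails** (recorded,
never dropped) when no candidate's prominence exceeds 3× the local noise
estimate — the robust SD (1.4826·MAD) of the raw-minus-smoothed residual.
The tallest candidate is refined by least squares with a pseudo-Voigt
profile (fixed 50 % Lorentzian fraction) plus a local linear background,
over a sub-window of ±1.5 estimated FWHM around the apex; a three-point
parabolic apex interpolation is the fallback when least squares fails,
flagged in `BandFit.method`.

Two guards keep misassignment visible instead of silently corrected: a
refined center outside the search window, or a refined FWHM below the
3 cm⁻¹ instrument resolution (no real band can appear narrower; such fits
are noise artifacts), both mark the fit unsuccessful. A secondary smoothed
maximum above 50 % of the primary sets `bimodal_flag`, signalling two
coexisting isotopic sub-populations in the window; callers should then
prefer the decomposition estimator.

## Labeling-fraction estimators

*Position* (default, matches the single-migrating-peak phenomenology):
`f = (c12 − ĉ)/(c12 − c13)`, clamped to [0, 1] with out-of-range fits
flagged. It is exact when a band shifts continuously with isotopic
content, as observed for phenylalanine between 1002 and 965 cm⁻¹ under
partial labeling.

*Decomposition*: non-negative least squares of each band window onto the
¹²C endmember, the ¹³C endmember, and a constant (both signs), with
`f = a13/(a12 + a13)`; undefined (NaN, flagged) when both coefficients
vanish. Correct when a window holds an intensity-weighted mixture of the
two endmember bands — two sub-populations of molecules rather than one
shifted band.

Per-cell summaries (`CellShiftProfile.mean_f`) average the per-band
estimates over required bands with defined values; band-to-band errors are
nearly independent, so the average is substantially more precise than any
single band.

## Classification

A band counts as *shifted* iff its fit succeeded and `delta ≥ delta_min`.
Default `delta_min = 5 cm⁻¹`: above the ~3 cm⁻¹ resolution (sub-resolution
jitter can never count), below 6 cm⁻¹, the smallest shift observed for any
biomarker band (δ(C–H) of strain TX1, 1312 → 1306 cm⁻¹). A cell is
**active** iff all four required Cyt c bands shifted and — by default —
the phenylalanine band as well (`require_phe=False` gives the
quartet-only rule). Failed fits count as not shifted: a cell missing the
phenylalanine window cannot be called active under the default rule.

Three band tables are packaged. `reference_strains` (the default) carries
the pure-strain positions; `sediment_enrichment` and `strain_TX1` carry
the environmental variants. Where summary text lists slightly different
Cyt c positions (749/1129/1312/1589 cm⁻¹), the packaged defaults use the
measurement-anchored values that all reported shifts refer to, with the
alternatives recorded in the table notes. The TX1 ¹³C positions are
observed values under incomplete labeling (the phenylalanine entry is
flagged `observed_partial`), not fully-labeled endmembers; fraction
estimates against that table are relative to the observed endpoint.

## Synthetic-data generator

Each cell is a sum of pseudo-Voigt bands (50 % Lorentzian), a background,
and a baseline, convolved with a Gaussian instrument response of 3 cm⁻¹
FWHM, plus additive white Gaussian noise:

* **Biomarker bands** at the table positions; in `interpolate` mode each
  band sits at `(1−f)·c12 + f·c13` (default, matching observed
  intermediate peaks), in `two_population` mode at the two endmember
  positions with weights `(1−f, f)`. The modes coincide bit-for-bit at
  f = 0 and f = 1.
* **Widths** 12 cm⁻¹ (Cyt c) and 8 cm⁻¹ (phenylalanine): unreported for
  the real instrument; chosen clearly above the resolution and narrow
  enough to keep the 1002/965 cm⁻¹ pair resolvable.
* **Relative amplitudes** 1.0/0.6/0.7/0.9 (Cyt c quartet), 0.5
  (phenylalanine), reflecting resonance enhancement of Cyt c; background
  bands 1240/1450/1664 cm⁻¹ at 0.2/0.3/0.3 with 18 cm⁻¹ width. All
  configurable; none are measured values.
* **Background bands do not shift with f** by default — they act as
  confounders for window isolation; a flag lets them co-shift for
  robustness testing.
* **Baseline**: broad Gaussian hump (center 1200 cm⁻¹, FWHM 1500 cm⁻¹,
  amplitude 2× the tallest band) plus a linear ramp (1e-3 of the tallest
  band per cm⁻¹), emulating cellular autofluorescence.
* **Cell-to-cell variability**: per-band center jitter (SD 0.5 cm⁻¹, well
  under the resolution) and lognormal amplitude spread (CV 0.1) — modest
  values representing reproducible band positions across a cohort.
* **Noise**: `snr` is the ratio of the tallest nominal band amplitude to
  the additive noise SD; `inf` gives noiseless spectra.
* **Grid**: 500–3200 cm⁻¹ at 1 cm⁻¹, the emulated acquisition range.
* **Seeding**: one integer seed; each cell draws from a substream derived
  from (seed, cell index), so cohorts are bit-reproducible and insensitive
  to generation order. Cells are active with probability
  `active_fraction`; actives draw f from a constant, uniform, or beta
  specification, inactives have f = 0. Ground truth (activity, f, jittered
  centers) accompanies every cohort.

What the generator does **not** emulate: cosmic-ray spikes, detector
etaloning, wavenumber miscalibration, cell-to-cell variation in band
*shape*, Mie scattering distortions, spectral contributions of other
biomolecules beyond the three background bands, and any coupling between
activity and overall signal strength. Passing tests therefore demonstrate
correctness of the algorithms under the stated generative model, not
instrument-grade robustness.

## Numerical choices and degenerate inputs

* Spectra need ≥ 2 points (≥ 16 for baseline correction); axes must be
  strictly increasing and finite; duplicate (cell, wavenumber) rows are
  rejected at read time.
* Resampling refuses extrapolation; the pipeline intersects the working
  grid with each cell's measured range instead of rejecting narrow
  acquisitions.
* Normalizing an identically zero spectrum is an error (there is no scale
  to recover), while baseline-correcting it is a no-op.
* Fraction estimates are clamped to [0, 1] with the clamped bands listed
  in the profile; a failed fit has no delta and no fraction.
* Bimodal windows report the taller smoothed apex; ties fall to the first
  maximum found on the grid.
* Problem sizes in the test suite (cohorts of 10–50 cells per condition,
  100-cell operating-characteristic cohorts) are chosen so the full suite
  completes in well under a minute per module while keeping binomial
  noise on rate estimates small at the asserted thresholds.

## Known limitations

* The preprocessing conventions (AsLS parameters, ℓ2 normalization) are
  community practice, not measured properties of any particular
  instrument; real deployments should calibrate them and can set every
  value via `PreprocessConfig` or CLI flags.
* The position estimator assumes band centers move linearly with isotopic
  content; real mode mixing can make the trajectory slightly nonlinear,
  biasing intermediate f estimates.
* The decomposition estimator needs endmember spectra on the working grid;
  with only partially labeled material available (as for strain TX1), the
  fully labeled endmember is unknown and fractions are relative.
* Classification treats bands independently; correlated baseline artifacts
  spanning several windows could in principle defeat the 4-band
  simultaneity requirement in either direction at very low SNR.
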