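# sipraman

Single-cell stable-isotope-probing (SIP) Raman analysis: detect
¹³C-induced redshifts of cytochrome c and phenylalanine Raman bands in
single-cell spectra, quantify per-cell labeling fractions, and apply a
sorting criterion that flags actively carbon-fixing chemoautotrophs.

## The problem

Chemoautotrophic bacteria fix inorganic carbon in dark environments such as
coastal sediments, but most are uncultured and their in-situ activity is
invisible to sequencing alone. When cells are incubated with
¹³C-bicarbonate, carbon fixed into biomass replaces ¹²C with the heavier
isotope, lowering the vibrational frequencies of carbon-containing bonds
and redshifting specific Raman bands. Because cytochrome c (Cyt c) is
resonance-enhanced at 532 nm excitation, its four bands dominate the
single-cell spectrum and make particularly sensitive reporters:

| band | mode | ¹²C position | fully ¹³C-labeled |
|---|---|---|---|
| pyrrole breathing | — | 747 cm⁻¹ | 725 cm⁻¹ |
| ν(C–N) | stretch | 1125 cm⁻¹ | 1115 cm⁻¹ |
| δ(C–H) | bend | 1312 cm⁻¹ | 1300 cm⁻¹ |
| ν(C–C) | stretch | 1584 cm⁻¹ | 1536 cm⁻¹ |
| phenylalanine ring breathing | — | 1002 cm⁻¹ | 965 cm⁻¹ |

A cell is classified as an **active carbon fixer** when all four Cyt c
bands — and, under the default rule, phenylalanine as well — show a
simultaneous redshift of at least `delta_min = 5 cm⁻¹` relative to the ¹²C
reference positions (above the ~3 cm⁻¹ spectral resolution, below the
smallest biomarker shift of 6 cm⁻¹).

Partial labeling produces intermediate band positions; the **labeling
fraction** is estimated per band as

    f = (c12 − ĉ) / (c12 − c13),   clamped to [0, 1],

where ĉ is the fitted band center, or alternatively by non-negative
least-squares unmixing of each band window onto the ¹²C/¹³C endmember
spectra (`f = a13 / (a12 + a13)`) when a window holds two coexisting
sub-populations.

No public single-cell spectra exist for this system, so the package ships a
seeded synthetic-spectrum generator (`sipraman.simulate`) reproducing the
band structure, isotope shifts, instrument resolution, autofluorescence
baseline, and cohort structure — the controlled test substrate for the
whole pipeline.

## Worked example

```python
import sipraman as sr

table = sr.load_band_table("reference_strains")
cfg = sr.SimConfig(band_table=table, n_cells=10, label_fraction=1.0,
                   active_fraction=1.0, snr=30.0, seed=42)
cohort, truth = sr.simulate_cohort(cfg)

for cell in cohort:
    prepped = sr.preprocess_spectrum(cell)          # resample, crop, baseline, l2
    profile = sr.compute_shift_profile(prepped, table)
    cls = sr.classify_cell(profile)                 # delta_min=5, phe required
    print(cell.cell_id, cls.is_active,
          {k: round(v, 1) for k, v in profile.delta.items()})
```

Output (first two cells):

```
cell_0000 True {'pyrrole_breathing': 21.7, 'nu_CN': 10.5, 'delta_CH': 11.5, 'nu_CC': 48.0, 'phe_ring': 36.7}
cell_0001 True {'pyrrole_breathing': 21.7, 'nu_CN': 10.3, 'delta_CH': 13.2, 'nu_CC': 47.1, 'phe_ring': 36.3}
```

Each delta is the fitted redshift in cm⁻¹; fully labeled cells land on the
endmember shifts (22/10/12/48 for Cyt c, 37 for phenylalanine), every delta
exceeds 5 cm⁻¹, and all 10 cells classify as active.

The same workflow from the shell:

```bash
sipraman simulate --n-cells 10 --label-fraction 1 --snr 30 --seed 42 -o run
sipraman classify run.spectra.csv -o run            # run.cells.csv + run.report.json
sipraman report run.spectra.csv -o run.means.csv    # mean ± SD per isotope group
```

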