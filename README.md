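# oascreen

Quantitative urinary organic-acid screening for inborn errors of metabolism
(IEM) from negative-mode LC-QTOF/MS full-scan data.

Urinary organic-acid analysis is a pivotal test in selective metabolic
screening: dozens of inherited enzyme defects (organic acidurias, fatty-acid
oxidation disorders, aminoacidopathies) each leave a characteristic pattern
of acids in urine. `oascreen` implements the computational core of a
targeted LC-QTOF/MS workflow for clinical laboratories:

* a **75-analyte panel** (71 disease markers, 4 medication markers) of
  deprotonated ions [M−H]⁻ with retention times, stable-isotope internal
  standards (19 ISTDs) and calibration ranges, shipped as a packaged table
  with molecular formulas validated against the monitored m/z values;
* **accurate-mass extraction and integration**: extracted ion chromatograms
  (EICs) at ppm tolerance, trapezoidal peak areas, MAD-based signal-to-noise;
* **quantification** by 6-point response-ratio calibration
  (area<sub>analyte</sub>/area<sub>ISTD</sub> vs concentration, OLS) for the
  68 analytes with standards, and by the relative-ISTD rule
  (conc = ratio × ISTD concentration) for surrogate-standard and medication
  analytes; LOD/LOQ at S/N = 3 and 10; creatinine normalization to
  µmol/mmol;
* **z-score profiling**: per analyte and age group (0–2 y, >2 y),
  z = (log₂ x − μ)/σ against a control cohort, with LOD imputation and the
  fixed σ = 0.774 = log₂(5)/3 for analytes never detected in controls (so
  5 × LOD ↦ z = 3); flags at |z| > 2.5 (borderline) and z > 3 (significant);
* **method cross-validation**: spiked recovery and linearity (acceptance
  band 80–120 %), classic Passing–Bablok regression with 95 % CIs, and
  per-analyte Welch-t / Mann–Whitney testing;
* a **synthetic-data module** that emulates control cohorts, IEM cases and
  whole instrument batches (Gaussian peaks, calibrants, QC/blank scheme), so
  the entire pipeline runs and is tested without instrument files.

## Worked example

A fully synthetic batch: 5 controls per age group plus a glutaric aciduria
type I (GA I) and an MCAD-deficiency case, rendered to instrument-level
peak lists and pushed through the whole pipeline:

```sh
oascreen simulate  --out-dir batch --seed 1 --n-controls 5 --cases GA1,MCADD
oascreen calibrate --batch-dir batch --out curves.json
oascreen quantify  --batch-dir batch --out-dir quant --curves curves.json
oascreen reference --results quant/results.csv --out ref.json
oascreen screen    --ref ref.json --sample quant/results.csv --out-dir screen
```

Flagged analytes in the GA I profile (`screen/profile_case-GA1.csv`):

```
                 analyte  conc_norm     z       flag
           Glutaric acid    485.700 11.38   elevated
  3-Hydroxyglutaric acid    570.100 10.02   elevated
       Homogentisic acid      7.682  3.24   elevated
            Fumaric acid     34.590  2.80 borderline
...
```

and for MCADD:

```
           Hexanoylglycine     20.590 11.01   elevated
    Phenylpropionylglycine     27.430 14.06   elevated
            Suberylglycine     29.420  8.52   elevated
```

`conc_norm` is µmol analyte per mmol creatinine; `z` is the standardized
log₂ deviation from the age-matched controls. The designated biomarkers of
both diseases stand out at z ≈ 8–14, the range where real cases are
unambiguous, while the handful of incidental borderline flags
(homogentisic, fumaric, …) reflects the deliberately tiny 5-control demo
reference — a production reference uses ≥46 controls per age group, as in
the packaged defaults. `screen/` also contains the corresponding profile
plots (one marker per analyte in panel order with ±2.5 / ±3 guide lines).

Method comparison against a reference method runs from a paired CSV:

```sh
oascreen compare --paired paired.csv --out-dir cmp
```

giving per-analyte recovery, Passing–Bablok slope/intercept with CIs, and
the significance test used.

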