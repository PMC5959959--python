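# Methods

This note documents the models, rules and numerical choices behind
`oascreen`, and what its synthetic data do and do not establish about real
measurements.

## Panel and mass arithmetic

The packaged panel (`data/table1_panel.csv`) lists 75 targeted urinary
analytes — 71 disease markers and 4 medication markers — monitored as
deprotonated ions in negative-mode electrospray, each with an HMDB
identifier, monitored m/z (4 decimals), retention time, assigned internal
standard, and, for the 68 analytes with pure standards, a calibration range
in µmol/L. The remaining seven (hawkinsin, 2-pyrroloylglycine,
3-hydroxysebacic acid, and the four medication markers) are quantified by
the relative-ISTD rule.

Monoisotopic masses use IUPAC atomic masses for C, H, N, O, S, and
[M−H]⁻ = M − 1.007276 Da (loss of H, retention of the electron). Molecular
formulas are not part of the published panel; they were assigned from the
analyte identities and validated against the monitored m/z column:
71 of 73 assignable formulas agree to ≤0.0005 Da, and that agreement is an
enforced test invariant. Two entries are stored verbatim without a formula:
hawkinsin, whose printed m/z (291.0777) equals the *neutral* monoisotopic
mass of C₁₁H₁₇NO₆S rather than the anion (an apparent table typo), and
levetiracetam, whose printed ion (202.0721) is not derivable from the drug
formula by deprotonation. Two further ions are in-source fragments
(3-hydroxypropionic acid 59.0133, 3-methylglutaconic acid 99.0452) and are
flagged and stored verbatim.

The 19 ISTDs are stable-isotope analogues of panel analytes; their m/z is
computed from the unlabeled formula plus label shifts (²H: +1.006277 Da,
¹³C: +1.003355 Da per atom) and their retention time equals the unlabeled
compound's. Spiked ISTD concentrations are configuration values
(default 25 µmol/L).

Feature matching uses default tolerances of 10 ppm in m/z and ±0.2 min in
retention time (both configurable); QTOF mass accuracy and the observed
0.05–0.07 min spacing of the critical isomer pairs motivate these. Matches
are ranked by RT closeness, then mass closeness, and any multiple match is
flagged ambiguous rather than resolved: adipic acid vs 3-methylglutaric
acid (same composition, 4.93 vs 5.00 min) is the canonical case and
requires the full biomarker profile plus clinical context. (The published
narrative quotes a 0.05 min difference for this pair while the table prints
0.07; the table values are stored.)

## Signal processing

The native input is centroided full-scan data. An EIC sums centroid
intensities within the ppm window per scan. Peak integration:

* the apex is the credible local maximum *nearest* the expected RT inside
  the ±0.2 min search window — choosing the nearest rather than the tallest
  maximum prevents a pathologically elevated isobaric neighbour
  ~0.1 min away from stealing the apex;
* integration bounds are the local minima flanking the apex (bounded by the
  window); the area is trapezoidal;
* noise is 1.4826 × MAD of the EIC intensities outside the peak region,
  floored at one count; a peak is "found" only when its apex exceeds
  3 × noise. LOD and LOQ are the concentrations at which S/N reaches 3
  and 10: LOD = 3·noise/slope, LOQ = 10·noise/slope on the response-ratio
  scale.

Vendor acquisition software performs continuous mass correction with
reference masses; inputs here are assumed mass-calibrated.

## Quantification

Response ratios (analyte area / ISTD area) are fitted against nominal
concentration by unweighted OLS over six levels (1/x weighting available).
Back-calculated negatives clip to zero with a below-LOD flag, which the
screening stage later imputes. The relative-ISTD mode assumes the analyte
shares its ISTD's response factor: conc = ratio × ISTD concentration ×
dilution factor. Dilution is an explicit per-sample factor (the reference
preparation dilutes 25 µL urine into 400 µL, factor 16, after adjusting
creatinine to 0–2 mmol/L, but pre-adjustment varies). All concentrations
are reported both as µmol/L and normalized to urine creatinine
(µmol/mmol); creatinine is an input from clinical chemistry, not measured
here.

Batch quality control follows the scheme of a QC sample and blank at the
start and after every 24th sample; the checker verifies placement, flags
QC recoveries outside a tolerance (default ±20 %), and flags blank
carry-over above a configurable fraction of the QC area. Precision is the
percent coefficient of variation over replicates; between-run CV is
computed over QC replicates.

## Z-score screening

Per analyte and age group (0–2 years and >2 years; age exactly 2 assigned
to the younger group), reference statistics are the mean and SD of
log₂-transformed creatinine-normalized concentrations in a control cohort,
with missing and below-LOD values imputed at the LOD before the transform.
An analyte imputed in every control is marked not-detected and assigned
mean = log₂(LOD) and the fixed SD 0.774. The log base is 2 because
0.774 = log₂(5)/3 to three decimals, which reproduces exactly the
convention that a result at five times the LOD reports z = 3 (natural log
would require 0.536, log₁₀ 0.233). A sample value is imputed up to the LOD
before scoring, so z = (log₂ max(x, LOD) − μ)/σ; z is therefore
non-decreasing in x, zero at or below the LOD for not-detected analytes,
and invariant under any common rescaling of all concentrations (the log
shift cancels). Signed z is reported for detected-but-low analytes (a
floor-at-zero variant is a caller choice).

Flags: elevated when z > 3.0, borderline when 2.5 < z ≤ 3.0, decreased when
z < −2.5, else normal; both thresholds are configurable. Estimated SDs
below 0.1 (degenerate cohorts) are raised to 0.1 to avoid unbounded z —
this affects only synthetic edge cases. A packaged disease-to-biomarker map
supports profile interpretation; it is an editable aid, not a classifier,
and no automated diagnosis is attempted.

## Method comparison

Recovery of spiked analytes is the slope of the OLS regression of measured
result on weighed-in amount, × 100 (a simple ratio recovery is also
exposed); the acceptance band is 80–120 %. Linearity is the R² of the same
fit. Passing–Bablok regression implements the classic estimator: all
pairwise slopes over pairs with distinct x, slopes equal to −1 excluded,
the median shifted by the count of slopes below −1; the intercept is
median(y − b·x); 95 % confidence bounds come from the rank-based normal
approximation with variance n(n−1)(2n+5)/18. The implementation is
cross-checked in the tests against an exhaustive O(n²) pure-Python oracle
and must agree exactly. The per-analyte difference test uses Welch's t when
both groups pass Shapiro–Wilk at α = 0.05, else Mann–Whitney U ("when
proper" operationalized; constant groups count as non-normal).

## Synthetic data: what it emulates and what it does not

The generator defines the study conditions under which everything is
tested:

* **Controls** — 46 per age group by default. The true reference
  distribution of the source cohort is unpublished, so control levels are a
  design choice made once: geometric-mean normalized concentration at twice
  each analyte's low calibration limit, log₂-SD 0.5, LOD at one tenth of
  the low limit. Surrogate-standard and medication analytes are absent in
  controls, as in real normal urine, which exercises the 0.774 rule.
  Creatinine is log-normal with median 1 mmol/L, clipped to 0.1–2 (the
  pre-adjusted range); the default sample dilution factor is 16.
* **Cases** — a control draw with designated biomarkers multiplied by
  fold-changes chosen so they land at z ≈ 5–15, the qualitative range
  reported for real cases (e.g. MCADD glycine conjugates > 5,
  3-hydroxyglutaric acid > 10 in GA I); built-in specs cover IVA, MCADD,
  PA, GA I, MMA, MSUD, 5-oxoprolinuria and MADD. Medication markers can be
  injected to emulate paracetamol use.
* **Instrument model** — each species becomes a Gaussian chromatographic
  peak (SD 0.008 min, FWHM ≈ 1.1 s) at its panel RT, area = response
  factor × injected concentration, sampled at 8 Hz, centroided at the
  target m/z with an optional per-peak mass-accuracy draw (typically
  2 ppm) and optional baseline noise on every monitored trace. The narrow
  peak width is deliberate: the published isomer pairs 0.05–0.07 min apart
  are adequately distinguished by the real method, so the emulation must
  resolve them too; at this width the noise-free round trip
  (truth → peaks → EIC → areas → concentrations) closes to <0.5 % for all
  75 analytes, which is the master integration test. Batches comprise
  QC + blank, six log-spaced calibrant levels spanning each calibration
  range, then samples with the QC pair re-injected after every 24th.

Everything is seeded through `numpy.random.Generator`; there is no global
random state, and fixed seeds give byte-identical artifacts.

What passing these tests shows: the algebra and order of operations of the
pipeline are correct, the estimators recover known truth at realistic noise
levels, and the screening rules reproduce the published worked values
(z = 3 at 5 × LOD; calibration R² ≥ 0.98 at 5 % response noise). What they
do not show: behaviour under real matrix effects (the published method
itself reports ion suppression for 4-hydroxybutyric and pyroglutamic acid,
and distorted peak shapes for 2-methylcitric acid and succinylacetone —
none of which the Gaussian model reproduces), real between-run drift, or
the clinical reference distribution, which must be established on a real
control cohort before diagnostic use.

## Problem sizes and reporting conventions

Test and acceptance computations use desk-scale sizes chosen as the
package's own defaults: cohorts of 46 controls per group, 100-replicate
oracle and coverage checks for Passing–Bablok, 10–20 fresh controls for the
false-positive rate, and single rendered batches for the round trip.
Concentrations serialize at 4 significant figures and z-scores at 2
decimals; result CSVs embed the configuration hash so identical configs
reproduce identical bytes.
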