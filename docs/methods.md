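# Methods

This note records the model structure, the default parameterization and the
reasoning behind the design choices that were genuinely open.

## Population physiology

Virtual subjects are drawn per age band with ages uniform over the band
(the within-band age distribution is not otherwise constrained by any input
we rely on; uniform is the least-informative choice).  Sex is Bernoulli
(default 50/50) and only affects the growth table.

* **Growth.** A bundled reference-style growth table (CSV; WHO/CDC-like
  medians for weight and height by age and sex, with log-normal CVs of
  ~12% for weight and 3.5% for height) is piecewise-linearly interpolated.
  Weight and height share a size z-score with correlation 0.7 so tall
  subjects tend to be heavy.  Requested ages outside the table's 0–18 year
  support raise a configuration error rather than extrapolating.
* **Body composition.** BSA uses the Mosteller formula (the simplest of the
  interchangeable options; configurable).  Liver volume is linear in BSA
  (706.2 mL/m² + 2.4 mL, density 1.05 g/mL), kidney 0.42% of body weight,
  blood 70 mL/kg plus a neonatal excess decaying over ~2 years.  Cardiac
  output is 190 L/h/m²; the liver receives 25% and the kidneys 19% of it.
* **MPPGL** (mg microsomal protein per g liver) follows the standard cubic
  log10-polynomial in age, ≈26 mg/g at birth rising to ≈40 mg/g in adults.
* **GFR** matures as a Hill function of postmenstrual age (half-maturation
  47.7 weeks, Hill 3.4) times an allometric size term `(W/70)^0.75`,
  asymptote 121 mL/min for the 70 kg reference adult.  Term birth is taken
  as 40 weeks PMA; preterm physiology is out of scope.
* **Plasma protein binding.** The unbound fraction is rescaled from the
  adult value by the age-varying binding-protein ratio,
  `fu_ped = 1/(1 + r·(1-fu_ad)/fu_ad)` with
  `r = 1 - 0.25·exp(-age/0.3 y)` (75% of adult at birth, adult by ~1 year).
* **CYP3A4 ontogeny.** Activity per mg microsomal protein relative to adult
  is a base Hill sigmoid in postnatal age (fraction at birth 0.05,
  half-age 0.07 y ≈ 26 days, Hill 1.2) plus an additive overshoot term —
  the product of a rising Hill (half-age 0.25 y, Hill 2.8) and a falling
  Hill (half-age 9 y, Hill 8) scaled by amplitude 0.65.  The function is
  continuous and positive, tends to exactly 1 as age grows (0.999 by age
  30), is monotone when the amplitude is zero, and with the default
  amplitude has a single interior maximum of ≈1.65 in early childhood.

The ontogeny defaults were calibrated deterministically, before any
Monte-Carlo analysis, so that the simulated per-kg clearance of a
CYP3A4-cleared drug reproduces the age profile consistently reported for
such substrates (midazolam being the canonical probe): a steep rise across
the first month, a peak in the 1–6 year range at roughly 2.5 times the
neonatal per-kg value, and a decline to ~60% of the peak by late
adolescence.  Concretely, the ratio of median AUC0–48 in the 2–6 year band
to each other band under a fixed mg/kg regimen was fitted to the target
profile 0.4/0.6/0.8/1.0/1.0/1.0/0.8/0.6 (bands from 0–2 weeks to 12–18
years) with least squares over the ontogeny parameters, then the fitted
values were rounded to the tidy defaults above.  All parameters live in
`population_default.yaml`; nothing is hard-coded.

Inter-individual variability is log-normal on CYP3A4 abundance (CV 35%, a
conventional magnitude for CYP enzymes) in addition to the growth-table
size variability.  Flows and volumes inherit size variability through BSA
and weight; no additional independent organ-level noise is applied by
default (CVs are configurable).

## Compound model

The dexamethasone defaults are literature values, user-overridable:
MW 392.46 g/mol, fu 0.30, blood:plasma 0.93, fm(CYP3A4) 0.85, tissue:plasma
partition coefficients 1.2 (liver, kidney) and 0.9 (rest), renal fraction
0.5 of unbound filtration, and unbound intrinsic clearance 7.5 µL/min/mg
microsomal protein.  For the reference adult these combine to a total
plasma clearance of ≈8.4 L/h, steady-state volume ≈0.85 L/kg and terminal
half-life ≈4–5 h, and for 2–6 year olds a per-kg clearance of
≈0.16 L/h/kg with t½ ≈ 3 h — consistent with reported human dexamethasone
PK.  A retrograde entry mode is also supported: stating an adult whole-body
plasma clearance back-calculates the per-mg CLint through the well-stirred
model at adult physiology (`clint_from_adult_cl`).

## PBPK structure and numerics

Five perfusion-limited compartments: venous blood, arterial blood, liver,
kidney, rest of body.  Tissue outflow concentration is `C_t·BP/Kp_t`;
hepatic elimination removes `CLint_u·fu_p·C_liv/Kp_liv` (which reproduces
the well-stirred clearance at steady state), renal elimination removes
`renal_fraction·GFR·fu_p·C_kid/Kp_kid`.  Flows must sum to cardiac output
within 0.1% at construction.  Reported plasma concentration is venous
blood concentration divided by the blood:plasma ratio.

IV administration is modeled as a short infusion (default 0.1 h, aligned
with the output grid; a duration of 0 gives a true bolus).  Because the
system is linear and time-invariant between dose events, profiles are
propagated exactly with matrix exponentials of the augmented (state +
infusion-rate) system, cached per step size — this makes mass balance,
dose linearity and superposition hold to ~1e-12 rather than to an ODE
tolerance.  A conventional stiff integrator (LSODA, rtol 1e-8, restarted
at dose events) is retained as an independent backend and agrees with the
matrix-exponential path to better than 1e-6; the cross-check is part of the
test suite.  The output grid is 0.1 h spacing plus exact dose event times,
default horizon 48 h after the first dose.

The 40 mg/day ceiling is enforced by proportionally scaling all doses in
any rolling 24 h window that exceeds it (per-dose caps, e.g. the 10 mg
guideline cap, are applied first when configured).

## NCA conventions

Default integration rule linear-up/log-down (the standard choice for IV
decay; the log rule applies only where concentration decreases through
positive values).  λz is fitted by log-linear regression over the last 3–6
positive points excluding Cmax, selecting the best adjusted r²;
AUC0–∞ = AUC0–tlast + Clast/λz; CL = dose/AUC0–∞ (single-dose
interpretation); Vd = CL/λz.  Observed values flagged below the LLOQ are
excluded from λz and treated as missing for AUC, closing the integral at
the last quantifiable point.

## Verification

Quantitative verification computes predicted-to-observed geometric-mean
ratios per study and metric, classified into nested 1.25/1.5/2-fold bands
(symmetric in r and 1/r; boundaries count inward, so a ratio of exactly
2.0 is acceptable).  Predicted metrics come from an age- and design-matched
virtual cohort (default 100 subjects × 10 replicate trials, pooled) whose
profiles are evaluated **on the study's sampling schedule** — otherwise a
dense simulation grid catches the infusion-end peak that sparse clinical
sampling cannot see, and Cmax/Tmax ratios become artifacts of the grid
rather than of the model.  For the same reason the residual error model of
the observed data can be applied to the simulated observations
(`residual_cv`), making self-consistency comparisons fully symmetric.
Observed metrics use study-reported values when available, else NCA on the
records with identical settings; because which variant a literature study
reported can be ambiguous, the report labels the metric used for every
ratio.

The VPC simulates a matched cohort at the observed time points, adds the
stated residual error if any, and overlays observed quantifiable points on
the mean and 5th–95th percentile envelope, reporting the covered fraction.

Real pediatric dexamethasone datasets are not publicly deposited, so the
shipped verification exercise is a self-consistency oracle: synthetic
studies generated from the pipeline's own model (four designs — single
3 mg/m², single 0.3 mg/kg, 3 mg/m² q6h, 4 mg q12h — with 20% proportional
error and LLOQ censoring) must verify within 1.25-fold and show ~90% VPC
coverage.  Passing shows the pipeline is internally coherent (simulation,
NCA, cohort matching and reporting are mutually consistent), not that the
model predicts real children; verification against real data requires
supplying observed studies in the documented CSV + descriptor format.

## Dose matching

The matching statistic is the median AUC0–48 (robust, and the natural
summary when distributions are displayed as box plots); means are a
configuration away.  The raw multiplier target/bin is exact under
dose-linear PK and is rounded to the nearest 20% of the reference dose,
ties up (toward the studied dose).  Matching runs use uncapped mg/kg
dosing: the 40 mg/day ceiling would bind for adolescents at the reference
doses and would turn a physiological adjustment into a body-size cutoff;
it is applied when absolute doses are emitted or "current practice"
regimens are simulated.  The three bands between 3 months and 2 years are
reported merged with the reference band when all match multiplier 1.0.

Default simulation size is 100 subjects × 10 replicates per band (fixed
seed, logged in the run manifest).  At that size the Monte-Carlo standard
error of a band's median AUC ratio is ≈1.5%, far inside the ±10% width of
each 20%-grid rounding window, and the resulting ladder is stable across
seeds: 0.4 (0–2 weeks), 0.6 (2–4 weeks), 0.8 (1–3 months), 1.0 (3 months–
6 years), 0.8 (6–12 years), 0.6 (12–18 years).  Multipliers are
scenario-independent (linear PK, no cap in the matching run), so the
per-scenario dose columns follow arithmetically from one ladder.

## Degenerate inputs and tie-breaks

Zero total clearance (no hepatic or renal elimination) flags the profile
as having divergent AUC instead of failing.  A regimen with no doses
yields an all-zero profile.  λz estimation raises a typed error when no
positive, declining tail exists.  Exposure-band edges: the age-band ladder
is contiguous, with the "2–4 weeks" band running to 1 calendar month so no
age is unassigned.  Multiplier rounding adds a 1e-9 guard before flooring
so exact halves round up regardless of float representation.

## Known limitations

* The physiology is a transparent parametric substitute for proprietary
  platform population libraries; absolute predictions inherit the
  literature defaults' uncertainty even though the *relative* (per-band)
  results are driven by well-characterized maturation patterns.
* Healthy physiology only: critical-illness CYP3A4 downregulation,
  preterm neonates, oral absorption, metabolites, auto-induction and
  drug–drug interactions are all out of scope.
* Timing of treatment initiation relative to extubation is not modeled;
  the output is proportional dose guidance, not absolute efficacy claims.
* The synthetic observed studies share the simulator's structural
  assumptions; they cannot reveal structural model misspecification.
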