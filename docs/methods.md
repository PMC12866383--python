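# Methods

## Escalation design

The engine implements the Bayesian optimal interval design for a target
DLT probability φ (default 0.25). The interval end points default to the
standard recommendations φ₁ = 0.6φ and φ₂ = 1.4φ; both can be
overridden in `BoinDesign`. Decision boundaries are the closed forms

λ_e = ln((1−φ₁)/(1−φ)) / ln(φ(1−φ₁)/(φ₁(1−φ))),
λ_d = ln((1−φ)/(1−φ₂)) / ln(φ₂(1−φ)/(φ(1−φ₂))),

which always satisfy λ_e < φ < λ_d. A cohort decision uses the
cumulative (n, y) at the current level; escalation into a nonexistent or
eliminated higher level degrades to *stay*, and a de-escalation demanded
at the lowest level terminates the trial (there is nowhere safer to go).
Overdose elimination uses the Beta(1+y, 1+n−y) posterior (uniform
prior): a level is removed, together with all higher levels, when
Pr(p > φ) > 0.95 and n ≥ 3. Both the cutoff and the minimum n are
design parameters.

MTD selection smooths the per-level rates with posterior means of
Beta(y+0.05, n−y+0.05) — the small prior mass keeps levels with zero
events distinguishable by sample size — then applies weighted
pool-adjacent-violators (inverse posterior variance weights) and picks
the non-eliminated tried level whose isotonic estimate is closest to φ.
Ties are broken toward the higher level when the tied estimate is below
φ and toward the lower level otherwise; this convention is what makes a
history of 0/3 and 0/9 at adjacent levels resolve to the larger, better
supported level.

Trial-level rules: at least `min_cohort` (3) evaluable patients per
level before a decision; at most `max_per_dl` (9) per level and
`max_total` (36) overall; the trial stops on the patient budget, on
elimination of all levels (no MTD), or when a level at its per-level cap
draws a *stay*. Evaluability is the dose-determining-set rule from the
safety module.

## Dosimetry pipeline

Quantification starts at calibrated activity fractions; image
processing is out of scope. The declared pipeline choices are:

* **Decay-uncorrected fractions.** fia(t) is what the camera sees
  relative to the injected activity, so fitted rates are *effective*
  (biological + physical, physical half-life fixed at 159.53 h) and the
  integral ∫fia dt needs no extra decay term.
* **Hybrid anchoring.** The planar series is multiplied by
  (SPECT fia / planar fia) at the matched time point (window ±3 h,
  default anchor the latest SPECT point, i.e. 24 h). Rescaling preserves
  ratios between time points; anchoring at both SPECT times is not
  implemented.
* **Fit.** Monoexponential by default (log-linear initialisation, then
  bounded least squares); biexponential available with ≥ 4 points;
  automatic downgrade biexp → monoexp → trapezoid-with-tail when points
  are missing, with a logged warning. The trapezoid route integrates the
  observed points and appends last value / terminal rate, the terminal
  rate taken from the last two samples and replaced by the physical
  decay rate when the terminal slope is non-negative (activity cannot
  outlive the radionuclide); a non-positive tail rate raises a
  divergent-integral error.
* **Dose conversion.** Self-dose only: ADC (Gy/GBq) = TIAC (h) × a
  per-organ dose factor (Gy per GBq·h). The default factors — kidneys
  0.050, pancreas 0.100, red marrow 0.0016, total body 0.0005 — are
  effective factors chosen to put simulated coefficients on the scale of
  reported organ coefficients for a ¹⁷⁷Lu-labelled peptide; any study
  using this package for real data should substitute factors from its
  own phantom/S-value computation via `DosimetryConfig.dose_factors`.
  Cross-dose terms are a known limitation.
* **Activity cap.** Max allowed cumulative activity per organ =
  EBRT threshold / ADC (2/23/40 Gy for red marrow/kidneys/pancreas);
  only organs with a configured threshold gate; the overall cap is the
  minimum and the limiting organ is recorded. The per-cycle gate allows
  a proposed administration when cumulative + proposed ≤ cap, reduces to
  the remaining headroom when that is at least the floor (the lowest
  ladder activity), and blocks otherwise. One dose reduction (one ladder
  step) is allowed per patient; a second request discontinues.

Report tables round to 2 significant figures, half away from zero;
count tables print percentages to one decimal with the same tie rule.

## Synthetic data

The generator emulates the measurement design of a dose-escalation
study with planar imaging at 1–3, 6, 24, 48, 72 and 168 h and SPECT/CT
at 1–3 and 24 h after the first administration. Kinetics are
single-compartment washout, fia(t) = f₀·exp(−(λ_bio + λ_phys)t), with
per-organ lognormal f₀ across patients and multiplicative lognormal
measurement noise (unit mean, default CV 10%). Defaults were calibrated
once so the population mean absorbed-dose coefficients land at 0.10
(kidneys), 0.055 (pancreas), 0.018 (red marrow) and 0.014 (total body)
Gy/GBq, with between-patient CVs 0.56/0.71/0.42 taken from the
corresponding reported SD/mean ratios; the total-body fraction is
pinned at ≈1 at t = 0, so its spread comes from noise only. This is a
calibration target, not a claim of realism: real curves are not
monoexponential at early times, organ fractions are correlated within a
patient, and evaluability loss (poor image quality) is not simulated —
so passing tests demonstrate correctness of the machinery, not fidelity
of any particular patient population.

DLT outcomes in trial simulation are Bernoulli at each level's true
probability, independent of simulated dosimetry; an absorbed-dose–
toxicity link is deliberately absent because the regime of interest is
one where organ doses sit far below toxicity thresholds. The
eligibility screen draws independent lognormal tumor and spleen uptake
(medians 3.5 and 5.0, σ 0.8 and 0.3), giving an analytic eligibility
probability Φ((ln 3.5 − ln 5)/√(0.8² + 0.3²)) ≈ 0.34 — roughly one in
three screened patients proceeds. Fixture rosters for safety tables are
fully deterministic: category counts nest (DLT ⊆ grade ≥ 3 TRAE ⊆ any
TRAE) so re-tabulation reproduces the specification exactly.

## Safety conventions

A DLT is a related, non-disease-attributable event of grade ≥ 3
(configurable per deployment; real protocols carry term-specific
severity criteria that are not modelled here) with onset within 42 days
of the first administration, day 1 being the day of that
administration. The dose-determining set requires ≥ 90% of the planned
cycle-1 activity and ≥ 42 days of observation, or earlier
discontinuation for a cycle-1 DLT. Exposure duration is
(last − first administration + 42 d)/7 weeks to two decimals. Safety
tables count each patient once per category at worst grade. Adverse
event terms are free text with exact matching; dictionary coding is out
of scope.

## Numerical choices and problem sizes

Posterior tail probabilities come from `scipy.stats.beta.sf`; tests
check them against brute-force quadrature of the density to 1e−8 for
all n ≤ 12. The TIAC closed form is verified against adaptive
quadrature to 1e−6 relative over 100 random parameter draws, the PAVA
implementation against exhaustive search over contiguous-block
partitions on ≤ 3 levels and against an independent isotonic-regression
fit. Operating-characteristic checks use 1000 simulated trials of a
3-level scenario (0.02, 0.25, 0.55) with a fixed seed — large enough
for a strict plurality to be stable, and the package's standard
simulation size for design evaluation. Monte-Carlo rate-recovery uses
200 replicates at CV 10%. All simulation entry points take a
`numpy.random.Generator`; identical seeds give bitwise-identical
records.

## Known limitations

Self-dose-only conversion with scalar dose factors; monoexponential
default kinetics (no uptake phase); single-anchor hybrid rescaling; no
blood-based marrow dosimetry; no accrual-time modelling (the ≥ 6-week
inter-cycle interval is schedule metadata only); no time-to-event or
model-based escalation variants; free-text AE grouping.
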