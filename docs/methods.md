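# Methods

## Viability normalization and plate QC

A plate carries three well roles: untreated controls (signal α), cell-free
background (β) and treated wells (γ). Viability is the affine rescaling

    viability% = 100 · (γ − β) / (α − β).

α and β are per-plate replicate means: each chip is sealed and read as a
unit, so anchors are never pooled across plates. The rescaling is invariant
to common gain and offset changes of the reader, which is the property the
tests check. Viabilities outside [0, 100] are *reported as computed* and
flagged `out_of_range`; clamping would hide assay failures (evaporation,
dispensing faults). Only the later conversion to fraction affected clamps.

Dispensing precision is `CV% = 100·sd/mean` over replicate signals, with the
sample (n−1) standard deviation — at the platform's replicate counts (three
wells per condition) the unbiased form is the conventional choice.

Condition keys normalize doses to a canonical per-drug unit (mass
concentrations to mg/mL, molar to M) before comparison, because panels
routinely mix mg/mL and µg/mL across drugs. Cross-dimension conversions
(mass ↔ molar) are refused rather than guessed.

## Dose–response models

**Median-effect model.** The mass-action form `fa/fu = (D/Dm)^m` (fa =
fraction affected, fu = 1 − fa, Dm = median-effect dose, m = sigmoidicity)
linearizes to `log(fa/fu) = m·log D − m·log Dm`, so the fit is closed-form
OLS on the median-effect plot; `r` is the Pearson correlation of the plotted
points and equals 1 exactly on noiseless model data. Points require fa
strictly inside (1e-6, 1 − 1e-6): the logit diverges at the boundaries, and
excluding near-total kill / no-effect points is standard for this
linearization. Viabilities are clamped to [0, 100] before fa conversion.

**4PL.** IC50s are reported from the variable-slope logistic
`v(D) = bottom + (top − bottom)/(1 + (D/IC50)^h)` (decreasing form),
fitted by bounded least squares with a deterministic multi-start: five
log-spaced IC50 seeds spanning the dose range crossed with slope seeds
{0.5, 1, 2, 4}, bounds bottom ∈ [−10, 50], top ∈ [50, 120], h ∈ [0.05, 20],
IC50 within 10³ of the dose range. The best RSS wins, so repeated fits are
identical without a global optimizer. IC50 is the inflection dose (relative
IC50, the variable-slope convention). Inputs with no decreasing trend
(OLS slope of viability on log-dose ≥ 0, or constant viability) raise a
non-convergence error carrying the diagnostic slope, rather than returning
a meaningless curve. Synergy scoring consumes the median-effect fits; the
4PL exists for IC50 reporting.

## Synergy scoring

For an observed combination effect fa, each drug's fit gives `Dx_j =
Dm_j·(fa/(1−fa))^{1/m_j}`, the dose of drug j alone matching that effect.
The package uses the general non-constant-ratio n-drug Combination Index

    CI = Σ_j D_j / Dx_j,      DRI_j = Dx_j / D_j,

so `CI = Σ 1/DRI_j` identically. The screen doses drugs on independent
grids, hence the non-constant-ratio form; no mutually-exclusive/alternate
form toggle is exposed. Classification uses the standard convention —
synergistic below 1, antagonistic above 1 — with an additive band
|CI − 1| ≤ δ, δ = 0.05 by default: an estimated CI is never exactly 1, and
a band this wide is well inside the noise of a 0.8%-CV assay while still
separating the regimes of interest (the motivating screens report CI 0.4
and 0.5). Ranking sorts by observed viability ascending, then CI, then
total normalized dose, with a stable sort.

The combination's fa comes from the replicate-mean viability of the
condition. Units convert within a drug only; CI/DRI are intra-drug ratios,
so cross-drug conversions never arise.

## Dose translation

The murine dose per administration is `(MTD / averaged DRI) · n`, where the
averaged DRI is the arithmetic mean over the combination's drugs and n is
the planned number of administrations. The grouping is (MTD/DRI)·n — the
worked arithmetic (300/49.8 × 2 = 12 mg/kg) multiplies by n. Whether that
quantity is per administration or cumulative is ambiguous on its face;
per-administration matches the dosing schedules it feeds (e.g. "12 mg/kg
for 2 days") and is adopted.

HED conversion uses the FDA body-surface-area rule for the mouse: divide
mg/kg by 12.3 (equivalently multiply by km 3/37; the two differ only in the
third significant figure). Display rounding is 2 significant figures;
arithmetic always uses raw values. Clinical reference doses printed in
mg/m² convert with the adult-human km 37. Reference doses for the
percent-of-clinical comparison must be supplied in config — published
regimens differ by protocol and the package does not pick one silently;
only conversions, not references, are built in.

## In-vivo analytics

Tumor volume is the ellipsoid approximation `V = ½·w·d·h` from three
orthogonal diameters (mm → mm³). Trial logic: treatment (and the response
baseline, day 0) start at the first scan whose maximal diameter reaches
5 mm; euthanasia at 15 mm. The spider-plot response at day x is
`100·(b_x − a)/a` with a the trigger-day volume; −100% is complete
regression. A response query without an exact scan uses the nearest scan
within ±2 days (scans are only once or twice a week), else errors.

Relapse is defined volumetrically, since sonographic detectability has no
universal cutoff: regression is volume < 1 mm³ (undetectable proxy), and a
later scan ≥ 10 mm³ is a relapse; each regression→rebound cycle yields one
relapse day. Both thresholds are module constants.

Kaplan–Meier estimation and the Mantel–Cox log-rank test are delegated to
lifelines (`KaplanMeierFitter`, `multivariate_logrank_test`) behind
`km_curve`/`logrank_test`; `death` and `euthanized` count as events,
`censored` leaves the risk set without a drop. P-values are two-sided from
the χ²(k−1) reference distribution. The tests cross-check both against a
hand-computed product-limit table and an exhaustive permutation oracle.
Animals that relapse and are re-treated are censored at study end if they
survive (the default); callers wanting relapse-as-event can encode it in
the events table directly.

## Simulators

**Screen.** Per replicate the generator emits control, background, and one
treated well per condition. Single-drug conditions take their true
viability from the drug's median-effect curve. Combination conditions are
planted with a target CI: the generating fa solves `Σ D_j/Dx_j(fa) = CI*`
by Brent bisection (the left side is strictly decreasing in fa; an
unattainable target raises a configuration error naming the combination).
Noise is multiplicative lognormal with mean 1 parameterized to the target
CV — luminescence is positive and the platform's precision is quoted as a
CV (0.8%), which is the default. Poisson cell-count variation
(CV = 1/√100 = 10% at the default 100 cells/well) can be folded in as an
extra variance term but is off by default, since the quoted 0.8% is already
the composite dispensing figure. Default drug parameters sit at the
measured primary-cell IC50s (CP 3.38 mg/mL, DOX 4.55 µg/mL, VCR
13.27 µg/mL; m = 1.5), with 7-point geometric grids spanning Dm/8…8·Dm and
the optimal screen combination (2 mg/mL CP + 4 µg/mL DOX + 2 µg/mL VCR)
planted at CI 0.5.

**Cohort.** Each subject grows exponentially, `V(t) = V₀·e^{g·t}`, from
30 mm³ until a scheduled twice-weekly scan first meets the 5 mm trigger
(that scan is its day 0). Afterward the net rate is g − r with r the arm's
regression rate; with probability `relapse_prob` the tumor re-seeds at
≥1 mm³ after `relapse_delay_days` and regrows at g. Scans report the
equal-axis diameter (2V)^{1/3} with 5% lognormal noise per axis; euthanasia
fires at the first scan whose measured maximal diameter meets the endpoint,
and survivors are censored at 84 days (12 weeks). Defaults: vehicle g =
ln 15/14 per day (15-fold growth in two weeks), single-drug arms net
ln 6/14 (6-fold in two weeks), combination net −0.35/day (regression below
detectability within ~2 weeks) with relapse probability 0.4 and a 21-day
delay (≈2 of 5 animals relapsing in the fourth week), n = 5 per arm.

What the simulators deliberately omit: biological replicate variance beyond
the composite CV, inter-animal growth-rate heterogeneity, treatment toxicity
deaths, mechanistic PK/PD and immune effects, and measurement-driven
treatment timing (the trigger is located on the noise-free trajectory).
Passing recovery tests therefore demonstrates that the estimators are
correct and robust at the platform's noise level — not that real screens
meet these assumptions.

## Numerical choices and edge cases

- Plate CSVs are written with `repr` floats and read with pandas'
  round-trip float parser, so simulator output survives a write/read cycle
  bit-exactly (this backs the determinism guarantees of the CLI).
- `classify_ci` needs CI > 0; `dose_for_fa` needs fa strictly in (0, 1);
  combination fa derived from viability is clamped into
  (1e-6, 1 − 1e-6) so extreme viabilities stay scoreable.
- Degenerate normalizations (α ≤ β), flat dose–response curves, empty
  screens, all-censored log-rank inputs and missing anchors all raise typed
  errors rather than returning NaNs.
- Problem sizes in the test suite (e.g. 200 seeded screen simulations per
  planted CI, 40-run ranking checks, 30-run cohort batteries) were chosen
  to make pass/fail criteria statistically meaningful at desk scale.

## Known limitations

- The median-effect fit weights all usable points equally on the logit
  scale; CompuSyn-style per-point weighting or confidence intervals on
  CI/DRI are not implemented.
- 4PL confidence intervals (profile likelihood) and biphasic models are out
  of scope.
- HED scaling covers mouse → human only.
- The screen CSV dialect is the package's own; vendor 384-well export
  formats need conversion upstream.
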