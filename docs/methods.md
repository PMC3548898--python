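# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind meldkit. It is the place to look when a default looks
arbitrary: each one is either a published value, or a choice made once and
documented here.

## Scores

MELD is computed on clamped labs (bilirubin/creatinine/INR floored at 1.0;
creatinine capped at 4.0 mg/dL and set to 4.0 for patients on ≥2 dialysis
sessions in the prior week), rounded **half-up** and constrained to [6, 40].
MELDNa takes the *integer* MELD score, applies the sodium adjustment with
sodium clamped to [125, 140] mmol/L, and **truncates** toward zero: truncation,
not rounding, reproduces the published worked examples (21.25 → 21,
33.75 → 33). Both rounding policies are selectable per `ScoreModel`.

The albumin extensions operate on the **unrounded** linear value of the base
score, clipped to [6, 40]:

    extended = base + g · (a + b · base),   g = 4.0 − clamp(albumin, 1.0, 4.0)

then round half-up and constrain. Using the unrounded base is what makes all
three published examples hold simultaneously: with the shipped coefficients
(a = 5.05, b = −0.125), 21.25 → 26 and 33.75 → 35 at albumin 2.0 g/dL, and
33.75 at albumin 4.0 g/dL rounds to 34 — the documented "one-point reduction"
that an integer base cannot produce. Centering the albumin term at the upper
clamp (g = 0 at 4.0 g/dL) means a normoalbuminemic candidate gains nothing.

**Shipped coefficients are reconstructed, not transcribed.** The original
supplementary formulas were not available; a = 5.05, b = −0.125 is the
solution of the three published integer constraints above plus the requirement
that the score never decrease as albumin falls anywhere on [6, 40]
(a + b·base ≥ 0 up to base 40). Any officially published coefficients can be
dropped into the same configuration file, and `derive` produces data-driven
ones.

A model with both extension coefficients exactly zero returns the base
`ScoreValue` unchanged (identity), rather than re-rounding the base's linear
value under its own policy — re-rounding would turn a null 5vMELD of a
truncated MELDNa 33.75 into 34.

Hyperalbuminemia (>5.0 g/dL) is excluded at *derivation* time only (albumin
infusion in severely ill patients makes the high tail uninformative about
synthetic function); scoring simply clamps to 4.0.

## Derivation

`derive_extension` fits a Cox proportional-hazards model (lifelines, Efron
tie-handling — event times are at day resolution, so ties are plentiful) with
covariates: unrounded base score b, albumin deficit g, and the interaction.
The interaction column is fitted centered, g·(b − 30), because g and g·b are
nearly collinear (correlation ≈ 0.99) and the raw parameterization inflates
the albumin-term standard error about five-fold; the estimates are mapped back
to the uncentered (a, b) parameterization afterwards, so the emitted model is
identical. Coefficients are rescaled by the base-score coefficient
(a = β_g/β_base, b = β_int/β_base after uncentering) so the derived points sit
on the base-score scale — the same construction by which the sodium adjustment
was originally grafted onto MELD, leaving the base score's own coefficients
untouched. Albumin is clamped *before* both the main and interaction terms
(one clamped value feeds both).

Absolute 90-day risk is `1 − S0(90)^exp(lp)` with the baseline survival taken
from the fitted model at covariates zero (Breslow-type estimator); requesting
a horizon beyond the fitted follow-up support is an error rather than a flat
extrapolation. Constant covariates are dropped from the fit and reported with
coefficient 0 and infinite SE; near-singular fits are retried with a damped
Newton step, then a 10⁻⁶ ridge (flagged on the result).

## Evaluation

Discrimination is Harrell's pair-based c for censored data: pairs are usable
when the member with the strictly shorter time had the event, or on tied times
when exactly one member had the event; tied scores count ½; tied-time
double-event pairs are unusable. The estimator is exact (no IPCW weighting),
deterministic, and is checked in the tests against an independent O(n²)
enumeration and against lifelines' `concordance_index`.

Model comparisons use the group jackknife (default 100 random groups;
configurable). Leave-one-group-out c values are obtained exactly by
inclusion–exclusion on per-subject pair sums — pairs touching the removed
group are subtracted via the per-subject totals and the doubly-subtracted
within-group pairs added back — so the jackknife costs little more than the
full statistic. The difference is reported as c(B) − c(A) with a normal
reference; CIs for single c-statistics are jackknife CIs and labelled as such.

## Reclassification

Risk strata are half-open `[low, high)` in percent (default 0/5/10/20/100): a
predicted risk of exactly 5% belongs to the 5–<10% stratum. Per cell, deaths
and survivors are counted at the horizon ignoring persons censored inside the
window; the cell's observed mortality is a Kaplan–Meier estimate over *all*
members. The minimum-cell rule (default 20) applies to the headline
reclassified-person count and to the calibration statistic, **not** to the NRI
numerators — that is the convention under which the published table's counts
(3,921 reclassified; 174/94 and 1,736/955 movement counts) are internally
consistent.

NRI = (up−down)/deaths + (down−up)/survivors, with the summed-binomial
asymptotic variance

    var = [(p_up,e + p_down,e) − (p_up,e − p_down,e)²]/n_e  +  (same for survivors)

which reproduces the published interval to 0.1 points.

The reclassification calibration statistic sums
`(observed − expected)² / (expected · (1 − p̄))` over qualifying off-diagonal
cells, observed deaths from the cell KM (falling back to raw death counts for
tables built from printed counts), expected = persons · mean predicted risk,
referred to χ²(cells − 2). The Hosmer–Lemeshow-style df convention presumes
estimated model parameters; accordingly the null-calibration test simulates
the statistic with per-replicate *re-fitted* risk models, under which the
p-values are uniform (Kolmogorov distance < 0.1 over 200 replicates).
"Correctly reclassified" means the cell's observed mortality lies closer to
the destination model's mean predicted risk than to the source model's — an
interpretive choice, since the original phrasing does not define it
operationally.

## Counterfactual estimator

Deaths averted = Σ count × (P_tx[destination band] − P_tx[source band]) over
above-diagonal cells of the decedents' band cross-tabulation (bands <10,
10–19, 20–29, 30–39, 40), truncated to whole persons — truncation, matching
the published arithmetic (106.292 → 106). The top band's transplant
probability is not published and must be configured if a cross-tab puts
off-diagonal mass there. All outputs carry the label **best-case**: the
estimator assumes every additional transplant prevents a death and ignores
displacement of candidates bumped down by the new score.

## Synthetic cohort generator

The generator emulates a national waiting-list cohort at listing:

- **Marginals** (median [IQR] targets): bilirubin 2.5 [1.4–4.9] and creatinine
  1.0 [0.8–1.3] mg/dL and INR 1.4 [1.2–1.7] as log-normals; sodium 137
  [134–140] mmol/L normal; albumin 3.0 [2.5–3.4] g/dL truncated-normal on
  [0.5, 5.0]. Only summaries are published, so shapes are the standard
  positively-skewed/symmetric choices; quartiles are matched via
  σ = ln(q3/q1)/(2·0.6745) (log-normal) or (q3−q1)/(2·0.6745). Labs are
  rounded to realistic precision (0.1; sodium to integers).
- **Dependence**: one latent "disease severity" factor with loadings 0.65,
  0.35, 0.65 on bilirubin/creatinine/INR and negative loadings on sodium and
  albumin. The albumin loading is found by bisection (common random numbers,
  pilot n = 6,000) so the *computed* MELD of the generated labs hits
  Spearman −0.41 with albumin; the sodium loading is then set so
  albumin↔sodium hits +0.30. Infeasible targets fail before sampling.
- **Mortality**: exponential death times with

      lp = 0.36 · (S − 15) + (ln 1.44 − 0.038 · (S − 30)) · g

  where S is the continuous sodium-adjusted severity (the true MELDNa-like
  quantity, clipped to [6, 40]) and g the albumin deficit. ln 1.44 and 0.038
  are the published albumin hazard and albumin×score interaction. The
  interaction is centered at S = 30 — about where decedents sit — so that the
  fitted *no-interaction* albumin hazard ratio lands inside the published CI
  (observed 1.52 vs 1.44 [1.35–1.54]) while the albumin effect stays positive
  through the top of the scale, as the published score behaves, and is
  greatest at low scores. The base-score coefficient 0.36/point is not
  published; it was calibrated once so the synthetic c-statistic of MELD
  matches the published 0.896 (final synthetic values 0.882/0.890/0.894/0.899
  for MELD/MELD-albumin/MELDNa/5vMELD). The baseline rate is solved so the
  realized Kaplan–Meier 90-day mortality (censoring at transplantation)
  equals its 10% target.
- **Transplantation**: band-specific exponential censoring whose rates are
  solved per band so the *observed* 90-day transplant fraction — transplant
  occurring first, under competing death — matches 3.0/11.4/46.9/61.3% for
  bands <10/10–19/20–29/30–39 (top band defaults to the 30–39 value).
  Administrative censoring closes follow-up at 365 days. Follow-up is
  ceiling-rounded to whole days (minimum 1), creating realistic event-day ties.
- All randomness flows from one seed; both calibrations re-scale a single set
  of unit-exponential draws, so cohorts are byte-identical across runs.

**What the generator does not emulate** — and hence what passing tests do not
show about registry data: no hyperalbuminemic tail (the 0.15% high-mortality
albumin-infusion subgroup), no missing sodium by default (configurable
fraction available), no withdrawal or too-sick-removal processes (only
death/transplant/administrative censoring), no within-band correlation between
transplant access and unmeasured death risk, no time-dependent labs, and
demographics are decorative (they carry no hazard). Proportional hazards and
exponential baselines are assumptions of convenience; the published study fit
semi-parametric models.

## Numerical conventions

Half-up rounding is `floor(x + 0.5)`; truncation is toward zero. Bisections
run 20–60 iterations on log-scaled brackets and are deterministic. The
jackknife SE uses the standard (G−1)/G factor; groups are `arange(n) % G`
permuted. An empty KM risk set or an event-free sample yields mortality 0 with
a warning rather than an error. The derivation split assigns
`round(fraction·n)` candidates to the derivation half.

## Problem sizes

Validation studies in the test suite use one simulated cohort of 20,000
candidates (≈1,900 deaths within 90 days) split 50/50 — matching the scale at
which the published study's comparisons were run — plus 200 replicates of
n = 2,000 for the null-calibration study; unit tests use 1,500–8,000. These
sizes give the stochastic assertions comfortable margins while keeping the
default test run fast.
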