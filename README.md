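# meldkit

Albumin-extended MELD scores for liver-transplant waiting-list mortality:
scoring, score derivation, censoring-aware evaluation, risk reclassification,
and counterfactual allocation analysis — with a calibrated synthetic
waiting-list cohort generator so the whole pipeline is testable without access
to the restricted national registry.

## The problem

Donor livers in most regions are allocated by the **MELD** score,

```
MELD = 10 × (0.957 ln Cr + 0.378 ln Bili + 1.120 ln INR + 0.643)
```

(labs clamped: floor 1.0; creatinine capped at 4.0 mg/dL, set to 4.0 on
dialysis), rounded and constrained to 6–40, or by its sodium adjustment
**MELDNa**:

```
MELDNa = MELD − Na − 0.025 × MELD × (140 − Na) + 140,   Na clamped to [125, 140]
```

Serum albumin — a marker of hepatic synthetic function and malnutrition —
carries mortality information beyond both: about three quarters of waiting-list
registrants are hypoalbuminemic, and each 1 g/dL drop in albumin (bounded 1.0–4.0
g/dL) raises adjusted 90-day mortality hazard roughly 44%, most strongly in
patients with *low* MELD, who are otherwise deprioritized. The albumin-extended
scores add points for the albumin deficit `g = 4.0 − clamp(albumin, 1, 4)` with
an attenuating interaction:

```
extended = base + g × (a + b × base)        # base = MELD or MELDNa (unrounded)
```

rounded and constrained to 6–40. `meld_albumin` extends MELD; `5vmeld` (the
five-variable MELD) extends MELDNa. Coefficients are configuration: the shipped
file carries values reconstructed from the published worked examples (see
`src/meldkit/data/reference_models.yaml`), and `meldkit.derive` re-derives them
from any cohort by Cox regression.

Around the scores, the package implements the full evaluation machinery of a
score-replacement study:

- **cohort** — file I/O, eligibility filtering (adults, first single-organ
  listing, no status-1/inactive/exception cases, complete labs), and
  waiting-list censoring semantics (death within 90 days is the event;
  transplantation, withdrawal and end of follow-up censor; removal "too sick
  to transplant" counts as death by default).
- **derive** — derivation/validation splits, Cox proportional-hazards fits
  (Efron ties, via lifelines), rescaling of albumin coefficients onto
  base-score points, and absolute 90-day risk prediction.
- **evaluate** — Harrell's censoring-aware c-statistic with an exact
  leave-group-out decomposition for group-jackknife model comparisons, and
  Kaplan–Meier mortality.
- **reclassification** — 4-strata risk reclassification tables (0–<5, 5–<10,
  10–<20, ≥20%), net reclassification improvement with asymptotic inference,
  and Hosmer–Lemeshow-type reclassification calibration statistics.
- **counterfactual** — the best-case deaths-averted estimator (band-specific
  transplant probabilities applied to decedents whose band would rise under
  the new score) and the low-MELD point-gain analysis.
- **simulate** — a synthetic cohort generator matched to the published
  cohort's lab marginals, rank correlations (albumin↔MELD −0.41,
  albumin↔sodium +0.30), injected albumin hazard (HR 1.44 per g/dL with a
  0.038 albumin×score interaction), band-specific transplant censoring
  (3.0/11.4/46.9/61.3% at 90 days), and 10% 90-day KM mortality.

## Worked example

The canonical vignette: a patient with refractory ascites, sodium 125 mmol/L,
albumin 2.0 g/dL.

```python
import meldkit as mk

models = mk.default_models()
for m in (10, 30):
    na = mk.meldna(m, 125.0)
    fv = mk.apply_albumin_extension(na, 2.0, models["5vmeld"])
    print(f"MELD {m}: MELDNa = {na.score}, 5vMELD = {fv.score}")

from meldkit.published import death_crosstab_meld_vs_5vmeld
from meldkit.counterfactual import deaths_averted
res = deaths_averted(death_crosstab_meld_vs_5vmeld())
print(f"best-case deaths averted: {res.persons} of {res.total_deaths} "
      f"({100*res.fraction_of_deaths:.1f}%)")
```

prints

```
MELD 10: MELDNa = 21, 5vMELD = 26
MELD 30: MELDNa = 33, 5vMELD = 35
best-case deaths averted: 106 of 1113 (9.5%)
```

At MELD 10, hyponatremia and hypoalbuminemia add 16 points of priority; at
MELD 30 the same labs add only 5 — the interaction terms deliberately damp the
adjustments where the base score is already high. The last line applies
observed 90-day transplant probabilities by MELD band to the published
cross-tabulation of 1,113 validation-cohort decedents: had 5vMELD driven
allocation, an estimated 106 of them (9.5%) would have been transplanted — a
best-case figure that ignores displacement of other candidates.

## Command line

```sh
meldkit simulate --n 20000 --seed 1 --out cohort.csv
meldkit score --model 5vmeld --in cohort.csv --out scored.csv
meldkit derive --base meldna --in cohort.csv --out coeffs.yaml
meldkit evaluate --in cohort.csv --models meld,meldna,5vmeld --out cstats.csv
meldkit reclassify --a meld --b 5vmeld --in cohort.csv --out table.csv --report nri.json
meldkit counterfactual --a meld --b 5vmeld --in cohort.csv --out averted.json
```

Every command writes a `.manifest.json` (seed, version, input digests) beside
its output; identical seeds give byte-identical artifacts.

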