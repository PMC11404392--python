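# Methods

## Scope and data model

The pipeline operates on three flat inputs: a prescription-level extract
(one row = one ambulatory opioid prescription, with the dosage instruction
pre-parsed into `units_per_dose x max_doses_per_day`), a provider roster
(role, specialty, division), and a drug conversion table (mg of opioid per
dispensing unit, oral-MME conversion factor). Free-text sig parsing and EHR
extraction are out of scope: source systems that run this kind of audit
already provide structured dosage fields. Readers validate row by row;
violating rows go to a rejects report with a reason and are never imputed —
these are audit artifacts, and `accepted + rejected = input rows` always
holds.

All dates are ISO-8601 and all windows are half-open `[start, end)`:
calendar quarters tile the year disjointly, and trailing windows are
`(as_of − lookback, as_of]`. This removes every boundary ambiguity of the
"last 12 months" and "quarterly" rules.

## Per-prescription quantities

* `MEDD = strength_mg_per_unit x units_per_dose x max_doses_per_day x
  mme_factor`, the maximum daily dose in oral-morphine milligrams. PRN sigs
  contribute their maximum permitted frequency — conservative, and standard
  MME audit practice.
* `day_supply = quantity_dispensed / (units_per_dose x max_doses_per_day)`,
  unrounded.
* Refills are excluded from both: the prescription as written is the audited
  act. Refills re-enter only in the "active prescription" test below.
* Guideline flags use strict `>` against the configured thresholds (defaults
  5 days / 50 MEDD / 90 MEDD): a prescription at exactly the threshold is
  compliant.

The conversion table ships as a versioned CSV of ~13 common oral opioids
with published oral-MME factors. Methadone carries a flat factor (4.0):
dose-dependent conversion tiers are a documented limitation, as are
transdermal and buccal forms, which the table omits.

## Cohort rules

* **Attribution**: a prescription counts toward the authorizing provider
  when one exists (advanced-practice and house-staff orders), else the
  ordering prescriber.
* **Eligibility**: providers with ≥1 attributed prescription in the
  trailing year, evaluated at the quarter's last day. Eligible providers
  with zero in-quarter prescriptions appear as explicit zero rows — they are
  part of the peer distribution thresholds are computed from.
* **Chronic-use registry**: a patient is chronic at a date iff they have ≥3
  prescriptions in the trailing year and at least one is *active*, defined
  as `written_date + ceil(day_supply x (refills + 1)) ≥ as_of`. "Active"
  had to be pinned here; this is the most inclusive defensible reading and
  is configurable via the day-supply inputs.
* A prescription's own chronic/nonchronic label is evaluated on the day it
  is written, with itself excluded from the count — a prescription can never
  flip its own patient's class, which makes labels deterministic and
  order-free. A patient's third-ever prescription is therefore still
  nonchronic.

## Metrics, thresholds, flags

The five metrics are counted independently (one prescription may contribute
to several). Metrics 4 and 5 default to counting *distinct patients*;
counting prescriptions instead is a configuration switch, recorded in every
output header, because both units are defensible readings of the metric
definitions.

Per (division, specialty) and metric, quartiles use linear interpolation
between closest ranks (numpy default, pinned for reproducibility). The
default outlier threshold is the literal `k x IQR` with `k = 1.5`;
`tukey_fence` mode gives `Q3 + k x IQR`. The rule's phrasing supports
either; the literal reading is the default and the mode is recorded in
report metadata. Extreme outliers sit strictly above `3 x` the outlier
threshold. Note that `1.5 x IQR` is a *low* fence (it is not anchored at
Q3), so small or homogeneous groups flag liberally — with an IQR of 0 any
provider above the common value is an outlier, which is the formula's honest
behaviour, not a bug. Groups smaller than `min_group_size` (default 5) are
computed anyway but flagged `low_n` rather than suppressed, preserving
auditability. Thresholds are recomputed each quarter from that quarter's
distribution.

Report tiers copy upstream values, never recompute them: provider
scorecards (five panels, provider value vs specialty median vs threshold,
with outlier/consistent color keys), leadership scorecards per specialty
(the partition *included = zero-prescribers + within + outliers*, a top-15
list ranked by value with ties broken by provider id, a scatter series, and
a Freedman–Diaconis histogram floored at 5 bins), and CMO tables (one row
per extreme outlier, sorted by the provider's worst value/threshold ratio;
a division's rows are exactly its slice of the enterprise table). JSON/CSV
rendering is deterministic; chart PNGs are best-effort extras.

## Evaluation statistics

Quarterly counts are modelled as `log E[count] = b0 + b1*q`, fit by
Fisher-scoring IRLS (convergence when the largest coefficient step is below
1e-10, cap 50 iterations), with a Wald test on `b1`. `100 x (1 − exp(b1))`
is the percent change per quarter. No exposure offset (the series is raw
division counts) and no overdispersion correction — both noted in outputs;
the Wald p-values are anti-conservative when counts are overdispersed.
The pre/post comparison pools the post quarters into one 2x2 table and uses
Pearson's chi-square without continuity correction; intervals are Wilson
score intervals. Neither choice is forced — they are pinned because they are
standard, well defined, and testable against closed forms (the tests verify
the chi-square against `n(ad−bc)²/(r₁r₂c₁c₂)` and Wilson against its
closed form; the IRLS fit is cross-checked against an independent GLM
implementation).

The reporting `proportion` helper rounds half-up, matching how published
tables are hand-rounded; banker's rounding would silently disagree on ties.

## Synthetic data: what it emulates, what it does not

The generator emulates a 3-division enterprise with 68 specialties and
~2,000 active prescribers over 5 quarters, roughly the published setting's
scale. Specialty sizes are heavy-tailed (lognormal weights), per-provider
quarterly volumes are negative-binomial (Gamma-Poisson, dispersion 6)
around lognormal latent rates (median 8 scripts/quarter, σ = 0.8) —
overdispersion and a heavy right tail are the phenomenon the scorecard
targets. A configurable fraction (default 4%) of providers is injected at
≥5x their specialty's median latent rate and recorded in `truth.csv`.
Exceedance fractions default near the published pre-period proportions
(27% of nonchronic scripts > 5 days, 13% > 50 MEDD, 6.6% of chronic scripts
> 90 MEDD). Chronic-pool patients receive ~12 long (30-day, 3–5 refill)
scripts per year, so they satisfy the registry rule by construction; all
other patients are single-prescription. An optional quarterly ratio scales
expected volume multiplicatively.

What it does not emulate: diagnosis codes and clinical context (the "OUD"
qualifier is operationalized purely by the prescription-count registry),
pharmacy adjudication, patient sharing between providers, seasonal
structure, or within-provider behaviour change. Passing tests therefore
demonstrate that the machinery is correct under realistic volume and
dispersion — not that real EHR extracts are this clean.

## Problem sizes and numerical choices

Tests and the acceptance script run the full pipeline at the default
enterprise scale (~2,000 providers, ~130,000 prescriptions over 5 quarters)
and the statistics at the published division volume (~400,000 prescriptions
per quarter), with 100–1,000 replicates for stochastic checks; these sizes
keep a complete run in the low tens of seconds while leaving Monte-Carlo
error well below the tolerances asserted. Chronicity labelling is exact
(pairwise within patient), not approximated, since patients with enough
prescriptions to matter are few. Ranking and flag ties are broken
deterministically (provider id ascending; strict `>` everywhere), so reruns
are byte-identical.

## Known limitations

* MEDD conversion factors vary slightly between published factor tables;
  results depend on the shipped table, which is versioned for that reason.
* The `1.5 x IQR` vs Tukey-fence ambiguity is real; both are implemented
  and neither is asserted to be the source institution's behaviour.
* The Poisson trend ignores overdispersion and eligibility offsets.
* The chronic registry is prescription-count-based only; a diagnosis-based
  opioid-use-disorder filter, if one existed upstream, is not modelled.
* De-duplication of prescriptions recorded both at ordering and at fill is
  assumed to have happened upstream (one row = one prescription).
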