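# rxscorecard

Quarterly opioid-prescribing scorecards by peer comparison, as a reusable
pipeline: from prescription-level records to per-provider metrics,
per-specialty outlier thresholds, three tiers of reports, and the trend
statistics used to evaluate whether prescribing changed.

## Who this is for

Health-system quality and informatics teams who want audit-and-feedback
("peer comparison") reporting on ambulatory opioid prescribing: show every
prescriber how their habits compare to peers in the same specialty and
division, give department leaders the distribution, and give chief medical
officers a short table of the providers furthest outside their peer group.

## The model

For each prescription, two derived quantities drive everything:

* **MEDD** (morphine equivalent daily dose) — the maximum daily opioid dose
  in oral-morphine milligrams,
  `MEDD = strength_mg x units_per_dose x max_doses_per_day x conversion_factor`;
* **calculated day supply** — `quantity_dispensed / (units_per_dose x
  max_doses_per_day)`.

Each eligible provider (≥1 attributed prescription in the trailing 12
months; prescriptions count toward the authorizing provider when one exists)
gets five quarterly metrics:

1. total opioid prescriptions;
2. distinct patients prescribed to;
3. prescriptions to nonchronic patients with day supply **> 5 days**;
4. nonchronic patients with prescriptions **> 50 MEDD**;
5. chronic patients with prescriptions **> 90 MEDD**;

where *chronic* means ≥3 opioid prescriptions in the trailing year with one
still active. Within each (division, specialty) peer group the outlier
threshold for a metric is `1.5 x IQR` of the provider distribution (the
conventional Tukey fence `Q3 + 1.5 x IQR` is available by configuration),
and the extreme-outlier threshold is 3x the outlier threshold. Impact is
evaluated with a Poisson log-linear trend on quarterly counts
(`log E[count] = b0 + b1 * quarter`) and pre/post chi-square tests on
guideline-exceedance proportions with Wilson confidence intervals.

## Worked example

The package ships a 21-prescription hand-auditable dataset
(`rxscorecard.generate_worked_fixture`) whose metrics are known by hand:

```sh
python - <<'EOF'
import pathlib, tempfile
import rxscorecard as rx
from rxscorecard.cli import load_dataset, score_quarter

tmp = pathlib.Path(tempfile.mkdtemp())
rx.generate_worked_fixture(tmp)
drug_table, roster, result = load_dataset(tmp)
table, thresholds, flags, bundle = score_quarter(
    result.frame, drug_table, roster, rx.RunConfig(), "2021Q3")
print(table.to_string(index=False))
print(flags[flags.status != "within"][["provider_id", "metric", "value",
      "outlier_threshold", "status"]].to_string(index=False))
EOF
```

prints the metric table

```
provider_id quarter  m1_rx_count  m2_patient_count  m3_gt5day  m4_gt50medd  m5_gt90medd
        P01  2021Q3            5                 4          3            1            0
        P02  2021Q3            6                 6          1            5            0
        P03  2021Q3            2                 2          1            0            1
        P04  2021Q3            0                 0          0            0            0
        P05  2021Q3            1                 1          0            0            0
        P07  2021Q3            1                 1          0            1            0
        P08  2021Q3            1                 1          0            0            0
```

— P04 prescribed nothing this quarter but stays in the peer distribution
because of a prescription earlier in the year — and the flag table shows,
among others, that P02 is an **extreme outlier** on metric 4 (5 nonchronic
patients above 50 MEDD against a specialty threshold of 1.5, beyond the
extreme cutoff of 4.5), which is exactly the row the chief-medical-officer
report surfaces.

The same pipeline is available from a shell:

```sh
rxscorecard simulate --out data --seed 7
rxscorecard score --data data --quarter 2021Q2 --out out
rxscorecard trend --data data --out out/trend
```

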