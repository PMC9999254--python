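# hapiphen

EHR phenotyping for **hospital-acquired pressure injuries (HAPI)**.

Pressure injuries (PIs, also charted as pressure ulcers, decubitus ulcers or
bedsores) are staged 1–4, with two categories that carry no visible numeric
stage: deep tissue injury (DTI) and unstageable. A HAPI is a PI that is new
or has worsened during a hospital stay — a core nursing-quality metric with
direct reimbursement consequences. Identifying HAPI stays in an EHR is hard
because the four data sources that can document a PI (timed chart events,
free-text notes, untimed ICD-9 diagnosis codes, procedure codes) frequently
disagree, and published MIMIC-III case definitions disagree with each other.

`hapiphen` is for clinical-informatics researchers who need reproducible
HAPI labels and honest classifier benchmarks. It provides:

* **A configurable rule engine** implementing four published labeling
  policies — EHAPI, CANTRIP, Cramer and Sotoodeh — parameterised by eight
  decision dimensions: exclusion of in-hospital deaths (D1), minimum age
  (D2), the admission window for present-on-admission PIs (D3), minimum
  numeric stage (D4), inclusion of DTI/unstageable events (D5), the note
  keyword route (D6), the new-or-worsened requirement (D7) and the ICD-9
  route (D8). The staging route compares an admission stage
  `adm = max over events ≤ cutoff of enc_adm(token)` with a discharge stage
  (last qualifying event after the cutoff under `enc_dis`), where
  `enc_adm(DTI)=4, enc_dis(DTI)=3, enc_adm(unstageable)=0,
  enc_dis(unstageable)=5`, and fires when `dis ≥ D4` (and `dis > adm` when
  D7 is on).
* **Keyword scanning with trigger-window negation** ("no bedsore observed",
  "bedsore: none") over a configurable lexicon.
* **Congruence analytics**: exact UpSet combination counts over source
  indications and over per-definition case sets.
* **A leakage-safe benchmark**: per-stay event timestamps (earliest timed PI
  evidence > 24 h for evidence stays; for the rest, durations sampled from
  the best chi-square parametric fit to case note durations and matched to
  true note spans by rank, `offset_k = min(sampled_(k), true_(k))`),
  documents restricted to notes strictly before the timestamp with lexicon
  phrases scrubbed, TF-IDF + gradient boosting and an embedding/max-pool
  sequence network, AUPRC/AUROC over repeated test sets, and a one-sided
  paired t-test between definitions.
* **A synthetic MIMIC-schema cohort generator** with planted PI
  trajectories, configurable source incongruence and exact ground-truth
  bookkeeping.

## Worked example

Generate a 300-stay synthetic cohort and compare the four definitions:

```bash
$ hapiphen simulate --n-stays 300 --seed 5 --out demo/
wrote 7 tables + ground_truth.csv to demo/

$ hapiphen compare-definitions --data demo/ --out demo/overlap.csv
{"union_cases": 25,
 "case_counts": {"ehapi": 16, "cantrip": 15, "cramer": 14, "sotoodeh": 21},
 "prevalence_pct": {"ehapi": 5.93, "cantrip": 5.14, "cramer": 4.73, "sotoodeh": 7.09}}

$ hapiphen label --data demo/ --definition ehapi --out demo/labels.csv
{"definition": "ehapi", "n_stays": 300, "n_eligible": 270, "n_cases": 16,
 "prevalence_pct": 5.93}
```

Reading the numbers: 25 stays are a case under at least one definition, but
the four policies each count a different subset (16, 15, 14 and 21 cases) —
the definitions genuinely disagree even on clean synthetic data, because
they differ in admission windows, minimum stages and which evidence routes
they accept. Under EHAPI, 30 of 300 stays are excluded (deaths in hospital,
under-age patients, present-on-admission PIs), leaving 270 eligible and a
5.9% prevalence. `demo/labels.csv` carries one row per stay with its
status (case/control/excluded), the route that fired (staging, keyword or
icd9), the event timestamp and the exclusion reason.

The same operations are available as library calls
(`hapiphen.label_cohort`, `hapiphen.congruence.definition_overlap`,
`hapiphen.benchmark.run_benchmark`); see `docs/methods.md` for the model
details and parameter semantics.

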