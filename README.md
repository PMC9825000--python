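# stageinv

Stage inference for non-small cell lung cancer (NSCLC) by **inverting the
treatment-decision rules** encoded in routinely collected claims and EHR
data.

## The problem

Administrative healthcare databases carry diagnosis, procedure and
medication codes for huge, population-representative cohorts — but rarely
the TNM stage, which is what oncology research actually stratifies on.
Guideline-recommended NSCLC treatment, however, is (largely) a function of
stage: surgery alone for early disease, surgery plus adjuvant therapy in
the middle, concurrent chemoradiation for locally advanced unresectable
disease, chemotherapy alone for metastatic disease. Restricted to treatment
patterns with a unique pre-image, that decision function `f: stage →
treatment` can be inverted, so the *observed* pattern of surgery,
chemotherapy (CTx) and radiotherapy (RTx) reads the stage back out:

| class | treatment pattern                          | TNM (7th ed.) stage |
|-------|--------------------------------------------|---------------------|
| 1     | surgical resection                         | IA, IB, IIA         |
| 2     | surgery + adjuvant CTx                     | IIB                 |
| 3     | surgery + adjuvant CTx, then adjuvant RTx  | IIIA                |
| 4     | surgery + adjuvant RTx, then adjuvant CTx  | IIIA                |
| 5     | neoadjuvant CTx + surgery                  | IIIA                |
| 6     | concurrent chemoradiation (no surgery)     | IIIB                |
| 7     | chemotherapy only                          | IV                  |

Patterns outside the table (RT alone, trimodality chemoradiation before
surgery, chemo in no recognizable temporal relation to surgery, ...) are
reported as `unclassified` rather than coerced.

The package provides, for this classifier:

- **`stageinv.io`** — delimited event / patient / code-map tables, config;
- **`stageinv.cohort`** — eligibility and washout filters with an attrition log;
- **`stageinv.patterns`** — merging coded events into treatment courses and
  extracting the temporal pattern (adjuvant / neoadjuvant / concurrent);
- **`stageinv.classifier`** — the seven-class inverse rule set and its
  fine/coarse stage projections;
- **`stageinv.metrics`** — confusion matrix, overall accuracy, one-vs-rest
  sensitivity / specificity / PPV / NPV / F1 / c-statistic with
  percentile-bootstrap CIs (for a hard classifier the c-statistic is the
  balanced accuracy, (Se + Sp)/2);
- **`stageinv.survival`** — Kaplan–Meier product-limit curves with Greenwood
  variance and plain-scale normal-approximation CIs, global and pairwise
  Bonferroni-corrected log-rank tests, and comparison of class-specific 2-
  and 5-year survival against published per-stage reference rates;
- **`stageinv.simulate`** — a synthetic cohort generator producing coded
  treatment sequences *forward* from the same decision rules (with tunable
  guideline concordance) and stage-specific Weibull survival calibrated to
  the reference 2-/5-year rates, so the entire pipeline is testable without
  access-restricted patient data.

## Worked example

```python
from stageinv import SimulationParams, simulate_cohort, default_code_map
from stageinv.pipeline import evaluate_validation, survival_by_class, reference_comparison

params = SimulationParams(n_patients=1375, concordance=0.9, seed=42)
records, truth = simulate_cohort(params)
code_map = default_code_map()

results = evaluate_validation(records, code_map, B=1000, seed=42)
print(f"overall accuracy: {results['overall_accuracy']:.3f}")
print(results["metric_table"].to_string(index=False))
```

prints

```
overall accuracy: 0.905
     metric                 I                II               III                IV
sensitivity 0.91 (0.89, 0.92) 0.90 (0.85, 0.95) 0.93 (0.88, 0.98) 0.88 (0.83, 0.92)
specificity 0.98 (0.96, 0.99) 0.98 (0.97, 0.98) 0.95 (0.93, 0.96) 0.98 (0.98, 0.99)
        ppv 0.99 (0.98, 1.00) 0.81 (0.75, 0.87) 0.55 (0.48, 0.62) 0.88 (0.84, 0.93)
        npv 0.82 (0.79, 0.85) 0.99 (0.98, 0.99) 1.00 (0.99, 1.00) 0.98 (0.97, 0.99)
         f1 0.95 (0.93, 0.96) 0.85 (0.81, 0.89) 0.69 (0.62, 0.75) 0.88 (0.84, 0.92)
c_statistic 0.94 (0.93, 0.95) 0.94 (0.91, 0.96) 0.94 (0.91, 0.96) 0.93 (0.91, 0.95)
```

1375 synthetic patients were generated with the validation-study coarse
stage mixture (68.6 / 8.9 / 7.9 / 14.5 % for I / II / III / IV); 90 % of
them received the guideline pattern for their stage, the rest a random
other class's pattern. The classifier recovers the coarse stage for 90.5 %
of patients; each cell shows the point metric and its 95 %
percentile-bootstrap CI over 1000 patient-level resamples. Survival follows
the same route:

```python
groups = survival_by_class(records, code_map)
print(reference_comparison(groups)[["class_id", "n", "stage",
      "reference_2yr", "predicted_2yr", "diff_2yr"]].round(3).to_string(index=False))
```

```
 class_id   n stage  reference_2yr  predicted_2yr  diff_2yr
        1 880    IA           0.93          0.903       NaN
        1 880    IB           0.85          0.903       NaN
        1 880   IIA           0.74          0.903       NaN
        2 158   IIB           0.64          0.652     0.012
        3  39  IIIA           0.55          0.641     0.091
        4  33  IIIA           0.55          0.727     0.177
        5  32  IIIA           0.55          0.625     0.075
        6  52  IIIB           0.34          0.423     0.083
        7 181    IV           0.17          0.265     0.095
```

Per class: its size, the Kaplan–Meier 2-year survival, the published
reference rate for the stage the class inverts to, and the signed
difference (class 1 maps to three stages, so no single difference is
formed). With 10 % treatment deviations, small advanced-stage classes pick
up misclassified early-stage patients and their observed survival drifts
above the reference — exactly the kind of misclassification bias the
validation machinery is there to quantify.

The same pipeline is scriptable from a shell: `stageinv simulate`,
`stageinv classify`, `stageinv validate`, `stageinv survival` (see
`stageinv --help`).

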