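# spdq

Scoring, development and validation toolkit for the **Spine painDETECT
questionnaire (SPDQ)** and its two-item short form (**SF-SPDQ**) — screening
instruments for neuropathic pain caused by spinal disorders (NeP-SD), built
by re-weighting the nine items of the painDETECT questionnaire (PD-Q).

It is intended for clinical researchers working with patient-reported pain
questionnaires: it scores cohorts, re-derives instruments from labeled data
with the same statistical recipe the published tools were built with, and
reports the standard diagnostic-accuracy statistics.

## The instruments

Each of the seven sensory items (burning, tingling, pain by light touch,
electric shock-like pain, pain on cold/heat stimulation, numbness, pain by
slight pressure) is graded 0–5 (never … very strongly). The pain-course
pattern contributes 0 / −1 / +1 / +1 depending on the category, and
radiating pain contributes 2 (yes) or 0 (no).

| | PD-Q | SPDQ weight | SF-SPDQ weight |
|---|---|---|---|
| burning | + | ×(+1) | — |
| tingling | + | ×(+2) | — |
| light touch | + | ×(−2) | — |
| electric shock | + | ×(−4) | ×(−4) |
| cold/heat | + | ×(−3) | — |
| numbness | + | ×(+8) | ×(+9) |
| slight pressure | + | ×(+1) | — |
| course pattern | + | ×0 | — |
| radiating | + | ×(+1) | — |
| constant subtracted | 0 | 12 | 7 |

The PD-Q total (unweighted sum) ranges −1…38, banded *unlikely* (≤12),
*uncertain* (13–18), *likely* (≥19). SPDQ and SF-SPDQ totals are the
weighted sums minus the constant, **positive at ≥ 0** (possible spinal
neuropathic pain); attainable ranges are −57…50 and −27…38.

The development machinery reproduces the recipe behind those numbers: a
two-group Fisher (canonical) discriminant `w ∝ W⁻¹(μ_case − μ_control)`
gives raw item coefficients, which are scaled and rounded to small integers;
the ROC threshold maximizing sensitivity + specificity becomes the constant
term; stepwise discriminant analysis (Wilks' lambda partial F, entry/stay
significance 0.15) selects short-form items. Validation uses exact-rational
sensitivity/specificity/PPV/NPV/likelihood ratios, the tie-aware
Mann–Whitney AUC, and Cohen's kappa for test–retest agreement.

Because no patient-level data were ever published, the package includes a
synthetic-cohort generator driven by the published per-group, per-item
response-count tables of the two validation cohorts (`multicenter`,
29 NeP-SD / 16 NocP controls; `websurvey`, 250 / 250).

## Worked example

```sh
$ spdq simulate --profile websurvey --n 250 --seed 7 --out cohort.csv
sampled 500 records from profile 'websurvey' -> cohort.csv

$ spdq score --input cohort.csv --out scored.csv
scored 500 rows (500 complete on all nine items) -> scored.csv

$ spdq evaluate --input cohort.csv --instrument sf-spdq --out report.json
SF-SPDQ on n=500: sens 85.2% spec 61.6% AUC 0.81 LR+ 2.2 LR- 0.2 PPV 68.9% NPV 80.6%
```

The simulated cohort reproduces the published web-survey *marginals* with
independent items, and the SF-SPDQ screen on it lands close to the
published operating point (sensitivity 84.4%, specificity 61.2%): high
sensitivity, modest specificity — a screen, not a diagnosis. Re-deriving an
instrument from the same cohort:

```sh
$ spdq develop --input cohort.csv --select --seed 7 --out instrument.json
developed instrument on 500 complete cases (0 excluded)
  weights: {'burning': 4, 'tingling': 3, 'cold_heat': 2, 'numbness': 9, 'slight_pressure': -2}
  constant: 25  cutoff: >= 0
```

Numbness dominates (weight +9), exactly as in the published instruments —
it is the one item whose response distribution separates the groups
sharply. The Python API mirrors the CLI:

```python
from spdq import QuestionnaireRecord, SF_SPDQ, score_instrument

rec = QuestionnaireRecord(numbness=3, electric_shock=1)
score_instrument(rec, SF_SPDQ)
# ScoreResult(instrument_name='SF-SPDQ', total=16, classification='positive', complete=True)
```

(9×3 − 4×1 − 7 = 16 ≥ 0 → screen positive.)

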