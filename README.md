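# pfindex

Lesion-quality analytics for **pulsed field ablation (PFA)** in the beating
swine ventricle: an implementation of the **PF index**, a score that combines
catheter **contact force** (CF, grams) and the number of PFA **applications**
("dose") to predict the depth of the resulting ventricular lesion.

PFA kills myocytes by irreversible electroporation rather than heating, and
the role of catheter–tissue contact in PFA lesion formation is much less
settled than it is for radiofrequency ablation. The PF index addresses the
question quantitatively: depth grows with dose, but *asymptotically* — each
extra application deepens the lesion by a diminishing increment — and the
gain at every dose is modulated by force. The index encodes this as

```
PFI(F, n) = A · ( B(F) · ln n + C(F) ),   B(F) = b0 + b1·F,   C(F) = c0 + c1·F
```

with `n` the application count, `F` the mean contact force (g), and `A`
fixed at 100 so that **PFI / 100 is the expected lesion depth in mm**. A
lesion titrated to an index of 450 is expected to be ≈4.5 mm deep, within a
±2 mm prediction band.

The package is aimed at preclinical ablation analysts and methodologists:
the raw per-lesion data behind the published summary statistics were never
deposited, so everything here operates either on your own lesion tables
(CSV, one row per lesion) or on **synthetic lesion datasets whose generators
are calibrated to the published marginal statistics** of the two study arms
(111 characterization lesions; 73 validation lesions).

## What is in the box

| module | contents |
|---|---|
| `pfindex.index` | the index formula, expected depth (PFI/100), CF/PFI strata, titration-to-target simulation |
| `pfindex.datagen` | `LesionRecord` CSV schema, characterization & validation generators, calibration of generator parameters to marginal statistics |
| `pfindex.fitting` | `PFIndexModel` / `PFIndexResults` — least-squares estimation of (b0, b1, c0, c1) from per-lesion data, statsmodels-style |
| `pfindex.stats` | OLS, one-way ANOVA, χ², grouped MAD outlier screening, strata summaries, ±2 mm accuracy |
| `pfindex.pipeline` | end-to-end characterization / validation / titration analyses with exclusion accounting, JSON + Markdown reports |
| `pfindex.experiments` | seeded replicate (Monte-Carlo) experiments over the generators |

A `pfindex` CLI wraps the pipeline (`generate`, `fit`, `characterize`,
`validate`, `titrate`, `all`).

## Worked example

```python
>>> from pfindex import (default_index_parameters, pf_index,
...                      simulate_titration, run_validation, PipelineConfig)
>>> params = default_index_parameters()   # calibrated to the published marginals
>>> {k: round(v, 4) for k, v in params.to_dict().items()}
{'b0': 1.2101, 'b1': 0.0077, 'c0': 0.6512, 'c1': 0.0064, 'a': 100.0}

>>> round(pf_index(32.0, 12, params), 1)   # mean study force, top dose
447.2
```

447/100 ≈ 4.5 mm expected depth — the published mean depth at the ×12 dose
was 4.52 mm. Titrating to a target of 450 at 55 g stops, per the foot-pedal
rule, at the first application whose running index reaches the target:

```python
>>> run = simulate_titration(450, [55.0], params, max_applications=12)
>>> run.applications_delivered, round(run.attained_pfi, 1), run.stopped_reason
(9, 458.8, 'target_reached')
>>> [round(v) for v in run.pfi_trajectory]
[100, 213, 280, 326, 363, 393, 418, 440, 459]
```

Note the shrinking increments (113, 67, 46, …): the asymptotic dose
response. A 600 target is *not* attainable within the 12-application
protocol at any supported force — the index saturates in the ~550 range,
matching the study's observation.

Running the validation analysis on one synthetic 73-lesion dataset:

```python
>>> report = run_validation(PipelineConfig(seed=7))
>>> report["accuracy"]
{'tolerance_mm': 2.0, 'fraction': 0.9589..., 'numerator': 70, 'denominator': 73}
```

70/73 lesions (96 %) have their depth predicted within ±2 mm by PFI/100 —
the study reported 69/73 (95 %).

Same thing from the shell:

```sh
pfindex validate --seed 7 --markdown
pfindex generate --seed 1 --dataset characterization --out lesions.csv
pfindex fit --lesions lesions.csv
```

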