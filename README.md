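# lungmorph

Histomorphometric quantification of air-space over-distension in lung
histology, for forensic differentiation of pulmonary barotrauma (with
arterial gas embolism, PBt/AGE) from drowning and non-diving causes of
death.

When a diver ascends while breath-holding, expanding gas over-distends and
ruptures the air spaces distal to the terminal bronchiole. On an
H&E-stained lung section this leaves a measurable signature: fewer, larger,
confluent air spaces. `lungmorph` turns calibrated brightfield field images
into that signature and into a diagnostic decision rule:

1. **Segmentation** — an adaptive threshold on the red channel separates
   unstained air from eosin-stained parenchyma, followed by automatic
   (Otsu) binarization, chromatic exclusion of oedema / erythrocytes /
   intra-alveolar cells, connected-component labeling, and removal of
   objects below 100 µm². Air spaces truncated at the field border are
   kept.
2. **Morphometry** — per field: the count of air spaces (CAS), the total
   area they occupy (AAS, µm²), the percentage of the field they occupy
   (PAS), and per object the maximum and minimum Feret (caliper) diameters
   (MaxDAS/MinDAS, µm). Per case: means over fields, with the
   area-per-air-space ratio AAS/CAS averaged per field.
3. **Statistics** — one-way ANOVA with Bonferroni post hoc contrasts
   against the drowning reference group (Shapiro–Wilk and Levene reported
   descriptively), and ROC analysis of the barotrauma group against the
   pooled controls: Mann–Whitney pair-counting AUC (ties ½), rank-sum
   p-value, and a Youden-J cut-off with its sensitivity and specificity.
4. **Synthetic histology** — a seeded generator of ground-truthed
   H&E-like parenchyma fields (Voronoi alveolar architecture, wall deletion
   as the over-distension mechanism, oedema/vessel/cell artifacts), with
   group presets calibrated end-to-end so pipeline-measured PAS approaches
   the published group levels (≈65 / 38 / 42 %). No autopsy material is
   required to exercise or validate the pipeline.

The statistics layer follows a model/results design:
`AirspaceDiagnostics` (built from a per-case DataFrame or
`CaseSummary` list) fits to a `DiagnosticReport` with `summary()`,
Table-style exports and ROC plotting.

## Worked example

Simulate a three-group study (6 cases per group, 4 slides per case, 6
fields per slide) and fit the diagnostic model:

```python
from lungmorph import TissueParams, default_presets, run_synthetic_study

base = TissueParams(field_width_px=256, field_height_px=192, um_per_px=1.4)
presets = default_presets(base)
spec = [(presets[g], 6) for g in ("pbt", "drowning", "control")]
result = run_synthetic_study(spec, slides_per_case=4, fields_per_slide=6, seed=0)
print(result.report.summary())
```

```
Group comparison (ANOVA + Bonferroni post hoc)
         parameter                    pbt           drowning            control   anova_F      anova_p
    Mean AAS (um2)  70451.74 (7819.45) ** 31147.14 (2639.56) 38214.39 (5790.33) 77.747017 1.210223e-08
Mean AAS/CAS (um2) 54299.09 (16244.85) ** 10117.17 (1808.69)  9791.43 (1151.36) 43.946305 5.343220e-07
      Mean PAS (%)        73.13 (8.12) **       32.33 (2.74)       39.67 (6.01) 77.747017 1.210223e-08
  Maximum DAS (um)      285.75 (71.87) **      132.22 (9.52)      134.05 (6.99) 26.345605 1.235072e-05
  Minimum DAS (um)      158.89 (49.65) **       67.38 (3.95)       67.87 (2.78) 20.085632 5.725817e-05

ROC: pbt vs pooled other groups
         parameter  auc    auc_p auc_flag       cutoff  sensitivity_percent  specificity_percent
      Mean PAS (%)  1.0 0.000108       **    55.969154                100.0                100.0
  ...
```

Reading the output: the barotrauma group occupies roughly twice the field
area with air (PAS 73 % vs 32/40 %), each air space is several times larger
(AAS/CAS), and the contrast against drowning is significant at p < 0.01
(`**`) for every parameter. On this simulated cohort every parameter
separates the groups perfectly (AUC 1.0); on the real biological scale the
published per-case spread makes the separation imperfect (AUC ≈ 0.81–0.94,
see below). A PAS cut-off of ≈56 % classifies every simulated case
correctly.

The same analysis runs from the shell over an on-disk cohort:

```bash
lungmorph simulate --outdir cohort --seed 3 --cases-per-group 6
lungmorph run --manifest cohort/manifest.csv --outdir results --seed 0
```

`run` applies the case-eligibility filter first (age > 65 years, post-mortem
interval > 30 h, high-pressure-oxygen CPR, ICU admission, chronic
emphysema), samples six fields per slide, and writes per-object, per-field
and per-case CSVs plus the two report tables and a JSON report.

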