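# maldipept

Serum MALDI-TOF peptidome profiling for predicting chemotherapy response in
small-cell lung cancer (SCLC), as an open, tested pipeline.

Linear-mode MALDI-TOF mass spectrometry of serum peptides (m/z 800–10,000 Da)
can separate SCLC patients who respond to first-line chemotherapy from those
who progress. The workflow this package implements is the classic
ClinPro-style recipe:

1. **Spectral preprocessing** — total-ion-current normalisation,
   recalibration against prominent common peaks, morphological "top-hat"
   baseline subtraction (minimum baseline width 10% of the m/z range),
   Savitzky–Golay smoothing, S/N ≥ 5 peak detection, zero-level peak-area
   integration, and cross-sample peak alignment into a sample × peak matrix.
2. **Differential screening** — per peak, a Welch t-test and an oriented ROC
   AUC between the *response* and *progression* groups; a peak is selected
   when p < 10⁻⁴ and AUC ≥ 0.75.
3. **Classification** — a genetic algorithm searches small peak panels and
   the neighbour count k of a k-nearest-neighbour classifier (Euclidean
   distance on z-scored areas), scored by repeated stratified holdout
   cross-validation (20% omitted, 10 iterations). Both the cross-validation
   rate and the resubstitution ("recognition") rate are reported, and the
   model is applied blindly to a validation cohort.
4. **Survival analysis** — Kaplan–Meier curves of progression-free and
   overall survival by classifier-assigned group, median survival with 95%
   CI (exponential-Greenwood bands), and the two-group log-rank test.

Because the patient sera behind such studies are typically not deposited,
the package ships a first-class synthetic-cohort generator
(`maldipept.synthdata`) that draws peak-area matrices, full profile spectra,
and linked survival times from the published group statistics (44 detectable
peaks of which 10 differ between groups at stated means ± SD; cohorts of
50/46 and 30/28; survival medians 9/3 months PFS, 13/7 months OS). Every
stage of the pipeline is testable against this generator's ground truth.

## Core quantities

For peak areas x in two groups with sample sizes n₁, n₂:

- Welch t = (x̄₁ − x̄₂) / √(s₁²/n₁ + s₂²/n₂), two-sided p from the t
  distribution with Welch–Satterthwaite degrees of freedom.
- AUC = (concordant pairs + ½ ties) / (n₁ n₂), reported as max(AUC, 1−AUC)
  with an explicit up/down-in-progression direction flag.
- Kaplan–Meier Ŝ(t) = Π_{tᵢ ≤ t} (1 − dᵢ/nᵢ); log-rank
  χ² = (ΣO − ΣE)² / ΣV with hypergeometric expectations per event time.
- GA fitness = mean holdout accuracy (%) − 0.5 × (panel size), maximised
  over feature subsets (≤ 8 peaks) and k ∈ {1, 3, 5, 7, 9}.

## Worked example

```python
import maldipept as mp

train = mp.generate_peak_table(mp.CohortConfig(seed=1))          # 50 + 46
screen = mp.screen_differential_peaks(train)
print(int(screen["selected"].sum()))                             # 9

model, report = mp.ga_select_features(train, cfg=mp.GAConfig(seed=1))
print([round(mz, 2) for mz in model.selected_mzs], model.k)
print(round(report.cross_validation_rate, 2), round(report.recognition_rate, 2))

val = mp.generate_peak_table(mp.validation_cohort_config(seed=2))  # 30 + 28
pred = mp.blind_classify(model, val)
cm = mp.confusion_metrics(val.group_labels, pred)
print(cm.summary())
```

prints (seed-exact):

```
7
[2082.49, 3158.66, 3323.35, 6496.45, 6649.03, 6795.74] 5
100.0 100.0
predicted    progression  response
true
progression           26         2
response               2        28

progression: 92.9% correct
response: 93.3% correct
overall accuracy: 93.1%
```

Seven of the ten configured differential peaks pass the dual screen in this
draw; the GA panel is led by the two strongest peaks (m/z 3323.35 and
6649.03, five of its six members are truly differential), cross-validates
perfectly on this synthetic training cohort, and classifies 54 of 58
blinded validation samples correctly.

The same workflow is scriptable from the shell:

```sh
maldipept simulate --cohort training --seed 1 --out train --survival
maldipept screen   --matrix train/areas.csv --out diffpeaks.csv
maldipept train    --matrix train/areas.csv --seed 1 --model model.json
maldipept classify --model model.json --matrix validation/areas.csv --out pred.csv
maldipept survive  --records train/survival_pfs.csv --out km.csv
```

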