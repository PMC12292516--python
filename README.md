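# somascan

Heath–Carter somatotyping from manual anthropometry **and** from full-body
3D-scan measurements, plus the method-comparison statistics needed to
validate the scan pathway against the manual reference.

Somatotyping summarises a physique as three numbers — endomorphy (relative
fatness), mesomorphy (musculoskeletal robustness), ectomorphy (linearity)
— on an open-ended scale conventionally floored at 0.1. The classical
protocol needs a trained anthropometrist with skinfold calipers, tape and
bone calipers. Optical full-body scanners measure circumferences and
breadths in seconds but cannot pinch skinfolds and often miss the head
apex, so a fully automated pathway needs two substitutions. `somascan`
implements both pathways and the statistics to compare them; it is aimed
at sports scientists, anthropometrists and biomedical engineers evaluating
scanner-based body-composition workflows.

## The model

**Manual (reference) pathway**, with skinfolds *SF* in mm, lengths in cm:

- endomorphy: with X = (SF_triceps + SF_subscapular + SF_supraspinale) · 170.18/height,
  `endo = −0.7182 + 0.1451·X − 0.00068·X² + 0.0000014·X³`
- mesomorphy: `0.858·humerus + 0.601·femur + 0.188·(biceps − SF_triceps/10)
  + 0.161·(calf − SF_calf/10) − 0.131·height + 4.5`
- ectomorphy from the height-to-weight ratio `HWR = height / weight^(1/3)`:
  `0.732·HWR − 28.58` for HWR ≥ 40.75; `0.463·HWR − 17.63` for
  38.25 ≤ HWR < 40.75; `0.1` below.

**Scan pathway** replaces what the scanner cannot measure:

- stature from the floor-to-C7-vertebra landmark (mm):
  `height = a·C7 + b`, shipped calibration `a = 0.1039`, `b = 19.39`
  (R² = 0.9218, Sy.x = 2.535 cm, n = 117), refittable with
  `fit_height_model`;
- relative fatness from the US Navy circumference equations (base-10 logs,
  cm), e.g. men: `BF% = 495/(1.0324 − 0.19077·log₁₀(waist − neck)
  + 0.15456·log₁₀(height)) − 450`, then `endo = BF%/5`;
- mesomorphy with the same linear form but uncorrected girths (no
  skinfolds), optionally taking caliper breadths (hybrid mode) to isolate
  the scanner's landmark error.

Both pathways feed a deterministic 13-category classifier (central,
balanced/dominant/co-dominant types) and somatochart coordinates
`x = ecto − endo`, `y = 2·meso − (endo + ecto)`. The agreement module
implements Bland–Altman limits of agreement, ICC(A,1) and ICC(C,1), SEE,
SME, CV and RMSE; the cohort module simulates paired manual/scan datasets
with configurable scanner bias so the whole validation design runs with no
external data.

## Worked example

`python examples/compute_somatotype.py` runs one physique through both
pathways:

```
manual pathway: endo 3.69  meso 5.46  ecto 1.63  HWR 41.28  BMI 24.17  category: endomorphic mesomorph
  scan pathway: endo 3.56  meso 5.84  ecto 1.64  HWR 41.29  BMI 24.16  category: endomorphic mesomorph
        circumference body fat: 17.79% (endomorphy = BF%/5)
```

The pathways agree to ~0.1–0.4 component units here: the scan endomorphy
comes from circumference body fat (17.79%/5) instead of skinfolds, and the
scan mesomorphy is slightly higher because girths enter uncorrected. Other
examples: `height_model.py` (calibration refit), `validation_study.py`
(full 117-subject synthetic validation with the agreement table and
13-category agreement), `classify_and_chart.py` (classifier + somatochart).

A thin CLI wraps the same functions:

```sh
somascan simulate --n 117 --seed 1 --out-dir data/
somascan compute --input data/manual.csv --pathway manual --out somato.csv
somascan validate --manual data/manual.csv --scan data/scan.csv --refit \
    --out agreement.csv --plots plots/
```

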