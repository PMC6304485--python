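# ivimr2

Quantitative liver-MRI analysis for staging early fibrosis: biexponential
**intravoxel incoherent motion (IVIM)** modelling with segmented fitting of
(D, D\*, f), multi-echo **R2\* relaxometry**, voxel-wise parameter maps with
fixed-area ROI measurement, a calibrated **synthetic rat-cohort generator**,
and the nonparametric statistical battery used in small-animal imaging
studies (Kruskal-Wallis, Mann-Whitney, paired t, Spearman stage
correlation).

The package targets the radiation-induced liver-injury setting: one hepatic
lobe is irradiated while the shielded contralateral lobe serves as a
within-animal control, fibrosis is staged F0–F2 (METAVIR) at follow-up, and
the question is which quantitative MR parameter tracks the stage. Because
no animal data ship with it, a synthetic cohort — calibrated to stage-wise
parameter distributions and the study's group structure (30 rats at
baseline, 8/8/7 survivors at one/two/three months, stage counts 8/10/5) —
makes every stage of the pipeline testable end to end.

## The models

Diffusion-weighted signal follows the IVIM biexponential

```
SI(b) / SI0 = (1 − f)·exp(−b·D) + f·exp(−b·D*)
```

with true diffusion `D`, pseudo-diffusion `D*` (capillary microcirculation)
and perfusion fraction `f`. Fitting is *segmented*, exploiting the scale
separation D\* ≫ D: the high-b points (b ≥ 200 s/mm²) give D by log-linear
fit, the extrapolated intercept gives `f = 1 − SI0_extrap/SI(0)` in closed
form, and a bounded 1-D search on the low-b points recovers D\*.

Gradient-echo decay is `SI(TE) = SI0·exp(−R2*·TE)`; R2\* (Hz) is the
negative slope of ln SI versus TE and rises with iron load and
deoxyhemoglobin — the histological correlates of progressing fibrosis.

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

```python
import ivimr2 as iv

cohort = iv.generate_cohort(seed=1)          # 30 rats, paired lobes, stages
table  = iv.tabular_mode(cohort)             # one ROI-measurement row per lobe
report = iv.build_study_report(table)

print(report.stage_comparison.to_string(index=False))
for p, c in report.correlations.items():
    print(f"{p:8s} r={c.r:+.3f} p={c.p_value:.2e} strength={c.strength}")
```

prints

```
  stage  n          D_star             D             f        R2_star
control 23 78.478 ± 27.237 0.761 ± 0.101 0.261 ± 0.068 39.266 ± 6.212
     F0  8 71.679 ± 26.601 0.638 ± 0.065 0.253 ± 0.043 51.108 ± 5.335
     F1 10 66.579 ± 22.283 0.571 ± 0.065 0.281 ± 0.092 59.178 ± 5.849
     F2  5 85.773 ± 19.456 0.623 ± 0.105 0.250 ± 0.033 66.248 ± 7.542
   KW p              0.371         0.000         0.815          0.000

D_star   r=-0.055 p=7.17e-01 strength=weak
D        r=-0.663 p=5.07e-07 strength=mild
f        r=+0.018 p=9.05e-01 strength=weak
R2_star  r=+0.863 p=1.26e-14 strength=high
```

Reading it: each row is mean ± SD of one stage group (D and D\* in
×10⁻³ mm²/s, f as a fraction, R2\* in Hz); the last row is the
Kruskal-Wallis p-value across the four groups. In this simulated cohort —
as in the study design it emulates — R2\* rises strongly and monotonically
with fibrosis stage (high positive Spearman correlation), D falls
moderately, and the perfusion parameters D\* and f carry no stage signal.

The same pipeline runs from the shell:

```sh
ivimr2 study --seed 1 --mode tabular --out study_out     # full study
ivimr2 simulate --seed 1 --out cohort                    # cohort CSV only
ivimr2 fit-ivim curve.csv --out fit.json                 # one (b, SI) curve
ivimr2 fit-r2star decay.csv                              # one (TE, SI) curve
```

`study` writes the measurement table, all report sub-tables (CSV +
Markdown), the correlation block (JSON) and a manifest recording seed,
config hash and outputs; the same seed reproduces every number
bit-identically in tabular mode. Imaging mode (`--mode imaging`) renders
per-rat voxel phantoms with Rician noise, fits parameter maps voxel-wise
and measures fixed-area ROIs instead of reading the draws directly.

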