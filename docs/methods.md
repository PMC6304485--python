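# Methods

This note documents the models, estimators, synthetic-data generator and
statistical procedures implemented in `ivimr2`, the assumptions behind them,
and the numerical choices that a maintainer would otherwise have to
reverse-engineer from the code.

## Forward signal models

**IVIM diffusion.** The diffusion-weighted signal of perfused tissue is
modelled as a two-compartment biexponential in the diffusion weighting `b`
(s/mm²):

    SI(b) = SI0 · [ (1 − f) · exp(−b·D) + f · exp(−b·D*) ]

`D` (mm²/s) is the true (Brownian) diffusion coefficient of tissue water,
`D*` (mm²/s) the pseudo-diffusion coefficient of blood circulating through
randomly oriented capillaries, and `f` the fraction of voxel signal in the
perfusion compartment. The model assumes two non-exchanging pools and
mono-exponential decay within each pool. Diffusivities are stored in mm²/s
internally and reported on the conventional ×10⁻³ mm²/s scale everywhere a
human reads them; this split exists purely to avoid silent unit errors.

**R2\* relaxometry.** Multi-echo gradient-echo decay is mono-exponential,
`SI(TE) = SI0 · exp(−R2*·TE)`, with R2\* in Hz and TE in milliseconds
(converted to seconds inside the model). R2\* = 1/T2\* increases with local
paramagnetic load (hemosiderin iron, deoxyhemoglobin), which is what makes it
a fibrosis-stage marker in this setting.

**Acquisition protocol.** Defaults ship in
`src/ivimr2/data/default_protocol.json`: 11 b-values
(0, 25, 50, 75, 100, 150, 200, 400, 600, 800, 1000 s/mm²) and 16 echo times
(3.4–92.1 ms in ≈5.9 ms steps), the rodent-liver protocol this pipeline
emulates, with a reference SI0 of 1000 arbitrary units.

**Noise.** Magnitude-MRI noise is Rician: each noise-free intensity S is
replaced by √((S+n₁)² + n₂²), n₁, n₂ ~ N(0, σ²). The single noise knob is
the SNR at b=0/TE=0 (σ = SI0/SNR), default 50 — a deliberately clean regime
in which noise-limit tests stay meaningful while stochastic behaviour is
still exercised. The acquisition chain itself (k-space, eddy currents,
motion) is not simulated; signals are generated at the model level.

## Estimators

**Segmented IVIM fit** (`order="d_first"`, the default):

1. High-b segment (b ≥ 200 s/mm² by default): ordinary least squares of
   ln SI on b. The slope magnitude is D̂; the exponentiated intercept is the
   tissue-only signal extrapolated to b = 0.
2. Perfusion fraction in closed form: f̂ = 1 − SI0_extrapolated / SI(b=0).
   Estimates outside [0, 1] are clipped to the boundary and flagged.
3. Low-b segment (b < 200, including b = 0): bounded one-dimensional least
   squares for D* with D̂ and f̂ held fixed (Brent search on [0, 0.5] mm²/s,
   initialisation 20×10⁻³, absolute tolerance 10⁻¹⁰, ≤ 500 iterations; flat
   objectives resolve toward lower D*).

The split point b = 200 is assigned to the *high*-b segment: the extra point
stabilises the two-parameter log-linear fit, and the perfusion residual
there, f·exp(−200·D*), is below 5×10⁻⁵ for physiological liver D*
(≥ 20×10⁻³ mm²/s). Segment ownership is configurable (`split_in_high`).

The literal alternative ordering (`order="low_b_first"`) fits the
biexponential on the low-b points first for (D*, f) with D profiled as a
nuisance, then the high-b mono-exponential for D. It is retained for
comparison but is ill-conditioned — six low-b points carry three effective
parameters — and is not the default.

Identifiability: when D* approaches D the compartments merge, f is
structurally unidentifiable, and the fit reports an f̂ near 0 with the
whole-curve decay in D̂; this is a property of the model, not of the
optimiser, and the degenerate case is exercised in the tests. Noise-free
recovery to the documented tolerances (D, f within 10⁻³ relative, D* within
10⁻² relative) holds in the physiological regime D* ≥ 50×10⁻³ mm²/s; at
smaller D* the perfusion compartment has not decayed out by b = 200 and a
segmented estimator is inherently biased, which is why the property test
(and the synthetic generator, below) enforce a separability floor.

**R2\* fit.** OLS of ln SI on TE over echoes with positive signal; R2\* is
the negative slope converted to Hz. Non-positive intensities (possible under
noise at long TE) are excluded from the log fit; fewer than two usable
points is an error. A negative rate estimate is clipped to 0 Hz and flagged.
Both fitters sort points into a canonical order first, so estimates are
exactly invariant under permutation of the input samples.

**Maps and ROIs.** Fitters are applied voxel-wise to 4-D volumes (x, y, z,
b or TE) under a mask, producing one `ParameterMap` per parameter with
per-voxel residual and convergence flags; maps round-trip through NIfTI-1
(nibabel, diagonal affine from the voxel size) and export as blue-to-red
pseudo-colour PNGs. ROIs are fixed-area discs (default 3 mm², the
homogeneous-liver region size used in small-animal liver imaging): a voxel
belongs to the ROI if its centre lies within the disc radius, and the radius
is chosen so the realized area is within half a voxel-area of the target
(≈ 8 voxels at 0.625 mm in-plane). An ROI touching any unmasked voxel is
rejected outright, mirroring the manual rule of excluding vessels and bile
ducts rather than averaging over them. Relative T1/T2 values are
liver-to-muscle signal-intensity ratios at the same slice level.

## Synthetic cohort generator

The generator reproduces the statistical structure of a longitudinal
irradiation study: 30 rats imaged at baseline; the right hepatic lobe
irradiated; follow-up imaging of 8, 8 and 7 survivors at one, two and three
months (attrition is modelled as these fixed final sizes, not as a
stochastic survival process); METAVIR staging of the irradiated lobe —
one-month rats F0, two-month rats F1, three-month rats 5 F2 : 2 F1, giving
stage counts 8/10/5; every rat's shielded left lobe serves as its own
control. The structure (ids, groups, stages) is fixed; only parameter draws
depend on the seed.

**Distributions.** Per-lobe ground truth is drawn from stage-wise normal
distributions (mean, SD) held in `StageDistributionTable`; only means and
SDs are available for calibration, so normality is the minimal assumption.
Draws are truncated to physical bounds — rates and diffusivities
non-negative, f in [0, 1] — and D* additionally to ≥ 20×10⁻³ mm²/s, the
separability floor below which pseudo-diffusion is indistinguishable from
tissue diffusion at this protocol's b-values and the biexponential reading
of the voxel breaks down. Because the study tables report moments of the
*observed* (bounded) quantities, the parent normal of each cell is solved
numerically so that the truncated distribution reproduces the tabulated
mean and SD exactly; where the tabulated moments are unattainable under
truncation (only the heavy-tailed baseline D* cell, SD comparable to the
mean), the generator falls back to plainly truncating the tabulated normal.

**Pairing.** Left and right lobes of one rat share physiology; each
parameter couples the two lobes through a Gaussian copula with correlation
0.3 by default (configurable). The copula preserves the stage-wise marginals
exactly regardless of the pairing strength. Follow-up left lobes are drawn
from the pooled control row by default; a per-timepoint left-lobe table is
available as an alternative source (`left_lobe_from_control_row=False`).

**Modes.** *Tabular* mode emits one row per lobe (76 rows by default:
30 baseline right lobes + 23 paired follow-up lobes × 2) in which the ROI
measurement equals the ground-truth draw, optionally perturbed by a relative
measurement error (default 0, since the stage tables already encode
between-animal dispersion). *Imaging* mode renders per-rat phantoms — two
32×32×3 lobes side by side at 0.625×0.625×3 mm voxels — through the forward
models with 2% relative voxel-to-voxel parameter heterogeneity and Rician
noise, fits them voxel-wise and measures centre-lobe ROIs. At high SNR the
two modes agree within 2% on stage means, which is the pipeline's
end-to-end consistency check.

What the generator does **not** emulate: spatial anatomy and partial-volume
effects, vessels/bile ducts inside the ROI, respiratory motion, registration
error between sequences, scanner drift, and any histology. Passing tests
therefore demonstrate correctness of the estimators and statistics under
the stated distributional model, not robustness to those real-world
confounds.

## Statistics

Kruskal-Wallis H (tie-corrected, midranks) across time points or stages;
Mann-Whitney U (midranks) for pairwise contrasts; paired-samples t on
right-minus-left lobe differences; Spearman rank correlation between each
parameter and the ordinal stage code (control=0, F0=1, F1=2, F2=3), with the
conventional strength bands |r| ≥ 0.8 high, 0.5 ≤ |r| < 0.8 mild, else weak.
All tests are two-sided at α = 0.05 with no multiple-testing correction,
matching the practice this battery mirrors. p-values come from exact
permutation enumeration when the pooled sample size is ≤ 12 (full
enumeration of group relabelings; for Mann-Whitney the two-sided p sums
both tails of the exact U distribution) and from the asymptotic reference
distribution otherwise. Degenerate inputs are reported, not raised:
all-identical groups give H = 0, p = 1; constant values give an undefined
correlation with a flag; zero-variance paired differences give p = 0 (for a
constant non-zero shift) or no p at all (all-zero differences).

The stage-correlation block pools the 23 control left lobes with the 23
staged right lobes (n = 46) by default — the pooling under which the
published correlation magnitudes are reproducible — with a right-lobes-only
mode (n = 23) available.

`build_study_report` assembles four mean ± SD sub-tables (right lobes by
time point, right lobes by stage, left-lobe stability, relative T1/T2
ratios) plus per-timepoint paired-lobe t tests and the correlation block;
identical input tables produce byte-identical reports. Because baseline
measurements occupy one row per rat (the pre-irradiation right lobe), the
left-lobe stability table covers the follow-up time points and the report
notes the absent baseline group as a warning rather than failing.

## Problem sizes and runtime choices

The acceptance script averages stage correlations over 500 simulated
cohorts and takes median Kruskal-Wallis p-values over the first 100 — sizes
at which the Monte-Carlo error of the reported means is an order of
magnitude below the comparison tolerances. Property tests use 10⁴ null
simulations for the type-I calibration check (5% ± 1.5%), 10⁵–10⁶ draws for
moment identities, and an 8×8×1-voxel-per-lobe grid at SNR 10⁶ for the
imaging-vs-tabular agreement check, which reduces the per-voxel fit count
without changing what the check demonstrates.

## Known limitations

- The segmented estimator's D* is noisy at realistic SNR (its relative
  error is the largest of the three IVIM parameters); this matches the
  large printed D* dispersions and is why D*-based conclusions are null.
- The low-b-first fit order is exposed for comparison but its (D*, f)
  estimates at realistic noise should not be trusted; no attempt is made to
  regularise it.
- Normal marginals with a Gaussian copula are an assumption of convenience;
  only location/scale of each cell is calibrated, not shape.
- Imaging mode places both lobes on one shared grid; inter-sequence
  registration is reduced to that shared grid and is out of scope.
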