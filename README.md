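# clampkit

Quantitative analysis of glucose metabolism studies in type 2 diabetes:
two-step hyperinsulinaemic-euglycaemic clamps with stable-isotope glucose
tracers, C-peptide deconvolution for insulin secretion, indirect
calorimetry, mixed-meal and continuous-glucose-monitoring (CGM) glycaemia
metrics, diet-energy arithmetic, and the repeated-measures statistics that
tie a two-arm pre/post dietary intervention together.  Because raw trial
data of this kind are rarely deposited, the package ships forward
simulators with known ground truth for every stage, so each estimator is
validated by inversion.

## Who it is for

Metabolic physiologists and trialists who run euglycaemic clamps with
D-[6,6-²H₂]glucose (or any single-tracer protocol reported as
tracer-to-tracee ratio), mixed-meal tolerance tests (MMTT) with C-peptide
sampling, and free-living CGM, and who need the full derivation chain from
raw time series to the outcome table: EGP suppression, glucose disposal,
insulin-normalized sensitivity indices, insulin secretion rate (ISR),
β-cell function, time in range, and the ANOVA layer over them.

## The models at the core

**Tracer kinetics (single-pool, non-steady state).**  With tracer infusion
F (mg kg⁻¹ min⁻¹), glucose G (converted to mg/mL), tracer-to-tracee ratio
z = TTR and effective distribution volume pV (pool fraction × volume,
default 0.65 × 220 = 143 mL/kg):

    Ra(t)  = [F(t) − pV · G(t) · dz/dt] / z(t)          (total appearance)
    RdT(t) = Ra(t) − pV · dG/dt                          (total disappearance)
    EGP(t) = Ra(t) − GIR(t) − F(t)                       (endogenous production)

At tracer steady state Ra collapses to the isotope-dilution identity F/z.
Derivatives come from cubic smoothing splines (penalty by generalized
cross-validation; TTR is smoothed in the log domain).  Per-phase summaries
use the last 30 min of each step (glucose CV < 5 % required): GDR is the
mean glucose infusion corrected for glucose-space change, and GDR/I and
RdT/I divide by steady-state insulin (µU/mL) to index whole-body and
peripheral insulin sensitivity.

**Insulin secretion.**  Plasma C-peptide is the convolution of the
prehepatic secretion rate with a two-exponential population impulse
response (Van Cauter parameters from age, BMI class and body surface
area).  ISR is recovered by non-negative least squares with a
second-difference penalty,

    min ‖C_obs − H·ISR‖² + λ‖D₂·ISR‖²,  ISR ≥ 0,

λ per series by generalized cross-validation.  β-cell function is the
time-averaged incremental ISR over the incremental glucose excursion,
divided by the insulin sensitivity index.

**Glycaemia, calorimetry, diet.**  Trapezoidal (incremental) AUCs;
duration-weighted CGM metrics with left-interval attribution and gap
exclusion (>30 min); Frayn stoichiometry for carbohydrate/fat oxidation
and non-oxidative glucose disposal; energy prescriptions (BMR × PAL,
30/35/35 protein/carbohydrate/fat energy split), mycoprotein fibre
accounting, and the Goldberg under-reporting screen.

**Statistics.**  Split-plot repeated-measures ANOVA with one between
factor (diet group) and one or two within factors (insulin step or meal
time, and pre/post intervention), Greenhouse-Geisser corrections, Tukey
HSD post hocs, and long-format cohort tables throughout.

## Worked example

Simulate one clamp visit and analyze it (the simulator integrates the
same single-pool balance the analysis inverts, with a PI controller
titrating the glucose infusion to 5 mmol/L):

```sh
clampkit simulate clamp --seed 3 --out sim
clampkit clamp analyze sim/clamp.csv --out-prefix out
```

```
phase       ra     rd_t      egp  glucose_mmol_l  insulin_pmol_l      gdr  egp_suppression_pct  rdt_per_insulin
basal 2.007408 1.974326 1.987408        7.297864      182.497325      NaN             0.000000              NaN
step1 3.680724 3.505581 0.923132        5.045752      503.253756 2.483468            53.550951         0.048378
step2 7.847003 7.958417 0.331320        4.912720     1152.248137 7.598197            83.329030         0.047968
```

Reading the table: basal endogenous production is ≈2.0 mg kg⁻¹ min⁻¹ and
is suppressed by ~54 % during the low-dose step (hepatic insulin
sensitivity) and ~83 % during the high-dose step; glucose disposal rises
to ≈7.6 mg kg⁻¹ min⁻¹ at high-dose insulin; RdT/I ≈ 0.048
mg kg⁻¹ min⁻¹ per µU/mL indexes peripheral insulin sensitivity.  The
generating truth for this seed was EGP 2.0 basal with 55 %/87 %
asymptotic suppression targets and step-2 disposal ≈8 — the steady-state
window averages sit slightly below the asymptotes because the transition
has a 30-min time constant.

The same pattern holds for the other stages, e.g.

```sh
clampkit simulate cgm --seed 3 --target-tir 70 --out sim
clampkit cgm summarize sim/cgm.csv     # -> "tir": 70.02 (4-10 mmol/L, duration-weighted)
```

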