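# Methods

This note records the models, the numerical choices, and what the
synthetic-data validation does and does not establish.

## Tracer kinetics

The clamp analysis is the Steele single-compartment model in
tracer-to-tracee-ratio (TTR) form.  Writing q and Q for tracer and tracee
masses in the accessible pool, removal is proportional to pool
composition, which yields for z = TTR and total measured glucose G:

    pV · G · dz/dt = F − z · Ra        ⇒        Ra = (F − pV·G·dz/dt)/z

with F the tracer infusion rate and Ra total appearance (endogenous
production + glucose infusion + tracer mass).  Note that the derivative
term is *not* divided by z a second time; the identity is exact for the
one-pool model and reduces to isotope dilution (Ra = F/z) at constant
enrichment.  RdT follows from total mass balance, RdT = Ra − pV·dG/dt, and
EGP = Ra − GIR − F.  The tracer mass F is subtracted from EGP even though
it is numerically negligible (≈0.02 mg kg⁻¹ min⁻¹): the books must
balance, and the steady-state unit tests check the identity to 1e-9.

Parameters (all configurable through `SteeleConfig`):

| parameter | default | units | rationale |
|---|---|---|---|
| pool fraction p | 0.65 | — | standard single-pool value for non-steady-state glucose turnover |
| distribution volume V | 220 | mL/kg | anatomical glucose space; pV = 143 mL/kg effective |
| steady-state window | last 30 | min per phase | qualifies when glucose CV < 5 % within the window |
| smoothing | GCV cubic spline | — | derivative stability without per-series hand-tuning |

Glucose enters the flux equations in mg/mL (1 mmol/L = 0.18016 mg/mL) so
that pV·G is a mass per kg and every flux is mg kg⁻¹ min⁻¹.

Numerical choices for differentiation:

* TTR is smoothed in the **log domain**.  Enrichment decays
  quasi-exponentially between plateaus and its assay error is
  multiplicative, so log-TTR has homoscedastic noise and mild curvature —
  both favour the spline and its derivative.
* The glucose space-correction derivative (in RdT and GDR) uses a local
  quadratic (Savitzky-Golay, 7-sample window) on uniform grids.  Clamped
  glucose has very low true derivative bandwidth, and the
  function-oriented GCV penalty systematically under-smooths derivatives;
  the wider local fit roughly halves the RdT recovery error.  On uneven
  grids the spline derivative is used.
* With `smoothing="none"` an interpolating cubic spline is used — the
  right choice for noise-free (simulated) data, and exact for linear
  series.  A 3-point moving average is available for very short series.
* Negative EGP values (a known artefact of the one-pool approximation at
  high insulin) are floored at zero for summaries and flagged; the raw
  values are retained.

GDR is mean glucose infusion over the steady-state window minus
pV×(glucose drift slope); the slope is a least-squares fit over the
window.  Falling glucose therefore *raises* GDR — glucose leaving its
distribution space is also being disposed.  Insulin-normalized indices
(GDR/I, RdT/I) divide by the window-mean insulin converted to µU/mL
(6.945 pmol/L per µU/mL).  Insulin clearance during a step is estimated
as infusion rate over the insulin increment, with the residual endogenous
component scaled by the C-peptide suppression ratio.

## C-peptide deconvolution

C-peptide kinetics use the standard two-exponential population model:
short half-life 4.95 min; long half-life 0.14×age + 29.2 min; fast-phase
fraction 0.76 (lean, non-diabetic) or 0.78 (obese or type 2 diabetes);
distribution volume 1.92×BSA + 0.64 L with DuBois body surface area.
These are the published population coefficients used by essentially every
ISR study; individual decay experiments are out of scope.

The discrete forward operator H treats ISR as piecewise linear between
sample times and constant before the first sample (the subject arrives in
steady state); kernel integrals against this basis are evaluated in
closed form, and the pre-history contributes a closed-form tail to the
first column.  A constant C-peptide series therefore deconvolves exactly
to the steady-state secretion rate C·vd·ln2 / (f·t_short + (1−f)·t_long).

The inverse problem is non-negative least squares with a second-divided-
difference (curvature) penalty.  The weight λ is chosen per series by
generalized cross-validation using the effective degrees of freedom of
the unconstrained ridge smoother (the non-negativity constraint is
inactive near the optimum for physiologic inputs).  An L-curve corner
selector is retained as an option, but it is unreliable when data are
(near) noiseless — the curve has no corner — which is why GCV is the
default.  On noisy data, residuals of any penalized fit are (I−S)ε and
hence negatively lag-1-correlated even for white measurement noise; the
whiteness diagnostic therefore compares the observed lag-1 correlation
against the smoother-implied expectation rather than against zero.

β-cell function is (ΔISR/ΔG)/IS where Δ denotes the incremental
(above-baseline) AUC over 0–120 min divided by 120 — a ratio of
time-averaged excursions, more robust to single-timepoint noise than
endpoint differences — and IS is an explicit argument (typically clamp
RdT/I), since meal-derived surrogates would conflate secretion and
action.  A non-positive glucose excursion returns a missing value.

## Calorimetry, glycaemia, diet

Frayn (1983) stoichiometry with urinary nitrogen defaulting to zero (urine
collection is rarely reported in clamp studies); negative oxidation rates
are clipped to zero and flagged; non-oxidative disposal is GDR − CHO
oxidation.  CGM metrics weight each reading by the interval to the next
reading (left attribution), exclude intervals >30 min as sensor gaps from
every denominator, and require ≥24 h of non-gap data; the below/in/above
partition sums to 100 % exactly.  MMTT AUCs are trapezoidal on the
nominal grid with interpolated endpoints.  Energy prescriptions multiply
BMR (Henry/Oxford weight-only equations by default, Mifflin-St Jeor
selectable) by a physical-activity level, default 1.6; the macronutrient
split is 30/35/35 % of energy at 4/4/9 kcal/g.  The Goldberg screen flags
energy-intake:BMR ratios below the lower 95 % confidence bound computed
from the conventional component CVs (23 %/day intake, 8.5 % BMR, 15 %
PAL; n=1, 7-day record ⇒ cut-off ≈ 1.10).

## Statistics

The three-way design (between: group; within: insulin step or meal time,
and pre/post intervention) is a split-plot ANOVA computed from the
orthogonal within-subject strata: subject means give the between-group
test (error: subjects within groups); subject-centred profiles give each
within main effect and its group interaction (error: factor × subjects
within groups); double-centred profiles give the within×within stratum.
This is exact for complete data and any group sizes.  Greenhouse-Geisser
epsilon is computed per stratum as tr(S)²/(d·tr(S²)) on the pooled
within-group covariance of the stratum scores (bounded to [1/d, 1]) and
reported alongside the uncorrected p whenever a within factor has more
than two levels.  Missing within-cells trigger listwise exclusion with a
warning.  The two-way mixed ANOVA for summary measures delegates to
`pingouin.mixed_anova` (and the in-house engine is cross-checked against
it, exactly, on that reduced design).  Tukey HSD post hocs delegate to
statsmodels; for within factors the comparison ignores the
repeated-measures correlation and is documented as a conservative screen.

## Synthetic data: what it emulates, what it does not

The clamp simulator integrates exactly the single-pool mass and TTR
balances above with prescribed EGP(t) and Rd(t) profiles
(piecewise-exponential approach to per-phase targets, time constant 30
min — the pace of insulin effect-site equilibration), a constant primed
tracer infusion, and a discrete PI controller that retunes the glucose
infusion every 5 min toward 5 mmol/L once insulin starts, ramping the
pump linearly between setpoints.  Default targets: basal EGP 2.0
mg kg⁻¹ min⁻¹ with 55 %/87 % suppression at the two steps,
insulin-stimulated disposal increments 1.5 and 6.0 mg kg⁻¹ min⁻¹, basal
glucose 7.3 mmol/L, basal insulin 180 pmol/L — values typical of the
obese type 2 diabetes population these protocols study.  Measurement
noise is multiplicative with CVs 1.5 % (glucose), 1.0 % (GC-MS
enrichment) and 5 % (immunoassays).

MMTT glucose and insulin are phenomenological log-normal rise-decay
shapes; only the C-peptide/ISR link is mechanistic (exact convolution),
because deconvolution testing requires it.  CGM traces are an
Ornstein-Uhlenbeck process with three daily meal excursions, contracted
toward the range midpoint by a bisection on the contraction factor —
monotone sample-by-sample — until the realized duration-weighted TIR is
within 2 pp of target.  Cohorts draw demographics from the eligibility
windows (age 58±8 y within 40–70, BMI 33±5 within 27–45, HbA1c 60±15)
and generate outcomes as level means + subject effect + residual, with
injectable post-intervention effects (sensitivity multiplier, TIR shift,
HbA1c shift) and an exchangeable-null mode for calibration.

Because the simulator and the estimator share the single-pool model,
passing forward-inverse tests demonstrates correct implementation and
noise robustness — not that the one-pool approximation is adequate for
real non-steady-state physiology (two-pool effects, changing pool
fraction, insulin-dependent volume are not emulated).  Similarly, the
population C-peptide kinetics are exactly true in simulation but only
approximately true in people.

## Recovery metrics and problem sizes

Forward-inverse accuracy is reported as RMSE normalized by the mean total
turnover (mean true Ra) for Ra, RdT and EGP alike: the three curves
differ only by exactly-known inputs, so their absolute errors coincide,
and self-normalizing the near-zero EGP curve would report the same
absolute accuracy as a large relative error.  EGP accuracy is additionally
assessed on the scale it is used — suppression percentage points.  The
first and last two samples are excluded from curve comparisons (spline
derivative estimates at window boundaries are unreliable).  Measured
performance at the defaults: ≤0.4 % noise-free, ≈3 % (Ra, EGP) and ≈4 %
(RdT) at assay noise over 50 replicates; suppression within ≈2.5 pp;
GDR within 1 %.

Validation sizes: 50 clamp replicates, 10 MMTT round trips, 100 random
CGM traces against brute-force bookkeeping, 1000 null cohorts (n=9+8) for
type-I calibration of all seven omnibus effects (each within 3–7 % at
α=0.05), and 100 cohorts at n=100/arm for power against a 37 %
sensitivity multiplier (>90 % detection).  The full suite runs in about a
minute; `scripts/acceptance.py` in under 30 s.

## Known limitations

* One-pool Steele only; no two-pool or minimal-model variants.
* Population C-peptide kinetics only; no individual kinetic fitting.
* Friedewald LDL refuses TG > 4.52 mmol/L rather than substituting an
  alternative estimator.
* Tukey post hocs on within factors ignore the repeated-measures
  correlation structure.
* The split-plot engine requires complete within-subject data after
  listwise exclusion (no mixed-effects fallback).
* Display rounding (1 d.p., half-up) is applied only at report
  boundaries; all internal computation is full precision.
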