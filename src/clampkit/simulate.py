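"""Forward simulators with known ground truth for every pipeline stage:
clamp tracer curves, MMTT C-peptide/ISR, CGM traces, and pre/post cohorts
with injectable effect sizes.

The clamp simulator integrates exactly the single-pool mass and
tracer-ratio balances that the analysis inverts,

    dG_mg/dt = (Ra - Rd) / (p*V),      dTTR/dt = (F - TTR*Ra) / (p*V*G_mg),

with prescribed EGP(t) and Rd(t) profiles (piecewise-exponential
transitions between phase targets), a constant tracer infusion started on
a primed plateau, and a discrete proportional-integral controller that
titrates the glucose infusion every 5 minutes toward euglycaemia
(5 mmol/L) once the low-dose insulin step begins.  Postprandial MMTT
shapes are phenomenological (log-normal rise-decay); only the
C-peptide/ISR link is mechanistic, because deconvolution testing
requires it.  All outputs are fully determined by their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import SimulationError, ValidationError
from .glycemia import CgmTrace
from .secretion import CpepKinetics, impulse_response, population_kinetics
from .tracer import MG_PER_ML_PER_MMOL_L, ClampSeries, SteeleConfig
from .units import INSULIN_PMOL_PER_UU


@dataclass(frozen=True)
class SimNoise:
    """Multiplicative measurement noise (coefficients of variation).

    Defaults reflect routine assay performance: bedside glucose analyser
    ~1.5%, GC-MS tracer enrichment ~1.5%, hormone immunoassays ~5%.
    """

    glucose_cv: float = 0.015
    ttr_cv: float = 0.01
    hormone_cv: float = 0.05

    @classmethod
    def none(cls) -> "SimNoise":
        return cls(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class StepProtocol:
    """Two-step clamp schedule: basal then low- and high-dose insulin."""

    basal_min: float = 60.0
    step1_min: float = 120.0
    step2_min: float = 120.0
    sample_dt_min: float = 5.0
    insulin_rates: tuple[float, float] = (30.0, 80.0)  # mU m-2 min-1
    glucose_target_mmol_l: float = 5.0

    @property
    def total_min(self) -> float:
        return self.basal_min + self.step1_min + self.step2_min

    def phase_at(self, t: float) -> str:
        if t < self.basal_min:
            return "basal"
        if t < self.basal_min + self.step1_min:
            return "step1"
        return "step2"


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated subject-visit.

    Clamp fluxes in mg kg-1 min-1.  ``egp_suppression`` gives the
    fractional suppression targets for step 1 and step 2 (step-2 default
    0.87, the deep suppression typical at high-dose insulin in this
    population); ``rd_increments`` the insulin-stimulated rises in Rd
    above basal, scaled by ``sensitivity_multiplier`` (pre -> post
    insulin-sensitization factor).  MMTT secretion is a basal rate plus a
    log-normal postprandial wave.
    """

    basal_egp: float = 2.0
    egp_suppression: tuple[float, float] = (0.55, 0.87)
    rd_increments: tuple[float, float] = (1.5, 6.0)
    transition_tau_min: float = 30.0  # insulin effect-site equilibration on EGP/Rd
    basal_glucose_mmol_l: float = 7.3
    basal_insulin_pmol_l: float = 180.0
    basal_cpep_pmol_l: float = 1900.0
    insulin_mcr_ml_m2_min: float = 550.0
    cpep_suppression: tuple[float, float] = (0.75, 0.55)
    tracer_inf_mg_kg_min: float = 0.02
    sensitivity_multiplier: float = 1.0
    # MMTT secretion wave: ISR(t) = basal + amplitude * exp(-(ln(t/peak))^2 / (2 width^2))
    isr_amplitude_pmol_min: float = 900.0
    isr_peak_min: float = 40.0
    isr_width: float = 0.6
    mmtt_glucose_rise_mmol_l: float = 3.5
    noise: SimNoise = field(default_factory=SimNoise)
    seed: int = 0

    def egp_targets(self) -> tuple[float, float, float]:
        s1, s2 = self.egp_suppression
        return (self.basal_egp, self.basal_egp * (1 - s1), self.basal_egp * (1 - s2))

    def rd_targets(self) -> tuple[float, float, float]:
        rd_basal = self.basal_egp + self.tracer_inf_mg_kg_min  # basal steady state
        m = self.sensitivity_multiplier
        return (rd_basal, rd_basal + self.rd_increments[0] * m, rd_basal + self.rd_increments[1] * m)


def _phase_curve(t: np.ndarray, boundaries: tuple[float, float], targets: tuple[float, float, float],
                 tau: float) -> np.ndarray:
    """Piecewise-exponential approach to per-phase targets, continuous in t."""
    out = np.empty_like(t, dtype=float)
    level_at_start = targets[0]
    t_start = t[0] if len(t) else 0.0
    segs = [(t_start, boundaries[0], targets[0]), (boundaries[0], boundaries[1], targets[1]),
            (boundaries[1], np.inf, targets[2])]
    for lo, hi, target in segs:
        mask = (t >= lo) & (t < hi)
        out[mask] = target + (level_at_start - target) * np.exp(-(t[mask] - lo) / tau)
        level_at_start = target + (level_at_start - target) * math.exp(-max(hi - lo, 0.0) / tau) \
            if np.isfinite(hi) else target
    return out


def simulate_clamp(
    truth: SimTruth,
    cfg: SteeleConfig | None = None,
    protocol: StepProtocol | None = None,
    seed: int | None = None,
) -> tuple[ClampSeries, pd.DataFrame]:
    """Forward-simulate a two-step clamp; returns (noisy series, truth table).

    The truth table carries the noise-free Ra/RdT/EGP/glucose/TTR on the
    sample grid for recovery testing.
    """
    cfg = cfg or SteeleConfig()
    protocol = protocol or StepProtocol()
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    dt = 0.25  # integration step, min
    control_dt = 5.0
    kp, ki = 1.5, 0.12  # PI gains, mg kg-1 min-1 per mmol/L (and per min)
    pv = cfg.effective_volume
    f_inf = truth.tracer_inf_mg_kg_min
    boundaries = (protocol.basal_min, protocol.basal_min + protocol.step1_min)

    n_steps = int(round(protocol.total_min / dt))
    times = np.arange(n_steps + 1) * dt
    egp_t = _phase_curve(times, boundaries, truth.egp_targets(), truth.transition_tau_min)
    rd_t = _phase_curve(times, boundaries, truth.rd_targets(), truth.transition_tau_min)

    g_mg = truth.basal_glucose_mmol_l * MG_PER_ML_PER_MMOL_L
    ra0 = truth.basal_egp + f_inf
    z = f_inf / ra0  # primed tracer plateau
    # PI setpoints every 5 min; the pump ramps linearly between setpoints so
    # the true Ra stays continuous (the inversion differentiates smooth fits)
    gir_level = 0.0
    gir_target = 0.0
    ramp_rate = 0.0
    e_prev = 0.0
    G = np.empty(n_steps + 1)
    Z = np.empty(n_steps + 1)
    GIR = np.empty(n_steps + 1)
    RA = np.empty(n_steps + 1)
    G[0], Z[0], GIR[0] = g_mg, z, gir_level
    RA[0] = egp_t[0] + gir_level + f_inf
    for i in range(n_steps):
        t = times[i]
        in_step = t >= protocol.basal_min
        if in_step and (abs(t / control_dt - round(t / control_dt)) < 1e-9):
            e = protocol.glucose_target_mmol_l - g_mg / MG_PER_ML_PER_MMOL_L
            gir_target = max(0.0, gir_target + kp * (e - e_prev) + ki * control_dt * e)
            ramp_rate = (gir_target - gir_level) / control_dt
            e_prev = e
        gir_level = min(gir_target, gir_level + ramp_rate * dt) if ramp_rate >= 0 \
            else max(gir_target, gir_level + ramp_rate * dt)
        ra = egp_t[i] + gir_level + f_inf
        g_mg += dt * (ra - rd_t[i]) / pv
        if g_mg <= 0.05 or g_mg > 5.0:
            raise SimulationError(
                f"glucose {g_mg / MG_PER_ML_PER_MMOL_L:.1f} mmol/L at t={t:.0f}: controller unstable"
            )
        z += dt * (f_inf - z * ra) / (pv * g_mg)
        G[i + 1], Z[i + 1], GIR[i + 1] = g_mg, z, gir_level
        RA[i + 1] = egp_t[i + 1] + gir_level + f_inf

    # sample grid
    stride = int(round(protocol.sample_dt_min / dt))
    idx = np.arange(0, n_steps + 1, stride)
    ts = times[idx]
    phases = np.array([protocol.phase_at(t) for t in ts])
    g_true_mmol = G[idx] / MG_PER_ML_PER_MMOL_L
    z_true = Z[idx]
    ra_true = RA[idx]
    rd_true = rd_t[idx]
    egp_true = egp_t[idx]
    gir_s = GIR[idx]

    # hormone traces: first-order approach to per-phase steady-state targets
    bsa = 2.1  # reference m^2; infusions are per m^2 so bsa cancels in recovery
    ins_targets = [truth.basal_insulin_pmol_l]
    cp_targets = [truth.basal_cpep_pmol_l]
    for j, iir in enumerate(protocol.insulin_rates):
        endog = truth.basal_insulin_pmol_l * truth.cpep_suppression[j]
        exog = iir * 1000.0 / truth.insulin_mcr_ml_m2_min * INSULIN_PMOL_PER_UU
        ins_targets.append(endog + exog)
        cp_targets.append(truth.basal_cpep_pmol_l * truth.cpep_suppression[j])
    insulin = _phase_curve(ts, boundaries, tuple(ins_targets), 8.0)
    cpep = _phase_curve(ts, boundaries, tuple(cp_targets), 30.0)

    nz = truth.noise
    g_meas = g_true_mmol * (1 + nz.glucose_cv * rng.standard_normal(len(ts)))
    z_meas = np.clip(z_true * (1 + nz.ttr_cv * rng.standard_normal(len(ts))), 1e-6, 0.999)
    ins_meas = insulin * (1 + nz.hormone_cv * rng.standard_normal(len(ts)))
    cp_meas = cpep * (1 + nz.hormone_cv * rng.standard_normal(len(ts)))

    series = ClampSeries(
        time=ts,
        glucose=np.maximum(g_meas, 0.1),
        ttr=z_meas,
        tracer_inf=np.full(len(ts), f_inf),
        gir=gir_s,
        insulin=np.maximum(ins_meas, 1.0),
        c_peptide=np.maximum(cp_meas, 1.0),
        phase=phases,
    )
    truth_df = pd.DataFrame(
        {
            "time_min": ts,
            "ra": ra_true,
            "rd_t": rd_true,
            "egp": egp_true,
            "glucose_mmol_l": g_true_mmol,
            "ttr": z_true,
            "gir": gir_s,
            "insulin_pmol_l": insulin,
            "cpeptide_pmol_l": cpep,
        }
    )
    return series, truth_df


# ---------------------------------------------------------------------------
# MMTT
# ---------------------------------------------------------------------------

def isr_profile(truth: SimTruth, t: np.ndarray, kinetics: CpepKinetics) -> np.ndarray:
    """Ground-truth secretion profile (pmol/min): basal + log-normal wave."""
    t = np.asarray(t, float)
    basal = kinetics.steady_state_isr(truth.basal_cpep_pmol_l)
    wave = np.zeros_like(t)
    pos = t > 0
    wave[pos] = np.exp(-((np.log(t[pos] / truth.isr_peak_min)) ** 2) / (2 * truth.isr_width**2))
    return basal + truth.isr_amplitude_pmol_min * wave


def cpeptide_from_isr(
    isr_t: np.ndarray,
    isr: np.ndarray,
    kinetics: CpepKinetics,
    basal_isr: float | None = None,
    dt_fine: float = 0.1,
) -> np.ndarray:
    """Noise-free C-peptide (pmol/L) from an ISR curve by forward convolution.

    Secretion before the grid start is held at ``basal_isr`` (default: the
    first ISR value), i.e. the subject arrives in steady state.
    """
    isr_t = np.asarray(isr_t, float)
    isr = np.asarray(isr, float)
    if basal_isr is None:
        basal_isr = float(isr[0])
    fine = np.arange(isr_t[0], isr_t[-1] + dt_fine / 2, dt_fine)
    isr_fine = np.interp(fine, isr_t, isr)
    excess = isr_fine - basal_isr
    h = impulse_response(kinetics, fine - fine[0])
    # C(t) = basal steady state + conv(excess, h)
    c_b = basal_isr * kinetics.kernel_integral
    conv = np.convolve(excess, h)[: len(fine)] * dt_fine
    c_fine = c_b + conv
    return np.interp(isr_t, fine, c_fine)


def simulate_mmtt(
    truth: SimTruth,
    kinetics: CpepKinetics,
    grid_min: np.ndarray | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a 120-min mixed-meal tolerance test.

    Returns (measured series, truth table).  Glucose and insulin follow
    phenomenological log-normal rise-decay shapes; C-peptide is the exact
    convolution of the ground-truth ISR with the subject's kinetics.
    """
    grid = np.asarray(grid_min if grid_min is not None else np.arange(0.0, 121.0, 10.0), float)
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    isr = isr_profile(truth, grid, kinetics)
    cpep = cpeptide_from_isr(grid, isr, kinetics)

    pos = grid > 0
    shape = np.zeros_like(grid)
    shape[pos] = np.exp(-((np.log(grid[pos] / 45.0)) ** 2) / (2 * 0.65**2))
    glucose = truth.basal_glucose_mmol_l + truth.mmtt_glucose_rise_mmol_l * shape
    ins_shape = np.zeros_like(grid)
    ins_shape[pos] = np.exp(-((np.log(grid[pos] / truth.isr_peak_min)) ** 2) / (2 * truth.isr_width**2))
    insulin = truth.basal_insulin_pmol_l * (1 + 2.5 * ins_shape)

    nz = truth.noise
    df = pd.DataFrame(
        {
            "time_min": grid,
            "glucose_mmol_l": np.maximum(glucose * (1 + nz.glucose_cv * rng.standard_normal(len(grid))), 0.1),
            "insulin_pmol_l": np.maximum(insulin * (1 + nz.hormone_cv * rng.standard_normal(len(grid))), 1.0),
            "cpeptide_pmol_l": np.maximum(cpep * (1 + nz.hormone_cv * rng.standard_normal(len(grid))), 1.0),
        }
    )
    truth_df = pd.DataFrame(
        {"time_min": grid, "isr_pmol_min": isr, "cpeptide_pmol_l": cpep, "glucose_mmol_l": glucose}
    )
    return df, truth_df


# ---------------------------------------------------------------------------
# CGM
# ---------------------------------------------------------------------------

def simulate_cgm(
    target_tir: float,
    days: int = 7,
    seed: int = 0,
    lo: float = 4.0,
    hi: float = 10.0,
    cadence_min: float = 5.0,
    start: str = "2022-01-01 00:00",
) -> CgmTrace:
    """Mean-reverting interstitial glucose with meal excursions, contracted
    toward mid-range so the realized duration-weighted TIR is within 2
    percentage points of ``target_tir`` (above it, when exactly attainable).

    The contraction G -> c + alpha*(G - c) about the range midpoint c is
    monotone in alpha sample-by-sample, so a bisection on alpha lands on
    the step of the empirical TIR function nearest the target.
    """
    if not 0 <= target_tir <= 100:
        raise ValidationError("target_tir must be in [0, 100]")
    rng = np.random.default_rng(seed)
    n = int(days * 24 * 60 / cadence_min)
    t_min = np.arange(n) * cadence_min

    theta, mu, sigma = 0.02, 8.5, 0.30  # OU: reversion/min, mean, diffusion
    g = np.empty(n)
    g[0] = mu
    for i in range(1, n):
        g[i] = g[i - 1] + theta * (mu - g[i - 1]) * cadence_min \
            + sigma * math.sqrt(cadence_min) * rng.standard_normal()
    # three daily meal excursions with jittered amplitude
    tod = t_min % (24 * 60)
    for meal_t in (8 * 60, 13 * 60, 19 * 60):
        for day in range(days):
            amp = max(rng.normal(2.5, 0.8), 0.0)
            onset = day * 24 * 60 + meal_t + rng.normal(0, 15)
            rel = t_min - onset
            bump = np.where(rel >= 0, (rel / 40.0) * np.exp(1 - rel / 40.0), 0.0)
            g += amp * bump

    center = (lo + hi) / 2.0

    def tir_of(alpha: float) -> float:
        gg = center + alpha * (g - center)
        return 100.0 * np.mean((gg >= lo) & (gg <= hi))

    alpha_lo, alpha_hi = 0.0, 4.0
    if tir_of(alpha_hi) > target_tir:
        raise SimulationError(f"cannot reach target TIR {target_tir} even at widest spread")
    for _ in range(60):
        mid = (alpha_lo + alpha_hi) / 2.0
        if tir_of(mid) >= target_tir:
            alpha_lo = mid
        else:
            alpha_hi = mid
    alpha = alpha_lo
    realized = tir_of(alpha)
    if abs(realized - target_tir) > 2.0:
        raise SimulationError(f"realized TIR {realized:.1f}% misses target {target_tir}% by > 2 pp")
    glucose = np.clip(center + alpha * (g - center), 2.2, 22.2)
    timestamps = pd.date_range(start, periods=n, freq=f"{int(cadence_min)}min")
    return CgmTrace(timestamps=timestamps, glucose=glucose)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: Trial-like demographic targets: mean age 58.3 y (SD 8.3), BMI 32.9 (4.7),
#: HbA1c 60 mmol/mol (15), height 173 cm (9); eligibility windows applied.
DEMOGRAPHICS = {
    "age": (58.3, 8.3, 40.0, 70.0),
    "bmi": (32.9, 4.7, 27.0, 45.0),
    "hba1c": (60.0, 15.0, 43.0, 120.0),
    "height": (173.0, 9.0, 150.0, 200.0),
}

DEFAULT_EFFECTS = {"is_multiplier": 1.0, "tir_shift": 0.0, "hba1c_shift": 0.0}

# outcome means and variance components for the cohort generator
_OUTCOME_MODELS = {
    # outcome: (within levels, per-level means, between-subject SD, residual SD)
    "rdt": (("basal", "step1", "step2"), (2.0, 3.5, 8.0), 1.0, 0.5),
    "rdt_per_insulin": (("step2",), (2.7,), 0.8, 0.3),
    "tir": (("day",), (53.0,), 20.0, 8.0),
    "hba1c": (("visit",), (60.0,), 12.0, 3.0),
}


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int):
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, bad.sum())
    return np.clip(out, lo, hi)


def simulate_demographics(n: int, seed: int = 0) -> pd.DataFrame:
    """Draw subject metadata from the trial-like eligibility distributions."""
    rng = np.random.default_rng(seed)
    cols = {k: _truncnorm(rng, *DEMOGRAPHICS[k], n) for k in DEMOGRAPHICS}
    df = pd.DataFrame(cols)
    df["sex"] = np.where(rng.random(n) < 0.3, "female", "male")
    df["weight"] = df["bmi"] * (df["height"] / 100.0) ** 2
    df["diabetic"] = True
    df.insert(0, "subject_id", [f"S{i + 1:03d}" for i in range(n)])
    return df


def simulate_cohort(
    n_per_group: int | tuple[int, int] = (9, 8),
    effects: dict | None = None,
    seed: int = 0,
    insulin_response: bool = True,
) -> dict:
    """Generate a pre/post two-group cohort with injectable effect sizes.

    ``effects``: is_multiplier scales the insulin-stimulated outcomes
    post-intervention (1.0 = none), tir_shift / hba1c_shift are additive
    post shifts.  ``insulin_response=False`` flattens the per-level means
    (full exchangeable null, for test calibration).  Returns a dict with
    the long-format cohort table, demographics, and the ground-truth
    effect log.
    """
    if isinstance(n_per_group, int):
        n_per_group = (n_per_group, n_per_group)
    if min(n_per_group) < 2:
        raise ValidationError("need at least 2 subjects per group")
    eff = dict(DEFAULT_EFFECTS)
    eff.update(effects or {})
    rng = np.random.default_rng(seed)
    n_total = sum(n_per_group)
    demo = simulate_demographics(n_total, seed=int(rng.integers(2**31 - 1)))
    groups = np.array(["OMNI"] * n_per_group[0] + ["VEG"] * n_per_group[1])
    demo["group"] = groups

    rows = []
    for outcome, (levels, mus, sd_b, sd_e) in _OUTCOME_MODELS.items():
        mus = np.asarray(mus, float)
        if not insulin_response:
            mus = np.full_like(mus, mus[0])
        base = mus[0]
        for s in range(n_total):
            b_subj = rng.normal(0.0, sd_b)
            for visit in ("pre", "post"):
                for lv, mu in zip(levels, mus):
                    m = mu
                    if visit == "post":
                        if outcome in ("rdt", "rdt_per_insulin"):
                            # multiplier acts on the insulin-stimulated component
                            stim = mu - base if outcome == "rdt" else mu
                            m = (base if outcome == "rdt" else 0.0) + stim * eff["is_multiplier"]
                        elif outcome == "tir":
                            m = mu + eff["tir_shift"]
                        elif outcome == "hba1c":
                            m = mu + eff["hba1c_shift"]
                    val = m + b_subj + rng.normal(0.0, sd_e)
                    if outcome == "tir":
                        val = float(np.clip(val, 0.0, 100.0))
                    rows.append(
                        {
                            "subject_id": demo["subject_id"].iloc[s],
                            "group": groups[s],
                            "intervention": visit,
                            "within_level": lv,
                            "outcome": outcome,
                            "value": val,
                        }
                    )
    table = pd.DataFrame(rows)
    return {"table": table, "demographics": demo, "effects": eff, "seed": seed}


def simulate_subject_series(
    demo_row: pd.Series,
    visit: str = "pre",
    effects: dict | None = None,
    seed: int = 0,
    noise: SimNoise | None = None,
) -> dict:
    """Full raw series (clamp, MMTT, CGM) for one subject-visit.

    Used by the end-to-end report demo; heavier than the outcome-level
    cohort generator.
    """
    eff = dict(DEFAULT_EFFECTS)
    eff.update(effects or {})
    rng = np.random.default_rng(seed)
    mult = eff["is_multiplier"] if visit == "post" else 1.0
    truth = SimTruth(
        sensitivity_multiplier=mult * float(np.exp(rng.normal(0.0, 0.10))),
        basal_glucose_mmol_l=float(np.clip(rng.normal(7.3, 1.2), 5.0, 12.0)),
        noise=noise or SimNoise(),
        seed=int(rng.integers(2**31 - 1)),
    )
    kin = population_kinetics(
        age=float(demo_row["age"]), sex=str(demo_row["sex"]), bmi=float(demo_row["bmi"]),
        diabetic=bool(demo_row["diabetic"]), weight=float(demo_row["weight"]),
        height=float(demo_row["height"]),
    )
    clamp_series, clamp_truth = simulate_clamp(truth)
    mmtt_df, mmtt_truth = simulate_mmtt(truth, kin, seed=int(rng.integers(2**31 - 1)))
    tir_target = float(np.clip(rng.normal(53.0, 15.0) + (eff["tir_shift"] if visit == "post" else 0.0),
                               5.0, 98.0))
    cgm = simulate_cgm(tir_target, days=7, seed=int(rng.integers(2**31 - 1)))
    return {
        "clamp": clamp_series,
        "clamp_truth": clamp_truth,
        "mmtt": mmtt_df,
        "mmtt_truth": mmtt_truth,
        "cgm": cgm,
        "kinetics": kin,
        "truth": truth,
    }
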