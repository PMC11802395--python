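"""Single-pool non-steady-state tracer kinetics for the two-step
hyperinsulinaemic-euglycaemic clamp with a stable glucose isotope
(e.g. D-[6,6-2H2]glucose) given as a primed-continuous infusion.

The analysis follows the Steele one-compartment model expressed in
tracer-to-tracee ratio (TTR) form.  With F the tracer infusion rate
(mg kg-1 min-1), G the glucose concentration and p*V the effective
distribution volume (pool fraction x anatomical volume, mL/kg), the
total rate of appearance of glucose is

    Ra(t) = [ F(t) - p*V * G_mg(t) * dTTR/dt ] / TTR(t)

which at tracer steady state collapses to the isotope-dilution identity
Ra = F/TTR.  Total rate of disappearance follows from mass balance,

    RdT(t) = Ra(t) - p*V * dG_mg/dt,

and endogenous glucose production is appearance not accounted for by
the exogenous inputs (glucose infusion GIR and the tracer mass itself):

    EGP(t) = Ra(t) - GIR(t) - F(t).

G_mg is glucose in mg/mL so that p*V*G_mg is a glucose mass per kg.
Time derivatives come from a cubic smoothing spline whose penalty is
chosen by generalized cross-validation; smoothing can be disabled or
replaced by a short moving average for very short series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, make_smoothing_spline

from .errors import (
    AlignmentError,
    DomainError,
    InsufficientDataError,
    SteadyStateNotReachedError,
    ValidationError,
)
from .units import insulin_pmol_to_uU

#: mg/mL of glucose per mmol/L (18.016 mg/dL / 100 mL/dL).
MG_PER_ML_PER_MMOL_L = 0.18016

PHASES = ("basal", "step1", "step2")


# ---------------------------------------------------------------------------
# configuration and containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SteeleConfig:
    """Constants of the single-pool analysis.

    pool_fraction
        Steele pool fraction p (dimensionless, 0 < p <= 1).  Default 0.65,
        the standard value for non-steady-state glucose turnover.
    dist_volume_ml_kg
        Anatomical glucose distribution volume V (mL/kg).  Default 220,
        giving an effective volume p*V = 143 mL/kg.
    smoothing
        'gcv_spline' (cubic smoothing spline, penalty by GCV), 'none'
        (interpolating cubic spline) or 'movavg' (3-point moving average
        with finite-difference derivatives, for very short series).
    ss_window_min
        Duration of the steady-state averaging window at the end of each
        phase (minutes, >= 20).
    ss_glucose_cv_max
        A window qualifies as steady state when the CV of glucose within
        it is below this fraction.
    """

    pool_fraction: float = 0.65
    dist_volume_ml_kg: float = 220.0
    smoothing: str = "gcv_spline"
    smoothing_param: float | None = None
    ss_window_min: float = 30.0
    ss_glucose_cv_max: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.pool_fraction <= 1:
            raise ValidationError("pool_fraction must be in (0, 1]")
        if self.dist_volume_ml_kg <= 0:
            raise ValidationError("dist_volume_ml_kg must be positive")
        if self.ss_window_min < 20:
            raise ValidationError("ss_window_min must be >= 20 min")
        if self.smoothing not in ("gcv_spline", "none", "movavg"):
            raise ValidationError(f"unknown smoothing method {self.smoothing!r}")

    @property
    def effective_volume(self) -> float:
        """p*V in mL/kg."""
        return self.pool_fraction * self.dist_volume_ml_kg


@dataclass
class ClampSeries:
    """Time-aligned clamp measurements for one subject-visit.

    Units: time min, glucose mmol/L, TTR dimensionless, tracer_inf and
    gir mg kg-1 min-1, insulin and c_peptide pmol/L, vo2/vco2 L/min.
    ``phase`` labels every sample as basal / step1 / step2.
    """

    time: np.ndarray
    glucose: np.ndarray
    ttr: np.ndarray
    tracer_inf: np.ndarray
    gir: np.ndarray
    insulin: np.ndarray
    c_peptide: np.ndarray
    phase: np.ndarray
    vo2: np.ndarray | None = None
    vco2: np.ndarray | None = None

    def __post_init__(self) -> None:
        arrays = ["time", "glucose", "ttr", "tracer_inf", "gir", "insulin", "c_peptide", "phase"]
        for name in arrays:
            setattr(self, name, np.asarray(getattr(self, name)))
        n = len(self.time)
        for name in arrays + ["vo2", "vco2"]:
            a = getattr(self, name)
            if a is not None and len(a) != n:
                raise ValidationError(f"ClampSeries.{name} has length {len(a)}, expected {n}")
        if np.any(np.diff(self.time) <= 0):
            raise ValidationError("time must be strictly increasing")
        if np.any((self.ttr <= 0) | (self.ttr >= 1)):
            raise ValidationError("ttr must lie in (0, 1)")
        if np.any(self.gir < 0):
            raise ValidationError("gir must be non-negative")
        present = set(np.unique(self.phase))
        unknown = present - set(PHASES)
        if unknown:
            raise ValidationError(f"unknown phase labels: {sorted(unknown)}")
        for ph in present:
            if np.sum(self.phase == ph) < 3:
                raise ValidationError(f"phase {ph!r} has fewer than 3 samples")

    def phase_mask(self, phase: str) -> np.ndarray:
        if phase not in PHASES:
            raise ValidationError(f"unknown phase {phase!r}")
        return self.phase == phase

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time_min": self.time,
                "glucose_mmol_l": self.glucose,
                "ttr": self.ttr,
                "tracer_inf_mg_kg_min": self.tracer_inf,
                "gir_mg_kg_min": self.gir,
                "insulin_pmol_l": self.insulin,
                "cpeptide_pmol_l": self.c_peptide,
                "phase": self.phase,
            }
        )
        if self.vo2 is not None:
            df["vo2_l_min"] = self.vo2
        if self.vco2 is not None:
            df["vco2_l_min"] = self.vco2
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ClampSeries":
        kwargs = {}
        for attr, col in (("vo2", "vo2_l_min"), ("vco2", "vco2_l_min")):
            if col in df.columns:
                kwargs[attr] = df[col].to_numpy(float)
        return cls(
            time=df["time_min"].to_numpy(float),
            glucose=df["glucose_mmol_l"].to_numpy(float),
            ttr=df["ttr"].to_numpy(float),
            tracer_inf=df["tracer_inf_mg_kg_min"].to_numpy(float),
            gir=df["gir_mg_kg_min"].to_numpy(float),
            insulin=df["insulin_pmol_l"].to_numpy(float),
            c_peptide=df["cpeptide_pmol_l"].to_numpy(float),
            phase=df["phase"].to_numpy(str),
            **kwargs,
        )


@dataclass
class TracerFluxes:
    """Ra/RdT/EGP time courses plus per-phase steady-state summaries.

    ``egp`` is floored at zero (negative values are a known artefact of
    the single-pool model at high insulin); ``egp_raw`` retains the
    unfloored values and ``negative_egp`` flags where flooring occurred.
    """

    time: np.ndarray
    ra: np.ndarray
    rd_t: np.ndarray
    egp: np.ndarray
    egp_raw: np.ndarray
    negative_egp: bool
    gdr: dict[str, float]
    ss_summary: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.time,
                "ra_mg_kg_min": self.ra,
                "rdt_mg_kg_min": self.rd_t,
                "egp_mg_kg_min": self.egp,
                "egp_raw_mg_kg_min": self.egp_raw,
            }
        )


# ---------------------------------------------------------------------------
# smoothing / differentiation
# ---------------------------------------------------------------------------

def smooth_and_differentiate(
    time: np.ndarray,
    values: np.ndarray,
    method: str = "gcv_spline",
    smoothing_param: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit a smooth curve to (time, values) and return (smoothed, d/dt) on the same grid.

    'gcv_spline' fits a cubic smoothing spline with the roughness penalty
    selected by generalized cross-validation; 'none' interpolates exactly
    (cubic spline, natural end conditions); 'movavg' applies a 3-point
    moving average and differentiates by central differences.
    """
    time = np.asarray(time, float)
    values = np.asarray(values, float)
    if len(time) < 4:
        raise InsufficientDataError("need at least 4 samples to smooth and differentiate")
    if np.any(np.diff(time) <= 0):
        raise ValidationError("time must be strictly increasing")

    if method == "movavg":
        kernel = np.ones(3) / 3.0
        smoothed = values.copy()
        smoothed[1:-1] = np.convolve(values, kernel, mode="valid")
        deriv = np.gradient(smoothed, time)
        return smoothed, deriv

    # A constant series defeats GCV (zero variance); its derivative is zero
    # by inspection.
    if np.ptp(values) == 0:
        return values.copy(), np.zeros_like(values)

    if method == "none":
        spline = CubicSpline(time, values, bc_type="natural")
    elif method == "gcv_spline":
        spline = make_smoothing_spline(time, values, lam=smoothing_param)
    else:
        raise ValidationError(f"unknown smoothing method {method!r}")
    return spline(time), spline.derivative()(time)


def _smoothed_state(series: ClampSeries, cfg: SteeleConfig):
    """Smoothed glucose (mg/mL), its derivative, smoothed TTR and its derivative.

    TTR is smoothed in the log domain: enrichment decays quasi-exponentially
    between plateaus and its assay noise is multiplicative, so log-TTR has
    homoscedastic noise and gentle curvature — both favour the spline fit.
    """
    g_mg = series.glucose * MG_PER_ML_PER_MMOL_L
    g_s, dg = smooth_and_differentiate(series.time, g_mg, cfg.smoothing, cfg.smoothing_param)
    # The space-correction term p*V*dG/dt needs a derivative-oriented
    # estimator: clamped glucose has low true derivative bandwidth, so a
    # local quadratic (Savitzky-Golay) over ~7 samples beats the
    # function-oriented GCV derivative.  Requires a uniform grid.
    dt_all = np.diff(series.time)
    uniform = np.allclose(dt_all, dt_all[0], rtol=1e-6)
    if cfg.smoothing == "gcv_spline" and uniform and len(series.time) >= 7:
        from scipy.signal import savgol_filter

        dg = savgol_filter(g_mg, 7, 2, deriv=1, delta=float(dt_all[0]))
    if np.any(series.ttr <= 0):
        raise DomainError("TTR must be positive everywhere")
    lz_s, dlz = smooth_and_differentiate(
        series.time, np.log(series.ttr), cfg.smoothing, cfg.smoothing_param
    )
    z_s = np.exp(lz_s)
    return g_s, dg, z_s, z_s * dlz


# ---------------------------------------------------------------------------
# fluxes
# ---------------------------------------------------------------------------

def steele_ra(series: ClampSeries, cfg: SteeleConfig | None = None) -> np.ndarray:
    """Total rate of glucose appearance Ra(t), mg kg-1 min-1 (Steele, TTR form).

    At constant TTR this reduces to the isotope-dilution identity F/TTR.
    Negative values are flagged with a warning but returned unclipped
    (flooring happens only downstream, in EGP).
    """
    cfg = cfg or SteeleConfig()
    g_s, _, z_s, dz = _smoothed_state(series, cfg)
    if np.any(z_s <= 0):
        raise DomainError("smoothed TTR must be positive over the evaluation window")
    pv = cfg.effective_volume
    ra = (series.tracer_inf - pv * g_s * dz) / z_s
    if np.any(ra < 0):
        warnings.warn("negative Ra encountered; check smoothing and TTR quality", stacklevel=2)
    return ra


def rd_total(ra: np.ndarray, series: ClampSeries, cfg: SteeleConfig | None = None) -> np.ndarray:
    """Total rate of glucose disappearance RdT(t) = Ra(t) - p*V*dG/dt.

    Equals Ra wherever glucose is at steady state.
    """
    cfg = cfg or SteeleConfig()
    ra = np.asarray(ra, float)
    if len(ra) != len(series.time):
        raise AlignmentError("Ra curve is not on the ClampSeries grid")
    _, dg, _, _ = _smoothed_state(series, cfg)
    return ra - cfg.effective_volume * dg


def egp(ra: np.ndarray, series: ClampSeries) -> tuple[np.ndarray, np.ndarray, bool]:
    """Endogenous glucose production EGP(t) = Ra(t) - GIR(t) - F(t).

    Returns (floored, raw, negative_flag).  The tracer infusion F is
    subtracted because it is exogenous glucose mass, however small.
    """
    ra = np.asarray(ra, float)
    if len(ra) != len(series.time):
        raise AlignmentError("Ra curve is not on the ClampSeries grid")
    raw = ra - series.gir - series.tracer_inf
    floored = np.maximum(raw, 0.0)
    return floored, raw, bool(np.any(raw < 0))


def suppression_pct(egp_basal: float, egp_step: float) -> float:
    """Percent suppression of EGP relative to basal: 100*(1 - step/basal).

    Negative if EGP rises above basal.
    """
    if egp_basal <= 0:
        raise DomainError("basal EGP must be positive to express suppression")
    return 100.0 * (1.0 - egp_step / egp_basal)


def _ss_window_mask(series: ClampSeries, cfg: SteeleConfig, phase: str) -> np.ndarray:
    mask = series.phase_mask(phase)
    if not mask.any():
        raise SteadyStateNotReachedError(f"no samples in phase {phase!r}")
    t_end = series.time[mask].max()
    window = mask & (series.time >= t_end - cfg.ss_window_min)
    g = series.glucose[window]
    if len(g) < 3:
        raise SteadyStateNotReachedError(f"fewer than 3 samples in the {phase!r} steady-state window")
    cv = float(np.std(g, ddof=1) / np.mean(g))
    if cv >= cfg.ss_glucose_cv_max:
        raise SteadyStateNotReachedError(
            f"glucose CV {cv:.3f} in the last {cfg.ss_window_min:g} min of {phase!r} "
            f"exceeds {cfg.ss_glucose_cv_max:g}; steady state not reached"
        )
    return window


def gdr(series: ClampSeries, cfg: SteeleConfig | None = None, phase: str = "step2") -> float:
    """Glucose disposal rate for one clamp phase, mg kg-1 min-1.

    Mean glucose infusion rate over the qualifying steady-state window,
    corrected for the change of glucose mass in its distribution space:
    GDR = mean(GIR) - p*V * (dG_mg/dt over window).  Falling glucose
    raises GDR (glucose leaving the space is also being disposed).
    """
    cfg = cfg or SteeleConfig()
    window = _ss_window_mask(series, cfg, phase)
    t = series.time[window]
    g_mg = series.glucose[window] * MG_PER_ML_PER_MMOL_L
    slope = float(np.polyfit(t, g_mg, 1)[0])  # least-squares drift over the window
    return float(np.mean(series.gir[window]) - cfg.effective_volume * slope)


def sensitivity_index(flux_mg_kg_min: float, ss_insulin_uU_ml: float) -> float:
    """Insulin-normalized flux (GDR/I or RdT/I), mg kg-1 min-1 per uU/mL."""
    if ss_insulin_uU_ml <= 0:
        raise DomainError("steady-state insulin must be positive")
    return flux_mg_kg_min / ss_insulin_uU_ml


def mcr_glucose(rd_ss_mg_kg_min: float, glucose_ss_mg_ml: float) -> float:
    """Metabolic clearance rate of glucose: Rd / G, mL kg-1 min-1."""
    if glucose_ss_mg_ml <= 0:
        raise DomainError("steady-state glucose must be positive")
    return rd_ss_mg_kg_min / glucose_ss_mg_ml


def mcr_insulin(
    iir_mU_m2_min: float,
    ss_insulin_uU_ml: float,
    basal_insulin_uU_ml: float,
    cpep_ratio: float,
) -> float:
    """Metabolic clearance rate of insulin during a clamp step, mL m-2 min-1.

    MCR_I = infusion rate / (steady-state insulin minus the residual
    endogenous component).  The residual endogenous insulin is estimated
    as basal insulin scaled by the C-peptide suppression ratio
    (C-peptide_ss / C-peptide_basal), since C-peptide tracks secretion.
    """
    endogenous = basal_insulin_uU_ml * cpep_ratio
    denom = ss_insulin_uU_ml - endogenous
    if denom <= 0:
        raise DomainError("steady-state insulin does not exceed the estimated endogenous component")
    return iir_mU_m2_min * 1000.0 / denom


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def analyze_clamp(series: ClampSeries, cfg: SteeleConfig | None = None) -> TracerFluxes:
    """Run the complete single-pool analysis on one clamp series.

    Produces Ra/RdT/EGP time courses, per-phase GDR and a per-phase
    steady-state summary table (means of Ra, RdT, EGP, GDR, glucose,
    insulin over each qualifying window, plus EGP suppression and
    insulin-normalized indices for the steps).
    """
    cfg = cfg or SteeleConfig()
    ra = steele_ra(series, cfg)
    rdt = rd_total(ra, series, cfg)
    egp_floored, egp_raw, neg = egp(ra, series)

    rows = []
    gdr_by_phase: dict[str, float] = {}
    basal_egp = np.nan
    basal_insulin = np.nan
    basal_cpep = np.nan
    for phase in PHASES:
        if not series.phase_mask(phase).any():
            continue
        try:
            window = _ss_window_mask(series, cfg, phase)
        except SteadyStateNotReachedError:
            warnings.warn(f"phase {phase!r}: steady state not reached; summary skipped", stacklevel=2)
            continue
        mean = lambda a: float(np.mean(a[window]))  # noqa: E731
        row = {
            "phase": phase,
            "ra": mean(ra),
            "rd_t": mean(rdt),
            "egp": mean(egp_floored),
            "glucose_mmol_l": mean(series.glucose),
            "insulin_pmol_l": mean(series.insulin),
            "cpeptide_pmol_l": mean(series.c_peptide),
        }
        row["gdr"] = gdr(series, cfg, phase) if phase != "basal" else np.nan
        if phase != "basal":
            gdr_by_phase[phase] = row["gdr"]
        ins_uU = insulin_pmol_to_uU(row["insulin_pmol_l"])
        row["mcr_glucose_ml_kg_min"] = mcr_glucose(
            row["rd_t"], row["glucose_mmol_l"] * MG_PER_ML_PER_MMOL_L
        )
        if phase == "basal":
            basal_egp = row["egp"]
            basal_insulin = row["insulin_pmol_l"]
            basal_cpep = row["cpeptide_pmol_l"]
            row["egp_suppression_pct"] = 0.0
            row["gdr_per_insulin"] = np.nan
            row["rdt_per_insulin"] = np.nan
        else:
            row["egp_suppression_pct"] = (
                suppression_pct(basal_egp, row["egp"]) if basal_egp > 0 else np.nan
            )
            row["gdr_per_insulin"] = sensitivity_index(row["gdr"], ins_uU)
            row["rdt_per_insulin"] = sensitivity_index(row["rd_t"], ins_uU)
        rows.append(row)

    return TracerFluxes(
        time=series.time.copy(),
        ra=ra,
        rd_t=rdt,
        egp=egp_floored,
        egp_raw=egp_raw,
        negative_egp=neg,
        gdr=gdr_by_phase,
        ss_summary=pd.DataFrame(rows),
    )
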