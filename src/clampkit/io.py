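"""Schema-validated CSV/JSON readers and writers, run configuration, and
the end-to-end report builder.

Units are encoded in column names (``glucose_mmol_l``, ``insulin_pmol_l``,
``gir_mg_kg_min``...) rather than a sidecar, which makes silent
mmol/mg confusion impossible; a ``glucose_mg_dl`` column is accepted and
converted with a logged note.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as stats_mod
from .errors import ValidationError
from .glycemia import CgmTrace, auc_trapezoid, cgm_summary
from .secretion import beta_cell_function, deconvolve_isr, population_kinetics
from .tracer import ClampSeries, SteeleConfig, analyze_clamp
from .units import glucose_mg_to_mmol, insulin_pmol_to_uU

logger = logging.getLogger("clampkit")


def setup_logging(level: int = logging.INFO) -> None:
    """Configure stderr logging for CLI use."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("clampkit")
    if not root.handlers:
        root.addHandler(handler)
    root.setLevel(level)


SCHEMAS: dict[str, dict[str, list[str]]] = {
    "clamp": {
        "required": ["time_min", "glucose_mmol_l", "ttr", "tracer_inf_mg_kg_min",
                     "gir_mg_kg_min", "insulin_pmol_l", "cpeptide_pmol_l", "phase"],
        "optional": ["vo2_l_min", "vco2_l_min"],
    },
    "mmtt": {
        "required": ["time_min", "glucose_mmol_l", "insulin_pmol_l", "cpeptide_pmol_l"],
        "optional": [],
    },
    "cgm": {"required": ["timestamp", "glucose_mmol_l"], "optional": []},
    "diet": {
        "required": ["date", "energy_kcal", "protein_g", "cho_g", "fat_g", "fibre_g"],
        "optional": ["mycoprotein_g"],
    },
    "cohort": {"required": stats_mod.COHORT_COLUMNS, "optional": []},
}


def read_series(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Raises :class:`ValidationError` naming any missing columns; converts
    a ``glucose_mg_dl`` column to mmol/L with a logged note.
    """
    if schema not in SCHEMAS:
        raise ValidationError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if "glucose_mg_dl" in df.columns and "glucose_mmol_l" not in df.columns:
        df["glucose_mmol_l"] = glucose_mg_to_mmol(df.pop("glucose_mg_dl").to_numpy(float))
        logger.info("%s: converted glucose_mg_dl -> glucose_mmol_l (/18.016)", path.name)
    missing = [c for c in SCHEMAS[schema]["required"] if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing required columns {missing} for schema {schema!r}")
    return df


@dataclass
class RunConfig:
    """Serializable configuration reproducing all default analysis choices."""

    steele: SteeleConfig = field(default_factory=SteeleConfig)
    deconv_lambda: float | None = None  # None = L-curve per series
    cgm_lo_mmol_l: float = 4.0
    cgm_hi_mmol_l: float = 10.0
    cgm_gap_min: float = 30.0
    cgm_min_hours: float = 24.0
    seed: int = 0
    output_dir: str = "clampkit_out"

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        steele = SteeleConfig(**d.pop("steele", {}))
        return cls(steele=steele, **d)


# ---------------------------------------------------------------------------
# per-file analyses used by the CLI and the report
# ---------------------------------------------------------------------------

def analyze_clamp_file(path: str | Path, config: RunConfig | None = None) -> dict:
    """Full tracer analysis of one clamp CSV: fluxes frame + phase summary."""
    config = config or RunConfig()
    series = ClampSeries.from_frame(read_series(path, "clamp"))
    fluxes = analyze_clamp(series, config.steele)
    return {
        "fluxes": fluxes.to_frame(),
        "summary": fluxes.ss_summary,
        "gdr": fluxes.gdr,
        "negative_egp": fluxes.negative_egp,
    }


def analyze_mmtt_file(path: str | Path, subject_meta: dict, config: RunConfig | None = None,
                      is_index: float | None = None) -> dict:
    """MMTT analysis: AUCs, deconvolved ISR, optional beta-cell index."""
    config = config or RunConfig()
    df = read_series(path, "mmtt")
    t = df["time_min"].to_numpy(float)
    kin = population_kinetics(
        age=subject_meta["age"], sex=subject_meta["sex"], bmi=subject_meta["bmi"],
        diabetic=subject_meta.get("diabetic", True), weight=subject_meta["weight"],
        height=subject_meta["height"],
    )
    sec = deconvolve_isr(df["cpeptide_pmol_l"].to_numpy(float), t, kin, lam=config.deconv_lambda)
    span = (0.0, min(120.0, t[-1]))
    out = {
        "glucose_auc": auc_trapezoid(t, df["glucose_mmol_l"].to_numpy(float), *span),
        "glucose_iauc": auc_trapezoid(t, df["glucose_mmol_l"].to_numpy(float), *span, incremental=True),
        "insulin_auc": auc_trapezoid(t, df["insulin_pmol_l"].to_numpy(float), *span),
        "isr_auc": sec.isr_auc,
        "isr": sec,
        "kinetics": kin,
    }
    if is_index is not None:
        out["beta_cell_index"] = beta_cell_function(
            t, sec.isr, t, df["glucose_mmol_l"].to_numpy(float), is_index, span_min=span[1]
        )
    return out


def analyze_cgm_file(path: str | Path, config: RunConfig | None = None) -> dict:
    config = config or RunConfig()
    trace = CgmTrace.from_frame(read_series(path, "cgm"), gap_min=config.cgm_gap_min)
    return cgm_summary(trace, config.cgm_lo_mmol_l, config.cgm_hi_mmol_l, config.cgm_min_hours)


# ---------------------------------------------------------------------------
# end-to-end report
# ---------------------------------------------------------------------------

def _discover(inputs: Path) -> tuple[pd.DataFrame, list[tuple[str, str, str, Path]]]:
    meta_path = inputs / "subjects.csv"
    if not meta_path.exists():
        raise ValidationError(f"no subjects.csv in {inputs}")
    meta = pd.read_csv(meta_path)
    found = []
    for kind in ("clamp", "mmtt", "cgm"):
        for p in sorted(inputs.glob(f"*_{kind}.csv")):
            stem = p.stem[: -(len(kind) + 1)]
            try:
                subject, visit = stem.rsplit("_", 1)
            except ValueError:
                continue
            if visit in ("pre", "post"):
                found.append((subject, visit, kind, p))
    if not found:
        raise ValidationError(f"no per-subject input files found in {inputs}")
    return meta, found


def run_report(config: RunConfig, inputs: str | Path) -> dict:
    """Derive per-subject outcomes from every discoverable input file and
    assemble the cohort summary (mean +/- SD by group x intervention) and
    two-way mixed-ANOVA effect tables for the summary measures.

    Input layout: ``subjects.csv`` (subject_id, group, age, sex, weight,
    height, bmi) plus ``<subject>_<pre|post>_{clamp,mmtt,cgm}.csv``.
    Per-file failures are warnings, not fatal (partial cohorts allowed).
    """
    inputs = Path(inputs)
    meta, found = _discover(inputs)
    meta = meta.set_index("subject_id")
    rows = []
    is_by_visit: dict[tuple[str, str], float] = {}

    for subject, visit, kind, path in found:
        if subject not in meta.index:
            logger.warning("%s: subject %s not in subjects.csv; skipped", path.name, subject)
            continue
        group = meta.loc[subject, "group"]

        def add(outcome: str, value: float, level: str = "summary") -> None:
            rows.append({"subject_id": subject, "group": group, "intervention": visit,
                         "within_level": level, "outcome": outcome, "value": float(value)})

        try:
            if kind == "clamp":
                res = analyze_clamp_file(path, config)
                summ = res["summary"].set_index("phase")
                for phase in summ.index:
                    add("egp", summ.loc[phase, "egp"], phase)
                    add("rdt", summ.loc[phase, "rd_t"], phase)
                if "step2" in summ.index:
                    add("gdr_step2", summ.loc["step2", "gdr"])
                    add("rdt_per_insulin", summ.loc["step2", "rdt_per_insulin"])
                    add("gdr_per_insulin", summ.loc["step2", "gdr_per_insulin"])
                    add("egp_suppression_step2_pct", summ.loc["step2", "egp_suppression_pct"])
                    is_by_visit[(subject, visit)] = float(summ.loc["step2", "rdt_per_insulin"])
                if "step1" in summ.index:
                    add("egp_suppression_step1_pct", summ.loc["step1", "egp_suppression_pct"])
            elif kind == "mmtt":
                smeta = meta.loc[subject].to_dict()
                res = analyze_mmtt_file(path, smeta, config,
                                        is_index=is_by_visit.get((subject, visit)))
                add("glucose_auc_2h", res["glucose_auc"])
                add("insulin_auc_2h", res["insulin_auc"])
                add("isr_auc_2h", res["isr_auc"])
                if "beta_cell_index" in res and np.isfinite(res.get("beta_cell_index", np.nan)):
                    add("beta_cell_index", res["beta_cell_index"])
            elif kind == "cgm":
                res = analyze_cgm_file(path, config)
                add("cgm_mean", res["mean"])
                add("cgm_tir_pct", res["tir"])
        except Exception as exc:  # per-file robustness: warn and continue
            logger.warning("%s: %s", path.name, exc)

    if not rows:
        raise ValidationError("no outcomes could be derived from the inputs")
    table = pd.DataFrame(rows)
    summaries = pd.concat(
        [stats_mod.outcome_summary(table, o) for o in sorted(table["outcome"].unique())],
        ignore_index=True,
    )
    effects = {}
    for outcome in sorted(table["outcome"].unique()):
        sub = table[table["outcome"] == outcome]
        if sub["intervention"].nunique() == 2 and sub["group"].nunique() == 2:
            try:
                effects[outcome] = stats_mod.anova_2way_summary(table, outcome)
            except Exception as exc:
                logger.warning("ANOVA for %s failed: %s", outcome, exc)
    return {"cohort_table": table, "summaries": summaries, "effects": effects}


def write_report(bundle: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["cohort_table"].to_csv(out / "cohort_table.csv", index=False)
    bundle["summaries"].to_csv(out / "summaries.csv", index=False)
    eff = []
    for outcome, frame in bundle["effects"].items():
        frame = frame.copy()
        frame.insert(0, "outcome", outcome)
        eff.append(frame)
    if eff:
        pd.concat(eff, ignore_index=True).to_csv(out / "effects.csv", index=False)
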