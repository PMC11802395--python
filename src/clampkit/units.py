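"""Unit conversions and closed-form fasting indices.

All concentrations follow the SI conventions of UK clinical chemistry:
glucose and lipids in mmol/L, insulin and C-peptide in pmol/L, HbA1c in
mmol/mol.  Conversions to the legacy units used in the clamp literature
(insulin in uU/mL, glucose in mg/dL) live here so that the factor appears
in exactly one place.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DomainError

#: pmol of insulin per uU (1 uU/mL = 6.945 pmol/L).
INSULIN_PMOL_PER_UU = 6.945

#: mg of glucose per mmol divided by dL per L (1 mmol/L = 18.016 mg/dL).
GLUCOSE_MG_DL_PER_MMOL_L = 18.016

#: Friedewald formula is not valid above this triglyceride concentration (mmol/L).
FRIEDEWALD_TG_LIMIT = 4.52


def _check_nonnegative(x, name: str) -> None:
    if np.any(np.asarray(x) < 0):
        raise DomainError(f"{name} must be non-negative")


def insulin_pmol_to_uU(x):
    """Convert insulin from pmol/L to uU/mL (divide by 6.945).

    Accepts scalars or arrays; negative input raises :class:`DomainError`.
    """
    _check_nonnegative(x, "insulin (pmol/L)")
    return np.asarray(x) / INSULIN_PMOL_PER_UU if np.ndim(x) else x / INSULIN_PMOL_PER_UU


def insulin_uU_to_pmol(x):
    """Convert insulin from uU/mL to pmol/L (multiply by 6.945)."""
    _check_nonnegative(x, "insulin (uU/mL)")
    return np.asarray(x) * INSULIN_PMOL_PER_UU if np.ndim(x) else x * INSULIN_PMOL_PER_UU


def glucose_mmol_to_mg(x):
    """Convert glucose from mmol/L to mg/dL (multiply by 18.016)."""
    _check_nonnegative(x, "glucose (mmol/L)")
    return np.asarray(x) * GLUCOSE_MG_DL_PER_MMOL_L if np.ndim(x) else x * GLUCOSE_MG_DL_PER_MMOL_L


def glucose_mg_to_mmol(x):
    """Convert glucose from mg/dL to mmol/L (divide by 18.016)."""
    _check_nonnegative(x, "glucose (mg/dL)")
    return np.asarray(x) / GLUCOSE_MG_DL_PER_MMOL_L if np.ndim(x) else x / GLUCOSE_MG_DL_PER_MMOL_L


def homa_ir(glucose_mmol_l: float, insulin_uU_ml: float) -> float:
    """Homeostatic model assessment of insulin resistance.

    HOMA-IR = fasting glucose (mmol/L) x fasting insulin (uU/mL) / 22.5.
    Both inputs must be strictly positive.
    """
    if glucose_mmol_l <= 0 or insulin_uU_ml <= 0:
        raise DomainError("HOMA-IR requires strictly positive glucose and insulin")
    return glucose_mmol_l * insulin_uU_ml / 22.5


def friedewald_ldl(total_chol: float, hdl: float, triglycerides: float) -> float:
    """LDL cholesterol by the Friedewald formula (all mmol/L).

    LDL = TC - HDL - TG/2.2.  Refuses TG > 4.52 mmol/L, where the fixed
    TG:VLDL ratio breaks down; a negative result is returned but flagged
    with a warning since it indicates inconsistent inputs.
    """
    for name, v in (("total cholesterol", total_chol), ("HDL", hdl), ("triglycerides", triglycerides)):
        if v < 0:
            raise DomainError(f"{name} must be non-negative")
    if triglycerides > FRIEDEWALD_TG_LIMIT:
        raise DomainError(
            f"Friedewald formula invalid for triglycerides > {FRIEDEWALD_TG_LIMIT} mmol/L "
            f"(got {triglycerides})"
        )
    ldl = total_chol - hdl - triglycerides / 2.2
    if ldl < 0:
        warnings.warn("Friedewald LDL is negative; inputs are inconsistent", stacklevel=2)
    return ldl


def dubois_bsa(weight_kg: float, height_cm: float) -> float:
    """Body surface area (m^2) by the DuBois & DuBois formula."""
    if weight_kg <= 0 or height_cm <= 0:
        raise DomainError("weight and height must be positive")
    return 0.007184 * weight_kg**0.425 * height_cm**0.725


def round_half_up(x: float, decimals: int = 1) -> float:
    """Display rounding: half-up at the report boundary (internal values stay full precision)."""
    factor = 10.0**decimals
    return float(np.floor(x * factor + 0.5) / factor)


@dataclass
class FastingPanel:
    """Fasting metabolite panel for one subject-visit.

    Concentrations: glucose and lipids mmol/L, insulin/C-peptide pmol/L,
    HbA1c mmol/mol, lactate mmol/L.  ``ldl`` may be supplied directly or
    computed from the lipid triad via :meth:`with_friedewald_ldl`.
    """

    glucose: float
    insulin: float
    c_peptide: float
    total_chol: float
    hdl: float
    triglycerides: float
    ldl: float | None = None
    hba1c: float | None = None
    lactate: float | None = None

    def __post_init__(self) -> None:
        for name in ("glucose", "insulin", "c_peptide", "total_chol", "hdl", "triglycerides"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise DomainError(f"FastingPanel.{name} must be non-negative")

    def with_friedewald_ldl(self) -> "FastingPanel":
        """Return a copy with LDL filled in from the Friedewald formula."""
        ldl = friedewald_ldl(self.total_chol, self.hdl, self.triglycerides)
        return FastingPanel(
            glucose=self.glucose, insulin=self.insulin, c_peptide=self.c_peptide,
            total_chol=self.total_chol, hdl=self.hdl, triglycerides=self.triglycerides,
            ldl=ldl, hba1c=self.hba1c, lactate=self.lactate,
        )

    @property
    def homa_ir(self) -> float:
        return homa_ir(self.glucose, insulin_pmol_to_uU(self.insulin))
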