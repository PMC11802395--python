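"""Diet-prescription arithmetic for a eucaloric high-protein intervention:
energy requirement, 30/35/35 macronutrient split, mycoprotein fibre
accounting, and the Goldberg screen for dietary under-reporting."""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError, ValidationError

KCAL_PER_G = {"protein": 4.0, "cho": 4.0, "fat": 9.0}
DEFAULT_FRACTIONS = {"protein": 0.30, "cho": 0.35, "fat": 0.35}
DEFAULT_PAL = 1.6
MYCOPROTEIN_FIBRE_DENSITY = 0.06  # g fibre per g wet mycoprotein (beta-glucan + chitin)

# Henry (Oxford, 2005) weight-only BMR equations, MJ/day: slope*weight + intercept
_HENRY_MJ = {
    ("male", 18, 30): (0.0669, 2.28),
    ("male", 30, 60): (0.0592, 2.48),
    ("male", 60, 150): (0.0563, 2.15),
    ("female", 18, 30): (0.0546, 2.33),
    ("female", 30, 60): (0.0407, 2.90),
    ("female", 60, 150): (0.0424, 2.38),
}
_KCAL_PER_MJ = 239.006


@dataclass(frozen=True)
class DietPrescription:
    """Daily prescription; grams follow the 4/4/9 kcal/g convention."""

    energy_kcal: float
    protein_g: float
    cho_g: float
    fat_g: float
    fibre_g: float = 0.0
    mycoprotein_g: float = 0.0

    def __post_init__(self) -> None:
        if self.mycoprotein_g < 0:
            raise ValidationError("mycoprotein_g must be non-negative")
        recon = 4.0 * self.protein_g + 4.0 * self.cho_g + 9.0 * self.fat_g
        if abs(recon - self.energy_kcal) > 0.005 * self.energy_kcal:
            raise ValidationError(
                f"macronutrient grams reconstruct {recon:.1f} kcal, not {self.energy_kcal:.1f}"
            )

    @property
    def protein_fraction(self) -> float:
        return 4.0 * self.protein_g / self.energy_kcal


def bmr_kcal(weight_kg: float, age: float, sex: str, height_cm: float | None = None,
             equation: str = "henry") -> float:
    """Basal metabolic rate, kcal/day.

    'henry' uses the Henry (Oxford) weight-only age-sex equations (UK
    dietetic default); 'mifflin' uses Mifflin-St Jeor (needs height).
    """
    if weight_kg <= 0:
        raise DomainError("weight must be positive")
    if sex not in ("male", "female"):
        raise ValidationError("sex must be 'male' or 'female'")
    if equation == "henry":
        for (s, lo, hi), (slope, intercept) in _HENRY_MJ.items():
            if s == sex and lo <= age < hi:
                return (slope * weight_kg + intercept) * _KCAL_PER_MJ
        raise ValidationError(f"no Henry equation for age {age}")
    if equation == "mifflin":
        if height_cm is None:
            raise ValidationError("Mifflin-St Jeor requires height_cm")
        base = 10.0 * weight_kg + 6.25 * height_cm - 5.0 * age
        return base + (5.0 if sex == "male" else -161.0)
    raise ValidationError(f"unknown BMR equation {equation!r}")


def energy_requirement(bmr: float, pal: float = DEFAULT_PAL) -> float:
    """Daily energy requirement: BMR times physical activity level."""
    if bmr <= 0:
        raise DomainError("BMR must be positive")
    if not 1.2 <= pal <= 2.5:
        raise ValidationError(f"physical activity level {pal} outside [1.2, 2.5]")
    return bmr * pal


def macro_split(energy_kcal: float, fractions: dict[str, float] | None = None) -> DietPrescription:
    """Convert an energy prescription into daily macronutrient grams."""
    fractions = fractions or DEFAULT_FRACTIONS
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValidationError("energy fractions must sum to 1")
    grams = {m: energy_kcal * frac / KCAL_PER_G[m] for m, frac in fractions.items()}
    return DietPrescription(
        energy_kcal=energy_kcal,
        protein_g=grams.get("protein", 0.0),
        cho_g=grams.get("cho", 0.0),
        fat_g=grams.get("fat", 0.0),
    )


def mycoprotein_fibre(myco_g: float, fibre_density: float = MYCOPROTEIN_FIBRE_DENSITY) -> float:
    """Fibre (g/day) contributed by a given mycoprotein intake."""
    if myco_g < 0:
        raise DomainError("mycoprotein intake must be non-negative")
    return myco_g * fibre_density


def goldberg_cutoff(
    pal: float = DEFAULT_PAL,
    n: int = 1,
    days: int = 7,
    cv_intake: float = 23.0,
    cv_bmr: float = 8.5,
    cv_pal: float = 15.0,
    z: float = 1.96,
) -> float:
    """Lower Goldberg confidence bound on the plausible EI:BMR ratio.

    cutoff = PAL * exp(-z * S / 100), with S the pooled CV (%):
    S = sqrt(cv_intake^2/days + cv_bmr^2 + cv_pal^2) / sqrt(n).
    Defaults: individual-level screen (n=1) of a 7-day weighed record
    with the conventional component CVs.
    """
    if n < 1 or days < 1:
        raise ValidationError("n and days must be >= 1")
    s = math.sqrt(cv_intake**2 / days + cv_bmr**2 + cv_pal**2) / math.sqrt(n)
    return pal * math.exp(-z * s / 100.0)


def goldberg_screen(
    energy_intake_kcal: float,
    bmr: float,
    cutoff: float | None = None,
) -> dict[str, float | bool]:
    """Flag dietary under-reporting: EI:BMR ratio below the Goldberg cut-off."""
    if bmr <= 0:
        raise DomainError("BMR must be positive")
    if cutoff is None:
        cutoff = goldberg_cutoff()
    ratio = energy_intake_kcal / bmr
    return {"ratio": ratio, "cutoff": cutoff, "under_reporter": ratio < cutoff}
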