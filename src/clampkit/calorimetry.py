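"""Indirect-calorimetry substrate oxidation (Frayn equations) and
non-oxidative glucose disposal during the clamp.

Frayn (1983) whole-body stoichiometry, rates in g/min from gas exchange
in L/min and urinary nitrogen excretion in g/min:

    CHO oxidation = 4.55*VCO2 - 3.21*VO2 - 2.87*N
    fat oxidation = 1.67*VO2 - 1.67*VCO2 - 1.92*N

Negative rates (RQ outside the oxidative range) are clipped to zero and
flagged.  Non-oxidative disposal ("storage") is GDR minus CHO oxidation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import DomainError


@dataclass(frozen=True)
class GasExchange:
    """Steady-state gas exchange: VO2/VCO2 in L/min, urinary nitrogen g/min."""

    vo2: float
    vco2: float
    urinary_n: float = 0.0

    def __post_init__(self) -> None:
        if self.vo2 <= 0:
            raise DomainError("VO2 must be positive")
        rq = self.vco2 / self.vo2
        if not 0.6 <= rq <= 1.3:
            warnings.warn(f"RQ {rq:.2f} outside the physiologic screen [0.6, 1.3]", stacklevel=2)

    @property
    def rq(self) -> float:
        return self.vco2 / self.vo2


@dataclass(frozen=True)
class OxidationRates:
    """Substrate oxidation normalized to body mass, with clipping flags."""

    cho_ox: float  # mg kg-1 min-1
    fat_ox: float  # mg kg-1 min-1
    cho_clipped: bool
    fat_clipped: bool


def frayn_oxidation(g: GasExchange, weight_kg: float) -> OxidationRates:
    """Carbohydrate and fat oxidation (mg kg-1 min-1) from gas exchange."""
    if weight_kg <= 0:
        raise DomainError("weight must be positive")
    cho = (4.55 * g.vco2 - 3.21 * g.vo2 - 2.87 * g.urinary_n) * 1000.0 / weight_kg
    fat = (1.67 * g.vo2 - 1.67 * g.vco2 - 1.92 * g.urinary_n) * 1000.0 / weight_kg
    return OxidationRates(
        cho_ox=max(cho, 0.0),
        fat_ox=max(fat, 0.0),
        cho_clipped=cho < 0,
        fat_clipped=fat < 0,
    )


def glucose_storage(gdr_mg_kg_min: float, cho_ox_mg_kg_min: float) -> tuple[float, bool]:
    """Non-oxidative glucose disposal: GDR - CHO oxidation.

    Returns (storage, negative_flag); a negative difference is reported
    as-is but flagged (oxidation exceeding disposal indicates measurement
    inconsistency).
    """
    if gdr_mg_kg_min < 0 or cho_ox_mg_kg_min < 0:
        raise DomainError("GDR and CHO oxidation must be non-negative")
    storage = gdr_mg_kg_min - cho_ox_mg_kg_min
    return storage, storage < 0
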