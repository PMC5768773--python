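"""Formate–ΣCO₂ disequilibrium index.

In serpentinizing systems formate can form abiotically by equilibration of
bicarbonate with hydrogen:

    HCO₃⁻ + H₂ = HCOO⁻ + H₂O

This module quantifies how far a fluid sits from that equilibrium as a
reaction-quotient index, ``ln(Q) − ln(K)`` with
``Q = ([HCOO⁻]·a_H2O)/([HCO₃⁻]·a_H2)``.  A positive index means formate
excess relative to equilibrium; near zero means the two species are close
to equilibrium.  ΣCO₂ (the sum of CO₂(aq), H₂CO₃, HCO₃⁻ and CO₃²⁻) is used
directly as the bicarbonate proxy — full carbonate speciation is out of
scope and the substitution is flagged with a warning.  The equilibrium
constant is user-supplied at the temperature of interest; no thermodynamic
database is bundled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

__all__ = ["EquilibriumInput", "SpeciationWarning", "disequilibrium_index"]


class SpeciationWarning(UserWarning):
    """ΣCO₂ used as-is in place of speciated bicarbonate."""


@dataclass(frozen=True)
class EquilibriumInput:
    """Inputs of the disequilibrium index.

    Concentrations in µmol/L; ``h2_activity`` may be a dimensionless
    activity or an mmol/kg proxy — only ratios of the same vent-to-vent
    choice are meaningful.  ``lnk`` is ln K of the formate-forming reaction
    at temperature ``temperature_c`` (metadata only).
    """

    formate: float
    sigma_co2: float
    h2_activity: float
    h2o_activity: float = 1.0
    lnk: Optional[float] = None
    temperature_c: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("formate", "sigma_co2", "h2_activity", "h2o_activity"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v!r}")


def disequilibrium_index(inp: EquilibriumInput, warn_speciation: bool = True) -> float:
    """ln(Q) − ln(K) for the formate-forming reaction.

    Strictly increasing in formate and decreasing in ΣCO₂ and H₂ activity;
    0 at equilibrium, positive for formate excess.
    """
    if inp.lnk is None:
        raise ValueError(
            "no equilibrium constant: supply lnk (ln K of HCO3- + H2 = HCOO- + H2O "
            "at the fluid temperature; not computed by this package)"
        )
    if warn_speciation:
        warnings.warn(
            "using total ΣCO₂ as the HCO₃⁻ proxy (no carbonate speciation)",
            SpeciationWarning,
            stacklevel=2,
        )
    q = (inp.formate * inp.h2o_activity) / (inp.sigma_co2 * inp.h2_activity)
    return math.log(q) - inp.lnk
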