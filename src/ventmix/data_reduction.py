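"""Corrections from raw measured isotope values to compound-specific values.

Three corrections, in the order a compound-specific radiocarbon (CSRA)
workflow applies them:

1. **Constant-contamination blank**: paired process standards — one
   radiocarbon-dead, one modern, carried through the full isolation
   procedure — determine the mass and F14C of extraneous carbon added
   during sample processing, which is then subtracted from sample
   measurements by isotope mass balance.
2. **Derivatization**: fatty acids are measured as methyl esters; the
   added methyl carbon (of F14C/δ13C inferred from a co-derivatized
   standard of known composition) is removed by a carbon-number-weighted
   balance.
3. **Co-eluting contaminant bounding**: when a target compound cannot be
   chromatographically separated from an unresolved complex mixture (UCM),
   the target's F14C is bracketed by assuming the contaminant is fully
   modern or fully dead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .isotope_core import Convention, IsotopeValue

__all__ = [
    "ProcessStandard",
    "BlankModel",
    "DerivatizationSpec",
    "ContaminantMixture",
    "BlankCorrectionWarning",
    "characterize_blank",
    "blank_correct",
    "underivatize",
    "infer_reagent",
    "contaminant_bounds",
]

#: Blank carbon fractions above this trigger a warning: in a well-behaved
#: CSRA procedure extraneous carbon stays at or below a few percent of
#: sample carbon.
BLANK_FRACTION_WARN = 0.03


class BlankCorrectionWarning(UserWarning):
    """A correction produced a flagged (clipped or unusually large) result."""


@dataclass(frozen=True)
class ProcessStandard:
    """A compound of known isotopic composition carried through the full
    isolation procedure to quantify extraneous carbon."""

    name: str
    known_f14c: IsotopeValue
    mass_c: float  # µg carbon
    measured_f14c: IsotopeValue

    def __post_init__(self) -> None:
        if not self.mass_c > 0:
            raise ValueError(f"standard {self.name!r}: mass_c must be > 0")


@dataclass(frozen=True)
class BlankModel:
    """Constant-contamination parameters: one pool of extraneous carbon with
    a single mass and F14C, shared by every sample of the batch."""

    mass_c: float  # µg extraneous carbon
    f14c: IsotopeValue
    mass_c_sigma: float = 0.0
    indeterminate_f14c: bool = False  # True when mass_c ≈ 0 (F14C unconstrained)

    def __post_init__(self) -> None:
        if self.mass_c < 0:
            raise ValueError("blank mass_c must be >= 0")


@dataclass(frozen=True)
class DerivatizationSpec:
    """Carbon bookkeeping for a derivatized compound (e.g. a FAME: one
    methyl carbon added to an n-carbon fatty acid)."""

    n_compound: int
    n_added: int
    reagent_f14c: Optional[IsotopeValue] = None
    reagent_d13c: Optional[IsotopeValue] = None

    def __post_init__(self) -> None:
        if self.n_compound < 1:
            raise ValueError("n_compound must be a positive integer")
        if self.n_added < 1:
            raise ValueError("n_added must be >= 1")

    @property
    def n_total(self) -> int:
        return self.n_compound + self.n_added


@dataclass(frozen=True)
class ContaminantMixture:
    """A combined chromatographic isolate: target compound plus co-eluting
    contaminant, with the target contributing ``target_fraction`` of the
    carbon (peak area used as the carbon proxy)."""

    combined_f14c: IsotopeValue
    target_fraction: float

    def __post_init__(self) -> None:
        if not (0 < self.target_fraction <= 1):
            raise ValueError("target_fraction must be in (0, 1]")


def _blank_solve(
    f_dead_known: float,
    m_dead: float,
    f_dead_meas: float,
    f_mod_known: float,
    m_mod: float,
    f_mod_meas: float,
) -> tuple[float, float]:
    """Solve the paired constant-contamination balances for (m_c, F_c).

    Each standard obeys F_meas·(m_s + m_c) = F_known·m_s + F_c·m_c.  With
    p = F_c·m_c both balances are linear in (m_c, p).
    """
    # p − F_meas·m_c = (F_meas − F_known)·m_s, per standard
    denom = f_mod_meas - f_dead_meas
    if denom == 0:
        raise ValueError("blank characterization: identical measured F14C for both standards")
    rhs_dead = (f_dead_meas - f_dead_known) * m_dead
    rhs_mod = (f_mod_meas - f_mod_known) * m_mod
    m_c = (rhs_dead - rhs_mod) / denom
    p = rhs_dead + f_dead_meas * m_c
    f_c = p / m_c if m_c != 0 else math.nan
    return m_c, f_c


def characterize_blank(
    dead: ProcessStandard,
    modern: ProcessStandard,
    mc_draws: int = 10_000,
    seed: int = 42,
) -> BlankModel:
    """Infer the constant-contamination blank from a dead/modern standard pair.

    Solves the two isotope mass balances
    ``F_meas,s·(m_s + m_c) = F_s·m_s + F_c·m_c`` exactly for the blank mass
    ``m_c`` and its F14C ``F_c``; sigmas come from Monte-Carlo resampling of
    the four measured/known F14C values.  When both standards measure at
    their known values the blank mass is zero and its F14C is flagged
    indeterminate.
    """
    if not dead.known_f14c.value < modern.known_f14c.value:
        raise ValueError("characterize_blank: 'dead' standard must have lower known F14C")
    m_c, f_c = _blank_solve(
        dead.known_f14c.value,
        dead.mass_c,
        dead.measured_f14c.value,
        modern.known_f14c.value,
        modern.mass_c,
        modern.measured_f14c.value,
    )
    atol = 1e-12 * max(dead.mass_c, modern.mass_c)
    if abs(m_c) <= atol:
        return BlankModel(
            mass_c=0.0,
            f14c=IsotopeValue(0.0, 0.0, Convention.F14C),
            indeterminate_f14c=True,
        )
    if m_c < 0 or not (-1e-9 <= f_c <= 1.2):
        raise ValueError(
            "characterize_blank: no physical solution "
            f"(m_c = {m_c:.4g} µg, F_c = {f_c:.4g}) for standards "
            f"{dead.name!r} and {modern.name!r}; check the measured values"
        )
    # Monte-Carlo over the four input uncertainties; unphysical draws dropped.
    rng = np.random.default_rng(seed)
    draws_m, draws_f = [], []
    fd = rng.normal(dead.known_f14c.value, dead.known_f14c.sigma, mc_draws)
    fm = rng.normal(modern.known_f14c.value, modern.known_f14c.sigma, mc_draws)
    md = rng.normal(dead.measured_f14c.value, dead.measured_f14c.sigma, mc_draws)
    mm = rng.normal(modern.measured_f14c.value, modern.measured_f14c.sigma, mc_draws)
    for i in range(mc_draws):
        try:
            mi, fi = _blank_solve(fd[i], dead.mass_c, md[i], fm[i], modern.mass_c, mm[i])
        except ValueError:
            continue
        if mi > 0 and math.isfinite(fi):
            draws_m.append(mi)
            draws_f.append(fi)
    sd_m = float(np.std(draws_m, ddof=1)) if len(draws_m) >= 2 else 0.0
    sd_f = float(np.std(draws_f, ddof=1)) if len(draws_f) >= 2 else 0.0
    return BlankModel(
        mass_c=m_c,
        f14c=IsotopeValue(max(f_c, 0.0), sd_f, Convention.F14C),
        mass_c_sigma=sd_m,
    )


def blank_correct(
    measured: IsotopeValue, sample_mass_c: float, blank: BlankModel
) -> tuple[IsotopeValue, float]:
    """Remove the constant-contamination blank from a sample measurement.

    Returns the corrected F14C (first-order propagated sigma) and the blank
    carbon fraction ``m_c/(m_s + m_c)``.  Corrections that push the value
    below zero are clipped with a warning, as are blank fractions above the
    few-percent level expected of a clean procedure.
    """
    if measured.convention is not Convention.F14C:
        raise ValueError("blank_correct expects an F14C measurement")
    if sample_mass_c <= blank.mass_c:
        raise ValueError(
            f"sample carbon ({sample_mass_c} µg) must exceed blank carbon "
            f"({blank.mass_c} µg)"
        )
    m_s, m_c = sample_mass_c, blank.mass_c
    f_true = (measured.value * (m_s + m_c) - blank.f14c.value * m_c) / m_s
    # first-order propagation over (F_meas, F_c, m_c)
    d_fmeas = (m_s + m_c) / m_s
    d_fc = -m_c / m_s
    d_mc = (measured.value - blank.f14c.value) / m_s
    var = (
        (d_fmeas * measured.sigma) ** 2
        + (d_fc * blank.f14c.sigma) ** 2
        + (d_mc * blank.mass_c_sigma) ** 2
    )
    blank_fraction = m_c / (m_s + m_c)
    if f_true < 0:
        warnings.warn(
            f"blank correction drove F14C to {f_true:.4g}; clipped to 0",
            BlankCorrectionWarning,
            stacklevel=2,
        )
        f_true = 0.0
    if blank_fraction > BLANK_FRACTION_WARN:
        warnings.warn(
            f"blank carbon is {blank_fraction:.1%} of total sample carbon "
            f"(> {BLANK_FRACTION_WARN:.0%})",
            BlankCorrectionWarning,
            stacklevel=2,
        )
    return IsotopeValue(f_true, math.sqrt(var), Convention.F14C), blank_fraction


def _underivatize_one(
    measured: IsotopeValue, reagent: IsotopeValue, n_c: int, n_a: int
) -> IsotopeValue:
    n_t = n_c + n_a
    value = (n_t * measured.value - n_a * reagent.value) / n_c
    var = (n_t / n_c * measured.sigma) ** 2 + (n_a / n_c * reagent.sigma) ** 2
    if measured.convention in (Convention.F14C, Convention.CONC):
        value = max(value, 0.0)
    return IsotopeValue(value, math.sqrt(var), measured.convention)


def underivatize(
    measured_f14c: Optional[IsotopeValue],
    measured_d13c: Optional[IsotopeValue],
    spec: DerivatizationSpec,
) -> tuple[Optional[IsotopeValue], Optional[IsotopeValue]]:
    """Remove the derivative carbon from measured isotope values.

    The carbon-number-weighted balance
    ``X_compound = ((n_c + n_a)·X_meas − n_a·X_reagent)/n_c`` is applied
    identically to F14C and δ13C (linear ‰ mixing for δ).
    """
    out_f = out_d = None
    if measured_f14c is not None:
        if spec.reagent_f14c is None:
            raise ValueError("spec.reagent_f14c required to correct F14C")
        out_f = _underivatize_one(measured_f14c, spec.reagent_f14c, spec.n_compound, spec.n_added)
    if measured_d13c is not None:
        if spec.reagent_d13c is None:
            raise ValueError("spec.reagent_d13c required to correct d13c")
        out_d = _underivatize_one(measured_d13c, spec.reagent_d13c, spec.n_compound, spec.n_added)
    return out_f, out_d


def infer_reagent(
    known: IsotopeValue, measured_as_derivative: IsotopeValue, n_compound: int, n_added: int
) -> IsotopeValue:
    """Infer the isotope value of the added derivative carbons from a
    co-derivatized standard of known composition (the inverse of
    :func:`underivatize` solved for the reagent term)."""
    if n_added < 1:
        raise ValueError("n_added must be >= 1")
    n_t = n_compound + n_added
    value = (n_t * measured_as_derivative.value - n_compound * known.value) / n_added
    var = (n_t / n_added * measured_as_derivative.sigma) ** 2 + (
        n_compound / n_added * known.sigma
    ) ** 2
    if measured_as_derivative.convention in (Convention.F14C, Convention.CONC):
        value = max(value, 0.0)
    return IsotopeValue(value, math.sqrt(var), measured_as_derivative.convention)


def contaminant_bounds(
    mix: ContaminantMixture,
    contaminant_f14c_range: tuple[float, float] = (0.0, 1.0),
) -> tuple[IsotopeValue, IsotopeValue]:
    """Bracket the target compound's F14C given a co-eluting contaminant.

    Mass balance ``F_target = (F_comb − (1 − x)·F_ucm)/x`` evaluated at both
    ends of the assumed contaminant F14C range (default: fully dead to fully
    modern).  Returns (lower, upper); the sigma of the combined measurement
    is propagated (σ_target = σ_comb/x).  Results below zero are clipped
    with a warning.
    """
    x = mix.target_fraction
    lo_ucm, hi_ucm = contaminant_f14c_range
    sigma = mix.combined_f14c.sigma / x

    def at(f_ucm: float) -> IsotopeValue:
        v = (mix.combined_f14c.value - (1 - x) * f_ucm) / x
        if v < 0:
            warnings.warn(
                f"contaminant bound {v:.4g} clipped to 0", BlankCorrectionWarning, stacklevel=3
            )
            v = 0.0
        return IsotopeValue(v, sigma, Convention.F14C)

    a, b = at(lo_ucm), at(hi_ucm)
    return (a, b) if a.value <= b.value else (b, a)
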