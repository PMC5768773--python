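"""Concentration-weighted two-endmember dual-isotope mixing and its inversion.

The model: the analyte (formate in vent fluids) at each vent is a mixture of

* a **dead** endmember — mantle-derived, abiotically synthesized,
  radiocarbon-free (F14C = 0), with a relatively negative δ13C — whose
  concentration contribution is shared across vents in the joint model; and
* a **modern** endmember — derived from seawater dissolved inorganic carbon,
  F14C ≈ 1.02, more positive δ13C — whose concentration varies per vent.

Forward mixing is concentration-weighted:

    C_tot = Σ C_i,   F_mix = Σ C_i F_i / C_tot,   δ_mix = Σ C_i δ_i / C_tot

(δ mixed linearly on the ‰ scale).  The per-vent inversion uses the F14C
balance alone; the joint fit is a weighted least-squares over the stacked
concentration, C·F and C·δ balances of all vents, with Monte-Carlo
uncertainty by refitting perturbed datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .isotope_core import (
    Convention,
    IsotopeValue,
    SigmaFloors,
    VentAverage,
)

__all__ = [
    "Endmember",
    "MixtureObservation",
    "MixingConfig",
    "VentApportionment",
    "ApportionmentResult",
    "McSummary",
    "forward_mix",
    "apportion_vent",
    "joint_fit",
    "mc_propagate",
]


@dataclass(frozen=True)
class Endmember:
    """A pure carbon source: concentration contribution plus isotope values."""

    label: str
    conc: IsotopeValue
    f14c: IsotopeValue
    d13c: IsotopeValue

    def __post_init__(self) -> None:
        if self.conc.value < 0:
            raise ValueError(f"endmember {self.label!r}: concentration must be >= 0")


@dataclass(frozen=True)
class MixtureObservation:
    """Observed totals of a mixture: concentration and (optionally) isotopes."""

    conc_total: IsotopeValue
    f14c_mix: Optional[IsotopeValue] = None
    d13c_mix: Optional[IsotopeValue] = None

    def __post_init__(self) -> None:
        if not self.conc_total.value > 0:
            raise ValueError("conc_total must be > 0")


@dataclass
class MixingConfig:
    """Configuration of the two-endmember model.

    ``f14c_modern`` defaults to 1.02 ± 0.04, the midpoint of the local
    seawater DIC range; set ``fit_f14c_modern`` to estimate it instead.
    ``f14c_dead`` is 0 by construction (a radiocarbon-free source).
    """

    f14c_dead: float = 0.0
    f14c_modern: float = 1.02
    f14c_modern_sigma: float = 0.04
    fit_f14c_modern: bool = False
    share_dead_conc: bool = True
    share_d13c: bool = True
    mc_draws: int = 10_000
    seed: int = 42
    floors: SigmaFloors = field(default_factory=SigmaFloors)
    clip_negative: bool = True

    def __post_init__(self) -> None:
        if self.mc_draws < 100:
            raise ValueError("mc_draws must be >= 100")


@dataclass(frozen=True)
class VentApportionment:
    """Per-vent split of the observed total into the two sources."""

    marker_id: str
    c_dead: IsotopeValue
    c_modern: IsotopeValue
    d13c_dead: Optional[IsotopeValue] = None
    d13c_modern: Optional[IsotopeValue] = None
    clipped: bool = False


@dataclass
class ApportionmentResult:
    """Joint-fit output: shared parameters, per-vent contributions, diagnostics."""

    shared: dict[str, IsotopeValue]
    per_vent: dict[str, VentApportionment]
    residuals: np.ndarray
    weighted_sse: float
    n_obs: int
    n_params: int
    clip_flags: list[str]
    mc: Optional[dict[str, "McSummary"]] = None


@dataclass(frozen=True)
class McSummary:
    """Monte-Carlo summary of one parameter."""

    mean: float
    sd: float
    q025: float
    q975: float
    n_ok: int
    n_failed: int


def forward_mix(endmembers: Sequence[Endmember]) -> MixtureObservation:
    """Concentration-weighted mixture of endmembers (uncertainties propagated
    to first order assuming independent inputs)."""
    if not endmembers:
        raise ValueError("forward_mix requires at least one endmember")
    c = np.array([e.conc.value for e in endmembers])
    if c.sum() <= 0:
        raise ValueError("all endmember concentrations are zero")
    sc = np.array([e.conc.sigma for e in endmembers])
    f = np.array([e.f14c.value for e in endmembers])
    sf = np.array([e.f14c.sigma for e in endmembers])
    d = np.array([e.d13c.value for e in endmembers])
    sd = np.array([e.d13c.sigma for e in endmembers])
    c_tot = c.sum()
    f_mix = float(c @ f / c_tot)
    d_mix = float(c @ d / c_tot)
    # delta-method: ∂F_mix/∂C_i = (F_i − F_mix)/C_tot, ∂F_mix/∂F_i = C_i/C_tot
    var_f = (((f - f_mix) / c_tot) ** 2 * sc**2).sum() + ((c / c_tot) ** 2 * sf**2).sum()
    var_d = (((d - d_mix) / c_tot) ** 2 * sc**2).sum() + ((c / c_tot) ** 2 * sd**2).sum()
    return MixtureObservation(
        conc_total=IsotopeValue(float(c_tot), float(np.sqrt((sc**2).sum())), Convention.CONC),
        f14c_mix=IsotopeValue(f_mix, float(np.sqrt(var_f)), Convention.F14C),
        d13c_mix=IsotopeValue(d_mix, float(np.sqrt(var_d)), Convention.DELTA13C),
    )


def apportion_vent(
    obs: MixtureObservation,
    cfg: Optional[MixingConfig] = None,
    marker_id: str = "",
    d13c_dead: Optional[float] = None,
    d13c_modern: Optional[float] = None,
) -> VentApportionment:
    """Split one vent's observed total between the two endmembers.

    The F14C balance gives ``C_modern = C_tot·F_mix/F_modern`` and
    ``C_dead = C_tot − C_modern`` (with F_dead = 0).  If the vent's δ13C is
    observed and one endmember δ is supplied, the other is solved by mass
    balance.  Negative source concentrations (F_mix above F_modern) are
    clipped to zero and flagged.
    """
    cfg = cfg or MixingConfig()
    if obs.f14c_mix is None:
        raise ValueError("apportion_vent requires an observed mixture F14C")
    c_tot, f_mix, f_mod = obs.conc_total.value, obs.f14c_mix.value, cfg.f14c_modern
    frac_mod = (f_mix - cfg.f14c_dead) / (f_mod - cfg.f14c_dead)
    c_modern = c_tot * frac_mod
    c_dead = c_tot - c_modern
    clipped = False
    if c_dead < 0 or c_modern < 0:
        clipped = True
        if cfg.clip_negative:
            c_modern = min(max(c_modern, 0.0), c_tot)
            c_dead = c_tot - c_modern
    # first-order sigmas over (C_tot, F_mix, F_modern)
    s_ct, s_f, s_fm = obs.conc_total.sigma, obs.f14c_mix.sigma, cfg.f14c_modern_sigma
    var_cm = (
        (frac_mod * s_ct) ** 2
        + (c_tot / (f_mod - cfg.f14c_dead) * s_f) ** 2
        + (c_tot * frac_mod / (f_mod - cfg.f14c_dead) * s_fm) ** 2
    )
    s_cm = math.sqrt(var_cm)
    s_cd = math.sqrt(var_cm + s_ct**2)  # conservative; dominated by the same terms
    out_dd = out_dm = None
    if obs.d13c_mix is not None and (d13c_dead is not None) != (d13c_modern is not None):
        # C_tot·δ_mix = C_dead·δ_dead + C_modern·δ_modern, solve the unknown δ
        d_mix = obs.d13c_mix.value
        if d13c_dead is not None and c_modern > 0:
            dm = (c_tot * d_mix - c_dead * d13c_dead) / c_modern
            out_dm = IsotopeValue(dm, 0.0, Convention.DELTA13C)
            out_dd = IsotopeValue(d13c_dead, 0.0, Convention.DELTA13C)
        elif d13c_modern is not None and c_dead > 0:
            dd = (c_tot * d_mix - c_modern * d13c_modern) / c_dead
            out_dd = IsotopeValue(dd, 0.0, Convention.DELTA13C)
            out_dm = IsotopeValue(d13c_modern, 0.0, Convention.DELTA13C)
    return VentApportionment(
        marker_id=marker_id,
        c_dead=IsotopeValue(max(c_dead, 0.0), s_cd, Convention.CONC),
        c_modern=IsotopeValue(max(c_modern, 0.0), s_cm, Convention.CONC),
        d13c_dead=out_dd,
        d13c_modern=out_dm,
        clipped=clipped,
    )


# ---------------------------------------------------------------------------
# Joint weighted least-squares fit
# ---------------------------------------------------------------------------


class _JointProblem:
    """Stacked weighted residuals for the joint cross-vent fit.

    Parameter vector: [C_dead, δ_dead, δ_mod, C_mod_1..C_mod_V, (F_mod)].
    Residual blocks per vent v (only those its observations support):

        (C_v − C_dead − C_mod,v) / σ_C
        (C_v·F_v − C_mod,v·F_mod) / σ_CF
        (C_v·δ_v − C_dead·δ_dead − C_mod,v·δ_mod) / σ_Cδ

    with delta-method sigmas on the products and configured floors.
    """

    def __init__(self, averages: Sequence[VentAverage], cfg: MixingConfig):
        self.cfg = cfg
        self.vents = [a for a in averages if a.concentration is not None]
        if len(self.vents) < 2:
            raise ValueError("joint_fit requires >= 2 vents with concentrations")
        if not any(a.f14c is not None for a in self.vents):
            raise ValueError("joint_fit requires >= 1 vent with F14C")
        fl = cfg.floors
        self.rows: list[tuple[int, str, float, float]] = []  # (vent idx, kind, y, sigma)
        for i, a in enumerate(self.vents):
            c, sc = a.concentration.value, fl.effective_sigma(a.concentration)
            self.rows.append((i, "conc", c, sc))
            if a.f14c is not None:
                f, sf = a.f14c.value, fl.effective_sigma(a.f14c)
                s = math.sqrt((f * sc) ** 2 + (c * sf) ** 2)
                self.rows.append((i, "cf", c * f, max(s, 1e-12)))
            if a.d13c is not None:
                d, sdl = a.d13c.value, fl.effective_sigma(a.d13c)
                s = math.sqrt((d * sc) ** 2 + (c * sdl) ** 2)
                self.rows.append((i, "cd", c * d, max(s, 1e-12)))
        self.n_obs = len(self.rows)
        self.n_vents = len(self.vents)
        self.n_params = 3 + self.n_vents + (1 if cfg.fit_f14c_modern else 0)
        if self.n_obs < self.n_params:
            raise ValueError(
                f"underdetermined joint fit: {self.n_obs} observations for "
                f"{self.n_params} parameters (deficit {self.n_params - self.n_obs})"
            )

    def unpack(self, x: np.ndarray):
        c_dead, d_dead, d_mod = x[0], x[1], x[2]
        c_mod = x[3 : 3 + self.n_vents]
        f_mod = x[-1] if self.cfg.fit_f14c_modern else self.cfg.f14c_modern
        return c_dead, d_dead, d_mod, c_mod, f_mod

    def residuals(self, x: np.ndarray) -> np.ndarray:
        c_dead, d_dead, d_mod, c_mod, f_mod = self.unpack(x)
        r = np.empty(self.n_obs)
        for k, (i, kind, y, s) in enumerate(self.rows):
            if kind == "conc":
                pred = c_dead + c_mod[i]
            elif kind == "cf":
                pred = c_mod[i] * f_mod
            else:
                pred = c_dead * d_dead + c_mod[i] * d_mod
            r[k] = (y - pred) / s
        return r

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        c_dead, d_dead, d_mod, c_mod, f_mod = self.unpack(x)
        J = np.zeros((self.n_obs, self.n_params))
        for k, (i, kind, y, s) in enumerate(self.rows):
            if kind == "conc":
                J[k, 0] = -1 / s
                J[k, 3 + i] = -1 / s
            elif kind == "cf":
                J[k, 3 + i] = -f_mod / s
                if self.cfg.fit_f14c_modern:
                    J[k, -1] = -c_mod[i] / s
            else:
                J[k, 0] = -d_dead / s
                J[k, 1] = -c_dead / s
                J[k, 2] = -c_mod[i] / s
                J[k, 3 + i] = -d_mod / s
        return J

    def initial_guess(self) -> np.ndarray:
        cfg = self.cfg
        c_mod0 = np.empty(self.n_vents)
        c_dead0 = []
        for i, a in enumerate(self.vents):
            c = a.concentration.value
            if a.f14c is not None:
                cm = c * a.f14c.value / cfg.f14c_modern
                c_mod0[i] = max(cm, 0.0)
                c_dead0.append(c - cm)
            else:
                c_mod0[i] = np.nan
        cd0 = max(float(np.mean(c_dead0)), 1e-6) if c_dead0 else 1.0
        for i, a in enumerate(self.vents):
            if np.isnan(c_mod0[i]):
                c_mod0[i] = max(a.concentration.value - cd0, 0.0)
        # δ initial values from a linear solve at fixed concentrations
        A, b = [], []
        for a, cm in zip(self.vents, c_mod0):
            if a.d13c is not None:
                A.append([cd0, cm])
                b.append(a.concentration.value * a.d13c.value)
        if len(A) >= 2:
            sol, *_ = np.linalg.lstsq(np.asarray(A), np.asarray(b), rcond=None)
            d_dead0, d_mod0 = float(sol[0]), float(sol[1])
        else:
            d_dead0, d_mod0 = -12.0, 8.0
        x0 = np.concatenate(([cd0, d_dead0, d_mod0], c_mod0))
        if cfg.fit_f14c_modern:
            x0 = np.append(x0, cfg.f14c_modern)
        return x0

    def solve(self) -> np.ndarray:
        x0 = self.initial_guess()
        lo = np.full(self.n_params, -np.inf)
        hi = np.full(self.n_params, np.inf)
        lo[0] = 0.0
        lo[3 : 3 + self.n_vents] = 0.0
        if self.cfg.fit_f14c_modern:
            lo[-1] = 1e-6
        x0 = np.clip(x0, lo + 1e-12, hi)
        res = least_squares(
            self.residuals, x0, jac=self.jacobian, bounds=(lo, hi), method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        if not res.success:
            raise RuntimeError(f"joint fit failed to converge: {res.message}")
        return res.x


def _perturbed(averages: Sequence[VentAverage], cfg: MixingConfig, rng) -> list[VentAverage]:
    """One Monte-Carlo draw of the dataset: each vent average perturbed by its
    effective sigma (reported sigma, floored)."""
    fl = cfg.floors
    out = []
    for a in averages:
        def draw(v: Optional[IsotopeValue]) -> Optional[IsotopeValue]:
            if v is None:
                return None
            val = rng.normal(v.value, fl.effective_sigma(v))
            if v.convention in (Convention.F14C, Convention.CONC):
                val = max(val, 1e-9 if v.convention is Convention.CONC else 0.0)
            return IsotopeValue(val, v.sigma, v.convention)

        out.append(
            VentAverage(
                marker_id=a.marker_id,
                n=a.n,
                concentration=draw(a.concentration),
                d13c=draw(a.d13c),
                f14c=draw(a.f14c),
            )
        )
    return out


def joint_fit(
    averages: Sequence[VentAverage],
    cfg: Optional[MixingConfig] = None,
    monte_carlo: bool = True,
) -> ApportionmentResult:
    """Fit the joint cross-vent model: one shared dead-endmember concentration
    and δ13C, one shared modern δ13C, and a per-vent modern concentration.

    Vents lacking F14C (or δ13C) contribute only the residual blocks their
    observations support.  Parameter uncertainties come from refitting
    ``cfg.mc_draws`` datasets perturbed by the observation sigmas
    (``monte_carlo=False`` skips this and reports point estimates only).
    """
    cfg = cfg or MixingConfig()
    with_conc = [a for a in averages if a.concentration is not None]
    if len(with_conc) == 1:
        return _single_vent_fit(with_conc[0], cfg)
    prob = _JointProblem(averages, cfg)
    x = prob.solve()
    c_dead, d_dead, d_mod, c_mod, f_mod = prob.unpack(x)
    r = prob.residuals(x)

    mc_summaries = None
    sds: dict[str, float] = {}
    if monte_carlo:
        mc_summaries = mc_propagate(
            lambda avgs: _fit_params(avgs, cfg), list(averages), cfg,
            param_names=_param_names(prob),
        )
        sds = {k: v.sd for k, v in mc_summaries.items()}

    shared = {
        "c_dead": IsotopeValue(float(c_dead), sds.get("c_dead", 0.0), Convention.CONC),
        "d13c_dead": IsotopeValue(float(d_dead), sds.get("d13c_dead", 0.0), Convention.DELTA13C),
        "d13c_modern": IsotopeValue(float(d_mod), sds.get("d13c_modern", 0.0), Convention.DELTA13C),
        "f14c_modern": IsotopeValue(
            float(f_mod),
            sds.get("f14c_modern", cfg.f14c_modern_sigma if not cfg.fit_f14c_modern else 0.0),
            Convention.F14C,
        ),
    }
    per_vent: dict[str, VentApportionment] = {}
    clip_flags: list[str] = []
    for i, a in enumerate(prob.vents):
        cm = float(c_mod[i])
        cd = a.concentration.value - cm
        clipped = cd < 0
        if clipped:
            clip_flags.append(a.marker_id)
            cd = max(cd, 0.0)
        per_vent[a.marker_id] = VentApportionment(
            marker_id=a.marker_id,
            c_dead=IsotopeValue(cd, sds.get("c_dead", 0.0), Convention.CONC),
            c_modern=IsotopeValue(max(cm, 0.0), sds.get(f"c_modern[{a.marker_id}]", 0.0), Convention.CONC),
            clipped=clipped,
        )
    return ApportionmentResult(
        shared=shared,
        per_vent=per_vent,
        residuals=r,
        weighted_sse=float(r @ r),
        n_obs=prob.n_obs,
        n_params=prob.n_params,
        clip_flags=clip_flags,
        mc=mc_summaries,
    )


def _single_vent_fit(a: VentAverage, cfg: MixingConfig) -> ApportionmentResult:
    """Degenerate joint fit: one fully observed vent reduces to the exact
    per-vent apportionment (no shared parameters to estimate)."""
    if a.f14c is None:
        raise ValueError("a single-vent fit requires that vent to have F14C")
    obs = MixtureObservation(conc_total=a.concentration, f14c_mix=a.f14c, d13c_mix=a.d13c)
    ap = apportion_vent(obs, cfg, marker_id=a.marker_id)
    shared = {
        "c_dead": ap.c_dead,
        "f14c_modern": IsotopeValue(cfg.f14c_modern, cfg.f14c_modern_sigma, Convention.F14C),
    }
    return ApportionmentResult(
        shared=shared,
        per_vent={a.marker_id: ap},
        residuals=np.zeros(0),
        weighted_sse=0.0,
        n_obs=2 if a.d13c is None else 3,
        n_params=2,
        clip_flags=[a.marker_id] if ap.clipped else [],
    )


def _param_names(prob: _JointProblem) -> list[str]:
    names = ["c_dead", "d13c_dead", "d13c_modern"]
    names += [f"c_modern[{a.marker_id}]" for a in prob.vents]
    if prob.cfg.fit_f14c_modern:
        names.append("f14c_modern")
    return names


def _fit_params(averages: Sequence[VentAverage], cfg: MixingConfig) -> np.ndarray:
    prob = _JointProblem(averages, cfg)
    return prob.solve()


def mc_propagate(
    fit_fn: Callable[[list[VentAverage]], np.ndarray],
    dataset: Sequence[VentAverage],
    cfg: MixingConfig,
    param_names: Optional[list[str]] = None,
    max_failure_rate: float = 0.10,
) -> dict[str, McSummary]:
    """Monte-Carlo uncertainty: refit ``cfg.mc_draws`` perturbed datasets.

    Each draw perturbs every observation by its effective sigma and calls
    ``fit_fn``; failed fits are recorded and excluded.  Reproducible given
    ``cfg.seed``.  Raises if more than ``max_failure_rate`` of draws fail.
    """
    rng = np.random.default_rng(cfg.seed)
    draws: list[np.ndarray] = []
    n_failed = 0
    for _ in range(cfg.mc_draws):
        perturbed = _perturbed(dataset, cfg, rng)
        try:
            draws.append(fit_fn(perturbed))
        except (ValueError, RuntimeError):
            n_failed += 1
    if cfg.mc_draws and n_failed / cfg.mc_draws > max_failure_rate:
        raise RuntimeError(
            f"Monte-Carlo failure rate {n_failed}/{cfg.mc_draws} exceeds "
            f"{max_failure_rate:.0%}"
        )
    arr = np.vstack(draws)
    if param_names is None:
        param_names = [f"p{i}" for i in range(arr.shape[1])]
    out = {}
    for j, name in enumerate(param_names):
        col = arr[:, j]
        out[name] = McSummary(
            mean=float(col.mean()),
            sd=float(col.std(ddof=1)) if len(col) >= 2 else 0.0,
            q025=float(np.percentile(col, 2.5)),
            q975=float(np.percentile(col, 97.5)),
            n_ok=len(col),
            n_failed=n_failed,
        )
    return out
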