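"""Synthetic vent-fluid datasets with the statistical structure the analysis
assumes.

The generator emulates a per-sample fluid table: four vents, each a
two-endmember mixture of a shared radiocarbon-free source and a per-vent
modern source, observed with independent Gaussian measurement noise per
channel and 1–6 replicate samples per vent.  Default truth values are the
field-scale estimates for Lost City formate (shared dead-endmember
concentration ≈ 112 µmol/L at δ13C −12.7‰; modern endmember F14C 1.02 at
δ13C +8.4‰; per-vent modern contributions 3–90 µmol/L).  One vent ("C" by
default) is generated without F14C, mirroring a sample too small for
radiocarbon analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .isotope_core import Convention, IsotopeValue, VentDataset, VentSample
from .mixing import Endmember, forward_mix

__all__ = ["GeneratorTruth", "generate"]


@dataclass
class GeneratorTruth:
    """True parameters of the simulated two-endmember world."""

    c_dead: float = 112.0  # µmol/L, shared across vents
    d13c_dead: float = -12.7  # ‰
    f14c_modern: float = 1.02
    d13c_modern: float = 8.4  # ‰
    c_modern: dict[str, float] = field(
        default_factory=lambda: {"C": 3.0, "2": 10.0, "B": 40.0, "3": 90.0}
    )
    replicates: dict[str, int] = field(
        default_factory=lambda: {"C": 2, "2": 2, "B": 3, "3": 6}
    )
    noise_f14c: float = 0.05
    noise_d13c: float = 0.5  # ‰
    noise_conc_rel: float = 0.05  # relative
    drop_f14c: tuple[str, ...] = ("C",)  # vents generated without F14C
    seed: int = 42
    analyte: str = "formate"

    def __post_init__(self) -> None:
        if self.c_dead < 0 or any(v < 0 for v in self.c_modern.values()):
            raise ValueError("concentrations must be >= 0")
        if set(self.replicates) != set(self.c_modern):
            raise ValueError("replicates and c_modern must cover the same vents")
        if any(n < 1 for n in self.replicates.values()):
            raise ValueError("replicate counts must be >= 1")

    def latent_mixture(self, marker: str):
        """Noise-free forward mixture at one vent."""
        dead = Endmember(
            "dead",
            IsotopeValue(self.c_dead, 0.0, Convention.CONC),
            IsotopeValue(0.0, 0.0, Convention.F14C),
            IsotopeValue(self.d13c_dead, 0.0, Convention.DELTA13C),
        )
        modern = Endmember(
            "modern",
            IsotopeValue(self.c_modern[marker], 0.0, Convention.CONC),
            IsotopeValue(self.f14c_modern, 0.0, Convention.F14C),
            IsotopeValue(self.d13c_modern, 0.0, Convention.DELTA13C),
        )
        return forward_mix([dead, modern])

    def to_json(self) -> str:
        d = asdict(self)
        d["drop_f14c"] = list(d["drop_f14c"])
        return json.dumps(d, indent=2, sort_keys=True)


def _truncated_normal(rng: np.random.Generator, loc: float, scale: float) -> float:
    """Gaussian draw truncated at 0 by resampling (no point mass at 0)."""
    if scale == 0:
        return max(loc, 0.0)
    for _ in range(1000):
        v = rng.normal(loc, scale)
        if v >= 0:
            return float(v)
    raise RuntimeError(f"truncated-normal resampling failed at loc={loc}, scale={scale}")


def generate(truth: Optional[GeneratorTruth] = None, seed: Optional[int] = None) -> tuple[VentDataset, GeneratorTruth]:
    """Generate one synthetic per-sample dataset plus the truth that made it.

    Per vent, the latent mixture is the exact forward mix of the two
    endmembers; each replicate adds independent Gaussian noise per channel
    (relative for concentration, absolute for the isotope channels).  F14C
    and concentration draws are truncated at zero by resampling.  Vents in
    ``truth.drop_f14c`` carry no F14C.  Deterministic given the seed.
    """
    truth = truth or GeneratorTruth()
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    samples: list[VentSample] = []
    for marker in truth.c_modern:
        latent = truth.latent_mixture(marker)
        c0, f0, d0 = latent.conc_total.value, latent.f14c_mix.value, latent.d13c_mix.value
        for _ in range(truth.replicates[marker]):
            c = _truncated_normal(rng, c0, truth.noise_conc_rel * c0)
            d = rng.normal(d0, truth.noise_d13c) if truth.noise_d13c > 0 else d0
            f = None
            if marker not in truth.drop_f14c:
                f = _truncated_normal(rng, f0, truth.noise_f14c)
            samples.append(
                VentSample(
                    marker_id=marker,
                    analyte=truth.analyte,
                    concentration=IsotopeValue(c, 0.0, Convention.CONC),
                    d13c=IsotopeValue(float(d), 0.0, Convention.DELTA13C),
                    f14c=IsotopeValue(f, 0.0, Convention.F14C) if f is not None else None,
                )
            )
    dataset = VentDataset(samples=samples, provenance="synthetic two-endmember generator")
    return dataset, truth
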