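"""Isotope conventions, value-with-uncertainty arithmetic, and replicate aggregation.

This module is the shared vocabulary of the package: every measured quantity
is an :class:`IsotopeValue` — a value plus a one-sigma uncertainty in a
declared convention (fraction modern radiocarbon F14C, per-mil delta-13C
versus VPDB, or a concentration in µmol/L).  Fluid samples are grouped by
vent marker and aggregated to per-vent means whose sigma is the sample
standard deviation across replicates, the convention used for vent-average
error bars in compound-specific radiocarbon field studies.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Convention",
    "IsotopeValue",
    "VentSample",
    "VentDataset",
    "VentAverage",
    "SigmaFloors",
    "aggregate_by_vent",
    "f14c_to_age",
    "age_to_f14c",
    "propagate_linear",
    "read_samples_csv",
    "write_samples_csv",
]

#: Decay constant of the conventional radiocarbon age (Libby mean life, years).
LIBBY_MEAN_LIFE = 8033.0

SAMPLE_CSV_COLUMNS = [
    "marker_id",
    "analyte",
    "conc_umol_L",
    "conc_sd",
    "d13c_permil",
    "d13c_sd",
    "f14c",
    "f14c_sd",
]


class Convention(enum.Enum):
    """Measurement convention of an :class:`IsotopeValue`."""

    F14C = "F14C"  # fraction modern radiocarbon, dimensionless
    DELTA13C = "DELTA13C"  # per-mil vs VPDB
    CONC = "CONC"  # µmol/L


@dataclass(frozen=True)
class IsotopeValue:
    """A measured quantity with a one-sigma uncertainty.

    Parameters
    ----------
    value
        The measured value in the declared convention.
    sigma
        One standard deviation, non-negative.
    convention
        One of :class:`Convention`.
    """

    value: float
    sigma: float
    convention: Convention

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"non-finite value: {self.value!r}")
        if not (self.sigma >= 0):
            raise ValueError(f"sigma must be non-negative, got {self.sigma!r}")
        if self.convention in (Convention.F14C, Convention.CONC) and self.value < 0:
            raise ValueError(
                f"{self.convention.value} values must be >= 0, got {self.value!r}"
            )

    def with_sigma(self, sigma: float) -> "IsotopeValue":
        return replace(self, sigma=sigma)


def f14c(value: float, sigma: float = 0.0) -> IsotopeValue:
    return IsotopeValue(value, sigma, Convention.F14C)


def d13c(value: float, sigma: float = 0.0) -> IsotopeValue:
    return IsotopeValue(value, sigma, Convention.DELTA13C)


def conc(value: float, sigma: float = 0.0) -> IsotopeValue:
    return IsotopeValue(value, sigma, Convention.CONC)


@dataclass(frozen=True)
class VentSample:
    """One fluid sample: analyte concentration and isotope values at a vent."""

    marker_id: str
    analyte: str = "formate"
    concentration: Optional[IsotopeValue] = None
    d13c: Optional[IsotopeValue] = None
    f14c: Optional[IsotopeValue] = None

    def __post_init__(self) -> None:
        if self.concentration is None and self.d13c is None and self.f14c is None:
            raise ValueError(
                f"sample at marker {self.marker_id!r} carries no measurements"
            )
        _check_convention(self.concentration, Convention.CONC, "concentration")
        _check_convention(self.d13c, Convention.DELTA13C, "d13c")
        _check_convention(self.f14c, Convention.F14C, "f14c")


def _check_convention(
    v: Optional[IsotopeValue], expected: Convention, name: str
) -> None:
    if v is not None and v.convention is not expected:
        raise ValueError(f"{name} must be {expected.value}, got {v.convention.value}")


@dataclass
class VentDataset:
    """An ordered collection of samples; the unit the mixing model consumes."""

    samples: list[VentSample] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def marker_ids(self) -> list[str]:
        """Distinct marker ids in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.marker_id, None)
        return list(seen)


@dataclass(frozen=True)
class VentAverage:
    """Replicate mean per vent; sigma is the sample standard deviation (0 if n=1)."""

    marker_id: str
    n: int
    concentration: Optional[IsotopeValue] = None
    d13c: Optional[IsotopeValue] = None
    f14c: Optional[IsotopeValue] = None


@dataclass(frozen=True)
class SigmaFloors:
    """Uncertainty floors applied when a vent average has sigma 0 (n = 1 or
    identical replicates).  Used only as least-squares weights and for
    Monte-Carlo perturbation, never reported as measurement sigmas."""

    f14c: float = 0.02
    d13c: float = 0.5
    conc_rel: float = 0.05  # relative (fraction of the value)

    def floor(self, v: IsotopeValue) -> float:
        if v.convention is Convention.F14C:
            return self.f14c
        if v.convention is Convention.DELTA13C:
            return self.d13c
        return self.conc_rel * abs(v.value)

    def effective_sigma(self, v: IsotopeValue) -> float:
        return max(v.sigma, self.floor(v))


def _mean_sd(values: Sequence[float], convention: Convention) -> IsotopeValue:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else 0.0
    if convention in (Convention.F14C, Convention.CONC) and mean < 0:
        mean = 0.0
    return IsotopeValue(mean, sd, convention)


def aggregate_by_vent(dataset: VentDataset) -> list[VentAverage]:
    """Average replicate samples per vent marker.

    Returns one :class:`VentAverage` per distinct ``marker_id``, in
    first-appearance order (the result is invariant under row permutation up
    to that ordering).  For each field the mean is taken over samples where
    the field is present; the sigma is the sample (n−1) standard deviation,
    or 0 when only one replicate carries the field.  Fields absent in every
    replicate are absent in the average.
    """
    if len(dataset) == 0:
        raise ValueError("cannot aggregate an empty dataset")
    out: list[VentAverage] = []
    for marker in sorted(dataset.marker_ids()):
        group = [s for s in dataset.samples if s.marker_id == marker]
        fields: dict[str, Optional[IsotopeValue]] = {}
        for name, convention in (
            ("concentration", Convention.CONC),
            ("d13c", Convention.DELTA13C),
            ("f14c", Convention.F14C),
        ):
            vals = [getattr(s, name).value for s in group if getattr(s, name) is not None]
            fields[name] = _mean_sd(vals, convention) if vals else None
        out.append(VentAverage(marker_id=marker, n=len(group), **fields))
    return out


def f14c_to_age(f: IsotopeValue) -> IsotopeValue:
    """Conventional radiocarbon age, age = −8033·ln(F14C), in years.

    The sigma is propagated to first order: σ_age = 8033·σ_F/F.  F14C values
    of zero or below have an undefined (infinite) age and raise.
    """
    _check_convention(f, Convention.F14C, "f14c_to_age input")
    if f.value <= 0:
        raise ValueError("F14C must be > 0 for a finite radiocarbon age")
    age = -LIBBY_MEAN_LIFE * math.log(f.value)
    sigma = LIBBY_MEAN_LIFE * f.sigma / f.value
    return _AgeValue(age, sigma)


@dataclass(frozen=True)
class _AgeValue:
    """A radiocarbon age in years with one-sigma uncertainty."""

    value: float
    sigma: float


def age_to_f14c(age: _AgeValue | float, sigma: float = 0.0) -> IsotopeValue:
    """Inverse of :func:`f14c_to_age` (provided for round-trip testing)."""
    if isinstance(age, _AgeValue):
        value, sigma = age.value, age.sigma
    else:
        value = float(age)
    f = math.exp(-value / LIBBY_MEAN_LIFE)
    return IsotopeValue(f, f * sigma / LIBBY_MEAN_LIFE, Convention.F14C)


def propagate_linear(
    fn: Callable[..., float],
    inputs: Sequence[tuple[float, float]] | Sequence[IsotopeValue],
    convention: Convention = Convention.CONC,
    rel_step: float = 1e-6,
) -> IsotopeValue:
    """First-order (delta-method) uncertainty propagation through ``fn``.

    ``inputs`` is a sequence of ``(value, sigma)`` pairs or IsotopeValues,
    assumed independent.  Partial derivatives are taken by central
    differences with a relative step.  The returned value is
    ``fn(*values)`` and the sigma is ``sqrt(Σ (∂fn/∂x_i · σ_i)²)``.
    """
    pairs = [
        (v.value, v.sigma) if isinstance(v, IsotopeValue) else (float(v[0]), float(v[1]))
        for v in inputs
    ]
    values = np.array([p[0] for p in pairs])
    sigmas = np.array([p[1] for p in pairs])
    center = float(fn(*values))
    var = 0.0
    for i in range(len(values)):
        if sigmas[i] == 0:
            continue
        h = rel_step * max(abs(values[i]), 1.0)
        up, dn = values.copy(), values.copy()
        up[i] += h
        dn[i] -= h
        deriv = (float(fn(*up)) - float(fn(*dn))) / (2 * h)
        var += (deriv * sigmas[i]) ** 2
    return IsotopeValue(center, math.sqrt(var), convention)


# ---------------------------------------------------------------------------
# CSV interface — one row per fluid sample, empty cell = missing.
# ---------------------------------------------------------------------------


def _cell(row: pd.Series, name: str) -> Optional[float]:
    v = row.get(name)
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def read_samples_csv(path) -> VentDataset:
    """Read the standard sample table.

    Header: ``marker_id, analyte, conc_umol_L, conc_sd, d13c_permil,
    d13c_sd, f14c, f14c_sd``.  Rows with unparsable cells raise with the
    offending line number.
    """
    df = pd.read_csv(path, dtype={"marker_id": str, "analyte": str})
    missing = [c for c in SAMPLE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample CSV missing columns: {missing}")
    samples = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            c = _cell(row, "conc_umol_L")
            d = _cell(row, "d13c_permil")
            f = _cell(row, "f14c")
            samples.append(
                VentSample(
                    marker_id=str(row["marker_id"]),
                    analyte=str(row["analyte"]),
                    concentration=conc(c, _cell(row, "conc_sd") or 0.0) if c is not None else None,
                    d13c=d13c(d, _cell(row, "d13c_sd") or 0.0) if d is not None else None,
                    f14c=f14c(f, _cell(row, "f14c_sd") or 0.0) if f is not None else None,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"sample CSV line {line}: {exc}") from exc
    return VentDataset(samples=samples, provenance=str(path))


def write_samples_csv(dataset: VentDataset, path) -> None:
    rows = []
    for s in dataset.samples:
        rows.append(
            {
                "marker_id": s.marker_id,
                "analyte": s.analyte,
                "conc_umol_L": s.concentration.value if s.concentration else None,
                "conc_sd": s.concentration.sigma if s.concentration else None,
                "d13c_permil": s.d13c.value if s.d13c else None,
                "d13c_sd": s.d13c.sigma if s.d13c else None,
                "f14c": s.f14c.value if s.f14c else None,
                "f14c_sd": s.f14c.sigma if s.f14c else None,
            }
        )
    pd.DataFrame(rows, columns=SAMPLE_CSV_COLUMNS).to_csv(path, index=False)
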