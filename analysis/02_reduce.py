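#!/usr/bin/env python
"""Compound-specific radiocarbon data reduction, demonstrated end to end.

Three corrections on lipid-style measurements:

1. blank characterization from a dead/modern process-standard pair
   (forward-simulated here, since raw standard measurements are lab data),
   then blank correction of a sample measurement;
2. removal of the methyl carbon from a fatty-acid methyl ester, with the
   methyl isotope signature inferred from a co-derivatized standard;
3. mass-balance bounds on the archaeal lipid (PMI) F14C given the
   co-eluting unresolved complex mixture: combined isolate 0.39 ± 0.02 with
   the target contributing 80% of the carbon.

Writes results/data_reduction.json.
"""

import json
from pathlib import Path

from ventmix.data_reduction import (
    ContaminantMixture,
    DerivatizationSpec,
    ProcessStandard,
    blank_correct,
    characterize_blank,
    contaminant_bounds,
    infer_reagent,
    underivatize,
)
from ventmix.isotope_core import Convention, IsotopeValue

OUT = Path(__file__).resolve().parent.parent / "results"


def _f(v, s=0.0):
    return IsotopeValue(v, s, Convention.F14C)


def _d(v, s=0.0):
    return IsotopeValue(v, s, Convention.DELTA13C)


def main() -> None:
    OUT.mkdir(exist_ok=True)
    out: dict = {}

    # -- blank: forward-simulate a 2 µg, F14C 0.5 contamination pool on
    #    100 µg standards, then invert it from the "measured" values
    m_c, f_c, mass = 2.0, 0.5, 100.0
    dead = ProcessStandard(
        "C26 alkane (dead)", _f(0.0016, 0.0006), mass,
        _f((0.0016 * mass + f_c * m_c) / (mass + m_c), 0.002),
    )
    modern = ProcessStandard(
        "C30 alkane (modern)", _f(0.9918, 0.0038), mass,
        _f((0.9918 * mass + f_c * m_c) / (mass + m_c), 0.003),
    )
    blank = characterize_blank(dead, modern, seed=42)
    corrected, frac = blank_correct(modern.measured_f14c, mass, blank)
    out["blank"] = {
        "true": {"mass_ug": m_c, "f14c": f_c},
        "recovered": {
            "mass_ug": blank.mass_c, "mass_ug_sd": blank.mass_c_sigma,
            "f14c": blank.f14c.value, "f14c_sd": blank.f14c.sigma,
        },
        "corrected_modern_standard": corrected.value,
        "blank_fraction": frac,
    }
    print(
        f"blank: recovered {blank.mass_c:.3f} ± {blank.mass_c_sigma:.3f} µg at "
        f"F14C {blank.f14c.value:.3f} ± {blank.f14c.sigma:.3f} (truth: 2.0 µg, 0.50); "
        f"blank is {frac:.1%} of sample carbon"
    )

    # -- derivatization: methyl signature from a co-methylated standard of
    #    known composition, then correction of a C16 FAME
    reagent_d = infer_reagent(_d(-30.0), _d(-32.9), n_compound=8, n_added=2)
    spec = DerivatizationSpec(16, 1, reagent_f14c=_f(0.0), reagent_d13c=reagent_d)
    fame_f, fame_d = underivatize(_f(0.112941, 0.002), _d(-10.0, 0.1), spec)
    out["derivatization"] = {
        "reagent_d13c": reagent_d.value,
        "c16_free_acid": {"f14c": fame_f.value, "d13c": fame_d.value},
    }
    print(
        f"methyl carbon: δ13C {reagent_d.value:.1f}‰; C16 acid corrected to "
        f"F14C {fame_f.value:.4f}, δ13C {fame_d.value:.2f}‰"
    )

    # -- UCM bounds on the archaeal lipid fraction
    mix = ContaminantMixture(_f(0.39, 0.02), target_fraction=0.80)
    lo, hi = contaminant_bounds(mix)
    out["ucm_bounds"] = {
        "lower": lo.value, "upper": hi.value, "sigma": lo.sigma,
        "rounded": [round(lo.value, 2), round(hi.value, 2)],
    }
    print(
        f"PMI F14C bounds: {lo.value:.4f} (UCM fully modern) to "
        f"{hi.value:.4f} (UCM fully dead), i.e. {round(lo.value, 2)}–{round(hi.value, 2)}"
    )

    (OUT / "data_reduction.json").write_text(json.dumps(out, indent=2) + "\n")


if __name__ == "__main__":
    main()
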