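# ventmix

Compound-specific radiocarbon (¹⁴C) data reduction and dual-isotope
two-endmember source apportionment for hydrothermal vent fluids.

Serpentinite-hosted vent fields carry formate at concentrations their tiny
dissolved-inorganic-carbon pools cannot explain. Radiocarbon separates the
candidate sources cleanly: mantle-derived, abiotically synthesized carbon
is ¹⁴C-free (F¹⁴C = 0), while carbon derived from modern seawater DIC has
F¹⁴C ≈ 1. `ventmix` implements the computations such a study runs between
the mass spectrometer and the interpretation:

- **Data reduction** — constant-contamination blank characterization from
  paired dead/modern process standards, methyl-derivatization correction
  for fatty acids measured as FAMEs, and mass-balance bounds for targets
  co-eluting with an unresolved complex mixture (UCM).
- **Mixing inversion** — per vent, the concentration-weighted F¹⁴C balance
  splits the measured total between a ¹⁴C-free endmember and a modern one;
  across vents, a weighted least-squares fit shares the dead-endmember
  concentration and both endmember δ¹³C values while letting the modern
  contribution vary per vent, with Monte-Carlo uncertainty.
- **Equilibrium screening** — a reaction-quotient index (ln Q − ln K) for
  formate–ΣCO₂ disequilibrium against a user-supplied equilibrium constant.
- **Synthetic data** — a generator producing per-sample vent tables from a
  known two-endmember truth, so the whole pipeline is testable end to end.

## The model

Each vent `v` observes a mixture of a shared radiocarbon-free source and a
vent-specific modern source:

    C_v        = C_dead + C_mod,v
    C_v · F_v  = C_mod,v · F_mod                      (F_dead = 0)
    C_v · δ_v  = C_dead · δ_dead + C_mod,v · δ_mod

with `F` fraction modern (F¹⁴C), `δ` the ‰ δ¹³C vs VPDB (mixed linearly),
and `F_mod = 1.02 ± 0.04` by default (seawater-DIC midpoint). The joint
fit minimizes the inverse-variance-weighted stacked residuals of these
balances; parameter uncertainties come from refitting Monte-Carlo
perturbed datasets. See `docs/methods.md` for the full account.

## Worked example

```
python analysis/01_simulate.py   # synthetic per-sample vent table
python analysis/03_apportion.py  # aggregate, apportion, joint fit
```

The simulated field (seed 42) has a true shared dead endmember of
112 µmol/L, δ¹³C −12.7‰, and modern contributions of 3/10/40/90 µmol/L at
vents C/2/B/3; vent C is generated without F¹⁴C, mirroring a sample too
small for AMS. The fit recovers:

```
joint fit (shared dead endmember, Monte-Carlo sigmas):
  C_dead        112.1 ± 4.5 µmol/L
  δ13C_dead     -12.7 ± 0.8 ‰
  δ13C_modern     8.1 ± 2.0 ‰
  C_modern[2]    7.0 ± 3.5 µmol/L
  C_modern[3]   93.0 ± 9.3 µmol/L
  C_modern[B]   42.6 ± 5.5 µmol/L
  C_modern[C]    4.7 ± 4.7 µmol/L
  weighted SSE 1.48 (11 obs, 7 params)
```

`C_dead` is the concentration of mantle-derived, radiocarbon-free formate
common to all vents; each `C_modern[v]` is that vent's seawater-derived
addition. The per-vent split of the hottest vent alone
(`dead 112.6 ± 13.5, modern 91.9 ± 11.9 µmol/L`) agrees with the joint
estimate, and `analysis/04_recovery.py` repeats the whole campaign
hundreds of times to verify the estimator is unbiased (relative bias
−0.7% over 200 campaigns) with conservative 95% intervals.

`analysis/02_reduce.py` demonstrates the data-reduction chain, e.g. the
UCM mass balance: a combined lipid isolate at F¹⁴C 0.39 ± 0.02 of which
the target is 80% of the carbon brackets the target at 0.24–0.49
depending on whether the contaminant is fully modern or fully dead.

A `ventmix` command exposes the same steps on CSV tables
(`ventmix simulate | correct | apportion | equilibrium | run`); schemas
are documented in the module docstrings.

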