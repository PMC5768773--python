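# Methods

## The scientific problem

Alkaline serpentinization systems such as the Lost City hydrothermal field
carry formate at concentrations far above what their vanishingly small
dissolved-inorganic-carbon pools would support, and compound-specific
radiocarbon analysis (CSRA) can tell where that carbon comes from: a
mantle-derived pool is radiocarbon-free (F¹⁴C = 0), while anything derived
from modern seawater DIC carries F¹⁴C ≈ 1. `ventmix` implements the
computational chain of such a study: the corrections that turn raw AMS
measurements into compound-specific isotope values, and the
concentration-weighted two-endmember mixing model that apportions each
vent's formate between a shared radiocarbon-free source and a per-vent
modern source.

## Data reduction

**Constant-contamination blank.** Sample processing adds a small pool of
extraneous carbon, modelled as a single pool with mass `m_c` (µg) and
fraction modern `F_c`. Two process standards of known F¹⁴C (one dead, one
modern) carried through the full procedure each obey

    F_meas · (m_s + m_c) = F_known · m_s + F_c · m_c

Two standards give two equations, which determine the two parameters
exactly (the system is linear in `(m_c, F_c·m_c)`). Sigmas come from
Monte-Carlo resampling of the four input F¹⁴C values (default 10,000
draws; unphysical draws are dropped). When both standards measure at their
known values, `m_c = 0` and `F_c` is flagged indeterminate rather than
invented. A single-pool model is the standard choice for small-sample ¹⁴C
work — two measurements cannot constrain separate "dead" and "modern"
contamination pools, so a two-pool model is a non-goal. Sample corrections
use the inverse balance; results pushed below zero are clipped and
flagged with a warning rather than rejected, and a warning is also raised
when the blank exceeds 3% of sample carbon, the level above which the
correction stops being a small perturbation.

**Derivatization.** A fatty acid measured as its methyl ester contains one
reagent-derived carbon in `n_c + 1`. The correction is a carbon-number
weighted balance, applied identically to F¹⁴C and δ¹³C:

    X_compound = ((n_c + n_a)·X_meas − n_a·X_reagent) / n_c

The reagent signature is not assumed; it is inferred by the inverse
balance from a co-derivatized standard of known composition (e.g. phthalic
acid → dimethyl ester, `n_a = 2`). `underivatize` and `infer_reagent` are
exact mutual inverses, which the property tests exercise over carbon
counts 1–40.

**Co-eluting contaminant.** When a target cannot be separated from an
unresolved complex mixture contributing fraction `1 − x` of the peak area,
the target F¹⁴C is bracketed by evaluating

    F_target = (F_comb − (1 − x)·F_ucm) / x

at the ends of an assumed contaminant range (default fully dead to fully
modern). Peak-area fraction is treated as carbon-mass fraction — the two
differ only through response-factor variation, which is unknowable here.
The interval width is `(1 − x)/x` times the assumed range and shrinks as
the isolate gets cleaner.

## The mixing model

Forward model, per vent `v`:

    C_v = C_dead + C_mod,v
    C_v·F_v = C_dead·F_dead + C_mod,v·F_mod      (F_dead ≡ 0)
    C_v·δ_v = C_dead·δ_dead + C_mod,v·δ_mod

δ¹³C mixes linearly on the ‰ scale. Exact ¹³C-abundance mixing differs by
under 0.1‰ over the −13 to +9‰ range involved, well inside measurement
noise, so the linear form is used throughout and is not switchable.
`F_mod` is fixed at 1.02 ± 0.04 by default — the midpoint of the local
seawater-DIC F¹⁴C range (0.993–1.052) — with an option to fit it instead.

**Per-vent inversion** uses the F¹⁴C balance alone:
`C_mod = C_tot·F_mix/F_mod`, `C_dead = C_tot − C_mod`, with first-order
sigmas over `(C_tot, F_mix, F_mod)`. A mixture hotter than the modern
endmember would give a negative `C_dead`; such values are clipped to zero
and flagged rather than hidden inside a constrained optimizer —
transparency over elegance, and realistic data sit far from the boundary.
If the vent's δ¹³C is observed and one endmember δ is supplied, the other
is solved by the δ balance.

**Joint fit.** Across vents the model shares `C_dead`, `δ_dead` and
`δ_mod` and gives each vent its own `C_mod,v`. The estimator is weighted
least squares over the stacked residuals of the three balances above, one
block per vent, each divided by its sigma; products (`C·F`, `C·δ`) get
delta-method sigmas from the per-vent ones. Vents lacking F¹⁴C (a real
situation: a sample can be too small for AMS) simply contribute fewer
residual rows. The system is solved with a bounded trust-region
least-squares routine with analytic Jacobian, initialized from the
per-vent inversions followed by a linear δ solve; with `n_obs <
n_params` the fit refuses to run and reports the deficit. A single
fully-observed vent degenerates to the exact per-vent inversion.

**Weights and floors.** Per-vent sigmas are the sample standard deviation
across replicates. Vents with one replicate would get infinite weight, so
configurable floors (F¹⁴C 0.02, δ¹³C 0.5‰, concentration 5% relative)
apply wherever the reported sigma falls below them. The floors are
weighting devices only — they never replace a reported sigma in output.
The field data themselves never print per-channel analytical sigmas, so
the floor values are this package's own choices of a plausible analytical
precision, made once.

**Uncertainty.** Monte-Carlo: perturb every vent-average observation by
its effective (floored) sigma, refit, and summarize the parameter draws
(mean, sd, 2.5/97.5 percentiles). Draws that fail to fit are recorded and
excluded; a failure rate above 10% aborts. Everything is reproducible
given the seed (default 42). Because the estimator also reports the
simpler cross-vent mean ± sd of per-vent `C_dead` values (the exact
estimator behind a published headline number is often unrecoverable),
both numbers appear in the analysis output; on synthetic data they agree
closely.

## Disequilibrium index

For the formate-forming reaction HCO₃⁻ + H₂ = HCOO⁻ + H₂O the index is
`ln Q − ln K` with `Q = [HCOO⁻]·a_H2O/([ΣCO₂]·a_H2)`. ΣCO₂ stands in for
bicarbonate without speciation — a flagged approximation that avoids
importing a thermodynamic database the analysis does not otherwise need;
for the same reason `ln K` is a required user input, not a computed
quantity. The index is strictly increasing in formate and decreasing in
ΣCO₂ and H₂; zero means equilibrium, positive means formate excess.

## Synthetic data generator

The generator stands in for a per-sample field table. Truth defaults are
the field-scale values: shared dead endmember 112 µmol/L at δ¹³C −12.7‰;
modern endmember F¹⁴C 1.02, δ¹³C +8.4‰; per-vent modern contributions
{C: 3, 2: 10, B: 40, 3: 90} µmol/L; replicate counts {C: 2, 2: 2, B: 3,
3: 6} (within the plausible 1–6 per vent; exact per-vent counts are a
package choice); vent C generated without F¹⁴C. Noise is independent
Gaussian per channel (F¹⁴C sd 0.05, δ¹³C sd 0.5‰, concentration 5%
relative), truncated at zero by resampling rather than clipping so no
point mass accumulates at zero and the recovery study stays unbiased.

What the generator does **not** emulate: correlated errors between
channels, vent-to-vent heterogeneity in the dead endmember, non-Gaussian
AMS error tails, temporal drift between sampling campaigns, or the lipid
laboratory chain (blank/derivatization corrections are validated by their
own round-trip oracles instead). Passing the recovery tests therefore
shows the estimator is consistent and well-calibrated *under the stated
noise model*, not that real field data meet that model.

## Numerical choices

- Least-squares tolerances `xtol = ftol = gtol = 1e-12`; noise-free
  synthetic data are recovered to better than 1e-6 relative.
- Product residual sigmas are floored at 1e-12 to avoid division by zero
  in degenerate all-zero-sigma inputs.
- Blank inversion accepts `F_c` down to −1e-9 to absorb rounding at the
  `F_c = 0` boundary.
- Replicate aggregation is the arithmetic mean ± (n−1) standard
  deviation; grouping is stable under row order.
- Radiocarbon ages use the single convention `age = −8033·ln F¹⁴C`; no
  calibration curves.

## Study sizes

The recovery study in the test suite uses 500 simulated campaigns with
200 Monte-Carlo refits each; the analysis driver defaults to 200
campaigns. Pilot runs at these sizes put the relative bias of `C_dead`
below 1% and 95%-interval coverage at 98–99% (the intervals are mildly
conservative because replicate scatter enters as a standard deviation,
not a standard error of the mean — the convention used for vent-average
error bars in the field).

## Known limitations

- Two endmembers only; the data cannot constrain more, and Bayesian
  mixing-polygon machinery is out of scope.
- No isotope fractionation during microbial uptake: the model reads
  mixtures, not process.
- δ¹³C is not blank-corrected (the blank model is ¹⁴C-only, matching how
  such corrections are reported in practice).
- The ΣCO₂-for-bicarbonate substitution makes the disequilibrium index a
  screening quantity, not a thermodynamic statement.
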