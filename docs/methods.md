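# Methods

## Model and assumptions

The package predicts water-to-cyclohexane partition coefficients from
alchemical solvation free energies under the dielectric-balancing premise:
a transfer calculation is only quantitatively trustworthy when the solute
polarization and the solvent dielectric environments are simultaneously
realistic.  The workflow therefore has four computational stages, each a
module:

1. **Solute modulation (G-DB).**  Partial charges are magnified by a
   constant factor (default 1.20) and Lennard-Jones σ inflated by
   (5/12)·|q_new − q_old| percent per atom.  The modulation is a pure
   parameter transform: ε, masses, and all bonded terms are untouched, and
   neutrality is preserved exactly because the scaling is linear.
   Solutes are assumed neutral (no tautomer/protonation handling); a
   non-zero net charge is refused unless explicitly allowed, because
   scaling multiplies it.
2. **TI assembly.**  Solvation free energy per solvent is the sum of a
   nonpolar (growth) leg on a 17-point λ grid — denser above λ = 0.5 where
   soft-core integrands curve — and a polar (charging) leg on 6 even
   steps.  ⟨∂H/∂λ⟩ inputs are assumed stationary and post-equilibration
   (an optional leading-fraction discard exists, default 0).
3. **Transfer relation.**  log P = (ΔG_wat − ΔG_cyh)/(2.303·R·T) with
   R = 8.31446×10⁻³ kJ/(mol·K), T = 298.15 K.  log P of the single neutral
   species is reported as the log D estimate.
4. **Evaluation.**  SAMPL-style error and correlation statistics with
   case-bootstrap uncertainties, the log D = 0 null baseline, and the
   50 % free-energy scaling ("say less") transform.

A dielectric module supplies the ε(0) estimator and the solvent-model
registry that defines "balanced": effective ε(0) within a fractional
tolerance (default 10 %) of 78.4 (water) and 2.0 (cyclohexane).

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| charge_scale | 1.20 | — | the +20 % magnification that polarizes a general-force-field solute for the condensed phase |
| sigma_coeff | 5/12 | — | coefficient of the percent-inflation rule that restores liquid densities |
| sigma_mode | per_atom_dq | — | the literal reading of the rule (|Δq| in e); `uniform_percent` treats the charge change as a percentage, a uniform 8.33 % |
| temperature | 298.15 | K | standard transfer temperature |
| λ schedules | 17-pt / 6-pt | — | nonpolar and polar leg grids |
| n_blocks | 5 | — | contiguous blocks for window standard errors |
| n_boot | 10 000 | — | bootstrap resamples for metric uncertainties |

The σ-rule ambiguity is genuine: with |Δq| in elementary-charge units the
per-atom inflations are below 0.1 %, while the percentage reading gives a
uniform 8.33 %.  We default to the literal per-atom reading and expose the
alternative as configuration rather than deciding silently.  Whether
hydrogens bonded to polar atoms should be exempt is likewise not decidable
from the rule as stated; none are exempted, and σ = 0 placeholders are
unaffected anyway under the multiplicative rule.

## Numerical choices

* **Quadrature.**  Composite trapezoid over the λ nodes — the standard
  choice for uneven TI grids; exact for affine integrands on any valid
  schedule (a tested invariant).  Window stderrs propagate through the
  trapezoid weights in quadrature; leg uncertainties combine in
  quadrature into ΔG_solv, and both solvents' uncertainties combine in
  quadrature into the log P uncertainty.
* **Block averaging.**  5 contiguous blocks per window.  With only 4
  degrees of freedom the stderr estimate is itself noisy (χ²₄), so
  end-to-end z-scores are Student-t-like rather than Gaussian; acceptance
  checks use ensemble calibration (≥ 90 % within 3σ) rather than a hard
  per-seed 3σ cut.
* **The 2.303 constant.**  The denominator uses the conventional literal
  2.303, not ln 10 = 2.302585…; an `exact_ln10` switch exposes the 0.02 %
  difference instead of hiding it.
* **Correlations on degenerate input** raise an explicit
  `UndefinedCorrelationError` (reported as `null` in JSON): the null
  baseline has zero prediction variance and must not fake a correlation
  of 0.  Kendall τ is the tie-corrected τ-b, since rounded log D data tie.
* **Topology I/O precision.**  Charges are written with 6 decimals and
  σ/ε with 7 significant figures — beyond force-field file conventions,
  and what makes round-trip identity a testable contract.  Atoms whose σ
  diverges from their shared atom type after per-atom inflation are
  written under uniquified type names, since the GROMACS `[atoms]` layout
  cannot carry per-atom σ.
* **Dielectric estimator.**  Conducting-boundary (tin-foil) fluctuation
  formula, the variant consistent with Ewald electrostatics.  Dipoles are
  handled in e·nm (1 e·nm = 48.0321 D); conversion constants are derived
  from CODATA values at import and covered by tests.
* **ΔH_vap** uses the ideal-vapor relation U_gas − U_liq + RT, neglecting
  the liquid pV term.

## What the synthetic generators emulate — and what they do not

The generators reproduce the *structure* of the workflow's inputs with
known ground truth: polynomial ⟨∂H/∂λ⟩ profiles with exact integrals and
homoscedastic Gaussian window noise; prediction sets whose experimental
values are uniform on [−4, 3] (the spread of the blind-challenge log D
measurements, dynamic range ≈ 7) with controlled slope, bias and Gaussian
noise — slope > 1 mimics the exaggerated dynamic range of over-polarized
predictions, bias > 0 the systematic cyclohexane preference; isotropic
Gaussian dipole series with variance inverted from the fluctuation
formula.  Defaults: 53 solutes, 100 samples per λ window, uniform
experimental distribution (only the range is known, so the maximum-entropy
choice).

They do **not** emulate serially correlated MD time series (samples are
i.i.d., so block averaging is exercised but not stressed), anharmonic or
diverging λ-endpoint integrands, heteroscedastic or solute-dependent
prediction errors, or any real molecular chemistry.  Passing tests
therefore demonstrate the correctness of the estimators and transforms,
not the accuracy of any force field against real partitioning data — the
headline blind-challenge accuracies require nanoseconds of MD per λ window
for 53 solutes in two solvents plus the external experimental log D set,
none of which this artifact runs or ships.

## Problem sizes

The test and acceptance runs use desk-scale ensembles chosen to make the
Monte-Carlo tolerances meaningful: 50-seed ensembles for end-to-end log P
recovery and bootstrap-spread checks, 100-topology ensembles for
round-trip/modulation invariants, 10⁵ frames for the 5 %-accuracy
dielectric recoveries, and 200–1000 bootstrap resamples inside loops
(10 000 remains the single-evaluation default).

## Known limitations

* The `[atomtypes]` parser supports the common 6/7-column layouts only;
  exotic GROMACS defines/macros are out of scope.
* The CYH-DC dipole-placement optimization loop (tuning a united-atom
  model's dipole to hit ε(0), density and ΔH_vap simultaneously) is not
  implemented; only the property estimators such a loop would call.
* MBAR/BAR estimators are deliberately absent: the workflow is TI-only.
* pKa/ionization corrections and solvent mutual-saturation corrections
  are out of scope; predictions are single-species log P values.
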