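# Methods

## Scope and model

`liefep` post-processes free-energy simulations; it never integrates
equations of motion.  Its inputs are per-sample ligand–surrounding
interaction energies (for LIE) and per-window energy-gap samples (for FEP),
in kcal/mol, organized by compound/transformation, state/environment and
replicate.  Two estimators form the core.

**Linear interaction energy.**  ΔG_bind = α·Δ⟨U_vdW⟩ + β·Δ⟨U_el⟩ + γ, where
Δ⟨U⟩ is the bound-minus-free difference of average interaction energies.
α defaults to 0.18 (the standard empirical value for the nonpolar term);
β and γ default to *fitted*, because in metal-containing binding sites the
electrostatic scaling absorbs large force-field sensitivities (for example
ligand–Zn²⁺ interactions) and is not transferable.  Calibration is ordinary
unweighted least squares of the free coefficients against experimental
ΔG = RT·ln Ki, with censored compounds (Ki above the assay limit) excluded.
Each coefficient can be independently fixed or freed; the fitted model
records which, plus the calibration ids and in-sample MUE.  A design matrix
with fewer rows than free coefficients, or with collinear/constant columns
(all Δ⟨U_el⟩ equal while β is free), raises a degenerate-fit error rather
than returning a pseudo-inverse solution.

**Zwanzig accumulation.**  For a transformation discretized into λ-windows,
δG(m→m+1) = −kT·ln⟨exp(−ΔU/kT)⟩ evaluated with `scipy.special.logsumexp`,
so gaps of thousands of kT cannot overflow.  The exponent carries ΔU/kT
(energy over thermal energy); a formulation that multiplies the energy gap
by kT instead does not survive dimensional analysis and is not implemented.
A leg's ΔG is the sum over windows and over its ordered stages
("subperturbations": charge annihilation, soft-core introduction, soft-core
annihilation for residue mutations).  Reverse accumulation estimates the
B→A free energy from the reverse gaps and reports its negative, so both
directions live on the A→B scale and coincide exactly for noiseless gaps.

## Conventions

- Units: kcal/mol throughout; R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹.
- Ki → ΔG at T = 298 K by default (assay temperature); the simulation
  temperature is configurable independently wherever kT enters.
- ΔΔG signs: B − A for ligand edges, mut − wt for mutations, so
  destabilizing changes are positive.
- SEM is always computed across replicate means, never across pooled raw
  samples: within-replicate autocorrelation (MD energy series are strongly
  autocorrelated) would otherwise understate the uncertainty.  SEMs of two
  states/environments combine in quadrature; a single replicate yields an
  undefined (absent) SEM, not zero.
- Hysteresis: per stage |ΔG_fwd(A→B) + ΔG_rev(B→A)|, summed over stages.
  Bidirectional gaps from the same window set suffice; independently
  simulated reverse legs are also accepted.
- Cycle closure: edges are validated to form exactly one closed cycle
  (every node degree 2, connected, no self-loops); the traversal starts at
  the first edge's A node along its stated direction, and each edge
  contributes +ΔΔG along its orientation, −ΔΔG against it.  The sign of the
  closure is therefore well defined given the edge list order.
- Residue-mutation legs carry their stage decomposition as input metadata;
  the package checks the stage count against the documented 4–11 range for
  side-chain annihilation but does not derive stages from chemistry.
- λ-schedule default: 51 uniformly spaced windows including both endpoints;
  arbitrary strictly increasing schedules with λ∈{0…1} endpoints are
  accepted per stage.

## Bundled benchmark tables

`liefep.datasets` transcribes the published IRAP/HFI benchmark: the
wild-type affinity series (35 compounds, 21 with measured Ki, the rest
censored at 100 μM), compounds 6–9 against wild-type and the F544I/F544V
mutants, the four-edge transformation cycles per enzyme form, and the
position-544 alanine-scan table.  Recomputing the published statistics from
these tables gives MUE 0.50 kcal/mol (25 wild-type pairs), 0.51 kcal/mol
(all 33 pairs), FEP-vs-experiment MUE 0.04/0.31/0.17 kcal/mol for
wt/F544I/F544V, and cycle closures 1.22 (F544I) and −0.19 (F544V) kcal/mol.
Two caveats are inherent to working from printed (2-decimal) values: the
wild-type cycle closure computes to 0.10 rather than the published 0.09,
and the Pearson R over the 33 pairs computes to 0.74 rather than the
published 0.71 — both consistent with the original statistics having been
taken on unrounded simulation output, which no reimplementation can
recover.  Two alanine-scan combinations (compound 7 F544I, compound 8
F544V) differ from the printed combined column by 0.01 for the same reason.

## Synthetic-data engine

The generators emulate the *statistical* structure of free-energy
simulation output, with exactly known answers; they make no attempt at
force-field realism (no water models, no ion electrostatics, no
conformational kinetics).

- **LIE series** — stationary AR(1) processes with specified population
  means per compound/state/component, marginal sd 2 kcal/mol and lag-1
  autocorrelation φ = 0.9 by default (MD interaction energies decorrelate
  over many sample intervals), 10 replicates per state to mirror standard
  replicate protocols.  True affinities follow from a known (α, β, γ), with
  optional Gaussian scatter (default 0.3 kcal/mol in calibration studies)
  emulating experimental error.
- **Gaussian gaps** — i.i.d. N(μ_m, σ_m²) forward gaps, exact
  ΔG = Σ(μ_m − σ_m²/(2kT)).  Reverse gaps are drawn from the conjugate
  distribution N(σ²/kT − μ, σ²), the exact distribution of the reverse
  perturbation for Gaussian overlap, so hysteresis vanishes in expectation.
- **Harmonic λ-path** — Metropolis sampling of
  U_λ = (1−λ)·k_A/2·(x−x_A)² + λ·k_B/2·(x−x_B)², for which
  ΔA = (kT/2)·ln(k_B/k_A) independent of the minima.  Chains start at the
  window's potential minimum, use uniform proposals (default step 1 Å,
  acceptance ≈ 0.5–0.75 at kT = 0.596), discard a 500-step burn-in and log
  acceptance rates.  Default sampling is 51 windows × 5×10³ samples —
  desk-scale counts chosen so the whole validation suite runs in seconds
  while leaving the estimator's stochastic error near 0.01 kcal/mol,
  comfortably resolvable against the analytic 0.413 for k: 1→4.
- **Cycle datasets** — edges built as differences of per-ligand true ΔG
  plus independent Gaussian noise; all cycles close exactly at zero noise
  and the mean |closure| grows as sd·√(edges)·√(2/π).

Randomness: every generator takes one root seed and derives per-compound /
per-window child streams via `numpy.random.SeedSequence.spawn`, so outputs
are bit-reproducible and independent of generation order.

What passing the synthetic suites shows: the estimators are implemented
correctly (they recover closed forms within quoted statistical error) and
their uncertainty conventions behave (SEM ∝ 1/√n, closure ∝ noise).  What
it does not show: accuracy on real systems, which is limited by force
fields, sampling and the LIE approximation itself, not by this arithmetic.

## Numerical choices and degenerate inputs

- Exponential averages via log-sum-exp; no clipping or sample discarding.
- Least squares via `numpy.linalg.lstsq` after an explicit rank check, so
  rank deficiency is an error, not a silently regularized fit.
- Pearson R is flagged undefined (not NaN) for fewer than two pairs or zero
  variance in either coordinate; MUE is still reported.
- Empty sample sets, non-finite energies, mismatched compound ids,
  duplicate replicate ids, non-monotone λ, and open/branching cycle edge
  sets all raise typed errors early.
- Reports print at 2 decimals (the field's customary precision in
  kcal/mol); machine-readable outputs keep full precision.

## Limitations

- Zwanzig exponential averaging only; BAR/MBAR and overlap-based estimators
  are natural extensions but out of scope, as are soft-core functional
  forms, topologies and anything that touches coordinates.
- The LIE calibration is unweighted; affinity-measurement errors are not
  propagated into the coefficient covariance.
- Censored affinities are used only for bound-consistency classification,
  never in fitting or MUE/R.
- The bundled benchmark cannot be regenerated from first principles here:
  the original MD sampling is not reproducible at desk scale, so the
  benchmark checks the analysis chain downstream of sampling.
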