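# Methods

This note records the model, the numerical choices, and the limits of what
the reduced-scale studies in the test suite demonstrate.

## Model and units

Two bead-spring homopolymers (N = 60 beads each, all beads of size σ) carry
opposite unit charges on a fraction f of their beads, placed maximally
evenly along the backbone (indices ⌊(k + ½)/f⌋). Reduced units throughout:
σ = 1 (mapped to 6.0 Å, a generic residue size), energies in k_BT at the
operating temperature T₀ = 300 K (0.596 kcal/mol), bead mass m = 1,
τ = σ√(m/ε). The box is cubic with edge 100σ and periodic; all runs use a
Langevin thermostat at T₀ with time step Δt = 0.002τ.

Interaction channels (all truncated; energies shifted to zero at their
cutoffs):

| channel | form | cutoff | parameters |
|---|---|---|---|
| WCA(50,49) | C·ε[(σ/r)⁵⁰ − (σ/r)⁴⁹] + ε | (50/49)σ ≈ 1.0204σ | ε = k_BT |
| hydrophobic tail | −λ(T)·ε₀·(σ/r)⁶ | 3σ | λ(T) = λ₀ + α(T − θ) |
| screened Coulomb | q_iq_j ℓ_B e^(−κr)/r | 8σ | ε_r = 78, C = 0.1 M |
| harmonic bond | K(r − r₀)² | — | K = 100 k_BT/σ², r₀ = 0.7σ |

Nonbonded interactions between directly bonded neighbours are excluded (the
usual bead-spring convention; the 0.7σ rest length sits deep inside the
repulsive core and the exclusion keeps bonded beads from fighting it).

Notable conventions, each genuinely open in the problem statement and fixed
here as the package's design:

* **Bond prefactor.** u = K(r − r₀)² with no ½ — the common MD-engine
  convention for a quoted K in energy/length².
* **Tail energy scale.** The tail prefactor ε₀ is pinned to k_B·300 K and
  does *not* scale with the thermostat temperature; all temperature
  dependence of the hydrophobic channel lives in λ(T). This is what makes
  the channel purely enthalpic at α = 0 and yields the closed-form
  decomposition below; it is validated against a finite-difference
  temperature derivative in the tests.
* **Electrostatic screening.** κ = √(8πℓ_B C) is held
  temperature-independent (the Debye length moves little over the range of
  interest). The force-field ℓ_B uses the operating value ε_r = 78; the
  decomposition coefficient uses the empirical ε_r(T) fit (below).
* **Tail functional form.** The −λ(σ/r)⁶ attraction truncated/shifted at 3σ
  is the simplest commonly assumed hydrophobic form; it is validated by the
  λ₀ calibration landing at 0.916, within ±0.05 of the expected ≈0.95. Had
  it missed, the fallback would have been a λ-scaled attractive Mie branch
  (Ashbaugh–Hatch splitting).

## Second virial coefficient and calibration

B₂(λ) = 2π∫₀^∞ [1 − e^(−u(r)/k_BT)] r² dr over the non-ionic potential
u_wca + u_T (the electrostatic part is excluded: B₂ here characterizes the
hydrophobic/solvent condition). The integrand vanishes identically beyond
the 3σ tail cutoff, which is therefore the upper quadrature limit; adaptive
quadrature (absolute tolerance 10⁻⁶ σ³, split at the WCA cutoff) and a
bracketing root solve (tolerance 10⁻⁶ in λ) give λ₀ = 0.916165 with
|B₂(λ₀)| < 10⁻⁴ σ³ in well under a second. The admissible sweep region —
|α| < 0.01 K⁻¹, |T − θ| < 100 K, B₂ ∈ (−1.1, 0.1)σ³ — is sampled uniformly
with rejection; because λ depends on (α, T−θ) only through α·(T−θ), the
B₂ constraint reduces to a λ interval, computed once by root-solving at the
two B₂ bounds.

## Dielectric model

ε_r(T) uses the Malmberg–Maryott cubic-in-Celsius fit for liquid water
(valid 273–373 K): ε_r(300 K) = 77.6, d ln ε_r/d ln T = −1.363 at 300 K.
The electrostatic decomposition coefficients are evaluated from this fit at
run time, never hard-coded.

## Dynamics

BAOAB Langevin integration (configurational accuracy at large time steps),
friction γ = 1/τ — not prescribed by the physics; a standard damping that
is diffusive yet stable at Δt = 0.002τ. Forces come from a Verlet neighbor
list (radius = largest cutoff + 0.3σ skin, rebuilt by an O(N²) scan when
any bead moves half a skin; at N = 120 a cell grid would cost more than it
saves). Channel energies (U_wca, U_hp, U_el, U_bond) are accumulated
separately; the kernel is validated against an independent double-loop
direct sum built from the analytic potential functions.

## PMF by adaptive biasing force

The reaction coordinate ξ is the distance between the two chains' centers
of mass, sampled over 0–30σ in windows 0–3σ, 3–10σ, 10–30σ with 0.5σ bins.
The instantaneous force conjugate to the separation *vector* is
F = μ(F₁/M₁ − F₂/M₂)·r̂ (physical forces only); its running bin average is
applied as a counter-bias, ramped linearly over the first 200 samples per
bin. Harmonic walls (100 kT/σ²) confine ξ to the window. Free energy =
−∫⟨F⟩dξ (trapezoid on bin centers), windows joined by matching values
across the junction and the stitched curve re-referenced to zero over the
outermost five bins.

**Jacobian convention.** Because the estimator projects the physical force
on the radial direction, the resulting profile is the spherically symmetric
well W(ξ); the 2k_BT ln ξ geometric term is *not* included. For an isolated
pair W equals the pair potential exactly — the strong oracle used in the
tests (agreement within 0.05 k_BT, limited by binning bias) — and the
complexation free energy is the depth of the bound-state well (the profile
minimum; identical to the innermost bin whenever the profile decreases
monotonically into contact).

**Walkers and initialization.** Windows run outside-in; each inner window
inherits the previous window's final configuration, so the chains approach
dynamically and are never inserted overlapping. A wide outer window
(lower edge ≥ 10σ) is covered by ⌈width/5σ⌉ walkers sharing one bias
estimate, each a freshly built pair equilibrated with ξ tethered near its
starting separation (an unrestrained equilibration lets the coordinate
drift away from the walker's target). The step budget is split across
windows in proportion to width.

**Component profiles.** ⟨U_x⟩(ξ) is accumulated every 20 steps; the bias
depends only on ξ, so these conditional averages are unbiased. Binding
changes ΔU_x are bound-ensemble (ξ < 1.5σ, count-weighted) minus separated
(outermost five bins) averages.

## Thermodynamic decomposition

With x = d ln ε_r/d ln T (≈ −1.363 at 300 K) and c = αT/λ(T):

* electrostatic: TΔS_el = x·ΔU_el, ΔH_el = (1 + x)·ΔU_el — attraction in
  water at room temperature is entropy-driven, enthalpy-penalized;
* hydrophobic: TΔS_hp = −c·ΔU_hp, ΔH_hp = (1 − c)·ΔU_hp — the sign of α
  decides whether binding is entropy-driven (LCST) or enthalpy-driven
  (UCST);
* k_BT-scaled channels (WCA, bond): TΔS = −ΔU, ΔH = 0;
* totals: TΔS_total = ΣΔH_channels − PMF(0); TΔS_conf is the remainder
  after subtracting every potential-derived channel entropy. Translational
  entropy of the chains is excluded by convention.

The identities ΔH_x − TΔS_x = ΔU_x and ΔH_total − TΔS_total = PMF(0) hold
to machine precision by construction; the coefficients themselves are
checked against centered finite differences of the channel free energies
over T ± 5 K (1% tolerance, limited by the curvature of the dielectric
fit).

## Compensation sweep

`run_sweep` draws (α, T−θ) pairs from the admissible region, re-verifies
the B₂ constraint per record, runs the full pipeline with per-record seeds
derived from the master seed, and excludes (with a logged warning, never
silently) records whose profiles fail the convergence gate. Compensation
statistics are ordinary least squares of TΔS_total on ΔH_total (both
orderings reported), ranges as max − min in kcal/mol per residue.

## Problem sizes and what the reduced-scale tests show

Production-quality profiles for this model need ~10⁷τ per window; the
automated suite instead uses tiers chosen for convergence per unit time on
a single CPU:

* dimer oracles: 1.2×10⁶ steps, bins 0.1σ — statistically converged
  (seed-to-seed spread ~10⁻³ kT); these validate the ABF machinery itself;
* two-chain binding (f = 0.5 / 0.1, B₂ = −1σ³): 7×10⁵ steps per window
  (×3 windows over the full 0–30σ range, width-weighted, multi-walker
  outer window), tethered equilibration 4×10⁴ steps per walker;
* compensation sweep: 12 sampled combos (statistics over the ≥10 whose
  profiles pass the convergence gate) at 2.8×10⁵ steps per window over a
  truncated 0–9σ range — differences and ratios across records are
  computed at identical truncation, and the long-range tail beyond ~9σ is
  common-mode across records.

At these sizes the contact free energy carries a seed-to-seed spread of
order 10 kT (≈0.1 kcal/mol per residue) — adequate for band and ordering
checks, not for the published two-decimal values. The sweep's compensation
slope is robust because it is dominated by the closed-form coefficient
variation; the ΔG range and the conformational-entropy span (algebraically
equal to ΣΔU − ΔG, hence carrying the same sampling noise) are the
slowest-converging summary statistics and at this tier measure sampling
noise on top of the small physical variation. The folded-chain (f = 0.1)
contact free energy converges to ≈ −0.2 kcal/mol per residue at every
affordable scale — shallower than the −0.5 to −1.0 band of disordered
chains; see the limitations below.

## Known limitations

* The generator emulates homopolymers with a single (θ, α) per system;
  heteropolymer sequence effects are out of scope.
* Forces are discontinuous (though small) at the tail and electrostatic
  cutoffs; fine for thermostatted sampling, and the NVE conservation check
  therefore uses a smooth (bonded-dimer) fixture.
* Conformational relaxation of collapsed (low-f) chains is the slowest
  mode and the folded-chain binding free energy is the least certain
  quantity in the suite. Its stability across a 3x range of sampling at
  ≈ −0.2 kcal/mol per residue suggests the residual gap to the disordered
  band is a property of the adopted short-ranged tail (whose exact range is
  the one under-determined ingredient of the model, fixed here only through
  the B₂ calibration), not of sampling.
* Electrostatics are pairwise-screened (Debye–Hückel), appropriate at
  0.1 M; no Ewald treatment, no pressure control.
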