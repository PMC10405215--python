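# eecsim

Water-reorganization thermodynamics from temperature-dependent
implicit-solvent potentials: a coarse-grained molecular-dynamics toolkit for
studying enthalpy–entropy compensation (EEC) in the association of two
oppositely charged polymers.

## The scientific problem

Biomolecular binding in water almost universally shows enthalpy–entropy
compensation: across chemically similar systems the binding free energy
ΔG = ΔH − TΔS barely moves, while ΔH and TΔS individually swing by many
kcal/mol and cancel. Water restructuring around the solutes is widely
believed to drive this, but explicit-water calculations cannot cleanly
separate the water contribution per interaction channel.

`eecsim` exploits the fact that implicit-solvent pair potentials are
potentials of mean force over the water degrees of freedom: their explicit
temperature dependence *is* the water contribution. For any channel whose
effective potential is w(r; T), the water-reorganization entropy and
enthalpy of an association process follow from

    Δs = −∂Δw/∂T,        Δh = Δw − T ∂Δw/∂T.

The model contains four channels for two 60-bead bead-spring chains carrying
opposite charge fractions *f* in a 100σ periodic box at T = 300 K:

* **WCA(50,49)** — a generalized Weeks–Chandler–Andersen repulsion
  (Mie exponents λ_r = 50, λ_a = 49, truncated/shifted at its minimum) with
  ε = k_BT: athermal in reduced units, hence purely entropic;
* **hydrophobic tail** — u_T(r) = −λ(T)·ε·(σ/r)⁶ (truncated/shifted at 3σ)
  with λ(T) = λ₀ + α(T − θ). The θ temperature is where the second virial
  coefficient B₂ = 2π∫(1 − e^(−u/kT)) r² dr of the non-ionic interaction
  vanishes; solving B₂(λ₀) = 0 gives λ₀ ≈ 0.92. α > 0 encodes LCST-type
  solvation (attraction strengthens on heating), α < 0 UCST-type;
* **screened Coulomb** — u(r) = q_i q_j ℓ_B e^(−κr)/r with ε_r = 78,
  0.1 M monovalent salt (Debye length ≈ 9.6 Å), κ held constant; the
  temperature dependence of ε_r(T) makes electrostatic attraction in water
  entropy-driven: TΔS_el = (T ε_r′/ε_r) ΔU_el ≈ −1.36 ΔU_el at 300 K;
* **harmonic bonds** — u = K(r − r₀)², K = 100 k_BT/σ², r₀ = 0.7σ
  (entropic, like the WCA channel).

The binding free energy is the potential of mean force (PMF) along the
chain center-of-mass distance, computed with the adaptive biasing force
(ABF) method in windows 0–3σ, 3–10σ, 10–30σ with 0.5σ bins; PMF(0) is the
free energy of complexation. Closed-form coefficients then decompose it
into per-channel (TΔS, ΔH) pairs plus a conformational-entropy remainder.
Sweeping (α, T − θ) over the experimentally motivated region
(|α| < 0.01 K⁻¹, |T − θ| < 100 K, B₂ ∈ (−1.1, 0.1)σ³) reproduces EEC: ΔG
nearly constant, TΔS vs ΔH on a line of slope ≈ 1, dominated by the
hydrophobic (water-reorganization) channel.

## Worked example

```python
from eecsim import ForceField, calibrate_lambda0, compute_pmf
from eecsim.pmf import binding_quantities
from eecsim.thermo import decompose
from eecsim.virial import b2_of_lambda
from scipy.optimize import brentq

ff = ForceField()
lam0 = calibrate_lambda0(ff)                      # 0.916165
print(f"lambda0 = {lam0:.6f}, B2(theta) = {b2_of_lambda(lam0, ff).value:.2e}")

# binding of two chains at f = 0.5 under B2 = -1 sigma^3 solvent conditions
lam = brentq(lambda l: b2_of_lambda(l, ff).value + 1.0, 0.3, 2.0)
profile = compute_pmf(0.5, ff.with_lambda(lam), seed=1105,
                      run_scale={"steps_per_window": 700_000, "equil_steps": 40_000},
                      min_samples=100)
bq = binding_quantities(profile)
print(f"PMF(0) = {bq.dG:.1f} kT = {bq.dG * 0.596 / 60:.2f} kcal/mol per residue")
```

prints (reduced-scale ABF; a few minutes on one CPU)

```
lambda0 = 0.916165, B2(theta) = 3.90e-07
PMF(0) = -65.3 kT = -0.65 kcal/mol per residue
```

i.e. the calibrated θ-point coupling, a numerically vanishing second virial
coefficient at θ, and a contact free energy of about −0.65 kcal/mol per
residue — inside the −0.5 to −1.0 kcal/mol range typical of protein–protein
and protein–ligand association. Passing the binding quantities to
`decompose(...)` splits this into the entropy-driven electrostatic part,
the α-dependent hydrophobic part, and the conformational remainder.

The same pipeline is scriptable from the shell:

```bash
eecsim calibrate
eecsim b2 --alpha 0.005 --out b2.tsv
eecsim pmf --f 0.5 --seed 1 --run-scale test --out pmf.tsv
eecsim decompose --pmf-table pmf.tsv
eecsim sweep --f 0.5 --n-combos 10 --seed 7 --run-scale test
```

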