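# dscft

Dipolar self-consistent field theory (DSCFT) for the potential of mean
force (PMF) between two ions in a polar solvent, with the PMF decomposed
into its energetic and entropic parts.

## The problem

Implicit-solvent models bury the solvent in an effective dielectric
constant ε(T).  Because ε depends on temperature, the familiar screened
Coulomb attraction between opposite ions is not purely energetic: part
of it — often most of it — is *entropy* gained by solvent dipoles that
are released from the ions' polarizing field when the pair forms.  This
package quantifies that electrostatic entropy for two ions in a dipolar
solvent, at two levels:

**Debye level (closed form).**  A solvent of number density 1/v with
permanent dipole moment μ̄ has bulk permittivity ε = ε₀(1 + ξ) with the
dimensionless dipole parameter

    ξ = β μ̄² / (3 v ε₀),      β = 1/k_BT.

Bringing charges q₁, q₂ from infinity to distance r then gives

    ΔF = q₁q₂ / (4π ε₀ (1+ξ) r),   ΔU = ΔF/(1+ξ),   −TΔS = ΔF·ξ/(1+ξ),

so the entropic fraction of the PMF is ξ/(1+ξ): entropy dominates for
ξ > 1 (water at room temperature has ξ ≈ 3.4 at μ̄ = 1 D, v = 30 Å³).

**Field-theoretic level (numerical).**  A mean-field model with explicit
solvent degrees of freedom: ions are Gaussian-smeared charges inside
smooth spherical cavities, and at every point the solvent obeys the
nonlinear Langevin constitutive relation

    D = ε₀E + n μ̄ L(βμ̄E) + n α E,     L(x) = coth x − 1/x,

where D is fixed by the ion charges alone (superposition of the two
radial displacements) and n(r) = (1 − φ₀(r))/v follows from the cavity
profiles by incompressibility.  The grand-potential difference ΔΩ(r) is
an axisymmetric volume integral of the local free-energy density; the
entropy comes from −∂ΔΩ/∂T (central finite difference, cross-checked
against the analytic orientational-entropy integral), and the local
polarization |P| = χ_or|∇φ| measures dipole release directly.

## Worked example

```bash
python examples/entropy_crossover.py
```

prints

```
entropy fraction of the PMF at r = 5 sigma (ref: infinite separation):
      xi  mu_bar_D  entropy_fraction
  0.2500    0.2723            0.2030
  0.5000    0.3851            0.3393
  1.0000    0.5447            0.5097
  2.0000    0.7703            0.6795
  4.0000    1.0893            0.8155
  (Debye predicts xi/(1+xi))

fraction = 1/2 at xi = 0.963  (Debye: exactly 1)
```

Each row solves the full nonlinear field model at r = 5σ for the dipole
moment that realizes the given ξ and reports which share of the pairing
free energy is entropic; the fractions track the Debye prediction
ξ/(1+ξ), and bisecting the dipole moment puts the energy→entropy
crossover at ξ ≈ 0.96, confirming the Debye threshold ξ = 1 at the
mean-field level.  Other examples cover the closed-form decomposition
(`debye_crossover.py`), the decomposed PMF curve with its unfavourable
short-range energy (`pmf_decomposition.py`), dielectric saturation
(`dielectric_saturation.py`), and the excess-polarization measure of
dipole release (`polarization_release.py`).

A thin CLI exposes the same pipelines:

```bash
dscft debye --xi 1                 # closed-form decomposition
dscft decompose --mu-bar 1.0 --separations "1.0:8.0:0.5" --out run/
dscft fit-eps --mu-bar 0.545 --separations "5.0:8.0:0.5" --out run/
```

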