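# Methods

## Model

Two fixed ions sit on the z axis at ±r/2 in a dipolar solvent treated at
the mean-field (saddle-point) level.  The ingredients:

* **Sources.**  Each ion is a Gaussian-smeared charge of valence z and
  smearing radius b (the smearing regularizes the self-energy).  The
  electric displacement of the pair is the superposition of the two
  isolated radial displacements D_i(s) = Q_enc(s)/4πs² — exact for an
  isolated ion by Gauss's law, approximate for the pair because the
  dielectric is nonlinear.  Solvent is excluded from a smooth spherical
  cavity around each ion, h(s) = ½[1 − tanh((s − mσ)/(cσ))]; by
  incompressibility the solvent volume fraction is 1 − φ₀ with
  φ₀ = h₁ + h₂, clipped at zero density where cavities overlap.
* **Dielectric closure.**  At every point the field magnitude solves
  D = ε₀E + nμ̄L(βμ̄E) + nαE, i.e. D = ε₀(1 + χ_or + χ_el)E with
  χ_or = nμ̄L(x)/(ε₀E) and χ_el = nα/ε₀.  In the weak-field bulk this
  reduces exactly to the Debye permittivity ε₀(1 + ξ),
  ξ = βμ̄²/(3vε₀); at strong fields the dipoles saturate and the local
  permittivity falls toward ε₀ (dielectric saturation).  The closure is
  stated with the Langevin function; the fugacity-weighted form via
  G(x) = L(x)sinh(x)/x² is algebraically identical wherever the density
  is pinned by incompressibility, which is everywhere in this model.
* **Free energy and entropy densities.**  Substituting the saddle-point
  relations into the Hamiltonian gives, up to separation-independent
  solvent terms,

      f = E·D − ½ε₀E² − ½nαE² − n k_BT ln(sinh x / x),   x = βμ̄E,

  which is stationary in E on the constitutive solution and reduces to
  D²/2ε in the weak-field limit.  Its temperature derivative at fixed D
  (an envelope-theorem identity) is the orientational entropy density
  s = n k_B[ln(sinh x/x) − xL(x)] ≤ 0.  Separation-independent terms
  may be dropped because the cavity superposition makes ∫φ₀ d³r — and
  with it every density-only functional — independent of separation.

The PMF is ΔΩ(r) = Ω(r) − Ω(∞); the entropic part is
ΔS = −∂ΔΩ/∂T at fixed v, μ̄ and geometry (the closure's only explicit
temperature dependence is through β), and ΔU = ΔΩ + TΔS.

## Numerical treatment

**Pointwise solve.**  The constitutive relation is inverted per point by
the fixed-point map E ← D/(ε₀(1+χ(E))).  The map derivative lies in
(0, 1) (because xL′(x) < L(x)), so plain iteration converges; an
oscillation-triggered under-relaxation of ½ is kept as a safeguard.
Iteration stops when the relative per-sweep change in |E| falls below
1e-13 (the self-consistent stopping criterion); the residual of the
constitutive relation is recorded.  Deep in saturation the contraction
factor approaches 1 − 1/x and the remaining error can exceed the change
tolerance by a few orders of magnitude; in the physically visited range
(x ≲ 20 near the cavity surface) the solution is accurate to ~1e-12.
Series branches for L(x), L(x)/x and ln(sinh x/x) extend to x ≈ 0.05–0.1
because the naive expressions lose ~eps/x² to cancellation, which would
otherwise put numerical noise above the stopping tolerance.

**ΔΩ versus infinite separation.**  Ω(r) − Ω(∞) is computed as a single
integral of f(pair) − f(ion 1 alone) − f(ion 2 alone), the three
integrands evaluated *on the same quadrature nodes*, so the large
self-energy densities cancel pointwise and the remaining integrand is
everywhere of the order of the ion–ion interaction.  The domain is a
midpoint-centred ball of radius 60σ, tiled by two per-ion half-space
grids of spherical rays: Gauss–Legendre panels along each ray with panel
edges placed analytically at every sharp feature the ray crosses (the
central ion's Gaussian core and tanh interface at fixed radii; the
remote ion's interface sphere at radii found from the ray–sphere
quadratic, with windows widened by the crossing obliquity), then
geometric panel growth so the far field costs O(log r) panels.  Rotational
symmetry reduces everything to the (radial, axial) plane with weight
2πs; mirror-symmetric pairs integrate one half-space and double.
Outside the ball the response is linear to high accuracy and the cross
term ∫D₁·D₂/ε_b (and its matching entropy) is added from a smooth
log-radial shell quadrature out to 3000σ plus the closed-form remainder
q₁q₂/4πR′.  Doubling the gridded ball changes ΔΩ by < 1e-5 relative;
the vacuum (μ̄ = 0) pipeline reproduces the Coulomb difference to
~1e-5, and halving the smearing radius changes ΔΩ by < 0.1% at contact
and < 1e-5 beyond 2σ.

**Entropy.**  The production route is the central finite difference of
ΔΩ over T ± 1 K (0.33% of T; identical grids at all three temperatures,
so discretization errors cancel in the difference).  The analytic
entropy-density integral provides an independent oracle; the two agree
to ~1e-5 relative, and `entropy_decomposition` raises if they disagree
beyond 0.5%.

**Excess polarization.**  Γ = ∫χ_or|∇φ| d³r grows roughly linearly with
the domain radius (the single-ion integrand decays only as 1/r²), so Γ
is defined on a fixed midpoint-centred sphere, radius 25σ by default.
Absolute values therefore depend on that convention; differences across
separations and curves normalized by a large-separation value do not,
and the normalized curves collapse across dipole moments to ~0.5%.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| μ̄ | solvent permanent dipole | (required), debye | water gas phase ≈ 1.85 D |
| v | solvent molecular volume | 30 Å³ | or number density ρ = 1/v |
| α | electronic polarizability | 0 | adds a linear χ_el = nα/ε₀ |
| T | temperature | 300 K | |
| σ | ion diameter | 3 Å | also the reduced length unit |
| b | charge smearing radius | 0.2 σ | results insensitive (see above) |
| m, c | cavity midpoint / width | 0.95, 0.01 | interface at mσ, width cσ; any sigmoid honouring "decays to zero by σ" behaves the same |
| ref. separation | PMF zero point | 8 σ | fraction-type analyses default to ∞ instead |
| δT | entropy finite-difference half-step | 1 K | |
| field tol | per-sweep |E| change | 1e-13 | |

The standard study conditions throughout (tests, examples, acceptance)
are the water-like set σ = 3 Å, T = 300 K, v = 30 Å³, monovalent
opposite charges, with μ̄ swept over 0–2 D.

## Design choices

* **Reference conventions.**  PMF curves are referenced to r = 8σ.
  Fixed-r entropy-fraction analyses (fraction versus ξ, the crossover
  bisection) are referenced to infinite separation, which the field
  theory provides directly.  The distinction matters: at water-like
  saturation strength the nonlinear halo around each ion extends to
  ~3σ, so a 5σ–8σ window still carries saturation corrections (windowed
  fraction 0.522 at ξ = 1 versus 0.510 for the ∞-referenced fraction,
  both → 0.5 at long range).
* **Effective dielectric.**  The Coulomb-tail fit ΔΩ = q₁q₂/4πεr + C
  recovers ε/ε₀ = 1 + ξ when applied to the genuinely long-range tail
  (within 1% fitting 8–12σ); fitting 5–8σ overshoots by up to ~2.5% at
  ξ = 2 for the same saturation-halo reason.
* **All internals in SI**; angstroms, debyes and kelvins at the API
  boundary, kJ/mol and reduced ε (1ε = 2.49 kJ/mol, 1σ = 3 Å) in
  tables.  Everything is deterministic — there is no randomness anywhere
  in the pipeline.

## Limitations

* Mean field: no dipole–dipole correlations, hence no reaction field —
  the effective permittivity is exactly Debye's, lower than simulations
  give for the same μ̄, and explicit-solvent simulations put the
  energy/entropy crossover somewhat below ξ = 1.  No solvation-shell
  structure: packing oscillations in the PMF and the layered
  polarization around ions are not reproduced.
* The displacement superposition degrades at close approach
  (r ≲ 1σ), where the nonlinearity couples the two sources and cavity
  overlap is handled by clipping the density at zero.
* Single ion pair at infinite dilution; no free ions, no screening.
* Γ is domain-convention dependent (see above); only normalized or
  differenced values are physically meaningful.
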