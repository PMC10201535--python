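"""Dipole release: excess polarization versus ion separation.

Integrates the local orientational polarization chi_or |grad phi| over a
fixed 25-sigma sphere for several separations.  Gamma falls as the ions
approach — solvent dipoles are released to rotate freely, which is the
microscopic source of the entropy gain — and the normalized curves for
different dipole moments collapse.
"""
from dscft import (PairGeometry, SolventSpec, default_ion_pair, gamma_curve,
                   polarization_map, solve_fields)

ions = default_ion_pair()
seps = [6.0, 9.0, 15.0, 24.0, 45.0]

for mu in (0.5, 1.0):
    df = gamma_curve(seps, SolventSpec(mu_bar=mu), ions)
    g = df["gamma_excess"].to_numpy()
    print(f"mu_bar = {mu} D: Gamma/Gamma(15 sigma) =",
          " ".join(f"{v:.3f}" for v in g / g[-1]))
print("  (monotone rise with separation; curves nearly collapse)\n")

sol = solve_fields(PairGeometry(*ions, 9.0), SolventSpec(mu_bar=1.0))
df = polarization_map(sol, [0.0, 1.5, 3.0, 6.0], [-4.5, 0.0, 4.5],
                      normalize=True)
print("normalized |P| samples (radial_A, axial_A -> P/Pmax):")
for _, row in df.iterrows():
    print(f"  ({row['radial_A']:4.1f}, {row['axial_A']:5.1f}) -> "
          f"{row['P_normalized']:.4f}")
print("\n|P| peaks beside each ion and vanishes far away, where dipole"
      "\norientations are random.")
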