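# scstrain

Computational models of how protein-induced membrane strain drives the
formation of respiratory supercomplexes (SCs) — assemblies of Complex I
(CI) and the Complex III dimer (CIII₂) — in the inner mitochondrial
membrane (IMM). The package is aimed at membrane biophysicists and
structural bioinformaticians who want reusable, tested implementations of
the bespoke analyses in this problem area, each runnable on synthetic data
with known ground truth.

## What's inside

* **`scstrain.lattice`** — a 2D lattice statistical-mechanics model of
  CI/CIII₂ assembly. Energies in k_BT: an oriented specific contact
  E_specific ≤ 0, non-specific adjacency E_nonspecific ≥ 0, and a strain
  penalty E_strain per protein–lipid boundary site, so
  H = n_spec·E_spec + n_nonspec·E_nonspec + n_strain·E_strain.
  Exact enumeration (Z = Σ e^{−βE}, G = −β⁻¹ ln Z) on small grids,
  numba-accelerated Metropolis Monte Carlo with replica standard errors,
  and parameter sweeps.
* **`scstrain.packing`** — the crowded IMM as randomly packed rigid disks
  (H = ½ΣΣ k·max(0, rᵢ+rⱼ−d_ij), relaxed to zero overlap), edge-to-edge
  and quinone nearest-neighbour distance statistics, and the analytic
  quinone-pool and 2D diffusion-time (τ = r²/4D) estimates.
* **`scstrain.fields`** — gridded leaflet surfaces from particle frames;
  mean curvature H(x,y) in Monge gauge; Helfrich bending energy
  G_curv = ½κ Σ w(2H)²ΔA (κ = 20 k_BT); thickness PMF by Boltzmann
  inversion F(d) = −k_BT ln ρ(d) and the strain integral
  ∫ρ_protein(d)F(d)dd; lipid end-to-end lengths, quinone flip-flop times,
  density-enrichment maps, and Kirkwood–Fröhlich dielectric profiles
  ε = 1 + var M/(3ε₀k_BT·V).
* **`scstrain.cryoem`** — membrane-belt detection in density maps: protein
  subtraction, a double-sigmoid axial profile model, an MLP profile
  classifier trained on synthetic data, and per-column thickness/shift
  maps. MRC I/O via gemmi.
* **`scstrain.network`** — residue contact graphs (Cα within 7.5 Å in
  more than 50% of frames) and ligand-state difference graphs.
* **`scstrain.synthetic`** — seeded generators for all of the above:
  bilayer frames with prescribed height/thickness fields, telegraph
  leaflet trajectories, dipole snapshots, toy density volumes, and Cα
  trajectories with exact contact persistences.

A thin CLI (`scstrain lattice|pack|fields|cryoem|network|synth`) wraps the
library and writes a JSON run manifest per invocation; the importable API
plus the narrative scripts in `examples/` are the primary interface.

## Worked example

```bash
python examples/lattice_assembly.py
```

prints

```
4x4 grid, 1 CI + 1 CIII2, E_specific=-3 kBT, E_strain=+1 kBT
  exact SC fraction      : 0.5377 (Z = 40.0, G = -3.689 kBT)
  Monte Carlo SC fraction: 0.5403 +/- 0.0042

SC population vs specific interaction energy (6x6, 2 CI + 2 CIII2):
  E_specific = -4 kBT : 0.924  ####################################
  E_specific = -3 kBT : 0.760  ##############################
  E_specific = -2 kBT : 0.502  ####################
  E_specific = -1 kBT : 0.254  ##########
  E_specific = +0 kBT : 0.107  ####
```

The exact and sampled SC fractions agree within one standard error, and
the sweep shows the assembly threshold: once the specific CI–CIII₂
interaction weakens past about −2 k_BT relative to the strain drive, the
SC population collapses. The other scripts in `examples/` cover membrane
crowding and quinone pools (`membrane_crowding.py` prints the
216.4 nm² / 14.7 nm / 7.6 nm / 6.2-quinone patch bookkeeping), Helfrich
energetics against the analytic integral, flip-flop kinetics, dielectric
profiles, cryo-EM segmentation, and contact networks.

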