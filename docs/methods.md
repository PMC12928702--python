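# Methods

`scstrain` implements the bespoke numerical models behind a membrane-strain
account of respiratory supercomplex (SC) formation in the inner
mitochondrial membrane (IMM): a lattice statistical-mechanics model of
CI/CIII₂ assembly, a disk-packing model of protein crowding, continuum
membrane energetics (Helfrich bending plus a thickness potential of mean
force), Kirkwood–Fröhlich dielectric profiles, a cryo-EM membrane-belt
detector, and residue contact networks. Every analysis is exercised on
synthetic inputs with known ground truth; this note records the models,
their assumptions, the defaults that matter, and the places where design
was genuinely open.

## Lattice model of supercomplex assembly

Proteins (CI and the CIII₂ dimer) occupy sites of an N×N hard-walled grid,
each with an orientation g ∈ {North, East, South, West}. The
configurational energy, in units of k_BT, is

    H = n_spec·E_specific + n_nonspec·E_nonspecific + n_strain·E_strain

* a **specific contact** (counted once per pair) requires two proteins of
  unlike type on 4-adjacent sites whose orientations point at each other
  across the shared edge — the single oriented CI–CIII₂ binding interface;
* every other protein–protein adjacency is **non-specific**;
* **strain** is charged once per (protein site, vacant 4-neighbour) pair,
  so a lipid site wedged between two proteins is counted twice. Assembly
  always reduces the strained-lipid count, which is the mechanism coupling
  membrane strain to aggregation.

Defaults: E_specific = −3, E_nonspecific = +1, E_strain = +1 (k_BT), β = 1.
Sampling is Metropolis Monte Carlo with two symmetric moves (translate a
random protein to a uniformly random empty site; re-draw an orientation),
10% burn-in, stride-10 sampling, and replica-level standard errors; the
production configuration is 10⁷ iterations × 100 replicas, while tests use
10⁵-scale chains, which already agree with exact enumeration to ≲1 SE on
all small grids. Exact enumeration (positions × orientations, within-type
permutations collapsed) is available up to a configurable microstate cap
and is the oracle for every sampled observable. The inner loop is
numba-JIT-compiled; energies are recomputed per move, which is optimal at
the protein counts of interest (≤ ~10).

**Temperature dependence — a model limitation.** With the sign conventions
above (E_specific ≤ 0 ≤ E_nonspecific, E_strain > 0) one can show the SC
fraction is monotone *increasing* in β: relative to a separated pair, the
specific-contact weight is exp(β(2E_strain − E_specific)) and the
non-specific weight exp(β(2E_strain − E_nonspecific)), so
d(SC)/dβ ∝ x·c + b·(x − y) with x = 2E_strain − E_specific > 0 and
x − y = E_nonspecific − E_specific > 0. Heating therefore always melts the
SC population in this Hamiltonian, for dilute and crowded systems alike
(verified by enumeration and MC up to E_strain = 4). An entropic reading
of the strain term (strained lipids losing entropy, so the dimensionless
strain penalty is temperature-independent while the enthalpic contact
terms scale with β) does not change this conclusion. The opposite
direction — heating favouring the SC — appears only when E_strain < 0,
i.e. when protein–lipid contact is *favourable*, which in turn inverts the
strain-drives-assembly mechanism. Both temperature behaviours are pinned
by tests; the package keeps the positive-strain convention because it is
the one consistent with the assembly mechanism and with the observation
that weakening the strain term depresses the SC population.

## Disk-packing model of IMM crowding

Membrane proteins are rigid circles in a square box (side 163 nm) with the
soft-overlap Hamiltonian H = ½ ΣΣ k·max(0, rᵢ + rⱼ − d_ij),
k = 1 kcal mol⁻¹ nm⁻¹. Configurations are drawn uniformly and relaxed by
gradient descent until H < 10⁻⁶ kcal/mol; the relaxation moves all disks
simultaneously each sweep (step 0.1 nm per unit force/k), which reaches the
same zero-overlap endpoint as sequential updates but vectorises. Centres
are clamped to the box (disks may overhang the walls).

The default census — 291 proteins of total area 14,586 nm², 48,300 lipids
on 16,905 nm² of bilayer — fixes the box-level totals; the per-type split
(12 CI at r = 6 nm, 15 CIII₂ at 5 nm, 60 CIV at 4 nm, 80 CV at 4.5 nm,
80 carriers at 2.6 nm, 44 others at 4.0313 nm) is an editable, documented
stand-in whose only hard constraint is that the totals hold (the residual
radius is solved from the area constraint). Observables: pooled and
nearest-neighbour edge-to-edge distances (d_ij − rᵢ − rⱼ, floored at 0)
between protein types, and nearest distances from protein edges to point
quinones placed uniformly in the lipid area.

Analytic bookkeeping: at a 1% quinone mole fraction the pool holds
483 molecules; two proteins occupy 2·(16,905 + 14,586)/291 = 216.4 nm², a
square patch of edge 14.7 nm; the mean distance between two uniform points
in a unit square is (2 + √2 + 5·asinh 1)/15 = 0.5214 (reported as 0.52),
giving 0.52 × 14.7 = 7.6 nm between neighbouring proteins and
216.4 × 483/16,905 = 6.2 quinones per two-protein patch. The reported
chain deliberately reproduces the rounded printed arithmetic
(0.52 and 14.7 before multiplying). The 2D diffusion time is
τ = r²/4D, so shortening the substrate path from 12 to 7 nm cuts the
diffusion time to (7/12)² = 0.34 of its value, independent of D.

## Membrane surfaces and deformation energetics

Headgroup beads are projected onto a 2D grid (default 0.5 nm). Each cell
stores the mean N- and P-leaflet heights; the midplane is their mean and
the local thickness their difference. Cells with counts below 50% of the
median cell count are down-weighted linearly (w = count/(0.5·median),
capped at 1); empty cells are nearest-neighbour filled so derivatives are
defined everywhere, but carry w = 0 and contribute no energy. Leaflet
assignment uses a coarse (4 nm) local midplane with a global fallback for
cells too thin to contain both leaflets, and refuses inputs whose leaflet
separation is under 1 nm.

Mean curvature is evaluated in Monge gauge by second-order central
differences. The default formula is the standard divergence form
(cross term −2Z_xZ_yZ_{xy}); a `paper` switch flips that sign for
comparison, the two agreeing wherever the surface gradient vanishes or is
axis-aligned. The boundary ring is masked. Oracles: H = 0 on affine
surfaces to machine precision; |H| = 1/R on a hemisphere and
|H| = Ak²/2 at sinusoid crests, both within 5% at 0.5 nm resolution.

Energies per frame-set, summed over cells within a mask radius (default
20 nm) of the protein centre and rescaled to an effective area of
1000 nm²:

    G_curv  = ½ κ Σ w (2H)² ΔA,      κ = 20 k_BT = 11.85 kcal/mol
    G_thick = Σ w F(d) ΔA

with F(d) the thickness PMF from Boltzmann inversion,
F = −k_BT ln ρ(d), minimum shifted to zero, empty bins masked (never
interpolated). κ and the temperature are independent configuration values
(the 11.85 kcal/mol conversion corresponds to ~298 K while the default
analysis temperature is 310 K). Standard deviations come from a seeded
bootstrap over frames (B = 200 by default).

Because G_curv is quadratic in derivatives of a sampled field, per-cell
sampling noise biases it upward; it converges slowly and needs either many
frames per grid or mild Gaussian pre-smoothing of the height field
(`smooth_sigma`, default off; ~0.75 nm suppresses the noise bias at the
cost of slightly widening narrow deformations). The analytic-oracle tests
use noiseless generator frames aggregated 60 per grid, where the estimator
lands within ~5% of the exact Helfrich integral.

Protein-induced strain is the overlap integral
G_strain = ∫ ρ_protein(d) F(d) dd on the PMF bins; more than 1% of
probability mass outside the PMF support is an error rather than an
extrapolation.

Other observables: lipid-chain end-to-end lengths (first/last chain bead,
e.g. CA1–CA18, grouped per lipid, missing labels skipped and counted);
quinone flip-flop times (mean residence interval between leaflet changes,
censored stubs excluded, bootstrap CI over molecules); and density
enrichment maps (per-cell density divided by the mean density of a
user-defined bulk zone, requiring ≥100 bulk samples).

Dielectric profiles use the Kirkwood–Fröhlich relation
ε = 1 + var M/(3 ε₀ k_B T V), with M the summed charge-weighted positions
within a 0.2 nm probe sphere (volume V taken as the full sphere; probes
must be interior), component variances summed over snapshots, and bins
with fewer than 100 snapshots masked. Units are e·nm for dipoles; the
conversion to SI happens once, in one place.

## Cryo-EM membrane detection

The axial density of a membrane slab is modelled as a double sigmoid,
baseline + A[σ((z−z₁)/w₁) − σ((z−z₂)/w₂)]. A multilayer perceptron
(3×100 hidden units, ReLU, Adam, early stopping) is trained to separate
membrane-like from non-membrane axial profiles on synthetic data: 20,000
noisy double sigmoids against 120,000 negatives drawn from a documented
mixture (white noise, smoothed noise, single sigmoids, Gaussian bumps,
linear ramps), 25% held out. Generation ranges are versioned constants:
profile length 64 samples, slab thickness 25–55 samples, interface widths
1–4, baseline 0–0.3, per-profile min–max normalisation. Held-out accuracy
is ≥99% and reproducible across seeds to well under 1.5 percentage points.
Profiles are classified in *sample* units, so maps should be sampled at
roughly 1 Å along the membrane normal (or resampled) for physical slabs to
fall inside the trained thickness range.

Segmentation: density within a mask radius (default 4 Å) of the atomic
model is zeroed; each in-plane column's axial profile is normalised,
classified, and — if membrane-like — fitted with a least-squares double
sigmoid (moment-based initialisation; non-convergent columns are flagged
and dropped). Thickness is z₂ − z₁ per column and shift is the midpoint
relative to the global mean midpoint. On noiseless-to-moderate-noise toy
slabs the thickness is recovered well within half a voxel; a
generator-imposed thinning ring is detected as significantly thinner than
bulk by a Welch t-test. Maps are read and written as MRC2014/CCP4 via
gemmi.

## Contact networks

Residues are nodes; an edge connects two residues whose Cα atoms are
within 7.5 Å in strictly more than 50% of frames (the threshold is a
strict inequality by design). Neighbour search uses a KD tree per frame
and is tested for exact equality against an O(n²·frames) recount;
persistence is the exact frame fraction. Inter-chain edges are included.
Difference graphs partition the edge union of two states into
state-exclusive and shared sets.

## Synthetic data: what it emulates, and what it does not

The generators impose known fields rather than letting them emerge:

* **Bilayer frames** place lipids uniformly in-plane (excluding an
  optional rigid cylindrical inclusion) with headgroups at
  z = h(x,y) ± d(x,y)/2 for prescribed height/thickness fields (Gaussian
  bumps or callables), straight chain beads between head and midplane,
  optional quinones with a prescribed enrichment ring, and isotropic
  Gaussian positional noise. By default in-plane positions are redrawn
  every frame, emulating the lateral diffusion that decorrelates sub-nm
  cell occupancy between 1-ns frames — without it, most 0.5 nm cells are
  never sampled and the fill step poisons curvature estimates. A
  `resample_positions=False` mode keeps positions frozen so frames differ
  only by the noise stream. Reference thickness is 4.05 nm; the default
  lipid density (~0.67 nm² per lipid in-plane) matches fluid bilayers, and
  densities beyond close packing (0.4 nm²/lipid) are rejected.
* **Telegraph trajectories** are continuous-time two-state processes with
  exponential holding times (default mean 125 ns, 200 molecules × 10 μs,
  1 ns sampling) and fair-coin initial states.
* **Dipole snapshots** are zero-mean Gaussians with prescribed per-bin
  component variance.
* **Toy maps** are double-sigmoid slabs (midpoints optionally varying
  in-plane for tilts and thinning rings) plus Gaussian protein blobs and
  voxel noise, with the ground-truth membrane mask returned.
* **Cα trajectories** place residues on a 16 Å lattice and dock designated
  pairs to 5 Å in exactly the requested fraction of frames, guaranteeing
  all other pairs stay beyond 9 Å under 4σ jitter; infeasible geometry is
  rejected up front.

All generators draw from a single seeded generator per call and are
bit-reproducible. Passing tests on these inputs demonstrates estimator
correctness under the stated noise models — not that real coarse-grained
trajectories satisfy those models: real membranes have correlated
undulations, non-Gaussian noise, protein flexibility and composition
coupling that the generators deliberately omit, and trajectory-derived
headline numbers are out of scope by design.

## Problem sizes

Default test and verification sizes were chosen to make each statistical
check decisive at its stated tolerance: lattice chains of 5×10⁴–1.5×10⁵
iterations × 16 replicas against exact enumeration, 180 noiseless frames
(3 grids × 60) for the bending-energy oracle, 10⁵ samples for PMF
recovery, 10⁴ snapshots for the dielectric closed form, 200 molecules ×
10 μs for flip-flop, the full 20,000/120,000 profile set for the
classifier, and 50 residues × 100 frames for network equivalence.

## Known limitations

* The lattice model cannot reproduce a temperature-driven increase of the
  SC population under its stated sign conventions (analysis above).
* Helfrich energetics ignore lipid tilt and higher-order elastic terms;
  G_curv is noise-biased and needs generous sampling or smoothing.
* The packing model is static — no diffusion dynamics, no curvature
  coupling — and the per-type census is a constrained placeholder.
* The profile classifier operates in sample units and assumes an axial
  membrane normal.
* Multi-MODEL PDB output carries static topology; per-frame metadata
  (e.g. flip-flopping quinone leaflet labels) survives only the CSV
  layout.
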