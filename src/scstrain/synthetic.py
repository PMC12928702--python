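"""Synthetic generators with known ground truth for every pipeline stage.

The generators emulate the *shape* of the data the analyses consume — they
impose prescribed midplane-height, thickness, occupancy and kinetic fields
rather than letting them emerge from dynamics:

* bilayer particle frames with prescribed height/thickness fields and an
  embedded cylindrical inclusion (stand-in for coarse-grained trajectory
  frames around a membrane protein);
* two-state telegraph trajectories of quinone headgroup leaflet occupancy
  with a prescribed mean flip time;
* per-z-bin dipole-moment snapshots with prescribed component variance
  (input to the Kirkwood-Frohlich dielectric profile);
* toy cryo-EM volumes whose axial density follows a double-sigmoid membrane
  slab plus protein blobs;
* C-alpha trajectories with designated residue contacts at exact
  persistence fractions.

Every generator takes an explicit seed and is bit-reproducible for a fixed
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .particles import ParticleFrame

__all__ = [
    "DeformationSpec",
    "TelegraphSpec",
    "TelegraphTrajectory",
    "DipoleSampleSet",
    "ToyMapSpec",
    "ContactSpec",
    "make_membrane_frames",
    "make_q_trajectory",
    "make_dipole_snapshots",
    "make_toy_map",
    "make_ca_trajectory",
]

#: smallest physically sensible in-plane area per lipid (nm^2); densities
#: beyond this are rejected as exceeding close packing
MIN_AREA_PER_LIPID_NM2 = 0.4


def _gaussian_bumps(x, y, bumps):
    """Sum of isotropic Gaussian bumps (amplitude, width, cx, cy)."""
    out = np.zeros_like(np.asarray(x, dtype=float))
    for amp, width, cx, cy in bumps:
        out += amp * np.exp(-(((x - cx) ** 2 + (y - cy) ** 2) / (2.0 * width**2)))
    return out


@dataclass(frozen=True)
class DeformationSpec:
    """Prescription of a synthetic bilayer patch.

    The midplane height h(x,y) and thickness d(x,y) = d0 + dd(x,y) are
    given either as parametric Gaussian bumps [(amplitude nm, width nm,
    cx, cy), ...] or as callables on (x, y) arrays.  An optional rigid
    cylindrical inclusion excludes lipids from its footprint and is filled
    with protein beads.
    """

    box_x: float = 40.0
    box_y: float = 40.0
    d0: float = 4.05
    n_lipids_per_leaflet: int = 1600
    height_bumps: tuple = ()
    thickness_bumps: tuple = ()
    height_field: object = None  # callable (x, y) -> nm
    thickness_perturbation_field: object = None  # callable (x, y) -> nm
    inclusion: tuple | None = None  # (cx, cy, radius nm, belt nm)
    noise_sd: float = 0.05
    n_quinones: int = 0
    enrichment_ring: tuple | None = None  # (r_inner, r_outer, factor), needs inclusion
    chain_beads: int = 2
    chain_first_label: str = "CA1"
    chain_last_label: str = "CA18"
    #: redraw in-plane positions each frame (emulates lateral lipid diffusion,
    #: which decorrelates sub-nm cell occupancy between 1-ns frames); with
    #: False, frames share positions and differ only by the noise stream
    resample_positions: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.box_x <= 0 or self.box_y <= 0:
            raise ValueError("box lengths must be positive")
        if self.d0 <= 0:
            raise ValueError("reference thickness d0 must be positive")
        if self.n_lipids_per_leaflet < 4:
            raise ValueError("need at least 4 lipids per leaflet")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.chain_beads < 2:
            raise ValueError("chains need at least first and last beads")
        area = self.box_x * self.box_y
        if self.inclusion is not None:
            area -= math.pi * self.inclusion[2] ** 2
        if self.n_lipids_per_leaflet * MIN_AREA_PER_LIPID_NM2 > area:
            raise ValueError(
                f"{self.n_lipids_per_leaflet} lipids exceed close packing of the "
                f"available area ({area:.0f} nm^2)"
            )

    def height(self, x, y):
        if self.height_field is not None:
            return np.asarray(self.height_field(x, y), dtype=float)
        return _gaussian_bumps(x, y, self.height_bumps)

    def thickness(self, x, y):
        d = np.full_like(np.asarray(x, dtype=float), self.d0)
        if self.thickness_perturbation_field is not None:
            return d + np.asarray(self.thickness_perturbation_field(x, y), dtype=float)
        return d + _gaussian_bumps(x, y, self.thickness_bumps)


def _sample_xy_outside_inclusion(rng, n, spec: DeformationSpec, weight_ring=None):
    """Uniform in-plane points excluding the inclusion disk; optional ring
    density boost (r_inner, r_outer, factor) measured from the inclusion
    centre (or box centre without an inclusion)."""
    if spec.inclusion is not None:
        cx, cy, rad = spec.inclusion[0], spec.inclusion[1], spec.inclusion[2]
    else:
        cx, cy, rad = spec.box_x / 2.0, spec.box_y / 2.0, 0.0
    factor = 1.0
    if weight_ring is not None:
        r_in, r_out, factor = weight_ring
    out = np.empty((0, 2))
    while len(out) < n:
        cand = rng.uniform(0.0, 1.0, size=(4 * n + 64, 2)) * (spec.box_x, spec.box_y)
        r = np.hypot(cand[:, 0] - cx, cand[:, 1] - cy)
        keep = r >= rad
        if weight_ring is not None:
            w = np.where((r >= r_in) & (r < r_out), factor, 1.0) / max(factor, 1.0)
            keep &= rng.uniform(size=len(cand)) < w
        out = np.vstack([out, cand[keep]])
    return out[:n]


def _inclusion_beads(spec: DeformationSpec) -> np.ndarray:
    """Beads filling the inclusion cylinder on a 0.4 nm grid, 5 z-levels."""
    cx, cy, rad = spec.inclusion[0], spec.inclusion[1], spec.inclusion[2]
    ax = np.arange(cx - rad, cx + rad + 1e-9, 0.4)
    ay = np.arange(cy - rad, cy + rad + 1e-9, 0.4)
    gx, gy = np.meshgrid(ax, ay, indexing="ij")
    inside = (gx - cx) ** 2 + (gy - cy) ** 2 <= rad**2
    xy = np.stack([gx[inside], gy[inside]], axis=1)
    h = spec.height(xy[:, 0], xy[:, 1])
    levels = np.linspace(-spec.d0 / 2.0, spec.d0 / 2.0, 5)
    pos = np.concatenate(
        [np.column_stack([xy, h + lv]) for lv in levels], axis=0
    )
    return pos


def make_membrane_frames(spec: DeformationSpec, n_frames: int = 1) -> list[ParticleFrame]:
    """Generate bilayer frames realising the spec's height/thickness fields.

    In-plane lipid positions are drawn once per spec (fluid, unstructured
    membrane); successive frames differ only by the Gaussian positional
    noise realisation.  Headgroup beads sit at z = h(x,y) +/- d(x,y)/2 for
    the N (upper) and P (lower) leaflets; each lipid carries a straight
    chain of beads from its head to the midplane, labelled
    ``chain_first_label`` ... ``chain_last_label``.
    """
    rng = np.random.default_rng(spec.seed)
    n_per = spec.n_lipids_per_leaflet

    def draw_inplane():
        xy = {
            "N": _sample_xy_outside_inclusion(rng, n_per, spec),
            "P": _sample_xy_outside_inclusion(rng, n_per, spec),
        }
        q_xy = (
            _sample_xy_outside_inclusion(
                rng, spec.n_quinones, spec, spec.enrichment_ring
            )
            if spec.n_quinones
            else np.empty((0, 2))
        )
        q_leaflet = rng.choice(["N", "P"], size=len(q_xy))
        return xy, q_xy, q_leaflet

    xy, q_xy, q_leaflet = draw_inplane()
    incl = _inclusion_beads(spec) if spec.inclusion is not None else np.empty((0, 3))
    box = np.array([spec.box_x, spec.box_y, 4.0 * spec.d0])

    frames = []
    m = spec.chain_beads
    for i_frame in range(n_frames):
        if spec.resample_positions and i_frame > 0:
            xy, q_xy, q_leaflet = draw_inplane()
        pos, cat, leaf, lid, lab = [], [], [], [], []
        lipid_counter = 0
        for leaflet, sign in (("N", +1.0), ("P", -1.0)):
            pts = xy[leaflet]
            h = spec.height(pts[:, 0], pts[:, 1])
            d = spec.thickness(pts[:, 0], pts[:, 1])
            z_head = h + sign * d / 2.0
            heads = np.column_stack([pts, z_head])
            pos.append(heads)
            n_l = len(pts)
            cat += ["lipid-head"] * n_l
            leaf += [leaflet] * n_l
            ids = np.arange(lipid_counter, lipid_counter + n_l)
            lid.append(ids)
            lab += [""] * n_l
            # straight chain: bead j interpolates head -> midplane
            for j in range(m):
                t = j / (m - 1)
                zc = z_head * (1 - t) + h * t
                pos.append(np.column_stack([pts, zc]))
                cat += ["lipid-chain"] * n_l
                leaf += [""] * n_l
                lid.append(ids)
                if j == 0:
                    lab += [spec.chain_first_label] * n_l
                elif j == m - 1:
                    lab += [spec.chain_last_label] * n_l
                else:
                    lab += [f"CB{j + 1}"] * n_l
            lipid_counter += n_l
        if len(q_xy):
            hq = spec.height(q_xy[:, 0], q_xy[:, 1])
            dq = spec.thickness(q_xy[:, 0], q_xy[:, 1])
            sgn = np.where(q_leaflet == "N", 1.0, -1.0)
            pos.append(np.column_stack([q_xy, hq + sgn * dq / 2.0]))
            cat += ["quinone-head"] * len(q_xy)
            leaf += list(q_leaflet)
            lid.append(np.full(len(q_xy), -1))
            lab += [""] * len(q_xy)
        if len(incl):
            pos.append(incl)
            cat += ["protein"] * len(incl)
            leaf += [""] * len(incl)
            lid.append(np.full(len(incl), -1))
            lab += [""] * len(incl)
        pos = np.concatenate(pos, axis=0)
        if spec.noise_sd > 0:
            pos = pos + rng.normal(scale=spec.noise_sd, size=pos.shape)
        frames.append(
            ParticleFrame(
                positions=pos,
                category=np.array(cat, dtype=object),
                leaflet=np.array(leaf, dtype=object),
                lipid_id=np.concatenate(lid),
                chain_label=np.array(lab, dtype=object),
                box=box,
            )
        )
    return frames


# ---------------------------------------------------------------------------
# telegraph (leaflet flip-flop) trajectories


@dataclass(frozen=True)
class TelegraphSpec:
    n_molecules: int = 200
    timestep_ns: float = 1.0
    total_time_ns: float = 10_000.0
    mean_flip_time_ns: float = 125.0
    seed: int = 0

    def __post_init__(self):
        if self.mean_flip_time_ns <= 0:
            raise ValueError("mean flip time must be positive")
        if self.total_time_ns <= self.timestep_ns:
            raise ValueError("total time must exceed the timestep")
        if self.n_molecules < 1:
            raise ValueError("need at least one molecule")


@dataclass
class TelegraphTrajectory:
    """Sampled leaflet labels, shape (n_molecules, n_steps); 0 = P, 1 = N."""

    labels: np.ndarray
    timestep_ns: float


def make_q_trajectory(spec: TelegraphSpec) -> TelegraphTrajectory:
    """Continuous-time two-state telegraph processes sampled at the timestep.

    Holding times in each leaflet are exponential with the prescribed mean;
    initial states are fair coin flips, so the stationary occupancy is
    0.5/0.5.  An infinite (or overflowing) mean flip time yields constant
    trajectories.
    """
    rng = np.random.default_rng(spec.seed)
    t_grid = np.arange(0.0, spec.total_time_ns, spec.timestep_ns)
    n_steps = len(t_grid)
    labels = np.empty((spec.n_molecules, n_steps), dtype=np.int8)
    tau = spec.mean_flip_time_ns
    for i in range(spec.n_molecules):
        start = int(rng.integers(0, 2))
        if not np.isfinite(tau):
            labels[i] = start
            continue
        n_exp = max(16, int(2 * spec.total_time_ns / tau) + 16)
        flips = np.cumsum(rng.exponential(tau, size=n_exp))
        while flips[-1] < spec.total_time_ns:
            flips = np.concatenate(
                [flips, flips[-1] + np.cumsum(rng.exponential(tau, size=n_exp))]
            )
        n_before = np.searchsorted(flips, t_grid, side="right")
        labels[i] = (start + n_before) % 2
    return TelegraphTrajectory(labels=labels, timestep_ns=spec.timestep_ns)


# ---------------------------------------------------------------------------
# dipole snapshots


@dataclass
class DipoleSampleSet:
    """Per-z-bin local dipole moment samples M (e nm), shape (n, nz, 3)."""

    samples: np.ndarray
    z_centers_nm: np.ndarray
    probe_radius_nm: float = 0.2


def make_dipole_snapshots(
    variance_per_component,
    n_snapshots: int,
    seed: int,
    z_centers_nm=None,
    probe_radius_nm: float = 0.2,
) -> DipoleSampleSet:
    """Zero-mean Gaussian dipole vectors with prescribed per-z variance.

    ``variance_per_component`` has shape (nz,) (shared by x,y,z components)
    or (nz, 3); units e^2 nm^2 per component.
    """
    var = np.asarray(variance_per_component, dtype=float)
    if np.any(var < 0):
        raise ValueError("variances must be non-negative")
    if var.ndim == 1:
        var = np.repeat(var[:, None], 3, axis=1)
    nz = var.shape[0]
    rng = np.random.default_rng(seed)
    samples = rng.normal(size=(n_snapshots, nz, 3)) * np.sqrt(var)[None, :, :]
    if z_centers_nm is None:
        z_centers_nm = np.arange(nz, dtype=float)
    return DipoleSampleSet(
        samples=samples,
        z_centers_nm=np.asarray(z_centers_nm, dtype=float),
        probe_radius_nm=probe_radius_nm,
    )


# ---------------------------------------------------------------------------
# toy cryo-EM maps


@dataclass(frozen=True)
class ToyMapSpec:
    """Toy voxel map: double-sigmoid membrane slab + protein blobs + noise.

    ``z1``/``z2`` (A) are the sigmoid midpoints of the two membrane
    interfaces; scalars give a flat slab, callables on (x, y) (A) give
    tilted or locally thinned slabs.
    """

    shape: tuple = (48, 48, 64)
    voxel_size: float = 2.0  # A
    z1: object = 40.0
    z2: object = 80.0
    w1: float = 4.0
    w2: float = 4.0
    amplitude: float = 1.0
    baseline: float = 0.0
    blobs: tuple = ()  # ((x, y, z, radius A, amplitude), ...)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")
        if self.w1 <= 0 or self.w2 <= 0:
            raise ValueError("sigmoid widths must be positive")
        zmax = self.shape[2] * self.voxel_size
        z1s = self.z1 if np.isscalar(self.z1) else None
        z2s = self.z2 if np.isscalar(self.z2) else None
        if z1s is not None and z2s is not None:
            if z2s <= z1s:
                raise ValueError("z2 must exceed z1")
            if z1s < 0 or z2s > zmax:
                raise ValueError("membrane slab lies outside the voxel grid")


def make_toy_map(spec: ToyMapSpec):
    """Return (CryoMap, voxel ground-truth membrane mask).

    The mask marks voxels between the two interface midpoints where the
    slab amplitude is non-zero.
    """
    from .cryoem import CryoMap

    nx, ny, nz = spec.shape
    vs = spec.voxel_size
    x = (np.arange(nx) + 0.5) * vs
    y = (np.arange(ny) + 0.5) * vs
    z = (np.arange(nz) + 0.5) * vs
    gx, gy = np.meshgrid(x, y, indexing="ij")
    z1 = spec.z1(gx, gy) if callable(spec.z1) else np.full_like(gx, spec.z1)
    z2 = spec.z2(gx, gy) if callable(spec.z2) else np.full_like(gx, spec.z2)
    if np.any(z2 <= z1):
        raise ValueError("z2 must exceed z1 everywhere")
    if np.any(z1 < 0) or np.any(z2 > nz * vs):
        raise ValueError("membrane slab lies outside the voxel grid")
    zz = z[None, None, :]
    # per-column double sigmoid (vectorised over the in-plane grid)
    vol = spec.baseline + spec.amplitude * (
        1.0 / (1.0 + np.exp(-(zz - z1[..., None]) / spec.w1))
        - 1.0 / (1.0 + np.exp(-(zz - z2[..., None]) / spec.w2))
    )
    for bx, by, bz, rad, amp in spec.blobs:
        r2 = (gx[..., None] - bx) ** 2 + (gy[..., None] - by) ** 2 + (zz - bz) ** 2
        vol = vol + amp * np.exp(-r2 / (2.0 * (rad / 2.0) ** 2))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(scale=spec.noise_sd, size=vol.shape)
    mask = (
        (zz >= z1[..., None]) & (zz <= z2[..., None]) & (spec.amplitude > 0)
    )
    return (
        CryoMap(data=vol.astype(np.float32), voxel_size=vs, origin=(0.0, 0.0, 0.0)),
        mask,
    )


# ---------------------------------------------------------------------------
# C-alpha trajectories with designated persistent contacts


@dataclass(frozen=True)
class ContactSpec:
    """Designated contacts: [(res_i, res_j, persistence fraction), ...]."""

    n_residues: int = 10
    n_frames: int = 100
    contacts: tuple = ()
    jitter_sd: float = 0.3  # A
    seed: int = 0
    contact_distance: float = 5.0  # A, docked pair separation
    grid_spacing: float = 16.0  # A, home-position lattice

    def __post_init__(self):
        if self.n_residues < 2:
            raise ValueError("need at least two residues")
        seen = set()
        for i, j, p in self.contacts:
            if not (0.0 <= p <= 1.0):
                raise ValueError("persistence fractions must lie in [0, 1]")
            if not (0 <= i < self.n_residues and 0 <= j < self.n_residues) or i == j:
                raise ValueError(f"invalid contact pair ({i}, {j})")
            if i in seen or j in seen:
                raise ValueError("a residue may appear in only one designated pair")
            seen.update((i, j))
        # geometric feasibility: docked pairs must stay < 7.5 A and every
        # other pair > 9 A under 4-sigma jitter
        margin = 4.0 * self.jitter_sd * math.sqrt(2.0)
        if self.contact_distance + margin >= 7.5:
            raise ValueError("jitter too large: docked pairs may exceed 7.5 A")
        if self.grid_spacing - self.contact_distance - margin <= 9.0:
            raise ValueError("grid spacing too small for the >9 A guarantee")


def make_ca_trajectory(spec: ContactSpec) -> np.ndarray:
    """C-alpha positions, shape (n_frames, n_residues, 3), in Angstrom.

    Residues live on a cubic lattice of ``grid_spacing``.  For a designated
    pair (i, j, p), residue j is docked ``contact_distance`` from residue i
    in exactly round(p * n_frames) randomly chosen frames and sits at its
    own lattice home otherwise, so the measured contact persistence equals
    the target within one frame.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    side = math.ceil(n ** (1.0 / 3.0))
    idx = np.arange(n)
    home = (
        np.stack(
            [idx % side, (idx // side) % side, idx // (side * side)], axis=1
        ).astype(float)
        * spec.grid_spacing
    )
    traj = np.repeat(home[None, :, :], spec.n_frames, axis=0)
    for i, j, p in spec.contacts:
        n_in = int(round(p * spec.n_frames))
        docked = rng.choice(spec.n_frames, size=n_in, replace=False)
        direction = home[j] - home[i]
        direction = direction / np.linalg.norm(direction)
        traj[docked, j] = home[i] + spec.contact_distance * direction
    if spec.jitter_sd > 0:
        jitter = rng.normal(scale=spec.jitter_sd, size=traj.shape)
        np.clip(jitter, -4.0 * spec.jitter_sd, 4.0 * spec.jitter_sd, out=jitter)
        traj = traj + jitter
    return traj
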