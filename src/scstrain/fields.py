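"""Gridded membrane surfaces and deformation observables.

Particle frames are projected onto a 2D grid (default 0.5 nm resolution);
the midplane height Z(x,y) is the mean of the N- and P-leaflet headgroup
heights per cell and the local thickness is their difference.  From these
fields the module computes:

* mean curvature H(x,y) of the midplane (Monge gauge, central finite
  differences) and the Helfrich bending energy
  G_curv = 1/2 kappa sum w (2H)^2 dA,
* the thickness potential of mean force F(d) = -kB T ln rho(d) by Boltzmann
  inversion of a reference thickness distribution, the thickness
  deformation energy G_thick = sum w F(d) dA, and the protein-induced
  strain integral G_strain = int rho_protein(d) F(d) dd,
* lipid-chain end-to-end lengths, quinone leaflet flip-flop times, local
  density enrichment maps, and Kirkwood-Frohlich dielectric profiles from
  local dipole-moment fluctuations.

Low-occupancy grid cells (count below half the median cell count) are
down-weighted linearly by their relative count; empty interior cells are
nearest-neighbour filled for derivative continuity but carry zero weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .constants import (
    DEFAULT_TEMPERATURE,
    E_CHARGE,
    EPS0_SI,
    GRID_RESOLUTION_NM,
    KAPPA_KCAL,
    KB_KCAL,
    KB_SI,
    MASK_RADIUS_NM,
    NORMALIZATION_AREA_NM2,
    PROBE_RADIUS_NM,
)
from .particles import ParticleFrame
from .synthetic import DipoleSampleSet, TelegraphTrajectory

__all__ = [
    "SurfaceGrid",
    "ThicknessPMF",
    "EnergyDecomposition",
    "DielectricProfile",
    "assign_leaflets",
    "grid_surfaces",
    "shift_map",
    "mean_curvature",
    "thickness_pmf",
    "strain_energy",
    "deformation_energies",
    "end_to_end",
    "flipflop_times",
    "density_enrichment",
    "local_dipole_moments",
    "dielectric_profile",
]


# ---------------------------------------------------------------------------
# leaflet assignment


def assign_leaflets(
    frame: ParticleFrame, coarse_resolution: float = 4.0, min_separation: float = 1.0
) -> ParticleFrame:
    """Label headgroup particles N (upper) or P (lower) by their z relative
    to a local midplane estimate on a coarse in-plane grid.

    Raises if the input does not contain two separable leaflets (mean
    leaflet separation below ``min_separation`` nm).
    """
    heads = np.isin(frame.category, ["lipid-head", "quinone-head"])
    if not heads.any():
        raise ValueError("no headgroup particles to assign")
    pos = frame.positions[heads]
    # local midplane: per coarse cell, midpoint of the z range
    ix = np.floor(pos[:, 0] / coarse_resolution).astype(int)
    iy = np.floor(pos[:, 1] / coarse_resolution).astype(int)
    key = ix * 100_000 + iy
    mid = np.empty(len(pos))
    global_mid = 0.5 * (pos[:, 2].min() + pos[:, 2].max())
    for k in np.unique(key):
        sel = key == k
        zs = pos[sel, 2]
        # cells too thin to contain both leaflets fall back to the global mid
        if zs.max() - zs.min() < min_separation:
            mid[sel] = global_mid
        else:
            mid[sel] = 0.5 * (zs.min() + zs.max())
    upper = pos[:, 2] >= mid
    if upper.all() or (~upper).all():
        raise ValueError("only one leaflet present")
    sep = pos[upper, 2].mean() - pos[~upper, 2].mean()
    if sep < min_separation:
        raise ValueError(
            f"leaflet separation {sep:.2f} nm below {min_separation} nm: "
            "input looks single-leaflet"
        )
    leaflet = frame.leaflet.copy()
    leaflet[np.flatnonzero(heads)[upper]] = "N"
    leaflet[np.flatnonzero(heads)[~upper]] = "P"
    return ParticleFrame(
        positions=frame.positions,
        category=frame.category,
        leaflet=leaflet,
        lipid_id=frame.lipid_id,
        chain_label=frame.chain_label,
        box=frame.box,
    )


# ---------------------------------------------------------------------------
# surface gridding


@dataclass
class SurfaceGrid:
    """Per-cell leaflet heights, midplane, thickness, counts and weights."""

    resolution: float
    x_centers: np.ndarray  # (nx,)
    y_centers: np.ndarray  # (ny,)
    n_height: np.ndarray  # (nx, ny)
    p_height: np.ndarray
    midplane: np.ndarray
    thickness: np.ndarray
    count: np.ndarray
    weight: np.ndarray
    filled: np.ndarray  # cells that were nearest-neighbour interpolated

    @property
    def cell_area(self) -> float:
        return self.resolution**2


def _bin_mean(xy, z, x_edges, y_edges):
    nx, ny = len(x_edges) - 1, len(y_edges) - 1
    ix = np.clip(np.searchsorted(x_edges, xy[:, 0], side="right") - 1, 0, nx - 1)
    iy = np.clip(np.searchsorted(y_edges, xy[:, 1], side="right") - 1, 0, ny - 1)
    s = np.zeros((nx, ny))
    c = np.zeros((nx, ny))
    np.add.at(s, (ix, iy), z)
    np.add.at(c, (ix, iy), 1.0)
    return s, c


def _nn_fill(a: np.ndarray, invalid: np.ndarray) -> np.ndarray:
    if not invalid.any():
        return a
    idx = ndimage.distance_transform_edt(
        invalid, return_distances=False, return_indices=True
    )
    return a[tuple(idx)]


def grid_surfaces(
    frames: list[ParticleFrame] | ParticleFrame,
    resolution: float = GRID_RESOLUTION_NM,
    box=None,
) -> SurfaceGrid:
    """Project headgroup beads onto a 2D grid and build the surface fields.

    Z = (N + P)/2, d = N - P per cell; cells with counts below 50% of the
    median count get weight count/(0.5 * median); empty cells are
    nearest-neighbour filled with weight 0.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if isinstance(frames, ParticleFrame):
        frames = [frames]
    if box is None:
        box = frames[0].box
    if box is None:
        allpos = np.vstack([f.positions for f in frames])
        box = allpos.max(axis=0)
    nx = max(int(round(box[0] / resolution)), 1)
    ny = max(int(round(box[1] / resolution)), 1)
    x_edges = np.linspace(0.0, box[0], nx + 1)
    y_edges = np.linspace(0.0, box[1], ny + 1)
    sums = {"N": np.zeros((nx, ny)), "P": np.zeros((nx, ny))}
    counts = {"N": np.zeros((nx, ny)), "P": np.zeros((nx, ny))}
    seen_both = False
    for fr in frames:
        for leaf in ("N", "P"):
            sel = (fr.category == "lipid-head") & (fr.leaflet == leaf)
            if not sel.any():
                continue
            s, c = _bin_mean(fr.positions[sel, :2], fr.positions[sel, 2], x_edges, y_edges)
            sums[leaf] += s
            counts[leaf] += c
    if counts["N"].sum() == 0 or counts["P"].sum() == 0:
        raise ValueError("need lipid headgroups in both leaflets")
    with np.errstate(invalid="ignore", divide="ignore"):
        n_h = sums["N"] / counts["N"]
        p_h = sums["P"] / counts["P"]
    count = counts["N"] + counts["P"]
    empty = (counts["N"] == 0) | (counts["P"] == 0)
    n_h = _nn_fill(n_h, ~np.isfinite(n_h))
    p_h = _nn_fill(p_h, ~np.isfinite(p_h))
    occupied = count[~empty]
    median = np.median(occupied) if len(occupied) else 0.0
    if median > 0:
        weight = np.minimum(1.0, count / (0.5 * median))
    else:
        weight = np.zeros_like(count)
    weight[empty] = 0.0
    mid = 0.5 * (n_h + p_h)
    thick = n_h - p_h
    return SurfaceGrid(
        resolution=resolution,
        x_centers=0.5 * (x_edges[:-1] + x_edges[1:]),
        y_centers=0.5 * (y_edges[:-1] + y_edges[1:]),
        n_height=n_h,
        p_height=p_h,
        midplane=mid,
        thickness=thick,
        count=count,
        weight=weight,
        filled=empty,
    )


def shift_map(grid: SurfaceGrid) -> np.ndarray:
    """Midplane height relative to its area-weighted mean (mean shift = 0)."""
    w = grid.weight
    if w.sum() == 0:
        raise ValueError("grid has no weighted cells")
    mean = (grid.midplane * w).sum() / w.sum()
    return grid.midplane - mean


# ---------------------------------------------------------------------------
# curvature


def mean_curvature(
    grid_or_z, resolution: float | None = None, formula: str = "standard"
) -> np.ndarray:
    """Mean curvature H(x,y) (nm^-1) of a height field in Monge gauge.

    Central second-order finite differences; the boundary ring is NaN.
    ``formula='standard'`` uses the divergence form with the -2 Zx Zy Zxy
    cross term; ``formula='paper'`` flips that sign (the two agree wherever
    the surface is axis-aligned or the gradient vanishes).
    """
    if isinstance(grid_or_z, SurfaceGrid):
        z = grid_or_z.midplane
        resolution = grid_or_z.resolution
    else:
        z = np.asarray(grid_or_z, dtype=float)
        if resolution is None:
            raise ValueError("resolution required for a bare height array")
    if z.shape[0] < 5 or z.shape[1] < 5:
        raise ValueError("grid must be at least 5x5 for curvature")
    zx, zy = np.gradient(z, resolution, edge_order=2)
    zxx = np.gradient(zx, resolution, axis=0, edge_order=2)
    zxy = np.gradient(zx, resolution, axis=1, edge_order=2)
    zyy = np.gradient(zy, resolution, axis=1, edge_order=2)
    sign = -2.0 if formula == "standard" else 2.0
    if formula not in ("standard", "paper"):
        raise ValueError("formula must be 'standard' or 'paper'")
    num = (1.0 + zx**2) * zyy + (1.0 + zy**2) * zxx + sign * zx * zy * zxy
    den = 2.0 * (1.0 + zx**2 + zy**2) ** 1.5
    h = num / den
    h[0, :] = h[-1, :] = np.nan
    h[:, 0] = h[:, -1] = np.nan
    return h


# ---------------------------------------------------------------------------
# thickness PMF and strain


@dataclass
class ThicknessPMF:
    """Boltzmann-inverted free energy of the membrane thickness."""

    bin_edges: np.ndarray  # (nb+1,) nm
    density: np.ndarray  # (nb,) normalised to sum * dz = 1
    free_energy: np.ndarray  # (nb,) kcal/mol, NaN on empty bins, min = 0
    temperature: float

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def evaluate(self, d: np.ndarray) -> np.ndarray:
        """F(d) by linear interpolation over the occupied bins."""
        valid = np.isfinite(self.free_energy)
        return np.interp(
            d, self.bin_centers[valid], self.free_energy[valid],
            left=np.nan, right=np.nan,
        )


def thickness_pmf(
    samples,
    temperature: float = DEFAULT_TEMPERATURE,
    bin_width: float = 0.05,
    bin_edges=None,
) -> ThicknessPMF:
    """F(d) = -kB T ln rho(d) from a thickness sample, minimum shifted to 0.

    Empty bins inside the support are masked (NaN), never interpolated.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if len(samples) < 1000:
        raise ValueError("need at least 10^3 thickness samples")
    if bin_edges is None:
        lo, hi = samples.min(), samples.max()
        if hi - lo < bin_width:  # degenerate single-valued sample
            lo, hi = lo - bin_width, hi + bin_width
        bin_edges = np.arange(lo, hi + bin_width, bin_width)
    counts, bin_edges = np.histogram(samples, bins=bin_edges)
    dz = bin_edges[1] - bin_edges[0]
    rho = counts / counts.sum() / dz
    kbt = KB_KCAL * temperature
    with np.errstate(divide="ignore"):
        f = np.where(rho > 0, -kbt * np.log(np.where(rho > 0, rho, 1.0)), np.nan)
    f = f - np.nanmin(f)
    return ThicknessPMF(
        bin_edges=np.asarray(bin_edges, dtype=float),
        density=rho,
        free_energy=f,
        temperature=temperature,
    )


def strain_energy(protein_samples, pmf: ThicknessPMF, max_outside: float = 0.01) -> float:
    """Protein-zone strain G = int rho_protein(d) F(d) dd on the PMF bins.

    ``protein_samples`` is the thickness sample measured in the protein
    zone; it is histogrammed on the PMF's bins.  More than ``max_outside``
    probability mass outside the PMF support is an error.
    """
    s = np.asarray(protein_samples, dtype=float).ravel()
    counts, _ = np.histogram(s, bins=pmf.bin_edges)
    outside = len(s) - counts.sum()
    valid = np.isfinite(pmf.free_energy)
    outside += counts[~valid].sum()
    if outside > max_outside * len(s):
        raise ValueError(
            f"{outside / len(s):.1%} of the protein-zone mass lies outside "
            "the PMF support"
        )
    dz = pmf.bin_width
    rho_p = counts / counts.sum() / dz
    return float(np.sum(rho_p[valid] * pmf.free_energy[valid]) * dz)


# ---------------------------------------------------------------------------
# deformation energies


@dataclass
class EnergyDecomposition:
    g_curv: float  # kcal/mol per normalization area
    g_curv_sd: float
    g_thick: float | None  # None when no PMF was supplied
    g_thick_sd: float | None
    kappa: float
    mask_radius: float
    normalization_area: float
    n_frames: int
    extras: dict = field(default_factory=dict)


def deformation_energies(
    frame_grids: list[SurfaceGrid],
    pmf: ThicknessPMF | None = None,
    kappa: float = KAPPA_KCAL,
    mask_radius: float = MASK_RADIUS_NM,
    center=None,
    normalization_area: float = NORMALIZATION_AREA_NM2,
    bootstrap: int = 200,
    seed: int = 0,
    curvature_formula: str = "standard",
    smooth_sigma: float = 0.0,
) -> EnergyDecomposition:
    """Helfrich bending and thickness deformation energies with bootstrap SDs.

    Each frame's grid contributes G_curv = 1/2 kappa sum w (2H)^2 dA and
    G_thick = sum w F(d) dA over cells within ``mask_radius`` of ``center``
    (grid centre by default), rescaled to the effective membrane area
    ``normalization_area``.  SDs come from resampling frames with
    replacement.
    """
    if len(frame_grids) < 2 and bootstrap > 0:
        raise ValueError("bootstrap needs at least two frames")
    g = frame_grids[0]
    gx, gy = np.meshgrid(g.x_centers, g.y_centers, indexing="ij")
    if center is None:
        center = (g.x_centers.mean(), g.y_centers.mean())
    in_mask = (gx - center[0]) ** 2 + (gy - center[1]) ** 2 <= mask_radius**2
    per_curv, per_thick = [], []
    for fg in frame_grids:
        if smooth_sigma > 0:
            # mild Gaussian pre-smoothing of the height field suppresses the
            # positive (2H)^2 bias from per-cell sampling noise
            z = ndimage.gaussian_filter(
                fg.midplane, sigma=smooth_sigma / fg.resolution, mode="nearest"
            )
            h = mean_curvature(z, fg.resolution, formula=curvature_formula)
        else:
            h = mean_curvature(fg, formula=curvature_formula)
        da = fg.cell_area
        cell_ok = in_mask & np.isfinite(h)
        w = fg.weight
        area_eff = (w * da)[cell_ok].sum()
        if area_eff == 0:
            raise ValueError("mask contains no weighted cells")
        gc = 0.5 * kappa * (w * (2.0 * h) ** 2 * da)[cell_ok].sum()
        per_curv.append(gc * normalization_area / area_eff)
        if pmf is not None:
            f = pmf.evaluate(fg.thickness)
            ok = cell_ok & np.isfinite(f)
            area_t = (w * da)[ok].sum()
            gt = (w * np.where(ok, f, 0.0) * da)[ok].sum()
            per_thick.append(gt * normalization_area / area_t)
    per_curv = np.asarray(per_curv)
    per_thick = np.asarray(per_thick) if pmf is not None else None
    rng = np.random.default_rng(seed)
    nf = len(frame_grids)
    if bootstrap > 0:
        idx = rng.integers(0, nf, size=(bootstrap, nf))
        curv_sd = float(per_curv[idx].mean(axis=1).std(ddof=1))
        thick_sd = (
            float(per_thick[idx].mean(axis=1).std(ddof=1)) if pmf is not None else None
        )
    else:
        curv_sd, thick_sd = 0.0, (0.0 if pmf is not None else None)
    return EnergyDecomposition(
        g_curv=float(per_curv.mean()),
        g_curv_sd=curv_sd,
        g_thick=float(per_thick.mean()) if pmf is not None else None,
        g_thick_sd=thick_sd,
        kappa=kappa,
        mask_radius=mask_radius,
        normalization_area=normalization_area,
        n_frames=nf,
        extras={
            "per_frame_g_curv": per_curv,
            "per_frame_g_thick": per_thick,
            "thickness_pmf_missing": pmf is None,
        },
    )


# ---------------------------------------------------------------------------
# chain end-to-end lengths


def end_to_end(
    frame: ParticleFrame, first_label: str = "CA1", last_label: str = "CA18"
) -> dict:
    """Per-chain Euclidean first-to-last bead distances, grouped by lipid.

    Chains missing either label are skipped and counted.
    """
    first = frame.chain_label == first_label
    last = frame.chain_label == last_label
    lengths, lipid_ids = [], []
    skipped = 0
    ids = np.unique(frame.lipid_id[(first | last) & (frame.lipid_id >= 0)])
    for lid in ids:
        a = frame.positions[first & (frame.lipid_id == lid)]
        b = frame.positions[last & (frame.lipid_id == lid)]
        if len(a) == 0 or len(b) == 0 or len(a) != len(b):
            skipped += 1
            continue
        lengths.extend(np.linalg.norm(a - b, axis=1))
        lipid_ids.extend([lid] * len(a))
    return {
        "lengths_nm": np.asarray(lengths),
        "lipid_id": np.asarray(lipid_ids, dtype=int),
        "n_skipped": skipped,
    }


# ---------------------------------------------------------------------------
# flip-flop times


def flipflop_times(
    traj: TelegraphTrajectory | np.ndarray,
    timestep_ns: float | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> dict:
    """Mean leaflet residence time (ns) pooled over molecules.

    Residence intervals are the gaps between successive leaflet changes;
    the censored stubs before the first and after the last transition are
    excluded.  The confidence interval is a bootstrap over molecules.  With
    no transitions at all the total observation time is reported as a
    censored lower bound (``censored=True``).
    """
    if isinstance(traj, TelegraphTrajectory):
        labels, dt = traj.labels, traj.timestep_ns
    else:
        labels = np.atleast_2d(np.asarray(traj))
        if timestep_ns is None:
            raise ValueError("timestep_ns required for a bare label array")
        dt = timestep_ns
    per_mol = []
    for row in labels:
        change = np.flatnonzero(np.diff(row) != 0) + 1
        if len(change) < 2:
            per_mol.append(np.empty(0))
            continue
        per_mol.append(np.diff(change) * dt)
    pooled = np.concatenate(per_mol) if per_mol else np.empty(0)
    if len(pooled) == 0:
        return {
            "mean_ns": float(labels.shape[1] * dt),
            "ci_ns": (np.nan, np.nan),
            "n_events": 0,
            "censored": True,
        }
    rng = np.random.default_rng(seed)
    n_mol = len(per_mol)
    boots = []
    for _ in range(n_boot):
        pick = rng.integers(0, n_mol, size=n_mol)
        sample = np.concatenate([per_mol[i] for i in pick])
        if len(sample):
            boots.append(sample.mean())
    lo, hi = np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan)
    return {
        "mean_ns": float(pooled.mean()),
        "ci_ns": (float(lo), float(hi)),
        "n_events": int(len(pooled)),
        "censored": False,
    }


# ---------------------------------------------------------------------------
# density enrichment


def density_enrichment(
    frames: list[ParticleFrame] | ParticleFrame,
    category: str,
    bulk_zone,
    resolution: float = 1.0,
    box=None,
) -> dict:
    """Per-cell density of ``category`` particles in fold-over-bulk units.

    ``bulk_zone`` is a callable on (x, y) cell-centre arrays returning the
    boolean reference region; its mean cell count defines 1.0.
    """
    if isinstance(frames, ParticleFrame):
        frames = [frames]
    if box is None:
        box = frames[0].box
    nx = max(int(round(box[0] / resolution)), 1)
    ny = max(int(round(box[1] / resolution)), 1)
    x_edges = np.linspace(0.0, box[0], nx + 1)
    y_edges = np.linspace(0.0, box[1], ny + 1)
    count = np.zeros((nx, ny))
    for fr in frames:
        sel = fr.category == category
        if not sel.any():
            continue
        _, c = _bin_mean(fr.positions[sel, :2], np.zeros(sel.sum()), x_edges, y_edges)
        count += c
    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    gx, gy = np.meshgrid(xc, yc, indexing="ij")
    bulk = np.asarray(bulk_zone(gx, gy), dtype=bool)
    if not bulk.any():
        raise ValueError("bulk zone is empty")
    n_bulk = count[bulk].sum()
    if n_bulk < 100:
        raise ValueError(f"bulk zone holds only {int(n_bulk)} samples (<100)")
    bulk_per_cell = n_bulk / bulk.sum()
    return {
        "map": count / bulk_per_cell,
        "x_centers": xc,
        "y_centers": yc,
        "bulk_mask": bulk,
        "bulk_count": float(n_bulk),
    }


# ---------------------------------------------------------------------------
# dielectric profiles


@dataclass
class DielectricProfile:
    z_nm: np.ndarray
    epsilon: np.ndarray  # NaN where masked
    probe_radius_nm: float
    temperature: float
    n_snapshots: int


def local_dipole_moments(positions, charges, probes, radius: float = PROBE_RADIUS_NM):
    """M(r_p) = sum q_i r_i over particles within ``radius`` of each probe.

    positions (n,3) nm, charges (n,) e, probes (m,3) nm -> (m,3) e nm.
    """
    from scipy.spatial import cKDTree

    positions = np.asarray(positions, dtype=float)
    charges = np.asarray(charges, dtype=float)
    probes = np.atleast_2d(np.asarray(probes, dtype=float))
    tree = cKDTree(positions)
    out = np.zeros((len(probes), 3))
    for k, neigh in enumerate(tree.query_ball_point(probes, r=radius)):
        if neigh:
            out[k] = (charges[neigh, None] * positions[neigh]).sum(axis=0)
    return out


def dielectric_profile(
    dipoles: DipoleSampleSet,
    temperature: float = DEFAULT_TEMPERATURE,
    min_snapshots: int = 100,
) -> DielectricProfile:
    """Kirkwood-Frohlich local dielectric constant per z bin.

    eps(z) = 1 + var M / (3 eps0 kB T V) with var M the summed component
    variance of the local dipole moment (e nm) over snapshots and V the
    probe-sphere volume.  Bins sampled by fewer than ``min_snapshots``
    snapshots are masked.
    """
    samples = dipoles.samples  # (n, nz, 3)
    n, nz, _ = samples.shape
    finite = np.isfinite(samples).all(axis=2)  # (n, nz)
    counts = finite.sum(axis=0)
    var = np.full(nz, np.nan)
    for b in range(nz):
        sel = finite[:, b]
        if sel.sum() >= 2:
            var[b] = samples[sel, b, :].var(axis=0, ddof=0).sum()
    v_m3 = (4.0 / 3.0) * math.pi * (dipoles.probe_radius_nm * 1e-9) ** 3
    conv = (E_CHARGE * 1e-9) ** 2  # (e nm)^2 -> C^2 m^2
    eps = 1.0 + var * conv / (3.0 * EPS0_SI * KB_SI * temperature * v_m3)
    eps[counts < min_snapshots] = np.nan
    return DielectricProfile(
        z_nm=dipoles.z_centers_nm,
        epsilon=eps,
        probe_radius_nm=dipoles.probe_radius_nm,
        temperature=temperature,
        n_snapshots=n,
    )
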