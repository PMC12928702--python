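"""2D lattice statistical mechanics of respiratory supercomplex assembly.

Complex I (CI) and the complex III dimer (CIII2) occupy sites of an N x N
grid, each in one of four orientations (North, East, South, West).  The
configurational energy has three tunable terms, all in units of kBT:

* ``E_specific``  (< 0) — paid once per pair of unlike proteins on adjacent
  sites whose orientations point at each other across the shared edge,
  modelling the single oriented CI-CIII2 binding interface;
* ``E_nonspecific`` (> 0) — paid once per any other protein-protein
  adjacency (wrong orientation or like types);
* ``E_strain`` — paid once per (protein site, vacant 4-neighbour) pair,
  modelling the strained lipid shell around each complex; a vacant site
  neighbouring two proteins is counted twice, so assembly always reduces
  the strained-lipid count.

The canonical ensemble over placements x orientations is evaluated either
by exact enumeration (small grids) or by Metropolis Monte Carlo with
translation/rotation moves; the production configuration is 10^7 iterations
over 100 replicas.  Boundaries are hard walls: edge sites simply have fewer
neighbours.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "LatticeParams",
    "LatticeState",
    "LatticeObservables",
    "hamiltonian",
    "classify_configuration",
    "enumerate_states",
    "run_mc",
    "sweep",
]

# orientation encoding and unit steps (N, E, S, W)
_DX = np.array([0, 1, 0, -1], dtype=np.int64)
_DY = np.array([1, 0, -1, 0], dtype=np.int64)
_OPPOSITE = np.array([2, 3, 0, 1], dtype=np.int64)

EMPTY, CI, CIII2 = 0, 1, 2
_TYPE_NAMES = {CI: "CI", CIII2: "CIII2"}


@dataclass(frozen=True)
class LatticeParams:
    """Model parameters; energies are dimensionless multiples of kBT."""

    n: int
    n_ci: int = 1
    n_ciii: int = 1
    e_specific: float = -3.0
    e_nonspecific: float = 1.0
    e_strain: float = 1.0
    beta: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("grid side must be at least 2")
        if self.n_ci + self.n_ciii > self.n**2:
            raise ValueError("more proteins than lattice sites")
        if self.n_ci < 0 or self.n_ciii < 0:
            raise ValueError("protein counts must be non-negative")


@dataclass
class LatticeState:
    """Positions (site indices), types and orientations of all proteins."""

    n: int
    sites: np.ndarray  # (P,) flat site index = x*n + y
    types: np.ndarray  # (P,) CI | CIII2
    orientations: np.ndarray  # (P,) 0..3

    def __post_init__(self):
        self.sites = np.asarray(self.sites, dtype=np.int64)
        self.types = np.asarray(self.types, dtype=np.int64)
        self.orientations = np.asarray(self.orientations, dtype=np.int64)
        if len(set(self.sites.tolist())) != len(self.sites):
            raise ValueError("two proteins on the same site")
        if np.any(self.sites < 0) or np.any(self.sites >= self.n**2):
            raise ValueError("site index outside the grid")

    @property
    def xy(self) -> np.ndarray:
        return np.stack([self.sites // self.n, self.sites % self.n], axis=1)


@dataclass
class LatticeObservables:
    """Ensemble observables; exact (enumeration) or sampled (MC)."""

    partition_function: float | None
    free_energy: float | None
    sc_fraction: float
    mean_specific: float
    mean_nonspecific: float
    mean_strain_sites: float
    sc_fraction_se: float = 0.0
    mean_specific_se: float = 0.0
    mean_nonspecific_se: float = 0.0
    mean_strain_sites_se: float = 0.0
    n_microstates: int | None = None
    method: str = "enumeration"
    extras: dict = field(default_factory=dict)


@njit(cache=True)
def _classify(n, sites, types, oris):
    """Counts of (specific, non-specific, strain) contacts for a state."""
    p = sites.shape[0]
    occ = np.full(n * n, -1, dtype=np.int64)
    for a in range(p):
        occ[sites[a]] = a
    n_spec = 0
    n_nonspec = 0
    n_strain = 0
    for a in range(p):
        x = sites[a] // n
        y = sites[a] % n
        for d in range(4):
            nx = x + _DX[d]
            ny = y + _DY[d]
            if nx < 0 or nx >= n or ny < 0 or ny >= n:
                continue
            b = occ[nx * n + ny]
            if b < 0:
                n_strain += 1
            elif b > a:  # count each protein pair once
                if (
                    types[a] != types[b]
                    and oris[a] == d
                    and oris[b] == _OPPOSITE[d]
                ):
                    n_spec += 1
                else:
                    n_nonspec += 1
    return n_spec, n_nonspec, n_strain


@njit(cache=True)
def _energy(n, sites, types, oris, e_spec, e_nonspec, e_strain):
    s, ns, st = _classify(n, sites, types, oris)
    return s * e_spec + ns * e_nonspec + st * e_strain


def classify_configuration(state: LatticeState) -> dict:
    """Specific contacts, non-specific contacts and strain-site count."""
    s, ns, st = _classify(state.n, state.sites, state.types, state.orientations)
    return {"specific": int(s), "nonspecific": int(ns), "strain_sites": int(st)}


def hamiltonian(state: LatticeState, params: LatticeParams) -> float:
    """Total configurational energy in kBT units."""
    return float(
        _energy(
            state.n,
            state.sites,
            state.types,
            state.orientations,
            params.e_specific,
            params.e_nonspecific,
            params.e_strain,
        )
    )


def _count_microstates(params: LatticeParams) -> int:
    n2 = params.n**2
    placements = (
        math.comb(n2, params.n_ci) * math.comb(n2 - params.n_ci, params.n_ciii)
    )
    return placements * 4 ** (params.n_ci + params.n_ciii)


def enumerate_states(
    params: LatticeParams, max_microstates: int = 10**8
) -> LatticeObservables:
    """Exact canonical averages by enumerating every placement x orientation.

    Proteins are distinguishable by type only: placements of each type are
    enumerated as site combinations, so within-type permutations are never
    double-counted.
    """
    n_micro = _count_microstates(params)
    if n_micro > max_microstates:
        raise ValueError(
            f"{n_micro} microstates exceed the cap {max_microstates}; use run_mc"
        )
    n, n2 = params.n, params.n**2
    p = params.n_ci + params.n_ciii
    types = np.array([CI] * params.n_ci + [CIII2] * params.n_ciii, dtype=np.int64)
    beta = params.beta

    z = 0.0
    acc = np.zeros(4)  # weighted sums: sc_indicator, spec, nonspec, strain
    for ci_sites in itertools.combinations(range(n2), params.n_ci):
        remaining = [s for s in range(n2) if s not in ci_sites]
        for ciii_sites in itertools.combinations(remaining, params.n_ciii):
            sites = np.array(ci_sites + ciii_sites, dtype=np.int64)
            for oris in itertools.product(range(4), repeat=p):
                o = np.array(oris, dtype=np.int64)
                s, ns, st = _classify(n, sites, types, o)
                e = s * params.e_specific + ns * params.e_nonspecific + st * params.e_strain
                w = math.exp(-beta * e)
                z += w
                acc += w * np.array([1.0 if s >= 1 else 0.0, s, ns, st])
    acc /= z
    g = -math.log(z) / beta if beta != 0 else None
    return LatticeObservables(
        partition_function=z,
        free_energy=g,
        sc_fraction=float(acc[0]),
        mean_specific=float(acc[1]),
        mean_nonspecific=float(acc[2]),
        mean_strain_sites=float(acc[3]),
        n_microstates=n_micro,
        method="enumeration",
    )


@njit(cache=True)
def _mc_chain(
    n, sites, types, oris, e_spec, e_nonspec, e_strain, beta,
    n_iter, burn_in, sample_stride, seed, record_codes,
):
    """Metropolis chain; returns accumulated observables and optional codes.

    Moves: with probability 1/2 translate a random protein to a random empty
    site (drawn by rejection over sites), else re-draw its orientation.
    Energy is recomputed in full per move (cheap at few proteins).
    """
    np.random.seed(seed)
    p = sites.shape[0]
    n2 = n * n
    e_cur = _energy(n, sites, types, oris, e_spec, e_nonspec, e_strain)
    n_samples = (n_iter - burn_in) // sample_stride
    codes = np.empty(n_samples if record_codes else 0, dtype=np.int64)
    sum_sc = 0.0
    sum_spec = 0.0
    sum_nonspec = 0.0
    sum_strain = 0.0
    k = 0
    for it in range(n_iter):
        a = np.random.randint(p)
        if np.random.random() < 0.5 and p < n2:
            # translation to a uniformly random empty site
            old = sites[a]
            new = old
            while True:
                cand = np.random.randint(n2)
                free = True
                for b in range(p):
                    if sites[b] == cand:
                        free = False
                        break
                if free:
                    new = cand
                    break
            sites[a] = new
            e_new = _energy(n, sites, types, oris, e_spec, e_nonspec, e_strain)
            if e_new <= e_cur or np.random.random() < np.exp(-beta * (e_new - e_cur)):
                e_cur = e_new
            else:
                sites[a] = old
        else:
            old_o = oris[a]
            oris[a] = np.random.randint(4)
            e_new = _energy(n, sites, types, oris, e_spec, e_nonspec, e_strain)
            if e_new <= e_cur or np.random.random() < np.exp(-beta * (e_new - e_cur)):
                e_cur = e_new
            else:
                oris[a] = old_o
        if it >= burn_in and (it - burn_in) % sample_stride == 0 and k < n_samples:
            s, ns, st = _classify(n, sites, types, oris)
            sum_sc += 1.0 if s >= 1 else 0.0
            sum_spec += s
            sum_nonspec += ns
            sum_strain += st
            if record_codes:
                code = 0
                for b in range(p):
                    code = code * (4 * n2) + sites[b] * 4 + oris[b]
                codes[k] = code
            k += 1
    return sum_sc / k, sum_spec / k, sum_nonspec / k, sum_strain / k, codes


def _random_state(params: LatticeParams, rng: np.random.Generator):
    n2 = params.n**2
    p = params.n_ci + params.n_ciii
    sites = rng.choice(n2, size=p, replace=False).astype(np.int64)
    types = np.array([CI] * params.n_ci + [CIII2] * params.n_ciii, dtype=np.int64)
    oris = rng.integers(0, 4, size=p).astype(np.int64)
    return sites, types, oris


def run_mc(
    params: LatticeParams,
    n_iter: int = 10_000_000,
    n_replicas: int = 100,
    *,
    burn_in_fraction: float = 0.1,
    sample_stride: int = 10,
    record_codes: bool = False,
) -> LatticeObservables:
    """Metropolis MC averages over independent replicas with replica SEs."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if params.n_ci + params.n_ciii < 1:
        raise ValueError("need at least one protein")
    rng = np.random.default_rng(params.seed)
    burn_in = int(burn_in_fraction * n_iter)
    per_rep = np.empty((n_replicas, 4))
    all_codes = []
    for r in range(n_replicas):
        sites, types, oris = _random_state(params, rng)
        chain_seed = int(rng.integers(0, 2**31 - 1))
        sc, sp, nsp, st, codes = _mc_chain(
            params.n, sites, types, oris,
            params.e_specific, params.e_nonspecific, params.e_strain,
            params.beta, n_iter, burn_in, sample_stride, chain_seed,
            record_codes,
        )
        per_rep[r] = (sc, sp, nsp, st)
        if record_codes:
            all_codes.append(codes)
    mean = per_rep.mean(axis=0)
    se = (
        per_rep.std(axis=0, ddof=1) / math.sqrt(n_replicas)
        if n_replicas > 1
        else np.zeros(4)
    )
    obs = LatticeObservables(
        partition_function=None,
        free_energy=None,
        sc_fraction=float(mean[0]),
        mean_specific=float(mean[1]),
        mean_nonspecific=float(mean[2]),
        mean_strain_sites=float(mean[3]),
        sc_fraction_se=float(se[0]),
        mean_specific_se=float(se[1]),
        mean_nonspecific_se=float(se[2]),
        mean_strain_sites_se=float(se[3]),
        method="mc",
    )
    if record_codes:
        obs.extras["codes"] = all_codes
    return obs


def sweep(
    e_specific_values=(-3.0,),
    e_strain_values=(1.0,),
    beta_values=(1.0,),
    n_values=(6,),
    *,
    n_ci: int = 2,
    n_ciii: int = 2,
    e_nonspecific: float = 1.0,
    n_iter: int = 100_000,
    n_replicas: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """MC observables over a cartesian parameter grid, long format.

    One row per (E_specific, E_strain, beta, N) combination; each cell gets a
    deterministic seed derived from the sweep seed and its index.
    """
    rows = []
    combos = list(
        itertools.product(
            sorted(e_specific_values), sorted(e_strain_values),
            sorted(beta_values), sorted(n_values),
        )
    )
    for idx, (es, est, beta, n) in enumerate(combos):
        params = LatticeParams(
            n=n, n_ci=n_ci, n_ciii=n_ciii,
            e_specific=es, e_nonspecific=e_nonspecific, e_strain=est,
            beta=beta, seed=seed * 100_003 + idx,
        )
        obs = run_mc(params, n_iter=n_iter, n_replicas=n_replicas)
        rows.append(
            {
                "n": n, "n_ci": n_ci, "n_ciii": n_ciii,
                "e_specific": es, "e_nonspecific": e_nonspecific,
                "e_strain": est, "beta": beta,
                "sc_fraction": obs.sc_fraction,
                "sc_fraction_se": obs.sc_fraction_se,
                "mean_specific": obs.mean_specific,
                "mean_nonspecific": obs.mean_nonspecific,
                "mean_nonspecific_se": obs.mean_nonspecific_se,
                "mean_strain_sites": obs.mean_strain_sites,
                "mean_strain_sites_se": obs.mean_strain_sites_se,
            }
        )
    return pd.DataFrame(rows)
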