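"""Particle frames: the bead-level container shared by the membrane analyses.

A :class:`ParticleFrame` holds one snapshot of a coarse-grained membrane
system: positions in nm, a category per particle (``lipid-head``,
``lipid-chain``, ``protein``, ``quinone-head``), leaflet labels (``N`` /
``P`` / ``""``) on headgroup particles, lipid ids and chain-bead labels.

Frames round-trip through a documented CSV layout
(x,y,z,category,leaflet,lipid_id,chain_label) and through multi-MODEL PDB
with this mapping: category -> resname (LPH, LPC, PRO, QUI), leaflet ->
chainID (N/P), lipid id -> resid, chain label -> atom name.  PDB stores
Angstrom, so coordinates are scaled by 10 on write and 0.1 on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ParticleFrame", "write_frames_csv", "read_frames_csv",
           "write_frames_pdb", "read_frames_pdb"]

CATEGORIES = ("lipid-head", "lipid-chain", "protein", "quinone-head")

_CAT_TO_RESNAME = {
    "lipid-head": "LPH",
    "lipid-chain": "LPC",
    "protein": "PRO",
    "quinone-head": "QUI",
}
_RESNAME_TO_CAT = {v: k for k, v in _CAT_TO_RESNAME.items()}


@dataclass
class ParticleFrame:
    positions: np.ndarray  # (n, 3) nm
    category: np.ndarray  # (n,) str
    leaflet: np.ndarray  # (n,) 'N' | 'P' | ''
    lipid_id: np.ndarray  # (n,) int, -1 for non-lipids
    chain_label: np.ndarray  # (n,) str, '' if none
    box: np.ndarray = field(default=None)  # (3,) nm

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        n = len(self.positions)
        self.category = np.asarray(self.category, dtype=object)
        self.leaflet = np.asarray(self.leaflet, dtype=object)
        self.lipid_id = np.asarray(self.lipid_id, dtype=int)
        self.chain_label = np.asarray(self.chain_label, dtype=object)
        for arr, name in [
            (self.category, "category"),
            (self.leaflet, "leaflet"),
            (self.lipid_id, "lipid_id"),
            (self.chain_label, "chain_label"),
        ]:
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n} positions")
        bad = set(self.category) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories {bad}")
        head = np.isin(self.category, ["lipid-head", "quinone-head"])
        if np.any((self.leaflet != "") & ~head):
            raise ValueError("leaflet labels allowed only on headgroup particles")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)

    def __len__(self) -> int:
        return len(self.positions)

    def select(self, category: str) -> np.ndarray:
        """Boolean mask of particles in the given category."""
        return self.category == category

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_nm": self.positions[:, 0],
                "y_nm": self.positions[:, 1],
                "z_nm": self.positions[:, 2],
                "category": self.category,
                "leaflet": self.leaflet,
                "lipid_id": self.lipid_id,
                "chain_label": self.chain_label,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, box=None) -> "ParticleFrame":
        return cls(
            positions=df[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float),
            category=df["category"].fillna("").to_numpy(dtype=object),
            leaflet=df["leaflet"].fillna("").to_numpy(dtype=object),
            lipid_id=df["lipid_id"].to_numpy(dtype=int),
            chain_label=df["chain_label"].fillna("").to_numpy(dtype=object),
            box=box,
        )


def write_frames_csv(frames: list[ParticleFrame], path) -> None:
    parts = []
    for i, fr in enumerate(frames):
        df = fr.to_dataframe()
        df.insert(0, "frame", i)
        parts.append(df)
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


def read_frames_csv(path, box=None) -> list[ParticleFrame]:
    df = pd.read_csv(path, keep_default_na=False)
    return [
        ParticleFrame.from_dataframe(g, box=box)
        for _, g in df.groupby("frame", sort=True)
    ]


def write_frames_pdb(frames: list[ParticleFrame], path) -> None:
    """Multi-MODEL PDB, one MODEL per frame (coordinates written in A).

    PDB topology is static across MODELs: readers take categories, leaflet
    labels and ids from the first MODEL.  Use the CSV layout when per-frame
    metadata (e.g. flip-flopping quinone leaflets) must survive a round
    trip.
    """
    with open(path, "w") as fh:
        for m, fr in enumerate(frames, start=1):
            fh.write(f"MODEL {m:>8d}\n")
            if fr.box is not None:
                bx, by, bz = 10.0 * fr.box
                fh.write(
                    f"CRYST1{bx:9.3f}{by:9.3f}{bz:9.3f}"
                    f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
                )
            for i in range(len(fr)):
                x, y, z = 10.0 * fr.positions[i]
                name = (fr.chain_label[i] or "BD")[:4]
                resname = _CAT_TO_RESNAME[fr.category[i]]
                chain = (fr.leaflet[i] or "X")[:1]
                resid = int(fr.lipid_id[i]) % 10000 if fr.lipid_id[i] >= 0 else 9999
                fh.write(
                    f"ATOM  {(i % 99999) + 1:5d} {name:<4s} {resname:<3s} "
                    f"{chain}{resid:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_frames_pdb(path) -> list[ParticleFrame]:
    """Read frames written by :func:`write_frames_pdb` (MDAnalysis backend)."""
    import MDAnalysis as mda

    u = mda.Universe(path)
    frames = []
    for _ in u.trajectory:
        atoms = u.atoms
        cats = np.array(
            [_RESNAME_TO_CAT.get(rn, "protein") for rn in atoms.resnames],
            dtype=object,
        )
        leaf = np.array(
            [
                cid if cid in ("N", "P") else ""
                for cid in atoms.chainIDs
            ],
            dtype=object,
        )
        head = np.isin(cats, ["lipid-head", "quinone-head"])
        leaf = np.where(head, leaf, "")
        lipid_id = np.where(
            np.isin(cats, ["lipid-head", "lipid-chain"]), atoms.resids, -1
        )
        labels = np.where(
            cats == "lipid-chain", atoms.names.astype(object), ""
        )
        box = (
            u.dimensions[:3] * 0.1 if u.dimensions is not None else None
        )
        frames.append(
            ParticleFrame(
                positions=atoms.positions * 0.1,
                category=cats,
                leaflet=leaf.astype(object),
                lipid_id=lipid_id,
                chain_label=labels.astype(object),
                box=box,
            )
        )
    return frames
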