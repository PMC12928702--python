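"""Residue interaction networks from C-alpha trajectories.

Residues are graph nodes; two residues are joined by an edge when their
C-alpha atoms are closer than a cutoff (7.5 A) in strictly more than a
persistence threshold (50%) of the trajectory frames.  Edges carry the
exact persistence fraction.  Difference graphs between two ligand states
partition the edge union into state-exclusive and shared contacts.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from scipy.spatial import cKDTree

__all__ = ["contact_graph", "graph_difference", "write_edge_tsv", "read_edge_tsv"]

CONTACT_CUTOFF_A = 7.5
PERSISTENCE_THRESHOLD = 0.5


def contact_graph(
    ca_trajectory,
    cutoff: float = CONTACT_CUTOFF_A,
    threshold: float = PERSISTENCE_THRESHOLD,
    node_labels=None,
    exclude_neighbors: int = 0,
) -> nx.Graph:
    """Build the persistence-thresholded residue contact graph.

    ``ca_trajectory`` is (n_frames, n_residues, 3) in Angstrom with a
    consistent residue order across frames.  Neighbour pairs are found per
    frame with a KD tree; an edge is kept iff its contact fraction is
    strictly greater than ``threshold``.  ``node_labels`` optionally maps
    residue index -> (chain, resid) node labels; ``exclude_neighbors``
    drops pairs within that many positions along the chain.
    """
    traj = np.asarray(ca_trajectory, dtype=float)
    if traj.ndim != 3 or traj.shape[2] != 3:
        raise ValueError("trajectory must have shape (n_frames, n_residues, 3)")
    n_frames, n_res, _ = traj.shape
    if n_frames < 1:
        raise ValueError("need at least one frame")
    counts: dict[tuple[int, int], int] = {}
    for f in range(n_frames):
        tree = cKDTree(traj[f])
        for i, j in tree.query_pairs(cutoff):
            if abs(i - j) <= exclude_neighbors:
                continue
            key = (i, j) if i < j else (j, i)
            counts[key] = counts.get(key, 0) + 1
    g = nx.Graph(cutoff=cutoff, threshold=threshold, n_frames=n_frames)
    if node_labels is None:
        node_labels = {i: ("A", i + 1) for i in range(n_res)}
    g.add_nodes_from(node_labels[i] for i in range(n_res))
    for (i, j), c in counts.items():
        persistence = c / n_frames
        if persistence > threshold:
            g.add_edge(node_labels[i], node_labels[j], persistence=persistence)
    return g


def graph_difference(ga: nx.Graph, gb: nx.Graph) -> dict:
    """Partition the edge union of two graphs over the same node universe.

    Returns edge sets only in A, only in B, and shared (frozenset keyed).
    """
    nodes_a, nodes_b = set(ga.nodes), set(gb.nodes)
    if nodes_a.isdisjoint(nodes_b):
        raise ValueError("graphs share no nodes; not comparable")
    ea = {frozenset(e) for e in ga.edges}
    eb = {frozenset(e) for e in gb.edges}
    return {
        "only_a": ea - eb,
        "only_b": eb - ea,
        "shared": ea & eb,
    }


def write_edge_tsv(g: nx.Graph, path) -> None:
    """Edge list as TSV: chainA resA chainB resB persistence."""
    with open(path, "w") as fh:
        fh.write("chain_a\tres_a\tchain_b\tres_b\tpersistence\n")
        for (ca, ra), (cb, rb), data in sorted(g.edges(data=True)):
            fh.write(f"{ca}\t{ra}\t{cb}\t{rb}\t{data['persistence']:.6f}\n")


def read_edge_tsv(path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("chain_a")
        for line in fh:
            ca, ra, cb, rb, p = line.split("\t")
            g.add_edge((ca, int(ra)), (cb, int(rb)), persistence=float(p))
    return g
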