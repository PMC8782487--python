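"""Weighted amino-acid networks and mutation perturbation networks.

An amino-acid network at distance threshold ``t`` is an undirected graph
whose nodes are residues and whose edge weight between residues *i* and
*j* counts the atom pairs (one atom in each residue) strictly closer than
``t`` Ångstroms.  The perturbation network of a mutation is the entrywise
absolute difference of the wild-type and mutant adjacency matrices with
all-zero rows and columns removed; its four topological measures — number
of nodes, number of edges, total edge weight, and diameter in hops —
quantify the structural change caused by the mutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import ResidueID, Structure

__all__ = [
    "AminoAcidNetwork",
    "PerturbationNetwork",
    "PerturbationMeasures",
    "Mutation",
    "build_network",
    "networks_over_thresholds",
    "adjacency_matrix",
    "perturbation_network",
    "measure",
    "score_mutant_set",
    "MEASURES",
    "default_threshold_grid",
]

MEASURES = ("nodes", "edges", "weight", "diameter")


class PerturbationMeasures(NamedTuple):
    nodes: int
    edges: int
    weight: int
    diameter: int


@dataclass
class AminoAcidNetwork:
    """Undirected residue contact graph with atom-pair-count edge weights."""

    threshold: float
    graph: nx.Graph

    @property
    def nodes(self) -> set[ResidueID]:
        return set(self.graph.nodes)

    @property
    def edge_weights(self) -> dict[tuple[ResidueID, ResidueID], int]:
        return {_key(u, v): int(d["weight"]) for u, v, d in self.graph.edges(data=True)}

    def weight(self, u: ResidueID, v: ResidueID) -> int:
        if self.graph.has_edge(u, v):
            return int(self.graph[u][v]["weight"])
        return 0


@dataclass
class PerturbationNetwork:
    """Pruned |A − B| difference graph between wild-type and mutant networks."""

    threshold: float
    graph: nx.Graph
    measures: PerturbationMeasures = field(init=False)

    def __post_init__(self) -> None:
        self.measures = _measures_of(self.graph)

    @property
    def nodes(self) -> set[ResidueID]:
        return set(self.graph.nodes)

    @property
    def edge_weights(self) -> dict[tuple[ResidueID, ResidueID], int]:
        return {_key(u, v): int(d["weight"]) for u, v, d in self.graph.edges(data=True)}


@dataclass(frozen=True, order=True)
class Mutation:
    """A point mutation label: chain, position, wild-type and mutant amino acid."""

    chain: str
    position: int
    wt_aa: str
    mut_aa: str

    @property
    def synonymous(self) -> bool:
        return self.wt_aa == self.mut_aa

    def __str__(self) -> str:
        return f"{self.chain}:{self.wt_aa}{self.position}{self.mut_aa}"


def _key(u: ResidueID, v: ResidueID) -> tuple[ResidueID, ResidueID]:
    return (u, v) if u <= v else (v, u)


class _PairDistances(NamedTuple):
    """All inter-residue atom-pair distances below a radius, residue-labelled."""

    rids: list[ResidueID]
    pair_i: np.ndarray  # residue index of first atom of each pair
    pair_j: np.ndarray
    dist: np.ndarray


def _pair_distances(structure: Structure, r_max: float) -> _PairDistances:
    rids = structure.residue_ids()
    coords = []
    res_idx = []
    for k, res in enumerate(structure):
        c = res.coords
        coords.append(c)
        res_idx.append(np.full(len(c), k))
    coords = np.concatenate(coords)
    res_idx = np.concatenate(res_idx)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=r_max, output_type="ndarray")
    if len(pairs) == 0:
        empty = np.empty(0)
        return _PairDistances(rids, empty.astype(int), empty.astype(int), empty)
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    ri, rj = res_idx[pairs[:, 0]], res_idx[pairs[:, 1]]
    inter = ri != rj
    lo, hi = np.minimum(ri, rj)[inter], np.maximum(ri, rj)[inter]
    return _PairDistances(rids, lo, hi, d[inter])


def _network_at(pd_cache: _PairDistances, t: float) -> nx.Graph:
    g = nx.Graph()
    mask = pd_cache.dist < t  # strictly closer than t
    if mask.any():
        n = len(pd_cache.rids)
        codes = pd_cache.pair_i[mask] * n + pd_cache.pair_j[mask]
        uniq, counts = np.unique(codes, return_counts=True)
        for code, w in zip(uniq, counts):
            u = pd_cache.rids[int(code) // n]
            v = pd_cache.rids[int(code) % n]
            g.add_edge(u, v, weight=int(w))
    return g


def build_network(structure: Structure, t: float) -> AminoAcidNetwork:
    """Build the amino-acid network of ``structure`` at threshold ``t`` (Å).

    The weight of edge (i, j) is the number of atom pairs, one atom in
    residue i and one in residue j, at Euclidean distance strictly less
    than ``t``.  Residue pairs with no such atom pair carry no edge.
    Sequence-adjacent residues are treated like any other pair.
    """
    if t <= 0:
        raise ValueError(f"distance threshold must be positive, got {t}")
    if len(structure) == 0:
        raise ValueError("cannot build a network from an empty structure")
    cache = _pair_distances(structure, t)
    g = _network_at(cache, t)
    g.add_nodes_from(structure.residue_ids())
    return AminoAcidNetwork(t, g)


def networks_over_thresholds(
    structure: Structure, thresholds: Sequence[float]
) -> dict[float, AminoAcidNetwork]:
    """Networks at several thresholds, computing atom-pair distances once."""
    thresholds = list(thresholds)
    if not thresholds or any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be a non-empty list of positive distances")
    cache = _pair_distances(structure, max(thresholds))
    out = {}
    for t in thresholds:
        g = _network_at(cache, t)
        g.add_nodes_from(structure.residue_ids())
        out[t] = AminoAcidNetwork(t, g)
    return out


def adjacency_matrix(
    net: AminoAcidNetwork | PerturbationNetwork,
    node_order: Sequence[ResidueID],
) -> np.ndarray:
    """Symmetric integer adjacency matrix of ``net`` in a given node order."""
    index = {rid: k for k, rid in enumerate(node_order)}
    missing = net.nodes - set(index)
    if missing:
        raise ValueError(f"nodes missing from node_order: {sorted(missing)[:5]}")
    a = np.zeros((len(node_order), len(node_order)), dtype=int)
    for (u, v), w in net.edge_weights.items():
        i, j = index[u], index[v]
        a[i, j] = a[j, i] = w
    return a


def perturbation_network(
    wt: AminoAcidNetwork, mut: AminoAcidNetwork
) -> PerturbationNetwork:
    """Perturbation network P = pruned |A − B| of two same-threshold networks.

    Edges are residue pairs whose weights differ between the two networks,
    weighted by the absolute difference (a pair present in only one network
    contributes its full weight).  Nodes are the endpoints of surviving
    edges — equivalent to dropping all-zero rows/columns of |A − B|.
    """
    if wt.threshold != mut.threshold:
        raise ValueError(
            f"threshold mismatch: wild-type {wt.threshold} vs mutant {mut.threshold}"
        )
    w_wt = wt.edge_weights
    w_mut = mut.edge_weights
    g = nx.Graph()
    for pair in set(w_wt) | set(w_mut):
        diff = abs(w_wt.get(pair, 0) - w_mut.get(pair, 0))
        if diff > 0:
            g.add_edge(*pair, weight=diff)
    return PerturbationNetwork(wt.threshold, g)


def _measures_of(g: nx.Graph) -> PerturbationMeasures:
    if g.number_of_nodes() == 0:
        return PerturbationMeasures(0, 0, 0, 0)
    total = sum(d["weight"] for _, _, d in g.edges(data=True))
    comps = list(nx.connected_components(g))
    biggest = max(len(c) for c in comps)
    # hop-count diameter on the largest component(s); ties take the larger value
    diam = max(
        nx.diameter(g.subgraph(c)) for c in comps if len(c) == biggest
    )
    return PerturbationMeasures(
        g.number_of_nodes(), g.number_of_edges(), int(total), int(diam)
    )


def measure(p: PerturbationNetwork) -> PerturbationMeasures:
    """The four measures (nodes, edges, weight, diameter) of a perturbation network."""
    return p.measures


def default_threshold_grid() -> list[float]:
    """71 distance thresholds from 3.0 to 10.0 Å in 0.1 Å steps."""
    return [round(t, 1) for t in np.linspace(3.0, 10.0, 71)]


def score_mutant_set(
    wt_structure: Structure,
    mutant_structures: Mapping[Mutation, Structure],
    thresholds: Sequence[float],
) -> pd.DataFrame:
    """Raw perturbation measures for a set of mutant structures.

    Returns one row per (mutation, threshold) with columns
    ``chain, position, wt_aa, mut_aa, threshold, nodes, edges, weight,
    diameter``.  The wild-type network at each threshold is built once and
    reused across mutations.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    if sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be ascending")
    wt_nets = networks_over_thresholds(wt_structure, thresholds)
    wt_rids = set(wt_structure.residue_ids())

    rows = []
    for mutation in sorted(mutant_structures):
        mut_structure = mutant_structures[mutation]
        if not wt_rids & set(mut_structure.residue_ids()):
            raise ValueError(
                f"mutant {mutation} shares no residues with the wild type"
            )
        mut_nets = networks_over_thresholds(mut_structure, thresholds)
        for t in thresholds:
            p = perturbation_network(wt_nets[t], mut_nets[t])
            rows.append(
                {
                    "chain": mutation.chain,
                    "position": mutation.position,
                    "wt_aa": mutation.wt_aa,
                    "mut_aa": mutation.mut_aa,
                    "threshold": t,
                    **p.measures._asdict(),
                }
            )
    return pd.DataFrame(rows)
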