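"""Directed hydrogen-bond network analysis.

A hydrogen bond is assigned geometrically: donor H within ``d_ha`` of an
acceptor oxygen on another molecule, with an O-H...O angle (at the
hydrogen) of at least ``angle_min`` degrees.  Acceptors are water oxygens
and ion oxygens; ion oxygens never donate.  If one H satisfies the
criterion for several acceptors, the shortest H...O distance wins, so each
H donates at most once.  Every reported statistic carries the criterion
used, because different geometric definitions shift the counts.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import networkx as nx
import numpy as np

from .forcefield import ClusterConfig

__all__ = [
    "HBondCriterion",
    "HBond",
    "HBondGraph",
    "detect_hbonds",
    "count_dangling",
    "count_ion_hbonds",
    "ring_census",
    "directed_water_cycles",
]


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric H-bond definition: H...O distance (A) and O-H...O angle (deg)."""

    d_ha: float = 2.5
    angle_min: float = 120.0


class HBond(NamedTuple):
    donor_mol: int
    donor_h_site: int
    acceptor_mol: int
    acceptor_site: int
    h_a_distance: float


@dataclass
class HBondGraph:
    """Directed hydrogen-bond graph over molecules of one configuration."""

    n_molecules: int
    n_waters: int
    ion_index: int | None
    edges: list[HBond]
    dangling_oh: list[tuple[int, int]]  # (molecule, H site index) not donating
    criterion: HBondCriterion

    @property
    def digraph(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.add_nodes_from(range(self.n_molecules))
        for e in self.edges:
            g.add_edge(e.donor_mol, e.acceptor_mol, donor_h_site=e.donor_h_site,
                       acceptor_site=e.acceptor_site, distance=e.h_a_distance)
        return g

    @property
    def undirected(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_molecules))
        g.add_edges_from((e.donor_mol, e.acceptor_mol) for e in self.edges)
        return g

    def water_digraph(self) -> nx.DiGraph:
        """Simple digraph of water->water donations (ion excluded)."""
        g = nx.DiGraph()
        for m in range(self.n_molecules):
            if m != self.ion_index:
                g.add_node(m)
        for e in self.edges:
            if e.acceptor_mol != self.ion_index:
                g.add_edge(e.donor_mol, e.acceptor_mol)
        return g

    def to_edge_list(self) -> list[str]:
        """Plain-text edge list: donor_idx H_site acceptor_idx O_site dist."""
        return [
            f"{e.donor_mol} {e.donor_h_site} {e.acceptor_mol} {e.acceptor_site} "
            f"{e.h_a_distance:.4f}"
            for e in self.edges
        ]


def _molecule_sites(cluster: ClusterConfig):
    """Flatten per-molecule donor-H and acceptor-O site geometry."""
    positions = cluster.site_positions()
    donors = []  # (mol, h_site, h_pos, covalent_o_pos)
    acceptors = []  # (mol, o_site, o_pos)
    for m, sp in enumerate(cluster.species_list):
        pos = positions[m]
        o_sites = [i for i, s in enumerate(sp.sites) if s.label == "O"]
        for i, s in enumerate(sp.sites):
            if s.label == "H":
                # covalent O = nearest O of the same molecule
                d = [np.linalg.norm(pos[i] - pos[j]) for j in o_sites]
                donors.append((m, i, pos[i], pos[o_sites[int(np.argmin(d))]]))
        for j in o_sites:
            acceptors.append((m, j, pos[j]))
    return donors, acceptors


def detect_hbonds(
    cluster: ClusterConfig, criterion: HBondCriterion | None = None
) -> HBondGraph:
    """Build the directed hydrogen-bond graph of a configuration."""
    crit = criterion or HBondCriterion()
    donors, acceptors = _molecule_sites(cluster)
    edges: list[HBond] = []
    dangling: list[tuple[int, int]] = []
    acc_mol = np.array([a[0] for a in acceptors])
    acc_pos = np.array([a[2] for a in acceptors]).reshape(-1, 3)
    for m, h_site, h_pos, o_pos in donors:
        mask = acc_mol != m
        if not mask.any():
            dangling.append((m, h_site))
            continue
        cand_pos = acc_pos[mask]
        d = np.linalg.norm(cand_pos - h_pos, axis=1)
        # O-H...O angle at the hydrogen
        v1 = o_pos - h_pos
        v2 = cand_pos - h_pos
        cosang = (v2 @ v1) / (np.linalg.norm(v1) * np.maximum(d, 1e-12))
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        ok = (d <= crit.d_ha) & (ang >= crit.angle_min)
        if not ok.any():
            dangling.append((m, h_site))
            continue
        idx_all = np.flatnonzero(mask)[ok]
        dists = d[ok]
        best = idx_all[int(np.argmin(dists))]
        am, asite, _ = acceptors[best]
        edges.append(HBond(m, h_site, am, asite, float(dists.min())))
    return HBondGraph(
        n_molecules=cluster.n_molecules,
        n_waters=cluster.n_waters,
        ion_index=cluster.ion_index,
        edges=edges,
        dangling_oh=dangling,
        criterion=crit,
    )


def count_dangling(graph: HBondGraph) -> int:
    """Number of water O-H bonds donating no hydrogen bond."""
    return len(graph.dangling_oh)


def count_ion_hbonds(graph: HBondGraph) -> tuple[int, dict[int, int]]:
    """Hydrogen bonds accepted by the ion: total and per-ion-oxygen-site.

    Returns ``(n_H, breakdown)`` with breakdown keyed by the ion's acceptor
    site index.
    """
    if graph.ion_index is None:
        raise ValueError("cluster has no ion")
    breakdown: dict[int, int] = {}
    n = 0
    for e in graph.edges:
        if e.acceptor_mol == graph.ion_index:
            n += 1
            breakdown[e.acceptor_site] = breakdown.get(e.acceptor_site, 0) + 1
    return n, breakdown


def ion_coordination(graph: HBondGraph) -> int:
    """Number of distinct water molecules donating at least one H bond to the ion."""
    if graph.ion_index is None:
        raise ValueError("cluster has no ion")
    return len({e.donor_mol for e in graph.edges if e.acceptor_mol == graph.ion_index})


def ring_census(graph: HBondGraph, max_len: int = 12) -> dict[int, int]:
    """Minimal-cycle-basis ring census of the undirected H-bond topology.

    Returns {ring length: count} for rings up to ``max_len`` (3 = trimer,
    4 = tetramer, ...).  A cube therefore counts as its 4-rings, not also
    the longer cycles they compose.
    """
    g = graph.undirected
    census: dict[int, int] = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        for cycle in nx.minimum_cycle_basis(sub):
            L = len(cycle)
            if L <= max_len:
                census[L] = census.get(L, 0) + 1
    return census


def directed_water_cycles(graph: HBondGraph, max_len: int = 8) -> list[list[int]]:
    """Directed donor->acceptor cycles among waters (for cycle inversion)."""
    g = graph.water_digraph()
    return [list(c) for c in nx.simple_cycles(g, length_bound=max_len)]
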