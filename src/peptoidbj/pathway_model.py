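"""Bond-counting tunneling-pathway model on molecular graphs.

Electron-transfer coupling between two anchor atoms is approximated as a
product of per-step decay factors along the best path through the bonded
network. A covalent bond contributes one unit to the effective bond count;
a hydrogen bond decays twice as fast and contributes two units (through-space
jumps are an optional third edge kind with configurable weight, excluded
from default builds). The predicted conductance scales as
ε_C^(effective bond count) for a per-covalent-bond decay factor ε_C, so the
best pathway is the minimum-weight path and conductance ratios between
structures are ε_C raised to the difference of their effective counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx

__all__ = [
    "BondKind",
    "MolecularGraph",
    "PathwayResult",
    "best_pathway",
    "compare_pathways",
    "build_backbone_graph",
    "DEFAULT_EDGE_COSTS",
]

DEFAULT_EDGE_COSTS = {"covalent": 1.0, "hydrogen": 2.0, "space": 3.0}


@dataclass
class MolecularGraph:
    """Atoms plus typed bonds with two designated anchor atoms.

    Atom ids are strings (sortable, used for deterministic tie-breaks);
    edge kinds are ``covalent``, ``hydrogen`` or ``space``.
    """

    graph: nx.Graph
    anchors: tuple[str, str]
    edge_costs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EDGE_COSTS)
    )

    def __post_init__(self) -> None:
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValueError("self-edges are not allowed")
            if data.get("kind") not in self.edge_costs:
                raise ValueError(f"unknown bond kind on edge {u}-{v}")
        for a in self.anchors:
            if a not in self.graph:
                raise ValueError(f"anchor {a} not in graph")

    def edge_cost(self, u, v) -> float:
        return self.edge_costs[self.graph.edges[u, v]["kind"]]

    def path_cost(self, path: Sequence[str]) -> float:
        return sum(self.edge_cost(u, v) for u, v in zip(path, path[1:]))


@dataclass
class PathwayResult:
    path: list[str]
    effective_bond_count: float
    epsilon_c: float
    conductance_factor: float
    n_covalent: int
    n_hydrogen: int
    n_space: int


def best_pathway(g: MolecularGraph, epsilon_c: float = 0.6) -> PathwayResult:
    """Minimum effective-bond-count path between the anchors.

    Edge weights are the configured per-kind costs (1 covalent, 2 hydrogen
    by default). Among equal-cost optima the lexicographically smallest
    atom-id sequence is returned. Conductance factor is
    ε_C^effective_bond_count.
    """
    if not (0.0 < epsilon_c <= 1.0):
        raise ValueError("epsilon_c must be in (0, 1]")
    src, dst = g.anchors
    wg = g.graph.copy()
    for u, v in wg.edges():
        wg.edges[u, v]["weight"] = g.edge_cost(u, v)
    try:
        paths = list(nx.all_shortest_paths(wg, src, dst, weight="weight"))
    except nx.NetworkXNoPath:
        raise ValueError("anchors are not connected") from None
    path = min(paths)  # lexicographic tie-break on the atom-id sequence
    cost = g.path_cost(path)
    kinds = [g.graph.edges[u, v]["kind"] for u, v in zip(path, path[1:])]
    return PathwayResult(
        path=list(path),
        effective_bond_count=cost,
        epsilon_c=epsilon_c,
        conductance_factor=epsilon_c ** cost,
        n_covalent=kinds.count("covalent"),
        n_hydrogen=kinds.count("hydrogen"),
        n_space=kinds.count("space"),
    )


def compare_pathways(g_with: MolecularGraph, g_without: MolecularGraph,
                     epsilon_c: float = 0.6):
    """Effective-bond-count difference and conductance ratio between two
    variants of a structure (typically with and without an H-bond shortcut).

    Returns ``(delta_bonds, ratio)`` with
    ``delta = count(without) - count(with)`` and ``ratio = ε_C^delta`` — the
    factor by which conductance drops when the shortcut is absent.
    """
    if set(g_with.anchors) != set(g_without.anchors):
        raise ValueError("graphs must share anchors")
    r_with = best_pathway(g_with, epsilon_c)
    r_without = best_pathway(g_without, epsilon_c)
    delta = r_without.effective_bond_count - r_with.effective_bond_count
    return delta, epsilon_c ** delta


def exhaustive_best_pathway(g: MolecularGraph, epsilon_c: float = 0.6) -> PathwayResult:
    """Brute-force minimum over all simple anchor-to-anchor paths.

    Exponential; intended as an independent check on small graphs only.
    """
    src, dst = g.anchors
    best: Optional[list[str]] = None
    best_cost = float("inf")
    for path in nx.all_simple_paths(g.graph, src, dst):
        c = g.path_cost(path)
        if c < best_cost - 1e-12 or (abs(c - best_cost) <= 1e-12
                                     and (best is None or list(path) < best)):
            best = list(path)
            best_cost = c
    if best is None:
        raise ValueError("anchors are not connected")
    kinds = [g.graph.edges[u, v]["kind"] for u, v in zip(best, best[1:])]
    return PathwayResult(
        path=best, effective_bond_count=best_cost, epsilon_c=epsilon_c,
        conductance_factor=epsilon_c ** best_cost,
        n_covalent=kinds.count("covalent"),
        n_hydrogen=kinds.count("hydrogen"),
        n_space=kinds.count("space"),
    )


def build_backbone_graph(residues: Sequence[str],
                         hbonds: Sequence[tuple[int, int]] = ()) -> MolecularGraph:
    """Backbone graph of an oligomer with terminal sulfur anchors.

    ``residues`` is a sequence of ``"peptide"`` / ``"peptoid"`` class labels.
    Each residue contributes backbone atoms N, CA, C and carbonyl O; peptide
    nitrogens additionally carry an amide H (a potential H-bond donor),
    peptoid nitrogens carry a side-chain carbon instead — N-substitution
    removes the donor. Terminal sulfur anchors are bonded to the first N and
    the last C.

    ``hbonds`` lists (donor_residue, acceptor_residue) annotations, adding a
    hydrogen edge from the donor's amide H to the acceptor's carbonyl O.
    Annotating a peptoid donor raises, since its nitrogen has no hydrogen.
    """
    if not residues:
        raise ValueError("empty sequence")
    g = nx.Graph()
    n_res = len(residues)

    def aid(i: int, name: str) -> str:
        return f"{i:02d}{name}"

    for i, cls in enumerate(residues):
        if cls not in ("peptide", "peptoid"):
            raise ValueError(f"unknown residue class {cls!r}")
        for name in ("N", "CA", "C", "O"):
            g.add_node(aid(i, name), element=name[0], residue=i)
        g.add_edge(aid(i, "N"), aid(i, "CA"), kind="covalent")
        g.add_edge(aid(i, "CA"), aid(i, "C"), kind="covalent")
        g.add_edge(aid(i, "C"), aid(i, "O"), kind="covalent")
        if cls == "peptide":
            g.add_node(aid(i, "H"), element="H", residue=i)
            g.add_edge(aid(i, "N"), aid(i, "H"), kind="covalent")
        else:
            g.add_node(aid(i, "CB"), element="C", residue=i)
            g.add_edge(aid(i, "N"), aid(i, "CB"), kind="covalent")
        if i + 1 < n_res:
            g.add_edge(aid(i, "C"), aid(i + 1, "N"), kind="covalent")

    g.add_node("S_head", element="S", residue=-1)
    g.add_node("S_tail", element="S", residue=n_res)
    g.add_edge("S_head", aid(0, "N"), kind="covalent")
    g.add_edge("S_tail", aid(n_res - 1, "C"), kind="covalent")

    for don, acc in hbonds:
        if residues[don] != "peptide":
            raise ValueError(
                f"residue {don} is a substituted amide with no N-H donor"
            )
        g.add_edge(aid(don, "H"), aid(acc, "O"), kind="hydrogen")

    return MolecularGraph(graph=g, anchors=("S_head", "S_tail"))
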