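"""Perturbation-map construction and the unified map data structure.

Nodes are ligand ids, edges are candidate alchemical transformations scored
by maximum-common-substructure similarity.  The builder lays a minimum
spanning tree over the dissimilarity (1 − similarity) so every ligand is
reachable, then greedily adds the most similar remaining pairs until every
node reaches a target degree — the added redundancy creates the cycles that
cycle-closure analysis needs.  Edge direction (a→b with a < b
lexicographically) is a storage convention, not physics.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
from rdkit import Chem

from .constants import EDGE_ARROW
from .exceptions import DisconnectedMapError, InsufficientCommonSubstructureError, McsTimeoutError
from .posesel import McsOptions, compute_mcs

__all__ = ["Edge", "PerturbationMap", "mcs_similarity", "build_map", "read_map", "write_map", "write_graphml"]


@dataclass(frozen=True)
class Edge:
    """Directed edge a→b with an MCS-similarity score in [0, 1]."""

    a: str
    b: str
    similarity: float

    @property
    def id(self) -> str:
        return f"{self.a}{EDGE_ARROW}{self.b}"


class PerturbationMap:
    """Connected graph of ligands (nodes) and transformations (edges).

    Invariants, checked on construction: no self-edges, no duplicate
    unordered pairs, similarities in [0, 1], every node connected.
    """

    def __init__(self, nodes: list[str], edges: list[Edge]):
        self.nodes = list(nodes)
        self.edges = list(edges)
        self._validate()

    def _validate(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node ids in perturbation map")
        for n in self.nodes:
            if EDGE_ARROW in n:
                raise ValueError(f"node id {n!r} contains the edge separator")
        node_set = set(self.nodes)
        seen: set[frozenset] = set()
        for e in self.edges:
            if e.a == e.b:
                raise ValueError(f"self-edge on node '{e.a}'")
            if e.a not in node_set or e.b not in node_set:
                raise ValueError(f"edge {e.id} references unknown node")
            key = frozenset((e.a, e.b))
            if key in seen:
                raise ValueError(f"duplicate edge between '{e.a}' and '{e.b}'")
            seen.add(key)
            if not (0.0 <= e.similarity <= 1.0):
                raise ValueError(f"edge {e.id}: similarity {e.similarity} outside [0, 1]")
        if len(self.nodes) > 1:
            g = self.to_networkx()
            if not nx.is_connected(g):
                comps = [sorted(c) for c in nx.connected_components(g)]
                raise DisconnectedMapError(
                    f"perturbation map is disconnected; components: {comps}"
                )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((e.a, e.b, {"similarity": e.similarity}) for e in self.edges)
        return g

    def degree(self, node: str) -> int:
        return sum(1 for e in self.edges if node in (e.a, e.b))

    @property
    def edge_ids(self) -> list[str]:
        return [e.id for e in self.edges]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PerturbationMap)
            and self.nodes == other.nodes
            and self.edges == other.edges
        )

    def __repr__(self) -> str:
        return f"PerturbationMap({len(self.nodes)} nodes, {len(self.edges)} edges)"


def mcs_similarity(
    mol_a: Chem.Mol, mol_b: Chem.Mol, opts: McsOptions | None = None
) -> float:
    """MCS heavy-atom count over the larger molecule's heavy-atom count.

    1.0 for identical molecules; 0.0 when no common substructure reaches the
    minimum-size threshold (failures never raise — an unusable pair simply
    scores zero and is not offered as an edge).
    """
    try:
        mapping = compute_mcs(mol_a, mol_b, opts)
    except (InsufficientCommonSubstructureError, McsTimeoutError):
        return 0.0
    heavy_a = sum(1 for at in mol_a.GetAtoms() if at.GetAtomicNum() > 1)
    heavy_b = sum(1 for at in mol_b.GetAtoms() if at.GetAtomicNum() > 1)
    return len(mapping) / max(heavy_a, heavy_b)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[ra] = rb
        return True


def build_map(ligands, target_degree: int = 2, opts: McsOptions | None = None,
              similarity: dict[tuple[str, str], float] | None = None) -> PerturbationMap:
    """Build a connected perturbation map from ligand similarity.

    Kruskal MST on distance 1 − similarity (ties broken by lexicographic
    edge id, so the result is deterministic), then the highest-similarity
    non-tree pairs are added greedily until every node has degree
    ``target_degree`` or candidates run out.  ``target_degree`` ≥ 2 puts
    every ligand on a cycle.

    ``ligands`` is a list of :class:`~nesfe.chemdata.LigandRecord`;
    ``similarity`` may supply precomputed scores keyed by sorted id pairs
    (used by the synthetic generators and for testing).
    """
    if ligands and hasattr(ligands[0], "id"):
        ids = [lig.id for lig in ligands]
    else:
        ids = [str(x) for x in ligands]
        if similarity is None:
            raise ValueError("bare ids require a precomputed similarity table")
    if len(ids) < 2:
        raise ValueError("need at least 2 ligands to build a map")
    if target_degree < 1:
        raise ValueError("target_degree must be ≥ 1")

    if similarity is None:
        mols = {lig.id: lig.to_mol() for lig in ligands}
        similarity = {}
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                key = tuple(sorted((a, b)))
                similarity[key] = mcs_similarity(mols[a], mols[b], opts)

    candidates = [
        Edge(a, b, s)
        for (a, b), s in similarity.items()
        if s > 0.0
    ]
    connected_nodes = {e.a for e in candidates} | {e.b for e in candidates}
    isolated = [n for n in ids if n not in connected_nodes]
    if isolated:
        raise DisconnectedMapError(
            f"ligand(s) {isolated} have zero similarity to every other ligand"
        )

    # Kruskal on (distance, edge id)
    uf = _UnionFind(ids)
    tree: list[Edge] = []
    for e in sorted(candidates, key=lambda e: (1.0 - e.similarity, e.id)):
        if uf.union(e.a, e.b):
            tree.append(e)
    if len(tree) != len(ids) - 1:
        comps: dict[str, list[str]] = {}
        for n in ids:
            comps.setdefault(uf.find(n), []).append(n)
        raise DisconnectedMapError(
            f"similarity graph is disconnected; components: {sorted(comps.values())}"
        )

    in_map = {frozenset((e.a, e.b)) for e in tree}
    degree = {n: 0 for n in ids}
    for e in tree:
        degree[e.a] += 1
        degree[e.b] += 1
    extra: list[Edge] = []
    for e in sorted(candidates, key=lambda e: (-e.similarity, e.id)):
        if frozenset((e.a, e.b)) in in_map:
            continue
        if degree[e.a] < target_degree or degree[e.b] < target_degree:
            extra.append(e)
            in_map.add(frozenset((e.a, e.b)))
            degree[e.a] += 1
            degree[e.b] += 1

    edges = sorted(tree + extra, key=lambda e: e.id)
    return PerturbationMap(ids, edges)


def write_map(path: str | Path, pmap: PerturbationMap) -> None:
    """Write the map as CSV with columns source,target,similarity."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target", "similarity"])
        for e in pmap.edges:
            writer.writerow([e.a, e.b, repr(float(e.similarity))])


def read_map(path: str | Path, nodes: list[str] | None = None) -> PerturbationMap:
    """Read a map CSV; ``nodes``, if given, fixes the node set (an edge
    naming an unlisted node, or a node left without edges, is an error)."""
    edges: list[Edge] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        need = {"source", "target", "similarity"}
        if reader.fieldnames is None or not need <= set(reader.fieldnames):
            raise ValueError(f"{path}: CSV must have header source,target,similarity")
        for row in reader:
            edges.append(Edge(row["source"].strip(), row["target"].strip(),
                              float(row["similarity"])))
    if nodes is None:
        seen: list[str] = []
        for e in edges:
            for n in (e.a, e.b):
                if n not in seen:
                    seen.append(n)
        nodes = seen
    else:
        known = set(nodes)
        for e in edges:
            if e.a not in known or e.b not in known:
                raise ValueError(f"edge {e.id} references unknown node")
    return PerturbationMap(nodes, edges)


def write_graphml(path: str | Path, pmap: PerturbationMap) -> None:
    """GraphML export for external visualization tools."""
    nx.write_graphml(pmap.to_networkx(), str(path))
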