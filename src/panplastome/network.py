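"""Haplotype networks: minimum spanning network (MSN) and a Bandelt-style
median-joining network with majority-rule median (Steiner) vectors.

Characters are unordered states compared by Hamming distance. All choices
the original algorithm leaves open are made deterministic: candidate medians
are considered in sorted sequence order, and three-way column ties take the
state of the lexicographically smallest haplotype id in the triplet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

from .errors import InputError
from .popgen import HaplotypeSet


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise InputError("sequences have unequal length")
    return sum(1 for x, y in zip(a, b) if x != y)


@dataclass
class HaploNetwork:
    """Observed haplotypes plus median vectors with Hamming-weighted edges."""

    graph: nx.Graph

    @property
    def observed_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if not d["is_median"]]

    @property
    def median_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["is_median"]]

    def total_cost(self) -> int:
        """Weight of a minimum spanning tree over the network's node set."""
        tree = nx.minimum_spanning_tree(self.graph, weight="weight")
        return int(sum(d["weight"] for _, _, d in tree.edges(data=True)))

    def edge_list(self) -> list[tuple[str, str, int]]:
        return sorted(
            (min(u, v), max(u, v), int(d["weight"]))
            for u, v, d in self.graph.edges(data=True)
        )


class _DSU:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _msn_edges(seqs: dict[str, str], epsilon: int = 0) -> list[tuple[str, str, int]]:
    """Union-of-all-MSTs edges via a grouped Kruskal sweep.

    An edge of weight w is kept when its endpoints lie in different
    components of the graph restricted to edges of weight < w - epsilon.
    """
    names = sorted(seqs)
    pairs = sorted(
        (hamming(seqs[a], seqs[b]), a, b) for a, b in combinations(names, 2)
    )
    edges: list[tuple[str, str, int]] = []
    kept_so_far: list[tuple[int, str, str]] = []
    for w, a, b in pairs:
        dsu = _DSU(names)
        for w2, a2, b2 in kept_so_far:
            if w2 < w - epsilon:
                dsu.union(a2, b2)
        if dsu.find(a) != dsu.find(b):
            edges.append((a, b, w))
            kept_so_far.append((w, a, b))
    return edges


def _mst_cost(seqs: dict[str, str]) -> int:
    names = sorted(seqs)
    if len(names) < 2:
        return 0
    pairs = sorted(
        (hamming(seqs[a], seqs[b]), a, b) for a, b in combinations(names, 2)
    )
    dsu = _DSU(names)
    cost = 0
    for w, a, b in pairs:
        if dsu.find(a) != dsu.find(b):
            dsu.union(a, b)
            cost += w
    return cost


def _build_network(seqs: dict[str, str], observed: dict[str, list[str]],
                   epsilon: int = 0) -> HaploNetwork:
    graph = nx.Graph()
    for name, seq in seqs.items():
        graph.add_node(
            name,
            sequence=seq,
            is_median=name not in observed,
            members=list(observed.get(name, [])),
        )
    for a, b, w in _msn_edges(seqs, epsilon):
        graph.add_edge(a, b, weight=w)
    return HaploNetwork(graph=graph)


def minimum_spanning_network(hs: HaplotypeSet, epsilon: int = 0) -> HaploNetwork:
    """MSN over observed haplotypes: the union of all minimum spanning trees
    of the complete Hamming-distance graph."""
    if not hs.haplotypes:
        raise InputError("empty haplotype set")
    seqs = {h.haplotype_id: h.sequence for h in hs.haplotypes}
    observed = {h.haplotype_id: h.members for h in hs.haplotypes}
    return _build_network(seqs, observed, epsilon)


def _majority_median(triplet: list[tuple[str, str]]) -> str:
    """Per-column majority over three sequences; three-way ties take the
    state of the lexicographically smallest haplotype id."""
    ordered = sorted(triplet)  # by haplotype id
    seqs = [s for _, s in ordered]
    out = []
    for col in zip(*seqs):
        if col.count(col[0]) >= 2:
            out.append(col[0])
        elif col.count(col[1]) >= 2:
            out.append(col[1])
        elif col.count(col[2]) >= 2:
            out.append(col[2])
        else:
            out.append(col[0])  # tie: state of smallest id
    return "".join(out)


def median_joining_network(hs: HaplotypeSet, epsilon: int = 0) -> HaploNetwork:
    """Median-joining network with majority medians.

    Iterates: build the MSN over the current node set; propose the majority
    median of every mutually connected triplet; add the candidate that most
    reduces the minimum-spanning cost; repeat to a fixpoint. Unsampled median
    vectors of degree < 3 are then removed and the network re-linked.
    """
    if not hs.haplotypes:
        raise InputError("empty haplotype set")
    if epsilon < 0:
        raise InputError("epsilon must be >= 0")
    seqs = {h.haplotype_id: h.sequence for h in hs.haplotypes}
    observed = {h.haplotype_id: h.members for h in hs.haplotypes}
    n_medians = 0

    while True:
        edges = _msn_edges(seqs, epsilon)
        adj: dict[str, set[str]] = {name: set() for name in seqs}
        for a, b, _ in edges:
            adj[a].add(b)
            adj[b].add(a)
        candidates: set[str] = set()
        existing = set(seqs.values())
        for u, v, w in combinations(sorted(seqs), 3):
            if v in adj[u] and w in adj[u] and w in adj[v]:
                med = _majority_median([(u, seqs[u]), (v, seqs[v]), (w, seqs[w])])
                if med not in existing:
                    candidates.add(med)
        if not candidates:
            break
        base_cost = _mst_cost(seqs)
        best: tuple[int, str] | None = None
        for med in sorted(candidates):
            trial = dict(seqs)
            trial["_trial"] = med
            reduction = base_cost - _mst_cost(trial)
            if reduction <= 0:
                continue
            if best is None or reduction > best[0]:  # tie: first (lex smallest)
                best = (reduction, med)
        if best is None:
            break
        n_medians += 1
        seqs[f"m{n_medians}"] = best[1]

    # prune unsampled medians of degree < 3, then re-link
    while True:
        net = _build_network(seqs, observed, epsilon)
        degree = dict(net.graph.degree)
        removable = [
            name for name in seqs
            if name not in observed and degree.get(name, 0) < 3
        ]
        if not removable:
            return net
        for name in removable:
            del seqs[name]


def annotate_composition(net: HaploNetwork,
                         groups: dict[str, str]) -> HaploNetwork:
    """Attach a group->count composition to every observed node.

    Raises on samples missing from the group table; medians get an empty
    composition.
    """
    for name, data in net.graph.nodes(data=True):
        comp: dict[str, int] = {}
        for member in data["members"]:
            if member not in groups:
                raise InputError(f"sample {member!r} missing from group table")
            grp = groups[member]
            comp[grp] = comp.get(grp, 0) + 1
        data["composition"] = comp
    return net


def composition_shares(composition: dict[str, int]) -> dict[str, float]:
    """Group counts of one node as percentages of its member total."""
    total = sum(composition.values())
    if total == 0:
        return {}
    return {g: round(100.0 * c / total, 2) for g, c in composition.items()}
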