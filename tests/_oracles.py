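"""Independent reference implementations used to freeze expected values.

Everything here is deliberately brute-force and shares no code with the
package: exhaustive pair enumeration, direct closed-form evaluation, and
spanning-tree enumeration on tiny instances.
"""

from __future__ import annotations

import math
from itertools import combinations


def hd_by_pair_enumeration(counts: list[int]) -> float:
    """Probability two samples drawn without replacement differ, times
    n/(n-1) correction -- enumerated over every unordered pair."""
    samples = []
    for hap_index, count in enumerate(counts):
        samples.extend([hap_index] * count)
    n = len(samples)
    pairs = list(combinations(range(n), 2))
    differing = sum(1 for i, j in pairs if samples[i] != samples[j])
    return differing / len(pairs)


def pi_by_pair_loop(rows: list[str]) -> float:
    """Mean pairwise per-site difference over gap/N-free columns."""
    keep = [
        c for c in range(len(rows[0]))
        if all(r[c] in "ACGT" for r in rows)
    ]
    pairs = list(combinations(rows, 2))
    total = 0.0
    for a, b in pairs:
        diffs = sum(1 for c in keep if a[c] != b[c])
        total += diffs / len(keep)
    return total / len(pairs)


def tn93_closed_form(pi: dict[str, float], p1: float, p2: float, q: float) -> float:
    """Direct step-by-step evaluation of the published closed form."""
    pi_r = pi["A"] + pi["G"]
    pi_y = pi["C"] + pi["T"]
    term1 = -(2 * pi["A"] * pi["G"] / pi_r) * math.log(
        1 - pi_r * p1 / (2 * pi["A"] * pi["G"]) - q / (2 * pi_r)
    )
    term2 = -(2 * pi["T"] * pi["C"] / pi_y) * math.log(
        1 - pi_y * p2 / (2 * pi["T"] * pi["C"]) - q / (2 * pi_y)
    )
    term3 = -2 * (
        pi_r * pi_y
        - pi["A"] * pi["G"] * pi_y / pi_r
        - pi["T"] * pi["C"] * pi_r / pi_y
    ) * math.log(1 - q / (2 * pi_r * pi_y))
    return term1 + term2 + term3


def mst_union_by_enumeration(names: list[str],
                             dist: dict[tuple[str, str], int]
                             ) -> set[tuple[str, str]]:
    """Union of all minimum spanning trees, by trying every edge subset."""
    edges = sorted(dist)
    n = len(names)

    def is_spanning_tree(subset) -> bool:
        if len(subset) != n - 1:
            return False
        parent = {x: x for x in names}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for a, b in subset:
            ra, rb = find(a), find(b)
            if ra == rb:
                return False
            parent[ra] = rb
        return True

    best_cost = None
    best_trees = []
    for subset in combinations(edges, n - 1):
        if not is_spanning_tree(subset):
            continue
        cost = sum(dist[e] for e in subset)
        if best_cost is None or cost < best_cost:
            best_cost = cost
            best_trees = [subset]
        elif cost == best_cost:
            best_trees.append(subset)
    union: set[tuple[str, str]] = set()
    for tree in best_trees:
        union.update(tree)
    return union


def balanced_tn93_pair(p1_sites: int, p2_sites: int, q_sites: int,
                       repeats: int) -> tuple[str, str]:
    """A sequence pair with exactly equal pooled base frequencies and the
    requested transition/transversion site counts.

    Substitutions are applied in reciprocal pairs (e.g. one A->G and one
    G->A) so pooled composition stays perfectly balanced.
    """
    if p1_sites % 2 or p2_sites % 2 or q_sites % 4:
        raise ValueError("need even transition and 4-divisible transversion counts")
    a = list("ACGT" * repeats)
    b = a[:]
    pos = {c: [i for i, x in enumerate(a) if x == c] for c in "ACGT"}
    cursor = {c: 0 for c in "ACGT"}

    def mutate(src: str, dst: str, k: int) -> None:
        for _ in range(k):
            b[pos[src][cursor[src]]] = dst
            cursor[src] += 1

    mutate("A", "G", p1_sites // 2)
    mutate("G", "A", p1_sites // 2)
    mutate("C", "T", p2_sites // 2)
    mutate("T", "C", p2_sites // 2)
    mutate("A", "C", q_sites // 4)
    mutate("C", "A", q_sites // 4)
    mutate("G", "T", q_sites // 4)
    mutate("T", "G", q_sites // 4)
    return "".join(a), "".join(b)
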