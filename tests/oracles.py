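"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's algorithms: parsimony costs come
from exhaustive enumeration of ancestral assignments, and the spatial
expectation from averaging over every candidate placement.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np


# ---------------------------------------------------------------------------
# trees as nested tuples (leaf = str, internal = 2-tuple)


def all_rooted_binary_trees(labels: list[str]):
    """Every rooted binary labelled topology on the given tips ((2n-3)!!)."""
    if len(labels) == 1:
        yield labels[0]
        return
    for smaller in all_rooted_binary_trees(labels[:-1]):
        for pos in _positions(smaller):
            yield _attach(smaller, pos, labels[-1])


def _positions(tree, path=()):
    yield path
    if isinstance(tree, tuple):
        yield from _positions(tree[0], path + (0,))
        yield from _positions(tree[1], path + (1,))


def _attach(tree, path, label):
    if not path:
        return (tree, label)
    children = list(tree)
    children[path[0]] = _attach(children[path[0]], path[1:], label)
    return tuple(children)


def tree_to_newick(tree) -> str:
    def fmt(node):
        if isinstance(node, str):
            return node
        return f"({fmt(node[0])},{fmt(node[1])})"

    return fmt(tree) + ";"


def tree_edges(tree):
    """(edges, tip_index, n_internal): node indices with tips first."""
    tips: list[str] = []
    edges: list[tuple[int, int]] = []
    internal_count = [0]

    def walk(node):
        if isinstance(node, str):
            tips.append(node)
            return ("tip", len(tips) - 1)
        kids = [walk(child) for child in node]
        my = ("int", internal_count[0])
        internal_count[0] += 1
        for kind, idx in kids:
            edges.append((my, (kind, idx)))
        return my

    root = walk(tree)
    t = len(tips)

    def flat(ref):
        kind, idx = ref
        return idx if kind == "tip" else t + idx

    flat_edges = [(flat(a), flat(b)) for a, b in edges]
    return flat_edges, {label: i for i, label in enumerate(tips)}, internal_count[0]


def brute_force_min_costs(tree, pg: float, pl: float) -> dict[tuple[int, ...], float]:
    """Minimum parsimony cost for EVERY binary tip pattern of the tree, by
    exhaustive enumeration of all internal-state assignments (vectorized)."""
    edges, tip_index, k = tree_edges(tree)
    t = len(tip_index)
    tip_states = np.array(
        list(itertools.product((0, 1), repeat=t)), dtype=np.int8
    )  # (2^t, t)
    int_states = np.array(
        list(itertools.product((0, 1), repeat=max(k, 1))), dtype=np.int8
    )  # (2^k, k)
    P, A = tip_states.shape[0], int_states.shape[0]
    states = np.empty((P, A, t + k), dtype=np.int8)
    states[:, :, :t] = tip_states[:, None, :]
    states[:, :, t:] = int_states[None, :, :k]
    cost = np.zeros((P, A))
    for parent, child in edges:
        ps, cs = states[:, :, parent], states[:, :, child]
        cost += np.where((ps == 0) & (cs == 1), pg, 0.0)
        cost += np.where((ps == 1) & (cs == 0), pl, 0.0)
    best = cost.min(axis=1)
    order = sorted(tip_index, key=tip_index.get)  # labels by index
    return {tuple(row): float(b) for row, b in zip(tip_states.tolist(), best)}, order


def enumerate_expected_pairs(n: int, c: int, w: int, circular: bool = False) -> Fraction:
    """Exact mean of the neighbour-pair count over all C(n, c) placements."""
    from math import comb

    total = 0
    for positions in itertools.combinations(range(n), c):
        flags = [0] * n
        for p in positions:
            flags[p] = 1
        count = 0
        for i in range(n):
            if not flags[i]:
                continue
            for d in range(1, w + 1):
                j = (i + d) % n if circular else i + d
                if not circular and j >= n:
                    break
                if j != i and flags[j]:
                    count += 1
                    break
        total += count
    return Fraction(total, comb(n, c))


def enumerate_expected_coupled(pairs: list[tuple[int, int]], n: int, n2: int) -> Fraction:
    """Exact mean coupled-pair count over ALL C(n, n2) candidate subsets."""
    from math import comb

    total = 0
    for subset in itertools.combinations(range(n), n2):
        s = set(subset)
        total += sum(1 for a, b in pairs if a in s and b in s)
    return Fraction(total, comb(n, n2))
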