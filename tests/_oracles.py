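"""Independent brute-force oracles used by the tests.

Everything here is deliberately written from first principles (exhaustive
enumeration, closed forms via math.comb, direct normal formulas) and never
calls the implementation under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# tree enumeration and brute-force parsimony
# ---------------------------------------------------------------------------

def rooted_binary_trees(leaves: list):
    """All rooted binary leaf-labeled topologies ((2n-3)!! of them)."""
    if len(leaves) == 1:
        return [leaves[0]]
    if len(leaves) == 2:
        return [(leaves[0], leaves[1])]
    smaller = rooted_binary_trees(leaves[:-1])
    new = leaves[-1]
    out = []
    for tree in smaller:
        # _n_edges counts every node's parent edge plus one virtual root
        # edge, i.e. exactly the number of insertion positions
        for i in range(_n_edges(tree)):
            out.append(_insert_at_edge(tree, new, i)[0])
    return out


def _n_edges(tree) -> int:
    if not isinstance(tree, tuple):
        return 1  # the edge leading to this leaf
    return 1 + sum(_n_edges(c) for c in tree)


def _insert_at_edge(tree, new, i):
    """Attach ``new`` as sibling of the subtree whose parent edge has index i
    (root edge = last index)."""
    if not isinstance(tree, tuple):
        if i == 0:
            return (tree, new), -1
        return tree, i - 1
    for pos, child in enumerate(tree):
        child2, i = _insert_at_edge(child, new, i)
        if i == -1:
            return tree[:pos] + (child2,) + tree[pos + 1 :], -1
    if i == 0:
        return (tree, new), -1
    return tree, i - 1


def tree_nodes(tree):
    """(internal nodes in postorder, leaf labels in postorder)."""
    internals, leaves = [], []

    def walk(node):
        if not isinstance(node, tuple):
            leaves.append(node)
            return ("leaf", len(leaves) - 1)
        kids = [walk(c) for c in node]
        internals.append(kids)
        return ("int", len(internals) - 1)

    walk(tree)
    return internals, leaves


def brute_force_lengths_all_characters(tree, n_states: int) -> tuple[list, np.ndarray]:
    """Minimum changes over *all* internal labelings, for every character.

    Returns (leaf order, array of length n_states**n_leaves) where character
    index c encodes leaf states base-n_states, first leaf least significant.
    """
    internals, leaves = tree_nodes(tree)
    n_int, n_leaf = len(internals), len(leaves)
    labelings = np.indices((n_states,) * n_int).reshape(n_int, -1).T  # (L, n_int)
    chars = np.indices((n_states,) * n_leaf).reshape(n_leaf, -1).T  # (C, n_leaf)

    cost_int = np.zeros(labelings.shape[0], dtype=np.int32)
    cost_leaf = np.zeros((labelings.shape[0], chars.shape[0]), dtype=np.int32)
    for parent_idx, kids in enumerate(internals):
        for kind, idx in kids:
            if kind == "int":
                cost_int += labelings[:, parent_idx] != labelings[:, idx]
            else:
                cost_leaf += (
                    labelings[:, parent_idx, None] != chars[None, :, idx]
                )
    total = cost_leaf + cost_int[:, None]
    return leaves, total.min(axis=0)


def brute_force_length(tree, states: dict) -> int:
    """Minimum changes for a single character (small trees only)."""
    internals, leaves = tree_nodes(tree)
    alphabet = sorted(set(states.values()))
    best = math.inf
    for lab in itertools.product(range(len(alphabet)), repeat=len(internals)):
        cost = 0
        for parent_idx, kids in enumerate(internals):
            for kind, idx in kids:
                if kind == "int":
                    cost += lab[parent_idx] != lab[idx]
                else:
                    cost += alphabet[lab[parent_idx]] != states[leaves[idx]]
        best = min(best, cost)
    return int(best)


def tuple_tree_to_newick(tree) -> str:
    def fmt(node):
        if not isinstance(node, tuple):
            return str(node)
        return "(" + ",".join(fmt(c) for c in node) + ")"

    return fmt(tree) + ";"


# ---------------------------------------------------------------------------
# exact statistics
# ---------------------------------------------------------------------------

def fisher_two_sided_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by direct hypergeometric enumeration
    (probability-mass rule), margins fixed."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def prob(x):
        return math.comb(r1, x) * math.comb(r2, c1 - x) / denom

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    total = 0.0
    for x in range(lo, hi + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


def pooled_z(k1, n1, k2, n2) -> float:
    p1, p2 = k1 / n1, k2 / n2
    pool = (k1 + k2) / (n1 + n2)
    var = pool * (1 - pool) * (1 / n1 + 1 / n2)
    if var == 0:
        return 0.0
    return (p1 - p2) / math.sqrt(var)


def wilson_interval(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    """Closed-form Wilson score interval (proportion scale)."""
    phat = k / n
    denom = 1 + z**2 / n
    center = (phat + z**2 / (2 * n)) / denom
    half = z * math.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
    return center - half, center + half


def pearson_r_and_p(x, y) -> tuple[float, float]:
    """Pearson correlation and the two-sided t-based p, from the formulas."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    xm, ym = x - x.mean(), y - y.mean()
    r = float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))
    t = r * math.sqrt((n - 2) / (1 - r**2))
    from scipy.stats import t as tdist

    p = 2 * tdist.sf(abs(t), df=n - 2)
    return r, float(p)
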