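"""Independent brute-force oracles used by both unit and acceptance tests.

These deliberately avoid the library's own algorithms: parsimony state sets
come from exhaustive enumeration of every internal-node labeling, and motif
hits from a per-window IUPAC character-set check.
"""

from __future__ import annotations

import itertools

import numpy as np

STATES = "ACGT-"

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"},
    "D": {"A", "G", "T"}, "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# random rooted binary trees and exhaustive small parsimony
# ---------------------------------------------------------------------------

def random_binary_tree(rng: np.random.Generator, n_leaves: int):
    """Nested-tuple rooted binary tree over leaf indices 0..n_leaves-1."""
    items: list = list(range(n_leaves))
    while len(items) > 1:
        j = int(rng.integers(1, len(items)))
        i = int(rng.integers(0, j))
        b = items.pop(j)
        a = items.pop(i)
        items.append((a, b))
    return items[0]


def tree_to_newick(tree, leaf_name=lambda i: f"L{i}") -> str:
    def render(node) -> str:
        if isinstance(node, int):
            return leaf_name(node)
        left, right = node
        return f"({render(left)},{render(right)})"

    return render(tree) + ";"


def _collect(tree, leaves, internals, parent_edges, parent=None):
    if isinstance(tree, int):
        leaves.append(tree)
        if parent is not None:
            parent_edges.append((parent, ("leaf", tree)))
        return ("leaf", tree)
    key = ("node", len(internals))
    internals.append(key)
    if parent is not None:
        parent_edges.append((parent, key))
    for child in tree:
        _collect(child, leaves, internals, parent_edges, key)
    return key


def tree_structure(tree):
    """(internal node keys, edges, clades) for exhaustive labeling.

    ``clades`` maps each internal key to the frozenset of leaf indices below
    it, so a test can pick an ingroup clade and find its MRCA key.
    """
    leaves: list[int] = []
    internals: list = []
    edges: list = []
    root = _collect(tree, leaves, internals, edges)

    def clade(node):
        if isinstance(node, int):
            return frozenset([node])
        return frozenset().union(*(clade(c) for c in node))

    clades = {}

    def walk(node, key_iter):
        if isinstance(node, int):
            return
        key = next(key_iter)
        clades[key] = clade(node)
        for child in node:
            walk(child, key_iter)

    walk(tree, iter(internals))
    return root, internals, edges, clades


_LABELINGS_CACHE: dict[int, np.ndarray] = {}


def _all_labelings(m: int) -> np.ndarray:
    if m not in _LABELINGS_CACHE:
        _LABELINGS_CACHE[m] = np.array(
            list(itertools.product(range(len(STATES)), repeat=m)), dtype=np.int8
        )
    return _LABELINGS_CACHE[m]


def brute_force_state_set(tree, leaf_states: dict[int, str], target_key) -> set[str]:
    """States at ``target_key`` achieving the global minimal mutation count.

    Enumerates every assignment of the 5 states to every internal node and
    counts state changes over all edges.
    """
    root, internals, edges, _ = tree_structure(tree)
    m = len(internals)
    lab = _all_labelings(m)
    idx = {key: k for k, key in enumerate(internals)}
    n_rows = lab.shape[0]
    cost = np.zeros(n_rows, dtype=np.int32)
    state_idx = {s: i for i, s in enumerate(STATES)}
    for a, b in edges:
        va = lab[:, idx[a]] if a[0] == "node" else np.full(n_rows, state_idx[leaf_states[a[1]]], dtype=np.int8)
        vb = lab[:, idx[b]] if b[0] == "node" else np.full(n_rows, state_idx[leaf_states[b[1]]], dtype=np.int8)
        cost += va != vb
    best = cost.min()
    target_col = lab[:, idx[target_key]]
    return {STATES[s] for s in np.unique(target_col[cost == best])}


def brute_force_min_cost(tree, leaf_states: dict[int, str]) -> int:
    root, internals, edges, _ = tree_structure(tree)
    lab = _all_labelings(len(internals))
    idx = {key: k for k, key in enumerate(internals)}
    n_rows = lab.shape[0]
    state_idx = {s: i for i, s in enumerate(STATES)}
    cost = np.zeros(n_rows, dtype=np.int32)
    for a, b in edges:
        va = lab[:, idx[a]] if a[0] == "node" else np.full(n_rows, state_idx[leaf_states[a[1]]], dtype=np.int8)
        vb = lab[:, idx[b]] if b[0] == "node" else np.full(n_rows, state_idx[leaf_states[b[1]]], dtype=np.int8)
        cost += va != vb
    return int(cost.min())


# ---------------------------------------------------------------------------
# naive motif scanning
# ---------------------------------------------------------------------------

def naive_motif_scan(seq: str, consensus: str, both_strands: bool = True):
    """(start, end, strand) of every window matching the IUPAC consensus."""
    w = len(consensus)
    hits = []
    for start in range(len(seq) - w + 1):
        window = seq[start : start + w]
        if all(ch in IUPAC_SETS[c] for ch, c in zip(window, consensus)):
            hits.append((start, start + w, "+"))
        if both_strands:
            rev = "".join(COMPLEMENT[ch] for ch in reversed(window))
            if all(ch in IUPAC_SETS[c] for ch, c in zip(rev, consensus)):
                hits.append((start, start + w, "-"))
    return sorted(set(hits))
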