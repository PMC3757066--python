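"""Small-parsimony ancestral reconstruction at the ingroup MRCA.

Given a gapped alignment and a rooted tree whose leaves name alignment rows,
infer for every alignment column the set of character states over
``{A, C, G, T, -}`` that the most recent common ancestor of the ingroup can
take in at least one maximum-parsimony labeling.  Gaps are treated as a fifth
character state; indel event semantics are applied downstream by the mutation
caller.

The per-column state sets are exact: the implementation runs unit-cost small
parsimony (Fitch counts) with an inside pass (minimal cost of each subtree
conditioned on the subtree root's state) and an outside pass (minimal cost of
the rest of the tree), so a state is reported at the MRCA iff the global
minimum mutation count is achievable with that state.  A single consensus row
is then resolved from the state sets by a deterministic tie-break, and the
full ambiguity bookkeeping is retained.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .seq_io import GAP, GappedAlignment, SequenceRecord

#: Parsimony state order; '-' sorts last in tie-breaks.
STATES = "ACGT-"
_STATE_INDEX = {s: i for i, s in enumerate(STATES)}
_INF = 10**6


class ReconstructionError(ValueError):
    """Raised for tree/alignment mismatches or an empty ingroup."""


@dataclass(frozen=True)
class Phylogeny:
    """A rooted tree plus the set of leaf names declared as the ingroup.

    The ingroup must be a subset of the leaves, and its MRCA must exclude at
    least one other leaf (i.e. there is a genuine outgroup to root against).
    """

    tree: dendropy.Tree
    ingroup: frozenset[str]

    def __post_init__(self) -> None:
        leaves = set(self.leaf_names)
        if not self.ingroup:
            raise ReconstructionError("ingroup is empty")
        missing = self.ingroup - leaves
        if missing:
            raise ReconstructionError(f"ingroup names not in tree: {sorted(missing)}")
        if not leaves - self.ingroup:
            raise ReconstructionError(
                "ingroup spans every leaf; at least one outgroup leaf is required"
            )

    @property
    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @classmethod
    def from_newick(cls, newick: str, ingroup: set[str] | list[str]) -> "Phylogeny":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        tree.is_rooted = True
        return cls(tree=tree, ingroup=frozenset(ingroup))

    @classmethod
    def from_file(cls, path: str | Path, ingroup: set[str] | list[str]) -> "Phylogeny":
        return cls.from_newick(Path(path).read_text(), ingroup)


@dataclass(frozen=True)
class AncestralReconstruction:
    """Per-column parsimony state sets at the ingroup MRCA plus one resolved row.

    Attributes
    ----------
    state_sets : tuple of frozenset
        For every alignment column, the maximum-parsimony states at the MRCA.
    consensus : str
        One resolved gapped row; ``consensus[c]`` is always in ``state_sets[c]``.
    ambiguous_cols : tuple of int
        Columns with more than one maximum-parsimony state.
    polymorphic_cols : tuple of int
        Columns at which the ingroup rows are not all identical (column
        granularity: a multi-column indel polymorphism contributes one entry
        per column; event-level counts live in the mutation catalogue).
    """

    state_sets: tuple[frozenset[str], ...]
    consensus: str
    ambiguous_cols: tuple[int, ...]
    polymorphic_cols: tuple[int, ...]

    @property
    def n_cols(self) -> int:
        return len(self.state_sets)

    def consensus_record(self, seq_id: str = "Concestor") -> SequenceRecord:
        """The consensus with gaps stripped, as an ungapped record."""
        return SequenceRecord(id=seq_id, residues=self.consensus.replace(GAP, ""))

    def ambiguity_table(self) -> pd.DataFrame:
        """Report of ambiguous columns: states, chosen state (1-based column shown too)."""
        rows = [
            {
                "column": c,
                "column_1based": c + 1,
                "states": "".join(sorted(self.state_sets[c], key=_STATE_INDEX.get)),
                "chosen": self.consensus[c],
            }
            for c in self.ambiguous_cols
        ]
        return pd.DataFrame(rows, columns=["column", "column_1based", "states", "chosen"])


def _resolve_multifurcations(tree: dendropy.Tree) -> dendropy.Tree:
    # Caterpillar resolution in input child order; unit-cost minima are
    # unchanged by how a polytomy is resolved.
    tree = tree.clone(depth=1)
    tree.resolve_polytomies(limit=2, update_bipartitions=False)
    return tree


def _ingroup_mrca(tree: dendropy.Tree, ingroup: frozenset[str]) -> dendropy.Node:
    node = tree.mrca(taxon_labels=list(ingroup))
    if node is None:
        raise ReconstructionError("could not locate ingroup MRCA")
    under = {lf.taxon.label for lf in node.leaf_iter()}
    extra = under - ingroup
    # The MRCA clade may contain non-ingroup leaves only if the ingroup is not
    # monophyletic in the supplied tree; reconstruction still proceeds (the
    # node is well defined) but outgroups nested inside would be a data error.
    if node.parent_node is None and extra:
        raise ReconstructionError(
            "ingroup MRCA is the root; the ingroup must exclude at least one leaf"
        )
    return node


def fitch_reconstruct(aln: GappedAlignment, tree: Phylogeny) -> AncestralReconstruction:
    """Infer the maximum-parsimony state sets at the ingroup MRCA.

    Uniform-cost small parsimony over the 5-state alphabet ``{A,C,G,T,-}``,
    vectorised across alignment columns.  The consensus at an ambiguous column
    is the state carried by the plurality of outgroup leaves at that column;
    if still tied, the plurality of ingroup leaves; if still tied, alphabetical
    with ``-`` last.

    Raises
    ------
    ReconstructionError
        If tree leaves and alignment rows disagree, or the ingroup is empty.
    """
    leaf_names = tree.leaf_names
    missing = [n for n in leaf_names if n not in aln]
    if missing:
        raise ReconstructionError(f"tree leaves missing from alignment: {missing}")

    work = _resolve_multifurcations(tree.tree)
    mrca = _ingroup_mrca(work, tree.ingroup)

    nodes = list(work.postorder_node_iter())
    node_id = {id(n): k for k, n in enumerate(nodes)}
    n_cols = aln.n_cols
    n_states = len(STATES)

    # Inside pass: cost[k, c, s] = minimal mutations within node k's subtree
    # given node k carries state s at column c.
    cost = np.zeros((len(nodes), n_cols, n_states), dtype=np.int64)
    for k, node in enumerate(nodes):
        if node.is_leaf():
            row = aln.row(node.taxon.label)
            idx = np.fromiter((_STATE_INDEX[ch] for ch in row), dtype=np.int64, count=n_cols)
            leaf_cost = np.full((n_cols, n_states), _INF, dtype=np.int64)
            leaf_cost[np.arange(n_cols), idx] = 0
            cost[k] = leaf_cost
        else:
            total = np.zeros((n_cols, n_states), dtype=np.int64)
            for child in node.child_nodes():
                c = cost[node_id[id(child)]]
                # unit-cost message: min(c(s), min_t c(t) + 1)
                total += np.minimum(c, c.min(axis=1, keepdims=True) + 1)
            cost[k] = total

    root = nodes[-1]
    total_min = cost[node_id[id(root)]].min(axis=1)  # per-column MP mutation count

    # Outside pass along the root -> MRCA path: outside[c, s] = minimal
    # mutations outside the current node's subtree given the node has state s.
    path = []
    node = mrca
    while node is not None:
        path.append(node)
        node = node.parent_node
    path.reverse()  # root ... mrca

    outside = np.zeros((n_cols, n_states), dtype=np.int64)
    for parent, child in zip(path, path[1:]):
        c_child = cost[node_id[id(child)]]
        msg_child = np.minimum(c_child, c_child.min(axis=1, keepdims=True) + 1)
        sans_child = cost[node_id[id(parent)]] - msg_child
        g = outside + sans_child
        outside = np.minimum(g, g.min(axis=1, keepdims=True) + 1)

    mrca_total = cost[node_id[id(mrca)]] + outside
    is_mp = mrca_total == total_min[:, None]

    # Tie-break tallies.
    ingroup_ids = [n for n in aln.ids if n in tree.ingroup]
    outgroup_ids = [n for n in leaf_names if n not in tree.ingroup]
    out_counts = _state_counts(aln, outgroup_ids)
    in_counts = _state_counts(aln, ingroup_ids)

    state_sets: list[frozenset[str]] = []
    consensus_chars: list[str] = []
    ambiguous: list[int] = []
    for c in range(n_cols):
        states = [STATES[s] for s in np.flatnonzero(is_mp[c])]
        state_sets.append(frozenset(states))
        if len(states) > 1:
            ambiguous.append(c)
        consensus_chars.append(
            _tie_break(states, out_counts[c], in_counts[c])
        )

    ingroup_rows = [aln.row(n) for n in ingroup_ids]
    polymorphic = tuple(
        c for c in range(n_cols)
        if len({row[c] for row in ingroup_rows}) > 1
    )

    return AncestralReconstruction(
        state_sets=tuple(state_sets),
        consensus="".join(consensus_chars),
        ambiguous_cols=tuple(ambiguous),
        polymorphic_cols=polymorphic,
    )


def _state_counts(aln: GappedAlignment, ids: list[str]) -> np.ndarray:
    counts = np.zeros((aln.n_cols, len(STATES)), dtype=np.int64)
    for rid in ids:
        row = aln.row(rid)
        for c, ch in enumerate(row):
            counts[c, _STATE_INDEX[ch]] += 1
    return counts


def _tie_break(states: list[str], out_counts: np.ndarray, in_counts: np.ndarray) -> str:
    if len(states) == 1:
        return states[0]
    # plurality among outgroup rows, then ingroup rows, then A<C<G<T<'-'
    def key(s: str) -> tuple[int, int, int]:
        i = _STATE_INDEX[s]
        return (-int(out_counts[i]), -int(in_counts[i]), i)

    return min(states, key=key)


def enumerate_alternates(
    recon: AncestralReconstruction, max_count: int
) -> tuple[list[str], int]:
    """Enumerate resolved consensus rows over the ambiguous columns.

    Returns up to ``max_count`` rows in a deterministic order (at each
    ambiguous column the consensus state comes first, remaining states in
    A<C<G<T<'-' order; columns vary fastest at the right), together with the
    total number of alternates (the product of state-set sizes).  The first
    row is always the primary consensus.
    """
    if max_count < 1:
        raise ValueError("max_count must be >= 1")
    cols = list(recon.ambiguous_cols)
    choices = []
    for c in cols:
        chosen = recon.consensus[c]
        rest = sorted(recon.state_sets[c] - {chosen}, key=_STATE_INDEX.get)
        choices.append([chosen] + rest)
    total = 1
    for ch in choices:
        total *= len(ch)
    out: list[str] = []
    base = list(recon.consensus)
    for combo in itertools.islice(itertools.product(*choices), max_count):
        row = base.copy()
        for c, s in zip(cols, combo):
            row[c] = s
        out.append("".join(row))
    return out, total


def pairwise_identity(aln: GappedAlignment, id_a: str, id_b: str) -> float:
    """Fraction of comparable columns (no gap in either row) that match."""
    row_a, row_b = aln.row(id_a), aln.row(id_b)
    comparable = matches = 0
    for a, b in zip(row_a, row_b):
        if a != GAP and b != GAP:
            comparable += 1
            if a == b:
                matches += 1
    if comparable == 0:
        raise ValueError(f"identity of {id_a!r} vs {id_b!r} undefined: no comparable columns")
    return matches / comparable


def mean_pairwise_identity(aln: GappedAlignment, ids: list[str]) -> float:
    """Mean of pairwise_identity over all unordered pairs in ``ids``."""
    pairs = list(itertools.combinations(ids, 2))
    if not pairs:
        raise ValueError("need at least two ids")
    return float(np.mean([pairwise_identity(aln, a, b) for a, b in pairs]))
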