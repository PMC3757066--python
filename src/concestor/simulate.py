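"""Ground-truth synthetic datasets emulating the study design.

The generator produces everything the pipeline consumes, with the truth
recorded alongside: a ~700-bp ancestral element with planted binding-site
instances (14 ABD-B ``TTTAY`` + 2 DSX ``RNNACWAWGTNNY`` by default), a rooted
tree of 31 ingroup alleles plus 7 outgroups, sequences evolved down the tree
by per-branch substitutions and geometric-length indels, the true alignment
maintained by construction (no realignment step, so indel placement is
exact), per-ingroup-leaf true event lists, F2 cross genotype counts under a
single semi-dominant locus, and noisy replicate reporter intensities.

The default (study-scale) tree shapes the ingroup as two caterpillar clades
joined by longer stem branches.  Shared internal branches are what let 31
alleles show ~98% mean pairwise identity while accumulating only ~50
polymorphic columns in total — on a star tree those two study-scale
conditions are mutually exclusive.  Branch substitution probabilities were
calibrated once to those two conditions and frozen (see docs/methods.md).

All randomness flows from a single integer seed; per-branch and per-stage
sub-streams are derived deterministically, so identical configs give
byte-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mutations import MutationEvent
from .activity import ActivityMeasurements
from .motifs import Motif, DEFAULT_MOTIFS
from .seq_io import GAP, GappedAlignment, SequenceRecord

_BASES = "ACGT"
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "S": "CG",
    "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT",
    "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults for the synthetic dataset.

    Branch "lengths" are per-site substitution probabilities.  ``stem_prob``
    is used for the two branches joining the ingroup clades to their MRCA
    (shared polymorphism), ``ingroup_prob`` for every other ingroup branch,
    and ``outgroup_prob`` for outgroup/backbone branches.
    """

    seed: int
    n_ingroup: int = 31
    n_outgroup: int = 7
    length: int = 700
    gc: float = 0.40
    ingroup_prob: float = 0.0008
    stem_prob: float = 0.008
    outgroup_prob: float = 0.012
    indel_prob: float = 1.0e-4
    indel_mean_len: float = 3.0
    planted_motifs: tuple[tuple[Motif, int], ...] = (
        (DEFAULT_MOTIFS[0], 14),
        (DEFAULT_MOTIFS[1], 2),
    )
    protect_planted: bool = True
    cross_n: int = 102
    noise_sd: float = 10.0
    n_replicates: int = 6
    newick: str | None = None

    def __post_init__(self) -> None:
        for name in ("ingroup_prob", "stem_prob", "outgroup_prob", "indel_prob", "gc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.length < 1 or self.n_ingroup < 2 or self.n_outgroup < 1:
            raise ValueError("length >= 1, n_ingroup >= 2, n_outgroup >= 1 required")


@dataclass(frozen=True)
class SimulatedDataset:
    """A dataset plus its generating truth."""

    config: SimulationConfig
    alignment: GappedAlignment
    newick: str
    ingroup_ids: tuple[str, ...]
    true_ancestor_row: str          # ingroup-MRCA row in the final alignment frame
    true_root_row: str              # tree-root row in the final alignment frame
    true_events: dict[str, tuple[MutationEvent, ...]]  # per ingroup leaf, vs MRCA
    motif_coords: tuple[tuple[str, int, int], ...]      # (motif name, start, end) on root
    motif_cols: tuple[tuple[str, int, int], ...]        # same windows, alignment columns
    f2_counts: tuple[int, int, int]
    reporter: tuple[ActivityMeasurements, ActivityMeasurements]


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, *key])


def generate_ancestor(config: SimulationConfig) -> tuple[SequenceRecord, tuple[tuple[str, int, int], ...]]:
    """An i.i.d.-background ancestor with non-overlapping planted motif instances.

    Background bases are drawn at the configured GC fraction; each planted
    instance is sampled uniformly from the strings compatible with its IUPAC
    consensus and placed uniformly at random without overlap.  Placement
    coordinates are returned with the sequence.

    Raises
    ------
    ValueError
        If the motifs cannot be packed into the requested length.
    """
    rng = _rng(config.seed, 1)
    L = config.length
    p = [
        (1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2
    ]  # A C G T
    seq = list(rng.choice(list(_BASES), size=L, p=p))

    need = sum(len(m.consensus) * k for m, k in config.planted_motifs)
    if need > L:
        raise ValueError(f"cannot pack {need} motif bp into length {L}")
    placements: list[tuple[str, int, int]] = []
    occupied = np.zeros(L, dtype=bool)
    for motif, count in config.planted_motifs:
        w = len(motif.consensus)
        for _ in range(count):
            placed = False
            for _attempt in range(10_000):
                start = int(rng.integers(0, L - w + 1))
                if not occupied[start : start + w].any():
                    inst = "".join(rng.choice(list(_IUPAC[c])) for c in motif.consensus)
                    seq[start : start + w] = list(inst)
                    occupied[start : start + w] = True
                    placements.append((motif.name, start, start + w))
                    placed = True
                    break
            if not placed:
                raise ValueError(f"infeasible packing of motif {motif.name}")
    placements.sort(key=lambda t: t[1])
    return SequenceRecord("ancestor", "".join(seq)), tuple(placements)


# ---------------------------------------------------------------------------
# tree construction
# ---------------------------------------------------------------------------

def study_scale_newick(config: SimulationConfig) -> str:
    """Newick for the default study-scale topology.

    Ingroup: two caterpillar clades (leaves ``mel.1.1`` ...) on stem branches
    of length ``stem_prob``; outgroups ``out.1`` ... attach as a ladder below
    the ingroup MRCA.  Branch lengths are per-branch substitution
    probabilities.
    """
    names = [f"mel.{i}.1" for i in range(1, config.n_ingroup + 1)]
    half = config.n_ingroup // 2
    b = config.ingroup_prob

    def caterpillar(leaves: list[str]) -> str:
        # subtree WITHOUT a branch length on its root; callers append one
        if len(leaves) == 1:
            return leaves[0]
        tree = f"{leaves[0]}:{b}"
        for k, name in enumerate(leaves[1:], start=1):
            tree = f"({tree},{name}:{b})"
            if k < len(leaves) - 1:
                tree += f":{b}"
        return tree

    ingroup = (
        f"({caterpillar(names[:half])}:{config.stem_prob},"
        f"{caterpillar(names[half:])}:{config.stem_prob})"
    )
    tree = ingroup
    for i in range(1, config.n_outgroup + 1):
        tree = f"({tree}:{config.outgroup_prob},out.{i}:{config.outgroup_prob})"
    return tree + ";"


class _Node:
    __slots__ = ("name", "length", "children")

    def __init__(self, name: str | None, length: float):
        self.name = name
        self.length = length
        self.children: list[_Node] = []


def _parse_newick(text: str) -> _Node:
    # Minimal newick reader for generator-internal trees (names, branch
    # lengths, no quoting); user-supplied trees for analysis go through
    # dendropy in the parsimony module.
    text = text.strip().rstrip(";")
    pos = 0

    def parse() -> _Node:
        nonlocal pos
        node = _Node(None, 0.0)
        if text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse())
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
        start = pos
        while pos < len(text) and text[pos] not in ",():":
            pos += 1
        name = text[start:pos] or None
        node.name = name
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] not in ",()":
                pos += 1
            node.length = float(text[start:pos])
        return node

    return parse()


# ---------------------------------------------------------------------------
# evolution along the tree
# ---------------------------------------------------------------------------

def simulate_evolution(config: SimulationConfig) -> SimulatedDataset:
    """Evolve the planted ancestor down the tree, keeping the true alignment.

    Substitutions flip a site to one of the three other bases uniformly, with
    per-branch per-site probability equal to the branch length.  Indel events
    initiate with probability ``indel_prob`` per site per branch; each is an
    insertion or deletion with equal probability and geometric length (mean
    ``indel_mean_len``).  With ``protect_planted`` set, planted-motif columns
    are kept intact on every branch (no substitutions or indels): the planted
    sites model binding sites under purifying selection, mirroring a study
    system in which essentially all characterized sites are conserved between
    the ancestor and its descendant alleles.  Binding-site gain/loss calling
    is exercised against explicitly constructed variants instead.

    The alignment is maintained by construction: every residue carries a
    persistent column identity, insertions mint fresh columns, deletions
    drop residues from a lineage, and the final alignment is the union of
    columns observed in at least one leaf.
    """
    ancestor, motif_coords = generate_ancestor(config)
    newick = config.newick or study_scale_newick(config)
    root_node = _parse_newick(newick)

    # Global ordered list of column ids; grows by insertion, order of
    # surviving ids never changes.
    column_order: list[int] = list(range(len(ancestor.residues)))
    order_pos = {cid: i for i, cid in enumerate(column_order)}
    next_id = len(column_order)

    protected: set[int] = set()
    if config.protect_planted:
        for _, start, end in motif_coords:
            protected.update(range(start, end))

    root_seq = list(zip(range(len(ancestor.residues)), ancestor.residues))

    node_rows: dict[int, list[tuple[int, str]]] = {}
    leaf_rows: dict[str, list[tuple[int, str]]] = {}
    # Ingroup leaves are those whose names do not start with "out."; the
    # ingroup MRCA node is located after evolution from the leaf name sets.
    branch_counter = [0]

    def evolve(node: _Node, seq: list[tuple[int, str]], rng_branch: int) -> None:
        nonlocal next_id
        rng = _rng(config.seed, 2, rng_branch)
        n = len(seq)
        out = list(seq)
        is_root = rng_branch == 0  # no branch above the root: nothing mutates
        if not is_root and n and node.length > 0:
            hits = np.flatnonzero(rng.random(n) < node.length)
            for i in hits:
                cid, ch = out[i]
                if cid in protected:
                    continue
                alts = [b for b in _BASES if b != ch]
                out[i] = (cid, alts[int(rng.integers(0, 3))])
        if not is_root and n and config.indel_prob > 0:
            n_events = rng.binomial(n, config.indel_prob)
            for _ in range(n_events):
                length = int(rng.geometric(1.0 / config.indel_mean_len))
                if rng.random() < 0.5 and len(out) > length:  # deletion
                    start = int(rng.integers(0, len(out) - length + 1))
                    span = out[start : start + length]
                    if any(cid in protected for cid, _ in span):
                        continue
                    del out[start : start + length]
                else:  # insertion
                    at = int(rng.integers(0, len(out) + 1))
                    # never split a protected motif window
                    prev_protected = at > 0 and out[at - 1][0] in protected
                    next_protected = at < len(out) and out[at][0] in protected
                    if prev_protected and next_protected:
                        continue
                    # insert after the preceding residue's column in global order
                    anchor = order_pos[out[at - 1][0]] + 1 if at > 0 else 0
                    new_cols = []
                    for k in range(length):
                        new_cols.append(
                            (next_id, _BASES[int(rng.integers(0, 4))])
                        )
                        next_id += 1
                    column_order[anchor:anchor] = [cid for cid, _ in new_cols]
                    for i2, cid in enumerate(column_order[anchor:], start=anchor):
                        order_pos[cid] = i2
                    out[at:at] = new_cols
        node_rows[id(node)] = out
        if not node.children:
            leaf_rows[node.name] = out
        for child in node.children:
            branch_counter[0] += 1
            evolve(child, out, branch_counter[0])

    evolve(root_node, root_seq, 0)

    # locate the ingroup MRCA node: smallest clade containing all non-"out." leaves
    ingroup_ids = tuple(sorted(n for n in leaf_rows if not n.startswith("out.")))

    def find_mrca(node: _Node) -> _Node | None:
        leaves_under = [lf for lf in _leaves(node)]
        if set(ingroup_ids) <= set(leaves_under):
            for child in node.children:
                deeper = find_mrca(child)
                if deeper is not None:
                    return deeper
            return node
        return None

    mrca_node = find_mrca(root_node)
    assert mrca_node is not None

    # Final columns: those carried by at least one leaf.
    seen: set[int] = set()
    for row in leaf_rows.values():
        seen.update(cid for cid, _ in row)
    final_cols = [cid for cid in column_order if cid in seen]
    col_index = {cid: i for i, cid in enumerate(final_cols)}
    n_cols = len(final_cols)

    def to_row(seq: list[tuple[int, str]]) -> str:
        row = [GAP] * n_cols
        for cid, ch in seq:
            if cid in col_index:
                row[col_index[cid]] = ch
        return "".join(row)

    leaf_order = list(_leaves(root_node))
    records = [(name, to_row(leaf_rows[name])) for name in leaf_order]
    alignment = GappedAlignment(records)
    mrca_row = to_row(node_rows[id(mrca_node)])
    root_row = to_row(node_rows[id(root_node)])

    # True per-ingroup-leaf event lists against the MRCA row, collapsed with
    # the same run rules the catalogue documents (independent scan here; the
    # public caller is cross-checked against these in tests).
    true_events = {
        name: tuple(_collapse_diff(mrca_row, alignment.row(name)))
        for name in ingroup_ids
    }

    # Planted windows in final alignment columns.  Motif columns are the
    # root's original column ids; indels never remove or split them, so the
    # mapped windows are contiguous in the final alignment.
    motif_cols = tuple(
        (name, col_index[start], col_index[end - 1] + 1)
        for name, start, end in motif_coords
        if start in col_index and (end - 1) in col_index
    )

    f2_counts = simulate_f2_cross(config.cross_n, config.seed)
    reporter = simulate_reporter(
        100.0, config.noise_sd, config.n_replicates, config.seed
    )

    return SimulatedDataset(
        config=config,
        alignment=alignment,
        newick=newick,
        ingroup_ids=ingroup_ids,
        true_ancestor_row=mrca_row,
        true_root_row=root_row,
        true_events=true_events,
        motif_coords=motif_coords,
        motif_cols=motif_cols,
        f2_counts=f2_counts,
        reporter=reporter,
    )


def _leaves(node: _Node):
    if not node.children:
        yield node.name
    for child in node.children:
        yield from _leaves(child)


def _collapse_diff(ancestor_row: str, allele_row: str) -> list[MutationEvent]:
    # Generator-side collapsing: substitutions per column, maximal
    # one-sided-gap runs as single indel events.  Kept separate from
    # mutations.call_mutations so the agreement between the two is a real
    # cross-check, not a tautology.
    events = []
    n = len(ancestor_row)
    i = 0
    while i < n:
        a, d = ancestor_row[i], allele_row[i]
        if a == d:
            i += 1
        elif GAP not in (a, d):
            events.append(MutationEvent("substitution", i, i + 1, a, d))
            i += 1
        else:
            kind = "deletion" if d == GAP else "insertion"
            j = i
            if kind == "deletion":
                while j < n and allele_row[j] == GAP and ancestor_row[j] != GAP:
                    j += 1
                events.append(MutationEvent("deletion", i, j, ancestor_row[i:j], ""))
            else:
                while j < n and ancestor_row[j] == GAP and allele_row[j] != GAP:
                    j += 1
                events.append(MutationEvent("insertion", i, j, "", allele_row[i:j]))
            i = j
    return events


def simulate_f2_cross(n: int, seed: int) -> tuple[int, int, int]:
    """F2 genotype class counts under one semi-dominant, fully penetrant locus.

    Genotypes are multinomial at (1/4, 1/2, 1/4); the phenotype class equals
    the genotype class, so the returned counts serve as both.
    """
    if n < 1:
        raise ValueError("cross size n must be >= 1")
    rng = _rng(seed, 3)
    counts = rng.multinomial(n, [0.25, 0.5, 0.25])
    return (int(counts[0]), int(counts[1]), int(counts[2]))


def simulate_reporter(
    true_percent: float, noise_sd: float, n_reps: int, seed: int
) -> tuple[ActivityMeasurements, ActivityMeasurements]:
    """Noisy replicate intensities for a (test, reference) construct pair.

    Reference intensities are Normal(100, ``noise_sd``), test intensities
    Normal(``true_percent``, ``noise_sd``) on the same arbitrary scale, both
    truncated positive by redrawing.
    """
    if true_percent <= 0:
        raise ValueError("true_percent must be positive")
    if n_reps < 2:
        raise ValueError("need at least two replicates")
    rng = _rng(seed, 4)

    def draw(mu: float) -> tuple[float, ...]:
        vals = []
        while len(vals) < n_reps:
            x = float(rng.normal(mu, noise_sd))
            if x > 0:
                vals.append(x)
        return tuple(vals)

    ref = ActivityMeasurements("reference", draw(100.0))
    test = ActivityMeasurements("test", draw(true_percent))
    return test, ref
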