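"""Ancestral state sets, consensus resolution, alternates, identity."""

import numpy as np
import pytest

from concestor.parsimony import (
    AncestralReconstruction,
    Phylogeny,
    ReconstructionError,
    enumerate_alternates,
    fitch_reconstruct,
    pairwise_identity,
)
from concestor.seq_io import GappedAlignment

from .oracles import (
    brute_force_state_set,
    random_binary_tree,
    tree_structure,
    tree_to_newick,
)


def single_column_alignment(states: dict[str, str]) -> GappedAlignment:
    # pad with a constant column so no column is all-gap even if states are
    return GappedAlignment([(name, s + "A") for name, s in states.items()])


class TestFitchReconstruct:
    def test_constant_column_is_unambiguous(self):
        aln = single_column_alignment({"P1": "A", "P2": "A", "P3": "A", "O1": "A"})
        ph = Phylogeny.from_newick("((P1,(P2,P3)),O1);", {"P1", "P2", "P3"})
        rec = fitch_reconstruct(aln, ph)
        assert rec.state_sets[0] == frozenset("A")
        assert rec.ambiguous_cols == ()

    def test_minority_ingroup_state_resolved_by_outgroup(self):
        aln = single_column_alignment({"P1": "A", "P2": "A", "P3": "G", "O1": "A"})
        ph = Phylogeny.from_newick("((P1,(P2,P3)),O1);", {"P1", "P2", "P3"})
        rec = fitch_reconstruct(aln, ph)
        assert rec.state_sets[0] == frozenset("A")
        assert rec.consensus[0] == "A"

    def test_ingroup_split_with_gap_outgroups_is_ambiguous(self):
        aln = single_column_alignment(
            {"P1": "A", "P2": "A", "P3": "G", "P4": "G", "O1": "-", "O2": "-"}
        )
        ph = Phylogeny.from_newick(
            "((((P1,P2),(P3,P4)),O1),O2);", {"P1", "P2", "P3", "P4"}
        )
        rec = fitch_reconstruct(aln, ph)
        assert {"A", "G"} <= set(rec.state_sets[0])
        assert 0 in rec.ambiguous_cols

    def test_polymorphic_cols_use_ingroup_only(self):
        aln = GappedAlignment(
            [("P1", "ACA"), ("P2", "ACA"), ("O1", "GCA")]
        )
        ph = Phylogeny.from_newick("((P1,P2),O1);", {"P1", "P2"})
        rec = fitch_reconstruct(aln, ph)
        assert rec.polymorphic_cols == ()

    def test_consensus_always_within_state_set(self, study_recon):
        for c, s in enumerate(study_recon.consensus):
            assert s in study_recon.state_sets[c]

    def test_leaf_name_mismatch_raises(self, tiny_aln):
        ph = Phylogeny.from_newick("((P1,ZZ),O1);", {"P1", "ZZ"})
        with pytest.raises(ReconstructionError, match="missing"):
            fitch_reconstruct(tiny_aln, ph)

    def test_empty_ingroup_rejected(self):
        with pytest.raises(ReconstructionError, match="empty"):
            Phylogeny.from_newick("((P1,P2),O1);", set())

    def test_matches_bruteforce_oracle_small_trees(self):
        """MP state sets at a clade's MRCA equal exhaustive-labeling minima."""
        rng = np.random.default_rng(7)
        for _ in range(150):
            n = int(rng.integers(4, 8))
            tree = random_binary_tree(rng, n)
            _, internals, _, clades = tree_structure(tree)
            # pick an internal node other than the root as the ingroup MRCA
            candidates = [k for k in internals if len(clades[k]) < n]
            if not candidates:
                continue
            target = candidates[int(rng.integers(0, len(candidates)))]
            ingroup = {f"L{i}" for i in clades[target]}
            col = "".join(rng.choice(list("ACGT-"), size=n))
            if set(col) == {"-"}:
                continue
            aln = single_column_alignment(
                {f"L{i}": col[i] for i in range(n)}
            )
            ph = Phylogeny.from_newick(tree_to_newick(tree), ingroup)
            rec = fitch_reconstruct(aln, ph)
            expect = brute_force_state_set(
                tree, {i: col[i] for i in range(n)}, target
            )
            assert set(rec.state_sets[0]) == expect, (tree, col, target)

    def test_outgroup_information_relates_to_ingroup_only_sets(self):
        """Full-tree MP sets always share a state with the ingroup-only sets.

        Outgroups re-weight the ambiguity at the ingroup MRCA: they can both
        drop ingroup-optimal states and admit new ones (e.g. ingroup {G, T}
        with a C outgroup yields {C, G, T}).  What always holds is that at
        least one ingroup-only optimal state stays optimal on the full tree,
        and the minimal mutation count never decreases when outgroups are
        added.
        """
        from .oracles import brute_force_min_cost

        rng = np.random.default_rng(11)
        for _ in range(60):
            n_in, n_out = int(rng.integers(2, 5)), int(rng.integers(1, 4))
            in_tree = random_binary_tree(rng, n_in)
            full = in_tree
            for k in range(n_out):
                full = (full, n_in + k)
            n = n_in + n_out
            col = "".join(rng.choice(list("ACGT-"), size=n))
            if set(col[:n_in]) == {"-"} or set(col) == {"-"}:
                continue
            leaf_states = {i: col[i] for i in range(n)}
            _, internals, _, clades = tree_structure(full)
            target = next(
                k for k in internals if clades[k] == frozenset(range(n_in))
            ) if n_in > 1 else None
            if target is None:
                continue
            with_out = brute_force_state_set(full, leaf_states, target)
            _, in_internals, _, in_clades = tree_structure(in_tree)
            in_root = next(
                k for k in in_internals if in_clades[k] == frozenset(range(n_in))
            )
            in_states = {i: col[i] for i in range(n_in)}
            without = brute_force_state_set(in_tree, in_states, in_root)
            assert with_out & without, (col, with_out, without)
            assert brute_force_min_cost(full, leaf_states) >= brute_force_min_cost(
                in_tree, in_states
            )


class TestEnumerateAlternates:
    def make_recon(self, consensus, sets):
        state_sets = tuple(frozenset(s) for s in sets)
        ambiguous = tuple(i for i, s in enumerate(state_sets) if len(s) > 1)
        return AncestralReconstruction(
            state_sets=state_sets,
            consensus=consensus,
            ambiguous_cols=ambiguous,
            polymorphic_cols=(),
        )

    def test_three_binary_columns_give_eight(self):
        rec = self.make_recon("ACG", ["AG", "CT", "GA"])
        alts, total = enumerate_alternates(rec, 100)
        assert total == 8 and len(alts) == 8
        assert len(set(alts)) == 8
        assert alts[0] == "ACG"

    def test_no_ambiguity_gives_consensus_only(self):
        rec = self.make_recon("ACG", ["A", "C", "G"])
        alts, total = enumerate_alternates(rec, 10)
        assert alts == ["ACG"] and total == 1

    def test_truncation_reports_full_count(self):
        rec = self.make_recon("A" * 8, ["AC"] * 8)
        alts, total = enumerate_alternates(rec, 50)
        assert len(alts) == 50 and total == 256
        assert alts[0] == "A" * 8

    def test_every_alternate_respects_state_sets(self):
        rec = self.make_recon("ACGT", ["AT", "C", "GC", "T"])
        alts, total = enumerate_alternates(rec, 100)
        assert total == 4
        for alt in alts:
            for c, s in enumerate(alt):
                assert s in rec.state_sets[c]


class TestPairwiseIdentity:
    @pytest.mark.parametrize(
        "a,b,expect",
        [
            ("ACGT", "ACGT", 1.0),
            ("ACGT", "ACGA", 0.75),
            ("AC-T", "ACTT", 1.0),  # gapped column excluded: 3/3
        ],
    )
    def test_examples(self, a, b, expect):
        aln = GappedAlignment([("x", a), ("y", b)])
        assert pairwise_identity(aln, "x", "y") == pytest.approx(expect)

    def test_no_comparable_columns_is_an_error(self):
        aln = GappedAlignment([("x", "A-"), ("y", "-A")])
        with pytest.raises(ValueError, match="undefined"):
            pairwise_identity(aln, "x", "y")
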