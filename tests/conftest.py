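"""Shared fixtures: a study-scale synthetic dataset and small hand alignments."""

from __future__ import annotations

import numpy as np
import pytest

from concestor.parsimony import Phylogeny, fitch_reconstruct
from concestor.seq_io import GappedAlignment
from concestor.simulate import SimulationConfig, simulate_evolution


@pytest.fixture(scope="session")
def study_ds():
    """Default study-scale dataset: 31 ingroup + 7 outgroup leaves, ~700 bp."""
    return simulate_evolution(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def study_phylogeny(study_ds):
    return Phylogeny.from_newick(study_ds.newick, set(study_ds.ingroup_ids))


@pytest.fixture(scope="session")
def study_recon(study_ds, study_phylogeny):
    return fitch_reconstruct(study_ds.alignment, study_phylogeny)


@pytest.fixture
def tiny_aln():
    return GappedAlignment(
        [
            ("P1", "ACGTAC-T"),
            ("P2", "ACGTACGT"),
            ("P3", "ACGAACGT"),
            ("O1", "ACGTACGT"),
        ]
    )


def random_gapped_row(rng: np.random.Generator, n: int, gap_frac: float = 0.15) -> str:
    chars = rng.choice(list("ACGT-"), size=n, p=[*(0.25 * (1 - gap_frac),) * 4, gap_frac])
    row = "".join(chars)
    if set(row) == {"-"}:  # keep at least one residue
        row = "A" + row[1:]
    return row
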