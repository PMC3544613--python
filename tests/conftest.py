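import numpy as np
import pytest

import promopop as pp


@pytest.fixture(scope="session")
def fixture_table():
    """Published 22-haplotype x 5-population count table with its map."""
    return pp.build_paper_fixture()


@pytest.fixture(scope="session")
def synthetic_study():
    """One deterministic synthetic cohort emulating the study design."""
    aln, pmap, haps = pp.simulate_study(seed=7)
    return aln, pmap, haps


@pytest.fixture()
def tiny_alignment():
    """Hand-built 6-record alignment with substitutions and a tandem indel.

    Columns (0-based):      0123456789
        a1, a2:             ACGTACGTAC      (reference-like)
        b1, b2:             ACGTACGTAT      (substitution at col 9)
        c1:                 AC--ACGTAC      (2-col deletion, cols 2-3)
        c2:                 AC--ACGTAT      (same deletion + substitution)
    """
    records = (
        ("a1", "ACGTACGTAC"),
        ("a2", "ACGTACGTAC"),
        ("b1", "ACGTACGTAT"),
        ("b2", "ACGTACGTAT"),
        ("c1", "AC--ACGTAC"),
        ("c2", "AC--ACGTAT"),
    )
    pmap = pp.PopulationMap(
        tuple(
            (acc, "X" if acc[0] in "ab" else "Y", "g1" if acc[0] in "ab" else "g2")
            for acc, _ in records
        )
    )
    return pp.AlignmentSet(records), pmap


@pytest.fixture(scope="session")
def single_motif_library():
    return pp.MotifLibrary((pp.Motif("GA1", "TAACAAA", "GAmyb", "GA"),))
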