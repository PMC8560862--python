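"""Shared fixtures: small deterministic references and loci built at test time."""

import numpy as np
import pytest

from aavkit import simulate
from aavkit.refmodel import Feature, ConstructAnnotation


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def small_refset(rng):
    """Dual-cut locus scaled down for unit tests (1.2 kb, cuts 300 nt apart)."""
    return simulate.make_test_refset(rng, wt_len=1200, cut_separation=300,
                                     vector_len=900)


@pytest.fixture()
def full_refset(rng):
    """Full-scale locus: 3.6-kb amplicon with cuts 606 nt apart."""
    return simulate.make_test_refset(rng)


@pytest.fixture()
def hdr_locus(rng):
    wt, spec, cut = simulate.make_test_hdr_locus(rng)
    return wt, spec, cut


@pytest.fixture()
def construct(rng):
    return simulate.make_test_construct(rng)


@pytest.fixture()
def tiny_construct():
    """A 1-kb construct with hand-placed features for endpoint arithmetic."""
    seq = "ACGT" * 250
    features = [
        Feature("ITR5", 50, 120, "+", "ITR"),
        Feature("prom", 150, 250, "+", "promoter"),
        Feature("cassette", 400, 600, "+", "sgRNA_cassette"),
        Feature("orf", 650, 850, "+", "ORF"),
        Feature("ITR3", 880, 950, "+", "ITR"),
    ]
    return ConstructAnnotation("toy", seq, features)
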