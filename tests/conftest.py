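"""Shared fixtures: one small simulated sort community, reused marker
profiles and rRNA references. Session-scoped because profile-null
calibration and community simulation dominate suite runtime."""

import numpy as np
import pytest

from sortvir.marker_screen import build_profile
from sortvir.synthetic_data import (
    CommunityConfig,
    simulate_community,
    synthetic_marker_alignments,
    synthetic_rrna_references,
)


@pytest.fixture(scope="session")
def marker_alignments():
    return synthetic_marker_alignments()


@pytest.fixture(scope="session")
def rrna_refs():
    return synthetic_rrna_references()


@pytest.fixture(scope="session")
def marker_profiles(marker_alignments):
    return [build_profile(aln, name=name)
            for name, aln in sorted(marker_alignments.items())]


@pytest.fixture(scope="session")
def small_community(marker_alignments, rrna_refs):
    """A scaled-down sorted cell: ~1 Mb host (GC 0.45, 18S) plus ~300 kb
    giant virus (GC 0.28, 30 markers), 2000 MDA-biased read pairs."""
    config = CommunityConfig(seed=1, n_pairs=2000, emit_sub1kb=2)
    genomes, contigs, pairs, truth = simulate_community(
        config, marker_alignments, rrna_refs
    )
    return {
        "config": config,
        "genomes": genomes,
        "contigs": contigs,
        "pairs": pairs,
        "truth": truth,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
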