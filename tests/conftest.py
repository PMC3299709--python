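"""Shared fixtures: all synthetic, generated at session start."""

from __future__ import annotations

import numpy as np
import pytest

from somaclone.synthdata import (ReadProfile, build_ancestral_genome,
                                 build_te_library, derive_clone,
                                 simulate_reads)
from somaclone.tieralign import TieredAligner, run_tiered_alignment


@pytest.fixture(scope="session")
def lib4():
    return build_te_library(4, seed=7)


@pytest.fixture(scope="session")
def lib6():
    return build_te_library(6, seed=7)


@pytest.fixture(scope="session")
def tiny_ancestor(lib6):
    return build_ancestral_genome(2, 150_000, 0.25, lib6, seed=3)


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test (order-independent)."""
    return np.random.default_rng(20120312)


@pytest.fixture(scope="session")
def pair_sim(lib6):
    """Two clones of a 0.56-Mb ancestor, clean reads at 10x, fully aligned.

    The workhorse fixture for integration-level checks (partition,
    coverage, calling, ledger recovery at unit scale)."""
    anc = build_ancestral_genome(2, 350_000, 0.2, lib6, seed=5)
    n = int(anc.total_len() * 10 / 355)
    aligner = TieredAligner(anc.chromosomes, lib6)
    clones, ledgers, results, readsets = [], [], [], []
    for i, cid in enumerate(("A", "B")):
        clone, ledger = derive_clone(anc, 1.6, 5.1, 35.2, lib6,
                                     seed=31 + i, clone_id=cid)
        reads = simulate_reads(clone, n, seed=41 + i,
                               profile=ReadProfile.error_free(
                                   organelle_frac=0.038,
                                   contaminant_frac=1.3e-4,
                                   duplicate_frac=0.0058))
        res = run_tiered_alignment(reads, anc.chromosomes, lib6,
                                   anc.organelles, anc.contaminants,
                                   aligner=aligner)
        clones.append(clone)
        ledgers.append(ledger)
        readsets.append(reads)
        results.append(res)
    return {"ancestor": anc, "library": lib6, "clones": clones,
            "ledgers": ledgers, "readsets": readsets, "results": results}
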