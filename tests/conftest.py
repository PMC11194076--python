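"""Shared fixtures: a compact genome bundle and a processed cohort.

The bundle is deliberately small (100 kb nuclear) so that whole-pipeline
tests stay fast; every statistic under test is scale-free.
"""

from __future__ import annotations

import numpy as np
import pytest

from uscfmeth.align import align_bisulfite, build_bs_index
from uscfmeth.fragments import PopulationMix, sample_fragments
from uscfmeth.genome import GenomeConfig, build_genome_bundle
from uscfmeth.methylome import MethylomeParams, build_methylome
from uscfmeth.protocol import apply_protocol
from uscfmeth.readproc import process_pairs
from uscfmeth.reads import emit_reads

SMALL = GenomeConfig(nuclear_length=100_000, mito_length=16_000, lambda_length=20_000)


@pytest.fixture(scope="session")
def bundle():
    return build_genome_bundle(SMALL, seed=1)


@pytest.fixture(scope="session")
def truth_flat(bundle):
    """Constant per-population methylation (no regional overrides)."""
    return build_methylome(
        bundle,
        MethylomeParams(island_level=None, hypo_region_level=None, hyper_region_level=None),
        seed=1,
    )


@pytest.fixture(scope="session")
def truth_default(bundle):
    return build_methylome(bundle, seed=1)


@pytest.fixture(scope="session")
def bs_index(bundle):
    return build_bs_index(bundle)


def simulate_cohort(bundle, truth, mix_kwargs, n, protocol="5mCAdpBS", seed=11, **emit_kwargs):
    """Simulate -> protocol -> reads -> trim/merge, returning pairs and library."""
    mix = PopulationMix(**mix_kwargs)
    frags = sample_fragments(bundle, truth, mix, n=n, seed=seed)
    library = apply_protocol(frags, protocol, bundle=bundle, seed=seed + 1)
    reads = emit_reads(library, seed=seed + 2, **emit_kwargs)
    merged, stats = process_pairs(reads.pairs)
    return frags, library, reads, merged, stats


def align_all(merged, index):
    return [a for a in (align_bisulfite(m, index) for m in merged) if a is not None]


@pytest.fixture(scope="session")
def mixed_cohort(bundle, truth_flat, bs_index):
    """A mixed uscfDNA/mncfDNA cohort through the full pipeline."""
    frags, library, reads, merged, stats = simulate_cohort(
        bundle,
        truth_flat,
        dict(
            weights={"uscfDNA": 0.45, "mncfDNA": 0.45, "gDNA_HMW": 0.02, "lambda": 0.08},
            mito_fraction=0.01,
        ),
        n=4000,
    )
    alignments = align_all(merged, bs_index)
    return {
        "fragments": frags,
        "library": library,
        "reads": reads,
        "merged": merged,
        "alignments": alignments,
    }
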