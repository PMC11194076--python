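"""Bisulfite alignment, deduplication and size binning."""

import numpy as np
import pytest

from uscfmeth.align import (
    AlignedFragment,
    SizeBins,
    align_bisulfite,
    bin_by_size,
    build_bs_index,
    deduplicate,
)
from uscfmeth.genome import GenomeBundle, GenomeConfig
from uscfmeth.readproc import MergedRead
from tests.conftest import align_all, simulate_cohort


def _merged(seq, name="read"):
    return MergedRead(sequence=seq, quality="F" * len(seq), pair_id=name, overlap=0)


def test_index_uses_collapsed_alphabet(bundle, bs_index):
    ref = bundle.references["nuclear"]
    k = bs_index.k
    km = ref[500 : 500 + k].replace("C", "T")
    assert 500 in list(bs_index.lookup(bs_index.top["nuclear"], km))


def test_index_k_larger_than_reference_errors():
    tiny = GenomeBundle(
        references={"nuclear": "ACGT" * 4, "mito": "ACGT" * 4, "lambda": "ACGT" * 4},
        annotations={},
        tss_expression={},
    )
    with pytest.raises(ValueError):
        build_bs_index(tiny, k=20)


def test_fully_converted_read_aligns_to_source(bundle, bs_index):
    ref = bundle.references["nuclear"]
    start, L = 12_345, 80
    converted = ref[start : start + L].replace("C", "T")
    a = align_bisulfite(_merged(converted), bs_index)
    assert a is not None
    assert (a.genome, a.start, a.end, a.strand) == ("nuclear", start, start + L, "+")
    assert a.mismatches == 0
    # every reference C under the read was seen as converted
    assert all(s == "converted" for _, s in a.observed)


def test_read_from_repeated_locus_is_unaligned():
    unit = "ATTGGCCATCGGATCACGGTTAACCGTA"
    seq = unit * 3 + "T" * 400 + unit * 3  # same 84-mer at two loci
    bundle = GenomeBundle(
        references={"nuclear": seq, "mito": "ACGT" * 100, "lambda": "AACCGGTT" * 50},
        annotations={},
        tss_expression={},
    )
    idx = build_bs_index(bundle)
    read = (unit * 3).replace("C", "T")
    assert align_bisulfite(_merged(read), idx) is None


def test_unconverted_reads_align_like_plain(bundle, truth_flat, bs_index):
    # BRcfDNA (no conversion) traverses the bisulfite-aware aligner unchanged
    _, library, _, merged, _ = simulate_cohort(
        bundle, truth_flat,
        dict(weights={"mncfDNA": 1.0}, mito_fraction=0.0),
        n=400, seed=41, protocol="BRcfDNA", error_rate=0.0,
    )
    alns = align_all(merged, bs_index)
    assert len(alns) >= 0.99 * len(merged)
    exact = sum(
        1
        for a in alns
        if (p := a.pair_id.split("|"))
        and a.genome == p[1]
        and a.start == int(p[2])
        and a.end == int(p[3])
    )
    assert exact >= 0.99 * len(alns)


def test_aligned_coordinates_match_truth(mixed_cohort):
    alns = mixed_cohort["alignments"]
    merged = mixed_cohort["merged"]
    assert len(alns) >= 0.95 * len(merged)
    exact = sum(
        1
        for a in alns
        if (p := a.pair_id.split("|"))
        and a.genome == p[1]
        and a.start == int(p[2])
        and a.end == int(p[3])
    )
    assert exact >= 0.99 * len(alns)


def _af(start, end, strand="+", genome="nuclear"):
    return AlignedFragment(
        genome=genome, start=start, end=end, strand=strand,
        unique=True, mismatches=0, observed=[],
    )


def test_deduplicate_keeps_first_and_is_idempotent():
    alns = [_af(10, 60), _af(10, 60), _af(10, 70), _af(10, 60, strand="-")]
    out, removed = deduplicate(alns)
    assert removed == 1
    assert [a.end for a in out] == [60, 70, 60]
    again, removed2 = deduplicate(out)
    assert removed2 == 0 and len(again) == len(out)


def test_duplication_rate_recovered():
    rng = np.random.default_rng(0)
    base = [_af(int(s), int(s) + 50) for s in rng.choice(100_000, 2000, replace=False)]
    dup_mask = rng.random(2000) < 0.2
    alns = base + [a for a, d in zip(base, dup_mask) if d]
    out, removed = deduplicate(alns)
    assert removed == int(dup_mask.sum())


def test_size_binning_half_open_convention():
    bins = SizeBins()
    assert bins.label_for(50) == "50-59"
    assert bins.label_for(49) == "40-49"
    assert bins.label_for(20) == "20-29"
    assert bins.label_for(199) == "190-199"
    assert bins.label_for(200) == "overflow"
    assert bins.label_for(19) == "overflow"
    assert bins.is_mncfdna(167) and not bins.is_uscfdna(167)
    assert bins.is_uscfdna(40) and bins.is_uscfdna(70) and not bins.is_uscfdna(71)


def test_binning_partitions_all_fragments(mixed_cohort):
    alns = mixed_cohort["alignments"]
    binned = bin_by_size(alns)
    assert sum(len(v) for v in binned.values()) == len(alns)


def test_sam_emission_is_valid(mixed_cohort, bundle, tmp_path):
    import pysam

    from uscfmeth.align import write_sam

    alns = mixed_cohort["alignments"][:50]
    path = tmp_path / "out.sam"
    write_sam(alns, bundle, path)
    with pysam.AlignmentFile(str(path)) as fh:
        recs = list(fh)
    assert len(recs) == 50
    for a, r in zip(alns, recs):
        assert (r.reference_name, r.reference_start, r.reference_end) == (
            a.genome, a.start, a.end,
        )
        assert r.is_reverse == (a.strand == "-")
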