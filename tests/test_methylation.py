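"""Methylation calling: site counts, per-bin pooling, categories, QC."""

import warnings

import numpy as np
import pytest

from uscfmeth.align import AlignedFragment, bin_by_size
from uscfmeth.genome import GenomeBundle
from uscfmeth.methylation import (
    ConversionQCWarning,
    SiteMethylationTable,
    call_sites,
    conversion_qc,
    fragment_methylation,
    per_bin_methylation,
)
from uscfmeth.methylome import MethylomeParams, build_methylome
from tests.conftest import align_all, simulate_cohort


@pytest.fixture(scope="module")
def toy_bundle():
    #           0123456789
    seq = "ATCGATTCAGCCGATCGATT" * 3
    return GenomeBundle(
        references={"nuclear": seq, "mito": "ACGT" * 10, "lambda": "AATT" * 10},
        annotations={},
        tss_expression={},
    )


def _aln(observed, start=0, end=20, strand="+"):
    return AlignedFragment(
        genome="nuclear", start=start, end=end, strand=strand,
        unique=True, mismatches=0, observed=observed, pair_id="x",
    )


def test_single_cpg_counted(toy_bundle):
    # position 2 is a C followed by G -> CpG dyad at 2
    t = call_sites([_aln([(2, "retained")])], toy_bundle)
    row = t.df.iloc[0]
    assert (row["pos"], row["context"], row["meth"], row["unmeth"]) == (2, "CpG", 1, 0)


def test_three_retained_one_converted_is_75_percent(toy_bundle):
    alns = [_aln([(2, "retained")])] * 3 + [_aln([(2, "converted")])]
    t = call_sites(alns, toy_bundle)
    assert t.pooled_percent(("CpG",)) == pytest.approx(75.0)


def test_bottom_strand_evidence_merges_to_dyad(toy_bundle):
    # G at position 3 pairs with the C at 2: same CpG dyad
    top = _aln([(2, "retained")])
    bottom = _aln([(3, "retained")], strand="-")
    t = call_sites([top, bottom], toy_bundle)
    cpg = t.df[t.df["context"] == "CpG"]
    assert len(cpg) == 1 and int(cpg.iloc[0]["meth"]) == 2


def test_unknown_genome_errors(toy_bundle):
    bad = AlignedFragment(
        genome="chrX", start=0, end=5, strand="+", unique=True, mismatches=0, observed=[]
    )
    with pytest.raises(KeyError):
        call_sites([bad], toy_bundle)


def test_pooled_percent_is_depth_weighted_mean(toy_bundle):
    alns = [_aln([(2, "retained"), (11, "converted")])] * 2 + [_aln([(2, "converted")])]
    t = call_sites(alns, toy_bundle)
    df = t.df[t.df["context"] == "CpG"]
    depth = df["meth"] + df["unmeth"]
    site_pct = 100.0 * df["meth"] / depth
    assert t.pooled_percent(("CpG",)) == pytest.approx(float(np.average(site_pct, weights=depth)))


@pytest.mark.parametrize("p", [0.0, 0.64, 0.80, 1.0])
def test_parameter_recovery_with_default_chemistry(bundle, p, truth_flat):
    mp = MethylomeParams(
        population_means={"uscfDNA": p}, island_level=None,
        hypo_region_level=None, hyper_region_level=None,
    )
    truth = build_methylome(bundle, mp, seed=2)
    from uscfmeth.align import build_bs_index

    _, _, _, merged, _ = simulate_cohort(
        bundle, truth, dict(weights={"uscfDNA": 1.0}, mito_fraction=0.0), n=1500, seed=51
    )
    idx = build_bs_index(bundle)
    alns = align_all(merged, idx)
    t = call_sites(alns, bundle)
    expected = 100.0 * (p * (1 - 0.01) + (1 - p) * (1 - 0.995))
    assert t.pooled_percent(("CpG",)) == pytest.approx(expected, abs=1.0)


def test_per_bin_methylation_omits_empty_bins(mixed_cohort, bundle):
    binned = bin_by_size(mixed_cohort["alignments"])
    pbm = per_bin_methylation(binned, bundle)
    for label, (cpg, chh, depth) in pbm.items():
        assert depth > 0
        assert 0 <= cpg <= 100
    empty_labels = {lab for lab, alns in binned.items() if not alns}
    assert not empty_labels & set(pbm)


def test_fragment_categories(toy_bundle):
    both_conv = _aln([(2, "converted"), (11, "converted")])
    fm = fragment_methylation(both_conv, toy_bundle)
    assert fm.fraction == 0.0 and fm.category == "zero"

    quarter = _aln([(2, "retained"), (11, "converted"), (22, "converted"), (31, "converted")])
    fm = fragment_methylation(quarter, toy_bundle)
    assert fm.fraction == pytest.approx(0.25) and fm.category == "(0,25]"

    none = _aln([])
    fm = fragment_methylation(none, toy_bundle)
    assert fm.fraction is None and fm.category is None


def test_conversion_qc_thresholds(toy_bundle):
    import pandas as pd

    def table(meth, unmeth, context="CpG"):
        return SiteMethylationTable(
            df=pd.DataFrame(
                {
                    "genome": ["lambda"] * 2,
                    "pos": [1, 2],
                    "strand": [".", "."],
                    "context": [context, "CHH"],
                    "meth": [meth, meth],
                    "unmeth": [unmeth, unmeth],
                }
            )
        )

    with warnings.catch_warnings():
        warnings.simplefilter("error")
        cpg, non = conversion_qc(table(1, 199))  # 0.5% methylation
    assert cpg == pytest.approx(99.5)
    with pytest.warns(ConversionQCWarning):
        conversion_qc(table(6, 194))  # 3% -> below both thresholds
    empty = SiteMethylationTable(df=pd.DataFrame(
        columns=["genome", "pos", "strand", "context", "meth", "unmeth"]))
    with pytest.raises(ValueError):
        conversion_qc(empty)


def test_bismark_cov_round_trip(toy_bundle, tmp_path):
    alns = [_aln([(2, "retained"), (11, "converted")])] * 3
    t = call_sites(alns, toy_bundle)
    path = tmp_path / "out.cov"
    t.write_bismark_cov(path)
    back = SiteMethylationTable.read_bismark_cov(path)
    orig = t.df[t.df["context"] == "CpG"].reset_index(drop=True)
    assert list(back.df["pos"]) == list(orig["pos"])
    assert list(back.df["meth"]) == list(orig["meth"])
    assert list(back.df["unmeth"]) == list(orig["unmeth"])
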