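"""DMR scanning: construction oracle, null calibration, sensitivity."""

import numpy as np
import pytest
from scipy import stats as sps

from uscfmeth.dmr import GroupMethylationMatrix, find_dmrs


def _matrix(positions, frac, groups, genome="nuclear"):
    return GroupMethylationMatrix(
        genomes=np.array([genome] * len(positions)),
        positions=np.asarray(positions),
        fractions=np.asarray(frac, dtype=float),
        samples=[f"s{i}" for i in range(len(groups))],
        groups=list(groups),
    )


def test_constructed_dmr_recovered():
    rng = np.random.default_rng(1)
    pos = np.array([100, 150, 200, 250])
    fr = np.empty((4, 10))
    fr[:, :5] = np.clip(rng.normal(0.9, 0.02, (4, 5)), 0, 1)
    fr[:, 5:] = np.clip(rng.normal(0.2, 0.02, (4, 5)), 0, 1)
    dmrs = find_dmrs(_matrix(pos, fr, ["A"] * 5 + ["B"] * 5), permutations=500, seed=2)
    assert len(dmrs) == 1
    d = dmrs[0]
    assert d.n_cpgs == 4
    assert d.mean_diff == pytest.approx(0.7, abs=0.05)
    assert d.start == 100 and d.end == 252


def test_large_gap_splits_candidates():
    rng = np.random.default_rng(3)
    pos = np.array([100, 150, 200, 400, 450, 500])  # 200 bp gap in the middle
    fr = np.empty((6, 10))
    fr[:, :5] = np.clip(rng.normal(0.8, 0.02, (6, 5)), 0, 1)
    fr[:, 5:] = np.clip(rng.normal(0.3, 0.02, (6, 5)), 0, 1)
    dmrs = find_dmrs(_matrix(pos, fr, ["A"] * 5 + ["B"] * 5), permutations=200, seed=4)
    assert len(dmrs) == 2
    assert {(d.start, d.end) for d in dmrs} == {(100, 202), (400, 502)}


def test_single_flip_within_valley_tolerance_kept_whole():
    # one opposite-sign site in nine leaves 89% consistency, above the 70%
    # valley threshold: the run is reported intact
    rng = np.random.default_rng(5)
    pos = np.arange(0, 9) * 50
    fr = np.empty((9, 12))
    fr[:, :6] = np.clip(rng.normal(0.8, 0.02, (9, 6)), 0, 1)
    fr[:, 6:] = np.clip(rng.normal(0.3, 0.02, (9, 6)), 0, 1)
    fr[4, :6], fr[4, 6:] = 0.1, 0.9
    dmrs = find_dmrs(_matrix(pos, fr, ["A"] * 6 + ["B"] * 6), permutations=200, seed=6)
    assert len(dmrs) == 1 and dmrs[0].n_cpgs == 9


def test_valley_trim_splits_sign_flips():
    # three inverted sites in the middle push consistency to 6/9 < 0.7:
    # the run is split and no reported region spans all nine sites
    rng = np.random.default_rng(5)
    pos = np.arange(0, 9) * 50
    fr = np.empty((9, 12))
    fr[:, :6] = np.clip(rng.normal(0.8, 0.02, (9, 6)), 0, 1)
    fr[:, 6:] = np.clip(rng.normal(0.3, 0.02, (9, 6)), 0, 1)
    for i in (3, 4, 5):
        fr[i, :6], fr[i, 6:] = 0.1, 0.9
    dmrs = find_dmrs(_matrix(pos, fr, ["A"] * 6 + ["B"] * 6), permutations=200, seed=6)
    assert dmrs, "expected at least one trimmed sub-run"
    assert all(d.n_cpgs < 9 for d in dmrs)
    assert {d.mean_diff > 0 for d in dmrs} == {True}


def test_requires_two_groups():
    with pytest.raises(ValueError):
        find_dmrs(_matrix([1, 2, 3], np.zeros((3, 4)), ["A"] * 4))


def test_few_permutations_warn():
    m = _matrix([100, 150, 200], np.full((3, 4), 0.5), ["A", "A", "B", "B"])
    with pytest.warns(UserWarning, match="permutations"):
        find_dmrs(m, permutations=50, seed=0)


def test_null_p_values_are_uniform():
    # identical group distributions: permutation p-values ~ U(0,1)
    rng = np.random.default_rng(7)
    pvals = []
    n_regions = 300
    for r in range(n_regions):
        pos = np.arange(5) * 40
        fr = np.clip(rng.normal(0.5, 0.15, (5, 10)), 0, 1)
        m = _matrix(pos, fr, ["A"] * 5 + ["B"] * 5)
        d = find_dmrs(m, min_diff=0.0, permutations=199, seed=int(rng.integers(2**31)))
        if d:
            # the max-|difference| segment carries the run's max-statistic
            # permutation p, which is the calibrated one
            pvals.append(min(x.p_value for x in d))
    assert len(pvals) >= n_regions * 0.5
    ks = sps.kstest(pvals, "uniform")
    assert ks.pvalue > 0.001
    # type-I control at q<0.01 (BH within each single-region scan => q = p)
    assert np.mean(np.asarray(pvals) < 0.01) <= 0.01 + 3 * np.sqrt(0.01 / len(pvals))


def test_sensitivity_for_planted_regions():
    # planted |delta| = 0.3 at depth 20, 8v8 samples
    rng = np.random.default_rng(8)
    depth = 20
    n_regions, n_sites = 30, 5
    positions, genomes, rows = [], [], []
    for r in range(n_regions):
        base = r * 10_000
        for s in range(n_sites):
            positions.append(base + s * 60)
            pa = 0.5 + 0.3 / 2
            pb = 0.5 - 0.3 / 2
            row = np.concatenate(
                [
                    rng.binomial(depth, pa, size=8) / depth,
                    rng.binomial(depth, pb, size=8) / depth,
                ]
            )
            rows.append(row)
    m = _matrix(positions, np.array(rows), ["A"] * 8 + ["B"] * 8)
    dmrs = find_dmrs(m, permutations=999, seed=9)
    sig = [d for d in dmrs if d.q_value < 0.01]
    recovered = {d.start // 10_000 for d in sig}
    assert len(recovered) >= 0.9 * n_regions


def test_valley_consistency_threshold():
    # a run with 70% consistent signs passes untrimmed
    rng = np.random.default_rng(10)
    pos = np.arange(10) * 30
    diffs_sign = np.array([1, 1, 1, 1, 1, 1, 1, -1, -1, -1])
    fr = np.empty((10, 10))
    for i, s in enumerate(diffs_sign):
        d = 0.3 * s
        fr[i, :5] = np.clip(0.5 + d / 2 + rng.normal(0, 0.01, 5), 0, 1)
        fr[i, 5:] = np.clip(0.5 - d / 2 + rng.normal(0, 0.01, 5), 0, 1)
    m = _matrix(pos, fr, ["A"] * 5 + ["B"] * 5)
    dmrs = find_dmrs(m, min_diff=0.05, permutations=200, seed=11)
    assert any(d.n_cpgs == 10 for d in dmrs)
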