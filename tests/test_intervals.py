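"""Interval arithmetic against brute-force oracles; shuffle-null enrichment."""

import subprocess

import numpy as np
import pytest

from uscfmeth.intervals import (
    IntervalSet,
    closest_feature,
    coverage_correlation,
    element_composition,
    intersect_bases,
    observed_ratio,
    shuffle_preserving_lengths,
)


def _random_set(rng, n, genome_len=10_000, max_len=200, genome="nuclear"):
    starts = rng.integers(0, genome_len - max_len, size=n)
    lengths = rng.integers(1, max_len, size=n)
    return IntervalSet(genome, np.sort(starts), np.sort(starts) + lengths)


def _brute_intersect(a, b):
    total = 0
    for s1, e1 in zip(a.starts, a.ends):
        for s2, e2 in zip(b.starts, b.ends):
            total += max(0, min(int(e1), int(e2)) - max(int(s1), int(s2)))
    return total


def test_intersect_examples():
    a = IntervalSet("nuclear", np.array([0]), np.array([10]))
    b = IntervalSet("nuclear", np.array([5]), np.array([15]))
    assert intersect_bases(a, b)[0] == 5
    c = IntervalSet("nuclear", np.array([100]), np.array([110]))
    assert intersect_bases(a, c)[0] == 0
    with pytest.raises(ValueError):
        intersect_bases(a, IntervalSet("mito", np.array([0]), np.array([5])))


def test_intersect_matches_brute_force_and_is_symmetric():
    rng = np.random.default_rng(7)
    for trial in range(25):
        a = _random_set(rng, int(rng.integers(1, 40)))
        b = _random_set(rng, int(rng.integers(1, 40)))
        ab = intersect_bases(a, b)[0]
        assert ab == _brute_intersect(a, b)
        assert ab == intersect_bases(b, a)[0]


def test_intersect_matches_bedtools():
    # independent oracle: bedtools intersect on the same intervals
    rng = np.random.default_rng(11)
    a = _random_set(rng, 50)
    b = _random_set(rng, 50)

    def fmt(s):
        return "".join(f"chr1\t{x}\t{y}\n" for x, y in zip(s.starts, s.ends))

    import tempfile, os

    with tempfile.TemporaryDirectory() as d:
        fa, fb = os.path.join(d, "a.bed"), os.path.join(d, "b.bed")
        open(fa, "w").write(fmt(a))
        open(fb, "w").write(fmt(b))
        res = subprocess.run(
            ["bedtools", "intersect", "-a", fa, "-b", fb],
            capture_output=True, text=True, check=True,
        )
    bedtools_total = sum(
        int(l.split("\t")[2]) - int(l.split("\t")[1])
        for l in res.stdout.splitlines()
        if l.strip()
    )
    assert intersect_bases(a, b)[0] == bedtools_total


def test_shuffle_preserves_length_multiset(bundle):
    rng = np.random.default_rng(3)
    frags = IntervalSet("nuclear", np.arange(0, 5000, 100), np.arange(0, 5000, 100) + 50)
    shuf = shuffle_preserving_lengths(frags, 100_000, rng)
    assert len(shuf) == len(frags)
    assert sorted(shuf.lengths) == sorted(frags.lengths)
    with pytest.raises(ValueError):
        shuffle_preserving_lengths(
            IntervalSet("nuclear", np.array([0]), np.array([200])), 100, rng
        )


def test_shuffle_coverage_is_uniform():
    rng = np.random.default_rng(4)
    n, L, flen = 2000, 50_000, 40
    frags = IntervalSet("nuclear", np.zeros(n, dtype=int), np.full(n, flen))
    window = (10_000, 20_000)
    cov = []
    for _ in range(10):
        s = shuffle_preserving_lengths(frags, L, rng)
        w = IntervalSet("nuclear", np.array([window[0]]), np.array([window[1]]))
        cov.append(intersect_bases(s, w)[0])
    expected = n * flen * (window[1] - window[0]) / L
    assert abs(np.mean(cov) - expected) < 4 * np.std(cov, ddof=1) / np.sqrt(10) + 5


def test_observed_ratio_whole_genome_is_exactly_one():
    frags = IntervalSet("nuclear", np.arange(0, 9000, 90), np.arange(0, 9000, 90) + 30)
    genome_mark = IntervalSet("nuclear", np.array([0]), np.array([10_000]))
    res = observed_ratio(frags, genome_mark, 10_000, replicates=5, seed=1)
    assert res.ratio == pytest.approx(1.0)


def test_observed_ratio_uniform_fragments_near_one():
    rng = np.random.default_rng(5)
    L = 200_000
    starts = np.sort(rng.integers(0, L - 60, size=3000))
    frags = IntervalSet("nuclear", starts, starts + 50)
    mark_starts = np.arange(0, L, 10_000)
    mark = IntervalSet("nuclear", mark_starts, mark_starts + 1000)  # 10% of genome
    res = observed_ratio(frags, mark, L, replicates=10, seed=2)
    assert abs(res.ratio - 1.0) <= 3 * res.null_sd / res.null_mean_fraction + 0.02


def test_observed_ratio_enrichment_closed_form():
    # fragments drawn 5x preferentially inside a mark covering 10% of the genome:
    # expected ratio (5*0.1)/(5*0.1 + 0.9) / 0.1 = 3.571
    rng = np.random.default_rng(6)
    L = 100_000
    mark = IntervalSet("nuclear", np.array([0]), np.array([L // 10]))
    n = 4000
    p_inside = 0.5 / (0.5 + 0.9)
    starts = np.where(
        rng.random(n) < p_inside,
        rng.integers(0, L // 10 - 1, size=n),
        rng.integers(L // 10, L - 1, size=n),
    )
    frags = IntervalSet("nuclear", np.sort(starts), np.sort(starts) + 1)
    res = observed_ratio(frags, mark, L, replicates=20, seed=3)
    assert res.ratio == pytest.approx((5 * 0.1) / (5 * 0.1 + 0.9) / 0.1, rel=0.1)


def test_observed_ratio_empty_mark_flagged():
    frags = IntervalSet("nuclear", np.array([0]), np.array([10]))
    empty = IntervalSet("nuclear", np.array([], dtype=int), np.array([], dtype=int))
    res = observed_ratio(frags, empty, 1000, replicates=2, seed=0)
    assert res.undefined and np.isnan(res.ratio)


def test_element_composition_duplication_rule():
    frags = IntervalSet("nuclear", np.array([100, 500]), np.array([150, 550]))
    ann = {
        "promoter": IntervalSet("nuclear", np.array([0]), np.array([200])),
        "cpg_island": IntervalSet("nuclear", np.array([120]), np.array([600])),
        "line": IntervalSet("nuclear", np.array([900]), np.array([950])),
    }
    comp = element_composition(frags, ann)
    assert comp["promoter"] == 50.0
    assert comp["cpg_island"] == 100.0  # both fragments; first counted twice overall
    assert comp["line"] == 0.0
    assert sum(comp.values()) > 100.0


def test_closest_feature_examples_and_oracle():
    feats = IntervalSet(
        "nuclear", np.array([100, 400, 800]), np.array([200, 500, 900]),
        names=["a", "b", "c"],
    )
    inside = IntervalSet("nuclear", np.array([150]), np.array([160]))
    assert closest_feature(inside, feats)[0] == ("a", 0)
    midpoint = IntervalSet("nuclear", np.array([295]), np.array([305]))
    name, dist = closest_feature(midpoint, feats)[0]
    assert name == "a"  # exact tie broken to the leftmost feature

    rng = np.random.default_rng(8)
    feats = _random_set(rng, 60)
    feats.names = [f"f{i}" for i in range(60)]
    queries = _random_set(rng, 200)
    results = closest_feature(queries, feats)
    for (s, e), (name, dist) in zip(zip(queries.starts, queries.ends), results):
        # brute-force oracle
        best = None
        for i, (fs, fe) in enumerate(zip(feats.starts, feats.ends)):
            if fe > s and fs < e:
                d = 0
            elif fe <= s:
                d = -(int(s) - int(fe) + 1)
            else:
                d = int(fs) - int(e) + 1
            key = (abs(d), int(fs))
            if best is None or key < best[0]:
                best = (key, feats.names[i], d)
        assert (name, dist) == (best[1], best[2])


def test_closest_feature_empty_errors():
    q = IntervalSet("nuclear", np.array([0]), np.array([10]))
    empty = IntervalSet("nuclear", np.array([], dtype=int), np.array([], dtype=int))
    with pytest.raises(ValueError):
        closest_feature(q, empty)


def test_coverage_correlation_identical_cohorts():
    rng = np.random.default_rng(9)
    starts = np.sort(rng.integers(0, 900_000, size=2000))
    a = IntervalSet("nuclear", starts, starts + 100)
    assert coverage_correlation(a, a, 1_000_000) == pytest.approx(1.0)
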