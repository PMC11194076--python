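"""TSS metaprofiles and feature-body methylation trends."""

import numpy as np
import pandas as pd
import pytest

from uscfmeth.genome import GInterval
from uscfmeth.intervals import IntervalSet
from uscfmeth.methylation import SiteMethylationTable
from uscfmeth.profiles import feature_trend, tss_profile


def _sites(positions, meth, unmeth, genome="nuclear"):
    return SiteMethylationTable(
        df=pd.DataFrame(
            {
                "genome": genome,
                "pos": positions,
                "strand": ".",
                "context": "CpG",
                "meth": meth,
                "unmeth": unmeth,
            }
        )
    )


def test_uniform_fragments_give_flat_curve():
    rng = np.random.default_rng(1)
    L = 100_000
    starts = np.sort(rng.integers(0, L - 60, size=20_000))
    frags = IntervalSet("nuclear", starts, starts + 50)
    tss = [GInterval(p, p + 1, f"t{i}", "+") for i, p in enumerate(range(5000, 95_000, 5000))]
    curve = tss_profile(frags, tss, L)
    vals = curve[curve["tier"] == "all"]["enrichment"].to_numpy()
    assert vals.mean() == pytest.approx(1.0)
    assert vals.std() < 0.1


def test_upstream_seeded_fragments_peak_upstream():
    L = 50_000
    tss_pos = 25_000
    starts = np.arange(tss_pos - 100, tss_pos - 40, 2)
    frags = IntervalSet("nuclear", starts, starts + 40)
    curve = tss_profile(frags, [GInterval(tss_pos, tss_pos + 1, "t", "+")], L)
    vals = curve[curve["tier"] == "all"]
    peak_pos = vals.loc[vals["enrichment"].idxmax(), "position"]
    assert -120 <= peak_pos < 0


def test_minus_strand_orientation_flips_curve():
    L = 50_000
    tss_pos = 25_000
    starts = np.arange(tss_pos + 40, tss_pos + 100, 2)  # downstream in genome coords
    frags = IntervalSet("nuclear", starts, starts + 40)
    curve = tss_profile(frags, [GInterval(tss_pos, tss_pos + 1, "t", "-")], L)
    vals = curve[curve["tier"] == "all"]
    peak_pos = vals.loc[vals["enrichment"].idxmax(), "position"]
    assert -150 <= peak_pos < 0  # genomically downstream = upstream of a minus-strand gene


def test_normalization_preserves_shape():
    rng = np.random.default_rng(2)
    L = 50_000
    starts = np.sort(rng.integers(0, L - 60, size=3000))
    frags = IntervalSet("nuclear", starts, starts + 50)
    tss = [GInterval(p, p + 1, f"t{i}", "+") for i, p in enumerate(range(5000, 45_000, 5000))]
    rel = tss_profile(frags, tss, L, normalization="relative")
    raw = tss_profile(frags, tss, L, normalization="none")
    r = rel[rel["tier"] == "all"]["enrichment"].to_numpy()
    w = raw[raw["tier"] == "all"]["enrichment"].to_numpy()
    nz = w > 0
    ratios = r[nz] / w[nz]
    assert np.allclose(ratios, ratios[0])


def test_tier_ordering_with_tier_scaled_enrichment():
    rng = np.random.default_rng(3)
    L = 100_000
    tss, expr, frag_starts = [], {}, []
    weights = {"high": 12, "medium": 6, "low": 2, "silent": 1}
    for i, p in enumerate(range(5000, 95_000, 3000)):
        tier = ["high", "medium", "low", "silent"][i % 4]
        name = f"t{i}"
        tss.append(GInterval(p, p + 1, name, "+"))
        expr[name] = tier
        n = weights[tier] * 12
        frag_starts += list(rng.integers(p - 150, p - 10, size=n))
    frag_starts += list(rng.integers(0, L - 60, size=3000))  # uniform background
    starts = np.sort(np.array(frag_starts))
    frags = IntervalSet("nuclear", starts, starts + 50)
    curve = tss_profile(frags, tss, L, tss_expression=expr)
    peak = {
        tier: curve[curve["tier"] == tier]["enrichment"].max()
        for tier in ("high", "medium", "low")
    }
    assert peak["high"] > peak["medium"] > peak["low"]


def test_feature_trend_flat_methylome():
    positions = np.arange(100, 40_000, 37)
    t = _sites(positions, np.full(len(positions), 8), np.full(len(positions), 2))
    feats = [GInterval(10_000, 12_000, "f1", "+"), GInterval(20_000, 23_000, "f2", "+")]
    trend = feature_trend(t, feats)
    vals = trend["mean_pct"].dropna()
    assert np.allclose(vals, 80.0)


def test_feature_trend_step_shape():
    positions = np.arange(0, 40_000, 23)
    inside = (positions >= 10_000) & (positions < 12_000)
    meth = np.where(inside, 1, 8)
    unmeth = np.where(inside, 9, 2)  # 10% inside the feature, 80% outside
    t = _sites(positions, meth, unmeth)
    trend = feature_trend(t, [GInterval(10_000, 12_000, "f", "+")])
    body = trend[trend["segment"] == "body"]["mean_pct"]
    up = trend[trend["segment"] == "upstream"]["mean_pct"]
    assert body.mean() == pytest.approx(10.0, abs=2.0)
    assert up.mean() == pytest.approx(80.0, abs=2.0)


def test_feature_trend_uncovered_windows_are_missing():
    t = _sites(np.array([10_500]), np.array([1]), np.array([1]))
    trend = feature_trend(t, [GInterval(10_000, 12_000, "f", "+")])
    assert trend["mean_pct"].isna().sum() > 0
    covered = trend.dropna(subset=["mean_pct"])
    assert (covered["mean_pct"] == 50.0).all()
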