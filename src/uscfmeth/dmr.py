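"""Differentially methylated region (DMR) scanning between two groups.

Candidate regions are maximal runs of CpG sites with inter-site gaps at
most ``maxdist``; runs are trimmed to maximal sub-runs in which at least a
``valley`` fraction of sites agree with the dominant sign of the
between-group difference (recursively splitting at the strongest
opposite-sign site), then filtered on site count and mean absolute
difference.  Significance comes from a group-label permutation test on the
mean absolute difference statistic, with Benjamini-Hochberg q-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .intervals import IntervalSet, closest_feature
from .methylation import SiteMethylationTable

__all__ = ["GroupMethylationMatrix", "DMR", "find_dmrs"]


@dataclass
class GroupMethylationMatrix:
    """CpG sites x samples methylation fractions with coverage filtering.

    ``fractions`` is (n_sites, n_samples) with NaN where a sample's depth
    at the site is below ``min_coverage``.
    """

    genomes: np.ndarray
    positions: np.ndarray
    fractions: np.ndarray
    samples: list[str]
    groups: list[str]
    min_coverage: int = 1

    def __post_init__(self) -> None:
        vals = self.fractions[~np.isnan(self.fractions)]
        if len(vals) and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("methylation fractions must lie in [0, 1]")

    @classmethod
    def from_site_tables(
        cls,
        tables: list[SiteMethylationTable],
        samples: list[str],
        groups: list[str],
        min_coverage: int = 1,
    ) -> "GroupMethylationMatrix":
        keys: set[tuple[str, int]] = set()
        per_sample: list[dict[tuple[str, int], float]] = []
        for t in tables:
            sub = t.df[t.df["context"] == "CpG"]
            depth = sub["meth"] + sub["unmeth"]
            sub = sub[depth >= min_coverage]
            d = {
                (g, int(p)): m / (m + u)
                for g, p, m, u in zip(sub["genome"], sub["pos"], sub["meth"], sub["unmeth"])
            }
            per_sample.append(d)
            keys |= set(d)
        ordered = sorted(keys)
        fr = np.full((len(ordered), len(tables)), np.nan)
        for j, d in enumerate(per_sample):
            for i, key in enumerate(ordered):
                if key in d:
                    fr[i, j] = d[key]
        return cls(
            genomes=np.array([k[0] for k in ordered]),
            positions=np.array([k[1] for k in ordered]),
            fractions=fr,
            samples=samples,
            groups=groups,
            min_coverage=min_coverage,
        )


@dataclass
class DMR:
    genome: str
    start: int
    end: int
    n_cpgs: int
    mean_diff: float
    p_value: float
    q_value: float = float("nan")
    nearest_feature: str | None = None
    nearest_distance: int | None = None

    def significant(self, q_threshold: float = 0.01) -> bool:
        return self.q_value < q_threshold


def _valley_segments(diffs: np.ndarray, valley: float, mincpgs: int) -> list[tuple[int, int]]:
    """Maximal sub-runs with >= valley sign consistency (index ranges)."""
    out: list[tuple[int, int]] = []

    def rec(lo: int, hi: int) -> None:
        if hi - lo < mincpgs:
            return
        d = diffs[lo:hi]
        total = np.sum(d)
        if total == 0:
            return
        s = 1.0 if total > 0 else -1.0
        cons = float(np.mean(np.sign(d) == s))
        if cons >= valley:
            out.append((lo, hi))
            return
        opp = np.flatnonzero(np.sign(d) != s)
        split = lo + opp[np.argmax(np.abs(d[opp]))]
        rec(lo, split)
        rec(split + 1, hi)

    rec(0, len(diffs))
    return out


def find_dmrs(
    matrix: GroupMethylationMatrix,
    mincpgs: int = 3,
    maxdist: int = 100,
    min_diff: float = 0.1,
    valley: float = 0.7,
    permutations: int = 1000,
    seed: int = 0,
    features: IntervalSet | None = None,
) -> list[DMR]:
    """Scan for DMRs between the two sample groups of the matrix.

    Returns every candidate surviving the run/valley/effect-size filters,
    each with a permutation p-value and a BH q-value; callers apply their
    own significance cut (q < 0.01 conventionally).
    """
    labels = sorted(set(matrix.groups))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    if permutations < 100:
        warnings.warn(f"{permutations} permutations gives coarse p-values", stacklevel=2)
    rng = np.random.default_rng(seed)
    ga = np.array([g == labels[0] for g in matrix.groups])
    n_samples = len(matrix.groups)
    n_a = int(ga.sum())

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # empty-slice nanmean
        mean_a = np.nanmean(matrix.fractions[:, ga], axis=1)
        mean_b = np.nanmean(matrix.fractions[:, ~ga], axis=1)
    usable = ~np.isnan(mean_a) & ~np.isnan(mean_b)

    def segment_stats(diffs: np.ndarray) -> list[tuple[int, int, float]]:
        """Valley segments of a run that survive the size/effect filters."""
        out = []
        for a, b in _valley_segments(diffs, valley, mincpgs):
            md = float(np.mean(diffs[a:b]))
            if abs(md) >= min_diff:
                out.append((a, b, md))
        return out

    dmrs: list[DMR] = []
    for genome in np.unique(matrix.genomes):
        sel = np.flatnonzero((matrix.genomes == genome) & usable)
        if len(sel) == 0:
            continue
        pos = matrix.positions[sel]
        run_breaks = np.flatnonzero(np.diff(pos) > maxdist)
        run_edges = [0, *[int(b) + 1 for b in run_breaks], len(sel)]
        for lo, hi in zip(run_edges[:-1], run_edges[1:]):
            if hi - lo < mincpgs:
                continue
            idx = sel[lo:hi]
            observed = segment_stats((mean_a - mean_b)[idx])
            if not observed:
                continue
            # permutation null: re-run the same segmentation on permuted
            # labels and take the max |mean difference| over discovered
            # segments.  Both the observed and the null statistics are
            # conditioned on a segment being discovered, so discovery
            # selection does not bias the tail probability.
            frac = matrix.fractions[idx, :]
            null_max: list[float] = []
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                for _ in range(permutations):
                    perm = rng.permutation(n_samples)
                    d = np.nanmean(frac[:, perm[:n_a]], axis=1) - np.nanmean(
                        frac[:, perm[n_a:]], axis=1
                    )
                    d = np.nan_to_num(d)
                    segs = segment_stats(d)
                    if segs:
                        null_max.append(max(abs(md) for _, _, md in segs))
            null_arr = np.asarray(null_max)
            for a, b, md in observed:
                seg = idx[a:b]
                p = (1 + int(np.sum(null_arr >= abs(md) - 1e-12))) / (1 + len(null_arr))
                dmrs.append(
                    DMR(
                        genome=str(genome),
                        start=int(matrix.positions[seg[0]]),
                        end=int(matrix.positions[seg[-1]]) + 2,  # cover the final dyad
                        n_cpgs=len(seg),
                        mean_diff=md,
                        p_value=p,
                    )
                )

    if dmrs:
        q = multipletests([d.p_value for d in dmrs], method="fdr_bh")[1]
        for d, qv in zip(dmrs, q):
            d.q_value = float(qv)
    if features is not None:
        for d in dmrs:
            one = IntervalSet(features.genome, np.array([d.start]), np.array([d.end]))
            name, dist = closest_feature(one, features)[0]
            d.nearest_feature = name
            d.nearest_distance = dist
    return dmrs


def dmrs_to_frame(dmrs: list[DMR]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [d.genome for d in dmrs],
            "start": [d.start for d in dmrs],
            "end": [d.end for d in dmrs],
            "n_cpgs": [d.n_cpgs for d in dmrs],
            "mean_diff": [d.mean_diff for d in dmrs],
            "p_value": [d.p_value for d in dmrs],
            "q_value": [d.q_value for d in dmrs],
            "nearest_feature": [d.nearest_feature for d in dmrs],
            "nearest_distance": [d.nearest_distance for d in dmrs],
        }
    )
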