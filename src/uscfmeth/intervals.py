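"""Interval arithmetic, shuffle-null enrichment and coverage correlation.

The enrichment statistic mirrors the classic shuffled-control design: the
fraction of fragment bases intersecting a mark is divided by the same
fraction measured on control fragment sets with the identical length
multiset placed uniformly at random ("observed ratio"; 1.0 means no
enrichment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome import GInterval

__all__ = [
    "IntervalSet",
    "EnrichmentResult",
    "intersect_bases",
    "shuffle_preserving_lengths",
    "observed_ratio",
    "element_composition",
    "closest_feature",
    "coverage_correlation",
]

logger = logging.getLogger(__name__)


@dataclass
class IntervalSet:
    """Sorted 0-based half-open intervals on one reference."""

    genome: str
    starts: np.ndarray
    ends: np.ndarray
    names: list[str] = field(default_factory=list)
    strands: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if np.any(self.ends <= self.starts):
            raise ValueError("all intervals must have end > start")
        if len(self.starts) > 1 and np.any(np.diff(self.starts) < 0):
            logger.info("IntervalSet input unsorted; sorting by start")
            order = np.argsort(self.starts, kind="stable")
            self.starts = self.starts[order]
            self.ends = self.ends[order]
            if self.names:
                self.names = [self.names[i] for i in order]
            if self.strands:
                self.strands = [self.strands[i] for i in order]

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def total_bases(self) -> int:
        return int(self.lengths.sum())

    @classmethod
    def from_intervals(cls, genome: str, intervals: list[GInterval]) -> "IntervalSet":
        if not intervals:
            return cls(genome, np.array([], dtype=np.int64), np.array([], dtype=np.int64))
        return cls(
            genome,
            np.array([iv.start for iv in intervals]),
            np.array([iv.end for iv in intervals]),
            [iv.name for iv in intervals],
            [iv.strand for iv in intervals],
        )

    @classmethod
    def from_fragments(cls, genome: str, alignments) -> "IntervalSet":
        alns = [a for a in alignments if a.genome == genome]
        if not alns:
            return cls(genome, np.array([], dtype=np.int64), np.array([], dtype=np.int64))
        return cls(
            genome,
            np.array([a.start for a in alns]),
            np.array([a.end for a in alns]),
            strands=[a.strand for a in alns],
        )

    def write_bed(self, path: str | Path) -> None:
        names = self.names or ["."] * len(self)
        strands = self.strands or ["."] * len(self)
        with open(path, "w") as fh:
            for s, e, n, st in zip(self.starts, self.ends, names, strands):
                fh.write(f"{self.genome}\t{s}\t{e}\t{n}\t0\t{st}\n")

    @classmethod
    def read_bed(cls, path: str | Path) -> "IntervalSet":
        starts, ends, names, strands, genome = [], [], [], [], None
        with open(path) as fh:
            for line in fh:
                f = line.rstrip("\n").split("\t")
                genome = genome or f[0]
                starts.append(int(f[1]))
                ends.append(int(f[2]))
                names.append(f[3] if len(f) > 3 else ".")
                strands.append(f[5] if len(f) > 5 else ".")
        return cls(genome or "", np.array(starts, dtype=np.int64),
                   np.array(ends, dtype=np.int64), names, strands)


@dataclass
class EnrichmentResult:
    mark: str
    fragment_class: str
    observed_fraction: float
    null_mean_fraction: float
    null_sd: float
    replicates: int
    undefined: bool = False

    @property
    def ratio(self) -> float:
        if self.undefined or self.null_mean_fraction == 0:
            return float("nan")
        return self.observed_fraction / self.null_mean_fraction


def intersect_bases(a: IntervalSet, b: IntervalSet) -> tuple[int, np.ndarray]:
    """Total overlapping bases between two interval sets, plus per-a overlaps.

    Sorted two-pointer sweep; overlap of a pair is
    ``max(0, min(ends) - max(starts))``.  Intervals within each set may
    themselves overlap; shared bases are then counted once per pair, the
    convention of pairwise intersection tools.
    """
    if a.genome != b.genome:
        raise ValueError(f"interval sets on different genomes: {a.genome} vs {b.genome}")
    per_a = np.zeros(len(a), dtype=np.int64)
    if len(a) == 0 or len(b) == 0:
        return 0, per_a
    bs, be = b.starts, b.ends
    j0 = 0
    max_b_len = int((be - bs).max())
    for i in range(len(a)):
        s, e = int(a.starts[i]), int(a.ends[i])
        # first b whose end could reach s: starts are sorted, ends within max_b_len
        j = np.searchsorted(bs, s - max_b_len, side="left")
        total = 0
        while j < len(bs) and bs[j] < e:
            ov = min(e, int(be[j])) - max(s, int(bs[j]))
            if ov > 0:
                total += ov
            j += 1
        per_a[i] = total
    return int(per_a.sum()), per_a


def shuffle_preserving_lengths(
    fragments: IntervalSet, genome_length: int, rng: np.random.Generator
) -> IntervalSet:
    """Random placement preserving the exact multiset of fragment lengths."""
    lengths = fragments.lengths
    if len(lengths) and int(lengths.max()) > genome_length:
        raise ValueError("fragment longer than the genome cannot be shuffled")
    starts = np.array(
        [rng.integers(0, genome_length - int(ln) + 1) for ln in lengths], dtype=np.int64
    )
    return IntervalSet(fragments.genome, starts, starts + lengths)


def observed_ratio(
    fragments: IntervalSet,
    mark: IntervalSet,
    genome_length: int,
    mark_name: str = "",
    fragment_class: str = "",
    replicates: int = 10,
    seed: int = 0,
) -> EnrichmentResult:
    """Observed intersecting-base fraction over the shuffled-null mean."""
    if len(mark) == 0:
        return EnrichmentResult(mark_name, fragment_class, float("nan"), float("nan"),
                                float("nan"), replicates, undefined=True)
    total = fragments.total_bases
    obs = intersect_bases(fragments, mark)[0] / total if total else 0.0
    null_fracs = []
    for r in range(replicates):
        rng = np.random.default_rng((seed + 1) * 100_003 + r)
        shuf = shuffle_preserving_lengths(fragments, genome_length, rng)
        null_fracs.append(intersect_bases(shuf, mark)[0] / total if total else 0.0)
    null = np.asarray(null_fracs)
    return EnrichmentResult(
        mark=mark_name,
        fragment_class=fragment_class,
        observed_fraction=obs,
        null_mean_fraction=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if replicates > 1 else 0.0,
        replicates=replicates,
    )


def _overlaps_any(fragments: IntervalSet, track: IntervalSet) -> np.ndarray:
    """Boolean: does each fragment overlap >= 1 interval of the track."""
    if len(track) == 0:
        return np.zeros(len(fragments), dtype=bool)
    _, per = intersect_bases(fragments, track)
    return per > 0


def element_composition(
    cpg_fragments: IntervalSet, annotations: dict[str, IntervalSet]
) -> dict[str, float]:
    """Per-element % of CpG-containing fragments overlapping that element.

    A fragment spanning several elements is counted in each of them, so the
    percentages may sum past 100 where tracks overlap.
    """
    n = len(cpg_fragments)
    out: dict[str, float] = {}
    for name, track in annotations.items():
        if n == 0:
            out[name] = float("nan")
            continue
        out[name] = 100.0 * float(_overlaps_any(cpg_fragments, track).sum()) / n
    return out


def closest_feature(
    intervals: IntervalSet, features: IntervalSet
) -> list[tuple[str, int]]:
    """Nearest feature (name, signed distance) for each interval.

    Distance is 0 on overlap, negative when the feature lies left of the
    interval, positive when right; ties go to the leftmost feature.
    """
    if len(features) == 0:
        raise ValueError("empty feature set")
    fs, fe = features.starts, features.ends
    names = features.names or [str(i) for i in range(len(features))]
    out: list[tuple[str, int]] = []
    for s, e in zip(intervals.starts.astype(int), intervals.ends.astype(int)):
        overlap = (fe > s) & (fs < e)
        signed = np.where(overlap, 0, np.where(fe <= s, -(s - fe + 1), fs - e + 1))
        dist = np.abs(signed)
        m = dist.min()
        cands = np.flatnonzero(dist == m)
        idx = int(cands[np.argmin(fs[cands])])  # ties -> leftmost feature
        out.append((names[idx], int(signed[idx])))
    return out


def coverage_correlation(
    a: IntervalSet, b: IntervalSet, genome_length: int, bin_size: int = 100_000
) -> float:
    """Pearson r between per-bin % of total coverage of two fragment cohorts."""
    n_bins = max(1, (genome_length + bin_size - 1) // bin_size)

    def binned(frags: IntervalSet) -> np.ndarray:
        cov = np.zeros(n_bins)
        for s, e in zip(frags.starts, frags.ends):
            i0, i1 = int(s) // bin_size, (int(e) - 1) // bin_size
            for i in range(i0, i1 + 1):
                lo = max(int(s), i * bin_size)
                hi = min(int(e), (i + 1) * bin_size)
                cov[i] += hi - lo
        total = cov.sum()
        return cov / total * 100.0 if total else cov

    va, vb = binned(a), binned(b)
    if np.allclose(va, va[0]) or np.allclose(vb, vb[0]):
        return float("nan")
    return float(np.corrcoef(va, vb)[0, 1])
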