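"""Fragment-size profiles, CpG density and G-quadruplex motif scanning.

The G-quadruplex motif is the classic pattern of four-plus runs of >= 3
guanines separated by loops of 1-7 arbitrary bases.  The scanner here is a
small backtracking matcher that mirrors the semantics of the pattern
``([gG]{3,}\\w{1,7}){3,}[gG]{3,}`` under a leftmost/greedy regex engine
(greedy quantifiers, preference for extending the repeat over stopping),
with failure memoisation so G-rich sequences stay linear-ish.  Matches are
reported non-overlapping, scanning resuming at each match end.

Motifs are called on the reference sequence spanned by the aligned
fragment, on the fragment's own strand: bisulfite conversion never touches
the G-runs of the primary strand, so converted and unconverted libraries
score identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import AlignedFragment, SizeBins
from .fragments import revcomp
from .genome import GenomeBundle

__all__ = [
    "SizeBinProfile",
    "size_profile",
    "gquad_scan",
    "gquad_bin_stats",
    "cpg_density_profile",
    "fragment_reference_sequence",
]

_G = frozenset("gG")


def _is_word(ch: str) -> bool:
    return ch.isalnum() or ch == "_"


def _g_run_ends(s: str, i: int) -> list[int]:
    """Possible end positions of a G-run of >=3 starting at i, greedy order."""
    j = i
    n = len(s)
    while j < n and s[j] in _G:
        j += 1
    if j - i < 3:
        return []
    return list(range(j, i + 2, -1))


def _loop_ends(s: str, i: int) -> list[int]:
    """Possible end positions of a 1-7 base loop starting at i, greedy order."""
    n = len(s)
    j = i
    while j < min(i + 7, n) and _is_word(s[j]):
        j += 1
    return list(range(j, i, -1))


def _match_at(s: str, i: int) -> int:
    """End of the match starting at i under greedy semantics, or -1."""
    failed: set[tuple[int, int]] = set()

    def rep(pos: int, count: int) -> int:
        key = (pos, min(count, 3))
        if key in failed:
            return -1
        # greedy: prefer one more (G-run + loop) unit before trying the tail
        for ge in _g_run_ends(s, pos):
            for le in _loop_ends(s, ge):
                r = rep(le, count + 1)
                if r >= 0:
                    return r
        if count >= 3:
            tails = _g_run_ends(s, pos)
            if tails:
                return tails[0]
        failed.add(key)
        return -1

    return rep(i, 0)


def gquad_scan(sequence: str) -> list[tuple[int, int]]:
    """Non-overlapping G-quadruplex motif matches (start, end) in a sequence."""
    out: list[tuple[int, int]] = []
    i = 0
    n = len(sequence)
    while i < n:
        if sequence[i] not in _G:
            i += 1
            continue
        end = _match_at(sequence, i)
        if end >= 0:
            out.append((i, end))
            i = end
        else:
            i += 1
    return out


def fragment_reference_sequence(a: AlignedFragment, bundle: GenomeBundle) -> str:
    """Reference sequence under a fragment, on the fragment's strand."""
    seq = bundle.references[a.genome][a.start : a.end]
    return seq if a.strand == "+" else revcomp(seq)


@dataclass
class SizeBinProfile:
    """Per-genome fragment size profile at 1-base and 10-base resolution."""

    genome: str
    counts: dict[str, int]
    fractions: dict[str, float]
    modal_length: int | None
    length_histogram: dict[int, int] = field(default_factory=dict)
    empty: bool = False

    def to_frame(self) -> pd.DataFrame:
        labels = list(self.counts)
        return pd.DataFrame(
            {
                "bin": labels,
                "count": [self.counts[b] for b in labels],
                "fraction": [self.fractions[b] for b in labels],
            }
        )


def size_profile(
    alignments: list[AlignedFragment], genome: str, bins: SizeBins | None = None
) -> SizeBinProfile:
    """Histogram fragment lengths for one reference."""
    bins = bins or SizeBins()
    lengths = [a.length for a in alignments if a.genome == genome]
    if not lengths:
        return SizeBinProfile(
            genome=genome,
            counts={},
            fractions={},
            modal_length=None,
            empty=True,
        )
    arr = np.asarray(lengths)
    values, freq = np.unique(arr, return_counts=True)
    modal = int(values[np.argmax(freq)])  # ties resolve to the smallest length
    counts: dict[str, int] = {lab: 0 for lab in bins.labels}
    counts["overflow"] = 0
    for ln in lengths:
        counts[bins.label_for(int(ln))] += 1
    total = len(lengths)
    fractions = {lab: c / total for lab, c in counts.items()}
    return SizeBinProfile(
        genome=genome,
        counts=counts,
        fractions=fractions,
        modal_length=modal,
        length_histogram={int(v): int(c) for v, c in zip(values, freq)},
    )


def gquad_bin_stats(
    binned: dict[str, list[AlignedFragment]],
    bundle: GenomeBundle,
    bins: SizeBins | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-bin (G-quad fragment %, normalized ratio); empty bins omitted.

    The normalized ratio divides the count of motif-containing fragments by
    the bin's midpoint length (20-29 -> 25), as conventionally reported.
    """
    bins = bins or SizeBins()
    out: dict[str, tuple[float, float]] = {}
    for label, alns in binned.items():
        if not alns or label == "overflow":
            continue
        hits = sum(
            1 for a in alns if gquad_scan(fragment_reference_sequence(a, bundle))
        )
        pct = 100.0 * hits / len(alns)
        out[label] = (pct, hits / bins.midpoint(label))
    return out


def cpg_density_profile(
    binned: dict[str, list[AlignedFragment]], bundle: GenomeBundle
) -> dict[str, float]:
    """Per-bin CpG density: reference CpG dyads under fragments / total bases."""
    out: dict[str, float] = {}
    for label, alns in binned.items():
        if not alns:
            continue
        dyads = 0
        bases = 0
        for a in alns:
            dyads += bundle.references[a.genome][a.start : a.end].count("CG")
            bases += a.length
        out[label] = dyads / bases if bases else 0.0
    return out
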