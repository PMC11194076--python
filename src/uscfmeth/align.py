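"""Small-scale three-letter bisulfite alignment, deduplication, size binning.

Bisulfite conversion collapses the sequence alphabet: on the top strand an
unmethylated C reads as T, on the bottom strand (seen in reference
coordinates) a G reads as A.  The index therefore stores two collapsed
k-mer tables per reference — C->T for top-strand hits and G->A for
bottom-strand hits — and alignment is seed-and-extend, end-to-end, with
bisulfite-compatible substitutions scored as free.  Only reads whose best
hit is strictly better than the second best are kept (uniqueness rule); no
clipping is ever produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .fragments import revcomp
from .genome import GenomeBundle
from .readproc import MergedRead

__all__ = [
    "AlignedFragment",
    "BisulfiteIndex",
    "build_bs_index",
    "align_bisulfite",
    "deduplicate",
    "SizeBins",
    "bin_by_size",
]

# observed states at reference cytosines
RETAINED, CONVERTED, OTHER = "retained", "converted", "other"


@dataclass
class AlignedFragment:
    """A merged read placed end-to-end on a reference.

    ``observed`` lists (reference position, state) for every reference C
    (top-strand alignments) or reference G (bottom-strand alignments)
    under the read, state in {retained, converted, other}.
    """

    genome: str
    start: int
    end: int
    strand: str
    unique: bool
    mismatches: int
    observed: list[tuple[int, str]]
    population: str | None = None
    pair_id: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


class BisulfiteIndex:
    """Two collapsed k-mer tables per reference (C->T top, G->A bottom)."""

    def __init__(self, bundle: GenomeBundle, k: int = 20):
        shortest = min(len(s) for s in bundle.references.values())
        if k > shortest:
            raise ValueError(f"k={k} exceeds shortest reference length {shortest}")
        self.k = k
        self.refs = dict(bundle.references)
        self.top: dict[str, dict[str, object]] = {}
        self.bottom: dict[str, dict[str, object]] = {}
        for name, seq in bundle.references.items():
            self.top[name] = self._table(seq.replace("C", "T"), k)
            self.bottom[name] = self._table(seq.replace("G", "A"), k)

    @staticmethod
    def _table(collapsed: str, k: int) -> dict[str, object]:
        table: dict[str, object] = {}
        for i in range(len(collapsed) - k + 1):
            km = collapsed[i : i + k]
            prev = table.get(km)
            if prev is None:
                table[km] = i
            elif isinstance(prev, int):
                table[km] = [prev, i]
            else:
                prev.append(i)
        return table

    @staticmethod
    def lookup(table: dict[str, object], km: str) -> Iterable[int]:
        hit = table.get(km)
        if hit is None:
            return ()
        if isinstance(hit, int):
            return (hit,)
        return hit


def build_bs_index(bundle: GenomeBundle, k: int = 20) -> BisulfiteIndex:
    """Build the collapsed-alphabet seed index for a genome bundle."""
    return BisulfiteIndex(bundle, k=k)


def _score_top(ref: str, start: int, read: str) -> int:
    mism = 0
    for j, b in enumerate(read):
        r = ref[start + j]
        if r != b and not (r == "C" and b == "T"):
            mism += 1
    return mism


def _score_bottom(ref: str, start: int, read_rc: str) -> int:
    mism = 0
    for j, b in enumerate(read_rc):
        r = ref[start + j]
        if r != b and not (r == "G" and b == "A"):
            mism += 1
    return mism


def align_bisulfite(
    read: MergedRead, index: BisulfiteIndex, max_mismatches: int = 3
) -> AlignedFragment | None:
    """Place one merged read; returns None when unaligned or non-unique.

    Seeds are taken from both read ends (so one sequencing error cannot
    kill both seeds), candidates are scored end-to-end, and
    bisulfite-compatible substitutions (ref C -> read T on top, ref G ->
    read A on bottom) are free.
    """
    k = index.k
    seq = read.sequence
    L = len(seq)
    if L < k:
        return None

    candidates: set[tuple[str, int, str]] = set()
    fwd = seq.replace("C", "T")
    rc = revcomp(seq)
    rcc = rc.replace("G", "A")
    for genome in index.refs:
        top = index.top[genome]
        bottom = index.bottom[genome]
        for km, off in ((fwd[:k], 0), (fwd[L - k :], L - k)):
            for p in BisulfiteIndex.lookup(top, km):
                candidates.add((genome, p - off, "+"))
        for km, off in ((rcc[:k], 0), (rcc[L - k :], L - k)):
            for p in BisulfiteIndex.lookup(bottom, km):
                candidates.add((genome, p - off, "-"))

    best: tuple[int, str, int, str] | None = None
    second = None
    for genome, start, strand in candidates:
        ref = index.refs[genome]
        if start < 0 or start + L > len(ref):
            continue
        score = _score_top(ref, start, seq) if strand == "+" else _score_bottom(ref, start, rc)
        key = (score, genome, start, strand)
        if best is None or score < best[0]:
            second = best
            best = key
        elif second is None or score < second[0]:
            second = key
    if best is None or best[0] > max_mismatches:
        return None
    if second is not None and second[0] == best[0]:
        return None  # non-unique placement

    score, genome, start, strand = best
    ref = index.refs[genome]
    observed: list[tuple[int, str]] = []
    if strand == "+":
        for j in range(L):
            if ref[start + j] == "C":
                b = seq[j]
                state = RETAINED if b == "C" else CONVERTED if b == "T" else OTHER
                observed.append((start + j, state))
    else:
        for j in range(L):
            if ref[start + j] == "G":
                b = rc[j]
                state = RETAINED if b == "G" else CONVERTED if b == "A" else OTHER
                observed.append((start + j, state))

    population = None
    if read.pair_id and "|" in read.pair_id:
        parts = read.pair_id.split("|")
        if len(parts) >= 6:
            population = parts[5]
    return AlignedFragment(
        genome=genome,
        start=start,
        end=start + L,
        strand=strand,
        unique=True,
        mismatches=score,
        observed=observed,
        population=population,
        pair_id=read.pair_id,
    )


def write_sam(
    alignments: list[AlignedFragment],
    bundle: GenomeBundle,
    path,
) -> None:
    """Emit alignments as plain-text SAM for interoperability.

    The record carries the reference-matching sequence (the reference slice
    under the fragment, since merged reads are placed end-to-end) with a
    fully-matching CIGAR; the truth population label, when known, travels in
    the ``XP`` tag.
    """
    import pysam

    names = sorted(bundle.references)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": len(bundle.references[n])} for n in names],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, a in enumerate(alignments):
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = a.pair_id or f"fragment_{i}"
            rec.reference_name = a.genome
            rec.reference_start = a.start
            rec.cigarstring = f"{a.length}M"
            rec.flag = 16 if a.strand == "-" else 0
            rec.mapping_quality = 60 if a.unique else 0
            rec.query_sequence = bundle.references[a.genome][a.start : a.end]
            tags = [("NM", a.mismatches)]
            if a.population:
                tags.append(("XP", a.population))
            rec.tags = tags
            out.write(rec)


def deduplicate(alignments: list[AlignedFragment]) -> tuple[list[AlignedFragment], int]:
    """Keep one representative per (genome, start, end, strand); first seen wins."""
    seen: set[tuple[str, int, int, str]] = set()
    out: list[AlignedFragment] = []
    for a in alignments:
        key = (a.genome, a.start, a.end, a.strand)
        if key in seen:
            continue
        seen.add(key)
        out.append(a)
    return out, len(alignments) - len(out)


@dataclass
class SizeBins:
    """10-base fragment-size bins; label "x-y" covers [x, y+1) half-open."""

    lo: int = 20
    hi: int = 200
    width: int = 10
    uscfdna_window: tuple[int, int] = (40, 70)  # inclusive length range
    mncfdna_window: tuple[int, int] = (120, 250)

    @property
    def labels(self) -> list[str]:
        return [f"{x}-{x + self.width - 1}" for x in range(self.lo, self.hi, self.width)]

    def label_for(self, length: int) -> str:
        if self.lo <= length < self.hi:
            x = self.lo + ((length - self.lo) // self.width) * self.width
            return f"{x}-{x + self.width - 1}"
        return "overflow"

    def midpoint(self, label: str) -> float:
        x, y = label.split("-")
        return (int(x) + int(y) + 1) / 2.0

    def is_uscfdna(self, length: int) -> bool:
        lo, hi = self.uscfdna_window
        return lo <= length <= hi

    def is_mncfdna(self, length: int) -> bool:
        lo, hi = self.mncfdna_window
        return lo <= length <= hi


def bin_by_size(
    alignments: list[AlignedFragment], bins: SizeBins | None = None
) -> dict[str, list[AlignedFragment]]:
    """Partition alignments into 10-base size bins (out-of-range -> "overflow")."""
    bins = bins or SizeBins()
    out: dict[str, list[AlignedFragment]] = {lab: [] for lab in bins.labels}
    out["overflow"] = []
    for a in alignments:
        out[bins.label_for(a.length)].append(a)
    return out
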