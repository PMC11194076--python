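"""Adapter trimming and read-pair merging.

cfDNA inserts are routinely shorter than the read length, so both mates
read through into the sequencing adapter and then overlap each other over
the whole insert.  Trimming removes 3' adapter occurrences (tolerating a
small mismatch rate); merging scans candidate overlaps between R1 and the
reverse complement of R2 from longest to shortest and emits a consensus
single-end read whose length is the insert length.  Pairs with no
acceptable overlap are rejected and excluded downstream, mirroring a
merged-only pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .fragments import revcomp
from .reads import ADAPTER_R1, ADAPTER_R2, ReadPair

__all__ = ["MergedRead", "TrimStats", "trim_adapters", "merge_pairs", "process_pairs"]


@dataclass
class MergedRead:
    sequence: str
    quality: str
    pair_id: str
    overlap: int

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class TrimStats:
    pairs_in: int = 0
    dropped_short: int = 0
    merge_rejected: int = 0
    merged: int = 0
    log: list[str] = field(default_factory=list)


def _find_adapter(read: str, adapter: str, min_match: int, max_mismatch_rate: float) -> int:
    """Earliest position where a 3' adapter occurrence starts, or -1."""
    n = len(read)
    for i in range(0, n - min_match + 1):
        m = min(n - i, len(adapter))
        if m < min_match:
            break
        allowed = int(max_mismatch_rate * m)
        mism = 0
        seg = read[i : i + m]
        for a, b in zip(seg, adapter):
            if a != b:
                mism += 1
                if mism > allowed:
                    break
        if mism <= allowed:
            return i
    return -1


def trim_adapters(
    pair: ReadPair,
    adapters: tuple[str, str] = (ADAPTER_R1, ADAPTER_R2),
    min_match: int = 8,
    max_mismatch_rate: float = 0.1,
    min_length: int = 20,
) -> ReadPair | None:
    """Remove 3' adapter read-through from both mates.

    Returns the trimmed pair, or None when either mate falls below
    ``min_length`` after trimming (the pair is dropped).
    """
    if not adapters[0] or not adapters[1]:
        raise ValueError("adapters must be non-empty")
    out = []
    for read, q, adapter in ((pair.r1, pair.q1, adapters[0]), (pair.r2, pair.q2, adapters[1])):
        i = _find_adapter(read, adapter, min_match, max_mismatch_rate)
        if i >= 0:
            read, q = read[:i], q[:i]
        out.append((read, q))
    if len(out[0][0]) < min_length or len(out[1][0]) < min_length:
        return None
    return ReadPair(name=pair.name, r1=out[0][0], q1=out[0][1], r2=out[1][0], q2=out[1][1])


def merge_pairs(
    pair: ReadPair, min_overlap: int = 11, max_mismatch_rate: float = 0.1
) -> MergedRead | None:
    """Merge a trimmed pair into a single fragment-length read.

    Candidate overlaps between the 3' end of R1 and the 5' end of
    revcomp(R2) are scanned from longest to shortest; the first one whose
    mismatch rate is within threshold is accepted.  Consensus bases take
    the higher-quality call at disagreements (R1 wins ties).
    """
    r1, q1 = pair.r1, pair.q1
    if not r1 or not pair.r2:
        return None
    rc2 = revcomp(pair.r2)
    qc2 = pair.q2[::-1]
    n1, n2 = len(r1), len(rc2)
    for o in range(min(n1, n2), min_overlap - 1, -1):
        seg1 = r1[n1 - o :]
        seg2 = rc2[:o]
        allowed = int(max_mismatch_rate * o)
        mism = 0
        ok = True
        for a, b in zip(seg1, seg2):
            if a != b:
                mism += 1
                if mism > allowed:
                    ok = False
                    break
        if not ok:
            continue
        head = r1[: n1 - o]
        qhead = q1[: n1 - o]
        cons = []
        qcons = []
        for j in range(o):
            a, b = seg1[j], seg2[j]
            qa, qb = q1[n1 - o + j], qc2[j]
            if a == b or qa >= qb:
                cons.append(a)
                qcons.append(max(qa, qb))
            else:
                cons.append(b)
                qcons.append(qb)
        tail = rc2[o:]
        qtail = qc2[o:]
        return MergedRead(
            sequence=head + "".join(cons) + tail,
            quality=qhead + "".join(qcons) + qtail,
            pair_id=pair.name,
            overlap=o,
        )
    # "outie" geometry: the insert is shorter than the read but its 3'
    # adapter stub was too short to trim, so rc(R2) starts with a few
    # leftover adapter bases and the true overlap is R1's prefix against
    # rc(R2)'s suffix.  Scan stub sizes from small (longest insert) up.
    for s in range(1, min(n1, n2) - min_overlap + 1):
        o = min(n1, n2) - s
        seg1 = r1[:o]
        seg2 = rc2[s : s + o]
        allowed = int(max_mismatch_rate * o)
        mism = 0
        ok = True
        for a, b in zip(seg1, seg2):
            if a != b:
                mism += 1
                if mism > allowed:
                    ok = False
                    break
        if not ok:
            continue
        cons = []
        qcons = []
        for j in range(o):
            a, b = seg1[j], seg2[j]
            qa, qb = q1[j], qc2[s + j]
            if a == b or qa >= qb:
                cons.append(a)
                qcons.append(max(qa, qb))
            else:
                cons.append(b)
                qcons.append(qb)
        return MergedRead(
            sequence="".join(cons), quality="".join(qcons), pair_id=pair.name, overlap=o
        )
    return None


def process_pairs(
    pairs: list[ReadPair],
    adapters: tuple[str, str] = (ADAPTER_R1, ADAPTER_R2),
    min_match: int = 8,
    min_overlap: int = 11,
    max_mismatch_rate: float = 0.1,
) -> tuple[list[MergedRead], TrimStats]:
    """Trim then merge a batch of pairs, keeping per-stage accounting."""
    stats = TrimStats(pairs_in=len(pairs))
    merged: list[MergedRead] = []
    for p in pairs:
        t = trim_adapters(p, adapters=adapters, min_match=min_match,
                          max_mismatch_rate=max_mismatch_rate)
        if t is None:
            stats.dropped_short += 1
            continue
        m = merge_pairs(t, min_overlap=min_overlap, max_mismatch_rate=max_mismatch_rate)
        if m is None:
            stats.merge_rejected += 1
            continue
        merged.append(m)
    stats.merged = len(merged)
    if stats.dropped_short or stats.merge_rejected:
        stats.log.append(
            f"dropped {stats.dropped_short} short pairs, rejected {stats.merge_rejected} unmergeable"
        )
    return merged, stats
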