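"""Paired-end read emission for simulated libraries.

Each library molecule yields one 150 x 2 read pair: R1 reads the molecule
5'->3', R2 reads the reverse complement.  Molecules shorter than the read
length produce read-through into the 3' sequencing adapter followed by
padding, exactly the situation adapter trimming and pair merging must
undo.  Sequencing error is a small iid per-base substitution rate at a
constant Phred quality.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fragments import revcomp
from .protocol import LibraryMolecule

__all__ = ["ADAPTER_R1", "ADAPTER_R2", "ReadPair", "SimulatedReads", "emit_reads"]

# standard TruSeq-style trim sequences
ADAPTER_R1 = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"
ADAPTER_R2 = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGT"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class ReadPair:
    name: str
    r1: str
    q1: str
    r2: str
    q2: str


@dataclass
class SimulatedReads:
    pairs: list[ReadPair]
    read_len: int
    truth: list[LibraryMolecule] = field(default_factory=list)

    def write_fastq(self, r1_path: str | Path, r2_path: str | Path) -> None:
        for path, which in ((r1_path, "r1"), (r2_path, "r2")):
            opener = gzip.open if str(path).endswith(".gz") else open
            with opener(path, "wt") as fh:
                for p in self.pairs:
                    seq = p.r1 if which == "r1" else p.r2
                    q = p.q1 if which == "r1" else p.q2
                    fh.write(f"@{p.name}/{which[-1]}\n{seq}\n+\n{q}\n")

    def write_truth_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for m in self.truth:
                fh.write(
                    f"{m.genome}\t{m.start}\t{m.end}\tmol{m.id}|{m.population}|{m.native_length}"
                    f"\t0\t{m.strand}\n"
                )


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(len(arr)) < error_rate)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def emit_reads(
    library: list[LibraryMolecule],
    read_len: int = 150,
    adapters: tuple[str, str] = (ADAPTER_R1, ADAPTER_R2),
    qual: int = 37,
    error_rate: float = 0.001,
    seed: int = 0,
) -> SimulatedReads:
    """Sequence a library into paired reads.

    Read names carry the truth record
    ``mol<id>|<genome>|<start>|<end>|<strand>|<population>|<native_length>``
    so downstream stages can be validated against the simulation.
    """
    if not library:
        raise ValueError("cannot sequence an empty library")
    rng = np.random.default_rng(seed)
    a1, a2 = adapters
    qline = chr(qual + 33) * read_len
    pairs: list[ReadPair] = []
    for m in library:
        template1 = m.sequence + a1
        template2 = revcomp(m.sequence) + a2
        r1 = (template1 + "A" * read_len)[:read_len]
        r2 = (template2 + "A" * read_len)[:read_len]
        r1 = _apply_errors(r1, error_rate, rng)
        r2 = _apply_errors(r2, error_rate, rng)
        name = f"mol{m.id}|{m.genome}|{m.start}|{m.end}|{m.strand}|{m.population}|{m.native_length}"
        pairs.append(ReadPair(name=name, r1=r1, q1=qline, r2=r2, q2=qline))
    return SimulatedReads(pairs=pairs, read_len=read_len, truth=list(library))
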