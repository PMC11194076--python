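"""Library-preparation protocols applied to sampled fragments.

Three workflows are modelled:

``BRcfDNA``
    Broad-range single-stranded library prep without bisulfite: lossless,
    no conversion, adapters on both ends.  Serves as the size-profile
    reference.
``BSSeq``
    Conventional whole-genome bisulfite: conversion *before* adapter
    ligation.  Every internal bond may break; every surviving sub-fragment
    above the cleanup length re-enters the library, so degradation products
    of long molecules masquerade as short cfDNA.
``5mCAdpBS``
    Pre-methylated adapters are ligated *before* conversion.  A single
    break separates the two adapters, so only break-free molecules retain
    both adapters and amplify; degradation removes molecules instead of
    reshaping them.  Adapter bases are 5mC-protected and never convert.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemistry import ChemistryParams
from .fragments import Fragment
from .genome import GenomeBundle

__all__ = ["LibraryMolecule", "apply_protocol", "PROTOCOLS", "normalize_protocol"]

PROTOCOLS = ("BRcfDNA", "BSSeq", "5mCAdpBS")
_ALIASES = {
    "brcfdna": "BRcfDNA",
    "brcfdna-seq": "BRcfDNA",
    "bsseq": "BSSeq",
    "bs-seq": "BSSeq",
    "5mcadpbs": "5mCAdpBS",
    "5mcadpbs-seq": "5mCAdpBS",
}


def normalize_protocol(name: str) -> str:
    key = name.lower()
    if key in _ALIASES:
        return _ALIASES[key]
    raise ValueError(f"unknown protocol {name!r}; expected one of {PROTOCOLS}")


@dataclass
class LibraryMolecule:
    """A molecule that entered the sequencing library.

    ``sequence`` is the (possibly bisulfite-converted) insert on the
    molecule's strand, 5'->3', without adapter bases.  ``native_length`` is
    the length of the originating fragment before any breakage.
    """

    id: int
    origin_id: int
    genome: str
    start: int
    end: int
    strand: str
    population: str
    sequence: str
    native_length: int
    adapters: str = "both"

    @property
    def length(self) -> int:
        return self.end - self.start


def _convert(
    seq: str,
    c_positions: np.ndarray,
    c_contexts: np.ndarray,
    meth: np.ndarray,
    chem: ChemistryParams,
    rng: np.random.Generator,
) -> str:
    """Bisulfite-convert one strand sequence; only C positions may change."""
    if len(c_positions) == 0:
        return seq
    conv_p = np.where(
        meth,
        chem.over_conversion,
        np.where(c_contexts == "CpG", chem.c_cpg, chem.c_non_cpg),
    )
    converted = rng.random(len(c_positions)) < conv_p
    if not converted.any():
        return seq
    out = np.frombuffer(seq.encode(), dtype="S1").copy()
    out[c_positions[converted]] = b"T"
    return out.tobytes().decode()


def _subfragment(frag: Fragment, a: int, b: int, new_id: int) -> Fragment:
    """Slice a fragment at strand-sequence offsets [a, b)."""
    if frag.strand == "+":
        gs, ge = frag.start + a, frag.start + b
    else:
        gs, ge = frag.end - b, frag.end - a
    sel = (frag.c_positions >= a) & (frag.c_positions < b)
    return Fragment(
        id=new_id,
        genome=frag.genome,
        start=gs,
        end=ge,
        strand=frag.strand,
        population=frag.population,
        c_positions=frag.c_positions[sel] - a,
        c_contexts=frag.c_contexts[sel],
        c_dyads=frag.c_dyads[sel],
        meth=frag.meth[sel],
    )


def apply_protocol(
    fragments: list[Fragment],
    protocol: str,
    chem: ChemistryParams | None = None,
    bundle: GenomeBundle | None = None,
    seed: int = 0,
) -> list[LibraryMolecule]:
    """Transform sampled fragments into library molecules under one protocol.

    Returns the molecules that would be amplified and sequenced; for
    ``5mCAdpBS`` that is exactly the zero-break subset of the input.
    """
    protocol = normalize_protocol(protocol)
    chem = chem or ChemistryParams()
    if bundle is None:
        raise ValueError("a GenomeBundle is required to reconstruct fragment sequences")
    rng = np.random.default_rng(seed)
    lam = chem.breakage_prob
    out: list[LibraryMolecule] = []
    mid = 0

    for frag in fragments:
        seq = frag.strand_sequence(bundle)
        if protocol == "BRcfDNA":
            out.append(
                LibraryMolecule(
                    id=mid,
                    origin_id=frag.id,
                    genome=frag.genome,
                    start=frag.start,
                    end=frag.end,
                    strand=frag.strand,
                    population=frag.population,
                    sequence=seq,
                    native_length=frag.length,
                )
            )
            mid += 1
            continue

        n_bonds = frag.length - 1
        breaks = np.flatnonzero(rng.random(n_bonds) < lam) + 1 if n_bonds > 0 else np.array([], int)
        frag.breaks = [int(b) for b in breaks]

        if protocol == "5mCAdpBS":
            frag.adapters = "both"
            if len(breaks):  # a break strips one adapter from each piece
                continue
            cseq = _convert(seq, frag.c_positions, frag.c_contexts, frag.meth, chem, rng)
            out.append(
                LibraryMolecule(
                    id=mid,
                    origin_id=frag.id,
                    genome=frag.genome,
                    start=frag.start,
                    end=frag.end,
                    strand=frag.strand,
                    population=frag.population,
                    sequence=cseq,
                    native_length=frag.length,
                )
            )
            mid += 1
            continue

        # BSSeq: conversion happens on every piece; all pieces >= cleanup length ligate
        edges = [0, *[int(b) for b in breaks], frag.length]
        for a, b in zip(edges[:-1], edges[1:]):
            if b - a < chem.min_fragment_length:
                continue
            piece = _subfragment(frag, a, b, frag.id)
            pseq = seq[a:b]
            cseq = _convert(pseq, piece.c_positions, piece.c_contexts, piece.meth, chem, rng)
            out.append(
                LibraryMolecule(
                    id=mid,
                    origin_id=frag.id,
                    genome=piece.genome,
                    start=piece.start,
                    end=piece.end,
                    strand=piece.strand,
                    population=piece.population,
                    sequence=cseq,
                    native_length=frag.length,
                )
            )
            mid += 1
    return out
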