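"""Sampling cfDNA fragments from the synthetic genome.

Four source populations are modelled: ultrashort single-stranded cfDNA
(~50 nt), mononucleosomal cfDNA (~167 bp), high-molecular-weight genomic
DNA contamination, and the unmethylated lambda spike-in.  Each population
has its own size distribution; the ultrashort population can be biased
toward promoter / CpG-island / G-quadruplex source loci by a configurable
enrichment factor, reflecting where this population is observed to
originate.  Per-cytosine methylation states are independent Bernoulli draws
from the ground-truth methylome at the fragment's CpG (and CHG/CHH) sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import ConfigError, GenomeBundle
from .methylome import MethylomeTruth

__all__ = ["SizeDist", "PopulationMix", "Fragment", "sample_fragments", "revcomp"]

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class SizeDist:
    """Fragment-size distribution: truncated discretized normal or uniform."""

    kind: str = "normal"  # "normal" | "uniform"
    mode: float = 50.0
    sd: float = 6.0
    lo: int = 30
    hi: int = 80

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "uniform":
            return rng.integers(self.lo, self.hi + 1, size=n)
        out = np.rint(rng.normal(self.mode, self.sd, size=n)).astype(int)
        bad = (out < self.lo) | (out > self.hi)
        while bad.any():
            out[bad] = np.rint(rng.normal(self.mode, self.sd, size=int(bad.sum()))).astype(int)
            bad = (out < self.lo) | (out > self.hi)
        return out


DEFAULT_SIZES = {
    "uscfDNA": SizeDist("normal", 50, 6, 30, 80),
    "mncfDNA": SizeDist("normal", 167, 10, 120, 250),
    "gDNA_HMW": SizeDist("uniform", lo=500, hi=2000),
    "lambda": SizeDist("uniform", lo=25, hi=100),
}


@dataclass(frozen=True)
class PopulationMix:
    """Population weights and placement biases for the fragment sampler."""

    weights: dict[str, float] = field(
        default_factory=lambda: {"uscfDNA": 0.30, "mncfDNA": 0.60, "gDNA_HMW": 0.05, "lambda": 0.05}
    )
    sizes: dict[str, SizeDist] = field(default_factory=lambda: dict(DEFAULT_SIZES))
    mito_fraction: float = 0.01
    uscfdna_enrichment: float = 4.0
    enrichment_tracks: tuple[str, ...] = ("promoter", "cpg_island", "gquad_source")

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"population weights must sum to 1 (got {total})")
        if self.uscfdna_enrichment < 1.0:
            raise ConfigError("uscfdna_enrichment must be >= 1")


@dataclass
class Fragment:
    """One sampled cfDNA molecule (0-based half-open genomic coordinates).

    ``c_positions`` are indices of cytosines along the fragment's *strand*
    sequence; ``meth`` the matching methylation states; ``c_contexts`` the
    reference context of each cytosine; ``c_dyads`` the top-strand position
    of the CpG dyad (or -1 for non-CpG cytosines).
    """

    id: int
    genome: str
    start: int
    end: int
    strand: str
    population: str
    c_positions: np.ndarray
    c_contexts: np.ndarray
    c_dyads: np.ndarray
    meth: np.ndarray
    breaks: list[int] = field(default_factory=list)
    adapters: str = "none"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("fragment end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start

    def strand_sequence(self, bundle: GenomeBundle) -> str:
        seq = bundle.references[self.genome][self.start : self.end]
        return seq if self.strand == "+" else revcomp(seq)


class _GenomeCache:
    """Byte-array views of the references plus CpG-site lookups."""

    def __init__(self, bundle: GenomeBundle, truth: MethylomeTruth):
        self.arr = {
            g: np.frombuffer(s.encode(), dtype="S1") for g, s in bundle.references.items()
        }
        self.sites = truth.sites


def annotate_cytosines(
    arr: np.ndarray, start: int, end: int, strand: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cytosine strand-indices, contexts and dyad positions for one fragment."""
    L = len(arr)
    if strand == "+":
        sub = arr[start:end]
        idx = np.flatnonzero(sub == b"C")
        pos = start + idx
        nxt = np.where(pos + 1 < L, arr[np.minimum(pos + 1, L - 1)], b"N")
        nxt2 = np.where(pos + 2 < L, arr[np.minimum(pos + 2, L - 1)], b"N")
        is_cpg = nxt == b"G"
        is_chg = ~is_cpg & (nxt2 == b"G")
        dyads = np.where(is_cpg, pos, -1)
    else:
        sub = arr[start:end]
        gidx = np.flatnonzero(sub == b"G")  # bottom-strand C sits opposite top-strand G
        pos = start + gidx
        pos = pos[::-1]  # strand order: 5'->3' on the minus strand
        idx = (end - 1) - pos
        prv = np.where(pos - 1 >= 0, arr[np.maximum(pos - 1, 0)], b"N")
        prv2 = np.where(pos - 2 >= 0, arr[np.maximum(pos - 2, 0)], b"N")
        is_cpg = prv == b"C"
        is_chg = ~is_cpg & (prv2 == b"C")
        dyads = np.where(is_cpg, pos - 1, -1)
    contexts = np.full(len(idx), "CHH", dtype="U3")
    contexts[is_chg] = "CHG"
    contexts[is_cpg] = "CpG"
    return idx.astype(int), contexts, dyads.astype(int)


def sample_fragments(
    bundle: GenomeBundle,
    truth: MethylomeTruth,
    mix: PopulationMix | None = None,
    n: int = 10_000,
    seed: int = 0,
) -> list[Fragment]:
    """Draw ``n`` fragments from the population mix.

    Positions are uniform over the target reference; ultrashort fragments
    are enriched at source loci by rejection sampling (a fragment touching a
    source interval is always accepted, others with probability
    ``1/enrichment``), giving the configured density ratio.
    """
    mix = mix or PopulationMix()
    rng = np.random.default_rng(seed)
    cache = _GenomeCache(bundle, truth)

    pops = list(mix.weights)
    counts = rng.multinomial(n, [mix.weights[p] for p in pops])

    # cumulative source-locus mask for O(1) overlap queries during rejection
    src_cum = None
    if "nuclear" in bundle.references and mix.uscfdna_enrichment > 1.0:
        mask = np.zeros(bundle.length("nuclear"), dtype=bool)
        for tr in mix.enrichment_tracks:
            for iv in bundle.annotations.get(tr, []):
                mask[iv.start : iv.end] = True
        src_cum = np.concatenate([[0], np.cumsum(mask)])

    fragments: list[Fragment] = []
    fid = 0
    for pop, cnt in zip(pops, counts):
        if cnt == 0:
            continue
        sizes = mix.sizes[pop].sample(cnt, rng)
        for size in sizes:
            genome = "lambda" if pop == "lambda" else "nuclear"
            if pop in ("uscfDNA", "mncfDNA") and rng.random() < mix.mito_fraction:
                genome = "mito"
            L = bundle.length(genome)
            size_i = int(min(size, L))
            enrich = (
                pop == "uscfDNA" and genome == "nuclear" and src_cum is not None
            )
            while True:
                start = int(rng.integers(0, L - size_i + 1))
                if not enrich:
                    break
                touches = src_cum[start + size_i] - src_cum[start] > 0
                if touches or rng.random() < 1.0 / mix.uscfdna_enrichment:
                    break
            end = start + size_i
            strand = "+" if rng.random() < 0.5 else "-"
            idx, contexts, dyads = annotate_cytosines(cache.arr[genome], start, end, strand)
            probs = np.full(len(idx), 0.0 if pop == "lambda" else truth.chh_prob)
            cpg = contexts == "CpG"
            if cpg.any():
                site_pos = truth.sites[genome]
                locs = np.searchsorted(site_pos, dyads[cpg])
                locs = np.clip(locs, 0, max(len(site_pos) - 1, 0))
                pv = truth.probs[(pop, genome)]
                if len(site_pos):
                    hit = site_pos[locs] == dyads[cpg]
                    vals = np.where(hit, pv[locs], 0.0)
                else:  # no CpG site in this reference at all
                    vals = np.zeros(int(cpg.sum()))
                p = probs.copy()
                p[cpg] = vals
                probs = p
            meth = rng.random(len(idx)) < probs
            fragments.append(
                Fragment(
                    id=fid,
                    genome=genome,
                    start=start,
                    end=end,
                    strand=strand,
                    population=pop,
                    c_positions=idx,
                    c_contexts=contexts,
                    c_dyads=dyads,
                    meth=meth,
                )
            )
            fid += 1
    return fragments
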