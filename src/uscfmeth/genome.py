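"""Synthetic reference genomes with annotation tracks.

A :class:`GenomeBundle` stands in for a real genome plus its regulatory
annotation: a "nuclear" reference tiled with gene units (promoter, UTRs,
exons, introns, TTS), CpG islands with shores and shelves, repeat classes
(SINE/LINE/simple repeats), histone-mark intervals, hypo-/hyper-methylated
regions and TSS points with expression tiers — together with a small
mitochondrial-like circle and a lambda-phage-like spike-in control.

The sequence itself is random but structured: CpG islands are CG-enriched
with planted CpG dyads, and a configurable fraction of promoters carries a
planted G-quadruplex motif, so motif- and composition-based statistics have
real signal to find.  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np

__all__ = ["GInterval", "GenomeConfig", "GenomeBundle", "build_genome_bundle", "ConfigError"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

MARK_TRACKS = (
    "h3k4me1",
    "h3k4me3",
    "h3k27ac",
    "h3k27me3",
    "h3k9me3",
    "h3k36me3",
    "hypomethylated_region",
    "hypermethylated_region",
)

ELEMENT_TRACKS = (
    "promoter",
    "cpg_island",
    "cpg_shore",
    "cpg_shelf",
    "exon",
    "first_exon",
    "intron",
    "five_utr",
    "three_utr",
    "tts",
    "intergenic",
    "sine",
    "line",
    "simple_repeat",
)

# telomere-like G4: four G-runs of 3 with TTA loops
GQUAD_MOTIF = "GGGTTAGGGTTAGGGTTAGGG"


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


class GInterval(NamedTuple):
    start: int
    end: int
    name: str = "."
    strand: str = "."


@dataclass(frozen=True)
class GenomeConfig:
    nuclear_length: int = 1_000_000
    mito_length: int = 16_000
    lambda_length: int = 48_000
    gc_content: float = 0.42
    island_gc: float = 0.62
    island_cpg_spacing: int = 8
    gene_unit_length: int = 10_000
    gquad_promoter_fraction: float = 0.6

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_content < 1.0 or not 0.0 < self.island_gc < 1.0:
            raise ConfigError("GC contents must be in (0, 1)")
        if not 0.0 <= self.gquad_promoter_fraction <= 1.0:
            raise ConfigError("gquad_promoter_fraction must be in [0, 1]")


@dataclass
class GenomeBundle:
    """Named references plus annotation tracks (0-based half-open intervals)."""

    references: dict[str, str]
    annotations: dict[str, list[GInterval]]
    tss_expression: dict[str, str]
    config: GenomeConfig = field(default_factory=GenomeConfig)

    def length(self, genome: str) -> int:
        return len(self.references[genome])

    def cpg_sites(self, genome: str) -> np.ndarray:
        """Top-strand C positions of all CpG dyads in a reference."""
        seq = np.frombuffer(self.references[genome].encode(), dtype="S1")
        return np.flatnonzero((seq[:-1] == b"C") & (seq[1:] == b"G"))

    def track(self, name: str) -> list[GInterval]:
        return self.annotations[name]

    # ---- persistence -------------------------------------------------

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "references.fa", "w") as fh:
            for name in sorted(self.references):
                fh.write(f">{name}\n")
                seq = self.references[name]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        for track in sorted(self.annotations):
            with open(outdir / f"{track}.bed", "w") as fh:
                for iv in self.annotations[track]:
                    fh.write(f"nuclear\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")
        with open(outdir / "tss_expression.tsv", "w") as fh:
            fh.write("tss_id\ttier\n")
            for tss_id in sorted(self.tss_expression):
                fh.write(f"{tss_id}\t{self.tss_expression[tss_id]}\n")

    @classmethod
    def load(cls, indir: str | Path) -> "GenomeBundle":
        from Bio import SeqIO

        indir = Path(indir)
        references = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(str(indir / "references.fa"), "fasta")
        }
        annotations: dict[str, list[GInterval]] = {}
        for bed in sorted(indir.glob("*.bed")):
            ivs = []
            with open(bed) as fh:
                for line in fh:
                    f = line.rstrip("\n").split("\t")
                    ivs.append(GInterval(int(f[1]), int(f[2]), f[3], f[5]))
            annotations[bed.stem] = ivs
        tss_expression = {}
        with open(indir / "tss_expression.tsv") as fh:
            next(fh)
            for line in fh:
                tss_id, tier = line.split()
                tss_expression[tss_id] = tier
        return cls(references=references, annotations=annotations, tss_expression=tss_expression)


def _random_seq(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def build_genome_bundle(config: GenomeConfig | None = None, seed: int = 0) -> GenomeBundle:
    """Construct a deterministic synthetic genome bundle.

    The nuclear reference is tiled with fixed-length gene units; within each
    unit the element layout is promoter → 5'UTR → first exon → introns/exons
    → 3'UTR → TTS (mirrored for minus-strand genes), with the remainder
    intergenic.  CpG islands sit over the TSS with 2 kb shores and shelves;
    marks are placed according to the gene's expression tier.
    """
    cfg = config or GenomeConfig()
    rng = np.random.default_rng(seed)

    unit = cfg.gene_unit_length
    # element sizes inside one unit
    prom, utr5, fex, intr, ex, utr3, tts_len = 1000, 200, 300, 800, 250, 300, 200
    gene_span = utr5 + fex + intr + ex + intr + ex + utr3 + tts_len
    if prom + gene_span + 2000 > unit:
        raise ConfigError(
            f"gene_unit_length {unit} too small for mandatory layout ({prom + gene_span + 2000})"
        )
    n_units = cfg.nuclear_length // unit
    if n_units < 1:
        raise ConfigError("nuclear_length smaller than one gene unit")

    ann: dict[str, list[GInterval]] = {t: [] for t in ELEMENT_TRACKS + MARK_TRACKS}
    ann["tss_points"] = []
    ann["gquad_source"] = []
    tss_expression: dict[str, str] = {}

    seq = _random_seq(cfg.nuclear_length, cfg.gc_content, rng)

    tiers = rng.choice(["high", "medium", "low", "silent"], size=n_units)
    gquad_flags = rng.random(n_units) < cfg.gquad_promoter_fraction

    for u in range(n_units):
        base = u * unit
        strand = "+" if u % 2 == 0 else "-"
        tss_id = f"tss_{u:05d}"
        tier = str(tiers[u])
        tss_expression[tss_id] = tier
        gname = f"gene_{u:05d}"

        # forward layout positions within the unit, then mirror for '-' genes
        parts = [
            ("promoter", prom),
            ("five_utr", utr5),
            ("first_exon", fex),
            ("intron", intr),
            ("exon", ex),
            ("intron", intr),
            ("exon", ex),
            ("three_utr", utr3),
            ("tts", tts_len),
        ]
        spans: list[tuple[str, int, int]] = []
        pos = base
        for track, size in parts:
            spans.append((track, pos, pos + size))
            pos += size
        gene_end = pos
        if strand == "-":
            # mirror within [base, gene_end)
            spans = [
                (track, base + (gene_end - e), base + (gene_end - s)) for track, s, e in spans
            ]
        for track, s, e in spans:
            ann[track].append(GInterval(s, e, gname, strand))
            if track == "first_exon":
                ann["exon"].append(GInterval(s, e, gname, strand))
        tss = spans[0][2] if strand == "+" else spans[0][1]  # promoter/5'UTR boundary
        if strand == "-":
            tss -= 1  # last transcribed base for minus-strand genes
        ann["tss_points"].append(GInterval(tss, tss + 1, tss_id, strand))
        ann["intergenic"].append(GInterval(gene_end, base + unit, f"ig_{u:05d}", "."))

        # CpG island over the TSS, shores and shelves flanking
        isl_s, isl_e = max(base, tss - 300), min(base + unit, tss + 300)
        ann["cpg_island"].append(GInterval(isl_s, isl_e, f"isl_{u:05d}", "."))
        ann["cpg_shore"].append(GInterval(max(base, isl_s - 2000), isl_s, f"shore_{u:05d}l", "."))
        ann["cpg_shore"].append(GInterval(isl_e, min(base + unit, isl_e + 2000), f"shore_{u:05d}r", "."))
        ann["cpg_shelf"].append(
            GInterval(max(base, isl_s - 4000), max(base, isl_s - 2000), f"shelf_{u:05d}l", ".")
        )
        ann["cpg_shelf"].append(
            GInterval(min(base + unit, isl_e + 2000), min(base + unit, isl_e + 4000), f"shelf_{u:05d}r", ".")
        )

        # repeats in the intergenic remainder
        ig_s, ig_e = gene_end, base + unit
        cursor = ig_s + int(rng.integers(0, 200))
        for track, size in (("sine", 300), ("line", 1000), ("simple_repeat", 200)):
            if cursor + size + 100 > ig_e:
                break
            ann[track].append(GInterval(cursor, cursor + size, f"{track}_{u:05d}", "."))
            cursor += size + int(rng.integers(100, 400))

        # marks by expression tier
        mark_win = GInterval(max(base, tss - 500), min(base + unit, tss + 500), gname, ".")
        body = GInterval(min(s for _, s, _ in spans[1:]), max(e for _, _, e in spans[1:]), gname, ".")
        if tier in ("high", "medium"):
            ann["h3k4me3"].append(mark_win)
            ann["h3k36me3"].append(body)
            ann["hypomethylated_region"].append(GInterval(isl_s, isl_e, gname, "."))
        if tier == "high":
            ann["h3k27ac"].append(mark_win)
        if tier in ("high", "medium", "low") and ig_e - ig_s > 1500:
            enh_s = ig_s + 200
            ann["h3k4me1"].append(GInterval(enh_s, enh_s + 600, f"enh_{u:05d}", "."))
        if tier == "silent":
            ann["h3k27me3"].append(GInterval(mark_win.start, body.end, gname, "."))
            ann["hypermethylated_region"].append(body)
            if ig_e - ig_s > 2500:
                ann["h3k9me3"].append(GInterval(ig_e - 1200, ig_e - 200, f"het_{u:05d}", "."))

        # CG-enrich the island and plant CpG dyads
        isl_len = isl_e - isl_s
        seq[isl_s:isl_e] = _random_seq(isl_len, cfg.island_gc, rng)
        for off in range(0, isl_len - 1, cfg.island_cpg_spacing):
            seq[isl_s + off] = b"C"
            seq[isl_s + off + 1] = b"G"

        # plant a G-quadruplex motif upstream of a fraction of TSSs
        if gquad_flags[u]:
            motif = GQUAD_MOTIF
            gq_s = tss - 150 if strand == "+" else tss + 150 - len(motif)
            gq_s = max(base, min(gq_s, base + unit - len(motif)))
            if strand == "+":
                seq[gq_s : gq_s + len(motif)] = np.frombuffer(motif.encode(), dtype="S1")
            else:
                rc = motif.translate(str.maketrans("ACGT", "TGCA"))[::-1]
                seq[gq_s : gq_s + len(motif)] = np.frombuffer(rc.encode(), dtype="S1")
            ann["gquad_source"].append(GInterval(gq_s, gq_s + len(motif), f"g4_{u:05d}", strand))

    references = {
        "nuclear": seq.tobytes().decode(),
        "mito": _random_seq(cfg.mito_length, 0.44, rng).tobytes().decode(),
        "lambda": _random_seq(cfg.lambda_length, 0.50, rng).tobytes().decode(),
    }
    for track, ivs in ann.items():
        kept = sorted(iv for iv in ivs if iv.end > iv.start)  # drop clipped-away flanks
        for iv in kept:
            if not (0 <= iv.start < iv.end <= cfg.nuclear_length):
                raise ConfigError(f"interval {iv} outside nuclear reference")
        ann[track] = kept
    return GenomeBundle(
        references=references, annotations=ann, tss_expression=tss_expression, config=cfg
    )
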