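"""Methylation calling from aligned observed cytosine states.

Evidence is accumulated per reference site: top-strand C observations and
bottom-strand G observations.  CpG dyads are reported unstranded (both
strands merged onto the top-strand C position, CGmap style); CHG/CHH sites
keep their strand.  Per-size-bin percentages pool counts across sites, so
the bin percentage equals the depth-weighted mean of per-site percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .align import CONVERTED, RETAINED, AlignedFragment, SizeBins
from .genome import GenomeBundle

__all__ = [
    "SiteMethylationTable",
    "FragmentMethylation",
    "call_sites",
    "per_bin_methylation",
    "fragment_methylation",
    "conversion_qc",
    "ConversionQCWarning",
]

CATEGORIES = ("zero", "(0,25]", "(25,75]", "(75,100]")


class ConversionQCWarning(UserWarning):
    """Bisulfite conversion efficiency below the accepted threshold."""


@dataclass
class SiteMethylationTable:
    """Per-site methylated/unmethylated counts.

    ``df`` columns: genome, pos, strand, context ({CpG, CHG, CHH}), meth,
    unmeth.  CpG rows are dyad-merged with strand ".".
    """

    df: pd.DataFrame

    def pooled_percent(self, contexts: tuple[str, ...] = ("CpG",)) -> float | None:
        sub = self.df[self.df["context"].isin(contexts)]
        depth = int(sub["meth"].sum() + sub["unmeth"].sum())
        if depth == 0:
            return None
        return 100.0 * float(sub["meth"].sum()) / depth

    def depth(self, contexts: tuple[str, ...] | None = None) -> int:
        sub = self.df if contexts is None else self.df[self.df["context"].isin(contexts)]
        return int(sub["meth"].sum() + sub["unmeth"].sum())

    def write_bismark_cov(self, path: str | Path, context: str = "CpG") -> None:
        """bismark coverage dialect: chrom, 1-based start, end, %, meth, unmeth."""
        sub = self.df[self.df["context"] == context].copy()
        depth = sub["meth"] + sub["unmeth"]
        sub = sub[depth > 0]
        pct = 100.0 * sub["meth"] / (sub["meth"] + sub["unmeth"])
        out = pd.DataFrame(
            {
                "chrom": sub["genome"],
                "start": sub["pos"] + 1,
                "end": sub["pos"] + 1,
                "pct": pct,
                "meth": sub["meth"],
                "unmeth": sub["unmeth"],
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")

    @classmethod
    def read_bismark_cov(cls, path: str | Path, context: str = "CpG") -> "SiteMethylationTable":
        raw = pd.read_csv(
            path, sep="\t", names=["chrom", "start", "end", "pct", "meth", "unmeth"]
        )
        df = pd.DataFrame(
            {
                "genome": raw["chrom"],
                "pos": raw["start"] - 1,
                "strand": ".",
                "context": context,
                "meth": raw["meth"],
                "unmeth": raw["unmeth"],
            }
        )
        return cls(df=df)


@dataclass
class FragmentMethylation:
    """Per-fragment CpG methylation summary and category."""

    fragment_id: str | None
    cpg_observed: int
    cpg_methylated: int

    @property
    def fraction(self) -> float | None:
        if self.cpg_observed == 0:
            return None
        return self.cpg_methylated / self.cpg_observed

    @property
    def category(self) -> str | None:
        f = self.fraction
        if f is None:
            return None
        if f == 0.0:
            return "zero"
        if f <= 0.25:
            return "(0,25]"
        if f <= 0.75:
            return "(25,75]"
        return "(75,100]"


def _context_top(ref: str, p: int) -> tuple[str, int]:
    """Context and dyad position of a top-strand C at reference position p."""
    n = len(ref)
    if p + 1 < n and ref[p + 1] == "G":
        return "CpG", p
    if p + 2 < n and ref[p + 2] == "G":
        return "CHG", -1
    return "CHH", -1


def _context_bottom(ref: str, p: int) -> tuple[str, int]:
    """Context and dyad position of a bottom-strand C (top-strand G) at p."""
    if p - 1 >= 0 and ref[p - 1] == "C":
        return "CpG", p - 1
    if p - 2 >= 0 and ref[p - 2] == "C":
        return "CHG", -1
    return "CHH", -1


def call_sites(
    alignments: list[AlignedFragment],
    bundle: GenomeBundle,
    subset: list[AlignedFragment] | None = None,
) -> SiteMethylationTable:
    """Accumulate observed states into per-site methylation counts.

    ``subset`` restricts calling to a sub-population (e.g. one size bin);
    observations in state "other" (sequencing errors) are ignored.
    """
    use = subset if subset is not None else alignments
    counts: dict[tuple[str, int, str, str], list[int]] = {}
    for a in use:
        if a.genome not in bundle.references:
            raise KeyError(f"alignment references unknown genome {a.genome!r}")
        ref = bundle.references[a.genome]
        top = a.strand == "+"
        for pos, state in a.observed:
            if state not in (RETAINED, CONVERTED):
                continue
            context, dyad = _context_top(ref, pos) if top else _context_bottom(ref, pos)
            if context == "CpG":
                key = (a.genome, dyad, ".", "CpG")
            else:
                key = (a.genome, pos, "+" if top else "-", context)
            row = counts.setdefault(key, [0, 0])
            row[0 if state == RETAINED else 1] += 1
    if counts:
        keys = sorted(counts)
        df = pd.DataFrame(
            {
                "genome": [k[0] for k in keys],
                "pos": [k[1] for k in keys],
                "strand": [k[2] for k in keys],
                "context": [k[3] for k in keys],
                "meth": [counts[k][0] for k in keys],
                "unmeth": [counts[k][1] for k in keys],
            }
        )
    else:
        df = pd.DataFrame(
            columns=["genome", "pos", "strand", "context", "meth", "unmeth"]
        )
    return SiteMethylationTable(df=df)


def per_bin_methylation(
    binned: dict[str, list[AlignedFragment]], bundle: GenomeBundle
) -> dict[str, tuple[float, float | None, int]]:
    """Pooled (CpG %, CHH %, CpG depth) per size bin; empty bins are omitted."""
    out: dict[str, tuple[float, float | None, int]] = {}
    for label, alns in binned.items():
        if not alns:
            continue
        table = call_sites(alns, bundle)
        cpg = table.pooled_percent(("CpG",))
        if cpg is None:
            continue
        chh = table.pooled_percent(("CHH",))
        out[label] = (cpg, chh, table.depth(("CpG",)))
    return out


def fragment_methylation(
    alignment: AlignedFragment, bundle: GenomeBundle
) -> FragmentMethylation:
    """Observed CpG count, methylated CpG count and category for one fragment."""
    ref = bundle.references[alignment.genome]
    top = alignment.strand == "+"
    n_obs = n_meth = 0
    for pos, state in alignment.observed:
        if state not in (RETAINED, CONVERTED):
            continue
        context, _ = _context_top(ref, pos) if top else _context_bottom(ref, pos)
        if context != "CpG":
            continue
        n_obs += 1
        if state == RETAINED:
            n_meth += 1
    return FragmentMethylation(
        fragment_id=alignment.pair_id, cpg_observed=n_obs, cpg_methylated=n_meth
    )


def conversion_qc(
    lambda_table: SiteMethylationTable,
    cpg_threshold: float = 99.0,
    non_cpg_threshold: float = 98.5,
) -> tuple[float, float]:
    """Conversion efficiencies from the unmethylated lambda spike-in.

    Efficiency = 100 - pooled methylation %; a :class:`ConversionQCWarning`
    is raised when CpG efficiency < 99% or non-CpG < 98.5%.
    """
    cpg_pct = lambda_table.pooled_percent(("CpG",))
    non_cpg_pct = lambda_table.pooled_percent(("CHG", "CHH"))
    if cpg_pct is None or non_cpg_pct is None:
        raise ValueError("lambda spike-in has zero depth; cannot estimate conversion")
    cpg_eff = 100.0 - cpg_pct
    non_cpg_eff = 100.0 - non_cpg_pct
    if cpg_eff < cpg_threshold or non_cpg_eff < non_cpg_threshold:
        warnings.warn(
            f"conversion efficiency below threshold: CpG {cpg_eff:.2f}% "
            f"(need >={cpg_threshold}), non-CpG {non_cpg_eff:.2f}% "
            f"(need >={non_cpg_threshold})",
            ConversionQCWarning,
            stacklevel=2,
        )
    return cpg_eff, non_cpg_eff
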