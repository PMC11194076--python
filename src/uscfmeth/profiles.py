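"""Metaprofiles: fragment enrichment over TSSs and methylation trends over features.

TSS curves count full fragment coverage in fixed windows around each
transcription start site, oriented by gene strand (negative positions are
upstream of transcription).  "Relative" normalisation divides the curve by
its own mean so cohorts of different depth are comparable; the operation
preserves curve shape.  Feature trends average per-site methylation
percentages in 100 bp windows over absolute flanks and a length-normalised
feature body.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .genome import GInterval
from .intervals import IntervalSet
from .methylation import SiteMethylationTable

__all__ = ["tss_profile", "feature_trend"]


def tss_profile(
    fragments: IntervalSet,
    tss_points: list[GInterval],
    genome_length: int,
    window: int = 1000,
    bin_size: int = 20,
    normalization: str = "relative",
    tss_expression: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Average fragment coverage around TSSs, per expression tier.

    Returns a tidy frame with columns ``tier`` ("all" plus any tiers found
    in ``tss_expression``), ``position`` (bin centre relative to the TSS,
    upstream negative) and ``enrichment``.
    """
    if window % bin_size != 0:
        raise ValueError("window must be a multiple of bin_size")
    cov = np.zeros(genome_length + 1)
    for s, e in zip(fragments.starts, fragments.ends):
        cov[max(0, int(s))] += 1
        cov[min(genome_length, int(e))] -= 1
    cov = np.cumsum(cov)[:genome_length]

    n_bins = 2 * window // bin_size
    groups: dict[str, list[np.ndarray]] = {"all": []}
    for tss in tss_points:
        strand = tss.strand
        if strand not in ("+", "-"):
            warnings.warn(f"TSS {tss.name} lacks a strand; treating as '+'", stacklevel=2)
            strand = "+"
        p = tss.start
        lo, hi = p - window, p + window
        win = np.zeros(2 * window)
        src_lo, src_hi = max(0, lo), min(genome_length, hi)
        if src_hi > src_lo:
            win[src_lo - lo : src_hi - lo] = cov[src_lo:src_hi]
        if strand == "-":
            win = win[::-1]
        binned = win.reshape(n_bins, bin_size).mean(axis=1)
        groups["all"].append(binned)
        if tss_expression and tss.name in tss_expression:
            groups.setdefault(tss_expression[tss.name], []).append(binned)

    positions = np.arange(-window, window, bin_size) + bin_size / 2.0
    rows = []
    for tier, curves in groups.items():
        if not curves:
            continue
        mean_curve = np.mean(curves, axis=0)
        if normalization == "relative":
            m = mean_curve.mean()
            if m > 0:
                mean_curve = mean_curve / m
        rows.append(pd.DataFrame({"tier": tier, "position": positions, "enrichment": mean_curve}))
    return pd.concat(rows, ignore_index=True)


def feature_trend(
    site_table: SiteMethylationTable,
    features: list[GInterval],
    genome: str = "nuclear",
    flank: int = 5000,
    window: int = 100,
    body_windows: int = 20,
    min_count: int = 1,
) -> pd.DataFrame:
    """Methylation % trend over scaled feature bodies with absolute flanks.

    Flanks are tiled with fixed ``window``-base probes; each feature body is
    split into ``body_windows`` equal windows regardless of its length.
    Windows covering fewer than ``min_count`` site observations are missing
    (NaN), never zero.  Returns columns ``segment`` (upstream/body/
    downstream), ``window_index`` and ``mean_pct``.
    """
    sub = site_table.df
    sub = sub[(sub["genome"] == genome) & (sub["context"] == "CpG")]
    depth = sub["meth"] + sub["unmeth"]
    sub = sub[depth >= 1]
    pos = sub["pos"].to_numpy()
    pct = (100.0 * sub["meth"] / (sub["meth"] + sub["unmeth"])).to_numpy()
    order = np.argsort(pos)
    pos, pct = pos[order], pct[order]

    n_flank = flank // window
    n_total = n_flank + body_windows + n_flank
    sums = np.zeros(n_total)
    counts = np.zeros(n_total, dtype=int)

    def add(widx: int, a: float, b: float) -> None:
        lo = int(np.searchsorted(pos, a, side="left"))
        hi = int(np.searchsorted(pos, b, side="left"))
        if hi > lo:
            sums[widx] += pct[lo:hi].sum()
            counts[widx] += hi - lo

    for ft in features:
        strand = ft.strand if ft.strand in ("+", "-") else "+"
        body_edges = np.linspace(ft.start, ft.end, body_windows + 1)
        for w in range(n_total):
            if w < n_flank:  # upstream, farthest first
                off_out = (n_flank - w) * window
                if strand == "+":
                    a, b = ft.start - off_out, ft.start - off_out + window
                else:
                    a, b = ft.end + off_out - window, ft.end + off_out
            elif w < n_flank + body_windows:
                k = w - n_flank
                kk = k if strand == "+" else body_windows - 1 - k
                a, b = body_edges[kk], body_edges[kk + 1]
            else:
                k = w - n_flank - body_windows
                if strand == "+":
                    a, b = ft.end + k * window, ft.end + (k + 1) * window
                else:
                    a, b = ft.start - (k + 1) * window, ft.start - k * window
            add(w, a, b)

    mean = np.full(n_total, np.nan)
    ok = counts >= min_count
    mean[ok] = sums[ok] / counts[ok]
    segment = (["upstream"] * n_flank + ["body"] * body_windows + ["downstream"] * n_flank)
    return pd.DataFrame(
        {"segment": segment, "window_index": np.arange(n_total), "mean_pct": mean}
    )
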