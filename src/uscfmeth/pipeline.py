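"""Pipeline orchestration: simulate -> process -> analyze.

Stage order mirrors a merged-read bisulfite pipeline: trim -> merge ->
align -> deduplicate -> size-bin, with per-stage retained-read accounting.
Every stochastic stage receives a seed derived deterministically from the
root seed, so re-running one stage never changes another's randomness, and
a manifest of output hashes makes reruns verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .align import AlignedFragment, bin_by_size, build_bs_index, align_bisulfite, deduplicate
from .config import RunConfig, stage_seed
from .dmr import GroupMethylationMatrix, dmrs_to_frame, find_dmrs
from .fragmentomics import cpg_density_profile, gquad_bin_stats, size_profile
from .fragments import sample_fragments
from .genome import GenomeBundle, build_genome_bundle
from .intervals import IntervalSet, element_composition, observed_ratio
from .methylation import (
    ConversionQCWarning,
    call_sites,
    conversion_qc,
    per_bin_methylation,
)
from .methylome import MethylomeTruth, build_methylome
from .profiles import feature_trend, tss_profile
from .protocol import apply_protocol
from .reads import ReadPair, SimulatedReads, emit_reads
from .readproc import process_pairs

logger = logging.getLogger(__name__)

__all__ = ["run_simulate", "run_process", "run_analyze", "run_all"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _provenance(cfg: RunConfig) -> str:
    return f"# config_hash={cfg.hash()} seed={cfg.seed}\n"


def run_simulate(cfg: RunConfig, outdir: str | Path | None = None) -> dict:
    """Generate references, truth files and paired FASTQ for one cohort."""
    outdir = Path(outdir or cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = build_genome_bundle(cfg.genome, seed=stage_seed(cfg.seed, "genome"))
    truth = build_methylome(bundle, cfg.methylome, seed=stage_seed(cfg.seed, "methylome"))
    frags = sample_fragments(
        bundle, truth, cfg.mix, n=cfg.n_fragments, seed=stage_seed(cfg.seed, "fragments")
    )
    library = apply_protocol(
        frags, cfg.protocol, cfg.chemistry, bundle, seed=stage_seed(cfg.seed, "protocol")
    )
    reads = emit_reads(
        library,
        read_len=cfg.read_len,
        error_rate=cfg.sequencing_error_rate,
        seed=stage_seed(cfg.seed, "reads"),
    )
    ref_dir = outdir / "reference"
    bundle.save(ref_dir)
    truth.save(outdir / "truth_methylome.tsv")
    reads.write_truth_bed(outdir / "truth_fragments.bed")
    r1, r2 = outdir / "reads_R1.fastq", outdir / "reads_R2.fastq"
    reads.write_fastq(r1, r2)
    manifest = {
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "n_fragments": len(frags),
        "n_library_molecules": len(library),
        "files": {
            str(p.relative_to(outdir)): _sha256(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {
        "bundle": bundle,
        "truth": truth,
        "fragments": frags,
        "library": library,
        "reads": reads,
        "outdir": outdir,
        "r1": r1,
        "r2": r2,
    }


def _read_fastq_pairs(r1_path: Path, r2_path: Path) -> list[ReadPair]:
    from Bio import SeqIO

    def load(path):
        return list(SeqIO.parse(str(path), "fastq"))

    recs1, recs2 = load(r1_path), load(r2_path)
    if not recs1 or len(recs1) != len(recs2):
        raise ValueError("empty or mismatched FASTQ pair")
    pairs = []
    for a, b in zip(recs1, recs2):
        name = a.id.rsplit("/", 1)[0]
        q1 = "".join(chr(q + 33) for q in a.letter_annotations["phred_quality"])
        q2 = "".join(chr(q + 33) for q in b.letter_annotations["phred_quality"])
        pairs.append(ReadPair(name=name, r1=str(a.seq), q1=q1, r2=str(b.seq), q2=q2))
    return pairs


def run_process(
    cfg: RunConfig,
    bundle: GenomeBundle | None = None,
    reads: SimulatedReads | None = None,
    r1: str | Path | None = None,
    r2: str | Path | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Trim, merge, align, deduplicate and size-bin a read cohort."""
    outdir = Path(outdir or cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if bundle is None:
        bundle = GenomeBundle.load(outdir / "reference")
    if reads is not None:
        pairs = reads.pairs
    else:
        pairs = _read_fastq_pairs(Path(r1), Path(r2))
    if not pairs:
        raise ValueError("no read pairs to process")

    merged, stats = process_pairs(pairs)
    index = build_bs_index(bundle)
    alignments: list[AlignedFragment] = []
    unaligned = 0
    for mr in merged:
        a = align_bisulfite(mr, index)
        if a is None:
            unaligned += 1
        else:
            alignments.append(a)
    alignments, n_dups = deduplicate(alignments)
    binned = bin_by_size(alignments, cfg.bins)

    frag_rows = [
        (a.genome, a.start, a.end, a.pair_id or ".", a.length, a.strand, int(a.unique))
        for a in alignments
    ]
    with open(outdir / "fragments.bed", "w") as fh:
        fh.write(_provenance(cfg))
        for g, s, e, n, ln, st, uq in frag_rows:
            fh.write(f"{g}\t{s}\t{e}\t{n}\t{ln}\t{st}\t{uq}\n")

    table = call_sites(alignments, bundle)
    table.write_bismark_cov(outdir / "coverage_cpg.cov")
    for cls_name, mask_fn in (
        ("uscfdna", cfg.bins.is_uscfdna),
        ("mncfdna", cfg.bins.is_mncfdna),
    ):
        cls_alns = [a for a in alignments if mask_fn(a.length)]
        if cls_alns:
            call_sites(cls_alns, bundle).write_bismark_cov(outdir / f"coverage_{cls_name}.cov")

    qc = {
        "pairs_in": stats.pairs_in,
        "dropped_short": stats.dropped_short,
        "merge_rejected": stats.merge_rejected,
        "merged": stats.merged,
        "unaligned": unaligned,
        "aligned": len(alignments) + n_dups,
        "duplicates_removed": n_dups,
        "retained": len(alignments),
        "retained_fraction": len(alignments) / stats.pairs_in if stats.pairs_in else 0.0,
    }
    lam_alns = [a for a in alignments if a.genome == "lambda"]
    if lam_alns:
        lam_table = call_sites(lam_alns, bundle)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConversionQCWarning)
            cpg_eff, non_cpg_eff = conversion_qc(lam_table)
        qc["lambda_cpg_efficiency"] = cpg_eff
        qc["lambda_non_cpg_efficiency"] = non_cpg_eff
        qc["conversion_warnings"] = [str(w.message) for w in caught]
    with open(outdir / "qc.json", "w") as fh:
        json.dump(qc, fh, indent=2, sort_keys=True)
    return {
        "alignments": alignments,
        "binned": binned,
        "site_table": table,
        "qc": qc,
        "bundle": bundle,
        "outdir": outdir,
    }


def run_analyze(
    cfg: RunConfig,
    bundle: GenomeBundle,
    alignments: list[AlignedFragment],
    outdir: str | Path | None = None,
) -> dict:
    """Run the enabled analyses and write one table per analysis."""
    outdir = Path(outdir or cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    toggles = cfg.analyses
    binned = bin_by_size(alignments, cfg.bins)
    results: dict = {}

    def write(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        with open(path, "w") as fh:
            fh.write(_provenance(cfg))
            df.to_csv(fh, sep="\t", index=False, float_format="%.6g")

    if toggles.get("size_profile"):
        rows = []
        for genome in bundle.references:
            prof = size_profile(alignments, genome, cfg.bins)
            if not prof.empty:
                df = prof.to_frame()
                df.insert(0, "genome", genome)
                rows.append(df)
                results[f"size_profile_{genome}"] = prof
        if rows:
            write(pd.concat(rows, ignore_index=True), "size_profile.tsv")

    if toggles.get("per_bin_methylation"):
        pbm = per_bin_methylation(binned, bundle)
        results["per_bin_methylation"] = pbm
        write(
            pd.DataFrame(
                [(b, v[0], v[1], v[2]) for b, v in pbm.items()],
                columns=["bin", "cpg_pct", "chh_pct", "cpg_depth"],
            ),
            "per_bin_methylation.tsv",
        )

    if toggles.get("gquad"):
        gq = gquad_bin_stats(binned, bundle, cfg.bins)
        results["gquad"] = gq
        write(
            pd.DataFrame(
                [(b, v[0], v[1]) for b, v in gq.items()],
                columns=["bin", "gquad_pct", "normalized_ratio"],
            ),
            "gquad_profile.tsv",
        )

    if toggles.get("cpg_density"):
        dens = cpg_density_profile(binned, bundle)
        results["cpg_density"] = dens
        write(
            pd.DataFrame(list(dens.items()), columns=["bin", "cpg_density"]),
            "cpg_density.tsv",
        )

    nuc_len = bundle.length("nuclear")
    classes = {
        "uscfDNA": [a for a in alignments if a.genome == "nuclear" and cfg.bins.is_uscfdna(a.length)],
        "mncfDNA": [a for a in alignments if a.genome == "nuclear" and cfg.bins.is_mncfdna(a.length)],
    }
    if toggles.get("element_composition"):
        rows = []
        for cls_name, alns in classes.items():
            cpg_alns = [
                a for a in alns if "CG" in bundle.references[a.genome][a.start : a.end]
            ]
            frag_set = IntervalSet.from_fragments("nuclear", cpg_alns)
            ann = {
                t: IntervalSet.from_intervals("nuclear", bundle.annotations[t])
                for t in (
                    "promoter", "cpg_island", "cpg_shore", "cpg_shelf", "exon",
                    "first_exon", "intron", "five_utr", "three_utr", "tts",
                    "intergenic", "sine", "line", "simple_repeat",
                )
            }
            comp = element_composition(frag_set, ann)
            rows += [(cls_name, el, pct) for el, pct in comp.items()]
            results[f"element_composition_{cls_name}"] = comp
        write(pd.DataFrame(rows, columns=["class", "element", "pct"]), "element_composition.tsv")

    if toggles.get("observed_ratio"):
        rows = []
        for cls_name, alns in classes.items():
            frag_set = IntervalSet.from_fragments("nuclear", alns)
            if len(frag_set) == 0:
                continue
            for mark in (
                "h3k4me1", "h3k4me3", "h3k27ac", "h3k27me3", "h3k9me3",
                "h3k36me3", "hypomethylated_region", "hypermethylated_region",
            ):
                res = observed_ratio(
                    frag_set,
                    IntervalSet.from_intervals("nuclear", bundle.annotations[mark]),
                    nuc_len,
                    mark_name=mark,
                    fragment_class=cls_name,
                    seed=stage_seed(cfg.seed, f"shuffle:{cls_name}:{mark}"),
                )
                rows.append(
                    (cls_name, mark, res.observed_fraction, res.null_mean_fraction,
                     res.null_sd, res.ratio)
                )
                results[f"observed_ratio_{cls_name}_{mark}"] = res
        write(
            pd.DataFrame(
                rows,
                columns=["class", "mark", "observed_fraction", "null_mean", "null_sd", "ratio"],
            ),
            "observed_ratio.tsv",
        )

    if toggles.get("tss_profile"):
        rows = []
        for cls_name, alns in classes.items():
            frag_set = IntervalSet.from_fragments("nuclear", alns)
            if len(frag_set) == 0:
                continue
            curve = tss_profile(
                frag_set,
                bundle.annotations["tss_points"],
                nuc_len,
                tss_expression=bundle.tss_expression,
            )
            curve.insert(0, "class", cls_name)
            rows.append(curve)
            results[f"tss_profile_{cls_name}"] = curve
        if rows:
            write(pd.concat(rows, ignore_index=True), "tss_profile.tsv")

    if toggles.get("feature_trend"):
        table = call_sites(alignments, bundle)
        trend = feature_trend(table, bundle.annotations["exon"])
        results["feature_trend"] = trend
        write(trend, "feature_trend_exon.tsv")

    if toggles.get("dmr"):
        tables = [call_sites(classes[c], bundle) for c in ("uscfDNA", "mncfDNA")]
        if all(len(t.df) for t in tables):
            matrix = GroupMethylationMatrix.from_site_tables(
                tables, ["uscfDNA", "mncfDNA"], ["uscfDNA", "mncfDNA"]
            )
            dmrs = find_dmrs(
                matrix,
                permutations=200,
                seed=stage_seed(cfg.seed, "dmr"),
            )
            results["dmrs"] = dmrs
            write(dmrs_to_frame(dmrs), "dmrs.tsv")

    if toggles.get("deconvolution") and cfg.panel_path:
        from .deconv import ReferencePanel, em_deconvolve

        panel = ReferencePanel.from_tsv(cfg.panel_path)
        table = call_sites(classes["uscfDNA"], bundle)
        site_map = {
            (g, int(p)): (m, m + u)
            for g, p, m, u in zip(
                table.df["genome"], table.df["pos"], table.df["meth"], table.df["unmeth"]
            )
        }
        meth = np.zeros(panel.n_sites)
        total = np.zeros(panel.n_sites)
        for i, (c, p) in enumerate(zip(panel.site_chrom, panel.site_pos)):
            if (c, int(p)) in site_map:
                meth[i], total[i] = site_map[(c, int(p))]
        est = em_deconvolve(meth, total, panel, seed=stage_seed(cfg.seed, "deconv"))
        results["deconvolution"] = est
        with open(outdir / "proportions.json", "w") as fh:
            json.dump(
                {
                    "config_hash": cfg.hash(),
                    "seed": cfg.seed,
                    "proportions": est.proportions,
                    "iterations": est.iterations,
                    "converged": est.converged,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
    return results


def run_all(cfg: RunConfig, outdir: str | Path | None = None) -> dict:
    sim = run_simulate(cfg, outdir)
    proc = run_process(cfg, bundle=sim["bundle"], reads=sim["reads"], outdir=outdir)
    ana = run_analyze(cfg, sim["bundle"], proc["alignments"], outdir=outdir)
    return {"simulate": sim, "process": proc, "analyze": ana}
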