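# uscfmeth

Simulation and analysis of **ultrashort single-stranded cell-free DNA
(uscfDNA) methylation**.

Plasma cfDNA contains, besides the familiar ~167 bp mononucleosomal
fragments (mncfDNA), an ultrashort single-stranded population of ~50 nt
whose methylation profile is hard to measure: sodium bisulfite — the
standard reagent for methylation sequencing — fragments DNA, so degradation
products of longer molecules masquerade as ultrashort cfDNA. An
adapter-first workflow (here called **5mCAdpBS**) ligates pre-methylated
single-stranded adapters *before* conversion; any bisulfite-induced break
separates the two adapters, so only intact molecules amplify and the
ultrashort size fraction stays uncontaminated.

`uscfmeth` implements both the measurement pipeline and a synthetic-data
generator that emulates the underlying biology and chemistry, so every
analytic stage can be validated end-to-end without any external download:

* **Simulation** — synthetic nuclear / mitochondrial-like / lambda
  references with annotation tracks (promoters, CpG islands/shores/shelves,
  repeats, histone marks, TSSs with expression tiers); population-specific
  methylomes (~64% uscfDNA vs ~80% mncfDNA CpG methylation, unmethylated
  lambda spike-in); fragment sampling; three library protocols (BRcfDNA,
  BSSeq, 5mCAdpBS) with per-bond breakage and context-specific conversion;
  150×2 paired FASTQ with truth files.
* **Read processing** — adapter trimming, overlap merging of read pairs
  (innie and outie geometries), seed-and-extend three-letter bisulfite
  alignment with a strict-uniqueness rule, deduplication, 10-base size
  binning.
* **Methylation calling** — per-site CpG/CHG/CHH counts (dyad-merged CpG,
  bismark-coverage output), per-size-bin methylation percentages,
  per-fragment methylation categories, lambda conversion-efficiency QC.
* **Fragmentomics & genomic context** — size profiles, CpG density,
  G-quadruplex motif scanning (`([gG]{3,}\w{1,7}){3,}[gG]{3,}`),
  element composition, shuffle-null observed-ratio enrichment, TSS
  metaprofiles by expression tier, feature-body methylation trends.
* **Cohort inference** — permutation-tested DMR scanning with
  metilene-style thresholds (`mincpgs 3, maxdist 100, minMethDiff 0.1,
  valley 0.7`, BH q-values) and CelFiE-style EM tissue-of-origin
  deconvolution.

## The models in brief

**Bisulfite degradation.** Each internal phosphodiester bond breaks
independently with probability λ, so an *n*-base fragment survives with
probability (1−λ)^(n−1). Calibrating λ on a 10% loss at 62 bp gives
λ ≈ 1.73×10⁻³ and predicts a 20% loss at 131 bp — the two published
degradation figures are mutually consistent under this model, and the
package uses one as calibration anchor and the other as a held-out check.

**Methylation observation.** An unmethylated cytosine reads as T with
probability *c* (0.995 CpG, 0.99 non-CpG by default); a methylated cytosine
erroneously reads as T with probability ε (0.01). The expected called
methylation at truth level *p* is therefore `100·(p(1−ε) + (1−p)(1−c))`,
which the calling stage recovers and the tests assert at
p ∈ {0, 0.64, 0.80, 1}.

**EM deconvolution.** Reads at site *i* originate from tissue *t* with
probability α_t and are methylated with the tissue's reference probability
β_ti; the E-step computes posterior memberships separately for methylated
and unmethylated reads, the M-step re-estimates α (and optionally β from
pooled panel+sample counts). The log-likelihood is non-decreasing by
construction and the implementation asserts it.

## Worked example

```
$ cat example.yaml
seed: 7
protocol: 5mcadpbs
n_fragments: 5000
outdir: example_out
genome:
  nuclear_length: 200000

$ uscfmeth all --config example.yaml
pipeline complete: 3864/3893 fragments retained -> example_out
```

5000 sampled fragments yield 3893 library molecules (the 5mCAdpBS protocol
removed broken molecules and most of the HMW genomic contamination); 3864
merge and align (29 unmergeable pairs were longer than 2×150−11 bases).
`qc.json` reports the lambda spike-in conversion control:

```
lambda_cpg_efficiency      99.52      # needs >= 99
lambda_non_cpg_efficiency  98.85      # needs >= 98.5
```

`per_bin_methylation.tsv` shows the size-resolved methylation signal — the
ultrashort bins sit well below the mononucleosomal bins because uscfDNA is
globally less methylated and preferentially drawn from hypomethylated
islands and promoters:

```
bin      cpg_pct   chh_pct  cpg_depth
40-49    42.9      1.04     1851
50-59    43.5      1.16     2441
160-169  69.1      1.17     7492
170-179  68.6      1.23     5889
```

and `observed_ratio.tsv` the epigenetic-mark enrichment of each size class
against length-matched shuffled controls (1.0 = no enrichment):

```
class     mark                   ratio
uscfDNA   h3k4me3                2.69
uscfDNA   h3k27ac                2.46
uscfDNA   hypomethylated_region  2.33
mncfDNA   h3k4me3                0.96
```

The subcommands `simulate`, `process` and `analyze` run the stages
separately; `--seed`, `--outdir` and `--protocol` override the YAML config.
All YAML keys mirror the dataclasses in `uscfmeth.config` (sections
`genome`, `methylome`, `chemistry`, `mix`, `bins`, `analyses`), and every
stage derives its own seed deterministically from the root seed.

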