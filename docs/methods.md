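# Methods

This note documents the models behind `uscfmeth`, the defaults and why
they were chosen, what the synthetic data does and does not emulate, and
the numerical choices that affect results.

## Degradation model

Bisulfite treatment nicks DNA. We model breakage as an independent
Bernoulli event at each of the `n−1` internal bonds of an `n`-base
fragment, so

```
P(intact) = (1 − λ)^(n−1)
```

`calibrate_breakage(loss, length)` inverts this for λ. The default λ is
anchored on a 10% loss for 62 bp fragments (λ ≈ 1.726×10⁻³); the model
then predicts a 20.1% loss at 131 bp, matching the independently published
figure — that pair of numbers is the model's held-out check, and the
acceptance script re-derives both directions. Degradation is assumed
spatially uniform; end-preferential nicking is not modelled (nothing in
the available chemistry data distinguishes the two at these sizes, and the
uniform model already reproduces both printed loss figures).

## Protocols

* **BRcfDNA** (broad-range single-stranded prep): lossless, no conversion.
  The size-profile reference.
* **BSSeq**: conversion before ligation. Every sub-fragment of a broken
  molecule that exceeds the cleanup length (default 20 nt) re-enters the
  library. This is the mechanism that floods the 70–130 base range with
  breakage artefacts of long genomic DNA.
* **5mCAdpBS**: pre-methylated adapters ligated before conversion. A
  single break leaves each piece with at most one adapter, so only
  zero-break molecules amplify; the library is exactly the intact subset
  of the input, and the size distribution equals BRcfDNA's reweighted by
  per-molecule survival (1−λ)^(n−1). Adapter bases are 5mC-protected and
  never convert.

## Conversion chemistry

Unmethylated C → T with efficiency `c_cpg = 0.995` / `c_non_cpg = 0.99`
(chosen so the simulated lambda control reproduces the accepted QC bands:
called CpG methylation < 1%, non-CpG < 1.5%). Methylated C → T with
over-conversion ε = 0.01; published protocols rarely state ε, so it is a
configurable free parameter. The expected called methylation at truth
level p is `100·(p(1−ε) + (1−p)(1−c))`; parameter recovery against this
closed form is asserted at p ∈ {0, 0.64, 0.80, 1}.

## Synthetic genome and methylome

The nuclear reference (default 1 Mb) is tiled with 10 kb gene units:
promoter (1 kb), 5′UTR, first exon, introns/exons, 3′UTR, TTS, remainder
intergenic, alternating strands. CpG islands (CG-enriched sequence with
planted dyads every 8 bp) sit over the TSS with 2 kb shores and shelves.
Histone-mark tracks follow the gene's expression tier (uniformly drawn
from high/medium/low/silent): H3K4me3/H3K27ac at active promoters,
H3K36me3 on active bodies, H3K27me3/H3K9me3/hypermethylated regions on
silent units, H3K4me1 enhancers in intergenic space. 60% of promoters
carry a planted telomere-type G-quadruplex motif (`GGGTTAGGGTTAGGGTTAGGG`).
A 16 kb mitochondrial-like circle and a 48 kb lambda-like spike-in complete
the bundle. All construction is deterministic in the seed.

Methylome defaults: uscfDNA 0.64, mncfDNA and HMW gDNA 0.80 per-site CpG
methylation probability (the levels reported for these populations in
plasma); CpG islands 0.10; annotated hypo-/hyper-methylated regions
0.05/0.95; mitochondrial sites 0.02 (mitochondrial DNA is expected to be
hypomethylated); lambda identically 0. Non-CpG methylation is a flat
0.002, consistent with the ~1% *called* non-CpG level that the conversion
chemistry alone produces in somatic tissue.

Fragment sizes: uscfDNA discretised normal, mode 50 sd 6 on [30, 80];
mncfDNA mode 167 sd 10 on [120, 250]; HMW gDNA uniform [500, 2000]; lambda
uniform [25, 100]. The ultrashort population is biased toward
promoter/island/G-quad source loci by rejection sampling with a default
density ratio of 4 (the real enrichment is qualitative, so this is a free
parameter chosen to give clearly detectable but not caricatured
enrichment).

**What the generator does not emulate:** real human sequence composition
and repeat structure, nucleosome-positioning fragmentation phasing, PCR
duplicates beyond exact-coordinate duplication, UMI errors, and
batch/sample-level variability. Passing tests therefore demonstrate the
correctness and calibration of the measurement machinery under the stated
generative model, not performance on real plasma libraries.

## Read processing

Reads are 150×2 with read-through into the sequencing adapter for short
inserts and a 0.001 iid substitution error rate at constant Phred 37
(typical modern-instrument figures; the publications this emulates do not
state them). Trimming removes 3′ adapter occurrences with ≥ 8 matching
bases and ≤ 10% mismatches. Merging scans innie overlaps (R1 suffix vs
revcomp(R2) prefix) from longest to shortest, accepting the first with
mismatch rate ≤ 0.1 at ≥ 11 bases; consensus takes the higher-quality
base. Inserts of length 143–149 leave adapter stubs shorter than the
8-base trim threshold, so the merger also scans the "outie" geometry (R1
prefix vs revcomp(R2) suffix) and discards the stubs — without this, a
few percent of mononucleosomal molecules would be silently lost just
below the read length. Unmergeable pairs (insert > 2·150−11) are dropped
and counted, mirroring a merged-only pipeline.

Alignment is seed-and-extend on collapsed-alphabet k-mer tables (C→T for
top-strand placements, G→A for bottom-strand, k = 20), end-to-end with no
clipping; bisulfite-compatible substitutions are free, other mismatches
capped at 3. A read is kept only when its best placement is strictly
better than the second best. Deduplication keeps the first fragment per
(genome, start, end, strand).

## Methylation calling

Top-strand C and bottom-strand G evidence accumulate per reference site;
CpG dyads are reported unstranded at the top-strand C coordinate (CGmap
convention), CHG/CHH keep strand. Per-bin percentages pool counts, so a
bin percentage equals the depth-weighted mean of per-site percentages;
empty bins are reported as missing, never 0%. Fragment methylation
categories close on the right: 0%, (0,25], (25,75], (75,100]; fragments
with no observed CpG carry no category. No M-bias end-trimming is applied
(offsets are configurable, default 0). Conversion QC warns when lambda
CpG efficiency < 99% or non-CpG < 98.5%.

## G-quadruplex scanning

The motif is the classic pattern of ≥ 4 runs of ≥ 3 G separated by 1–7
base loops. The scanner is a hand-written backtracking matcher that
mirrors leftmost/greedy regex semantics exactly (greedy quantifiers,
extension preferred over repeat termination, failure memoisation for
G-rich inputs); it is verified against a generic regex engine on random
sequences, which keeps implementation and oracle independent. Matches are
non-overlapping; scanning is on the fragment's own strand only, using the
reference sequence under the aligned fragment — conversion never touches
primary-strand G-runs, so converted and unconverted libraries score
identically. The per-bin "normalized ratio" divides the count of
motif-containing fragments by the bin's midpoint length (20–29 → 25), as
conventionally printed, and is exposed alongside the plain percentage
because its dimensional interpretation is ambiguous.

## Interval statistics

Intersections use a sorted sweep equal to the pairwise
`max(0, min(ends)−max(starts))` sum (verified against brute force and
bedtools). Shuffled controls preserve the exact multiset of fragment
lengths with uniform placement over the whole reference; no exclusion
regions are applied. The observed ratio divides the observed
intersecting-base fraction by the mean over 10 shuffle replicates
(single-replicate mode remains available for fidelity with designs that
used one control per sample); the null SD is reported so callers can judge
significance. TSS metaprofiles count full fragment coverage in 20 bp bins
over ±1 kb, oriented by gene strand; "relative" normalisation divides by
the curve mean and preserves shape. Feature trends average per-site
methylation in 100 bp flank windows (±5 kb) and 20 length-normalised body
windows, requiring ≥ 1 observation per window. Closest-feature distances
are 0 on overlap, signed by side, ties to the leftmost feature (bedtools
convention). The 100 kb-bin coverage correlation is Pearson r on per-bin
percent of total coverage.

## DMR scanning

Candidate regions are maximal CpG runs with inter-site gaps ≤ 100 bp,
trimmed to sub-runs in which ≥ 70% of sites share the dominant difference
sign (recursively splitting at the strongest opposite-sign site — our
reading of a "valley 0.7" filter), then filtered to ≥ 3 CpGs and
|mean difference| ≥ 0.1. The exact binary-segmentation/2D-KS machinery of
metilene is deliberately not reproduced; the permutation test below is
the package's own significance machinery at the same thresholds.

Significance: group labels are permuted; for each permutation the same
segmentation is re-run on the permuted differences and the max
|mean difference| over discovered segments is recorded. Both observed and
null statistics are thereby conditioned on segment discovery — without
this the selection step biases the tail probability (conditioning only
the observed side makes p-values anti-conservative; we verified the
conditional p-values are uniform under the null by KS test). BH q-values
follow; the conventional significance cut is q < 0.01. Note the p-value
floor of a permutation test: with 5v5 samples only 252 distinct label
splits exist, so q < 0.01 is barely reachable; the sensitivity study in
the test suite uses 8v8 samples, where the floor is far below the
threshold.

## EM deconvolution

Model: a read at site i comes from tissue t with probability α_t and is
methylated with probability β_ti. E-step: posterior memberships computed
separately for methylated (∝ α_t β_ti) and unmethylated (∝ α_t(1−β_ti))
reads. M-step: α from summed posterior weights; optionally β from pooled
panel+sample counts (the full joint model), in which case the reported
log-likelihood includes the panel binomial terms so monotonicity holds for
the quantity actually optimised. β is fixed by default: at desk-scale
site counts, joint re-estimation costs identifiability for little gain.
Optional extra "unknown" components with free β (off by default) absorb
signal absent from the panel. β is clipped to [10⁻¹⁰, 1−10⁻¹⁰];
convergence when the log-likelihood gain < 10⁻⁶; a monotonicity assertion
guards the implementation. Panels with (near-)identical tissue profiles
trigger a non-identifiability warning. Panel site selection is taken as
given — the panel defines the informative sites.

## Problem sizes and determinism

Default scales — 1 Mb nuclear reference, 20k-fragment cohorts, 100k
Monte-Carlo draws for the degradation check, 10 shuffle replicates,
199–999 permutations — were chosen so each quantity's sampling error is
comfortably inside the tolerance it is compared at (e.g. the binomial SE
of the 131 bp loss at 100k draws is 0.13 percentage points against a ±1
band). The test suite uses a 100 kb bundle and proportionally smaller
cohorts; every statistic under test is scale-free. All randomness flows
from a root seed through per-stage CRC-derived seeds, so re-running one
stage never perturbs another and identical seeds give byte-identical
outputs.

## Known limitations

* The aligner is exact-match seeded and ungapped; indel-bearing reads are
  lost (none are simulated).
* Size-bin labels follow the half-open convention "x–y" = [x, y+1);
  length 200 falls in the overflow class.
* The mncfDNA class window is configurable because both 120–250 and
  120–200 appear in common use; the default is 120–250.
* Fragment-level methylation categories are computed from observed
  per-fragment CpG states directly rather than from alignment-flag
  bookkeeping; the information content is the same but file-format
  round-trips are not needed.
* With wide fragment-size distributions the sample mode is a noisy
  statistic; modal-length checks in the tests use dedicated cohorts of
  several thousand fragments.
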