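# Methods

## Relative copy number from qPCR

The estimand is mtDNA copies per diploid nuclear genome.  Under ideal
amplification every cycle doubles the template, so for a nuclear /
mitochondrial gene pair the threshold-cycle difference ΔCt = Ct_nuc −
Ct_mito satisfies N = 2^ΔCt, where N is the mitochondrial-to-nuclear
template ratio.  The paired method forms ΔCt1 from (BECN1, ND1) and ΔCt2
from (NEB, ND6) and averages the two N values arithmetically.  The
geometric-mean method instead references both mitochondrial genes to the
geometric mean of the two nuclear signals; since Ct is a log2 scale, that
geometric mean is the arithmetic mean of the nuclear Cts.  The two methods
coincide exactly whenever the nuclear mean Cts are equal (an identity the
test suite asserts over random plates).

Choices the assay description leaves open, and what this package does:

- **Replicates are averaged in Ct space** (mean of triplicate Cts per
  gene) before ΔCt is formed, matching standard ΔΔCt practice.
- **Amplification efficiency is fixed at 2.0 in the estimator.**  An
  efficiency parameter exists only in the simulator, for robustness
  experiments; estimating efficiency per plate is out of scope.
- **Undetermined wells** (no amplification in 40 cycles) are excluded from
  the replicate mean rather than imputed at the cycle cap — imputation
  would bias ΔCt — and flagged `HAS_UNDETERMINED`.
- **QC thresholds** are conventions, all configurable: replicate SD > 0.5
  cycles flags `HIGH_CT_SD`; an NTC well amplifying at Ct ≤ 35 fails the
  plate gene; a reference sample (e.g. NA12878, included on every plate)
  deviating > 20% from its across-plate mean flags the plate.  The
  reference is reporting-only: sample values are never renormalized to it.
- Inter-day CV pools one value per day; intra-day CV pools repeated runs
  within a day; an axis with fewer than two observations reports "NA"
  rather than a fabricated zero.

## Relative copy number from low-pass WGS

A diploid cell has two copies of each autosome, so

    mtDNAcn = (mito mean depth / autosomal mean depth) × 2.

Mean depth per contig is aligned reference bases divided by contig length,
accumulated in one streaming pass over the SAM/BAM.  "Aligned reference
bases" counts CIGAR M/=/X only — deletions, skips and clips do not
represent sequenced bases over a site.  The streaming pass is verified
against an independent brute-force oracle that builds per-position depth
arrays and averages them; the two must agree exactly, field by field.

- **Autosomal mean is length-weighted** over autosomes only (total
  autosomal aligned bases / total autosomal length).  Sex chromosomes are
  excluded to remove sex-dependent bias; unplaced contigs are excluded as
  unreliable.  Contig classes are recognized from common human reference
  dialects (chr1–22/1–22, chrM/MT/M/NC_012920.1, X/Y) with a per-contig
  override table for anything else.
- **Default read filters**: drop duplicates (they inflate depth most at
  0.5–1X), secondary and supplementary records (double counting),
  unmapped reads, and MAPQ 0 (multi-mappers, including reads torn between
  the mitochondrial genome and nuclear NUMT copies).  All filters are
  configurable down to a no-filter mode.
- **NUMT caveat**: no mitochondrial-region blacklisting is applied; NUMT
  cross-mapping slightly inflates autosomal-origin mito coverage on real
  data.  The simulator can plant a mito-identical autosomal segment to
  study this; it is off by default.
- The mitochondrial contig length is always taken from the alignment
  header, never hard-coded.

## Concordance

Method agreement is the Pearson product-moment correlation on the raw
mtDNAcn scale (the natural scale for reporting; a log-scale option exists
for heavy-tailed cohorts).  Degenerate inputs (n < 3, zero variance) raise
errors rather than returning NaN.  Cohort summaries use sample SD (n−1).
Bland–Altman / Deming-style bias analysis is deliberately out of scope.

## Haplogroup regions

A k-mer set classifier: each labeled mitochondrial consensus contributes
its distinct k-mers (k = 12 by default; the genome is circular, so k-mers
wrap the origin).  A query is scored per haplogroup by

    score(h) = |kmers(query) ∩ kmers(h)| / |kmers(h)|,

an asymmetric fraction robust to extra query content such as read sets.
m substitutions destroy at most m·k matching k-mers, so small private
variant loads barely move the score.  k = 12 makes 4^k ≫ genome length,
keeping chance collisions rare — but not zero: two unrelated 16.5 kb
sequences share ~L²/4^k ≈ 16 k-mers by chance (score ≈ 0.001).  A call is
therefore accepted only when the top score clears a floor (default 0.05,
orders of magnitude above chance and far below genuine matches); below it
the sample is "unclassified".  Ties break lexicographically with a `TIED`
flag.  Regions come from a longest-prefix lookup in an editable TSV
(A/B/C/D/X → Americas, L → Africa, ...).

This module is a simplified stand-in for PhyloTree-library k-mer
classifiers (Phy-mer and kin): it ships no real phylogenetic panel, no
k-mer weighting, no haplogroup nesting, and no heteroplasmy awareness.
The packaged default panel is synthetic — planted-variant sequences
derived from one random ancestor — which suffices to exercise and test
the scoring machinery; building a real panel from labeled consensus FASTA
is the supported user path.

## Simulator

The simulator emulates the validation-study conditions so every estimator
runs end-to-end offline.

- **Cohort truth**: per-sample true mtDNAcn ~ lognormal with moments
  matched to the group mean ± SD.  Defaults are the study groups this
  package models: infants 229.2 ± 66.4, mothers 136.7 ± 41.8 relative
  copies.  Lognormal guarantees positivity without truncation.
- **Ct plates**: nuclear baseline Ct 25.0 cycles (a plausible value for
  2 ng input on this panel); mitochondrial Cts sit log_eff(R) cycles
  earlier; i.i.d. Gaussian noise of SD 0.15 cycles per well (a typical
  within-triplicate scatter; the source studies report their CVs only in
  supplementary material, so this default is an explicit assumption);
  triplicates; one undetermined NTC well per gene.  Doubling the input
  mass shifts every Ct one cycle earlier, so ratio estimators are
  mass-invariant.  With zero noise and efficiency 2 the paired estimator
  recovers R to machine precision.
- **Alignments**: toy genome of two 200 kb autosomes plus a 16,569 bp
  mitochondrial contig; 100 bp error-free reads, CIGAR `100M`, MAPQ 60,
  primary; per-contig read counts Poisson with mean length·depth/read
  length, mitochondrial depth (R/2)·autosomal depth.  Two 200 kb autosomes
  at 1X give ~4,000 autosomal reads (depth CV ≈ 1.6%) and ~16,600
  mitochondrial reads (CV ≈ 0.8%) — enough Poisson statistics that the
  coverage estimator's error is a few percent, mirroring the precision
  regime of real 0.5–1X data, while keeping simulation fast.  An analytic
  `expected_depth_profile` provides the noiseless limit for identity
  checks.
- **Not modeled**: sequencing error, quality scores, GC bias, insert-size
  structure, duplicates, alignment ambiguity.  Passing tests therefore
  demonstrate estimator correctness given faithful alignments and
  well-behaved chemistry — not robustness to mapping artifacts or
  extraction effects on real specimens.

## Reproduction script sizes

`scripts/acceptance.py` uses 20 samples for the noiseless three-way
identity, 36 (18+18) and 40 (21+19) samples for the two noisy concordance
surrogates, and 164 samples per group for the cohort-mean checks — the
cohort sizes of the study designs the simulator emulates.  Every random
draw descends from the single `--seed` argument.

## Known limitations

- The ΔCt estimators assume efficiency exactly 2; real assays run at
  1.85–2.0, which biases absolute values (not concordance).
- No absolute quantification: results are relative copy numbers; standard
  curves are out of scope.
- The haplogroup caller's packaged panel is synthetic; calls on real data
  require a user-built panel and remain approximate relative to
  phylogenetically-aware tools.
- No mtDNA variant calling or heteroplasmy estimation.
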