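# Methods

## Scope and data model

The package analyses deep targeted-panel sequencing of serial ascites
cfDNA (with spheroid-cell and FFPE specimens as comparators): per-sample
variant tables (1-based inclusive coordinates), CNVKit-dialect per-bin
log2 copy ratios and segment tables (0-based half-open), a cohort
manifest mapping participants to timepointed samples, and BED gene
intervals. Coordinate conversion is centralised in `formats` and the two
conventions never mix elsewhere.

## Somatic triage without a germline reference

A variant is *likely somatic* when strictly below 0.05% in gnomAD
exomes, 0.5% in gnomAD genomes and 2% in 1000 Genomes, for every
database with an annotation present. Missing annotations count as rare —
absence from population databases is itself somatic evidence — and the
reason string records it for audit. A minor-allele-count rule (< 100) is
applied only when counts are available; the frequency thresholds are the
operative rule because they are what annotation columns carry. All
boundary comparisons in the package are strict exactly as printed
(`<`, `>`), and tests pin the boundary cases.

A variant is *verifiable* when reported in more than one of a
participant's samples, or — if unique — when VAF > 0.05 and depth > 150.
TMB is verified-somatic variants per callable megabase (default 1.94 Mb,
a typical large-panel small-variant footprint), reported to one decimal.

Per-sample total variant counts are screened for cohort outliers (an
FFPE-artifact tell): the single most outlying sample (max |count −
median|, ties toward the larger count) is excluded, the remainder give a
mean and SD, and every sample with |Z| > 3 against them is flagged. The
exclusion stops a grossly artefactual sample from masking itself.

## Tumour purity

Under the TP53 double-hit model the mutant VAF *v* gives
t = 2v/(1 + v); the anchor is the maximum-VAF deleterious TP53 variant
(the clonal hit under the gatekeeper assumption — the choice when a
sample carries two deleterious TP53 calls is otherwise arbitrary).
Fallbacks, in order: proportional scaling of another clonal variant's
VAF against a reference sample of known purity (for samples whose TP53
mutation sits on a deleted segment), then an externally supplied
estimate. The method used is recorded per sample.

## Copy number, repair, LGA

Copy number inverts the tumour/normal mixture of the log2 ratio,
`cn = max(0, (2·2^log2r − 2(1−t))/t)`; integer copy number is half-up
rounded, which makes LGA calls robust to sub-half-copy log2 noise.
Segment reliability uses the Iglewicz–Hoaglin modified Z on segment mean
depth, one-sided high at 3.5; when the MAD degenerates to zero the
recommended mean-absolute-deviation fallback (scale 1.253314) applies,
and when that is also zero nothing is flagged. Flagged segments take the
mean of their non-flagged flanking segments' copy-number estimate
(single flank at contig ends). Because the modified Z is scale-free, a
~40-segment profile occasionally yields a false flag at the 3.5 cut
(a few percent of samples); the repair then overwrites a healthy
segment and can shift the LGA count by one or two — an inherent cost of
the published rule that the replicate-stability tolerance (|ΔLGA| ≤ 2)
absorbs.

LGA counting walks, per chromosome, the ordered subsequence of segments
strictly longer than 10 Mb — non-qualifying interveners are skipped,
the reading consistent with "adjacent to other > 10 Mb segments" — and
counts each boundary between consecutive members with differing integer
copy number. An alternative per-segment counting unit (each altered
member once) is exposed via `per_segment=True`. Whole chromosomes are
the adjacency universe since panels carry no centromere annotation; an
arm-level BED can be supplied by splitting contigs upstream.

Gene amplification calls use the overlap-length-weighted mean segment
copy number over a gene interval; amplified means fold = cn/2 strictly
above 2. Profile divergence between two samples on one bin grid is the
percentage of bins whose containing-segment integer copy number differs
(bins, not breakpoint unions, are the comparison unit — the grid is the
panel's native resolution). Cohort profiles cluster hierarchically with
average linkage on correlation distance; constant profiles get distance
1 with a warning. The region-density comparison (e.g. 17p13.1 vs
17q21.31 reads/Mb in nanopore data, to confirm an arm loss) is a
classical paired t-test; zero-variance differences are reported as
undefined rather than p = 0.

## LOH

The statistic is the percentage of occupied, chromosome-limited 100-kb
bins whose mean eligible VAF is strictly outside [0.4, 0.6]. Eligible
("non-homozygous") variants have VAF in [0.05, 0.95] — a configurable
operationalisation that keeps allele-imbalanced LOH heterozygotes while
excluding fixed homozygotes. All detected variants feed the statistic
(germline SNPs carry the signal); the somatic filter is deliberately not
applied first. Bins anchor at position 0 of each contig and truncate at
contig ends; single-variant bins are admitted (`min_variants_per_bin`
configurable). Results are unreliable below 150× mean depth or median
VAF 0.1, with the failing guard named. LOH% > 16 additionally sets the
flag for the whole-genome HRD cut-off used in the PARPi literature —
on targeted panels this threshold is routinely exceeded and is reported
for context, not as a classifier.

## Clonal analysis

Input preparation completes the variant × sample grid per participant
(absent = 0 alternate reads at the sample's median depth), attaches the
local integer copy number from each sample's segments, and applies two
exclusion rules: variants on copy-number-0 segments in *any* matched
sample are dropped entirely (`cn0`), and when any sample of a
participant has purity below 0.30, variants with VAF ≥ 0.30 in that
sample are dropped (`low-purity-vaf`) since high-VAF calls at low purity
are likelier germline leakage. The exclusion log partitions the input.
When the purity anchor itself is cn0-excluded, an *unrepresented
high-frequency clone* warning is emitted instead of a cluster.

CCF = clip(v·(t·cn + 2(1−t)) / (t·m̂), 0, 1) with multiplicity
m̂ = clip(round(v·(t·cn + 2(1−t))/t), 1, cn). Clustering is a
transparent stand-in for full Bayesian clonal inference: a
k-means-initialised spherical Gaussian mixture per k = 1..8, best of 10
seeded restarts, k selected by BIC, stopping after two consecutive BIC
worsenings. Two numerical choices matter. First, the BIC uses the
mixture likelihood; a hard-assignment (k-means SSE) profile is monotone
in k on this data and always over-splits. Second, component variance is
floored at 2×10⁻³ (sd ≈ 0.045, the CCF sampling noise of 500–1000×
panels): clipping CCFs into [0, 1] piles truncal variants at exactly
1.0, and without the floor a component collapses onto that atom with
spuriously high likelihood. A PyClone-VI input exporter is provided for
users who want the original tool; panel data cannot phase alleles, so
the export sets major_cn = max(cn − 1, 1), minor_cn = cn − major_cn.

A clone prevalence shift is |ΔCCF| strictly greater than 0.10 between
consecutive samples — absolute CCF points, not relative change, the
reading consistent with how serial clone fractions are plotted.

## Consensus genomic-instability score

Cohort medians of LGA, LOH% and TMB are computed over each participant's
*initial* sample only; serial samples are scored against those fixed
medians rather than moving their own baseline (a switch allows
recomputation over all samples). A sample scores one point per marker
strictly above its median; ties score zero. Unreliable LOH is excluded
from the median and contributes zero to that sample's score, with a
flag. The absolute HRD annotations (LGA ≥ 20; LOH > 16% strict) are
independent of the cohort-relative score.

## The synthetic cohort generator

Every recovery claim is tested against cohorts with known truth, because
the measurements this pipeline targets come from patient sequencing that
cannot be redistributed. The generator's defaults emulate the study
design the pipeline is built for: serial cfDNA pairs (13–559 days
apart) for six participants, tumour purity drawn in 0.30–0.93, mean
depth 900× (lognormal per variant, sdlog 0.25), a truncal clone carrying
a deleterious TP53 variant inside a < 10 Mb hemizygous-deletion tract
(so its VAF is exactly t/(2 − t)) plus two subclones with L∞-separated
CCFs, copy-neutral LOH tracts (2,0) covering 40% of the genome,
6–16 planted LGA boundaries as alternating balanced (1,1)/(2,2) runs of
> 10 Mb segments, a focal 12-copy amplification, germline heterozygous
SNPs at 1 per 100-kb bin with a 0.05% rare fraction whose population AFs
pass the somatic filter, and beta-binomial read counts with
overdispersion ρ = 0.005 — the mid-range of values consistent with
duplicate-sequencing deltas at ~900× and with typical targeted-panel
overdispersion. The genome is a six-contig, 617 Mb panel model with TP53
and MYC near their hg19 coordinates; all segment boundaries snap to the
100-kb bin grid.

Deliberate simplifications, and what they mean for the tests:

* **Tract-coherent germline phasing.** Within one truth segment all SNP
  alternate alleles sit on the same haplotype (mode `tract`; `random`
  is available). Real panels phase randomly per SNP, which dilutes the
  mean-VAF LOH signal in densely occupied bins; passing LOH-recovery
  tests therefore bound the statistic's best case, and real-data LOH%
  is noisier at high per-bin variant density.
* **Balanced gains for LGA runs.** (2,2) keeps the LGA and LOH channels
  orthogonal, so planted fractions are recoverable exactly; real gains
  are often imbalanced and would add to measured LOH%.
* **Bin log2 = log2((t·CN + 2(1 − t))/2) + Gaussian noise** (sd 0.05
  default) — the exact inverse of the rescaling formula, making
  rescaling exactly invertible at zero noise. Segment tables derive
  from the truth layout (segmentation is consumed as input; a naive
  |Δlog2| < 0.3 merge segmenter exists as plumbing only). Segment mean
  depth is drawn directly (lognormal, sdlog 0.1) rather than averaged
  from bins: inter-segment depth spread in panels reflects shared
  capture bias, and per-bin averaging would CLT-shrink short segments'
  variance and provoke spurious modified-Z repairs.
* **FFPE artefacts** are emulated as excess low-VAF variants with
  population AF 0 (they pass triage and inflate the total count, which
  is what makes artefact-laden samples cohort outliers); no
  trinucleotide signature structure is simulated.
* **No read-level simulation** (FASTQ/BAM) and no allele-specific
  segmentation.

Truth and rendering consume independent child seeds, so technical
replicates re-render one truth. Replicate comparisons use binomial read
noise (ρ = 0): technical replicates re-sequence one library, whose
capture/library overdispersion is shared rather than redrawn. Outputs
are byte-identical for identical (config, seed).

At purity 0.9 the copy-neutral LOH VAF expectations (1 ± t)/2 reach the
0.05/0.95 eligibility boundary, so LOH% plateaus (and can dip 1–2
points) between t = 0.7 and 0.9; monotonicity in purity is therefore a
property of the informative range t ≲ 0.85, while the ±5-point recovery
tolerance holds throughout.

## Problem sizes

Tests and the acceptance script run the 617 Mb panel genome (~6,200
bins), 900× or criterion-stated depths, cohorts of 1–6 participants,
100-run rate estimates for clone-count recovery and shift detection,
and 1,000-case brute-force cross-checks for the LGA counter, the outlier
flagger and the consensus scorer — sizes chosen so the full suite
completes in a few minutes on one core while keeping every rate estimate
at the resolution its tolerance needs.
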