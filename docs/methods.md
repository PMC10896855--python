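# Methods

This note documents the models, defaults and numerical choices behind
`atacre`, and what the synthetic studies used for validation do and do
not establish about real data.

## Coordinates and interval algebra

All internal coordinates are 0-based half-open (BED convention);
1-based inclusive coordinates exist only at the parse/format boundary
(`parse_region_string` / `format_region`), where comma
thousands-separators are accepted because printed genome-browser spans
use them. Interval merging treats book-ended intervals
(`end == next start`) as mergeable, matching `bedtools merge`
defaults. Overlap queries require ≥ 1 shared base by default
(half-open abutment is not overlap). Nearest-gene assignment measures
from the region midpoint to the gene TSS, signed positive when the
midpoint lies downstream of the TSS in the gene's orientation;
equidistant ties go to the lexicographically smaller gene id so the
result is deterministic.

## Tn5 insertion correction

The transposase duplicates 9 bp at its insertion site, so the
conventional correction shifts plus-strand 5′ ends +4 and minus-strand
5′ ends −5. Both ends of a fragment are treated as independent 5′
ends (standard practice for fragment-level ATAC data), each yielding
one single-base insertion event; events shifted off a chromosome end
are dropped and counted. Binned coverage assigns each event to exactly
one `pos // bin_width` bin (default 300 nt), so track totals equal
event counts — the conservation law asserted in the tests. The 150-bp
recentered pseudo-reads (75 bp flank each side, clipped and flagged at
chromosome edges) are an export/visualization representation; counting
always uses the single-base events, which keeps totals unambiguous.

## Simplified peak caller

Per-bin counts are tested against a Poisson null with rate
λ = max(genome-wide mean, local mean over a 10-kb window) — a one-level
version of the local-λ idea used by standard callers. P-values are
BH-adjusted genome-wide; bins with q ≤ q_max (default 0.05) are merged
across gaps of at most one non-significant bin. The summit is the
center of the highest-count bin and the score is −log₁₀(q) there.
This caller is a defined, testable stand-in with the right qualitative
behaviour (calibrated nulls, single peaks over planted clusters); it
is not a reimplementation of any published caller, and bin-granular
boundaries (±300 bp) are its known resolution limit.

## Consensus regions and the enhancer-mark constraint

Candidate loci are the merged union of all samples' peaks. A locus
counts as supported in a group when ≥ `min_support` (default 2) of
that group's samples have an overlapping peak; the default
`each_group` mode requires support in every group, and an `any_group`
mode is provided because reproducibility-in-one-group is a plausible
alternative reading of "reproducible region". Loci must also overlap a
merged H3K4me1 region by ≥ 1 bp (overlap fraction recorded). The two
filters are pure intersections, so their order does not change the
result — asserted as a property test on synthetic data.

## Differential model

Counts are normalized by median-of-ratios size factors (computed over
regions positive in every sample, rescaled to geometric mean 1; total
count ratios as a warned fallback). Per region the two groups are
compared with a Wald statistic on
log₂((μ̂₁ + c)/(μ̂₀ + c)), pseudocount c = 0.5, with variance
(1/μ̂ + α)/(n ln²2) per group under the NB parameterization
Var = μ + αμ².

The dispersion α is the pooled within-group method-of-moments estimate
per region, **floored at the experiment-wide mean of those
estimates**. At 2-3 replicates per group a per-feature moment estimate
is too noisy to stand alone: with only the nominal 10⁻⁸ floor a normal
Wald test rejects ~11% of nulls at α = 0.05, and a t(df = n₁+n₂−2)
reference fixes the size but leaves the test unable to produce usable
FDR-level q-values at realistic effect sizes. Flooring at the mean
dispersion is the minimal cross-feature information sharing (a
common-dispersion moderation in the spirit of edgeR/DESeq2, without
their trend fitting); simulated null rejection rates are 0.03-0.05
across dispersions 0.01-0.3 and the test retains ~0.96 power for
3-fold effects at mean 100, dispersion 0.1, n = 3/group. The normal
reference is used with this moderation. One consequence: the method
assumes most features are unchanged (both for size factors and for the
dispersion floor), so designs where a majority of features shift in
one direction will be mis-normalized — as in any median-of-ratios
workflow.

Differential accessibility calls use **raw p < 0.05** (the analysis is
deliberately permissive because individual regulatory regions are
expected to contribute small effects); BH q-values are always
reported alongside. Expression calls use the stricter adjusted
p < 0.05 **and** |log₂FC| > 0.5, both strict inequalities.

## Annotation and integration

Feature classes are assigned by region midpoint with priority
promoter > exon > intron > intergenic. The promoter window is
−1000/+100 bp around the TSS, oriented by strand — a common default,
configurable because no single community definition exists. A region
straddling classes gets its midpoint's class, so every region has
exactly one class and class counts partition the region set.
Concordance requires the region's accessibility direction and its
nearest gene's expression call to match (`acc_up_expr_up`,
`acc_down_expr_down`); distinct-gene tallies deduplicate shared
nearest genes, which is why pair counts can exceed gene counts.

## Motif model

PWMs are probability matrices (JASPAR text input via Biopython) with a
pseudocount of 0.001 per cell folded in before log₂-odds against the
background nucleotide model (uniform by default). The hit threshold
for a tail probability p is computed exactly: position scores are
discretized to δ = 0.01 bits and convolved position-wise into the full
null score distribution; the cutoff is the smallest score whose tail
mass is ≤ p. Sequences are scanned on both strands; windows containing
non-ACGT characters are skipped. Enrichment compares the fraction of
target regions with ≥ 1 hit (200-bp windows on region midpoints)
against background regions via a one-sided binomial test with the
background fraction as null proportion (a continuity guard replaces a
zero background fraction), BH-corrected across motifs, with a
hypergeometric companion p-value. A GC-matched background sampler
(decile histogram matching) is provided; because any real study's
background construction is tool-specific, motif q-values from real
datasets are not expected to be numerically reproduced.

## Protein-microarray scoring

Raw spot intensity is F/B with the background median floored at 1
intensity unit. Local normalization divides each spot by the median of
its 8-connected neighbours (radius configurable; edge and corner spots
use the 5 or 3 existing neighbours). The noise model is the mean and
SD of all valid normalized intensities after discarding the brightest
5% — binders are rare bright outliers, and trimming keeps them from
inflating the noise SD; the model requires ≥ 30 spots and a positive
SD. Z-scores are per array; a protein is a hit only when all 4 of its
spots (2 replicate spots × 2 dye-swap arrays) exceed Z = 3.0
strictly. Labeled-primer control probes (ids prefixed `T7`) are
excluded from the noise model and never callable. The whole chain is
invariant to rescaling all intensities by a constant.

## Assay calculators

Reporter activity: per-well firefly/Renilla ratio, construct fold =
mean ratio / mean empty-vector ratio, SEM from the construct's
replicates only (empty-vector variability is not propagated, matching
the usual presentation). ChIP-qPCR: percent input
= 100·2^(Ct_input − log₂(1/dilution) − Ct_IP) with the input dilution
fraction a required parameter, fold enrichment = percent-input ratio
over the IgG control; amplification efficiency is fixed at 2.0 per
cycle (no standard-curve correction). Both are invariant to a global
Ct shift.

## Synthetic studies

The generator emulates the statistical structure of a two-condition
bulk multi-omic experiment at desk scale. Defaults: 2 chromosomes ×
2.5 Mb, 200 non-overlapping genes with 1-4 exons, 300 disjoint
accessible regions (widths ~N(600, 100²) clipped to [300, 900]), 10%
planted differential regions with a 3-fold group effect of random
sign, 3 samples per group, 2×10⁵ fragments per sample. Fragments mix
uniform background insertions (50%) with Gaussian clusters around
region centers (sd = width/4); lengths follow a nucleosome-free
(~80 bp) / mono-nucleosome (~200 bp) mixture, and the left fragment
end is placed so its corrected insertion lands on the drawn position.
Injured-group samples multiply a planted region's insertion weight by
effect^direction; because weights are renormalized within a sample,
the realized count ratio is slightly compressed relative to the
nominal effect (~5% at the defaults), a compositional property shared
with real libraries.

H3K4me1 marks cover exactly round(cover_frac × n_regions) accessible
regions (default 0.8), covering planted differential regions first —
injury-responsive CREs are modelled as marked enhancers — and padding
each covered region by up to 400 bp without touching an uncovered
neighbour, so coverage counts are exact. RNA counts are NB draws
(dispersion 0.05) around lognormal baseline means (median 500); half
of the planted differential regions pass a same-direction 2 log₂-unit
shift to their nearest gene. The 4-fold magnitude is chosen so that a
3-replicate design can detect every planted change at adjusted
p < 0.05 — with n = 3 even an oracle NB test cannot reliably detect
2-fold shifts at FDR level, and validated knockdown-scale responses
are typically this large. Concordance is planted only at regions whose
nearest gene has ≥ 2 kb of margin over the second-nearest TSS, so
bin-level jitter in called peak boundaries cannot flip the pairing.
Microarrays are dye-swap pairs with lognormal foreground/background
and one planted 10× binder among 500 proteins by default.

All generators are deterministic: streams are spawned from
(seed, stage-index) so adding samples or stages never reshuffles
earlier draws, and written studies are byte-identical under a fixed
seed.

**What passing these studies shows — and does not.** The synthetic
studies verify the pipeline's logic, calibration and conservation
laws under a model where the generator's assumptions (independent NB
counts, unimodal peaks, uniform background, no duplicates or
mitochondrial reads, no GC or mappability bias, no batch structure)
hold exactly. They do not establish performance under real-data
pathologies, and the genome-scale counts of any particular study
depend on its deposited raw data; desk-scale runs make no claim to
reproduce them.

## Problem sizes

Defaults keep a full end-to-end run at a few seconds on one CPU
(1.2 M fragments total, ~16,700 bins per chromosome, 2000-feature
null calibrations), with the complete test suite under a minute.
These sizes were chosen as the smallest at which the statistical
checks (calibration bands, sensitivity, exact pair recovery) are
stable across seeds.
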