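# Methods

## Problem setting

Cultivar identification from reduced-representation sequencing proceeds in
two reductions: from millions of called SNPs to a core panel of
high-information, genome-spanning markers, and from the core panel to the
smallest marker combination that still separates every pair of accessions.
This package implements both reductions, the surrounding filtering and
population-structure summaries, and the concordance statistics used to
validate a fingerprint on replicate material. It consumes a called VCF;
read QC, alignment and variant calling are upstream and out of scope.

## Genotype model

A genotype is an unordered diploid allele pair over {A, C, G, T}, or
missing; phase is never represented. Panels store calls as an
`int8 (samples × markers × 2)` array with sorted allele codes, which makes
the distance, cover and concordance operations simple vectorised
comparisons. Two encodings are provided: IUPAC single letters
(heterozygotes R/Y/M/K/S/W, missing "N"), which is injective over the 10
diploid genotypes plus missing, and a six-way display category (four
homozygote classes, heterozygote, missing) used for fingerprint grids.

Printed validation tables mix two cell dialects. A cell with two plain
bases ("A/G") is the unordered genotype. A cell containing exactly one
IUPAC ambiguity letter ("R/A", or order-transposed "G/R") records the
sample call (the ambiguity letter, expanded) against the reference-genome
base, which is stored on the marker. This content-based rule, rather than
a fixed field order, is needed because published tables are not consistent
about field order; the heterozygote dialect of plain cells is required for
the year-replicate stability table to reproduce its printed discordances.

## Hard filtering

A site passes iff mean depth ≥ 5×, MAF ≥ 0.05, call rate ≥ 0.70, site
quality ≥ 30, and none of the exclusion conditions QD < 2.0, MQ < 40.0,
FS > 60.0, SOR > 6.0, MQRankSum < −12.5, ReadPosRankSum < −8.0 holds. The
six annotation thresholds are applied as exclusions — the GATK hard-filter
convention — because retaining only sites with QD < 2.0 would contradict
standard practice. "Information integrity" is read as the site call rate.
MAF uses called alleles only. Sites lacking an annotation are kept by
default (rank-sum annotations are undefined without heterozygotes);
a `drop` policy is available. Sites lacking depth or quality values pass
those criteria vacuously. Removals are attributed to the first failing
criterion in the fixed order depth, MAF, completeness, qual, QD, MQ, FS,
SOR, MQRankSum, ReadPosRankSum, so report counts always conserve the
input count, and filtering is idempotent by construction.

## Marker informativeness

PIC follows Botstein: `1 − Σ pᵢ² − Σ_{i<j} 2 pᵢ² pⱼ²`. For a biallelic
marker the maximum is 0.375 at p = 0.5, and PIC is bounded above by the
expected heterozygosity `1 − Σ pᵢ²` (checked as a property test on random
frequency vectors). Published cultivar-fingerprint panels occasionally
print biallelic PIC values slightly above 0.375 (e.g. 0.38); such values
are not representable under the Botstein form with two alleles and most
likely reflect rounding or a variant formula, so this package documents
the bound rather than attempting to reproduce them.

## Distances and concordance

Distance is genotype-level identity-by-state: samples differ at a marker
when both calls are present and the unordered genotypes are unequal, so
A/A vs A/G counts as a difference — necessary for pairs of varieties that
are separable only by a hom/het contrast at a single locus. Missing calls
never count as differences; each pairwise count is accompanied by the
number of comparable (both-called) markers.

Replicate stability is modal-call concordance: per marker, the most
frequent genotype across replicates is the reference (ties broken to the
alphabetically smallest pair), and the statistic is the percentage of
non-missing calls equal to their marker's modal call, reported to two
decimals. On the shipped 15-marker × 10-replicate table this yields
146/150 = 97.33%, with the discordance list naming each non-modal call.
Pairwise panel concordance compares shared sample × marker calls under a
`strict` mode (genotype equality) or an `allele-overlap` mode in which a
heterozygote matches a constituent homozygote — useful when one platform
under-calls heterozygotes; strict is the default.

## Core panel and minimal discriminating set

Core-panel candidates need PIC ≥ 0.30 and call rate ≥ 0.90 (defaults).
"Uniform distribution over chromosomes" is an equal per-chromosome quota:
⌊target/n_chrom⌋ per chromosome, remainder going to the chromosomes whose
best candidate has the highest PIC (ties by label); within a chromosome,
candidates rank by PIC descending, position ascending. If the quota-filled
set leaves some pair under-distinguished, candidates are appended greedily
by marginal pair coverage; a pair identical across all candidates raises
an error naming the pair. Chromosome balance constrains only the core
panel, not the minimal set (real minimal sets need not touch every
chromosome).

"Distinguish" is formalised as: a marker subset S k-distinguishes a sample
pair when ≥ k markers of S have both calls present and unequal (k = 1
default). Minimisation is then k-multicover over the C(n,2) pairs, with
per-marker covered-pair bitmasks. The greedy solver adds the marker
covering the most pairs still below multiplicity k (ties: higher PIC, then
lower (chromosome, position), then marker order) and inherits the
ln(#pairs)+1 approximation guarantee. The exact solver is branch-and-bound:
greedy upper bound, ⌈remaining deficit / best single-marker cover⌉ lower
bound, branching on the unmet pair with fewest remaining covering markers;
among equal-size optima it returns the lexicographically smallest subset
by marker order. Instances over 25 markers are refused unless a small
`size_cap` bounds the depth; both solvers re-verify their output before
returning. All tie-breaks are deterministic, so results are reproducible
bit for bit.

## Population structure

PCA operates on alternate-allele dosages (0/1/2) with Patterson scaling:
centre by 2p̂, scale by √(2p̂(1−p̂)), with missing dosages imputed to the
marker mean (a `drop-marker` policy is available) and zero-variance
markers dropped; scores come from an SVD of the scaled matrix. Subgroup
assignment clusters the top 10 components (or all available) with k-means
(10 restarts, fixed seed) for each K in range and selects the K with the
highest mean silhouette width, ties to the smaller K. The replaced
upstream tools — model-based admixture estimation with cross-validation,
and maximum-likelihood trees — are deliberate methodological
substitutions: silhouette-over-K provides the subgroup-count diagnostic,
and the tree is Saitou–Nei neighbor joining (via scikit-bio, negative
branches clamped to zero) on genotype-difference proportions
d(s,t)/m(s,t). Clade statements about an unrooted NJ tree are evaluated
as bipartitions.

## Synthetic panels

The generator emulates the study design the analysis targets: 39
accessions in four subgroups (5/4/18/9 founders plus three F1 hybrids
appended to the first subgroup, mirroring a collection with three named
crosses), with the second subgroup a diverged congeneric outgroup at
elevated drift. Defaults: F = (0.1, 0.5, 0.1, 0.1); ancestral MAF uniform
on [0.05, 0.5]; 5,000 markers uniform over nine chromosomes (the desk-scale
stand-in for a genome-wide panel); missing rate 0.02; replicate-clone
per-call error 0.02, chosen to match the observed 4/150 discordant calls
in ten-year replicate data. Subpopulation frequencies are Balding–Nichols
Beta draws around the ancestral frequency; genotypes are Hardy–Weinberg
within subpopulation; hybrids draw one gamete from each parent's realised
genotype; clones copy a parent and flip each call to a random different
genotype with the error rate. Site annotations are drawn from normal
models clipped to the passing side of each filter threshold, so planted
failures (one property forced past its threshold, the genotype column
forced clean) are attributable to exactly one criterion.

The generator is a statistical emulation, not a sequencing simulator: no
linkage disequilibrium, no read-level errors, no allele-frequency
spectrum realism beyond the Balding–Nichols family. Passing structure
tests therefore demonstrate correct recovery of planted population
structure, not performance on any particular real collection.

`plant_minimal_set` builds panels with a known minimum: sample 1 is
homozygous-ref across the planted set S, samples 2..|S|+1 each differ from
sample 1 at exactly one S-marker, and every non-S marker duplicates the
dose pattern of some S-marker. Each critical pair is then covered only by
markers of one duplicate class, the classes are disjoint, and any
one-per-class selection covers all pairs — so the minimum is exactly |S|
regardless of how many extra (distinct-profile) samples are added.

## Problem sizes and numerical choices

The test and acceptance runs use desk-scale sizes chosen to exercise every
code path with comfortable statistical margins: 2,000 markers × 40 samples
(20 seeds) for structure recovery; ≤ 12-marker instances for
exhaustive-enumeration cross-checks of the exact solver; planted-set sizes
2–6 over 20–50 markers; a 20-site fixture for filter attribution. PIC
requires frequencies summing to 1 within 1e-9. The silhouette diagnostic
is undefined for a single cluster; all-identical score matrices short-cut
to one group and are flagged. VCF round-trips preserve chrom/pos/ref/alt
and genotypes exactly; site quality, mean depth and annotations travel in
QUAL and INFO (mean depth in a dedicated `DPM` INFO field).

## Known limitations

- Filtering is site-level only; no per-call GQ/AD genotype masking.
- Indels and multi-allelic sites are out of scope (multi-allelics are
  dropped by default, or split with a flag).
- The exact solver is exponential in the worst case and guarded; the
  greedy path is the default at scale.
- Subgroup-count selection by silhouette can occasionally prefer K ± 1 on
  stochastic panels even when clustering accuracy (ARI) is essentially
  perfect; the diagnostic curve is reported so users can inspect the
  decision.
- The one-locus "similar" verdict is a heuristic for flagging possibly
  identical varieties, not a statistical test.
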