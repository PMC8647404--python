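# Methods

This note documents the models, estimators, conventions and numerical
choices behind every popsweep module, in the order the pipeline runs them.

## Synthetic data: what is emulated, and what is not

The generator reproduces the *statistical* design of a three-population
resequencing comparison — an anadromous population (AP), a landlocked
population (LP) and a sea population (SP), ten diploid individuals each —
not its sequence content.

**Drift model.** Each variant site draws an ancestral allele frequency
p ~ Uniform(0.05, 0.95); each population k draws its frequency from the
Balding–Nichols distribution Beta(p(1−Fₖ)/Fₖ, (1−p)(1−Fₖ)/Fₖ), and
diploid genotypes are Binomial(2, p_pop) under Hardy–Weinberg
equilibrium. Balding–Nichols was chosen because it is the simplest drift
model with a closed-form calibration target — the expected pairwise Fst
between two populations with equal F is F itself — which turns the Fst
estimators into testable code. The default drift vector **F = (0.02,
0.25, 0.03)** encodes the observed topology of this study system: the two
marine-connected populations (AP, SP) are genetically close while the
landlocked population is strongly diverged, so PCA splits {AP, SP} from
LP and the NJ tree places LP on a long branch.

**Variant content.** SNP density defaults to 0.004/bp (about one variant
per 250 bp — the order of magnitude of ~3.2 M SNPs on an ~800 Mb genome)
and 37 % of variants are InDels (the reported SNP:InDel proportion).
SNP alternates carry a mild transition bias (P = 0.56), so simulated
Ti/Tv sits near the 1.2–1.3 range typical of fish resequencing panels.
InDel lengths are drawn from a truncated geometric distribution on
1–10 bp with parameter 0.5, making mononucleotide insertions/deletions
the most frequent class, as the observed length spectra show; the exact
real-data distribution is unknown, so only this qualitative feature is
matched. Missing genotypes are injected at 1 % to exercise missing-data
paths.

**Filter metrics.** QUAL/QD/MQ/FS are drawn uniformly from their passing
ranges, and a configurable 5 % of sites violate exactly one threshold,
giving the filter module both populations of records. These metrics are
*labels*, not products of a read-level error model.

**Gene models.** Each gene gets one transcript with 1–3 exons, 30 bp UTR
stubs on the terminal exons, introns of 80–300 bp, and a coding sequence
built as ATG + random non-stop codons + stop, written into the reference
(reverse-complemented for minus-strand genes). Every CDS is therefore a
valid ORF with correct GFF3 phases; both strands occur.

**Sweep injection.** Inside a sweep interval the target population's
alt-allele frequency is resampled from Beta(0.02·K, (1−0.02)·K), K = 50,
mapped onto the minor allele so the *major* allele approaches fixation
(mean minor frequency 0.02), and the population's genotypes at those
sites are regenerated. Other populations are untouched. The strength
parameters are free choices — real sweeps have no single canonical
magnitude — set so that a 100 kb sweep on a weakly drifted background
reliably clears the published thresholds (Fst > 0.25, π ratio > 2); the
sweep-recovery acceptance check measures exactly this.

**What passing tests do not show.** The generator has no linkage
disequilibrium, recombination, coalescent genealogy, sequencing error or
alignment artefacts. Calibration and recovery results therefore validate
the *estimators and calling logic*, not robustness to real-data
confounders such as background selection, batch effects or mapping bias.

**qPCR tables.** Ct = gene baseline + per-sample loading offset −
log2(fold change) + Gaussian technical noise, with three housekeeping
genes whose expectation is group-independent, five biological replicates
per group and technical triplicates. All randomness (including the
loading offset) scales with one noise parameter, so a zero-noise run is
exact arithmetic — the basis of the exact ΔΔCT recovery checks.

## Hard filtering

Rules are applied in a fixed order and each removed record reports the
first rule that fired: (1) SNP within 5 bp of an InDel position / InDel
within 10 bp of another InDel (distances between VCF POS coordinates —
the anchor-point convention is not standardized, so POS distance is used
and documented); (2) clusters: any run of more than `cluster_size` (2)
variants whose POS span is ≤ `cluster_window_bp` (5), matching the
"no more than 2 variants per 5 bp window" semantics of the GATK
cluster filter (span compared with ≤ window, the GATK convention);
(3) QUAL < 30; (4) QD < 2.0; (5) MQ < 40; (6) FS > 60.0. Proximity and
cluster relations are evaluated against the *full input* set, which makes
the filter idempotent on its own passing set (verified by a property
test). A record lacking a metric skips that metric's rule, logged.

Multi-allelic sites are split into biallelic records at read time (each
ALT versus REF; other ALT alleles count as reference, genotypes with any
missing allele stay missing). All downstream computation assumes split
records; a test verifies summaries are invariant to pre-splitting.

## Summaries

Transitions are A↔G and C↔T; everything else is a transversion. A
sample-site genotype is a heterozygous SNP call iff its alleles differ,
and a homozygous SNP call iff both alleles are the alternate (a
homozygous-reference call is not a SNP for that sample); population
tallies sum the per-sample calls. **Reported Ti/Tv and Het-ratio are
truncated — not rounded — to two decimals**: the published trios
(1.28/1.27/1.27 and 30.49/29.19/30.82 %) are consistent with truncation
but not with rounding (e.g. 1855653/1451416 = 1.27851 → printed 1.27),
so truncation is the implemented convention. Whether the original
per-population counts pool ten genomes or use a merged call set is not
derivable from the published tables; the summary functions accept either
a pooled set or a single-sample view.

## Annotation

Coordinates convert once at the boundary from 1-based VCF POS to 0-based
half-open intervals. Derived features per transcript: introns are gaps
between consecutive exons; splice donor = first 2 intronic bases after an
exon in transcription direction, acceptor = last 2 before the next exon;
splice region = intronic bases 3–8 from either boundary plus the 3 exonic
bases adjacent to a junction; gene flanks are 5 kb by strand (upstream /
downstream). Flank size and splice extents follow the conventions of the
classic annotation tool whose category vocabulary these tables use; both
are constructor arguments.

Region precedence per transcript: CDS > splice donor/acceptor > splice
region > intron; a base inside the gene span hitting no transcript
feature is INTRAGENIC (this includes UTR exon bases — UTR is deliberately
not a category); otherwise flanks, then INTERGENIC. Across transcripts
and genes the single highest-severity call is reported, because the
published tables count each variant once; the fixed severity order is
EXON_DELETED > FRAME_SHIFT > STOP_GAINED > STOP_LOST > START_LOST >
codon-change+indel classes > plain codon indel classes >
NON_SYNONYMOUS_CODING > splice classes > SYNONYMOUS classes > INTRON >
UPSTREAM > DOWNSTREAM > INTRAGENIC > INTERGENIC, with deterministic
gene-id/transcript-id tie-breaks. Where a variant is simultaneously
intragenic to one gene and in the flank of another, the severity order
decides (flank wins); this cross-gene case is the one place the two
orderings the category system suggests could disagree, and the severity
order is authoritative here.

CDS SNPs mutate the containing codon on the coding strand and translate
with the standard genetic code: same amino acid → SYNONYMOUS_CODING
(SYNONYMOUS_STOP if the codon was and remains a stop); new stop →
STOP_GAINED; lost stop → STOP_LOST; destroyed initial ATG → START_LOST;
otherwise NON_SYNONYMOUS_CODING.

CDS InDels are left-normalized against the reference first (shift left
while the base preceding the edit equals its last base). Net CDS length
change mod 3 ≠ 0 → FRAME_SHIFT. In-frame edits: codon-aligned →
CODON_INSERTION / CODON_DELETION, otherwise the codon-change variants. A
deletion covering an entire exon → EXON_DELETED. Stop-codon logic for
in-frame InDels is an interpretation (the category tables list
STOP_GAINED/STOP_LOST for InDels without defining it): a deletion
removing any base of the terminal stop codon → STOP_LOST; an in-frame
edit whose re-joined or inserted codons contain a premature stop →
STOP_GAINED. Frameshifts keep FRAME_SHIFT (higher severity regardless).

Correctness is established two ways: a per-base brute-force classifier
(independent straight-line code) must agree on every base of toy genomes,
and a hand-designed variant set exercises all 20 categories with known
answers, including both strands.

## Sweep scan

Only full-length windows are emitted (starts at 0, step, 2·step, …;
trailing partial windows are dropped — a partial window would need a
different π denominator). π uses the full window length as denominator,
so monomorphic bases contribute zero, matching the per-bp convention of
standard windowed scans. Sites with fewer than two called alleles in a
population are skipped.

Hudson's ratio-of-averages estimator is the default (robust to rare
variants, standard for windowed scans); Weir–Cockerham (1984) two-
population variance components is provided for comparison and agrees
with Hudson within 0.01 at n = 50/population in calibration tests.
Estimates are reported raw and may be negative. Windows where the Hudson
denominator is zero (no variation in either population) are undefined and
ineligible.

Selection calling: eligible ∧ Fst > 0.25 ∧ (π ratio > 2 ∨ π ratio < 0.5),
all thresholds strict, applied to raw (not rank-transformed) values as
printed. π-ratio orientation: numerator = first-named population of the
comparison ("AP vs LP" ⇒ π_AP/π_LP). A zero denominator with positive
numerator gives +∞ (eligible, counts as > 2); both zero is undefined
(ineligible). `min_sites_per_window` (default 10) guards against
noise-dominated windows; it is a package addition, config-exposed.
Overlapping or book-ended selected windows with the same low-diversity
population merge into maximal regions. Gene assignment is half-open
interval intersection with ≥ 1 bp overlap (bedtools semantics);
book-ended gene/region pairs do not overlap.

## Population structure

PCA: missing dosages are imputed to the variant mean; variants are
centered by 2p̂ and scaled by √(2p̂(1−p̂)) with p̂ estimated from
non-missing calls; monomorphic and zero-variance variants are dropped;
the kinship matrix X·Xᵀ/m is eigendecomposed; coordinates are
eigenvectors scaled by √eigenvalue. Eigenvector signs are fixed by
forcing the largest-magnitude loading of each component positive, so
outputs are solver-independent. The eigenvalue sum equals the kinship
trace (tested to 1e-9 relative).

Distances: allele sharing, d(i,j) = mean(|gᵢ−gⱼ|)/2 over sites called in
both samples — simple, standard for SNP dosage matrices, and invariant to
ref/alt relabeling; the tree method itself does not prescribe a distance.
A pair with no shared called sites is an error naming the pair.

Neighbor joining follows Saitou–Nei with the standard Q criterion. Ties
(within 1e-12) break to the smallest (i, j) index pair. Negative branch
estimates are clamped to zero with the deficit transferred to the sibling
edge (the common convention), logged. The final three nodes are joined as
an unrooted trifurcation with closed-form pendant lengths. On additive
matrices the output reproduces every pairwise distance exactly (tested on
random trees to 1e-9).

Bootstrap resamples variants (columns) with replacement — the standard
unit when the tree is built from SNPs; the resampling unit is otherwise
unspecified in this kind of analysis and is documented here as the
package's choice. Support for each internal bipartition of the full-data
tree is the percentage of replicates containing it (canonical side = the
smaller half, lexicographic tie-break), stored as internal node labels in
Newick output. The pipeline default is 100 replicates (the CLI default
for standalone tree building is 1000).

## Expression

Technical replicates are averaged per (sample, gene); the per-sample
reference is the arithmetic mean of the three housekeeping Cts —
identical to geometric-mean normalization of expression levels under the
method's own 100 % efficiency assumption (2^((a+b+c)/3) is the geometric
mean of 2^a, 2^b, 2^c); amplification efficiency is fixed at 2, with no
efficiency correction. ΔΔCT subtracts the calibrator-group mean ΔCt, so
the calibrator group's mean ΔΔCT is exactly zero and its geometric-mean
RQ is exactly 1. The calibrator defaults to the alphabetically first
group and is configurable — the original analysis does not name its
calibrator, and the choice only rescales all groups by a constant.

Group statistics: one-way ANOVA (F, p), pairwise Welch t-tests, and
compact letter displays at α = 0.05 via the insert-and-absorb algorithm.
Duncan's multiple-range test was deliberately replaced by Welch pairwise
comparisons: Duncan's test is nonstandard, inflates type-I error, and its
parameters are underdetermined here; the letters convey the same grouping
summary. Singleton groups are excluded from testing with a warning.

## Pipeline and reproducibility

One root seed drives everything; stage-specific generators derive from it
(simulation = seed, qPCR = seed + 1, bootstrap = seed + 2), so stages are
individually reproducible. Every artifact is SHA-256 hashed into
`manifest.json`, and rerunning an identical configuration reproduces
identical hashes (tested). A configuration must contain exactly one input
source (`simdata` or `inputs`). Stage failures abort with the stage name
and offending input.

## Problem sizes in tests and acceptance checks

Calibration and recovery checks use sizes at which their expectations are
sharp but cheap: Fst calibration at 20 000 sites × 2 × 50 samples × 20
seeds (the Hudson ratio's sampling error there is well inside the ±0.02
band); sweep recovery on 300 kb chromosomes with one 100 kb sweep × 20
seeds; PCA separation at 2 000 sites × 2 × 20 samples; NJ exactness on 50
random 4–10-taxon trees; ΔΔCT recovery over 50 seeds. The demo pipeline
uses two 400 kb chromosomes with two injected sweeps and 100 bootstrap
replicates and completes in seconds on one CPU.

## Known limitations

- No linkage, recombination or coalescent structure in the simulator;
  window statistics on real data are autocorrelated in ways these tests
  do not probe.
- InDel effect classification assumes edits stay within one transcript's
  CDS after normalization; deletions spanning a CDS/intron boundary are
  classified by the CDS bases they remove.
- The Weir–Cockerham estimator is implemented for two populations only
  (the pairwise design used here).
- Filter metrics are simulated labels; the filter's behaviour on real
  GATK annotations is structurally identical but not empirically
  validated here.
- UTRs and HGVS notation are out of scope; the category system is the
  classic region/effect vocabulary only.
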