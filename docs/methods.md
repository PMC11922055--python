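# Methods

This note documents the models behind `stallkit`: what the synthetic
generators emulate, the estimators the analysis stages implement, the
defaults and why they were chosen, and what the package's passing tests do
and do not establish about real data.

## The synthetic reference and reduction chemistry

The tRNA reference holds isodecoder genes — random tRNA-length (74–79 nt)
DNA sequences with unique ids of the form `Leu-UAA-2` (amino acid, anticodon
displayed RNA-style, copy index). Substrate genes carry the 5'-CCG-3'
consensus centred on the annotated C12 (0-based index 11) and the anticodon
in the anticodon-loop region; decoys are unconstrained and carry no
modification annotation. The default complement is 26 Ser/Leu substrates
over 9 anticodons (Leu AAG×3, CAA×3, CAG×2, UAA×3, UAG×2; Ser AGA×3, CGA×3,
GCU×3, UGA×4), chosen so that every isodecoder named in the knockout
depletion profile exists. Sequences are DNA (T, not U) throughout files for
FASTA/FASTQ compatibility.

Chemical-probing reads model the borohydride-reduction chemistry as a
three-way branch per molecule of a substrate gene under the `reduced`
treatment: with probability `s` (stoichiometry, default 0.9) the molecule is
acetylated, and an acetylated molecule either terminates reverse
transcription — the read's 5'-most covered position is `c12_index + 1`, an
unambiguous pileup convention for "stops adjacent to C12" — with probability
`p_stop`, carries T at C12 with probability `p_mis`, or reads through as C.
Under `mock`, only background errors occur. A per-base background error
`epsilon` (default 0.002, substituting a uniformly random different base)
applies independently at every position of every read. Default chemistry
makes Leu substrates stop-prone (`p_mis = 0.35`, `p_stop = 0.35`) and Ser
substrates misincorporation-penetrant (`p_mis = 0.6`, `p_stop = 0.1`),
reproducing the qualitative Leu/Ser contrast in stop propensity versus
misincorporation penetrance; no per-site stoichiometries are published, so
these are package conventions and fully configurable. Reads can be emitted
with a 6-nt 5' UMI, 3-nt 3' UMI and a 21-nt 3' adapter so the preprocessing
stage is exercised end to end.

Under this model the expected net misincorporation rate at C12 is

    E[net] = s * p_mis / (1 - s * p_stop)

because truncated molecules never contribute to the C12 denominator. The
estimator-consistency test verifies convergence to this value within three
Monte-Carlo standard deviations at 50,000 reads.

## Site calling

Preprocessing removes a 3' adapter when a read suffix matches an adapter
prefix over at least 10 nt with at most one mismatch (longest overlap wins),
deduplicates on the full sequence *including* UMI bases keeping the first
occurrence, then strips the UMIs. Alignment is an exhaustive ungapped scan
of every read over all references and offsets, keeping all placements that
achieve the minimum mismatch count when that count is within 10% of the
read length (mirroring the 0.1 mismatch-fraction convention of short-read
aligners); multimapping reads receive fractional weight `1/multimap_count`,
summed in full precision. Pileups accumulate weighted base counts per
covered position plus an RT-stop count at `start − 1` for every alignment
beginning after the reference 5' end.

The misincorporation rate at a cytidine is `T/(C+T)`; A/G reads are tracked
in the pileup but excluded from the rate, matching a C→T-specific readout.
Mock subtraction is a difference floored at zero, not a ratio — the simplest
estimator of the reduction-dependent signal. A site passes when reduced
depth is strictly greater than `min_depth = 100` (the "> 100 reads"
convention) and the net rate is at least `min_net_rate = 0.02` (the 2%
stoichiometry floor). Coordinates are 0-based half-open internally and
1-based in TSV reports. Knockout sensitivity marks WT-passing sites whose
net rate collapses below 2% in the knockout comparison; positions present in
only one table are reported uncallable rather than raising.

## Isodecoder quantification and differential abundance

tRNA-seq-style reads are full length, sampled proportionally to per-gene
abundance, with modification-induced mismatches injected at annotated C12
positions (default rate 0.3 when the modification is present, 0 in the
knockout) plus a 0.001 per-base background. Quantification forgives
mismatches at tolerated sites (default: all annotated C12 positions) before
the mismatch-fraction test, and uses fractional multimapper weights —
isodecoders are near-identical in real data, and unique-only counting would
discard exactly the signal of interest. Proportions are normalized within
each replicate, so the analysis operates on composition, as isodecoder
profiling does.

The default knockout abundance profile divides Leu-UAA-2 by 4 and
Ser-AGA-3, Ser-UGA-4, Leu-AAG-3 and Leu-UAA-3 by 1.5. Because proportions
renormalize, the recoverable Leu-UAA-2 fold on the proportion scale is
`4 × (Σ_KO w / Σ_WT w) ≈ 3.7` rather than exactly 4; the ±15% recovery
tolerance covers this compression, and the tests assert it.

Differential abundance reports `log2fc` on mean proportions with a 1e-6
pseudocount and p values from a two-sided **pooled-variance** t test on log
proportions across replicates, BH-adjusted. The pooled (rather than Welch)
test is a deliberate choice: replicate libraries are sequenced to comparable
depth, so log-proportion variances are equal across conditions by design,
and at 2–3 replicates per condition the Satterthwaite approximation is
severely conservative (measured type-I error ≈ 0.02 at nominal 0.05 with
n = 2), whereas the pooled test is exact under normality and holds the
nominal size in the package's null-calibration test. This is a transparent
substitute for the full mixture-model quantification used by dedicated
isodecoder-profiling software, whose internals are out of scope here.

## Footprints and codon occupancy

The transcriptome generator emits random CDSs (ATG start, 150–300 sense
codons by default, single terminal stop) with configurable codon weights and
optional embedded codon runs for reporter-style constructs. Dwell models
assign every sense codon a strictly positive weight, normalized at
construction to mean 1 over the 61 codons so that recovered occupancies are
directly comparable to injected weights; the default knockout model doubles
the weight of the monosome stall codons (UUG, CUA, CUU, UUA) or the disome
collision codons (UCA, CUC, UUG, UUA).

Footprints sample a gene proportionally to expression, then an A-site codon
within the gene's interior proportionally to dwell weight, then a length
from the library distribution (monosome lengths 25–39 peaking at 28–31;
disome lengths 50–70 peaking at 58–62); the 5' end is placed using the same
offset table the analyzer uses, so simulator and analyzer share one
convention and dwell recovery is unbiased by construction. Offsets are
15 nt for monosome lengths 25–31 and 16 nt for 32–39; disome offsets add a
30-nt trailing-ribosome span (45/46 nt, defined for lengths ≥ 46), placing
the *leading* ribosome's A site — published offset rules for this design
are not stated, so these defaults are package conventions, configurable and
mirrored by the simulator. The size partition assigns length 40 to the
disome class (mono `[25,40)`, di `[40,80]`), resolving the overlap in the
printed selection ranges by a half-open convention.

Occupancy follows standard pause-score practice: genes qualify at a mean
interior density of 0.5 footprints/codon; the first and last 20 codons are
excluded to avoid initiation/termination artifacts; per-position densities
are normalized by the gene's interior mean; occupancy of a codon is the
equal-weighted mean over all interior occurrences across qualifying genes,
rescaled so the mean over observed codons is exactly 1. Meta-codon profiles
use the same gene normalization, averaging density at offsets −W..+W around
interior occurrences (default W = 30), which keeps the offset-0 value
consistent with the (unrescaled) occupancy within 2% in the consistency
test. TE is footprint density over RNA density per gene (replicates summed;
CDS length cancels in ΔTE); the TE-down/up thresholds are ±log2(1.5) after
a 32-count minimum in all libraries — thresholds the source analyses leave
unstated, adopted here as conventional effect-size cuts.

## Codon bias

"Average codon usage" is the unweighted per-gene mean of frequency vectors
(terminal stop excluded), preventing long genes from dominating; a pooled
mode is available. Family-relative representation is
`r(c) = f(c)/Σ_{c'∈family} f(c')` and skew is the difference
`r_set − r_background` — symmetric, bounded, and exactly zero-sum within
each family, which the property tests assert. The U/A-rich Leu class is
{UUA, UUG, CUA, CUU} and the C/G-rich class {CUC, CUG}; Ser codons are
classified analogously by the GC content of their variable positions
({UCA, UCU, AGU} vs {UCC, UCG, AGC}) — the Ser split is a package
convention, since only the Leu lists are established. Dipeptide frequencies
are adjacent amino-acid pairs of the translated CDS with a 1e-6 pseudocount
in the log2 enrichment.

## Assays and the cohort model

The qPCR model is ideal doubling: `Ct = base_ct − log2(template) + noise`,
with the oxidized reaction seeing only the charged fraction of each tRNA
target, the control seeing the full template, and the spike-in unaffected by
treatment. The charged fraction `2^(−ΔΔCt)` therefore inverts the generator
exactly at zero noise; replicate means are used per (target, treatment), and
values above 1 are reported with a warning rather than capped. Relative
expression uses the classic `2^(−ΔΔCt)` with an optional reference gene and
a calibrator sample mapping to 1. Sanger misincorporation is
`100·T/(C+T)` minus the water-control value, clamped at zero since
background can exceed signal by chance. Densitometry normalization is
`100·signal/loading` (the published formula is garbled; this is the adopted
reading, flagged as an interpretation). Mendelian goodness of fit is a
Pearson chi-square with df = categories − 1; the Gcn2-stratum comparison
collapses to a 2×2 (Thumpd1-null vs not) for a two-sided Fisher exact test,
with the full 3×3 table reported alongside.

The dihybrid-cross cohort model reweights the Mendelian prior
(1:2:1 ⊗ 1:2:1) by genotype viabilities `v(thumpd1, gcn2)` and renormalizes.
Default viabilities are solved in closed form from
`0.25·v/(0.75 + 0.25·v) = p`: `v = 13/29` for Thumpd1-null on a functional
Gcn2 background (expected 13% exactly) and `v = 11/13` on the Gcn2-null
background (22% exactly); all other genotypes have `v = 1`, so the
unit-viability model reduces exactly to 1:2:1 marginals per locus.

## Numerical choices and degenerate inputs

Every generator draws from a single seeded `numpy.random.Generator` per
call with no global state, and fixed (config, seed) pairs are
byte-reproducible. Pileup counts are kept as reals (fractional multimapper
weights are never rounded) and depth comparisons use real values. Rates at
zero-coverage denominators are defined as 0; division-by-zero cases in
ratios and TE are omitted with a log note rather than propagated as
infinities; an empty alignment set yields a zero-count table with a
warning; an all-zero abundance or viability vector, a zero-gene reference,
stop codons in coding positions and out-of-range probabilities raise
configuration errors.

## Problem sizes

The test suite and the acceptance script run the pipelines at desk scale:
1000 reads/gene for site calling (36 genes, two treatments), 2 replicates ×
200,000 reads per condition for quantification, 1–5×10^5 footprints per
library for occupancy (10-seed ranking checks at 10^5 per condition), 500
cohorts of 262 offspring, and 200 simulated null datasets for the
calibration check. These sizes were chosen as the smallest at which the
Monte-Carlo error is comfortably inside each stated tolerance.

## What the synthetic data does and does not establish

The generators reproduce the statistical structure the analyses rely on —
branch probabilities of the reduction chemistry, compositional abundance
shifts, dwell-proportional A-site sampling, ideal qPCR doubling, reweighted
Mendelian draws — so passing tests establish that the estimators are
correct, calibrated and consistent under their assumed models. They do not
model ligation or PCR amplification bias, position-dependent sequencing
error, RT stops in the tRNA-seq arm (full-length reads only), rRNA/ncRNA
contamination, genome alignment of real footprints, UTRs (transcripts are
bare CDSs), amplification-efficiency deviations from perfect doubling, or
litter effects in breeding data. Recovery on real libraries therefore
depends on upstream processing quality in ways these tests cannot certify.
Cross-reactivity of other modifications with the reduction chemistry and
rRNA acetylation are likewise out of scope.
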