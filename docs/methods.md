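# Methods

## System and scope

The pipeline analyses genomic variation among five African cichlid
genomes, with the Nile Tilapia assembly (anchored into linkage groups, LGs)
as the common reference and four radiation species (Nb, Ab, Pn, Mz) as the
ingroup, one sequenced individual per species.  Read mapping and variant
calling are outside the pipeline; their output (per-species VCFs) is either
supplied by the user or produced by the synthetic generator.  All internal
coordinates are 1-based inclusive (VCF/GFF convention); BED input/output is
converted at the boundary, and a structural variant's span is
`end − pos + 1` (so the shortest admissible inversion spans 51 bp).

## Filtering

SNP/indel calls are kept iff phred quality > 30 (strict), site depth
within [6, 5000] (both ends inclusive — the usual reading of GATK-style
"between" expressions; boundary behaviour is pinned by tests) and Fisher
strand bias < 200 (strict).  Records missing any of the three fields are
rejected with an explicit reason, never silently kept.  Depth is taken as
site-level DP.  TE exclusion removes any variant whose span overlaps an
annotated TE interval by ≥ 1 bp (the intersectBed default); SNPs and
indels are tested at their anchor base, structural variants over their
whole span, and partial overlap counts.  Both operations partition their
input and are idempotent.

## Effect annotation

Every SNP/indel receives exactly one category via a configurable severity
order: start/stop loss > frameshift > non-synonymous > in-frame >
synonymous > intron > upstream > downstream > intergenic.  Coding SNPs are
resolved by substituting the alternate base in the affected codon
(reverse-complemented for minus-strand genes) and translating with the
standard genetic code (ATG-start assumption; no alternative codon tables).
Coding indels are frameshift iff their length is not a multiple of three;
disruption of the first/last codon gives start/stop loss, which takes
precedence.  Junction-spanning indels are classified by their
CDS-overlapping part.  Upstream/downstream means within 5 kb of the
gene's 5′/3′ end on its coding strand; a position inside one gene's intron
is INTRON even when within 5 kb of a neighbouring gene, keeping categories
a partition.  Positions inside a gene span but in non-coding exonic
sequence (UTR) are classified INTRON — the category set carries no UTR
class, and synthetic gene models have exon = CDS so the case does not
arise there.  When a gene has several transcripts the first-listed mRNA is
used.

Window densities use non-overlapping 50-kb windows (step configurable;
counts then sum to the per-LG totals).  The indel length spectrum reports,
per length bin, the fraction of exonic and of all indels, with the mass
beyond the largest bin reported as a truncation remainder.

## Structural variants

The reference self-consistency filter removes any call overlapping
(≥ 1 bp, same class) an SV called from mapping the reference species'
reads to its own assembly — such calls are assembly artefacts shared by
every sample.  Library merging follows mergeBed: same-class intervals that
overlap or are bookended coalesce to their envelope (merge distance
configurable, default 0).  Multi-way overlap sweeps interval breakpoints
and reports maximal regions covered by same-class calls of at least
`min_species` species, equal by construction to a per-base sweep.  Gene
overlap uses the gene span (not exons), ≥ 1 bp.

Per-LG counts normalized by LG length in Mb feed the generalized ESD test
(Rosner): iteratively remove the most extreme studentized point, compare
R_i with λ_i = (n−i)·t_{p,n−i−1} / sqrt((n−i−1+t²)(n−i+1)),
p = 1 − α/(2(n−i+1)); the outlier count is the largest i with R_i > λ_i.
The maximum number of outliers tested defaults to r = 3 (not dictated by
the source analysis; configurable), and a zero-variance step yields
R_i = 0.  Simulation places the empirical type-I error at α = 0.05,
n = 22 near 0.057 — the test's known slight liberality at this n, within
the accepted band.  GO enrichment is a one-sided Fisher exact test per
term with Benjamini–Hochberg correction (significant iff q < 0.05).

## Placement, dating, rates

Variant identity across species: SNPs match on (LG, position, alternate
allele), indels on (LG, position, ref, alt), and SVs of the same class by
reciprocal overlap ≥ 0.5 under transitive closure, keyed by the envelope
region (the threshold is configurable; the source tooling's default is not
published).  A sharing pattern equal to a clade's leaf set maps to that
clade's stem branch; all other patterns are excluded — with one individual
per species, deeper homoplasy resolution (e.g. a Fitch down-pass) is
unsupported, so it is deliberately not attempted.  Exactly 7 of the 15
non-empty ingroup subsets are assignable.  The reference lineage carries
no variants by construction, so reference-lineage changes are absorbed by
the ingroup stem branch; outputs carry that caveat.

NPRS minimizes the squared change in rate (branch length / duration)
between each branch and its parent branch, with the root's children
compared against their mean rate (r8s-style root handling).  Ages are
parameterized on a relative scale — root at 1, each internal node a
fraction (0, 1) of its parent's age, leaves at 0 — and rescaled so the
calibrated node (Pn–Mz split, 2.3 My) sits exactly at its age; the
objective is evaluated on the rescaled ages.  This makes the calibration
exact and scale-consistency (calibration × c ⇒ all ages × c) hold by
construction.  Optimization is multi-start Nelder–Mead (default 10 seeded
restarts) followed by cyclic bounded Brent polish per coordinate
(tolerance 1e-10 on W); in the clock limit the truth is recovered to
better than 1e-8 My.  Branch durations (parent age − child age) are the
rate denominators — stem durations, not node ages.

## Synthetic data

The generator emulates the study conditions at desk scale: 4 LGs × 2 Mb,
80 genes (CDS 50–200 codons, ATG…stop, no internal stops, 1–4 exons,
random strand), TE intervals covering 15% of the genome outside gene
spans, and the fixed topology with node ages 12 / 8 / 2.3 My for the
ingroup root, anc(Ab,Pn,Mz) and anc(Pn,Mz) (the last being the published
calibration), Tilapia split at 20 My, clock-like branch lengths at 1e-3
substitutions/site/My.  Variants arise per branch as Poisson(λ · duration)
with default rates shaped like the published pattern: SNP rates peak on
the ingroup stem (500/My vs 80–360/My elsewhere), inversion/deletion
rates peak on the terminals, indel rates are uniform (so indel rank order
is not a scored quantity).  A 5% homoplasy fraction re-draws the sharing
pattern onto one of the 8 non-clade subsets; 25 assembly artefacts are
emitted into every species call set and the reference self-call set;
2% of records are drawn to fail each hard filter.  Exonic indels take a
length divisible by three with probability 0.8.  SV lengths are
log-uniform on [51, 2000] bp — deliberately shorter than real cichlid
inversions (which reach tens of Mb) so that thousands of events fit a
desk-scale genome; distinct same-class events never overlap, mirroring
the no-recurrent-mutation rule and keeping truth and interval clustering
unambiguous.  Call-quality attributes are drawn once per variant and
shared by all carriers, so filtering removes a variant wholesale and
truth bookkeeping stays exact.

What passing tests therefore show: the operations are correct against
independent oracles, and the pipeline recovers generating parameters
(branch-rate rank order, homoplasy fraction, in-frame bias) under the
stated conditions.  What they do not show: robustness to mapping bias,
caller-specific artefacts, breakpoint uncertainty, genotyping error
correlated across species, or real TE landscapes — none of which the
generator models.

## Problem sizes and numerics

Default synthetic runs hold ~19k distinct variants (~41k species records);
rank-recovery replicates run the full pipeline 100 times in the test
suite and 20 times in the acceptance script.  ESD calibration uses 10^4
(tests) / 4·10^3 (script) Gaussian replicates at n = 22.  All randomness
flows from a single integer seed per run; fixed seeds give byte-identical
outputs.  Degenerate inputs error loudly: empty spectra, n < 3 for ESD,
leaf calibrations, zero-duration branches, records on unknown LGs.
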