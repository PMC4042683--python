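# cichlidvar

Comparative genomic-variation analysis for the five sequenced African
cichlid genomes: the Nile Tilapia (*Oreochromis niloticus*) reference and
four representatives of the East-African adaptive radiations —
*Neolamprologus brichardi* (Nb), *Astatotilapia burtoni* (Ab),
*Pundamilia nyererei* (Pn) and *Metriaclima zebra* (Mz).

The package implements, as a tested and reusable pipeline, the analysis
stages downstream of read mapping and variant calling:

- **Hard filtering** of SNP/indel calls (phred quality > 30, site depth in
  [6, 5000], Fisher strand bias < 200) and exclusion of variants
  overlapping transposable-element (TE) intervals.
- **Effect annotation** of SNPs and indels against the reference gene
  models: synonymous/non-synonymous (strand-aware codon retranslation),
  frameshift/in-frame and start/stop-loss for coding indels, intron,
  upstream/downstream (within 5 kb of the gene, 5′/3′ on its coding
  strand), intergenic — with a single highest-severity category per
  variant; plus per-species category tables, the indel length ("mod 3")
  spectrum and 50-kb window densities.
- **Structural-variant consolidation**: a reference self-consistency
  filter (SVs also called when the reference's own reads are mapped back
  to its assembly are treated as assembly artefacts), merging of
  paired-end/mate-pair call sets with mergeBed semantics, multi-way
  cross-species overlap, gene overlap, the generalized ESD (Rosner)
  outlier test on length-normalized per-linkage-group counts, and GO
  enrichment (one-sided Fisher, Benjamini–Hochberg FDR).
- **Phylogenetic placement and rates**: a cross-species presence/absence
  matrix (exact keys for SNPs/indels; reciprocal-overlap ≥ 0.5 equivalence
  classes for SVs), maximum-parsimony assignment of each variant to the
  stem branch of the clade matching its sharing pattern on the fixed
  rooted topology `(Tilapia,(Nb,(Ab,(Pn,Mz))))` — non-clade (homoplasic)
  patterns are excluded — nonparametric rate smoothing (NPRS) dating
  calibrated at the Pn–Mz split (2.3 My), and per-branch rates
  (lineage-specific count / branch duration in My).
- **Synthetic data generator**: a desk-scale stand-in for the
  read-mapping/variant-calling stages.  It builds a multi-linkage-group
  reference with codon-aware gene models and TE intervals, then draws
  SNPs, indels, inversions and deletions on the branches of the fixed
  topology at per-branch Poisson rates, with configurable homoplasy,
  in-frame bias for exonic indels, filter-failure fractions and assembly
  artefacts — recording full ground truth for every emitted variant.

For placement, each variant's sharing pattern S ⊆ {Nb, Ab, Pn, Mz} maps to
the branch above the most recent common ancestor of S iff S equals that
clade's leaf set; NPRS minimizes
W = Σ_k (r_k − r_parent(k))² (+ the root-children term with their mean
rate), where r_k = branch length / branch duration, subject to one fixed
calibration.

## Worked example

```
python analysis/03_run_pipeline.py
```

prints (seed 42):

```
  Nb: 6325 SNP/indel calls, 351 failed hard filters, 1345 in TE regions
  ...
  presence matrix: 15394 distinct variants; 14617 placed on branches,
  777 excluded as homoplasic (5.0%)
  NPRS objective W = 2.94e-31 (clock-like input, so ~0 expected)
  SNP: fastest branch anc(Nb,Ab,Pn,Mz) (383.9/My)
  INVERSION: fastest branch Mz (130.9/My)
  DELETION: fastest branch Mz (163.5/My)
  exonic indel div-3 mass: 0.82 (generator bias 0.8 + background)
```

i.e. the pipeline recovers the generating pattern: SNP evolution fastest on
the stem of the radiation, inversion/deletion evolution fastest on the
terminal branches, the homoplasy fraction (5%) recovered from the excluded
patterns, and exonic indels enriched for lengths divisible by three.  The
report bundle (category tables, indel spectrum, SNP density bedGraph, SV
summary, branch-rate table, `manifest.json` with per-stage counts) lands in
`results/pipeline/`.

The other drivers: `analysis/01_published_tables.py` recomputes the
published per-species SNP/indel summary tables from their printed counts
(totals, percentages, the ns/s ratio of 0.7); `02_simulate_dataset.py`
writes a full synthetic dataset as VCF/GFF3/BED/FASTA/Newick;
`04_esd_calibration.py` calibrates the ESD outlier test;
`05_rate_rank_recovery.py` scores branch-rate rank recovery over pipeline
replicates.

A thin CLI wraps the same machinery:
`cichlidvar simulate --seed 42 --out simdir/` and
`cichlidvar run --seed 42 --out rundir/ [--config pipeline.yaml]`.

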