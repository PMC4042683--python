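"""Effect classification, indel spectrum, window densities, summaries."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from cichlidvar import published
from cichlidvar.core import GenomeAnnotation, VariantClass, VariantRecord
from cichlidvar.effects import (
    EffectCall,
    EffectCategory,
    INDEL_TABLE_ROWS,
    SNP_TABLE_ROWS,
    classify_indel,
    classify_snp,
    div3_mass,
    mod3_spectrum,
    summarize_categories,
    summary_from_counts,
    window_density,
)


def snp(lg, pos, ref, alt, **kw):
    return VariantRecord(species_id="Nb", lg=lg, pos=pos,
                         var_class=VariantClass.SNP, ref_allele=ref,
                         alt_allele=alt, **kw)


def indel(lg, pos, ref, alt, **kw):
    return VariantRecord(species_id="Nb", lg=lg, pos=pos,
                         var_class=VariantClass.INDEL, ref_allele=ref,
                         alt_allele=alt, **kw)


class TestClassifySNP:
    # toy gene fwd1: CDS 101-109 = ATG GGA TAA on + strand
    def test_synonymous_third_position(self, toy_annotation):
        call = classify_snp(snp("LG1", 106, "A", "G"), toy_annotation)
        assert call.category is EffectCategory.SYNONYMOUS  # GGA->GGG, Gly
        assert call.gene_id == "fwd1"

    def test_nonsynonymous_first_position(self, toy_annotation):
        call = classify_snp(snp("LG1", 104, "G", "A"), toy_annotation)
        assert call.category is EffectCategory.NONSYNONYMOUS  # GGA->AGA

    def test_minus_strand_codon(self, toy_annotation):
        # rev1 sense CDS is ATG CCT TGA; genomic 15006 is codon2 pos1 (C)
        # genome base there is complement(C)=G; G->C flips sense C->G:
        # CCT->GCT, Pro->Ala
        call = classify_snp(snp("LG1", 15_006, "G", "C"), toy_annotation)
        assert call.category is EffectCategory.NONSYNONYMOUS
        assert call.gene_id == "rev1"

    def test_upstream_boundary_5kb(self):
        L = 30_000
        seq = "A" * L
        ann = GenomeAnnotation(
            lg_lengths={"LG1": L},
            genes=[_gene("g1", 10_001, strand="+")],
            te_intervals=[], sequences={"LG1": seq})
        at_4999 = classify_snp(snp("LG1", 10_001 - 4_999, "A", "G"), ann)
        assert at_4999.category is EffectCategory.UPSTREAM
        at_5001 = classify_snp(snp("LG1", 10_001 - 5_001, "A", "G"), ann)
        assert at_5001.category is EffectCategory.INTERGENIC

    def test_intron_beats_neighbor_proximity(self):
        # position in g1's intron that is also within 5 kb of g2
        L = 40_000
        seq = list("A" * L)
        seq[10_000:10_003] = "ATG"; seq[12_000:12_006] = "GGGTAA"
        seq[14_000:14_003] = "ATG"; seq[14_003:14_009] = "GGGTAA"
        ann = GenomeAnnotation(
            lg_lengths={"LG1": L},
            genes=[
                # g1: two exons with an intron 10004..12000
                _gene2exon("g1", (10_001, 10_003), (12_001, 12_006)),
                _gene2exon("g2", (14_001, 14_003), (14_004, 14_009)),
            ],
            te_intervals=[], sequences={"LG1": "".join(seq)})
        call = classify_snp(snp("LG1", 11_000, "A", "G"), ann)
        assert call.category is EffectCategory.INTRON
        assert call.gene_id == "g1"


def _gene(gene_id, start, strand="+", lg="LG1"):
    from cichlidvar.core import GeneModel
    return GeneModel(gene_id, lg, strand, exons=[(start, start + 8)],
                     cds=[(start, start + 8)])


def _gene2exon(gene_id, ex1, ex2, lg="LG1"):
    from cichlidvar.core import GeneModel
    return GeneModel(gene_id, lg, "+", exons=[ex1, ex2], cds=[ex1, ex2])


class TestClassifyIndel:
    @pytest.fixture()
    def cds_ann(self):
        # + strand gene, CDS 101-130: ATG + 8 codons AAA + TAA stop
        L = 20_000
        seq = list("C" * L)
        cds = "ATG" + "AAA" * 8 + "TAA"
        seq[100:130] = cds
        from cichlidvar.core import GeneModel
        return GenomeAnnotation(
            lg_lengths={"LG1": L},
            genes=[GeneModel("g1", "LG1", "+", [(101, 130)], [(101, 130)])],
            te_intervals=[], sequences={"LG1": "".join(seq)})

    def test_inframe_3bp_deletion(self, cds_ann):
        seq = cds_ann.sequences["LG1"]
        rec = indel("LG1", 110, seq[109:113], seq[109])
        assert classify_indel(rec, cds_ann).category is EffectCategory.INFRAME

    def test_frameshift_2bp_deletion(self, cds_ann):
        seq = cds_ann.sequences["LG1"]
        rec = indel("LG1", 110, seq[109:112], seq[109])
        assert classify_indel(rec, cds_ann).category is EffectCategory.FRAMESHIFT

    def test_start_lost_precedence(self, cds_ann):
        seq = cds_ann.sequences["LG1"]
        rec = indel("LG1", 100, seq[99:103], seq[99])  # removes codon ATG
        assert classify_indel(rec, cds_ann).category is EffectCategory.START_LOST

    def test_stop_lost(self, cds_ann):
        seq = cds_ann.sequences["LG1"]
        rec = indel("LG1", 127, seq[126:130], seq[126])
        assert classify_indel(rec, cds_ann).category is EffectCategory.STOP_LOST

    def test_flank_and_intergenic_insertion(self, toy_annotation):
        # 500 is within 5 kb 3' of fwd1 (+ strand, CDS 101-109)
        near = classify_indel(indel("LG1", 500, "A", "ATT"), toy_annotation)
        assert near.category is EffectCategory.DOWNSTREAM
        far = classify_indel(indel("LG1", 7_000, "A", "ATT"), toy_annotation)
        assert far.category is EffectCategory.INTERGENIC


class TestBruteForceOracle:
    """classify_snp against full-CDS retranslation on a synthetic genome."""

    def test_cds_snps_match_full_retranslation(self, small_annotation):
        rng = np.random.default_rng(21)
        ann = small_annotation
        n_checked = 0
        for g in ann.genes:
            cp = g.coding_positions()
            for _ in range(40):
                i = int(rng.integers(0, len(cp)))
                pos = cp[i]
                ref = ann.base(g.lg, pos)
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                call = classify_snp(snp(g.lg, pos, ref, alt), ann)
                expected = _oracle_category(ann, g, pos, alt)
                assert call.category is expected, (g.gene_id, pos)
                n_checked += 1
        assert n_checked >= 1000

    def test_strand_symmetry(self, small_annotation):
        """Reverse-complementing genome and variants preserves categories."""
        ann = small_annotation
        flipped = _reverse_complement_annotation(ann)
        rng = np.random.default_rng(22)
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        for _ in range(300):
            lg = str(rng.choice(sorted(ann.lg_lengths)))
            L = ann.lg_lengths[lg]
            pos = int(rng.integers(1, L + 1))
            ref = ann.base(lg, pos)
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            fwd = classify_snp(snp(lg, pos, ref, alt), ann)
            rev = classify_snp(
                snp(lg, L - pos + 1, comp[ref], comp[alt]), flipped)
            assert fwd.category is rev.category


def _oracle_category(ann, gene, pos, alt):
    """Translate the gene's full CDS with and without the alternate base."""
    cp = gene.coding_positions()
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}

    def sense(base):
        return base if gene.strand == "+" else comp[base]

    ref_cds = "".join(sense(ann.base(gene.lg, p)) for p in cp)
    alt_cds = "".join(
        sense(alt) if p == pos else sense(ann.base(gene.lg, p)) for p in cp
    )
    same = str(Seq(ref_cds).translate()) == str(Seq(alt_cds).translate())
    return EffectCategory.SYNONYMOUS if same else EffectCategory.NONSYNONYMOUS


def _reverse_complement_annotation(ann):
    from cichlidvar.core import GeneModel
    comp = str.maketrans("ACGT", "TGCA")
    seqs = {lg: s.translate(comp)[::-1] for lg, s in ann.sequences.items()}
    genes = []
    for g in ann.genes:
        L = ann.lg_lengths[g.lg]
        flip = lambda iv: (L - iv[1] + 1, L - iv[0] + 1)
        genes.append(GeneModel(
            g.gene_id, g.lg, "+" if g.strand == "-" else "-",
            exons=sorted(map(flip, g.exons)), cds=sorted(map(flip, g.cds))))
    L_by = ann.lg_lengths
    te = sorted((lg, L_by[lg] - e0, L_by[lg] - s0) for lg, s0, e0 in ann.te_intervals)
    return GenomeAnnotation(lg_lengths=dict(L_by), genes=genes,
                            te_intervals=te, sequences=seqs)


class TestMod3Spectrum:
    def _call(self, length, exonic):
        rec = indel("LG1", 100, "A" * (length + 1), "A")
        cat = EffectCategory.INFRAME if exonic else EffectCategory.INTERGENIC
        return EffectCall(rec, cat, "g1" if exonic else None)

    def test_exonic_div3_mass(self):
        calls = [self._call(3, True), self._call(6, True), self._call(2, True)]
        df = mod3_spectrum(calls, max_len=9)
        assert div3_mass(df, "exon_fraction") == pytest.approx(2 / 3)

    def test_uniform_genomewide_div3(self):
        calls = [self._call(L, False) for L in range(1, 10)]
        df = mod3_spectrum(calls, max_len=9)
        assert div3_mass(df, "genome_fraction") == pytest.approx(3 / 9)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            mod3_spectrum([])

    def test_generator_bias_recovered(self, default_dataset):
        """Exonic in-frame enrichment ~= the generator's bias parameter."""
        from cichlidvar.effects import classify
        ds = default_dataset
        ann = ds.annotation
        calls = []
        for sp, records in ds.per_species.items():
            for r in records:
                if r.var_class is VariantClass.INDEL:
                    calls.append(classify(r, ann))
        df = mod3_spectrum(calls, max_len=ds.config.indel_max_len)
        exonic_n = sum(
            1 for c in calls if c.category in
            {EffectCategory.FRAMESHIFT, EffectCategory.INFRAME,
             EffectCategory.START_LOST, EffectCategory.STOP_LOST})
        assert exonic_n > 200
        p = ds.config.exon_inframe_bias
        # residual 1/3 of the non-biased draws also land on multiples of 3
        expected = p + (1 - p) * (3 / ds.config.indel_max_len) / 1
        tol = 4 * np.sqrt(expected * (1 - expected) / exonic_n) + 0.02
        assert abs(div3_mass(df, "exon_fraction") - expected) < tol


class TestWindowDensity:
    def _ann(self, length):
        return GenomeAnnotation(lg_lengths={"LG1": length}, genes=[],
                                te_intervals=[])

    def test_three_windows(self):
        ann = self._ann(120_000)
        recs = [snp("LG1", p, "A", "G") for p in (10_000, 60_000, 110_000)]
        df = window_density(recs, ann, window=50_000)
        assert list(df["count"]) == [1, 1, 1]
        assert list(df["window_start"]) == [1, 50_001, 100_001]

    def test_empty(self):
        df = window_density([], self._ann(120_000), window=50_000)
        assert df["count"].sum() == 0 and len(df) == 3

    def test_uniform_counts_conserve_and_look_uniform(self):
        rng = np.random.default_rng(9)
        L = 1_000_000
        ann = self._ann(L)
        recs = [snp("LG1", int(p), "A", "G")
                for p in rng.integers(1, L + 1, size=10_000)]
        df = window_density(recs, ann, window=50_000)
        assert df["count"].sum() == 10_000
        from scipy import stats
        chi2 = ((df["count"] - df["count"].mean()) ** 2 / df["count"].mean()).sum()
        p = stats.chi2.sf(chi2, df=len(df) - 1)
        assert p > 0.01

    def test_beyond_lg_errors(self):
        with pytest.raises(ValueError):
            window_density([snp("LG1", 200_000, "A", "G")],
                           self._ann(120_000))


class TestSummaries:
    def test_published_counts_recover_percentages(self):
        s = summary_from_counts(published.SNP_COUNTS, SNP_TABLE_ROWS)
        for sp in published.SPECIES:
            assert s.counts.loc["Total", sp] == published.SNP_TOTALS[sp]
            for cat, pct in published.SNP_PERCENTS[sp].items():
                assert s.percentages.loc[cat, sp] == pytest.approx(pct)
        assert s.ns_s_ratio["Nb"] == pytest.approx(0.7)

    def test_equal_categories_give_equal_percent(self):
        counts = {"Nb": {row: 10 for row in SNP_TABLE_ROWS}}
        s = summary_from_counts(counts, SNP_TABLE_ROWS)
        assert (s.percentages["Nb"] == 16.7).all()

    def test_exact_recovery_from_calls(self):
        rng = np.random.default_rng(2)
        per_cat = {row: int(rng.integers(1, 30)) for row in SNP_TABLE_ROWS}
        cat_of = {
            "Synonymous": EffectCategory.SYNONYMOUS,
            "Non-synonymous": EffectCategory.NONSYNONYMOUS,
            "Upstream": EffectCategory.UPSTREAM,
            "Downstream": EffectCategory.DOWNSTREAM,
            "Intron": EffectCategory.INTRON,
            "Intergenic": EffectCategory.INTERGENIC,
        }
        calls, pos = [], 1
        for row, n in per_cat.items():
            for _ in range(n):
                cat = cat_of[row]
                gene = None if cat is EffectCategory.INTERGENIC else "g1"
                calls.append(EffectCall(snp("LG1", pos, "A", "G"), cat, gene))
                pos += 1
        s = summarize_categories({"Nb": calls}, VariantClass.SNP)
        for row, n in per_cat.items():
            assert s.counts.loc[row, "Nb"] == n
        assert s.counts.loc["Total", "Nb"] == sum(per_cat.values())

    def test_zero_synonymous_ratio_undefined(self):
        counts = {"Nb": {"Non-synonymous": 5, "Intron": 5}}
        s = summary_from_counts(counts, SNP_TABLE_ROWS)
        assert s.ns_s_ratio["Nb"] is None
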