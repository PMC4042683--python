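"""Published per-species summary tables of the five-genome comparison.

These are the printed counts of the study's summary tables, used as inputs:
the per-category SNP/indel tallies (with totals) and the inversion/deletion
summaries per species.  They let the summary machinery be checked for
arithmetic self-consistency (category counts partition the totals, printed
percentages and the non-synonymous/synonymous ratio are recovered) without
the ~1 Tb of raw read data behind them.
"""

from __future__ import annotations

SPECIES = ("Nb", "Ab", "Pn", "Mz")

#: SNP effect-category counts per species (printed values).
SNP_COUNTS: dict[str, dict[str, int]] = {
    "Nb": {
        "Synonymous": 440_813, "Non-synonymous": 311_551,
        "Upstream": 1_503_602, "Downstream": 2_940_995,
        "Intron": 7_693_416, "Intergenic": 5_955_045,
    },
    "Ab": {
        "Synonymous": 410_635, "Non-synonymous": 289_739,
        "Upstream": 1_415_307, "Downstream": 2_784_038,
        "Intron": 7_232_387, "Intergenic": 5_577_008,
    },
    "Pn": {
        "Synonymous": 411_584, "Non-synonymous": 290_001,
        "Upstream": 1_346_770, "Downstream": 2_659_723,
        "Intron": 6_962_386, "Intergenic": 5_319_811,
    },
    "Mz": {
        "Synonymous": 405_220, "Non-synonymous": 291_171,
        "Upstream": 1_349_864, "Downstream": 2_664_669,
        "Intron": 6_958_755, "Intergenic": 5_303_501,
    },
}

#: Printed SNP totals per species.
SNP_TOTALS = {"Nb": 18_845_422, "Ab": 17_709_114, "Pn": 16_990_275,
              "Mz": 16_973_180}

#: Printed SNP percentages (1 decimal) per category and species.
SNP_PERCENTS: dict[str, dict[str, float]] = {
    "Nb": {"Synonymous": 2.3, "Non-synonymous": 1.7, "Upstream": 8.0,
           "Downstream": 15.6, "Intron": 40.8, "Intergenic": 31.6},
    "Ab": {"Synonymous": 2.3, "Non-synonymous": 1.6, "Upstream": 8.0,
           "Downstream": 15.7, "Intron": 40.8, "Intergenic": 31.5},
    "Pn": {"Synonymous": 2.4, "Non-synonymous": 1.7, "Upstream": 7.9,
           "Downstream": 15.7, "Intron": 41.0, "Intergenic": 31.3},
    "Mz": {"Synonymous": 2.4, "Non-synonymous": 1.7, "Upstream": 8.0,
           "Downstream": 15.7, "Intron": 41.0, "Intergenic": 31.2},
}

#: Indel category counts per species (printed values).
INDEL_COUNTS: dict[str, dict[str, int]] = {
    "Nb": {"Exon": 15_583, "Upstream": 183_740, "Downstream": 413_967,
           "Intron": 1_007_681, "Intergenic": 696_342},
    "Ab": {"Exon": 14_909, "Upstream": 174_367, "Downstream": 394_421,
           "Intron": 959_217, "Intergenic": 651_827},
    "Pn": {"Exon": 9_912, "Upstream": 113_395, "Downstream": 259_539,
           "Intron": 629_137, "Intergenic": 428_708},
    "Mz": {"Exon": 13_663, "Upstream": 147_365, "Downstream": 337_612,
           "Intron": 819_930, "Intergenic": 554_392},
}

#: Printed indel totals per species.
INDEL_TOTALS = {"Nb": 2_317_313, "Ab": 2_194_741, "Pn": 1_440_691,
                "Mz": 1_872_962}

#: Printed indel percentages (1 decimal).
INDEL_PERCENTS: dict[str, dict[str, float]] = {
    "Nb": {"Exon": 0.7, "Upstream": 7.9, "Downstream": 17.9, "Intron": 43.5,
           "Intergenic": 30.0},
    "Ab": {"Exon": 0.7, "Upstream": 7.9, "Downstream": 18.0, "Intron": 43.7,
           "Intergenic": 29.7},
    "Pn": {"Exon": 0.7, "Upstream": 7.9, "Downstream": 18.0, "Intron": 43.7,
           "Intergenic": 29.7},
    "Mz": {"Exon": 0.7, "Upstream": 7.9, "Downstream": 18.0, "Intron": 43.8,
           "Intergenic": 29.6},
}

#: Published non-synonymous/synonymous ratio ("around 0.7").
NS_S_RATIO = 0.7

#: Inversion summaries per species.
INVERSIONS = {
    "Nb": {"number": 621, "longest_bp": 11_374_460, "shortest_bp": 51,
           "average_bp": 98_025, "genes_affected": 262},
    "Ab": {"number": 683, "longest_bp": 19_074_784, "shortest_bp": 51,
           "average_bp": 58_793, "genes_affected": 306},
    "Pn": {"number": 371, "longest_bp": 24_423_750, "shortest_bp": 51,
           "average_bp": 214_075, "genes_affected": 162},
    "Mz": {"number": 389, "longest_bp": 14_318_936, "shortest_bp": 51,
           "average_bp": 161_034, "genes_affected": 154},
}

#: Deletion summaries per species.
DELETIONS = {
    "Nb": {"number": 15_833, "longest_bp": 982_119, "shortest_bp": 50,
           "average_bp": 561, "genes_affected": 3_509},
    "Ab": {"number": 10_695, "longest_bp": 634_424, "shortest_bp": 50,
           "average_bp": 795, "genes_affected": 2_705},
    "Pn": {"number": 9_840, "longest_bp": 2_445_312, "shortest_bp": 50,
           "average_bp": 981, "genes_affected": 2_710},
    "Mz": {"number": 10_070, "longest_bp": 790_935, "shortest_bp": 50,
           "average_bp": 646, "genes_affected": 2_634},
}

#: SNPs traced to the common ancestor of the four radiation species
#: (printed as 9.8 million).
STEM_SNPS_MILLIONS = 9.8

#: Calibration: Lake Victoria / Lake Malawi split (My).
PN_MZ_SPLIT_MY = 2.3

#: Number of annotated genes on the 22 linkage groups.
N_GENES_22LG = 20_162

#: Number of linkage groups in the anchored reference.
N_LINKAGE_GROUPS = 22
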