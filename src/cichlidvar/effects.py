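"""SNP/indel effect classification, the indel length spectrum and
window densities.

A variant receives exactly one category, chosen by a configurable
severity order (start/stop loss > frameshift > non-synonymous > in-frame >
synonymous > intron > upstream > downstream > intergenic).  Coding effects
are strand-aware: the affected codon is read off the reference, substituted
and translated with the standard genetic code.  Upstream/downstream means
within 5 kb of the gene's 5'/3' end on its coding strand.
"""

from __future__ import annotations

import enum
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Optional

import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .core import GeneModel, GenomeAnnotation, VariantClass, VariantRecord

FLANK_BP = 5000  # "within 5 kb upstream/downstream of a gene"


class EffectCategory(str, enum.Enum):
    START_LOST = "START_LOST"
    STOP_LOST = "STOP_LOST"
    FRAMESHIFT = "FRAMESHIFT"
    NONSYNONYMOUS = "NONSYNONYMOUS"
    INFRAME = "INFRAME"
    SYNONYMOUS = "SYNONYMOUS"
    INTRON = "INTRON"
    UPSTREAM = "UPSTREAM"
    DOWNSTREAM = "DOWNSTREAM"
    INTERGENIC = "INTERGENIC"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Highest-to-lowest severity; the first matching category is reported.
DEFAULT_PRECEDENCE = tuple(EffectCategory)

EXONIC_CATEGORIES = frozenset(
    {
        EffectCategory.START_LOST,
        EffectCategory.STOP_LOST,
        EffectCategory.FRAMESHIFT,
        EffectCategory.NONSYNONYMOUS,
        EffectCategory.INFRAME,
        EffectCategory.SYNONYMOUS,
    }
)


@dataclass(frozen=True)
class EffectCall:
    variant: VariantRecord
    category: EffectCategory
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category is not EffectCategory.INTERGENIC and self.gene_id is None:
            raise ValueError("non-intergenic effect requires a gene_id")


class EffectIndex:
    """Interval lookups over an annotation, built once and cached.

    Trees are keyed per LG over half-open [start-1, end) windows; CDS hits
    carry the gene so the affected codon can be resolved.
    """

    def __init__(self, ann: GenomeAnnotation):
        self.ann = ann
        self.cds: dict[str, IntervalTree] = {lg: IntervalTree() for lg in ann.lg_lengths}
        self.exon: dict[str, IntervalTree] = {lg: IntervalTree() for lg in ann.lg_lengths}
        self.span: dict[str, IntervalTree] = {lg: IntervalTree() for lg in ann.lg_lengths}
        self.upstream: dict[str, IntervalTree] = {lg: IntervalTree() for lg in ann.lg_lengths}
        self.downstream: dict[str, IntervalTree] = {lg: IntervalTree() for lg in ann.lg_lengths}
        self._coding_pos_cache: dict[str, dict[int, int]] = {}
        for g in ann.genes:
            for s, e in g.cds:
                self.cds[g.lg].addi(s - 1, e, g)
            for s, e in g.exons:
                self.exon[g.lg].addi(s - 1, e, g)
            gs, ge = g.span
            self.span[g.lg].addi(gs - 1, ge, g)
            L = ann.lg_lengths[g.lg]
            five = (max(1, gs - FLANK_BP), gs - 1) if g.strand == "+" else (ge + 1, min(L, ge + FLANK_BP))
            three = (ge + 1, min(L, ge + FLANK_BP)) if g.strand == "+" else (max(1, gs - FLANK_BP), gs - 1)
            if five[0] <= five[1]:
                self.upstream[g.lg].addi(five[0] - 1, five[1], g)
            if three[0] <= three[1]:
                self.downstream[g.lg].addi(three[0] - 1, three[1], g)

    def coding_index(self, gene: GeneModel, pos: int) -> int:
        """0-based index of a genomic position within the gene's coding order."""
        cache = self._coding_pos_cache.get(gene.gene_id)
        if cache is None:
            cache = {p: i for i, p in enumerate(gene.coding_positions())}
            self._coding_pos_cache[gene.gene_id] = cache
        return cache[pos]

    def codon_at(self, gene: GeneModel, codon_idx: int) -> str:
        """Reference codon (coding strand) at codon index."""
        cp = gene.coding_positions()
        bases = [self.ann.base(gene.lg, p) for p in cp[3 * codon_idx: 3 * codon_idx + 3]]
        if gene.strand == "-":
            bases = [_COMPLEMENT[b] for b in bases]
        return "".join(bases)


_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}


def get_effect_index(ann: GenomeAnnotation) -> EffectIndex:
    idx = getattr(ann, "_effect_index", None)
    if idx is None:
        idx = EffectIndex(ann)
        ann._effect_index = idx
    return idx


def _pick(candidates: list[tuple[EffectCategory, Optional[str]]],
          precedence=DEFAULT_PRECEDENCE) -> tuple[EffectCategory, Optional[str]]:
    order = {c: i for i, c in enumerate(precedence)}
    return min(candidates, key=lambda c: order[c[0]])


def _noncoding_candidates(idx: EffectIndex, lg: str, pos: int):
    """Intron/upstream/downstream/intergenic candidates for a position."""
    cands = []
    for iv in idx.span[lg].at(pos - 1):
        cands.append((EffectCategory.INTRON, iv.data.gene_id))
    if not cands:
        for iv in idx.upstream[lg].at(pos - 1):
            cands.append((EffectCategory.UPSTREAM, iv.data.gene_id))
        for iv in idx.downstream[lg].at(pos - 1):
            cands.append((EffectCategory.DOWNSTREAM, iv.data.gene_id))
    if not cands:
        cands.append((EffectCategory.INTERGENIC, None))
    return cands


def classify_snp(v: VariantRecord, ann: GenomeAnnotation,
                 precedence=DEFAULT_PRECEDENCE) -> EffectCall:
    """Classify a SNP into its highest-severity effect category."""
    if v.var_class is not VariantClass.SNP:
        raise ValueError("classify_snp requires a SNP record")
    idx = get_effect_index(ann)
    if v.lg not in idx.cds:
        raise ValueError(f"record on LG {v.lg} absent from annotation")
    candidates = []
    for iv in idx.cds[v.lg].at(v.pos - 1):
        gene: GeneModel = iv.data
        if gene.cds_length % 3 != 0:
            raise ValueError(f"gene {gene.gene_id} violates the frame invariant")
        ci = idx.coding_index(gene, v.pos)
        codon_idx, offset = divmod(ci, 3)
        ref_codon = idx.codon_at(gene, codon_idx)
        ref_base = v.ref_allele if gene.strand == "+" else _COMPLEMENT[v.ref_allele]
        if ref_codon[offset] != ref_base:
            raise ValueError(
                f"reference mismatch at {v.lg}:{v.pos} in {gene.gene_id}"
            )
        alt_base = v.alt_allele if gene.strand == "+" else _COMPLEMENT[v.alt_allele]
        alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1:]
        same = str(Seq(ref_codon).translate()) == str(Seq(alt_codon).translate())
        cat = EffectCategory.SYNONYMOUS if same else EffectCategory.NONSYNONYMOUS
        candidates.append((cat, gene.gene_id))
    if not candidates:
        candidates = _noncoding_candidates(idx, v.lg, v.pos)
    cat, gene_id = _pick(candidates, precedence)
    return EffectCall(variant=v, category=cat, gene_id=gene_id)


def _indel_affected_span(v: VariantRecord) -> tuple[int, int]:
    """Reference bases touched by an indel (anchor base for insertions)."""
    if len(v.ref_allele) > len(v.alt_allele):  # deletion
        return (v.pos + len(v.alt_allele), v.pos + len(v.ref_allele) - 1)
    return (v.pos, v.pos)


def classify_indel(v: VariantRecord, ann: GenomeAnnotation,
                   precedence=DEFAULT_PRECEDENCE) -> EffectCall:
    """Classify an indel; CDS-overlapping part decides for junction indels."""
    if v.var_class is not VariantClass.INDEL:
        raise ValueError("classify_indel requires an INDEL record")
    idx = get_effect_index(ann)
    if v.lg not in idx.cds:
        raise ValueError(f"record on LG {v.lg} absent from annotation")
    s, e = _indel_affected_span(v)
    length = v.span_length
    candidates = []
    for iv in idx.cds[v.lg].overlap(s - 1, e):
        gene: GeneModel = iv.data
        if gene.cds_length % 3 != 0:
            raise ValueError(f"gene {gene.gene_id} violates the frame invariant")
        hit_coding = [
            idx.coding_index(gene, p)
            for p in range(max(s, iv.begin + 1), min(e, iv.end) + 1)
        ]
        n = gene.cds_length
        if any(ci < 3 for ci in hit_coding):
            cat = EffectCategory.START_LOST
        elif any(ci >= n - 3 for ci in hit_coding):
            cat = EffectCategory.STOP_LOST
        elif length % 3 != 0:
            cat = EffectCategory.FRAMESHIFT
        else:
            cat = EffectCategory.INFRAME
        candidates.append((cat, gene.gene_id))
    if not candidates:
        candidates = _noncoding_candidates(idx, v.lg, v.pos)
    cat, gene_id = _pick(candidates, precedence)
    return EffectCall(variant=v, category=cat, gene_id=gene_id)


def classify(v: VariantRecord, ann: GenomeAnnotation,
             precedence=DEFAULT_PRECEDENCE) -> EffectCall:
    if v.var_class is VariantClass.SNP:
        return classify_snp(v, ann, precedence)
    if v.var_class is VariantClass.INDEL:
        return classify_indel(v, ann, precedence)
    raise ValueError("effect classification applies to SNPs and indels only")


# ---------------------------------------------------------------------------
# Spectra, densities, summaries


def mod3_spectrum(calls: list[EffectCall], max_len: int = 30) -> pd.DataFrame:
    """Length spectrum of exonic vs genome-wide indels.

    Returns one row per length 1..max_len with the fraction of exonic and
    of all indels having that length (each column sums to 1 minus the mass
    beyond ``max_len``, reported in ``df.attrs['truncated']``).
    """
    if not calls:
        raise ValueError("mod3_spectrum requires at least one indel call")
    lengths = []
    for c in calls:
        if c.variant.var_class is not VariantClass.INDEL:
            raise ValueError("mod3_spectrum accepts indel calls only")
        lengths.append((c.variant.span_length, c.category in EXONIC_CATEGORIES))
    n_all = len(lengths)
    n_ex = sum(1 for _, ex in lengths if ex)
    rows = []
    for L in range(1, max_len + 1):
        all_L = sum(1 for l, _ in lengths if l == L)
        ex_L = sum(1 for l, ex in lengths if l == L and ex)
        rows.append(
            {
                "length": L,
                "exon_fraction": ex_L / n_ex if n_ex else 0.0,
                "genome_fraction": all_L / n_all,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["truncated"] = {
        "exon": 1.0 - df["exon_fraction"].sum() if n_ex else 0.0,
        "genome": 1.0 - df["genome_fraction"].sum(),
    }
    return df


def div3_mass(df: pd.DataFrame, column: str = "exon_fraction") -> float:
    """Total probability mass at lengths divisible by three."""
    sel = df["length"] % 3 == 0
    total = df[column].sum()
    return float(df.loc[sel, column].sum() / total) if total else 0.0


def window_density(records: list[VariantRecord], ann: GenomeAnnotation,
                   window: int = 50_000, step: Optional[int] = None) -> pd.DataFrame:
    """Per-LG variant counts in fixed windows (default non-overlapping 50 kb).

    Windows are [k*step+1, k*step+window] with the last truncated at the LG
    end; with ``step == window`` counts per LG sum to the record total.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    step = step or window
    by_lg: dict[str, list[int]] = {lg: [] for lg in ann.lg_lengths}
    for r in records:
        if r.lg not in ann.lg_lengths:
            raise ValueError(f"record on LG {r.lg} absent from annotation")
        if r.pos > ann.lg_lengths[r.lg]:
            raise ValueError(f"record at {r.lg}:{r.pos} beyond LG length")
        by_lg[r.lg].append(r.pos)
    rows = []
    for lg, L in ann.lg_lengths.items():
        positions = sorted(by_lg[lg])
        start = 1
        while start <= L:
            end = min(start + window - 1, L)
            lo = bisect_left(positions, start)
            hi = bisect_right(positions, end)
            rows.append({"lg": lg, "window_start": start, "window_end": end,
                         "count": hi - lo})
            start += step
    return pd.DataFrame(rows)


#: Row labels of the published per-species summary, SNP block.
SNP_TABLE_ROWS = ("Synonymous", "Non-synonymous", "Upstream", "Downstream",
                  "Intron", "Intergenic")
#: Row labels of the published per-species summary, indel block.
INDEL_TABLE_ROWS = ("Exon", "Upstream", "Downstream", "Intron", "Intergenic")

_SNP_CAT_TO_ROW = {
    EffectCategory.SYNONYMOUS: "Synonymous",
    EffectCategory.NONSYNONYMOUS: "Non-synonymous",
    EffectCategory.UPSTREAM: "Upstream",
    EffectCategory.DOWNSTREAM: "Downstream",
    EffectCategory.INTRON: "Intron",
    EffectCategory.INTERGENIC: "Intergenic",
}


def _indel_row(cat: EffectCategory) -> str:
    return "Exon" if cat in EXONIC_CATEGORIES else _SNP_CAT_TO_ROW[cat]


@dataclass
class CategorySummary:
    """Per-species effect-category table with percentages and the
    non-synonymous/synonymous ratio (1 decimal, as published)."""

    counts: pd.DataFrame       # rows = categories + "Total", cols = species
    percentages: pd.DataFrame  # same shape minus Total, 1 decimal
    ns_s_ratio: dict[str, Optional[float]]


def summary_from_counts(counts_by_species: dict[str, dict[str, int]],
                        rows: tuple[str, ...]) -> CategorySummary:
    """Build the summary from per-category counts (one dict per species)."""
    species = list(counts_by_species)
    counts = pd.DataFrame(
        {sp: [counts_by_species[sp].get(r, 0) for r in rows] for sp in species},
        index=list(rows),
    )
    totals = counts.sum(axis=0)
    counts.loc["Total"] = totals
    pct = (100.0 * counts.loc[list(rows)] / totals).round(1)
    ratio: dict[str, Optional[float]] = {}
    for sp in species:
        syn = counts_by_species[sp].get("Synonymous", 0)
        nonsyn = counts_by_species[sp].get("Non-synonymous", 0)
        ratio[sp] = round(nonsyn / syn, 1) if syn else None
    return CategorySummary(counts=counts, percentages=pct, ns_s_ratio=ratio)


def summarize_categories(
    calls_by_species: dict[str, list[EffectCall]], variant_class: VariantClass
) -> CategorySummary:
    """Tally highest-effect calls per species into the published layout."""
    rows = SNP_TABLE_ROWS if variant_class is VariantClass.SNP else INDEL_TABLE_ROWS
    tallies: dict[str, dict[str, int]] = {}
    for sp, calls in calls_by_species.items():
        tally: dict[str, int] = {}
        for c in calls:
            if c.variant.var_class is not variant_class:
                raise ValueError("mixed variant classes in summarize_categories")
            row = (_SNP_CAT_TO_ROW[c.category]
                   if variant_class is VariantClass.SNP
                   else _indel_row(c.category))
            tally[row] = tally.get(row, 0) + 1
        tallies[sp] = tally
    return summary_from_counts(tallies, rows)
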