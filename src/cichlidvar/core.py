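"""Core domain types shared across the pipeline.

The pipeline compares four East-African cichlid genomes (Neolamprologus
brichardi ``Nb``, Astatotilapia burtoni ``Ab``, Pundamilia nyererei ``Pn``,
Metriaclima zebra ``Mz``) against the Nile Tilapia reference assembly.  All
internal coordinates are 1-based inclusive (VCF convention); BED input/output
is converted at the boundary.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

import dendropy

INGROUP_SPECIES = ("Nb", "Ab", "Pn", "Mz")
REFERENCE_SPECIES = "Tilapia"

#: Rooted species topology of the five sequenced cichlid genomes.
FIXED_TOPOLOGY_NEWICK = "(Tilapia,(Nb,(Ab,(Pn,Mz))));"


class VariantClass(str, enum.Enum):
    SNP = "SNP"
    INDEL = "INDEL"
    INVERSION = "INVERSION"
    DELETION = "DELETION"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Structural-variant classes (interval-valued records with an END).
SV_CLASSES = (VariantClass.INVERSION, VariantClass.DELETION)

#: Minimum structural-variant span in bp.
MIN_SV_SPAN = 50


@dataclass(frozen=True)
class VariantRecord:
    """One called variant in one species.

    ``pos`` is 1-based.  SNP/indel records carry ``ref_allele``/``alt_allele``;
    inversion/deletion records carry a 1-based inclusive ``end``.  ``qual`` is
    the phred-scaled call quality, ``dp`` the site read depth and ``fs`` the
    phred-scaled Fisher strand-bias score.
    """

    species_id: str
    lg: str
    pos: int
    var_class: VariantClass
    ref_allele: str = ""
    alt_allele: str = ""
    end: Optional[int] = None
    qual: Optional[float] = None
    dp: Optional[int] = None
    fs: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.var_class in SV_CLASSES:
            if self.end is None:
                raise ValueError(f"{self.var_class} requires an end coordinate")
            if self.end < self.pos:
                raise ValueError("end < pos for structural variant")
            if self.span_length < MIN_SV_SPAN:
                raise ValueError(
                    f"structural variant span {self.span_length} < {MIN_SV_SPAN} bp"
                )
        elif self.var_class is VariantClass.SNP:
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("SNP alleles must be single bases")
            if self.ref_allele == self.alt_allele:
                raise ValueError("SNP ref == alt")
        elif self.var_class is VariantClass.INDEL:
            if abs(len(self.ref_allele) - len(self.alt_allele)) < 1:
                raise ValueError("indel must change allele length")

    @property
    def is_sv(self) -> bool:
        return self.var_class in SV_CLASSES

    @property
    def span_length(self) -> int:
        """Inclusive span in bp (SV) or |len(ref)-len(alt)| (indel), 1 for SNP."""
        if self.is_sv:
            return self.end - self.pos + 1
        if self.var_class is VariantClass.INDEL:
            return abs(len(self.ref_allele) - len(self.alt_allele))
        return 1

    @property
    def span(self) -> tuple[int, int]:
        """1-based inclusive interval used for interval operations.

        SNPs and indels occupy their anchor position only; insertions
        therefore span a single base.
        """
        if self.is_sv:
            return (self.pos, self.end)
        return (self.pos, self.pos)

    @property
    def key(self):
        """Class-specific identity used for cross-species matching."""
        if self.var_class is VariantClass.SNP:
            return ("SNP", self.lg, self.pos, self.alt_allele)
        if self.var_class is VariantClass.INDEL:
            return ("INDEL", self.lg, self.pos, self.ref_allele, self.alt_allele)
        return (self.var_class.value, self.lg, self.pos, self.end)


@dataclass
class GeneModel:
    """Strand-aware gene model with 1-based inclusive exon and CDS intervals."""

    gene_id: str
    lg: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur[0] <= prev[1]:
                raise ValueError(f"overlapping exons in {self.gene_id}")

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def coding_positions(self) -> list[int]:
        """Genomic positions of coding bases in translation order.

        For minus-strand genes the order runs from the rightmost CDS base
        leftwards; the caller complements bases as needed.
        """
        pos = [p for s, e in self.cds for p in range(s, e + 1)]
        return pos[::-1] if self.strand == "-" else pos


@dataclass
class GenomeAnnotation:
    """Linkage groups, gene models and transposable-element intervals.

    ``te_intervals`` are 0-based half-open (BED convention) as read;
    ``sequences`` optionally maps lg -> nucleotide string for codon lookups.
    """

    lg_lengths: dict[str, int]
    genes: list[GeneModel] = field(default_factory=list)
    te_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g in self.genes:
            L = self.lg_lengths.get(g.lg)
            if L is None:
                raise ValueError(f"gene {g.gene_id} on unknown LG {g.lg}")
            if g.span[1] > L:
                raise ValueError(f"gene {g.gene_id} extends beyond {g.lg} length {L}")
            if g.cds and g.cds_length % 3 != 0:
                raise ValueError(
                    f"gene {g.gene_id} CDS length {g.cds_length} not a multiple of 3"
                )
        for lg, s0, e0 in self.te_intervals:
            L = self.lg_lengths.get(lg)
            if L is None or e0 > L or s0 < 0 or s0 >= e0:
                raise ValueError(f"TE interval ({lg},{s0},{e0}) outside LG bounds")
        self._effect_index = None

    def base(self, lg: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        return self.sequences[lg][pos - 1]


class SpeciesTree:
    """Rooted binary species tree with branch lengths and (after dating) ages.

    Thin wrapper over a :class:`dendropy.Tree`; nodes are addressed by the
    frozenset of descendant leaf labels (their clade).
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        root = tree.seed_node
        for node in tree.preorder_node_iter():
            if node.child_nodes() and len(node.child_nodes()) != 2:
                raise ValueError("tree must be rooted and strictly binary")
        if not root.child_nodes():
            raise ValueError("tree has no internal structure")
        self._index_clades()

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
        return cls(tree)

    def _index_clades(self) -> None:
        self.clades: dict[frozenset, dendropy.Node] = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                node.clade = frozenset([node.taxon.label])
            else:
                node.clade = frozenset().union(*(c.clade for c in node.child_nodes()))
            self.clades[node.clade] = node

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    @property
    def leaf_labels(self) -> set[str]:
        return set(self.root.clade)

    def node(self, leaves: Iterable[str]) -> dendropy.Node:
        key = frozenset(leaves)
        if key not in self.clades:
            raise KeyError(f"no clade with leaf set {sorted(key)}")
        return self.clades[key]

    def ages(self) -> dict[frozenset, float]:
        """Node ages (My before present) keyed by clade; requires dating."""
        out = {}
        for node in self.tree.preorder_node_iter():
            age = getattr(node, "age", None)
            if age is None:
                raise ValueError("tree is not dated; run nprs_date first")
            out[node.clade] = age
        return out

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()
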