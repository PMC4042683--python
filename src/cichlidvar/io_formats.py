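"""Readers and writers for the standard formats the pipeline touches.

VCF is read with :mod:`pysam`; GFF3 with :mod:`gffutils`; FASTA with
:mod:`pyfaidx`; Newick with :mod:`dendropy`.  Written VCF/GFF3/BED are plain
valid text so the same files round-trip through the readers.  Coordinate
conventions: VCF and GFF3 are 1-based inclusive (kept as-is internally), BED
is 0-based half-open (converted on read/write).
"""

from __future__ import annotations

import os
from typing import Iterable, Optional

import gffutils
import pysam
from pyfaidx import Fasta

from .core import (
    GeneModel,
    GenomeAnnotation,
    SpeciesTree,
    VariantClass,
    VariantRecord,
)

_SVTYPE_TO_CLASS = {"INV": VariantClass.INVERSION, "DEL": VariantClass.DELETION}
_CLASS_TO_SVTYPE = {v: k for k, v in _SVTYPE_TO_CLASS.items()}


# ---------------------------------------------------------------------------
# VCF


def parse_variants(path: str, species_id: str) -> list[VariantRecord]:
    """Read a VCF 4.x file into :class:`VariantRecord` objects.

    One record is produced per ALT allele.  Structural variants are
    recognised by the ``SVTYPE`` INFO key (``INV``/``DEL``) and require
    ``END``; other records are typed by allele lengths.  ``DP`` and ``FS``
    are taken from INFO, falling back to the first sample's FORMAT fields.
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(path) as vcf:
        for line_no, rec in enumerate(vcf, start=1):
            try:
                records.extend(_convert_vcf_record(rec, species_id))
            except (ValueError, KeyError) as exc:
                raise ValueError(
                    f"{path}: malformed record {line_no} "
                    f"({rec.chrom}:{rec.pos}): {exc}"
                ) from exc
    return records


def _convert_vcf_record(rec, species_id: str) -> list[VariantRecord]:
    info = rec.info
    dp = info.get("DP")
    fs = info.get("FS")
    if (dp is None or fs is None) and rec.samples:
        sample = rec.samples[0]
        if dp is None:
            dp = sample.get("DP")
        if fs is None:
            fs = sample.get("FS")
    if isinstance(fs, tuple):
        fs = fs[0]
    svtype = info.get("SVTYPE")
    if isinstance(svtype, tuple):
        svtype = svtype[0]
    out = []
    for alt in rec.alts or ():
        if svtype is not None:
            if svtype not in _SVTYPE_TO_CLASS:
                raise ValueError(f"unsupported SVTYPE {svtype}")
            end = info.get("END", rec.stop if rec.stop > rec.pos else None)
            if end is None:
                raise ValueError("SV record lacks END")
            out.append(
                VariantRecord(
                    species_id=species_id, lg=rec.chrom, pos=rec.pos,
                    var_class=_SVTYPE_TO_CLASS[svtype], end=int(end),
                    qual=rec.qual, dp=dp, fs=fs,
                )
            )
        else:
            ref = rec.ref
            var_class = (
                VariantClass.SNP
                if len(ref) == 1 and len(alt) == 1
                else VariantClass.INDEL
            )
            out.append(
                VariantRecord(
                    species_id=species_id, lg=rec.chrom, pos=rec.pos,
                    var_class=var_class, ref_allele=ref, alt_allele=alt,
                    qual=rec.qual, dp=dp, fs=fs,
                )
            )
    return out


VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of structural variant">',
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">',
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Site read depth">',
    '##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled strand-bias p-value">',
]


def write_variants(path: str, records: Iterable[VariantRecord],
                   lg_lengths: Optional[dict[str, int]] = None) -> None:
    """Write records as a single-species VCF 4.2 text file."""
    with open(path, "w") as fh:
        for line in VCF_HEADER_LINES:
            fh.write(line + "\n")
        if lg_lengths:
            for lg, length in lg_lengths.items():
                fh.write(f"##contig=<ID={lg},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in sorted(records, key=lambda r: (r.lg, r.pos)):
            info = []
            if r.is_sv:
                info.append(f"SVTYPE={_CLASS_TO_SVTYPE[r.var_class]}")
                info.append(f"END={r.end}")
                ref, alt = "N", f"<{_CLASS_TO_SVTYPE[r.var_class]}>"
            else:
                ref, alt = r.ref_allele, r.alt_allele
            if r.dp is not None:
                info.append(f"DP={r.dp}")
            if r.fs is not None:
                info.append(f"FS={r.fs:g}")
            qual = f"{r.qual:g}" if r.qual is not None else "."
            fh.write(
                f"{r.lg}\t{r.pos}\t.\t{ref}\t{alt}\t{qual}\t.\t"
                + (";".join(info) or ".") + "\n"
            )


# ---------------------------------------------------------------------------
# Annotation: GFF3 + BED (TEs) + LG length table


def parse_annotation(gff_path: str, te_path: Optional[str], lg_path: str,
                     fasta_path: Optional[str] = None) -> GenomeAnnotation:
    """Assemble a :class:`GenomeAnnotation` from GFF3 + BED + LG-length TSV.

    GFF3 coordinates (1-based inclusive) are kept; BED (0-based half-open)
    intervals are stored unchanged in half-open form.  When a gene has
    several mRNAs the first listed is used.
    """
    lg_lengths = _read_two_column_int(lg_path)
    genes = _genes_from_gff(gff_path)
    te = read_bed(te_path) if te_path else []
    sequences = {}
    if fasta_path:
        with Fasta(fasta_path) as fa:
            sequences = {name: str(fa[name][:]) for name in fa.keys()}
    return GenomeAnnotation(
        lg_lengths=lg_lengths, genes=genes, te_intervals=te, sequences=sequences
    )


def _genes_from_gff(gff_path: str) -> list[GeneModel]:
    db = gffutils.create_db(
        gff_path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for gene in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        parent = mrnas[0] if mrnas else gene
        exons = [(f.start, f.end) for f in db.children(parent, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(parent, featuretype="CDS")]
        if not exons:
            exons = list(cds)
        strand = gene.strand
        if strand not in "+-":
            raise ValueError(f"unknown strand {strand!r} for gene {gene.id}")
        genes.append(
            GeneModel(gene_id=gene.id, lg=gene.seqid, strand=strand,
                      exons=exons, cds=cds)
        )
    return genes


def write_annotation(ann: GenomeAnnotation, gff_path: str, te_path: str,
                     lg_path: str, fasta_path: Optional[str] = None) -> None:
    """Emit the annotation as GFF3 + TE BED + LG TSV (+ optional FASTA)."""
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(ann.genes, key=lambda g: (g.lg, g.span[0])):
            s, e = g.span
            base = f"{g.lg}\tcichlidvar\t"
            fh.write(base + f"gene\t{s}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            mrna = f"{g.gene_id}.t1"
            fh.write(base + f"mRNA\t{s}\t{e}\t.\t{g.strand}\t.\tID={mrna};Parent={g.gene_id}\n")
            for xs, xe in g.exons:
                fh.write(base + f"exon\t{xs}\t{xe}\t.\t{g.strand}\t.\tParent={mrna}\n")
            for cs, ce in g.cds:
                fh.write(base + f"CDS\t{cs}\t{ce}\t.\t{g.strand}\t0\tParent={mrna}\n")
    write_bed(te_path, ann.te_intervals)
    with open(lg_path, "w") as fh:
        for lg, length in ann.lg_lengths.items():
            fh.write(f"{lg}\t{length}\n")
    if fasta_path:
        write_fasta(fasta_path, ann.sequences)


def read_bed(path: str) -> list[tuple[str, int, int]]:
    """Read BED3 intervals (0-based half-open, kept half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            lg, s0, e0 = line.split("\t")[:3]
            out.append((lg, int(s0), int(e0)))
    return out


def write_bed(path: str, intervals: Iterable[tuple[str, int, int]]) -> None:
    with open(path, "w") as fh:
        for lg, s0, e0 in intervals:
            fh.write(f"{lg}\t{s0}\t{e0}\n")


def write_fasta(path: str, sequences: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    # drop any stale pyfaidx index so re-reads see the new content
    for suffix in (".fai",):
        idx = path + suffix
        if os.path.exists(idx):
            os.remove(idx)


def _read_two_column_int(path: str) -> dict[str, int]:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, val = line.split("\t")[:2]
            out[key] = int(val)
    return out


def read_gene2go(path: str) -> dict[str, set[str]]:
    """Two-column TSV gene_id -> GO term (one pair per line)."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            out.setdefault(gene, set()).add(term)
    return out


# ---------------------------------------------------------------------------
# Trees


def parse_tree(path: str) -> SpeciesTree:
    """Read a rooted binary Newick tree with branch lengths."""
    with open(path) as fh:
        return SpeciesTree.from_newick(fh.read())


def write_tree(tree: SpeciesTree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")
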