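"""Synthetic five-genome data generator with recorded ground truth.

Emulates the study system at desk scale: a multi-linkage-group reference
with codon-aware gene models and transposable-element intervals, and
variants of four classes (SNP, indel, inversion, deletion) arising on the
branches of the fixed rooted topology (Tilapia,(Nb,(Ab,(Pn,Mz)))) at
per-branch Poisson rates, with a configurable fraction of homoplasic
variants re-drawn onto non-clade species subsets.  Default branch rates
reproduce the study's qualitative pattern: SNP rates peak on the ingroup
stem, inversion/deletion rates peak on the terminal branches, indel rates
are uniform.  Every emitted variant carries a ground-truth record (branch
of origin, effect category, hard-filter fate, TE overlap) so downstream
recovery is checkable.

Call-quality attributes (qual/dp/fs) are drawn once per variant and shared
by every species carrying it, so hard filtering removes a variant wholesale
and the truth bookkeeping stays exact.
"""

from __future__ import annotations

import os
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio.Seq import Seq

from . import io_formats
from .core import (
    GeneModel,
    GenomeAnnotation,
    INGROUP_SPECIES,
    REFERENCE_SPECIES,
    SpeciesTree,
    VariantClass,
    VariantRecord,
)
from .phylo import EXCLUDED, branch_label
from .sv import SVCallSet

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
_STOPS = ("TAA", "TAG", "TGA")

#: The seven branches of the ingroup subtree, tipward to rootward.
BRANCH_CLADES: dict[str, frozenset] = {
    "Nb": frozenset({"Nb"}),
    "Ab": frozenset({"Ab"}),
    "Pn": frozenset({"Pn"}),
    "Mz": frozenset({"Mz"}),
    "anc(Pn,Mz)": frozenset({"Pn", "Mz"}),
    "anc(Ab,Pn,Mz)": frozenset({"Ab", "Pn", "Mz"}),
    "anc(Nb,Ab,Pn,Mz)": frozenset({"Nb", "Ab", "Pn", "Mz"}),
}

#: All non-empty ingroup subsets that are NOT clades (homoplasy patterns).
NON_CLADE_SUBSETS: list[frozenset] = sorted(
    (
        frozenset(s)
        for s in (
            {"Nb", "Ab"}, {"Nb", "Pn"}, {"Nb", "Mz"}, {"Ab", "Pn"}, {"Ab", "Mz"},
            {"Nb", "Ab", "Pn"}, {"Nb", "Ab", "Mz"}, {"Nb", "Pn", "Mz"},
        )
    ),
    key=lambda s: (len(s), sorted(s)),
)


def _default_rates() -> dict[str, dict[str, float]]:
    """Per-branch event rates (events/My), shaped like the study's pattern."""
    snp = {"Nb": 80.0, "Ab": 110.0, "Pn": 150.0, "Mz": 200.0,
           "anc(Pn,Mz)": 270.0, "anc(Ab,Pn,Mz)": 360.0,
           "anc(Nb,Ab,Pn,Mz)": 500.0}
    indel = {b: 60.0 for b in BRANCH_CLADES}
    deletion = {"anc(Nb,Ab,Pn,Mz)": 30.0, "anc(Ab,Pn,Mz)": 45.0,
                "anc(Pn,Mz)": 60.0, "Nb": 90.0, "Ab": 120.0,
                "Pn": 160.0, "Mz": 210.0}
    inversion = {"anc(Nb,Ab,Pn,Mz)": 25.0, "anc(Ab,Pn,Mz)": 40.0,
                 "anc(Pn,Mz)": 55.0, "Nb": 75.0, "Ab": 100.0,
                 "Pn": 140.0, "Mz": 190.0}
    return {"SNP": snp, "INDEL": indel, "DELETION": deletion,
            "INVERSION": inversion}


def scaled_rates(factor: float) -> dict[str, dict[str, float]]:
    """Default rate table uniformly scaled (for smaller problem sizes)."""
    return {cls: {b: lam * factor for b, lam in per_branch.items()}
            for cls, per_branch in _default_rates().items()}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genomes.

    Node ages (My): ingroup root 12, anc(Ab,Pn,Mz) 8, anc(Pn,Mz) 2.3 (the
    published calibration); Tilapia split 20.  Branch lengths on the emitted
    tree are clock-like (``subst_rate_per_my`` substitutions/site/My).
    """

    n_lg: int = 4
    lg_length: int = 2_000_000
    n_genes: int = 80
    te_fraction: float = 0.15
    tilapia_split_my: float = 20.0
    ingroup_root_my: float = 12.0
    anc_abpnmz_my: float = 8.0
    anc_pnmz_my: float = 2.3
    subst_rate_per_my: float = 1e-3
    rates: dict[str, dict[str, float]] = field(default_factory=_default_rates)
    rate_scale: float = 1.0
    homoplasy_fraction: float = 0.05
    exon_inframe_bias: float = 0.8
    p_exonic_indel: float = 0.1
    indel_max_len: int = 10
    sv_min_len: int = 51
    sv_max_len: int = 2_000
    fail_qual_fraction: float = 0.02
    fail_dp_fraction: float = 0.02
    fail_fs_fraction: float = 0.02
    n_artifact_svs: int = 25
    n_go_terms: int = 25

    def __post_init__(self) -> None:
        if self.rate_scale != 1.0:
            if self.rate_scale < 0:
                raise ValueError("rate_scale must be non-negative")
            self.rates = {
                cls: {b: lam * self.rate_scale for b, lam in per_branch.items()}
                for cls, per_branch in self.rates.items()
            }
            self.rate_scale = 1.0
        if not (0.0 <= self.homoplasy_fraction <= 1.0):
            raise ValueError("homoplasy_fraction must lie in [0, 1]")
        if not (self.tilapia_split_my > self.ingroup_root_my
                > self.anc_abpnmz_my > self.anc_pnmz_my > 0):
            raise ValueError("node ages inconsistent with the topology")
        for cls, per_branch in self.rates.items():
            if any(v < 0 for v in per_branch.values()):
                raise ValueError(f"negative rate for {cls}")

    def node_ages(self) -> dict[frozenset, float]:
        return {
            frozenset(INGROUP_SPECIES) | {REFERENCE_SPECIES}: self.tilapia_split_my,
            frozenset(INGROUP_SPECIES): self.ingroup_root_my,
            frozenset({"Ab", "Pn", "Mz"}): self.anc_abpnmz_my,
            frozenset({"Pn", "Mz"}): self.anc_pnmz_my,
            **{frozenset({sp}): 0.0 for sp in INGROUP_SPECIES},
            frozenset({REFERENCE_SPECIES}): 0.0,
        }

    def branch_durations(self) -> dict[str, float]:
        ages = self.node_ages()
        parent = {
            "Nb": frozenset(INGROUP_SPECIES),
            "Ab": frozenset({"Ab", "Pn", "Mz"}),
            "Pn": frozenset({"Pn", "Mz"}),
            "Mz": frozenset({"Pn", "Mz"}),
            "anc(Pn,Mz)": frozenset({"Ab", "Pn", "Mz"}),
            "anc(Ab,Pn,Mz)": frozenset(INGROUP_SPECIES),
            "anc(Nb,Ab,Pn,Mz)": frozenset(INGROUP_SPECIES) | {REFERENCE_SPECIES},
        }
        return {
            label: ages[parent[label]] - ages[BRANCH_CLADES[label]]
            for label in BRANCH_CLADES
        }


def true_tree_newick(cfg: SimulationConfig) -> str:
    """Clock-like Newick for the fixed topology at the configured ages."""
    r = cfg.subst_rate_per_my
    d = cfg.branch_durations()
    return (
        f"({REFERENCE_SPECIES}:{cfg.tilapia_split_my * r:.10f},"
        f"(Nb:{cfg.ingroup_root_my * r:.10f},"
        f"(Ab:{cfg.anc_abpnmz_my * r:.10f},"
        f"(Pn:{cfg.anc_pnmz_my * r:.10f},Mz:{cfg.anc_pnmz_my * r:.10f})"
        f":{d['anc(Pn,Mz)'] * r:.10f})"
        f":{d['anc(Ab,Pn,Mz)'] * r:.10f})"
        f":{d['anc(Nb,Ab,Pn,Mz)'] * r:.10f});"
    )


def true_tree(cfg: SimulationConfig) -> SpeciesTree:
    return SpeciesTree.from_newick(true_tree_newick(cfg))


# ---------------------------------------------------------------------------
# Annotation


def simulate_annotation(cfg: SimulationConfig,
                        rng: np.random.Generator) -> GenomeAnnotation:
    """Random reference with codon-aware multi-exon genes and TE intervals.

    Gene CDSs start with ATG, contain no internal stop and end with a stop
    codon; CDS length is a positive multiple of 3.  TE intervals are placed
    outside gene spans until coverage reaches ``te_fraction`` per LG.
    """
    lg_names = [f"LG{i + 1}" for i in range(cfg.n_lg)]
    lg_lengths = {lg: cfg.lg_length for lg in lg_names}
    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
    sequences = {
        lg: base_bytes[rng.integers(0, 4, size=cfg.lg_length, dtype=np.uint8)].copy()
        for lg in lg_names
    }
    genes: list[GeneModel] = []
    per_lg = np.array_split(np.arange(cfg.n_genes), cfg.n_lg)
    for lg, idxs in zip(lg_names, per_lg):
        cursor = 1 + int(rng.integers(2_000, 5_000))
        for gi in idxs:
            n_codons = int(rng.integers(50, 201))
            cds_seq = _random_cds(rng, n_codons)
            n_exons = int(rng.integers(1, 5))
            strand = "+" if rng.random() < 0.5 else "-"
            exons, total_span = _split_exons(rng, len(cds_seq), n_exons, cursor)
            if exons[-1][1] + 10_000 > cfg.lg_length:
                raise ValueError(
                    f"cannot pack {cfg.n_genes} genes into LGs of "
                    f"{cfg.lg_length} bp"
                )
            gene = GeneModel(
                gene_id=f"gene{gi + 1:04d}", lg=lg, strand=strand,
                exons=exons, cds=list(exons),
            )
            _write_cds_into_genome(sequences[lg], gene, cds_seq)
            genes.append(gene)
            cursor = exons[-1][1] + int(rng.integers(12_000, 24_000))
    ann = GenomeAnnotation(
        lg_lengths=lg_lengths,
        genes=genes,
        te_intervals=[],
        sequences={lg: seq.tobytes().decode("ascii")
                   for lg, seq in sequences.items()},
    )
    ann.te_intervals = _place_tes(cfg, rng, ann)
    # re-validate TE bounds after the late assignment
    return GenomeAnnotation(
        lg_lengths=ann.lg_lengths, genes=ann.genes,
        te_intervals=ann.te_intervals, sequences=ann.sequences,
    )


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
    need = n_codons - 2
    codons: list[str] = []
    while len(codons) < need:
        draw = base_bytes[
            rng.integers(0, 4, size=(need - len(codons) + 8, 3), dtype=np.uint8)
        ]
        for row in draw:
            c = row.tobytes().decode("ascii")
            if c not in _STOPS and len(codons) < need:
                codons.append(c)
    return "ATG" + "".join(codons) + _STOPS[int(rng.integers(0, 3))]


def _split_exons(rng: np.random.Generator, cds_len: int, n_exons: int,
                 start: int) -> tuple[list[tuple[int, int]], int]:
    if n_exons > 1:
        cuts = sorted(rng.choice(np.arange(1, cds_len), size=n_exons - 1,
                                 replace=False))
    else:
        cuts = []
    pieces = np.diff([0, *map(int, cuts), cds_len])
    exons = []
    pos = start
    for piece in pieces:
        exons.append((pos, pos + int(piece) - 1))
        pos += int(piece) + int(rng.integers(100, 501))
    return exons, exons[-1][1] - start + 1


def _write_cds_into_genome(seq: np.ndarray, gene: GeneModel, cds_seq: str) -> None:
    positions = np.asarray(gene.coding_positions(), dtype=np.int64) - 1
    bases = cds_seq if gene.strand == "+" else "".join(
        _COMPLEMENT[b] for b in cds_seq)
    seq[positions] = np.frombuffer(bases.encode("ascii"), dtype=np.uint8)


def _place_tes(cfg: SimulationConfig, rng: np.random.Generator,
               ann: GenomeAnnotation) -> list[tuple[str, int, int]]:
    if cfg.te_fraction <= 0:
        return []
    te = []
    for lg, L in ann.lg_lengths.items():
        spans = sorted(g.span for g in ann.genes if g.lg == lg)
        covered = 0
        target = cfg.te_fraction * L
        occupied = [(s - 1, e) for s, e in spans]  # half-open
        attempts = 0
        while covered < target and attempts < 100_000:
            attempts += 1
            length = int(rng.integers(200, 2001))
            s0 = int(rng.integers(0, L - length))
            e0 = s0 + length
            if any(s0 < oe and os_ < e0 for os_, oe in occupied):
                continue
            occupied.append((s0, e0))
            te.append((lg, s0, e0))
            covered += length
    return sorted(te)


def simulate_gene2go(cfg: SimulationConfig, ann: GenomeAnnotation,
                     rng: np.random.Generator) -> dict[str, set[str]]:
    """Random gene -> GO map (1-4 terms per gene from a fixed pool)."""
    terms = [f"GO:{7000 + i:07d}" for i in range(cfg.n_go_terms)]
    out = {}
    for g in ann.genes:
        k = int(rng.integers(1, 5))
        out[g.gene_id] = set(rng.choice(terms, size=k, replace=False))
    return out


# ---------------------------------------------------------------------------
# Variants


@dataclass
class TruthRecord:
    branch: str                   # branch label or EXCLUDED (homoplasy) or ARTIFACT
    species: frozenset
    category: Optional[str]       # effect category for SNP/indel, else None
    passes_filters: bool
    fail_reasons: tuple[str, ...]
    te_overlap: bool


@dataclass
class GroundTruth:
    records: dict[tuple, TruthRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    annotation: GenomeAnnotation
    per_species: dict[str, list[VariantRecord]]
    truth: GroundTruth
    reference_self_calls: SVCallSet
    tree_newick: str
    gene2go: dict[str, set[str]]


class _TruthIndex:
    """Per-LG precomputed gene/TE lookups for generator-side truth."""

    def __init__(self, ann: GenomeAnnotation):
        self.genes: dict[str, list[dict]] = {lg: [] for lg in ann.lg_lengths}
        for g in ann.genes:
            cp = g.coding_positions()
            self.genes[g.lg].append({
                "gene": g, "span": g.span, "cp": cp,
                "idx_of": {p: i for i, p in enumerate(cp)}, "n": len(cp),
            })
        self.te: dict[str, tuple[list[int], list[int]]] = {}
        for lg in ann.lg_lengths:
            ivs = sorted((s0, e0) for l, s0, e0 in ann.te_intervals if l == lg)
            self.te[lg] = ([s for s, _ in ivs], [e for _, e in ivs])


def simulate_variants(cfg: SimulationConfig, ann: GenomeAnnotation,
                      rng: np.random.Generator) -> SimulatedDataset:
    """Draw variants on the fixed topology and record full ground truth."""
    durations = cfg.branch_durations()
    truth = GroundTruth()
    per_species: dict[str, list[VariantRecord]] = {sp: [] for sp in INGROUP_SPECIES}
    lg_names = sorted(ann.lg_lengths)
    used_positions: set[tuple[str, int]] = set()
    sv_registry: dict[tuple[str, VariantClass], list[tuple[int, int]]] = {}
    tidx = _TruthIndex(ann)
    total = 0
    for label in BRANCH_CLADES:
        for vc in VariantClass:
            lam = cfg.rates.get(vc.value, {}).get(label, 0.0) * durations[label]
            n = int(rng.poisson(lam))
            for _ in range(n):
                total += 1
                _emit_variant(cfg, ann, rng, vc, label, per_species, truth,
                              lg_names, used_positions, tidx, sv_registry)
    if total == 0:
        raise ValueError("configuration produced zero variants")
    ref_self = _emit_artifacts(cfg, ann, rng, per_species, truth, lg_names,
                               used_positions, tidx, sv_registry)
    for sp in per_species:
        per_species[sp].sort(key=lambda r: (r.lg, r.pos))
    return SimulatedDataset(
        config=cfg, annotation=ann, per_species=per_species, truth=truth,
        reference_self_calls=ref_self, tree_newick=true_tree_newick(cfg),
        gene2go=simulate_gene2go(cfg, ann, rng),
    )


def _emit_variant(cfg, ann, rng, vc, label, per_species, truth, lg_names,
                  used, tidx, sv_registry) -> None:
    lg = lg_names[int(rng.integers(0, len(lg_names)))]
    seq = ann.sequences[lg]
    L = ann.lg_lengths[lg]
    if vc is VariantClass.SNP:
        pos = _fresh_position(rng, lg, 1, L, used)
        ref = seq[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        rec_args = dict(lg=lg, pos=pos, var_class=vc, ref_allele=ref,
                        alt_allele=alt)
        span = (pos, pos)
    elif vc is VariantClass.INDEL:
        rec_args, span = _draw_indel(cfg, ann, rng, lg, used)
        pos = rec_args["pos"]
    else:
        pos, end = _place_sv(cfg, rng, lg, L, vc, sv_registry, cfg.sv_max_len)
        rec_args = dict(lg=lg, pos=pos, var_class=vc, end=end)
        span = (pos, end)
    qual, dp, fs, passes, reasons = _draw_quality(cfg, rng)
    # sharing pattern: the branch's clade, or a homoplasic subset
    if rng.random() < cfg.homoplasy_fraction:
        species = NON_CLADE_SUBSETS[int(rng.integers(0, len(NON_CLADE_SUBSETS)))]
        branch = EXCLUDED
    else:
        species = BRANCH_CLADES[label]
        branch = label
    te_hit = _overlaps_te(tidx, lg, span)
    category = (_truth_effect(tidx, ann, rec_args) if vc in
                (VariantClass.SNP, VariantClass.INDEL) else None)
    proto = VariantRecord(species_id="truth", **rec_args, qual=qual, dp=dp, fs=fs)
    truth.records[proto.key] = TruthRecord(
        branch=branch, species=species, category=category,
        passes_filters=passes, fail_reasons=tuple(reasons), te_overlap=te_hit,
    )
    for sp in sorted(species):
        per_species[sp].append(
            VariantRecord(species_id=sp, **rec_args, qual=qual, dp=dp, fs=fs)
        )


def _place_sv(cfg, rng, lg, L, vc, sv_registry, max_len,
              max_tries: int = 500) -> tuple[int, int]:
    """Draw a log-uniform SV span that overlaps no same-class span.

    Distinct events never share sequence of the same class, mirroring the
    no-recurrent-mutation rule, so truth and interval clustering stay
    unambiguous.
    """
    intervals = sv_registry.setdefault((lg, vc), [])
    for _ in range(max_tries):
        length = int(np.exp(rng.uniform(np.log(cfg.sv_min_len),
                                        np.log(min(max_len, L // 2)))))
        pos = int(rng.integers(1, L - length + 1))
        end = pos + length - 1
        i = bisect_right([e for _, e in intervals], pos - 1)
        if i < len(intervals) and intervals[i][0] <= end:
            continue
        intervals.insert(i, (pos, end))
        return pos, end
    raise RuntimeError("could not place a non-overlapping structural variant")


def _fresh_position(rng, lg, lo, hi, used, max_tries: int = 1000) -> int:
    for _ in range(max_tries):
        pos = int(rng.integers(lo, hi + 1))
        if (lg, pos) not in used:
            used.add((lg, pos))
            return pos
    raise RuntimeError("could not find an unused position")


def _draw_indel(cfg, ann, rng, lg, used):
    seq = ann.sequences[lg]
    L = ann.lg_lengths[lg]
    exonic = rng.random() < cfg.p_exonic_indel
    if exonic:
        cds_genes = [g for g in ann.genes if g.lg == lg and g.cds]
        g = cds_genes[int(rng.integers(0, len(cds_genes)))]
        cp = g.coding_positions()
        # keep away from the first/last codon so mod-3 semantics dominate
        interior = sorted(cp[3:-3])
        pos = None
        for _ in range(100):
            cand = interior[int(rng.integers(0, len(interior) - cfg.indel_max_len))]
            if (lg, cand) not in used:
                pos = cand
                used.add((lg, cand))
                break
        if pos is None:
            pos = _fresh_position(rng, lg, 1, L - cfg.indel_max_len - 1, used)
        if rng.random() < cfg.exon_inframe_bias:
            length = 3 * int(rng.integers(1, cfg.indel_max_len // 3 + 1))
        else:
            length = int(rng.integers(1, cfg.indel_max_len + 1))
    else:
        pos = _fresh_position(rng, lg, 1, L - cfg.indel_max_len - 1, used)
        length = int(rng.integers(1, cfg.indel_max_len + 1))
    if rng.random() < 0.5:  # deletion
        ref = seq[pos - 1: pos + length]
        alt = seq[pos - 1]
    else:  # insertion
        ref = seq[pos - 1]
        alt = ref + "".join(rng.choice(_BASES, size=length))
    args = dict(lg=lg, pos=pos, var_class=VariantClass.INDEL,
                ref_allele=ref, alt_allele=alt)
    return args, (pos, pos)


def _draw_quality(cfg, rng):
    reasons = []
    if rng.random() < cfg.fail_qual_fraction:
        qual = float(rng.uniform(1.0, 29.5))
        reasons.append("low_qual")
    else:
        qual = float(rng.uniform(35.0, 90.0))
    if rng.random() < cfg.fail_dp_fraction:
        dp = int(rng.integers(1, 6)) if rng.random() < 0.5 else int(rng.integers(5001, 6001))
        reasons.append("bad_depth")
    else:
        dp = int(np.clip(rng.poisson(25), 6, 5000))
    if rng.random() < cfg.fail_fs_fraction:
        fs = float(rng.uniform(210.0, 400.0))
        reasons.append("strand_bias")
    else:
        fs = float(rng.uniform(0.0, 50.0))
    return qual, dp, fs, not reasons, reasons


def _overlaps_te(tidx: "_TruthIndex", lg: str, span: tuple[int, int]) -> bool:
    s, e = span
    starts, ends = tidx.te[lg]
    # TE intervals are disjoint and sorted: the only candidate is the first
    # interval ending beyond the query start
    i = bisect_right(ends, s - 1)
    return i < len(starts) and starts[i] < e


def _truth_effect(tidx: "_TruthIndex", ann: GenomeAnnotation,
                  rec_args: dict) -> str:
    """Generator-side effect truth via linear scans over gene models.

    Deliberately simple and structurally independent of the interval-tree
    classifier it is used to check.
    """
    lg, pos = rec_args["lg"], rec_args["pos"]
    vc = rec_args["var_class"]
    ref, alt = rec_args.get("ref_allele", ""), rec_args.get("alt_allele", "")
    genes = tidx.genes[lg]
    if vc is VariantClass.SNP or len(ref) <= len(alt):
        affected = (pos, pos)
    else:
        affected = (pos + len(alt), pos + len(ref) - 1)
    best = None
    severity = ["START_LOST", "STOP_LOST", "FRAMESHIFT", "NONSYNONYMOUS",
                "INFRAME", "SYNONYMOUS", "INTRON", "UPSTREAM", "DOWNSTREAM",
                "INTERGENIC"]

    def better(cat):
        nonlocal best
        if best is None or severity.index(cat) < severity.index(best):
            best = cat

    for entry in genes:
        g = entry["gene"]
        gs, ge = entry["span"]
        if affected[1] < gs - 5000 or affected[0] > ge + 5000:
            continue
        idx_of = entry["idx_of"]
        hit = [idx_of[p] for p in range(affected[0], affected[1] + 1)
               if p in idx_of]
        if hit:
            if vc is VariantClass.INDEL:
                n = entry["n"]
                if any(i < 3 for i in hit):
                    better("START_LOST")
                elif any(i >= n - 3 for i in hit):
                    better("STOP_LOST")
                elif abs(len(ref) - len(alt)) % 3 != 0:
                    better("FRAMESHIFT")
                else:
                    better("INFRAME")
            else:
                i = idx_of[pos]
                codon_idx, off = divmod(i, 3)
                cp = entry["cp"]
                codon = [ann.base(lg, p)
                         for p in cp[3 * codon_idx: 3 * codon_idx + 3]]
                if g.strand == "-":
                    codon = [_COMPLEMENT[b] for b in codon]
                alt_b = alt if g.strand == "+" else _COMPLEMENT[alt]
                mutated = codon.copy()
                mutated[off] = alt_b
                same = str(Seq("".join(codon)).translate()) == str(
                    Seq("".join(mutated)).translate())
                better("SYNONYMOUS" if same else "NONSYNONYMOUS")
            continue
        if gs <= pos <= ge:
            better("INTRON")
    if best is None or best in ("UPSTREAM", "DOWNSTREAM"):
        for entry in genes:
            g = entry["gene"]
            gs, ge = entry["span"]
            if gs <= pos <= ge or pos < gs - 5000 or pos > ge + 5000:
                continue
            five = (gs - 5000, gs - 1) if g.strand == "+" else (ge + 1, ge + 5000)
            three = (ge + 1, ge + 5000) if g.strand == "+" else (gs - 5000, gs - 1)
            if five[0] <= pos <= five[1]:
                better("UPSTREAM")
            if three[0] <= pos <= three[1]:
                better("DOWNSTREAM")
    return best or "INTERGENIC"


def _emit_artifacts(cfg, ann, rng, per_species, truth, lg_names, used,
                    tidx, sv_registry) -> SVCallSet:
    """Assembly artefacts: SVs present in the reference self-calls AND in
    every species call set (all genomes map to the same flawed reference)."""
    calls = []
    for _ in range(cfg.n_artifact_svs):
        lg = lg_names[int(rng.integers(0, len(lg_names)))]
        L = ann.lg_lengths[lg]
        vc = VariantClass.DELETION if rng.random() < 0.5 else VariantClass.INVERSION
        pos, end = _place_sv(cfg, rng, lg, L, vc, sv_registry, cfg.sv_max_len)
        qual, dp, fs, passes, reasons = _draw_quality(cfg, rng)
        args = dict(lg=lg, pos=pos, var_class=vc, end=end)
        proto = VariantRecord(species_id=REFERENCE_SPECIES, **args,
                              qual=qual, dp=dp, fs=fs)
        calls.append(proto)
        truth.records[proto.key] = TruthRecord(
            branch="ARTIFACT", species=frozenset(INGROUP_SPECIES),
            category=None, passes_filters=passes,
            fail_reasons=tuple(reasons),
            te_overlap=_overlaps_te(tidx, lg, (pos, end)),
        )
        for sp in INGROUP_SPECIES:
            per_species[sp].append(
                VariantRecord(species_id=sp, **args, qual=qual, dp=dp, fs=fs)
            )
    return SVCallSet(REFERENCE_SPECIES, calls, "merged")


# ---------------------------------------------------------------------------
# Top-level convenience


def simulate_dataset(cfg: Optional[SimulationConfig] = None,
                     seed: int = 0) -> SimulatedDataset:
    """Generate annotation + variants + truth under one seed."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(seed)
    ann = simulate_annotation(cfg, rng)
    return simulate_variants(cfg, ann, rng)


def write_dataset(ds: SimulatedDataset, outdir: str) -> dict[str, str]:
    """Write the dataset in the exact formats the parsers read."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    ann = ds.annotation
    paths["gff"] = os.path.join(outdir, "annotation.gff3")
    paths["te"] = os.path.join(outdir, "te.bed")
    paths["lg"] = os.path.join(outdir, "lg_lengths.tsv")
    paths["fasta"] = os.path.join(outdir, "reference.fa")
    io_formats.write_annotation(ann, paths["gff"], paths["te"], paths["lg"],
                                fasta_path=paths["fasta"])
    paths["tree"] = os.path.join(outdir, "species_tree.nwk")
    with open(paths["tree"], "w") as fh:
        fh.write(ds.tree_newick + "\n")
    for sp, records in ds.per_species.items():
        p = os.path.join(outdir, f"{sp}.vcf")
        io_formats.write_variants(p, records, ann.lg_lengths)
        paths[f"vcf_{sp}"] = p
    paths["ref_self"] = os.path.join(outdir, "Tilapia_self.vcf")
    io_formats.write_variants(paths["ref_self"], ds.reference_self_calls.calls,
                              ann.lg_lengths)
    paths["gene2go"] = os.path.join(outdir, "gene2go.tsv")
    with open(paths["gene2go"], "w") as fh:
        for gene in sorted(ds.gene2go):
            for term in sorted(ds.gene2go[gene]):
                fh.write(f"{gene}\t{term}\n")
    paths["truth"] = os.path.join(outdir, "ground_truth.tsv")
    with open(paths["truth"], "w") as fh:
        fh.write("key\tbranch\tspecies\tcategory\tpasses_filters\t"
                 "fail_reasons\tte_overlap\n")
        for key in sorted(ds.truth.records, key=str):
            t = ds.truth.records[key]
            fh.write(
                "|".join(map(str, key)) + f"\t{t.branch}\t"
                + ",".join(sorted(t.species)) + f"\t{t.category or '.'}\t"
                + f"{int(t.passes_filters)}\t"
                + (",".join(t.fail_reasons) or ".") + f"\t{int(t.te_overlap)}\n"
            )
    return paths
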