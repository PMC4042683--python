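"""Hard filters and transposable-element exclusion.

The hard filter reproduces the study's GATK-style thresholds: phred quality
strictly greater than 30, site depth between 6 and 5000 inclusive, and
Fisher strand bias strictly below 200.  Variants overlapping annotated
transposable-element intervals by at least 1 bp are excluded, structural
variants included.
"""

from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree

from .core import GenomeAnnotation, VariantRecord


@dataclass(frozen=True)
class FilterThresholds:
    """Hard-filter thresholds (defaults are the study values)."""

    min_qual: float = 30.0   # strict >
    min_dp: int = 6          # inclusive
    max_dp: int = 5000       # inclusive
    max_fs: float = 200.0    # strict <

    def __post_init__(self) -> None:
        if self.min_dp > self.max_dp:
            raise ValueError("min_dp > max_dp")
        if min(self.min_qual, self.min_dp, self.max_fs) < 0:
            raise ValueError("thresholds must be non-negative")


def failure_reasons(rec: VariantRecord, thr: FilterThresholds) -> list[str]:
    """Every hard-filter criterion the record fails (empty list = pass)."""
    reasons = []
    if rec.qual is None or rec.dp is None or rec.fs is None:
        reasons.append("missing_field")
    if rec.qual is not None and not rec.qual > thr.min_qual:
        reasons.append("low_qual")
    if rec.dp is not None and not (thr.min_dp <= rec.dp <= thr.max_dp):
        reasons.append("bad_depth")
    if rec.fs is not None and not rec.fs < thr.max_fs:
        reasons.append("strand_bias")
    return reasons


def hard_filter(
    records: list[VariantRecord], thr: FilterThresholds = FilterThresholds()
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, list[str]]]]:
    """Partition records into (kept, rejected-with-reasons).

    A record is kept iff qual > min_qual, min_dp <= dp <= max_dp and
    fs < max_fs.  Records with any of qual/dp/fs missing are rejected with
    reason ``missing_field``, never silently kept.
    """
    kept, rejected = [], []
    for rec in records:
        reasons = failure_reasons(rec, thr)
        if reasons:
            rejected.append((rec, reasons))
        else:
            kept.append(rec)
    return kept, rejected


def build_te_index(ann: GenomeAnnotation) -> dict[str, IntervalTree]:
    """Per-LG interval trees over TE intervals (kept 0-based half-open)."""
    trees: dict[str, IntervalTree] = {lg: IntervalTree() for lg in ann.lg_lengths}
    for lg, s0, e0 in ann.te_intervals:
        trees[lg].addi(s0, e0)
    return trees


def exclude_te(
    records: list[VariantRecord], ann: GenomeAnnotation
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Partition records into (kept, excluded) by >=1 bp TE overlap.

    SNPs and indels are tested at their anchor position; structural
    variants over their whole [pos, end] span (partial overlap counts).
    """
    trees = build_te_index(ann)
    kept, excluded = [], []
    for rec in records:
        if rec.lg not in trees:
            raise ValueError(f"record on LG {rec.lg} absent from annotation")
        s, e = rec.span  # 1-based inclusive -> half-open query
        if trees[rec.lg].overlap(s - 1, e):
            excluded.append(rec)
        else:
            kept.append(rec)
    return kept, excluded
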