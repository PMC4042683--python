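"""Structural-variant consolidation and summary statistics.

Covers the reference self-consistency filter (SVs also called when the
reference species' reads are mapped back to its own assembly are treated as
assembly artefacts), merging of paired-end and mate-pair call sets
(mergeBed semantics), multi-way cross-species overlap, gene overlap, the
generalized ESD outlier test on length-normalized per-LG counts, and GO
enrichment of affected genes (one-sided Fisher with Benjamini-Hochberg FDR).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GenomeAnnotation, SV_CLASSES, VariantClass, VariantRecord


@dataclass
class SVCallSet:
    """Structural-variant calls of one species from one library type."""

    species_id: str
    calls: list[VariantRecord] = field(default_factory=list)
    provenance: str = "merged"  # paired_end | mate_pair | merged

    def __post_init__(self) -> None:
        for c in self.calls:
            if c.var_class not in SV_CLASSES:
                raise ValueError("SVCallSet accepts inversions/deletions only")
        self.calls = sorted(self.calls, key=lambda c: (c.lg, c.pos, c.end))

    def by_class(self, var_class: VariantClass) -> list[VariantRecord]:
        return [c for c in self.calls if c.var_class is var_class]


def _interval_index(calls: list[VariantRecord]) -> dict[tuple[str, VariantClass], IntervalTree]:
    trees: dict[tuple[str, VariantClass], IntervalTree] = {}
    for c in calls:
        trees.setdefault((c.lg, c.var_class), IntervalTree()).addi(c.pos - 1, c.end)
    return trees


def self_consistency_filter(
    calls: SVCallSet, reference_self_calls: SVCallSet
) -> tuple[SVCallSet, SVCallSet]:
    """Drop calls overlapping (>=1 bp, same class) a reference self-call."""
    trees = _interval_index(reference_self_calls.calls)
    kept, removed = [], []
    for c in calls.calls:
        tree = trees.get((c.lg, c.var_class))
        if tree is not None and tree.overlap(c.pos - 1, c.end):
            removed.append(c)
        else:
            kept.append(c)
    return (
        SVCallSet(calls.species_id, kept, calls.provenance),
        SVCallSet(calls.species_id, removed, calls.provenance),
    )


def merge_library_calls(pe: SVCallSet, mp: SVCallSet,
                        merge_distance: int = 0) -> SVCallSet:
    """Union of two call sets with mergeBed semantics.

    Same-class intervals that overlap or are within ``merge_distance`` bp
    (0 = bookended) coalesce to their envelope.
    """
    if pe.species_id != mp.species_id:
        raise ValueError("merge_library_calls requires call sets of one species")
    merged: list[VariantRecord] = []
    pool = pe.calls + mp.calls
    for var_class in SV_CLASSES:
        per_lg: dict[str, list[VariantRecord]] = {}
        for c in pool:
            if c.var_class is var_class:
                per_lg.setdefault(c.lg, []).append(c)
        for lg, calls in per_lg.items():
            calls.sort(key=lambda c: (c.pos, c.end))
            cur = calls[0]
            for nxt in calls[1:]:
                if nxt.pos <= cur.end + 1 + merge_distance:
                    if nxt.end > cur.end:
                        cur = replace(cur, end=nxt.end)
                else:
                    merged.append(cur)
                    cur = nxt
            merged.append(cur)
    return SVCallSet(pe.species_id, merged, "merged")


@dataclass(frozen=True)
class OverlapRegion:
    lg: str
    start: int  # 1-based inclusive
    end: int
    var_class: VariantClass
    species: frozenset[str]


def multiway_overlap(callsets: list[SVCallSet], min_species: int = 2) -> list[OverlapRegion]:
    """Maximal regions covered by same-class calls of >= min_species species.

    A sweep over interval breakpoints tracks which species cover each
    elementary segment; adjacent segments with the same species set merge.
    """
    if len(callsets) < 2:
        raise ValueError("multiway_overlap requires at least two call sets")
    if min_species > len(callsets):
        raise ValueError("min_species exceeds the number of call sets")
    out: list[OverlapRegion] = []
    for var_class in SV_CLASSES:
        per_lg: dict[str, list[tuple[int, int, str]]] = {}
        for cs in callsets:
            for c in cs.by_class(var_class):
                per_lg.setdefault(c.lg, []).append((c.pos, c.end, cs.species_id))
        for lg, ivs in sorted(per_lg.items()):
            points = sorted({p for s, e, _ in ivs for p in (s, e + 1)})
            segments = []
            for a, b in zip(points, points[1:]):
                cover = frozenset(sp for s, e, sp in ivs if s <= a and b - 1 <= e)
                if len(cover) >= min_species:
                    segments.append((a, b - 1, cover))
            for a, b, cover in segments:
                if out and out[-1].lg == lg and out[-1].var_class is var_class \
                        and out[-1].end + 1 == a and out[-1].species == cover:
                    out[-1] = OverlapRegion(lg, out[-1].start, b, var_class, cover)
                else:
                    out.append(OverlapRegion(lg, a, b, var_class, cover))
    return out


def genes_affected(calls: SVCallSet, ann: GenomeAnnotation) -> set[str]:
    """Genes whose span overlaps any call by >= 1 bp."""
    trees: dict[str, IntervalTree] = {}
    for g in ann.genes:
        s, e = g.span
        trees.setdefault(g.lg, IntervalTree()).addi(s - 1, e, g.gene_id)
    hit: set[str] = set()
    for c in calls.calls:
        tree = trees.get(c.lg)
        if tree is not None:
            hit.update(iv.data for iv in tree.overlap(c.pos - 1, c.end))
    return hit


# ---------------------------------------------------------------------------
# Generalized ESD (Rosner) outlier test


@dataclass
class ESDResult:
    alpha: float
    r: int
    statistics: list[float]      # R_i, i = 1..r
    critical: list[float]        # lambda_i
    n_outliers: int
    outlier_ids: list[int]       # indices into x of the declared outliers


def esd_critical_value(n: int, i: int, alpha: float) -> float:
    """Rosner's critical value lambda_i for the i-th extreme deviate."""
    p = 1.0 - alpha / (2.0 * (n - i + 1))
    t = stats.t.ppf(p, df=n - i - 1)
    return (n - i) * t / np.sqrt((n - i - 1 + t * t) * (n - i + 1))


def esd_test(x, alpha: float = 0.05, r: int = 3) -> ESDResult:
    """Generalized extreme studentized deviate test for up to ``r`` outliers.

    Iteratively removes the most extreme studentized point; the number of
    outliers is the largest i for which R_i exceeds lambda_i.  Steps with
    zero variance yield R_i = 0 (no outlier detectable there).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("esd_test requires n >= 3")
    if not (1 <= r <= n - 2):
        raise ValueError("r must satisfy 1 <= r <= n - 2")
    remaining = list(range(n))
    stats_R, crit, removed = [], [], []
    for i in range(1, r + 1):
        vals = x[remaining]
        sd = vals.std(ddof=1)
        if sd == 0:
            R, j_max = 0.0, remaining[0]
        else:
            dev = np.abs(vals - vals.mean())
            k = int(np.argmax(dev))
            R, j_max = float(dev[k] / sd), remaining[k]
        stats_R.append(R)
        crit.append(float(esd_critical_value(n, i, alpha)))
        removed.append(j_max)
        remaining.remove(j_max)
    n_out = 0
    for i in range(r, 0, -1):
        if stats_R[i - 1] > crit[i - 1]:
            n_out = i
            break
    return ESDResult(alpha=alpha, r=r, statistics=stats_R, critical=crit,
                     n_outliers=n_out, outlier_ids=removed[:n_out])


def per_lg_normalized_counts(calls: SVCallSet, ann: GenomeAnnotation,
                             var_class: VariantClass) -> pd.Series:
    """Per-LG call counts normalized by LG length in Mb."""
    counts = {lg: 0 for lg in ann.lg_lengths}
    for c in calls.by_class(var_class):
        counts[c.lg] += 1
    return pd.Series(
        {lg: counts[lg] / (ann.lg_lengths[lg] / 1e6) for lg in ann.lg_lengths}
    )


# ---------------------------------------------------------------------------
# GO enrichment


def go_enrichment(affected: set[str], universe: set[str],
                  gene2go: dict[str, set[str]], fdr: float = 0.05) -> pd.DataFrame:
    """One-sided Fisher enrichment of GO terms among affected genes.

    Returns one row per term with the 2x2 table, raw p and BH q; a term is
    significant iff q < ``fdr``.
    """
    if not universe or not gene2go:
        raise ValueError("empty universe or gene2go map")
    if not affected <= universe:
        raise ValueError("affected genes must be a subset of the universe")
    terms: dict[str, set[str]] = {}
    for gene, gos in gene2go.items():
        if gene in universe:
            for t in gos:
                terms.setdefault(t, set()).add(gene)
    rows = []
    for term, members in sorted(terms.items()):
        a = len(affected & members)
        b = len(affected) - a
        c = len(members) - a
        d = len(universe) - len(affected) - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({"term": term, "affected_with": a, "affected_without": b,
                     "other_with": c, "other_without": d, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["q"] < fdr
        df = df.sort_values("p", kind="mergesort").reset_index(drop=True)
    return df
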