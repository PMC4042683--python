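"""Phylogenetic placement of variants and per-branch rates.

Each cross-species variant (identified by exact coordinates for SNPs/indels,
by reciprocal-overlap equivalence classes for structural variants) is placed
on the species tree by maximum parsimony: a sharing pattern that equals the
leaf set of a clade maps to that clade's stem branch; any other pattern
(homoplasy, with one individual per species) is excluded.  Divergence times
come from nonparametric rate smoothing (NPRS) anchored at one calibration
(the Pundamilia/Metriaclima split, 2.3 My), and per-branch rates are
lineage-specific counts divided by the branch's duration in My.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize

from .core import INGROUP_SPECIES, SpeciesTree, VariantClass, VariantRecord

EXCLUDED = "EXCLUDED"

#: Published calibration: Lake Victoria / Lake Malawi lineages split.
PN_MZ_CALIBRATION_MY = 2.3


# ---------------------------------------------------------------------------
# Presence matrix


@dataclass
class PresenceMatrix:
    """variant key -> set of species carrying it (all sets non-empty)."""

    entries: dict[tuple, frozenset] = field(default_factory=dict)
    var_class_of: dict[tuple, VariantClass] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0] + 1), inter / (b[1] - b[0] + 1))


def build_presence_matrix(
    per_species: dict[str, list[VariantRecord]],
    reciprocal: float = 0.5,
) -> PresenceMatrix:
    """Cross-species presence/absence matrix.

    SNPs match on (lg, pos, alt); indels on (lg, pos, ref, alt).  Structural
    variants of the same class match when their reciprocal overlap reaches
    ``reciprocal`` (transitive closure); each equivalence class is keyed by
    its envelope region.
    """
    matrix = PresenceMatrix()
    sv_pool: dict[tuple[str, VariantClass], list[tuple[int, int, str]]] = {}
    exact: dict[tuple, set[str]] = {}
    exact_class: dict[tuple, VariantClass] = {}
    for sp, records in per_species.items():
        for r in records:
            if r.is_sv:
                sv_pool.setdefault((r.lg, r.var_class), []).append((r.pos, r.end, sp))
            else:
                k = r.key
                exact.setdefault(k, set()).add(sp)
                exact_class[k] = r.var_class
    for k, species in exact.items():
        matrix.entries[k] = frozenset(species)
        matrix.var_class_of[k] = exact_class[k]
    for (lg, var_class), ivs in sv_pool.items():
        for start, end, members in _cluster_reciprocal(ivs, reciprocal):
            key = (var_class.value, lg, start, end)
            if key in matrix.entries:
                raise ValueError(f"conflicting variant classes at key {key}")
            matrix.entries[key] = frozenset(members)
            matrix.var_class_of[key] = var_class
    return matrix


def _cluster_reciprocal(ivs: list[tuple[int, int, str]], f: float):
    """Union-find transitive closure under reciprocal overlap >= f."""
    n = len(ivs)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    order = sorted(range(n), key=lambda i: ivs[i][0])
    active: list[int] = []
    for i in order:
        s_i, e_i, _ = ivs[i]
        active = [j for j in active if ivs[j][1] >= s_i]
        for j in active:
            if _reciprocal_overlap(ivs[i][:2], ivs[j][:2]) >= f:
                parent[find(i)] = find(j)
        active.append(i)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    for members in clusters.values():
        start = min(ivs[i][0] for i in members)
        end = max(ivs[i][1] for i in members)
        yield start, end, {ivs[i][2] for i in members}


# ---------------------------------------------------------------------------
# Parsimony branch assignment


@dataclass
class BranchAssignment:
    """variant key -> stem-branch clade (frozenset of leaves) or EXCLUDED."""

    assignments: dict[tuple, object] = field(default_factory=dict)
    var_class_of: dict[tuple, VariantClass] = field(default_factory=dict)

    def counts_by_branch(self) -> dict[object, dict[VariantClass, int]]:
        out: dict[object, dict[VariantClass, int]] = {}
        for key, branch in self.assignments.items():
            vc = self.var_class_of[key]
            out.setdefault(branch, {}).setdefault(vc, 0)
            out[branch][vc] += 1
        return out

    @property
    def n_excluded(self) -> int:
        return sum(1 for b in self.assignments.values() if b == EXCLUDED)


def assign_branch(matrix: PresenceMatrix, tree: SpeciesTree) -> BranchAssignment:
    """Parsimony placement: a species set equal to a clade's leaf set maps to
    that clade's stem branch; every other pattern is EXCLUDED."""
    leaves = tree.leaf_labels
    out = BranchAssignment(var_class_of=dict(matrix.var_class_of))
    for key, species in matrix.entries.items():
        unknown = species - leaves
        if unknown:
            raise ValueError(f"species {sorted(unknown)} not in tree")
        out.assignments[key] = species if species in tree.clades else EXCLUDED
    return out


def branch_label(clade: frozenset) -> str:
    if len(clade) == 1:
        return next(iter(clade))
    ordered = [sp for sp in INGROUP_SPECIES if sp in clade]
    ordered += sorted(clade - set(INGROUP_SPECIES))
    return "anc(" + ",".join(ordered) + ")"


# ---------------------------------------------------------------------------
# NPRS dating


@dataclass
class Chronogram:
    tree: SpeciesTree
    calibration_clade: frozenset
    calibration_age: float
    objective: float
    converged: bool

    def ages(self) -> dict[frozenset, float]:
        return self.tree.ages()

    def branch_duration(self, clade: frozenset) -> float:
        node = self.tree.node(clade)
        if node.parent_node is None:
            raise ValueError("the root has no stem branch")
        return node.parent_node.age - node.age


def _free_nodes(tree: SpeciesTree):
    """Internal non-root nodes in preorder (their age fraction is free)."""
    return [
        n for n in tree.tree.preorder_node_iter()
        if n.parent_node is not None and not n.is_leaf()
    ]


def _relative_ages(tree: SpeciesTree, fracs: np.ndarray) -> None:
    """Assign node.rel_age: root 1, leaves 0, internals fraction of parent."""
    tree.root.rel_age = 1.0
    free = _free_nodes(tree)
    for n, f in zip(free, fracs):
        n.rel_age = f * n.parent_node.rel_age
    for n in tree.tree.leaf_node_iter():
        n.rel_age = 0.0


def _nprs_objective(tree: SpeciesTree, fracs: np.ndarray,
                    cal_node, cal_age: float) -> float:
    """NPRS roughness W on the calibrated time scale.

    W sums squared rate differences between each branch and its parent
    branch, plus squared deviations of the root's child branches from their
    mean rate; rates are branch length / branch duration.
    """
    _relative_ages(tree, fracs)
    rel_cal = cal_node.rel_age
    if rel_cal <= 0:
        return np.inf
    scale = cal_age / rel_cal
    rates: dict[int, float] = {}
    for n in tree.tree.preorder_node_iter():
        if n.parent_node is None:
            continue
        dur = (n.parent_node.rel_age - n.rel_age) * scale
        if dur <= 0:
            return np.inf
        rates[id(n)] = (n.edge.length or 0.0) / dur
    W = 0.0
    root_children = tree.root.child_nodes()
    mean_root = float(np.mean([rates[id(c)] for c in root_children]))
    for c in root_children:
        W += (rates[id(c)] - mean_root) ** 2
    for n in tree.tree.preorder_node_iter():
        if n.parent_node is None or n.parent_node.parent_node is None:
            continue
        W += (rates[id(n)] - rates[id(n.parent_node)]) ** 2
    return W


def nprs_date(tree: SpeciesTree, calibration: tuple[frozenset, float],
              n_restarts: int = 10, seed: int = 0,
              tol: float = 1e-10) -> Chronogram:
    """Date the tree by nonparametric rate smoothing.

    Node ages are parameterized on a relative scale (root = 1, each internal
    node a fraction of its parent's age, leaves 0) and rescaled so the
    calibrated node sits exactly at its age; the smoothing objective W is
    minimized by multi-start Nelder-Mead followed by cyclic 1-D (Brent)
    coordinate polish.  Multiplying the calibration age by c multiplies all
    ages by c exactly.
    """
    cal_clade, cal_age = calibration
    cal_node = tree.node(cal_clade)
    if cal_node.is_leaf():
        raise ValueError("calibration node must be internal")
    free = _free_nodes(tree)
    k = len(free)
    rng = np.random.default_rng(seed)
    eps = 1e-9

    def obj_logit(x):
        fracs = 1.0 / (1.0 + np.exp(-np.asarray(x)))
        return _nprs_objective(tree, fracs, cal_node, cal_age)

    best_f, best_W = None, np.inf
    converged = False
    if k == 0:
        best_f = np.empty(0)
        best_W = _nprs_objective(tree, best_f, cal_node, cal_age)
        converged = True
    for _ in range(max(1, n_restarts)):
        x0 = rng.normal(0.0, 1.0, size=k)
        res = optimize.minimize(
            obj_logit, x0, method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000},
        )
        f = 1.0 / (1.0 + np.exp(-res.x))
        W = _nprs_objective(tree, f, cal_node, cal_age)
        if W < best_W:
            best_W, best_f = W, f
            converged = bool(res.success)
    # cyclic coordinate polish directly on the fractions
    f = np.clip(best_f, eps, 1 - eps)
    for _ in range(50):
        W_before = _nprs_objective(tree, f, cal_node, cal_age)
        for i in range(k):
            def obj_i(fi, i=i):
                trial = f.copy()
                trial[i] = fi
                return _nprs_objective(tree, trial, cal_node, cal_age)
            res = optimize.minimize_scalar(
                obj_i, bounds=(eps, 1 - eps), method="bounded",
                options={"xatol": 1e-14},
            )
            if res.fun < _nprs_objective(tree, f, cal_node, cal_age):
                f[i] = res.x
        W_after = _nprs_objective(tree, f, cal_node, cal_age)
        if W_before - W_after < tol * max(1.0, W_before):
            converged = True
            break
    best_W = _nprs_objective(tree, f, cal_node, cal_age)
    _relative_ages(tree, f)
    scale = cal_age / cal_node.rel_age
    for n in tree.tree.preorder_node_iter():
        n.age = n.rel_age * scale
    return Chronogram(tree=tree, calibration_clade=cal_clade,
                      calibration_age=cal_age, objective=float(best_W),
                      converged=converged)


# ---------------------------------------------------------------------------
# Branch rates


def branch_rates(assign: BranchAssignment, chrono: Chronogram,
                 classes: Optional[list[VariantClass]] = None) -> pd.DataFrame:
    """Per-branch table of counts, durations (My) and rates (events/My).

    EXCLUDED variants are dropped.  Branch duration is the stem duration
    (parent age minus child age); a zero-duration branch is an error.
    """
    classes = classes or list(VariantClass)
    counts = assign.counts_by_branch()
    branches = sorted(
        (b for b in chrono.tree.clades if chrono.tree.node(b).parent_node is not None),
        key=lambda b: (len(b), branch_label(b)),
    )
    rows = []
    for clade in branches:
        dur = chrono.branch_duration(clade)
        if dur <= 0:
            raise ValueError(f"branch {branch_label(clade)} has zero duration")
        for vc in classes:
            n = counts.get(clade, {}).get(vc, 0)
            rows.append({
                "branch": branch_label(clade),
                "clade": clade,
                "var_class": vc.value,
                "count": n,
                "duration_my": dur,
                "rate_per_my": n / dur,
            })
    return pd.DataFrame(rows)
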