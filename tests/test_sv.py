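"""SV consolidation, multi-way overlap, ESD outlier test, GO enrichment."""

import numpy as np
import pytest
from scipy import stats

from cichlidvar.core import GenomeAnnotation, GeneModel, VariantClass, VariantRecord
from cichlidvar.sv import (
    SVCallSet,
    esd_critical_value,
    esd_test,
    genes_affected,
    go_enrichment,
    merge_library_calls,
    multiway_overlap,
    self_consistency_filter,
)


def sv(pos, end, vc=VariantClass.DELETION, sp="Nb", lg="LG1"):
    return VariantRecord(species_id=sp, lg=lg, pos=pos, var_class=vc, end=end)


class TestSelfConsistency:
    def test_same_class_overlap_removed(self):
        calls = SVCallSet("Nb", [sv(100, 300)])
        ref = SVCallSet("Tilapia", [sv(250, 400, sp="Tilapia")])
        kept, removed = self_consistency_filter(calls, ref)
        assert not kept.calls and len(removed.calls) == 1

    def test_cross_class_overlap_kept(self):
        calls = SVCallSet("Nb", [sv(100, 300)])
        ref = SVCallSet("Tilapia",
                        [sv(250, 400, vc=VariantClass.INVERSION, sp="Tilapia")])
        kept, removed = self_consistency_filter(calls, ref)
        assert len(kept.calls) == 1 and not removed.calls

    def test_empty_reference_keeps_all(self):
        calls = SVCallSet("Nb", [sv(100, 300), sv(500, 700)])
        kept, removed = self_consistency_filter(calls, SVCallSet("Tilapia", []))
        assert len(kept.calls) == 2 and not removed.calls


class TestMergeLibraryCalls:
    def test_overlapping_merge(self):
        out = merge_library_calls(SVCallSet("Nb", [sv(10, 100)], "paired_end"),
                                  SVCallSet("Nb", [sv(50, 150)], "mate_pair"))
        assert [(c.pos, c.end) for c in out.calls] == [(10, 150)]

    def test_bookended_merge(self):
        out = merge_library_calls(SVCallSet("Nb", [sv(10, 100)], "paired_end"),
                                  SVCallSet("Nb", [sv(101, 150)], "mate_pair"))
        assert [(c.pos, c.end) for c in out.calls] == [(10, 150)]

    def test_disjoint_sorted_concatenation(self):
        out = merge_library_calls(SVCallSet("Nb", [sv(500, 600)], "paired_end"),
                                  SVCallSet("Nb", [sv(10, 100)], "mate_pair"))
        assert [(c.pos, c.end) for c in out.calls] == [(10, 100), (500, 600)]

    def test_idempotent_and_commutative(self):
        rng = np.random.default_rng(12)
        def rand_set(prov):
            calls = []
            for _ in range(40):
                p = int(rng.integers(1, 50_000))
                calls.append(sv(p, p + int(rng.integers(50, 2000))))
            return SVCallSet("Nb", calls, prov)
        a, b = rand_set("paired_end"), rand_set("mate_pair")
        ab = merge_library_calls(a, b)
        ba = merge_library_calls(b, a)
        assert [(c.pos, c.end, c.var_class) for c in ab.calls] == \
               [(c.pos, c.end, c.var_class) for c in ba.calls]
        again = merge_library_calls(ab, SVCallSet("Nb", [], "mate_pair"))
        assert [(c.pos, c.end) for c in again.calls] == \
               [(c.pos, c.end) for c in ab.calls]


class TestMultiwayOverlap:
    def test_pairwise_region(self):
        regions = multiway_overlap(
            [SVCallSet("Nb", [sv(100, 200)]),
             SVCallSet("Pn", [sv(150, 250, sp="Pn")])], min_species=2)
        (r,) = regions
        assert (r.start, r.end) == (150, 200)
        assert r.species == frozenset({"Nb", "Pn"})

    def test_four_species_common_region(self):
        callsets = [SVCallSet(sp, [sv(100, 200, sp=sp)])
                    for sp in ("Nb", "Ab", "Pn", "Mz")]
        regions = multiway_overlap(callsets, min_species=4)
        (r,) = regions
        assert (r.start, r.end) == (100, 200)
        assert r.species == frozenset({"Nb", "Ab", "Pn", "Mz"})

    def test_min_species_exceeds_sets_errors(self):
        with pytest.raises(ValueError):
            multiway_overlap([SVCallSet("Nb", []), SVCallSet("Pn", [])],
                             min_species=3)

    def test_matches_perbase_sweep(self):
        rng = np.random.default_rng(13)
        L = 10_000
        species = ("Nb", "Ab", "Pn", "Mz")
        callsets = []
        for sp in species:
            calls = []
            for _ in range(15):
                p = int(rng.integers(1, L - 400))
                calls.append(sv(p, p + int(rng.integers(50, 400)), sp=sp))
            callsets.append(SVCallSet(sp, calls))
        for min_sp in (2, 3):
            regions = multiway_overlap(callsets, min_species=min_sp)
            # per-base oracle
            cover = np.zeros((len(species), L + 2), dtype=bool)
            for si, cs in enumerate(callsets):
                for c in cs.calls:
                    cover[si, c.pos:c.end + 1] = True
            by_base = {}
            for pos in range(1, L + 1):
                s = frozenset(species[si] for si in range(len(species))
                              if cover[si, pos])
                if len(s) >= min_sp:
                    by_base[pos] = s
            from_regions = {}
            for r in regions:
                for pos in range(r.start, r.end + 1):
                    from_regions[pos] = r.species
            assert from_regions == by_base
            # regions are maximal: neighbours differ
            for r in regions:
                assert by_base.get(r.start - 1) != by_base[r.start]
                assert by_base.get(r.end + 1) != by_base[r.end]


class TestGenesAffected:
    def _ann(self, spans):
        genes = [GeneModel(f"g{i}", "LG1", "+", [s], [])
                 for i, s in enumerate(spans)]
        return GenomeAnnotation(lg_lengths={"LG1": 100_000}, genes=genes,
                                te_intervals=[])

    def test_inversion_spanning_three_genes(self):
        ann = self._ann([(1_000, 2_000), (3_000, 4_000), (5_000, 6_000),
                         (50_000, 51_000)])
        calls = SVCallSet("Nb", [sv(1_500, 5_500, vc=VariantClass.INVERSION)])
        assert genes_affected(calls, ann) == {"g0", "g1", "g2"}

    def test_intergenic_call_empty(self):
        ann = self._ann([(1_000, 2_000)])
        calls = SVCallSet("Nb", [sv(10_000, 11_000)])
        assert genes_affected(calls, ann) == set()

    def test_matches_allpairs_bruteforce(self):
        rng = np.random.default_rng(14)
        spans = []
        cursor = 1
        while cursor < 90_000 and len(spans) < 800:
            s = cursor + int(rng.integers(10, 100))
            e = s + int(rng.integers(50, 300))
            spans.append((s, e))
            cursor = e + 1
        ann = self._ann(spans)
        calls = SVCallSet("Nb", [
            sv(int(p), int(p) + int(rng.integers(50, 5_000)))
            for p in rng.integers(1, 90_000, size=60)
        ])
        got = genes_affected(calls, ann)
        brute = {
            g.gene_id for g in ann.genes
            if any(c.pos <= g.span[1] and g.span[0] <= c.end
                   for c in calls.calls)
        }
        assert got == brute


class TestESD:
    def test_constant_vector_no_outliers(self):
        res = esd_test([1.0] * 22, alpha=0.05, r=3)
        assert res.n_outliers == 0
        assert res.statistics == [0.0, 0.0, 0.0]

    def test_single_gross_outlier_detected(self):
        rng = np.random.default_rng(15)
        x = list(rng.normal(0, 1, size=21)) + [10.0]
        res = esd_test(x, alpha=0.05, r=3)
        assert res.n_outliers >= 1
        assert 21 in res.outlier_ids

    def test_critical_value_reference(self):
        # published reference value for n=54, alpha=0.05: lambda_1 ~= 3.16
        assert esd_critical_value(54, 1, 0.05) == pytest.approx(3.16, abs=0.01)

    def test_lambda_strictly_decreasing(self):
        lams = [esd_critical_value(22, i, 0.05) for i in range(1, 6)]
        assert all(a > b for a, b in zip(lams, lams[1:]))

    def test_statistics_match_direct_formulas(self):
        rng = np.random.default_rng(16)
        x = rng.normal(0, 1, size=22)
        res = esd_test(x, alpha=0.05, r=3)
        vals = list(x)
        for i in range(3):
            arr = np.array(vals)
            dev = np.abs(arr - arr.mean())
            k = int(np.argmax(dev))
            R = dev[k] / arr.std(ddof=1)
            assert res.statistics[i] == pytest.approx(R)
            n, step = 22, i + 1
            p = 1 - 0.05 / (2 * (n - step + 1))
            t = stats.t.ppf(p, n - step - 1)
            lam = (n - step) * t / np.sqrt((n - step - 1 + t**2) * (n - step + 1))
            assert res.critical[i] == pytest.approx(lam)
            vals.pop(k)

    def test_too_small_n_errors(self):
        with pytest.raises(ValueError):
            esd_test([1.0, 2.0], r=1)


class TestGOEnrichment:
    def test_matches_hypergeometric_tail(self):
        # affected: 8 with term, 2 without; others: 10 with, 80 without
        affected = {f"a{i}" for i in range(10)}
        others = {f"b{i}" for i in range(90)}
        universe = affected | others
        gene2go = {g: {"GO:1"} for g in list(sorted(affected))[:8]}
        gene2go.update({g: {"GO:1"} for g in list(sorted(others))[:10]})
        df = go_enrichment(affected, universe, gene2go, fdr=0.05)
        row = df[df.term == "GO:1"].iloc[0]
        # one-sided Fisher equals the hypergeometric upper tail
        expected = stats.hypergeom.sf(8 - 1, 100, 18, 10)
        assert row.p == pytest.approx(expected, rel=1e-10)

    def test_affected_equals_universe_degenerate(self):
        universe = {f"g{i}" for i in range(20)}
        gene2go = {g: {"GO:1"} for g in list(sorted(universe))[:5]}
        df = go_enrichment(universe, universe, gene2go, fdr=0.05)
        assert np.allclose(df.p, 1.0)
        assert not df.significant.any()

    def test_term_absent_from_affected(self):
        affected = {"a1"}
        universe = {"a1", "b1", "b2", "b3"}
        gene2go = {"b1": {"GO:9"}, "b2": {"GO:9"}}
        df = go_enrichment(affected, universe, gene2go)
        assert df[df.term == "GO:9"].iloc[0].p == pytest.approx(1.0)

    def test_bh_qvalues_monotone_in_p_rank(self):
        rng = np.random.default_rng(17)
        universe = {f"g{i}" for i in range(200)}
        affected = set(list(sorted(universe))[:40])
        terms = [f"GO:{i}" for i in range(15)]
        gene2go = {}
        for g in universe:
            k = int(rng.integers(1, 4))
            gene2go[g] = set(rng.choice(terms, size=k, replace=False))
        df = go_enrichment(affected, universe, gene2go)
        assert (df.q.diff().dropna() >= -1e-12).all()
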