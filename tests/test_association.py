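import math

import numpy as np
import pytest

from _oracles import hypergeom_tails_bruteforce, spearman_bruteforce
from fresco import association
from fresco.association import (
    SeparationResult,
    domain_enrichment,
    go_enrichment,
    hypergeom_tails,
    ogt_correlation,
    ogt_screen,
    sequence_separation,
)
from fresco.geometry import Ball, BestMatch
from fresco.miner import Pattern, PatternStats
from fresco.structure_io import AnnotationTables, DomainInterval, StructureDataset

from conftest import make_structure


def _stats(pattern, per_radius, matches=None, n_total=None):
    ids = tuple(per_radius)
    n = n_total if n_total is not None else len(ids)
    return PatternStats(
        pattern=pattern,
        support=len(ids) / n,
        supporting_ids=ids,
        per_structure_radius=dict(per_radius),
        cohesive_radius=float(np.mean(list(per_radius.values()))),
        best_matches=matches or {},
    )


class TestHypergeomTails:
    def test_saturated_draw(self):
        p_enr, p_dep = hypergeom_tails(5, 5, 5, 10)
        assert p_enr == pytest.approx(1 / 252, rel=1e-12)
        assert p_dep == pytest.approx(1.0)

    def test_empty_sample(self):
        assert hypergeom_tails(0, 0, 5, 10) == (1.0, 1.0)

    def test_matches_pmf_summation(self, rng):
        for _ in range(200):
            N = int(rng.integers(1, 31))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            lo = max(0, n - (N - K))
            hi = min(n, K)
            k = int(rng.integers(lo, hi + 1))
            p_enr, p_dep = hypergeom_tails(k, n, K, N)
            o_enr, o_dep = hypergeom_tails_bruteforce(k, n, K, N)
            assert p_enr == pytest.approx(o_enr, abs=1e-12)
            assert p_dep == pytest.approx(o_dep, abs=1e-12)

    def test_tails_overlap_by_pmf(self, rng):
        from scipy.stats import hypergeom as H

        for _ in range(50):
            N = int(rng.integers(2, 31))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            lo, hi = max(0, n - (N - K)), min(n, K)
            k = int(rng.integers(lo, hi + 1))
            p_enr, p_dep = hypergeom_tails(k, n, K, N)
            assert p_enr + p_dep == pytest.approx(1.0 + H.pmf(k, N, K, n), abs=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_tails(3, 2, 5, 10)


def _ball():
    return Ball((0.0, 0.0, 0.0), 1.0)


class TestDomainEnrichment:
    def _toy(self):
        # 100-residue structure, one domain covering positions 1-50
        coords = [("ALA", (float(i), 0.0, 0.0)) for i in range(100)]
        s = make_structure(coords, structure_id="S")
        ds = StructureDataset([s])
        tables = AnnotationTables(domains={"S": [DomainInterval("A", 1, 50, "D1")]})
        return s, ds, tables

    def test_combinatorial_toy(self):
        s, ds, tables = self._toy()
        # best match picks residues at seq positions 10, 20, 30 => indices 9, 19, 29
        bm = BestMatch(1.0, _ball(), {"ALA": 9, "GLY": 19, "VAL": 29})
        st = _stats(Pattern.of("ALA", "GLY", "VAL"), {"S": 1.0}, {"S": bm})
        (res,) = domain_enrichment([st], tables, ds)
        assert (res.k_overlap, res.n_sample, res.K_category, res.N_population) == (3, 3, 50, 100)
        expected = (math.comb(50, 3) / math.comb(100, 3))
        assert res.p_enriched == pytest.approx(expected, rel=1e-9)
        assert res.p_enriched == pytest.approx(0.1212, abs=5e-4)

    def test_saturated_category_is_unsurprising(self):
        s, ds, _ = self._toy()
        tables = AnnotationTables(domains={"S": [DomainInterval("A", 1, 100, "D1")]})
        bm = BestMatch(1.0, _ball(), {"ALA": 9, "GLY": 19, "VAL": 29})
        st = _stats(Pattern.of("ALA", "GLY", "VAL"), {"S": 1.0}, {"S": bm})
        (res,) = domain_enrichment([st], tables, ds)
        assert res.p_enriched == pytest.approx(1.0)

    def test_depletion_detected_for_matches_outside_domains(self):
        s, ds, tables = self._toy()
        # 10 patterns, all matching far outside the domain
        stats = []
        for i in range(10):
            idx = 60 + 3 * i
            bm = BestMatch(1.0, _ball(), {"ALA": idx, "GLY": idx + 1, "VAL": idx + 2})
            stats.append(_stats(Pattern.of("ALA", "GLY", f"L{i}"), {"S": 1.0}, {"S": bm}))
        results = domain_enrichment(stats, tables, ds, alpha=0.5)
        assert all(r.k_overlap == 0 for r in results)
        assert all(r.p_depleted < r.p_enriched for r in results)

    def test_unannotated_structure_excluded(self):
        s, ds, tables = self._toy()
        s2 = make_structure([("GLY", (0, 0, 5))], structure_id="T")
        ds2 = StructureDataset([s, s2])
        bm = BestMatch(1.0, _ball(), {"ALA": 9})
        st = _stats(Pattern.of("ALA"), {"S": 1.0, "T": 0.0}, {"S": bm})
        (res,) = domain_enrichment([st], tables, ds2)
        assert res.N_population == 100  # T's residue not counted


class TestGoEnrichment:
    def _fixture(self, radii, members, n=30, term="GO:1", min_structures=3):
        structures = [make_structure([("ALA", (0, 0, 0))], structure_id=f"S{i}")
                      for i in range(n)]
        ds = StructureDataset(structures)
        go = {f"S{i}": {term} if i in members else {"GO:other"} for i in range(n)}
        tables = AnnotationTables(go=go)
        st = _stats(Pattern.of("ALA"), radii, n_total=n)
        return ds, tables, st

    def test_boundary_radius_not_counted(self):
        members = set(range(10))
        radii = {f"S{i}": (3.0 if i < 5 else 1.0) for i in range(10)}
        ds, tables, st = self._fixture(radii, members, n=10)
        (res,) = [r for r in go_enrichment([st], tables, ds, min_structures=3)
                  if r.category == "GO:1"]
        assert res.n_sample == 5  # the five radius-3.0 structures are excluded

    def test_rare_terms_skipped(self):
        members = set(range(9))
        radii = {f"S{i}": 1.0 for i in range(30)}
        ds, tables, st = self._fixture(radii, members)
        results = go_enrichment([st], tables, ds, min_structures=10)
        assert all(r.category != "GO:1" for r in results)

    def test_perfect_coincidence_hits_floor(self):
        members = set(range(10))
        radii = {f"S{i}": (1.0 if i in members else 5.0) for i in range(30)}
        ds, tables, st = self._fixture(radii, members)
        (res,) = [r for r in go_enrichment([st], tables, ds, min_structures=3)
                  if r.category == "GO:1"]
        assert (res.k_overlap, res.n_sample, res.K_category, res.N_population) == (10, 10, 10, 30)
        assert res.p_enriched == pytest.approx(1 / math.comb(30, 10), rel=1e-9)

    def test_shuffled_labels_give_superuniform_p(self, rng):
        # permutation consistency: with random GO membership the enrichment
        # p-values must not pile up near zero (they are discrete and
        # conservative, so P(p <= a) should not exceed a by much)
        n = 40
        radii = {f"S{i}": (1.0 if i < 20 else 5.0) for i in range(n)}
        ps = []
        for _ in range(300):
            members = set(rng.choice(n, size=15, replace=False).tolist())
            ds, tables, st = self._fixture(radii, members, n=n)
            (res,) = [r for r in go_enrichment([st], tables, ds, min_structures=3)
                      if r.category == "GO:1"]
            ps.append(res.p_enriched)
        ps = np.asarray(ps)
        for a in (0.01, 0.05, 0.1, 0.25, 0.5):
            frac = float(np.mean(ps <= a))
            assert frac <= a + 3.0 * math.sqrt(a * (1 - a) / len(ps))


class TestOgtCorrelation:
    def test_perfect_concordance_low_t(self):
        radii = {f"S{i}": float(i) for i in range(10)}
        ogt = {f"S{i}": 20.0 + 5.0 * i for i in range(10)}
        st = _stats(Pattern.of("ALA", "GLY"), radii)
        res = ogt_correlation(st, ogt)
        assert res.rho == pytest.approx(1.0)
        assert res.significant and res.direction == "low_T"

    def test_perfect_discordance_high_t(self):
        radii = {f"S{i}": float(10 - i) for i in range(10)}
        ogt = {f"S{i}": 20.0 + 5.0 * i for i in range(10)}
        st = _stats(Pattern.of("ALA", "GLY"), radii)
        res = ogt_correlation(st, ogt)
        assert res.rho == pytest.approx(-1.0)
        assert res.significant and res.direction == "high_T"

    def test_37_degree_rows_removed(self):
        radii = {f"S{i}": float(i) for i in range(8)}
        ogt = {f"S{i}": (37.0 if i < 3 else 20.0 + i) for i in range(8)}
        st = _stats(Pattern.of("ALA"), radii)
        res = ogt_correlation(st, ogt)
        assert res.n_structures == 5

    def test_too_few_pairs_is_na(self):
        radii = {f"S{i}": float(i) for i in range(4)}
        ogt = {f"S{i}": 20.0 + i for i in range(4)}
        st = _stats(Pattern.of("ALA"), radii)
        res = ogt_correlation(st, ogt)
        assert math.isnan(res.rho) and res.direction == "none"

    def test_rho_matches_bruteforce_with_ties(self, rng):
        for _ in range(100):
            n = 12
            radii_vals = rng.integers(0, 5, size=n).astype(float)
            ogt_vals = rng.integers(15, 20, size=n).astype(float)
            radii = {f"S{i}": radii_vals[i] for i in range(n)}
            ogt = {f"S{i}": ogt_vals[i] for i in range(n)}
            st = _stats(Pattern.of("ALA"), radii)
            res = ogt_correlation(st, ogt)
            if np.std(radii_vals) == 0 or np.std(ogt_vals) == 0:
                continue
            assert res.rho == pytest.approx(
                spearman_bruteforce(radii_vals, ogt_vals), abs=1e-12
            )

    def test_rank_invariance_under_monotone_transform(self, rng):
        radii = {f"S{i}": float(v) for i, v in enumerate(rng.uniform(1, 8, size=15))}
        ogt = {f"S{i}": float(v) for i, v in enumerate(rng.uniform(15, 90, size=15))}
        st = _stats(Pattern.of("ALA"), radii)
        base = ogt_correlation(st, ogt)
        transformed = {k: math.exp(v / 20.0) for k, v in ogt.items()}
        res = ogt_correlation(st, transformed)
        assert res.rho == pytest.approx(base.rho, abs=1e-12)

    def test_screen_applies_bonferroni(self):
        # near-perfect (but not perfect) concordance at n = 6: significant
        # on its own at alpha = 0.01 yet not across a 50-pattern screen
        ranks = [1.0, 2.0, 3.0, 4.0, 6.0, 5.0]
        radii = {f"S{i}": ranks[i] for i in range(6)}
        ogt = {f"S{i}": 20.0 + i for i in range(6)}
        stats = [_stats(Pattern.of("ALA", f"L{j}"), radii) for j in range(50)]
        single = ogt_correlation(stats[0], ogt, alpha=0.01, m_tests=1)
        assert 0.01 / 50 < single.p_value <= 0.01
        assert single.significant
        screened = ogt_screen(stats, ogt, alpha=0.01)
        assert not screened[0].significant


class TestSequenceSeparation:
    def _structure(self):
        return make_structure(
            [("ALA", (0, 0, 0)), ("GLY", (1, 0, 0)), ("VAL", (2, 0, 0)),
             ("LEU", (3, 0, 0)), ("SER", (4, 0, 0))]
        )

    def test_short_range_mean(self):
        s = make_structure([("ALA", (0, 0, 0))] * 0 + [
            ("ALA", (0, 0, 0)), ("GLY", (1, 0, 0)), ("VAL", (2, 0, 0))])
        # craft seq positions 10, 12, 14 on one chain
        from fresco.structure_io import LabeledPoint, StructureObject

        pts = [
            LabeledPoint("ALA", (0, 0, 0), "A", 10),
            LabeledPoint("GLY", (1, 0, 0), "A", 12),
            LabeledPoint("VAL", (2, 0, 0), "A", 14),
        ]
        s = StructureObject("S", pts)
        bm = BestMatch(1.0, _ball(), {"ALA": 0, "GLY": 1, "VAL": 2})
        res = sequence_separation(bm, s)
        assert res.mean_separation == pytest.approx(8 / 3)
        assert res.category == "short_range"

    def test_long_range(self):
        from fresco.structure_io import LabeledPoint, StructureObject

        pts = [
            LabeledPoint("ALA", (0, 0, 0), "A", 5),
            LabeledPoint("GLY", (1, 0, 0), "A", 200),
        ]
        s = StructureObject("S", pts)
        bm = BestMatch(1.0, _ball(), {"ALA": 0, "GLY": 1})
        res = sequence_separation(bm, s)
        assert res.mean_separation == 195
        assert res.category == "long_range"

    def test_cross_chain(self):
        from fresco.structure_io import LabeledPoint, StructureObject

        pts = [
            LabeledPoint("ALA", (0, 0, 0), "A", 1),
            LabeledPoint("GLY", (1, 0, 0), "B", 1),
        ]
        s = StructureObject("S", pts)
        bm = BestMatch(1.0, _ball(), {"ALA": 0, "GLY": 1})
        assert sequence_separation(bm, s).category == "cross_chain"

    def test_singleton_undefined(self):
        s = self._structure()
        bm = BestMatch(0.0, _ball(), {"ALA": 0})
        res = sequence_separation(bm, s)
        assert math.isnan(res.mean_separation) and res.category == "undefined"

    def test_intermediate_band(self):
        from fresco.structure_io import LabeledPoint, StructureObject

        pts = [
            LabeledPoint("ALA", (0, 0, 0), "A", 1),
            LabeledPoint("GLY", (1, 0, 0), "A", 9),
        ]
        s = StructureObject("S", pts)
        assert sequence_separation(BestMatch(1.0, _ball(), {"ALA": 0, "GLY": 1}), s).category == "intermediate"
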