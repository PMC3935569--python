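"""Co-expression thresholds, iGA statistic, enrichment, regulator discovery."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import eqtlnet as eq
from eqtlnet.network import (
    CorrelationThresholds,
    corr_test,
    correlation_thresholds,
    find_master_regulators,
    iga_pc,
    run_iga,
    term_enrichment,
)


def brute_force_pc(ranks, N_total, n_members):
    """Independent oracle: enumerate hypergeometric tails with math.comb."""
    def tail(j, r):
        # P(X >= j), X ~ Hypergeom(N_total, n_members, r)
        total = math.comb(N_total, r)
        acc = 0
        for i in range(j, min(n_members, r) + 1):
            if r - i <= N_total - n_members:
                acc += math.comb(n_members, i) * math.comb(N_total - n_members, r - i)
        return acc / total

    pcs = [tail(j, r) for j, r in enumerate(ranks, start=1)]
    best = min(pcs)
    j_best = next(j for j, p in enumerate(pcs, start=1) if p <= best + 1e-12)
    return pcs[j_best - 1], j_best


class TestIgaPc:
    def test_worked_instance(self):
        # N=10, members at ranks (1, 2, 5): PC = min(0.3, 1/15, 0.0833) = 1/15 at j=2
        pc, n_changed = iga_pc([1, 2, 5], 10)
        assert pc == pytest.approx(1.0 / 15.0)
        assert n_changed == 2

    def test_single_member_at_top(self):
        pc, n_changed = iga_pc([1], 10)
        assert pc == pytest.approx(0.1) and n_changed == 1

    def test_bottom_ranks_not_significant(self):
        pc, _ = iga_pc([8, 9, 10], 10)
        assert pc > 0.9

    def test_rank_validation(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            iga_pc([3, 3, 5], 10)
        with pytest.raises(ValueError, match="within"):
            iga_pc([0, 2], 10)

    def test_exhaustive_oracle_small_instances(self):
        """Full sweep: every rank subset for N_total <= 11 matches enumeration."""
        for N in range(1, 12):
            for m in range(1, N + 1):
                for ranks in itertools.combinations(range(1, N + 1), m):
                    got = iga_pc(list(ranks), N)
                    want = brute_force_pc(list(ranks), N, m)
                    assert got[0] == pytest.approx(want[0], rel=1e-9), (N, ranks)
                    assert got[1] == want[1], (N, ranks)

    def test_oracle_sampled_instances_to_30(self):
        """Seeded random subsets for 12 <= N_total <= 30 match enumeration."""
        rng = np.random.default_rng(0)
        for N in range(12, 31):
            for _ in range(50):
                m = int(rng.integers(1, N + 1))
                ranks = sorted(rng.choice(np.arange(1, N + 1), size=m, replace=False))
                got = iga_pc([int(r) for r in ranks], N)
                want = brute_force_pc([int(r) for r in ranks], N, m)
                assert got[0] == pytest.approx(want[0], rel=1e-9)
                assert got[1] == want[1]

    def test_invariant_to_nonmember_shuffling(self):
        """PC depends only on member ranks, not on which non-members sit between."""
        assert iga_pc([2, 7, 11], 40) == iga_pc([2, 7, 11], 40, n_members=3)


class TestCorrelationThresholds:
    def _null_expr(self, m=400, n=210, seed=0):
        rng = np.random.default_rng(seed)
        return eq.ExpressionSet(
            pd.DataFrame(rng.standard_normal((m, n)),
                         index=[f"ET{i}" for i in range(m)],
                         columns=[f"L{i}" for i in range(n)])
        )

    def test_null_cuts_bracket_theory(self):
        # null Pearson r at n=210: the 0.005 tail sits near +-0.178
        E = self._null_expr()
        cuts = correlation_thresholds(E, n_group=200, alpha=0.01, seed=1)
        from scipy import stats as sps
        t = sps.t.isf(0.005, 208)
        theory = t / np.sqrt(208 + t**2)
        assert cuts.pos_cut == pytest.approx(theory, abs=0.02)
        assert cuts.neg_cut == pytest.approx(-theory, abs=0.02)

    def test_large_alpha_cuts_approach_median(self):
        # as alpha grows the two cuts close in on the null median near zero
        E = self._null_expr(m=100, n=50, seed=2)
        cuts = correlation_thresholds(E, n_group=50, alpha=0.5, seed=3)
        assert abs(cuts.pos_cut) < 0.2 and abs(cuts.neg_cut) < 0.2
        assert cuts.neg_cut < 0 < cuts.pos_cut

    def test_deterministic_given_seed(self):
        E = self._null_expr(m=120, n=40, seed=4)
        a = correlation_thresholds(E, n_group=50, alpha=0.05, seed=9)
        b = correlation_thresholds(E, n_group=50, alpha=0.05, seed=9)
        assert (a.pos_cut, a.neg_cut) == (b.pos_cut, b.neg_cut)

    def test_too_few_lines_rejected(self):
        E = self._null_expr(m=20, n=3)
        with pytest.raises(ValueError, match="4 lines"):
            correlation_thresholds(E, n_group=5)


class TestCorrTest:
    def test_zero_correlation_p_one(self):
        assert corr_test(0.0, 100) == pytest.approx(1.0)

    def test_published_flowering_pair(self):
        # r = -0.54 at n = 210 reported with P = 4.06E-17
        p = corr_test(-0.54, 210)
        assert 1e-18 < p < 1e-16

    def test_hand_t_value(self):
        # r = 0.5, n = 12: t = 1.826, two-sided p ~ 0.098
        p = corr_test(0.5, 12)
        t = 0.5 * np.sqrt(10) / np.sqrt(0.75)
        assert t == pytest.approx(1.826, abs=0.001)
        assert p == pytest.approx(0.098, abs=0.002)


class TestMasterRegulators:
    def test_planted_hotspot_regulator_recovered(self, small_population, small_catalog):
        cfg, binmap, G, truth, E, P = small_population
        cuts = CorrelationThresholds(pos_cut=0.60, neg_cut=-0.52, alpha=0.01, n_pairs=0)
        cands = find_master_regulators(small_catalog, E, cuts, min_targets=100)
        reg_id = E.etrait_ids[truth.regulator_etraits[0]]
        top = cands[0]
        assert top.regulator == reg_id
        assert top.n_targets >= 120 and top.label == "master"

    def test_cis_gene_without_overlap_not_candidate(self, small_population, small_catalog):
        cfg, binmap, G, truth, E, P = small_population
        cuts = CorrelationThresholds(pos_cut=0.60, neg_cut=-0.52, alpha=0.01, n_pairs=0)
        cands = find_master_regulators(small_catalog, E, cuts)
        assert all(c.n_targets > 0 for c in cands)

    def test_target_invariants(self, small_population, small_catalog):
        cfg, binmap, G, truth, E, P = small_population
        cuts = CorrelationThresholds(pos_cut=0.60, neg_cut=-0.52, alpha=0.01, n_pairs=0)
        for cand in find_master_regulators(small_catalog, E, cuts):
            for tid, r in cand.targets:
                assert r >= 0.60 or r <= -0.52


class TestRunIga:
    def test_gene_set_without_cis_members_empty(self, small_population, small_catalog):
        cfg, binmap, G, truth, E, P = small_population
        null_ids = [E.etrait_ids[i] for i in range(cfg.n_etraits)
                    if truth.cis_coef[i] == 0][:5]
        gs = eq.GeneSet("no-cis", null_ids)
        groups, edges = run_iga(gs, small_catalog, E)
        assert groups == [] and edges == []

    def test_output_mirrors_group_table(self, small_population, small_catalog):
        from eqtlnet.network import iga_to_frame

        cfg, binmap, G, truth, E, P = small_population
        reg = truth.regulator_etraits[0]
        members = [E.etrait_ids[i] for i in [reg] + truth.targets_of(reg)[:10]]
        groups, _ = run_iga(eq.GeneSet("s", members), small_catalog, E)
        df = iga_to_frame(groups)
        assert list(df.columns) == ["group", "members", "number_changed",
                                    "P_value_changed", "significant"]


class TestTermEnrichment:
    def _annotation(self):
        genes = [f"g{i}" for i in range(20)]
        pairs = pd.DataFrame(
            {"gene": genes[:5] + genes[5:12], "term": ["T1"] * 5 + ["T2"] * 7}
        )
        return genes, eq.AnnotationTable(pairs)

    def test_perfect_overlap_exhaustive_count(self):
        genes, ann = self._annotation()
        res = term_enrichment(eq.GeneSet("t", genes[:5]), ann, eq.GeneSet("u", genes))
        p1 = res.loc[res["term"] == "T1", "p"].iloc[0]
        assert p1 == pytest.approx(1.0 / math.comb(20, 5))
        assert res.iloc[0]["term"] == "T1"

    def test_null_targets_rarely_significant(self):
        genes, ann = self._annotation()
        rng = np.random.default_rng(5)
        n_sig = 0
        for _ in range(50):
            tgt = list(rng.choice(genes, 5, replace=False))
            res = term_enrichment(eq.GeneSet("t", tgt), ann, eq.GeneSet("u", genes))
            n_sig += int((res["p_adj"] < 0.05).any())
        assert n_sig <= 5
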