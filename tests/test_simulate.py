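"""Generator correctness: map totals, RIL genetics, planted effects, determinism."""

import numpy as np
import pandas as pd
import pytest

import eqtlnet as eq
from eqtlnet.simulate import (
    haldane_r,
    ril_switch_prob,
    plant_model,
    simulate_expression,
    simulate_ril_genotypes,
)


def paper_scale_cfg(**kw):
    base = dict(n_lines=210, n_chromosomes=12, n_bins=1619, genome_mb=372.2,
                genome_cm=1625.0, n_etraits=10, n_cis=5, regulators=[], n_traits=0,
                trait_specs=[], seed=0)
    base.update(kw)
    return eq.SimConfig(**base)


class TestBinMap:
    def test_totals_match_config(self):
        bm = eq.generate_bin_map(paper_scale_cfg())
        assert bm.n_bins == 1619 and len(bm.chromosomes) == 12
        mb = bm.chrom_sizes_bp().sum() / 1e6
        cm = bm.chrom_sizes_cm().sum()
        assert abs(mb - 372.2) / 372.2 < 1e-3
        assert abs(cm - 1625.0) / 1625.0 < 1e-3
        # whole-genome map density 1625 / 372.2 = 4.37 cM/Mb
        assert cm / mb == pytest.approx(4.37, abs=0.02)

    def test_two_bins_one_chromosome(self):
        bm = eq.generate_bin_map(paper_scale_cfg(n_chromosomes=1, n_bins=2,
                                                 genome_mb=2.0, genome_cm=10.0))
        assert bm.n_bins == 2
        assert bm.table["phys_start"].iloc[1] == bm.table["phys_end"].iloc[0] + 1

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="n_bins"):
            eq.generate_bin_map(paper_scale_cfg(n_bins=5))


class TestRilGenetics:
    def test_switch_prob_closed_form(self):
        # r = 0.25 at fixation gives R = 2r/(1+2r) = 1/3
        d = -50.0 * np.log(1 - 2 * 0.25)
        assert haldane_r(d) == pytest.approx(0.25)
        assert ril_switch_prob(d) == pytest.approx(1.0 / 3.0)

    def test_zero_distance_identical_genotypes(self):
        table = pd.DataFrame(
            {"bin_id": ["a", "b"], "chrom": ["c1", "c1"],
             "phys_start": [1, 11], "phys_end": [10, 20], "genetic_pos": [0.0, 0.0]}
        )
        bm = eq.BinMap(table)
        G = eq.simulate_ril_genotypes(bm, paper_scale_cfg(n_lines=500, n_chromosomes=1, n_bins=2))
        assert (G.calls.iloc[:, 0] == G.calls.iloc[:, 1]).all()

    def test_monte_carlo_switch_frequency(self):
        # 10 000 line-pairs at d = 10 cM: empirical switch rate within 3 SE of R(d)
        d = 10.0
        table = pd.DataFrame(
            {"bin_id": ["a", "b"], "chrom": ["c1", "c1"],
             "phys_start": [1, 11], "phys_end": [10, 20], "genetic_pos": [0.0, d]}
        )
        bm = eq.BinMap(table)
        G = eq.simulate_ril_genotypes(bm, paper_scale_cfg(n_lines=10_000, n_chromosomes=1, n_bins=2))
        R = ril_switch_prob(d)
        emp = (G.calls.iloc[:, 0] != G.calls.iloc[:, 1]).mean()
        se = np.sqrt(R * (1 - R) / 10_000)
        assert abs(emp - R) < 3 * se

    def test_map_expansion_properties(self):
        d = np.linspace(0.1, 500, 200)
        r, R = haldane_r(d), ril_switch_prob(d)
        assert (R >= r).all()
        assert (np.diff(R) > 0).all()
        assert R[-1] == pytest.approx(0.5, abs=1e-3)

    def test_allele_frequency_balanced(self):
        cfg = paper_scale_cfg(n_chromosomes=4, n_bins=80, n_lines=400)
        bm = eq.generate_bin_map(cfg)
        G = eq.simulate_ril_genotypes(bm, cfg)
        freq = (G.calls == "B").mean(axis=0)
        # binomial 4-sigma band around 0.5 at n=400 is within [0.4, 0.6]
        assert ((freq > 0.4) & (freq < 0.6)).all()


class TestPlantedModel:
    def test_cis_coefficient_variance_fraction(self):
        # a^2 Var(g) / (a^2 Var(g) + sd^2) = ve with Var(g) = 1
        cfg = paper_scale_cfg(n_chromosomes=2, n_bins=20, n_etraits=50, n_cis=50, cis_ve=0.25)
        bm = eq.generate_bin_map(cfg)
        truth = plant_model(bm, cfg)
        a = np.abs(truth.cis_coef[truth.cis_coef != 0])
        assert np.allclose(a**2 / (a**2 + 1.0), 0.25)

    def test_regulator_target_count_and_dag_order(self):
        cfg = paper_scale_cfg(
            n_chromosomes=2, n_bins=40, n_etraits=200, n_cis=20,
            regulators=[eq.RegulatorSpec(n_targets=150),
                        eq.RegulatorSpec(n_targets=5, parent=0)],
        )
        bm = eq.generate_bin_map(cfg)
        truth = plant_model(bm, cfg)
        r1, r2 = truth.regulator_etraits
        assert len(truth.targets_of(r1)) == 150 + 1  # 150 targets plus the chained regulator
        assert r2 in truth.targets_of(r1)
        assert len(truth.targets_of(r2)) == 5

    def test_regulator_cycle_rejected(self):
        cfg = paper_scale_cfg(
            regulators=[eq.RegulatorSpec(n_targets=1, parent=1),
                        eq.RegulatorSpec(n_targets=1, parent=0)],
        )
        with pytest.raises(ValueError, match="cycle"):
            cfg.validate()


class TestExpression:
    def _tiny(self, **kw):
        cfg = paper_scale_cfg(n_chromosomes=2, n_bins=20, n_lines=40,
                              n_etraits=30, n_cis=15, **kw)
        bm = eq.generate_bin_map(cfg)
        G = eq.simulate_ril_genotypes(bm, cfg)
        truth = plant_model(bm, cfg)
        return cfg, bm, G, truth

    def test_noiseless_expression_follows_genotype_exactly(self):
        cfg, bm, G, truth = self._tiny()
        cfg.noise_sd = 0.0
        truth.cis_coef = np.where(truth.cis_coef != 0, 1.0, 0.0)  # a_g = 1
        E = simulate_expression(G, truth, cfg)
        g = int(np.flatnonzero(truth.cis_coef)[0])
        x = G.numeric()[:, truth.anchor_bin[g]]
        e = E.values.to_numpy()[g]
        mu = e[x == -1][0] + 1.0  # e = mu +/- 1 by genotype
        assert np.allclose(e, mu + x)

    def test_planted_edge_gives_strong_correlation(self):
        cfg = paper_scale_cfg(
            n_chromosomes=2, n_bins=20, n_lines=200, n_etraits=50, n_cis=10,
            regulators=[eq.RegulatorSpec(n_targets=5, target_ve=0.8)],
        )
        bm = eq.generate_bin_map(cfg)
        G = eq.simulate_ril_genotypes(bm, cfg)
        truth = plant_model(bm, cfg)
        E = simulate_expression(G, truth, cfg)
        reg = truth.regulator_etraits[0]
        V = E.values.to_numpy()
        for tgt in truth.targets_of(reg):
            assert abs(np.corrcoef(V[reg], V[tgt])[0, 1]) > 0.8

    def test_line_permutation_equivariance(self):
        cfg, bm, G, truth = self._tiny()
        E1 = simulate_expression(G, truth, cfg)
        perm = np.random.default_rng(1).permutation(G.n_lines)
        Gp = eq.GenotypeMatrix(G.calls.iloc[perm])
        E2 = simulate_expression(Gp, truth, cfg)
        pd.testing.assert_frame_equal(E1.values.iloc[:, perm], E2.values)

    def test_same_seed_byte_identical(self):
        cfg = paper_scale_cfg(n_chromosomes=3, n_bins=30, n_etraits=40, n_cis=20,
                              n_traits=2, trait_specs=None,
                              regulators=[eq.RegulatorSpec(n_targets=5)])
        a = eq.simulate_population(cfg)
        b = eq.simulate_population(cfg)
        pd.testing.assert_frame_equal(a[0].table, b[0].table)
        pd.testing.assert_frame_equal(a[1].calls, b[1].calls)
        pd.testing.assert_frame_equal(a[3].values, b[3].values)
        pd.testing.assert_frame_equal(a[4].values, b[4].values)


class TestPhenotypes:
    def test_pleiotropic_bin_shared_by_default_traits(self):
        cfg = paper_scale_cfg(n_chromosomes=3, n_bins=30, n_etraits=20, n_cis=10,
                              n_traits=3, trait_specs=None)
        bm = eq.generate_bin_map(cfg)
        truth = plant_model(bm, cfg)
        first = [m["causal"][0][0] for m in truth.trait_models[:2]]
        assert first[0] == first[1]

    def test_null_trait_is_pure_noise(self):
        cfg = paper_scale_cfg(n_chromosomes=3, n_bins=60, n_lines=200,
                              n_etraits=10, n_cis=0,
                              trait_specs=[eq.TraitSpec(name="null", causal_bins=[], n_causal=0)])
        bm, G, truth, E, P = eq.simulate_population(cfg)
        y = P.values["null"].to_numpy()
        X = G.numeric()
        r = np.array([abs(np.corrcoef(y, X[:, j])[0, 1]) for j in range(bm.n_bins)])
        assert r.max() < 0.35  # no planted signal anywhere

    def test_presence_filter_exercised(self):
        cfg = paper_scale_cfg(n_chromosomes=2, n_bins=20, n_lines=60,
                              n_etraits=100, n_cis=0, absent_fraction=0.3)
        bm, G, truth, E, P = eq.simulate_population(cfg)
        assert E.presence is not None
        kept = eq.filter_etraits(E)
        assert 0 < kept.n_etraits < E.n_etraits
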