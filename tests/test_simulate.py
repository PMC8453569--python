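"""Generator tests: determinism, Hardy-Weinberg structure, variance bookkeeping."""

import numpy as np
import pytest

from rhmscan import (
    SimulationConfig,
    simulate_dataset,
    simulate_genotypes,
    simulate_qtl_effects,
    simulate_testday_records,
)


def test_identical_seed_gives_bitwise_identical_outputs():
    cfg = SimulationConfig(
        n_animals=30, snps_per_chromosome=[50, 40], seed=7,
        parities_per_animal=2, testdays_per_lactation=(3, 4),
        qtl_windows=[("1", (10, 30), 0.02)],
    )
    ds1, tr1, tab1 = simulate_dataset(cfg)
    ds2, tr2, tab2 = simulate_dataset(cfg)
    np.testing.assert_array_equal(ds1.dosages, ds2.dosages)
    assert ds1.marker_map.equals(ds2.marker_map)
    np.testing.assert_array_equal(tr1.u, tr2.u)
    assert tab1.data.equals(tab2.data)


def test_invalid_maf_range_rejected():
    with pytest.raises(ValueError, match="maf_range"):
        SimulationConfig(maf_range=(0.0, 0.5))
    with pytest.raises(ValueError, match="maf_range"):
        SimulationConfig(maf_range=(0.1, 0.6))


def test_qtl_window_outside_chromosome_rejected():
    with pytest.raises(ValueError, match="outside chromosome"):
        SimulationConfig(
            snps_per_chromosome=[50], qtl_windows=[("1", (30, 60), 0.01)]
        )


def test_allele_frequency_and_heterozygosity_match_hardy_weinberg():
    # p fixed at 0.3: E[het fraction] = 2 * 0.3 * 0.7 = 0.42
    cfg = SimulationConfig(
        n_animals=1000, snps_per_chromosome=[200], maf_range=(0.3, 0.3),
        n_sire_families=0, seed=1,  # unrelated mode: binomial sampling error applies
    )
    ds = simulate_genotypes(cfg)
    het = (ds.dosages == 1.0).mean()
    n_draws = 1000 * 200
    se = np.sqrt(0.42 * 0.58 / n_draws)
    assert abs(het - 0.42) < 3 * se
    # symmetric case: per-SNP allele frequency ~ 0.5
    cfg = SimulationConfig(
        n_animals=500, snps_per_chromosome=[100], maf_range=(0.5, 0.5),
        n_sire_families=0, seed=2,
    )
    ds = simulate_genotypes(cfg)
    freqs = ds.dosages.mean(axis=0) / 2
    assert abs(freqs.mean() - 0.5) < 3 * np.sqrt(0.5 * 0.5 / (2 * 500 * 100))


def test_marker_map_positions_increase_within_chromosome():
    ds = simulate_genotypes(SimulationConfig(n_animals=5, snps_per_chromosome=[30, 30], seed=3))
    for chrom in ("1", "2"):
        bp = ds.marker_map.loc[ds.marker_map["chrom"] == chrom, "bp"].to_numpy()
        assert np.all(np.diff(bp) > 0)


class TestQtlEffects:
    def test_zero_regional_variance_gives_exact_zeros(self):
        cfg = SimulationConfig(
            n_animals=50, snps_per_chromosome=[60], seed=4,
            qtl_windows=[("1", (0, 30), 0.0)],
        )
        ds = simulate_genotypes(cfg)
        truth = simulate_qtl_effects(ds, cfg)
        assert np.all(truth.regional["1:0-30"] == 0.0)

    def test_rescaling_hits_target_variance_exactly_in_grm_metric(self):
        from rhmscan import build_grm

        cfg = SimulationConfig(
            n_animals=80, snps_per_chromosome=[100], maf_range=(0.2, 0.5), seed=5,
            true_components={"u": 0.25, "pu": 0, "pw": 0, "h": 0, "e": 0.5},
            qtl_windows=[("1", (20, 60), 0.03)],
        )
        ds = simulate_genotypes(cfg)
        truth = simulate_qtl_effects(ds, cfg)

        def metric_var(values, snps):
            g = build_grm(ds, snps)
            return float(values @ g.pinv() @ values) / g.rank

        v = truth.regional["1:20-60"]
        assert metric_var(v, np.arange(20, 60)) == pytest.approx(0.03, rel=1e-9)
        assert metric_var(truth.u, np.arange(100)) == pytest.approx(0.25, rel=1e-9)
        # the plain sample variance scales with the GRM diagonal
        g_v = build_grm(ds, np.arange(20, 60))
        expected_sample = 0.03 * np.mean(np.diag(g_v.matrix))
        assert np.var(v, ddof=1) == pytest.approx(expected_sample, rel=0.5)

    def test_monomorphic_window_raises_naming_the_window(self):
        cfg = SimulationConfig(
            n_animals=20, snps_per_chromosome=[40], seed=6,
            qtl_windows=[("1", (0, 10), 0.02)],
        )
        ds = simulate_genotypes(cfg)
        ds.dosages[:, 0:10] = 1.0  # constant: no variance in the window
        with pytest.raises(ValueError, match=r"1:\[0,10\)"):
            simulate_qtl_effects(ds, cfg)

    def test_disjoint_windows_give_uncorrelated_breeding_values(self):
        rs = []
        for seed in range(8):
            cfg = SimulationConfig(
                n_animals=1000, snps_per_chromosome=[80], seed=seed,
                qtl_windows=[("1", (0, 30), 0.02), ("1", (40, 70), 0.02)],
            )
            ds = simulate_genotypes(cfg)
            truth = simulate_qtl_effects(ds, cfg)
            r = np.corrcoef(truth.regional["1:0-30"], truth.regional["1:40-70"])[0, 1]
            rs.append(abs(r))
        assert np.median(rs) < 0.1


class TestTestdayRecords:
    def test_all_zero_variances_and_coefficients_give_zero_records(self):
        cfg = SimulationConfig(
            n_animals=10, snps_per_chromosome=[20], seed=8,
            true_components={k: 0.0 for k in ("u", "pu", "pw", "h", "e")},
            fixed_effect_coefficients={
                "intercept": np.zeros(1), "parity": np.zeros(5),
                "litter_size": np.zeros(2), "season": np.zeros(2), "fim": np.zeros(22),
            },
        )
        ds, truth, tab = simulate_dataset(cfg)
        assert np.all(tab.data["fpc"].to_numpy() == 0.0)

    def test_residual_only_variance_recovered(self):
        cfg = SimulationConfig(
            n_animals=300, snps_per_chromosome=[20], seed=9,
            true_components={"u": 0, "pu": 0, "pw": 0, "h": 0, "e": 1.0},
            parities_per_animal=3, testdays_per_lactation=(4, 6),
        )
        _, _, tab = simulate_dataset(cfg)
        v = tab.data["fpc"].to_numpy()
        v = v - v.mean()
        n = v.size
        # chi-square interval for a sample variance of ~n iid N(0,1) records
        assert abs(np.var(v, ddof=1) - 1.0) < 4 * np.sqrt(2.0 / n)

    def test_records_within_a_parity_share_permanent_effects(self):
        cfg = SimulationConfig(
            n_animals=20, snps_per_chromosome=[30], seed=10,
            true_components={"u": 0.5, "pu": 0.5, "pw": 0.5, "h": 0.0, "e": 0.0},
            fixed_effect_coefficients={
                "intercept": np.zeros(1), "parity": np.zeros(5),
                "litter_size": np.zeros(2), "season": np.zeros(2), "fim": np.zeros(22),
            },
            parities_per_animal=1, testdays_per_lactation=(3, 3),
        )
        ds, truth, tab = simulate_dataset(cfg)
        # with h = e = 0 and no fixed effects, records repeat u+pu+pw exactly
        for _, grp in tab.data.groupby(["animal_id", "parity"]):
            assert grp["fpc"].nunique() == 1

    def test_zero_testdays_rejected(self):
        with pytest.raises(ValueError, match="testdays_per_lactation"):
            SimulationConfig(testdays_per_lactation=(0, 0))

    def test_parity_capped_and_record_counts_in_range(self, small_sim):
        cfg, dataset, truth, table = small_sim
        assert table.data["parity"].max() <= 5
        counts = table.data.groupby(["animal_id", "parity"]).size()
        assert counts.max() <= cfg.testdays_per_lactation[1]

    def test_phenotypic_variance_adds_up(self):
        comps = {"u": 0.15, "pu": 0.1, "pw": 0.1, "h": 0.3, "e": 0.35}
        cfg = SimulationConfig(
            n_animals=400, snps_per_chromosome=[100], seed=11,
            true_components=comps,
            qtl_windows=[("1", (20, 70), 0.05)],
            fixed_effect_coefficients={
                "intercept": np.zeros(1), "parity": np.zeros(5),
                "litter_size": np.zeros(2), "season": np.zeros(2), "fim": np.zeros(22),
            },
            parities_per_animal=3, testdays_per_lactation=(4, 6),
        )
        _, _, tab = simulate_dataset(cfg)
        total = sum(comps.values()) + 0.05
        observed = tab.data["fpc"].var(ddof=1)
        assert observed == pytest.approx(total, rel=0.15)
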