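"""REML engine: likelihood oracles, optimizer behaviour, ratios, LRT machinery."""

import math

import numpy as np
import pytest

from rhmscan import (
    SimulationConfig,
    VarianceComponents,
    build_grm,
    build_model_frame,
    derived_ratios,
    fit_reml,
    fortnight_in_milk,
    lrt,
    mixture_pvalue,
    restricted_loglik,
    simulate_dataset,
    TestDayREML,
)
from .conftest import make_table
from .oracles import dense_restricted_loglik, residual_only_reml


def _tiny_frame(seed, n_animals=8, trait="fpc", with_regional=False):
    cfg = SimulationConfig(
        n_animals=n_animals,
        snps_per_chromosome=[30, 20],
        maf_range=(0.25, 0.5),
        parities_per_animal=2,
        testdays_per_lactation=(3, 3),
        seed=seed,
    )
    ds, _, tab = simulate_dataset(cfg)
    # keep the record count small for the dense oracle
    tab.data = tab.data.iloc[: min(30, len(tab.data))].reset_index(drop=True)
    tab = type(tab)(tab.data)
    grms = {"u": build_grm(ds)}
    if with_regional:
        grms["v"] = build_grm(ds, np.arange(10), None)
    return build_model_frame(tab, trait, grms)


class TestModelFrame:
    def test_random_term_level_counts(self):
        rows = []
        for a in ("a", "b", "c"):
            for parity in (1, 2):
                for k in (0, 1):
                    rows.append((a, "1", 100 * parity + 30 * k + 10, 100 * parity,
                                 parity, 1, 1, 30 * k + 10))
        table = make_table(rows)
        from rhmscan import GRM

        grm = GRM(np.eye(3), ["a", "b", "c"], n_snps=10)
        frame = build_model_frame(table, "fpc", {"u": grm})
        assert frame.term("pw").n_levels == 6
        assert frame.term("pu").n_levels == 3
        # all records in one flock on 4 dates -> 4 flock-test-day levels
        assert frame.term("h").n_levels == 4

    def test_fortnight_capping(self):
        assert fortnight_in_milk(295) == 22  # ceil(295/14) = 22
        assert fortnight_in_milk(1) == 1
        assert fortnight_in_milk(320) == 22  # capped
        np.testing.assert_array_equal(fortnight_in_milk(np.array([14, 15])), [1, 2])

    def test_unknown_trait_and_missing_animals(self, small_sim):
        _, dataset, _, table = small_sim
        grm = build_grm(dataset)
        with pytest.raises(ValueError, match="unknown trait"):
            build_model_frame(table, "nope", {"u": grm})
        half = grm.align(dataset.sample_ids[:20])
        with pytest.raises(ValueError, match="absent"):
            build_model_frame(table, "fpc", {"u": half})

    def test_full_column_rank(self, small_frame):
        assert np.linalg.matrix_rank(small_frame.X) == small_frame.p


class TestRestrictedLoglik:
    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_dense_oracle(self, seed):
        frame = _tiny_frame(seed, with_regional=(seed % 2 == 0))
        rng = np.random.default_rng(seed)
        comps = {t.name: float(rng.uniform(0.05, 0.8)) for t in frame.terms}
        comps["e"] = float(rng.uniform(0.2, 1.0))
        ours = restricted_loglik(frame, comps)
        oracle = dense_restricted_loglik(frame, comps)
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_residual_only_matches_closed_form(self):
        frame = _tiny_frame(3)
        s2, loglik = residual_only_reml(frame)
        zeros = {t.name: 0.0 for t in frame.terms}
        assert restricted_loglik(frame, {**zeros, "e": s2}) == pytest.approx(
            loglik, abs=1e-8
        )
        # and s2 maximizes: nearby points are worse
        for fac in (0.8, 1.25):
            assert restricted_loglik(frame, {**zeros, "e": s2 * fac}) < loglik

    def test_invariant_to_record_order(self):
        frame = _tiny_frame(4)
        comps = {t.name: 0.3 for t in frame.terms} | {"e": 0.5}
        base = restricted_loglik(frame, comps)
        rng = np.random.default_rng(0)
        perm = rng.permutation(frame.n)
        import dataclasses

        shuffled = dataclasses.replace(
            frame,
            y=frame.y[perm],
            X=frame.X[perm],
            terms=[
                dataclasses.replace(t, level_index=t.level_index[perm])
                for t in frame.terms
            ],
            animal_ids=[frame.animal_ids[i] for i in perm],
        )
        assert restricted_loglik(shuffled, comps) == pytest.approx(base, abs=1e-8)

    def test_differences_invariant_to_fixed_effect_shift(self):
        # adding a vector in the column space of X shifts neither REML logL
        # nor, a fortiori, any logL difference
        frame = _tiny_frame(5)
        comps = {t.name: 0.2 for t in frame.terms} | {"e": 0.4}
        base = restricted_loglik(frame, comps)
        import dataclasses

        shifted = dataclasses.replace(frame, y=frame.y + frame.X @ np.ones(frame.p))
        assert restricted_loglik(shifted, comps) == pytest.approx(base, abs=1e-8)

    def test_zero_residual_rejected(self):
        frame = _tiny_frame(6)
        with pytest.raises(ValueError, match="residual"):
            restricted_loglik(frame, {t.name: 0.1 for t in frame.terms} | {"e": 0.0})


class TestFitReml:
    def test_pure_residual_simulation_sends_others_to_boundary(self):
        cfg = SimulationConfig(
            n_animals=120, snps_per_chromosome=[150], maf_range=(0.1, 0.5),
            true_components={"u": 0, "pu": 0, "pw": 0, "h": 0, "e": 1.0},
            parities_per_animal=2, testdays_per_lactation=(4, 5), seed=21,
        )
        ds, _, tab = simulate_dataset(cfg)
        frame = build_model_frame(tab, "fpc", {"u": build_grm(ds)})
        fit = fit_reml(frame)
        assert fit.converged
        comps = fit.components.as_dict()
        vary = np.var(frame.y, ddof=1)
        for name in ("u", "pu", "pw", "h"):
            assert comps[name] < 0.05 * vary
        se_e = fit.components.se["e"]
        assert abs(comps["e"] - 1.0) < 3 * se_e

    def test_optimum_beats_random_grid(self):
        frame = _tiny_frame(7, n_animals=12)
        fit = fit_reml(frame)
        rng = np.random.default_rng(1)
        vary = np.var(frame.y, ddof=1)
        for _ in range(5):
            comps = {t.name: float(rng.uniform(0.01, 1.0) * vary) for t in frame.terms}
            comps["e"] = float(rng.uniform(0.05, 1.0) * vary)
            assert fit.loglik >= restricted_loglik(frame, comps) - 1e-6

    def test_loglik_not_below_initial_point(self, small_frame):
        fit = fit_reml(small_frame)
        k = len(small_frame.terms) + 1
        vary = np.var(small_frame.y, ddof=1)
        init = {t.name: vary / k for t in small_frame.terms} | {"e": vary / k}
        assert fit.loglik >= restricted_loglik(small_frame, init) - 1e-9

    def test_recovery_within_sampling_error(self):
        # single medium replicate.  u (additive, GRM) and pu (permanent env,
        # identity on animals) are strongly negatively correlated estimators
        # in a half-sib design, so the single-replicate check targets their
        # sum plus the well-identified components; the replicate-averaged
        # recovery of the individual components lives in the acceptance suite.
        truth = {"u": 0.11, "pu": 0.07, "pw": 0.06, "h": 0.40, "e": 0.36}
        cfg = SimulationConfig(
            n_animals=250, snps_per_chromosome=[300] * 4,
            true_components=dict(truth), parities_per_animal=3,
            testdays_per_lactation=(3, 4), seed=22,
        )
        ds, _, tab = simulate_dataset(cfg)
        frame = build_model_frame(tab, "fpc", {"u": build_grm(ds)})
        fit = fit_reml(frame)
        assert fit.converged
        comps = fit.components.as_dict()
        cov = fit.components.covariance
        sum_est = comps["u"] + comps["pu"]
        idx = [n for n in ("u", "pu") if n in cov.index]
        g = np.ones(len(idx))
        se_sum = math.sqrt(float(g @ cov.loc[idx, idx].to_numpy() @ g))
        assert abs(sum_est - (truth["u"] + truth["pu"])) < 4 * se_sum
        for name in ("pw", "h", "e"):
            est, se = comps[name], fit.components.se[name]
            assert abs(est - truth[name]) < 4 * se, (name, est, se)

    def test_results_summary_renders(self, small_sim):
        _, dataset, _, table = small_sim
        res = TestDayREML(table, "fpc", build_grm(dataset)).fit()
        text = res.summary()
        assert "sigma_p" in text and "h2" in text and res.converged


class TestDerivedRatios:
    # printed variance-component tables for five milk traits:
    # (u, pu, pw, h, total) and the expected ratios at 2 dp
    CASES = [
        ("MY", (24811, 16967, 52716, 96410, 254968), (0.10, 0.16, 0.37, 0.38)),
        ("F%", (0.1276, 0.0734, 0.0620, 0.4530, 1.1201), (0.11, 0.18, 0.23, 0.40)),
        ("P%", (0.0588, 0.0306, 0.0257, 0.1269, 0.3786), (0.15, 0.24, 0.30, 0.33)),
        ("PY", (71, 44, 168, 333, 805), (0.09, 0.14, 0.35, 0.41)),
    ]

    @pytest.mark.parametrize("name,comps,expected", CASES, ids=[c[0] for c in CASES])
    def test_published_component_tables(self, name, comps, expected):
        u, pu, pw, h, total = comps
        vc = VarianceComponents.from_total(u, pu, pw, h, total)
        r = vc.ratios()
        got = (r["h2"], r["r_acr"], r["r_wit"], r["ftd2"])
        for g, e in zip(got, expected):
            assert abs(g - e) <= 0.01
        # ordering invariant h2 <= r_acr <= r_wit
        assert r["h2"] <= r["r_acr"] <= r["r_wit"]

    def test_all_residual_gives_zero_ratios(self):
        vc = VarianceComponents(u=0, pu=0, pw=0, h=0, e=2.0)
        assert all(v == 0.0 for v in vc.ratios().values())

    def test_zero_phenotypic_variance_rejected(self):
        vc = VarianceComponents(u=0, pu=0, pw=0, h=0, e=0.0)
        with pytest.raises(ValueError):
            vc.ratios()

    def test_delta_method_se_positive_on_fit(self, small_frame):
        fit = fit_reml(small_frame)
        out = derived_ratios(fit.components)
        for name, (val, se) in out.items():
            assert 0.0 <= val <= 1.0
            assert se >= 0.0 and np.isfinite(se)


class TestLrtMachinery:
    def _fits(self, l_full, l_null):
        from rhmscan.model import FitResult

        def mk(l):
            return FitResult(
                components=VarianceComponents(u=0.1, pu=0.1, pw=0.1, h=0.1, e=0.6),
                loglik=l, converged=True, n_iter=3, grad_norm=0.0,
                ai_matrix=None, pinned=[], n_records=100, rank_x=5,
                trait="fpc", dropped_columns=[],
            )

        return mk(l_full), mk(l_null)

    def test_basic_difference(self):
        full, null = self._fits(-100.0, -105.0)
        assert lrt(full, null) == pytest.approx(10.0)

    def test_identical_likelihoods(self):
        full, null = self._fits(-50.0, -50.0)
        assert lrt(full, null) == 0.0

    def test_numerically_negative_clamped_with_flag(self):
        full, null = self._fits(-50.0 - 5e-10, -50.0)
        stat, clamped = lrt(full, null, return_clamped=True)
        assert stat == 0.0 and clamped

    def test_mismatched_frames_rejected(self):
        full, null = self._fits(-1.0, -2.0)
        null.n_records = 99
        with pytest.raises(ValueError, match="same records"):
            lrt(full, null)

    def test_mixture_pvalues(self):
        assert mixture_pvalue(0.0) == 1.0
        assert mixture_pvalue(13.48) == pytest.approx(1.21e-4, rel=0.005)
        # chi2(1) 95th percentile halved
        assert mixture_pvalue(3.841458820694124) == pytest.approx(0.025, rel=1e-6)
        with pytest.raises(ValueError):
            mixture_pvalue(-1.0)
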