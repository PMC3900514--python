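import numpy as np
import pandas as pd
import pytest

from trawlsim import params
from trawlsim.economics import (CatchMatrix, CostModel, PriceSchedule,
                                catches, closed_form_q, estimate_q,
                                estimate_q_from_catches, fit_cost_model,
                                gains, medits_catchability, predict_cost,
                                revenue, selectivity, spatial_f, total_F,
                                weight_at_length)

TABLE_COST = params.DEFAULT_COST_MODEL


class TestSelectivity:
    @pytest.mark.parametrize("species", ["DPS", "HKE", "MUT"])
    def test_half_retention_at_L50(self, species):
        p = params.DEFAULT_SPECIES_PARAMS[species]
        assert selectivity(p.L50, p.L50, p.L75) == pytest.approx(0.5)

    @pytest.mark.parametrize("species", ["DPS", "HKE", "MUT"])
    def test_three_quarters_at_L75(self, species):
        p = params.DEFAULT_SPECIES_PARAMS[species]
        assert selectivity(p.L75, p.L50, p.L75) == pytest.approx(0.75)

    def test_quarter_at_mirror_point(self):
        # logistic symmetry about L50: S(2*L50 - L75) = 0.25
        assert selectivity(2 * 15 - 18, 15, 18) == pytest.approx(0.25)

    def test_strictly_increasing_with_limits(self):
        l = np.linspace(-200, 400, 500)
        s = selectivity(l, 90, 110)
        assert (np.diff(s) > 0).all()
        assert selectivity(-1e5, 90, 110) < 1e-10
        assert selectivity(1e5, 90, 110) == pytest.approx(1.0)

    def test_requires_L75_above_L50(self):
        with pytest.raises(ValueError):
            selectivity(10, 20, 20)


class TestSpatialF:
    def test_zero_effort_zero_mortality(self):
        f = spatial_f(0.002, [0.5, 1.0], [0, 0])
        assert np.allclose(f, 0.0)

    def test_arithmetic(self):
        f = spatial_f(0.002, [1.0], [100])
        assert f[0, 0] == pytest.approx(0.2)

    def test_increasing_in_length(self):
        sel = selectivity(np.arange(10, 200, 5), 90, 110)
        f = spatial_f(0.002, sel, [10])
        assert (np.diff(f[0]) > 0).all()


class TestEstimateQ:
    def test_uniform_effort_closed_form(self, rng):
        n = rng.uniform(1, 100, 30)
        e = np.full(30, 600.0)
        assert estimate_q(1.2, n, e) == pytest.approx(1.2 / 600, rel=1e-9)

    def test_example_arithmetic(self):
        n = np.ones(5)
        e = np.full(5, 600.0)
        assert estimate_q(1.2, n, e) == pytest.approx(0.002, rel=1e-9)

    def test_matches_closed_form_on_100_random_instances(self, rng):
        for _ in range(100):
            m = rng.integers(3, 40)
            n = rng.uniform(0.1, 50, m)
            e = rng.integers(1, 200, m).astype(float)
            F = rng.uniform(0.2, 2.0)
            assert estimate_q(F, n, e) == pytest.approx(
                closed_form_q(F, n, e), rel=1e-6)

    def test_recovers_generative_q(self, rng):
        q_true = params.DEFAULT_SPECIES_PARAMS["DPS"].q   # 0.0022
        n = rng.uniform(1, 100, 100)
        e = rng.integers(1, 50, 100).astype(float)
        ref = q_true * e * n                    # catches generated under q
        q_hat = estimate_q_from_catches(ref, n, e)
        assert q_hat == pytest.approx(q_true, abs=1e-4)

    def test_unidentifiable_errors(self):
        with pytest.raises(ValueError):
            estimate_q(1.0, np.ones(3), np.zeros(3))


class TestMeditsCatchability:
    @pytest.mark.parametrize("lca,swept,expected",
                             [(85, 100, 0.85), (15, 100, 0.15), (7, 7, 1.0)])
    def test_ratio(self, lca, swept, expected):
        assert medits_catchability(lca, swept) == pytest.approx(expected)

    def test_ratio_above_one_logged(self, caplog):
        with caplog.at_level("WARNING"):
            q = medits_catchability(120, 100)
        assert q == pytest.approx(1.2)
        assert "herding" in caplog.text

    def test_zero_swept_errors(self):
        with pytest.raises(ValueError):
            medits_catchability(1.0, 0.0)


def simple_weight(l):
    return np.asarray(l, dtype=float) * 10.0   # grams


class TestCatches:
    def test_zero_f_zero_catch(self):
        cm = catches(np.full((3, 2), 50.0), [10, 20], 0.9,
                     np.zeros((3, 2)), simple_weight)
        assert cm.total_numbers() == 0.0

    def test_point_example(self):
        # n = qM*index = 100, f = 0.1 -> c = 10
        cm = catches(np.array([[125.0]]), [10.0], 0.8,
                     np.array([[0.1]]), simple_weight)
        assert cm.standing[0, 0] == pytest.approx(100.0)
        assert cm.numbers[0, 0] == pytest.approx(10.0)
        assert cm.biomass_kg[0, 0] == pytest.approx(10 * 100 / 1000)

    def test_matches_double_loop_oracle(self, rng):
        index = rng.uniform(0, 200, size=(6, 4))
        f = rng.uniform(0, 0.5, size=(6, 4))
        mids = np.array([10.0, 20.0, 30.0, 40.0])
        qM = 0.85
        cm = catches(index, mids, qM, f, simple_weight)
        total = 0.0
        kg = 0.0
        for c in range(6):
            for l in range(4):
                n = qM * index[c, l]
                catch = n * f[c, l]
                total += catch
                kg += catch * simple_weight(mids[l]) / 1000
        assert cm.total_numbers() == pytest.approx(total, rel=1e-12)
        assert cm.total_biomass_kg() == pytest.approx(kg, rel=1e-12)

    def test_harvest_rate_capped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            cm = catches(np.array([[10.0]]), [10.0], 1.0,
                         np.array([[1.7]]), simple_weight)
        assert cm.numbers[0, 0] == pytest.approx(10.0)   # capped at n
        assert "capped" in caplog.text

    def test_homogeneous_degree_one_in_abundance(self, rng):
        index = rng.uniform(0, 100, size=(4, 3))
        f = rng.uniform(0, 0.4, size=(4, 3))
        mids = [5.0, 10.0, 15.0]
        one = catches(index, mids, 0.5, f, simple_weight)
        two = catches(3 * index, mids, 0.5, f, simple_weight)
        assert two.total_numbers() == pytest.approx(3 * one.total_numbers())
        assert two.total_biomass_kg() == pytest.approx(
            3 * one.total_biomass_kg())


class TestRevenue:
    def test_one_kg_large_dps(self):
        cm = CatchMatrix(species="DPS", midpoints=np.array([32.0]),
                         standing=np.array([[10.0]]),
                         numbers=np.array([[1.0]]),
                         biomass_kg=np.array([[1.0]]))
        assert revenue(cm, params.DEFAULT_PRICES["DPS"]) == pytest.approx(16.0)

    def test_two_kg_mid_band(self):
        cm = CatchMatrix(species="DPS", midpoints=np.array([23.0]),
                         standing=np.array([[10.0]]),
                         numbers=np.array([[2.0]]),
                         biomass_kg=np.array([[2.0]]))
        assert revenue(cm, params.DEFAULT_PRICES["DPS"]) == pytest.approx(10.0)

    def test_zero_catch(self):
        cm = CatchMatrix(species="DPS", midpoints=np.array([23.0]),
                         standing=np.zeros((1, 1)), numbers=np.zeros((1, 1)),
                         biomass_kg=np.zeros((1, 1)))
        assert revenue(cm, params.DEFAULT_PRICES["DPS"]) == 0.0

    def test_unpriced_class_errors_with_names(self):
        sched = PriceSchedule("MUT", [(0.0, 100.0, 5.0)])
        cm = CatchMatrix(species="MUT", midpoints=np.array([150.0]),
                         standing=np.ones((1, 1)), numbers=np.ones((1, 1)),
                         biomass_kg=np.ones((1, 1)))
        with pytest.raises(KeyError, match="MUT.*150"):
            revenue(cm, sched)


def plane_records(n=6, seed=0):
    r = np.random.default_rng(seed)
    ps = r.uniform(1e4, 5e4, n)
    fuel = r.uniform(0.9, 1.4, n)
    tc = TABLE_COST.beta0 + TABLE_COST.beta_ps * ps + TABLE_COST.beta_e * fuel
    return pd.DataFrame({"PS": ps, "E": fuel, "TC": tc})


class TestCostModel:
    def test_noiseless_recovery_exact(self):
        model = fit_cost_model(plane_records())
        assert model.beta_ps == pytest.approx(TABLE_COST.beta_ps, rel=1e-9)
        assert model.beta_e == pytest.approx(TABLE_COST.beta_e, rel=1e-9)
        assert model.beta0 == pytest.approx(TABLE_COST.beta0, rel=1e-9)
        assert model.fitted

    def test_constant_ps_flagged_singular(self):
        df = plane_records()
        df["PS"] = 1000.0
        model = fit_cost_model(df)
        assert model.singular

    def test_residuals_orthogonal_to_regressors(self, rng):
        df = plane_records()
        df["TC"] = df["TC"] + rng.normal(0, 1e5, len(df))
        model = fit_cost_model(df)
        resid = df["TC"] - (model.beta0 + model.beta_ps * df["PS"]
                            + model.beta_e * df["E"])
        scale = np.abs(df["TC"]).max()
        assert abs(resid.sum()) / scale < 1e-8
        assert abs((resid * df["PS"]).sum()) / (scale * df["PS"].max()) < 1e-8
        assert abs((resid * df["E"]).sum()) / (scale * df["E"].max()) < 1e-8

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            fit_cost_model(plane_records(n=3))

    def test_predict_cost_examples(self):
        model = CostModel(beta0=-1.607e7, beta_ps=220.0, beta_e=1.321e7)
        assert predict_cost(model, 0.0, 0.0) == pytest.approx(-1.607e7)
        assert predict_cost(model, 1e4, 1.25) == pytest.approx(2_642_500.0)

    def test_predict_cost_linearity(self):
        model = CostModel(beta0=1.0, beta_ps=3.0, beta_e=7.0)
        delta = 12.5
        assert (predict_cost(model, 10 + delta, 2.0)
                - predict_cost(model, 10, 2.0)) == pytest.approx(3.0 * delta)


class TestGains:
    @pytest.mark.parametrize("r,tc,expected", [(0, 0, 0), (100, 40, 60)])
    def test_examples(self, r, tc, expected):
        assert gains(r, tc) == expected

    def test_identity(self, rng):
        r, tc = rng.uniform(0, 1e6, 2)
        assert gains(r, tc) + tc == pytest.approx(r)


class TestTotalF:
    def cm(self, standing, numbers):
        standing = np.asarray(standing, dtype=float)
        numbers = np.asarray(numbers, dtype=float)
        return CatchMatrix(species="X", midpoints=np.zeros(standing.shape[1]),
                           standing=standing, numbers=numbers,
                           biomass_kg=numbers)

    def test_constant_harvest_rate(self, rng):
        n = rng.uniform(1, 100, size=(5, 3))
        assert total_F(self.cm(n, 0.1 * n)) == pytest.approx(0.1)

    def test_small_f_doubles_with_effort(self, rng):
        sel = selectivity(np.array([15.0, 25.0]), 15, 18)
        n = rng.uniform(10, 100, size=(6, 2))
        e = rng.integers(1, 5, 6).astype(float)
        for mult, tol in [(2.0, 1e-12)]:
            f1 = np.minimum(spatial_f(1e-4, sel, e), 1.0)
            f2 = np.minimum(spatial_f(1e-4, sel, mult * e), 1.0)
            F1 = total_F(self.cm(n, n * f1))
            F2 = total_F(self.cm(n, n * f2))
            assert F2 == pytest.approx(mult * F1, rel=1e-9)

    def test_invariant_to_cell_relabeling(self, rng):
        n = rng.uniform(1, 100, size=(5, 2))
        c = n * rng.uniform(0, 0.5, size=(5, 2))
        perm = rng.permutation(5)
        assert total_F(self.cm(n, c)) == pytest.approx(
            total_F(self.cm(n[perm], c[perm])))

    def test_zero_abundance_errors(self):
        with pytest.raises(ValueError):
            total_F(self.cm(np.zeros((2, 2)), np.zeros((2, 2))))


class TestWeightAtLength:
    def test_power_law(self):
        assert weight_at_length(144.0, 0.00001532, 2.942) == pytest.approx(
            0.00001532 * 144.0 ** 2.942)

    def test_negative_length_errors(self):
        with pytest.raises(ValueError):
            weight_at_length(-1.0, 0.01, 3.0)


class TestSpeciesParams:
    def test_table_invariants_hold(self):
        for p in params.DEFAULT_SPECIES_PARAMS.values():
            assert p.L75 > p.L50 > 0
            assert p.q > 0 and 0 < p.qM <= 1

    def test_invalid_selectivity_order_rejected(self):
        from trawlsim.economics import SexParams, SpeciesParams
        sex = SexParams(linf=100, k=0.5, t0=0.0, M=1.0, a=0.001, b=3.0)
        with pytest.raises(ValueError):
            SpeciesParams(code="X", male=sex, female=sex, L50=50, L75=40,
                          q=0.001, qM=0.5, F_lca_mean=1.0, F_lca_sd=0.1)


class TestPriceSchedule:
    def test_bands_must_be_contiguous(self):
        with pytest.raises(ValueError):
            PriceSchedule("X", [(0.0, 10.0, 1.0), (12.0, 20.0, 2.0)])

    def test_open_top_band(self):
        sched = params.DEFAULT_PRICES["DPS"]
        assert sched.price_for(30.0) == 16.0
        assert sched.price_for(500.0) == 16.0
        assert sched.price_for(20.9) == 2.5
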