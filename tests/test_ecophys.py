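import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from algevo import ecophys as ep
from algevo import synthetic_data as sd


def make_curve(times, od, **kw):
    defaults = dict(strain="s", substrate="x", fraction="u", replicate=1)
    defaults.update(kw)
    return ep.GrowthCurve(time=times, od=od, **defaults)


class TestFitGrowth:
    def test_noiseless_logistic_recovery(self):
        t = sd.growth_time_grid()
        od = sd.logistic(t, 0.5, 1.0, 0.01)
        fit = ep.fit_growth(make_curve(t, od))
        assert fit.model == "logistic"
        assert abs(fit.r - 0.5) < 1e-6
        assert abs(fit.K - 1.0) < 1e-6

    def test_flat_curve_is_no_growth(self):
        t = sd.growth_time_grid()
        fit = ep.fit_growth(make_curve(t, np.full_like(t, 0.01)))
        assert fit.model == "none"
        assert math.isnan(fit.lag)

    def test_peak_decline_uses_exponential_window(self):
        t = np.arange(0.0, 30.0)
        od = np.where(t <= 12, 0.01 * np.exp(0.4 * np.minimum(t, 12)),
                      0.01 * np.exp(0.4 * 12) * np.exp(-0.15 * (t - 12)))
        fit = ep.fit_growth(make_curve(t, od))
        assert fit.model == "exponential"
        assert abs(fit.r - 0.4) < 0.05

    def test_scale_equivariance(self):
        t = sd.growth_time_grid()
        od = sd.logistic(np.clip(t - 4.0, 0, None), 0.45, 0.8, 0.01)
        f1 = ep.fit_growth(make_curve(t, od))
        f2 = ep.fit_growth(make_curve(t, 3.0 * od))
        assert abs(f1.r - f2.r) < 1e-6
        assert abs(f2.K - 3 * f1.K) < 1e-5
        assert abs(f2.n0 - 3 * f1.n0) < 1e-6
        assert abs(f1.lag - f2.lag) < 1e-5

    @pytest.mark.parametrize("lag", [0.0, 6.0, 18.0])
    def test_noisy_lag_recovery(self, lag):
        prm = pd.DataFrame(
            [dict(strain="s", substrate="x", fraction="u", r=0.4, K=1.0,
                  n0=0.01, lag=lag)]
        )
        errs = []
        for rep in range(5):
            df = sd.sim_growth(prm, seed=rep, noise_sigma=0.01, replicates=1)
            fit = ep.fit_growth(
                make_curve(df.time_h.to_numpy(), df.od600.to_numpy())
            )
            errs.append(abs(fit.lag - lag))
        assert np.median(errs) < 1.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="6 time points"):
            make_curve(np.arange(4.0), np.ones(4))


class TestClassifyGrowth:
    def frame(self, r, dod):
        return pd.DataFrame(
            [dict(strain="s", substrate="x", fraction="u",
                  r=r, K=0.01 + dod, n0=0.01, lag=0.0)]
        )

    def test_clear_growth(self):
        out = ep.classify_growth(self.frame(0.5, 0.9))
        assert bool(out.iloc[0].grows)

    def test_spurious_rate_on_flat_data(self):
        out = ep.classify_growth(self.frame(0.5, 0.01))
        assert not bool(out.iloc[0].grows)

    def test_simulated_panel_classification(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(30):
            grower = i % 2 == 0
            rows.append(
                dict(strain=f"s{i}", substrate="x", fraction="u",
                     r=float(rng.uniform(0.2, 0.6)) if grower else 0.0,
                     K=float(rng.uniform(0.5, 1.0)), n0=0.01,
                     lag=float(rng.uniform(0, 10)) if grower else 0.0)
            )
        prm = pd.DataFrame(rows)
        curves = sd.sim_growth(prm, seed=1, noise_sigma=0.01, replicates=1)
        _, mean = ep.fit_growth_table(curves)
        calls = ep.classify_growth(mean).set_index("strain")
        correct = sum(
            bool(calls.loc[f"s{i}"].grows) == (i % 2 == 0) for i in range(30)
        )
        assert correct >= 29


class TestFisher:
    def test_single_discordant_pair(self):
        table = pd.DataFrame(dict(g=[True, False], ph=[True, False]))
        _, p, _ = ep.genotype_phenotype_test(table, "g", "ph")
        assert p == 1.0

    def test_perfect_separation_closed_form(self):
        table = pd.DataFrame(dict(g=[True] * 10 + [False] * 10,
                                  ph=[True] * 10 + [False] * 10))
        orr, p, tab = ep.genotype_phenotype_test(table, "g", "ph")
        assert np.isclose(p, 2 / math.comb(20, 10), rtol=1e-12)
        assert orr > 1

    def test_balanced_table_symmetric(self):
        table = pd.DataFrame(dict(g=[True] * 10 + [False] * 10,
                                  ph=([True] * 5 + [False] * 5) * 2))
        orr, p, _ = ep.genotype_phenotype_test(table, "g", "ph")
        assert p == 1.0
        assert orr == 1.0

    def test_degenerate_margin_rejected(self):
        table = pd.DataFrame(dict(g=[True, True], ph=[True, False]))
        with pytest.raises(ValueError, match="degenerate"):
            ep.genotype_phenotype_test(table, "g", "ph")

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_table_enumeration(self, seed):
        """Oracle: sum point probabilities <= observed over all tables with
        the same margins, in exact rational arithmetic."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 41))
        g = rng.random(n) < rng.uniform(0.2, 0.8)
        ph = rng.random(n) < rng.uniform(0.2, 0.8)
        if g.all() or (~g).all() or ph.all() or (~ph).all():
            pytest.skip("degenerate margins")
        table = pd.DataFrame(dict(g=g, ph=ph))
        _, p, tab = ep.genotype_phenotype_test(table, "g", "ph")
        (a, b), (c, d) = tab
        r1, r2 = a + b, c + d
        c1 = a + c

        def point(aa):
            return Fraction(
                math.comb(r1, aa) * math.comb(r2, c1 - aa), math.comb(n, c1)
            )

        obs = point(a)
        total = sum(
            point(aa)
            for aa in range(max(0, c1 - r2), min(r1, c1) + 1)
            if point(aa) <= obs
        )
        assert np.isclose(p, float(total), rtol=1e-9)


class TestActivitySlope:
    def test_linear_series(self):
        t = np.arange(0.0, 30.0)
        slope, ok = ep.activity_slope(t, 0.02 * t, 0.5)
        assert ok and np.isclose(slope, 0.04)

    def test_saturating_series_uses_rising_window(self):
        t = np.arange(0.0, 30.0)
        peak = 0.02 * 9
        # saturation with post-peak decline (product breakdown): flat and
        # falling windows never qualify as the activity phase
        y = np.where(t <= 9, 0.02 * t, peak - 0.005 * (t - 9))
        slope, ok = ep.activity_slope(t, y, 1.0)
        assert ok and abs(slope - 0.02) / 0.02 < 0.01

    def test_all_zero_series(self):
        t = np.arange(0.0, 30.0)
        assert ep.activity_slope(t, np.zeros_like(t), 1.0) == (0.0, True)

    def test_baseline_invariance(self):
        rng = np.random.default_rng(1)
        t = np.arange(0.0, 30.0)
        y = 0.015 * t + rng.normal(0, 1e-5, t.shape)
        s1, _ = ep.activity_slope(t, y, 1.0)
        s2, _ = ep.activity_slope(t, y + 5.0, 1.0)
        assert np.isclose(s1, s2, atol=1e-9)

    def test_noisy_series_flagged_low_quality(self):
        rng = np.random.default_rng(2)
        t = np.arange(0.0, 30.0)
        y = rng.normal(0, 1.0, t.shape)
        _, ok = ep.activity_slope(t, y, 1.0)
        assert not ok


class TestHaloRatio:
    def test_super_broadcaster(self):
        ratio, cls = ep.halo_ratio(2.0, 10.0)
        assert ratio == 5.0 and cls == "super-broadcaster"

    def test_non_broadcaster(self):
        ratio, cls = ep.halo_ratio(2.0, 2.0)
        assert ratio == 1.0 and cls == "non-broadcaster"

    def test_artifact_clamped(self):
        ratio, _ = ep.halo_ratio(2.0, 1.0)
        assert ratio == 1.0

    def test_zero_colony_rejected(self):
        with pytest.raises(ValueError):
            ep.halo_ratio(0.0, 1.0)


class TestExpressionRatio:
    def ct_table(self, target_shift, n_rep=3, sigma=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for gene, shift in [("alyA", target_shift), ("rpoD", 0.0), ("gyrB", 0.0)]:
            for rep in range(1, n_rep + 1):
                rows.append(dict(gene=gene, condition="control", replicate=rep,
                                 ct=20.0 + shift + rng.normal(0, sigma)))
                rows.append(dict(gene=gene, condition="treated", replicate=rep,
                                 ct=20.0 + rng.normal(0, sigma)))
        return pd.DataFrame(rows)

    EFF = {"alyA": 2.0, "rpoD": 2.0, "gyrB": 2.0}

    def test_no_shift_ratio_one(self):
        out = ep.expression_ratio(self.ct_table(0.0), self.EFF, permutations=50)
        assert np.isclose(out.iloc[0].ratio, 1.0)

    def test_three_cycle_shift_is_eightfold(self):
        out = ep.expression_ratio(self.ct_table(3.0), self.EFF, permutations=50)
        assert np.isclose(out.iloc[0].ratio, 8.0)

    def test_seeded_bitwise_reproducibility(self):
        ct = self.ct_table(2.0, sigma=0.2, seed=3)
        a = ep.expression_ratio(ct, self.EFF, permutations=300, seed=7)
        b = ep.expression_ratio(ct, self.EFF, permutations=300, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_reference_rejected(self):
        ct = self.ct_table(1.0)
        with pytest.raises(ValueError, match="reference"):
            ep.expression_ratio(ct[ct.gene != "rpoD"], self.EFF)

    def test_bad_efficiency_rejected(self):
        with pytest.raises(ValueError, match="efficiency"):
            ep.expression_ratio(
                self.ct_table(1.0), {"alyA": 2.5, "rpoD": 2.0, "gyrB": 2.0}
            )

    def test_simulated_induction_recovered(self):
        """Planted 4-fold induction, 3 replicates, sigma 0.2."""
        ratios, ps = [], []
        for i in range(25):
            ct = self.ct_table(2.0, sigma=0.2, seed=100 + i)  # E=2: 4-fold
            out = ep.expression_ratio(ct, self.EFF, permutations=400, seed=i)
            ratios.append(out.iloc[0].ratio)
            ps.append(out.iloc[0].p_permutation)
        assert 3.0 <= np.median(ratios) <= 5.0
        assert np.mean(np.array(ps) < 0.05) >= 0.8


def test_pheno_geno_table_construction():
    cn = pd.DataFrame(
        {"PL6": [1, 0], "PL7": [0, 0], "PL15": [2, 0], "PL17": [0, 1]},
        index=["s1", "s2"],
    )
    calls = pd.DataFrame(
        [
            dict(strain="s1", substrate="Dp>50", fraction="u", grows=True),
            dict(strain="s2", substrate="Dp>50", fraction="u", grows=False),
        ]
    )
    out = ep.build_pheno_geno_table(cn, calls).set_index("strain")
    assert bool(out.loc["s1", "has_aly"]) and bool(out.loc["s1", "has_oal"])
    assert not bool(out.loc["s2", "has_aly"]) and bool(out.loc["s2", "has_oal"])
    assert bool(out.loc["s1", "grows_Dp>50"])
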