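import numpy as np
import pandas as pd
import pytest
from scipy import stats

from selfscape.core_data import CALL_DTYPE, HET, HOM_ALT, HOM_REF
from selfscape.spatial_ibd import (
    DistanceBinSpec,
    bin_pairs,
    fit_exp_decay,
    fit_linear,
    fst_distance_regression,
    haversine_km,
    ibd_pair_stats,
    multiscale_binned_ibd,
    pairwise_site_fst,
    weir_cockerham_theta,
)
from selfscape.haplogroup_clustering import qt_cluster
from selfscape.synthetic_data import (
    LandscapeSpec,
    SimPanelSpec,
    SimSiteSpec,
    generate_equilibrium_site,
    generate_landscape,
    generate_panel,
)



class TestHaversine:
    def test_identical_points(self):
        assert haversine_km(51.0, 13.0, 51.0, 13.0) == 0.0

    def test_half_and_quarter_circumference(self):
        # antipodal equatorial points: pi * R; quarter: pi * R / 2
        assert haversine_km(0, 0, 0, 180) == pytest.approx(20015.1, abs=0.1)
        assert haversine_km(0, 0, 0, 90) == pytest.approx(10007.5, abs=0.1)

    def test_symmetry_vectorised(self):
        rng = np.random.default_rng(0)
        lat = rng.uniform(-80, 80, 20)
        lon = rng.uniform(-179, 179, 20)
        d1 = haversine_km(lat[:10], lon[:10], lat[10:], lon[10:])
        d2 = haversine_km(lat[10:], lon[10:], lat[:10], lon[:10])
        assert np.allclose(d1, d2)


class TestBinning:
    def test_single_bin_same_group(self):
        out = bin_pairs(
            np.zeros(5), np.ones(5, bool), np.zeros(5),
            DistanceBinSpec(bin_width_km=150),
        )
        assert len(out) == 1
        assert out["n_pairs"].iloc[0] == 5
        assert out["p_same_haplogroup"].iloc[0] == 1.0

    def test_floor_rule(self):
        out = bin_pairs(
            np.array([10.0, 170.0, 320.0]), None, None,
            DistanceBinSpec(bin_width_km=150),
        )
        assert out["n_pairs"].tolist() == [1, 1, 1]
        assert out["bin_low_km"].tolist() == [0.0, 150.0, 300.0]
        assert out["bin_high_km"].tolist() == [150.0, 300.0, 450.0]

    def test_quantiles_match_direct_computation(self):
        vals = np.array([0.0, 0.1, 0.15, 0.2, 0.3, 0.32, 0.4, 0.55, 0.6, 0.8, 1.0])
        out = bin_pairs(
            np.zeros(len(vals)), None, vals, DistanceBinSpec(bin_width_km=1.0)
        )
        for col, q in zip(("q09", "q25", "q50", "q75", "q91"),
                          (0.09, 0.25, 0.50, 0.75, 0.91)):
            assert out[col].iloc[0] == pytest.approx(np.quantile(vals, q))
        # quantiles weakly ordered
        row = out.iloc[0]
        assert row["q09"] <= row["q25"] <= row["q50"] <= row["q75"] <= row["q91"]

    def test_conservation_and_empty_bins(self):
        d = np.array([5.0, 5.0, 25.0])
        out = bin_pairs(d, None, None, DistanceBinSpec(bin_width_km=10.0))
        assert out["n_pairs"].sum() == 3
        assert out["n_pairs"].tolist() == [2, 0, 1]
        assert np.isnan(out["q50"].iloc[1])


class TestLinearFit:
    def test_exact_line_recovered(self):
        x_mid = np.arange(10) + 0.5
        binned = pd.DataFrame(
            {
                "bin_low_km": np.arange(10.0),
                "bin_high_km": np.arange(10.0) + 1,
                "n_pairs": 10,
                "p_same_haplogroup": 2 * x_mid + 1,
            }
        )
        fit = fit_linear(binned)
        assert fit.params["m"] == pytest.approx(2.0, abs=1e-10)
        assert fit.params["b"] == pytest.approx(1.0, abs=1e-10)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_constant_response_zero_slope(self):
        binned = pd.DataFrame(
            {
                "bin_low_km": np.arange(5.0), "bin_high_km": np.arange(5.0) + 1,
                "n_pairs": 7, "p_same_haplogroup": 0.4,
            }
        )
        assert fit_linear(binned).params["m"] == pytest.approx(0.0, abs=1e-12)

    def test_weighted_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        n = 12
        x = np.arange(n) + 0.5
        y = 0.3 - 0.01 * x + rng.normal(0, 0.05, n)
        w = np.ones(n)
        w[3] = 500  # heavy outlier bin
        y[3] += 0.4
        binned = pd.DataFrame(
            {"bin_low_km": np.arange(float(n)), "bin_high_km": np.arange(float(n)) + 1,
             "n_pairs": w.astype(int), "p_same_haplogroup": y}
        )
        fit_w = fit_linear(binned, weighting="by_n_pairs", min_pairs_per_bin=0)
        fit_u = fit_linear(binned, weighting="none", min_pairs_per_bin=0)
        # closed-form weighted normal equations oracle
        sw, swx = w.sum(), (w * x).sum()
        swxx, swy, swxy = (w * x * x).sum(), (w * y).sum(), (w * x * y).sum()
        m_oracle = (sw * swxy - swx * swy) / (sw * swxx - swx**2)
        b_oracle = (swy - m_oracle * swx) / sw
        assert fit_w.params["m"] == pytest.approx(m_oracle, abs=1e-10)
        assert fit_w.params["b"] == pytest.approx(b_oracle, abs=1e-10)
        assert abs(fit_w.params["b"] - fit_u.params["b"]) > 1e-3

    def test_too_few_bins_rejected(self):
        binned = pd.DataFrame(
            {"bin_low_km": [0.0], "bin_high_km": [1.0], "n_pairs": [9],
             "p_same_haplogroup": [0.5]}
        )
        with pytest.raises(ValueError):
            fit_linear(binned)


class TestExpFit:
    @staticmethod
    def _frame(x, y, n=50):
        return pd.DataFrame(
            {"bin_low_km": x - 0.5, "bin_high_km": x + 0.5,
             "n_pairs": n, "p_same_haplogroup": y}
        )

    def test_noiseless_decay_recovered(self):
        x = np.linspace(0.5, 400, 30)
        y = 0.8 * np.exp(-0.01 * x)
        fit = fit_exp_decay(self._frame(x, y))
        assert fit.converged
        assert fit.params["C"] == pytest.approx(0.8, rel=1e-6)
        assert fit.params["lam"] == pytest.approx(0.01, rel=1e-6)

    def test_noiseless_saturating_recovered(self):
        x = np.linspace(0.5, 800, 40)
        y = 0.35 - 0.3 * np.exp(-0.005 * x)
        fit = fit_exp_decay(self._frame(x, y), form="EXP_SATURATING")
        assert fit.converged
        assert fit.params["K"] == pytest.approx(0.35, rel=1e-6)
        assert fit.params["C"] == pytest.approx(0.3, rel=1e-6)
        assert fit.params["lam"] == pytest.approx(0.005, rel=1e-6)

    def test_noisy_saturating_recovery_rate(self):
        # sigma = 0.01 noise on 40 bins; parameters within 10% in >= 95/100
        x = np.linspace(5, 1200, 40)
        truth = {"K": 0.35, "C": 0.3, "lam": 0.005}
        ok = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = truth["K"] - truth["C"] * np.exp(-truth["lam"] * x)
            y = y + rng.normal(0, 0.01, len(x))
            fit = fit_exp_decay(self._frame(x, y), form="EXP_SATURATING")
            if fit.converged and all(
                abs(fit.params[k] - v) <= 0.1 * v for k, v in truth.items()
            ):
                ok += 1
        assert ok >= 95

    def test_increasing_response_does_not_converge_as_decay(self):
        x = np.linspace(0.5, 100, 20)
        y = 0.1 + 0.005 * x  # strictly increasing
        fit = fit_exp_decay(self._frame(x, y), form="EXP_DECAY")
        assert not fit.converged

    def test_too_few_bins_rejected(self):
        x = np.array([1.0, 2.0])
        with pytest.raises(ValueError):
            fit_exp_decay(self._frame(x, np.array([0.5, 0.4])))


class TestWeirCockerham:
    def test_hand_computed_single_locus_toy(self):
        # pop A: 3 hom-ref, 1 het -> n=4, p=1/8, h=1/4
        # pop B: 1 hom-ref, 2 het, 3 hom-alt -> n=6, p=2/3, h=1/3
        a = np.array([[HOM_REF], [HOM_REF], [HOM_REF], [HET]], dtype=CALL_DTYPE)
        b = np.array(
            [[HOM_REF], [HET], [HET], [HOM_ALT], [HOM_ALT], [HOM_ALT]],
            dtype=CALL_DTYPE,
        )
        n1, n2 = 4.0, 6.0
        p1, p2 = 1 / 8, 2 / 3
        h1, h2 = 1 / 4, 1 / 3
        r = 2.0
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        av = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4) / (nbar - 1)
        )
        bv = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2
            - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        cv = hbar / 2
        expected = av / (av + bv + cv)
        assert weir_cockerham_theta(a, b) == pytest.approx(expected, abs=1e-12)

    def test_opposite_fixation_gives_one(self):
        a = np.zeros((10, 8), dtype=CALL_DTYPE)
        b = np.full((10, 8), HOM_ALT, dtype=CALL_DTYPE)
        assert weir_cockerham_theta(a, b) == pytest.approx(1.0, abs=1e-12)

    def test_identical_frequencies_near_zero(self):
        _, freqs = generate_panel(SimPanelSpec(n_markers=139, seed=0))
        a = generate_equilibrium_site(
            SimSiteSpec("a", n_plants=200, inbreeding_F=0.5), freqs, seed=1
        )
        b = generate_equilibrium_site(
            SimSiteSpec("b", n_plants=200, inbreeding_F=0.5), freqs, seed=2
        )
        assert abs(weir_cockerham_theta(a, b)) < 0.02

    def test_panmictic_split_centered_on_zero(self):
        # splitting one population in half: theta averages ~0 over replicates
        _, freqs = generate_panel(SimPanelSpec(n_markers=139, seed=5))
        rng = np.random.default_rng(6)
        thetas = []
        for _ in range(50):
            calls = generate_equilibrium_site(
                SimSiteSpec("s", n_plants=80, inbreeding_F=0.9), freqs, seed=rng
            )
            perm = rng.permutation(80)
            thetas.append(
                weir_cockerham_theta(calls[perm[:40]], calls[perm[40:]])
            )
        assert abs(np.mean(thetas)) < 0.01


class TestFstRegression:
    @staticmethod
    def _linear_fst_table(n=30, slope=0.02, intercept=-0.05):
        km = np.linspace(1, 3000, n)
        return pd.DataFrame(
            {
                "site_a": [f"a{i}" for i in range(n)],
                "site_b": [f"b{i}" for i in range(n)],
                "fst": intercept + slope * np.log(km),
                "km": km,
                "ln_km": np.log(km),
            }
        )

    def test_exact_linear_every_window_slope_equals_global(self):
        table = self._linear_fst_table()
        res = fst_distance_regression(table, window=10)
        assert res.slope == pytest.approx(0.02, abs=1e-12)
        assert len(res.window_slopes) == 30 - 10 + 1
        assert np.allclose(res.window_slopes["slope"], 0.02)

    def test_shuffled_response_null_slope(self):
        rng = np.random.default_rng(3)
        rejections = 0
        n_perm = 40
        for _ in range(n_perm):
            table = self._linear_fst_table(n=100)
            table["fst"] = rng.permutation(table["fst"].to_numpy())
            res = fst_distance_regression(table, window=200)
            # |t| >= 2 should be rare under the permutation null
            if res.p_value < 0.046:
                rejections += 1
        assert rejections <= 0.05 * n_perm + 2

    def test_zero_distance_pairs_excluded(self):
        table = self._linear_fst_table(n=10)
        table.loc[0, "km"] = 0.0
        table.loc[0, "ln_km"] = np.nan
        res = fst_distance_regression(table, window=5)
        assert res.n_excluded_zero_distance == 1
        assert len(res.pairs) == 9

    def test_fewer_pairs_than_window_global_only(self):
        table = self._linear_fst_table(n=8)
        res = fst_distance_regression(table, window=500)
        assert res.window_slopes.empty
        assert res.slope == pytest.approx(0.02, abs=1e-12)


class TestScenarioContrast:
    def test_eurasia_positive_ibd_north_america_flatter(self):
        eur_rho, na_rho = [], []
        eur_slope, na_slope = [], []
        for seed in range(3):
            for scenario, rhos, slopes in (
                ("EURASIA", eur_rho, eur_slope),
                ("NORTH_AMERICA", na_rho, na_slope),
            ):
                gt, meta, _ = generate_landscape(
                    LandscapeSpec(
                        scenario=scenario, n_sites=20, extent_km=3000,
                        frequency_gradient_scale_km=1000,
                        n_founder_clones=3, clone_fraction=0.9,
                        plants_per_site_min=6, plants_per_site_max=10,
                        panel=SimPanelSpec(n_markers=139), seed=seed,
                    )
                )
                a = qt_cluster(gt)
                stats_df = ibd_pair_stats(gt, meta, a)
                ok = stats_df["mismatch_fraction"].notna()
                rho, _ = stats.spearmanr(
                    stats_df.loc[ok, "km"], stats_df.loc[ok, "mismatch_fraction"]
                )
                rhos.append(rho)
                fst = pairwise_site_fst(gt, meta, min_plants_per_site=4)
                reg = fst_distance_regression(fst, window=50)
                slopes.append(reg.slope)
        assert np.mean(eur_rho) > np.mean(na_rho)
        assert np.mean(eur_slope) > 0
        assert np.mean(eur_slope) > np.mean(na_slope)

    def test_multiscale_binning_conserves_pairs(self):
        gt, meta, _ = generate_landscape(
            LandscapeSpec(
                scenario="EURASIA", n_sites=10, plants_per_site_min=3,
                plants_per_site_max=5, panel=SimPanelSpec(n_markers=60), seed=4,
            )
        )
        a = qt_cluster(gt)
        pair_stats = ibd_pair_stats(gt, meta, a)
        for w, table in multiscale_binned_ibd(pair_stats, (150.0, 10.0)).items():
            assert table["n_pairs"].sum() == len(pair_stats)
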