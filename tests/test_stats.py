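"""Mixed-effects comparisons, effect sizes, Tukey contrasts, rmcorr."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nircat.stats import hedges_g, lmm_region_tukey, lmm_treatment, rmcorr
from nircat.synthetic import DesignSpec, simulate_metrics_table


def _one_region_design(mean_sham, mean_gdx, animal_sd, slice_sd, seed, n_animals=6, n_slices=2):
    return DesignSpec(
        n_animals_per_group=n_animals,
        slices_per_animal=n_slices,
        regions=("DLS",),
        group_means={
            "sham": {"DLS": {"density_pct": mean_sham}},
            "GDX": {"DLS": {"density_pct": mean_gdx}},
        },
        animal_sd=animal_sd,
        slice_sd=slice_sd,
        seed=seed,
    )


class TestHedgesG:
    def test_hand_computed_example(self):
        """{4,5,6} vs {1,2,3}: d = 3/1, J = 1 - 3/(4*4-1) = 0.8 -> g = 2.4."""
        assert hedges_g([4, 5, 6], [1, 2, 3]) == pytest.approx(2.4)
        assert hedges_g([1, 2, 3], [4, 5, 6]) == pytest.approx(-2.4)

    def test_matches_reference_implementation(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        x, y = rng.normal(1, 1, 12), rng.normal(0, 1.3, 9)
        assert hedges_g(x, y) == pytest.approx(
            pg.compute_effsize(x, y, eftype="hedges"), rel=1e-9
        )

    def test_affine_invariance(self):
        x, y = [4.0, 5.0, 6.5], [1.0, 2.0, 3.3]
        g = hedges_g(x, y)
        xs = [3.7 * v - 11 for v in x]
        ys = [3.7 * v - 11 for v in y]
        assert hedges_g(xs, ys) == pytest.approx(g, abs=1e-10)


class TestLmmTreatment:
    def test_zero_variance_degenerate_flagged(self):
        d = _one_region_design(40.0, 20.0, 0.0, 0.0, seed=0, n_animals=2)
        res, _ = lmm_treatment(simulate_metrics_table(d), "density_pct")
        assert res.degenerate
        assert res.fixed_effect_estimate == pytest.approx(-20.0)

    def test_zero_residual_reduces_to_animal_mean_t(self):
        """slice_sd = 0: the mixed model collapses to the two-sample t on
        animal means (balanced design), to 1e-6."""
        d = _one_region_design(40.0, 30.0, 8.0, 0.0, seed=1)
        tab = simulate_metrics_table(d)
        res, _ = lmm_treatment(tab, "density_pct")
        means = tab.groupby(["animal_id", "treatment"], observed=True)["density_pct"].mean().reset_index()
        t_ref = sps.ttest_ind(
            means.loc[means.treatment == "GDX", "density_pct"],
            means.loc[means.treatment == "sham", "density_pct"],
        ).statistic
        assert res.t_value == pytest.approx(t_ref, abs=1e-6)
        assert res.denominator_df == 10

    def test_zero_fitted_animal_variance_matches_ols(self):
        """Animal means equal within group: fitted animal variance ~0 and the
        treatment t agrees with the ordinary regression t."""
        import statsmodels.formula.api as smf

        rows = []
        for g, mu in (("sham", 40.0), ("GDX", 30.0)):
            for a in range(3):
                aid = f"{g}_a{a}"
                for s, dev in enumerate((-3.0, 1.0, 2.0)):
                    rows.append(
                        {"animal_id": aid, "treatment": g, "region": "DLS",
                         "slice_id": f"{aid}s{s}", "density_pct": mu + dev}
                    )
        tab = pd.DataFrame(rows)
        res, _ = lmm_treatment(tab, "density_pct")
        ols = smf.ols('density_pct ~ C(treatment, levels=["sham", "GDX"])', data=tab).fit()
        assert res.variance_animal < 1e-2
        assert res.t_value == pytest.approx(float(ols.tvalues.iloc[1]), rel=1e-3)

    def test_effect_sizes_affine_invariant(self):
        d = DesignSpec(seed=5)
        tab = simulate_metrics_table(d)
        sub = tab[tab.region == "DLS"]
        _, e1 = lmm_treatment(sub, "density_pct")
        sub2 = sub.copy()
        sub2["density_pct"] = 3.7 * sub2["density_pct"] - 11.0
        _, e2 = lmm_treatment(sub2, "density_pct")
        assert e1.cohens_f2 == pytest.approx(e2.cohens_f2, abs=1e-10)
        assert e1.eta2_partial == pytest.approx(e2.eta2_partial, abs=1e-10)
        for k in e1.hedges_g:
            assert e1.hedges_g[k] == pytest.approx(e2.hedges_g[k], abs=1e-10)

    def test_single_group_rejected(self):
        d = DesignSpec(seed=0)
        tab = simulate_metrics_table(d)
        with pytest.raises(ValueError, match="two treatment groups"):
            lmm_treatment(tab[tab.treatment == "sham"], "density_pct")

    def test_missing_metric_rejected(self):
        tab = simulate_metrics_table(DesignSpec(seed=0))
        with pytest.raises(ValueError):
            lmm_treatment(tab, "nope")
        tab2 = tab.copy()
        tab2["density_pct"] = np.nan
        with pytest.raises(ValueError, match="no non-missing"):
            lmm_treatment(tab2, "density_pct")


class TestRegionTukey:
    def _design(self, mus, seed, n_animals=6):
        means = {
            g: {r: {"density_pct": m} for r, m in mus.items()} for g in ("sham", "GDX")
        }
        return DesignSpec(
            n_animals_per_group=n_animals,
            slices_per_animal=2,
            regions=tuple(mus),
            group_means=means,
            animal_sd=5.0,
            slice_sd=5.0,
            seed=seed,
        )

    def test_adjusted_p_at_least_raw(self):
        d = self._design({"DMS": 30.0, "DLS": 40.0, "NAc": 15.0}, seed=2)
        _, contrasts, _ = lmm_region_tukey(simulate_metrics_table(d), "density_pct", "sham")
        assert len(contrasts) == 3
        for c in contrasts:
            assert c.adjusted_p >= c.p_raw - 1e-12
            assert 0 <= c.adjusted_p <= 1

    def test_null_two_regions_small_z(self):
        """Identical planted means: |z| is small and adjusted p is direction-
        free (median |z| < 1 over repeated simulations)."""
        zs, ps = [], []
        for seed in range(60):
            d = self._design({"DMS": 30.0, "DLS": 30.0}, seed=seed)
            _, contrasts, _ = lmm_region_tukey(simulate_metrics_table(d), "density_pct", "sham")
            zs.append(abs(contrasts[0].z_value))
            ps.append(contrasts[0].adjusted_p)
        assert np.median(zs) < 1.0
        assert np.median(ps) > 0.3

    def test_shifted_region_detected(self):
        """One region 2 pooled SDs above the others: both of its contrasts are
        significant in >= 90% of simulations."""
        hits = 0
        n_sim = 60
        for seed in range(n_sim):
            # pooled slice-level SD ~ sqrt(5^2+5^2) ~ 7.1 -> shift ~ 14
            d = self._design({"DMS": 30.0, "DLS": 30.0, "NAc": 44.0}, seed=1000 + seed)
            _, contrasts, _ = lmm_region_tukey(
                simulate_metrics_table(d), "density_pct", "sham"
            )
            nac = [c for c in contrasts if "NAc" in c.pair]
            hits += all(c.adjusted_p < 0.05 for c in nac)
        assert hits / n_sim >= 0.9

    def test_one_region_rejected(self):
        d = self._design({"DLS": 30.0}, seed=0)
        with pytest.raises(ValueError, match="2 regions"):
            lmm_region_tukey(simulate_metrics_table(d), "density_pct", "sham")

    def test_hedges_g_reported_per_pair(self):
        d = self._design({"DMS": 30.0, "DLS": 40.0, "NAc": 15.0}, seed=3)
        tab = simulate_metrics_table(d)
        _, _, eff = lmm_region_tukey(tab, "density_pct", "GDX")
        sub = tab[tab.treatment == "GDX"]
        for pair, g in eff.hedges_g.items():
            a, b = pair.split("-")
            expected = hedges_g(
                sub.loc[sub.region == a, "density_pct"],
                sub.loc[sub.region == b, "density_pct"],
            )
            assert g == pytest.approx(expected, rel=1e-12)


class TestRmcorr:
    def test_common_slope_lines_give_unity(self):
        """Points on parallel lines of slope +1: r_m is exactly 1."""
        rows = []
        for s, intercept in enumerate((0.0, 5.0, -3.0)):
            for x in (1.0, 2.0, 3.0, 4.0):
                rows.append({"animal_id": f"a{s}", "x": x, "y": x + intercept})
        res = rmcorr(pd.DataFrame(rows), "x", "y")
        assert res.r_m == pytest.approx(1.0)
        assert res.p_value == 0.0
        assert res.df == 12 - 3 - 1

    def test_matches_reference_package(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        rows = []
        for s in range(6):
            x = rng.normal(2 * s, 1, 5)
            y = 0.6 * x + rng.normal(-3 * s, 0.8, 5)
            rows += [{"animal_id": f"a{s}", "x": xv, "y": yv} for xv, yv in zip(x, y)]
        df = pd.DataFrame(rows)
        mine = rmcorr(df, "x", "y")
        ref = pg.rm_corr(data=df, x="x", y="y", subject="animal_id")
        assert mine.r_m == pytest.approx(float(ref.r.iloc[0]), abs=1e-9)
        assert mine.df == int(ref.dof.iloc[0])
        assert mine.p_value == pytest.approx(float(ref.pval.iloc[0]), rel=1e-6)

    def test_null_mean_near_zero(self):
        """Independent X and Y within subject: mean r_m over sims ~ 0."""
        vals = []
        for seed in range(300):
            rng = np.random.default_rng(seed)
            rows = []
            for s in range(6):
                for _ in range(4):
                    rows.append(
                        {"animal_id": f"a{s}", "x": rng.normal(), "y": rng.normal()}
                    )
            vals.append(rmcorr(pd.DataFrame(rows), "x", "y").r_m)
        assert abs(np.mean(vals)) < 0.05

    def test_recovers_within_subject_correlation_where_pooled_fails(self):
        """Within-subject r = 0.7 with anticorrelated subject means: rmcorr
        recovers ~0.7 while the naive pooled correlation does not."""
        r_ms, pooled = [], []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            rows = []
            for s in range(6):
                mu_x = float(s)
                mu_y = -2.0 * s  # between-subject anticorrelation
                cov = [[1.0, 0.7], [0.7, 1.0]]
                xy = rng.multivariate_normal([mu_x, mu_y], cov, size=5)
                rows += [{"animal_id": f"a{s}", "x": v[0], "y": v[1]} for v in xy]
            df = pd.DataFrame(rows)
            r_ms.append(rmcorr(df, "x", "y").r_m)
            pooled.append(float(np.corrcoef(df["x"], df["y"])[0, 1]))
        assert np.mean(r_ms) == pytest.approx(0.7, abs=0.1)
        assert np.mean(pooled) < 0.0  # swamped by the between-subject trend

    def test_subjects_with_single_observation_dropped(self):
        rows = [
            {"animal_id": "a1", "x": 1.0, "y": 1.0},
            {"animal_id": "a1", "x": 2.0, "y": 2.5},
            {"animal_id": "a2", "x": 1.0, "y": 0.5},
            {"animal_id": "a2", "x": 3.0, "y": 3.0},
            {"animal_id": "lonely", "x": 9.0, "y": 9.0},
        ]
        res = rmcorr(pd.DataFrame(rows), "x", "y")
        assert res.n_subjects == 2
        assert res.n_obs == 4

    def test_too_few_subjects_rejected(self):
        rows = [{"animal_id": "a1", "x": float(i), "y": float(i)} for i in range(5)]
        with pytest.raises(ValueError, match="2 subjects"):
            rmcorr(pd.DataFrame(rows), "x", "y")
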