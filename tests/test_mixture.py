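"""Calibration, anchored mixture fitting and the 3→2→1 fallback."""

import numpy as np
import pytest

import locusdyn as ld
from locusdyn.mixture import COMPONENT_ORDER


def _immobile_dapps(sigma, n, seed):
    params = ld.MotionParams(model="immobile", sigma_loc=sigma, dt=0.1, n_steps=1200)
    tracks = ld.simulate_immobile(params, n, seed=seed)
    return ld.dapp_table(tracks)["d_app"].to_numpy()


class TestDappDistribution:
    def test_histogram_integrates_to_one(self):
        vals = ld.sample_dapp_values([1.0], [-2.0], [0.3], 500, seed=1)
        dist = ld.DappDistribution(vals)
        area = np.sum(dist.density * np.diff(dist.bin_edges))
        assert np.isclose(area, 1.0)

    def test_nonpositive_values_counted(self):
        vals = np.concatenate([ld.sample_dapp_values([1.0], [-2.0], [0.2], 200, seed=2),
                               [-1e-4, 0.0, -2e-5]])
        dist = ld.DappDistribution(vals)
        assert dist.n_excluded_nonpositive == 3
        assert len(dist.log_values) == 200

    def test_all_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ld.DappDistribution(np.array([-1.0, 0.0]))


class TestCalibrateDfix:
    def test_recovers_known_mode_of_immobile_population(self):
        """Gaussian-fit mode agrees with an independent KDE mode estimate."""
        from scipy.stats import gaussian_kde

        d = _immobile_dapps(0.02, 500, seed=11)
        dist = ld.DappDistribution(d)
        cal = ld.calibrate_dfix(dist)
        lv = dist.log_values
        kde = gaussian_kde(lv)
        xs = np.linspace(lv.min(), lv.max(), 400)
        mode = 10 ** xs[np.argmax(kde(xs))]
        rng = np.random.default_rng(99)
        boots = []
        for _ in range(40):
            rv = rng.choice(d, size=len(d), replace=True)
            lb = np.log10(rv[rv > 0])
            kb = gaussian_kde(lb)
            boots.append(10 ** xs[np.argmax(kb(xs))])
        combined_se = np.sqrt(cal.se**2 + np.var(boots, ddof=1))
        assert abs(cal.d_fix - mode) < 3 * combined_se

    def test_two_disjoint_runs_agree(self):
        cal_a = ld.calibrate_dfix(ld.DappDistribution(_immobile_dapps(0.10, 400, seed=21)))
        cal_b = ld.calibrate_dfix(ld.DappDistribution(_immobile_dapps(0.10, 400, seed=22)))
        assert abs(cal_a.d_fix - cal_b.d_fix) < 3 * np.hypot(cal_a.se, cal_b.se)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            ld.calibrate_dfix(ld.DappDistribution(10 ** np.random.default_rng(3).normal(-3, 0.3, 20)))

    def test_preset_calibration_near_fixed_cell_scale(self, immobile_calibration):
        """The calibrated immobile preset lands at the 1e-3 um^2/s order."""
        assert 1e-4 < immobile_calibration.d_fix < 3e-3


class TestFitMixture:
    def test_three_component_recovery(self, immobile_calibration):
        cal = immobile_calibration
        mu = np.log10(cal.d_fix)
        truth_w = (0.30, 0.45, 0.25)
        vals = ld.sample_dapp_values(truth_w, [mu, -2.25, -1.25], [0.25, 0.2, 0.2], 600, seed=31)
        fit = ld.fit_mixture(ld.DappDistribution(vals), cal)
        assert fit.converged
        fr = fit.fractions
        for lab, w in zip(COMPONENT_ORDER, truth_w):
            assert abs(fr[lab] - 100 * w) <= 5
        means = {c.label: c.mean for c in fit.components}
        assert means["fixed"] == pytest.approx(mu)  # anchoring is exact
        assert abs(means["slow"] + 2.25) < 0.15
        assert abs(means["fast"] + 1.25) < 0.15

    def test_weights_sum_to_one(self, immobile_calibration):
        vals = ld.sample_dapp_values([0.5, 0.5], [-2.5, -1.2], [0.2, 0.2], 500, seed=32)
        fit = ld.fit_with_fallback(ld.DappDistribution(vals), immobile_calibration)
        assert np.isclose(sum(c.weight for c in fit.components), 1.0, atol=1e-6)
        assert np.isclose(sum(fit.fractions.values()), 100.0, atol=1e-6)

    def test_component_ordering(self, immobile_calibration):
        cal = immobile_calibration
        vals = ld.sample_dapp_values(
            [0.3, 0.4, 0.3], [np.log10(cal.d_fix), -2.2, -1.2], [0.25, 0.2, 0.2], 600, seed=33
        )
        fit = ld.fit_with_fallback(ld.DappDistribution(vals), cal)
        means = [c.mean for c in fit.components]
        assert means == sorted(means)

    def test_single_population_leaves_little_weight_elsewhere(self, immobile_calibration):
        """Values drawn only from the anchored law: free components < 5%."""
        cal = immobile_calibration
        vals = ld.sample_dapp_values([1.0], [np.log10(cal.d_fix)], [cal.log10_sd], 600, seed=34)
        fit = ld.fit_with_fallback(ld.DappDistribution(vals), cal)
        fr = fit.fractions
        assert fr["slow"] < 5 and fr["fast"] < 5
        assert fr["fixed"] > 90


class TestFallback:
    def test_missing_fast_component_dropped(self, immobile_calibration):
        """No fast population: the fit reports fixed + slow only."""
        cal = immobile_calibration
        vals = ld.sample_dapp_values(
            [0.6, 0.4], [np.log10(cal.d_fix), -2.25], [0.25, 0.2], 600, seed=41
        )
        fit = ld.fit_with_fallback(ld.DappDistribution(vals), cal)
        fr = fit.fractions
        assert fr["fast"] == 0.0
        assert "fast" in fit.fallback_applied
        assert abs(fr["fixed"] - 60) <= 6
        assert abs(fr["slow"] - 40) <= 6

    def test_missing_fixed_component_dropped(self, immobile_calibration):
        """No fixed population: the anchored peak is dropped, fast + slow stay."""
        vals = ld.sample_dapp_values([0.5, 0.5], [-2.25, -1.25], [0.2, 0.2], 600, seed=42)
        fit = ld.fit_with_fallback(ld.DappDistribution(vals), immobile_calibration)
        fr = fit.fractions
        assert fr["fixed"] == 0.0
        assert "fixed" in fit.fallback_applied
        assert abs(fr["slow"] - 50) <= 6 and abs(fr["fast"] - 50) <= 6

    def test_clean_three_component_sample_needs_no_fallback(self, immobile_calibration):
        cal = immobile_calibration
        vals = ld.sample_dapp_values(
            [0.3, 0.4, 0.3], [np.log10(cal.d_fix), -2.25, -1.25], [0.25, 0.2, 0.2],
            800, seed=43,
        )
        fit = ld.fit_with_fallback(ld.DappDistribution(vals), cal)
        assert fit.fallback_applied == []
        assert len(fit.components) == 3

    def test_absent_component_is_statistically_free_to_remove(self, immobile_calibration):
        """Dropping a truly absent peak costs no significant fit quality."""
        from scipy import stats as sps

        from locusdyn.mixture import _make_fit

        cal = immobile_calibration
        vals = ld.sample_dapp_values(
            [0.6, 0.4], [np.log10(cal.d_fix), -2.25], [0.25, 0.2], 600, seed=44
        )
        dist = ld.DappDistribution(vals)
        full = _make_fit(dist, ["fixed", "slow", "fast"], cal, True)
        reduced = _make_fit(dist, ["fixed", "slow"], cal, True)
        d_par = reduced.dof - full.dof
        f_stat = ((reduced.rss - full.rss) / d_par) / (full.rss / full.dof)
        assert f_stat < sps.f.ppf(0.95, d_par, full.dof)


class TestComponentFractions:
    def test_percent_table(self, immobile_calibration):
        vals = ld.sample_dapp_values([0.5, 0.5], [-2.25, -1.25], [0.2, 0.2], 600, seed=51)
        fit = ld.fit_with_fallback(ld.DappDistribution(vals), immobile_calibration)
        table = ld.component_fractions(fit)
        assert list(table["component"]) == list(COMPONENT_ORDER)
        assert np.isclose(table["percent"].sum(), 100.0)
        assert table.set_index("component").loc["fixed", "percent"] == 0.0

    def test_labelled_population_fraction_recovery(self, immobile_calibration):
        """End-to-end: trajectory mixture fractions match positive-D_app labels."""
        comps = ld.preset_components()
        spec = ld.PopulationSpec(
            (ld.Component("fast", comps["fast"], 0.25),
             ld.Component("slow", comps["slow"], 0.45),
             ld.Component("fixed", comps["fixed"], 0.30)),
            n_tracks=600,
            seed=52,
        )
        tracks = ld.sample_population(spec)
        tab = ld.dapp_table(tracks)
        fit = ld.fit_with_fallback(
            ld.DappDistribution(tab["d_app"].to_numpy()), immobile_calibration
        )
        pos = tab[tab["d_app"] > 0]
        truth = pos["label"].value_counts(normalize=True) * 100
        for lab in COMPONENT_ORDER:
            assert abs(fit.fractions[lab] - truth.get(lab, 0.0)) <= 6
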