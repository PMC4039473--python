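"""Hierarchical robust-t fits, HDI contrasts, PPC, and JZS Bayes factors.

Independent oracles: a brute-force sorted-scan HDI, a dense N x N
covariance marginal-likelihood path integrated with scipy's adaptive
quadrature, and the synthetic generator's ground truth.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.special import gammaln

from cfskit.bayes import (ContrastResult, ConvergenceError, RMDataset,
                          SamplerSettings, bf_table, contrast_hdi,
                          fit_one_way, fit_two_way, jzs_anova_bf,
                          posterior_predictive)
from cfskit.bayes import (R_FIXED, R_NUISANCE, _effect_matrices,
                          _sum_to_zero_basis)
from cfskit.synthdata import EffectProfile, generate_threshold_dataset

FAST = SamplerSettings(chains=2, draws=600, warmup=400, seed=7,
                       check_convergence=False)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def sorted_scan_hdi(draws: np.ndarray, prob: float) -> tuple[float, float]:
    """Narrowest interval containing ``prob`` of the draws, by exhaustive
    scan over the sorted sample."""
    x = np.sort(np.asarray(draws))
    n = len(x)
    m = int(np.ceil(prob * n))
    widths = x[m - 1:] - x[:n - m + 1]
    k = int(np.argmin(widths))
    return float(x[k]), float(x[k + m - 1])


def dense_log_marginal(data: RMDataset, with_condition: bool) -> float:
    """Marginal likelihood of the two-condition model via an explicit
    N x N covariance and scipy adaptive quadrature over the g's."""
    y = data.table["value"].to_numpy(dtype=float)
    n = len(y)
    ytil = y - y.mean()
    mats = _effect_matrices(data)

    def log_m(gs, gc):
        sigma = np.eye(n)
        sigma += gs * mats["subject"] @ mats["subject"].T
        if with_condition:
            sigma += gc * mats["condition"] @ mats["condition"].T
        sign, logdet = np.linalg.slogdet(sigma)
        q = float(ytil @ np.linalg.solve(sigma, ytil))
        return -0.5 * logdet - 0.5 * (n - 1) * np.log(q)

    def log_invgamma_pdf(g, r):
        return (0.5 * np.log(r**2 / 2) - gammaln(0.5)
                - 1.5 * np.log(g) - r**2 / (2 * g))

    # integrate in s = log g over a wide window
    lo, hi = -15.0, 15.0
    if with_condition:
        def f(sc, ss):
            gs, gc = np.exp(ss), np.exp(sc)
            return np.exp(log_m(gs, gc) + log_invgamma_pdf(gs, R_NUISANCE)
                          + log_invgamma_pdf(gc, R_FIXED) + ss + sc)
        val, _ = integrate.dblquad(f, lo, hi, lo, hi, epsabs=0, epsrel=1e-8)
    else:
        def f(ss):
            gs = np.exp(ss)
            return np.exp(log_m(gs, 0.0) + log_invgamma_pdf(gs, R_NUISANCE)
                          + ss)
        val, _ = integrate.quad(f, lo, hi, epsabs=0, epsrel=1e-10, limit=200)
    return float(np.log(val))


def make_dataset(rng, n_participants=8, conds=("a", "b", "c"),
                 effects=None, sd=0.1):
    effects = np.zeros(len(conds)) if effects is None else np.asarray(effects)
    rows = []
    for i in range(n_participants):
        subj = rng.normal(0, 0.05)
        for j, c in enumerate(conds):
            rows.append({"participant": f"p{i}", "condition": c,
                         "value": 1.0 + effects[j] + subj
                         + rng.normal(0, sd)})
    return RMDataset(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------

class TestRMDataset:
    def test_incomplete_crossing_rejected(self, rng):
        data = make_dataset(rng)
        broken = data.table.iloc[:-1]
        with pytest.raises(ValueError):
            RMDataset(table=broken)

    def test_matrix_layout(self, rng):
        data = make_dataset(rng, n_participants=4)
        mat = data.to_matrix()
        assert mat.shape == (4, 3)
        first = data.table.iloc[0]
        assert mat[0, 0] == first["value"]


# ---------------------------------------------------------------------------
# hierarchical fits
# ---------------------------------------------------------------------------

class TestOneWayFit:
    def test_deflections_sum_to_zero_every_draw(self, rng):
        data = make_dataset(rng, effects=[0.1, -0.05, -0.05])
        fit = fit_one_way(data, FAST)
        eff = fit.stacked("condition_effect")
        np.testing.assert_allclose(eff.sum(axis=1), 0.0, atol=1e-10)
        subj = fit.stacked("subject_effect")
        np.testing.assert_allclose(subj.sum(axis=1), 0.0, atol=1e-10)

    def test_recovers_known_effects_single_fit(self, rng):
        data = make_dataset(rng, n_participants=20,
                            effects=[0.15, 0.0, -0.15], sd=0.08)
        fit = fit_one_way(data, FAST)
        eff = fit.stacked("condition_effect")
        mean, sd = eff.mean(axis=0), eff.std(axis=0)
        truth = np.array([0.1, -0.05, -0.1])
        truth = np.array([0.15, 0.0, -0.15]) - 0.0
        # truth inside a 3-posterior-SD band (99.7% region)
        assert np.all(np.abs(mean - truth) < 3 * sd + 0.02)

    def test_seeded_reproducibility(self, rng):
        data = make_dataset(rng)
        a = fit_one_way(data, FAST).stacked("condition_effect")
        b = fit_one_way(data, FAST).stacked("condition_effect")
        np.testing.assert_array_equal(a, b)

    def test_outliers_shrink_posterior_nu(self, rng):
        clean = make_dataset(rng, n_participants=12, sd=0.05)
        contaminated = RMDataset(table=clean.table.assign(
            value=lambda d: np.where(np.arange(len(d)) % 9 == 0,
                                     d["value"] + 1.0, d["value"])))
        nu_clean = fit_one_way(clean, FAST).stacked("nu").mean()
        nu_dirty = fit_one_way(contaminated, FAST).stacked("nu").mean()
        assert nu_dirty < nu_clean

    def test_robustness_vs_outlier(self, rng):
        """A single gross outlier moves the robust condition means less
        than it moves the raw cell means (the normal-theory estimate)."""
        data = make_dataset(rng, n_participants=10, sd=0.05)
        tab = data.table.copy()
        raw_means0 = tab.groupby("condition", sort=False)["value"].mean()
        fit0 = fit_one_way(data, FAST).stacked("condition_effect").mean(axis=0)
        tab.loc[0, "value"] += 2.0
        dirty = RMDataset(table=tab)
        raw_means1 = dirty.groupby_means = \
            tab.groupby("condition", sort=False)["value"].mean()
        fit1 = fit_one_way(dirty, FAST).stacked("condition_effect").mean(axis=0)
        raw_shift = np.abs((raw_means1 - raw_means1.mean())
                           - (raw_means0 - raw_means0.mean())).max()
        robust_shift = np.abs(fit1 - fit0).max()
        assert robust_shift < raw_shift

    def test_too_few_participants(self, rng):
        data = make_dataset(rng, n_participants=2)
        with pytest.raises(ValueError):
            fit_one_way(data, FAST)

    def test_convergence_gate_raises(self, rng):
        data = make_dataset(rng)
        strict = SamplerSettings(chains=2, draws=40, warmup=5, seed=1,
                                 rhat_threshold=1.0000001,
                                 check_convergence=True)
        with pytest.raises(ConvergenceError) as err:
            fit_one_way(data, strict)
        assert err.value.offending  # names the offending parameters


class TestTwoWayFit:
    @pytest.fixture(scope="class")
    def additive_fit(self):
        rng = np.random.default_rng(21)
        rows = []
        cond_eff = {"a": 0.12, "b": 0.0, "c": -0.12}
        targ_eff = {2.0: 0.05, 5.0: -0.05}
        for i in range(12):
            subj = rng.normal(0, 0.05)
            for c, ce in cond_eff.items():
                for t, te in targ_eff.items():
                    rows.append({"participant": f"p{i}", "condition": c,
                                 "target_speed": t,
                                 "value": 1.0 + ce + te + subj
                                 + rng.normal(0, 0.06)})
        data = RMDataset(table=pd.DataFrame(rows))
        return data, fit_two_way(data, FAST)

    def test_additive_truth_interaction_hdis_include_zero(self, additive_fit):
        _, fit = additive_fit
        inter = fit.stacked("interaction")  # (draws, J, K)
        for j in range(inter.shape[1]):
            for k in range(inter.shape[2]):
                lo, hi = np.quantile(inter[:, j, k], [0.025, 0.975])
                assert lo <= 0.0 <= hi

    def test_recovers_both_main_effects(self, additive_fit):
        _, fit = additive_fit
        ce = fit.stacked("condition_effect").mean(axis=0)
        te = fit.stacked("target_effect").mean(axis=0)
        np.testing.assert_allclose(ce, [0.12, 0.0, -0.12], atol=0.05)
        np.testing.assert_allclose(te, [0.05, -0.05], atol=0.03)

    def test_all_deflection_groups_sum_to_zero(self, additive_fit):
        _, fit = additive_fit
        inter = fit.stacked("interaction")
        np.testing.assert_allclose(inter.sum(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(inter.sum(axis=2), 0.0, atol=1e-10)
        np.testing.assert_allclose(
            fit.stacked("target_effect").sum(axis=1), 0.0, atol=1e-10)

    def test_requires_target_column(self, rng):
        data = make_dataset(rng)
        with pytest.raises(ValueError):
            fit_two_way(data, FAST)


# ---------------------------------------------------------------------------
# contrasts and HDI
# ---------------------------------------------------------------------------

class TestContrasts:
    @pytest.fixture(scope="class")
    def fit(self):
        rng = np.random.default_rng(31)
        data = make_dataset(rng, n_participants=10,
                            effects=[0.2, -0.1, -0.1], sd=0.05)
        return fit_one_way(data, FAST)

    def test_hdi_matches_sorted_scan_oracle(self, fit):
        res = contrast_hdi(fit, [1.0, -0.5, -0.5], prob=0.95)
        lo, hi = sorted_scan_hdi(res.samples, 0.95)
        assert res.hdi[0] == pytest.approx(lo, abs=1e-9)
        assert res.hdi[1] == pytest.approx(hi, abs=1e-9)

    def test_hdi_validity_on_skewed_sample(self, fit):
        """The interval contains exactly ceil(prob*n) draws and is the
        narrowest such interval (checked against every candidate)."""
        res = contrast_hdi(fit, [0.0, 1.0, -1.0], prob=0.9)
        draws = res.samples
        n = len(draws)
        m = int(np.ceil(0.9 * n))
        inside = np.sum((draws >= res.hdi[0]) & (draws <= res.hdi[1]))
        assert inside >= m
        x = np.sort(draws)
        width = res.hdi[1] - res.hdi[0]
        assert np.all(x[m - 1:] - x[:n - m + 1] >= width - 1e-12)

    def test_zero_weights_degenerate(self, fit):
        res = contrast_hdi(fit, [0.0, 0.0, 0.0])
        assert res.hdi == (0.0, 0.0)
        assert not res.excludes_zero

    def test_weights_must_sum_to_zero(self, fit):
        with pytest.raises(ValueError):
            contrast_hdi(fit, [1.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            contrast_hdi(fit, [1.0, -1.0])  # wrong length

    def test_strong_contrast_excludes_zero(self, fit):
        res = contrast_hdi(fit, {"a": 1.0, "b": -0.5, "c": -0.5})
        assert res.excludes_zero
        assert res.hdi[0] > 0

    def test_joint_vs_one_at_a_time_identical(self, fit):
        """No multiplicity adjustment: each contrast depends only on the
        posterior, so computing several changes nothing."""
        single = contrast_hdi(fit, [1.0, -1.0, 0.0])
        batch = [contrast_hdi(fit, w) for w in
                 ([1.0, -1.0, 0.0], [1.0, 0.0, -1.0], [0.0, 1.0, -1.0])]
        assert batch[0].hdi == single.hdi
        np.testing.assert_array_equal(batch[0].samples, single.samples)


# ---------------------------------------------------------------------------
# posterior predictive
# ---------------------------------------------------------------------------

class TestPosteriorPredictive:
    def test_one_replicate_per_retained_draw(self, rng):
        data = make_dataset(rng)
        fit = fit_one_way(data, FAST)
        ppc = posterior_predictive(fit, data, seed=3)
        assert ppc["n_replicates"] == FAST.chains * FAST.draws
        assert ppc["replicates"].shape == (ppc["n_replicates"],
                                           len(data.table))

    def test_coverage_near_nominal_when_well_specified(self, rng):
        data = make_dataset(rng, n_participants=15, sd=0.08)
        fit = fit_one_way(data, FAST)
        ppc = posterior_predictive(fit, data, prob=0.95, seed=4)
        assert 0.88 <= ppc["coverage"] <= 1.0

    def test_predictions_in_range_of_observed(self, rng):
        """Standardised residuals of observed vs predictive mean stay
        bounded for a correctly specified fit."""
        data = make_dataset(rng, n_participants=12, sd=0.08)
        fit = fit_one_way(data, FAST)
        ppc = posterior_predictive(fit, data, seed=5)
        resid = (data.table["value"].to_numpy() - ppc["predictive_mean"])
        scale = ppc["replicates"].std(axis=0)
        assert np.abs(resid / scale).max() < 4.0

    def test_design_mismatch_rejected(self, rng):
        data = make_dataset(rng)
        fit = fit_one_way(data, FAST)
        other = make_dataset(rng, conds=("a", "b", "c", "d"))
        with pytest.raises(ValueError):
            posterior_predictive(fit, other)


# ---------------------------------------------------------------------------
# JZS Bayes factors
# ---------------------------------------------------------------------------

class TestBayesFactors:
    def test_model_vs_itself_is_one(self, rng):
        data = make_dataset(rng)
        assert jzs_anova_bf(data, "mask_speed", "mask_speed").bf == 1.0

    def test_reciprocity(self, rng):
        data = make_dataset(rng, effects=[0.1, 0.0, -0.1])
        ab = jzs_anova_bf(data, "mask_speed", "null", seed=2)
        ba = jzs_anova_bf(data, "null", "mask_speed", seed=2)
        assert ab.bf * ba.bf == pytest.approx(1.0, rel=1e-9)

    def test_two_condition_reduction_matches_dense_quadrature_oracle(self):
        rng = np.random.default_rng(17)
        data = make_dataset(rng, n_participants=10, conds=("a", "b"),
                            effects=[0.08, -0.08], sd=0.08)
        res = jzs_anova_bf(data, "mask_speed", "null")
        oracle = np.exp(dense_log_marginal(data, True)
                        - dense_log_marginal(data, False))
        assert res.bf == pytest.approx(oracle, rel=0.01)

    def test_strong_effect_large_bf(self, rng):
        data = make_dataset(rng, n_participants=20,
                            effects=[0.3, 0.0, -0.3], sd=0.1)
        assert jzs_anova_bf(data, "mask_speed", "null").bf > 10

    def test_null_truth_favours_null_in_majority(self):
        wins = 0
        n_rep = 20
        for s in range(n_rep):
            r = np.random.default_rng(1000 + s)
            data = make_dataset(r, n_participants=10, sd=0.1)
            if jzs_anova_bf(data, "mask_speed", "null").bf < 1.0:
                wins += 1
        assert wins > n_rep / 2

    def test_unknown_model_label(self, rng):
        data = make_dataset(rng)
        with pytest.raises(ValueError):
            jzs_anova_bf(data, "bogus", "null")
        with pytest.raises(ValueError):
            jzs_anova_bf(data, "full", "null")  # needs a two-way dataset

    def test_two_way_table_prefers_generating_model(self):
        profile = EffectProfile(tuning_amplitude=0.45, participant_sd=0.2,
                                residual_scale=0.07, outlier_rate=0.0)
        data, _ = generate_threshold_dataset(16, profile, design="exp2",
                                             seed=11)
        table = bf_table(data, reference="full", seed=0, mc_draws=8000)
        assert set(table["model"]) == {"null", "mask_speed", "target_speed",
                                       "additive"}
        row = table.set_index("model")
        # a mask-speed effect exists in truth: the null is soundly beaten
        assert row.loc["null", "bf_vs_full"] < 1.0

    def test_sum_to_zero_basis_orthonormal(self):
        for m in (2, 3, 6):
            q = _sum_to_zero_basis(m)
            assert q.shape == (m, m - 1)
            np.testing.assert_allclose(q.T @ q, np.eye(m - 1), atol=1e-12)
            np.testing.assert_allclose(q.sum(axis=0), 0.0, atol=1e-12)
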