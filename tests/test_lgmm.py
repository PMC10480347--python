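"""Growth mixture model: likelihood oracles, EM behavior, posteriors,
information criteria, likelihood-ratio testing and model selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from trajprs import datagen as dg
from trajprs import lgmm


def _make_data(frames, classmb=()):
    """MixtureData from (subject_id, wave, time, harmonized) tuples; wave 0
    rows provide the pre-deployment covariate when requested."""
    long = pd.DataFrame(frames, columns=["subject_id", "wave", "time_months", "harmonized"])
    long["observed"] = 1
    cohort = pd.DataFrame({"subject_id": sorted(long["subject_id"].unique())})
    return lgmm.MixtureData(long, cohort, classmb)


class TestMarginalLoglik:
    def test_single_point_matches_normal_density(self):
        """One subject, one observation, no random effects: the mixture
        likelihood is a plain normal density."""
        data = _make_data([(1, 1, 0.0, 12.0)])
        beta = np.array([[10.0, 0.5]])
        ll = lgmm.marginal_loglik(data, beta, np.zeros((0, 0)), 4.0,
                                  np.zeros((0, 1)), 0)
        assert ll == pytest.approx(stats.norm.logpdf(12.0, 10.0, 2.0), abs=1e-12)

    def test_duplicating_subjects_doubles_loglik(self, two_class_fixture):
        cfg, cohort, long = two_class_fixture
        data = lgmm.MixtureData(long, cohort)
        beta = np.array([[10.0, -0.5], [50.0, 2.0]])
        psi = np.array(cfg.re_cov)
        gamma = np.array([[0.3, 0.0]])
        ll1 = lgmm.marginal_loglik(data, beta, psi, cfg.resid_sd**2, gamma, 2)

        long2 = pd.concat([long, long.assign(subject_id=long["subject_id"] + 10_000)])
        cohort2 = pd.concat([cohort, cohort.assign(subject_id=cohort["subject_id"] + 10_000)])
        data2 = lgmm.MixtureData(long2.reset_index(drop=True), cohort2.reset_index(drop=True))
        ll2 = lgmm.marginal_loglik(data2, beta, psi, cfg.resid_sd**2, gamma, 2)
        assert ll2 == pytest.approx(2 * ll1, rel=1e-12)

    def test_permutation_leaves_loglik_unchanged(self, two_class_fit):
        fit, cohort, long = two_class_fit
        data = lgmm.MixtureData(long, cohort, fit.spec.classmb_covariates)
        ll = lgmm.marginal_loglik(data, fit.beta, fit.psi, fit.sigma2, fit.gamma, 2)
        order = np.array([1, 0])
        beta_p, gamma_p, _ = lgmm._apply_order(order, fit.beta, fit.gamma, fit.posterior)
        ll_p = lgmm.marginal_loglik(data, beta_p, fit.psi, fit.sigma2, gamma_p, 2)
        assert ll_p == pytest.approx(ll, abs=1e-8)


def test_one_class_matches_direct_marginal_mle():
    """EM for the one-class model agrees with a generic optimizer run on an
    independently coded Gaussian marginal likelihood (random intercept+slope)."""
    cfg = dg.GeneratorConfig(
        n_subjects=50, seed=13, class_shares=(1.0,), class_intercepts=(20.0,),
        class_slopes=(0.5,), prs_class_logor=np.zeros((6, 0)),
        covariate_class_logor=np.zeros((10, 0)),
        re_cov=((9.0, 0.3), (0.3, 0.25)), resid_sd=3.0,
        target_complete_share=1.0, unit_nonresponse_rate=0.0,
    )
    cohort, long = dg.generate(cfg)
    post = long[long["wave"] >= 1]
    groups = {s: g for s, g in post.groupby("subject_id")}

    def direct_negll(theta):
        b0, b1, l0, c10, l1, ls = theta
        L = np.array([[np.exp(l0), 0.0], [c10, np.exp(l1)]])
        psi = L @ L.T
        s2 = np.exp(2 * ls)
        total = 0.0
        for g in groups.values():
            t = g["time_months"].to_numpy()
            y = g["harmonized"].to_numpy()
            Z = np.column_stack([np.ones_like(t), t])
            V = Z @ psi @ Z.T + s2 * np.eye(len(t))
            total += stats.multivariate_normal.logpdf(y, b0 + b1 * t, V)
        return -total

    res = optimize.minimize(direct_negll, [20.0, 0.5, np.log(3.0), 0.0,
                                           np.log(0.5), np.log(3.0)],
                            method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
    fit = lgmm.fit_lgmm(long, cohort, lgmm.LGMMSpec(n_classes=1, seed=1))
    assert fit.loglik == pytest.approx(-res.fun, abs=1e-4)


def test_em_loglik_monotone(two_class_fixture):
    cfg, cohort, long = two_class_fixture
    data = lgmm.MixtureData(long, cohort)
    rng = np.random.default_rng(0)
    beta0 = np.array([[15.0, 0.0], [40.0, 0.0]]) + rng.normal(0, 1, (2, 2))
    trace: list[float] = []
    lgmm._em_iterate(data, beta0, 4.0 * np.eye(2), 9.0, np.zeros((1, 2)), 2,
                     max_iter=60, tol=1e-12, trace=trace)
    diffs = np.diff(trace)
    assert (diffs >= -1e-8 * (1 + np.abs(trace[:-1]))).all()


def test_near_noise_free_two_class_recovery():
    """With (almost) no noise the mixture recovers the generating lines and
    classifies every subject with certainty."""
    cfg = dg.GeneratorConfig(
        n_subjects=120, seed=14, class_shares=(0.5, 0.5),
        class_intercepts=(10.0, 50.0), class_slopes=(-0.5, 2.0),
        prs_class_logor=np.zeros((6, 1)), covariate_class_logor=np.zeros((10, 1)),
        re_cov=((0.0, 0.0), (0.0, 0.0)), resid_sd=1e-3,
        target_complete_share=1.0, unit_nonresponse_rate=0.0,
    )
    cohort, long = dg.generate(cfg)
    spec = lgmm.LGMMSpec(n_classes=2, random_effects="none", multistart=(4, 40), seed=2)
    fit = lgmm.fit_lgmm(long, cohort, spec)
    np.testing.assert_allclose(fit.beta[:, 0], [10.0, 50.0], atol=1e-3)
    np.testing.assert_allclose(fit.beta[:, 1], [-0.5, 2.0], atol=1e-3)
    assert fit.posterior.max(axis=1).min() > 1 - 1e-6


def test_four_class_recovery_moderate_n(four_class_fit, small_cfg):
    fit, _, _ = four_class_fit
    assert fit.n_classes == 4
    # canonical order sorts by final-time mean: low, decreasing, increasing, high
    truth = np.array([[12.0, -0.3], [45.0, -2.8], [18.0, 2.5], [55.0, 0.0]])
    np.testing.assert_allclose(fit.beta, truth, atol=1.5)
    share_truth = np.array([0.772, 0.080, 0.105, 0.043])
    np.testing.assert_allclose(fit.class_shares, share_truth, atol=0.06)


def test_lcga_matches_lgmm_when_no_random_effects():
    cfg = dg.GeneratorConfig(
        n_subjects=300, seed=15, re_cov=((0.0, 0.0), (0.0, 0.0)),
        class_shares=(0.6, 0.4), class_intercepts=(10.0, 45.0),
        class_slopes=(0.0, 1.5), prs_class_logor=np.zeros((6, 1)),
        covariate_class_logor=np.zeros((10, 1)),
        target_complete_share=1.0, unit_nonresponse_rate=0.0,
    )
    cohort, long = dg.generate(cfg)
    f_lcga = lgmm.fit_lgmm(long, cohort, lgmm.LGMMSpec(
        n_classes=2, random_effects="none", multistart=(3, 40), seed=3))
    f_lgmm = lgmm.fit_lgmm(long, cohort, lgmm.LGMMSpec(
        n_classes=2, random_effects="intercept+slope", multistart=(3, 40), seed=3))
    gain = f_lgmm.loglik - f_lcga.loglik
    assert gain > -1e-4          # nesting
    assert gain < 5.0            # no real random-effect signal to absorb


class TestPosteriors:
    def test_rows_sum_to_one(self, four_class_fit):
        fit, cohort, long = four_class_fit
        post = lgmm.posterior_probs(fit, long, cohort)
        vals = post.filter(like="class").to_numpy()
        np.testing.assert_allclose(vals.sum(axis=1), 1.0, atol=1e-8)

    def test_one_class_posteriors_are_unity(self, two_class_fixture):
        _, cohort, long = two_class_fixture
        fit = lgmm.fit_lgmm(long, cohort, lgmm.LGMMSpec(n_classes=1))
        assert (fit.posterior == 1.0).all()

    def test_equidistant_subject_splits_evenly(self):
        data = _make_data([(1, 1, 0.0, 30.0)])
        beta = np.array([[20.0, 0.0], [40.0, 0.0]])
        P, _ = lgmm._posteriors(data, beta, np.zeros((0, 0)), 25.0,
                                np.zeros((1, 1)), 0)
        np.testing.assert_allclose(P, [[0.5, 0.5]], atol=1e-12)

    def test_matches_brute_force_bayes_rule(self, two_class_fit):
        fit, cohort, long = two_class_fit
        data = lgmm.MixtureData(long, cohort, fit.spec.classmb_covariates)
        sub = data.subject_ids[:5]
        post = lgmm.posterior_probs(fit, long, cohort)
        post = post[post["subject_id"].isin(sub)].set_index("subject_id")
        pri = lgmm._probs(data.W, fit.gamma)
        obs = long[(long["wave"] >= 1) & (long["observed"] == 1)]
        for j, sid in enumerate(sub):
            g = obs[obs["subject_id"] == sid].sort_values("wave")
            t = g["time_months"].to_numpy()
            y = g["harmonized"].to_numpy()
            Z = np.column_stack([np.ones_like(t), t])
            V = Z @ fit.psi @ Z.T + fit.sigma2 * np.eye(len(t))
            dens = np.array([
                stats.multivariate_normal.pdf(y, fit.beta[k, 0] + fit.beta[k, 1] * t, V)
                for k in range(2)
            ])
            expect = dens * pri[j]
            expect /= expect.sum()
            np.testing.assert_allclose(
                post.loc[sid, ["class1", "class2"]].to_numpy(float), expect, atol=1e-8)


class TestEntropyAndCriteria:
    def _fit_with_posterior(self, P):
        P = np.asarray(P, dtype=float)
        return lgmm.LGMMFit(
            spec=lgmm.LGMMSpec(n_classes=P.shape[1]), beta=np.zeros((P.shape[1], 2)),
            psi=np.eye(2), sigma2=1.0, gamma=np.zeros((P.shape[1] - 1, 1)),
            loglik=0.0, n_params=0, posterior=P, converged=True,
            n_subjects=P.shape[0], subject_ids=np.arange(P.shape[0]),
            classmb_names=("const",),
        )

    def test_hand_computed_value(self):
        fit = self._fit_with_posterior([[0.9, 0.1], [0.2, 0.8]])
        assert lgmm.entropy(fit) == pytest.approx(0.40456, abs=1e-4)

    def test_degenerate_and_uniform_bounds(self):
        assert lgmm.entropy(self._fit_with_posterior([[1, 0], [0, 1]])) == 1.0
        assert lgmm.entropy(self._fit_with_posterior([[0.5, 0.5]] * 4)) == pytest.approx(0.0, abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            lgmm.entropy(self._fit_with_posterior(np.ones((3, 1))))

    def test_ssa_bic_hand_values(self):
        fit = self._fit_with_posterior(np.ones((100, 2)) * 0.5)
        fit.loglik, fit.n_params, fit.n_subjects = -100.0, 5, 100
        assert lgmm.ssa_bic(fit) == pytest.approx(200 + 5 * np.log(102 / 24), abs=1e-9)
        fit.n_subjects = int(round(24 * np.e)) - 2  # (n+2)/24 = e
        assert lgmm.ssa_bic(fit) == pytest.approx(200 + 5 * 1.0, abs=0.05)
        fit.n_subjects = 100
        fit.n_params = 6
        assert lgmm.ssa_bic(fit) > 200 + 5 * np.log(102 / 24)

    def test_classify_tie_breaks_low_and_reports_mean_max(self):
        fit = self._fit_with_posterior([[0.5, 0.5], [0.1, 0.9], [0.7, 0.3]])
        fit.subject_ids = np.array([11, 12, 13])
        table, mean_max = lgmm.classify(fit)
        assert table["assigned_class"].tolist() == [1, 2, 1]
        assert mean_max == pytest.approx((0.5 + 0.9 + 0.7) / 3)
        hard, mm = lgmm.classify(self._fit_with_posterior([[1, 0], [0, 1]]))
        assert mm == 1.0


@pytest.fixture(scope="module")
def strong_two_class():
    cfg = dg.GeneratorConfig(
        n_subjects=150, seed=16, class_shares=(0.5, 0.5),
        class_intercepts=(10.0, 50.0), class_slopes=(0.0, 1.0),
        prs_class_logor=np.zeros((6, 1)), covariate_class_logor=np.zeros((10, 1)),
        re_cov=((1.0, 0.0), (0.0, 0.01)), resid_sd=2.0,
        target_complete_share=1.0, unit_nonresponse_rate=0.0,
    )
    cohort, long = dg.generate(cfg)
    data = lgmm.MixtureData(long, cohort)
    spec1 = lgmm.LGMMSpec(n_classes=1, random_effects="none", seed=1)
    spec2 = lgmm.LGMMSpec(n_classes=2, random_effects="none",
                          multistart=(3, 30), seed=1)
    f1 = lgmm._fit_on_data(data, spec1)
    f2 = lgmm._fit_on_data(data, spec2)
    return data, f1, f2


class TestLmrLrt:
    def test_equal_logliks_give_p_one(self, strong_two_class):
        _, f1, f2 = strong_two_class
        f2_same = lgmm.LGMMFit(**{**f2.__dict__, "loglik": f1.loglik})
        out = lgmm.lmr_lrt(f2_same, f1)
        assert out["statistic"] == 0.0 and out["p_value"] == pytest.approx(1.0)

    def test_power_on_separated_classes(self, strong_two_class):
        data, f1, f2 = strong_two_class
        assert lgmm.lmr_lrt(f2, f1)["p_value"] < 0.01
        boot = lgmm.lmr_lrt(f2, f1, mode="bootstrap", data=data, n_boot=119, seed=4,
                            boot_spec_overrides={"multistart": (1, 20)})
        assert boot["p_value"] <= 0.01

    def test_non_nested_rejected(self, strong_two_class, four_class_fit):
        _, f1, f2 = strong_two_class
        with pytest.raises(ValueError):
            lgmm.lmr_lrt(f1, f2)
        f4, _, _ = four_class_fit
        with pytest.raises(ValueError):
            lgmm.lmr_lrt(f4, f1)

    def test_bootstrap_null_not_anticonservative(self):
        """When the truth has K-1 classes the bootstrap p-values should not
        pile up near zero (coarse calibration check at small B)."""
        cfg = dg.GeneratorConfig(
            n_subjects=60, seed=17, class_shares=(1.0,), class_intercepts=(20.0,),
            class_slopes=(0.2,), prs_class_logor=np.zeros((6, 0)),
            covariate_class_logor=np.zeros((10, 0)),
            re_cov=((0.0, 0.0), (0.0, 0.0)), resid_sd=5.0,
            target_complete_share=1.0, unit_nonresponse_rate=0.0,
        )
        pvals = []
        for rep in range(12):
            cohort, long = dg.generate(cfg.replace(seed=1000 + rep))
            data = lgmm.MixtureData(long, cohort)
            f1 = lgmm._fit_on_data(data, lgmm.LGMMSpec(
                n_classes=1, random_effects="none", seed=rep))
            f2 = lgmm._fit_on_data(data, lgmm.LGMMSpec(
                n_classes=2, random_effects="none", multistart=(1, 20),
                polish=False, seed=rep))
            pvals.append(lgmm.lmr_lrt(
                f2, f1, mode="bootstrap", data=data, n_boot=19, seed=rep,
                boot_spec_overrides={"multistart": (1, 15)})["p_value"])
        pvals = np.array(pvals)
        assert (pvals <= 0.05).mean() <= 0.25
        assert pvals.mean() > 0.3


class TestSelectModel:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["family", "n_classes", "loglik", "ssa_bic",
                                           "entropy", "lmr_lrt_p", "smallest_class_share"])

    def test_sparse_extra_class_is_rejected(self):
        """A five-class candidate whose smallest class holds 2.66% of subjects
        loses to the four-class model despite a better criterion value."""
        tab = self._table([
            ("lgmm", 3, -100, 320.0, 0.86, 0.001, 0.20),
            ("lgmm", 4, -90, 300.0, 0.85, 0.001, 0.043),
            ("lgmm", 5, -80, 290.0, 0.84, 0.001, 0.0266),
        ])
        assert lgmm.select_model(tab) == ("lgmm", 4)

    def test_single_row(self):
        tab = self._table([("lgmm", 1, -100, 210.0, np.nan, np.nan, 1.0)])
        assert lgmm.select_model(tab) == ("lgmm", 1)

    def test_strictly_improving_with_guards_ok(self):
        tab = self._table([
            ("lgmm", 1, -120, 250.0, np.nan, np.nan, 1.0),
            ("lgmm", 2, -100, 230.0, 0.9, 0.001, 0.4),
            ("lgmm", 3, -90, 220.0, 0.9, 0.001, 0.2),
        ])
        assert lgmm.select_model(tab) == ("lgmm", 3)

    def test_family_comparison_by_criterion(self):
        tab = self._table([
            ("lcga", 2, -110, 240.0, 0.95, 0.001, 0.4),
            ("lgmm", 2, -100, 230.0, 0.92, 0.001, 0.4),
        ])
        assert lgmm.select_model(tab) == ("lgmm", 2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lgmm.select_model(self._table([]))
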