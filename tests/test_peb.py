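"""Group-level tests: design construction, empirical-Bayes fit against
conjugate oracles, Bayesian model reduction exactness, greedy search and
model averaging."""

import numpy as np
import pandas as pd
import pytest

from spectraldcm.inversion import GaussianDensity, SubjectDCM, default_priors, ParameterPacking
from spectraldcm.peb import (
    BMAResult,
    DesignMatrix,
    MissingCovariateError,
    ReducedModel,
    bma,
    bmr,
    build_design,
    extract_likelihood,
    fit_peb,
    greedy_search,
)
from spectraldcm.simulate import CohortConfig, emulate_first_level, sample_cohort


def covariate_table(n=4, bdi=(10, 20, 30, 40), treatment=False, sex=None):
    df = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "bdi": list(bdi),
            "age": np.linspace(25, 40, n),
            "sex": sex if sex is not None else [0, 1] * (n // 2) + [0] * (n % 2),
        }
    )
    if treatment:
        df["treatment"] = [0, 1] * (n // 2) + [0] * (n % 2)
    return df


def toy_subject(names, post_mean, post_var, prior):
    packing = ParameterPacking(names)
    mean = np.zeros(packing.size)
    var = np.diag(prior.cov).copy()
    for nm, v in post_mean.items():
        mean[packing.index(nm)] = v
    for nm, v in post_var.items():
        var[packing.index(nm)] = v
    return SubjectDCM(
        region_names=tuple(names),
        prior=GaussianDensity(prior.mean, prior.cov, packing.names),
        posterior=GaussianDensity(mean, np.diag(var), packing.names),
        free_energy=0.0,
        variance_explained_pct=90.0,
    )


class TestBuildDesign:
    def test_centering_arithmetic(self):
        d = build_design(covariate_table())
        np.testing.assert_allclose(d.column("bdi"), [-15, -5, 5, 15])
        assert d.column_names == ("mean", "bdi", "age", "sex")
        np.testing.assert_allclose(d.column("mean"), 1.0)

    def test_sex_coded_half(self):
        d = build_design(covariate_table())
        assert set(d.column("sex")) == {-0.5, 0.5}

    def test_constant_sex_warns_rank_deficiency(self):
        with pytest.warns(UserWarning, match="rank-deficient"):
            build_design(covariate_table(sex=[1, 1, 1, 1]))

    def test_primary_vs_followup_shape(self):
        d4 = build_design(covariate_table())
        d5 = build_design(covariate_table(treatment=True), with_treatment=True)
        assert d4.n_covariates == 4
        assert d5.n_covariates == 5
        assert d5.column_names[-1] == "treatment"

    def test_missing_values_reported_with_exclusions(self):
        df = covariate_table()
        df.loc[2, "age"] = np.nan
        with pytest.raises(MissingCovariateError) as exc:
            build_design(df)
        assert exc.value.excluded == ["s2"]

    def test_design_matrix_invariants(self):
        with pytest.raises(ValueError, match="group mean"):
            DesignMatrix(("a", "b"), ("mean",), np.array([[1.0], [2.0]]), (False,))
        with pytest.raises(ValueError, match="centered"):
            DesignMatrix(("a", "b"), ("mean", "x"), np.array([[1.0, 1.0], [1.0, 2.0]]), (False, True))


class TestFitPeb:
    NAMES = ("SMA", "MC")

    def intercept_design(self, n):
        return DesignMatrix(
            tuple(f"s{i}" for i in range(n)), ("mean",), np.ones((n, 1)), (False,)
        )

    def test_equal_precision_subjects_average(self):
        # equal posterior covariances: both subjects get the same weight, so
        # the group mean is the (prior-shrunk) arithmetic mean and is
        # invariant to swapping the subjects
        prior = default_priors(self.NAMES)
        d1 = toy_subject(self.NAMES, {"a_SMA<-MC": 0.2}, {"a_SMA<-MC": 0.0025}, prior)
        d2 = toy_subject(self.NAMES, {"a_SMA<-MC": 0.4}, {"a_SMA<-MC": 0.0025}, prior)
        peb = fit_peb([d1, d2], self.intercept_design(2), selection=["a_SMA<-MC"])
        swapped = fit_peb([d2, d1], self.intercept_design(2), selection=["a_SMA<-MC"])
        assert peb.posterior.mean[0] == pytest.approx(swapped.posterior.mean[0], abs=1e-9)
        # shrunk arithmetic mean from the conjugate oracle at the fitted
        # gamma, applied to the extracted subject likelihoods
        m_ls = []
        for d in (d1, d2):
            eta, L = extract_likelihood(d.posterior.marginal([0]), d.prior.marginal([0]))
            m_ls.append(eta[0] / L[0, 0])
            c_i = 1.0 / L[0, 0] + peb.random_effects_var[0]
        expect = (sum(m_ls) / c_i) / (16.0 + 2.0 / c_i)
        assert peb.posterior.mean[0] == pytest.approx(expect, abs=1e-6)

    def test_unequal_precision_matches_conjugate_oracle(self):
        prior = default_priors(self.NAMES)
        subs = [
            toy_subject(self.NAMES, {"a_SMA<-MC": 0.1}, {"a_SMA<-MC": 0.0025}, prior),
            toy_subject(self.NAMES, {"a_SMA<-MC": 0.5}, {"a_SMA<-MC": 0.01}, prior),
            toy_subject(self.NAMES, {"a_SMA<-MC": 0.3}, {"a_SMA<-MC": 0.005}, prior),
        ]
        peb = fit_peb(subs, self.intercept_design(3), selection=["a_SMA<-MC"])
        # independent conjugate-Gaussian oracle at the fitted gamma: the
        # group mean is the precision-weighted average of the extracted
        # subject likelihoods, shrunk by the group prior
        re_var = peb.random_effects_var[0]
        num, den = 0.0, 1.0 / (1.0 / 16.0)
        for s in subs:
            eta, L = extract_likelihood(s.posterior.marginal([0]), s.prior.marginal([0]))
            m_L = eta[0] / L[0, 0]
            c = 1.0 / L[0, 0] + re_var
            num += m_L / c
            den += 1.0 / c
        assert peb.posterior.mean[0] == pytest.approx(num / den, abs=1e-6)

    def test_severity_effect_recovery_interval(self):
        # +0.2 per unit of the (centered) severity column on one coupling;
        # the 95% interval must contain it and exclude 0 in >= 90% of reps
        rng = np.random.default_rng(0)
        prior = default_priors(self.NAMES)
        hits_interval, excludes_zero = 0, 0
        n_rep, n_sub = 20, 40
        for rep in range(n_rep):
            z = rng.normal(0, 1, n_sub)
            subs = []
            for i in range(n_sub):
                theta = 0.2 * z[i] + rng.normal(0, 0.1)
                subs.append(
                    toy_subject(self.NAMES, {"a_SMA<-MC": theta + rng.normal(0, 0.05)}, {"a_SMA<-MC": 0.0025}, prior)
                )
            design = DesignMatrix(
                tuple(f"s{i}" for i in range(n_sub)),
                ("mean", "severity"),
                np.column_stack([np.ones(n_sub), z - z.mean()]),
                (False, True),
            )
            peb = fit_peb(subs, design, selection=["a_SMA<-MC"])
            i_eff = peb.effect_names.index("severity:a_SMA<-MC")
            m = peb.posterior.mean[i_eff]
            sd = np.sqrt(peb.posterior.cov[i_eff, i_eff])
            if 0.1 <= m <= 0.3:
                hits_interval += 1
            if abs(m) > 1.96 * sd:
                excludes_zero += 1
        assert hits_interval >= 0.9 * n_rep
        assert excludes_zero >= 0.9 * n_rep

    def test_rank_error_with_too_few_subjects(self):
        prior = default_priors(self.NAMES)
        subs = [toy_subject(self.NAMES, {}, {}, prior) for _ in range(2)]
        design = build_design(covariate_table().iloc[:2])
        with pytest.raises(ValueError, match="rank"):
            fit_peb(subs, design, selection=["a_SMA<-MC"])

    def test_mismatched_packings_rejected(self):
        p1 = default_priors(("SMA", "MC"))
        p2 = default_priors(("AI", "PI"))
        s1 = toy_subject(("SMA", "MC"), {}, {}, p1)
        s2 = toy_subject(("AI", "PI"), {}, {}, p2)
        with pytest.raises(ValueError, match="packing"):
            fit_peb([s1, s2], self.intercept_design(2), selection=["a_SMA<-MC"])


class TestBmr:
    def test_identity_reduction(self):
        rng = np.random.default_rng(1)
        M = rng.normal(0, 1, (3, 3))
        post = GaussianDensity(rng.normal(0, 1, 3), 0.1 * (M @ M.T + 3 * np.eye(3)))
        prior = GaussianDensity(np.zeros(3), np.eye(3))
        df, red = bmr(post, prior, prior)
        assert df == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(red.mean, post.mean, atol=1e-10)
        np.testing.assert_allclose(red.cov, post.cov, atol=1e-10)

    def test_one_dimensional_direct_evidence_oracle(self):
        # y ~ N(theta, s2); evidence under prior N(0, v) is N(y; 0, s2 + v)
        from scipy.stats import norm

        y, s2 = 0.8, 0.25
        v_full, v_red = 1.0, 0.01
        post_prec = 1 / s2 + 1 / v_full
        post = GaussianDensity(np.array([(y / s2) / post_prec]), np.array([[1 / post_prec]]))
        prior = GaussianDensity(np.array([0.0]), np.array([[v_full]]))
        reduced_prior = GaussianDensity(np.array([0.0]), np.array([[v_red]]))
        df, red = bmr(post, prior, reduced_prior)
        oracle = norm.logpdf(y, 0, np.sqrt(s2 + v_red)) - norm.logpdf(y, 0, np.sqrt(s2 + v_full))
        assert df == pytest.approx(oracle, abs=1e-8)
        # reduced posterior from direct conjugate update
        prec_r = 1 / s2 + 1 / v_red
        assert red.mean[0] == pytest.approx((y / s2) / prec_r, abs=1e-8)
        assert red.cov[0, 0] == pytest.approx(1 / prec_r, abs=1e-10)

    def test_pruning_signs_on_known_truth(self):
        # pruning a null effect increases evidence; pruning a strong one
        # decreases it
        rng = np.random.default_rng(2)
        prior = default_priors(("SMA", "MC"))
        n_sub = 30
        z = rng.normal(0, 1, n_sub)
        subs = [
            toy_subject(
                ("SMA", "MC"),
                {"a_SMA<-MC": 0.3 * z[i] + rng.normal(0, 0.03), "a_MC<-SMA": rng.normal(0, 0.03)},
                {"a_SMA<-MC": 0.0025, "a_MC<-SMA": 0.0025},
                prior,
            )
            for i in range(n_sub)
        ]
        design = DesignMatrix(
            tuple(f"s{i}" for i in range(n_sub)),
            ("mean", "severity"),
            np.column_stack([np.ones(n_sub), z - z.mean()]),
            (False, True),
        )
        peb = fit_peb(subs, design, selection=["a_SMA<-MC", "a_MC<-SMA"])
        var = np.diag(peb.prior.cov).copy()
        i_null = peb.effect_names.index("severity:a_MC<-SMA")
        i_strong = peb.effect_names.index("severity:a_SMA<-MC")
        for idx, expect_positive in [(i_null, True), (i_strong, False)]:
            v = var.copy()
            v[idx] = 1e-8
            df, _ = bmr(peb.posterior, peb.prior, GaussianDensity(peb.prior.mean, np.diag(v), peb.effect_names))
            assert (df > 0) == expect_positive

    def test_non_psd_inputs_rejected(self):
        bad = GaussianDensity(np.zeros(2), np.array([[1.0, 0.0], [0.0, -0.5]]))
        ok = GaussianDensity(np.zeros(2), np.eye(2))
        with pytest.raises(ValueError):
            bmr(bad, ok, ok)


def strong_effect_peb(rng, n_sub=30):
    prior = default_priors(("SMA", "MC"))
    subs = [
        toy_subject(
            ("SMA", "MC"),
            {"a_SMA<-MC": 0.3 + rng.normal(0, 0.02), "a_MC<-SMA": -0.25 + rng.normal(0, 0.02)},
            {"a_SMA<-MC": 0.0004, "a_MC<-SMA": 0.0004},
            prior,
        )
        for i in range(n_sub)
    ]
    design = DesignMatrix(tuple(f"s{i}" for i in range(n_sub)), ("mean",), np.ones((n_sub, 1)), (False,))
    return fit_peb(subs, design, selection=["a_SMA<-MC", "a_MC<-SMA"])


class TestGreedySearchAndBma:
    def test_strong_effects_nothing_pruned(self):
        peb = strong_effect_peb(np.random.default_rng(3))
        models = greedy_search(peb)
        assert len(models) == 2 ** len(peb.effect_names)  # k = all (2 effects)
        best = max(models, key=lambda m: m.delta_f)
        assert best.free_mask.all()
        res = bma(models)
        assert np.all(res.pp > 0.95)

    def test_null_effects_mostly_pruned(self):
        rng = np.random.default_rng(4)
        prior = default_priors(("SMA", "MC"))
        n_sub = 40
        z = rng.normal(0, 1, n_sub)
        subs = [
            toy_subject(
                ("SMA", "MC"),
                {"a_SMA<-MC": rng.normal(0, 0.02), "a_MC<-SMA": rng.normal(0, 0.02)},
                {"a_SMA<-MC": 0.0004, "a_MC<-SMA": 0.0004},
                prior,
            )
            for i in range(n_sub)
        ]
        design = DesignMatrix(
            tuple(f"s{i}" for i in range(n_sub)),
            ("mean", "severity", "age"),
            np.column_stack([np.ones(n_sub), z - z.mean(), rng.normal(0, 1, n_sub)]),
            (False, True, False),
        )
        peb = fit_peb(subs, design, selection=["a_SMA<-MC", "a_MC<-SMA"])
        res = bma(greedy_search(peb))
        assert np.mean(res.pp < 0.5) >= 0.8

    def test_deterministic_search(self):
        peb = strong_effect_peb(np.random.default_rng(5))
        m1 = greedy_search(peb)
        m2 = greedy_search(peb)
        for a, b in zip(m1, m2):
            np.testing.assert_array_equal(a.free_mask, b.free_mask)
            assert a.delta_f == b.delta_f

    def test_bma_single_model(self):
        peb = strong_effect_peb(np.random.default_rng(6))
        model = ReducedModel(np.array([True, True]), 0.0, peb.posterior)
        res = bma([model])
        np.testing.assert_allclose(res.weights, [1.0])
        np.testing.assert_allclose(res.pp, 1.0)

    def test_bma_equal_evidence_split(self):
        g1 = GaussianDensity(np.array([0.2, 0.0]), np.diag([0.01, 1e-8]))
        g2 = GaussianDensity(np.array([0.25, 0.1]), np.diag([0.02, 0.01]))
        m1 = ReducedModel(np.array([True, False]), 1.7, g1)
        m2 = ReducedModel(np.array([True, True]), 1.7, g2)
        res = bma([m1, m2])
        np.testing.assert_allclose(res.weights, [0.5, 0.5])
        assert res.pp[1] == pytest.approx(0.5)
        assert res.pp[0] == pytest.approx(1.0)

    def test_bma_mixture_moments_match_oracle(self):
        rng = np.random.default_rng(7)
        models = []
        for df in [0.0, 0.7, -0.4]:
            mu = rng.normal(0, 1, 2)
            var = rng.uniform(0.01, 0.1, 2)
            models.append(ReducedModel(np.array([True, True]), df, GaussianDensity(mu, np.diag(var))))
        res = bma(models)
        # independent Gaussian-mixture moment oracle
        F = np.array([m.delta_f for m in models])
        w = np.exp(F - F.max())
        w /= w.sum()
        for k in range(2):
            mean = sum(wi * m.posterior.mean[k] for wi, m in zip(w, models))
            second = sum(wi * (m.posterior.cov[k, k] + m.posterior.mean[k] ** 2) for wi, m in zip(w, models))
            assert res.mean[k] == pytest.approx(mean, abs=1e-10)
            assert res.variance[k] == pytest.approx(second - mean**2, abs=1e-10)
        assert res.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_pp_monotone_under_added_dominant_models(self):
        g_free = GaussianDensity(np.array([0.3]), np.array([[0.01]]))
        g_off = GaussianDensity(np.array([0.0]), np.array([[1e-8]]))
        base = [ReducedModel(np.array([True]), 0.0, g_free), ReducedModel(np.array([False]), 0.0, g_off)]
        pp0 = bma(base).pp[0]
        added = base + [ReducedModel(np.array([True]), 3.0, g_free)]
        assert bma(added).pp[0] >= pp0

    def test_sign_recovery_of_retained_severity_effects(self):
        # generating severity slopes: + on one coupling, - on the other
        hits, total = 0, 0
        for seed in range(6):
            cfg = CohortConfig(
                network="left_motor",
                n_subjects=40,
                effects={"bdi": {("SMA", "MC"): 0.012, ("MC", "SMA"): -0.012}},
                between_sd=0.1,
                generate_bold=False,
                seed=seed,
            )
            cohort = sample_cohort(cfg)
            dcms = emulate_first_level(cohort, posterior_sd=0.05, seed=seed + 50)
            peb = fit_peb(dcms, build_design(cohort.covariates_df()))
            res = bma(greedy_search(peb))
            frame = res.to_frame()
            sev = frame[(frame.covariate == "bdi") & frame.retained]
            for _, row in sev.iterrows():
                truth = {("SMA", "MC"): 0.012, ("MC", "SMA"): -0.012}.get(
                    (row.target_region, row.source_region)
                )
                if truth is not None:
                    total += 1
                    if np.sign(row["mean"]) == np.sign(truth):
                        hits += 1
        assert total > 0
        assert hits / total >= 0.95
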