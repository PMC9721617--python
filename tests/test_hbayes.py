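"""Hierarchical inference: joint density oracle, sampler calibration,
coefficient summaries and effect sizes."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr
from scipy.stats import multivariate_normal

from twostep.cohort import CohortSpec, generate_cohort
from twostep.exceptions import InputError, NumericalError
from twostep.hbayes import (
    BETA_PRIOR_SD,
    CohortData,
    GroupModel,
    PosteriorDraws,
    effect_size,
    fit_hierarchical,
    joint_log_density,
    summarize_coefficient,
)
from twostep.agents import M1Params, session_loglik
from twostep.task import PLANETS, TrialRecord, stimulus_id


def _toy_cohort():
    """2 subjects (one placebo, one amisulpride), 3 trials x 2 sessions."""
    rows = []
    plan = [(1, 1, "red", 2), (2, 2, "red", -1), (1, 2, "green", 4)]
    for sid, drug in (("a", "placebo"), ("b", "amisulpride")):
        for sess in (1, 2):
            for t, (s, a, p, r) in enumerate(plan, start=1):
                rows.append(dict(subject_id=sid, session=sess, trial=t,
                                 first_state=s, action=a,
                                 stimulus_id=stimulus_id(s, a), planet=p,
                                 reward=r, drug=drug, serum_group="NA"))
    return pd.DataFrame(rows)


class TestJointLogDensity:
    def test_matches_term_by_term_oracle(self):
        """Hand-assembled sum: hyper-priors + MVN subject priors with the
        amisulpride shift + per-session choice likelihoods."""
        cohort = _toy_cohort()
        rng = np.random.default_rng(2)
        mu = rng.normal(0, 0.5, 6)
        sigma = np.abs(rng.normal(0.8, 0.2, 6))
        R = np.eye(6)
        R[0, 3] = R[3, 0] = -0.2
        beta = {("ami", "omega"): 0.7, ("nal", "eta"): -0.4}
        group = GroupModel(mu=mu, sigma=sigma, corr=R, beta_drug=beta)
        latents = rng.normal(0, 0.5, (2, 6))

        got = joint_log_density(cohort, "M1", group, latents)

        S = np.diag(sigma) @ R @ np.diag(sigma)
        mean_pla = mu.copy()
        mean_ami = mu.copy()
        mean_ami[3] += 0.7  # d_omega shift for the amisulpride subject
        expected = (multivariate_normal.logpdf(latents[0], mean_pla, S)
                    + multivariate_normal.logpdf(latents[1], mean_ami, S))
        # likelihoods, via the public single-session evaluator
        plan = [(1, 1, "red", 2), (2, 2, "red", -1), (1, 2, "green", 4)]
        for i in range(2):
            for sess in (1, 2):
                est = latents[i, :3] + (latents[i, 3:] if sess == 2 else 0)
                params = M1Params(omega=ndtr(est[0]), gamma=ndtr(est[1]),
                                  eta=np.exp(est[2]))
                recs = [TrialRecord("x", sess, t, s, a, stimulus_id(s, a), p, r)
                        for t, (s, a, p, r) in enumerate(plan, start=1)]
                expected += session_loglik(params, "M1", recs)
        # hyper-priors (unnormalized kernels, as documented)
        expected += -0.5 * np.sum(mu ** 2)
        expected += -0.5 * np.sum(sigma ** 2)
        flat_betas = np.array([0.7, -0.4])
        expected += -0.5 * np.sum((flat_betas / BETA_PRIOR_SD) ** 2)
        sign, logdet = np.linalg.slogdet(R)
        expected += (2.0 - 1.0) * logdet  # LKJ(2) kernel
        assert got == pytest.approx(expected, abs=1e-8)

    def test_null_betas_make_arm_labels_exchangeable(self):
        cohort = _toy_cohort()
        group = GroupModel(mu=np.zeros(6), sigma=np.ones(6), corr=np.eye(6))
        latents = np.random.default_rng(0).normal(0, 0.4, (2, 6))
        base = joint_log_density(cohort, "M1", group, latents)
        swapped = cohort.copy()
        swapped["drug"] = swapped["drug"].map(
            {"placebo": "amisulpride", "amisulpride": "placebo"})
        assert joint_log_density(swapped, "M1", group, latents) \
            == pytest.approx(base, abs=1e-10)

    def test_additive_decomposition_over_subjects(self):
        """Removing one subject changes the joint density by exactly that
        subject's prior + likelihood terms."""
        cohort = _toy_cohort()
        group = GroupModel(mu=np.zeros(6), sigma=np.full(6, 0.9),
                           corr=np.eye(6),
                           beta_drug={("ami", "omega"): 0.5})
        latents = np.random.default_rng(1).normal(0, 0.3, (2, 6))
        both = joint_log_density(cohort, "M1", group, latents)
        only_a = joint_log_density(cohort[cohort.subject_id == "a"], "M1",
                                   group, latents[:1])
        S = np.diag(group.sigma) @ group.corr @ np.diag(group.sigma)
        mean_b = group.mu.copy()
        mean_b[3] += 0.5
        prior_b = multivariate_normal.logpdf(latents[1], mean_b, S)
        data_b = CohortData(cohort[cohort.subject_id == "b"], "M1")
        lik_b = float(data_b.subject_logliks(latents[1:2])[0])
        assert both - only_a == pytest.approx(prior_b + lik_b, abs=1e-8)

    def test_dominance_of_likelihood_at_huge_hyper_sd(self):
        """With sigma ~ 1e3 the subject prior is locally flat: the joint
        density differences across latent values reduce to likelihood
        differences."""
        cohort = _toy_cohort().query("subject_id == 'a'")
        group = GroupModel(mu=np.zeros(6), sigma=np.full(6, 1e3),
                           corr=np.eye(6))
        rng = np.random.default_rng(3)
        l1 = rng.normal(0, 0.5, (1, 6))
        l2 = rng.normal(0, 0.5, (1, 6))
        data = CohortData(cohort, "M1")
        d_joint = (joint_log_density(cohort, "M1", group, l1)
                   - joint_log_density(cohort, "M1", group, l2))
        d_lik = float(data.subject_logliks(l1)[0] - data.subject_logliks(l2)[0])
        assert d_joint == pytest.approx(d_lik, abs=1e-4)

    def test_shape_mismatch_rejected(self):
        cohort = _toy_cohort()
        group = GroupModel(mu=np.zeros(6), sigma=np.ones(6), corr=np.eye(6))
        with pytest.raises(InputError):
            joint_log_density(cohort, "M1", group, np.zeros((3, 6)))


class TestSamplerCalibration:
    def test_flat_likelihood_recovers_the_prior(self):
        """Single-trial sessions make the M1 likelihood constant (log 0.5
        per trial, independent of parameters), so the fitted posterior must
        reproduce the prior: mu ~ N(0,1), sigma ~ HalfNormal(0,1),
        beta ~ N(0,1.5), correlations ~ LKJ(2).  This exercises every Gibbs
        move against analytically known targets."""
        spec = CohortSpec(n_per_arm={"placebo": 8, "amisulpride": 8,
                                     "naltrexone": 8},
                          n_trials=1, master_seed=3)
        trials, _ = generate_cohort(spec)
        fit = fit_hierarchical(trials, "M1", chains=4, iterations=2000,
                               warmup=600, seed=9)
        post = fit.posterior
        mu = post["mu"].values.reshape(-1, 6)
        sig = post["sigma"].values.reshape(-1, 6)
        beta = post["beta"].values.reshape(-1, 6)
        corr = post["corr"].values.reshape(-1, 6, 6)
        assert np.allclose(mu.mean(0), 0.0, atol=0.12)
        assert np.allclose(mu.std(0), 1.0, atol=0.12)
        assert np.allclose(sig.mean(0), np.sqrt(2 / np.pi), atol=0.1)
        assert np.allclose(beta.mean(0), 0.0, atol=0.3)
        assert np.allclose(beta.std(0), 1.5, atol=0.3)
        # LKJ(2), K=6: marginal correlation is 2 Beta(a,a)-1, a = 2 + 4/2,
        # variance 1/(2a+1) = 1/9; the correlation block mixes slowest, so
        # tolerances reflect its Monte-Carlo error at this run length
        offdiag = corr[:, 0, 1]
        assert offdiag.mean() == pytest.approx(0.0, abs=0.1)
        assert offdiag.var() == pytest.approx(1.0 / 9.0, abs=0.045)

    def test_informative_cohort_recovers_subject_parameters(self, tiny_cohort):
        spec, trials, truth = tiny_cohort
        fit = fit_hierarchical(trials, "M1", chains=2, iterations=500,
                               warmup=250, seed=5)
        pm = fit.subject_posterior_means().set_index("subject_id")
        t = truth.set_index("subject_id").loc[pm.index]
        assert np.corrcoef(t["omega0"], pm["omega0"])[0, 1] > 0.5
        assert np.corrcoef(t["eta0"], pm["eta0"])[0, 1] > 0.5

    def test_minimum_arm_size_enforced(self):
        spec = CohortSpec(n_per_arm={"placebo": 4, "amisulpride": 1},
                          n_trials=5, master_seed=0)
        trials, _ = generate_cohort(spec)
        with pytest.raises(InputError):
            fit_hierarchical(trials, "M1", chains=1, iterations=20, warmup=10)


class TestSummaries:
    def test_degenerate_draws(self):
        s = summarize_coefficient(np.full(2000, 2.0), "x")
        assert s.mean == 2.0 and s.ci_low == 2.0 and s.ci_high == 2.0
        assert s.tail_prob == 0.0

    def test_standard_normal_quantiles(self):
        draws = np.random.default_rng(0).standard_normal(100_000)
        s = summarize_coefficient(draws, "z", tail="below_zero")
        assert s.ci_low == pytest.approx(-1.96, abs=0.03)
        assert s.ci_high == pytest.approx(1.96, abs=0.03)
        assert s.tail_prob == pytest.approx(0.5, abs=0.01)

    def test_tail_symmetry(self):
        draws = np.concatenate([np.linspace(-3, 3, 1001)])
        below = summarize_coefficient(draws, "x", "below_zero").tail_prob
        above = summarize_coefficient(draws, "x", "above_zero").tail_prob
        assert below == pytest.approx(above, abs=1e-3)

    def test_empty_draws_rejected(self):
        with pytest.raises(InputError):
            summarize_coefficient(np.array([]), "x")

    def test_interval_contains_mean(self):
        draws = np.random.default_rng(1).gamma(2.0, 1.0, 5000)
        s = summarize_coefficient(draws, "g")
        assert s.ci_low <= s.mean <= s.ci_high


class TestEffectSize:
    def test_zero_beta_gives_zero(self):
        assert np.all(effect_size(np.zeros(10), np.ones(10), np.ones(10)) == 0)

    def test_pooled_sd_arithmetic(self):
        d = effect_size(np.array([0.787]), np.array([1.0]), np.array([1.0]))
        assert d[0] == pytest.approx(0.787 / np.sqrt(2), abs=1e-4)
        assert d[0] == pytest.approx(0.5565, abs=1e-4)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(NumericalError):
            effect_size(np.ones(3), np.zeros(3), np.zeros(3))


class TestModelVariants:
    def test_serum_covariate_adds_high_serum_regressor(self):
        spec = CohortSpec(n_per_arm={"placebo": 5, "amisulpride": 6,
                                     "naltrexone": 5},
                          serum_split=0.5, serum_measured=1.0,
                          n_trials=40, master_seed=9)
        trials, _ = generate_cohort(spec)
        fit = fit_hierarchical(trials, "M1", chains=2, iterations=150,
                               warmup=75, seed=2, serum_covariate=True)
        regs = [str(r) for r in fit.posterior["regressor"].values]
        assert regs == ["ami", "nal", "serum_high"]
        # low-serum effect = beta_ami; high-serum adds beta_serum on top
        assert fit.beta_draws("serum_high", "eta").ndim == 1

    def test_stickiness_flag_upgrades_m1(self):
        spec = CohortSpec(n_per_arm={"placebo": 5, "amisulpride": 5},
                          model_id="M1_sticky", n_trials=40, master_seed=10)
        trials, _ = generate_cohort(spec)
        fit = fit_hierarchical(trials, "M1", chains=2, iterations=150,
                               warmup=75, seed=3, stickiness=True)
        assert fit.model_id == "M1_sticky"
        pars = [str(p) for p in fit.posterior["parameter"].values]
        assert pars == ["omega", "gamma", "eta", "rho", "pi"]

    def test_stickiness_flag_rejected_for_td_models(self, tiny_cohort):
        _, trials, _ = tiny_cohort
        with pytest.raises(InputError):
            fit_hierarchical(trials, "M2", stickiness=True)
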