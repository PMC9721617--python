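"""Joint two-session hierarchical Bayesian estimation of choice-model
parameters and group-level drug/serum effects.

The generative model: each subject i has an estimation-space latent vector
theta_i = (baselines, session differences), one pair per native parameter,

    theta_i ~ MVN(mu + A_i beta, S),    S = diag(sigma) R diag(sigma)

where A_i adds the drug-arm (and optionally high-serum) regression
coefficients beta to the session-difference components.  Hyper-priors:
mu ~ N(0, 1), sigma ~ HalfNormal(0, 1), R ~ LKJ(2), beta ~ N(0, 1.5).
Session-1 native parameters are transforms of the baselines, session-2 of
baseline + difference (probit for [0,1] parameters, exp for eta).

Sampling is Metropolis-within-Gibbs:

* subject blocks — adaptive random-walk Metropolis, proposal covariances
  learned during warmup and frozen after (``samplers.BlockAdaptiveRW``);
* (mu, beta) — exact conjugate multivariate-normal Gibbs draw (the latents
  are linear-Gaussian in these given S);
* (sigma, R) — univariate slice sampling in an unconstrained space
  (log sigma; canonical partial correlations for R, under which the LKJ
  prior factorizes exactly).

Convergence is summarized with split-R-hat and effective sample size via
arviz; any group-level quantity with R-hat >= 1.01 is reported in
``PosteriorDraws.warnings``.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from . import _kernels, samplers
from .exceptions import ConfigError, InputError, NumericalError
from .task import DEFAULT_TRANSITIONS, PLANETS
from .transforms import latent_names, model_family, param_kinds, param_names

ARM_LABELS = ("placebo", "amisulpride", "naltrexone")
MU_PRIOR_SD = 1.0
BETA_PRIOR_SD = 1.5
LKJ_ETA = 2.0


# ---------------------------------------------------------------------------
# data preparation

class CohortData:
    """Flat-array view of a trial table, ready for the likelihood kernels."""

    def __init__(self, trials: pd.DataFrame, model_id: str,
                 serum_covariate: bool = False):
        required = {"subject_id", "session", "trial", "first_state", "action",
                    "planet", "reward", "drug"}
        missing = required - set(trials.columns)
        if missing:
            raise InputError(f"trial table missing columns {sorted(missing)}")
        self.model_id = model_id
        self.family = model_family(model_id)
        self.serum_covariate = serum_covariate

        trials = trials.sort_values(["subject_id", "session", "trial"], kind="stable")
        self.subjects = list(dict.fromkeys(trials["subject_id"]))
        self.n_subjects = len(self.subjects)
        sub_index = {s: i for i, s in enumerate(self.subjects)}

        arms = trials.groupby("subject_id", sort=False)["drug"].first()
        bad = set(arms) - set(ARM_LABELS)
        if bad:
            raise InputError(f"unknown drug labels {sorted(bad)}")
        self.arm = np.array([arms[s] for s in self.subjects])
        if "serum_group" in trials.columns:
            serum = trials.groupby("subject_id", sort=False)["serum_group"].first()
            self.serum = np.array([str(serum[s]) for s in self.subjects])
        else:
            self.serum = np.array(["NA"] * self.n_subjects)
        self.x_ami = (self.arm == "amisulpride").astype(float)
        self.x_nal = (self.arm == "naltrexone").astype(float)
        # "1 for high serum level and 0 otherwise"
        self.x_serum = ((self.arm == "amisulpride") & (self.serum == "high")).astype(float)

        self.fs = trials["first_state"].to_numpy(np.int64) - 1
        self.act = trials["action"].to_numpy(np.int64) - 1
        self.planet = np.array([PLANETS.index(p) for p in trials["planet"]], dtype=np.int64)
        self.reward = trials["reward"].to_numpy(np.float64)

        seg_keys = trials[["subject_id", "session"]].drop_duplicates()
        self.seg_subject = np.array([sub_index[s] for s in seg_keys["subject_id"]])
        self.seg_session = seg_keys["session"].to_numpy(np.int64)
        if not np.all(np.isin(self.seg_session, (1, 2))):
            raise InputError("session labels must be 1 or 2")
        sizes = trials.groupby(["subject_id", "session"], sort=False).size().to_numpy()
        self.offsets = np.concatenate([[0], np.cumsum(sizes)]).astype(np.int64)
        self.n_trials_total = int(self.offsets[-1])
        self.tmap = self._infer_tmap(trials)

        counts = np.bincount(self.seg_subject, minlength=self.n_subjects)
        if np.any(counts == 0):
            raise InputError("subject with no sessions")

    def _infer_tmap(self, trials) -> np.ndarray:
        tmap = -np.ones((2, 2), dtype=np.int64)
        pairs = trials[["first_state", "action", "planet"]].drop_duplicates()
        for _, row in pairs.iterrows():
            s, a = int(row.first_state) - 1, int(row.action) - 1
            p = PLANETS.index(row.planet)
            if tmap[s, a] == -1:
                tmap[s, a] = p
            elif tmap[s, a] != p:
                raise InputError(
                    f"inconsistent spaceship->planet transition for state "
                    f"{s + 1}, action {a + 1}"
                )
        default = np.asarray(DEFAULT_TRANSITIONS, dtype=np.int64)
        tmap[tmap == -1] = default[tmap == -1]
        if tmap[0, 0] == tmap[0, 1] or tmap[1, 0] == tmap[1, 1]:
            raise InputError("transition map does not reach both planets from each state")
        return tmap

    # regressors on the session-difference block, in fixed order
    @property
    def regressor_names(self) -> tuple[str, ...]:
        base = ("ami", "nal")
        return base + ("serum_high",) if self.serum_covariate else base

    def regressor_matrix(self) -> np.ndarray:
        cols = [self.x_ami, self.x_nal]
        if self.serum_covariate:
            cols.append(self.x_serum)
        return np.column_stack(cols)

    def segment_logliks(self, kernel_params: np.ndarray) -> np.ndarray:
        """Log-likelihood per segment; ``kernel_params`` is (2 * n_subjects, 5)."""
        rows = 2 * self.seg_subject + (self.seg_session - 1)
        return _kernels.segment_logliks(
            np.ascontiguousarray(kernel_params[rows]), self.family,
            self.fs, self.act, self.planet, self.reward, self.offsets, self.tmap,
        )

    @property
    def _kind_codes(self) -> np.ndarray:
        codes = {"unit_interval": 0, "positive": 1, "unbounded": 2}
        return np.array([codes[kk] for kk in param_kinds(self.model_id)],
                        dtype=np.int64)

    def subject_logliks(self, latents: np.ndarray) -> np.ndarray:
        """Per-subject total log-likelihood under estimation-space latents."""
        return _kernels.latents_logliks(
            np.ascontiguousarray(latents, dtype=np.float64), self._kind_codes,
            self.family, self.model_id == "M3", self.fs, self.act,
            self.planet, self.reward, self.offsets, self.seg_subject,
            self.seg_session, self.tmap)


# ---------------------------------------------------------------------------
# group model containers

@dataclass
class GroupModel:
    """Group-level parameters: hyper-means/SDs, correlation, drug effects.

    ``beta_drug`` maps ("ami" | "nal", native parameter name) to the shift of
    that parameter's session-difference mean; ``beta_serum`` maps parameter
    name to the extra shift for high-serum amisulpride subjects.
    """

    mu: np.ndarray
    sigma: np.ndarray
    corr: np.ndarray
    beta_drug: dict[tuple[str, str], float] = field(default_factory=dict)
    beta_serum: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.corr = np.asarray(self.corr, dtype=float)
        d = self.mu.size
        if self.sigma.shape != (d,) or self.corr.shape != (d, d):
            raise ConfigError("inconsistent group model dimensions")
        if np.any(self.sigma <= 0):
            raise ConfigError("hyper SDs must be positive")
        np.linalg.cholesky(self.corr)  # PD check


def _beta_vector(group: GroupModel, data: CohortData) -> np.ndarray:
    pnames = param_names(data.model_id)
    k = len(pnames)
    P = len(data.regressor_names)
    beta = np.zeros(P * k)
    for r, reg in enumerate(data.regressor_names):
        for j, pname in enumerate(pnames):
            if reg == "serum_high":
                beta[r * k + j] = group.beta_serum.get(pname, 0.0)
            else:
                beta[r * k + j] = group.beta_drug.get((reg, pname), 0.0)
    return beta


def _subject_means(mu: np.ndarray, beta: np.ndarray, X: np.ndarray, k: int) -> np.ndarray:
    """Per-subject prior means: deltas shifted by the subject's regressors."""
    n, P = X.shape
    means = np.tile(mu, (n, 1))
    shift = X @ beta.reshape(P, k)
    means[:, k:] += shift
    return means


def _mvn_logpdf_rows(resid: np.ndarray, sigma: np.ndarray, L_corr: np.ndarray) -> np.ndarray:
    """Row-wise MVN log density with covariance diag(sigma) R diag(sigma)."""
    L = sigma[:, None] * L_corr
    w = solve_triangular(L, resid.T, lower=True)
    logdet = np.sum(np.log(np.diag(L)))
    d = resid.shape[1]
    return -0.5 * np.sum(w ** 2, axis=0) - logdet - 0.5 * d * np.log(2 * np.pi)


def joint_log_density(cohort: pd.DataFrame | CohortData, model_id: str,
                      group: GroupModel, latents: np.ndarray,
                      serum_covariate: bool = False) -> float:
    """Full joint log density: hyper-priors + subject priors + likelihoods.

    The reference implementation of the model the Gibbs sampler targets;
    used directly for testing and for debugging sampler moves.
    """
    data = cohort if isinstance(cohort, CohortData) else CohortData(
        cohort, model_id, serum_covariate)
    latents = np.atleast_2d(np.asarray(latents, dtype=float))
    d = len(latent_names(data.model_id))
    if latents.shape != (data.n_subjects, d):
        raise InputError(
            f"latents shape {latents.shape} != ({data.n_subjects}, {d})")
    k = len(param_names(data.model_id))
    beta = _beta_vector(group, data)
    means = _subject_means(group.mu, beta, data.regressor_matrix(), k)
    L_corr = np.linalg.cholesky(group.corr)

    lp = float(np.sum(_mvn_logpdf_rows(latents - means, group.sigma, L_corr)))
    lp += float(np.sum(data.subject_logliks(latents)))
    # hyper-priors (unnormalized where constant)
    lp += float(-0.5 * np.sum((group.mu / MU_PRIOR_SD) ** 2))
    lp += float(-0.5 * np.sum(group.sigma ** 2))  # HalfNormal(0,1) kernel
    lp += float(-0.5 * np.sum((beta / BETA_PRIOR_SD) ** 2))
    y = samplers.corr_to_cpc(group.corr)
    # LKJ(2) on R itself (without the CPC Jacobian): (eta - 1) log det R
    lp += float((LKJ_ETA - 1.0) * 2.0 * np.sum(np.log(np.diag(L_corr))))
    if not np.isfinite(lp):
        raise NumericalError("non-finite joint log density")
    return lp


# ---------------------------------------------------------------------------
# posterior container

@dataclass
class PosteriorDraws:
    """Labelled MCMC draws plus sampler metadata and diagnostics."""

    idata: az.InferenceData
    model_id: str
    options: dict
    warnings: list[str] = field(default_factory=list)

    @property
    def posterior(self):
        return self.idata.posterior

    def draws(self, var: str, **sel) -> np.ndarray:
        """Flattened (chain x draw) posterior draws of one quantity."""
        da = self.posterior[var].sel(**sel)
        return da.stack(sample=("chain", "draw")).to_numpy().T.reshape(
            -1, *da.shape[2:])

    def beta_draws(self, regressor: str, parameter: str) -> np.ndarray:
        return np.asarray(self.draws("beta", regressor=regressor, parameter=parameter))

    def sigma_draws(self, latent: str) -> np.ndarray:
        return np.asarray(self.draws("sigma", latent=latent))

    def subject_posterior_means(self) -> pd.DataFrame:
        theta = self.posterior["theta"].mean(("chain", "draw")).to_numpy()
        names = list(self.posterior["latent"].values)
        df = pd.DataFrame(theta, columns=names)
        df.insert(0, "subject_id", list(self.posterior["subject"].values))
        return df

    def effect_size_draws(self, regressor: str, parameter: str) -> np.ndarray:
        beta = self.beta_draws(regressor, parameter)
        sb = self.sigma_draws(f"{parameter}0")
        sd = self.sigma_draws(f"d_{parameter}")
        return effect_size(beta, sb, sd)

    def rhat(self, group_level_only: bool = True) -> pd.DataFrame:
        names = ["mu", "sigma", "beta"] if group_level_only else None
        r = az.rhat(self.idata, var_names=names)
        return r.to_dataframe() if hasattr(r, "to_dataframe") else r

    def max_rhat(self) -> float:
        r = az.rhat(self.idata, var_names=["mu", "sigma", "beta"])
        return float(max(r[v].max() for v in r.data_vars))

    def summary(self, tail: str = "below_zero") -> pd.DataFrame:
        """Coefficient table for all drug/serum effects, with effect sizes."""
        rows = []
        post = self.posterior
        for reg in post["regressor"].values:
            for par in post["parameter"].values:
                b = self.beta_draws(str(reg), str(par))
                s = summarize_coefficient(b, f"beta_{reg}_d_{par}", tail)
                d = self.effect_size_draws(str(reg), str(par))
                ds = summarize_coefficient(d, "d", tail)
                rows.append({
                    "coefficient": s.name, "mean": s.mean,
                    "ci_low": s.ci_low, "ci_high": s.ci_high,
                    "tail": s.tail, "tail_prob": s.tail_prob,
                    "d_mean": ds.mean, "d_ci_low": ds.ci_low,
                    "d_ci_high": ds.ci_high,
                })
        return pd.DataFrame(rows)

    def to_netcdf(self, path) -> None:
        self.idata.to_netcdf(str(path))


@dataclass(frozen=True)
class CoefficientSummary:
    """Posterior mean, central 95% interval and tail probability."""

    name: str
    mean: float
    ci_low: float
    ci_high: float
    tail: str
    tail_prob: float


def summarize_coefficient(draws: np.ndarray, name: str,
                          tail: str = "below_zero") -> CoefficientSummary:
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size == 0:
        raise InputError("empty draw array")
    if tail not in ("below_zero", "above_zero"):
        raise InputError(f"unknown tail {tail!r}")
    lo, hi = np.percentile(draws, [2.5, 97.5])
    p = float(np.mean(draws < 0.0)) if tail == "below_zero" else float(np.mean(draws > 0.0))
    return CoefficientSummary(name=name, mean=float(draws.mean()),
                              ci_low=float(lo), ci_high=float(hi),
                              tail=tail, tail_prob=p)


def effect_size(beta_draws: np.ndarray, sigma_baseline: np.ndarray,
                sigma_delta: np.ndarray) -> np.ndarray:
    """Standardized drug effect: beta / sqrt(sigma_0^2 + sigma_delta^2).

    Computed draw-wise; the pooled SD combines the baseline and
    session-difference variance components of the affected parameter.
    """
    beta_draws = np.asarray(beta_draws, dtype=float)
    pooled = np.sqrt(np.asarray(sigma_baseline) ** 2 + np.asarray(sigma_delta) ** 2)
    if np.any(pooled == 0):
        raise NumericalError("zero pooled SD in effect size")
    return beta_draws / pooled


# ---------------------------------------------------------------------------
# the Gibbs sampler

def fit_hierarchical(
    cohort: pd.DataFrame | CohortData,
    model_id: str = "M1",
    chains: int = 4,
    iterations: int = 3000,
    warmup: int = 1000,
    seed: int = 0,
    serum_covariate: bool = False,
    stickiness: bool = False,
    progress: bool = False,
) -> PosteriorDraws:
    """Sample the joint hierarchical posterior for one choice model.

    ``iterations`` counts total sweeps per chain including ``warmup`` (the
    default 3000/1000 leaves 2000 retained draws per chain across 4 chains).
    ``stickiness`` upgrades M1 to its sticky variant; ``serum_covariate``
    adds the high-serum regressor to the session-difference means.
    """
    if stickiness:
        if model_id not in ("M1", "M1_sticky"):
            raise InputError("stickiness extension applies to M1")
        model_id = "M1_sticky"
    data = cohort if isinstance(cohort, CohortData) else CohortData(
        cohort, model_id, serum_covariate)
    if data.model_id != model_id:
        data = CohortData(cohort, model_id, serum_covariate)
    if iterations <= warmup:
        raise ConfigError("iterations must exceed warmup")
    arm_counts = pd.Series(data.arm).value_counts()
    if (arm_counts < 2).any():
        raise InputError("need at least 2 subjects in every present arm")

    lnames = latent_names(model_id)
    pnames = param_names(model_id)
    D, k = len(lnames), len(pnames)
    n = data.n_subjects
    X = data.regressor_matrix()
    P = X.shape[1] * k
    ncpc = samplers.n_cpc(D)
    keep = iterations - warmup

    root = np.random.SeedSequence(seed)
    chain_seeds = root.spawn(chains)

    store_mu = np.empty((chains, keep, D))
    store_sigma = np.empty((chains, keep, D))
    store_beta = np.empty((chains, keep, X.shape[1], k))
    store_corr = np.empty((chains, keep, D, D))
    store_theta = np.empty((chains, keep, n, D))
    accept_rates = np.empty(chains)

    init = _init_latents(data, D)
    for c in range(chains):
        rng = np.random.default_rng(chain_seeds[c])
        out = _run_chain(data, D, k, P, X, ncpc, iterations, warmup, rng,
                         progress, init=init)
        store_mu[c], store_sigma[c], store_beta[c], store_corr[c], store_theta[c], accept_rates[c] = out

    coords = {
        "latent": list(lnames),
        "parameter": list(pnames),
        "regressor": list(data.regressor_names),
        "subject": list(data.subjects),
        "latent2": list(lnames),
    }
    idata = az.from_dict(
        posterior={
            "mu": store_mu,
            "sigma": store_sigma,
            "beta": store_beta,
            "corr": store_corr,
            "theta": store_theta,
        },
        coords=coords,
        dims={
            "mu": ["latent"],
            "sigma": ["latent"],
            "beta": ["regressor", "parameter"],
            "corr": ["latent", "latent2"],
            "theta": ["subject", "latent"],
        },
    )
    options = dict(chains=chains, iterations=iterations, warmup=warmup,
                   seed=seed, serum_covariate=serum_covariate,
                   model_id=model_id, sampler="metropolis-within-gibbs")
    idata.posterior.attrs.update({str(kk): str(v) for kk, v in options.items()})

    result = PosteriorDraws(idata=idata, model_id=model_id, options=options)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        rh = az.rhat(idata, var_names=["mu", "sigma", "beta"])
    for var in rh.data_vars:
        vals = np.asarray(rh[var]).ravel()
        if np.any(vals >= 1.01):
            result.warnings.append(
                f"R-hat >= 1.01 for {var} (max {np.nanmax(vals):.3f})")
    mean_acc = float(accept_rates.mean())
    if mean_acc < 0.1:
        result.warnings.append(
            f"low subject-block Metropolis acceptance ({mean_acc:.2f})")
    result.options["subject_accept_rate"] = mean_acc
    return result


def _init_latents(data: CohortData, D: int) -> np.ndarray:
    """Per-subject penalized-ML starting values (Nelder-Mead, weak prior).

    Cuts the burn-in that a zero start would need for subjects far from the
    origin; chains jitter around this common start.
    """
    from scipy.optimize import minimize

    init = np.zeros((data.n_subjects, D))
    kinds = data._kind_codes
    params = np.zeros(5)
    for i in range(data.n_subjects):
        segs = np.where(data.seg_subject == i)[0]
        slices = [(data.offsets[s], data.offsets[s + 1],
                   int(data.seg_session[s])) for s in segs]

        def negpost(lat):
            ll = 0.0
            for lo, hi, sess in slices:
                _kernels.fill_session_params(lat, kinds, data.model_id == "M3",
                                             sess, params)
                ll += _kernels.session_loglik(
                    params, data.family, data.fs[lo:hi], data.act[lo:hi],
                    data.planet[lo:hi], data.reward[lo:hi], data.tmap)
            return -(ll - 0.5 * np.sum(lat ** 2))

        res = minimize(negpost, np.zeros(D), method="Nelder-Mead",
                       options=dict(maxiter=60 * D, xatol=1e-3, fatol=1e-3))
        init[i] = np.clip(res.x, -4, 4)
    return init


def _run_chain(data: CohortData, D, k, P, X, ncpc, iterations, warmup, rng,
               progress, init=None):
    n = data.n_subjects
    keep = iterations - warmup
    # state, jittered per chain around the penalized-ML start
    latents = (init if init is not None else np.zeros((n, D))) \
        + 0.1 * rng.standard_normal((n, D))
    mu = 0.1 * rng.standard_normal(D)
    beta = np.zeros(P)
    log_sigma = 0.1 * rng.standard_normal(D) - 0.5
    y_cpc = np.zeros(ncpc)

    prior_prec = np.concatenate([
        np.full(D, 1.0 / MU_PRIOR_SD ** 2), np.full(P, 1.0 / BETA_PRIOR_SD ** 2)
    ])
    W_right = np.zeros((n, D, P))  # A_i blocks: regressors on delta rows
    for i in range(n):
        for r in range(X.shape[1]):
            for j in range(k):
                W_right[i, k + j, r * k + j] = X[i, r]

    rw = samplers.BlockAdaptiveRW(n, D, init_scale=0.15)
    # scalar step sizes for the interweaved non-centered moves (see sweep)
    nc_scale = np.full(2 * D, -1.6)  # log step sizes: [sigma coords, mu coords]
    nc_scale_beta = np.full(P, -1.6)
    cur_loglik = data.subject_logliks(latents)
    n_acc = 0
    n_prop = 0

    out_mu = np.empty((keep, D))
    out_sigma = np.empty((keep, D))
    out_beta = np.empty((keep, X.shape[1], k))
    out_corr = np.empty((keep, D, D))
    out_theta = np.empty((keep, n, D))

    for it in range(iterations):
        sigma = np.exp(log_sigma)
        L_corr = samplers.cpc_to_cholesky(y_cpc, D)
        means = _subject_means(mu, beta.copy(), X, k)

        # --- subject latent blocks: vectorized adaptive RWM (two scans)
        cur_prior = _mvn_logpdf_rows(latents - means, sigma, L_corr)
        for _ in range(2):
            prop = rw.propose(latents, rng)
            prop_loglik = data.subject_logliks(prop)
            prop_prior = _mvn_logpdf_rows(prop - means, sigma, L_corr)
            log_ratio = (prop_loglik + prop_prior) - (cur_loglik + cur_prior)
            accept = np.log(rng.random(n)) < log_ratio
            latents[accept] = prop[accept]
            cur_loglik[accept] = prop_loglik[accept]
            cur_prior[accept] = prop_prior[accept]
            rw.update(latents, accept)
            if it >= warmup:
                n_acc += int(accept.sum())
                n_prop += n

        # --- (mu, beta): conjugate MVN draw given latents and S
        L_S = sigma[:, None] * L_corr
        Q = np.linalg.inv(L_S @ L_S.T)
        lam = np.diag(prior_prec).astype(float)
        rhs = np.zeros(D + P)
        QW = Q @ W_right  # (n, D, P) after broadcasting
        lam[:D, :D] += n * Q
        lam[:D, D:] += QW.sum(axis=0)
        lam[D:, :D] += QW.sum(axis=0).T
        lam[D:, D:] += np.einsum("ndp,ndq->pq", W_right, QW)
        Qth = latents @ Q.T
        rhs[:D] = Qth.sum(axis=0)
        rhs[D:] = np.einsum("ndp,nd->p", W_right, Qth)
        L_lam = np.linalg.cholesky(lam)
        mean_psi = np.linalg.solve(lam, rhs)
        z = rng.standard_normal(D + P)
        psi = mean_psi + solve_triangular(L_lam.T, z, lower=False)
        mu = psi[:D]
        beta = psi[D:]

        # --- (sigma, R): coordinate-wise slice sampling in (log sigma, CPC)
        # space; the conditional depends on the latents only through their
        # residual scatter matrix, precomputed once per sweep
        means = _subject_means(mu, beta, X, k)
        resid = latents - means
        C = resid.T @ resid
        u = np.concatenate([log_sigma, y_cpc])

        def cov_logp(val, idx):
            u[idx] = val
            return _kernels.cov_slice_logp(u, D, C, n, LKJ_ETA)

        for idx in range(D + ncpc):
            u[idx] = samplers.slice_update(
                u[idx], lambda v, idx=idx: cov_logp(v, idx), rng, w=0.4)
        log_sigma = u[:D].copy()
        y_cpc = u[D:].copy()

        # --- interweaved non-centered (ASIS) moves.  Holding the
        # standardized residuals fixed, a change of sigma_d only rescales
        # latent column d around its mean, and a change of mu_d only
        # translates it; the MVN-prior and Jacobian terms cancel exactly,
        # leaving likelihood x hyper-prior ratios.  These scalar moves break
        # the funnel coupling that makes centered Gibbs mix slowly in the
        # hyper-SDs of weakly identified latent dimensions.
        lr = (it + 10.0) ** -0.6 if it < warmup else 0.0
        means = _subject_means(mu, beta, X, k)
        for d in range(D):
            step = np.exp(nc_scale[d]) * rng.standard_normal()
            ls_p = log_sigma[d] + step
            ratio = np.exp(ls_p - log_sigma[d])
            latents_p = latents.copy()
            latents_p[:, d] = means[:, d] + ratio * (latents[:, d] - means[:, d])
            loglik_p = data.subject_logliks(latents_p)
            lp_cur = -0.5 * np.exp(2 * log_sigma[d]) + log_sigma[d]
            lp_prop = -0.5 * np.exp(2 * ls_p) + ls_p
            acc_nc = np.log(rng.random()) < (
                np.sum(loglik_p) + lp_prop - np.sum(cur_loglik) - lp_cur)
            if acc_nc:
                log_sigma[d] = ls_p
                latents = latents_p
                cur_loglik = loglik_p
            nc_scale[d] += lr * (float(acc_nc) - 0.44)
        for d in range(D):
            step = np.exp(nc_scale[D + d]) * rng.standard_normal()
            mu_p = mu[d] + step
            latents_p = latents.copy()
            latents_p[:, d] = latents[:, d] + step
            loglik_p = data.subject_logliks(latents_p)
            lp_cur = -0.5 * (mu[d] / MU_PRIOR_SD) ** 2
            lp_prop = -0.5 * (mu_p / MU_PRIOR_SD) ** 2
            acc_nc = np.log(rng.random()) < (
                np.sum(loglik_p) + lp_prop - np.sum(cur_loglik) - lp_cur)
            if acc_nc:
                mu[d] = mu_p
                latents = latents_p
                cur_loglik = loglik_p
            nc_scale[D + d] += lr * (float(acc_nc) - 0.44)
        # beta translation moves: shift the affected subjects' delta column
        # together with the coefficient (prior and Jacobian cancel as above)
        for r in range(X.shape[1]):
            xcol = X[:, r]
            if not np.any(xcol):
                continue
            for j in range(k):
                bidx = r * k + j
                step = np.exp(nc_scale_beta[bidx]) * rng.standard_normal()
                beta_p = beta[bidx] + step
                latents_p = latents.copy()
                latents_p[:, k + j] = latents[:, k + j] + step * xcol
                loglik_p = data.subject_logliks(latents_p)
                lp_cur = -0.5 * (beta[bidx] / BETA_PRIOR_SD) ** 2
                lp_prop = -0.5 * (beta_p / BETA_PRIOR_SD) ** 2
                acc_nc = np.log(rng.random()) < (
                    np.sum(loglik_p) + lp_prop - np.sum(cur_loglik) - lp_cur)
                if acc_nc:
                    beta[bidx] = beta_p
                    latents = latents_p
                    cur_loglik = loglik_p
                nc_scale_beta[bidx] += lr * (float(acc_nc) - 0.44)

        if it == warmup - 1:
            rw.freeze()
        if it >= warmup:
            s = it - warmup
            out_mu[s] = mu
            out_sigma[s] = np.exp(log_sigma)
            out_beta[s] = beta.reshape(X.shape[1], k)
            Lc = samplers.cpc_to_cholesky(y_cpc, D)
            out_corr[s] = Lc @ Lc.T
            out_theta[s] = latents
        if progress and (it + 1) % 200 == 0:
            print(f"  sweep {it + 1}/{iterations}", flush=True)

    return (out_mu, out_sigma, out_beta, out_corr, out_theta,
            n_acc / max(n_prop, 1))
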