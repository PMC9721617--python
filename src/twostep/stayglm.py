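"""Model-agnostic hierarchical logistic regression of stay behaviour.

The outcome is whether the current first-stage choice targets the same
planet as the previous trial's choice ("staying").  Population effects form
the full factorial of previous points x previous-state (same/different) x
session x drug; within-subject terms (everything except drug) are correlated
random effects drawn from an MVN with an LKJ-prior correlation matrix.
Priors follow the regularizing defaults of the hierarchical-regression
ecosystem this analysis mirrors: Normal(0, 3) slopes, Student-t(3, 0, 10)
intercept, Half-Cauchy(0, 2) random-effect SDs, LKJ(2) correlations.

Sampling: Metropolis-within-Gibbs where both the fixed-effect block and the
per-subject random-effect blocks use one-step IRLS Gaussian approximations
as independence-style proposals (Gamerman 1997), and the random-effect
covariance is slice-sampled in (log SD, partial-correlation) space.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.special import expit

from . import _kernels, samplers
from .exceptions import ConfigError, InputError
from .hbayes import summarize_coefficient
from .task import TrialRecord, code_stay_events

WITHIN_TERMS_FULL = (
    "intercept", "prev_points", "diff_state", "session",
    "prev_points:diff_state", "prev_points:session", "diff_state:session",
    "prev_points:diff_state:session",
)
WITHIN_TERMS_NARROW = ("intercept", "diff_state", "session")


@dataclass(frozen=True)
class GlmPriors:
    """Prior scales for the stay regression."""

    sd_scale: float = 2.0          # Half-Cauchy(0, 2) on random-effect SDs
    slope_sd: float = 3.0          # Normal(0, 3) on regression coefficients
    intercept_df: float = 3.0      # Student-t(3, 0, 10) on the intercept
    intercept_scale: float = 10.0
    lkj_eta: float = 2.0


def odds_ratio(log_odds: float) -> float:
    """Multiplicative change in stay odds per unit of the predictor."""
    return float(np.exp(log_odds))


def build_stay_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Stay/switch coding of a cohort trial table.

    One row per trial from the second onward within each subject-session:
    ``stayed`` (0/1), ``prev_points`` (previous trial's reward, raw integer
    scale), ``diff_state`` (1 when the first-stage state differs from the
    previous trial), ``session`` (0 = first, 1 = second session), plus the
    subject's drug and serum labels.
    """
    required = {"subject_id", "session", "trial", "first_state", "action",
                "planet", "reward", "drug"}
    missing = required - set(trials.columns)
    if missing:
        raise InputError(f"trial table missing columns {sorted(missing)}")
    bad = set(trials["drug"]) - {"placebo", "amisulpride", "naltrexone"}
    if bad:
        raise InputError(f"unknown drug labels {sorted(bad)}")
    rows = []
    for (sid, sess), g in trials.sort_values("trial").groupby(
            ["subject_id", "session"], sort=False):
        records = [
            TrialRecord(sid, sess, int(r.trial), int(r.first_state),
                        int(r.action), 0, r.planet, int(r.reward))
            for r in g.itertuples()
        ]
        drug = g["drug"].iloc[0]
        serum = g["serum_group"].iloc[0] if "serum_group" in g else "NA"
        for ev in code_stay_events(records):
            rows.append({
                "subject_id": sid, "session": int(sess) - 1,
                "trial": ev.trial_index,
                "prev_points": ev.prev_points,
                "diff_state": int(not ev.same_first_state),
                "stayed": int(ev.stayed),
                "drug": drug, "serum_group": serum,
            })
    return pd.DataFrame(rows)


def _group_columns(table: pd.DataFrame, serum: bool) -> tuple[list[str], np.ndarray]:
    """Drug dummy columns; the serum variant splits amisulpride low/high."""
    drug = table["drug"].to_numpy()
    if serum:
        high = (table["serum_group"].to_numpy() == "high")
        cols = ["ami_low", "ami_high", "nal"]
        G = np.column_stack([
            (drug == "amisulpride") & ~high,
            (drug == "amisulpride") & high,
            drug == "naltrexone",
        ]).astype(float)
    else:
        cols = ["ami", "nal"]
        G = np.column_stack([
            drug == "amisulpride", drug == "naltrexone",
        ]).astype(float)
    return cols, G


def _within_design(table: pd.DataFrame, terms) -> np.ndarray:
    pp = table["prev_points"].to_numpy(float)
    ds = table["diff_state"].to_numpy(float)
    se = table["session"].to_numpy(float)
    cols = {
        "intercept": np.ones(len(table)),
        "prev_points": pp,
        "diff_state": ds,
        "session": se,
        "prev_points:diff_state": pp * ds,
        "prev_points:session": pp * se,
        "diff_state:session": ds * se,
        "prev_points:diff_state:session": pp * ds * se,
    }
    return np.column_stack([cols[t] for t in terms])


@dataclass
class GlmPosterior:
    """Posterior draws of the stay regression with labelled coefficients."""

    idata: az.InferenceData
    coef_names: list[str]
    re_terms: list[str]
    options: dict
    warnings: list[str] = field(default_factory=list)

    @property
    def posterior(self):
        return self.idata.posterior

    def coef_draws(self, name: str) -> np.ndarray:
        return self.posterior["beta"].sel(coef=name).to_numpy().ravel()

    def summary(self, tail: str = "below_zero") -> pd.DataFrame:
        rows = []
        for name in self.coef_names:
            d = self.coef_draws(name)
            s = summarize_coefficient(d, name, tail)
            rows.append({
                "coefficient": name, "mean": s.mean, "ci_low": s.ci_low,
                "ci_high": s.ci_high, "tail": s.tail,
                "tail_prob": s.tail_prob, "odds_ratio": odds_ratio(s.mean),
            })
        return pd.DataFrame(rows)

    def subject_slopes(self) -> pd.DataFrame:
        """Posterior-mean per-subject previous-points slopes, session 2.

        ``same_state_slope``: d(log-odds of staying)/d(prev_points) in
        same-state trials; ``interaction_slope``: the difference of the
        different-state and same-state slopes.  Both combine the fixed
        effects relevant to the subject's drug group with the subject's
        random effects, at session = 1 (second session).
        """
        post = self.posterior
        beta_mean = post["beta"].mean(("chain", "draw"))
        beta = pd.Series(beta_mean.to_numpy(),
                         index=[str(c) for c in beta_mean["coef"].values])
        b = post["b"].mean(("chain", "draw")).to_numpy()
        subjects = list(post["subject"].values)
        groups = self.options["subject_groups"]
        gcols = self.options["group_cols"]
        rows = []
        for i, sid in enumerate(subjects):
            def fixed(term):
                total = beta.get(term, 0.0)
                for gc in gcols:
                    if groups[i].get(gc, 0.0):
                        total += beta.get(f"{term}:{gc}", 0.0)
                return float(total)

            def rand(term):
                if term in self.re_terms:
                    return float(b[i, self.re_terms.index(term)])
                return 0.0

            same = (fixed("prev_points") + fixed("prev_points:session")
                    + rand("prev_points") + rand("prev_points:session"))
            inter = (fixed("prev_points:diff_state")
                     + fixed("prev_points:diff_state:session")
                     + rand("prev_points:diff_state")
                     + rand("prev_points:diff_state:session"))
            rows.append({"subject_id": sid, "same_state_slope": same,
                         "interaction_slope": inter})
        return pd.DataFrame(rows)


def fit_stay_glm(
    table: pd.DataFrame,
    priors: GlmPriors | None = None,
    chains: int = 4,
    iterations: int = 3000,
    warmup: int = 1000,
    seed: int = 0,
    serum: bool = False,
    random_effects: str = "full",
    progress: bool = False,
) -> GlmPosterior:
    """Hierarchical Bernoulli-logit fit of the stay table.

    ``random_effects="full"`` gives every within-subject term a correlated
    random effect; ``"narrow"`` restricts them to the intercept and the
    previous-state and session slopes.
    """
    priors = priors or GlmPriors()
    if iterations <= warmup:
        raise ConfigError("iterations must exceed warmup")
    if random_effects not in ("full", "narrow"):
        raise InputError("random_effects must be 'full' or 'narrow'")
    y = table["stayed"].to_numpy(float)
    if y.min() == y.max():
        raise InputError("degenerate outcome: only one stay/switch class present")
    re_terms = list(WITHIN_TERMS_FULL if random_effects == "full"
                    else WITHIN_TERMS_NARROW)
    W = _within_design(table, WITHIN_TERMS_FULL)
    Z = _within_design(table, re_terms)
    gcols, G = _group_columns(table, serum)
    X = np.hstack([W] + [W * G[:, [j]] for j in range(G.shape[1])])
    coef_names = list(WITHIN_TERMS_FULL) + [
        f"{t}:{g}" for g in gcols for t in WITHIN_TERMS_FULL]
    p_fix = X.shape[1]
    q = Z.shape[1]

    subjects = list(dict.fromkeys(table["subject_id"]))
    sub_map = {s: i for i, s in enumerate(subjects)}
    sub_idx = np.array([sub_map[s] for s in table["subject_id"]])
    n_sub = len(subjects)
    first_rows = [int(np.argmax(sub_idx == i)) for i in range(n_sub)]
    subject_groups = [
        {gc: float(G[r, j]) for j, gc in enumerate(gcols)} for r in first_rows]

    # proposal-side Gaussian prior precision for the fixed block (exact
    # Student-t intercept density enters the MH ratio instead)
    prior_prec_diag = np.full(p_fix, 1.0 / priors.slope_sd ** 2)
    intercept_ix = [coef_names.index("intercept")]
    prior_prec_diag[intercept_ix] = 1.0 / priors.intercept_scale ** 2

    ncpc = samplers.n_cpc(q)
    keep = iterations - warmup
    chain_seeds = np.random.SeedSequence(seed).spawn(chains)

    s_beta = np.empty((chains, keep, p_fix))
    s_b = np.empty((chains, keep, n_sub, q))
    s_sd = np.empty((chains, keep, q))
    s_corr = np.empty((chains, keep, q, q))
    acc_fix = np.empty(chains)

    for c in range(chains):
        rng = np.random.default_rng(chain_seeds[c])
        out = _run_glm_chain(
            y, X, Z, sub_idx, n_sub, prior_prec_diag, intercept_ix, priors,
            iterations, warmup, rng, progress)
        s_beta[c], s_b[c], s_sd[c], s_corr[c], acc_fix[c] = out

    idata = az.from_dict(
        posterior={"beta": s_beta, "b": s_b, "sigma_re": s_sd, "corr_re": s_corr},
        coords={"coef": coef_names, "subject": subjects,
                "re_term": re_terms, "re_term2": re_terms},
        dims={"beta": ["coef"], "b": ["subject", "re_term"],
              "sigma_re": ["re_term"], "corr_re": ["re_term", "re_term2"]},
    )
    options = dict(chains=chains, iterations=iterations, warmup=warmup,
                   seed=seed, serum=serum, random_effects=random_effects,
                   group_cols=gcols, subject_groups=subject_groups,
                   fixed_accept_rate=float(acc_fix.mean()))
    result = GlmPosterior(idata=idata, coef_names=coef_names,
                          re_terms=re_terms, options=options)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        rh = az.rhat(idata, var_names=["beta", "sigma_re"])
    for var in rh.data_vars:
        vals = np.asarray(rh[var]).ravel()
        if np.any(vals >= 1.01):
            result.warnings.append(
                f"R-hat >= 1.01 for {var} (max {np.nanmax(vals):.3f})")
    if acc_fix.mean() < 0.1:
        result.warnings.append(
            f"low fixed-block acceptance ({acc_fix.mean():.2f})")
    return result


def _bern_loglik(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    return y * eta - np.logaddexp(0.0, eta)


def _irls_proposal(Xd, y, offset, prior_prec, g):
    """One-step IRLS Gaussian approximation around g (Gamerman 1997)."""
    eta = offset + Xd @ g
    p = expit(eta)
    w = p * (1.0 - p) + 1e-10
    z = eta - offset + (y - p) / w
    lam = np.diag(prior_prec) + Xd.T @ (w[:, None] * Xd)
    rhs = Xd.T @ (w * z)
    U = cholesky(lam)  # upper
    m = cho_solve((U, False), rhs)
    return m, U


def _mvn_logq(x, m, U):
    """Log density of N(m, lam^{-1}) with lam = U'U (upper Cholesky)."""
    r = U @ (x - m)
    return float(np.sum(np.log(np.diag(U))) - 0.5 * r @ r)


def _run_glm_chain(y, X, Z, sub_idx, n_sub, prior_prec_diag, intercept_ix,
                   priors, iterations, warmup, rng, progress):
    n_rows, p_fix = X.shape
    q = Z.shape[1]
    ncpc = samplers.n_cpc(q)
    keep = iterations - warmup

    beta = 0.01 * rng.standard_normal(p_fix)
    b = 0.01 * rng.standard_normal((n_sub, q))
    log_sd = np.full(q, -1.0) + 0.1 * rng.standard_normal(q)
    y_cpc = np.zeros(ncpc)

    rows_of = [np.where(sub_idx == i)[0] for i in range(n_sub)]

    out_beta = np.empty((keep, p_fix))
    out_b = np.empty((keep, n_sub, q))
    out_sd = np.empty((keep, q))
    out_corr = np.empty((keep, q, q))
    n_acc = 0
    n_try = 0

    def fixed_logprior(g):
        lp = -0.5 * np.sum((np.delete(g, intercept_ix) / priors.slope_sd) ** 2)
        for ix in intercept_ix:
            t = g[ix] / priors.intercept_scale
            lp += -0.5 * (priors.intercept_df + 1) * np.log1p(
                t * t / priors.intercept_df)
        return lp

    re_offset = np.einsum("rq,rq->r", Z, b[sub_idx])

    for it in range(iterations):
        # --- fixed effects: IRLS independence-style MH
        m1, U1 = _irls_proposal(X, y, re_offset, prior_prec_diag, beta)
        prop = m1 + solve_triangular(U1, rng.standard_normal(p_fix), lower=False)
        m2, U2 = _irls_proposal(X, y, re_offset, prior_prec_diag, prop)
        eta_cur = re_offset + X @ beta
        eta_prop = re_offset + X @ prop
        log_ratio = (
            np.sum(_bern_loglik(eta_prop, y)) + fixed_logprior(prop)
            + _mvn_logq(beta, m2, U2)
            - np.sum(_bern_loglik(eta_cur, y)) - fixed_logprior(beta)
            - _mvn_logq(prop, m1, U1)
        )
        accepted = np.log(rng.random()) < log_ratio
        if accepted:
            beta = prop
        if it >= warmup:
            n_acc += int(accepted)
            n_try += 1

        fix_offset = X @ beta

        # --- random-effect covariance pieces for the subject updates
        sd = np.exp(log_sd)
        L_corr = samplers.cpc_to_cholesky(y_cpc, q)
        L_S = sd[:, None] * L_corr
        Sinv = cho_solve((L_S, True), np.eye(q))

        # --- subject random effects: per-subject IRLS MH
        for i in range(n_sub):
            r = rows_of[i]
            Zi = Z[r]
            yi = y[r]
            oi = fix_offset[r]
            mi, Ui = _irls_proposal_mvn(Zi, yi, oi, Sinv, b[i])
            bp = mi + solve_triangular(Ui, rng.standard_normal(q), lower=False)
            mi2, Ui2 = _irls_proposal_mvn(Zi, yi, oi, Sinv, bp)
            eta_c = oi + Zi @ b[i]
            eta_p = oi + Zi @ bp
            lr = (
                np.sum(_bern_loglik(eta_p, yi)) - 0.5 * bp @ Sinv @ bp
                + _mvn_logq(b[i], mi2, Ui2)
                - np.sum(_bern_loglik(eta_c, yi)) + 0.5 * b[i] @ Sinv @ b[i]
                - _mvn_logq(bp, mi, Ui)
            )
            if np.log(rng.random()) < lr:
                b[i] = bp
        re_offset = np.einsum("rq,rq->r", Z, b[sub_idx])

        # --- (sd, corr) of the random effects: slice sampling
        C = b.T @ b
        u = np.concatenate([log_sd, y_cpc])
        for idx in range(q + ncpc):
            def logp(v, idx=idx):
                u[idx] = v
                return _kernels.cov_slice_logp(
                    u, q, C, n_sub, priors.lkj_eta, 1, priors.sd_scale)
            u[idx] = samplers.slice_update(u[idx], logp, rng, w=0.4)
        log_sd = u[:q].copy()
        y_cpc = u[q:].copy()

        if it >= warmup:
            s = it - warmup
            out_beta[s] = beta
            out_b[s] = b
            out_sd[s] = np.exp(log_sd)
            Lc = samplers.cpc_to_cholesky(y_cpc, q)
            out_corr[s] = Lc @ Lc.T
        if progress and (it + 1) % 200 == 0:
            print(f"  sweep {it + 1}/{iterations}", flush=True)

    return out_beta, out_b, out_sd, out_corr, n_acc / max(n_try, 1)


def _irls_proposal_mvn(Zd, y, offset, prior_prec, g):
    eta = offset + Zd @ g
    p = expit(eta)
    w = p * (1.0 - p) + 1e-10
    z = eta - offset + (y - p) / w
    lam = prior_prec + Zd.T @ (w[:, None] * Zd)
    rhs = Zd.T @ (w * z)
    U = cholesky(lam)
    m = cho_solve((U, False), rhs)
    return m, U


# ---------------------------------------------------------------------------
# linking random slopes to computational parameters

@dataclass(frozen=True)
class LinkageResult:
    """Standardized regressions of GLM slopes on model parameters."""

    same_state: pd.DataFrame | None
    interaction: pd.DataFrame | None
    degenerate: bool = False
    message: str = ""


def link_slopes_to_params(glm_post: GlmPosterior,
                          params: pd.DataFrame) -> LinkageResult:
    """Predict per-subject stay-regression slopes from model parameters.

    ``params`` must carry subject_id plus columns omega, gamma, eta (the
    session-2 values, native or estimation space).  Slopes and predictors
    are standardized; two separate linear models are fit, one for the
    same-state previous-points slope, one for the different-vs-same
    interaction slope.  Returns classical 95% intervals per standardized
    coefficient.
    """
    slopes = glm_post.subject_slopes()
    merged = slopes.merge(params, on="subject_id", how="inner")
    if len(merged) != len(slopes) or len(merged) != len(params):
        raise InputError("subject sets of GLM fit and parameter table differ")
    preds = ["omega", "gamma", "eta"]
    Xp = merged[preds].to_numpy(float)
    if np.any(Xp.std(axis=0) < 1e-12):
        return LinkageResult(None, None, degenerate=True,
                             message="zero variance in model parameters")
    Xs = (Xp - Xp.mean(0)) / Xp.std(0)
    tables = []
    for col in ("same_state_slope", "interaction_slope"):
        yv = merged[col].to_numpy(float)
        if yv.std() < 1e-12:
            return LinkageResult(None, None, degenerate=True,
                                 message=f"zero variance in {col}")
        ys = (yv - yv.mean()) / yv.std()
        A = np.column_stack([np.ones(len(ys)), Xs])
        coef, res, *_ = np.linalg.lstsq(A, ys, rcond=None)
        resid = ys - A @ coef
        dof = len(ys) - A.shape[1]
        s2 = float(resid @ resid) / max(dof, 1)
        cov = s2 * np.linalg.inv(A.T @ A)
        se = np.sqrt(np.diag(cov))
        from scipy.stats import t as tdist
        crit = tdist.ppf(0.975, max(dof, 1))
        tables.append(pd.DataFrame({
            "predictor": ["intercept"] + preds,
            "coef": coef, "se": se,
            "ci_low": coef - crit * se, "ci_high": coef + crit * se,
        }))
    return LinkageResult(same_state=tables[0], interaction=tables[1])
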