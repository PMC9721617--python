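"""Model comparison and validation: trial-wise PSIS-LOO, bootstrapped
pseudo-BMA weights, posterior predictive accuracy and checks, and the
simulate-fit-recover harness.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from . import _kernels, agents, task
from .cohort import CohortSpec, generate_cohort, _native_params
from .exceptions import InputError
from .hbayes import CohortData, PosteriorDraws, fit_hierarchical
from .stayglm import build_stay_table, fit_stay_glm
from .transforms import latent_names, latents_to_kernel_params, param_kinds, param_names, to_native

PARETO_K_THRESHOLD = 0.7


# ---------------------------------------------------------------------------
# pointwise log-likelihood

@dataclass
class PointwiseLogLik:
    """Per-draw, per-trial log-likelihoods for one fitted model."""

    matrix: np.ndarray          # (chains, draws, n_trials_total)
    labels: pd.DataFrame        # subject, session, trial per column
    model_id: str

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[-1]

    def to_idata(self) -> az.InferenceData:
        # a trivial posterior group is required by the LOO entry point
        dummy = np.zeros(self.matrix.shape[:2] + (1,))
        return az.from_dict(posterior={"_dummy": dummy},
                            log_likelihood={"choice": self.matrix})

    def draw_totals(self) -> np.ndarray:
        """Total data log-likelihood per draw (rows summed per draw)."""
        return self.matrix.reshape(-1, self.n_trials).sum(axis=1)


def _draw_latents(draws: PosteriorDraws, max_draws: int | None):
    """theta draws as (chains, kept, n_subjects, D) with even thinning."""
    theta = draws.posterior["theta"].to_numpy()
    chains, ndraws = theta.shape[:2]
    if max_draws is not None and chains * ndraws > max_draws:
        stride = int(np.ceil(chains * ndraws / max_draws))
        theta = theta[:, ::stride]
    return theta


def pointwise_loglik(draws: PosteriorDraws, cohort: pd.DataFrame | CohortData,
                     model_id: str | None = None,
                     max_draws: int | None = 2000) -> PointwiseLogLik:
    """Per-trial log-likelihood decomposition under the posterior draws.

    Columns sum (per draw) to the total choice log-likelihood, so the LOO
    machinery sees exactly the likelihood the hierarchical fit used.
    """
    model_id = model_id or draws.model_id
    if model_id != draws.model_id:
        raise InputError("model_id does not match the fitted draws")
    data = cohort if isinstance(cohort, CohortData) else CohortData(cohort, model_id)
    if list(draws.posterior["subject"].values) != list(data.subjects):
        raise InputError("draws and cohort subjects do not match")
    theta = _draw_latents(draws, max_draws)
    chains, kept, n, D = theta.shape
    seg_rows = 2 * data.seg_subject + (data.seg_session - 1)
    nseg = len(seg_rows)
    P = np.empty((chains * kept * nseg, 5))
    flat = theta.reshape(chains * kept, n, D)
    for d in range(chains * kept):
        P[d * nseg:(d + 1) * nseg] = latents_to_kernel_params(
            flat[d], model_id)[seg_rows]
    out = np.empty((chains * kept, data.n_trials_total))
    _kernels.pointwise_logliks(
        P, data.family, data.fs, data.act, data.planet, data.reward,
        data.offsets, data.tmap, out)
    labels = pd.DataFrame({
        "subject_id": np.repeat([data.subjects[i] for i in data.seg_subject],
                                np.diff(data.offsets)),
        "session": np.repeat(data.seg_session, np.diff(data.offsets)),
    })
    labels["trial"] = labels.groupby(["subject_id", "session"]).cumcount() + 1
    return PointwiseLogLik(matrix=out.reshape(chains, kept, -1),
                           labels=labels, model_id=model_id)


# ---------------------------------------------------------------------------
# LOO comparison and pseudo-BMA

@dataclass
class ComparisonResult:
    """Per-model LOO estimates, pairwise differences, pseudo-BMA weights."""

    table: pd.DataFrame
    pairwise: pd.DataFrame
    weights: dict[str, float]
    elpd_pointwise: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def best(self) -> str:
        return str(self.table["looic"].idxmin())


def loo_compare(logliks: dict[str, PointwiseLogLik], n_boot: int = 1000,
                seed: int = 0) -> ComparisonResult:
    """PSIS-LOO comparison of models sharing one trial set.

    Reports elpd and LOOIC (= -2 elpd) with standard errors, pairwise elpd
    differences with the SE of the paired pointwise differences, Pareto-k
    tail diagnostics, and bootstrapped pseudo-BMA weights.
    """
    names = list(logliks)
    if len(names) < 1:
        raise InputError("need at least one model")
    n_points = {m: logliks[m].n_trials for m in names}
    if len(set(n_points.values())) != 1:
        raise InputError(f"mismatched trial sets: {n_points}")
    elpd_i: dict[str, np.ndarray] = {}
    rows = []
    for m in names:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            res = az.loo(logliks[m].to_idata(), pointwise=True, var_name="choice")
        pointwise = np.asarray(res.loo_i).ravel()
        k = np.asarray(res.pareto_k).ravel()
        elpd_i[m] = pointwise
        rows.append({
            "model": m, "elpd": float(res.elpd_loo), "se": float(res.se),
            "looic": -2.0 * float(res.elpd_loo), "p_loo": float(res.p_loo),
            "max_pareto_k": float(np.nanmax(k)),
            "n_high_pareto_k": int(np.sum(k > PARETO_K_THRESHOLD)),
        })
    table = pd.DataFrame(rows).set_index("model")
    best = table["elpd"].idxmax()
    table["d_elpd"] = table["elpd"] - table.loc[best, "elpd"]
    pair_rows = []
    for a in names:
        for b in names:
            if a >= b:
                continue
            diff = elpd_i[a] - elpd_i[b]
            pair_rows.append({
                "model_a": a, "model_b": b,
                "d_elpd": float(diff.sum()),
                "d_se": float(np.sqrt(len(diff) * diff.var(ddof=1)))
                if len(diff) > 1 else 0.0,
            })
    pairwise = pd.DataFrame(pair_rows)
    weights = pseudo_bma_weights(elpd_i, n_boot=n_boot, seed=seed)
    table["weight"] = [weights[m] for m in table.index]
    return ComparisonResult(table=table, pairwise=pairwise, weights=weights,
                            elpd_pointwise=elpd_i)


def pseudo_bma_weights(elpd_pointwise: dict[str, np.ndarray],
                       n_boot: int = 1000, seed: int = 0) -> dict[str, float]:
    """Bayesian-bootstrap-stabilized softmax of the LOO elpd estimates.

    Each replicate draws Dirichlet(1, ..., 1) weights over trials, rescales
    the weighted pointwise elpds to a total, applies a softmax over models,
    and the replicate weights are averaged.
    """
    names = list(elpd_pointwise)
    if len(names) < 2:
        return {names[0]: 1.0} if names else {}
    E = np.stack([np.asarray(elpd_pointwise[m], dtype=float) for m in names])
    n = E.shape[1]
    rng = np.random.default_rng(seed)
    w = rng.dirichlet(np.ones(n), size=n_boot)  # (n_boot, n)
    z = n * (w @ E.T)                            # (n_boot, n_models)
    z -= z.max(axis=1, keepdims=True)
    soft = np.exp(z)
    soft /= soft.sum(axis=1, keepdims=True)
    mean = soft.mean(axis=0)
    mean /= mean.sum()
    return {m: float(mean[j]) for j, m in enumerate(names)}


# ---------------------------------------------------------------------------
# posterior predictive accuracy

def posterior_predictive_accuracy(draws: PosteriorDraws,
                                  cohort: pd.DataFrame | CohortData,
                                  model_id: str | None = None,
                                  n_draws: int = 8000,
                                  rule: str = "modal") -> pd.DataFrame:
    """Per-subject accuracy of posterior choice predictions.

    For every retained draw and trial the predicted choice is the
    higher-valued action (exact ties credit 0.5); accuracies are averaged
    over draws and trials within subject.  ``rule="probability"`` credits
    the model probability of the observed choice instead.
    """
    if rule not in ("modal", "probability"):
        raise InputError("rule must be 'modal' or 'probability'")
    model_id = model_id or draws.model_id
    data = cohort if isinstance(cohort, CohortData) else CohortData(cohort, model_id)
    theta = _draw_latents(draws, n_draws)
    chains, kept, n, D = theta.shape
    seg_rows = 2 * data.seg_subject + (data.seg_session - 1)
    nseg = len(seg_rows)
    flat = theta.reshape(chains * kept, n, D)
    P = np.empty((chains * kept * nseg, 5))
    for d in range(chains * kept):
        P[d * nseg:(d + 1) * nseg] = latents_to_kernel_params(
            flat[d], model_id)[seg_rows]
    seg_acc = _kernels.predictive_accuracy(
        P, data.family, data.fs, data.act, data.planet, data.reward,
        data.offsets, data.tmap, rule == "modal")
    sizes = np.diff(data.offsets)
    df = pd.DataFrame({
        "subject_id": [data.subjects[i] for i in data.seg_subject],
        "session": data.seg_session, "accuracy": seg_acc, "n_trials": sizes,
    })
    per_subject = (
        df.assign(w=df.accuracy * df.n_trials)
        .groupby("subject_id", sort=False)
        .apply(lambda g: g.w.sum() / g.n_trials.sum(), include_groups=False)
        .rename("accuracy").reset_index()
    )
    return per_subject


# ---------------------------------------------------------------------------
# parameter recovery

@dataclass
class RecoveryReport:
    """Simulate -> fit -> score output for one cohort specification."""

    latent_table: pd.DataFrame    # r, bias, 95% coverage per latent
    beta_table: pd.DataFrame      # injected vs recovered group effects
    scatter: pd.DataFrame         # true and recovered values per subject
    fit: PosteriorDraws

    def r(self, latent: str) -> float:
        return float(self.latent_table.set_index("latent").loc[latent, "r"])

    @property
    def overall_coverage(self) -> float:
        return float(self.latent_table["coverage"].mean())


def parameter_recovery(spec: CohortSpec, **fit_kwargs) -> RecoveryReport:
    """Generate a cohort with known ground truth, refit it, and score
    per-latent Pearson correlation, bias and 95%-interval coverage, plus
    recovery of the injected group-level drug effects."""
    trials, truth = generate_cohort(spec)
    fit = fit_hierarchical(trials, spec.model_id, **fit_kwargs)
    names = list(latent_names(spec.model_id))
    truth = truth.set_index("subject_id").loc[
        list(fit.posterior["subject"].values)]
    post_mean = fit.posterior["theta"].mean(("chain", "draw")).to_numpy()
    lo = fit.posterior["theta"].quantile(0.025, dim=("chain", "draw")).to_numpy()
    hi = fit.posterior["theta"].quantile(0.975, dim=("chain", "draw")).to_numpy()
    rows = []
    scat = {"subject_id": list(truth.index)}
    for j, name in enumerate(names):
        t = truth[name].to_numpy(float)
        m = post_mean[:, j]
        rows.append({
            "latent": name,
            "r": float(np.corrcoef(t, m)[0, 1]),
            "bias": float(np.mean(m - t)),
            "coverage": float(np.mean((t >= lo[:, j]) & (t <= hi[:, j]))),
        })
        scat[f"true_{name}"] = t
        scat[f"recovered_{name}"] = m
    beta_rows = []
    pnames = param_names(spec.model_id)
    for reg in fit.posterior["regressor"].values:
        arm = {"ami": "amisulpride", "nal": "naltrexone"}.get(str(reg))
        for par in pnames:
            b = fit.beta_draws(str(reg), par)
            injected = spec.drug_effects.get((arm, f"d_{par}"), 0.0) if arm else \
                spec.serum_effects.get(f"d_{par}", 0.0)
            qlo, qhi = np.percentile(b, [2.5, 97.5])
            beta_rows.append({
                "regressor": str(reg), "parameter": par, "true": injected,
                "post_mean": float(b.mean()), "ci_low": float(qlo),
                "ci_high": float(qhi),
                "covered": bool(qlo <= injected <= qhi),
            })
    return RecoveryReport(latent_table=pd.DataFrame(rows),
                          beta_table=pd.DataFrame(beta_rows),
                          scatter=pd.DataFrame(scat), fit=fit)


# ---------------------------------------------------------------------------
# posterior predictive check

@dataclass
class PPCResult:
    """Synthetic-vs-observed stay behaviour at posterior-mean parameters."""

    synthetic: pd.DataFrame
    stay_curves: pd.DataFrame
    glm_comparison: pd.DataFrame | None = None


def _stay_curve(table: pd.DataFrame, source: str, n_bins: int = 5) -> pd.DataFrame:
    tab = table.copy()
    lo, hi = tab.prev_points.min(), tab.prev_points.max()
    edges = np.linspace(lo - 0.5, hi + 0.5, n_bins + 1)
    tab["points_bin"] = pd.cut(tab.prev_points, edges).apply(
        lambda iv: 0.5 * (iv.left + iv.right))
    out = (tab.groupby(["points_bin", "diff_state"], observed=True)
           .stayed.agg(["mean", "size"]).reset_index())
    out["source"] = source
    return out


def posterior_predictive_check(draws: PosteriorDraws,
                               cohort: pd.DataFrame,
                               seed: int = 0,
                               refit_glm: bool = False,
                               glm_kwargs: dict | None = None) -> PPCResult:
    """Simulate every subject at posterior-mean parameters and compare stay
    behaviour (binned stay-probability curves; optionally a refitted stay
    regression) with the source cohort."""
    model_id = draws.model_id
    data = CohortData(cohort, model_id)
    kinds = param_kinds(model_id)
    k = len(kinds)
    post_mean = draws.posterior["theta"].mean(("chain", "draw")).to_numpy()
    root = np.random.SeedSequence(seed)
    n_trials = int(np.diff(data.offsets).max())
    frames = []
    meta = cohort.groupby("subject_id", sort=False).first()
    for i, sid in enumerate(data.subjects):
        for sess in (1, 2):
            est = post_mean[i, :k] + (post_mean[i, k:] if sess == 2 else 0.0)
            native = [to_native(est[j], kinds[j]) for j in range(k)]
            params = _native_params(model_id, native)
            s1, s2, s3 = [int(c.generate_state(1)[0] % 2**31)
                          for c in np.random.SeedSequence((seed, i, sess)).spawn(3)]
            cfg = task.default_config(n_trials, seed=s1)
            walks = task.generate_session_walks(cfg, s2)
            records = agents.simulate_choices(params, model_id, cfg, walks,
                                              seed=s3, subject_id=sid, session=sess)
            df = pd.DataFrame(records).rename(columns={"trial_index": "trial"})
            df["drug"] = meta.loc[sid, "drug"]
            df["serum_group"] = meta.loc[sid, "serum_group"] \
                if "serum_group" in meta else "NA"
            frames.append(df)
    synthetic = pd.concat(frames, ignore_index=True)
    obs_tab = build_stay_table(cohort)
    syn_tab = build_stay_table(synthetic)
    curves = pd.concat([_stay_curve(obs_tab, "observed"),
                        _stay_curve(syn_tab, "synthetic")], ignore_index=True)
    glm_cmp = None
    if refit_glm:
        kwargs = dict(chains=2, iterations=600, warmup=300, seed=seed)
        kwargs.update(glm_kwargs or {})
        fit_obs = fit_stay_glm(obs_tab, **kwargs)
        fit_syn = fit_stay_glm(syn_tab, **kwargs)
        a = fit_obs.summary().set_index("coefficient")[["mean", "ci_low", "ci_high"]]
        b = fit_syn.summary().set_index("coefficient")[["mean", "ci_low", "ci_high"]]
        glm_cmp = a.join(b, lsuffix="_observed", rsuffix="_synthetic").reset_index()
    return PPCResult(synthetic=synthetic, stay_curves=curves,
                     glm_comparison=glm_cmp)


# ---------------------------------------------------------------------------
# plotting helpers (display only)

def plot_recovery(report: RecoveryReport, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = report.latent_table["latent"].tolist()
    fig, axes = plt.subplots(1, len(names), figsize=(3 * len(names), 3))
    for ax, name in zip(np.atleast_1d(axes), names):
        t = report.scatter[f"true_{name}"]
        m = report.scatter[f"recovered_{name}"]
        ax.scatter(t, m, s=12, alpha=0.7)
        lims = [min(t.min(), m.min()), max(t.max(), m.max())]
        ax.plot(lims, lims, "k--", lw=0.8)
        ax.set_title(f"{name} (r={report.r(name):.2f})")
        ax.set_xlabel("true")
    np.atleast_1d(axes)[0].set_ylabel("posterior mean")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_stay_curves(ppc: PPCResult, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(8, 3.2), sharey=True)
    for ax, ds in zip(axes, (0, 1)):
        for source, style in (("observed", "o-"), ("synthetic", "s--")):
            sub = ppc.stay_curves.query(
                "diff_state == @ds and source == @source")
            ax.plot(sub["points_bin"], sub["mean"], style, label=source)
        ax.set_title("same first state" if ds == 0 else "different first state")
        ax.set_xlabel("previous points (binned)")
    axes[0].set_ylabel("P(stay)")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
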