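"""Synthetic study cohorts with the hierarchical structure the inference
stage assumes.

A cohort couples three ingredients: (i) subject-level latent parameters in
estimation space, drawn from a correlated multivariate Gaussian whose
session-difference means are shifted by drug-arm effects; (ii) the task
environment (reward walks, first-state sequences) regenerated independently
per subject and session; (iii) forward simulation of the chosen generative
model.  The output is a trial table in the standard CSV schema plus a
ground-truth table for recovery scoring, both fully reproducible from the
master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import agents, task
from .exceptions import ConfigError, InputError
from .transforms import latent_names, param_kinds, param_names, to_native

ARMS = ("placebo", "amisulpride", "naltrexone")
SERUM_GROUPS = ("low", "high", "NA")

TRIAL_COLUMNS = [
    "subject_id", "session", "trial", "first_state", "action",
    "stimulus_id", "planet", "reward", "drug", "serum_group",
]


def _default_correlation(k: int, baseline_delta_corr: float = -0.3) -> np.ndarray:
    """Unit-diagonal PD matrix with a mild baseline<->difference coupling.

    A negative correlation between each parameter's baseline and its session
    difference emulates regression to the mean, the dominant dependence seen
    in repeated-measures designs.
    """
    R = np.eye(k)
    half = k // 2
    for j in range(half):
        R[j, half + j] = R[half + j, j] = baseline_delta_corr
    return R


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of one synthetic cohort.

    ``hyper_means``/``hyper_sds`` are in estimation space, ordered as
    ``latent_names(model_id)`` (baselines first, then session differences).
    ``drug_effects`` maps (arm, latent-difference name) to an additive shift
    of that arm's difference mean, e.g. ``("amisulpride", "d_omega"): 0.8``.
    ``serum_effects`` optionally adds a further shift for high-serum
    amisulpride subjects.
    """

    n_per_arm: dict[str, int]
    model_id: str = "M1"
    hyper_means: tuple[float, ...] = ()
    hyper_sds: tuple[float, ...] = ()
    correlation: np.ndarray | None = None
    drug_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    serum_effects: dict[str, float] = field(default_factory=dict)
    serum_measured: float = 1.0   # fraction of amisulpride subjects with serum data
    serum_split: float = 0.5      # fraction of measured subjects labelled high
    n_trials: int = 200
    n_sessions: int = 2
    master_seed: int = 0

    def __post_init__(self):
        for arm in self.n_per_arm:
            if arm not in ARMS:
                raise InputError(f"unknown drug arm {arm!r}")
        k = len(latent_names(self.model_id))
        means = self.hyper_means or _default_means(self.model_id)
        sds = self.hyper_sds or _default_sds(self.model_id)
        if len(means) != k or len(sds) != k:
            raise ConfigError(f"hyper vectors must have length {k}")
        if any(s <= 0 for s in sds):
            raise ConfigError("hyper_sds must be positive")
        object.__setattr__(self, "hyper_means", tuple(means))
        object.__setattr__(self, "hyper_sds", tuple(sds))
        R = self.correlation if self.correlation is not None else _default_correlation(k)
        R = np.asarray(R, dtype=float)
        if R.shape != (k, k) or not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ConfigError("correlation must be symmetric with unit diagonal")
        try:
            np.linalg.cholesky(R)
        except np.linalg.LinAlgError as err:
            raise ConfigError("correlation matrix is not positive-definite") from err
        object.__setattr__(self, "correlation", R)
        names = latent_names(self.model_id)
        for (arm, name) in self.drug_effects:
            if arm not in ("amisulpride", "naltrexone"):
                raise InputError(f"drug effects only for active arms, got {arm!r}")
            if name not in names or not name.startswith("d_"):
                raise InputError(f"{name!r} is not a session-difference latent")
        for name in self.serum_effects:
            if name not in names or not name.startswith("d_"):
                raise InputError(f"{name!r} is not a session-difference latent")

    @property
    def latent_labels(self) -> tuple[str, ...]:
        return latent_names(self.model_id)

    def arm_mean(self, arm: str, serum_high: bool = False) -> np.ndarray:
        """Hyper-mean vector with this arm's effects added to the deltas."""
        mu = np.array(self.hyper_means, dtype=float)
        names = self.latent_labels
        for (a, name), beta in self.drug_effects.items():
            if a == arm:
                mu[names.index(name)] += beta
        if serum_high and arm == "amisulpride":
            for name, beta in self.serum_effects.items():
                mu[names.index(name)] += beta
        return mu

    def scale_tril(self) -> np.ndarray:
        """Cholesky factor of diag(sd) @ R @ diag(sd); valid even at sd -> 0."""
        return np.diag(self.hyper_sds) @ np.linalg.cholesky(self.correlation)


def _default_means(model_id: str) -> tuple[float, ...]:
    base = {"omega": 0.0, "gamma": -0.5, "eta": 0.3, "rho": 0.2, "pi": 0.0,
            "alpha": 0.0, "alpha1": 0.0, "alpha2": 0.3, "lambda": 0.0}
    names = param_names(model_id)
    return tuple(base[n] for n in names) + tuple(0.0 for _ in names)


def _default_sds(model_id: str) -> tuple[float, ...]:
    names = param_names(model_id)
    return tuple(0.8 for _ in names) + tuple(0.5 for _ in names)


def sample_subject_latents(spec: CohortSpec, arm: str, seed: int,
                           serum_high: bool = False) -> np.ndarray:
    """One MVN draw of (baselines, session differences) for a subject."""
    if arm not in ARMS:
        raise InputError(f"unknown drug arm {arm!r}")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(len(spec.latent_labels))
    return spec.arm_mean(arm, serum_high) + spec.scale_tril() @ z


def _assign_serum(n_ami: int, spec: CohortSpec, rng) -> list[str]:
    n_measured = int(round(spec.serum_measured * n_ami))
    n_high = int(round(spec.serum_split * n_measured))
    labels = (["high"] * n_high + ["low"] * (n_measured - n_high)
              + ["NA"] * (n_ami - n_measured))
    return list(rng.permutation(labels))


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort.

    Returns ``(trials, ground_truth)``: the trial table in the standard
    schema and per-subject latents plus session-wise native parameters.
    """
    names = list(spec.latent_labels)
    pnames = param_names(spec.model_id)
    kinds = param_kinds(spec.model_id)
    k = len(pnames)
    root = np.random.SeedSequence(spec.master_seed)
    arm_order = [arm for arm in ARMS if spec.n_per_arm.get(arm, 0) > 0]
    serum_rng = np.random.default_rng(root.spawn(1)[0])
    trial_rows: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    sid = 0
    for arm in arm_order:
        n = spec.n_per_arm[arm]
        serum = _assign_serum(n, spec, serum_rng) if arm == "amisulpride" else ["NA"] * n
        for j in range(n):
            sid += 1
            subject_id = f"s{sid:03d}"
            ss = np.random.SeedSequence((spec.master_seed, sid))
            seeds = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(1 + 2 * spec.n_sessions)]
            latents = sample_subject_latents(spec, arm, seeds[0], serum[j] == "high")
            truth = {"subject_id": subject_id, "arm": arm, "serum_group": serum[j]}
            truth.update({name: latents[i] for i, name in enumerate(names)})
            for sess in range(1, spec.n_sessions + 1):
                est = latents[:k] + (latents[k:] if sess == 2 else 0.0)
                native = [to_native(est[i], kinds[i]) for i in range(k)]
                params = _native_params(spec.model_id, native)
                cfg = task.default_config(spec.n_trials, seed=seeds[2 * sess - 1])
                walks = task.generate_session_walks(cfg, seeds[2 * sess])
                records = agents.simulate_choices(
                    params, spec.model_id, cfg, walks, seed=seeds[0] + sess,
                    subject_id=subject_id, session=sess,
                )
                df = pd.DataFrame(records)
                df = df.rename(columns={"trial_index": "trial"})
                df["drug"] = arm
                df["serum_group"] = serum[j]
                trial_rows.append(df[TRIAL_COLUMNS])
                for i, pname in enumerate(pnames):
                    truth[f"{pname}_s{sess}"] = native[i]
            truth_rows.append(truth)
    trials = pd.concat(trial_rows, ignore_index=True)
    return trials, pd.DataFrame(truth_rows)


def _native_params(model_id: str, native: list[float]):
    if model_id == "M1":
        return agents.M1Params(omega=native[0], gamma=native[1], eta=native[2])
    if model_id == "M1_sticky":
        return agents.M1Params(omega=native[0], gamma=native[1], eta=native[2],
                               rho=native[3], pi=native[4])
    if model_id == "M2":
        return agents.RLParams(omega=native[0], eta=native[1], alpha1=native[2],
                               alpha2=native[3], lam=native[4])
    if model_id == "M3":
        return agents.RLParams(omega=native[0], eta=native[1], alpha1=native[2],
                               alpha2=native[2], lam=native[3])
    raise InputError(f"unknown model_id {model_id!r}")


def default_study_spec(master_seed: int = 2023) -> CohortSpec:
    """Cohort spec echoing the published study layout.

    Arm sizes 35/38/39 (placebo/amisulpride/naltrexone), 200 trials per
    session, two sessions, an amisulpride shift of +0.8 on the session
    difference of the model-based weight (the scale of the reported
    estimate), and a 18-high / 14-low serum split among the 32
    serum-measured amisulpride subjects.
    """
    return CohortSpec(
        n_per_arm={"placebo": 35, "amisulpride": 38, "naltrexone": 39},
        model_id="M1",
        drug_effects={("amisulpride", "d_omega"): 0.8},
        serum_measured=32 / 38,
        serum_split=18 / 32,
        n_trials=200,
        master_seed=master_seed,
    )
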