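"""Estimation-space <-> native-space parameter transforms.

Hierarchical priors and drug regressions live in an unconstrained
"estimation" space: parameters bounded in [0, 1] (omega, gamma, the learning
rates, lambda) are mapped through the standard-normal CDF (inverse probit),
the positive inverse temperature eta through exp, and the unbounded
stickiness parameters rho/pi through the identity.  A subject's session-2
native parameter is the transform of (baseline' + delta').
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, ndtri

from .exceptions import InputError

KINDS = ("unit_interval", "positive", "unbounded")


def to_native(latent, kind: str):
    """Map estimation-space values to native space."""
    x = np.asarray(latent, dtype=float)
    if kind == "unit_interval":
        out = ndtr(x)
    elif kind == "positive":
        # clip to keep sampler excursions finite; exp(700) is already ~1e304
        out = np.exp(np.minimum(x, 700.0))
    elif kind == "unbounded":
        out = x.copy()
    else:
        raise InputError(f"unknown transform kind {kind!r}")
    return out if out.ndim else float(out)


def to_estimation(native, kind: str):
    """Inverse of :func:`to_native`."""
    v = np.asarray(native, dtype=float)
    if kind == "unit_interval":
        out = ndtri(v)
    elif kind == "positive":
        out = np.log(v)
    elif kind == "unbounded":
        out = v.copy()
    else:
        raise InputError(f"unknown transform kind {kind!r}")
    return out if out.ndim else float(out)


#: per-model native parameter names and transform kinds, in kernel packing
#: order (see twostep._kernels for the family layouts).
MODEL_PARAMS: dict[str, tuple[tuple[str, str], ...]] = {
    "M1": (
        ("omega", "unit_interval"),
        ("gamma", "unit_interval"),
        ("eta", "positive"),
    ),
    "M1_sticky": (
        ("omega", "unit_interval"),
        ("gamma", "unit_interval"),
        ("eta", "positive"),
        ("rho", "unbounded"),
        ("pi", "unbounded"),
    ),
    "M2": (
        ("omega", "unit_interval"),
        ("eta", "positive"),
        ("alpha1", "unit_interval"),
        ("alpha2", "unit_interval"),
        ("lambda", "unit_interval"),
    ),
    "M3": (
        ("omega", "unit_interval"),
        ("eta", "positive"),
        ("alpha", "unit_interval"),
        ("lambda", "unit_interval"),
    ),
}

MODEL_IDS = tuple(MODEL_PARAMS)


def model_family(model_id: str) -> int:
    from . import _kernels

    if model_id in ("M1", "M1_sticky"):
        return _kernels.FAMILY_DET
    if model_id in ("M2", "M3"):
        return _kernels.FAMILY_TD
    raise InputError(f"unknown model_id {model_id!r}")


def param_names(model_id: str) -> tuple[str, ...]:
    if model_id not in MODEL_PARAMS:
        raise InputError(f"unknown model_id {model_id!r}")
    return tuple(name for name, _ in MODEL_PARAMS[model_id])


def param_kinds(model_id: str) -> tuple[str, ...]:
    if model_id not in MODEL_PARAMS:
        raise InputError(f"unknown model_id {model_id!r}")
    return tuple(kind for _, kind in MODEL_PARAMS[model_id])


def latent_names(model_id: str) -> tuple[str, ...]:
    """Estimation-space latent labels: baselines then session differences."""
    names = param_names(model_id)
    return tuple(f"{n}0" for n in names) + tuple(f"d_{n}" for n in names)


def latents_to_kernel_params(latents: np.ndarray, model_id: str) -> np.ndarray:
    """Native kernel parameter rows for both sessions of each subject.

    ``latents`` is (n_subjects, 2K) with baselines in the first K columns and
    session differences in the last K.  Returns (n_subjects * 2, 5) with
    session 1 in even rows and session 2 in odd rows, padded with zeros to
    the fixed kernel width; M3's tied learning rate is duplicated into both
    alpha slots.
    """
    latents = np.atleast_2d(np.asarray(latents, dtype=float))
    kinds = param_kinds(model_id)
    k = len(kinds)
    n = latents.shape[0]
    if latents.shape[1] != 2 * k:
        raise InputError(
            f"latent width {latents.shape[1]} != 2x{k} for model {model_id}"
        )
    out = np.zeros((2 * n, 5))
    for j, kind in enumerate(kinds):
        s1 = to_native(latents[:, j], kind)
        s2 = to_native(latents[:, j] + latents[:, k + j], kind)
        col = j
        out[0::2, col] = s1
        out[1::2, col] = s2
    if model_id == "M3":  # duplicate alpha into the alpha2 slot, shift lambda
        out[:, 4] = out[:, 3]  # lambda was packed at index 3
        out[:, 3] = out[:, 2]  # alpha2 := alpha
    return out
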