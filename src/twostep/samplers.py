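"""MCMC building blocks: slice sampling, adaptive Metropolis, LKJ geometry.

The hierarchical fits in this package run on a Metropolis-within-Gibbs
scheme composed from three primitives:

* a vectorized adaptive random-walk Metropolis step for blocks that are
  conditionally expensive but low-dimensional (one block per subject);
  proposal covariances are learned during warmup (Haario-style) and frozen
  afterwards, so the post-warmup chain is a valid time-homogeneous kernel;
* a univariate stepping-out slice sampler (Neal 2003) for
  variance/correlation hyper-parameters, which needs no tuning;
* an unconstrained parameterization of correlation matrices through
  canonical partial correlations (CPCs).  Under LKJ(eta) the CPCs are
  independent scaled-Beta variables, which gives an exact, factorized prior
  density in the unconstrained space (Lewandowski, Kurowicka & Joe, 2009).
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# correlation matrices via canonical partial correlations

def n_cpc(dim: int) -> int:
    return dim * (dim - 1) // 2


def cpc_to_cholesky(y: np.ndarray, dim: int) -> np.ndarray:
    """Lower Cholesky factor of a correlation matrix from unconstrained y.

    ``z = tanh(y)`` are the canonical partial correlations, filled into the
    strictly lower triangle column-major by row (row i, columns < i).
    """
    z = np.tanh(np.asarray(y, dtype=float))
    L = np.zeros((dim, dim))
    L[0, 0] = 1.0
    idx = 0
    for i in range(1, dim):
        rem = 1.0
        for j in range(i):
            L[i, j] = z[idx] * np.sqrt(rem)
            rem *= 1.0 - z[idx] ** 2
            idx += 1
        L[i, i] = np.sqrt(rem)
    return L


def lkj_cpc_logpdf(y: np.ndarray, dim: int, eta: float = 2.0) -> float:
    """Log density (up to a constant) of LKJ(eta) in CPC space, Jacobian included.

    The CPC at row i, column j has marginal 2*Beta(b, b) - 1 with
    b = eta + (dim - 1 - (j + 1)) / 2; adding the tanh Jacobian log(1 - z^2)
    turns the exponent (b - 1) into b.
    """
    y = np.asarray(y, dtype=float)
    log1mz2 = -2.0 * np.log(np.cosh(y))  # log(1 - tanh(y)^2), overflow-safe
    total = 0.0
    idx = 0
    for i in range(1, dim):
        for j in range(i):
            b = eta + 0.5 * (dim - 2 - j)
            total += b * log1mz2[idx]
            idx += 1
    return float(total)


def cholesky_to_corr(L: np.ndarray) -> np.ndarray:
    return L @ L.T


def corr_to_cpc(R: np.ndarray) -> np.ndarray:
    """Inverse of :func:`cpc_to_cholesky` (for initialization round-trips)."""
    dim = R.shape[0]
    L = np.linalg.cholesky(R)
    y = np.empty(n_cpc(dim))
    idx = 0
    for i in range(1, dim):
        rem = 1.0
        for j in range(i):
            z = L[i, j] / np.sqrt(rem)
            z = np.clip(z, -1 + 1e-12, 1 - 1e-12)
            y[idx] = np.arctanh(z)
            rem *= 1.0 - z ** 2
            idx += 1
    return y


# ---------------------------------------------------------------------------
# univariate slice sampler

def slice_update(x0: float, logp, rng: np.random.Generator, w: float = 1.0,
                 max_steps: int = 50) -> float:
    """One stepping-out slice-sampling update of a scalar coordinate.

    ``logp`` is the (unnormalized) conditional log density as a function of
    the coordinate.  Always returns a valid sample; degenerate shrinkage
    falls back to ``x0``.
    """
    lp0 = logp(x0)
    height = lp0 + np.log(rng.random())
    u = rng.random()
    left = x0 - w * u
    right = left + w
    steps = max_steps
    while steps > 0 and logp(left) > height:
        left -= w
        steps -= 1
    steps = max_steps
    while steps > 0 and logp(right) > height:
        right += w
        steps -= 1
    for _ in range(100):
        x1 = rng.uniform(left, right)
        if logp(x1) > height:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0


# ---------------------------------------------------------------------------
# vectorized adaptive random-walk Metropolis (one block per "unit")

class BlockAdaptiveRW:
    """Per-unit adaptive Gaussian random-walk proposals.

    Tracks, for each of ``n_units`` independent blocks of dimension ``dim``,
    a running empirical covariance (Welford) and a log step-size adapted
    toward ``target_accept``.  Adaptation happens only while ``adapting`` is
    True; :meth:`freeze` fixes the kernels for the sampling phase.
    """

    def __init__(self, n_units: int, dim: int, init_scale: float = 0.15,
                 target_accept: float = 0.3):
        self.n = n_units
        self.d = dim
        self.target = target_accept
        self.log_scale = np.full(n_units, np.log(init_scale))
        self.chol = np.tile(np.eye(dim), (n_units, 1, 1))
        self._mean = np.zeros((n_units, dim))
        self._m2 = np.zeros((n_units, dim, dim))
        self._count = 0
        self._step = 0
        self.adapting = True

    def propose(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal((self.n, self.d))
        step = np.einsum("nij,nj->ni", self.chol, z)
        return x + np.exp(self.log_scale)[:, None] * step

    def update(self, x: np.ndarray, accepted: np.ndarray):
        """Record the current state and adapt scales/covariances."""
        if not self.adapting:
            return
        self._step += 1
        lr = (self._step + 10.0) ** -0.6
        self.log_scale += lr * (accepted.astype(float) - self.target)
        self._count += 1
        delta = x - self._mean
        self._mean += delta / self._count
        self._m2 += np.einsum("ni,nj->nij", delta, x - self._mean)
        if self._count >= 50 and self._step % 25 == 0:
            cov = self._m2 / max(self._count - 1, 1)
            cov = cov + 1e-6 * np.eye(self.d)
            # scale by the Gelman-Roberts-Gilks optimum; per-unit log_scale
            # keeps fine-tuning acceptance around it
            try:
                self.chol = np.linalg.cholesky(2.38 ** 2 / self.d * cov)
            except np.linalg.LinAlgError:
                pass

    def freeze(self):
        self.adapting = False
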