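"""Two-component Gaussian mixture fit to the in-play acceleration index.

The in-play intensity histogram is bimodal: a low peak (waiting, walking)
and a high peak (chasing, swinging). Its density is modeled as

    p(x) = (1 - w_high) N(x | mu_low, sigma_low^2) + w_high N(x | mu_high, sigma_high^2)

and the five free parameters (mu_low, sigma_low, mu_high, sigma_high,
w_high) are estimated by maximum likelihood with the EM algorithm. This
module implements the EM iteration itself; components are always relabeled
so that ``mu_low <= mu_high`` (ties broken by sigma), making the five
features deterministic.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
import json

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, DensityMixin
from sklearn.utils.validation import check_is_fitted

from .config import RunConfig
from .errors import ConfigError, DegenerateFitError, InsufficientDataError

_LOG_2PI = float(np.log(2.0 * np.pi))


def normal_pdf(x, mu: float, sigma: float):
    """Density of N(mu, sigma^2) at ``x`` (scalar or array)."""
    if sigma <= 0:
        raise ConfigError(f"sigma must be > 0, got {sigma}")
    z = (np.asarray(x, dtype=float) - mu) / sigma
    out = np.exp(-0.5 * z * z) / (sigma * np.sqrt(2.0 * np.pi))
    return out if np.ndim(x) else float(out)


@dataclass
class MixtureFit:
    """Estimated mixture parameters plus fit diagnostics."""

    mu_low: float
    sigma_low: float
    mu_high: float
    sigma_high: float
    w_high: float
    log_likelihood: float
    n_iter: int
    converged: bool
    n_samples: int
    seed: int

    @property
    def w_low(self) -> float:
        return 1.0 - self.w_high

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "MixtureFit":
        with open(path) as fh:
            return cls(**json.load(fh))


def mixture_pdf(x, fit: MixtureFit):
    """Two-component mixture density at ``x``."""
    return (fit.w_low * normal_pdf(x, fit.mu_low, fit.sigma_low)
            + fit.w_high * normal_pdf(x, fit.mu_high, fit.sigma_high))


class IntensityMixture(DensityMixin, BaseEstimator):
    """Univariate two-component Gaussian mixture fitted by EM.

    Parameters
    ----------
    tol : float
        Convergence threshold on the improvement of the mean per-sample
        log-likelihood between iterations (scale-free across pool sizes).
    max_iter : int
        Iteration cap per initialization.
    n_init : int
        Number of initializations; the first is a deterministic median
        split, the rest draw random per-sample responsibilities from
        ``random_state``. The run with the best final log-likelihood wins.
    var_floor : float
        Lower bound on component variances (G^2), guarding against a
        component collapsing onto a single point.
    min_samples : int
        Minimum pool size accepted by :meth:`fit`.

    Attributes
    ----------
    mu_low_, sigma_low_, mu_high_, sigma_high_, w_high_ : float
        The five mixture features, labeled so ``mu_low_ <= mu_high_``.
    log_likelihood_ : float
        Total log-likelihood of the winning run.
    log_likelihood_trace_ : ndarray
        Mean per-sample log-likelihood after each EM iteration of the
        winning run (non-decreasing, up to floating-point error).
    n_iter_ : int
        Iterations used by the winning run.
    converged_ : bool
        Whether the winning run met ``tol`` before ``max_iter``.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 500, n_init: int = 10,
                 var_floor: float = 1e-6, min_samples: int = 100,
                 random_state: int = 0):
        self.tol = tol
        self.max_iter = max_iter
        self.n_init = n_init
        self.var_floor = var_floor
        self.min_samples = min_samples
        self.random_state = random_state

    # -- EM internals -------------------------------------------------------

    @staticmethod
    def _log_joint(x: np.ndarray, w, mu, var) -> np.ndarray:
        """log( w_k * N(x | mu_k, var_k) ), shape (n, 2)."""
        return (np.log(w) - 0.5 * (_LOG_2PI + np.log(var))
                - 0.5 * (x[:, None] - mu) ** 2 / var)

    def _run(self, x: np.ndarray, resp: np.ndarray):
        """One EM run from initial responsibilities; returns params + trace."""
        prev = -np.inf
        trace = []
        converged = False
        params = None
        r1 = resp[:, 1]
        n = len(x)
        for _ in range(self.max_iter):
            # M-step, specialized to two components on flat arrays
            n1 = float(r1.sum())
            n0 = n - n1
            if min(n0, n1) < 1e-10:
                return None  # component starved -> degenerate run
            r0 = 1.0 - r1
            mu0 = float((r0 * x).sum() / n0)
            mu1 = float((r1 * x).sum() / n1)
            var0 = max(float((r0 * (x - mu0) ** 2).sum() / n0), self.var_floor)
            var1 = max(float((r1 * (x - mu1) ** 2).sum() / n1), self.var_floor)
            w1 = n1 / n
            params = (np.array([1.0 - w1, w1]), np.array([mu0, mu1]),
                      np.array([var0, var1]))
            # E-step + log-likelihood
            lj0 = (np.log1p(-w1) - 0.5 * (_LOG_2PI + np.log(var0))
                   - 0.5 * (x - mu0) ** 2 / var0)
            lj1 = (np.log(w1) - 0.5 * (_LOG_2PI + np.log(var1))
                   - 0.5 * (x - mu1) ** 2 / var1)
            ln = np.logaddexp(lj0, lj1)
            mean_ll = float(ln.mean())
            trace.append(mean_ll)
            r1 = np.exp(lj1 - ln)
            if mean_ll - prev < self.tol:
                converged = True
                break
            prev = mean_ll
        return params, np.asarray(trace), converged

    def _initial_responsibilities(self, x: np.ndarray, rng: np.random.Generator,
                                  which: int) -> np.ndarray:
        n = len(x)
        if which == 0:  # deterministic median split
            hi = x > np.median(x)
            resp = np.column_stack([~hi, hi]).astype(float)
            # guard: constant pools put everything on one side
            if resp[:, 1].sum() in (0, n):
                resp = np.full((n, 2), 0.5)
            return resp
        u = rng.random(n)
        return np.column_stack([u, 1.0 - u])

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y=None) -> "IntensityMixture":
        x = np.asarray(X, dtype=float).ravel()
        if len(x) < self.min_samples:
            raise InsufficientDataError(
                f"mixture fit needs at least {self.min_samples} samples, "
                f"got {len(x)}"
            )
        if not np.isfinite(x).all():
            raise InsufficientDataError("pool contains non-finite values")
        rng = np.random.default_rng(self.random_state)
        best = None
        for i in range(self.n_init):
            out = self._run(x, self._initial_responsibilities(x, rng, i))
            if out is None:
                continue
            if best is None or out[1][-1] > best[1][-1]:
                best = out
        if best is None:
            raise DegenerateFitError(
                "every EM initialization collapsed onto a singular component"
            )
        (w, mu, var), trace, converged = best
        order = np.lexsort((np.sqrt(var), mu))  # mu ascending, sigma breaks ties
        mu, sd, w = mu[order], np.sqrt(var[order]), w[order]
        self.mu_low_, self.mu_high_ = float(mu[0]), float(mu[1])
        self.sigma_low_, self.sigma_high_ = float(sd[0]), float(sd[1])
        self.w_high_ = float(w[1])
        self.log_likelihood_ = float(trace[-1] * len(x))
        self.log_likelihood_trace_ = trace
        self.n_iter_ = len(trace)
        self.converged_ = bool(converged)
        self.n_samples_ = len(x)
        return self

    def score_samples(self, X) -> np.ndarray:
        """Per-sample log density under the fitted mixture."""
        check_is_fitted(self, "w_high_")
        x = np.asarray(X, dtype=float).ravel()
        w = np.array([1.0 - self.w_high_, self.w_high_])
        mu = np.array([self.mu_low_, self.mu_high_])
        var = np.array([self.sigma_low_, self.sigma_high_]) ** 2
        return logsumexp(self._log_joint(x, w, mu, var), axis=1)

    def score(self, X, y=None) -> float:
        return float(self.score_samples(X).mean())

    def to_fit(self) -> MixtureFit:
        check_is_fitted(self, "w_high_")
        return MixtureFit(
            mu_low=self.mu_low_, sigma_low=self.sigma_low_,
            mu_high=self.mu_high_, sigma_high=self.sigma_high_,
            w_high=self.w_high_, log_likelihood=self.log_likelihood_,
            n_iter=self.n_iter_, converged=self.converged_,
            n_samples=self.n_samples_, seed=int(self.random_state),
        )


def fit_gmm_em(pool, cfg: RunConfig | None = None) -> MixtureFit:
    """Fit the two-component mixture to a pooled index sample (EM, ML)."""
    cfg = cfg or RunConfig()
    est = IntensityMixture(tol=cfg.em_tol, max_iter=cfg.em_max_iter,
                           n_init=cfg.em_n_init, var_floor=cfg.em_var_floor,
                           min_samples=cfg.em_min_samples,
                           random_state=cfg.em_seed)
    return est.fit(pool).to_fit()
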