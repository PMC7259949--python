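"""Logistic mixed-effects regression via Laplace-approximated maximum
likelihood.

Supports the random structure used throughout the trial-wise analyses: a
per-participant random intercept plus an uncorrelated random slope of one
predictor.  For participant g with design row x, predictor z and random
effects b = (b0, b1), b0 ~ N(0, s0^2), b1 ~ N(0, s1^2) independent,

    P(y = 1) = logistic(x'beta + b0 + b1 * z).

The marginal log-likelihood integrates b out with a Laplace approximation
around the per-participant posterior mode (found by Newton's method); the
fixed effects and the log standard deviations are then maximised jointly
with L-BFGS-B.  Wald standard errors come from the numerical Hessian of
the Laplace log-likelihood over the fixed-effect block with the variance
parameters held at their estimates (the same convention as lme4's glmer).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

_LOG_SD_MIN = np.log(1e-4)
_LOG_SD_MAX = np.log(20.0)


def _expit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


@dataclass
class GLMMFit:
    beta: np.ndarray
    beta_se: np.ndarray
    sigmas: np.ndarray  # random-effect SDs (intercept[, slope])
    loglik: float
    converged: bool
    n_obs: int


class LogisticGLMM:
    """Laplace-ML logistic mixed model with diagonal random-effect covariance.

    Parameters
    ----------
    y : (n,) binary outcomes.
    X : (n, p) fixed-effect design (include the intercept column).
    Z : (n, d) random-effect design per observation; column 0 should be the
        constant 1 (random intercept), column 1 (optional) the predictor
        whose slope varies by participant.
    groups : (n,) participant labels.
    """

    def __init__(self, y, X, Z, groups):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        Z = np.asarray(Z, dtype=float)
        groups = np.asarray(groups)
        self.p = X.shape[1]
        self.d = Z.shape[1]
        self.n_obs = len(y)
        self._blocks = []
        for g in np.unique(groups):
            m = groups == g
            self._blocks.append((y[m], X[m], Z[m]))
        self._modes = [np.zeros(self.d) for _ in self._blocks]

    # -- inner problem: posterior mode of b for one participant ---------
    @staticmethod
    def _block_loglik(b, y, X, Z, beta, prec):
        eta = X @ beta + Z @ b
        # log Bernoulli likelihood, numerically safe
        ll = np.sum(y * eta - np.logaddexp(0.0, eta))
        return ll - 0.5 * b @ (prec * b)

    def _newton_mode(self, b, y, X, Z, beta, prec):
        xb = X @ beta
        for _ in range(100):
            eta = xb + Z @ b
            mu = _expit(eta)
            grad = Z.T @ (y - mu) - prec * b
            w = mu * (1.0 - mu)
            H = (Z * w[:, None]).T @ Z + np.diag(prec)
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:  # pragma: no cover
                step = grad / np.diag(H)
            # step-halving line search on the penalised loglik
            f0 = self._block_loglik(b, y, X, Z, beta, prec)
            t = 1.0
            for _ in range(30):
                b_new = b + t * step
                if self._block_loglik(b_new, y, X, Z, beta, prec) >= f0 - 1e-12:
                    break
                t *= 0.5
            b = b + t * step
            if np.max(np.abs(grad)) < 1e-9:
                break
        return b, H

    def loglik(self, beta, log_sd):
        """Laplace marginal log-likelihood at (beta, log random-effect SDs)."""
        sd = np.exp(np.asarray(log_sd, dtype=float))
        prec = 1.0 / sd**2
        total = 0.0
        for k, (y, X, Z) in enumerate(self._blocks):
            b, H = self._newton_mode(self._modes[k].copy(), y, X, Z, beta, prec)
            self._modes[k] = b
            sign, logdetH = np.linalg.slogdet(H)
            if sign <= 0:  # pragma: no cover - H is positive definite
                return -np.inf
            total += (
                self._block_loglik(b, y, X, Z, beta, prec)
                - np.sum(np.log(sd))
                - 0.5 * logdetH
            )
        return total

    def fit(self, start_beta=None) -> GLMMFit:
        p, d = self.p, self.d
        beta0 = np.zeros(p) if start_beta is None else np.asarray(start_beta, float)
        x0 = np.concatenate([beta0, np.full(d, np.log(0.3))])

        def nll(params):
            val = self.loglik(params[:p], params[p:])
            return -val if np.isfinite(val) else 1e10

        bounds = [(None, None)] * p + [(_LOG_SD_MIN, _LOG_SD_MAX)] * d
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7},
        )
        beta = res.x[:p]
        log_sd = res.x[p:]
        ll = -res.fun

        # Wald covariance: numerical Hessian over the fixed-effect block
        def nll_beta(b):
            return -self.loglik(b, log_sd)

        H = _numerical_hessian(nll_beta, beta)
        try:
            cov = np.linalg.inv(H)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:  # pragma: no cover
            se = np.full(p, np.nan)
        return GLMMFit(
            beta=beta,
            beta_se=se,
            sigmas=np.exp(log_sd),
            loglik=float(ll),
            converged=bool(res.success),
            n_obs=self.n_obs,
        )


def _numerical_hessian(f, x, rel_step=1e-4):
    """Central-difference Hessian of scalar f at x."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            if i == j:
                val = (f(x + ei) - 2.0 * f0 + f(x - ei)) / (h[i] ** 2)
            else:
                val = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4.0 * h[i] * h[j])
            H[i, j] = H[j, i] = val
    return H
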