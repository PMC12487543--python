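"""Negative binomial mixed model: NB2 likelihood, city random intercept,
log person-years offset, adaptive Gauss-Hermite quadrature, cluster-robust
(sandwich) variance.

The marginal log-likelihood for city c with strata i is

    log L_c = log \\int prod_i NB2(y_ci | mu_ci = exp(x_ci' b + off_ci + u),
                                   alpha) phi(u; 0, sigma^2) du,

where NB2 has Var = mu + alpha mu^2.  The integral is evaluated by
Gauss-Hermite quadrature adapted per city: nodes are centered at the
empirical-Bayes mode of the integrand and scaled by its curvature, which
keeps a 15-node rule accurate even for cities with thousands of deaths.
The score is the posterior expectation of the complete-data score at the
same nodes, and the observed information follows Louis' identity
(E[complete Hessian] + posterior variance of the complete score), so no
numerical differentiation is needed.  Optimization is deterministic
quasi-Newton on (beta, log alpha, log sigma).

The cluster-robust variance is the sandwich A^{-1} B A^{-1} with A the
observed information of the marginal likelihood and B the outer product of
per-city marginal scores, times the finite-cluster factor g/(g-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

_LOG2PI = np.log(2.0 * np.pi)


def _check_design(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pivoted QR identifies which columns are aliased
        from scipy.linalg import qr
        _, r, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        aliased = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        aliased += [names[j] for j in piv[len(diag):]]
        raise ValueError(f"design matrix is rank deficient; aliased columns: "
                         f"{sorted(set(aliased))}")


@dataclass
class NBMixedResult:
    """Fitted NB mixed model with model-based and cluster-robust covariances."""

    params: np.ndarray            # [beta..., log_alpha, log_sigma]
    exog_names: list[str]
    llf: float
    start_llf: float
    converged: bool
    n_iter: int
    grad_norm: float
    cov_model: np.ndarray         # for [beta..., log_alpha, log_sigma]
    cov_robust: np.ndarray
    n_obs: int
    n_groups: int
    message: str = ""

    @property
    def beta(self) -> pd.Series:
        return pd.Series(self.params[:-2], index=self.exog_names)

    @property
    def alpha(self) -> float:
        return float(np.exp(self.params[-2]))

    @property
    def sigma2(self) -> float:
        return float(np.exp(self.params[-1]) ** 2)

    def se(self, mode: str = "robust") -> pd.Series:
        cov = self.cov_robust if mode == "robust" else self.cov_model
        return pd.Series(np.sqrt(np.diag(cov)[:-2]), index=self.exog_names)

    def rate_ratios(self, mode: str = "robust") -> pd.DataFrame:
        se = self.se(mode)
        lo = self.beta - 1.96 * se
        hi = self.beta + 1.96 * se
        return pd.DataFrame({"rr": np.exp(self.beta), "ci_low": np.exp(lo),
                             "ci_high": np.exp(hi), "log_rr": self.beta,
                             "se": se})


class NBMixedModel:
    """NB2 regression with a cluster random intercept and offset.

    Parameters
    ----------
    y : counts per stratum
    X : design matrix (include the constant explicitly)
    offset : log exposure (log corrected person-years); must be finite
    groups : cluster labels (the city of each stratum)
    n_quad : Gauss-Hermite nodes (default 15, mode-adapted)
    """

    def __init__(self, y, X, offset, groups, exog_names=None, n_quad: int = 15):
        y = np.asarray(y, float)
        X = np.asarray(X, float)
        offset = np.asarray(offset, float)
        if not np.all(np.isfinite(offset)):
            raise ValueError("offset must be finite; drop zero-exposure strata")
        if np.any(y < 0):
            raise ValueError("negative counts")
        groups = np.asarray(groups)
        order = np.argsort(groups, kind="mergesort")
        self._order = order
        self.y = y[order]
        self.X = X[order]
        self.offset = offset[order]
        g_sorted = groups[order]
        self.group_labels, self.gidx = np.unique(g_sorted, return_inverse=True)
        self.n_groups = len(self.group_labels)
        self.n_obs = len(self.y)
        self.exog_names = (list(exog_names) if exog_names is not None
                           else [f"x{j}" for j in range(X.shape[1])])
        _check_design(self.X, self.exog_names)
        self.n_quad = n_quad
        self._z, self._w = np.polynomial.hermite.hermgauss(n_quad)
        self._logw = np.log(self._w)
        self._b_cache = np.zeros(self.n_groups)

    # ----- building blocks ------------------------------------------------

    def _groupsum(self, arr: np.ndarray) -> np.ndarray:
        """Sum rows within each group; works on 1-D or 2-D (n, K) arrays."""
        if arr.ndim == 1:
            return np.bincount(self.gidx, weights=arr, minlength=self.n_groups)
        out = np.empty((self.n_groups, arr.shape[1]))
        for k in range(arr.shape[1]):
            out[:, k] = np.bincount(self.gidx, weights=arr[:, k],
                                    minlength=self.n_groups)
        return out

    def _nb_const(self, theta: float) -> np.ndarray:
        return (special.gammaln(self.y + theta) - special.gammaln(theta)
                - special.gammaln(self.y + 1.0) + theta * np.log(theta))

    def _find_modes(self, eta: np.ndarray, alpha: float, sig2: float,
                    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-city mode and curvature of the log integrand (concave in b)."""
        b = self._b_cache.copy()
        for _ in range(100):
            mu = np.exp(eta + b[self.gidx])
            u = (self.y - mu) / (1.0 + alpha * mu)
            g1 = self._groupsum(u) - b / sig2
            w = mu * (1.0 + alpha * self.y) / (1.0 + alpha * mu) ** 2
            h = self._groupsum(w) + 1.0 / sig2
            step = np.clip(g1 / h, -4.0, 4.0)
            b = b + step
            if np.max(np.abs(step)) < 1e-11:
                break
        mu = np.exp(eta + b[self.gidx])
        w = mu * (1.0 + alpha * self.y) / (1.0 + alpha * mu) ** 2
        h = self._groupsum(w) + 1.0 / sig2
        self._b_cache = b.copy()
        return b, h

    def _unpack(self, params):
        beta = np.asarray(params[:-2], float)
        alpha = float(np.exp(params[-2]))
        sigma = float(np.exp(params[-1]))
        return beta, alpha, sigma

    # ----- likelihood, score, information ---------------------------------

    def loglike(self, params) -> float:
        return self._eval(params, want_score=False)[0]

    def score(self, params) -> np.ndarray:
        return self._eval(params, want_score=True)[1]

    def _eval(self, params, want_score: bool):
        beta, alpha, sigma = self._unpack(params)
        eta = self.X @ beta + self.offset
        if sigma == 0.0:
            return self._eval_sigma0(eta, alpha, want_score)
        sig2 = sigma * sigma
        theta = 1.0 / alpha
        bhat, h = self._find_modes(eta, alpha, sig2)
        tau = 1.0 / np.sqrt(h)
        # nodes per city and per row
        bn_c = bhat[:, None] + np.sqrt(2.0) * tau[:, None] * self._z[None, :]
        bn = bn_c[self.gidx]                                   # (n, K)
        log_mu = eta[:, None] + bn
        mu = np.exp(log_mu)
        log_thmu = np.log(theta + mu)
        const = self._nb_const(theta)
        ll = (const[:, None] + self.y[:, None] * log_mu
              - (theta + self.y)[:, None] * log_thmu)
        S = self._groupsum(ll)                                  # (G, K)
        prior = -0.5 * bn_c ** 2 / sig2
        core = self._logw[None, :] + self._z[None, :] ** 2 + S + prior
        m = core.max(axis=1, keepdims=True)
        sumexp = np.exp(core - m).sum(axis=1)
        logL_c = (m[:, 0] + np.log(sumexp) + 0.5 * np.log(2.0) + np.log(tau)
                  - np.log(sigma) - 0.5 * _LOG2PI)
        llf = float(logL_c.sum())
        if not np.isfinite(llf):
            bad = self.group_labels[~np.isfinite(logL_c)]
            raise FloatingPointError(
                f"non-finite marginal likelihood for clusters {list(bad[:5])}")
        if not want_score:
            return llf, None
        pi = np.exp(core - m - np.log(sumexp)[:, None])         # (G, K)
        pi_r = pi[self.gidx]                                    # (n, K)
        u = (self.y[:, None] - mu) / (1.0 + alpha * mu)
        v = (pi_r * u).sum(axis=1)
        g_beta = self.X.T @ v
        dldth_k = (-log_thmu - (theta + self.y)[:, None] / (theta + mu))
        dldth_0 = (special.digamma(self.y + theta) - special.digamma(theta)
                   + np.log(theta) + 1.0)
        dla = -theta * (dldth_0[:, None] + dldth_k)             # d ll / d log(alpha)
        g_la = float((pi_r * dla).sum())
        g_ls = float((pi * (bn_c ** 2 / sig2 - 1.0)).sum())
        grad = np.concatenate([g_beta, [g_la, g_ls]])
        return llf, grad

    def _eval_sigma0(self, eta, alpha, want_score):
        theta = 1.0 / alpha
        mu = np.exp(eta)
        ll = (self._nb_const(theta) + self.y * np.log(mu)
              - (theta + self.y) * np.log(theta + mu))
        llf = float(ll.sum())
        if not want_score:
            return llf, None
        u = (self.y - mu) / (1.0 + alpha * mu)
        dldth = (special.digamma(self.y + theta) - special.digamma(theta)
                 + np.log(theta) + 1.0 - np.log(theta + mu)
                 - (theta + self.y) / (theta + mu))
        grad = np.concatenate([self.X.T @ u, [-theta * dldth.sum()], [0.0]])
        return llf, grad

    def _information(self, params):
        """Observed information (Louis) and per-cluster marginal scores."""
        beta, alpha, sigma = self._unpack(params)
        eta = self.X @ beta + self.offset
        sig2 = max(sigma * sigma, 1e-300)
        theta = 1.0 / alpha
        p = self.X.shape[1]
        dim = p + 2
        bhat, h = self._find_modes(eta, alpha, sig2)
        tau = 1.0 / np.sqrt(h)
        bn_c = bhat[:, None] + np.sqrt(2.0) * tau[:, None] * self._z[None, :]
        bn = bn_c[self.gidx]
        mu = np.exp(eta[:, None] + bn)
        const = self._nb_const(theta)
        ll = (const[:, None] + self.y[:, None] * np.log(mu)
              - (theta + self.y)[:, None] * np.log(theta + mu))
        S = self._groupsum(ll)
        prior = -0.5 * bn_c ** 2 / sig2
        core = self._logw[None, :] + self._z[None, :] ** 2 + S + prior
        m = core.max(axis=1, keepdims=True)
        pi = np.exp(core - m)
        pi /= pi.sum(axis=1, keepdims=True)                     # (G, K)
        pi_r = pi[self.gidx]

        u = (self.y[:, None] - mu) / (1.0 + alpha * mu)
        dldth_k = (-np.log(theta + mu) - (theta + self.y)[:, None] / (theta + mu))
        dldth_0 = (special.digamma(self.y + theta) - special.digamma(theta)
                   + np.log(theta) + 1.0)
        dldth = dldth_0[:, None] + dldth_k
        dla = -theta * dldth
        msig = bn_c ** 2 / sig2 - 1.0                           # (G, K)

        # per-city per-node complete-data scores s_ck (dim,)
        K = self.n_quad
        s_nodes = np.empty((self.n_groups, K, dim))
        for k in range(K):
            s_nodes[:, k, :p] = self._groupsum(u[:, k][:, None] * self.X)
            s_nodes[:, k, p] = self._groupsum(dla[:, k])
        s_nodes[:, :, p + 1] = msig

        s_mean = (pi[:, :, None] * s_nodes).sum(axis=1)         # (G, dim)
        e_ssT = np.einsum("gk,gki,gkj->gij", pi, s_nodes, s_nodes)
        var_s = e_ssT - np.einsum("gi,gj->gij", s_mean, s_mean)

        # E[complete Hessian]
        w2 = mu * (1.0 + alpha * self.y)[:, None] / (1.0 + alpha * mu) ** 2
        d_beta = (pi_r * w2).sum(axis=1)
        H_bb = -(self.X.T * d_beta) @ self.X
        du_dla = -alpha * (self.y[:, None] - mu) * mu / (1.0 + alpha * mu) ** 2
        H_bla = self.X.T @ (pi_r * du_dla).sum(axis=1)
        d2ldth2 = (special.polygamma(1, self.y[:, None] + theta)
                   - special.polygamma(1, theta) + 1.0 / theta
                   - 2.0 / (theta + mu)
                   + (theta + self.y)[:, None] / (theta + mu) ** 2)
        d2_la = theta * dldth + theta ** 2 * d2ldth2
        H_lala = float((pi_r * d2_la).sum())
        H_lsls = float((pi * (-2.0 * bn_c ** 2 / sig2)).sum())

        H = np.zeros((dim, dim))
        H[:p, :p] = H_bb
        H[:p, p] = H[p, :p] = H_bla
        H[p, p] = H_lala
        H[p + 1, p + 1] = H_lsls
        H += var_s.sum(axis=0)
        A = -(H + H.T) / 2.0
        return A, s_mean

    # ----- fitting --------------------------------------------------------

    def _start_params(self):
        import statsmodels.api as sm
        try:
            nb = sm.NegativeBinomial(self.y, self.X, offset=self.offset)
            res = nb.fit(disp=0, maxiter=200)
            beta0 = res.params[:-1]
            alpha0 = max(float(res.params[-1]), 1e-3)
            if not np.all(np.isfinite(beta0)):
                raise ValueError
        except Exception:
            pois = sm.GLM(self.y, self.X, offset=self.offset,
                          family=sm.families.Poisson()).fit()
            beta0 = pois.params
            mu = pois.mu
            resid2 = (self.y - mu) ** 2 - mu
            denom = float((mu ** 2).sum())
            alpha0 = max(float(resid2.sum() / denom) if denom > 0 else 0.1, 1e-3)
        return np.concatenate([beta0, [np.log(alpha0), np.log(0.2)]])

    def fit(self, start_params=None, maxiter: int = 500, gtol: float = 1e-6,
            ftol: float = 1e-9, sigma_fixed: float | None = None,
            ) -> NBMixedResult:
        """Maximize the marginal likelihood; deterministic given the data.

        On line-search failure the optimizer restarts once from a fixed
        perturbation of the start; the better of the two solutions is kept
        and convergence diagnostics are carried in the result.
        ``sigma_fixed=0`` enforces no random effect (plain fixed-effects NB2).
        """
        if sigma_fixed is not None:
            if sigma_fixed != 0:
                raise NotImplementedError("only sigma_fixed=0 is supported")
            return self._fit_sigma0(start_params, maxiter, gtol, ftol)
        x0 = np.asarray(start_params, float) if start_params is not None \
            else self._start_params()
        bounds = [(None, None)] * self.X.shape[1] + \
            [(-12.0, 5.0), (np.log(1e-3), 2.0)]
        x0 = np.clip(x0, [b[0] if b[0] is not None else -np.inf for b in bounds],
                     [b[1] if b[1] is not None else np.inf for b in bounds])
        start_llf = self.loglike(x0)

        def negll(x):
            f, g = self._eval(x, want_score=True)
            return -f, -g

        best = None
        for attempt, xs in enumerate([x0, x0 + np.concatenate(
                [np.zeros(self.X.shape[1]), [0.3, 0.3]])]):
            self._b_cache = np.zeros(self.n_groups)
            opt = optimize.minimize(negll, xs, jac=True, method="L-BFGS-B",
                                    bounds=bounds,
                                    options={"maxiter": maxiter, "ftol": ftol,
                                             "gtol": gtol})
            if best is None or -opt.fun > -best.fun:
                best = opt
            if opt.success and -opt.fun >= start_llf - 1e-6:
                break
        opt = best
        params = opt.x
        llf = -float(opt.fun)
        grad_norm = float(np.max(np.abs(opt.jac)))
        converged = bool(opt.success) and llf >= start_llf - 1e-6
        A, s_c = self._information(params)
        cov_model = _safe_inv(A)
        g = self.n_groups
        if g < 2:
            raise ValueError("cluster-robust variance needs >= 2 clusters")
        B = s_c.T @ s_c * (g / (g - 1.0))
        cov_robust = cov_model @ B @ cov_model
        cov_robust = (cov_robust + cov_robust.T) / 2.0
        return NBMixedResult(
            params=params, exog_names=self.exog_names, llf=llf,
            start_llf=float(start_llf), converged=converged,
            n_iter=int(opt.nit), grad_norm=grad_norm,
            cov_model=(cov_model + cov_model.T) / 2.0, cov_robust=cov_robust,
            n_obs=self.n_obs, n_groups=g, message=str(opt.message))


    def _fit_sigma0(self, start_params, maxiter, gtol, ftol) -> NBMixedResult:
        p = self.X.shape[1]
        x0 = np.asarray(start_params, float)[:p + 1] if start_params is not None \
            else self._start_params()[:p + 1]

        def negll(x):
            full = np.concatenate([x, [-np.inf]])
            beta, alpha, _ = self._unpack(np.concatenate([x, [0.0]]))
            eta = self.X @ beta + self.offset
            f, g = self._eval_sigma0(eta, alpha, want_score=True)
            return -f, -g[:-1]

        start_llf = -negll(x0)[0]
        bounds = [(None, None)] * p + [(-12.0, 5.0)]
        opt = optimize.minimize(negll, x0, jac=True, method="L-BFGS-B",
                                bounds=bounds,
                                options={"maxiter": maxiter, "ftol": ftol,
                                         "gtol": gtol})
        params = np.concatenate([opt.x, [np.log(1e-300)]])
        beta, alpha, _ = self._unpack(np.concatenate([opt.x, [0.0]]))
        eta = self.X @ beta + self.offset
        theta = 1.0 / alpha
        mu = np.exp(eta)
        # observed information of the fixed-effects NB2 (analytic)
        w2 = mu * (1.0 + alpha * self.y) / (1.0 + alpha * mu) ** 2
        H_bb = -(self.X.T * w2) @ self.X
        u = (self.y - mu) / (1.0 + alpha * mu)
        du_dla = -alpha * (self.y - mu) * mu / (1.0 + alpha * mu) ** 2
        H_bla = self.X.T @ du_dla
        dldth = (special.digamma(self.y + theta) - special.digamma(theta)
                 + np.log(theta) + 1.0 - np.log(theta + mu)
                 - (theta + self.y) / (theta + mu))
        d2ldth2 = (special.polygamma(1, self.y + theta)
                   - special.polygamma(1, theta) + 1.0 / theta
                   - 2.0 / (theta + mu) + (theta + self.y) / (theta + mu) ** 2)
        d2_la = theta * dldth + theta ** 2 * d2ldth2
        dim = p + 2
        A = np.zeros((dim, dim))
        A[:p, :p] = -H_bb
        A[:p, p] = A[p, :p] = -H_bla
        A[p, p] = -float(d2_la.sum())
        A[p + 1, p + 1] = 1.0      # placeholder row for the absent log sigma
        cov_model = _safe_inv(A)
        cov_model[p + 1, p + 1] = 0.0
        scores = np.column_stack([
            np.column_stack([self._groupsum(u[:, None] * self.X)]),
            self._groupsum(-theta * dldth),
            np.zeros(self.n_groups)])
        g = self.n_groups
        if g < 2:
            raise ValueError("cluster-robust variance needs >= 2 clusters")
        B = scores.T @ scores * (g / (g - 1.0))
        cov_robust = cov_model @ B @ cov_model
        return NBMixedResult(
            params=params, exog_names=self.exog_names, llf=-float(opt.fun),
            start_llf=float(start_llf), converged=bool(opt.success),
            n_iter=int(opt.nit), grad_norm=float(np.max(np.abs(opt.jac))),
            cov_model=(cov_model + cov_model.T) / 2.0,
            cov_robust=(cov_robust + cov_robust.T) / 2.0,
            n_obs=self.n_obs, n_groups=g, message=str(opt.message))


def _safe_inv(A: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(A)


def marginal_loglik(y, X, offset, groups, beta, alpha, sigma,
                    n_quad: int = 15) -> float:
    """Marginal log-likelihood at given parameters.

    ``sigma = 0`` collapses exactly to the sum of NB2 log-pmfs.
    """
    model = NBMixedModel(y, X, offset, groups, n_quad=n_quad)
    params = np.concatenate([np.asarray(beta, float),
                             [np.log(alpha),
                              np.log(sigma) if sigma > 0 else -np.inf]])
    if sigma == 0:
        b, a = np.asarray(beta, float), float(alpha)
        eta = model.X @ b + model.offset
        return model._eval_sigma0(eta, a, want_score=False)[0]
    return model.loglike(params)


def fit_nb_mixed(y, X, offset, groups, exog_names=None, n_quad: int = 15,
                 start_params=None) -> NBMixedResult:
    """Convenience wrapper: construct and fit the mixed model."""
    return NBMixedModel(y, X, offset, groups, exog_names=exog_names,
                        n_quad=n_quad).fit(start_params=start_params)


def robust_variance(result: NBMixedResult) -> np.ndarray:
    """The cluster-robust (sandwich) covariance computed at fit time."""
    return result.cov_robust
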