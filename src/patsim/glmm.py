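"""Logistic mixed-effects models by Laplace-approximate maximum likelihood.

``LogisticGLMM`` fits binary-outcome models with subject-level random
effects, the model family behind trial-wise memory analyses::

    logit P(y_ij = 1) = x_ij' beta + z_ij' b_i,   b_i ~ N(0, Sigma)

The marginal likelihood integrates the random effects per subject; the
integral is approximated by Laplace's method around the per-subject joint
mode (found by damped Newton iterations, vectorized across subjects).  The
random-effect covariance is parameterized through the log-Cholesky factor,
keeping it positive semi-definite.  Wald standard errors for the fixed
effects come from the observed information of the Laplace log-likelihood at
the estimated covariance (the convention of the standard mixed-model
packages this mirrors).

Non-convergence triggers an automatic fallback ladder (full covariance ->
diagonal -> random intercept only), and complete separation triggers a
Firth-penalized fixed-effects fit; both are recorded on the results object.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, stats

__all__ = ["LogisticGLMM", "LogisticGLMMResults", "firth_logistic"]

_SEPARATION_BOUND = 15.0  # |log-odds| beyond this signals separation
_LADDER = ("full", "diagonal", "intercept")


def _sigmoid(eta):
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _bernoulli_ll(y, eta, w):
    # numerically stable sum of y*eta - log(1 + exp(eta)) over valid entries
    return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))


def plain_logistic(X, y, maxiter=100, tol=1e-10):
    """ML logistic regression via damped Newton with a tiny ridge."""
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        eta = X @ beta
        mu = _sigmoid(eta)
        grad = X.T @ (y - mu)
        W = mu * (1.0 - mu)
        H = X.T @ (X * W[:, None]) + 1e-10 * np.eye(X.shape[1])
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(grad)) < tol:
            break
    return beta


def firth_logistic(X, y, maxiter=100, tol=1e-8):
    """Firth-penalized logistic regression (Jeffreys-prior score adjustment).

    Finite estimates exist even under complete separation.  Returns
    (beta, cov).
    """
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(maxiter):
        mu = _sigmoid(X @ beta)
        W = mu * (1.0 - mu)
        XW = X * W[:, None]
        info = X.T @ XW + 1e-12 * np.eye(p)
        info_inv = np.linalg.inv(info)
        # hat diagonal of W^(1/2) X (X'WX)^-1 X' W^(1/2)
        h = np.einsum("ij,jk,ik->i", XW, info_inv, X)
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(score)) < tol:
            break
    mu = _sigmoid(X @ beta)
    W = mu * (1.0 - mu)
    cov = np.linalg.inv(X.T @ (X * W[:, None]) + 1e-12 * np.eye(p))
    return beta, cov


def _theta_size(q, structure):
    return {"full": q + q * (q - 1) // 2, "diagonal": q, "intercept": 1}[structure]


def _chol_from_theta(theta, q, structure):
    L = np.zeros((q, q))
    if structure == "full":
        L[np.diag_indices(q)] = np.exp(theta[:q])
        if q > 1:
            L[np.tril_indices(q, -1)] = theta[q:]
    else:  # diagonal / intercept (q == 1 for intercept)
        L[np.diag_indices(q)] = np.exp(theta)
    return L


class LogisticGLMM:
    """Binary-outcome mixed model with subject-level random effects.

    Parameters
    ----------
    endog : (n,) 0/1 outcomes.
    exog : (n, p) fixed-effects design.
    groups : (n,) subject labels.
    exog_re : (n, q) random-effects design (defaults to an intercept).
    """

    def __init__(self, endog, exog, groups, exog_re=None,
                 exog_names=None, exog_re_names=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        self.groups = np.asarray(groups)
        n = self.endog.size
        if self.exog.shape[0] != n or self.groups.size != n:
            raise ValueError("endog, exog and groups must have matching length")
        if exog_re is None:
            exog_re = np.ones((n, 1))
        self.exog_re = np.asarray(exog_re, dtype=float)
        if self.exog_re.shape[0] != n:
            raise ValueError("exog_re length mismatch")
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{j}" for j in range(self.exog.shape[1])
        ]
        self.exog_re_names = list(exog_re_names) if exog_re_names is not None else [
            f"re{j}" for j in range(self.exog_re.shape[1])
        ]
        self._build_padded()

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame) -> "LogisticGLMM":
        """Build from an lme4-style formula, e.g.
        ``"outcome ~ age * cat_spec + resp_bias + (1 + cat_spec | subject)"``.
        """
        m = re.search(r"\(([^|]+)\|\s*([\w.]+)\s*\)", formula)
        if m is None:
            raise ValueError("formula needs a random part '(terms | group)'")
        re_formula, group_var = m.group(1).strip(), m.group(2)
        fixed = re.sub(r"[-+]?\s*\(([^|]+)\|\s*[\w.]+\s*\)", "", formula).strip()
        fixed = re.sub(r"[+\s]+$", "", fixed)
        fixed = re.sub(r"~\s*\+", "~ ", fixed)
        if fixed.rstrip().endswith("~"):
            fixed += " 1"
        y, X = patsy.dmatrices(fixed, data, return_type="dataframe")
        Z = patsy.dmatrix("1 + " + re_formula if not re_formula.startswith("0")
                          else re_formula, data, return_type="dataframe")
        keep = ~(X.isna().any(axis=1) | y.iloc[:, 0].isna() | Z.isna().any(axis=1))
        return cls(
            endog=y.loc[keep].to_numpy().ravel(),
            exog=X.loc[keep].to_numpy(),
            groups=data.loc[keep.index[keep], group_var].to_numpy(),
            exog_re=Z.loc[keep].to_numpy(),
            exog_names=list(X.columns),
            exog_re_names=list(Z.columns),
        )

    # -- internal machinery ------------------------------------------------

    def _build_padded(self):
        labels, inv = np.unique(self.groups, return_inverse=True)
        self.group_labels = labels
        m = labels.size
        counts = np.bincount(inv)
        nmax = counts.max()
        p = self.exog.shape[1]
        q = self.exog_re.shape[1]
        self._Y = np.zeros((m, nmax))
        self._W = np.zeros((m, nmax))
        self._Xf = np.zeros((m, nmax, p))
        self._Z = np.zeros((m, nmax, q))
        pos = np.zeros(m, dtype=int)
        for i, g in enumerate(inv):
            j = pos[g]
            self._Y[g, j] = self.endog[i]
            self._W[g, j] = 1.0
            self._Xf[g, j] = self.exog[i]
            self._Z[g, j] = self.exog_re[i]
            pos[g] += 1
        self.n_groups = m
        self.p = p
        self.q_full = q

    def _neg_marginal_ll(self, beta, theta, structure, bhat):
        """Negative Laplace log marginal likelihood; updates bhat in place."""
        q = 1 if structure == "intercept" else self.q_full
        Z = self._Z[:, :, :q]
        L = _chol_from_theta(theta, q, structure)
        diag = np.diag(L).copy()
        if np.any(diag < 1e-8):
            diag = np.maximum(diag, 1e-8)
            L = L.copy()
            L[np.diag_indices(q)] = diag
        Sigma = L @ L.T
        Sigma_inv = np.linalg.inv(Sigma + 1e-12 * np.eye(q))
        logdet_sigma = 2.0 * np.sum(np.log(diag))
        eta0 = np.einsum("mnp,p->mn", self._Xf, beta)
        b = bhat[:, :q]
        # damped Newton for the per-subject joint modes, vectorized
        for _ in range(100):
            eta = eta0 + np.einsum("mnq,mq->mn", Z, b)
            mu = _sigmoid(eta)
            resid = self._W * (self._Y - mu)
            grad = np.einsum("mnq,mn->mq", Z, resid) - b @ Sigma_inv
            w = self._W * mu * (1.0 - mu)
            H = np.einsum("mnq,mn,mnr->mqr", Z, w, Z) + Sigma_inv[None]
            step = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
            gmax = np.max(np.abs(grad))
            # per-subject step halving on the penalized objective
            scale = np.ones(self.n_groups)
            f0 = self._penalized(eta0, Z, b, Sigma_inv)
            for _ in range(25):
                b_new = b + scale[:, None] * step
                f1 = self._penalized(eta0, Z, b_new, Sigma_inv)
                bad = f1 < f0 - 1e-12
                if not np.any(bad):
                    break
                scale[bad] *= 0.5
            b = b + scale[:, None] * step
            if gmax < 1e-9:
                break
        bhat[:, :q] = b
        eta = eta0 + np.einsum("mnq,mq->mn", Z, b)
        mu = _sigmoid(eta)
        ll = np.sum(
            self._W * (self._Y * eta - np.logaddexp(0.0, eta)), axis=1
        )
        quad = np.einsum("mq,qr,mr->m", b, Sigma_inv, b)
        w = self._W * mu * (1.0 - mu)
        H = np.einsum("mnq,mn,mnr->mqr", Z, w, Z) + Sigma_inv[None]
        sign, logdet_H = np.linalg.slogdet(H)
        logmarg = ll - 0.5 * quad - 0.5 * logdet_sigma - 0.5 * logdet_H
        return -float(np.sum(logmarg))

    def _penalized(self, eta0, Z, b, Sigma_inv):
        eta = eta0 + np.einsum("mnq,mq->mn", Z, b)
        ll = np.sum(self._W * (self._Y * eta - np.logaddexp(0.0, eta)), axis=1)
        return ll - 0.5 * np.einsum("mq,qr,mr->m", b, Sigma_inv, b)

    def _fit_one(self, structure, start_beta, maxiter, gtol):
        q = 1 if structure == "intercept" else self.q_full
        tsize = _theta_size(q, structure)
        theta0 = np.concatenate([
            np.full(q, np.log(0.5)), np.zeros(tsize - q)
        ]) if structure == "full" else np.full(tsize, np.log(0.5))
        x0 = np.concatenate([start_beta, theta0])
        bhat = np.zeros((self.n_groups, self.q_full))

        def objective(x):
            return self._neg_marginal_ll(
                x[: self.p], x[self.p:], structure, bhat
            )

        bounds = [(None, None)] * self.p
        if structure == "full":
            bounds += [(-6.0, 4.0)] * q + [(-10.0, 10.0)] * (tsize - q)
        else:
            bounds += [(-6.0, 4.0)] * tsize
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": gtol},
        )
        return res, structure, bhat

    def _beta_cov(self, res, structure):
        """Observed information over beta at the estimated covariance."""
        x = res.x
        bhat = np.zeros((self.n_groups, self.q_full))

        def f(beta):
            return self._neg_marginal_ll(beta, x[self.p:], structure, bhat)

        p = self.p
        beta = x[:p].copy()
        h = 1e-4 * (1.0 + np.abs(beta))
        H = np.zeros((p, p))
        f0 = f(beta)
        for i in range(p):
            for j in range(i, p):
                bpp = beta.copy(); bpp[i] += h[i]; bpp[j] += h[j]
                bpm = beta.copy(); bpm[i] += h[i]; bpm[j] -= h[j]
                bmp = beta.copy(); bmp[i] -= h[i]; bmp[j] += h[j]
                bmm = beta.copy(); bmm[i] -= h[i]; bmm[j] -= h[j]
                H[i, j] = H[j, i] = (
                    f(bpp) - f(bpm) - f(bmp) + f(bmm)
                ) / (4.0 * h[i] * h[j])
        try:
            cov = np.linalg.inv(H)
            if np.any(np.diag(cov) <= 0):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H + 1e-6 * np.eye(p))
            cov = np.abs(cov)
        return cov, f0

    def fit(self, re_structure: str = "full", maxiter: int = 200,
            gtol: float = 1e-6, ladder: bool = True) -> "LogisticGLMMResults":
        """Fit by Laplace ML, walking the fallback ladder on non-convergence.

        re_structure: 'full', 'diagonal', 'intercept', or 'none' (ordinary
        logistic regression on the pooled data).
        """
        start_beta = plain_logistic(self.exog, self.endog)
        if re_structure == "none":
            return self._fit_fixed_only(start_beta)
        if np.max(np.abs(start_beta)) > _SEPARATION_BOUND:
            warnings.warn("complete separation detected; Firth fallback")
            return self._fit_firth()
        rungs = _LADDER[_LADDER.index(re_structure):] if ladder else (re_structure,)
        if self.q_full == 1:
            rungs = tuple(r for r in rungs if r == "intercept") or ("intercept",)
        last = None
        for structure in rungs:
            res, structure, bhat = self._fit_one(structure, start_beta, maxiter, gtol)
            converged = bool(res.success) or (
                np.max(np.abs(res.jac)) < 1e-2 if res.jac is not None else False
            )
            last = (res, structure, bhat, converged)
            if converged:
                break
            warnings.warn(
                f"Laplace fit did not converge with {structure!r} covariance;"
                " falling back"
            )
        res, structure, bhat, converged = last
        beta = res.x[: self.p]
        if np.max(np.abs(beta)) > _SEPARATION_BOUND:
            warnings.warn("separation in mixed fit; Firth fallback")
            return self._fit_firth()
        cov_beta, nll = self._beta_cov(res, structure)
        q = 1 if structure == "intercept" else self.q_full
        L = _chol_from_theta(res.x[self.p:], q, structure)
        cov_re = L @ L.T
        return LogisticGLMMResults(
            model=self,
            params=beta,
            cov_params=cov_beta,
            cov_re=cov_re,
            re_names=self.exog_re_names[:q],
            llf=-nll,
            converged=converged,
            re_structure_used=structure,
            random_modes=bhat[:, :q],
        )

    def _fit_fixed_only(self, start_beta):
        beta = plain_logistic(self.exog, self.endog)
        if np.max(np.abs(beta)) > _SEPARATION_BOUND:
            warnings.warn("complete separation detected; Firth fallback")
            return self._fit_firth()
        mu = _sigmoid(self.exog @ beta)
        W = mu * (1.0 - mu)
        cov = np.linalg.inv(self.exog.T @ (self.exog * W[:, None]))
        llf = _bernoulli_ll(self.endog, self.exog @ beta, np.ones_like(self.endog))
        return LogisticGLMMResults(
            model=self, params=beta, cov_params=cov,
            cov_re=np.zeros((0, 0)), re_names=[], llf=llf,
            converged=True, re_structure_used="none",
            random_modes=np.zeros((self.n_groups, 0)),
        )

    def _fit_firth(self):
        beta, cov = firth_logistic(self.exog, self.endog)
        llf = _bernoulli_ll(self.endog, self.exog @ beta, np.ones_like(self.endog))
        return LogisticGLMMResults(
            model=self, params=beta, cov_params=cov,
            cov_re=np.zeros((0, 0)), re_names=[], llf=llf,
            converged=True, re_structure_used="firth", separation=True,
            random_modes=np.zeros((self.n_groups, 0)),
        )


@dataclass
class LogisticGLMMResults:
    """Fixed-effect estimates, Wald inference and fit diagnostics."""

    model: LogisticGLMM
    params: np.ndarray
    cov_params: np.ndarray
    cov_re: np.ndarray
    re_names: list
    llf: float
    converged: bool
    re_structure_used: str
    random_modes: np.ndarray
    separation: bool = False

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_params), 0.0, None))

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
        return np.column_stack(
            [self.params - zcrit * self.bse, self.params + zcrit * self.bse]
        )

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.params)

    def summary_frame(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self.conf_int(alpha)
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "z": self.zvalues,
                "p": self.pvalues,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "odds_ratio": self.odds_ratios,
                "or_ci_low": np.exp(ci[:, 0]),
                "or_ci_high": np.exp(ci[:, 1]),
            },
            index=self.model.exog_names,
        )

    def summary(self) -> str:
        head = (
            f"Logistic mixed model (Laplace ML)\n"
            f"groups: {self.model.n_groups}  obs: {self.model.endog.size}  "
            f"logLik: {self.llf:.2f}\n"
            f"random-effect structure: {self.re_structure_used}"
            f"{'  [separation -> Firth]' if self.separation else ''}"
            f"{'' if self.converged else '  [NOT CONVERGED]'}\n"
        )
        re_part = ""
        if self.cov_re.size:
            sds = np.sqrt(np.diag(self.cov_re))
            re_part = "random-effect SDs: " + ", ".join(
                f"{n}={s:.3f}" for n, s in zip(self.re_names, sds)
            ) + "\n"
        return head + re_part + self.summary_frame().to_string(
            float_format=lambda v: f"{v: .4f}"
        )
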