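"""Linear mixed models with a single random effect and grouped residual
variances.

Implements the Gaussian LMM

    y = X beta + Z b + eps,   b_d ~ N(0, tau^2),   eps_i ~ N(0, sigma^2_{g(i)})

with one scalar random effect per grouping unit (``donor``): a random
intercept (Z column of ones) or a random slope on a covariate.  Residual
variances may differ between observation strata (e.g. disomic vs trisomic
clones) -- the heteroscedastic structure statsmodels' MixedLM does not fit.

Estimation profiles the fixed effects out of the (RE)ML criterion and
optimizes the variance parameters on the log scale; each donor block is
rank-one so the likelihood uses Sherman-Morrison / matrix-determinant-lemma
identities and costs O(n).  Wald t-tests use a between-within degrees-of-
freedom approximation: effects constant within donors are tested against
(number of donors - number of between-donor coefficients), the rest against
(n - number of donors - number of within-donor coefficients).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class LMMResult:
    params: pd.Series
    se: pd.Series
    dof: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame            # columns: low, high (95%)
    tau: float                        # random-effect SD
    sigmas: dict                      # residual SD per variance group
    loglik: float                     # value of the fitted criterion (ML or REML)
    loglik_ml: float                  # ML log-likelihood at the fitted parameters
    method: str
    aic: float
    bic: float
    nobs: int
    k_params: int
    fitted: np.ndarray                # marginal fitted values X beta
    resid: np.ndarray                 # conditional residuals y - X beta - Z bhat
    std_resid: np.ndarray             # conditional residuals / sigma_{g(i)}
    ranef: pd.Series                  # BLUPs per donor
    groups: np.ndarray
    converged: bool
    cov_params: pd.DataFrame
    theta: np.ndarray                 # internal variance parameters (log scale)

    def contrast(self, c, df=None):
        """Estimate, SE, t, p and 95% CI for a linear combination c'beta."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.params.to_numpy())
        se = float(np.sqrt(c @ self.cov_params.to_numpy() @ c))
        df = float(self.dof.min()) if df is None else float(df)
        t = est / se if se > 0 else np.inf * np.sign(est)
        p = 2 * stats.t.sf(abs(t), df)
        half = stats.t.ppf(0.975, df) * se
        return {"estimate": est, "se": se, "t": t, "df": df, "p": float(p),
                "ci_low": est - half, "ci_high": est + half}


class MixedModel:
    """See module docstring.  ``random`` is "intercept" or an array of
    per-observation covariate values for a random slope."""

    def __init__(self, y, X, groups, random="intercept", variance_groups=None,
                 xnames=None):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        self.n, self.p = self.X.shape
        if len(self.y) != self.n:
            raise ValueError("y and X length mismatch")
        self.xnames = list(xnames) if xnames is not None else [
            f"x{j}" for j in range(self.p)]
        groups = np.asarray(groups)
        self.group_labels, self.group_codes = np.unique(groups, return_inverse=True)
        self.n_groups = len(self.group_labels)
        if isinstance(random, str):
            if random != "intercept":
                raise ValueError("random must be 'intercept' or a covariate array")
            self.z = np.ones(self.n)
        else:
            self.z = np.asarray(random, dtype=float)
            if len(self.z) != self.n:
                raise ValueError("random-slope covariate length mismatch")
        if variance_groups is None:
            self.vg_labels, self.vg_codes = np.array(["all"]), np.zeros(self.n, int)
        else:
            vg = np.asarray(variance_groups)
            self.vg_labels, self.vg_codes = np.unique(vg, return_inverse=True)
        self.n_vg = len(self.vg_labels)
        self._blocks = [np.where(self.group_codes == d)[0]
                        for d in range(self.n_groups)]
        resid0 = self.y - self.X @ np.linalg.lstsq(self.X, self.y, rcond=None)[0]
        self._scale = max(float(np.std(resid0)), 1e-8 * max(1.0, float(np.std(self.y))), 1e-12)

    # -- likelihood ---------------------------------------------------------

    def _decompose(self, theta):
        tau = np.exp(theta[0])
        sigmas = np.exp(theta[1:1 + self.n_vg])
        return tau, sigmas

    def _gls(self, tau, sigmas):
        """Return beta, XtViX, XtViy, logdetV, rss(beta) pieces via rank-one
        block inversions."""
        w = 1.0 / sigmas[self.vg_codes] ** 2      # D^{-1} diagonal
        logdet = float(np.sum(np.log(sigmas[self.vg_codes] ** 2)))
        XtViX = np.zeros((self.p, self.p))
        XtViy = np.zeros(self.p)
        block_info = []
        for idx in self._blocks:
            Xd, yd, zd, wd = self.X[idx], self.y[idx], self.z[idx], w[idx]
            a = wd * zd
            denom = 1.0 + tau ** 2 * float(zd @ a)
            logdet += np.log(denom)
            coef = tau ** 2 / denom
            Xw = Xd * wd[:, None]
            Xa = Xd.T @ a
            ya = float(yd @ a)
            XtViX += Xd.T @ Xw - coef * np.outer(Xa, Xa)
            XtViy += Xd.T @ (wd * yd) - coef * Xa * ya
            block_info.append((idx, a, denom, coef))
        beta = np.linalg.solve(XtViX, XtViy)
        quad = 0.0
        for idx, a, denom, coef in block_info:
            rd = self.y[idx] - self.X[idx] @ beta
            ra = float(rd @ a)
            quad += float(rd @ (w[idx] * rd)) - coef * ra * ra
        return beta, XtViX, logdet, quad, block_info, w

    def _neg_crit(self, theta, reml):
        tau, sigmas = self._decompose(theta)
        if not np.all(np.isfinite(theta)) or tau > 1e6 * self._scale:
            return 1e12
        try:
            beta, XtViX, logdet, quad, _, _ = self._gls(tau, sigmas)
        except np.linalg.LinAlgError:
            return 1e12
        ll = -0.5 * (logdet + quad + self.n * np.log(2 * np.pi))
        if reml:
            sign, ld = np.linalg.slogdet(XtViX)
            if sign <= 0:
                return 1e12
            ll -= 0.5 * ld
            ll += 0.5 * self.p * np.log(2 * np.pi)
        if not np.isfinite(ll):
            return 1e12
        return -ll

    # -- fitting ------------------------------------------------------------

    def fit(self, method: str = "reml", start=None) -> LMMResult:
        reml = method.lower() == "reml"
        s = np.log(self._scale)
        if start is None:
            starts = [
                np.concatenate([[s - 1.5], np.full(self.n_vg, s)]),
                np.concatenate([[s + 0.5], np.full(self.n_vg, s - 0.5)]),
            ]
        else:
            starts = [np.asarray(start, dtype=float)]
        best = None
        for x0 in starts:
            res = optimize.minimize(
                self._neg_crit, x0, args=(reml,), method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 4000})
            if best is None or res.fun < best.fun:
                best = res
        theta = best.x
        tau, sigmas = self._decompose(theta)
        beta, XtViX, logdet, quad, block_info, w = self._gls(tau, sigmas)
        cov = np.linalg.inv(XtViX)
        se = np.sqrt(np.diag(cov))
        ll_ml = -0.5 * (logdet + quad + self.n * np.log(2 * np.pi))
        loglik = -best.fun

        # BLUPs and conditional residuals
        bhat = np.zeros(self.n_groups)
        resid = self.y - self.X @ beta
        cond = resid.copy()
        for d, (idx, a, denom, coef) in enumerate(block_info):
            rd = resid[idx]
            bhat[d] = tau ** 2 * float(rd @ a) / denom
            cond[idx] = rd - self.z[idx] * bhat[d]
        std_resid = cond / sigmas[self.vg_codes]

        dof = self._between_within_dof()
        tvals = np.divide(beta, se, out=np.full_like(beta, np.inf), where=se > 0)
        pvals = 2 * stats.t.sf(np.abs(tvals), dof)
        half = stats.t.ppf(0.975, dof) * se
        k = self.p + 1 + self.n_vg
        names = self.xnames
        return LMMResult(
            params=pd.Series(beta, index=names),
            se=pd.Series(se, index=names),
            dof=pd.Series(dof, index=names),
            tvalues=pd.Series(tvals, index=names),
            pvalues=pd.Series(pvals, index=names),
            conf_int=pd.DataFrame({"low": beta - half, "high": beta + half},
                                  index=names),
            tau=float(tau),
            sigmas={str(l): float(s_) for l, s_ in zip(self.vg_labels, sigmas)},
            loglik=float(loglik), loglik_ml=float(ll_ml),
            method="REML" if reml else "ML",
            aic=float(2 * k - 2 * ll_ml), bic=float(k * np.log(self.n) - 2 * ll_ml),
            nobs=self.n, k_params=k,
            fitted=self.X @ beta, resid=cond, std_resid=std_resid,
            ranef=pd.Series(bhat, index=[str(l) for l in self.group_labels]),
            groups=self.group_labels[self.group_codes],
            converged=bool(best.success or best.fun < 1e11),
            cov_params=pd.DataFrame(cov, index=names, columns=names),
            theta=theta,
        )

    def _between_within_dof(self) -> np.ndarray:
        between = np.zeros(self.p, dtype=bool)
        for j in range(self.p):
            col = self.X[:, j]
            constant_within = all(
                np.ptp(col[idx]) < 1e-12 for idx in self._blocks)
            between[j] = constant_within
        p_b = int(between.sum())
        p_w = self.p - p_b
        df_b = max(self.n_groups - p_b, 1)
        df_w = max(self.n - self.n_groups - p_w, 1)
        return np.where(between, df_b, df_w).astype(float)


def lr_test_variances(het: LMMResult, hom: LMMResult):
    """Likelihood-ratio test of heteroscedastic vs single residual variance.

    Both results must be fits of the same criterion (both ML or both REML)
    with identical fixed effects and ``hom`` nested in ``het``; with equal
    fixed-effect structures the REML criteria are directly comparable, and
    REML is the better-calibrated choice at the sample sizes seen here.
    Returns (LR, p) with p from chi-square on the difference in
    variance-parameter count.
    """
    if het.method != hom.method:
        raise ValueError("LR test requires two fits of the same criterion")
    if list(het.params.index) != list(hom.params.index):
        raise ValueError("models are not nested: fixed effects differ")
    df = len(het.sigmas) - len(hom.sigmas)
    if df <= 0:
        raise ValueError("het model must have more variance parameters")
    lr = max(0.0, 2.0 * (het.loglik - hom.loglik))
    p = float(stats.chi2.sf(lr, df))
    return lr, p
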