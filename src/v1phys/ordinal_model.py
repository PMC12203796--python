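"""Cumulative link mixed model (ordinal regression with a random intercept).

Model:  P(Y_i <= k | u_a) = F(theta_k - x_i' beta - u_a),
        u_a ~ Normal(0, sigma_u^2)  per animal,

with F the logistic (default) or normal CDF.  The per-animal random
intercept is integrated out by adaptive Gauss-Hermite quadrature (the
integrand is re-centred at its mode and scaled by the local curvature;
one node reduces to the Laplace approximation).  The marginal likelihood
is maximised by quasi-Newton (BFGS) on an unconstrained parameterisation:
first threshold + log-increments (ordering is enforced by construction),
fixed effects, and log sigma_u.

Fitting with ``fix_sigma=0`` gives the plain proportional-odds model on
pooled data, which is used both as the starting value and as an
independent cross-check against ``statsmodels`` in the test-suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .group_stats import benjamini_hochberg

__all__ = [
    "CLMMFit",
    "DevianceTest",
    "build_design",
    "fit_clmm",
    "marginal_loglik",
    "anova_deviance",
    "cox_snell_r2",
    "marginal_contrasts",
    "simulate_from_design",
    "make_cohort_meta",
]

_REQUIRED = ("animal", "genotype", "sf", "category")


# --------------------------------------------------------------------------
# design matrix
# --------------------------------------------------------------------------

def build_design(
    data: pd.DataFrame,
    terms: Sequence[str] = ("genotype", "sf", "genotype:sf"),
    genotype_ref: str = "WT",
    sf_levels: Optional[Sequence] = None,
) -> tuple:
    """Treatment-coded model matrix for the fixed effects.

    SF is treated as an unordered factor (reference = lowest level);
    genotype reference defaults to WT.  Returns (X, column names, info).
    """
    for c in _REQUIRED[:3]:
        if c not in data.columns:
            raise ValueError(f"missing column '{c}'")
    geno_levels = list(pd.unique(data["genotype"]))
    if genotype_ref in geno_levels:
        geno_levels = [genotype_ref] + sorted(g for g in geno_levels if g != genotype_ref)
    else:
        geno_levels = sorted(geno_levels)
    if sf_levels is None:
        sf_levels = sorted(pd.unique(data["sf"]))
    cols, names = [], []
    g = data["genotype"].to_numpy()
    s = data["sf"].to_numpy()
    if "genotype" in terms:
        for lev in geno_levels[1:]:
            cols.append((g == lev).astype(float))
            names.append(f"genotype[{lev}]")
    if "sf" in terms:
        for lev in sf_levels[1:]:
            cols.append(np.isclose(s.astype(float), float(lev)).astype(float)
                        if np.issubdtype(np.asarray(sf_levels).dtype, np.number)
                        else (s == lev).astype(float))
            names.append(f"sf[{lev}]")
    if "genotype:sf" in terms:
        for glev in geno_levels[1:]:
            gcol = (g == glev).astype(float)
            for lev in sf_levels[1:]:
                scol = (np.isclose(s.astype(float), float(lev)).astype(float)
                        if np.issubdtype(np.asarray(sf_levels).dtype, np.number)
                        else (s == lev).astype(float))
                cols.append(gcol * scol)
                names.append(f"genotype[{glev}]:sf[{lev}]")
    X = np.column_stack(cols) if cols else np.empty((len(data), 0))
    info = {"genotype_levels": geno_levels, "sf_levels": list(sf_levels), "terms": tuple(terms)}
    return X, names, info


# --------------------------------------------------------------------------
# likelihood machinery
# --------------------------------------------------------------------------

def _link_funcs(link: str):
    if link == "logit":
        F = special.expit

        def f(x):  # logistic pdf
            e = special.expit(x)
            return e * (1.0 - e)

        def fp(x):  # derivative of the pdf
            e = special.expit(x)
            return e * (1.0 - e) * (1.0 - 2.0 * e)

    elif link == "probit":
        F = stats.norm.cdf
        f = stats.norm.pdf

        def fp(x):
            return -x * stats.norm.pdf(x)

    else:
        raise ValueError("link must be 'logit' or 'probit'")
    return F, f, fp


class _CLMMProblem:
    """Pre-indexed data + vectorised marginal log-likelihood."""

    def __init__(self, y, X, groups, K, link="logit", n_quad=15):
        self.y = np.asarray(y, dtype=int)  # 0-based categories
        self.X = np.asarray(X, dtype=float)
        self.K = int(K)
        self.link = link
        self.n_quad = int(n_quad)
        self.F, self.f, self.fp = _link_funcs(link)
        uniq, self.g = np.unique(np.asarray(groups), return_inverse=True)
        self.group_labels = list(uniq)
        self.n_groups = len(uniq)
        self.n, self.p = self.X.shape
        if self.y.min() < 0 or self.y.max() > K - 1:
            raise ValueError("categories out of range")
        z, w = special.roots_hermite(self.n_quad)
        self.zk, self.logwk = z, np.log(w)
        self.has_upper = self.y < (K - 1)
        self.has_lower = self.y > 0

    # -- conditional per-observation quantities at offset u (per obs) --------
    def _logp_obs(self, theta, eta, u_obs):
        yu = np.where(self.has_upper, self.y, 0)
        yl = np.where(self.has_lower, self.y - 1, 0)
        A = theta[yu] - eta - u_obs
        B = theta[yl] - eta - u_obs
        FA = np.where(self.has_upper, self.F(A), 1.0)
        FB = np.where(self.has_lower, self.F(B), 0.0)
        return np.log(np.clip(FA - FB, 1e-300, None))

    def _d_obs(self, theta, eta, u_obs):
        """(log p, d/du log p, d2/du2 log p) per observation."""
        yu = np.where(self.has_upper, self.y, 0)
        yl = np.where(self.has_lower, self.y - 1, 0)
        A = theta[yu] - eta - u_obs
        B = theta[yl] - eta - u_obs
        FA = np.where(self.has_upper, self.F(A), 1.0)
        FB = np.where(self.has_lower, self.F(B), 0.0)
        fA = np.where(self.has_upper, self.f(A), 0.0)
        fB = np.where(self.has_lower, self.f(B), 0.0)
        fpA = np.where(self.has_upper, self.fp(A), 0.0)
        fpB = np.where(self.has_lower, self.fp(B), 0.0)
        p = np.clip(FA - FB, 1e-300, None)
        d1 = -(fA - fB) / p
        d2 = (fpA - fpB) / p - d1**2
        return np.log(p), d1, d2

    def loglik(self, theta, beta, sigma):
        eta = self.X @ beta if self.p else np.zeros(self.n)
        if sigma < 1e-8:
            return float(self._logp_obs(theta, eta, 0.0).sum())
        # mode of the per-animal integrand by damped Newton
        u = np.zeros(self.n_groups)
        for _ in range(60):
            _, d1, d2 = self._d_obs(theta, eta, u[self.g])
            grad = np.bincount(self.g, weights=d1, minlength=self.n_groups) - u / sigma**2
            hess = np.bincount(self.g, weights=d2, minlength=self.n_groups) - 1.0 / sigma**2
            step = -grad / hess
            np.clip(step, -5.0 * sigma, 5.0 * sigma, out=step)
            u += step
            if np.max(np.abs(grad)) < 1e-10:
                break
        _, _, d2 = self._d_obs(theta, eta, u[self.g])
        hess = np.bincount(self.g, weights=d2, minlength=self.n_groups) - 1.0 / sigma**2
        shat = 1.0 / np.sqrt(-hess)
        # adaptive GH: integral ~ sqrt(2) shat sum_j w_j e^{z_j^2} e^{h(u_j)}
        fmat = np.empty((self.n_groups, self.n_quad))
        for j, z in enumerate(self.zk):
            uj = u + np.sqrt(2.0) * shat * z
            lp = self._logp_obs(theta, eta, uj[self.g])
            fmat[:, j] = (
                np.bincount(self.g, weights=lp, minlength=self.n_groups)
                - uj**2 / (2.0 * sigma**2)
                - 0.5 * np.log(2.0 * np.pi) - np.log(sigma)
            )
        arg = fmat + (self.logwk + self.zk**2)[None, :]
        ll = 0.5 * np.log(2.0) + np.log(shat) + special.logsumexp(arg, axis=1)
        return float(ll.sum())


def _pack(theta, beta, sigma, fix_sigma):
    t_free = np.concatenate([[theta[0]], np.log(np.maximum(np.diff(theta), 1e-8))])
    x = np.concatenate([t_free, beta])
    if fix_sigma is None:
        x = np.concatenate([x, [np.log(max(sigma, 1e-6))]])
    return x


def _unpack(x, K, p, fix_sigma):
    t_free = x[: K - 1]
    theta = np.concatenate([[t_free[0]], t_free[0] + np.cumsum(np.exp(t_free[1:]))])
    beta = x[K - 1 : K - 1 + p]
    sigma = fix_sigma if fix_sigma is not None else float(np.exp(x[-1]))
    return theta, beta, sigma


@dataclass
class CLMMFit:
    beta: pd.Series
    thresholds: np.ndarray
    sigma_u: float
    loglik: float
    n_obs: int
    n_groups: int
    K: int
    converged: bool
    grad_norm: float
    link: str
    n_quad: int
    terms: tuple
    info: dict
    _problem: _CLMMProblem = field(repr=False, default=None)
    _params: np.ndarray = field(repr=False, default=None)
    _fix_sigma: Optional[float] = field(repr=False, default=None)
    _vcov: Optional[np.ndarray] = field(repr=False, default=None)

    @property
    def n_fixed(self) -> int:
        return len(self.beta)

    def vcov_fixed(self) -> np.ndarray:
        """Fixed-effect covariance from the numerical Hessian at the optimum."""
        if self._vcov is not None:
            return self._vcov
        prob, x0 = self._problem, self._params
        K, p = self.K, self.n_fixed

        def nll(x):
            theta, beta, sigma = _unpack(x, K, p, self._fix_sigma)
            return -prob.loglik(theta, beta, sigma)

        m = len(x0)
        H = np.empty((m, m))
        h = 1e-4 * np.maximum(1.0, np.abs(x0))
        f0 = nll(x0)
        fi = np.empty(m)
        for i in range(m):
            e = np.zeros(m); e[i] = h[i]
            fi[i] = nll(x0 + e)
        for i in range(m):
            ei = np.zeros(m); ei[i] = h[i]
            H[i, i] = (fi[i] - 2 * f0 + nll(x0 - ei)) / h[i] ** 2
            for j in range(i + 1, m):
                ej = np.zeros(m); ej[j] = h[j]
                fij = nll(x0 + ei + ej)
                H[i, j] = H[j, i] = (fij - fi[i] - fi[j] + f0) / (h[i] * h[j])
        cov = np.linalg.pinv(H)
        sl = slice(K - 1, K - 1 + p)
        self._vcov = cov[sl, sl]
        if np.any(np.diag(self._vcov) <= 0):
            raise np.linalg.LinAlgError("singular fixed-effect covariance")
        return self._vcov

    def summary_dict(self) -> dict:
        return {
            "beta": self.beta.to_dict(),
            "thresholds": self.thresholds.tolist(),
            "sigma_u": self.sigma_u,
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "K": self.K,
            "converged": self.converged,
            "link": self.link,
            "n_quad": self.n_quad,
        }


def _start_thresholds(y, K, F_inv):
    freq = np.bincount(y, minlength=K).astype(float)
    freq = np.maximum(freq, 0.5)
    cum = np.cumsum(freq)[:-1] / freq.sum()
    theta = F_inv(np.clip(cum, 1e-4, 1 - 1e-4))
    return np.maximum.accumulate(theta + 1e-6 * np.arange(K - 1))


def fit_clmm(
    data: pd.DataFrame,
    terms: Sequence[str] = ("genotype", "sf", "genotype:sf"),
    link: str = "logit",
    n_quad: int = 15,
    fix_sigma: Optional[float] = None,
    genotype_ref: str = "WT",
    sf_levels: Optional[Sequence] = None,
    K: Optional[int] = None,
    start: Optional[np.ndarray] = None,
    gtol: float = 1e-6,
) -> CLMMFit:
    """Fit the cumulative link mixed model by maximum marginal likelihood.

    ``data`` needs columns animal, genotype, sf, category (1..K).
    ``fix_sigma=0`` fits the fixed-effects proportional-odds model.
    """
    for c in _REQUIRED:
        if c not in data.columns:
            raise ValueError(f"missing column '{c}'")
    y = data["category"].to_numpy(dtype=int) - 1
    if K is None:
        K = int(y.max()) + 1
    if K < 2:
        raise ValueError("need at least 2 ordinal categories")
    X, names, info = build_design(data, terms, genotype_ref, sf_levels)
    groups = data["animal"].to_numpy()
    per_geno = data.groupby("genotype")["animal"].nunique()
    if (per_geno < 2).any():
        warnings.warn("fewer than 2 animals in a genotype; random-effect variance weakly identified")

    prob = _CLMMProblem(y, X, groups, K, link=link, n_quad=n_quad)
    F_inv = special.logit if link == "logit" else stats.norm.ppf

    if start is None:
        theta0 = _start_thresholds(y, K, F_inv)
        beta0 = np.zeros(prob.p)
        if fix_sigma is None or fix_sigma > 0:
            # proportional-odds start (sigma fixed at 0), then sigma_u = 0.1
            po = fit_clmm(
                data, terms, link=link, n_quad=1, fix_sigma=0.0,
                genotype_ref=genotype_ref, sf_levels=sf_levels, K=K, gtol=gtol,
            )
            theta0, beta0 = po.thresholds, po.beta.to_numpy()
        x0 = _pack(theta0, beta0, 0.1 if fix_sigma is None else max(fix_sigma, 1e-6), fix_sigma)
    else:
        x0 = np.asarray(start, dtype=float)

    def nll(x):
        theta, beta, sigma = _unpack(x, K, prob.p, fix_sigma)
        return -prob.loglik(theta, beta, sigma)

    res = optimize.minimize(nll, x0, method="BFGS", options={"gtol": gtol, "maxiter": 2000})
    if not res.success:  # polish from the BFGS iterate
        res2 = optimize.minimize(nll, res.x, method="BFGS", options={"gtol": gtol * 10, "maxiter": 2000})
        if res2.fun <= res.fun:
            res = res2
    theta, beta, sigma = _unpack(res.x, K, prob.p, fix_sigma)
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
    converged = bool(res.success or grad_norm < 1e-3)
    if not converged:
        warnings.warn(f"CLMM did not converge (max |grad| = {grad_norm:.3g})")
    ll = -float(res.fun)
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite log-likelihood at optimum")
    return CLMMFit(
        beta=pd.Series(beta, index=names),
        thresholds=theta,
        sigma_u=float(sigma),
        loglik=ll,
        n_obs=prob.n,
        n_groups=prob.n_groups,
        K=K,
        converged=converged,
        grad_norm=grad_norm,
        link=link,
        n_quad=n_quad,
        terms=tuple(terms),
        info=info,
        _problem=prob,
        _params=res.x,
        _fix_sigma=fix_sigma,
    )


def marginal_loglik(
    data: pd.DataFrame,
    theta: np.ndarray,
    beta: np.ndarray,
    sigma_u: float,
    terms: Sequence[str] = ("genotype", "sf", "genotype:sf"),
    link: str = "logit",
    n_quad: int = 15,
    genotype_ref: str = "WT",
    K: Optional[int] = None,
) -> float:
    """Marginal log-likelihood at fixed parameter values (for validation)."""
    y = data["category"].to_numpy(dtype=int) - 1
    if K is None:
        K = int(y.max()) + 1
    X, _, _ = build_design(data, terms, genotype_ref)
    prob = _CLMMProblem(y, X, data["animal"].to_numpy(), K, link=link, n_quad=n_quad)
    return prob.loglik(np.asarray(theta, float), np.asarray(beta, float), float(sigma_u))


# --------------------------------------------------------------------------
# inference
# --------------------------------------------------------------------------

@dataclass
class DevianceTest:
    chi2: float
    df: int
    p_value: float
    models: tuple


def anova_deviance(full: CLMMFit, reduced: CLMMFit) -> DevianceTest:
    """Likelihood-ratio test between nested fits (e.g. dropping genotype:sf)."""
    if full.n_obs != reduced.n_obs:
        raise ValueError("models fitted to different data")
    df = full.n_fixed - reduced.n_fixed
    if df <= 0:
        df = max(df, 0)
    chi2 = 2.0 * (full.loglik - reduced.loglik)
    if chi2 < -1e-4:
        warnings.warn(
            "full model log-likelihood below the reduced model's; refit with better starts"
        )
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return DevianceTest(chi2=chi2, df=df, p_value=p, models=(str(full.terms), str(reduced.terms)))


def cox_snell_r2(full: CLMMFit, null: CLMMFit) -> float:
    """1 - exp((2/n) (ll_null - ll_full))."""
    if full.n_obs != null.n_obs:
        raise ValueError("models fitted to different data")
    return float(1.0 - np.exp(2.0 / full.n_obs * (null.loglik - full.loglik)))


def marginal_contrasts(
    fit: CLMMFit,
    sf_levels: Optional[Sequence] = None,
    genotype_a: Optional[str] = None,
    genotype_b: Optional[str] = None,
    correct: str = "bh",
) -> pd.DataFrame:
    """Per-SF genotype difference (a - b) on the latent scale.

    The latent-scale linear predictor difference at each SF level, its
    delta-method SE from the fixed-effect covariance, the normal Z ratio,
    two-sided p, and Benjamini-Hochberg corrected p across the SF levels.
    """
    geno_levels = fit.info["genotype_levels"]
    if genotype_b is None:
        genotype_b = geno_levels[0]
    if genotype_a is None:
        others = [g for g in geno_levels if g != genotype_b]
        if len(others) != 1:
            raise ValueError("specify genotype_a explicitly")
        genotype_a = others[0]
    if sf_levels is None:
        sf_levels = fit.info["sf_levels"]
    V = fit.vcov_fixed()
    names = list(fit.beta.index)

    def _indicator(genotype, sf):
        c = np.zeros(len(names))
        if genotype == geno_levels[0]:
            return c
        key = f"genotype[{genotype}]"
        if key in names:
            c[names.index(key)] = 1.0
        ikey = f"genotype[{genotype}]:sf[{sf}]"
        if ikey in names:
            c[names.index(ikey)] = 1.0
        return c

    rows = []
    for sf in sf_levels:
        c = _indicator(genotype_a, sf) - _indicator(genotype_b, sf)
        est = float(c @ fit.beta.to_numpy())
        se = float(np.sqrt(c @ V @ c))
        z = est / se if se > 0 else 0.0
        p = float(2.0 * stats.norm.sf(abs(z)))
        rows.append({"sf": sf, "estimate": est, "se": se, "z_ratio": z, "p_value": p})
    out = pd.DataFrame(rows)
    if correct == "bh":
        out["p_corrected"] = benjamini_hochberg(out["p_value"].to_numpy())
    elif correct == "none":
        out["p_corrected"] = out["p_value"]
    else:
        raise ValueError("correct must be 'bh' or 'none'")
    return out


# --------------------------------------------------------------------------
# model-based simulation (validation studies)
# --------------------------------------------------------------------------

def make_cohort_meta(
    n_animals: dict, cells_per_animal: int, sf_levels: Sequence, genotype_ref: str = "WT"
) -> pd.DataFrame:
    """One row per cell x SF for a two-genotype cohort."""
    rows = []
    for genotype in sorted(n_animals):
        for a in range(n_animals[genotype]):
            animal = f"{genotype}{a + 1}"
            for c in range(cells_per_animal):
                for sf in sf_levels:
                    rows.append(
                        {"cell": f"{animal}_c{c}", "animal": animal, "genotype": genotype, "sf": sf}
                    )
    return pd.DataFrame(rows)


def simulate_from_design(
    meta: pd.DataFrame,
    theta: np.ndarray,
    beta: np.ndarray,
    sigma_u: float,
    terms: Sequence[str] = ("genotype", "sf", "genotype:sf"),
    link: str = "logit",
    genotype_ref: str = "WT",
    rng=None,
) -> pd.DataFrame:
    """Draw ordinal categories from the CLMM at the given parameters."""
    rng = np.random.default_rng(rng)
    F, _, _ = _link_funcs(link)
    X, names, _ = build_design(meta, terms, genotype_ref)
    beta = np.asarray(beta, dtype=float)
    if len(beta) != X.shape[1]:
        raise ValueError(f"beta length {len(beta)} != design width {X.shape[1]} ({names})")
    theta = np.asarray(theta, dtype=float)
    animals, inv = np.unique(meta["animal"].to_numpy(), return_inverse=True)
    u = rng.normal(0.0, sigma_u, size=len(animals))
    eta = X @ beta + u[inv]
    gamma = F(theta[None, :] - eta[:, None])  # (n, K-1) cumulative probs
    U = rng.random(len(meta))
    y = 1 + (U[:, None] > gamma).sum(axis=1)
    out = meta.copy()
    out["category"] = y.astype(int)
    return out
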