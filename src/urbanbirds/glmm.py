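"""Random-intercept generalized linear mixed models fit by maximum likelihood.

The fitting engine behind the per-species presence/abundance models, the
site-level richness and total-abundance models, and the community-turnover
model.  All three families share the same structure:

    g(E[y_ij]) = x_ij' beta + u_i,     u_i ~ N(0, sigma_u^2)

with one random intercept per site and canonical links (identity for
gaussian, logit for binomial, log for Poisson).  Everything is maximum
likelihood -- never REML -- so that AIC is comparable across fixed-effect
subsets during all-subsets model selection.

For the gaussian family the marginal likelihood has a closed form
(compound-symmetric covariance within each group) and is profiled over the
variance ratio.  For binomial and Poisson responses the site intercepts are
integrated out with a Laplace approximation: penalised iteratively
reweighted least squares finds the joint mode of (beta, u) for a candidate
sigma_u, and a one-dimensional search maximises the Laplace log-likelihood
over log sigma_u.  A dense Gauss-Hermite quadrature oracle
(:func:`loglik_oracle`) is provided for validating the Laplace
approximation on small problems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln

FAMILIES = ("gaussian", "binomial", "poisson")

_LOG2PI = float(np.log(2.0 * np.pi))


class GLMMError(ValueError):
    """Invalid model specification or data."""


def _validate_family(family: str) -> str:
    if family not in FAMILIES:
        raise GLMMError(f"unknown family {family!r}; expected one of {FAMILIES}")
    return family


def _encode_groups(groups):
    codes, labels = pd.factorize(np.asarray(groups), sort=True)
    if (codes < 0).any():
        raise GLMMError("missing values in grouping variable")
    return codes.astype(np.intp), labels


class MixedGLM:
    """Random-intercept GLMM for one response.

    Parameters
    ----------
    endog : array-like
        Response vector.  Binomial responses must be 0/1; Poisson responses
        non-negative.  Non-integer Poisson responses (season-averaged
        abundances) are rounded to the nearest integer by default; pass
        ``round_poisson=False`` to refuse them instead.
    exog : array-like, shape (n, p)
        Fixed-effect design matrix including the intercept column.
    groups : array-like
        Grouping labels (one random intercept per distinct label).
    family : {"gaussian", "binomial", "poisson"}
    exog_names : sequence of str, optional
    """

    def __init__(self, endog, exog, groups, family="gaussian", exog_names=None,
                 round_poisson=True):
        self.family = _validate_family(family)
        y = np.asarray(endog, dtype=float)
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if y.ndim != 1 or X.shape[0] != y.shape[0]:
            raise GLMMError("endog and exog have incompatible shapes")
        if not (np.isfinite(y).all() and np.isfinite(X).all()):
            raise GLMMError("non-finite values in endog/exog")
        if family == "binomial":
            if not np.isin(y, (0.0, 1.0)).all():
                raise GLMMError("binomial response must be coded 0/1")
        elif family == "poisson":
            if (y < 0).any():
                raise GLMMError("poisson response must be non-negative")
            if not np.allclose(y, np.round(y)):
                if round_poisson:
                    warnings.warn(
                        "non-integer poisson response rounded to the nearest "
                        "integer (season-averaged abundances)", UserWarning,
                        stacklevel=2)
                    y = np.round(y)
                else:
                    raise GLMMError("non-integer poisson response")
        self.endog = y
        self.exog = X
        self.group_idx, self.group_labels = _encode_groups(groups)
        if self.group_idx.shape[0] != y.shape[0]:
            raise GLMMError("groups length mismatch")
        self.n_groups = len(self.group_labels)
        self.nobs, self.k_exog = X.shape
        if exog_names is None:
            exog_names = [f"x{j}" for j in range(self.k_exog)]
        self.exog_names = list(exog_names)
        if len(self.exog_names) != self.k_exog:
            raise GLMMError("exog_names length mismatch")
        # constant term of the log-likelihood (kept so quadrature oracles and
        # plain-GLM comparisons agree exactly)
        if family == "poisson":
            self._llconst = -float(gammaln(y + 1.0).sum())
        else:
            self._llconst = 0.0
        # dense group indicator: n and m are small (tens to hundreds), so
        # BLAS products against Z beat repeated bincounts in the inner loop
        Z = np.zeros((self.nobs, self.n_groups))
        Z[np.arange(self.nobs), self.group_idx] = 1.0
        self._Z = Z

    # ------------------------------------------------------------------
    def set_endog(self, endog) -> "MixedGLM":
        """Swap the response in place (design unchanged).

        Used by the randomised-null calibration, which refits the same
        2^K designs against fresh simulated responses each iteration.
        """
        y = np.asarray(endog, dtype=float)
        if y.shape != self.endog.shape or not np.isfinite(y).all():
            raise GLMMError("replacement endog has wrong shape or NaNs")
        if self.family == "binomial" and not np.isin(y, (0.0, 1.0)).all():
            raise GLMMError("binomial response must be coded 0/1")
        if self.family == "poisson":
            if (y < 0).any() or not np.allclose(y, np.round(y)):
                raise GLMMError("poisson response must be a non-negative integer")
            self._llconst = -float(gammaln(y + 1.0).sum())
        self.endog = y
        return self

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str, terms,
                       group: str, family: str = "gaussian",
                       add_intercept: bool = True, **kwargs) -> "MixedGLM":
        """Build a model from a modeling frame by column name."""
        terms = list(terms)
        missing = [c for c in [response, *terms, group] if c not in data.columns]
        if missing:
            raise GLMMError(f"columns missing from frame: {missing}")
        cols = [np.ones(len(data))] if add_intercept else []
        names = ["Intercept"] if add_intercept else []
        for t in terms:
            cols.append(data[t].to_numpy(dtype=float))
            names.append(t)
        X = np.column_stack(cols) if cols else np.empty((len(data), 0))
        return cls(data[response].to_numpy(), X, data[group].to_numpy(),
                   family=family, exog_names=names, **kwargs)

    # ------------------------------------------------------------------
    # family helpers (canonical links)
    def _loglik_obs(self, eta):
        y = self.endog
        if self.family == "binomial":
            return float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        # poisson; overflow to -inf is fine (the line search backs off)
        with np.errstate(over="ignore"):
            return float(np.sum(y * eta - np.exp(eta))) + self._llconst

    def _mu_w(self, eta):
        if self.family == "binomial":
            mu = 1.0 / (1.0 + np.exp(-eta))
            return mu, mu * (1.0 - mu)
        with np.errstate(over="ignore"):
            mu = np.exp(eta)
        return mu, mu

    # ------------------------------------------------------------------
    def _pirls(self, sigma_u, beta, u, max_iter=60, tol=1e-10):
        """Joint penalised mode of (beta, u) at fixed sigma_u.

        Returns beta, u, D (per-group curvature sums + 1/sigma^2),
        penalised log-likelihood at the mode, and a convergence flag.
        """
        X, y, g, m = self.exog, self.endog, self.group_idx, self.n_groups
        Z = self._Z
        inv_s2 = 1.0 / (sigma_u * sigma_u)
        eta = X @ beta + u[g]
        pen = self._loglik_obs(eta) - 0.5 * inv_s2 * float(u @ u)
        converged = False
        D = None
        for _ in range(max_iter):
            mu, w = self._mu_w(eta)
            r = y - mu
            score_b = X.T @ r
            score_u = r @ Z - u * inv_s2
            WX = X * w[:, None]
            A = X.T @ WX
            B = Z.T @ WX
            D = w @ Z + inv_s2
            BD = B / D[:, None]
            S = A - B.T @ BD
            rhs = score_b - BD.T @ score_u
            try:
                db = np.linalg.solve(S, rhs)
            except np.linalg.LinAlgError:
                return beta, u, D, pen, False
            du = (score_u - B @ db) / D
            step = 1.0
            for _ in range(25):
                nb = beta + step * db
                nu = u + step * du
                neta = X @ nb + nu[g]
                npen = self._loglik_obs(neta) - 0.5 * inv_s2 * float(nu @ nu)
                if np.isfinite(npen) and npen >= pen - 1e-13:
                    break
                step *= 0.5
            else:
                converged = abs(float(score_b @ db) + float(score_u @ du)) < 1e-6
                break
            improved = npen - pen
            beta, u, eta, pen = nb, nu, neta, npen
            if improved < tol * (abs(pen) + 1.0):
                converged = True
                break
        # refresh curvature at the final point
        mu, w = self._mu_w(eta)
        D = w @ Z + inv_s2
        return beta, u, D, pen, converged

    def _laplace_loglik(self, log_sigma, state):
        """Laplace marginal log-likelihood maximised over (beta, u)."""
        sigma = float(np.exp(log_sigma))
        beta, u, D, pen, ok = self._pirls(sigma, state["beta"], state["u"])
        state["beta"], state["u"], state["ok"] = beta, u, ok
        ll = pen - 0.5 * float(np.log(sigma * sigma * D).sum())
        return ll, beta, u, D

    # ------------------------------------------------------------------
    def fit(self, sigma0: float | None = None,
            search_step: float = 0.7) -> "MixedGLMResults":
        """Maximum-likelihood fit; returns a results object.

        ``sigma0`` warm-starts the random-intercept SD search and
        ``search_step`` sets the initial bracket half-width in log sigma --
        all-subsets enumeration passes the full-model estimate with a small
        step, which roughly halves the cost per subset fit.
        """
        if self.family == "gaussian":
            return self._fit_gaussian()
        return self._fit_laplace(sigma0, search_step)

    # -- non-gaussian ---------------------------------------------------
    def _fit_laplace(self, sigma0, search_step=0.7):
        lo, hi = np.log(1e-4), np.log(50.0)
        state = {"beta": np.zeros(self.k_exog), "u": np.zeros(self.n_groups),
                 "ok": True}
        # crude warm start for beta from an intercept guess
        if self.k_exog and self.exog_names and self.exog_names[0] == "Intercept":
            ybar = float(self.endog.mean())
            if self.family == "poisson":
                state["beta"][0] = np.log(max(ybar, 1e-3))
            else:
                ybar = min(max(ybar, 1e-3), 1 - 1e-3)
                state["beta"][0] = np.log(ybar / (1 - ybar))

        cache: dict[float, float] = {}

        def f(t):
            t = float(t)
            if t not in cache:
                cache[t] = self._laplace_loglik(t, state)[0]
            return cache[t]

        t0 = float(np.log(sigma0)) if sigma0 and sigma0 > 0 else np.log(0.3)
        t0 = min(max(t0, lo + 0.2), hi - 0.2)
        t_hat = _maximize_scalar(f, t0, lo, hi, step=search_step)
        ll, beta, u, D = self._laplace_loglik(t_hat, state)
        sigma_u = float(np.exp(t_hat))
        at_boundary = t_hat <= lo + 1e-8
        if at_boundary:
            sigma_u = 0.0
        # conditional covariance of beta: Schur complement of the joint
        # penalised Hessian at the mode
        mu, w = self._mu_w(self.exog @ beta + u[self.group_idx])
        WX = self.exog * w[:, None]
        A = self.exog.T @ WX
        B = self._Z.T @ WX
        S = A - B.T @ (B / D[:, None])
        try:
            cov = np.linalg.inv(S)
            bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            cov = np.full((self.k_exog, self.k_exog), np.nan)
            bse = np.full(self.k_exog, np.nan)
        converged = bool(state["ok"]) and bool(np.isfinite(ll))
        separation = bool(np.max(np.abs(beta)) > 30.0) if self.k_exog else False
        k = self.k_exog + 1  # sigma_u always counted, boundary included
        return MixedGLMResults(
            model=self, params=beta, bse=bse, cov_params=cov,
            sigma_u=sigma_u, sigma_e=None, llf=float(ll), k_params=k,
            converged=converged and not separation, separation=separation,
            ranef=u)

    # -- gaussian -------------------------------------------------------
    def _gauss_profile(self, lam):
        """Profile (beta, sigma_e) out of the gaussian marginal at
        variance ratio lam = sigma_u^2/sigma_e^2."""
        X, y, g, m = self.exog, self.endog, self.group_idx, self.n_groups
        n, p = self.nobs, self.k_exog
        ng = np.bincount(g, minlength=m).astype(float)
        c = lam / (1.0 + lam * ng)  # shrinkage per group
        Xg = np.empty((m, p))
        for j in range(p):
            Xg[:, j] = np.bincount(g, weights=X[:, j], minlength=m)
        yg = np.bincount(g, weights=y, minlength=m)
        XtVX = X.T @ X - (Xg * c[:, None]).T @ Xg
        XtVy = X.T @ y - (Xg * c[:, None]).T @ yg
        try:
            beta = np.linalg.solve(XtVX, XtVy)
        except np.linalg.LinAlgError:
            return None
        e = y - X @ beta
        eg = np.bincount(g, weights=e, minlength=m)
        rss = float(e @ e - (c * eg * eg).sum())
        if rss <= 0:
            return None
        sigma2_e = rss / n
        logdet = float(np.log1p(lam * ng).sum())
        ll = -0.5 * (n * (_LOG2PI + np.log(sigma2_e) + 1.0) + logdet)
        return ll, beta, sigma2_e, XtVX, c, ng

    def _fit_gaussian(self):
        def neg(t):
            out = self._gauss_profile(float(np.exp(t)))
            # large finite (not inf) keeps Brent's arithmetic clean
            return 1e30 if out is None else -out[0]

        res = optimize.minimize_scalar(neg, bounds=(np.log(1e-8), np.log(1e4)),
                                       method="bounded",
                                       options={"xatol": 1e-6})
        t_hat = float(res.x)
        # boundary lam = 0 (plain regression) checked explicitly
        out0 = self._gauss_profile(0.0)
        out = self._gauss_profile(float(np.exp(t_hat)))
        lam = float(np.exp(t_hat))
        if out is None or (out0 is not None and out0[0] >= out[0] - 1e-10):
            out, lam = out0, 0.0
        if out is None:
            raise GLMMError("gaussian fit failed (zero residual variance?)")
        ll, beta, sigma2_e, XtVX, c, ng = out
        cov = sigma2_e * np.linalg.inv(XtVX)
        bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        sigma_u = float(np.sqrt(lam * sigma2_e))
        # BLUPs of the random intercepts
        e = self.endog - self.exog @ beta
        eg = np.bincount(self.group_idx, weights=e, minlength=self.n_groups)
        u = c * eg if lam > 0 else np.zeros(self.n_groups)
        k = self.k_exog + 2  # sigma_u and sigma_e
        return MixedGLMResults(
            model=self, params=beta, bse=bse, cov_params=cov,
            sigma_u=sigma_u, sigma_e=float(np.sqrt(sigma2_e)), llf=float(ll),
            k_params=k, converged=True, separation=False, ranef=u)


@dataclass
class MixedGLMResults:
    """ML estimates from a :class:`MixedGLM` fit."""

    model: MixedGLM
    params: np.ndarray
    bse: np.ndarray
    cov_params: np.ndarray
    sigma_u: float
    sigma_e: float | None
    llf: float
    k_params: int
    converged: bool
    separation: bool
    ranef: np.ndarray = field(repr=False, default=None)

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k_params

    @property
    def param_names(self):
        return self.model.exog_names

    def conf_int(self, alpha=0.05):
        from scipy.stats import norm
        z = norm.ppf(1 - alpha / 2)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return np.column_stack([lo, hi])

    def params_series(self) -> pd.Series:
        return pd.Series(self.params, index=self.param_names)

    def to_dict(self) -> dict:
        return {
            "family": self.model.family,
            "terms": self.param_names,
            "beta": [float(b) for b in self.params],
            "se": [float(s) for s in self.bse],
            "sigma_u": float(self.sigma_u),
            "sigma_e": None if self.sigma_e is None else float(self.sigma_e),
            "loglik": float(self.llf),
            "k": int(self.k_params),
            "aic": float(self.aic),
            "converged": bool(self.converged),
        }

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            f"Mixed GLM ({self.model.family}), random intercept over "
            f"{self.model.n_groups} groups, n={self.model.nobs}",
            f"logLik {self.llf:.4f}   k {self.k_params}   AIC {self.aic:.4f}   "
            f"sigma_u {self.sigma_u:.4f}"
            + ("" if self.sigma_e is None else f"   sigma_e {self.sigma_e:.4f}"),
            f"{'term':<22}{'beta':>10}{'se':>10}{'ci_lo':>10}{'ci_hi':>10}",
        ]
        for name, b, s, (lo, hi) in zip(self.param_names, self.params,
                                        self.bse, ci):
            lines.append(f"{name:<22}{b:>10.4f}{s:>10.4f}{lo:>10.4f}{hi:>10.4f}")
        if not self.converged:
            lines.append("WARNING: fit did not converge")
        return "\n".join(lines)


# ----------------------------------------------------------------------
def _maximize_scalar(f, t0, lo, hi, step=0.7, ftol=1e-9, max_eval=40):
    """Bracket + golden/parabolic maximisation of a smooth unimodal scalar
    function on [lo, hi], warm-started at t0.

    Tuned for the Laplace profile over log sigma_u: evaluations are
    expensive (each is an inner PIRLS solve) so the bracket is grown
    geometrically from the warm start and refined with successive parabolic
    interpolation, falling back to bisection when the parabola misbehaves.
    Returns the best abscissa; boundary maxima are handled (the profile is
    monotone when sigma_u -> 0 is the MLE).
    """
    evals = [0]

    def clamp(t):
        return min(max(t, lo), hi)

    # grow a bracket around t0
    a, b, c = clamp(t0 - step), clamp(t0), clamp(t0 + step)
    fa, fb, fc = f(a), f(b), f(c)
    evals[0] = 3
    while fb < fa - ftol and a > lo and evals[0] < max_eval:
        c, fc, b, fb = b, fb, a, fa
        a = clamp(a - (c - b) * 2.0)
        fa = f(a)
        evals[0] += 1
    while fb < fc - ftol and c < hi and evals[0] < max_eval:
        a, fa, b, fb = b, fb, c, fc
        c = clamp(c + (b - a) * 2.0)
        fc = f(c)
        evals[0] += 1
    if fa >= fb and a <= lo + 1e-12:
        return lo
    if fc >= fb and c >= hi - 1e-12:
        return hi
    # refine: parabolic interpolation with golden fallback.  The profile is
    # flat to second order at the optimum, so a bracket of width ~5e-3 in
    # log sigma bounds the log-likelihood error far below AIC resolution.
    inv_gold = 0.3819660112501051
    for _ in range(max_eval - evals[0]):
        # stop on a narrow bracket, or when the profile is flat across the
        # whole bracket (near-boundary sigma_u, where log sigma resolution
        # is meaningless)
        if c - a < 2e-2 or fb - min(fa, fc) < 1e-7:
            break
        denom = (b - a) * (fb - fc) - (b - c) * (fb - fa)
        if abs(denom) > 1e-14:
            t = b - 0.5 * ((b - a) ** 2 * (fb - fc)
                           - (b - c) ** 2 * (fb - fa)) / denom
        else:
            t = None
        if t is None or not (a < t < c) or abs(t - b) < 1e-7:
            # golden step into the larger interval
            t = b + inv_gold * ((c - b) if (c - b) > (b - a) else (a - b))
        ft = f(t)
        if ft >= fb:
            if t < b:
                c, fc = b, fb
            else:
                a, fa = b, fb
            b, fb = t, ft
        else:
            if t < b:
                a, fa = t, ft
            else:
                c, fc = t, ft
    return b


def loglik_oracle(model: MixedGLM, beta, sigma_u, sigma_e=None,
                  n_nodes: int = 201) -> float:
    """Marginal log-likelihood by dense Gauss-Hermite quadrature.

    Integrates the random intercept out numerically, group by group.  A
    validation tool only: refuses more than 8 groups.
    """
    if model.n_groups > 8:
        raise GLMMError("oracle quadrature limited to <= 8 groups")
    beta = np.asarray(beta, dtype=float)
    sigma_u = float(sigma_u)
    y, X, g = model.endog, model.exog, model.group_idx
    eta0 = X @ beta
    nodes, wts = np.polynomial.hermite.hermgauss(n_nodes)
    total = 0.0
    for i in range(model.n_groups):
        sel = g == i
        yi, ei = y[sel], eta0[sel]
        if sigma_u <= 0:
            total += _obs_loglik(model.family, yi, ei, sigma_e)
            continue
        u = np.sqrt(2.0) * sigma_u * nodes
        ll_u = np.array([_obs_loglik(model.family, yi, ei + uu, sigma_e)
                         for uu in u])
        mx = ll_u.max()
        total += mx + np.log(np.sum(wts * np.exp(ll_u - mx)) / np.sqrt(np.pi))
    return float(total)


def _obs_loglik(family, y, eta, sigma_e):
    if family == "binomial":
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    if family == "poisson":
        return float(np.sum(y * eta - np.exp(eta) - gammaln(y + 1.0)))
    s2 = sigma_e * sigma_e
    r = y - eta
    return float(-0.5 * np.sum(_LOG2PI + np.log(s2) + r * r / s2))
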