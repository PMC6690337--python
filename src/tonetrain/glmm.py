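"""Logistic mixed-effects models by maximum likelihood.

``BinomialMixedModel`` fits a logistic regression with subject-level
random effects to trial-level binary accuracy data:

    y_it ~ Bernoulli(logistic(x_it' beta + z_it' u_i)),   u_i ~ N(0, Sigma)

The marginal likelihood integrates the random effects out numerically:
adaptive Gauss–Hermite quadrature when a single random effect is present
(per-subject mode and curvature relocate the nodes), and a Laplace
approximation for multivariate random effects.  ``fit`` maximises the
marginal likelihood with L-BFGS-B over the fixed effects and a
log-Cholesky parameterisation of Sigma, and walks a deterministic
fallback ladder on non-convergence: full covariance → correlations
removed → random intercept only, recording the level reached.

Standard errors come from the inverse observed information (numerical
Hessian at the optimum); inference is Wald, z = beta/SE with a normal
reference and no df correction, matching the reporting convention of the
analyses this implements.  No multiple-testing adjustment is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import linalg, optimize
from scipy.special import expit, logsumexp
from scipy.stats import norm

__all__ = ["ModelSpec", "BinomialMixedModel", "BinomialMixedResults", "fit_glmm"]

_SEPARATION_CAP = 10.0  # |beta| beyond this is flagged as quasi-separation
_LADDER = ("full", "no_correlations", "intercept_only")


@dataclass
class ModelSpec:
    """Declarative description of one analysis model.

    ``fixed`` and ``random`` list term names; a term is either a column
    of the (contrast-coded) trial table, the literal ``"intercept"``, or
    a product ``"a:b"`` of columns.  Random terms are the within-subject
    slopes; a random intercept is always included.  ``task`` and
    ``sessions`` filter the trial table before fitting.
    """

    name: str
    outcome: str
    fixed: list[str]
    random: list[str] = field(default_factory=list)
    group: str = "subject_id"
    task: str | None = None
    sessions: tuple | None = None
    correlated: bool = True


def _softplus(eta: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, eta)


def term_matrix(data: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[str]]:
    """Resolve term names (columns, "intercept", "a:b" products) to a matrix."""
    cols = []
    unknown = []
    for term in terms:
        if term == "intercept":
            cols.append(np.ones(len(data)))
            continue
        parts = term.split(":")
        if any(p not in data.columns for p in parts):
            unknown.extend(p for p in parts if p not in data.columns)
            continue
        prod = np.ones(len(data))
        for p in parts:
            prod = prod * data[p].to_numpy(dtype=float)
        cols.append(prod)
    if unknown:
        raise KeyError(
            f"unknown term column(s): {sorted(set(unknown))}; "
            f"available: {sorted(data.columns)}"
        )
    return np.column_stack(cols) if cols else np.empty((len(data), 0)), list(terms)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if X.shape[1] == 0:
        raise ValueError("design matrix has no columns")
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if bad:
        raise ValueError(f"design matrix is rank deficient; aliased term(s): {bad}")


def _fit_plain_logistic(
    y: np.ndarray, X: np.ndarray, maxiter: int = 100, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, float]:
    """Newton–Raphson logistic regression (random variances fixed at zero)."""
    beta = np.zeros(X.shape[1])
    ll = -np.inf
    for _ in range(maxiter):
        eta = X @ beta
        p = expit(eta)
        new_ll = float(np.sum(y * eta - _softplus(eta)))
        grad = X.T @ (y - p)
        W = p * (1.0 - p)
        H = X.T @ (X * W[:, None])
        try:
            step = linalg.solve(H, grad, assume_a="pos")
        except linalg.LinAlgError:
            step = linalg.lstsq(H, grad)[0]
        # step-halving keeps the likelihood non-decreasing
        scale = 1.0
        while scale > 1e-8:
            cand = beta + scale * step
            eta_c = X @ cand
            if np.sum(y * eta_c - _softplus(eta_c)) >= new_ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        if abs(new_ll - ll) < tol * (abs(new_ll) + 1.0):
            ll = new_ll
            break
        ll = new_ll
    eta = X @ beta
    p = expit(eta)
    W = p * (1.0 - p)
    cov = linalg.pinvh(X.T @ (X * W[:, None]))
    return beta, cov, float(np.sum(y * eta - _softplus(eta)))


class BinomialMixedModel:
    """Logistic mixed model for grouped binary trial data.

    Parameters
    ----------
    endog : array (n,)
        Binary outcomes.
    exog : array (n, k)
        Fixed-effects design matrix.
    groups : array (n,)
        Group (subject) labels.
    exog_re : array (n, q), optional
        Random-effects design matrix per row; first column should be the
        constant (random intercept).  ``None`` fits a plain logistic
        regression.
    """

    def __init__(
        self,
        endog,
        exog,
        groups,
        exog_re=None,
        exog_names: list[str] | None = None,
        re_names: list[str] | None = None,
        quad_points: int = 15,
    ) -> None:
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim == 1:
            self.exog = self.exog[:, None]
        if not np.isin(self.endog, (0.0, 1.0)).all():
            raise ValueError("outcome must be binary 0/1")
        self.exog_names = exog_names or [f"x{i}" for i in range(self.exog.shape[1])]
        _check_rank(self.exog, self.exog_names)
        codes, uniques = pd.factorize(np.asarray(groups))
        if len(uniques) < 2 and exog_re is not None:
            raise ValueError("need at least 2 groups to estimate random effects")
        self.group_codes = codes
        self.group_labels = list(uniques)
        self.n_groups = len(uniques)
        if exog_re is not None:
            exog_re = np.asarray(exog_re, dtype=float)
            if exog_re.ndim == 1:
                exog_re = exog_re[:, None]
        self.exog_re = exog_re
        self.re_names = re_names or (
            [f"re{i}" for i in range(exog_re.shape[1])] if exog_re is not None else []
        )
        self.quad_points = quad_points
        self._gh_nodes, self._gh_weights = hermgauss(quad_points)
        self._rows_by_group = [
            np.flatnonzero(self.group_codes == g) for g in range(self.n_groups)
        ]
        self._warm: dict[tuple, np.ndarray] = {}

    # ---------------------------------------------------------------- params
    def _n_cov_params(self, structure: str, q: int) -> int:
        if structure == "no_correlations":
            return q
        return q * (q + 1) // 2  # log-Cholesky

    def _unpack(self, params: np.ndarray, structure: str, q: int):
        k = self.exog.shape[1]
        beta = params[:k]
        theta = params[k:]
        if q == 0:
            return beta, None
        if structure == "no_correlations":
            L = np.diag(np.exp(theta))
        else:
            L = np.zeros((q, q))
            pos = 0
            for i in range(q):
                for j in range(i + 1):
                    if i == j:
                        L[i, j] = np.exp(theta[pos])
                    else:
                        L[i, j] = theta[pos]
                    pos += 1
        return beta, L

    # ------------------------------------------------------------- likelihood
    def loglike(self, params: np.ndarray, structure: str = "full", q: int | None = None) -> float:
        """Marginal log-likelihood (random effects integrated out)."""
        if self.exog_re is None:
            beta = params
            eta = self.exog @ beta
            return float(np.sum(self.endog * eta - _softplus(eta)))
        q = q if q is not None else self.exog_re.shape[1]
        beta, L = self._unpack(params, structure, q)
        if q == 1:
            sigma = float(L[0, 0])
            return self._loglike_agq1(beta, sigma, structure)
        return self._loglike_laplace(beta, L, q, structure)

    def _loglike_agq1(self, beta: np.ndarray, sigma: float, structure: str) -> float:
        """Adaptive Gauss–Hermite quadrature for a single random effect."""
        y = self.endog
        g = self.group_codes
        G = self.n_groups
        z = self.exog_re[:, 0]
        eta_fixed = self.exog @ beta
        if sigma < 1e-8:
            eta = eta_fixed
            return float(np.sum(y * eta - _softplus(eta)))
        key = ("agq1", structure)
        u = self._warm.get(key, np.zeros(G)).copy()
        inv_s2 = 1.0 / (sigma * sigma)
        for _ in range(100):
            eta = eta_fixed + u[g] * z
            p = expit(eta)
            grad = np.bincount(g, weights=z * (y - p), minlength=G) - u * inv_s2
            w = p * (1.0 - p)
            hess = np.bincount(g, weights=z * z * w, minlength=G) + inv_s2
            step = grad / hess
            u += step
            if np.max(np.abs(step)) < 1e-9:
                break
        self._warm[key] = u
        eta = eta_fixed + u[g] * z
        p = expit(eta)
        hess = np.bincount(g, weights=z * z * p * (1 - p), minlength=G) + inv_s2
        sd_hat = 1.0 / np.sqrt(hess)
        t, w_gh = self._gh_nodes, self._gh_weights
        log_terms = np.empty((len(t), G))
        for k_ in range(len(t)):
            u_k = u + np.sqrt(2.0) * sd_hat * t[k_]
            eta_k = eta_fixed + u_k[g] * z
            f_k = (
                np.bincount(g, weights=y * eta_k - _softplus(eta_k), minlength=G)
                + norm.logpdf(u_k, 0.0, sigma)
            )
            log_terms[k_] = np.log(w_gh[k_]) + t[k_] ** 2 + f_k
        ll_g = np.log(np.sqrt(2.0) * sd_hat) + logsumexp(log_terms, axis=0)
        return float(np.sum(ll_g))

    def _loglike_laplace(self, beta: np.ndarray, L: np.ndarray, q: int, structure: str) -> float:
        """Laplace approximation for multivariate random effects."""
        y = self.endog
        eta_fixed = self.exog @ beta
        Sigma = L @ L.T + 1e-10 * np.eye(q)
        try:
            c = linalg.cho_factor(Sigma, lower=True)
        except linalg.LinAlgError:
            return -np.inf
        Sigma_inv = linalg.cho_solve(c, np.eye(q))
        logdet_sigma = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
        key = ("laplace", structure, q)
        U = self._warm.get(key)
        if U is None or U.shape != (self.n_groups, q):
            U = np.zeros((self.n_groups, q))
        U = U.copy()
        total = 0.0
        for gi, rows in enumerate(self._rows_by_group):
            Z = self.exog_re[rows]
            yg = y[rows]
            ef = eta_fixed[rows]
            u = U[gi]
            f_prev = -np.inf
            for _ in range(100):
                eta = ef + Z @ u
                p = expit(eta)
                grad = Z.T @ (yg - p) - Sigma_inv @ u
                W = p * (1.0 - p)
                H = Z.T @ (Z * W[:, None]) + Sigma_inv
                try:
                    step = linalg.solve(H, grad, assume_a="pos")
                except linalg.LinAlgError:
                    step = linalg.lstsq(H, grad)[0]
                f_cur = float(np.sum(yg * eta - _softplus(eta)) - 0.5 * u @ Sigma_inv @ u)
                scale = 1.0
                while scale > 1e-8:
                    cand = u + scale * step
                    eta_c = ef + Z @ cand
                    f_c = float(
                        np.sum(yg * eta_c - _softplus(eta_c)) - 0.5 * cand @ Sigma_inv @ cand
                    )
                    if f_c >= f_cur - 1e-12:
                        break
                    scale *= 0.5
                u = u + scale * step
                if np.max(np.abs(scale * step)) < 1e-9 or abs(f_c - f_prev) < 1e-12:
                    break
                f_prev = f_c
            U[gi] = u
            eta = ef + Z @ u
            p = expit(eta)
            W = p * (1.0 - p)
            H = Z.T @ (Z * W[:, None]) + Sigma_inv
            sign, logdet_h = np.linalg.slogdet(H)
            if sign <= 0:
                return -np.inf
            total += (
                float(np.sum(yg * eta - _softplus(eta)))
                - 0.5 * float(u @ Sigma_inv @ u)
                - 0.5 * logdet_sigma
                - 0.5 * logdet_h
            )
        self._warm[key] = U
        return total

    # ------------------------------------------------------------------- fit
    def _structure_for(self, level: str) -> tuple[str, np.ndarray, list[str]]:
        """Map a fallback level to (cov structure, exog_re, re names)."""
        if level == "intercept_only":
            return "no_correlations", self.exog_re[:, :1], self.re_names[:1]
        if level == "no_correlations":
            return "no_correlations", self.exog_re, self.re_names
        return "full", self.exog_re, self.re_names

    def fit(
        self,
        start_params: np.ndarray | None = None,
        fallback: bool = True,
        start_level: str = "full",
        maxiter: int = 500,
        gtol: float = 1e-3,
        verbose: bool = False,
    ) -> "BinomialMixedResults":
        """Maximise the marginal likelihood, walking the fallback ladder.

        Convergence requires the optimizer to report success with a
        projected-gradient sup-norm below ``gtol`` (relative likelihood
        tolerance 1e-8).  On failure the random-effects structure is
        simplified: correlations removed, then intercept only; the level
        reached is recorded on the results.  ``start_level`` enters the
        ladder lower down (e.g. ``"no_correlations"`` for models
        declared without slope correlations).
        """
        y, X = self.endog, self.exog
        k = X.shape[1]
        if self.exog_re is None:
            beta, cov, llf = _fit_plain_logistic(y, X)
            return BinomialMixedResults(
                model=self, params=beta, cov_params=cov, llf=llf, converged=True,
                fallback_level="none", structure="none", re_names=[], cov_re=None,
                optim_trace=[],
            )
        beta0, _, _ = _fit_plain_logistic(y, X)
        q_full = self.exog_re.shape[1]
        if start_level not in _LADDER:
            raise ValueError(f"unknown ladder level {start_level!r}")
        ladder = list(_LADDER)[list(_LADDER).index(start_level):]
        levels = ladder if fallback else [start_level]
        if q_full == 1:
            levels = ["full"]  # ladder collapses for a single random effect
        last_exc: Exception | None = None
        attempt = None
        for level in levels:
            structure, exog_re, re_names = self._structure_for(level)
            q = exog_re.shape[1]
            sub = BinomialMixedModel(
                y, X, self.group_codes, exog_re,
                exog_names=self.exog_names, re_names=re_names,
                quad_points=self.quad_points,
            ) if exog_re is not self.exog_re else self
            n_cov = self._n_cov_params(structure, q)
            if start_params is not None and len(start_params) == k + n_cov:
                p0 = np.asarray(start_params, dtype=float)
            else:
                p0 = np.concatenate([beta0, np.full(n_cov, 0.0)])
                if structure == "full" and q > 1:
                    theta0 = np.zeros(n_cov)
                    pos = 0
                    for i in range(q):
                        for j in range(i + 1):
                            theta0[pos] = np.log(0.5) if i == j else 0.0
                            pos += 1
                    p0 = np.concatenate([beta0, theta0])
                else:
                    p0 = np.concatenate([beta0, np.full(n_cov, np.log(0.5))])
            trace: list[float] = []

            def neg_ll(p, _sub=sub, _structure=structure, _q=q):
                val = _sub.loglike(p, structure=_structure, q=_q)
                return -val if np.isfinite(val) else 1e12

            # accepted-iterate likelihood trace (line-search evaluations are
            # not monotone; the accepted sequence is)
            callback = (lambda xk: trace.append(-neg_ll(xk))) if verbose else None

            bounds = [(None, None)] * k + [
                (-8.0, 5.0) if _is_log_diag(i, structure, q) else (-10.0, 10.0)
                for i in range(n_cov)
            ]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = optimize.minimize(
                    neg_ll, p0, method="L-BFGS-B", bounds=bounds, callback=callback,
                    options={"maxiter": maxiter, "ftol": 1e-8, "gtol": gtol},
                )
            grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
            converged = bool(res.success) and np.isfinite(res.fun) and grad_norm < max(
                gtol * 10, 1e-2 * (1 + abs(res.fun))
            )
            attempt = (sub, structure, q, re_names, res, trace, level)
            if converged:
                break
            last_exc = RuntimeError(res.message)
        sub, structure, q, re_names, res, trace, level = attempt
        params = res.x
        cov_params = self._cov_params(sub, params, structure, q)
        beta, L = sub._unpack(params, structure, q)
        cov_re = L @ L.T if L is not None else None
        results = BinomialMixedResults(
            model=self, params=params, cov_params=cov_params,
            llf=float(-res.fun), converged=bool(res.success), fallback_level=level,
            structure=structure, re_names=re_names,
            cov_re=pd.DataFrame(cov_re, index=re_names, columns=re_names)
            if cov_re is not None else None,
            optim_trace=trace,
        )
        if not results.converged and last_exc is not None:
            warnings.warn(
                f"model {getattr(self, 'name', '')} did not fully converge at any "
                f"fallback level (last: {last_exc})", RuntimeWarning, stacklevel=2,
            )
        return results

    @staticmethod
    def _cov_params(sub: "BinomialMixedModel", params, structure, q) -> np.ndarray:
        from statsmodels.tools.numdiff import approx_hess1

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            H = approx_hess1(params, lambda p: sub.loglike(p, structure=structure, q=q))
        try:
            cov = linalg.pinvh(-H)
        except linalg.LinAlgError:
            cov = np.full((len(params), len(params)), np.nan)
        d = np.diag(cov)
        if np.any(d < 0):
            cov = cov.copy()
            np.fill_diagonal(cov, np.where(d < 0, np.nan, d))
        return cov


def _is_log_diag(i: int, structure: str, q: int) -> bool:
    if structure == "no_correlations":
        return True
    pos = 0
    for r in range(q):
        for c in range(r + 1):
            if pos == i:
                return r == c
            pos += 1
    return False


class BinomialMixedResults:
    """Estimates, uncertainties and diagnostics from a fitted model."""

    def __init__(
        self, model, params, cov_params, llf, converged, fallback_level,
        structure, re_names, cov_re, optim_trace,
    ) -> None:
        self.model = model
        self.params = np.asarray(params)
        self._cov = np.asarray(cov_params)
        self.llf = llf
        self.converged = converged
        self.fallback_level = fallback_level
        self.structure = structure
        self.re_names = re_names
        self.cov_re = cov_re
        self.optim_trace = optim_trace
        k = model.exog.shape[1]
        self.fe_params = pd.Series(self.params[:k], index=model.exog_names)
        with np.errstate(invalid="ignore"):
            self.bse = pd.Series(np.sqrt(np.diag(self._cov)[:k]), index=model.exog_names)
        self.zvalues = self.fe_params / self.bse
        self.pvalues = 2.0 * norm.sf(np.abs(self.zvalues))
        self.separation_flags = np.abs(self.fe_params.to_numpy()) > _SEPARATION_CAP
        if self.separation_flags.any():
            flagged = [n for n, f in zip(model.exog_names, self.separation_flags) if f]
            warnings.warn(
                f"possible separation: |estimate| > {_SEPARATION_CAP} for {flagged}",
                RuntimeWarning, stacklevel=2,
            )

    def wald_table(self) -> pd.DataFrame:
        """Coefficient report (term, beta, SE, z, p), sorted by term name."""
        tab = pd.DataFrame(
            {
                "term": self.fe_params.index,
                "beta": self.fe_params.to_numpy(),
                "se": self.bse.to_numpy(),
                "z": self.zvalues.to_numpy(),
                "p": self.pvalues,
                "separation_flag": self.separation_flags,
            }
        )
        return tab.sort_values("term", kind="stable").reset_index(drop=True)

    def summary(self) -> str:
        lines = [
            "Binomial mixed model (logit link), marginal ML",
            f"  groups: {self.model.n_groups}   obs: {len(self.model.endog)}",
            f"  log-likelihood: {self.llf:.4f}   converged: {self.converged}"
            f"   fallback level: {self.fallback_level}",
            "",
            f"{'term':<30}{'beta':>10}{'SE':>10}{'z':>10}{'p':>10}",
        ]
        for _, row in self.wald_table().iterrows():
            lines.append(
                f"{row['term']:<30}{row['beta']:>10.4f}{row['se']:>10.4f}"
                f"{row['z']:>10.2f}{row['p']:>10.4f}"
            )
        if self.cov_re is not None:
            lines += ["", "random-effect SDs:"]
            for nm in self.re_names:
                lines.append(f"  {nm}: {np.sqrt(self.cov_re.loc[nm, nm]):.4f}")
        return "\n".join(lines)


def fit_glmm(
    spec: ModelSpec,
    data: pd.DataFrame,
    quad_points: int = 15,
    fallback: bool = True,
    verbose: bool = False,
) -> BinomialMixedResults:
    """Fit one analysis model described by a :class:`ModelSpec`.

    Filters the trial table by the spec's task/session, resolves the
    term names to design matrices (random intercept always included),
    and fits with the fallback ladder.
    """
    df = data
    if spec.task is not None:
        df = df[df["task"] == spec.task]
    if spec.sessions is not None:
        df = df[df["session"].isin(spec.sessions)]
    if df.empty:
        raise ValueError(f"model {spec.name!r}: no rows after task/session filter")
    y = df[spec.outcome].to_numpy(dtype=float)
    X, xnames = term_matrix(df, spec.fixed)
    re_terms = ["intercept"] + [t for t in spec.random if t != "intercept"]
    if len(df[spec.group].unique()) < 2:
        Z, znames = None, []
    else:
        Z, znames = term_matrix(df, re_terms)
    model = BinomialMixedModel(
        y, X, df[spec.group].to_numpy(), Z,
        exog_names=xnames, re_names=znames, quad_points=quad_points,
    )
    start_level = "full"
    if Z is not None and not spec.correlated and Z.shape[1] > 1:
        start_level = "no_correlations"
    return model.fit(fallback=fallback, start_level=start_level, verbose=verbose)
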