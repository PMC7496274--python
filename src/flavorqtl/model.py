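"""REML mixed model for the half-diallel marker-trait scan.

The model is ``y = fixed + cross.genotype + error`` with a separate genetic
variance component for every cross.  Two parameterizations arise:

* replicated data (several observations per genotype): variance components
  are the per-cross genotypic variances sigma2_g[c] plus a residual sigma2_e;
  the covariance is block diagonal over genotype groups
  (sigma2_e*I + sigma2_g*J within a group) and is inverted in closed form.
* one observation per genotype (genotype means, the usual scan input):
  sigma2_g[c] and sigma2_e are only identified through their sum, so the
  model collapses to heteroscedastic per-cross total variances v_c
  (``collapsed=True`` on the result).  This is the likelihood's identifiable
  parameterization of "cross.genotype + error" on means.

The restricted likelihood is maximized over non-negative components by
bounded quasi-Newton (L-BFGS-B; analytic gradient in the collapsed case)
followed by a Nelder-Mead polish.  Fixed effects are estimated by GLS at the
optimum; rank-deficient fixed designs are handled by pseudo-inverse.  Wald
tests for a block of fixed columns are computed as the quadratic form on the
subspace of those columns orthogonal to the remaining columns in the
V^{-1} metric — a basis-invariant construction whose degrees of freedom are
the rank of that subspace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

_LOGP_CAP = 300.0
_EPS = 1e-12


@dataclass
class VarianceComponents:
    """Estimated variance components of the half-diallel mixed model.

    When ``collapsed`` is True, ``sigma2_g`` holds the per-cross *total*
    variances v_c (genotypic + residual, jointly unidentifiable on genotype
    means) and ``sigma2_e`` is NaN.
    """

    sigma2_g: dict
    sigma2_e: float
    collapsed: bool

    def as_array(self, cross_order) -> np.ndarray:
        v = [self.sigma2_g[c] for c in cross_order]
        if not self.collapsed:
            v.append(self.sigma2_e)
        return np.asarray(v, dtype=float)


class HalfDiallelMixedLM:
    """Linear mixed model with per-cross genetic variance components.

    Parameters
    ----------
    endog : (n,) response (trait values or genotype means).
    exog : (n, p) fixed-effect design (intercept, nuisance and marker columns).
    cross : (n,) cross label per observation.
    genotype_id : optional (n,) genotype label; omitted or all-unique labels
        trigger the collapsed (heteroscedastic per-cross) parameterization.
    exog_names : optional column names for reporting.
    """

    def __init__(self, endog, exog, cross, genotype_id=None, exog_names=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("endog and exog have different lengths")
        if np.isnan(self.endog).any() or np.isnan(self.exog).any():
            raise ValueError("missing values must be removed before fitting")
        n, p = self.exog.shape
        cross = np.asarray(cross, dtype=object)
        if cross.shape[0] != n:
            raise ValueError("cross labels do not match endog")
        self.cross_order = list(dict.fromkeys(cross))
        self.cross_codes = np.array(
            [self.cross_order.index(c) for c in cross], dtype=np.intp
        )
        self.n_cross = len(self.cross_order)
        self.exog_names = (
            list(exog_names) if exog_names is not None else [f"x{j}" for j in range(p)]
        )

        if genotype_id is None:
            self.collapsed = True
        else:
            genotype_id = np.asarray(genotype_id, dtype=object)
            uniq, codes = np.unique(genotype_id, return_inverse=True)
            self.collapsed = len(uniq) == n
            if not self.collapsed:
                self.group_codes = codes
                self.group_sizes = np.bincount(codes).astype(float)
                # cross of each genotype group (groups never span crosses)
                gc = np.full(len(uniq), -1, dtype=np.intp)
                gc[codes] = self.cross_codes
                if np.any(gc < 0):
                    raise ValueError("empty genotype group")
                self.group_cross = gc
        self.n_vc = self.n_cross if self.collapsed else self.n_cross + 1

    # ------------------------------------------------------------------
    # restricted log-likelihood (constants dropped)

    def loglike_restricted(self, variances) -> float:
        v = np.asarray(variances, dtype=float)
        ll, *_ = self._reml_parts(v)
        return ll

    def _reml_parts(self, v):
        X, y = self.exog, self.endog
        if self.collapsed:
            var_i = v[self.cross_codes]
            w = 1.0 / var_i
            sw = np.sqrt(w)
            Xw = X * sw[:, None]
            yw = y * sw
            A = Xw.T @ Xw
            Xty = Xw.T @ yw
            logdetV = float(np.sum(np.log(var_i)))
            yVy = float(yw @ yw)
        else:
            se = v[-1]
            sg = v[self.group_cross]  # per group
            r = self.group_sizes
            gamma = sg / (se + r * sg)
            S = np.zeros((len(r), X.shape[1]))
            np.add.at(S, self.group_codes, X)
            sy = np.zeros(len(r))
            np.add.at(sy, self.group_codes, y)
            A = (X.T @ X - S.T @ (gamma[:, None] * S)) / se
            Xty = (X.T @ y - S.T @ (gamma * sy)) / se
            logdetV = float(np.sum((r - 1) * np.log(se) + np.log(se + r * sg)))
            yVy = float(y @ y - gamma @ (sy**2)) / se
        # pseudo-logdet over the column space of X (rank fixed across v)
        evals = np.linalg.eigvalsh((A + A.T) / 2.0)
        tol = max(evals.max(), 0.0) * len(evals) * np.finfo(float).eps
        pos = evals[evals > tol]
        logdetA = float(np.sum(np.log(pos))) if pos.size else 0.0
        Ainv = np.linalg.pinv((A + A.T) / 2.0, hermitian=True)
        beta = Ainv @ Xty
        quad = yVy - float(Xty @ beta)
        ll = -0.5 * (logdetV + logdetA + quad)
        return ll, beta, Ainv, quad

    def _neg_ll_grad_collapsed(self, v):
        """Objective and analytic gradient for the collapsed case."""
        X, y = self.exog, self.endog
        var_i = v[self.cross_codes]
        w = 1.0 / var_i
        sw = np.sqrt(w)
        Xw = X * sw[:, None]
        yw = y * sw
        A = Xw.T @ Xw
        Xty = Xw.T @ yw
        evals = np.linalg.eigvalsh((A + A.T) / 2.0)
        tol = max(evals.max(), 0.0) * len(evals) * np.finfo(float).eps
        pos = evals[evals > tol]
        logdetA = float(np.sum(np.log(pos))) if pos.size else 0.0
        Ainv = np.linalg.pinv((A + A.T) / 2.0, hermitian=True)
        beta = Ainv @ Xty
        resid = y - X @ beta
        quad = float(np.sum(resid * resid * w))
        logdetV = float(np.sum(np.log(var_i)))
        nll = 0.5 * (logdetV + logdetA + quad)
        # dl/dv_c = -0.5 [ sum_{i in c} (1/v_i - h_i/v_i^2) - sum (r_i/v_i)^2 ]
        H = X @ Ainv
        h = np.einsum("ij,ij->i", H, X)
        tr_term = w - h * w * w
        quad_term = (resid * w) ** 2
        per_i = tr_term - quad_term
        grad = 0.5 * np.bincount(self.cross_codes, weights=per_i, minlength=self.n_cross)
        return nll, grad

    # ------------------------------------------------------------------

    def fit(self, start=None, tol: float = 1e-10, maxiter: int = 500, polish: bool = True):
        X, y = self.exog, self.endog
        n = len(y)
        scale = float(np.var(y)) if n > 1 else 0.0
        # degenerate response: all components at the zero bound
        beta0, rss0, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid0 = y - X @ beta0
        if float(resid0 @ resid0) <= max(scale, 1.0) * n * 1e-28:
            return self._degenerate_results(beta0)

        lb = max(scale, 1e-8) * 1e-10
        if start is None:
            start = self._start_values(resid0)
        start = np.clip(np.asarray(start, dtype=float), lb * 10, None)
        bounds = [(lb, None)] * self.n_vc

        if self.collapsed:
            res = optimize.minimize(
                self._neg_ll_grad_collapsed,
                start,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-15, "gtol": 1e-12},
            )
        else:
            res = optimize.minimize(
                lambda v: -self.loglike_restricted(v),
                start,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-15, "gtol": 1e-12},
            )
        if polish:
            # derivative-free refinement sharpens bound-constrained optima to
            # the closed-form/grid-oracle precision
            pol = optimize.minimize(
                lambda v: -self.loglike_restricted(v),
                res.x,
                method="Nelder-Mead",
                bounds=bounds,
                options={"xatol": tol, "fatol": tol, "maxiter": 4000},
            )
            best = pol if pol.fun <= res.fun else res
            converged = bool(res.success or pol.success)
        else:
            best = res
            converged = bool(res.success)
        v = np.asarray(best.x, dtype=float)

        ll, beta, Ainv, _ = self._reml_parts(v)
        v_rep = np.where(v <= lb * 10, 0.0, v)  # report bound hits as 0
        if self.collapsed:
            vc = VarianceComponents(
                {c: float(v_rep[i]) for i, c in enumerate(self.cross_order)},
                float("nan"),
                True,
            )
        else:
            vc = VarianceComponents(
                {c: float(v_rep[i]) for i, c in enumerate(self.cross_order)},
                float(v[-1]),
                False,
            )
        return HalfDiallelMixedLMResults(
            self, vc, np.asarray(beta), Ainv, float(ll), converged, v
        )

    def _start_values(self, resid0):
        if self.collapsed:
            v0 = np.array(
                [
                    max(np.var(resid0[self.cross_codes == c]), 1e-6)
                    for c in range(self.n_cross)
                ]
            )
            return v0
        tot = max(float(np.var(resid0)), 1e-6)
        return np.array([tot / 2] * self.n_cross + [tot / 2])

    def _degenerate_results(self, beta):
        vc = VarianceComponents(
            {c: 0.0 for c in self.cross_order},
            float("nan") if self.collapsed else 0.0,
            self.collapsed,
        )
        p = self.exog.shape[1]
        v_internal = np.full(self.n_vc, 0.0)
        return HalfDiallelMixedLMResults(
            self, vc, beta, np.zeros((p, p)), 0.0, True, v_internal, degenerate=True
        )

    # whitening at given variances (V^{-1/2} action on a vector/matrix)
    def _whiten(self, arr, v):
        arr = np.asarray(arr, dtype=float)
        vec = arr.ndim == 1
        A = arr[:, None] if vec else arr
        if self.collapsed:
            out = A / np.sqrt(v[self.cross_codes])[:, None]
        else:
            se = v[-1]
            sg = v[self.group_cross]
            r = self.group_sizes
            coef = 1.0 / np.sqrt(se + r * sg) - 1.0 / np.sqrt(se)
            means = np.zeros((len(r), A.shape[1]))
            np.add.at(means, self.group_codes, A)
            means /= r[:, None]
            out = A / np.sqrt(se) + coef[self.group_codes, None] * means[self.group_codes]
        return out[:, 0] if vec else out


class HalfDiallelMixedLMResults:
    """REML fit: variance components, GLS fixed effects and Wald machinery."""

    def __init__(self, model, vc, params, cov, llf, converged, v_internal, degenerate=False):
        self.model = model
        self.vc = vc
        self.params = params
        self._cov = cov
        self.llf = llf
        self.converged = converged
        self.degenerate = degenerate
        self._v = v_internal
        self.nobs = len(model.endog)

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self._cov), 0.0, None))

    def cov_params(self) -> np.ndarray:
        return self._cov

    def wald_test(self, cols) -> tuple[float, int, float]:
        """Basis-invariant Wald chi-square for H0: the ``cols`` block of the
        fixed design contributes nothing beyond the remaining columns.

        Returns (statistic, df, p) with df = rank of the tested subspace
        after projecting out the nuisance columns in the V^{-1} metric.
        """
        stat, df, p, _ = self._wald_parts(cols)
        return stat, df, p

    def partial_r2(self, cols) -> float:
        """Variance explained by the ``cols`` block on the whitened scale."""
        stat, df, p, base_rss = self._wald_parts(cols)
        return float(stat / base_rss) if base_rss > 0 else 0.0

    def _wald_parts(self, cols):
        if self.degenerate:
            return 0.0, 0, 1.0, 0.0
        model = self.model
        cols = np.asarray(cols, dtype=int)
        p = model.exog.shape[1]
        others = np.setdiff1d(np.arange(p), cols)
        v = np.where(self._v <= 0, _EPS, self._v)
        Xw = model._whiten(model.exog, v)
        yw = model._whiten(model.endog, v)
        X0, X1 = Xw[:, others], Xw[:, cols]
        if X0.shape[1]:
            # SVD-based orthonormal basis so rank-deficient nuisance designs
            # only project out their true column space
            U0, s0, _ = np.linalg.svd(X0, full_matrices=False)
            tol0 = max(X0.shape) * np.finfo(float).eps * (s0[0] if s0.size else 0.0)
            Q0 = U0[:, s0 > max(tol0, 1e-12)]
            y0 = yw - Q0 @ (Q0.T @ yw)
            R1 = X1 - Q0 @ (Q0.T @ X1)
        else:
            y0 = yw
            R1 = X1
        base_rss = float(y0 @ y0)
        if R1.size == 0:
            return 0.0, 0, 1.0, base_rss
        U, s, Vt = np.linalg.svd(R1, full_matrices=False)
        # directions below this share of the leading singular value are
        # treated as inestimable (collinear with the nuisance columns)
        tol = max(s[0] * 1e-7, 1e-10) if s.size else 0.0
        rank = int(np.sum(s > tol))
        if rank == 0:
            return 0.0, 0, 1.0, base_rss
        proj = U[:, :rank].T @ y0
        stat = float(proj @ proj)
        pval = float(stats.chi2.sf(stat, rank))
        self._last_directions = Vt[:rank].T  # (len(cols), rank) contrast basis
        return stat, rank, pval, base_rss

    def kenward_roger_test(self, cols) -> tuple[float, int, float, float]:
        """Small-sample Wald test of the ``cols`` block with the
        Kenward-Roger correction (collapsed/heteroscedastic models).

        Plug-in GLS Wald chi-squares ignore the sampling error of the REML
        variance estimates and run liberal at half-diallel sample sizes; the
        Kenward-Roger adjustment inflates the fixed-effect covariance and
        refers a scaled statistic to an F distribution with an estimated
        denominator df.  Returns (wald_statistic, df, p, denominator_df);
        the statistic is the unscaled Wald quadratic form (chi-square scale).
        """
        if self.degenerate:
            return 0.0, 0, 1.0, float("inf")
        model = self.model
        if not model.collapsed:
            stat, df, p = self.wald_test(cols)
            return stat, df, p, float("inf")
        cols = np.asarray(cols, dtype=int)
        X = model.exog
        n, p_dim = X.shape
        v = np.clip(self._v, _EPS, None)
        codes = model.cross_codes
        k = model.n_vc
        w = 1.0 / v[codes]
        Phi = self._cov  # pinv(X' V^-1 X)
        beta = self.params

        # test exactly the estimable directions of the projection-based Wald
        # (marker-coefficient combinations not collinear with the nuisance)
        wald_stat, q, chi2_p, _ = self._wald_parts(cols)
        if q == 0:
            return 0.0, 0, 1.0, float("inf")
        V_r = self._last_directions  # (len(cols), q)
        L = np.zeros((p_dim, q))
        L[cols] = V_r

        # per-component derivative blocks (V is linear and diagonal in v)
        P_list, Q_list = [], []
        for c in range(k):
            rows = codes == c
            Xc = X[rows]
            XtX = Xc.T @ Xc
            P_list.append(-XtX / v[c] ** 2)
            Q_list.append(XtX / v[c] ** 3)

        # REML expected information of the variance components
        H = X @ Phi @ X.T
        Pmat = np.diag(w) - (w[:, None] * w[None, :]) * H
        M2 = Pmat**2
        G = np.zeros((n, k))
        G[np.arange(n), codes] = 1.0
        info = 0.5 * (G.T @ M2 @ G)
        Wcov = np.linalg.pinv((info + info.T) / 2.0, hermitian=True)

        # adjusted covariance  Phi_A = Phi + 2 Lambda  (R terms vanish)
        mid = np.zeros_like(Phi)
        for c in range(k):
            for d in range(k):
                Qcd = Q_list[c] if c == d else 0.0
                term = (Qcd - P_list[c] @ Phi @ P_list[d]) if c == d else (
                    -P_list[c] @ Phi @ P_list[d]
                )
                mid += Wcov[c, d] * term
        Phi_A = Phi + 2.0 * (Phi @ mid @ Phi)

        bL = L.T @ beta
        MA = L.T @ Phi_A @ L
        Fstar = float(bL @ np.linalg.solve(MA, bL)) / q

        Theta = L @ np.linalg.solve(L.T @ Phi @ L, L.T)
        TP = [Theta @ Phi @ P_list[c] @ Phi for c in range(k)]
        tr1 = np.array([np.trace(t) for t in TP])
        A1 = float(tr1 @ Wcov @ tr1)
        A2 = 0.0
        for c in range(k):
            for d in range(k):
                A2 += Wcov[c, d] * float(np.sum(TP[c].T * TP[d]))
        Bq = (A1 + 6.0 * A2) / (2.0 * q)
        g = ((q + 1.0) * A1 - (q + 4.0) * A2) / ((q + 2.0) * A2) if A2 > 0 else 0.0
        denom = 3.0 * q + 2.0 * (1.0 - g)
        c1 = g / denom
        c2 = (q - g) / denom
        c3 = (q + 2.0 - g) / denom
        Estar = 1.0 / (1.0 - A2 / q) if A2 < q else 1.0
        Vstar = (2.0 / q) * (1.0 + c1 * Bq) / ((1.0 - c2 * Bq) ** 2 * (1.0 - c3 * Bq))
        rho = Vstar / (2.0 * Estar**2) if Estar > 0 else 1.0
        m = 4.0 + (q + 2.0) / (q * rho - 1.0) if q * rho > 1.0 else float("inf")
        lam = m / (Estar * (m - 2.0)) if np.isfinite(m) and m > 2.0 else 1.0
        FKR = max(lam * Fstar, 0.0)
        if np.isfinite(m):
            pval = float(stats.f.sf(FKR, q, m))
        else:
            pval = float(stats.chi2.sf(q * FKR, q))
        return wald_stat, q, pval, float(m)

    def summary(self) -> str:
        lines = ["Half-diallel mixed model (REML)"]
        lines.append(f"  n obs: {self.nobs}   converged: {self.converged}")
        kind = "per-cross total variance v_c (collapsed)" if self.vc.collapsed else "per-cross genotypic variance"
        lines.append(f"  variance components ({kind}):")
        for c, val in self.vc.sigma2_g.items():
            lines.append(f"    {c:>16s}: {val:.6g}")
        if not self.vc.collapsed:
            lines.append(f"    {'residual':>16s}: {self.vc.sigma2_e:.6g}")
        lines.append("  fixed effects:")
        for name, b, se in zip(self.model.exog_names, self.params, self.bse):
            lines.append(f"    {name:>16s}: {b:+.6g} (SE {se:.3g})")
        return "\n".join(lines)


def logp_from_p(p: float, cap: float = _LOGP_CAP) -> float:
    """-log10 P, capped to avoid infinities at machine-zero P."""
    if p <= 0.0:
        return cap
    return float(min(cap, -np.log10(p)))


def sum_to_zero_basis(k: int = 4) -> np.ndarray:
    """Orthonormal basis (k x k-1) of the sum-to-zero subspace (Helmert)."""
    H = np.zeros((k, k - 1))
    for j in range(1, k):
        H[:j, j - 1] = 1.0
        H[j, j - 1] = -j
        H[:, j - 1] /= np.sqrt(j * (j + 1))
    return H
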