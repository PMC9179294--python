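"""Variance-components linear mixed model for the twin/sister design.

The model for an individual outcome (an MRS) is

    y = X beta + u_family + u_mzpair + e

with independent random intercepts ``u_family ~ N(0, sigma2_f)`` shared by
every member of a family, an additional ``u_mzpair ~ N(0, sigma2_z)``
shared by monozygotic co-twins, and residual ``e ~ N(0, sigma2_e)``.  The
implied covariance of a family block is

    V_F = sigma2_f J + sigma2_z J_mz + sigma2_e I

so MZ co-twins have covariance ``sigma2_f + sigma2_z`` and DZ twins or
sisters ``sigma2_f``.  Variance components are estimated by restricted
maximum likelihood (REML) on the log scale with a bounded quasi-Newton
optimizer; fixed effects follow by generalized least squares at the
optimum.  The likelihood is evaluated family-blockwise, with families
grouped by covariance pattern so each distinct block matrix is inverted
once per evaluation.

``FamilyLMM`` / ``FamilyLMMResults`` follow the statsmodels model/results
convention; the module-level ``fit_reml``, ``build_covariance``,
``opera_scale`` and ``family_corr`` functions are the pipeline surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .cohort import Cohort

_LOG_LB, _LOG_UB = -15.0, 15.0  # bounds on log variance ratios

COMPONENT_NAMES = {
    "nested": ("sigma2_family", "sigma2_mzpair", "sigma2_resid"),
    "zygosity_pairs": ("sigma2_family", "sigma2_mzpair", "sigma2_dzpair",
                       "sigma2_resid"),
}


class ConvergenceError(RuntimeError):
    """REML optimizer failed; carries the optimizer trajectory."""

    def __init__(self, message: str, trajectory: list):
        super().__init__(message)
        self.trajectory = trajectory


# -- covariance structure ----------------------------------------------

class FamilyCovariance:
    """Block-diagonal covariance implied by the variance components."""

    def __init__(self, family_ids: list[str], blocks: list[np.ndarray],
                 row_positions: list[np.ndarray]):
        self.family_ids = family_ids
        self.blocks = blocks
        self.row_positions = row_positions

    def dense(self) -> np.ndarray:
        n = sum(len(r) for r in self.row_positions)
        V = np.zeros((n, n))
        for rows, block in zip(self.row_positions, self.blocks):
            V[np.ix_(rows, rows)] = block
        return V


def _family_patterns(cohort: Cohort):
    """Group families by covariance pattern.

    A pattern is the family size plus the within-family twin-pair
    labelling; families sharing a pattern share the same block matrix for
    any variance components.  Returns
    ``{pattern: (index_array (m, k), mz_design (k, k), dz_design (k, k))}``.
    """
    tab = cohort.table
    zyg = tab["zygosity"].to_numpy()
    pair = tab["pair_id"].to_numpy(object)
    patterns: dict[tuple, list[np.ndarray]] = {}
    for rows in cohort.family_index().values():
        labels = []
        seen: dict = {}
        nxt = 0
        for pos in rows:
            p = pair[pos]
            if p is not None and not pd.isna(p) and zyg[pos] in ("MZ", "DZ"):
                key = (zyg[pos], p)
            else:
                key = ("solo", pos)
            if key not in seen:
                seen[key] = nxt
                nxt += 1
            labels.append((seen[key], key[0]))
        patterns.setdefault(tuple(labels), []).append(rows)
    out = {}
    for labels, fam_rows in patterns.items():
        k = len(labels)
        mz = np.zeros((k, k))
        dz = np.zeros((k, k))
        for i, (li, ti) in enumerate(labels):
            for j, (lj, tj) in enumerate(labels):
                if li == lj and ti == tj == "MZ":
                    mz[i, j] = 1.0
                if li == lj and ti == tj == "DZ":
                    dz[i, j] = 1.0
        out[labels] = (np.asarray(fam_rows, dtype=int), mz, dz)
    return out


def build_covariance(cohort: Cohort,
                     components: tuple[float, float, float]) -> FamilyCovariance:
    """Per-family covariance blocks for components (sigma2_f, sigma2_z, sigma2_e).

    Every block is symmetric positive semi-definite by construction
    (a non-negative combination of J, MZ-pair J blocks and I).
    """
    s2f, s2z, s2e = components
    if min(s2f, s2z, s2e) < 0:
        raise ValueError("variance components must be non-negative")
    fids, blocks, rows_out = [], [], []
    tab = cohort.table
    zyg = tab["zygosity"].to_numpy()
    pair = tab["pair_id"].to_numpy(object)
    for fid, rows in cohort.family_index().items():
        k = len(rows)
        V = s2f * np.ones((k, k)) + s2e * np.eye(k)
        for i in range(k):
            for j in range(k):
                pi, pj = pair[rows[i]], pair[rows[j]]
                if (zyg[rows[i]] == "MZ" and zyg[rows[j]] == "MZ"
                        and pi is not None and not pd.isna(pi) and pi == pj):
                    V[i, j] += s2z
        fids.append(fid)
        blocks.append(V)
        rows_out.append(rows)
    return FamilyCovariance(fids, blocks, rows_out)


# -- model --------------------------------------------------------------

class FamilyLMM:
    """Linear mixed model with family and MZ-pair random intercepts.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Outcome, aligned to cohort row order.
    exog : array-like, shape (n, p)
        Fixed-effect design matrix (include the intercept explicitly).
    cohort : Cohort
        Supplies the family and MZ-pair structure.
    exog_names : sequence of str, optional
        Column names for reporting.
    structure : {"nested", "zygosity_pairs"}
        ``"nested"`` (default) is a family intercept for all members plus
        an extra MZ-pair intercept; ``"zygosity_pairs"`` instead gives
        every twin pair its own intercept with zygosity-specific variances
        (sigma2_mzpair for MZ, sigma2_dzpair for DZ) on top of the family
        intercept.
    """

    def __init__(self, endog, exog, cohort: Cohort, exog_names=None,
                 structure: str = "nested"):
        if structure not in COMPONENT_NAMES:
            raise ValueError(f"unknown structure {structure!r}")
        self.structure = structure
        y = np.asarray(endog, dtype=float)
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if len(y) != len(cohort) or X.shape[0] != len(cohort):
            raise ValueError("endog/exog not aligned to cohort")
        if np.isnan(y).any() or np.isnan(X).any():
            raise ValueError("endog and exog must be complete")
        if exog_names is None:
            exog_names = [f"x{j}" for j in range(X.shape[1])]
        if len(exog_names) != X.shape[1]:
            raise ValueError("exog_names length mismatch")
        self._check_rank(X, exog_names)
        self.endog, self.exog = y, X
        self.exog_names = list(exog_names)
        self.cohort = cohort
        self.n, self.p = X.shape
        self.patterns = _family_patterns(cohort)
        self.n_families = cohort.n_families
        zyg = cohort.table["zygosity"]
        self._has_mz = bool((zyg == "MZ").any())
        self._has_dz = bool(((zyg == "DZ")
                             & cohort.table["pair_id"].notna()).any())
        sizes = cohort.table.groupby("family_id").size()
        self._has_multi = bool((sizes > 1).any())
        # family and MZ-pair intercepts are confounded when every family
        # is exactly one MZ pair: pin sigma2_f to zero in that case
        self._mz_only = bool((zyg == "MZ").all() and (sizes == 2).all()
                             and cohort.table["pair_id"].notna().all())

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str,
                       predictors: list[str], cohort: Cohort,
                       add_intercept: bool = True) -> "FamilyLMM":
        """Build the model from named columns of a cohort-aligned frame."""
        if not np.array_equal(data["id"].to_numpy(), cohort.ids):
            raise ValueError("data rows not aligned to cohort ids")
        cols = list(predictors)
        X = data[cols].to_numpy(dtype=float)
        names = cols
        if add_intercept:
            X = np.column_stack([np.ones(len(data)), X])
            names = ["const"] + cols
        return cls(data[outcome].to_numpy(dtype=float), X, cohort, names)

    @staticmethod
    def _check_rank(X: np.ndarray, names) -> None:
        _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0
        rank = int((diag > tol).sum())
        if rank < X.shape[1]:
            bad = [names[j] for j in piv[rank:]]
            raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    # -- likelihood machinery -----------------------------------------
    @property
    def n_vc(self) -> int:
        """Number of variance components in the chosen structure."""
        return len(COMPONENT_NAMES[self.structure])

    def _expand(self, components) -> tuple[float, float, float, float]:
        """Map structure-specific components to (s2f, s2mz, s2dz, s2e)."""
        components = tuple(components)
        if len(components) != self.n_vc:
            raise ValueError(f"expected {self.n_vc} components")
        if self.structure == "nested":
            s2f, s2z, s2e = components
            return s2f, s2z, 0.0, s2e
        return components

    def _accumulate(self, components):
        """Blockwise GLS cross-products and log|V| at given components."""
        s2f, s2mz, s2dz, s2e = components
        X, y = self.exog, self.endog
        xtvx = np.zeros((self.p, self.p))
        xtvy = np.zeros(self.p)
        ytvy = 0.0
        logdet = 0.0
        for idx, mz, dz in self.patterns.values():
            k = mz.shape[0]
            V = (s2f * np.ones((k, k)) + s2mz * mz + s2dz * dz
                 + s2e * np.eye(k))
            sign, ld = np.linalg.slogdet(V)
            if sign <= 0:
                return None
            Vinv = np.linalg.inv(V)
            Xg = X[idx]                     # (m, k, p)
            yg = y[idx]                     # (m, k)
            VinvX = np.einsum("kl,mlp->mkp", Vinv, Xg)
            xtvx += np.einsum("mkp,mkq->pq", VinvX, Xg)
            xtvy += np.einsum("mkp,mk->p", VinvX, yg)
            ytvy += float(np.einsum("mk,kl,ml->", yg, Vinv, yg))
            logdet += idx.shape[0] * ld
        return xtvx, xtvy, ytvy, logdet

    def _reml_loglike(self, components) -> float:
        acc = self._accumulate(self._expand(components))
        if acc is None:
            return -np.inf
        xtvx, xtvy, ytvy, logdet = acc
        sign, ld_xtvx = np.linalg.slogdet(xtvx)
        if sign <= 0:
            return -np.inf
        beta = np.linalg.solve(xtvx, xtvy)
        quad = ytvy - xtvy @ beta
        return -0.5 * ((self.n - self.p) * np.log(2 * np.pi) + logdet
                       + ld_xtvx + quad)

    def _ml_loglike(self, components) -> float:
        acc = self._accumulate(self._expand(components))
        if acc is None:
            return -np.inf
        xtvx, xtvy, ytvy, logdet = acc
        beta = np.linalg.solve(xtvx, xtvy)
        quad = ytvy - xtvy @ beta
        return -0.5 * (self.n * np.log(2 * np.pi) + logdet + quad)

    # -- fitting --------------------------------------------------------
    def _profiled_crit(self, gammas) -> float:
        """-2 x profiled REML criterion over variance ratios.

        With V = sigma2_e W(gamma), W = I + gamma_f J + gamma_mz J_mz
        (+ gamma_dz J_dz under the zygosity_pairs structure), the residual
        variance has the closed form sigma2_e = q / (n - p) where q is the
        GLS residual quadratic form under W; the criterion below is -2
        REML log-likelihood with sigma2_e profiled out, up to the additive
        constant (n - p)(1 + log 2 pi).
        """
        acc = self._accumulate((*gammas, 1.0))
        if acc is None:
            return np.inf
        xtvx, xtvy, ytvy, logdetw = acc
        sign, ld_xtvx = np.linalg.slogdet(xtvx)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(xtvx, xtvy)
        q = ytvy - xtvy @ beta
        if q <= 0:
            return np.inf
        df = self.n - self.p
        return df * np.log(q / df) + logdetw + ld_xtvx

    def fit(self, method: str = "reml", maxiter: int = 200,
            n_restarts: int = 4) -> "FamilyLMMResults":
        """Maximize the REML criterion over the variance components.

        The family and MZ-pair components are optimized as log variance
        ratios (relative to the residual) with a bounded quasi-Newton
        optimizer, the residual variance being profiled out in closed
        form.  Structurally unidentified components (no MZ pairs ->
        sigma2_z; no multi-member families -> sigma2_f; MZ-pairs-only
        cohorts, where family and pair intercepts are confounded ->
        sigma2_f) are pinned to exactly zero, as are ratios that converge
        to the lower boundary.  On non-convergence the optimizer restarts
        from perturbed points; persistent failure raises
        :class:`ConvergenceError` with the trajectory.
        """
        if method != "reml":
            raise ValueError("only REML fitting is supported")
        free_f = self._has_multi and not self._mz_only
        if self.structure == "nested":
            free = np.array([free_f, self._has_mz, False])
        else:
            free = np.array([free_f, self._has_mz, self._has_dz])
        trajectory: list = []

        def unpack(theta):
            g = np.zeros(3)
            g[free] = np.exp(theta)
            return g

        if free.any():
            def crit(theta):
                return self._profiled_crit(unpack(theta))

            rng = np.random.default_rng(0)
            best = None
            start = np.log(np.full(int(free.sum()), 0.5))
            for attempt in range(n_restarts + 1):
                theta0 = start if attempt == 0 else (
                    start + rng.normal(0, 1.0 + attempt, start.shape))
                res = optimize.minimize(
                    crit, theta0, method="L-BFGS-B",
                    bounds=[(_LOG_LB, _LOG_UB)] * len(theta0),
                    options={"maxiter": maxiter, "ftol": 1e-13,
                             "gtol": 1e-9})
                trajectory.append({"attempt": attempt,
                                   "success": bool(res.success),
                                   "fun": float(res.fun),
                                   "nit": int(res.nit)})
                if best is None or res.fun < best.fun - 1e-10:
                    best = res
                if res.success:
                    break
            if best is None or not np.isfinite(best.fun):
                raise ConvergenceError("REML optimization failed", trajectory)
            gammas = unpack(best.x)
            gammas[gammas < 1e-6] = 0.0  # boundary snap
            converged = bool(best.success)
        else:
            gammas = np.zeros(3)
            converged = True

        acc = self._accumulate((*gammas, 1.0))
        xtwx, xtwy, ytwy, _ = acc
        beta = np.linalg.solve(xtwx, xtwy)
        q = ytwy - xtwy @ beta
        s2e = q / (self.n - self.p)
        if self.structure == "nested":
            comps = np.array([gammas[0] * s2e, gammas[1] * s2e, s2e])
        else:
            comps = np.array([gammas[0] * s2e, gammas[1] * s2e,
                              gammas[2] * s2e, s2e])
        llf_reml = self._reml_loglike(comps)
        llf_ml = self._ml_loglike(comps)

        xtvx, xtvy, ytvy, _ = self._accumulate(self._expand(comps))
        cov_params = np.linalg.inv(xtvx)
        params = cov_params @ xtvy
        return FamilyLMMResults(self, params, cov_params, comps, llf_reml,
                                llf_ml, converged=converged,
                                trajectory=trajectory)


class FamilyLMMResults:
    """Fitted :class:`FamilyLMM`: estimates, uncertainty, diagnostics.

    Wald inference with a normal reference distribution; the Bayesian
    information criterion uses the maximum-likelihood log-likelihood
    evaluated at the REML variance components, with parameter count
    ``p + n_vc`` (fixed effects plus the structure's variance components)
    and sample size ``n`` individuals.
    """

    def __init__(self, model, params, cov_params, components, llf_reml,
                 llf_ml, converged, trajectory):
        self.model = model
        self._params = np.asarray(params)
        self.cov_params = np.asarray(cov_params)
        self.components = dict(zip(COMPONENT_NAMES[model.structure],
                                   np.asarray(components)))
        self.llf_reml = float(llf_reml)
        self.llf_ml = float(llf_ml)
        self.converged = converged
        self.trajectory = trajectory

    # -- fixed effects --------------------------------------------------
    @property
    def params(self) -> pd.Series:
        return pd.Series(self._params, index=self.model.exog_names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)),
                         index=self.model.exog_names)

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * stats.norm.sf(np.abs(self.zvalues)),
                         index=self.model.exog_names)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame({"lower": self.params - q * self.bse,
                             "upper": self.params + q * self.bse})

    # -- fit statistics --------------------------------------------------
    @property
    def n_params(self) -> int:
        return self.model.p + self.model.n_vc

    @property
    def bic(self) -> float:
        return -2.0 * self.llf_ml + self.n_params * np.log(self.model.n)

    def intraclass_correlations(self) -> dict[str, float]:
        """Implied within-pair correlations of the outcome.

        Under the nested structure an MZ co-twin's variance carries the
        extra pair component, so the MZ correlation is
        ``(s2f + s2z) / (s2f + s2z + s2e)`` while DZ twins and sisters
        have ``s2f / (s2f + s2e)``.
        """
        s2f = self.components["sigma2_family"]
        s2z = self.components["sigma2_mzpair"]
        s2e = self.components["sigma2_resid"]
        if self.model.structure == "zygosity_pairs":
            s2d = self.components["sigma2_dzpair"]
            return {"mz": (s2f + s2z) / (s2f + s2z + s2e),
                    "dz": (s2f + s2d) / (s2f + s2d + s2e),
                    "dz_sib": s2f / (s2f + s2e)}
        return {"mz": (s2f + s2z) / (s2f + s2z + s2e),
                "dz_sib": s2f / (s2f + s2e)}

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Family variance-components linear mixed model (REML)",
            "=" * 64,
            f"N individuals: {self.model.n:>6d}    "
            f"N families: {self.model.n_families:>6d}",
            f"REML loglike: {self.llf_reml: .4f}    "
            f"ML loglike: {self.llf_ml: .4f}",
            f"BIC (ML, k={self.n_params}): {self.bic: .4f}    "
            f"converged: {self.converged}",
            "-" * 64,
            f"{'':>14s} {'coef':>9s} {'se':>8s} {'z':>7s} {'P>|z|':>9s}"
            f" {'[0.025':>8s} {'0.975]':>8s}",
        ]
        for name in self.model.exog_names:
            lines.append(
                f"{name:>14.14s} {self.params[name]:>9.4f} "
                f"{self.bse[name]:>8.4f} {self.zvalues[name]:>7.2f} "
                f"{self.pvalues[name]:>9.2e} {ci.loc[name, 'lower']:>8.4f} "
                f"{ci.loc[name, 'upper']:>8.4f}")
        lines.append("-" * 64)
        icc = self.intraclass_correlations()
        for name, val in self.components.items():
            lines.append(f"{name:>20s}: {val:.6f}")
        lines.append(f"implied correlations: MZ {icc['mz']:.3f}, "
                     f"DZ/sister {icc['dz_sib']:.3f}")
        return "\n".join(lines)

    def to_json(self) -> dict:
        ci = self.conf_int()
        return {
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "pvalues": self.pvalues.to_dict(),
            "conf_int": {k: [ci.loc[k, "lower"], ci.loc[k, "upper"]]
                         for k in self.model.exog_names},
            "components": self.components,
            "llf_reml": self.llf_reml,
            "llf_ml": self.llf_ml,
            "bic": self.bic,
            "n_individuals": self.model.n,
            "n_families": self.model.n_families,
            "converged": self.converged,
            "n_optimizer_attempts": len(self.trajectory),
        }


def fit_reml(y, X, cohort: Cohort, exog_names=None,
             structure: str = "nested") -> FamilyLMMResults:
    """Fit the family/MZ-pair variance-components model by REML."""
    return FamilyLMM(y, X, cohort, exog_names=exog_names,
                     structure=structure).fit()


# -- OPERA scaling -------------------------------------------------------

@dataclass(frozen=True)
class OperaCoefficient:
    """Association per adjusted standard deviation of the predictor.

    The raw mixed-model coefficient is multiplied by the standard deviation
    of the predictor's residuals after OLS adjustment for the model's other
    covariates, giving the change in outcome per covariate-adjusted SD of
    the predictor.
    """

    estimate: float
    ci_lower: float
    ci_upper: float
    p_value: float
    adjusted_sd: float


def opera_scale(fit: FamilyLMMResults, predictor: str,
                covariate_matrix: np.ndarray | None = None,
                alpha: float = 0.05) -> OperaCoefficient:
    """Scale a fitted coefficient per adjusted SD of its predictor.

    ``predictor`` names a fixed effect in ``fit``; the predictor column is
    regressed (OLS) on the remaining fixed effects (or an explicit
    ``covariate_matrix``) and the raw coefficient, CI bounds and the
    p-value's implied scale are multiplied by the residual SD.
    """
    names = fit.model.exog_names
    if predictor not in names:
        raise KeyError(f"predictor {predictor!r} not among fixed effects")
    j = names.index(predictor)
    x = fit.model.exog[:, j]
    if covariate_matrix is None:
        covariate_matrix = np.delete(fit.model.exog, j, axis=1)
    C = np.asarray(covariate_matrix, dtype=float)
    if C.size:
        beta, *_ = np.linalg.lstsq(C, x, rcond=None)
        resid = x - C @ beta
    else:
        resid = x - x.mean()
    s = float(resid.std(ddof=1))
    if s <= 0:
        raise ValueError("zero-variance residualized predictor")
    ci = fit.conf_int(alpha)
    return OperaCoefficient(
        estimate=float(fit.params[predictor] * s),
        ci_lower=float(ci.loc[predictor, "lower"] * s),
        ci_upper=float(ci.loc[predictor, "upper"] * s),
        p_value=float(fit.pvalues[predictor]),
        adjusted_sd=s,
    )


# -- family-aware correlation --------------------------------------------

@dataclass(frozen=True)
class FamilyCorrResult:
    """Pearson correlation with family-clustered uncertainty."""

    r: float
    ci_lower: float
    ci_upper: float
    p_clustered: float
    p_naive: float
    n: int
    n_families: int
    n_boot: int


def _fisher_p(r: float, n_eff: int) -> float:
    if n_eff <= 3:
        return 1.0
    if 1.0 - abs(r) < 1e-15:
        return 0.0
    z = np.arctanh(r) * np.sqrt(n_eff - 3)
    return float(2 * stats.norm.sf(abs(z)))


def family_corr(x, y, cohort: Cohort, n_boot: int = 1000, seed: int = 0,
                alpha: float = 0.05) -> FamilyCorrResult:
    """Pearson correlation with a family-resampling bootstrap CI.

    The percentile CI resamples whole families with replacement, respecting
    the within-family dependence of twins and sisters.  The clustered
    p-value uses a Fisher z statistic with effective sample size equal to
    the number of families (singleton sisters count as their own family);
    the naive individual-level Fisher z p-value is reported alongside.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(cohort) or len(y) != len(cohort):
        raise ValueError("x/y not aligned to cohort")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200")
    r = float(np.corrcoef(x, y)[0, 1])

    # resampling whole families only needs per-family sufficient statistics:
    # a bootstrap draw is a multinomial count vector over families, and the
    # resampled correlation is a function of count-weighted family sums
    fam_rows = list(cohort.family_index().values())
    n_fam = len(fam_rows)
    stats_mat = np.empty((n_fam, 6))
    for i, rows in enumerate(fam_rows):
        xf, yf = x[rows], y[rows]
        stats_mat[i] = [len(rows), xf.sum(), yf.sum(), (xf * xf).sum(),
                        (yf * yf).sum(), (xf * yf).sum()]
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_fam, np.full(n_fam, 1.0 / n_fam),
                             size=n_boot).astype(float)
    tot = counts @ stats_mat
    nb, sx, sy, sxx, syy, sxy = tot.T
    var_x = nb * sxx - sx ** 2
    var_y = nb * syy - sy ** 2
    ok = (var_x > 0) & (var_y > 0)
    boots = np.full(n_boot, r)
    boots[ok] = (nb[ok] * sxy[ok] - sx[ok] * sy[ok]) / np.sqrt(
        var_x[ok] * var_y[ok])
    # median-unbiased quantiles (Hyndman-Fan type 8): the standard choice
    # for percentile-CI endpoints, slightly wider in the tails than linear
    # interpolation at finite bootstrap sizes
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2],
                         method="median_unbiased")
    return FamilyCorrResult(
        r=r, ci_lower=float(lo), ci_upper=float(hi),
        p_clustered=_fisher_p(r, n_fam), p_naive=_fisher_p(r, len(x)),
        n=len(x), n_families=n_fam, n_boot=n_boot,
    )
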