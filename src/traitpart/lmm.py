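"""Random-intercept mixed models for the blocked factorial design.

The only mixed model the analysis needs is a Gaussian response with fixed
factorial (or single-slope) terms and a random intercept per block, fitted by
restricted maximum likelihood.  The variance structure is profiled down to a
single ratio rho = var_block/var_resid, optimized in one dimension; fixed
effects are the GLS solution at the optimum.  F-tests use Satterthwaite
denominator degrees of freedom computed from the REML information matrix, and
collapse to the classical two-stratum RCBD ANOVA (den_df = (b-1)(t-1)) on
balanced layouts.  Marginal/conditional variance explained follows the
standard fixed-versus-fixed-plus-random decomposition.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .decompose import effect_columns

logger = logging.getLogger("traitpart")

FIXED_TERMS = ("nutrient", "fence", "nutrient:fence")


@dataclass
class LMMFit:
    coef: np.ndarray
    coef_names: list[str]
    se: np.ndarray
    var_block: float
    var_resid: float
    reml_criterion: float  # -2 * restricted log-likelihood
    fitted_fixed: np.ndarray
    X: np.ndarray
    y: np.ndarray
    Z: np.ndarray
    groups: np.ndarray
    term_cols: dict[str, list[int]] = field(default_factory=dict)
    converged: bool = True

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(self.coef, index=self.coef_names)


def _group_matrix(groups: np.ndarray) -> np.ndarray:
    labels = pd.unique(groups)
    return (groups[:, None] == labels[None, :]).astype(float)


def _neg2_reml(rho: float, y: np.ndarray, X: np.ndarray, Z: np.ndarray):
    n, p = X.shape
    Vs = np.eye(n) + rho * (Z @ Z.T)
    L = np.linalg.cholesky(Vs)
    Wy = np.linalg.solve(Vs, y)
    WX = np.linalg.solve(Vs, X)
    XtWX = X.T @ WX
    beta = np.linalg.solve(XtWX, X.T @ Wy)
    r = y - X @ beta
    rss = float(r @ np.linalg.solve(Vs, r))
    sigma2 = rss / (n - p)
    logdet_V = 2.0 * float(np.log(np.diag(L)).sum())
    sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    crit = (n - p) * (np.log(2 * np.pi * sigma2) + 1.0) + logdet_V + logdet_XtWX
    return crit, beta, sigma2, XtWX


def _reml_grad(rho: float, y: np.ndarray, X: np.ndarray, Z: np.ndarray) -> float:
    """d(-2 restricted loglik)/d rho with sigma^2 profiled out."""
    n, p = X.shape
    B = Z @ Z.T
    Vs = np.eye(n) + rho * B
    Vi = np.linalg.inv(Vs)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    Vir = Vi @ r
    rss = float(r @ Vir)
    t1 = float(np.trace(Vi @ B))
    t2 = float(np.trace(np.linalg.solve(XtViX, X.T @ Vi @ B @ Vi @ X)))
    t3 = (n - p) * float(Vir @ B @ Vir) / rss
    return t1 - t2 - t3


def fit_random_intercept_lmm(
    y: np.ndarray | pd.Series,
    X: pd.DataFrame,
    groups: Sequence,
) -> LMMFit:
    """REML fit by 1-D profile optimization over var_block/var_resid.

    The boundary solution var_block = 0 is permitted (and reproduces OLS).
    Raises on rank-deficient fixed-effect matrices, naming the aliased columns.
    """
    Xm = X.to_numpy(float)
    names = list(X.columns)
    yv = np.asarray(y, float)
    groups = np.asarray(groups)
    if len(pd.unique(groups)) < 2:
        raise ValueError("need at least 2 groups for a random intercept")
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        q, r = np.linalg.qr(Xm)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in np.where(diag <= 1e-10 * diag.max())[0]]
        raise ValueError(f"fixed-effect matrix is rank deficient; aliased: {bad}")
    Z = _group_matrix(groups)

    def obj(t: float) -> float:
        return _neg2_reml(10.0**t, yv, Xm, Z)[0]

    res = optimize.minimize_scalar(
        obj, bounds=(-10.0, 6.0), method="bounded",
        options={"xatol": 1e-10},
    )
    crit0 = _neg2_reml(0.0, yv, Xm, Z)[0]
    rho = 10.0**res.x if res.fun < crit0 else 0.0
    if rho > 0:
        # polish the interior optimum to machine precision on the analytic
        # stationarity condition, so GLS F statistics carry ~1e-9 accuracy
        a, b = rho * 0.98, rho * 1.02
        ga, gb = _reml_grad(a, yv, Xm, Z), _reml_grad(b, yv, Xm, Z)
        for _ in range(8):
            if ga * gb <= 0:
                break
            a, b = a * 0.7, b * 1.4
            ga, gb = _reml_grad(a, yv, Xm, Z), _reml_grad(b, yv, Xm, Z)
        if ga * gb <= 0:
            rho = float(
                optimize.brentq(
                    _reml_grad, a, b, args=(yv, Xm, Z), xtol=1e-14, rtol=1e-15
                )
            )
        if _neg2_reml(rho, yv, Xm, Z)[0] >= crit0:
            rho = 0.0
    crit, beta, sigma2, XtWX = _neg2_reml(rho, yv, Xm, Z)
    C = sigma2 * np.linalg.inv(XtWX)
    term_cols = {nm: [i] for i, nm in enumerate(names) if nm != "Intercept"}
    return LMMFit(
        coef=beta,
        coef_names=names,
        se=np.sqrt(np.diag(C)),
        var_block=rho * sigma2,
        var_resid=sigma2,
        reml_criterion=crit,
        fitted_fixed=Xm @ beta,
        X=Xm,
        y=yv,
        Z=Z,
        groups=groups,
        term_cols=term_cols,
    )


def _satterthwaite_pieces(fit: LMMFit):
    n, p = fit.X.shape
    V = fit.var_resid * np.eye(n) + fit.var_block * (fit.Z @ fit.Z.T)
    Vi = np.linalg.inv(V)
    XtViX = fit.X.T @ Vi @ fit.X
    C = np.linalg.inv(XtViX)
    ViX = Vi @ fit.X
    P = Vi - ViX @ C @ ViX.T
    Vb = fit.Z @ fit.Z.T
    Ve = np.eye(n)
    comps = (Vb, Ve)
    info = np.empty((2, 2))
    PV = [P @ Vk for Vk in comps]
    for a in range(2):
        for b in range(2):
            info[a, b] = 0.5 * np.trace(PV[a] @ PV[b])
    A = np.linalg.pinv(info)  # asymptotic cov of (var_block, var_resid)
    # dC/dtheta_k = C X' Vi Vk Vi X C
    dC = [C @ (ViX.T @ Vk @ ViX) @ C for Vk in comps]
    return C, dC, A


def _contrast_ddf(l: np.ndarray, C, dC, A, n, p) -> float:
    c = float(l @ C @ l)
    g = np.array([float(l @ dCk @ l) for dCk in dC])
    denom = float(g @ A @ g)
    if denom <= 0 or not np.isfinite(denom):
        return float(n - p)
    ddf = 2.0 * c**2 / denom
    return float(np.clip(ddf, 1.0, n - p if n - p >= 1 else 1.0))


def lmm_anova(
    fit: LMMFit, terms: Mapping[str, Sequence[int]] | None = None
) -> pd.DataFrame:
    """Wald F-tests per fixed term with Satterthwaite denominator df.

    On a balanced b-block 2x2 design the result matches the classical
    two-stratum RCBD ANOVA exactly, with den_df = (b-1)(t-1).
    """
    if not fit.converged:
        raise RuntimeError("cannot test a non-converged fit")
    terms = dict(terms) if terms is not None else fit.term_cols
    n, p = fit.X.shape
    C, dC, A = _satterthwaite_pieces(fit)
    rows = []
    for term, cols in terms.items():
        cols = list(cols)
        q = len(cols)
        if q == 1:
            l = np.zeros(p)
            l[cols[0]] = 1.0
            Fstat = float(fit.coef[cols[0]] ** 2 / (l @ C @ l))
            ddf = _contrast_ddf(l, C, dC, A, n, p)
        else:
            L = np.zeros((q, p))
            for r_i, ci in enumerate(cols):
                L[r_i, ci] = 1.0
            M = L @ C @ L.T
            Mi = np.linalg.inv(M)
            Fstat = float(fit.coef[cols] @ Mi @ fit.coef[cols]) / q
            # eigen-contrast combination of per-direction Satterthwaite dfs
            w, U = np.linalg.eigh(M)
            nus = []
            for i in range(q):
                l = (U[:, i] @ L)
                nus.append(_contrast_ddf(l, C, dC, A, n, p))
            nus = np.array(nus)
            good = nus > 2.0
            E = float((nus[good] / (nus[good] - 2.0)).sum())
            ddf = 2.0 * E / (E - q) if E > q else float(n - p)
        pval = float(stats.f.sf(Fstat, q, ddf))
        rows.append((term, q, ddf, Fstat, pval))
    return pd.DataFrame(rows, columns=["term", "num_df", "den_df", "F", "p"])


def nakagawa_r2(fit: LMMFit) -> tuple[float, float]:
    """(marginal, conditional) variance explained.

    marginal = var(fitted_fixed) / (var(fitted_fixed) + var_block + var_resid);
    conditional adds var_block to the numerator.
    """
    if np.var(fit.y) == 0:
        raise ValueError("zero-variance response: R2 undefined")
    vf = float(np.var(fit.fitted_fixed, ddof=1))
    tot = vf + fit.var_block + fit.var_resid
    return vf / tot, (vf + fit.var_block) / tot


def _factorial_X(design: pd.DataFrame, terms: Sequence[str] = FIXED_TERMS) -> pd.DataFrame:
    X = pd.DataFrame(
        effect_columns(design, terms), columns=list(terms), index=design["plot_id"]
    )
    X.insert(0, "Intercept", 1.0)
    return X


def _residual_skew(fit: LMMFit) -> float:
    return float(stats.skew(fit.y - fit.fitted_fixed))


def treatment_effect_suite(
    cwm: pd.DataFrame,
    biomass: pd.DataFrame,
    design: pd.DataFrame,
    log_transform: Mapping[str, bool] | None = None,
) -> pd.DataFrame:
    """Factorial mixed-model F-tests for every CWM component and biomass.

    One model per site x response (each trait's specific/fixed/itv component
    plus total biomass): nutrient, fence and their interaction fixed, block
    random.  ``log_transform`` maps response names (e.g. ``"SLA:specific"``,
    ``"biomass"``) to a flag; a skewness advisory (|skew| > 1) is reported but
    never auto-applied.
    """
    log_transform = dict(log_transform or {})
    rows = []
    for site, dsite in design.groupby("site", sort=True):
        dsite = dsite.sort_values("plot_id")
        X = _factorial_X(dsite)
        groups = dsite["block"].to_numpy()
        responses: dict[str, pd.Series] = {}
        sub = cwm[cwm["plot_id"].isin(set(dsite["plot_id"]))]
        for (trait, comp), grp in sub.groupby(["trait", "component"], sort=True):
            responses[f"{trait}:{comp}"] = grp.set_index("plot_id")["value"]
        responses["biomass"] = biomass.set_index("plot_id")["total_biomass"]
        for name, ser in responses.items():
            yv = ser.reindex(dsite["plot_id"])
            if yv.isna().any():
                logger.warning("site %s response %s: missing plots, skipped", site, name)
                continue
            logged = bool(log_transform.get(name, False))
            vals = yv.to_numpy(float)
            if logged:
                if (vals <= 0).any():
                    logger.warning(
                        "site %s response %s: nonpositive values, log skipped",
                        site, name,
                    )
                    logged = False
                else:
                    vals = np.log(vals)
            fit = fit_random_intercept_lmm(vals, X, groups)
            tab = lmm_anova(fit)
            skew = _residual_skew(fit)
            for r in tab.itertuples(index=False):
                rows.append(
                    (site, name, r.term, r.num_df, r.den_df, r.F, r.p,
                     logged, abs(skew) > 1.0)
                )
    return pd.DataFrame(
        rows,
        columns=["site", "response", "term", "num_df", "den_df", "F", "p",
                 "logged", "skew_advisory"],
    )


def trait_biomass_models(
    cwm: pd.DataFrame,
    biomass: pd.DataFrame,
    design: pd.DataFrame,
) -> pd.DataFrame:
    """Single-trait biomass regressions with a block random intercept.

    Per site x trait x component: biomass ~ CWM value, block random.  Reports
    slope, Satterthwaite F/p, marginal and conditional R2, and the P < 0.05
    display flag.  Zero-variance predictors and sites with < 4 complete plots
    are skipped with a warning.
    """
    rows = []
    bio = biomass.set_index("plot_id")["total_biomass"]
    for site, dsite in design.groupby("site", sort=True):
        dsite = dsite.sort_values("plot_id")
        groups_all = dsite["block"].to_numpy()
        sub = cwm[cwm["plot_id"].isin(set(dsite["plot_id"]))]
        for (trait, comp), grp in sub.groupby(["trait", "component"], sort=True):
            x = grp.set_index("plot_id")["value"].reindex(dsite["plot_id"])
            y = bio.reindex(dsite["plot_id"])
            mask = ~(x.isna() | y.isna())
            if mask.sum() < 4:
                logger.warning(
                    "site %s %s:%s: fewer than 4 plots with data, skipped",
                    site, trait, comp,
                )
                continue
            xv = x[mask.to_numpy()].to_numpy(float)
            yv = y[mask.to_numpy()].to_numpy(float)
            if np.var(xv) == 0:
                logger.warning(
                    "site %s %s:%s: zero-variance predictor, skipped",
                    site, trait, comp,
                )
                continue
            X = pd.DataFrame({"Intercept": 1.0, "cwm": xv})
            fit = fit_random_intercept_lmm(yv, X, groups_all[mask.to_numpy()])
            tab = lmm_anova(fit, {"cwm": [1]})
            r2m, r2c = nakagawa_r2(fit)
            r = tab.iloc[0]
            rows.append(
                (site, trait, comp, float(fit.coef[1]), float(fit.se[1]),
                 float(r.F), float(r.den_df), float(r.p), r2m, r2c,
                 bool(r.p < 0.05))
            )
    return pd.DataFrame(
        rows,
        columns=["site", "trait", "component", "slope", "se", "F", "den_df",
                 "p", "r2_marginal", "r2_conditional", "significant"],
    )
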