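"""Two-stage and one-stage random-effects pooling of case-control studies.

The central statistical machinery of the package.  Stage one fits an
ordinary logistic regression within each study,

    logit P(Y=1 | X, Z) = alpha_k + beta_k X + gamma_k' Z_k,

where X is the genetic exposure (coded under a chosen inheritance model)
and Z_k are study-specific confounders.  Stage two combines the estimated
log odds ratios under the random-effects model

    beta_hat_k = beta + b_k + e_k,   b_k ~ N(0, sigma2_b),  e_k ~ N(0, sigma2_k),

with the pooled estimate a weighted mean using inverse marginal variances
w_k = 1 / (sigma2_k + sigma2_b):

    beta_hat = sum(w_k beta_hat_k) / sum(w_k),    var(beta_hat) = 1 / sum(w_k).

The between-study variance sigma2_b is estimated either by the
DerSimonian-Laird moment estimator or by an iterated (pseudo-maximum
likelihood style) weighted estimator.  The module also provides the
one-stage alternative — a logistic model with a shared exposure effect and
a normally distributed random study slope, fitted by Gauss-Hermite
quadrature — plus heterogeneity statistics (Q, I-squared),
meta-regression on study-level covariates, Egger's regression test for
funnel-plot asymmetry, the Breslow-Day test of odds-ratio homogeneity
across strata, and a stratified-analysis driver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats

__all__ = [
    "StudyEffect",
    "PooledResult",
    "HeterogeneityResult",
    "OneStageFit",
    "EggerResult",
    "fit_study_logistic",
    "pool_two_stage",
    "heterogeneity",
    "meta_regression",
    "egger_test",
    "breslow_day",
    "stratified_association",
    "fit_one_stage",
    "effect_from_2x2",
]

_SEPARATION_BETA = 15.0


@dataclass
class StudyEffect:
    """First-stage result for one study: log-OR and its variance."""

    study: str
    beta: float
    var_beta: float
    intercept: float = np.nan
    gamma: dict = field(default_factory=dict)
    n_cases: int = 0
    n_controls: int = 0
    converged: bool = True

    @property
    def se(self) -> float:
        return float(np.sqrt(self.var_beta))


@dataclass
class PooledResult:
    """Pooled log-OR under the two-stage random-effects model."""

    method: str
    beta: float
    var_beta: float
    sigma2_b: float
    weights: np.ndarray
    k: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.var_beta))

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    def ci(self, level: float = 0.95):
        z = stats.norm.ppf(0.5 + level / 2)
        return self.beta - z * self.se, self.beta + z * self.se


@dataclass
class HeterogeneityResult:
    """Cochran's Q and the I-squared heterogeneity percentage."""

    q: float
    df: int
    pvalue: float
    i2: float  # percent


@dataclass
class OneStageFit:
    """One-stage random-slope logistic fit (Gauss-Hermite marginal ML)."""

    beta: float
    sigma2_b: float
    intercepts: np.ndarray
    loglik: float
    se_beta: float
    nodes: int
    converged: bool
    strict_common_intercept: bool = False


@dataclass
class EggerResult:
    """Egger regression test of funnel-plot asymmetry."""

    intercept: float
    se: float
    pvalue: float
    slope: float
    df: int
    funnel: pd.DataFrame = field(repr=False, default=None)


def effect_from_2x2(a: float, b: float, c: float, d: float, study: str = "",
                    continuity: bool = False) -> StudyEffect:
    """Log-OR and Woolf variance from a 2x2 table.

    ``a``/``b`` are exposed cases/controls, ``c``/``d`` unexposed.  With
    ``continuity=True`` (or automatically when a cell is zero and requested
    by the caller) 0.5 is added to every cell.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if continuity or (cells == 0).any():
        cells = cells + 0.5
        flagged = (np.array([a, b, c, d]) == 0).any()
    else:
        flagged = False
    a_, b_, c_, d_ = cells
    beta = float(np.log(a_ * d_ / (b_ * c_)))
    var = float(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    return StudyEffect(
        study, beta, var,
        intercept=float(np.log(c_ / d_)),
        n_cases=int(a + c), n_controls=int(b + d),
        converged=not flagged,
    )


def fit_study_logistic(y, x, z=None, study: str = "",
                       separation: str = "warn") -> StudyEffect:
    """Stage-one logistic fit of outcome on exposure within one study.

    Maximum likelihood on complete-case rows; the exposure variance comes
    from the inverse observed information.  Separation (|beta| above 15 or
    no convergence within 100 iterations) marks the result not converged;
    with ``separation="continuity"`` and no covariates, a 0.5
    continuity-corrected 2x2 estimate is substituted instead.

    Parameters
    ----------
    y, x
        Binary outcome and (numeric) exposure, same length.
    z
        Optional confounder array/DataFrame (study-specific set allowed).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if z is not None:
        z = np.asarray(pd.DataFrame(z), dtype=float)
        keep = ~np.isnan(y) & ~np.isnan(x) & ~np.isnan(z).any(axis=1)
    else:
        keep = ~np.isnan(y) & ~np.isnan(x)
    y, x = y[keep], x[keep]
    if z is not None:
        z = z[keep]
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    n_case, n_ctrl = int(y.sum()), int((1 - y).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("study needs at least one case and one control")
    if np.ptp(x) == 0:
        raise ValueError(f"exposure invariant in study {study!r}")

    design = np.column_stack([np.ones_like(x), x] + ([z] if z is not None else []))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=100)
            converged = bool(res.mle_retvals.get("converged", True))
            beta = float(res.params[1])
            var = float(res.cov_params()[1, 1])
            intercept = float(res.params[0])
            gamma = {f"z{j}": float(v) for j, v in enumerate(res.params[2:])}
        except Exception:
            converged, beta, var, intercept, gamma = False, np.nan, np.nan, np.nan, {}

    separated = (not converged) or (np.isfinite(beta) and abs(beta) > _SEPARATION_BETA)
    if separated:
        binary_exposure = set(np.unique(x)) <= {0.0, 1.0}
        if separation == "continuity" and z is None and binary_exposure:
            a = float(((y == 1) & (x == 1)).sum())
            b = float(((y == 0) & (x == 1)).sum())
            c = float(((y == 1) & (x == 0)).sum())
            d = float(((y == 0) & (x == 0)).sum())
            eff = effect_from_2x2(a, b, c, d, study=study, continuity=True)
            eff.converged = False
            return eff
        warnings.warn(f"separation suspected in study {study!r}; effect flagged",
                      stacklevel=2)
        return StudyEffect(study, beta, var, intercept, gamma,
                           n_case, n_ctrl, converged=False)
    return StudyEffect(study, beta, var, intercept, gamma,
                       n_case, n_ctrl, converged=True)


def _as_arrays(effects):
    betas = np.array([e.beta for e in effects], dtype=float)
    variances = np.array([e.var_beta for e in effects], dtype=float)
    if (variances <= 0).any() or not np.isfinite(variances).all():
        raise ValueError("every study effect needs a positive finite variance")
    return betas, variances


def heterogeneity(effects) -> HeterogeneityResult:
    """Cochran's Q against chi-square(K-1) and I-squared (percent).

    Q uses fixed-effect inverse-variance weights; I2 = max(0, (Q - df)/Q)
    expresses the share of total variation attributable to between-study
    heterogeneity rather than chance.
    """
    betas, variances = _as_arrays(effects)
    k = betas.size
    if k < 2:
        raise ValueError("heterogeneity needs at least two studies")
    v = 1.0 / variances
    beta_fe = float(np.sum(v * betas) / np.sum(v))
    q = float(np.sum(v * (betas - beta_fe) ** 2))
    df = k - 1
    p = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return HeterogeneityResult(q, df, p, i2)


def pool_two_stage(effects, method: str = "moment"):
    """Second-stage pooling of per-study log-ORs under random effects.

    ``method="moment"`` is the DerSimonian-Laird estimator: with fixed
    weights v_k = 1/sigma2_k and Q the fixed-effect heterogeneity
    statistic,

        sigma2_b = max(0, (Q - (K-1)) / (sum v - sum v^2 / sum v)).

    ``method="pml"`` iterates a weighted moment equation with the weights
    refreshed at each step,

        sigma2_b <- sum(w_k^2 [(beta_k - beta)^2 - sigma2_k]) / sum(w_k^2),

    floored at zero, to tolerance 1e-8 (max 200 iterations).  Both then
    apply the inverse-marginal-variance weighting exactly.

    Returns ``(PooledResult, HeterogeneityResult)``; only converged
    effects should be passed.
    """
    effects = list(effects)
    betas, variances = _as_arrays(effects)
    k = betas.size
    if k < 2:
        raise ValueError("pooling needs at least two studies")
    het = heterogeneity(effects)

    if method == "moment":
        v = 1.0 / variances
        denom = np.sum(v) - np.sum(v**2) / np.sum(v)
        sigma2_b = max(0.0, (het.q - (k - 1)) / denom) if denom > 0 else 0.0
    elif method == "pml":
        sigma2_b = 0.0
        for _ in range(200):
            w = 1.0 / (variances + sigma2_b)
            beta = np.sum(w * betas) / np.sum(w)
            new = np.sum(w**2 * ((betas - beta) ** 2 - variances)) / np.sum(w**2)
            new = max(0.0, float(new))
            if abs(new - sigma2_b) < 1e-8:
                sigma2_b = new
                break
            sigma2_b = new
    else:
        raise ValueError(f"unknown pooling method {method!r}")

    w = 1.0 / (variances + sigma2_b)
    beta = float(np.sum(w * betas) / np.sum(w))
    var_beta = float(1.0 / np.sum(w))
    return PooledResult(method, beta, var_beta, float(sigma2_b), w, k), het


def meta_regression(effects, covariates):
    """Weighted regression of study effects on study-level covariates.

    Explains between-study heterogeneity by methodological or population
    characteristics.  First pass: fixed-effect weights 1/sigma2_k give the
    residual Q, extended method-of-moments gives the residual
    between-study variance; second pass refits with weights
    1/(sigma2_k + sigma2_b).  Returns a dict with the coefficient table
    (coef, se, z, p), the residual ``sigma2_b`` and R2 relative to the
    intercept-only model's between-study variance.
    """
    betas, variances = _as_arrays(effects)
    k = betas.size
    X = pd.DataFrame(covariates)
    if len(X) != k:
        raise ValueError("one covariate row per study required")
    names = ["intercept"] + [str(c) for c in X.columns]
    M = np.column_stack([np.ones(k), X.to_numpy(dtype=float)])
    p = M.shape[1]
    if k <= p:
        raise ValueError("need more studies than coefficients")
    if np.linalg.matrix_rank(M) < p:
        # identify the offending columns for the error message
        bad = [names[j] for j in range(1, p)
               if np.linalg.matrix_rank(np.delete(M, j, axis=1)) == np.linalg.matrix_rank(M)]
        raise ValueError(f"collinear covariates: {bad}")

    def _wls(tau2):
        w = 1.0 / (variances + tau2)
        Wh = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(M * Wh[:, None], betas * Wh, rcond=None)
        resid = betas - M @ coef
        return coef, resid, w

    coef, resid, v = _wls(0.0)
    q_res = float(np.sum(v * resid**2))
    # method-of-moments residual tau2 with the usual trace correction
    P = M.T * v
    trace = np.trace(np.linalg.solve(P @ M, P * v @ M))
    denom = np.sum(v) - trace
    tau2 = max(0.0, (q_res - (k - p)) / denom) if denom > 0 else 0.0

    coef, resid, w = _wls(tau2)
    cov = np.linalg.inv((M.T * w) @ M)
    se = np.sqrt(np.diag(cov))
    z = coef / se
    table = pd.DataFrame(
        {"coef": coef, "se": se, "z": z, "p": 2 * stats.norm.sf(np.abs(z))},
        index=names,
    )
    base = pool_two_stage(effects, "moment")[0].sigma2_b
    r2 = max(0.0, 1 - tau2 / base) if base > 0 else 0.0
    return {"table": table, "sigma2_b": float(tau2), "r2": float(r2),
            "q_residual": q_res, "df_residual": k - p}


def egger_test(effects) -> EggerResult:
    """Egger's regression test for small-study / participation bias.

    Regresses the standardized effect beta_k/se_k on the precision 1/se_k
    by ordinary least squares; under no small-study effect the intercept
    is zero.  The intercept t-test uses K-2 degrees of freedom.  The
    returned ``funnel`` frame carries (beta_k, 1/se_k) coordinates for a
    funnel plot.
    """
    betas, variances = _as_arrays(effects)
    k = betas.size
    if k < 3:
        raise ValueError("Egger's test needs at least three studies")
    se = np.sqrt(variances)
    snd = betas / se
    prec = 1.0 / se
    M = np.column_stack([np.ones(k), prec])
    coef, *_ = np.linalg.lstsq(M, snd, rcond=None)
    resid = snd - M @ coef
    s2 = float(resid @ resid) / (k - 2)
    cov = s2 * np.linalg.inv(M.T @ M)
    se_int = float(np.sqrt(cov[0, 0]))
    t = coef[0] / se_int if se_int > 0 else 0.0
    p = 2 * float(stats.t.sf(abs(t), k - 2))
    funnel = pd.DataFrame({"beta": betas, "precision": prec,
                           "study": [e.study for e in effects]})
    return EggerResult(float(coef[0]), se_int, p, float(coef[1]), k - 2, funnel)


def breslow_day(tables, tarone: bool = True):
    """Breslow-Day test of odds-ratio homogeneity across 2x2 strata.

    ``tables`` is a sequence of 2x2 arrays ``[[a, b], [c, d]]`` with rows
    exposed/unexposed and columns case/control.  The common OR is the
    Mantel-Haenszel estimate; each stratum's expected exposed-case count
    under that OR solves the standard quadratic; the statistic sums
    (a - E)^2 / Var(a) and, with ``tarone=True``, subtracts the Tarone
    correction term.  Strata with a zero margin are dropped with a
    warning.  Returns ``(statistic, df, pvalue)``.
    """
    kept = []
    for t in tables:
        t = np.asarray(t, dtype=float)
        if t.shape != (2, 2) or (t < 0).any():
            raise ValueError("each stratum must be a non-negative 2x2 table")
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            warnings.warn("stratum with zero margin dropped from Breslow-Day",
                          stacklevel=2)
            continue
        kept.append(t)
    if len(kept) < 2:
        raise ValueError("Breslow-Day needs at least two usable strata")

    # Mantel-Haenszel common odds ratio
    num = sum(t[0, 0] * t[1, 1] / t.sum() for t in kept)
    den = sum(t[0, 1] * t[1, 0] / t.sum() for t in kept)
    or_mh = num / den if den > 0 else np.inf

    stat = 0.0
    sum_dev = 0.0
    sum_var = 0.0
    for t in kept:
        a = t[0, 0]
        n1 = t[0].sum()      # exposed
        n2 = t[1].sum()      # unexposed
        m1 = t[:, 0].sum()   # cases
        # E solves E(n2 - m1 + E) = R (n1 - E)(m1 - E); expanded:
        #   (1 - R) E^2 + [ (n2 - m1) + R (n1 + m1) ] E - R n1 m1 = 0
        R = or_mh
        qa = 1 - R
        qb = (n2 - m1) + R * (n1 + m1)
        qc = -R * n1 * m1
        if abs(qa) < 1e-12:
            E = -qc / qb
        else:
            disc = qb**2 - 4 * qa * qc
            roots = np.array([(-qb + np.sqrt(disc)) / (2 * qa),
                              (-qb - np.sqrt(disc)) / (2 * qa)])
            valid = roots[(roots >= max(0, m1 - n2) - 1e-9)
                          & (roots <= min(n1, m1) + 1e-9)]
            E = float(valid[0])
        var = 1.0 / (1 / E + 1 / (n1 - E) + 1 / (m1 - E) + 1 / (n2 - m1 + E))
        stat += (a - E) ** 2 / var
        sum_dev += a - E
        sum_var += var
    if tarone:
        stat -= sum_dev**2 / sum_var
    df = len(kept) - 1
    return float(stat), df, float(stats.chi2.sf(stat, df))


def stratified_association(studies, exposure: str, stratum: str,
                           outcome: str = "status", method: str = "moment",
                           min_studies: int = 2):
    """Two-stage pooled analysis within each level of a stratifying variable.

    Runs the full first-stage + pooling pipeline on the subjects of each
    stratum separately (the stratum variable must already be harmonized and
    categorical), then tests homogeneity of the exposure OR across strata
    with the Breslow-Day test on the stratum-collapsed 2x2 tables.

    Parameters
    ----------
    studies
        Sequence of per-study DataFrames with ``outcome``, ``exposure`` and
        ``stratum`` columns (exposure binary for the Breslow-Day part).

    Returns a dict: stratum level -> (PooledResult, HeterogeneityResult),
    plus ``"breslow_day": (stat, df, p)`` across strata when computable.
    """
    levels = sorted(
        set().union(*[set(df[stratum].dropna().unique()) for df in studies])
    )
    if not levels:
        raise ValueError(f"stratum variable {stratum!r} has no observed levels")
    out = {}
    tables = []
    for lev in levels:
        effects = []
        a = b = c = d = 0.0
        for i, df in enumerate(studies):
            sub = df[df[stratum] == lev]
            y = sub[outcome].to_numpy(dtype=float)
            x = sub[exposure].to_numpy(dtype=float)
            ok = ~np.isnan(y) & ~np.isnan(x)
            y, x = y[ok], x[ok]
            if y.size == 0 or len(set(y)) < 2 or np.ptp(x) == 0:
                continue
            try:
                eff = fit_study_logistic(y, x, study=f"study{i}",
                                         separation="continuity")
            except ValueError:
                continue
            if np.isfinite(eff.beta) and np.isfinite(eff.var_beta):
                effects.append(eff)
            xb = x >= (np.nanmax(x) if set(np.unique(x)) <= {0.0, 1.0} else np.nanmedian(x))
            a += float(((y == 1) & xb).sum())
            b += float(((y == 0) & xb).sum())
            c += float(((y == 1) & ~xb).sum())
            d += float(((y == 0) & ~xb).sum())
        if len(effects) >= min_studies:
            out[lev] = pool_two_stage(effects, method=method)
            tables.append(np.array([[a, b], [c, d]]))
        else:
            out[lev] = None
            warnings.warn(f"stratum {lev!r}: fewer than {min_studies} usable studies",
                          stacklevel=2)
    usable = [t for t in tables if (t.sum(axis=0) > 0).all() and (t.sum(axis=1) > 0).all()]
    if len(usable) >= 2:
        out["breslow_day"] = breslow_day(usable)
    return out


def _one_stage_negloglik(params, y_by_study, x_by_study, nodes, weights,
                         strict: bool):
    K = len(y_by_study)
    if strict:
        alphas = np.repeat(params[0], K)
        beta, log_sigma = params[1], params[2]
    else:
        alphas = params[:K]
        beta, log_sigma = params[K], params[K + 1]
    sigma = np.exp(log_sigma)
    log_w = np.log(weights / np.sqrt(np.pi))
    slopes = beta + np.sqrt(2.0) * sigma * nodes  # (Q,)
    total = 0.0
    for k in range(K):
        y, x = y_by_study[k], x_by_study[k]
        eta = alphas[k] + np.outer(x, slopes)          # (n_k, Q)
        ll = y[:, None] * eta - np.logaddexp(0.0, eta)  # Bernoulli loglik
        total += special.logsumexp(ll.sum(axis=0) + log_w)
    return -total


def fit_one_stage(y, x, study, n_nodes: int = 21, strict_common_intercept: bool = False,
                  start=None) -> OneStageFit:
    """One-stage random-slope logistic model across pooled studies.

    Fits logit P(Y=1) = alpha_k + (beta + b_k) X with b_k ~ N(0, sigma2_b),
    maximizing the marginal likelihood with the random slope integrated out
    by Gauss-Hermite quadrature (default 21 nodes).  By default each study
    gets its own fixed intercept, which is statistically necessary when the
    case-control ratio is design-determined per study; pass
    ``strict_common_intercept=True`` to force the single shared intercept
    of the textbook random-slope formulation.

    sigma_b is parameterized on the log scale (floor ~ 2e-4), so the
    estimate can approach but not cross zero.

    Parameters
    ----------
    y, x, study
        Flat arrays over all subjects: binary outcome, exposure, and a
        study label per subject.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    study = np.asarray(study)
    ok = ~np.isnan(y) & ~np.isnan(x)
    y, x, study = y[ok], x[ok], study[ok]
    labels = pd.unique(study)
    K = len(labels)
    if K < 2:
        raise ValueError("one-stage pooling needs at least two studies")
    y_by = [y[study == lab] for lab in labels]
    x_by = [x[study == lab] for lab in labels]

    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)

    if start is None:
        alphas0 = []
        beta0 = []
        for yy, xx in zip(y_by, x_by):
            p = np.clip(yy.mean(), 0.05, 0.95)
            alphas0.append(np.log(p / (1 - p)))
            try:
                eff = fit_study_logistic(yy, xx, separation="continuity")
                if np.isfinite(eff.beta):
                    beta0.append(eff.beta)
            except ValueError:
                pass
        beta_init = float(np.median(beta0)) if beta0 else 0.0
        if strict_common_intercept:
            start = np.array([np.mean(alphas0), beta_init, np.log(0.1)])
        else:
            start = np.array(alphas0 + [beta_init, np.log(0.1)])

    bounds = None
    n_fixed = 1 if strict_common_intercept else K
    lo = [-20.0] * n_fixed + [-10.0, np.log(2e-4)]
    hi = [20.0] * n_fixed + [10.0, np.log(5.0)]
    bounds = list(zip(lo, hi))

    res = optimize.minimize(
        _one_stage_negloglik, start,
        args=(y_by, x_by, nodes, weights, strict_common_intercept),
        method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500},
    )
    converged = bool(res.success)
    if not converged:  # one perturbed restart before flagging
        res2 = optimize.minimize(
            _one_stage_negloglik, start * 0.5,
            args=(y_by, x_by, nodes, weights, strict_common_intercept),
            method="L-BFGS-B", bounds=bounds, options={"maxiter": 500},
        )
        if res2.fun < res.fun:
            res = res2
        converged = bool(res.success or res2.success)

    params = res.x
    if strict_common_intercept:
        alphas = np.repeat(params[0], K)
        beta, log_sigma = params[1], params[2]
        i_beta = 1
    else:
        alphas = params[:K]
        beta, log_sigma = params[K], params[K + 1]
        i_beta = K
    sigma2_b = float(np.exp(log_sigma) ** 2)

    # SE of beta from the numerical observed information (central differences)
    h = 1e-4
    def f1(b):
        p = params.copy()
        p[i_beta] = b
        return _one_stage_negloglik(p, y_by, x_by, nodes, weights,
                                    strict_common_intercept)
    d2 = (f1(beta + h) - 2 * res.fun + f1(beta - h)) / h**2
    se_beta = float(1 / np.sqrt(d2)) if d2 > 0 else np.nan

    return OneStageFit(float(beta), sigma2_b, np.asarray(alphas, dtype=float),
                       float(-res.fun), se_beta, n_nodes, converged,
                       strict_common_intercept)
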