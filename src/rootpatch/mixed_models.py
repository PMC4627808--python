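"""Count models for herbivore abundance and follow-up linear models.

The central model is a Poisson GLMM for per-block herbivore counts:

    y_bi ~ Poisson(mu_bi),  log mu_bi = region_r(i) + beta1 * z_bi + u_i,
    u_i ~ N(0, sigma_site^2),

with one model per z-standardized predictor so that slopes are
comparable across predictors.  The site random intercept is integrated
out by a Laplace approximation of the marginal likelihood (adaptive
Gauss-Hermite quadrature with 10 nodes is available as a cross-check);
with the random-effect variance pinned at zero the fit reduces exactly
to a Poisson GLM solved by IRLS.

Around it: zero-inflation mitigation by summing counts over blocks of
adjacent cores, exclusion of sites whose counts are spatially
autocorrelated (global Moran's I), Nakagawa-Schielzeth conditional R2
on the latent scale, parametric-bootstrap likelihood-ratio p-values,
predictor ranking by |slope|, Gaussian mixed models of Mantel
coefficients against land use and soil, and simple site-level OLS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.stats import chi2 as chi2_dist

import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "AggregatedTransect",
    "GLMMFit",
    "LMMFit",
    "aggregate_blocks",
    "exclude_autocorrelated_sites",
    "fit_poisson_glmm",
    "conditional_r2",
    "parametric_bootstrap_p",
    "rank_predictors",
    "fit_mcc_lmm",
    "fit_site_level_lm",
]


# ---------------------------------------------------------------------------
# block aggregation
# ---------------------------------------------------------------------------

@dataclass
class AggregatedTransect:
    """Block-level data for one site: summed counts, averaged predictors."""
    site_id: str
    region_id: str
    blocks: pd.DataFrame        # block, count, one column per predictor


def aggregate_blocks(counts, predictors: pd.DataFrame, site_id: str = "",
                     region_id: str = "", block_size: int = 3) -> AggregatedTransect:
    """Sum counts and average predictors over consecutive core triples.

    ``counts`` is the per-core herbivore count vector in transect
    order; ``predictors`` the aligned plot-level predictor table.  A
    block inherits NaN for a predictor when any constituent plot is
    missing it (e.g. CWM-omitted), so that block drops out of the fit
    for that predictor only.  A trailing incomplete block is dropped
    with a warning.
    """
    y = np.asarray(counts)
    n = y.size
    if len(predictors) != n:
        raise ValueError("counts and predictors must align per core")
    n_blocks = n // block_size
    if n_blocks * block_size != n:
        warnings.warn(f"dropping trailing incomplete block of "
                      f"{n - n_blocks * block_size} cores", stacklevel=2)
    idx = np.repeat(np.arange(n_blocks), block_size)
    y = y[: n_blocks * block_size]
    pred = predictors.iloc[: n_blocks * block_size]
    out = pd.DataFrame({"block": np.arange(n_blocks),
                        "count": np.bincount(idx, weights=y).astype(int)})
    grouped = pred.groupby(idx)
    means = grouped.mean()
    # NaN-poisoning: pandas mean skips NaN; force NaN if any member missing
    has_nan = pred.isna().groupby(idx).any()
    means = means.mask(has_nan)
    for col in predictors.columns:
        out[col] = means[col].to_numpy()
    return AggregatedTransect(site_id=site_id, region_id=region_id, blocks=out)


def pool_aggregated(aggs: list[AggregatedTransect]) -> pd.DataFrame:
    """Stack per-site blocks into one analysis table."""
    frames = []
    for a in aggs:
        f = a.blocks.copy()
        f.insert(0, "site_id", a.site_id)
        f.insert(1, "region_id", a.region_id)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def exclude_autocorrelated_sites(moran_by_site: dict, alpha: float = 0.05):
    """Drop sites whose counts show significant global Moran's I.

    Returns (kept site ids, report DataFrame with I, p and excluded flag).
    """
    rows = []
    kept = []
    for site, res in moran_by_site.items():
        excl = res.p < alpha
        rows.append({"site_id": site, "moran_i": res.i, "p": res.p,
                     "excluded": excl})
        if not excl:
            kept.append(site)
    return kept, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Poisson GLMM (Laplace)
# ---------------------------------------------------------------------------

class GLMMConvergenceError(RuntimeError):
    pass


@dataclass
class GLMMFit:
    """One Poisson mixed-model fit for a single standardized predictor."""
    predictor: str
    region_intercepts: dict
    mean_intercept: float
    slope: float | None
    var_site: float
    loglik: float
    chi2: float | None = None
    p: float | None = None
    r2: float | None = None
    converged: bool = True
    n_obs: int = 0
    n_sites: int = 0
    # internals needed for simulation / refits
    _y: np.ndarray | None = field(default=None, repr=False)
    _X: np.ndarray | None = field(default=None, repr=False)
    _site_idx: np.ndarray | None = field(default=None, repr=False)
    _params: np.ndarray | None = field(default=None, repr=False)
    _colnames: list = field(default_factory=list, repr=False)


def _inner_modes(beta_eta: np.ndarray, y: np.ndarray, site_idx: np.ndarray,
                 n_sites: int, sigma2: float, b0: np.ndarray | None = None):
    """Newton solve for the per-site posterior modes of the random intercepts.

    Vectorized over sites (each mode is a scalar).  Returns the modes
    and the per-site sums of fitted means W_i = sum_j mu_ij.
    """
    b = np.zeros(n_sites) if b0 is None else b0.copy()
    sum_y = np.bincount(site_idx, weights=y, minlength=n_sites)
    for _ in range(50):
        mu = np.exp(beta_eta + b[site_idx])
        w = np.bincount(site_idx, weights=mu, minlength=n_sites)
        grad = sum_y - w - b / sigma2
        hess = w + 1.0 / sigma2
        step = grad / hess
        step = np.clip(step, -4.0, 4.0)
        b += step
        if np.max(np.abs(step)) < 1e-11:
            break
    mu = np.exp(beta_eta + b[site_idx])
    w = np.bincount(site_idx, weights=mu, minlength=n_sites)
    return b, w


def _laplace_nll(params: np.ndarray, y, X, site_idx, n_sites,
                 fix_sigma0: bool = False, b_cache: dict | None = None) -> float:
    """Negative Laplace-approximated marginal log-likelihood.

    ``params`` = (beta..., log sigma_site) unless ``fix_sigma0``; the
    log y! constant is dropped.
    """
    if fix_sigma0:
        beta = params
        eta = X @ beta
        mu = np.exp(eta)
        return -(y @ eta - mu.sum())
    beta, log_sigma = params[:-1], params[-1]
    # clamp so boundary excursions of the optimizer stay finite
    sigma2 = np.exp(2.0 * np.clip(log_sigma, -15.0, 5.0))
    eta0 = X @ beta
    b0 = None if b_cache is None else b_cache.get("b")
    b, w = _inner_modes(eta0, y, site_idx, n_sites, sigma2, b0)
    if b_cache is not None:
        b_cache["b"] = b
    eta = eta0 + b[site_idx]
    ll = (y @ eta - np.exp(eta).sum()
          - 0.5 * (b * b).sum() / sigma2
          - 0.5 * np.log1p(sigma2 * w).sum())
    return -ll


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(10)


def _agq_nll(params: np.ndarray, y, X, site_idx, n_sites) -> float:
    """Adaptive 10-node Gauss-Hermite marginal NLL (cross-check mode)."""
    beta, log_sigma = params[:-1], params[-1]
    sigma2 = np.exp(2.0 * log_sigma)
    eta0 = X @ beta
    b_hat, w = _inner_modes(eta0, y, site_idx, n_sites, sigma2)
    h = w + 1.0 / sigma2                       # negative Hessian at mode
    scale = np.sqrt(2.0 / h)
    sum_y = np.bincount(site_idx, weights=y, minlength=n_sites)
    # per-site integrand at each shifted node via sufficient stats;
    # the y'Xb term is node-independent and added once at the end
    log_parts = np.empty((n_sites, _GH_NODES.size))
    for q, (t, wq) in enumerate(zip(_GH_NODES, _GH_WEIGHTS)):
        b = b_hat + scale * t
        mu_sum = np.bincount(site_idx, weights=np.exp(eta0 + b[site_idx]),
                             minlength=n_sites)
        g = (sum_y * b - mu_sum - 0.5 * b * b / sigma2
             - 0.5 * np.log(2 * np.pi * sigma2))
        log_parts[:, q] = np.log(wq) + t * t + g + np.log(scale)
    ll = special.logsumexp(log_parts, axis=1).sum() + float(y @ eta0)
    return -ll


def _irls_poisson(y: np.ndarray, X: np.ndarray, tol: float = 1e-12,
                  max_iter: int = 200) -> np.ndarray:
    """Plain Poisson-GLM IRLS (log link), used for starts and sigma=0 fits."""
    n, p = X.shape
    beta = np.zeros(p)
    mean_y = max(y.mean(), 1e-8)
    # crude start: intercept-like columns get log(mean)
    beta += np.linalg.lstsq(X, np.full(n, np.log(mean_y)), rcond=None)[0]
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = np.exp(eta)
        wx = X * mu[:, None]
        z = eta + (y - mu) / mu
        # weighted LS step: (X'WX) beta = X'W z
        beta = np.linalg.solve(X.T @ wx, X.T @ (mu * z))
        ll = y @ (X @ beta) - np.exp(np.clip(X @ beta, -30, 30)).sum()
        if abs(ll - ll_old) < tol * (abs(ll) + 1):
            break
        ll_old = ll
    return beta


def _design(df: pd.DataFrame, predictor: str | None):
    """Region indicator columns (no global intercept) plus the predictor."""
    regions = sorted(df["region_id"].unique())
    cols = []
    names = []
    for r in regions:
        cols.append((df["region_id"] == r).to_numpy(float))
        names.append(f"region[{r}]")
    if predictor is not None:
        cols.append(df[predictor].to_numpy(float))
        names.append(predictor)
    return np.column_stack(cols), names, regions


def fit_poisson_glmm(agg: pd.DataFrame | list, predictor: str | None,
                     *, standardize: bool = True,
                     log_transform: bool = False,
                     var_site: float | None = None,
                     method: str = "laplace",
                     compute_lrt: bool = True) -> GLMMFit:
    """Poisson GLMM of block counts on one standardized predictor.

    Parameters
    ----------
    agg
        Pooled block table (or list of :class:`AggregatedTransect`)
        with columns ``site_id``, ``region_id``, ``count`` and the
        predictor.  Blocks with a missing predictor value are dropped.
    predictor
        Column to use as the single slope term; None fits the
        intercept-only (region + random intercept) model.
    standardize
        z-score the predictor over the retained pooled blocks.
    log_transform
        ln(x + 1) before standardization (used for bare-soil cover).
    var_site
        If 0, pins the random-intercept variance and the model
        collapses to a Poisson GLM fitted by IRLS.
    method
        "laplace" (default) or "agq" (adaptive 10-node Gauss-Hermite).
    """
    if isinstance(agg, list):
        agg = pool_aggregated(agg)
    df = agg.copy()
    if predictor is not None:
        df = df.dropna(subset=[predictor])
        if log_transform:
            df[predictor] = np.log(df[predictor].astype(float) + 1.0)
        if standardize:
            x = df[predictor].to_numpy(float)
            sd = x.std(ddof=1)
            if sd == 0:
                raise ValueError(f"predictor {predictor!r} is constant")
            df[predictor] = (x - x.mean()) / sd
    y = df["count"].to_numpy(float)
    if np.all(y == 0):
        raise ValueError("all counts are zero: degenerate likelihood")
    if df["site_id"].nunique() < 2:
        raise ValueError("need at least 2 sites")
    sites, site_idx = np.unique(df["site_id"], return_inverse=True)
    X, names, regions = _design(df, predictor)
    n_sites = sites.size

    beta0 = _irls_poisson(y, X)
    if var_site == 0:
        beta = beta0
        ll = float(y @ (X @ beta) - np.exp(X @ beta).sum())
        params = beta
        sigma2 = 0.0
        converged = True
    else:
        nll = _agq_nll if method == "agq" else _laplace_nll
        x0 = np.concatenate([beta0, [np.log(0.3)]])
        cache = {}
        args = ((y, X, site_idx, n_sites) if method == "agq"
                else (y, X, site_idx, n_sites, False, cache))
        res = optimize.minimize(nll, x0, args=args, method="L-BFGS-B",
                                options={"maxiter": 500, "ftol": 1e-12,
                                         "gtol": 1e-8})
        params = res.x
        sigma2 = float(np.exp(2 * params[-1]))
        ll = float(-res.fun)
        converged = bool(res.success)

    region_ic = {r: float(params[i]) for i, r in enumerate(regions)}
    slope = float(params[len(regions)]) if predictor is not None else None
    fit = GLMMFit(
        predictor=predictor or "(intercept)",
        region_intercepts=region_ic,
        mean_intercept=float(np.mean(list(region_ic.values()))),
        slope=slope,
        var_site=sigma2,
        loglik=ll,
        converged=converged,
        n_obs=y.size,
        n_sites=n_sites,
        _y=y, _X=X, _site_idx=site_idx, _params=np.asarray(params, float),
        _colnames=names,
    )
    fit.r2 = conditional_r2(fit)
    if predictor is not None and compute_lrt:
        reduced = fit_poisson_glmm(df, None, standardize=False,
                                   var_site=var_site, method=method)
        fit.chi2 = max(0.0, 2.0 * (fit.loglik - reduced.loglik))
    return fit


def conditional_r2(fit: GLMMFit, resid_variance: str = "lognormal") -> float:
    """Nakagawa-Schielzeth conditional R2 on the latent log scale.

    (var_fixed + var_site) / (var_fixed + var_site + var_resid), where
    var_fixed is the variance of the fixed-effect linear predictor and
    var_resid the Poisson observation-level variance approximated as
    ln(1 + 1/lambda_bar) ("lognormal", default) or trigamma(lambda_bar).
    """
    eta_fixed = fit._X @ fit._params[: fit._X.shape[1]]
    var_f = float(np.var(eta_fixed))
    lam_bar = float(np.mean(np.exp(eta_fixed + 0.5 * fit.var_site)))
    if resid_variance == "lognormal":
        var_e = float(np.log1p(1.0 / lam_bar))
    elif resid_variance == "trigamma":
        var_e = float(special.polygamma(1, lam_bar))
    else:
        raise ValueError("resid_variance must be 'lognormal' or 'trigamma'")
    total = var_f + fit.var_site + var_e
    if total == 0:
        raise ValueError("zero total variance")
    return (var_f + fit.var_site) / total


def simulate_from_fit(fit: GLMMFit, rng: np.random.Generator) -> np.ndarray:
    """Draw one Poisson response vector from a fitted model's parameters."""
    beta = fit._params[: fit._X.shape[1]]
    b = rng.normal(0.0, np.sqrt(fit.var_site), fit.n_sites)
    mu = np.exp(fit._X @ beta + b[fit._site_idx])
    return rng.poisson(mu)


def _refit(fit: GLMMFit, y_new: np.ndarray) -> float:
    """Refit a model structure to a new response; returns log-likelihood."""
    x0 = fit._params.copy()
    cache = {}
    res = optimize.minimize(
        _laplace_nll, x0,
        args=(y_new, fit._X, fit._site_idx, fit.n_sites, False, cache),
        method="L-BFGS-B", options={"maxiter": 300, "ftol": 1e-11})
    if not np.isfinite(res.fun):
        raise GLMMConvergenceError("bootstrap refit failed")
    return float(-res.fun)


def parametric_bootstrap_p(fit_full: GLMMFit, fit_reduced: GLMMFit,
                           n_boot: int = 500, seed=None) -> tuple[float, int]:
    """Parametric-bootstrap p-value for the LRT of nested Poisson GLMMs.

    Responses are simulated from the reduced model's fitted
    parameters; both models are refit to each draw and the observed
    likelihood-ratio statistic is referred to the bootstrap LRT
    distribution.  Returns (p, n_failed_refits).
    """
    rng = np.random.default_rng(seed)
    lrt_obs = max(0.0, 2.0 * (fit_full.loglik - fit_reduced.loglik))
    exceed = 0
    failed = 0
    done = 0
    for _ in range(n_boot):
        y_star = simulate_from_fit(fit_reduced, rng)
        if np.all(y_star == 0):
            failed += 1
            continue
        try:
            ll_r = _refit(fit_reduced, y_star)
            ll_f = _refit(fit_full, y_star)
        except GLMMConvergenceError:
            failed += 1
            continue
        done += 1
        if max(0.0, 2.0 * (ll_f - ll_r)) >= lrt_obs:
            exceed += 1
    if done == 0:
        raise GLMMConvergenceError("all bootstrap refits failed")
    return (1.0 + exceed) / (done + 1.0), failed


def rank_predictors(fits: list[GLMMFit],
                    means: dict | None = None) -> pd.DataFrame:
    """Result table sorted by |slope| descending (ties: predictor name).

    Mirrors the reporting schema: predictor, mean (sd) on the original
    scale when supplied, chi2, p, mean intercept, slope, conditional R2.
    """
    rows = []
    for f in fits:
        m = means.get(f.predictor) if means else None
        rows.append({
            "predictor": f.predictor,
            "mean": None if m is None else m[0],
            "sd": None if m is None else m[1],
            "chi2": f.chi2,
            "p": f.p,
            "mean_intercept": f.mean_intercept,
            "slope": f.slope,
            "r2": f.r2,
        })
    out = pd.DataFrame(rows)
    out["_abs"] = out["slope"].abs()
    out = (out.sort_values(["_abs", "predictor"], ascending=[False, True],
                           kind="mergesort")
           .drop(columns="_abs").reset_index(drop=True))
    return out


# ---------------------------------------------------------------------------
# Gaussian LMMs of Mantel coefficients; site-level linear models
# ---------------------------------------------------------------------------

@dataclass
class LMMFit:
    """Backward-selected Gaussian mixed model of Mantel coefficients."""
    retained: list
    params: pd.Series | None
    dropped: pd.DataFrame       # term, p at removal
    formula: str
    empty: bool = False


_MAIN_TERMS = ["lui", "whc", "distance"]
_INTERACTIONS = [("lui", "whc"), ("lui", "distance"), ("whc", "distance")]


def _lmm_design(df: pd.DataFrame, terms: list) -> tuple[np.ndarray, list]:
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for t in terms:
        if isinstance(t, tuple):
            cols.append(df[t[0]].to_numpy(float) * df[t[1]].to_numpy(float))
            names.append(f"{t[0]}:{t[1]}")
        else:
            cols.append(df[t].to_numpy(float))
            names.append(t)
    return np.column_stack(cols), names


def _fit_lmm_ml(df: pd.DataFrame, terms: list):
    X, names = _lmm_design(df, terms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(df["r"].to_numpy(float), X, groups=df["site_id"])
        last_err = None
        for method in ("lbfgs", "powell", "cg"):
            try:
                res = model.fit(reml=False, method=method, maxiter=300)
            except (np.linalg.LinAlgError, ValueError) as err:
                last_err = err
                continue
            if np.isfinite(res.llf):       # guard against degenerate fits
                return res, names
            last_err = RuntimeError("non-finite log-likelihood")
    raise GLMMConvergenceError(f"mixed model did not converge: {last_err}")


def _lmm_term_p(df, terms, term, method, n_boot, rng):
    """p-value for dropping one term from a Gaussian LMM (ML LRT).

    A full model too ill-conditioned to fit cannot defend the term
    (p = 1); an unfittable reduced model keeps it (p = 0).
    """
    reduced_terms = [t for t in terms if t != term]
    try:
        res_full, _ = _fit_lmm_ml(df, terms)
    except GLMMConvergenceError:
        return 1.0
    try:
        res_red, _ = _fit_lmm_ml(df, reduced_terms)
    except GLMMConvergenceError:
        return 0.0
    lrt = max(0.0, 2.0 * (res_full.llf - res_red.llf))
    if method == "lrt":
        return float(chi2_dist.sf(lrt, df=1))
    # parametric bootstrap: simulate from the reduced fit
    X_red, _ = _lmm_design(df, reduced_terms)
    fe = np.asarray(res_red.fe_params)
    cov_re = np.asarray(res_red.cov_re)
    tau2 = float(cov_re[0, 0]) if cov_re.size else 0.0   # already response-scaled
    sigma2 = float(res_red.scale)
    sites, site_idx = np.unique(df["site_id"], return_inverse=True)
    exceed = 0
    done = 0
    sim = df.copy()
    for _ in range(n_boot):
        b = rng.normal(0, np.sqrt(max(tau2, 0.0)), sites.size)
        y = X_red @ fe + b[site_idx] + rng.normal(0, np.sqrt(sigma2), len(df))
        sim["r"] = y
        try:
            rf, _ = _fit_lmm_ml(sim, terms)
            rr, _ = _fit_lmm_ml(sim, reduced_terms)
        except Exception:
            continue
        done += 1
        if max(0.0, 2.0 * (rf.llf - rr.llf)) >= lrt:
            exceed += 1
    if done == 0:
        return float(chi2_dist.sf(lrt, df=1))
    return (1.0 + exceed) / (done + 1.0)


def fit_mcc_lmm(mcc_table: pd.DataFrame, site_covariates: pd.DataFrame,
                *, alpha: float = 0.05, p_method: str = "bootstrap",
                n_boot: int = 500, seed=None) -> LMMFit:
    """Backward-stepwise Gaussian LMM of Mantel coefficients.

    Response: per-site, per-distance-class Mantel coefficients of a
    spatially structured parameter.  Fixed effects: land-use intensity
    (LUI), water-holding capacity (WHC), distance-class center and all
    pairwise interactions; random intercept per site.  Terms are
    removed one at a time — the term with the largest p above
    ``alpha``, interactions before the main effects they contain —
    with p from a parametric bootstrap LRT (or the asymptotic
    chi-square LRT when ``p_method='lrt'``).

    ``mcc_table`` needs columns site_id, distance, r;
    ``site_covariates`` maps site_id to lui and whc.
    """
    if mcc_table.empty:
        return LMMFit(retained=[], params=None,
                      dropped=pd.DataFrame(columns=["term", "p"]),
                      formula="", empty=True)
    df = mcc_table.merge(site_covariates, on="site_id", how="left")
    if df["site_id"].nunique() < 2:
        raise ValueError("random intercept inestimable with a single site")
    df = df.dropna(subset=["r", "lui", "whc", "distance"]).copy()
    # standardize predictors so the interaction columns are well
    # conditioned; term retention is invariant to this rescaling
    for col in _MAIN_TERMS:
        x = df[col].to_numpy(float)
        sd = x.std(ddof=1)
        df[col] = (x - x.mean()) / (sd if sd > 0 else 1.0)
    rng = np.random.default_rng(seed)
    terms: list = list(_INTERACTIONS) + _MAIN_TERMS
    dropped = []
    while True:
        in_inter = {t for pair in terms if isinstance(pair, tuple)
                    for t in pair}
        candidates = [t for t in terms
                      if isinstance(t, tuple) or t not in in_inter]
        if not candidates:
            break
        pvals = {t: _lmm_term_p(df, terms, t, p_method, n_boot, rng)
                 for t in candidates}
        worst = max(pvals, key=lambda t: (pvals[t], isinstance(t, tuple)))
        if pvals[worst] <= alpha:
            break
        terms.remove(worst)
        name = worst if isinstance(worst, str) else f"{worst[0]}:{worst[1]}"
        dropped.append({"term": name, "p": pvals[worst]})
        if not terms:
            break
    res, names = _fit_lmm_ml(df, terms)
    formula = "r ~ " + " + ".join(names) + " + (1 | site)"
    return LMMFit(retained=[t if isinstance(t, str) else f"{t[0]}:{t[1]}"
                            for t in terms],
                  params=pd.Series(res.fe_params, index=names),
                  dropped=pd.DataFrame(dropped, columns=["term", "p"]),
                  formula=formula)


def fit_site_level_lm(site_summary: pd.DataFrame,
                      response: str) -> tuple[float, float]:
    """OLS of a per-site summary on land-use intensity; returns (R2, p)."""
    df = site_summary.dropna(subset=[response, "lui"])
    if len(df) < 3:
        raise ValueError("need at least 3 sites")
    x = df["lui"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("LUI constant across sites")
    X = sm.add_constant(x)
    res = sm.OLS(df[response].to_numpy(float), X).fit()
    return float(res.rsquared), float(res.f_pvalue)
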