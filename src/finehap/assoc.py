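"""Association stages: cis-eQTL scan with latent factors and BH-FDR,
conditional models, a single-component kinship mixed model, proportional-odds
severity regression, stratified additive tests, and the correlated-traits
global-null Monte Carlo test.

The global-null test asks: given m correlated test statistics, what is the
probability under the joint null of seeing at least k of them with two-sided
p below alpha? Draws z ~ MVN(0, R) answer it by simulation, with a binomial
standard error on the Monte Carlo estimate.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import minimize_scalar
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.stats.multitest import multipletests

__all__ = [
    "estimate_latent_factors",
    "cis_eqtl_scan",
    "bh_fdr",
    "conditional_effect",
    "lmm_test",
    "ordinal_logistic",
    "stratified_additive_test",
    "global_null_test",
    "GlobalNullResult",
    "KinshipLMMFit",
]


def _with_intercept(X: np.ndarray | None, n: int) -> np.ndarray:
    if X is None or (hasattr(X, "shape") and np.asarray(X).size == 0):
        return np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.column_stack([np.ones(n), X])


def _residualize(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of the columns of Y on X (least squares)."""
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ coef


def estimate_latent_factors(expression: pd.DataFrame | np.ndarray,
                            covariates=None, n_factors: int = 11) -> np.ndarray:
    """Latent expression factors: top singular directions over individuals of
    the covariate-residualized, gene-standardized expression matrix.

    ``expression`` is genes x individuals. Returns an orthonormal
    ``(n_individuals, n_factors)`` matrix; ``n_factors = 0`` returns an empty
    factor set.
    """
    E = np.asarray(expression, dtype=float)
    n = E.shape[1]
    if n_factors == 0:
        return np.empty((n, 0))
    if n_factors >= n:
        raise ValueError("n_factors must be below the number of individuals")
    X = _with_intercept(covariates, n)
    R = _residualize(E.T, X).T  # residualize each gene across individuals
    sd = R.std(axis=1, ddof=1)
    sd[sd == 0] = 1.0
    Z = (R - R.mean(axis=1, keepdims=True)) / sd[:, None]
    _, s, Vt = np.linalg.svd(Z, full_matrices=False)
    if n_factors > np.sum(s > 1e-10):
        raise ValueError("n_factors exceeds the rank of the residual matrix")
    return Vt[:n_factors].T


def _ols_records(y: np.ndarray, x: np.ndarray, covariates: np.ndarray | None):
    """beta, se, t, p, n of x in an OLS of y on [1, covariates, x]."""
    n = y.size
    X = _with_intercept(covariates, n)
    X = np.column_stack([X, x])
    res = sm.OLS(y, X).fit()
    return (float(res.params[-1]), float(res.bse[-1]), float(res.tvalues[-1]),
            float(res.pvalues[-1]), n)


def cis_eqtl_scan(dosages: pd.DataFrame, variant_positions: pd.Series | dict,
                  expression: pd.DataFrame, tss: pd.DataFrame,
                  covariates=None, window: int = 500_000,
                  maf_min: float = 0.05) -> tuple[pd.DataFrame, list[str]]:
    """Additive-dosage OLS of expression on each variant-gene pair in cis.

    ``dosages``: individuals x variants (values in [0, 2]);
    ``expression``: genes x individuals; ``tss``: columns (gene, tss).
    Pairs with ``|position - tss| <= window`` are tested; variants with
    minor-allele frequency below ``maf_min`` are excluded and returned in the
    second element. One BH family covers the whole scan.
    """
    d = np.asarray(dosages, dtype=float)
    if np.any((d < 0) | (d > 2)):
        raise ValueError("dosages must lie in [0, 2]")
    if dosages.shape[0] != expression.shape[1]:
        raise ValueError("individuals must align between dosages and expression")
    pos = pd.Series(variant_positions)
    tssmap = tss.set_index("gene")["tss"] if "gene" in tss.columns else tss["tss"]

    excluded = []
    kept = []
    for v in dosages.columns:
        x = dosages[v].to_numpy(float)
        f = x.mean() / 2.0
        maf = min(f, 1 - f)
        if maf < maf_min:
            excluded.append(str(v))
        elif np.ptp(x) == 0:
            raise ValueError(f"constant dosage for variant {v}")
        else:
            kept.append(v)

    rows = []
    for v in kept:
        x = dosages[v].to_numpy(float)
        for g in expression.index:
            if g not in tssmap.index or abs(int(pos[v]) - int(tssmap[g])) > window:
                continue
            y = expression.loc[g].to_numpy(float)
            beta, se, t, p, n = _ols_records(y, x, covariates)
            rows.append({"variant": str(v), "unit": str(g), "beta": beta, "se": se,
                         "stat": t, "p": p, "n": n})
    out = pd.DataFrame(rows, columns=["variant", "unit", "beta", "se", "stat", "p", "n"])
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
    else:
        out["q"] = pd.Series(dtype=float)
    return out, excluded


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value set")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def conditional_effect(target_dosage, conditioning_dosages, y, covariates=None
                       ) -> dict:
    """Target effect re-estimated with conditioning dosages as covariates.

    Raises on perfect collinearity between the target and the conditioning
    set (including conditioning on the target itself).
    """
    x = np.asarray(target_dosage, dtype=float)
    C = np.asarray(conditioning_dosages, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    for j in range(C.shape[1]):
        r = np.corrcoef(x, C[:, j])[0, 1]
        if np.isclose(abs(r), 1.0, atol=1e-12):
            raise ValueError("conditioning variant is perfectly collinear with the target")
    resid = _residualize(x[:, None], _with_intercept(C, x.size)).ravel()
    if np.allclose(resid, 0, atol=1e-10):
        raise ValueError("target is collinear with the conditioning set")
    cov = C if covariates is None else np.column_stack([np.asarray(covariates, float), C])
    beta, se, t, p, n = _ols_records(np.asarray(y, float), x, cov)
    return {"beta": beta, "se": se, "stat": t, "p": p, "n": n}


@dataclass
class KinshipLMMFit:
    """Single-variance-component mixed-model fit on the kinship eigenbasis."""

    beta: np.ndarray
    se: np.ndarray
    names: list[str]
    sigma2_g: float
    sigma2_e: float
    dosage_beta: float
    dosage_se: float
    dosage_p: float
    loglik_reml: float


def lmm_test(trait, dosage, covariates=None, kinship=None) -> KinshipLMMFit:
    """REML linear mixed model with one genetic variance component.

    ``y = X b + g + e`` with ``g ~ N(0, sigma2_g K)`` and
    ``e ~ N(0, sigma2_e I)``. The kinship matrix is eigen-decomposed once;
    the variance ratio is profiled out on that basis and optimized by
    bounded scalar search. A Wald p-value is reported for the dosage term.
    With ``K = I`` the fit collapses to OLS.
    """
    y = np.asarray(trait, dtype=float)
    n = y.size
    x = np.asarray(dosage, dtype=float)
    X = _with_intercept(covariates, n)
    X = np.column_stack([X, x])
    names = [f"c{i}" for i in range(X.shape[1] - 1)] + ["dosage"]
    K = np.eye(n) if kinship is None else np.asarray(kinship, dtype=float)
    if K.shape != (n, n) or not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("kinship must be a symmetric n x n matrix")
    evals, U = np.linalg.eigh(K)
    if evals.min() < -1e-8:
        raise ValueError("kinship matrix is not positive semi-definite")
    evals = np.clip(evals, 0.0, None)
    yr = U.T @ y
    Xr = U.T @ X
    p = X.shape[1]

    def reml_neg(log_lam: float):
        lam = np.exp(log_lam)
        w = 1.0 / (lam * evals + 1.0)
        XtWX = Xr.T @ (Xr * w[:, None])
        XtWy = Xr.T @ (yr * w)
        beta = np.linalg.solve(XtWX, XtWy)
        r = yr - Xr @ beta
        rss = float(np.sum(w * r * r))
        s2e = rss / (n - p)
        _, logdet_xwx = np.linalg.slogdet(XtWX)
        nll = 0.5 * ((n - p) * np.log(s2e) - np.sum(np.log(w))
                     + logdet_xwx + (n - p))
        return nll, beta, s2e, XtWX

    # coarse grid then bounded refinement of log(sigma2_g / sigma2_e)
    grid = np.linspace(-10, 8, 37)
    vals = [reml_neg(g)[0] for g in grid]
    j = int(np.argmin(vals))
    lo, hi = grid[max(j - 1, 0)], grid[min(j + 1, grid.size - 1)]
    opt = minimize_scalar(lambda g: reml_neg(g)[0], bounds=(lo, hi), method="bounded")
    nll, beta, s2e, XtWX = reml_neg(float(opt.x))
    lam = float(np.exp(opt.x))
    if lam < 1e-8:
        lam = 0.0  # boundary: effectively no genetic component
    cov = np.linalg.inv(XtWX) * s2e
    se = np.sqrt(np.diag(cov))
    z = beta[-1] / se[-1]
    pval = float(2 * stats.norm.sf(abs(z)))
    return KinshipLMMFit(beta=beta, se=se, names=names,
                         sigma2_g=lam * s2e, sigma2_e=s2e,
                         dosage_beta=float(beta[-1]), dosage_se=float(se[-1]),
                         dosage_p=pval, loglik_reml=-float(nll))


def ordinal_logistic(severity, predictor, covariates=None) -> dict:
    """Proportional-odds regression of an ordered categorical outcome.

    Returns the predictor's log-odds ``beta`` with 95% CI and p, plus the
    category thresholds. With two categories this reduces to binary logistic
    regression.
    """
    y = np.asarray(severity)
    cats = np.unique(y)
    if cats.size < 2:
        raise ValueError("severity must have at least two observed categories")
    x = np.asarray(predictor, dtype=float)[:, None]
    if covariates is not None:
        X = np.column_stack([x, np.asarray(covariates, dtype=float)])
    else:
        X = x
    Xdf = pd.DataFrame(X, columns=["predictor"] + [f"c{i}" for i in range(X.shape[1] - 1)])
    model = OrderedModel(pd.Categorical(y, ordered=True), Xdf, distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="bfgs", disp=False, maxiter=500)
    beta = float(res.params["predictor"])
    se = float(res.bse["predictor"])
    if not np.isfinite(se) or abs(beta) > 20:
        raise RuntimeError("ordinal fit failed (possible separation)")
    thresholds = model.transform_threshold_params(res.params)[1:-1]
    return {"beta": beta, "se": se, "ci_low": beta - 1.96 * se,
            "ci_high": beta + 1.96 * se,
            "p": float(2 * stats.norm.sf(abs(beta / se))),
            "thresholds": np.asarray(thresholds, dtype=float),
            "n": int(y.size), "converged": bool(res.mle_retvals.get("converged", True))}


def stratified_additive_test(status, modifier_dosage, stratum_genotype,
                             covariates=None, strata=(0, 2)) -> pd.DataFrame:
    """Logistic regression of status on a modifier dosage within homozygote
    strata of a background genotype; one OR (95% CI) per stratum."""
    y = np.asarray(status, dtype=float)
    x = np.asarray(modifier_dosage, dtype=float)
    g = np.asarray(stratum_genotype)
    rows = []
    for s in strata:
        mask = g == s
        if not mask.any():
            raise ValueError(f"empty stratum {s}")
        if np.ptp(x[mask]) == 0:
            rows.append({"stratum": s, "n": int(mask.sum()), "beta": np.nan,
                         "se": np.nan, "or": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p": np.nan,
                         "note": "no modifier variation in stratum"})
            continue
        X = _with_intercept(None if covariates is None
                            else np.asarray(covariates, float)[mask], int(mask.sum()))
        X = np.column_stack([X, x[mask]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y[mask], X).fit(disp=False, maxiter=200)
        b, se = float(res.params[-1]), float(res.bse[-1])
        rows.append({"stratum": s, "n": int(mask.sum()), "beta": b, "se": se,
                     "or": float(np.exp(b)), "ci_low": float(np.exp(b - 1.96 * se)),
                     "ci_high": float(np.exp(b + 1.96 * se)),
                     "p": float(res.pvalues[-1]), "note": ""})
    return pd.DataFrame(rows)


@dataclass
class GlobalNullResult:
    """Monte Carlo global-null test over m correlated traits."""

    m: int
    alpha: float
    k: int
    p: float
    mc_se: float
    n_draws: int
    seed: int
    R: np.ndarray


def global_null_test(p_values=None, R=None, alpha: float = 0.05,
                     k: int | None = None, n_draws: int = 1_000_000,
                     seed: int = 0) -> GlobalNullResult:
    """Probability of >= k of m two-sided tests below alpha under a
    correlated multivariate-normal null.

    ``k`` defaults to the observed count of ``p < alpha``. Draws are chunked
    so memory stays modest; the result is deterministic under ``seed``.
    """
    if R is None:
        raise ValueError("a trait correlation matrix R is required")
    R = np.asarray(R, dtype=float)
    m = R.shape[0]
    if R.shape != (m, m) or not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("R must be square and symmetric")
    ev = np.linalg.eigvalsh(R)
    if ev.min() < -1e-8:
        raise ValueError("R must be positive semi-definite")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("R must have unit diagonal")
    if k is None:
        if p_values is None:
            raise ValueError("either k or observed p-values must be given")
        k = int(np.sum(np.asarray(p_values, dtype=float) < alpha))
    if n_draws < 10_000:
        warnings.warn("fewer than 10^4 Monte Carlo draws", stacklevel=2)
    if k <= 0:
        return GlobalNullResult(m=m, alpha=alpha, k=k, p=1.0, mc_se=0.0,
                                n_draws=n_draws, seed=seed, R=R)

    zcrit = stats.norm.isf(alpha / 2.0)
    # PSD square root (Cholesky with jitter fallback)
    try:
        Lc = np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(R)
        Lc = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
    rng = np.random.default_rng(seed)
    hits = 0
    done = 0
    chunk = 200_000
    while done < n_draws:
        b = min(chunk, n_draws - done)
        z = rng.standard_normal((b, m)) @ Lc.T
        counts = (np.abs(z) > zcrit).sum(axis=1)
        hits += int((counts >= k).sum())
        done += b
    p = hits / n_draws
    se = float(np.sqrt(max(p * (1 - p), 1.0 / n_draws) / n_draws))
    return GlobalNullResult(m=m, alpha=alpha, k=int(k), p=float(p), mc_se=se,
                            n_draws=int(n_draws), seed=int(seed), R=R)
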