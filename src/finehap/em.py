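"""EM haplotype-frequency estimation and posterior-weighted haplotype GLM.

Multi-SNP haplotype frequencies are estimated from unphased diploid genotypes
by expectation-maximization over the latent phase: the E-step distributes
each individual over its compatible unordered haplotype pairs in proportion
to ``(2 - delta_ab) * p_a * p_b`` under Hardy-Weinberg, the M-step re-counts
haplotypes from those weights. Haplotype effects on a binary outcome are then
tested with a logistic model additive in haplotype dosage, fitted on
pair-expanded pseudo-observations whose weights fold in both the phase prior
and the outcome likelihood, re-computed each outer iteration — the classic
posterior-weighted haplotype regression for unphased case-control data.

Genotype codes are 0/1/2 counts of the alternate allele; missing is -1 and is
expanded over both alleles in the E-step rather than dropping the individual.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm as _norm

__all__ = [
    "enumerate_compatible_pairs",
    "em_haplotype_frequencies",
    "haplotype_glm",
    "posterior_quality_summary",
    "HaplotypeTable",
    "PhasePosterior",
    "HaploGLMFit",
    "SeparationError",
]

MISSING = -1


class SeparationError(RuntimeError):
    """Raised when a logistic fit is unbounded (complete separation)."""


def enumerate_compatible_pairs(genotype_row, het_cap: int = 20) -> list[tuple[tuple, tuple]]:
    """All unordered haplotype pairs whose site-wise sums reproduce a genotype.

    Heterozygous sites contribute a 0/1 split between the two haplotypes;
    missing sites (code -1) are expanded over both alleles on both
    haplotypes. With ``h`` ambiguous splits there are ``2**(h-1)`` unordered
    pairs for a fully typed genotype.
    """
    g = np.asarray(genotype_row, dtype=int)
    if np.all(g == MISSING):
        raise ValueError("individual with all genotypes missing")
    bad = ~np.isin(g, (0, 1, 2, MISSING))
    if bad.any():
        raise ValueError(f"invalid genotype code at site {int(np.flatnonzero(bad)[0])}")
    het = np.flatnonzero(g == 1)
    miss = np.flatnonzero(g == MISSING)
    if het.size > het_cap:
        raise ValueError(f"{het.size} heterozygous sites exceed the cap of {het_cap}")

    base = np.where(g == 2, 1, 0)
    pairs: set[tuple[tuple, tuple]] = set()
    for het_assign in itertools.product((0, 1), repeat=het.size):
        for miss_assign in itertools.product(((0, 0), (0, 1), (1, 0), (1, 1)),
                                             repeat=miss.size):
            h1 = base.copy()
            h2 = base.copy()
            h1[het] = het_assign
            h2[het] = 1 - np.asarray(het_assign, dtype=int)
            for s, (a, b) in zip(miss, miss_assign):
                h1[s], h2[s] = a, b
            t1, t2 = tuple(h1.tolist()), tuple(h2.tolist())
            pairs.add((t1, t2) if t1 <= t2 else (t2, t1))
    return sorted(pairs)


@dataclass
class HaplotypeTable:
    """Converged EM frequency estimates."""

    haplotypes: list[str]
    frequencies: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray

    def as_series(self) -> pd.Series:
        return pd.Series(self.frequencies, index=self.haplotypes, name="frequency")


@dataclass
class PhasePosterior:
    """Per-individual compatible pairs with posterior phase weights."""

    haplotypes: list[str]
    pair_index: list[np.ndarray]  # per individual: (n_pairs, 2) haplotype indices
    weights: list[np.ndarray]

    @property
    def n_individuals(self) -> int:
        return len(self.pair_index)

    def max_posterior(self) -> np.ndarray:
        return np.array([w.max() for w in self.weights])


def _index_pairs(genotypes: np.ndarray, het_cap: int):
    """Enumerate pairs for every individual and index them against the
    distinct haplotype set of the whole sample."""
    hap_index: dict[tuple, int] = {}
    per_ind = []
    for row in genotypes:
        pairs = enumerate_compatible_pairs(row, het_cap=het_cap)
        idx = np.empty((len(pairs), 2), dtype=np.int64)
        for k, (a, b) in enumerate(pairs):
            idx[k, 0] = hap_index.setdefault(a, len(hap_index))
            idx[k, 1] = hap_index.setdefault(b, len(hap_index))
        per_ind.append(idx)
    haps = [None] * len(hap_index)
    for h, i in hap_index.items():
        haps[i] = "".join(map(str, h))
    return haps, per_ind


def em_haplotype_frequencies(genotypes, tol: float = 1e-8, max_iter: int = 5000,
                             het_cap: int = 20, n_starts: int = 1,
                             seed: int = 0):
    """EM haplotype frequencies from unphased genotypes.

    Returns ``(HaplotypeTable, PhasePosterior)``. Initialization is uniform
    over the haplotypes compatible with the sample; ``n_starts > 1`` adds
    Dirichlet-perturbed restarts and keeps the best likelihood (to escape
    symmetric stationary points). Convergence is a relative log-likelihood
    change below ``tol``; non-convergence is flagged, not fatal. The
    log-likelihood is asserted non-decreasing at every EM step.
    """
    genotypes = np.asarray(genotypes)
    if genotypes.ndim != 2 or genotypes.shape[0] < 1:
        raise ValueError("need a 2-D genotype matrix with >= 1 individual")
    if tol <= 0:
        raise ValueError("tol must be positive")
    haps, per_ind = _index_pairs(genotypes, het_cap)
    H = len(haps)
    n = genotypes.shape[0]

    # flat pair arrays for vectorized E/M steps
    pair_a = np.concatenate([p[:, 0] for p in per_ind])
    pair_b = np.concatenate([p[:, 1] for p in per_ind])
    pair_ind = np.concatenate([np.full(len(p), i) for i, p in enumerate(per_ind)])
    mult = np.where(pair_a == pair_b, 1.0, 2.0)

    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(1, n_starts)):
        p = np.full(H, 1.0 / H) if start == 0 else rng.dirichlet(np.full(H, 2.0))
        trace = []
        prev_ll = -np.inf
        converged = False
        for it in range(1, max_iter + 1):
            lik = mult * p[pair_a] * p[pair_b]
            per_ind_sum = np.bincount(pair_ind, weights=lik, minlength=n)
            if np.any(per_ind_sum <= 0):
                # a haplotype needed by some individual has frequency 0;
                # re-seed those pairs uniformly
                lik = lik + 1e-300
                per_ind_sum = np.bincount(pair_ind, weights=lik, minlength=n)
            ll = float(np.sum(np.log(per_ind_sum)))
            if trace and ll < trace[-1] - 1e-9:
                raise AssertionError("EM log-likelihood decreased")
            trace.append(ll)
            w = lik / per_ind_sum[pair_ind]
            counts = (np.bincount(pair_a, weights=w, minlength=H)
                      + np.bincount(pair_b, weights=w, minlength=H))
            p = counts / (2.0 * n)
            if prev_ll > -np.inf and abs(ll - prev_ll) <= tol * (abs(prev_ll) + 1e-12):
                converged = True
                break
            prev_ll = ll
        if not converged:
            warnings.warn("EM did not converge within max_iter", stacklevel=2)
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], p, len(trace), converged, np.asarray(trace))

    ll, p, n_iter, converged, trace = best
    table = HaplotypeTable(haps, p, ll, n_iter, converged, trace)

    lik = mult * p[pair_a] * p[pair_b] + 1e-300
    per_ind_sum = np.bincount(pair_ind, weights=lik, minlength=n)
    w = lik / per_ind_sum[pair_ind]
    weights = [w[pair_ind == i] for i in range(n)]
    posterior = PhasePosterior(haps, per_ind, weights)
    return table, posterior


def posterior_quality_summary(posterior: PhasePosterior) -> dict:
    """Median / interquartile range / minimum of the per-individual maximum
    phase posterior (the phasing-confidence summary)."""
    if posterior.n_individuals == 0:
        raise ValueError("empty posterior set")
    mx = posterior.max_posterior()
    q25, med, q75 = np.percentile(mx, [25, 50, 75])
    return {"median": float(med), "iqr": (float(q25), float(q75)),
            "min": float(mx.min()), "n": int(mx.size)}


@dataclass
class HaploGLMFit:
    """Posterior-weighted haplotype logistic regression fit."""

    reference: str
    table: pd.DataFrame  # per non-reference haplotype class
    covariate_coefficients: pd.Series
    frequencies: pd.Series
    n_outer: int
    converged: bool
    pooled_rare: list[str] = field(default_factory=list)

    def coefficient(self, haplotype: str) -> float:
        return float(self.table.loc[haplotype, "beta"])


def haplotype_glm(posterior: PhasePosterior, outcome, covariates=None,
                  reference_haplotype: str | None = None, min_freq: float = 0.05,
                  tol: float = 1e-6, max_iter: int = 50,
                  frequencies: np.ndarray | None = None) -> HaploGLMFit:
    """Additive haplotype-dosage logistic regression with phase uncertainty.

    Each individual is expanded over its compatible haplotype pairs; rows are
    weighted by the posterior probability of the pair given genotype *and*
    outcome, recomputed from the current coefficients each outer iteration.
    Haplotypes with frequency below ``min_freq`` are pooled into one "rare"
    class; the reference haplotype (default: most frequent) gets no
    coefficient. Wald CIs are ``beta +/- 1.96 SE``.
    """
    y = np.asarray(outcome, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    n = posterior.n_individuals
    if y.size != n:
        raise ValueError("outcome length must match the posterior set")
    haps = posterior.haplotypes
    H = len(haps)

    if frequencies is None:
        freq = np.zeros(H)
        for idx, w in zip(posterior.pair_index, posterior.weights):
            np.add.at(freq, idx[:, 0], w)
            np.add.at(freq, idx[:, 1], w)
        freq /= 2.0 * n
    else:
        freq = np.asarray(frequencies, dtype=float)
    freq_s = pd.Series(freq, index=haps)

    if reference_haplotype is None:
        reference_haplotype = freq_s.idxmax()
    if reference_haplotype not in haps:
        raise ValueError(f"reference haplotype {reference_haplotype!r} not in sample")
    if freq_s[reference_haplotype] < min_freq:
        raise ValueError("reference haplotype frequency is below min_freq")

    common = [h for h in haps if freq_s[h] >= min_freq and h != reference_haplotype]
    rare = [h for h in haps if freq_s[h] < min_freq]
    classes = common + (["rare"] if rare else [])
    class_of = np.full(H, -1, dtype=int)
    for k, h in enumerate(common):
        class_of[haps.index(h)] = k
    for h in rare:
        class_of[haps.index(h)] = len(common)

    # pair-expanded design
    pair_a = np.concatenate([p[:, 0] for p in posterior.pair_index])
    pair_b = np.concatenate([p[:, 1] for p in posterior.pair_index])
    pair_ind = np.concatenate([np.full(len(p), i)
                               for i, p in enumerate(posterior.pair_index)])
    prior_w = np.concatenate(posterior.weights)
    n_rows = pair_a.size

    dosage = np.zeros((n_rows, len(classes)))
    for side in (pair_a, pair_b):
        cls = class_of[side]
        keep = cls >= 0
        np.add.at(dosage, (np.flatnonzero(keep), cls[keep]), 1.0)

    X_cov = None
    cov_names: list[str] = []
    if covariates is not None:
        cov_df = pd.DataFrame(covariates)
        cov_names = [str(c) for c in cov_df.columns]
        X_cov = cov_df.to_numpy(dtype=float)[pair_ind]
    X = np.column_stack([np.ones(n_rows), dosage] +
                        ([X_cov] if X_cov is not None else []))
    names = ["intercept"] + classes + cov_names
    y_rows = y[pair_ind]

    w = prior_w.copy()
    beta_prev = None
    res = None
    converged = False
    for outer in range(1, max_iter + 1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(y_rows, X, family=sm.families.Binomial(), freq_weights=w)
            res = model.fit(maxiter=200)
        beta = res.params
        if not np.all(np.isfinite(beta)) or np.abs(beta[1:1 + len(classes)]).max() > 15:
            raise SeparationError("unbounded haplotype coefficient (separation)")
        if beta_prev is not None and np.abs(beta - beta_prev).max() < tol:
            converged = True
            break
        beta_prev = beta
        # posterior over pairs given genotype and outcome
        eta = X @ beta
        p1 = expit(eta)
        lik_y = np.where(y_rows > 0.5, p1, 1.0 - p1)
        w = prior_w * lik_y
        norm = np.bincount(pair_ind, weights=w, minlength=n)
        w = w / np.maximum(norm[pair_ind], 1e-300)

    # Wald SEs from the observed-data information of the phase-mixture
    # likelihood (Louis' identity), not from the weighted pseudo-likelihood:
    # per individual, log L_i = log sum_k c_ik P(y_i | x_ik, beta), whose
    # Hessian is sum_k w_ik [H_ik + g_ik g_ik'] - (sum_k w_ik g_ik)(.)'
    # with g_ik = (y - pi) x and H_ik = -pi (1 - pi) x x'.
    beta = res.params
    eta = X @ beta
    pi = expit(eta)
    lik_y = np.where(y_rows > 0.5, pi, 1.0 - pi)
    w_post = prior_w * lik_y
    norm = np.bincount(pair_ind, weights=w_post, minlength=n)
    w_post = w_post / np.maximum(norm[pair_ind], 1e-300)
    resid = y_rows - pi
    G = X * resid[:, None]  # per-row score g_ik
    p_dim = X.shape[1]
    H = -(X * (w_post * pi * (1 - pi))[:, None]).T @ X  # sum w H_ik
    H += (X * (w_post * resid * resid)[:, None]).T @ X  # + sum w g g'
    Gbar = np.zeros((n, p_dim))  # per-individual averaged score
    for d in range(p_dim):
        Gbar[:, d] = np.bincount(pair_ind, weights=w_post * G[:, d], minlength=n)
    H -= Gbar.T @ Gbar
    info = -H
    cov = np.linalg.pinv(info)
    se_obs = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    params = pd.Series(res.params, index=names)
    bse = pd.Series(se_obs, index=names)
    rows = []
    for k, cls in enumerate(classes):
        b, se = params[cls], bse[cls]
        f = float(freq_s[rare].sum()) if cls == "rare" else float(freq_s[cls])
        rows.append({"haplotype": cls, "beta": b, "se": se,
                     "or": float(np.exp(b)),
                     "ci_low": b - 1.96 * se, "ci_high": b + 1.96 * se,
                     "p": float(2 * _norm.sf(abs(b / se))) if se > 0 else np.nan,
                     "frequency": f, "pooled_rare": cls == "rare"})
    table = pd.DataFrame(rows).set_index("haplotype")
    cov_coef = params[["intercept"] + cov_names]
    return HaploGLMFit(reference=reference_haplotype, table=table,
                       covariate_coefficients=cov_coef, frequencies=freq_s,
                       n_outer=outer, converged=converged, pooled_rare=rare)
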