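"""Validation utilities: independent oracles and calibration replicates.

These routines deliberately avoid the production code paths they check:
the EM oracle maximizes the multinomial phase likelihood by grid search /
constrained optimization rather than EM; the copying-model oracle sums and
maximizes over *all* donor paths by enumeration; the calibration helpers
re-simulate small studies many times to measure CI coverage, frequency
recovery and null p-value uniformity of the association stages.
"""
from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from . import assoc, em
from .paint import CopyingModelParams

__all__ = [
    "phase_loglik",
    "grid_oracle_loglik",
    "exhaustive_copying_posteriors",
    "exhaustive_viterbi",
    "draw_case_control",
    "glm_ci_coverage",
    "em_frequency_errors",
    "null_pvalues_eqtl",
    "null_pvalues_lmm",
    "null_pvalues_ordinal",
    "null_pvalues_stratified",
    "null_pvalues_haplo_glm",
]

# ---------------------------------------------------------------------------
# EM oracle: direct maximization of the observed-data likelihood


def _pair_arrays(genotypes, het_cap=20):
    haps, per_ind = em._index_pairs(np.asarray(genotypes), het_cap)
    pair_a = np.concatenate([p[:, 0] for p in per_ind])
    pair_b = np.concatenate([p[:, 1] for p in per_ind])
    breaks = np.cumsum([0] + [len(p) for p in per_ind])[:-1]
    mult = np.where(pair_a == pair_b, 1.0, 2.0)
    return haps, pair_a, pair_b, breaks, mult


def phase_loglik(p, pair_a, pair_b, breaks, mult) -> float:
    """Observed-data log-likelihood of haplotype frequencies ``p``."""
    lik = mult * p[pair_a] * p[pair_b]
    return float(np.sum(np.log(np.add.reduceat(lik, breaks) + 1e-300)))


def _compositions(total: int, k: int):
    """Integer compositions of ``total`` into ``k`` non-negative parts."""
    for dividers in itertools.combinations(range(total + k - 1), k - 1):
        prev = -1
        parts = []
        for d in dividers:
            parts.append(d - prev - 1)
            prev = d
        parts.append(total + k - 2 - prev)
        yield parts


def grid_oracle_loglik(genotypes, het_cap: int = 20, n_polish_starts: int = 30,
                       seed: int = 0) -> float:
    """Maximum log-likelihood over the frequency simplex, by a method
    independent of EM.

    Up to 4 candidate haplotypes: exhaustive grid at step 0.01; 5: step
    0.02; more: many-start SLSQP on the simplex polished from the best of a
    large Dirichlet sample. Used as the reference the EM optimum must reach.
    """
    haps, pair_a, pair_b, breaks, mult = _pair_arrays(genotypes, het_cap)
    k = len(haps)
    if k == 1:
        return phase_loglik(np.array([1.0]), pair_a, pair_b, breaks, mult)

    def ll_many(P):  # (G, k) grid of frequency vectors
        lik = mult[None, :] * P[:, pair_a] * P[:, pair_b]
        per_ind = np.add.reduceat(lik, breaks, axis=1) + 1e-300
        return np.log(per_ind).sum(axis=1)

    best_p, best_ll = None, -np.inf
    if k <= 5:
        step_n = 100 if k <= 4 else 50
        grid = np.array([c for c in _compositions(step_n, k)], dtype=float) / step_n
        # chunk to bound memory
        for lo in range(0, len(grid), 100_000):
            chunk = grid[lo:lo + 100_000]
            lls = ll_many(chunk)
            j = int(np.argmax(lls))
            if lls[j] > best_ll:
                best_ll, best_p = float(lls[j]), chunk[j]
    else:
        rng = np.random.default_rng(seed)
        sample = rng.dirichlet(np.full(k, 0.5), size=20_000)
        lls = ll_many(sample)
        order = np.argsort(lls)[::-1]
        best_ll = float(lls[order[0]])
        best_p = sample[order[0]]
        starts = sample[order[:n_polish_starts]]
    # SLSQP polish (also for small k: refines off-grid optima)
    starts = [best_p] if k <= 5 else list(starts)

    def neg(p):
        p = np.clip(p, 1e-12, 1.0)
        return -phase_loglik(p / p.sum(), pair_a, pair_b, breaks, mult)

    cons = ({"type": "eq", "fun": lambda p: p.sum() - 1.0},)
    bounds = [(0.0, 1.0)] * k
    for s in starts:
        res = minimize(neg, s, method="SLSQP", bounds=bounds, constraints=cons,
                       options={"maxiter": 300, "ftol": 1e-12})
        if res.success or np.isfinite(res.fun):
            best_ll = max(best_ll, -float(res.fun))
    return best_ll


# ---------------------------------------------------------------------------
# copying-model oracle: exhaustive path enumeration


def _path_tables(target, donors, distances, params: CopyingModelParams):
    target = np.asarray(target)
    donors = np.asarray(donors)
    D, L = donors.shape
    s = 1.0 - np.exp(-params.rho * np.asarray(distances, dtype=float))
    emit = np.where(donors == target[None, :], 1.0 - params.theta, params.theta)
    trans = []
    for j in range(L - 1):
        T = np.full((D, D), s[j] / D)
        np.fill_diagonal(T, (1.0 - s[j]) + s[j] / D)
        trans.append(T)
    return emit, trans, D, L


def exhaustive_copying_posteriors(target, donors, distances,
                                  params: CopyingModelParams):
    """Posterior copying probabilities by brute-force summation over all
    ``D**L`` donor paths. Returns ``(posteriors, log_likelihood)``."""
    emit, trans, D, L = _path_tables(target, donors, distances, params)
    post = np.zeros((L, D))
    total = 0.0
    for path in itertools.product(range(D), repeat=L):
        p = emit[path[0], 0] / D
        for j in range(1, L):
            p *= trans[j - 1][path[j - 1], path[j]] * emit[path[j], j]
        total += p
        for j, d in enumerate(path):
            post[j, d] += p
    return post / total, float(np.log(total))


def exhaustive_viterbi(target, donors, distances, params: CopyingModelParams):
    """Best donor path by enumeration; first in lexicographic order on ties.
    Returns ``(path, log_probability, unique)``."""
    emit, trans, D, L = _path_tables(target, donors, distances, params)
    best_p, best_path, n_best = -1.0, None, 0
    for path in itertools.product(range(D), repeat=L):
        p = emit[path[0], 0] / D
        for j in range(1, L):
            p *= trans[j - 1][path[j - 1], path[j]] * emit[path[j], j]
        if p > best_p * (1 + 1e-12):
            best_p, best_path, n_best = p, path, 1
        elif np.isclose(p, best_p, rtol=1e-9):
            n_best += 1
    return np.array(best_path), float(np.log(best_p)), n_best == 1


# ---------------------------------------------------------------------------
# case-control calibration for the posterior-weighted haplotype GLM

CAL_HAPS = ("00000", "11111", "01101", "10010")
CAL_FREQS = (0.40, 0.30, 0.15, 0.15)
CAL_TARGET = "01101"


def draw_case_control(rng, n: int = 2000, haps=CAL_HAPS, freqs=CAL_FREQS,
                      target=CAL_TARGET, log_or: float = float(np.log(1.67)),
                      alpha: float = -0.5):
    """Unphased genotypes and status under an additive haplotype model."""
    H = np.array([[int(c) for c in h] for h in haps])
    idx = rng.choice(len(haps), size=(n, 2), p=np.asarray(freqs) / np.sum(freqs))
    genotypes = H[idx[:, 0]] + H[idx[:, 1]]
    t = list(haps).index(target)
    dosage = (idx == t).sum(axis=1)
    y = (rng.random(n) < expit(alpha + log_or * dosage)).astype(int)
    return genotypes, y, dosage


def glm_ci_coverage(n_reps: int = 200, n: int = 2000,
                    log_or: float = float(np.log(1.67)), seed: int = 0) -> dict:
    """Fraction of replicates whose 95% Wald CI covers the true log-OR."""
    rng = np.random.default_rng(seed)
    cover, betas, failures = 0, [], 0
    done = 0
    while done < n_reps:
        G, y, _ = draw_case_control(rng, n=n, log_or=log_or)
        table, post = em.em_haplotype_frequencies(G)
        try:
            fit = em.haplotype_glm(post, y, reference_haplotype="00000",
                                   frequencies=table.frequencies)
        except em.SeparationError:
            failures += 1
            if failures > n_reps // 10:
                raise
            continue
        row = fit.table.loc[CAL_TARGET]
        betas.append(row["beta"])
        cover += int(row["ci_low"] <= log_or <= row["ci_high"])
        done += 1
    return {"coverage": cover / n_reps, "mean_beta": float(np.mean(betas)),
            "true_log_or": log_or, "n_reps": n_reps, "n": n,
            "separation_failures": failures}


def em_frequency_errors(n_reps: int = 100, n: int = 2000, seed: int = 0) -> np.ndarray:
    """Max absolute EM frequency error against the generating frequencies."""
    rng = np.random.default_rng(seed)
    errs = []
    for _ in range(n_reps):
        G, _, _ = draw_case_control(rng, n=n, log_or=0.0)
        table, _ = em.em_haplotype_frequencies(G)
        est = table.as_series()
        e = max(abs(est.get(h, 0.0) - f) for h, f in zip(CAL_HAPS, CAL_FREQS))
        errs.append(e)
    return np.asarray(errs)


# ---------------------------------------------------------------------------
# null p-value draws, one per association stage


def null_pvalues_eqtl(n_pairs: int = 1000, n: int = 150, seed: int = 0) -> np.ndarray:
    """cis-eQTL scan p-values with expression independent of dosage."""
    import pandas as pd
    rng = np.random.default_rng(seed)
    n_var, n_gene = max(1, n_pairs // 100), 100
    dos = pd.DataFrame(rng.binomial(2, 0.3, size=(n, n_var)).astype(float),
                       columns=[f"v{i}" for i in range(n_var)])
    pos = {f"v{i}": 1_000_000 + i for i in range(n_var)}
    expr = pd.DataFrame(rng.normal(size=(n_gene, n)),
                        index=[f"g{i}" for i in range(n_gene)])
    tss = pd.DataFrame({"gene": expr.index, "tss": 1_000_000})
    cov = rng.normal(size=(n, 3))
    rec, _ = assoc.cis_eqtl_scan(dos, pos, expr, tss, covariates=cov,
                                 maf_min=0.05)
    return rec["p"].to_numpy()


def null_pvalues_lmm(n_reps: int = 300, n: int = 200, seed: int = 0) -> np.ndarray:
    """Kinship LMM dosage p-values for a heritable trait and unrelated dosage."""
    from .simulate import simulate_kinship
    rng = np.random.default_rng(seed)
    K, draw = simulate_kinship([4] * (n // 4), rng)
    out = []
    for _ in range(n_reps):
        g = draw(1.0, rng)
        y = g + rng.normal(size=n)
        x = rng.binomial(2, 0.3, size=n).astype(float)
        cov = rng.normal(size=(n, 2))
        out.append(assoc.lmm_test(y, x, cov, K).dosage_p)
    return np.asarray(out)


def null_pvalues_ordinal(n_reps: int = 300, n: int = 200, seed: int = 0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    out = []
    c1, c2 = -0.84, 0.35
    for _ in range(n_reps):
        x = rng.binomial(2, 0.2, size=n).astype(float)
        u = rng.random(n)
        y = np.where(u < expit(c1), 0, np.where(u < expit(c2), 1, 2))
        try:
            out.append(assoc.ordinal_logistic(y, x)["p"])
        except RuntimeError:
            continue
    return np.asarray(out)


def null_pvalues_stratified(n_reps: int = 300, n: int = 400, seed: int = 0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_reps):
        g = rng.choice([0, 2], size=n)
        x = rng.binomial(2, 0.3, size=n).astype(float)
        y = rng.binomial(1, 0.4, size=n)
        tab = assoc.stratified_additive_test(y, x, g)
        out.extend(tab["p"].dropna().tolist())
    return np.asarray(out)


def null_pvalues_haplo_glm(n_reps: int = 200, n: int = 500, seed: int = 0) -> np.ndarray:
    """Target-haplotype Wald p under a zero-effect case-control model."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_reps):
        G, y, _ = draw_case_control(rng, n=n, log_or=0.0, alpha=0.0)
        table, post = em.em_haplotype_frequencies(G)
        try:
            fit = em.haplotype_glm(post, y, reference_haplotype="00000",
                                   frequencies=table.frequencies)
        except em.SeparationError:
            continue
        out.append(fit.table.loc[CAL_TARGET, "p"])
    return np.asarray(out)
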