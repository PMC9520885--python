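"""Copying-model chromosome painting.

A target chromosome is modelled as an imperfect mosaic of donor chromosomes
(the Li-Stephens copying model): the hidden state at site ``j`` is the donor
being copied; between sites the chain stays on its donor with probability
``(1 - s_j) + s_j / D`` and moves to each other donor with probability
``s_j / D``, where ``s_j = 1 - exp(-rho * d_j)`` and ``d_j`` is the genetic
distance; emissions match the donor allele with probability ``1 - theta``.
Forward-backward posteriors are computed with per-site rescaling so panels of
10^5 sites do not underflow. Sites are then labelled by the tag haplotype of
the maximum-posterior donor class, and switch points are read off wherever
the argmax label changes between consecutive sites.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CopyingModelParams",
    "PaintingMatrix",
    "LabelPath",
    "default_params",
    "copying_forward_backward",
    "viterbi_copying",
    "label_sites_by_tag_haplotype",
    "detect_switch_points",
    "select_homozygotes",
    "painting_quality",
]


@dataclass
class CopyingModelParams:
    """Copying-model parameters: switch scale ``rho`` and mismatch rate ``theta``."""

    rho: float
    theta: float

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        if not (0.0 < self.theta <= 0.5):
            raise ValueError("theta must lie in (0, 0.5]")


def default_params(n_donors: int, distances, expected_switches: float | None = None
                   ) -> CopyingModelParams:
    """Defaults in the spirit of the painting literature: ``theta`` is half the
    Watterson rate ``1 / sum_{i<D} 1/i``, and ``rho`` is scaled so the expected
    number of switches across the painted region is about the donor count."""
    d = np.asarray(distances, dtype=float)
    total = float(d.sum())
    if expected_switches is None:
        expected_switches = float(n_donors)
    rho = expected_switches / total if total > 0 else 1.0
    harmonic = np.sum(1.0 / np.arange(1, max(n_donors, 2)))
    theta = min(0.5, 0.5 / harmonic) if harmonic > 0 else 0.1
    return CopyingModelParams(rho=rho, theta=max(theta, 1e-4))


@dataclass
class PaintingMatrix:
    """Site x donor copying posteriors for one target chromosome."""

    posteriors: np.ndarray  # (n_sites, n_donors)
    donor_ids: np.ndarray
    log_likelihood: float
    scales: np.ndarray  # per-site forward normalizers

    @property
    def n_sites(self) -> int:
        return self.posteriors.shape[0]

    @property
    def n_donors(self) -> int:
        return self.posteriors.shape[1]

    def max_posterior_per_site(self) -> np.ndarray:
        return self.posteriors.max(axis=1)

    def argmax_donor(self) -> np.ndarray:
        return self.posteriors.argmax(axis=1)


def _check_inputs(target: np.ndarray, donors: np.ndarray):
    target = np.asarray(target)
    donors = np.asarray(donors)
    if donors.ndim != 2 or donors.shape[0] < 1:
        raise ValueError("need at least one donor")
    if target.ndim != 1 or target.size != donors.shape[1]:
        raise ValueError("target and donors must share one site grid")
    return target, donors


def _switch_probs(distances, rho: float, n_sites: int) -> np.ndarray:
    d = np.asarray(distances, dtype=float)
    if d.size != n_sites - 1:
        raise ValueError("need one genetic distance per inter-site interval")
    if np.any(d < 0):
        raise ValueError("genetic distances must be >= 0")
    return 1.0 - np.exp(-rho * d)


def copying_forward_backward(target, donors, distances,
                             params: CopyingModelParams,
                             donor_ids=None) -> PaintingMatrix:
    """Scaled forward-backward posteriors of the copying chain."""
    target, donors = _check_inputs(target, donors)
    L, D = donors.shape[1], donors.shape[0]
    s = _switch_probs(distances, params.rho, L)
    emit = np.where(donors.T == target[None, :].T, 1.0 - params.theta, params.theta)

    alpha = np.empty((L, D))
    scales = np.empty(L)
    a = emit[0] / D
    scales[0] = a.sum()
    alpha[0] = a / scales[0]
    for j in range(1, L):
        a = emit[j] * ((1.0 - s[j - 1]) * alpha[j - 1] + s[j - 1] / D)
        scales[j] = a.sum()
        alpha[j] = a / scales[j]

    beta = np.empty((L, D))
    beta[-1] = 1.0
    for j in range(L - 2, -1, -1):
        tmp = emit[j + 1] * beta[j + 1]
        b = (1.0 - s[j]) * tmp + s[j] * tmp.mean()
        beta[j] = b / scales[j + 1]

    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    ids = np.arange(D) if donor_ids is None else np.asarray(donor_ids)
    return PaintingMatrix(posteriors=post, donor_ids=ids,
                          log_likelihood=float(np.log(scales).sum()), scales=scales)


def viterbi_copying(target, donors, distances, params: CopyingModelParams):
    """Maximum-probability donor path; ties broken toward the lower donor index.

    Returns ``(path, log_probability)``.
    """
    target, donors = _check_inputs(target, donors)
    L, D = donors.shape[1], donors.shape[0]
    s = _switch_probs(distances, params.rho, L)
    log_emit = np.where(donors.T == target[None, :].T,
                        np.log(1.0 - params.theta), np.log(params.theta))

    delta = log_emit[0] - np.log(D)
    back = np.zeros((L, D), dtype=np.int64)
    for j in range(1, L):
        stay = np.log((1.0 - s[j - 1]) + s[j - 1] / D)
        move = np.log(s[j - 1] / D) if s[j - 1] > 0 else -np.inf
        best_prev = int(np.argmax(delta))  # lowest index on ties
        cand_move = delta[best_prev] + move
        cand_stay = delta + stay
        take_stay = cand_stay >= cand_move  # prefer staying on ties
        new_delta = np.where(take_stay, cand_stay, cand_move)
        back[j] = np.where(take_stay, np.arange(D), best_prev)
        # a move to d from a different best_prev may beat staying on d only
        # when best_prev != d; when best_prev == d, stay and move coincide
        delta = new_delta + log_emit[j]
    path = np.empty(L, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for j in range(L - 1, 0, -1):
        path[j - 1] = back[j, path[j]]
    return path, float(delta.max())


@dataclass
class LabelPath:
    """Per-site argmax tag-haplotype label with label posteriors."""

    labels: np.ndarray  # per-site argmax label
    label_names: np.ndarray
    label_posteriors: np.ndarray  # (n_sites, n_labels)
    positions: np.ndarray | None = None

    def switch_sites(self) -> np.ndarray:
        return np.flatnonzero(self.labels[1:] != self.labels[:-1]) + 1


def label_sites_by_tag_haplotype(painting: PaintingMatrix, donor_tag_labels,
                                 positions=None) -> LabelPath:
    """Collapse donor posteriors onto tag-haplotype labels.

    The label posterior at a site is the sum of its donors' posteriors; the
    per-site label is the argmax, ties broken toward the lexicographically
    smaller label string.
    """
    donor_labels = np.asarray(donor_tag_labels, dtype=object)
    if donor_labels.size != painting.n_donors:
        raise ValueError("every donor needs a tag-haplotype label")
    if any(lab is None or lab == "" for lab in donor_labels):
        raise ValueError("unlabeled donor in panel")
    names = np.array(sorted(set(donor_labels.tolist())), dtype=object)
    group = np.searchsorted(names, donor_labels.astype(str))
    lp = np.zeros((painting.n_sites, names.size))
    for g in range(names.size):
        lp[:, g] = painting.posteriors[:, group == g].sum(axis=1)
    arg = lp.argmax(axis=1)  # argmax returns the first (lexicographically lowest) tie
    return LabelPath(labels=names[arg], label_names=names, label_posteriors=lp,
                     positions=None if positions is None else np.asarray(positions))


def detect_switch_points(label_path: LabelPath, positions=None) -> list[dict]:
    """One record per change of consecutive argmax labels, located at the
    inter-site interval where the change occurs."""
    labels = np.asarray(label_path.labels)
    if labels.size == 0:
        raise ValueError("empty label path")
    pos = positions if positions is not None else label_path.positions
    out = []
    for j in np.flatnonzero(labels[1:] != labels[:-1]):
        rec = {"site_before": int(j), "site_after": int(j + 1),
               "from_label": labels[j], "to_label": labels[j + 1]}
        if pos is not None:
            rec["interval_bp"] = (int(pos[j]), int(pos[j + 1]))
        out.append(rec)
    return out


def select_homozygotes(data, tag_sites, haplotype: str) -> np.ndarray:
    """Indices of individuals homozygous for ``haplotype`` at the tag sites.

    ``data`` is either a phased panel (both chromosomes must match the allele
    string) or an unphased genotype matrix (codes must equal twice the
    allele).
    """
    tag_sites = np.asarray(tag_sites, dtype=int)
    want = np.array([int(c) for c in haplotype], dtype=int)
    if want.size != tag_sites.size:
        raise ValueError("haplotype string length must match the tag sites")
    if hasattr(data, "alleles"):  # phased panel
        a = data.alleles[:, tag_sites].astype(int)
        match = (a == want[None, :]).all(axis=1)
        both = match[0::2] & match[1::2]
        return np.flatnonzero(both)
    g = np.asarray(data)[:, tag_sites]
    return np.flatnonzero((g == 2 * want[None, :]).all(axis=1))


def painting_quality(paintings: list[PaintingMatrix]) -> dict:
    """Per-chromosome median of the per-site maximum posterior, with the
    cohort-level range and median of those medians."""
    if not paintings:
        raise ValueError("need at least one painted chromosome")
    med = np.array([float(np.median(p.max_posterior_per_site())) for p in paintings])
    return {"per_chromosome_median": med,
            "min": float(med.min()), "max": float(med.max()),
            "median": float(np.median(med))}
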