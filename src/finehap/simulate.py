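"""Synthetic cohorts with the statistical structure the locus analysis assumes.

The generator emulates a two-population study of a ~300-kb locus: a
European-like population with long haplotypes (few mosaic switches) and an
African-like population with shorter haplotypes (more switches), five tag
SNPs whose allele strings define the common locus haplotypes, a high-risk
target haplotype carrying injected haplotype-specific variants, case/control
status under additive haplotype log-odds, one cis-regulated expression trait
within a multi-gene expression matrix, seven correlated quantitative traits,
an ordinal three-level severity outcome, and optional family-block kinship.

Chromosomes are built as founder mosaics: between consecutive sites a
chromosome switches to a uniformly chosen *other* founder with probability
``1 - exp(-rho * d_j)`` (``d_j`` the inter-site distance in Morgans) and each
emitted allele is flipped with probability ``mu``. Ground truth (donor paths,
injected positions, the shared target segment) is recorded for recovery tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .panel import HaplotypePanel

__all__ = [
    "PopulationSpec",
    "SpecificVariantSpec",
    "EffectSpec",
    "SimConfig",
    "TruthRecord",
    "Cohort",
    "simulate_founders",
    "simulate_mosaic_panel",
    "inject_specific_variants",
    "simulate_phenotypes",
    "simulate_expression_matrix",
    "simulate_kinship",
    "simulate_cohort",
    "default_trait_correlation",
]

# Tag-haplotype allele strings at the five tag SNPs. "hap1" is the
# non-risk reference background; "hap2" the European risk background;
# "hap4" the high-risk target background carrying the specific variants.
TAG_HAPLOTYPES = {
    "hap1": "00000",
    "hap2": "11111",
    "hap3": "01111",
    "hap4": "01101",
    "hap5": "01100",
    "hap6": "01001",
}

TRAIT_NAMES = ["fev1_pct", "fev1_fvc", "bdr", "feno", "log_ige", "eos", "neut"]


def tag_string(haplotype: str) -> str:
    """Translate a haplotype name ('hap4') to its tag allele string; allele
    strings pass through unchanged."""
    return TAG_HAPLOTYPES.get(haplotype, haplotype)


@dataclass
class PopulationSpec:
    name: str
    n_individuals: int
    switch_scale: float  # rho multiplying Morgan distances
    mutation_rate: float = 1e-4
    tag_hap_freqs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.switch_scale < 0:
            raise ValueError("switch_scale must be >= 0")
        if not (0.0 <= self.mutation_rate <= 0.5):
            raise ValueError("mutation_rate must lie in [0, 0.5]")


@dataclass
class SpecificVariantSpec:
    """Injection plan for the target-haplotype-specific variants.

    ``on_target_freq`` may be a scalar or a ``(low, high)`` range; per-variant
    carrier frequencies are drawn uniformly from the range, mirroring the
    observed 0.75-0.97 spread on the target background. Off-target carriage is
    restricted to the populations listed in ``off_target_populations`` (the
    European-like population stays at frequency zero).
    """

    k_variants: int = 9
    on_target_freq: float | tuple[float, float] = (0.75, 0.97)
    off_target_freq: float = 0.02
    off_target_populations: tuple[str, ...] = ("AA",)

    def draw_on_freqs(self, rng: np.random.Generator) -> np.ndarray:
        if np.isscalar(self.on_target_freq):
            f = np.full(self.k_variants, float(self.on_target_freq))
        else:
            lo, hi = self.on_target_freq
            f = rng.uniform(lo, hi, size=self.k_variants)
        if np.any((f < 0) | (f > 1)) or not (0.0 <= self.off_target_freq <= 1.0):
            raise ValueError("injection frequencies must lie in [0, 1]")
        if np.any(f < self.off_target_freq):
            raise ValueError("on-target frequency must be >= off-target frequency")
        return f


def default_trait_correlation() -> np.ndarray:
    """Correlation for the seven traits: a lung-function block, an
    inflammation/allergy block, and correlated blood counts."""
    R = np.eye(7)
    blocks = [((0, 1), 0.6), ((0, 2), 0.3), ((1, 2), 0.3),
              ((3, 4), 0.35), ((3, 5), 0.3), ((4, 5), 0.35),
              ((5, 6), 0.3), ((4, 6), 0.15)]
    for (i, j), r in blocks:
        R[i, j] = R[j, i] = r
    return R


@dataclass
class EffectSpec:
    """Forward-model effects, all on interpretable scales.

    Haplotype log-odds default to the study's headline estimates
    (log 1.35 for the European risk background, log 1.67 for the target);
    the expression effect and trait effects are in residual-SD units per
    allele; the ordinal effect is a proportional-odds log-odds per allele
    with thresholds placed so the baseline severity categories split
    roughly 19:18:26 (mild:moderate:severe).
    """

    hap_log_or: dict = field(
        default_factory=lambda: {"hap2": float(np.log(1.35)), "hap4": float(np.log(1.67))}
    )
    baseline_prevalence: float = 0.35
    eqtl_beta: float = 0.75
    trait_beta: np.ndarray = field(
        default_factory=lambda: np.array([-0.15, 0.0, 0.0, 0.0, -0.12, 0.0, -0.12])
    )
    trait_corr: np.ndarray = field(default_factory=default_trait_correlation)
    ordinal_beta: float = 1.58
    ordinal_thresholds: tuple[float, float] = (-0.8398, 0.3528)
    target_haplotype: str = "hap4"

    def validate(self) -> None:
        R = np.asarray(self.trait_corr, dtype=float)
        if R.shape != (len(self.trait_beta), len(self.trait_beta)):
            raise ValueError("trait_corr dimension must match trait_beta length")
        if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ValueError("trait_corr must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(R).min() <= 0:
            raise ValueError("trait_corr must be positive definite")


@dataclass
class SimConfig:
    """Full cohort configuration; defaults are the study conditions."""

    n_founders: int = 40  # per population
    n_sites: int = 400
    locus_start: int = 39_674_647
    locus_span: int = 297_749
    chrom: str = "chr17"
    tag_site_indices: np.ndarray | None = None  # default: 5 sites across the centre
    population_specs: list[PopulationSpec] = field(default_factory=lambda: [
        PopulationSpec("EA", 100, switch_scale=500.0,
                       tag_hap_freqs={"hap1": 0.56, "hap2": 0.36, "hap5": 0.05, "hap6": 0.03}),
        PopulationSpec("AA", 1060, switch_scale=2000.0,
                       tag_hap_freqs={"hap1": 0.31, "hap2": 0.28, "hap3": 0.175, "hap4": 0.145,
                                      "hap5": 0.03, "hap6": 0.02}),
    ])
    specific_variant_spec: SpecificVariantSpec = field(default_factory=SpecificVariantSpec)
    effect_spec: EffectSpec = field(default_factory=EffectSpec)
    family_blocks: list[int] | None = None
    monomorphic_fraction: float = 0.3
    # recombination landscape: a low-rate core (the haplotype block carrying
    # the tag SNPs) flanked by higher background rates, as at real
    # hotspot-bounded loci
    base_rate_cm_per_mb: float = 1.5
    core_rate_cm_per_mb: float = 0.01
    core_span: int = 60_000
    seed: int = 0

    def site_rates(self, positions: np.ndarray) -> np.ndarray:
        centre = positions[0] + (positions[-1] - positions[0]) / 2
        rates = np.full(positions.size, self.base_rate_cm_per_mb)
        core = np.abs(positions - centre) <= self.core_span / 2
        rates[core] = self.core_rate_cm_per_mb
        return rates

    def interval_distances(self, positions: np.ndarray) -> np.ndarray:
        """Inter-site distances in Morgans under the piecewise-constant map."""
        rates = self.site_rates(positions)
        mid_rates = 0.5 * (rates[:-1] + rates[1:])
        return np.diff(positions) * mid_rates * 1e-8

    def site_positions(self) -> np.ndarray:
        pos = np.linspace(self.locus_start, self.locus_start + self.locus_span,
                          self.n_sites).round().astype(np.int64)
        # enforce strict monotonicity on coarse grids
        return pos + np.arange(self.n_sites) * (np.diff(pos).min() == 0)

    def resolve_tag_sites(self) -> np.ndarray:
        if self.tag_site_indices is not None:
            tag = np.asarray(self.tag_site_indices, dtype=np.int64)
        else:
            mid = self.n_sites // 2
            step = max(1, int(round(self.n_sites * 0.025)))  # ~30 kb core span
            tag = mid + step * np.arange(-2, 3)
        if np.any(np.diff(tag) <= 0) or tag.min() < 0 or tag.max() >= self.n_sites:
            raise ValueError("tag_site_indices must be strictly increasing within the locus")
        if tag.size != 5:
            raise ValueError("exactly five tag sites are required")
        return tag


@dataclass
class TruthRecord:
    """Ground truth for parameter-recovery tests."""

    donor_paths: np.ndarray  # (n_chrom, n_sites) global founder index
    founder_tag_labels: np.ndarray  # label of each founder
    n_switches: np.ndarray
    injected_site_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    injected_positions: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    injected_on_freqs: np.ndarray = field(default_factory=lambda: np.array([]))
    carrier_label: str = ""
    critical_segment_sites: tuple[int, int] | None = None
    critical_segment_bp: tuple[int, int] | None = None
    effects: EffectSpec | None = None

    def to_json_dict(self) -> dict:
        d = {
            "carrier_label": self.carrier_label,
            "injected_site_indices": self.injected_site_indices.tolist(),
            "injected_positions": self.injected_positions.tolist(),
            "injected_on_freqs": np.asarray(self.injected_on_freqs).tolist(),
            "critical_segment_sites": self.critical_segment_sites,
            "critical_segment_bp": self.critical_segment_bp,
            "n_switches": self.n_switches.tolist(),
        }
        if self.effects is not None:
            eff = asdict(self.effects)
            eff["trait_beta"] = np.asarray(eff["trait_beta"]).tolist()
            eff["trait_corr"] = np.asarray(eff["trait_corr"]).tolist()
            d["effects"] = eff
        return d


@dataclass
class Cohort:
    """Everything one synthetic study produces."""

    config: SimConfig
    panel: HaplotypePanel
    truth: TruthRecord
    phenotypes: pd.DataFrame
    expression: pd.DataFrame  # genes x individuals
    gene_tss: pd.DataFrame
    kinship: np.ndarray
    recomb_distances: np.ndarray  # Morgans between consecutive sites


# ---------------------------------------------------------------------------
# elementary generators


def simulate_founders(n_founders: int, n_sites: int, allele_freq_sampler,
                      seed: int | np.random.Generator = 0) -> np.ndarray:
    """Binary founder haplotype pool, one row per founder.

    ``allele_freq_sampler`` is a scalar frequency, an array of per-site
    frequencies, or a callable ``f(rng, n_sites) -> frequencies``.
    """
    if n_founders < 2 or n_sites < 5:
        raise ValueError("need at least 2 founders and 5 sites")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if callable(allele_freq_sampler):
        freqs = np.asarray(allele_freq_sampler(rng, n_sites), dtype=float)
    else:
        freqs = np.broadcast_to(np.asarray(allele_freq_sampler, dtype=float), (n_sites,))
    if np.any((freqs < 0) | (freqs > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    return (rng.random((n_founders, n_sites)) < freqs).astype(np.uint8)


def simulate_mosaic_panel(founders: np.ndarray, distances: np.ndarray, n_chrom: int,
                          switch_scale: float, mutation_rate: float,
                          seed: int | np.random.Generator = 0,
                          founder_indices: np.ndarray | None = None):
    """Mosaic chromosomes copied from a founder pool.

    Returns ``(alleles, donor_paths, n_switches)``. ``founder_indices``
    restricts copying to a subset of founder rows (used for per-population
    pools sharing one global founder matrix).
    """
    if switch_scale < 0:
        raise ValueError("switch_scale must be >= 0")
    if not (0.0 <= mutation_rate <= 0.5):
        raise ValueError("mutation_rate must lie in [0, 0.5]")
    distances = np.asarray(distances, dtype=float)
    if np.any(distances < 0):
        raise ValueError("recombination distances must be >= 0")
    n_sites = founders.shape[1]
    if distances.size != n_sites - 1:
        raise ValueError("need one distance per inter-site interval")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pool = np.arange(founders.shape[0]) if founder_indices is None else np.asarray(founder_indices)
    D = pool.size

    switch_p = 1.0 - np.exp(-switch_scale * distances)
    paths = np.empty((n_chrom, n_sites), dtype=np.int32)
    paths[:, 0] = pool[rng.integers(0, D, size=n_chrom)]
    events = rng.random((n_chrom, n_sites - 1)) < switch_p
    for j in range(1, n_sites):
        paths[:, j] = paths[:, j - 1]
        hit = events[:, j - 1]
        if D > 1 and hit.any():
            # uniform over the D-1 *other* founders
            offs = rng.integers(1, D, size=int(hit.sum()))
            cur = np.searchsorted(pool, paths[hit, j - 1])
            paths[hit, j] = pool[(cur + offs) % D]
    alleles = founders[paths, np.arange(n_sites)].astype(np.uint8)
    if mutation_rate > 0:
        flips = rng.random(alleles.shape) < mutation_rate
        alleles[flips] ^= 1
    return alleles, paths, events.sum(axis=1)


def inject_specific_variants(panel: HaplotypePanel, target_tag_haplotype: str,
                             k_variants: int, on_freq, off_freq: float,
                             region_site_indices: np.ndarray,
                             seed: int | np.random.Generator = 0,
                             off_target_chrom_mask: np.ndarray | None = None):
    """Plant alternate alleles at monomorphic sites inside ``region_site_indices``.

    Chromosomes whose tag label equals ``target_tag_haplotype`` carry each
    injected allele with probability ``on_freq`` (scalar or per-variant
    array); all other chromosomes (optionally restricted by
    ``off_target_chrom_mask``) carry it with probability ``off_freq``.
    Returns ``(new_panel, injected_site_indices, on_freqs)``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    region = np.asarray(region_site_indices, dtype=int)
    mono = region[panel.alleles[:, region].sum(axis=0) == 0]
    if mono.size < k_variants:
        raise ValueError(
            f"region holds {mono.size} monomorphic candidate sites; {k_variants} required")
    sites = np.sort(rng.choice(mono, size=k_variants, replace=False))
    on = np.broadcast_to(np.asarray(on_freq, dtype=float), (k_variants,))
    if np.any((on < 0) | (on > 1)) or not (0.0 <= off_freq <= 1.0):
        raise ValueError("injection frequencies must lie in [0, 1]")

    labels = panel.tag_labels()
    is_target = labels == target_tag_haplotype
    off_mask = ~is_target
    if off_target_chrom_mask is not None:
        off_mask &= np.asarray(off_target_chrom_mask, dtype=bool)
    alleles = panel.alleles.copy()
    for j, s in enumerate(sites):
        carrier = np.zeros(panel.n_chromosomes, dtype=bool)
        carrier[is_target] = rng.random(int(is_target.sum())) < on[j]
        carrier[off_mask] = rng.random(int(off_mask.sum())) < off_freq
        alleles[carrier, s] = 1
    new_panel = HaplotypePanel(alleles, panel.positions, list(panel.sample_ids),
                               chrom=panel.chrom, tag_site_indices=panel.tag_site_indices,
                               population=panel.population, ref=panel.ref, alt=panel.alt)
    return new_panel, sites, np.asarray(on)


# ---------------------------------------------------------------------------
# phenotypes


def _covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    cov = pd.DataFrame({
        "sex": rng.integers(0, 2, size=n),
        "site": rng.integers(0, 3, size=n),
        "pc1": rng.normal(size=n),
        "pc2": rng.normal(size=n),
        "pc3": rng.normal(size=n),
    })
    return cov


def covariate_design(cov: pd.DataFrame) -> np.ndarray:
    """Numeric design columns (no intercept) for the simulated covariates."""
    site = pd.get_dummies(cov["site"], prefix="site", drop_first=True).to_numpy(float)
    return np.column_stack([cov[["sex", "pc1", "pc2", "pc3"]].to_numpy(float), site])


def simulate_phenotypes(panel: HaplotypePanel, effect_spec: EffectSpec,
                        seed: int | np.random.Generator = 0,
                        polygenic: np.ndarray | None = None) -> pd.DataFrame:
    """Per-individual outcomes under the forward model.

    Case/control status follows a logistic model additive in tag-haplotype
    dosage; the single expression trait is linear in target-haplotype dosage;
    the seven quantitative traits are ``dosage * b`` plus correlated Gaussian
    noise (plus an optional shared polygenic component); severity comes from
    a latent proportional-odds model.
    """
    effect_spec.validate()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    labels = panel.tag_labels()
    n = panel.n_samples
    target = tag_string(effect_spec.target_haplotype)
    dosage = {h: (labels.reshape(-1, 2) == h).sum(axis=1) for h in set(labels)}
    d_target = dosage.get(target, np.zeros(n))

    cov = _covariates(n, rng)
    X = covariate_design(cov)
    cov_beta = np.array([0.2, 0.1, 0.1, 0.1, 0.1, -0.1])[: X.shape[1]]

    alpha = np.log(effect_spec.baseline_prevalence / (1 - effect_spec.baseline_prevalence))
    eta = alpha + X @ cov_beta
    for h, b in effect_spec.hap_log_or.items():
        hs = tag_string(h)
        if hs in dosage:
            eta = eta + b * dosage[hs]
    status = (rng.random(n) < expit(eta)).astype(int)

    expression = effect_spec.eqtl_beta * d_target + rng.normal(size=n)

    m = len(effect_spec.trait_beta)
    L = np.linalg.cholesky(np.asarray(effect_spec.trait_corr, dtype=float))
    noise = rng.normal(size=(n, m)) @ L.T
    traits = d_target[:, None] * np.asarray(effect_spec.trait_beta)[None, :] + noise
    if polygenic is not None:
        traits = traits + np.asarray(polygenic)[:, None]

    c1, c2 = effect_spec.ordinal_thresholds
    u = rng.random(n)
    p1 = expit(c1 - effect_spec.ordinal_beta * d_target)
    p2 = expit(c2 - effect_spec.ordinal_beta * d_target)
    severity = np.where(u < p1, 0, np.where(u < p2, 1, 2))

    out = pd.DataFrame({"sample_id": panel.sample_ids, "status": status,
                        "expression": expression,
                        "target_dosage": d_target, "severity": severity})
    for j, name in enumerate(TRAIT_NAMES[:m]):
        out[name] = traits[:, j]
    return pd.concat([out, cov], axis=1)


def simulate_expression_matrix(panel: HaplotypePanel, effect_spec: EffectSpec,
                               n_genes: int = 27, seed: int | np.random.Generator = 0,
                               batch_effect: float = 0.6):
    """Gene x individual expression with one cis-regulated gene.

    A hidden binary batch shifts half the genes by ``batch_effect`` (what the
    latent-factor stage is meant to absorb). Returns
    ``(expression_df, tss_df, target_gene, batch)``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    labels = panel.tag_labels()
    target = tag_string(effect_spec.target_haplotype)
    d_target = (labels.reshape(-1, 2) == target).sum(axis=1).astype(float)
    n = panel.n_samples
    genes = [f"G{i + 1:02d}" for i in range(n_genes)]
    target_gene = genes[n_genes // 2]
    batch = rng.integers(0, 2, size=n)
    expr = rng.normal(size=(n_genes, n))
    shifted = rng.random(n_genes) < 0.5
    expr[shifted] += batch_effect * batch[None, :]
    expr[n_genes // 2] += effect_spec.eqtl_beta * d_target

    centre = int(panel.positions[panel.n_sites // 2])
    tss = centre + np.linspace(-450_000, 450_000, n_genes).round().astype(np.int64)
    expr_df = pd.DataFrame(expr, index=genes, columns=panel.sample_ids)
    tss_df = pd.DataFrame({"gene": genes, "chrom": panel.chrom, "tss": tss})
    return expr_df, tss_df, target_gene, batch


def simulate_kinship(family_blocks: list[int], seed: int | np.random.Generator = 0,
                     sib_coeff: float = 0.5):
    """Block-diagonal kinship (full sibs within a block) and a matched
    polygenic draw helper. Returns ``(K, draw)`` where ``draw(sigma2, rng)``
    samples a polygenic component with covariance ``sigma2 * K``."""
    blocks = list(family_blocks)
    if any(b < 1 for b in blocks):
        raise ValueError("block sizes must be >= 1")
    n = sum(blocks)
    K = np.zeros((n, n))
    i = 0
    for b in blocks:
        K[i:i + b, i:i + b] = sib_coeff
        i += b
    np.fill_diagonal(K, 1.0)
    Lc = np.linalg.cholesky(K + 1e-10 * np.eye(n))

    def draw(sigma2: float, rng: np.random.Generator) -> np.ndarray:
        return np.sqrt(sigma2) * (Lc @ rng.normal(size=n))

    return K, draw


def planted_truth_panel(seed: int = 0, n_hom_per_group: int = 12,
                        n_region_sites: int = 120, k_variants: int = 9,
                        on_freq=(0.75, 0.97), off_freq: float = 0.0,
                        background_freq: float = 0.3):
    """Homozygote groups over one region with a shared background, plus
    injected target-specific variants — the controlled setting for
    discovery recall/precision.

    Every chromosome shares one region background (drawn once at
    ``background_freq``), so after injection the *only* sites specific to the
    target group are the injected ones. Six homozygote groups (two per the
    European-like population, four per the African-like) each contribute
    ``n_hom_per_group`` individuals. Returns
    ``(panel, group_of_individual, injected_site_indices, on_freqs)``.
    """
    rng = np.random.default_rng(seed)
    group_haps = [("EA", "hap1"), ("EA", "hap2"),
                  ("AA", "hap1"), ("AA", "hap2"), ("AA", "hap3"), ("AA", "hap4")]
    tag_sites = np.linspace(10, n_region_sites - 10, 5).astype(int)
    background = (rng.random(n_region_sites) < background_freq).astype(np.uint8)
    background[tag_sites] = 0

    rows, groups, populations = [], [], []
    for pop, hap in group_haps:
        h = background.copy()
        h[tag_sites] = [int(c) for c in TAG_HAPLOTYPES[hap]]
        for _ in range(n_hom_per_group):
            rows += [h.copy(), h.copy()]
            groups.append(f"{pop}_{hap}")
            populations += [pop, pop]
    alleles = np.vstack(rows)
    n_ind = len(groups)
    positions = 1_000_000 + 500 * np.arange(n_region_sites)
    panel = HaplotypePanel(alleles, positions,
                           [f"{g}_{i}" for i, g in enumerate(groups)],
                           tag_site_indices=tag_sites,
                           population=np.array(populations, dtype=object))

    if np.isscalar(on_freq):
        on = np.full(k_variants, float(on_freq))
    else:
        on = rng.uniform(on_freq[0], on_freq[1], size=k_variants)
    candidates = np.setdiff1d(np.flatnonzero(alleles.sum(axis=0) == 0), tag_sites)
    panel, inj_sites, on = inject_specific_variants(
        panel, TAG_HAPLOTYPES["hap4"], k_variants, on,
        off_freq, candidates, rng)
    return panel, np.array(groups, dtype=object), inj_sites, on


# ---------------------------------------------------------------------------
# whole-cohort assembly


def _founder_freq_sampler(monomorphic_fraction: float):
    def sampler(rng, n_sites):
        f = rng.uniform(0.1, 0.5, size=n_sites)
        f[rng.random(n_sites) < monomorphic_fraction] = 0.0
        return f
    return sampler


def _true_shared_segment(paths: np.ndarray, founder_labels: np.ndarray,
                         target_chrom: np.ndarray, tag_sites: np.ndarray,
                         target_label: str):
    """Maximal run of sites, containing the tag cluster, at which every
    target chromosome's donor carries the target label."""
    lab = founder_labels[paths[target_chrom]]
    shared = (lab == target_label).all(axis=0)
    mid = int(tag_sites[2])
    if not shared[mid]:
        return None
    lo = mid
    while lo > 0 and shared[lo - 1]:
        lo -= 1
    hi = mid
    while hi < shared.size - 1 and shared[hi + 1]:
        hi += 1
    return lo, hi


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate one full synthetic study deterministically from its config."""
    rng = np.random.default_rng(config.seed)
    positions = config.site_positions()
    tag_sites = config.resolve_tag_sites()
    n_sites = config.n_sites
    distances = config.interval_distances(positions)

    # one founder pool per population; founders carry assigned tag haplotypes
    # one ancestral per-site frequency vector shared by both populations,
    # with a monomorphic fraction reserved for variant injection (denser
    # inside the core, where the injected variants must land)
    site_freqs = _founder_freq_sampler(config.monomorphic_fraction)(rng, n_sites)
    centre = positions[0] + (positions[-1] - positions[0]) / 2
    core = np.abs(positions - centre) <= config.core_span / 2
    site_freqs[core & (rng.random(n_sites) < 0.3)] = 0.0
    # the tag-cluster interior is ancestrally invariant: the injected variants
    # are the novel variation on the target background, as in the study locus
    cluster = np.arange(tag_sites[0], tag_sites[-1] + 1)
    site_freqs[np.setdiff1d(cluster, tag_sites)] = 0.0
    pools, founder_labels = [], []
    for spec in config.population_specs:
        pool = simulate_founders(config.n_founders, n_sites, site_freqs, rng)
        # deterministic founder counts per tag haplotype (largest remainder),
        # so the population haplotype frequencies are the stated conditions
        names = list(spec.tag_hap_freqs)
        probs = np.array([spec.tag_hap_freqs[h] for h in names], dtype=float)
        probs = probs / probs.sum()
        counts = np.floor(probs * config.n_founders).astype(int)
        rem = probs * config.n_founders - counts
        for j in np.argsort(-rem)[: config.n_founders - counts.sum()]:
            counts[j] += 1
        assigned = np.repeat(names, counts)
        rng.shuffle(assigned)
        for i, h in enumerate(assigned):
            pool[i, tag_sites] = [int(c) for c in TAG_HAPLOTYPES[h]]
        pools.append(pool)
        founder_labels.append(assigned)
    founders = np.vstack(pools)
    founder_labels = np.concatenate(founder_labels)

    all_alleles, all_paths, all_switches, populations, sample_ids = [], [], [], [], []
    for p_idx, spec in enumerate(config.population_specs):
        idx = np.arange(config.n_founders) + p_idx * config.n_founders
        alleles, paths, nsw = simulate_mosaic_panel(
            founders, distances, 2 * spec.n_individuals, spec.switch_scale,
            spec.mutation_rate, rng, founder_indices=idx)
        all_alleles.append(alleles)
        all_paths.append(paths)
        all_switches.append(nsw)
        populations += [spec.name] * (2 * spec.n_individuals)
        sample_ids += [f"{spec.name}{i + 1:04d}" for i in range(spec.n_individuals)]

    panel = HaplotypePanel(np.vstack(all_alleles), positions, sample_ids,
                           chrom=config.chrom, tag_site_indices=tag_sites,
                           population=np.array(populations, dtype=object))
    paths = np.vstack(all_paths)
    truth = TruthRecord(donor_paths=paths, founder_tag_labels=founder_labels,
                        n_switches=np.concatenate(all_switches),
                        effects=config.effect_spec)

    # inject specific variants into the true shared target segment
    sv = config.specific_variant_spec
    target_name = config.effect_spec.target_haplotype
    target_str = tag_string(target_name)
    labels = panel.tag_labels()
    target_chroms = np.flatnonzero(labels == target_str)
    seg = None
    if target_chroms.size:
        hom = (labels[0::2] == target_str) & (labels[1::2] == target_str)
        hom_chroms = np.flatnonzero(np.repeat(hom, 2))
        use = hom_chroms if hom_chroms.size >= 4 else target_chroms
        seg = _true_shared_segment(paths, founder_labels, use, tag_sites, target_name)
    if seg is None:
        seg = (int(tag_sites[0]), int(tag_sites[-1]))
    region_sites = np.arange(seg[0], seg[1] + 1)

    off_pops = set(sv.off_target_populations)
    off_mask = np.isin(panel.population, list(off_pops))
    on_freqs = sv.draw_on_freqs(rng)
    panel, inj_sites, on_freqs = inject_specific_variants(
        panel, target_str, sv.k_variants, on_freqs, sv.off_target_freq,
        region_sites, rng, off_target_chrom_mask=off_mask)

    truth.injected_site_indices = inj_sites
    truth.injected_positions = positions[inj_sites]
    truth.injected_on_freqs = on_freqs
    truth.carrier_label = target_str
    truth.critical_segment_sites = (int(seg[0]), int(seg[1]))
    truth.critical_segment_bp = (int(positions[seg[0]]), int(positions[seg[1]]))

    # kinship (identity unless family blocks requested)
    n_total = panel.n_samples
    polygenic = None
    if config.family_blocks:
        blocks = list(config.family_blocks)
        if sum(blocks) != n_total:
            raise ValueError("family blocks must partition the cohort")
        K, draw = simulate_kinship(blocks, rng)
        polygenic = draw(0.5, rng)
    else:
        K = np.eye(n_total)

    phenotypes = simulate_phenotypes(panel, config.effect_spec, rng, polygenic=polygenic)
    phenotypes.insert(1, "population",
                      [panel.population[2 * i] for i in range(n_total)])
    expr_df, tss_df, target_gene, batch = simulate_expression_matrix(
        panel, config.effect_spec, seed=rng)
    tss_df.attrs["target_gene"] = target_gene
    phenotypes["expr_batch"] = batch

    return Cohort(config=config, panel=panel, truth=truth, phenotypes=phenotypes,
                  expression=expr_df, gene_tss=tss_df, kinship=K,
                  recomb_distances=distances)
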