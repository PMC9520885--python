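"""End-to-end pipeline: simulate -> haplotype EM/GLM -> painting ->
critical region -> consensus & specific variants -> eQTL -> phenotype stages.

Every stage draws its randomness from a seed derived deterministically from
the global seed and the stage name, so a rerun with the same configuration
is reproducible end to end. Outputs are plain text (VCF/TSV/BED/JSON) plus a
run manifest carrying the configuration hash and seed.
"""
from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, em, io as fio, paint, region as creg
from .panel import HaplotypePanel
from .simulate import (SimConfig, Cohort, simulate_cohort, tag_string,
                       covariate_design, TRAIT_NAMES, TAG_HAPLOTYPES)

__all__ = ["RunConfig", "stage_seed", "run_pipeline", "paint_homozygotes",
           "variant_dosages"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Pipeline configuration; stage parameters default to the study rules."""

    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    min_haplotype_freq: float = 0.05
    n_latent_factors: int = 2  # matched to the 27-gene synthetic matrix
    eqtl_window: int = 500_000
    eqtl_maf_min: float = 0.05
    fdr_threshold: float = 0.10
    extend_frac: float = 0.05
    min_boundary_events: int = 2
    global_null_alpha: float = 0.05
    global_null_draws: int = 1_000_000
    severity_subsample: int = 63

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        cfg = cls(**raw)
        for k, v in sim_raw.items():
            setattr(cfg.sim, k, v)
        return cfg

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)
        blob = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def paint_homozygotes(panel: HaplotypePanel, distances, chrom_indices,
                      donor_indices, params: paint.CopyingModelParams | None = None):
    """Paint each listed chromosome against the donor set (leave-one-out)
    and collapse donors to tag-haplotype labels.

    Returns ``(paintings, label_paths)`` where ``label_paths`` is an
    ``(n_targets, n_sites)`` array of per-site argmax labels.
    """
    donor_indices = np.asarray(donor_indices)
    labels_all = panel.tag_labels()
    if params is None:
        params = paint.default_params(donor_indices.size - 1, distances)
    paintings, rows = [], []
    for t in chrom_indices:
        donors = donor_indices[donor_indices != t]
        pm = paint.copying_forward_backward(panel.alleles[t], panel.alleles[donors],
                                            distances, params, donor_ids=donors)
        lp = paint.label_sites_by_tag_haplotype(pm, labels_all[donors],
                                                positions=panel.positions)
        paintings.append(pm)
        rows.append(lp.labels)
    return paintings, np.vstack(rows)


def variant_dosages(panel: HaplotypePanel, site_indices) -> pd.DataFrame:
    """Per-individual alternate-allele dosage at selected sites."""
    g = panel.genotypes(np.asarray(site_indices, dtype=int))
    cols = [f"v{panel.positions[s]}" for s in np.asarray(site_indices, dtype=int)]
    return pd.DataFrame(g.astype(float), index=panel.sample_ids, columns=cols)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage and write artifacts under ``outdir``.

    Returns a summary dictionary (also written as ``summary.json``).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": config.config_hash(), "seed": config.seed}

    def fail(stage, exc):
        raise RuntimeError(f"pipeline stage {stage!r} failed") from exc

    # --- simulate -----------------------------------------------------------
    config.sim.seed = stage_seed(config.seed, "simulate")
    cohort = simulate_cohort(config.sim)
    panel = cohort.panel
    fio.write_phased_panel(panel, out / "panel.vcf")
    cohort.phenotypes.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    pos = panel.positions
    cm = np.concatenate([[0.0], np.cumsum(cohort.recomb_distances) * 100.0])
    fio.write_recomb_map(out / "recomb_map.txt", pos,
                         config.sim.site_rates(pos), cm)
    fio.dump_json(cohort.truth.to_json_dict(), out / "truth.json")

    # --- haplotype EM + posterior-weighted GLM (per population) -------------
    tag = panel.tag_site_indices
    glm_rows = []
    posterior_quality = {}
    for popname in pd.unique(panel.population):
        ind_mask = np.asarray([panel.population[2 * i] == popname
                               for i in range(panel.n_samples)])
        G = panel.genotypes(tag)[ind_mask]
        table, post = em.em_haplotype_frequencies(G)
        posterior_quality[popname] = em.posterior_quality_summary(post)
        y = cohort.phenotypes.loc[ind_mask, "status"].to_numpy()
        covs = covariate_design(cohort.phenotypes.loc[ind_mask])
        ref_hap = TAG_HAPLOTYPES["hap1"]
        try:
            fit = em.haplotype_glm(post, y, covs, reference_haplotype=ref_hap,
                                   min_freq=config.min_haplotype_freq,
                                   frequencies=table.frequencies)
            t = fit.table.reset_index()
            t.insert(0, "population", popname)
            glm_rows.append(t)
        except (em.SeparationError, ValueError) as exc:
            summary.setdefault("glm_failures", {})[popname] = str(exc)
    if glm_rows:
        glm_table = pd.concat(glm_rows, ignore_index=True)
        glm_table.to_csv(out / "haplotype_glm.tsv", sep="\t", index=False)
        summary["haplotype_glm"] = glm_table.to_dict("records")
    summary["phase_posterior_quality"] = posterior_quality

    # --- painting of target homozygotes -------------------------------------
    target_str = tag_string(config.sim.effect_spec.target_haplotype)
    labels = panel.tag_labels()
    pop_of_chrom = panel.population
    target_pop = "AA"
    hom_ind = paint.select_homozygotes(panel, tag, target_str)
    hom_ind = hom_ind[[panel.population[2 * i] == target_pop for i in hom_ind]]
    if hom_ind.size < 2:
        fail("painting", RuntimeError("fewer than two target homozygotes"))
    hom_chroms = np.sort(np.concatenate([2 * hom_ind, 2 * hom_ind + 1]))
    donor_pool = np.flatnonzero(pop_of_chrom == target_pop)
    paintings, label_paths = paint_homozygotes(panel, cohort.recomb_distances,
                                               hom_chroms, donor_pool)
    quality = paint.painting_quality(paintings)
    summary["painting_quality"] = {k: v for k, v in quality.items()
                                   if k != "per_chromosome_median"}
    summary["n_target_homozygotes"] = int(hom_ind.size)
    summary["n_target_homozygote_chromosomes"] = int(hom_chroms.size)

    # --- critical region -----------------------------------------------------
    interval = creg.find_shared_segment(label_paths, target_str, pos,
                                        chrom=panel.chrom,
                                        min_boundary_events=config.min_boundary_events)
    if interval is None:
        fail("critical_region", RuntimeError("no site shared by all target chromosomes"))
    extended = creg.extend_interval(interval, frac=config.extend_frac)
    fio.write_interval_bed(out / "critical_region.bed", [interval, extended])
    summary["critical_region"] = {
        "shared_start": interval.start, "shared_end": interval.end,
        "shared_kb": interval.width_kb,
        "boundary_evidence": list(interval.boundary_evidence),
        "below_threshold": interval.below_threshold,
        "extended_start": extended.start, "extended_end": extended.end,
        "extended_kb": extended.width_kb,
    }

    # --- consensus + specific variants ---------------------------------------
    region_sites = np.flatnonzero((pos >= extended.start) & (pos <= extended.end))
    groups = {"EA_hap1": ("EA", "hap1"), "EA_hap2": ("EA", "hap2"),
              "AA_hap1": ("AA", "hap1"), "AA_hap2": ("AA", "hap2"),
              "AA_hap3": ("AA", "hap3"), "AA_hap4": ("AA", "hap4")}
    consensuses = {}
    for gname, (popname, hap) in groups.items():
        ind = paint.select_homozygotes(panel, tag, TAG_HAPLOTYPES[hap])
        ind = ind[[panel.population[2 * i] == popname for i in ind]]
        if ind.size < 1:
            continue
        chroms = np.concatenate([2 * ind, 2 * ind + 1])
        if chroms.size < 2:
            continue
        consensuses[gname] = creg.build_consensus(
            panel.alleles[np.ix_(chroms, region_sites)], group=gname)
    if "AA_hap4" not in consensuses:
        fail("consensus", RuntimeError("no target-haplotype homozygote group"))
    others = [c for g, c in consensuses.items() if g != "AA_hap4"]
    calls, ambiguous = creg.call_specific_variants(
        consensuses["AA_hap4"], others, positions=pos[region_sites])
    call_sites = np.array([region_sites[c.site_index] for c in calls], dtype=int)
    summary["n_variants_in_region"] = int(region_sites.size)
    summary["n_specific_variants"] = len(calls)
    summary["n_ambiguous_sites"] = int(ambiguous.size)

    # truth comparison
    truth_sites = set(cohort.truth.injected_site_indices.tolist())
    found = set(call_sites.tolist())
    tp = len(truth_sites & found)
    summary["specific_variant_recall"] = tp / max(len(truth_sites), 1)
    summary["specific_variant_precision"] = tp / max(len(found), 1)

    # frequency table over the full sample by population x tag haplotype
    group_assign = np.array([f"{p}_{l}" for p, l in zip(pop_of_chrom, labels)],
                            dtype=object)
    wanted = {f"{p}_{TAG_HAPLOTYPES[h]}": f"{p}_{h}" for p, h in groups.values()}
    group_assign = np.array([wanted.get(g, "") for g in group_assign], dtype=object)
    if call_sites.size:
        freq = creg.frequency_table(panel.alleles, group_assign, call_sites,
                                    positions=pos)
        freq.to_csv(out / "specific_variant_frequencies.tsv", sep="\t")
        r2 = creg.pairwise_r2(panel.alleles, call_sites)
        pd.DataFrame(r2).to_csv(out / "specific_variant_r2.tsv", sep="\t",
                                index=False)

    # --- eQTL scan ------------------------------------------------------------
    eqtl_sites = call_sites if call_sites.size else cohort.truth.injected_site_indices
    dos = variant_dosages(panel, eqtl_sites)
    vpos = pd.Series({c: int(c[1:]) for c in dos.columns})
    covs = covariate_design(cohort.phenotypes)
    factors = assoc.estimate_latent_factors(cohort.expression, covs,
                                            n_factors=config.n_latent_factors)
    X = np.column_stack([covs, factors])
    records, excluded = assoc.cis_eqtl_scan(dos, vpos, cohort.expression,
                                            cohort.gene_tss, covariates=X,
                                            window=config.eqtl_window,
                                            maf_min=config.eqtl_maf_min)
    records.to_csv(out / "eqtl.tsv", sep="\t", index=False)
    target_gene = cohort.gene_tss.attrs.get("target_gene")
    sig = records[records["q"] <= config.fdr_threshold]
    summary["eqtl"] = {"n_tests": int(len(records)),
                       "n_excluded_maf": len(excluded),
                       "n_significant": int(len(sig)),
                       "significant_genes": sorted(sig["unit"].unique().tolist()),
                       "target_gene": target_gene}

    # --- quantitative traits: LMM per trait + global null --------------------
    lead = dos.columns[len(dos.columns) // 2] if len(dos.columns) else None
    if lead is not None:
        x = dos[lead].to_numpy()
        traits = cohort.phenotypes[TRAIT_NAMES]
        fits = {t: assoc.lmm_test(traits[t].to_numpy(), x, covs, cohort.kinship)
                for t in TRAIT_NAMES}
        trait_tab = pd.DataFrame(
            {"trait": TRAIT_NAMES,
             "beta": [fits[t].dosage_beta for t in TRAIT_NAMES],
             "se": [fits[t].dosage_se for t in TRAIT_NAMES],
             "p": [fits[t].dosage_p for t in TRAIT_NAMES]})
        trait_tab.to_csv(out / "trait_lmm.tsv", sep="\t", index=False)
        resid = assoc._residualize(traits.to_numpy(float),
                                   np.column_stack([np.ones(len(traits)), covs]))
        R = np.corrcoef(resid, rowvar=False)
        gn = assoc.global_null_test(trait_tab["p"].to_numpy(), R,
                                    alpha=config.global_null_alpha,
                                    n_draws=config.global_null_draws,
                                    seed=stage_seed(config.seed, "global_null"))
        fio.dump_json({"m": gn.m, "alpha": gn.alpha, "k": gn.k, "p": gn.p,
                       "mc_se": gn.mc_se, "n_draws": gn.n_draws,
                       "seed": gn.seed}, out / "global_null.json")
        summary["global_null"] = {"k": gn.k, "p": gn.p, "mc_se": gn.mc_se}
        summary["trait_lmm"] = trait_tab.to_dict("records")

    # --- severity (ordinal) + stratified additive test ------------------------
    rng = np.random.default_rng(stage_seed(config.seed, "severity"))
    ph = cohort.phenotypes
    adults = np.flatnonzero((ph["population"] == "AA") & (ph["status"] == 1))
    if adults.size >= config.severity_subsample:
        adults = rng.choice(adults, size=config.severity_subsample, replace=False)
    if adults.size >= 10:
        sub = ph.iloc[adults]
        try:
            osev = assoc.ordinal_logistic(sub["severity"].to_numpy(),
                                          sub["target_dosage"].to_numpy(),
                                          covariate_design(sub))
            osev.pop("thresholds")
            summary["severity_ordinal"] = osev
        except RuntimeError as exc:
            summary["severity_ordinal"] = {"error": str(exc)}

    if lead is not None:
        g_strat = panel.genotypes(tag[[1]])[:, 0]  # second tag SNP genotype
        try:
            strat = assoc.stratified_additive_test(ph["status"].to_numpy(),
                                                   dos[lead].to_numpy(),
                                                   g_strat, covs)
            strat.to_csv(out / "stratified_additive.tsv", sep="\t", index=False)
            summary["stratified"] = strat.to_dict("records")
        except ValueError as exc:
            summary["stratified"] = {"error": str(exc)}

    manifest = {"config_hash": config.config_hash(), "seed": config.seed,
                "stages": ["simulate", "haplo_em", "painting", "critical_region",
                           "consensus", "eqtl", "traits", "severity"],
                "package": "finehap-0.1.0"}
    fio.dump_json(manifest, out / "manifest.json")
    fio.dump_json(summary, out / "summary.json")
    return summary
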