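"""Simulate the synthetic two-population cohort and write its artifacts.

Generates the study-structured cohort (100 European-like and 1060
African-like individuals over a ~300-kb locus with a low-recombination core,
five tag SNPs, a high-risk target haplotype carrying nine injected specific
variants, phenotypes, and a 27-gene expression matrix) and serializes
everything under results/cohort/.
"""
import json
import sys
from pathlib import Path

import numpy as np

from finehap import io as fio
from finehap.simulate import SimConfig, simulate_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=seed)
    cohort = simulate_cohort(cfg)
    panel = cohort.panel

    fio.write_phased_panel(panel, OUT / "panel.vcf")
    cohort.phenotypes.to_csv(OUT / "phenotypes.tsv", sep="\t", index=False)
    cohort.expression.to_csv(OUT / "expression.tsv", sep="\t")
    cohort.gene_tss.to_csv(OUT / "gene_tss.tsv", sep="\t", index=False)
    cm = np.concatenate([[0.0], np.cumsum(cohort.recomb_distances) * 100.0])
    fio.write_recomb_map(OUT / "recomb_map.txt", panel.positions,
                         cfg.site_rates(panel.positions), cm)
    fio.dump_json(cohort.truth.to_json_dict(), OUT / "truth.json")
    meta = {
        "seed": seed,
        "chrom": panel.chrom,
        "tag_site_indices": panel.tag_site_indices.tolist(),
        "target_tag_haplotype": "01101",
        "target_gene": cohort.gene_tss.attrs.get("target_gene"),
        "n_individuals": panel.n_samples,
        "n_sites": panel.n_sites,
    }
    fio.dump_json(meta, OUT / "cohort_meta.json")

    labels = panel.tag_labels()
    hom = (labels[0::2] == "01101") & (labels[1::2] == "01101")
    pop = np.array([panel.population[2 * i] for i in range(panel.n_samples)])
    print(f"cohort: {panel.n_samples} individuals, {panel.n_sites} sites")
    print(f"target-haplotype homozygotes (AA): {int((hom & (pop == 'AA')).sum())}")
    seg = cohort.truth.critical_segment_bp
    print(f"true shared target segment: {seg[0]}-{seg[1]} "
          f"({(seg[1] - seg[0] + 1) / 1000:.1f} kb)")
    print(f"injected specific variants: {len(cohort.truth.injected_positions)} "
          f"at {cohort.truth.injected_positions.tolist()}")
    print(f"artifacts written to {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
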