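"""Readers and writers for the pipeline's standard formats.

Phased panels travel as VCF (phased GT, e.g. ``0|1``); recombination maps as
3-column whitespace-delimited text (position_bp, rate_cM_per_Mb, map_cM);
tables as TSV; intervals as BED (0-based half-open on disk, 1-based
inclusive in memory); truth records and summaries as JSON.
"""
from __future__ import annotations

import importlib.resources
import json
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .panel import GenomicInterval, HaplotypePanel, RecombinationMap

__all__ = [
    "read_phased_panel",
    "write_phased_panel",
    "read_recomb_map",
    "write_recomb_map",
    "apply_site_qc",
    "write_interval_bed",
    "read_interval_bed",
    "load_table2_frequencies",
]

MISSING = -1
VALID_BASES = {"A", "C", "G", "T"}


def write_phased_panel(panel: HaplotypePanel, path) -> None:
    """Serialize a panel as a minimal phased VCFv4.2 text file."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={panel.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.sample_ids) + "\n")
        a = panel.alleles
        for j in range(panel.n_sites):
            gts = "\t".join(f"{a[2 * i, j]}|{a[2 * i + 1, j]}"
                            for i in range(panel.n_samples))
            fh.write(f"{panel.chrom}\t{panel.positions[j]}\tv{j + 1}\t"
                     f"{panel.ref[j]}\t{panel.alt[j]}\t.\tPASS\t.\tGT\t{gts}\n")


def read_phased_panel(vcf_path, region: str | None = None) -> HaplotypePanel:
    """Load a phased biallelic panel from VCF.

    Unphased genotypes and multi-allelic records raise with the offending
    position named. The allele matrix has two rows per sample.
    """
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    cols, positions, refs, alts = [], [], [], []
    chrom = None
    it = vcf(region) if region else vcf
    for var in it:
        if len(var.ALT) != 1:
            raise ValueError(f"multi-allelic record at {var.CHROM}:{var.POS}")
        g = np.asarray(var.genotypes)  # (n_samples, 3): a, b, phased flag
        if np.any(g[:, 2] == 0):
            raise ValueError(f"unphased genotype at {var.CHROM}:{var.POS}")
        if np.any(g[:, :2] < 0):
            raise ValueError(f"missing allele in phased record at {var.CHROM}:{var.POS}")
        cols.append(g[:, :2].reshape(-1))
        positions.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        chrom = var.CHROM
    if not cols:
        raise ValueError("no records in VCF (or region empty)")
    alleles = np.stack(cols, axis=1).astype(np.uint8)
    return HaplotypePanel(alleles, np.asarray(positions), samples,
                          chrom=chrom, ref=np.asarray(refs, dtype=object),
                          alt=np.asarray(alts, dtype=object))


def write_recomb_map(path, positions, rates_cm_per_mb, map_cm) -> None:
    df = pd.DataFrame({"position_bp": np.asarray(positions, dtype=np.int64),
                       "rate_cM_per_Mb": rates_cm_per_mb, "map_cM": map_cm})
    df.to_csv(path, sep=" ", index=False)


def read_recomb_map(path) -> RecombinationMap:
    """3-column whitespace text: position_bp, rate_cM_per_Mb, map_cM."""
    df = pd.read_csv(path, sep=r"\s+")
    if df.shape[1] < 3:
        raise ValueError("recombination map needs 3 columns")
    df.columns = ["position_bp", "rate_cM_per_Mb", "map_cM"] + list(df.columns[3:])
    return RecombinationMap(df["position_bp"].to_numpy(float),
                            df["rate_cM_per_Mb"].to_numpy(float),
                            df["map_cM"].to_numpy(float))


def apply_site_qc(genotypes: np.ndarray, site_meta: pd.DataFrame,
                  min_call_rate: float = 0.90):
    """Site-level QC on an individuals x sites genotype matrix.

    Removal rules, applied in order with one count per rule: duplicated
    position, non-SNP alleles (REF/ALT longer than one base), invalid
    allele characters, monomorphic sites, and call rate below
    ``min_call_rate`` (missing coded -1). Returns
    ``(filtered_genotypes, filtered_meta, report)`` with
    ``removed + retained == input``.
    """
    g = np.asarray(genotypes)
    n, L = g.shape
    if len(site_meta) != L:
        raise ValueError("site_meta must describe every column")
    reasons = {"duplicated": 0, "non_snp": 0, "invalid_allele": 0,
               "monomorphic": 0, "low_call_rate": 0}
    keep = np.ones(L, dtype=bool)
    seen = set()
    for j in range(L):
        pos = site_meta.iloc[j]["position"]
        ref = str(site_meta.iloc[j].get("ref", "A")).upper()
        alt = str(site_meta.iloc[j].get("alt", "G")).upper()
        col = g[:, j]
        called = col != MISSING
        if pos in seen:
            reasons["duplicated"] += 1
        elif len(ref) != 1 or len(alt) != 1:
            reasons["non_snp"] += 1
        elif ref not in VALID_BASES or alt not in VALID_BASES:
            reasons["invalid_allele"] += 1
        elif called.any() and np.all(col[called] == col[called][0]) and col[called][0] in (0, 2):
            reasons["monomorphic"] += 1
        elif called.mean() < min_call_rate:
            reasons["low_call_rate"] += 1
        else:
            seen.add(pos)
            continue
        keep[j] = False
        seen.add(pos)
    report = {"input_sites": L, "retained": int(keep.sum()),
              "removed": int((~keep).sum()), "by_reason": reasons,
              "min_call_rate": min_call_rate}
    assert report["retained"] + report["removed"] == L
    return g[:, keep], site_meta.loc[keep].reset_index(drop=True), report


def write_interval_bed(path, intervals: list[GenomicInterval]) -> None:
    """BED output: 0-based half-open, extra columns carry boundary evidence."""
    with Path(path).open("w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t"
                     f"evidence={iv.boundary_evidence[0]},{iv.boundary_evidence[1]}"
                     f";below_threshold={int(iv.below_threshold)}\n")


def read_interval_bed(path) -> list[GenomicInterval]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        out.append(GenomicInterval(f[0], int(f[1]) + 1, int(f[2])))
    return out


def load_table2_frequencies() -> pd.DataFrame:
    """The published per-background frequency table of the nine
    target-specific variants (packaged TSV fixture)."""
    ref = importlib.resources.files("finehap") / "data" / "table2_frequencies.tsv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t")


def dump_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
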