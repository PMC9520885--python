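"""Core in-memory containers shared across the pipeline.

A :class:`HaplotypePanel` holds a phased, biallelic allele matrix with two
rows per diploid individual, together with 1-based physical positions and the
indices of the tag SNPs whose alleles define the locus haplotypes. A
:class:`RecombinationMap` carries a cumulative genetic map (cM) and converts
physical site grids into inter-site distances in Morgans.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HaplotypePanel",
    "RecombinationMap",
    "GenomicInterval",
]


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes over one locus.

    Parameters
    ----------
    alleles
        ``(n_chromosomes, n_sites)`` array of 0/1 allele codes. Chromosomes
        ``2*i`` and ``2*i + 1`` belong to diploid individual ``i``.
    positions
        1-based physical positions (bp), strictly increasing.
    sample_ids
        One identifier per diploid individual (``n_chromosomes / 2``).
    tag_site_indices
        0-based indices of the tag SNPs defining the locus haplotypes.
    population
        Optional per-chromosome population label.
    """

    alleles: np.ndarray
    positions: np.ndarray
    sample_ids: list[str]
    chrom: str = "chrS"
    tag_site_indices: np.ndarray | None = None
    population: np.ndarray | None = None
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if self.alleles.shape[1] != self.positions.size:
            raise ValueError("positions length must equal the site count")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.alleles.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("expected two chromosomes per sample id")
        if self.tag_site_indices is not None:
            self.tag_site_indices = np.asarray(self.tag_site_indices, dtype=np.int64)
        if self.ref is None:
            self.ref = np.full(self.n_sites, "A", dtype=object)
        if self.alt is None:
            self.alt = np.full(self.n_sites, "G", dtype=object)

    @property
    def n_chromosomes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def tag_labels(self) -> np.ndarray:
        """Per-chromosome tag-haplotype label: the allele string at the tag sites."""
        if self.tag_site_indices is None:
            raise ValueError("panel has no tag_site_indices")
        tags = self.alleles[:, self.tag_site_indices]
        return np.array(["".join(map(str, row)) for row in tags], dtype=object)

    def genotypes(self, site_indices: np.ndarray | None = None) -> np.ndarray:
        """Unphased diploid genotype codes (0/1/2) per individual."""
        a = self.alleles if site_indices is None else self.alleles[:, site_indices]
        return (a[0::2].astype(np.int16) + a[1::2].astype(np.int16)).astype(np.int8)

    def subset_sites(self, mask_or_indices) -> "HaplotypePanel":
        idx = np.asarray(mask_or_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return HaplotypePanel(
            alleles=self.alleles[:, idx],
            positions=self.positions[idx],
            sample_ids=list(self.sample_ids),
            chrom=self.chrom,
            tag_site_indices=None,
            population=None if self.population is None else self.population.copy(),
            ref=self.ref[idx],
            alt=self.alt[idx],
        )


@dataclass
class RecombinationMap:
    """Cumulative genetic map: position (bp), local rate (cM/Mb), map (cM)."""

    positions: np.ndarray
    rates_cm_per_mb: np.ndarray
    map_cm: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.rates_cm_per_mb = np.asarray(self.rates_cm_per_mb, dtype=np.float64)
        self.map_cm = np.asarray(self.map_cm, dtype=np.float64)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("map positions must be strictly increasing")
        if np.any(self.rates_cm_per_mb < 0):
            raise ValueError("negative recombination rate in map")

    def interpolate_cm(self, positions) -> np.ndarray:
        """Cumulative cM at arbitrary positions (linear; clamped beyond range)."""
        q = np.asarray(positions, dtype=np.float64)
        if q.size and (q.min() < self.positions[0] or q.max() > self.positions[-1]):
            warnings.warn("query positions outside map range are clamped", stacklevel=2)
        return np.interp(q, self.positions, self.map_cm)

    def interval_distances(self, site_positions) -> np.ndarray:
        """Inter-site genetic distances in Morgans for a site grid."""
        cm = self.interpolate_cm(site_positions)
        d = np.diff(cm) / 100.0
        return np.clip(d, 0.0, None)


@dataclass
class GenomicInterval:
    """1-based inclusive genomic interval with boundary-evidence bookkeeping."""

    chrom: str
    start: int
    end: int
    boundary_evidence: tuple[int, int] = (0, 0)
    below_threshold: bool = False
    note: str = ""
    site_span: tuple[int, int] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("interval start must be <= end")

    @property
    def width(self) -> int:
        return int(self.end - self.start + 1)

    @property
    def width_kb(self) -> float:
        return self.width / 1000.0
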