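"""Diploid genotype matrix container used throughout the SNP pipeline.

Genotypes are coded as alternate-allele counts {0, 1, 2}; missing calls are
stored as -1. The container carries the per-record metadata the quality
filters need (QUAL, per-genotype depth, biallelic-SNP flag) plus optional
truth flags from the simulator (paralog injection).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MISSING = -1

__all__ = ["GenotypeMatrix", "MISSING"]


@dataclass
class GenotypeMatrix:
    genotypes: np.ndarray  # (n_samples, n_loci) int8, -1 = missing
    sample_ids: np.ndarray  # (n_samples,) str
    locus_ids: np.ndarray  # (n_loci,) str
    populations: np.ndarray  # (n_samples,) str
    qual: np.ndarray | None = None  # (n_loci,) float
    depth: np.ndarray | None = None  # (n_samples, n_loci) int
    biallelic_snp: np.ndarray | None = None  # (n_loci,) bool
    paralog_truth: np.ndarray | None = None  # (n_loci,) bool

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.locus_ids = np.asarray(self.locus_ids, dtype=object)
        self.populations = np.asarray(self.populations, dtype=object)
        n, m = self.genotypes.shape
        if len(self.sample_ids) != n or len(self.populations) != n:
            raise ValueError("sample annotation length mismatch")
        if len(self.locus_ids) != m:
            raise ValueError("locus annotation length mismatch")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        bad = ~np.isin(self.genotypes, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        if self.biallelic_snp is None:
            self.biallelic_snp = np.ones(m, dtype=bool)

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def called(self) -> np.ndarray:
        """Boolean matrix marking non-missing genotypes."""
        return self.genotypes != MISSING

    def take_loci(self, idx: np.ndarray) -> "GenotypeMatrix":
        """Subset loci (boolean mask or integer index)."""
        return GenotypeMatrix(
            genotypes=self.genotypes[:, idx],
            sample_ids=self.sample_ids,
            locus_ids=self.locus_ids[idx],
            populations=self.populations,
            qual=None if self.qual is None else np.asarray(self.qual)[idx],
            depth=None if self.depth is None else np.asarray(self.depth)[:, idx],
            biallelic_snp=None
            if self.biallelic_snp is None
            else np.asarray(self.biallelic_snp)[idx],
            paralog_truth=None
            if self.paralog_truth is None
            else np.asarray(self.paralog_truth)[idx],
        )

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            genotypes=self.genotypes[idx, :],
            sample_ids=self.sample_ids[idx],
            locus_ids=self.locus_ids,
            populations=self.populations[idx],
            qual=self.qual,
            depth=None if self.depth is None else np.asarray(self.depth)[idx, :],
            biallelic_snp=self.biallelic_snp,
            paralog_truth=self.paralog_truth,
        )
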