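"""SNP filtering and population differentiation.

The filter chain reproduces a standard reduced-representation workflow:

1. keep biallelic SNPs with QUAL >= 30, mask genotypes with depth < 3,
   then require minor allele count >= 2 and non-reference allele count >= 6
   over the called genotypes (vcftools --minQ/--minDP/--mac/--non-ref-ac
   semantics, applied in that order);
2. drop samples with less than 15% of loci genotyped;
3. the excess-heterozygosity paralog screen: keep only loci whose observed
   heterozygote fraction is strictly below the expected heterozygosity
   2 p(1-p). Collapsed paralogs masquerade as SNPs where essentially every
   individual is heterozygous (Ho near 1 at p near 0.5), so this removes
   them at the cost of being very conservative.

Differentiation is the Weir & Cockerham (1984) theta, combined across loci
as a ratio of sums of the a, b, c variance components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "quality_filter",
    "completeness_filter",
    "het_stats",
    "paralog_filter",
    "simulate_hwe_panel",
    "pairwise_fst",
    "weir_cockerham_theta",
    "FstResult",
]


def quality_filter(
    g: GenotypeMatrix,
    min_qual: float = 30.0,
    min_dp: int = 3,
    min_mac: int = 2,
    min_non_ref_ac: int = 6,
) -> GenotypeMatrix:
    """Record-level quality filtering with fixed evaluation order.

    Order: biallelic SNPs only; QUAL >= min_qual; genotypes with DP < min_dp
    set to missing; then allele-count thresholds computed over the remaining
    called genotypes. Records without QUAL (NaN) are kept; genotypes without
    DP (coded -1) are kept with their call.
    """
    keep = np.ones(g.n_loci, dtype=bool)
    if g.biallelic_snp is not None:
        keep &= np.asarray(g.biallelic_snp, dtype=bool)
    if g.qual is not None:
        qual = np.asarray(g.qual, dtype=float)
        keep &= np.isnan(qual) | (qual >= min_qual)
    geno = g.genotypes.copy()
    if g.depth is not None:
        low_dp = (np.asarray(g.depth) >= 0) & (np.asarray(g.depth) < min_dp)
        geno[low_dp] = MISSING
    called = geno != MISSING
    alt = np.where(called, geno, 0).sum(axis=0)
    total = 2 * called.sum(axis=0)
    ref = total - alt
    mac = np.minimum(alt, ref)
    keep &= (mac >= min_mac) & (alt >= min_non_ref_ac)
    out = GenotypeMatrix(
        genotypes=geno,
        sample_ids=g.sample_ids,
        locus_ids=g.locus_ids,
        populations=g.populations,
        qual=g.qual,
        depth=g.depth,
        biallelic_snp=g.biallelic_snp,
        paralog_truth=g.paralog_truth,
    )
    return out.take_loci(keep)


def completeness_filter(
    g: GenotypeMatrix, min_frac: float = 0.15
) -> tuple[GenotypeMatrix, list[str]]:
    """Drop samples genotyped at less than ``min_frac`` of loci (strict <)."""
    frac = g.called.mean(axis=1)
    keep = frac >= min_frac
    if not keep.any():
        raise ValueError("completeness filter removed every sample")
    dropped = [str(s) for s in g.sample_ids[~keep]]
    return g.take_samples(keep), dropped


def het_stats(g: GenotypeMatrix, unbiased: bool = False) -> pd.DataFrame:
    """Per-locus reference-allele frequency, observed and expected heterozygosity.

    Returns a DataFrame indexed by locus id with columns ``p_hat`` (reference
    allele frequency), ``ho``, ``he`` (= 2 p(1-p), optionally with the
    2n/(2n-1) small-sample correction) and ``n_called``. Loci with no called
    genotypes are excluded.
    """
    called = g.called
    n_called = called.sum(axis=0)
    alt = np.where(called, g.genotypes, 0).sum(axis=0)
    n_het = ((g.genotypes == 1) & called).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_ref = 1.0 - alt / (2.0 * n_called)
        ho = n_het / n_called
    he = 2.0 * p_ref * (1.0 - p_ref)
    if unbiased:
        he = he * (2.0 * n_called) / np.maximum(2.0 * n_called - 1.0, 1.0)
    df = pd.DataFrame(
        {
            "p_hat": p_ref,
            "ho": ho,
            "he": he,
            "n_called": n_called,
        },
        index=pd.Index(g.locus_ids, name="locus"),
    )
    return df[df["n_called"] > 0]


def paralog_filter(
    g: GenotypeMatrix, unbiased: bool = False
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Keep loci with Ho strictly below He; report the removals.

    Monomorphic loci (ho = he = 0) fail the strict inequality and are
    removed, but the minor-allele-count filter upstream has usually removed
    them already. Returns (filtered matrix, removed-locus table with p_hat,
    ho, he).
    """
    stats = het_stats(g, unbiased=unbiased)
    stats = stats.reindex(pd.Index(g.locus_ids, name="locus"))
    ok = (stats["ho"] < stats["he"]).fillna(False).to_numpy()
    removed = stats[~ok].drop(columns="n_called")
    return g.take_loci(ok), removed


def simulate_hwe_panel(
    n_snps: int = 100, n_samples: int = 100, seed: int = 0
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Reference panel of SNPs in Hardy-Weinberg equilibrium.

    Per locus p ~ U(0.05, 0.95) and genotypes ~ Binomial(2, p). Used as the
    null scatter (p_hat vs Ho) against which excess-heterozygosity outliers
    are judged.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, size=n_snps)
    geno = rng.binomial(2, p, size=(n_samples, n_snps)).astype(np.int8)
    g = GenotypeMatrix(
        genotypes=geno,
        sample_ids=np.array([f"hwe{i + 1}" for i in range(n_samples)], dtype=object),
        locus_ids=np.array([f"hwe_snp{k + 1}" for k in range(n_snps)], dtype=object),
        populations=np.array(["HWE"] * n_samples, dtype=object),
    )
    return g, het_stats(g)


@dataclass(frozen=True)
class FstResult:
    pair: tuple[str, str]
    theta: float
    n_loci_used: int


def weir_cockerham_theta(
    geno_a: np.ndarray, geno_b: np.ndarray
) -> tuple[float, int]:
    """Multilocus Weir & Cockerham (1984) theta for two populations.

    ``geno_a`` and ``geno_b`` are (samples, loci) alternate-allele count
    matrices with -1 for missing. Per locus the a (among-population), b
    (among-individual) and c (within-individual) variance components are
    computed from sample sizes, allele frequencies and heterozygote
    fractions; the multilocus estimate is sum(a) / sum(a + b + c) over loci
    with a positive denominator. Returns (theta, number of loci used).
    """
    r = 2.0
    called_a = geno_a != MISSING
    called_b = geno_b != MISSING
    n1 = called_a.sum(axis=0).astype(float)
    n2 = called_b.sum(axis=0).astype(float)
    usable = (n1 >= 1) & (n2 >= 1) & (n1 + n2 >= 3)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(called_a, geno_a, 0).sum(axis=0) / (2.0 * n1)
        p2 = np.where(called_b, geno_b, 0).sum(axis=0) / (2.0 * n2)
        h1 = ((geno_a == 1) & called_a).sum(axis=0) / n1
        h2 = ((geno_b == 1) & called_b).sum(axis=0) / n2
        n_bar = (n1 + n2) / r
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1.0))
            * (p_bar * (1.0 - p_bar) - s2 * (r - 1.0) / r - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar)
            - s2 * (r - 1.0) / r
            - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
        )
        c = h_bar / 2.0
    denom = a + b + c
    usable &= np.isfinite(denom) & (np.abs(denom) > 0)
    if not usable.any():
        raise ValueError("no locus with a defined theta denominator")
    theta = float(a[usable].sum() / denom[usable].sum())
    return theta, int(usable.sum())


def pairwise_fst(
    g: GenotypeMatrix, pops: tuple[str, ...] | None = None
) -> list[FstResult]:
    """Weir-Cockerham theta for every unordered population pair."""
    if pops is None:
        pops = tuple(sorted(set(g.populations)))
    for pop in pops:
        idx = g.populations == pop
        if (g.called[idx].sum(axis=0) >= 2).sum() == 0:
            raise ValueError(f"population {pop} has <2 called samples at every locus")
    results = []
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            ga = g.genotypes[g.populations == pops[i]]
            gb = g.genotypes[g.populations == pops[j]]
            theta, n_used = weir_cockerham_theta(ga, gb)
            results.append(FstResult((pops[i], pops[j]), theta, n_used))
    return results
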