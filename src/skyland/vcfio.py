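"""VCF reading/writing for the SNP filtering pipeline.

Reading goes through :mod:`pysam`; only diploid GT fields are supported.
Multi-allelic and non-SNP records are retained but flagged so the quality
filter can drop them. Writing emits plain-text VCF v4.2 with QUAL and
per-genotype DP, sufficient for round-tripping simulated data.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pysam

from .genotypes import MISSING, GenotypeMatrix

__all__ = ["read_vcf", "write_vcf", "VcfFormatError"]


class VcfFormatError(ValueError):
    pass


def read_vcf(
    path: str | Path,
    populations: dict[str, str] | None = None,
) -> GenotypeMatrix:
    """Load a VCF into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path
        Uncompressed or bgzipped VCF with GT (and optionally DP) per sample.
    populations
        Optional sample_id -> population label mapping; samples absent from
        the mapping get the label ``"?"``.
    """
    vf = pysam.VariantFile(str(path))
    if "GT" not in vf.header.formats:
        raise VcfFormatError(f"{path}: no GT FORMAT field declared")
    samples = list(vf.header.samples)
    has_dp = "DP" in vf.header.formats
    geno_cols, dp_cols, quals, ids, biallelic = [], [], [], [], []
    for rec in vf:
        alts = rec.alts or ()
        is_biallelic_snp = (
            len(alts) == 1
            and rec.ref is not None
            and len(rec.ref) == 1
            and len(alts[0]) == 1
            and alts[0] in "ACGT"
            and rec.ref in "ACGT"
        )
        col = np.full(len(samples), MISSING, dtype=np.int8)
        dpc = np.zeros(len(samples), dtype=int)
        for j, s in enumerate(samples):
            call = rec.samples[s]
            gt = call.get("GT")
            if gt is None or any(a is None for a in gt):
                col[j] = MISSING
            else:
                col[j] = sum(1 for a in gt if a > 0)
            if has_dp:
                dp = call.get("DP")
                dpc[j] = -1 if dp is None else int(dp)
            else:
                dpc[j] = -1
        geno_cols.append(col)
        dp_cols.append(dpc)
        quals.append(np.nan if rec.qual is None else float(rec.qual))
        ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
        biallelic.append(is_biallelic_snp)
    if not geno_cols:
        raise VcfFormatError(f"{path}: no records")
    pops = np.array(
        [populations.get(s, "?") if populations else "?" for s in samples],
        dtype=object,
    )
    return GenotypeMatrix(
        genotypes=np.column_stack(geno_cols),
        sample_ids=np.array(samples, dtype=object),
        locus_ids=np.array(ids, dtype=object),
        populations=pops,
        qual=np.array(quals),
        depth=np.column_stack(dp_cols),
        biallelic_snp=np.array(biallelic, dtype=bool),
    )


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as plain-text VCF v4.2 (GT:DP)."""
    gt_strings = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=synth1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in g.sample_ids)
            + "\n"
        )
        qual = g.qual if g.qual is not None else np.full(g.n_loci, 99.0)
        for k in range(g.n_loci):
            cols = []
            for j in range(g.n_samples):
                gt = gt_strings[int(g.genotypes[j, k])]
                dp = 10 if g.depth is None else int(g.depth[j, k])
                cols.append(f"{gt}:{dp}")
            q = qual[k]
            qs = "." if not np.isfinite(q) else f"{q:g}"
            fh.write(
                f"synth1\t{k + 1}\t{g.locus_ids[k]}\tA\tG\t{qs}\tPASS\t.\tGT:DP\t"
                + "\t".join(cols)
                + "\n"
            )
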