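import numpy as np
import pytest

from skyland.genotypes import GenotypeMatrix
from skyland.raster import RasterGrid


@pytest.fixture
def grid_factory():
    """Build a RasterGrid from a 2-D array with sane defaults."""

    def make(values, mask=None, cell_size=1.0, origin=(0.0, 0.0)):
        values = np.asarray(values, dtype=float)
        return RasterGrid(values, mask, cell_size, origin)

    return make


@pytest.fixture
def plane_dem():
    """Plane descending northward at 0.1 m/m, 50 m cells, 9x9."""
    n = 9
    cell = 50.0
    grid = RasterGrid(np.zeros((n, n)), cell_size=cell)
    _, y = grid.xy_grids()
    return grid.like(1000.0 - 0.1 * y)


def geno_matrix(geno, pops, **kw):
    geno = np.asarray(geno, dtype=np.int8)
    n, m = geno.shape
    return GenotypeMatrix(
        genotypes=geno,
        sample_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
        locus_ids=np.array([f"l{j}" for j in range(m)], dtype=object),
        populations=np.array(pops, dtype=object),
        **kw,
    )


TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc
chr1\t1\tsnp1\tA\tG\t50\tPASS\t.\tGT:DP\t0/0:10\t0/1:10\t1/1:10
chr1\t2\tsnp2\tA\tG\t50\tPASS\t.\tGT:DP\t./.:0\t0/1:10\t1/1:10
chr1\t3\tsnp3\tA\tG,T\t50\tPASS\t.\tGT:DP\t0/0:10\t0/1:10\t1/2:10
"""


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path
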