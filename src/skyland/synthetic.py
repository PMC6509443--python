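"""Synthetic study system: a three-peak sky-island landscape with matching
genotype and mitochondrial-haplotype data.

The generators emulate the study design the analysis pipeline assumes:

* a DEM with three Gaussian mountains on a low floor — the northern peak
  near 1,100 m, the central and southern peaks above 1,200 m, ~5 km apart,
  with a high connecting ridge on the southern (C-S) side and an
  intermediate (~900 m) saddle on the northern (C-N) side;
* three populations whose allele frequencies drift from a common ancestral
  pool under the Balding-Nichols model, so each population pair has a known
  expected differentiation;
* paralog-contaminated SNP loci built by collapsing two duplicated gene
  copies fixed for alternate alleles, which makes every individual appear
  heterozygous;
* aligned haplotype sequences from a three-population star-ish genealogy
  with a deep south split and a shallow north/central split.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .alignment import HaplotypeAlignment
from .genotypes import MISSING, GenotypeMatrix
from .raster import RasterGrid

__all__ = [
    "MountainSpec",
    "PopModel",
    "default_mountains",
    "make_three_mountain_dem",
    "sample_localities",
    "simulate_genotypes",
    "inject_paralogs",
    "simulate_haplotypes",
]

POPULATIONS = ("N", "C", "S")


@dataclass(frozen=True)
class MountainSpec:
    """One Gaussian mountain: peak location, target peak elevation, footprint."""

    peak_xy: tuple[float, float]
    peak_elev: float
    spread: float
    label: str

    def __post_init__(self) -> None:
        if not self.spread > 0:
            raise ValueError("spread must be positive")


@dataclass(frozen=True)
class RidgeSpec:
    """A Gaussian ridge along the segment between two peaks.

    The elevation contribution decays with distance to the segment
    ``a_xy``-``b_xy``; ``crest_elev`` is the target total elevation at the
    segment midpoint and ``spread`` sets how steeply the flanks fall away.
    A small spread gives a narrow causeway with steep sides; a large one a
    broad saddle.
    """

    a_xy: tuple[float, float]
    b_xy: tuple[float, float]
    crest_elev: float
    spread: float
    label: str
    profile_power: float = 2.0  # 2 = Gaussian; >2 = flat crest, steep flanks

    def __post_init__(self) -> None:
        if not self.spread > 0:
            raise ValueError("spread must be positive")
        if not self.profile_power >= 2.0:
            raise ValueError("profile_power must be >= 2")


def default_mountains(floor_elev: float = 400.0) -> list[MountainSpec]:
    """The default three-mountain geometry (map units metres).

    Peaks sit on a NE-SW line 5 km apart: the northern peak near 1,100 m,
    the central and southern peaks at 1,230 m.
    """
    c = (10_000.0, 5_000.0)
    dx, dy = 4_700.0, 1_710.0  # 5,001 m apart, bearing ~70 deg
    return [
        MountainSpec((c[0] + dx, c[1] + dy), 1_100.0, 1_200.0, "N"),
        MountainSpec(c, 1_230.0, 1_200.0, "C"),
        MountainSpec((c[0] - dx, c[1] - dy), 1_230.0, 1_200.0, "S"),
    ]


def default_ridges(
    specs: list[MountainSpec] | None = None, floor_elev: float = 400.0
) -> list[RidgeSpec]:
    """The two inter-peak connections of the default landscape.

    The northern corridor is a broad Gaussian saddle cresting near 950 m —
    gentle slopes, so mid-elevation (800-1,000 m) terrain is extensive
    there. The southern corridor is a high flat-topped ridge (quartic
    profile) cresting near 1,160 m whose steep flanks leave little
    mid-elevation terrain along the southern transition. This mirrors the
    study landscape, where the shortest southern-corridor route crosses the
    high ridge between the central and southern mountains while
    northern-corridor paths stay at intermediate elevations.
    """
    if specs is None:
        specs = default_mountains(floor_elev)
    xy = {s.label: s.peak_xy for s in specs}
    return [
        RidgeSpec(xy["C"], xy["N"], 950.0, 1_200.0, "NC"),
        RidgeSpec(xy["C"], xy["S"], 1_160.0, 700.0, "CS", profile_power=4.0),
    ]


def make_three_mountain_dem(
    specs: list[MountainSpec] | None = None,
    floor_elev: float = 400.0,
    grid_shape: tuple[int, int] = (200, 400),
    cell_size: float = 50.0,
    seed: int = 0,
    noise_amp: float = 5.0,
    noise_smooth_cells: float = 10.0,
    ridges: list[RidgeSpec] | None = None,
) -> RasterGrid:
    """Seeded three-mountain DEM.

    Elevation is floor + a sum of Gaussian components (three peak bumps
    plus, by default, the two inter-peak ridges of
    :func:`default_ridges`) whose amplitudes are solved by a small linear
    system so the elevation at each peak and ridge crest equals its target
    even where footprints overlap, plus smooth seeded noise
    (Gaussian-filtered white noise scaled to ``noise_amp`` standard
    deviation) clipped below at the floor. Pass ``ridges=[]`` for a pure
    three-bump landscape.
    """
    if specs is None:
        specs = default_mountains(floor_elev)
    labels = [s.label for s in specs]
    if sorted(labels) != ["C", "N", "S"]:
        raise ValueError("need exactly three mountains labelled N, C, S")
    grid = RasterGrid(
        np.zeros(grid_shape), cell_size=cell_size, origin=(0.0, 0.0),
        crs_label="synthetic local metric",
    )
    xg, yg = grid.xy_grids()
    extent_x = grid_shape[1] * cell_size
    extent_y = grid_shape[0] * cell_size
    for s in specs:
        if not (0 <= s.peak_xy[0] <= extent_x and 0 <= s.peak_xy[1] <= extent_y):
            raise ValueError(f"peak {s.label} at {s.peak_xy} lies outside the grid")
        if s.peak_elev <= floor_elev:
            raise ValueError(f"peak {s.label} not above the floor elevation")
    z = analytic_elevation(xg, yg, specs, floor_elev, ridges)
    if noise_amp > 0:
        rng = np.random.default_rng(seed)
        white = rng.standard_normal(grid_shape)
        smooth = ndimage.gaussian_filter(white, sigma=noise_smooth_cells)
        smooth *= noise_amp / smooth.std()
        z = np.maximum(z + smooth, floor_elev)
    return grid.like(z)


def _seg_dist2(x, y, a: tuple[float, float], b: tuple[float, float]):
    """Squared distance from (x, y) to the segment a-b."""
    ax, ay = a
    bx, by = b
    vx, vy = bx - ax, by - ay
    L2 = vx * vx + vy * vy
    t = np.clip(((x - ax) * vx + (y - ay) * vy) / L2, 0.0, 1.0)
    px, py = ax + t * vx, ay + t * vy
    return (x - px) ** 2 + (y - py) ** 2


def _basis_terms(
    specs: list[MountainSpec], ridges: list[RidgeSpec]
) -> list[tuple]:
    """(control point, squared-distance function, spread) per component."""
    terms = []
    for s in specs:
        terms.append(
            (
                s.peak_xy,
                (lambda x, y, p=s.peak_xy: (x - p[0]) ** 2 + (y - p[1]) ** 2),
                s.spread,
                s.peak_elev,
                2.0,
            )
        )
    for r in ridges:
        mid = (0.5 * (r.a_xy[0] + r.b_xy[0]), 0.5 * (r.a_xy[1] + r.b_xy[1]))
        terms.append(
            (
                mid,
                (lambda x, y, rr=r: _seg_dist2(x, y, rr.a_xy, rr.b_xy)),
                r.spread,
                r.crest_elev,
                r.profile_power,
            )
        )
    return terms


def _bump(d2: np.ndarray, spread: float, power: float) -> np.ndarray:
    """Radial profile exp(-((d/spread)^power) / 2); Gaussian when power = 2."""
    return np.exp(-0.5 * (d2 / spread**2) ** (power / 2.0))


def _solved_amplitudes(
    specs: list[MountainSpec], ridges: list[RidgeSpec], floor_elev: float
) -> np.ndarray:
    """Component amplitudes so summed bumps hit each control elevation.

    Control points are the peaks (target: peak_elev) and the ridge midpoints
    (target: crest_elev); a small linear system accounts for the overlap of
    the components at those points.
    """
    terms = _basis_terms(specs, ridges)
    k = len(terms)
    basis = np.empty((k, k))
    for i, (pt, _, _, _, _) in enumerate(terms):
        for j, (_, d2fn, spread, _, power) in enumerate(terms):
            basis[i, j] = _bump(d2fn(pt[0], pt[1]), spread, power)
    targets = np.array([t[3] - floor_elev for t in terms])
    return np.linalg.solve(basis, targets)


def analytic_elevation(
    x: np.ndarray,
    y: np.ndarray,
    specs: list[MountainSpec] | None = None,
    floor_elev: float = 400.0,
    ridges: list[RidgeSpec] | None = None,
) -> np.ndarray:
    """Noise-free elevation of the synthetic landscape at map coordinates.

    ``ridges=None`` uses the default inter-peak connections; pass ``[]`` for
    a pure three-bump landscape.
    """
    if specs is None:
        specs = default_mountains(floor_elev)
    if ridges is None:
        ridges = default_ridges(specs, floor_elev)
    amps = _solved_amplitudes(specs, ridges, floor_elev)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.full(np.broadcast(x, y).shape, floor_elev, dtype=float)
    for amp, (_, d2fn, spread, _, power) in zip(amps, _basis_terms(specs, ridges)):
        z = z + amp * _bump(d2fn(x, y), spread, power)
    return z


def sample_localities(
    specs: list[MountainSpec] | None = None,
    n_per_pop: dict[str, int] | None = None,
    seed: int = 0,
    elev_range: tuple[float, float] = (870.0, 1_030.0),
    bearing_spread: float = 60.0,
    floor_elev: float = 400.0,
    ridges: list[RidgeSpec] | None = None,
) -> pd.DataFrame:
    """Sample coordinates on the mid-elevation north-facing flank of each peak.

    The species occupies talus on northerly aspects between roughly 850 and
    1,050 m, so each sample is placed along a ray from its peak at a compass
    bearing within ``bearing_spread`` degrees of north, at the radius where
    the (noise-free) landscape reaches a target elevation drawn uniformly
    from ``elev_range``. Population centroids therefore fall on mid-slope
    terrain, as the real sample centroids do, not on the summits.

    Default sample sizes follow the study design imbalance: 6 northern,
    40 central, 32 southern individuals.
    """
    if specs is None:
        specs = default_mountains(floor_elev)
    if n_per_pop is None:
        n_per_pop = {"N": 6, "C": 40, "S": 32}
    rng = np.random.default_rng(seed)
    rows = []
    for s in sorted(specs, key=lambda m: m.label):
        n = n_per_pop[s.label]
        for i in range(n):
            bearing = np.radians(rng.uniform(-bearing_spread, bearing_spread))
            target = rng.uniform(*elev_range)
            ux, uy = np.sin(bearing), np.cos(bearing)  # compass bearing from north
            lo, hi = 0.0, 4.0 * s.spread
            for _ in range(60):  # bisect: elevation decreases with radius
                mid = 0.5 * (lo + hi)
                z = analytic_elevation(
                    s.peak_xy[0] + mid * ux,
                    s.peak_xy[1] + mid * uy,
                    specs,
                    floor_elev,
                    ridges,
                )
                if z > target:
                    lo = mid
                else:
                    hi = mid
            r = 0.5 * (lo + hi)
            rows.append(
                {
                    "sample_id": f"{s.label}{i + 1:02d}",
                    "population": s.label,
                    "x": float(s.peak_xy[0] + r * ux),
                    "y": float(s.peak_xy[1] + r * uy),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PopModel:
    """Balding-Nichols population model for SNP simulation.

    ``f_per_pop`` gives each population's drift parameter F (its expected
    differentiation from the ancestral pool); F = 0 means the population
    frequency equals the ancestral frequency exactly.
    """

    n_per_pop: dict[str, int] = field(
        default_factory=lambda: {"N": 6, "C": 40, "S": 32}
    )
    n_snps: int = 2_000
    f_per_pop: dict[str, float] = field(
        default_factory=lambda: {"N": 0.01, "C": 0.01, "S": 0.25}
    )
    missing_rate: float = 0.0
    paralog_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for k, f in self.f_per_pop.items():
            if not 0.0 <= f < 1.0:
                raise ValueError(f"F for {k} must be in [0, 1)")
        for name, frac in (("missing_rate", self.missing_rate),
                           ("paralog_fraction", self.paralog_fraction)):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def simulate_genotypes(model: PopModel) -> GenotypeMatrix:
    """Simulate biallelic SNP genotypes under the Balding-Nichols model.

    Per locus the ancestral alternate-allele frequency is p ~ U(0.05, 0.95);
    each population draws its own frequency from
    Beta(p (1-F)/F, (1-p) (1-F)/F) and genotypes are Binomial(2, p_pop).
    Missing genotypes are assigned uniformly at random. QUAL and per-genotype
    depths are synthesised so the VCF quality filters can run on the output.
    """
    rng = np.random.default_rng(model.seed)
    m = model.n_snps
    p = rng.uniform(0.05, 0.95, size=m)
    geno_blocks, ids, pops = [], [], []
    for label in POPULATIONS:
        n = model.n_per_pop.get(label, 0)
        f = model.f_per_pop.get(label, 0.0)
        if f == 0.0:
            pk = p
        else:
            ratio = (1.0 - f) / f
            pk = rng.beta(p * ratio, (1.0 - p) * ratio)
        geno_blocks.append(rng.binomial(2, pk, size=(n, m)).astype(np.int8))
        ids.extend(f"{label}{i + 1:02d}" for i in range(n))
        pops.extend(label for _ in range(n))
    geno = np.vstack(geno_blocks)
    depth = rng.poisson(20, size=geno.shape) + 1
    if model.missing_rate > 0:
        miss = rng.random(geno.shape) < model.missing_rate
        geno[miss] = MISSING
    qual = rng.uniform(40.0, 100.0, size=m)
    g = GenotypeMatrix(
        genotypes=geno,
        sample_ids=np.array(ids, dtype=object),
        locus_ids=np.array([f"snp{k + 1}" for k in range(m)], dtype=object),
        populations=np.array(pops, dtype=object),
        qual=qual,
        depth=depth,
        paralog_truth=np.zeros(m, dtype=bool),
    )
    if model.paralog_fraction > 0:
        g = inject_paralogs(g, model.paralog_fraction, seed=model.seed + 1)
    return g


def inject_paralogs(
    g: GenotypeMatrix, fraction: float, seed: int = 0, near_fixed: float = 0.0
) -> GenotypeMatrix:
    """Replace a fraction of loci with collapsed-paralog loci.

    Each injected locus is the merge of two duplicated gene copies fixed
    (or, with probability ``near_fixed`` per allele, nearly fixed) for
    alternate alleles: reads from both copies pile up on one locus, so every
    individual genotypes as heterozygous. Truth flags are recorded in
    ``paralog_truth``. Exactly round(fraction * n_loci) loci are replaced.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    m = g.n_loci
    k = int(round(fraction * m))
    if k == 0:
        return g
    chosen = rng.choice(m, size=k, replace=False)
    geno = g.genotypes.copy()
    for locus in chosen:
        # copy 1 fixed REF, copy 2 fixed ALT -> merged call is het everywhere;
        # near_fixed lets an occasional copy carry the other allele
        copy1 = (rng.random(g.n_samples) < near_fixed).astype(np.int8)  # alt count 0/1
        copy2 = 1 - (rng.random(g.n_samples) < near_fixed).astype(np.int8)
        merged = np.clip(copy1 + copy2, 0, 2).astype(np.int8)
        missing = g.genotypes[:, locus] == MISSING
        merged[missing] = MISSING
        geno[:, locus] = merged
    flags = (
        np.zeros(m, dtype=bool)
        if g.paralog_truth is None
        else g.paralog_truth.copy()
    )
    flags[chosen] = True
    return GenotypeMatrix(
        genotypes=geno,
        sample_ids=g.sample_ids,
        locus_ids=g.locus_ids,
        populations=g.populations,
        qual=g.qual,
        depth=g.depth,
        biallelic_snp=g.biallelic_snp,
        paralog_truth=flags,
    )


_BASES = np.array(list("ACGT"))


def _mutate(seq: np.ndarray, n_mut: int, rng: np.random.Generator) -> np.ndarray:
    """Apply n_mut substitutions at uniform sites, each to a different base."""
    out = seq.copy()
    if n_mut == 0:
        return out
    sites = rng.integers(0, len(seq), size=n_mut)
    for s in sites:
        choices = _BASES[_BASES != out[s]]
        out[s] = rng.choice(choices)
    return out


def simulate_haplotypes(
    t_cs: float = 20.0,
    t_nc: float = 4.0,
    n_per_pop: dict[str, int] | None = None,
    seq_length: int = 11_310,
    seed: int = 0,
    intra_expected: float = 1.0,
    gap_sites_s: int = 0,
) -> HaplotypeAlignment:
    """Aligned haplotypes from a three-population genealogy.

    The central founder is the ancestral sequence; the northern founder is
    ``Poisson(t_nc)`` substitutions away and the southern founder
    ``Poisson(t_cs)`` away (t_nc < t_cs: the south split is deeper). Each
    individual adds ``Poisson(intra_expected)`` private substitutions.
    ``gap_sites_s`` optionally places a deletion ('-') of that many sites in
    the southern founder, exercising the gap-as-fifth-state rules.
    """
    import warnings

    if not t_nc < t_cs:
        raise ValueError("t_nc must be smaller than t_cs (shallow north/central split)")
    if max(t_cs, t_nc) > 0.5 * seq_length:
        warnings.warn(
            "expected substitutions exceed half the sequence length; "
            "distances will saturate",
            stacklevel=2,
        )
    if n_per_pop is None:
        n_per_pop = {"N": 6, "C": 40, "S": 32}
    rng = np.random.default_rng(seed)
    ancestor = rng.choice(_BASES, size=seq_length)
    founders = {
        "C": ancestor,
        "N": _mutate(ancestor, rng.poisson(t_nc), rng),
        "S": _mutate(ancestor, rng.poisson(t_cs), rng),
    }
    if gap_sites_s > 0:
        start = rng.integers(0, seq_length - gap_sites_s)
        founders["S"] = founders["S"].copy()
        founders["S"][start : start + gap_sites_s] = "-"
    seqs, ids, pops = [], [], []
    for label in POPULATIONS:
        for i in range(n_per_pop.get(label, 0)):
            seqs.append(_mutate(founders[label], rng.poisson(intra_expected), rng))
            ids.append(f"{label}{i + 1:02d}")
            pops.append(label)
    return HaplotypeAlignment(
        np.array(seqs, dtype="U1"),
        np.array(ids, dtype=object),
        np.array(pops, dtype=object),
    )
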