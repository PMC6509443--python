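# Methods and design notes

This note records the models implemented in `skyland`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that affect results.

## Circuit model

A resistance raster is turned into a resistor network: one node per
unmasked cell; edges between 8-neighbours by default (4-neighbour
available). Edge resistance is the arithmetic mean of the two cell
resistances, scaled by √2 for diagonal edges — the "average resistance"
cell-connection convention of grid-based circuit connectivity tools.
Average-conductance weighting is a one-line change in `build_graph` if
needed; the arithmetic-mean convention is the default because it is the
common default in published landscape applications.

Effective resistance is computed from the conductance Laplacian with one
node grounded per connected component. The reduced system is factorized
once per surface with sparse LU and reused for every focal pair and for
current maps; at the grid sizes used here (≤ 2·10⁵ nodes) a single
factorization serving all pairs is both faster and more accurate than
iterative solves per pair. A Jacobi-preconditioned conjugate-gradient
solver (tolerance 1e-10) is available via `CircuitSolver(..., "cg")` for
grids too large to factorize.

Numerical facts the tests pin down: agreement with a dense
Laplacian-pseudoinverse oracle to better than 1e-8 relative; exact
series/parallel closed forms; current conservation at non-focal nodes
below 1e-10; Rayleigh monotonicity (raising any resistance or masking any
cell never lowers any pairwise resistance).

Focal points are population centroids (mean of sample coordinates)
snapped to the nearest unmasked cell center, with an error if no valid
cell lies within 10 cell widths. Centroids, not short-circuited regions,
because the downstream statistics compare single numbers per pair;
a multi-point focal mode would change absolute values but not the
corridor comparisons the pipeline reports. Disconnection (a corridor
severed by masking) yields an infinite resistance flag, not an exception:
it is a legitimate analysis outcome.

## Terrain surfaces

Eight landscape surfaces: slope, TPI (8-neighbour), roughness
(3×3 range), northness (cos aspect), westness (−sin aspect), TWI, NDVI,
and solar incidence. Slope/aspect use Horn's 3×3 stencil; cells whose
window touches NoData or the grid edge are masked, never padded. Flat
cells (gradient < 1e-9) have undefined aspect and map to 0 in the
directional surfaces. TWI is ln(a / tan β) with a = (upstream count + 1) ×
cell size from single-direction (D8) steepest-descent flow accumulation
and tan β floored at 0.001. D8 was chosen over multiple-flow-direction
variants for determinism and hand-traceable tests; TWI enters the analysis
only through a monotone rescale, so the variant choice does not affect the
corridor comparisons qualitatively. Solar incidence is the standard
hillshade cosine, clamped at zero, with a default sun position of
equinox noon at the study latitude (azimuth 180°, altitude 51°).

Each surface is rescaled affinely onto resistance [1, 100], optionally
after negation ("inversion") so that larger values always mean more
resistance to movement. The floor is 1 rather than 0 because
zero-resistance cells would create infinite-conductance edges. Which
surfaces are inverted is configuration; the defaults encode the ecology of
a moisture-limited, north-slope salamander: northness, westness, TWI and
NDVI inverted (north-facing, wetter, greener terrain is favourable),
slope, TPI, roughness and solar not inverted (steep, exposed, sunny
terrain is unfavourable). TPI uses its signed value by default; an
absolute-value variant is available. The elevation restriction masks
cells strictly below the cutoff (default 500 m), so a cell exactly at the
cutoff is retained.

The Gaussian elevation band s(z) = exp(−(z−z₀)²/2σ²) is treated as a
suitability in [0, 1] and inverted during rescaling; σ defaults to 50 m,
half the 50 m sweep interval, so adjacent bands overlap at e^(−1/8).

## Synthetic landscape

`make_three_mountain_dem` builds elevation as floor (400 m) plus Gaussian
components plus smooth seeded noise (Gaussian-filtered white noise, 5 m
standard deviation, 10-cell correlation length, clipped at the floor).
The default grid is 200×400 cells of 50 m (10×20 km).

Components and their targets (amplitudes are solved by a small linear
system so each control point hits its target elevation exactly despite
overlap):

| component | geometry | target |
|---|---|---|
| N peak | Gaussian, σ = 1,200 m | 1,100 m |
| C peak | Gaussian, σ = 1,200 m | 1,230 m |
| S peak | Gaussian, σ = 1,200 m | 1,230 m |
| C–N ridge | Gaussian in distance to the C–N segment, σ = 1,200 m | crest 950 m |
| C–S ridge | quartic (flat-topped) in distance to the C–S segment, σ = 700 m | crest 1,160 m |

Peaks sit on a NE–SW line 5 km apart. The two ridge components encode the
study landscape's asymmetry: the northern transition is a broad,
gentle-sloped saddle at intermediate elevation, so 800–1,000 m terrain is
extensive there; the southern transition is a high flat-topped ridge with
steep flanks, so its mid-elevation terrain is a thin strip and the only
broad southern route runs over the high crest. A pure three-bump
landscape (available via `ridges=[]`) cannot produce this asymmetry — with
smooth isotropic bumps the southern corridor always has a cheap
mid-elevation contour detour around the ridge — which is why the ridge
components exist. The geometry was fixed by exploring saddle/crest
heights and ridge profiles against the qualitative corridor pattern the
landscape is meant to embody (northern corridor cheaper at 800–1,000 m
bands, costlier at 1,100–1,200 m bands, stepwise N–S dispersal), and then
frozen.

`sample_localities` places samples on the mid-elevation (870–1,030 m)
flanks at compass bearings within ±60° of north — the species occupies
talus on northerly aspects between roughly 850 and 1,050 m — with default
sample sizes 6/40/32 (N/C/S), the study design's imbalance. Placing the
samples mid-slope matters: population centroids then fall on mid-elevation
terrain, as real sampling centroids do. (Scattering samples around the
summits instead puts every focal node on a peak, and the elevation-band
analysis degenerates into a comparison of summit neighbourhoods.)

What the landscape does *not* emulate: real ridge-and-valley microrelief
(the noise is smooth and isotropic), hydrology-conditioned DEMs, land
cover, and real NDVI/solar fields (NDVI tests use synthetic band
rasters). Passing tests therefore demonstrate that the pipeline recovers
the designed macro-topographic signal, not that it would denoise a messy
real DEM.

## Genotype model

SNPs are simulated under the Balding–Nichols model: ancestral alternate
frequency p ~ U(0.05, 0.95) per locus; each population draws
p_k ~ Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k) and genotypes are
Binomial(2, p_k). F_k is each population's expected differentiation from
the ancestral pool; defaults F_N = F_C = 0.01, F_S = 0.25 encode the deep
south split and shallow north/central split, and give a known expected
F_ST per pair — which is what makes parameter-recovery tests possible.
F = 0 is handled exactly (p_k = p). Missingness is uniform at random.
QUAL (U(40,100)) and per-genotype depth (1 + Poisson(20)) are synthesized
so the VCF quality filters have something to act on.

Collapsed paralogs are injected by merging two simulated duplicate gene
copies fixed for alternate alleles: every genotyped individual then calls
heterozygous (Ho = 1, p̂ = 0.5). A `near_fixed` parameter can soften this;
the default is hard fixation, the worst case the filter must catch, and
exactly round(fraction × n_loci) loci are replaced with truth flags kept.

The filter chain and boundary rules: biallelic SNPs only; QUAL ≥ 30 kept;
genotypes with DP < 3 set to missing; then minor allele count ≥ 2 and
non-reference allele count ≥ 6 computed over the remaining called
genotypes; samples with < 15% of loci called dropped (≥ 15% kept); the
paralog screen keeps loci with Ho strictly below He. He is the plug-in
2p̂(1−p̂) (a 2n/(2n−1) unbiased variant is available by option); with the
plug-in form, monomorphic loci (Ho = He = 0) fail the strict rule, but the
allele-count filter has removed them already. The evaluation order is
declared, not inferred from any external tool, and re-running the chain
on its own output is a no-op (tested).

θ is Weir & Cockerham (1984) with ratio-of-sums multilocus combining;
loci with an undefined or zero denominator are skipped and counted;
negative estimates are reported as computed, never truncated.

## Haplotype model and network

Haplotypes descend from a three-population genealogy: the central founder
is the ancestral sequence; the northern founder is Poisson(t_NC)
substitutions away, the southern founder Poisson(t_CS), with t_NC < t_CS
enforced (defaults 4 and 20 on an 11,310-site alignment); individuals add
Poisson(1) private substitutions. An optional deletion in the southern
founder exercises the gap-as-fifth-state rules. A warning is raised when
expected substitutions exceed half the sequence length (saturation).

Collapsing treats N as a wildcard (sequences identical at all sites where
both are called merge; ties go to the haplotype with fewer Ns in its
representative) because the 90%-coverage screen still admits up to 10%
missing sites; the gap character is never wildcarded. Step distances
are Hamming counts over sites where neither sequence is N, gap counted as
a state.

The network is a minimum-spanning network: pairs in order of increasing
steps; an edge is added when it joins components not connected at any
strictly smaller distance, with all ties at the joining distance kept (so
reticulations among equally parsimonious connections survive). Full
statistical-parsimony inference of unsampled intermediate haplotypes is
deliberately not performed: the inferences the pipeline draws (relative
step counts between population groups) depend only on step counts, which
the MSN preserves.

The connection limit is the largest step count j whose probability of a
fully parsimonious connection is at least α (default 0.95). That
probability is computed under a Jukes–Cantor/Poisson model derived for
this package: per-site substitution counts are Poisson with rate set so
the expected visible-difference fraction equals j/m (JC distance
correction); the connection is parsimonious when each of the j differing
sites was hit exactly once and no identical site was hit at all, giving

    P(j; m) = (λe^{−λ}/d)^j · (e^{−λ}/(1−d))^{m−j},  d = j/m,
    λ = −(3/4)·ln(1 − 4d/3).

P is decreasing in j and increasing in m, so the limit is non-decreasing
in alignment length and in 1−α (tested); it is floored at 1 step. For an
11,310-site alignment the 95% limit is ≈ 24 steps, comfortably above the
simulated split depths. This estimator follows the logic of the classical
statistical-parsimony criterion but is an independent derivation; a
user-supplied fixed limit overrides it.

## Scale of the shipped analyses

The test suite and `scripts/acceptance.py` run the landscape analyses on
the full 200×400-cell grid (80,000 cells) and the genetic analyses at
2,000 loci × 78 samples and 100 replicate seeds; solver-verification
grids are ≤ 8×8 against a dense oracle and 30×30 for the monotonicity
perturbations. These sizes were chosen so a complete from-scratch run
finishes in a couple of minutes on one CPU while keeping every qualitative
contrast far from its decision boundary.

## Known limitations

* Raster I/O is ESRI ASCII grid only; GeoTIFF input raises a clear error.
  No reprojection or resampling — all rasters must be co-registered.
* The corridor layer is descriptive by design; no significance tests,
  no least-cost paths, no resistance-surface optimization.
* The paralog screen is deliberately severe (strict Ho < He): on clean
  HWE data it discards roughly half the loci by chance. That is the
  intended behaviour of the method being implemented, not a target for
  tuning.
* The TCS-style connection limit is a re-derivation, not a re-implementation
  of any specific historical program; absolute limits may differ from
  other software even though the monotone behaviour matches.
* Balding–Nichols is exchangeable across loci (no linkage, no selection),
  and the haplotype genealogy is star-like within populations.
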