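# Methods

## Cross-species temporal transcriptome comparison

**Model.** Each gene's behavior in one species is summarized by the shape of
its expression over time, not its level: log2(TPM+1) values across
timepoints are z-scored within each (gene, species, replicate) profile,
z_i = (x_i − μ)/σ with sample SD (n−1). Profiles of both species and all
replicates are pooled into a single fuzzy c-means run so that the k cluster
labels form one shared vocabulary of temporal programs; "the gene shifted
between species" is then a statement about labels, not about distances.

**Filters (in order).** A gene enters clustering only if
(1) *abundance*: it exceeds 10 TPM at ≥ 1 timepoint in every replicate of
both species; (2) *dynamics*: its replicate-mean TPM changes more than
1.5-fold between some pair of timepoints in ≥ 1 species, with a pseudocount
of 1 in the ratio ((max+1)/(min+1)) to stabilize near-zero means — replicate
means are used because a single per-species ratio only exists at that level
(a per-replicate variant is selectable); (3) *replicate consistency*: its
summed squared z-difference D = Σ_t Σ_{(r,r′)} (z_r − z_r′)², over all
C(r, 2) unordered replicate pairs and all timepoints, is ≤ 6 in both
species. The pairwise-sum reading is the only symmetric generalization of a
"squared difference between all three replicates" that reduces to the
3-replicate case. Constant profiles z-score to all-zeros with a flag (never
NaN) and are excluded from clustering: they carry no temporal pattern.

**Clustering.** Standard fuzzy c-means: membership
u_ij = 1/Σ_l (d_ij/d_il)^(2/(m−1)), centroid c_j = Σ u^m x / Σ u^m,
fuzzifier m = 2 (the conventional default), convergence when the largest
centroid coordinate moves < 1e-6, cap 300 iterations. Centroids are
initialized from a seeded k-means (10 restarts) rather than uniform random
memberships: the run is deterministic given the seed and starts near the
density modes, which matters when k temporal shapes are spread around the
circle of possible 3-point profiles. A profile exactly on a centroid takes
membership 1 there (the m→ limit of the update; no division by zero).
Hardening is argmax with ties to the lowest cluster index (logged).

**Assignment and shifts.** Per gene and species, the hard labels of the
replicates are reduced to the label held by ≥ 2 replicates; pairwise-distinct
labels mean the gene is dropped (consistency failure). Among genes assigned
in both species, *assigned shifts* have different majority labels and
*robust shifts* have disjoint replicate label sets; disjointness implies
differing majorities, so robust ⊆ assigned always.

**Enrichment and the term-shift graph.** Over-representation of a term
(K genes in a universe of N) in a cluster (n genes, overlap k) is the
hypergeometric upper tail P(X ≥ k), BH-corrected across the terms of one
(species, cluster) call, called at adjusted p < 0.05 (raw-p mode is
available). The default universe is the clustered gene list of that
species; the background is configurable because reasonable analyses differ
here. For every term enriched only in species A at cluster a and only in
species B at cluster b, the arc (a, b) gains weight 1; terms enriched at
the same cluster in both species are recorded as shared. Arc direction runs
from the first species in the sample sheet to the second.

## Growth model

Daily recursion over t_total days (default 20; the headline ratio is
provably independent of this). Symmetric phase (days 1..t_total/2):
p_t = p_{t−1}·2^{f(t)}; f(t) declines linearly from f_early = 1.4 to
f_late = 0.9 divisions/day by default — only "higher early, lower late"
matters, since any choice shared by both runs cancels. Mixed phase:
p_t = p_{t−1}·r_a(t) + p_{t−1}·r_s(t)·2^{f(t)}, n_t = n_{t−1} + p_{t−1}·r_a(t),
with r_a ramping linearly 0→1 by default (the schedule is a config input;
every schedule gives the same cross-run ratio, which `invariance_scan`
verifies over a grid of p0, t_total and r_a choices to 1e-9 relative). A
species window (start, end, f_w) replaces f for days start < t ≤ end and
must lie inside the symmetric phase. Divisions per day come from measured
cycles as f = 24/T. Cell-cycle estimation weights each tracked cell
equally: tracks with > 2 divisions average their intervals within the track
first.

## Lumen segmentation and morphometry

**Per-slice detection.** Each slice is thresholded (per-slice Otsu by
default, robust to depth-dependent attenuation; a global-percentile
alternative is available), the shell mask is hole-filled, and every
enclosed cavity ≥ min_area (50 μm²) yields a closed boundary polygon.
Slices whose intensity range is below 0.2× the stack's range carry no
marker signal and are skipped — per-slice Otsu on such slices would only
amplify faint out-of-focus bleed. Each boundary vertex is then relocated
sub-pixel to the fluorescence ridge along the outward ray from the contour
centroid (parabolic peak interpolation on a lightly smoothed profile,
sampling reach 4 in-plane voxels). The ridge line is the midline of the
stained membrane and is an unbiased surface localizer for a symmetric
stain + PSF, unlike any fixed-threshold crossing, which lands wherever the
threshold happens to cut the blurred profile (an ~0.5–1 μm inward bias in
practice).

**Linking and meshing.** Contours in adjacent slices join the same lumen
when their centroids are closer than twice the smaller contour's equivalent
radius and their 2D projections overlap; greedy in slice order, merges
continue the lower id. Each lumen's contours are resampled to 128
counter-clockwise vertices by arc length, consecutive rings are aligned by
the circular shift minimizing total edge length (prevents band twisting),
bands contribute two triangles per quad, and the end rings are fan-capped.
Surface area is the triangle-area sum; the largest lumen (by area; volume
ranking available) is the reported quantity per stack. Lumens spanning one
slice are degenerate and excluded from area statistics.

**Morphometrics.** Apical footprints are shoelace areas of delineated
simple polygons (self-intersections are rejected, not mismeasured).
Nuclear position is the apical distance as % of the mean of three
apicobasal thickness measurements, clamped to 100% with a warning for
oblique sections. Volume:surface ratios and early/late fold-reductions
(ratio to 1 decimal, nearest-integer "N-fold" label) are plain arithmetic;
`group_summary` emits descriptive tables only — inferential statistics are
deliberately left to downstream tools.

## Synthetic data

**Expression.** The generator emulates a two-species organoid RNA-seq
design: 3 replicate batches, 7 collection days (0, 2, 3, 5, 10, 15, 25) and
a 16,763-gene shared-ortholog list by default. Temporal archetypes are k=10
equally spaced directions in the plane of mean-zero three-point profiles
(monotone rises/falls, early/late peaks, transient dips), linearly
interpolated when more timepoints are simulated. Each expressed gene gets a
baseline of 5–9 log2 TPM and follows its archetype with amplitude 2 log2
units (~4-fold swing); 10% of genes are silent (0.5–5 TPM, flat). A planted
fraction (default 20%) of expressed genes uses an archetype offset by 3
positions (108°) in the second species — far from every neighboring shape,
so recovery is well-posed. Counts are negative-binomial with dispersion
0.05 (~22% CV, typical of replicate batches of pooled isogenic organoids)
around the length-weighted compositional expectation at depth 1e7.

Because TPM is compositional, the per-sample normalizer would couple every
measured profile to the whole transcriptome's dynamics; one balancing
spike-in-like gene (`SPIKE_BALANCE`) tops the expected TPM column sum to
exactly 1e6 per timepoint so that planted log2 profiles stay exactly affine
in their archetype after normalization. It is excluded from ground truth
and scoring (and in practice removes itself at the dynamics filter). In
noise-free mode counts equal their expectations and recovered z-profiles
correlate 1.0 with the planted shapes.

Terms: each archetype owns 3 terms of 30 genes, 80% drawn from its stable
(non-shifted) genes — these enrich at the same cluster in both species —
plus 12 "shift terms" drawn from shifted genes of one designated archetype,
which should surface as the heaviest arc between the planted pair.

What this generator does *not* emulate: batch effects, library-composition
drift, ortholog mis-annotation, genes with intermediate/mixture dynamics,
or correlated gene modules beyond the term structure. Passing recovery
tests therefore demonstrates that the pipeline's inference is correct under
its own model, not that real cross-species counts are this clean.

**Phantoms.** Lumens are membrane-like shells (value 1.0 over 0.1
background, 2 μm thick) straddling an analytic sphere/ellipsoid surface,
blurred with a PSF of one in-plane voxel *in physical units* (so the
phantom's optics are invariant under z-resampling — a per-axis 1-voxel blur
would make the axial PSF grow with dz and change the object being imaged),
then optionally noised (documented robustness level: Gaussian SD 0.05
against shell amplitude 0.9). True areas come from a dense icosphere
triangulation of the analytic surface (subdivision 5, ~20k faces; within
0.5% of 4πr² and of the Thomsen ellipsoid approximation). Tracks draw
inter-division intervals from a truncated normal (> 0).

## Problem sizes and numerical tolerances

The test suite and recovery checks run at 2,000 genes × 3 timepoints × 3
replicates × 2 species (the three contrasted days), sphere phantoms of
r = 50 μm at dz ∈ {16, 8, 4, 2} μm with 1 μm in-plane pixels, and 10-point
parameter grids for the growth invariance scan — sizes at which every stage
completes in seconds while leaving the planted structure non-trivial to
recover. Key tolerances: TPM column sums 1e-6 relative; z-profiles 1e-9;
growth invariance 1e-9 relative; fuzzy memberships row-sum 1e-9; sphere
mesh area 5% of closed form (−0.2% observed at dz = 2); per-slice circle
area 2%.

## Known limitations

- Shift recovery degrades gracefully but unavoidably as archetype spacing
  approaches the replicate noise scale; with 3 timepoints all shapes live
  on a 1-D circle, so k ≫ 10 is not identifiable there.
- The linking rule is greedy per slice pair; lumens that split and re-merge
  across gaps larger than one slice are treated as separate objects.
- Fan caps slightly under-measure curved end caps; the error shrinks with
  dz and is covered by the sphere-phantom tolerance.
- The growth model is deterministic and density-independent; it predicts
  ratios, not absolute counts.
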