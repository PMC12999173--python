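# Methods

This note records the models, parameter choices and numerical decisions
behind `azprofile`, in the order the pipeline runs.

## Coordinate and unit conventions

Voxel arrays are `(z, y, x)` with spacing `(dz, dy, dx)` in µm; the default
sampling (0.079 × 0.079 µm lateral, 0.370 µm axial) reflects typical
high-NA confocal acquisition, so the axial voxel is ~4.7× the lateral one.
All physical distances — nearest-neighbour distances, neighbourhood radii,
match tolerances, segmentation distances — are computed with the
anisotropic spacing; index-space distances would distort every density
statistic. Table coordinates are `(x_um, y_um, z_um)` at voxel centres,
origin at voxel (0,0,0). Physical centroids are intensity-weighted.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with complete ground truth.

**Domains.** Boxes partitioned into near-equal slabs along one axis
(compartments), optionally restricted to an axis-aligned cylinder ("tube").
This is deliberately not a neuroanatomical model: no branching, no boutons.
Passing tests therefore demonstrate correctness of the measurement and
statistics machinery on fields with the right point-process and mark
structure, not robustness to arbitrary real-tissue geometry.

**Point processes.** `hardcore`: a Poisson number of centres (density ×
foreground volume) placed by dart throwing with a minimum separation
(default 0.35 µm, roughly the physical packing limit of adjacent active
zones); placement failure after a bounded retry budget raises rather than
silently under-filling. `thomas`: Poisson parents with Gaussian-scattered
offspring; offspring falling outside the domain are rejected, not
reflected, so the realized density is slightly reduced near boundaries —
documented, not corrected. An optional `edge_margin_um` insets all centres
from the stack faces; the benchmark scenarios use 0.5 µm so every
ground-truth punctum is fully imaged (an un-imaged half-punctum at the
stack face is an annotation question, not a detector question).

**Marks.** Integrated intensities are lognormal:
`log I = µ + σ·(√w·F + √(1−w)·ε)` with `w = spatial_corr_weight`. The
spatial component `F` mixes two unit-variance fields sampled at the
centres: a Gaussian-smoothed white-noise field of physical scale
`corr_length` (the single knob for neighbour-intensity correlation), and a
Gaussian-smoothed map of the realized centre density, weighted by
`density_coupling` (per-compartment multipliers on top). Density coupling
makes dense regions bright — the "hot spot" structure; switching it off in
chosen compartments (`apply_condition_effect`, scaling by `1 − decoupling`)
emulates a condition that dissolves hot spots there while leaving the point
pattern untouched (the centre stream is independent of the mark stream, so
control and treated marks can share identical geometry). Both fields are
standardized over the sampled centres, so with density coupling off the
log-intensity marginal is exactly Normal(µ, σ²). Spot sizes are lognormally
jittered (`sigma_logsd`, default 0.1) with their z-score correlated to the
intensity z-score by `size_intensity_coupling`.

**Rendering.** Each cluster is an anisotropic 3D Gaussian truncated at 4σ
and normalized so its voxel sum equals its integrated intensity exactly
(flux is conserved before noise). Optional PSF convolution (FFT), constant
background (default 2 counts, giving Poisson noise a floor), Poisson or
Gaussian noise, and 16-bit quantization clipping at 65535 (a warning fires
if >0.1 % of voxels clip). All randomness flows from one seed through named
per-stage streams, so identical spec + seed is bit-reproducible and stages
can be regenerated independently.

**Reference scenarios.** Three regimes are frozen as module-level
constructors and used by the examples, tests and the acceptance script:

* `dense_spec` — Kenyon-cell-like: 0.132 clusters/µm³ (≈800 in a
  256×256×40 stack), hard core 0.35 µm, σ_xy 0.12 µm / σ_z 0.30 µm,
  lognormal log-sd 0.5 with log-mean 8.8 chosen so the blurred peak height
  is ~100 counts, i.e. peak SNR ≈ 10 under Poisson noise. Real
  per-cell-type densities per µm³ are unknown; this regime
  reproduces the qualitative "dense, partially merging puncta" situation.
* `sparse_spec` — DPM/APL-like: 0.02 clusters/µm³ with a 1.0 µm hard core
  and brighter puncta (log-mean 9.8, peak SNR ≈ 30). This is the regime in
  which detection is expected to be near-perfect: every pair is resolvable
  at confocal axial blur and localization noise is small against the match
  tolerance.
* `hotspot_spec` — Thomas-clustered with density-coupled marks, five ~10 µm
  slab compartments in a 50 µm-long box. Many small parent clusters
  (0.12 parents/µm³, ~6 offspring, 0.6 µm scatter) keep the neighbourhood
  radius r ≈ 1.8 µm well below the slab width; because neighbourhoods
  ignore compartment boundaries (by definition), per-compartment
  correlations are only resolvable when compartments are several r wide —
  a geometric constraint that applies equally to real compartments.

## PSF extraction and deconvolution

Beads are local 26-neighbourhood maxima above `min_peak`; any bead with a
second maximum within `isolation_radius_um` (default 2 µm) is skipped and
counted. Each qualifying bead is cropped to 21×32×32 voxels (z·y·x), the
median of the crop border is subtracted as background (clipped at zero),
the crop is shifted by linear resampling so its intensity centroid sits on
the geometric centre, and crops are averaged then normalized to unit sum.
Sub-voxel centring and border-median background are this module's choices;
with an even crop dimension the geometric centre falls between voxels, so a
half-voxel linear resample slightly broadens the kernel — irrelevant for
deconvolution, but exact-recovery tests use odd crops.

Richardson–Lucy is the standard multiplicative update
`e ← e · (k* ⊛ (d / (k ⊛ e)))` with 20 iterations by default. Every
convolution reflectively pads by one kernel half-width and crops back,
which makes a flat field an exact fixed point, avoids edge ringing, and
conserves total flux of interior sources to <1 % over 20 iterations; the
ratio denominator is floored at 10⁻¹² of the image maximum. Estimates are
clipped at zero each iteration (non-negativity). No blind, Wiener or TV
variants; no GPU path.

## Spot detection and segmentation

**Maxima.** Candidates are voxels at least as bright as all in-bounds
26-neighbours, strictly brighter than at least one (so plateaus and flat
images yield no spurious seeds), and ≥ the intensity threshold. Candidates
are processed in decreasing intensity (ties broken lexicographically on
(z, y, x) for determinism); a candidate is accepted iff the connected
region reachable from it through voxels ≥ (candidate − noise_tolerance)
contains no previously accepted seed. This descending-flood prominence rule
is implemented as a union-find sweep over intensity-sorted voxels
(numba-compiled, near-linear time); the test suite checks it voxel-for-
voxel against a literal per-candidate flood on random stacks. Seed count is
monotonically non-increasing in both threshold and noise tolerance.

**Segmentation.** Per seed, the spherically averaged radial profile (≤30
distance bins, physical distances, up to `max_spot_radius_um`) is fit by
`A·exp(−d²/2σ²) + B` with `B` = median of the profile tail (last quarter of
populated bins) and `A` = seed value − B; the local threshold is
`T = B + A·exp(−sd_value²/2)` — the SD-value isocontour of the fitted
amplitude (default sd_value 2, i.e. the e⁻² contour ≈ a 2σ ball for an
isotropic spot). σ itself only matters for the record; a degenerate fit
falls back to the half-max width. The region is the 26-connected component
of voxels ≥ max(T, global threshold) containing the seed, grown within a
window of half-extent 2×`max_spot_radius_um` per axis (a practical bound;
per-seed and translation-invariant, so tiling is unaffected). Voxels
claimed by several seeds go to the physically nearest seed, ties to the
brighter one; every seed keeps at least its own voxel.

**Measurement.** The 3D ROIs are applied to the *raw* (non-deconvolved)
image: volume = voxel count on the analysis grid, integrated intensity =
total raw value in the region, centroid = intensity-weighted position in
µm. Detection runs on the deconvolved (optionally ×2 laterally upsampled)
image, where the Gaussian model is most valid; the recorded spacing makes
physical volumes recoverable regardless of the grid used. Parameter sweeps
score 3D maxima directly (no upsampling): lateral upsampling refines ROI
boundaries, not peak existence, and the 0.3 µm match tolerance (~4 lateral
voxels) dominates localization.

**Tiling.** Large stacks split into an `nx × ny` XY grid; each tile is
expanded by `tile_margin` voxels, processed independently, and a cluster is
kept iff its *seed* lies in the tile's half-open core `[start, end)` — each
seed owned by exactly one tile, duplicates deleted by construction. With
margins of at least one spot extent (a warning fires otherwise) the stitched
table equals the untiled run record for record.

## Spatial statistics

NND excludes self; mean NND is per sample, and r = 3 × mean NND (the
multiplier is configurable). AZ density counts clusters within r
*including* the cluster itself (so an isolated cluster has density 1);
local intensity is the mean integrated intensity within r, again including
self. No edge correction is applied to boundary clusters — a known,
accepted bias of the measurement convention. Neighbour statistics use a
k-d tree with neighbour lists summed in sorted order, so they equal the
O(n²) brute force bitwise. Nearest-neighbour intensity correlations use
natural logs (Pearson R is base- and scale-invariant, so per-sample mean
normalization changes nothing); intensity-volume correlations are
untransformed; density vs local intensity is untransformed by default with
a log switch. Per-compartment correlations group clusters by the
compartment under their centroid but keep sample-wide r and neighbourhoods
(neighbourhoods do not stop at compartment borders); groups with fewer than
3 clusters or a degenerate margin are reported missing, not zero.

## Detection benchmarking

Detections and truths are matched greedily: all pairs within the tolerance
sorted by distance (ties by detected id, then truth id), accepted when both
endpoints are free. Greedy matching equals maximum-cardinality matching on
small instances (checked exhaustively) and is symmetric in TP count. The
default tolerance is 0.3 µm — about four lateral voxels and under one
axial voxel; the axial voxel (0.37 µm) therefore slightly exceeds the
tolerance, which is the binding constraint on sparse-regime scores.
F = 2PR/(P+R), defined as 0 when P = R = 0.

## Group statistics

Mann–Whitney uses the exact null distribution when the combined sample size
is ≤ 20 without ties, otherwise the tie-corrected normal approximation; two
identical constant samples give p = 1 by convention. Kruskal–Wallis is the
omnibus for ≥3 groups with pairwise Mann–Whitney post hoc under
Benjamini–Hochberg correction (the compact-letter display follows the
insert-and-absorb construction: two groups share a letter iff their
comparison is not rejected). Condition-by-compartment comparisons take
per-sample, per-compartment R values, difference the group *means* (median
is a one-line change), test with Mann–Whitney across samples and correct
across the compartment family at q = 0.05; a Fisher z-transform is
available but off by default, since the test is rank-based and the
difference is descriptive. Under label permutations of a null pool the
familywise false-rejection rate stays at or below the nominal q.

## Problem sizes

The test suite and acceptance script run at desk scale by design: the dense
benchmark uses one 256×256×40 stack (~800 puncta; the tiling and
measurement stages are exercised on smaller stacks), oracle equivalence
uses 100 tables of up to 500 points, parameter-recovery runs operate on the
generator's point-and-mark level (3–6k points per sample, 5 seeds per
condition) without rendering, and permutation nulls use 100 relabelings of
a 23-sample pool. These sizes give stable statistics for every check while
keeping a full run in the minutes range on one CPU.

## Known limitations

* Domains are boxes/tubes with slab compartments; no neurite geometry.
* No sub-voxel spot localization (centroids only) and no watershed or
  learned segmentation alternatives.
* No edge correction in density statistics; boundary clusters are biased
  low.
* Thomas-process density is approximate near domain boundaries (rejection,
  not reflection).
* The density-coupled mark model makes the log-intensity marginal only
  approximately normal when `density_coupling > 0`.
* Richardson–Lucy is run a fixed number of iterations (no stopping rule or
  regularization); at very low SNR it amplifies noise into spurious maxima,
  which the threshold/noise-tolerance sweep must then suppress.
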