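# Methods

`blastoquant` re-implements, as a tested pipeline, the quantitative core of
an analysis of unequal totipotency between the two blastomeres of the 2-cell
mouse embryo: an image-derived eccentricity statistic for mRNA FISH signal,
twin-pair lineage-count ratio statistics, and clustering-based twin-pair
recovery. Because the underlying specimen data are not published as raw
tables, every stage runs against a synthetic-data generator with known
ground truth; this note records the models, the defaults and why, and what
a green test does and does not establish.

## The eccentricity statistic

For an ROI (a blastomere outline, or a circle around a whole embryo or
oocyte) on a 2D projection, let `(x_i, y_i)` be the ROI pixel coordinates
and `w_i` their intensities. The **centroid** is the unweighted mean
position, the **centre of mass** the intensity-weighted mean, and the
eccentricity

    E = sqrt(dx^2 + dy^2),   dx = x_com - x_centroid,  dy = y_com - y_centroid

i.e. the hypotenuse of the right triangle with legs `dx`, `dy`. `E = 0`
for any spatially uniform signal; it grows with inhomogeneity, except for
purely radial inhomogeneity, to which it is blind by construction. Both
sums run over ROI pixels only — background outside the drawn region never
contributes. `E` is reported in pixels and, because the original figure
units are unstated, also normalized by the equivalent ROI radius
`sqrt(area/pi)` (`e_norm`).

Properties the test suite asserts: exact agreement with a per-pixel
summation oracle; invariance under intensity scaling and integer
translation; equivariance under right-angle rotation; strict decrease of
`E` under a constant additive offset (background dilutes the weighted
mean toward the centroid — which is why batches must share one
normalization window).

Coordinate convention: 0-based, x = column rightward, y = row downward,
pixel centres at integer coordinates.

## Imaging pipeline

* **Equatorial MIP.** Stacks are reduced to a maximum-intensity projection
  of 10 slices centred on the equatorial plane. The equator is the slice
  of maximal specimen cross-section (foreground by Otsu threshold on the
  summed channels; ties resolved to the plateau centre). The projection records
  `span_um = n_slices x slice_interval_um`, following the source
  protocol's own arithmetic, although a 10-slice window strictly spans 9
  intervals; the bookkeeping is kept verbatim for comparability.
* **Orientation.** The long axis of the specimen mask (major principal
  axis from second central moments) is rotated parallel to the image
  y-axis; bilinear interpolation; angle reported in (-90, 90]. A mask with
  major/minor axis ratio < 1.02 has no meaningful long axis: angle 0, with
  a warning.
* **ROIs.** Three modes: `ground_truth` (generator masks pass through, for
  oracle work), `segment`, and `circle_fit`. Segmentation must cope with
  punctate FISH signal, so each channel is Gaussian-smoothed (sigma 4 px),
  scaled by its 99.5th percentile, combined by pixelwise max with DAPI,
  thresholded with Li's method, hole-filled, and eroded by 0.75 sigma to
  undo the blur-induced boundary dilation (calibrated once against
  generator masks across geometries; residual area error ~2% at realistic
  cell radii, up to ~6% for very small cells). Touching blastomeres are
  split by a two-marker watershed on the distance transform; anything
  other than exactly two components for a 2-cell image is an error.
* **Normalization.** One shared (low, high) window — given, or the batch-
  global 0.1/99.9 percentiles — is applied to every projection in a batch,
  mirroring the "identical contrast and brightness" convention. A constant
  batch maps to 0 with a warning.

## Group comparison

Eccentricity groups are independent specimens, so the default test is the
two-sided Mann–Whitney rank-sum. For combined n <= 25 the permutation
distribution of the rank sum is enumerated exactly by dynamic programming
(midranks doubled to stay integral; the distribution is symmetric, so the
two-sided p is the mass at least as far from the mean as observed);
otherwise the normal approximation with tie correction (scipy) is used.
A signed-rank variant is available behind `paired=True` for within-embryo
pairings.

## Synthetic confocal stacks

The simulator emulates post-deconvolution Airyscan-like two-channel
(FISH + DAPI) stacks: 512x512 px slices, 0.22 um slice interval, 0.18
um/px, a thin slab of 25 slices through the equator of spherical cells
(two tangent r = 110 px blastomeres, or one r = 140 px oocyte). Slice k of
a cell is a disc of radius `sqrt(R^2 - dz_k^2)`, so the equatorial slice
has the largest cross-section and the equator-finding heuristic is
exercised for real.

FISH spots are sampled from one of four in-plane density families over the
cell disc (strength `g` in [0, 1]):

| family | density | expected COM offset |
|---|---|---|
| uniform | constant | 0 |
| gradient | `1 + g u / r` along a seeded random direction | `g r / 4` |
| cortical | Gaussian shell at 0.85 r (width 0.08 r) | 0 (radial) |
| polarized_cap | von Mises `exp(kappa cos(theta))`, kappa = 5 g | `(2r/3) I1(kappa)/I0(kappa)` |

The axial coordinate is uniform over the sphere chord at the sampled
in-plane position, so the in-plane marginal of the spot cloud is exactly
the stated 2D family and the closed-form offsets above are the ground
truth the measured E must recover. Spots are rendered as in-plane
Gaussians (sigma 1 px) on their nearest slice with a Gaussian amplitude
falloff over +/-2 neighbouring slices; Poisson shot noise and Gaussian
read noise are applied per voxel.

Default photometry (peak amplitude 500, background 2, read noise 1) puts
the render in the bright-spot/near-zero-background regime of deconvolved
Airyscan data. This matters for validity, not cosmetics: a maximum — not
sum — projection saturates where spot columns overlap, and residual
background dilutes the weighted COM, both of which bias measured E
downward. At the default density the remaining relative bias is ~5-8% of
the analytic offset at g = 0.8, within the spot-sampling noise band. The
recovery tests therefore compare measured E against the analytic offset
at 3 sampling SEs, where the SE uses the number of spots actually inside
the projection window (`GroundTruth.sampling_se`) — the projection never
sees the rest — and take the median of three seeds per grid point so a
single unlucky draw cannot dominate.

Replicate-heavy studies (the rank-sum power/null suite) run on scaled-down
stacks. Because the MIP's saturation bias grows with the spot **coverage
fraction** `n_window * pi (2 sigma)^2 / (pi r^2)`, a faithful scale-down
preserves that dimensionless number, not the absolute spot count: 128x128
px, r = 40, PSF sigma 0.6 px, 195 spots reproduces the ~0.16 coverage of
the full-size defaults. Scaling down naively (same spot count, smaller
cell) triples the coverage and makes measured E depend on spot count,
which would spuriously break the count-insensitivity of the statistic.

Controls: `rnase_mode` zeroes all specific signal (hybridization-after-
RNase emulation: FISH channel is background only); `injected_cell_factor`
multiplies one blastomere's expected spot count (mRNA micro-injection
emulation). What the generator does **not** model: optical sectioning
physics, deconvolution artefacts, chromatic shift, autofluorescence
texture, or any specific transcript's true spatial form — the density
families are minimal shapes spanning the qualitative patterns, not a
claim about the real distribution. A green recovery test establishes that
the measurement pipeline is calibrated against its own stated world, not
that real FISH images obey these densities.

## Twin-pair lineage counts

Each pair draws a reconstituted total `T ~ round(Normal(mu_total=100,
sigma_total=15))`, truncated at 2 — "the sum of the two halves equals an
intact blastocyst" is built in, and a t-test convenience wrapper
(`half_sum_vs_intact`) checks it against intact controls generated at the
same `mu_total`. Mean lineage fractions (TE, PE, EPI) = (0.70, 0.17,
0.13), giving ~50-cell members with ~6-7 EPI cells each, matching the
scale at which the >= 4 EPI threshold is meaningful. Member counts are
`round(T f s)` and `round(T f (1-s))` with a per-layer split fraction `s`:

* EPI: `s ~ Beta(a, a)` with `a = 1/beta`; `beta = 0` is the exactly
  balanced limit (every ratio exactly 1 at zero noise — the rounding
  construction guarantees it).
* PE: follows the EPI split with Normal(0, 0.03) jitter (PE formation
  depends on FGF4 from the EPI, so their imbalances are coupled).
* TE: independent `Normal(0.5, 0.04)` — tight, first-lineage-decision
  balance.

The default `beta = 0.5` (i.e. Beta(2, 2)) was calibrated once by Monte
Carlo at n_pairs = 1000, as the stated procedure prescribes: it gives a
median EPI `C_high/C_low` ratio of 2.0 while the median TE ratio stays at
~1.12 (< 1.2). Pairs in which the lower count is 0 are flagged unbounded
(both-zero: undefined) and excluded from medians but tallied — the
convention for "no or too few EPI cells" members.

## Expression matrices and pair recovery

Log-normal model: gene g, pair j, member m has
`log x = b_g + u_gj + e_gjm`, with gene baseline `b_g ~ Normal(6, 1)`,
shared pair effect `u ~ Normal(0, 0.25)` and member deviation
`e ~ Normal(0, 0.3)`. The within-pair SD default (0.3, comparable to the
pair effect) is chosen so that hierarchical clustering of 9 default pairs
recovers only part of them — the partial-recovery regime observed for
real blastomere pairs — rather than all or none. Genes in `high_cv_genes`
get 10x within-pair SD, emulating transcripts with strong
blastomere-to-blastomere variability; such a gene tops the CV ranking of
interblastomere ratios (higher/lower, per pair; CV = sample SD / mean of
the finite ratios) in >= 95% of seeds.

**Pair recovery** is defined on the dendrogram: a pair is recovered iff
its two members merge with each other before either merges with anything
else (a leaf–leaf merge in the linkage record). The original analysis
names neither distance nor linkage, so the recovery definition — not the
metric — carries the meaning; defaults are Euclidean distance on
per-feature z-scores with average linkage for count vectors, and
(1 - Pearson) with average linkage for expression matrices, both
configurable. `recovery_null` gives the chance-level reference by
clustering i.i.d. Gaussian samples (a single pair is trivially always
recovered). Identical samples in different pairs make siblinghood
tie-break dependent; scipy's merge order is deterministic, and a warning
is emitted.

## Pair outcome accounting and tests

`pair_outcomes` tallies complete / singleton / neither pairs from per-pair
boolean endpoints; the singleton percentage is computed among represented
pairs (complete + singleton) only. The allocation test is the two-sided
Fisher exact test (scipy; the test suite checks it against exhaustive
hypergeometric enumeration). `survival_summary` reports the pooled
percentage rounded to one decimal — note that pooled ratios can differ
from published replicate-mean rates when replicate sizes are unknown.

## Numerical and degenerate-input conventions

* Zero total intensity inside an ROI is an error, deliberately distinct
  from E = 0.
* Exact rank-sum p-values switch to the normal approximation above
  combined n = 25 (DP table size, and the exact tail is no longer needed
  there).
* Constant normalization batches map to 0 with a warning; explicitly
  supplied inverted bounds are an error.
* CV ranking ties are broken by input gene order; NaN CVs rank last.
* All generators take integer seeds and are bit-reproducible.

## Known limitations

* Measured E is a mildly biased (low) estimator of the density COM offset
  under a maximum-intensity projection; the bias grows with spot density
  and background. The defaults keep it within the sampling band, but
  quantitative use at much higher densities would need a sum projection
  or explicit correction.
* The 2-cell segmentation assumes roughly circular, touching blastomeres
  in a single plane; it is not a general embryo segmenter.
* The count model ties PE to EPI by a fixed jitter rather than an explicit
  FGF4 mechanism; only the ratio structure, not lineage dynamics, is
  modelled.
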