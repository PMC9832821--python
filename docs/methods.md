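# Methods

This note documents the models, conventions, parameter defaults, and design
choices behind `q3d`, and what the synthetic-data validation does and does
not demonstrate about real light-sheet data.

## Coordinate conventions

One convention is used repo-wide: 0-based voxel indices; voxel `i` along an
axis with spacing `s` covers the half-open world interval `[i·s, (i+1)·s)`
μm, with the voxel center at `(i+0.5)·s`; the world origin sits at the grid
corner. A point whose coordinate is exactly on a voxel boundary belongs to
the higher-index voxel. The acquisition grid defaults to 3.26 × 3.26 × 3.0
μm (anisotropic light-sheet voxels); the atlas grid is isotropic at 25 μm.
Plaque volumes are carried through registration unscaled (no Jacobian
correction); the spherical smoothing kernel (below) is the mechanism that
absorbs registration-quality variation.

## Segmentation

Voxel classification is driven by the hFTAA (565–605 nm) channel, which
stains whole plaques; the qFTAA (498–520 nm) channel is only read out at
measurement time. Two classifiers implement one surface:

- `ThresholdClassifier` — plaque where intensity exceeds a scalar threshold.
- `RandomForestVoxelClassifier` — scikit-learn random forest over a minimal
  per-voxel feature stack: raw intensity plus Gaussian-smoothed intensity at
  σ = 1 and 2 voxels (edge-padded). Training labels come from synthetic
  fixtures with known plaque support, not manual annotation.

Connected components default to 26-connectivity (plaques are compact blobs;
6 and 18 are available). Components with volume below a global noise floor
are dropped; the default floor is **200 μm³** (~6 acquisition voxels, well
below any plausible plaque) — the threshold is a free config parameter, as
no canonical value exists. The filter is applied before any intensity
lookup. Per surviving component: volume = voxel count × voxel volume
(3.26 × 3.26 × 3.0 = 31.88 μm³ per acquisition voxel), center of mass =
mean of member voxel centers, and per-channel peak intensity. Peak lookup
defaults to the maximum within the component mask for both channels
(robust to the center of mass falling in a hollow plaque core); reading the
voxel nearest the center of mass is available as `at_center_voxel`.
Maturity = peak_q / peak_h; components with a non-positive hFTAA peak keep
their count and size but are flagged and excluded from maturity means.

## Atlas mapping

Downsampling to the atlas grid assigns each source voxel to the target
voxel containing its center and averages; this reduces exactly to a block
mean for integer spacing ratios and remains well defined for the
non-integer 3.26 → 25 μm ratio. The output grid ends at the target voxel
holding the last source voxel center, so every output voxel averages at
least one source voxel (the world extent is preserved to within one target
voxel).

Spatial transforms are *inputs* (identity for synthetic cohorts): a 4 × 4
affine on μm coordinates followed by optional trilinear interpolation of a
dense displacement field sampled at atlas voxel centers. Points mapping
outside the displacement domain are flagged and excluded downstream with a
logged count — how out-of-atlas plaques were originally handled is not
documented, so exclusion-with-count is the package's choice. Region
assignment is a floor-divide lookup into the labeled atlas volume.

## Voxel statistics

Per brain and metric — plaque count, mean plaque volume, mean maturity —
values are binned onto the atlas grid. Mean maps are undefined (NaN) where
no plaque (or, for maturity, no ratio-defined plaque) falls.

**Smoothing.** A spherical ROI of 15-voxel diameter (375 μm; all 1,791
integer offsets with center distance ≤ 7.5 voxels) is placed at every
voxel. Count maps are ROI *sums*, truncated at the volume boundary
(zero-padded convolution, computed by FFT). Mean maps are plaque-weighted
ROI means — Σ(metric × count)/Σ(count) — rather than voxel-averaged means,
so the smoothed value remains a true mean over the plaques in the ROI; this
extension beyond count-summing is a package choice. All three metrics are
smoothed before testing.

**Testing.** Per voxel, a two-sided t-test between treated and control
brains; Welch (unequal variance) by default with a pooled-variance option.
A voxel is tested when each group has ≥ 2 finite values and the groups are
not jointly constant; undefined voxels are excluded from the family rather
than assigned p = 1, so they do not dilute the FDR correction. BH step-up
adjustment (statsmodels) runs over the tested voxels of one metric × one
cohort comparison. SAV maps are `p_adj < α` with α ∈ {0.05, 0.10}; the
α = 0.05 set is nested in the α = 0.10 set by construction.

Region-level statistics aggregate per brain and region: density = count /
region volume (plaques per mm³), means over plaques; Welch t-tests across
groups per region, with both raw and BH-adjusted p-values reported per
metric family (the appropriate multiple-testing family across anatomical
regions is a reporting choice, flagged in the output metadata).

## Colocalization

Overlap between two SAV maps within the brain mask is tested against the
hypergeometric null: intersection of independently placed fixed-size voxel
sets. The tail is summed in log space from `gammaln` terms over whichever
tail is shorter (complementing when needed), so populations of ~3 × 10⁷
voxels never enter a factorial; the implementation matches an exhaustive
binomial-coefficient enumeration for all parameter choices with N ≤ 25 and
scipy's `hypergeom` at scale. Because distinct treatment fingerprints
*deplete* overlap, the depletion tail P(X ≤ k) is the headline statistic;
both tails are always reported, along with the overlap normalized three
ways (by the smaller set, the union, and the population — no single
denominator is canonical).

SAV clustering is tested against a Monte-Carlo null: 500 simulations (the
published count) each scatter |SAV| voxels uniformly without replacement
over the brain mask — "unconstrained spatial distribution" is read as
uniform over valid tissue voxels, not the bounding box — and count
connected components. SAV component connectivity defaults to 6
(face-adjacency, the conservative reading of "touching"; 26 available).
fold = mean(null)/observed ≫ 1 indicates spatially confined clusters; an
empty SAV map yields a flagged, undefined fold.

## Expression similarity

Expression spots are assigned to containing voxels (half-open rule) and
averaged within voxels; all comparisons are restricted to spot-covered
voxels, since the atlas does not sample every voxel. Expression is
discretized into quantile bins over covered voxels — default 2 (median
split), the minimal faithful treatment of both inputs as discrete data;
the bin count is configurable. MI is the plug-in estimate in nats.
Normalized MI divides by √(H(SAV)·H(expr)); this normalization is a
declared package choice, as is the convention that constant expression
carries MI = 0 (flagged degenerate). Ranking percentile = 100 × (#genes
with strictly smaller MI)/n_genes, ties sharing a percentile, so a unique
maximum among 100 genes ranks at 99.0. No numeric comparison against
published per-gene MI magnitudes is attempted: those require the original
SAV maps and the external transcriptomics resource.

## Synthetic data

The generators define the validation conditions:

- **Phantoms** render plaques as uniform-intensity spheres with Gaussian
  edge blur (σ = 1 acquisition voxel by default) over constant background
  with additive Gaussian noise. Plaque radii are log-normal (median 8 μm,
  log-σ 0.35 by default) — no canonical size law exists, so this is a
  modeling choice. Maturity varies linearly along a spatial axis (default
  base 0.45, gradient 0.3 per normalized z), emulating spatially varying
  plaque age. hFTAA peaks are log-normal around 1000 (CV 15%) over
  background 100; the ground-truth table of a rendered brain records
  background-inclusive peaks, i.e. exactly what a perfect measurement of
  the image returns. Minimum center separation 1.5 × (rᵢ + rⱼ) keeps
  components unambiguous; exact-recovery tests use 3× and σ_edge = 0,
  because the half-max isosurface of a blurred digital sphere falls
  slightly inside its lattice support (measured ~30–45 voxel mismatch at
  radii 3–7 voxels), making blurred volumes inherently approximate.
- **Cohorts** draw per-brain plaque counts with a log-normal multiplicative
  factor (default CV 5%), and plant multiplicative effects inside spherical
  atlas regions for treated brains only: count effects thin plaques
  (keep-probability = factor), size effects scale radii (volume scales as
  the cube), maturity effects scale the qFTAA peak. Statistics-stage
  cohorts skip image rendering and work from ground-truth tables directly
  (separation is irrelevant when nothing is segmented); this is what makes
  5-vs-5 studies over ~5,000 plaques/brain run in seconds.
- **Expression atlases** place spots at mask voxel centers; planted genes
  have Poisson rates increasing monotonically with the Gaussian-smoothed
  local density of a reference map, other genes are spatially unstructured,
  with optional gamma-Poisson overdispersion (default 0.1). The default
  scale — 500 genes × 2,000 spots — is a deliberate scale-down of the
  ~23k-gene × ~34k-location resource the real analysis used.

All generators are bit-reproducible given (spec, seed); seeds flow through
`numpy.random.SeedSequence` spawning.

**What passing tests show — and don't.** The phantoms validate the
*mechanics*: exact component recovery, correct measurement arithmetic,
calibrated voxel tests, FDR control, exact tail probabilities, and the
ability to recover planted regiospecific effects at realistic cohort sizes.
They do not emulate vasculature, diffuse amyloid, irregular plaque
morphology, clearing/staining artifacts, stitching seams, or registration
error, so classifier performance on phantoms does not predict performance
on real acquisitions, and the planted-effect recovery rates are not
sensitivity claims about real studies.

## Validation problem sizes and numerical notes

Cohort statistics run on a 65 × 65 × 48 atlas window (5 vs 5 brains,
~5,000 plaques per brain, 15-voxel kernel); the clustering bound uses one
~10,000-voxel sphere in a 200³ mask with the full 500 simulations; oracle
checks cover 1,000 random p-vectors (BH), all hypergeometric parameters
with N ≤ 25, and brute-force flood fill / block-mean / binning oracles for
the array operations. In the planted-effect recovery check, the
false-positive region is defined *beyond* the effect sphere dilated by the
kernel radius: voxels within one kernel radius of the effect genuinely
differ between groups (their ROI overlaps the effect), so the null only
holds outside the dilated sphere.

FFT-based smoothing introduces ~1e-10 relative error; counts are clipped
at zero, and weight denominators are compared against 0.5 (weights are
integer-valued counts) before division. Rendered channels are float32, so
measured peak ratios agree with ground truth to ~1e-7 relative. The t-test
excludes rather than imputes degenerate voxels; BH is computed only over
the tested family.

## Known limitations

- Count effects support thinning (factor ≤ 1) only; count inflation would
  require post-hoc placement and is not implemented.
- The Monte-Carlo null is uniform placement; spatial-autocorrelation-
  preserving nulls are out of scope by design.
- The random-forest feature bank is minimal (3 features); it is a stand-in
  for a full interactive feature stack, adequate for phantom SNR ≥ 10.
- Displacement-field inversion is not implemented (affine round-trips only).
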