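# Methods

This note records the models, conventions and numerical choices behind
`melissoscope`, and what the synthetic experiments do and do not
demonstrate about real micrographs.

## Statistics book

`melissoscope.book` holds the published per-taxon marginal statistics
(mean, SD) of the 30 descriptors for 7 taxa × 3 modalities.  These
numbers parameterize everything downstream: phantom geometry, phantom
colour, and the feature-mode sampler.  One entry is derived rather than
published: the spread of the per-grain optical-density SD
(`density_variation`) has no tabulated value, so it is reconstructed by
the delta method from the intensity statistics,
sd(OD) ≈ IV / (MI · ln 10), where IV is the intensity variation and MI
the mean intensity.  The exine sculpture class per taxon (echinate,
striate, psilate, reticulate, micro-reticulate) is part of the book.

## Phantom generator

**Grain geometry.**  A grain is an ellipse in polar form
r(θ) = ab / √((b cos θ′)² + (a sin θ′)²) with the major axis 2a drawn
from Normal(length mean, length SD) truncated at > 2 µm and the axis
ratio from Normal(elongation mean, SD) truncated at ≥ 1, random
orientation, rasterized by polygon fill over 2048 boundary samples.
Exine modulation: echinate adds 24 sharp radial spines of height 2 µm
(cos⁴⁰ bumps); striate / reticulate / micro-reticulate add a sinusoidal
boundary ripple of 0.30 / 0.20 / 0.12 µm at frequency 10 / 16 / 24;
psilate adds nothing.  These geometric constants are fixed by
configuration and were chosen to reproduce ordering relations (echinate
grains have the longest perimeter and the lowest 2D roughness), not to
match texture statistics quantitatively.  Grains whose minor axis spans
fewer than 20 px are rejected as a sizing error.  Default pixel size is
0.16 µm/px (typical sampling for a 40× objective), giving grains of
roughly 110–400 px.

**Height field.**  Each grain carries a cone in the normalized interior
distance dn (Euclidean distance transform over its maximum):
h = 3·z̄·dn, where z̄ is the taxon's published mean EDF-Z.  The mean of
dn over a disc is 1/3, so the baseline-referenced mean height over the
grain matches z̄ by construction, and the height stays below one plane
spacing in a wide band along the rim — which keeps rim pixels assigned
to the bottom focal plane, where the unblurred colours live.  Echinate
grains additionally get ~40 raised apices (+2 × spine height) on a ring
at mid-radius; these drive the "spines sit higher in the Z-map"
property.

**Rendering.**  The all-in-focus image is composed first: a per-modality
background (BF bright, DF near-black, Ph mid-grey), grain interiors
drawn per pixel from Normal(published RGB means, √3 × intensity
variation per channel), and a 3 px rim halo for DF and Ph.  Interior
colours are clipped into the modality's segmentation threshold box by
default, so the published segmentation settings succeed on synthetic
fields (the original workflow needed manual outline corrections, which
the generator sidesteps); unclipped colours are available via
`SceneConfig(clip_colours=False)` for robustness testing.  Plane k of
the stack shows each pixel Gaussian-blurred with
σ = defocus_sigma_per_µm × |z_k − z_pixel| (default 0.3 px/µm),
implemented by compositing one blurred copy per defocus level.  Because
a threshold box is a convex set and Gaussian blur is a convex
combination, interior-with-interior mixing cannot push pixels out of the
box; only the rim band can, and the cone relief keeps that band in
focus.  Grains are placed largest-first by rejection sampling with a
3 px exclusion margin; overlapping and touching grains are out of scope.

**Feature-mode sampler.**  `sample_feature_table` draws each descriptor
independently from Normal(mean, SD) per taxon, truncating size-like
descriptors at > 0.  Independence is forced by the data situation — only
marginal moments are published, no covariances — and it matters for
interpretation: real descriptors are strongly correlated within a taxon
(Area with Length with Volume …), so the synthetic classification
problem is *easier* than the real one.  Classification rates measured on
sampled tables are therefore a favourable surrogate, not a reproduction;
they show the statistical chain is implemented correctly and that the
published per-taxon separations are more than sufficient for the
reported rates, nothing more.

## Measurement conventions

Several descriptor definitions are not uniquely pinned down by standard
usage; the package fixes them as follows, each cross-checked for
consistency against the published per-taxon tables.

- **Calipers.**  Feret extents are computed on the convex hull of
  boundary-pixel corners (a pixel is a unit square), so an axis-aligned
  100 px square has MinFeret exactly 100.  The angular scan is refined
  with the exact critical directions (antipodal vertex pair for
  MaxFeret, edge support lines for MinFeret), making the extents exact.
  MaxFeret90 is the extent perpendicular to the MaxFeret direction.
- **Length, Width, Elongation.**  Length = MaxFeret;
  Elongation = MaxFeret/MinFeret; Width = Area/Length.  These are the
  readings that reproduce the published Width and Elongation values from
  the published Area/Length/Feret columns (e.g. bright-field *Brassica*:
  424.08/25.36 = 16.72 vs tabulated 16.69).
- **Perimeter and roughness.**  The perimeter is the polygonal length of
  the marching-squares iso-contour after a 7-point circular moving
  average; the smoothing removes the half-pixel staircase (a digital
  disc then measures within ~0.5% of πd, and its circularity within
  [0.98, 1.02]).  The convex hull is taken of the same smoothed polygon,
  so Roughness = hull perimeter / perimeter is structurally ≤ 1.
  Shape Factor uses the hull perimeter (4πA/P_hull²), the only variant
  consistent with Shape Factor ≥ Circularity across the published rows.
- **Mean Chord.**  Mean foreground run length of scan lines at 0°, 45°,
  90° and 135° (diagonal runs weighted by √2 px), averaged over the four
  directions; for a disc this converges to (π/4)·d.
- **Volumes.**  The equivalent cylinder is a capsule (spherocylinder)
  with diameter Width and total length Length; at Length = Width it
  degenerates exactly to the equivalent sphere.  A measured
  Length < Width is clamped with a warning.  Sample means of these
  nonlinear transforms are compared to published means only within a
  Jensen-gap tolerance of 2%.
- **Colour.**  mean intensity = per-pixel (R+G+B)/3 averaged; brightness
  and its variation are the intensity statistics × 100/255 (exact
  identities); hue is the peak 1° bin of the HSV hue histogram and hue
  variation the circular SD √(−2 ln R̄) in degrees; optical density uses
  a white reference of 255, OD = −log₁₀(max(I, 1)/255) per pixel.
- **EDF surface.**  Pixel-cell triangulation: corner heights are the
  mean of the adjacent in-mask pixel-centre heights, each ps×ps cell
  contributes two triangles.  A flat field yields exactly the
  planimetric area and every cell contributes at least ps², so
  EDF Roughness ≥ 1 with equality iff flat.  The corner rule introduces
  an O(1/n) boundary bias on tilted fields (≈1% on a 60-px ramp).  The
  symbols of the original two-triangle formula are not publicly defined;
  this triangulation is the package's reading of that structure and is a
  stand-in.  Likewise the mean EDF-Z baseline — the minimum height over
  the grain — is chosen because object-relative height is the only
  meaning consistent with per-taxon values of 5–20 µm inside a 32 µm
  stack; absolute stage position carries no information across fields.
- **Focus stacking.**  Variance of the Laplacian of luminance in a 9 px
  window (the proprietary reconstruction used originally is not
  documented); ties in the per-pixel argmax go to the lower plane;
  optional 3×3 median smoothing of the plane-index map (default on)
  suppresses isolated misfocus pixels.

## Segmentation settings

Per-modality defaults follow the published settings table: BF uses
thresholding only (box (85,80,62)–(130,122,98) inclusive, logical AND
over channels); DF adds contour smoothing (size 16) and 6 iterations of
3×3 opening; Ph adds small-object cleaning (16 px, read as area) and 3
iterations of 3×3 opening.  The proprietary "object smoothing filter"
semantics are unpublished; it is implemented as closing-then-opening
with a disc of half the stated size, a stand-in.  Components touching
the field border are excluded by default (a clipped grain has invalid
descriptors).  Segmentation operates on the EDF composite.

## Statistical chain

Tukey HSD p-values come from the studentized range with the
Tukey–Kramer adjustment for unequal group sizes; the compact letter
display uses the insert-and-absorb algorithm, with letters ordered by
descending group mean.  Factor analysis is the eigendecomposition of the
correlation matrix of the standardized descriptors, no rotation;
eigenvector signs are fixed (largest-magnitude component positive) for
determinism.  The retention rule keeps factors with eigenvalue > 1 plus
every factor holding some variable's maximum squared loading.  The
discriminant analysis feeds the *standardized* retained factor scores
(score/√eigenvalue) to the S_w⁻¹S_b eigenproblem, solved as a
generalized symmetric eigenproblem on the scatter matrices with a ridge
of 10⁻⁸·trace if S_w is singular; at most min(q, k−1) axes with
eigenvalue > 10⁻¹⁰ are kept and rescaled to unit pooled within-class
variance, which makes nearest-centroid Euclidean assignment equal to the
standard discriminant rule.  Ties go to the lexicographically first
label.  CCR is resubstitution by default — the original report gives a
single rate with no mention of held-out data — with k-fold
cross-validation available behind a flag, refitting the whole
standardize→FA→retain→LDA chain per fold.

## Problem sizes and determinism

The acceptance script uses 500 rasterized masks per geometry target and
300 sampled vectors per taxon for the classification surrogates; the
test suite uses 300 masks and smaller tables.  These sizes put the
Monte-Carlo standard error of each recovered mean well inside the
stated comparison tolerances (2–3%).  All randomness flows from a
single seed through named `SeedSequence` substreams, so every run —
masks, rendered stacks, sampled tables, reports — is bit-reproducible.

## Known limitations

- Phantoms are not photorealistic: Gaussian defocus instead of a real
  PSF, no chromatic effects, no overlapping or touching grains, no
  apertures/colpi (aperture detection is explicitly out of scope).
- The feature-mode sampler ignores descriptor covariances (see above);
  image-mode fields are small and class-balanced, unlike real slides.
- Published values quantize relief at the 8 µm plane spacing; sub-plane
  depth interpolation is out of scope.
- The compact-letter display is not unique in degenerate cases
  (non-transitive significance patterns); the implementation is
  deterministic but other valid letterings exist.
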