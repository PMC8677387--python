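# Methods

This note documents the models and numerical choices behind `liverseg`,
the defaults that matter, what the synthetic phantoms do and do not
emulate, and known limitations.

## Geometry conventions

Volumes are axis-aligned 3D arrays indexed `data[x, y, z]`; physical
position = `origin + index · spacing` (mm). Direction cosines are not
supported. Masks are strict {0, 1} grids on the same geometry. All
surfaces in the package are 6-neighbour digital surfaces: a foreground
voxel belongs to the surface iff a face neighbour (or the volume
exterior) is background — the thinnest closed digital surface.

## Landmark registration

The deformation between training and target is fitted from paired
points alone (no intensity optimization): a least-squares affine
transform absorbs the global trend, and the residual displacements are
interpolated by a tensor-product cubic B-spline on a uniform control
grid (`control_spacing`, default 32 mm). With zero regularization the
spline interpolates the residuals exactly (minimum-norm least squares);
`regularization_weight` λ adds a ridge penalty ‖c‖² on the spline
coefficients, trading landmark fidelity for smaller corrections. The
affine stage is what makes identity pairs produce an exactly zero field
and pure translations an exactly constant field; a landmark-free
B-spline fit would decay between landmarks instead.

The field uses the pull-back convention: the displacement stored at a
target-grid point maps it into the moving (training) image, so warping
is a single resampling pass (`linear` for intensities, `nearest` for
masks — linear interpolation of a mask is rejected because it would
break binarity).

## Gabor patch features

A bank of real, even-symmetric (cosine-phase) Gabor kernels is built
per volume: `n_orientations` evenly spaced in [0°, 180°) ×
`n_scales` wavelengths (defaults 6 × (3, 4, 6, 8) mm, Gaussian envelope
σ = 0.5 λ, kernel radius 8 voxels). Each kernel is DC-corrected to zero
mean and scaled to unit L2 norm, which makes the features exactly
invariant to intensity offsets. Feature entry *j* of a patch is the
mean of |response of kernel *j*| over the in-plane patch window
(default 9 × 9) on the axial slice containing the patch centre; the
default bank yields a 24-vector. Filtering is done once per volume
(per-slice FFT convolution with reflect padding) and mean-pooled with a
uniform filter, which away from the volume border is identical to
filtering each patch separately.

Magnitude pooling makes the features insensitive to contrast polarity
and approximately translation-invariant within the window — useful for
texture matching, but it also bounds how precisely a patch can be
localized across its own width (see Limitations).

## Dictionary learning and the boundary score

Patch features from `N` (default 500) centres sampled uniformly without
replacement on the training gold surface train an overcomplete
dictionary by K-SVD (`t` atoms, sparsity `T0`, ≤ 30 iterations, early
stop at relative objective change < 1e-6):

- sparse coding by OMP — greedy selection of the atom most correlated
  with the residual, ties broken toward the lowest atom index,
  least-squares re-fit on the support each step;
- per-atom update by rank-1 SVD of the residual matrix restricted to
  the samples using that atom (sign fixed by the largest component of
  the left singular vector, for determinism);
- atoms unused in an iteration are replaced by the worst-reconstructed
  training sample, renormalized.

The recorded objective ‖Y − DX‖²_F is non-increasing across
iterations. All randomness (initial dictionary = random subset of
training columns) derives from the config seed.

A test patch's boundary score is the residual of its best `T0`-sparse
approximation, `L(y) = ‖y − D·OMP(D, y, T0)‖₂`.

Two design choices depart from common K-SVD practice and matter a lot:

1. **Features are L2-normalized** before training and scoring (columns
   with norm < 1e-9 are zeroed as textureless). The raw residual has a
   trivial attractor: the zero code is always feasible, so
   `L(y) ≤ ‖y‖` and weakly textured patches score low no matter how
   unlike the boundary they look. On phantoms this measurably drags
   selections into flat regions; unit-norm (cosine-style) matching
   scores texture signature instead of energy and removes the
   attractor. `normalize=False` restores the raw residual.
2. **The pipeline codes with `T0 = 1`** (`KSVDConfig` itself defaults
   to the conventional `t = 64`, `T0 = 4`). With m = 24 and t ≫ m, an
   OMP budget of 4 atoms reconstructs almost *any* feature vector
   well, flattening the score landscape; nearest-atom matching keeps
   the dictionary selective for boundary-like signatures. Measured on
   the default phantom, the fraction of selected points within 2
   voxels of the true surface rises from ~68 % (raw features, T0 = 4)
   to ~95 % (normalized, T0 = 1).

## Candidate generation and selection

Each prior-boundary vertex `v` generates candidates `v ± k·e_axis`,
k = 1..radius (default 5), per axis — up to 30 points, clipped to the
volume. Per vertex, the candidate with the smallest reconstruction
error is kept (candidates whose patch crosses the volume border are
dropped and counted; numerically tied errors, within 1e-12, resolve to
the lowest (z, y, x) centre). The output is the deduplicated union
over vertices — one point per vertex, not a global top-K, so coverage
follows the prior surface.

## Void filling

The predicted cloud is repaired into a watertight surface and solid:

1. **Voxelize** the points and dilate by a small ball (`dilation`
   default 1 L1 ball = 7 voxels for a single point; `ball="euclidean"`
   seals diagonal gaps of the same radius).
2. **Octree scan-conversion** over the smallest power-of-two cube
   covering the volume: nodes intersecting the shell subdivide until
   max depth (leaf ≈ 1 voxel), homogeneous empty regions stay coarse.
   Occupancy queries use a summed-area table.
3. **Parity labelling** of the finest-leaf centres: along each of the
   six axis-parallel directions from the border, a corner's label flips
   once per maximal shell run crossed; the six votes are combined by
   majority (a closed shell is unanimous and provably matches an
   exterior flood fill, which the tests assert; open shells and
   tangent rays produce logged conflicts). A final exterior flood fill
   absorbs any surviving cavity, so the labelled solid is cavity-free
   by construction.
4. **Dual contouring** of the 0/1 field: one vertex per dual cell
   (2 × 2 × 2 block of leaf centres) crossed by the interface, placed
   at the centroid of the cell's sign-change edge midpoints; one quad
   per sign-change edge, wound so normals point outward. The label
   field is first made *well-composed* (2 × 2 checkerboard faces
   repaired by growing the solid) because diagonal label patterns pinch
   the dual surface into edges shared by four faces; with the repair,
   every mesh edge is shared by exactly two faces and `trimesh`
   verifies watertightness. A one-voxel zero pad closes solids that
   touch the volume border.

Because the dilation thickens the crust, the solid is eroded back by
the same ball after labelling. The pipeline (not the bare `fill_voids`)
additionally:

- seals with a Euclidean ball of radius 5 — selected clouds carry
  voxel-scale scatter and occasional stragglers, and pinholes anywhere
  let the exterior flood fill erase the interior entirely;
- **recenters** the surface by eroding the sealed solid by the median
  depth of the input points inside it — the closing's boundary follows
  the crust's *outer* envelope (observed +9 % volume bias on phantoms;
  −1 % after recentring). The correction is computed from the point
  cloud itself, not from any reference mask;
- smooths the binary solid (Gaussian σ = 1.5 voxels, rethreshold at
  0.5) to remove the voxel-scale jitter inherited from per-vertex
  picks, in keeping with the goal of a smooth boundary.

`prune_redundant_points` drops points farther than `delta` (default
2 mm) from the reconstructed surface; distances are measured to the
mesh vertex set, which over-estimates the true surface distance by at
most about half an edge length (sub-voxel).

## Evaluation metrics

For segmentation A vs gold B on one grid: VOE = 100·(1 − |A∩B|/|A∪B|);
RVD = 100·(|A| − |B|)/|B| (signed; a flag gives |RVD|); ASSD, RMSSSD
and MSSD are the mean, root-mean-square and maximum over the pooled
set of nearest-surface distances computed in both directions between
the 6-neighbour surface voxel sets, in physical mm (KD-tree queries,
exact to 1e-9 vs an O(n²) oracle in the tests). MSSD is the unsquared
maximum (the symmetric Hausdorff distance between surface voxel sets).
Aggregation across cases reports the arithmetic mean ± sample (n−1)
standard deviation per metric.

## Synthetic phantoms

`make_phantom_pair` builds a training/target pair with full ground
truth: a superellipsoid organ (default radii (34, 30, 26) voxels in a
96³, 1 mm grid; exponent 2.5) over a flat background with +100
intensity contrast. The boundary carries a concentric-ring texture
(wavelength 4 voxels, Gaussian half-width 2, amplitude 50) — locally an
oriented grating tangent to the surface, which is what makes Gabor
features informative about boundary proximity; ambient speckle
(amplitude 30, different correlation lengths inside vs outside) fills
both sides but fades inside the band; a background "confuser" blob
matches the organ's mean intensity with a different texture scale. The
target volume is the training volume resampled through a stored smooth
sinusoidal field (one period per axis, amplitude 4 mm plus a small
constant shift), each volume then gets independent Gaussian noise
(σ = 2). Landmarks are a 3³ grid spanning the organ with exact
correspondences from the analytic field. Everything derives from one
seed.

What the phantom does **not** emulate: anatomical liver shape and its
deep concavities, CT acquisition physics (beam hardening, anisotropic
slice spacing, partial-volume ramps), neighbouring organs with shared
boundaries, and landmark placement error (phantom landmarks are exact;
clinical landmarks are not). Passing phantom tests therefore
demonstrates the machinery is correct and self-consistent under the
stated texture model, not clinical-grade accuracy.

A peculiarity worth knowing: near the organ's top/bottom caps the ring
texture varies mostly across slices, so the in-plane features carry
little boundary signal there; the cap localization relies on the band's
energy envelope. This mirrors a genuine weakness of 2D in-plane
features for axially-tangent surfaces.

## Problem sizes

Default test and reproduction sizes: 96³ phantom end-to-end (~25 s on
one CPU), 64³ phantoms for module-level integration tests, spheres of
radius 20 in 56³ grids for void-filling checks (radius chosen so the
half-voxel discretization of a rasterized ball stays well inside the
stated volume tolerances), 200 random 6 × 10 problems for the
OMP-vs-exhaustive oracle, and the planted-dictionary protocol
(m = 16, t = 24, N = 600, 1-sparse, coefficients in [1, 2]) for K-SVD
recovery.

## Known limitations

- Single atlas: one training volume and mask; no multi-atlas fusion.
- Axis-aligned geometry only (no direction cosines or oblique
  acquisitions); NIfTI float volumes round-trip at float32 precision.
- The candidate search is axis-aligned and excludes the vertex itself,
  so even a perfect score landscape leaves ~1 voxel of scatter; the
  void-filling smoothing absorbs most but not all of it.
- Mean-|response| pooling is nearly translation-invariant within the
  patch window, capping achievable localization sharpness at roughly
  the band half-width.
- Parity labelling on heavily fragmented shells degrades to the
  majority vote + flood-fill fallback; pathological clouds (e.g. two
  widely separated parallel sheets) can still fool it.
- The NIfTI writer does not preserve NaN voxels (MetaImage does); the
  reader rejects non-finite data either way.
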