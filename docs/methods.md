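# Methods

This note documents the models, conventions and numerical choices behind
`segrepeat`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic validation does and does not
establish.

## Coordinate conventions

World coordinates are RAS millimetres taken from the NIfTI affine. Voxel
indexing is 0-based; voxel *centers* map through the affine,
`world = A @ (i, j, k, 1)`. Binary masks are uint8; any value > 0.5 on read
is foreground, so float masks from other tools are tolerated. Landmark
correspondence is always by name, never by file order.

## Attachment morphing

The atlas→subject map is a full 12-DOF affine minimizing
Σᵢ ‖A sᵢ + t − tᵢ‖² over matched landmark pairs, solved through the
SVD-based pseudoinverse of the homogeneous design matrix. A full affine
(not a similarity) is the default because landmark-set morphing of
attachment points must absorb anisotropic size differences between atlas
and subject; an Umeyama similarity fit (rotation + isotropic scale +
translation) is provided for sensitivity checks. The fit refuses
degenerate configurations: the smallest singular value of the centered
source matrix must exceed 1e-9 × the largest (coplanar or collinear
landmarks cannot pin down an affine).

Snapping relocates an attachment to the exact closest point on the bone
mesh — over triangle interiors, edges and vertices, not just the vertex
set — because "nearest plausible surface point" means the continuous
surface. A displacement larger than `max_snap_mm` (default 15 mm) is
refused with a warning rather than applied: an attachment that far off the
bone signals a registration problem that needs human review, and the bound
is the automated stand-in for that visual check.

## Sub-volume decomposition

The muscle axis is the straight segment from origin to insertion
(direction d, length L, mid-point projection c). Level k (k = 1..9) keeps
the voxels whose center projection p·d satisfies |p·d − c| ≤ k·0.05·L;
level 10 returns the uncut segmentation. Three choices matter:

- **Level 10 = complete segmentation**, not the ±50 %·L slab: muscle
  tissue can extend past the attachment planes, and the full segmentation
  is the clinically meaningful endpoint.
- **Closed slabs (≤)**: including voxels exactly on a plane guarantees
  nesting S₁ ⊆ … ⊆ S₁₀ and makes the tie-break reproducible against the
  brute-force per-voxel oracle.
- **No antialiasing**: projections use voxel centers; partial-voxel plane
  crossings are not weighted. Tests therefore use a one-voxel-slab
  tolerance wherever analytic volumes are compared.

The iliopsoas standardization removes voxels whose projection falls
strictly below (toward the origin) a plane through the mid-point of the
left/right iliac-crest landmarks, normal to the axis. The mid-point is the
canonical choice because a single plane normal to a fixed axis cannot in
general pass through both landmarks. A plane proximal to the whole muscle
is a warned no-op; one that would erase the muscle raises, since it
indicates landmark/segmentation mismatch.

## Agreement metrics

- **Jaccard index** on voxel masks (native representation for overlap);
  requires bit-identical grids, undefined when both masks are empty.
- **Maximal Hausdorff distance** between the vertex sets of the 0.5-level
  marching-cubes isosurfaces, in mm. Vertex-set HD (not point-to-triangle)
  matches the convention of the mesh libraries commonly used for this
  metric; KD-trees accelerate the nearest-neighbour queries but return
  exact distances, so the result equals brute force bit-for-bit.
- **Normalized volume variance**: sample variance (n−1) over the mean,
  ×100. This literal definition carries units of mm³, which makes its
  absolute scale depend on muscle size; a dimensionless
  coefficient-of-variation variant (SD/mean ×100) is provided. With only a
  handful of repeats both are noisy — they are population-level summaries.
  Degenerate all-equal inputs return exactly 0 (no floating-point
  residue), which the end-to-end zero-noise identity test relies on.

Each metric is computed per level and averaged over all C(n,2) unordered
repeat pairs. A level that is empty in any repeat is flagged and excluded;
downstream statistics drop such subjects listwise (conservative, logged).

## Statistics

The branch is chosen per metric (one omnibus test per metric): Shapiro–Wilk
on every level column, parametric only if all pass at α = 0.05, a constant
column forcing the nonparametric branch. The parametric branch runs the
classical one-way within-subject ANOVA (F = MS_level/MS_error, df = k−1 and
(n−1)(k−1)); no sphericity correction is applied, matching the analysis
this pipeline reproduces — a Greenhouse–Geisser option would be a natural
extension. The nonparametric branch runs Friedman's χ² with midrank ties.
Post hoc, all C(k,2) level pairs are tested (paired t or Wilcoxon
signed-rank with zero-discard/midrank ties) and Bonferroni-corrected by the
full family size — the whole pairwise matrix is reported, so the whole
family is the honest correction denominator.

ICC(1,1) and ICC(3,1) follow Shrout–Fleiss mean-squares formulas with
F-based 95 % confidence intervals. Estimates are returned unclamped: a
negative ICC is informative (between-subject variance below error
variance), and clamping would bias agreement summaries upward. With zero
error variance the ICC is exactly 1 and the CI degenerates to [1, 1].

## The phantom world

The generator emulates the *statistical* situation of a segmentation
repeatability study, not muscle anatomy:

- tube-like muscles (straight, spindle-tapered, or laterally bowed — the
  bowed form models a muscle whose belly swings away from the straight
  attachment line, as the iliopsoas does around the iliac crest) rasterized
  at 0.817 mm in-plane / 4 mm through-plane, the acquisition scale of
  1.5 T coronal T1-weighted clinical scans;
- the muscle axis runs along the slice normal, so one array slice is one
  contour the operator would draw, and the terminal slices are the
  extremities that are genuinely hard to identify on MRI;
- repeats displace each slice's contour by thresholding its signed
  Euclidean distance transform at a Gaussian-correlated random field
  (correlation length 8 mm by default) instead of zero. The field is
  normalized by the discrete L2 norm of the smoothing kernel, giving exact
  unit marginal variance; the boundary-displacement SD then interpolates
  linearly in the normalized axial coordinate |p·d − c|/(L/2) from
  `belly_sigma_mm` (default 0.5 mm) to `extremity_sigma_mm` (default
  3 mm). Terminal slices can be dropped entirely with probability
  `end_slice_dropout_prob` (a missed end contour). Each repeat is reduced
  to its largest 6-connected component;
- default cohort geometry: gluteus medius as a 100 mm × r20 mm tapered
  tube, iliopsoas as a 180 mm × r15 mm bowed tube (25 mm bow) — hip-muscle
  scale, chosen once;
- twelve bony landmarks sit at fixed offsets in the muscle frame; the
  atlas point sets are exact preimages under a seeded ground-truth affine
  (mild rotation/scale/shear + translation), so registration must recover
  that affine to numerical precision when landmark jitter is zero;
- one global seed expands into per-repeat, per-slice substreams via
  `SeedSequence` spawn keys: repeats are independent, the study is
  bit-reproducible, and any slice's noise can be regenerated in isolation.

Grids are auto-sized to the muscle plus a 5-voxel margin by default; a
fixed clinical matrix (e.g. 512×512×40) is accepted and checked against
the required extent. Auto-sizing keeps the 20-phantom simulation suites
fast without changing voxel spacing, i.e. without changing the physics of
the discretization.

**What a green test establishes — and what it does not.** The phantoms
have smooth convex-ish cross-sections, no intensity information, no
inter-operator bias, no pathology-induced contrast loss, and noise that is
independent across slices. Green tests establish that the *pipeline*
(morphing, cutting, metrics, statistics) is correct and that the expected
qualitative patterns follow from extremity-weighted noise; they do not
certify the absolute repeatability values of any real operator or scanner.

## Observed behaviour of the level trends

On 20 extremity-noise phantoms × 3 repeats, mean JI decreases monotonically
with level (full segmentations agree least) and mean HD increases
(Spearman ρ ≈ 1) — the two headline patterns of segmentation-error
concentration at the extremities. The volume metric is subtler: the
*literal* nVV (variance/mean, units mm³) **increases** with level under
extremity-weighted noise, because the added end-slice variance outgrows the
mean volume; the *relative* spread (CoV) under uniform contour noise
decreases with level (ρ ≈ −0.99), which is the pattern a dimensionless
volume-variability measure shows when absolute fluctuations accumulate
more slowly than the mean grows. Reported nVV values in the literature are
on the few-percent scale, consistent only with a relative measure; both
forms are exposed and the tests assert each trend in the regime where its
mechanism operates.

## Known limitations

- Voxel-selection cutting (no oblique re-slicing): level boundaries are
  jagged at the one-voxel scale; all analytic comparisons carry a
  voxel-slab tolerance.
- The Gaussian-correlated boundary field is an assumption; real operator
  error distributions are uncharacterized, and inter-slice independence is
  a simplification of how humans propagate contours.
- Left/right muscles, when both present, are treated as independent
  subjects; within-patient correlation is not modelled.
- The statistics layer assumes complete subjects × levels matrices after
  listwise deletion; no mixed-model handling of missingness.
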