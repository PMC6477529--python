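# Methods

## Inputs and lesion definition

The pipeline starts from a 3D intensity volume and a co-registered lesion
probability map or binary mask (NIfTI). Probability maps are thresholded
strictly above 0.5 (configurable); producing the probability map itself —
i.e. the segmentation model — is out of scope. On each slice, connected
components with **more than 10 voxels** (strict inequality, so ≥ 11) are
kept as probable lesions; smaller components are treated as segmentation
artifacts. In-plane connectivity is 8-connected by default (configurable
to 4): the convention matches the diagonal linking used across slices and
the 8-neighborhood used by region growing.

Components on adjacent slices that touch directly above/below or
diagonally (26-connectivity restricted to consecutive slices) are linked
into a 3D lesion aggregate. A component with no adjacent-slice contact is
a single-slice lesion. Linking is implemented with union–find over voxel
contacts; a property test checks it against full 3D connected-component
labeling.

Each 3D lesion's voxel intensities are **despiked** by clamping
(winsorizing) to mean ± 3 SD — clamping rather than exclusion, so voxel
counts downstream are unchanged. Mean and SD are computed once on the raw
values (population SD, ddof = 0; the convention matters little at lesion
sizes of interest and is fixed for reproducibility). The despiked extremes
gMin/gMax anchor both texture normalization and region growing; despiking
exists precisely so that isolated spikes do not define those extremes.

## Shape features

A lesion mask is embedded in its bounding square, isotropically rescaled
so that square fills a 60 × 60 canvas, re-binarized at 0.5, and its
centroid translated to the canvas center (Zernike moments are not
translation invariant; centroid centering is our choice — the convention
is configurable). The source mask is padded with one zero ring before
resampling so that interpolation across the mask border is exact; without
it the outermost half-voxel of foreground is lost.

Zernike moments are computed as the discrete inner product

    Z_nm = (n+1)/π · Σ_pixels f · V*_nm(r, θ) · ΔA,

with V_nm(r, θ) = R_nm(r)·e^{imθ} and R_nm the standard factorial sum.
Two unit-disc mappings are provided:

- **circumscribed** (default): the whole canvas lies inside the unit disc,
  so no foreground is discarded; appropriate because normalized lesions
  fill the canvas and corner content would otherwise be clipped, breaking
  rotation invariance for canvas-filling shapes.
- **inscribed**: the classical convention; the basis is orthogonal on the
  disc grid and a full-disc image yields Z_00 ≈ 1. Used by the
  orthogonality and reconstruction tests.

Pixels straddling the disc rim contribute with fractional coverage
(8 × 8 subsampling), which is what pushes the discrete orthogonality of
the inscribed basis below 1% relative inner product on the 60 × 60 grid.

The feature vector is the ordered list of |Z_nm| for m ≥ 0 (n ascending,
m ascending): 12 values at max order 5, 36 at order 10, per the
distinct-magnitude count ((n+2)/2)² for even n and (n+3)(n+1)/4 for odd.
Magnitudes are emitted raw (not normalized by Z_00). Default maximum
order is 5: higher orders encode detail below the scale that survives the
one-size-fits-all 60 × 60 rescaling.

## Texture features

Despiked intensities are min–max normalized, s = (f − gMin)/(gMax − gMin).
A flat lesion (gMax = gMin) maps to s = 0 with a warning rather than an
error, since synthetic fixtures can legitimately be flat. Each s
contributes fractional membership to the two histogram bins whose centers
bracket it (piecewise-linear, conserving unit mass per voxel; values at or
beyond the outermost bin centers belong entirely to the outer bins). The
histogram is divided by the voxel count, so it sums to 1 and lesions of
different sizes are comparable. Default 5 bins, configurable 3–15: fewer
bins cannot differentiate distributions, more bins go sparse on the small
lesions that dominate real size distributions.

Whether texture vectors describe individual 2D lesion images or whole 3D
aggregates is genuinely ambiguous in practice; both modes are implemented.
The default is per-2D-component histograms normalized by the **parent**
3D lesion's gMin/gMax, so slices of one lesion share a reference range
while clustering still operates on individual lesion images.

## Clustering and the gap statistic

K-means is a plain Lloyd iteration: initial centroids drawn without
replacement from the data rows, assignment by Euclidean or Manhattan
distance (ties to the lowest centroid index), centroids updated as
coordinate-wise means, convergence on an assignment fixed point or 100
iterations. Manhattan assignment with mean updates mirrors the reference
protocol (true k-medians is available via `centroid_update="median"`). A
cluster emptied during iteration is re-seeded from the point farthest
from its assigned centroid. `n_init` independent restarts keep the best
solution by the assignment objective; the default of 10 restarts follows
standard practice — single-restart runs leave the dispersion at the true
cluster count inflated by local minima often enough to disturb
cluster-count selection.

Within-cluster dispersion is W_k = Σ_r Σ_{x∈C_r} ‖x − x̄_r‖² — squared
Euclidean deviations regardless of the assignment metric, as the
dispersion is defined as a squared deviation even where histogram
similarity is assessed with Manhattan distance (both choices are exposed).

The gap statistic compares log W_k against B = 10 reference datasets drawn
uniformly and independently over each feature's observed [min, max]
(no PCA rotation; a constant column stays constant), for k = 1…N (default
N = 20, capped at the number of rows). With s_k = sd_k·√(1 + 1/B), the
chosen count is the smallest k with Gap(k) ≥ Gap(k+1) − s_{k+1}; if no k
satisfies the rule the maximum N is returned with a warning. Exactly-zero
dispersions (duplicate rows at large k) are floored at 1e−300 before the
logarithm. Given a seed the whole curve is bit-for-bit reproducible.

## Potential growth index

Boundary seeds are mask voxels with at least one non-mask 4-neighbor
(out-of-bounds counts as non-mask). Growth is breadth-first over
8-neighborhoods: a non-mask, unvisited voxel joins the growth set iff
gMax − f(p) < γ·(gMax − gMin), strict, with γ = 1.02 and gMax/gMin from
the parent 3D lesion; accepted voxels seed further growth. Voxels of
other lesions never qualify — the penumbra is tissue at risk of
conversion, not existing lesion. Note that with γ > 1 the acceptance
bound lies slightly below gMin; the criterion is discriminative only
because healthy tissue is much darker than the lesion range, which the
synthetic fixtures reproduce.

Growth is uncapped by default. Capping the search at the l rings used for
scoring is available for speed (`max_rings`), but is not exactly
equivalent: a qualifying voxel inside the rings can be reachable only
through a qualifying voxel beyond them (8-connected growth vs 4-connected
rings), so the uncapped search is the reference behavior.

Layers are successive one-voxel-thick 4-connected dilation fronts,
disjoint from the mask and from each other, clipped at image bounds;
l = 3 by default. Weights w_i = i/(l(l+1)/2) increase outward — a growth
voxel far from the boundary indicates a broader penumbra — and sum to 1.
P_g = Σ GV_i·w_i / V_l lies in [0, 1], is 0 when nothing qualifies, and is
non-decreasing in γ on fixed geometry.

One-way ANOVA (scipy's F test) compares P_g across shape clusters and
across texture clusters, with a per-cluster n/mean/SD table. Because
K-means depends on its initial seeds, the pipeline repeats clustering for
1,000 re-seeded trials (configurable) and reports the range of P and F
values across trials; trial clusterings that leave a cluster with fewer
than two members have those clusters dropped from that trial's ANOVA
(the standalone ANOVA operation rejects such input instead).

## Synthetic fixtures

`synthetic_fixtures` generates everything the tests need: masks from four
shape families (disc, ellipse with 0.4 axis ratio at random orientation,
cross, random-walk blob), intensity images, planted Gaussian feature
clusters with guaranteed center separation, and multi-slice demo volumes
with a ground-truth manifest.

The intensity model is piecewise linear in the Euclidean distance to the
mask boundary: plateau (default 120) in the deep core, descending to
`boundary_level` (default 0.55) of the dynamic range at the mask edge,
then continuing from that level to background (default 40) over
`edge_width` voxels outside; independent Gaussian noise (default SD 3,
i.e. ≈ 4% of the dynamic range) on top. The interior descent reflects
that a probability-0.5 segmentation cuts through the middle of a real
lesion's partial-volume ramp — the mask boundary is not where the signal
reaches background. This matters for the growth index: with a step edge
(edge_width 0) exterior voxels sit ≈ 0.55 of the dynamic range below
gMin and essentially never qualify (P_g ≈ 0), while shallow ramps put the
first rings within noise of gMin and P_g rises with edge width. Every
noise-free voxel value has a closed form, which the oracle tests exploit.

What the fixtures do **not** emulate: MRI bias fields, partial-volume
mixing beyond the linear ramp, anatomically shaped lesions or their
spatial distribution, through-plane anisotropy (lesions are repeated
identically across slices), and correlated noise. Passing tests therefore
demonstrate the correctness and the qualitative behavior of the
operations — rotation invariance, conservation, monotonicity, recovery of
planted structure — not clinical performance on real FLAIR data.

Demo volumes place each lesion on a non-overlapping cell grid across 3
consecutive slices, with per-lesion edge width (2–6), core depth (3–6),
and boundary level (0.45–0.65) drawn from one seeded generator; the
probability map exceeds 0.5 exactly on lesion voxels.

## Problem sizes and numerical choices

Default test/demo problem sizes — 18 lesions on a 200 × 200 × 9 grid (6
on 120 × 120 × 9 in the shared test fixture), 50 points per planted
cluster, 50 seeds per recovery setting, 8 candidate ks with 10 reference
datasets in recovery runs — were chosen so the full suite exercises every
code path at desk scale while remaining comfortably reproducible on one
CPU. Tolerances: quarter-turn rotation invariance holds to 1e−9
(identical pixel multisets), resampled rotations to 5% relative L2,
conjugate symmetry to 1e−12, disc-anchor moments to ~1e−2 absolute
(rim discretization at 60 × 60), and fuzzy conservation to 1e−12.
Ties: nearest-centroid ties break to the lowest centroid index;
intensity ties at the growth threshold are rejected (strict inequality);
half-open (prev, cur] size bins put a bounding square of exactly 50 in
bin 50.

## Known limitations

- Scaling every lesion to one canvas blurs small lesions and discards
  fine contour detail of large ones; order ≤ 5 features are below the
  scale where this matters, but higher-order use would warrant per-size
  scaling groups.
- The gap statistic's uniform-box reference is distribution-naive; on
  strongly correlated features it can over-estimate k.
- P_g validity as a predictor of actual lesion growth requires
  longitudinal data and is outside what synthetic fixtures can show.
- The 2D connectivity convention for the minimum-size filter (4 vs 8) is
  not fixed by the protocol; 8 is the default and the choice is exposed.
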