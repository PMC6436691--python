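# Methods

`lamglm` extracts per-layer signals from volumetric MRI of the cerebral
cortex by treating every voxel value as a linear mixture of laminar
signals weighted by partial volume, and solving the resulting *spatial*
general linear model.  This note documents the model, the numerical
choices, and what the simulated benchmark does and does not demonstrate.

## The spatial GLM

For an ROI of n voxels and k layers, the design matrix **X** (n x k)
holds each voxel's volume distribution over the layers; with data **Y**
(n x m, one column per volume or time point) the model is
**Y** = **X B** + eps.  Assuming a laminar signal common to the ROI, OLS
unmixes the partial-volume contributions; GLS whitens with a Gaussian
spatial noise correlation Omega_ij = exp(-d_ij^2 / 2 sigma^2), with
sigma = L_c / (2 sqrt(2 ln 2)) so that the correlation length L_c is the
FWHM: Omega has a unit diagonal, equals 1/2 at distance L_c/2, and
reduces to the identity at L_c = 0.  (A normalised Gaussian correlation
is the only form consistent with a unit diagonal; a density-style
1/(sigma sqrt(2 pi)) prefactor would contradict it, so none is used.)
Solvers use QR/Cholesky factorisations, never explicit inverses.

Two classical extractions are expressed in the same frame:

* **interpolation** — each design column is divided by its own sum and
  the transpose multiplied with the data: a convex weighted average.
  A variant normalising by the voxel count instead is available
  (`normalise="count"`).  Convexity bounds the estimates by the data
  range but leaves partial-volume leakage in place.
* **classification** — each row of **X** is redistributed entirely to
  its largest entry (ties go to the deeper layer, a convention);
  regression on the resulting orthogonal binary design equals per-layer
  means of the assigned voxels.

Because voxel intensities are spatially correlated, voxel counts
overstate the degrees of freedom; the package deliberately reports no
standard errors and instead exposes residuals.

## Partial-volume geometry

A voxel is an axis-aligned unit cube; a layer boundary crossing it is
locally a plane with unit normal n at signed offset t from the centre.
The cumulative cut volume uses the exact corner-sum formula
(sum over cube corners of (-1)^parity relu(t' - n.c)^3 / (6 n1 n2 n3)
after reflecting all normal components positive), with analytic 2-D/1-D
reductions when components fall below 1e-7 — exact, branch-free and
continuous in the offset; the intersection area is its derivative.  Layer
fractions are differences of the cumulative volume at consecutive
boundary offsets; all planes within one voxel share the voxel's normal
(parallel-plane assumption, valid while the voxel is small against the
radius of curvature).  Anisotropic voxels reduce to the unit cube by
scaling the normal with the edge lengths and renormalising.

The orientation-averaged kernel K(t) — the mean cumulative volume over
uniformly random cube orientations, i.e. the average projection of a
cube onto a line — is tabulated at build time by Fibonacci-sphere
quadrature (20 000 orientations, 513 offsets), symmetrised so that
K(t) = 1 - K(-t) exactly, and interpolated with a cubic spline.  Its
coefficients are computed rather than copied from the literature because
no printed polynomial was available to copy.

## Equivolume layering

Inputs are the WM and pial surfaces as binary masks (SDF via exact
Euclidean distance transforms, half-voxel interface correction) or as
geometric surfaces with an exact signed-distance method (the simulator's
extruded polylines; closed triangle meshes via `trimesh`).  All layering
runs on a grid upsampled 2x relative to the acquisition.

1. **Laplace potential.**  Dirichlet 0 on the WM side, 1 beyond the pial
   surface, 7-point Laplacian over the ribbon, conjugate gradients to a
   residual well below 1e-6 (the tolerance is a config knob).  Ribbon
   components touching only one boundary set are flagged.
2. **Normal field.**  The gradient of the potential is taken in the
   Fourier domain under a separable Tukey window (default alpha = 0.5;
   alpha = 0 is the plain spectral derivative), then unit-normalised.
   The window tapers high spatial frequencies so the divergence is
   usable; outside the ribbon the potential saturates at its Dirichlet
   values, which is the natural harmonic continuation.
3. **Curvature.**  Mean curvature = half the divergence of the normal
   field by central differences.  For the extruded geometry of the
   benchmark this equals half the single principal curvature exactly;
   for general 3-D folds using it in the layering formula is a
   first-order approximation, documented as such.
4. **Equivolume boundaries.**  Per voxel, depth u0 = sdf_wm and
   thickness T = sdf_wm - sdf_pial (straight-line distances standing in
   for streamline length).  The cross-section of a cortical column
   widens as w(u) = 1 + c (u - u0) with c = 2 x mean curvature anchored
   at the voxel, so the boundary at cumulative volume fraction alpha
   solves a quadratic with the stable root
   d = 2 alpha F_T / (b + sqrt(b^2 + 2 c alpha F_T)), b = 1 - c u0.
   The endpoints land exactly on the two surface crossings for any
   curvature, c -> 0 recovers equidistant spacing, and an annulus
   reproduces the analytic equal-area radius (sqrt(10) for radii 2 and
   4) to machine precision when fed exact fields.  Curvature is held
   voxel-constant; values that would collapse the column width inside
   the ribbon (w < 0.05) are clamped with a warning.  Unequal layer
   volume fractions are supported.

**Design assembly.**  A native voxel's row is produced from the mean of
its 8 sub-voxels' boundary offsets, re-expressed about the native voxel
centre along the local normal, followed by one cube cut (mode
`oriented`) or one kernel evaluation (mode `average_kernel`).  Averaging
the sub-voxel fraction rows instead is available
(`aggregate="fractions"`) and agrees closely on smooth cortex; the
offset-mean form is the default because it mirrors a level-set pipeline
that carries one plane stack per voxel.  Rows are not renormalised —
partially cortical voxels contribute partial volume — and any voxel with
positive cortical content belongs to the ROI.  An identically zero layer
column raises a rank-deficiency error naming the layer; a diagnostics
report (column sums, correlations, rank, condition number) warns when
the layer count exceeds the voxels spanned by the cortical thickness.

## The simulated cortex

The ground truth is a 2-D six-layer ribbon: midline
y = A sin(2 pi x / lambda) over one full period (one gyrus, one sulcus)
plus 2 mm of run-in, thickness 3.0 mm, boundaries initially equidistant
along the midline normals.  Defaults A = 4 mm and lambda = 22 mm keep
the minimal midline radius of curvature (lambda^2 / 4 pi^2 A ~ 3.1 mm)
at or above the cortical thickness — the regime in which cortical folds
stay physiological and the parallel-plane partial-volume model is
meaningful; sharper folds would compress the inner layers by an order of
magnitude.  Mesh columns are placed so all column strips have equal
area, then interior vertices relax along their (straight) columns with
displacements proportional to the area imbalance of adjacent cells,
damping 0.5, until every quadrilateral's area is within 1e-3 of the
global mean (a deterministic spring-mass settling; the residual history
is monotone and convergence takes ~50 iterations at 256 columns).

The relaxed mesh is rotated 30 degrees in-plane (breaking grid
alignment), extruded along z through the whole grid, and rasterised to
64^3 voxels of 0.5 mm with an 8^3 sub-voxel lattice per voxel; because
the extrusion is translational the in-plane 8^2 lattice decides the
occupancy exactly.  Per-layer totals come out equal to ~0.1% and
invariant under the rotation.  Downsampling is block-mean (factor 2
gives the 1.0 mm condition, conserving layer volumes exactly).

What the simulation does **not** emulate: measurement noise, bias
fields, veins and intensity structure within a layer, surface
reconstruction error, 3-D folding (the extrusion has a single principal
curvature), and any temporal structure.  Benchmark results therefore
bound the *geometric* leakage of each method under ideal segmentation;
real-data performance degrades with noise and model violations, and the
GLM is the most sensitive of the three to both.

## The PSF benchmark

For each layer j, the voxelised image of unit signal confined to that
layer is simply its true occupancy column.  Each method unmixes the k
indicator volumes using a design built **only** from the WM/pial
surfaces (never the ground-truth occupancy), over an ROI spanning the
central 75% of the fold — symmetric about the midline inflection, so
positive and negative curvature are represented exactly equally.  The
layering is computed once on the 2x-upsampled base grid and reused when
the volumes are downsampled to 1.0 mm: the boundaries do not change with
acquisition resolution, only the design assembly does.  No noise is
added and the GLM uses OLS.

Column j of the resulting k x k matrix P is the estimated profile of
experiment j; each column is normalised to unit total retrieved signal
so that entries read as *percentages of the injected signal*, and the k
profiles are aligned on the true layer (integer offsets, no sub-layer
interpolation) and averaged.  The offset-0 value x100 is the peak
percentage.  An oracle design assembled from the true occupancy yields
the identity PSF under OLS to 1e-6, which separates estimator error from
layering-reconstruction error.

The oriented-vs-average-kernel comparison reruns the experiment with
both design modes and reports the maximum absolute difference between
aligned profiles (headline, in percentage points) and between raw PSF
matrices.  Winner-takes-all classification makes the matrix-level
difference jumpy (a borderline voxel flips discretely); the
profile-level figure is the stable summary.

With the default scenario the peaks are GLM 96.8 / classification 75.8 /
interpolation 68.2 at 0.5 mm and GLM 93.2 / 57.2 / 49.0 at 1.0 mm, with
GLM > classification > interpolation at both resolutions, interpolation
and classification degrading with coarser voxels while the GLM barely
moves, GLM undershoots oscillating around its peak at 1.0 mm (where six
layers face only three voxels across the thickness), and a kernel
difference of 0.5 pp.  The GLM peak is the one number that measures
nothing but the residual mismatch between the reconstructed layering and
the truth, so it depends directly on implementation accuracy: with the
exact-surface SDFs used here only ~3% of the injected signal is
misassigned at 0.5 mm, whereas pipelines with coarser surface handling
lose more and peak lower.  Sensitivity runs with mask-rasterised SDFs
and with sub-voxel fraction averaging shifted this peak by 1-2 points
without materially moving the other five.

## Numerical and design choices

* Laplace: CG on the SPD 7-point system; unlabelled neighbours get
  homogeneous Neumann treatment.
* SDF from masks: two distance transforms with a half-voxel shift;
  zero-crossing within one voxel of the true interface.
* Classification ties: deeper layer wins (first index).  Ties occur on
  exactly grid-aligned geometry; the convention only matters there.
* Aligned profiles use integer layer offsets; short diagonals average
  over the entries that exist.
* The benchmark is fully deterministic: rerunning any command with the
  same configuration reproduces the report byte for byte.
* Degenerate inputs: non-unit normals, NaN offsets, non-ascending
  boundaries, non-watertight meshes, all-zero design columns and
  underdetermined systems raise errors; near-singular covariances get a
  1e-8 ridge with a warning.

## Problem sizes

The standard benchmark uses a 256-column mesh, a 64^3 rasterisation grid
(layering at 128^3, ~300k supported voxels, CG system of ~10^5
unknowns), an ROI of ~19k voxels at 0.5 mm and ~2.7k at 1.0 mm, and
completes in well under a minute on one CPU; unit tests use a reduced
48^2 x 8 fold.
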