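# Methods

`fshapems` implements a functional-shape (F-shape) analysis chain for
macular OCT thickness maps: each eye's GCIPL thickness field is attached as
a scalar signal to the geometry of its ILM surface, all eyes are brought
into correspondence by atlas registration, and the per-vertex residual
thickness against the estimated mean template is used as the classification
feature for separating multiple-sclerosis (MS) eyes from healthy ones.
This note records the model, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## Data model and region of interest

A thickness map is a 2D scalar field on a pixel lattice (µm values, one
isotropic pixel pitch in mm).  Left eyes are mirrored about the vertical
midline so all maps follow right-eye (OD) orientation with nasal on the
right.  The region of interest is the closed rectangular frame between two
axis-aligned rectangles; the default coordinates (outer 65..395 × 75..360,
inner 205..275 × 200..250, inclusive, treated as 0-based lattice indices)
target the horseshoe-shaped perifoveal band where MS-related GCIPL thinning
concentrates, while excluding the foveal pit, and contain
331·286 − 69·49 = 91,285 lattice points.  Only the open interior of the
inner rectangle is excluded, so both boundaries belong to the ROI.  On
reduced lattices the frame is scaled proportionally (the defaults are
referred to a nominal 461×461 lattice covering the 6 mm scan).

Pixel pitch defaults to 6 mm divided by the lattice width, matching the
instrument's 6×6 mm macular scan; it is configurable wherever a grid is
constructed.

## Mesh decimation

The ROI is covered by a coarse square grid whose ideal side is
`s = sqrt(1/fraction)` lattice units — one retained vertex per s×s cell
keeps the stated fraction of lattice points (s = 5.0 at 4%; the classical
value s = 4.92 corresponds to fraction ≈ 0.041 and is available as an
explicit override, and it is what the geometry tests use).  Cut positions
at multiples of s are snapped to the nearest lattice integer; the high edge
is forced to be a cut, absorbing the last interior cut when the leftover
sliver would be shorter than s/2.  At s ≈ 4.92 this produces rectangles
with side lengths 4 or 5, each split along its main (lower-left to
upper-right) diagonal into two right triangles.  Rectangles whose interior
meets the inner hole are dropped whole, keeping every face a right triangle
and making the mesh an annulus (Euler characteristic 0; a mesh without the
hole is a disc, characteristic 1).  Subject meshes use 4% of the lattice
points and the template mesh 4.5%, a deliberately denser reference that
gives the registration a finer target.

An F-shape is assembled per eye by reading the ILM elevation (µm) as the
vertex z-coordinate and the GCIPL thickness as the vertex signal, at the
shared lattice positions, so all subject F-shapes share one connectivity.
Lateral coordinates are stored in lattice units with the pitch carried as
metadata; registration converts everything to millimetres (elevation
µm → mm) so kernel widths have a single length unit.

## Registration model

Geometric deformation is a kernel diffeomorphic flow: per-vertex momenta
`p` define a velocity field v(x) = Σ_j K(x, x_j) p_j with Gaussian kernel
K of width σ_V, integrated by `shoot_steps` forward-Euler steps of the
point-particle Hamiltonian system (geodesic shooting).  The deformation
cost is the initial-momentum RKHS norm H = pᵀK(X)p.  Signal change is a
per-vertex functional increment ζ, so a registered subject is
(φ_p(X_m), f_m + ζ); the signal is transported pointwise without Jacobian
rescaling since thickness is a pointwise measurement, not a density.

The data attachment A is a functional-varifold squared kernel norm between
triangulated F-shapes: faces interact through a Gaussian kernel on
centroids (width σ_W), the squared cosine of the angle between unit
normals, and a Gaussian kernel on mean face signals (width σ_sig), each
pair weighted by the two face areas.  It requires no correspondence
between meshes, is symmetric, non-negative, and vanishes exactly on
identical F-shapes.

The atlas objective is

    J = γ_f‖f_m‖² + Σ_i [ pᵢᵀK(X_m)pᵢ + γ_ζ‖ζᵢ‖² + γ_w A((φ_{pᵢ}(X_m), f_m+ζᵢ), (Xᵢ, fᵢ)) ]

with L² norms weighted by each vertex's one-third share of adjacent face
area.  The weights are computed once on the hypertemplate and frozen, so
the penalties stay quadratic in the signal variables while the geometry
moves.

### Defaults and their rationale

| parameter | default | why |
| --- | --- | --- |
| γ_f | 1e−4 | weak pull of the template signal toward zero; keeps the template identifiable without biasing it visibly |
| γ_ζ | 1e−2 | ridge-like shrinkage of per-subject signal increments; residual features are proportionally shrunk, which leaves t-statistics and linear classifiers unaffected |
| γ_w | 1 | puts the data term at the same order as the deformation energy on the synthetic cohort |
| σ_V | 1.5 mm | smooth, large-scale anatomical deformation (foveal position shifts are a few tenths of a mm) |
| σ_W | 0.5 mm | varifold resolution of a few mesh cells |
| σ_sig | 40 µm | must bridge the gap between the zero-initialized template signal and physiological thickness (~60–80 µm): a much narrower kernel makes the signal term flat at the start and the optimization cannot leave the zero template; 40 µm still resolves the ~13 µm MS thinning |
| shoot_steps | 10 | Euler discretization of the geodesic flow |
| tol | 1e−4 | absolute objective-decrease stopping rule (a relative rule is available by config) |

Optimization is alternating adaptive gradient descent with backtracking:
a step is accepted only if the objective decreases, the step size shrinks
(×0.5) on rejection and grows (×1.5) on acceptance, so accepted-objective
traces are non-increasing by construction.  Momenta and signal increments
keep separate step sizes: the two blocks live on different scales (mm vs
µm) and a shared step starves whichever block has smaller curvature.
Template geometry updates use a 10×-reduced step and can be frozen
entirely (`update_template_geometry=False`), which is the default in the
desk-scale pipeline configuration because it is substantially cheaper and
nearly indistinguishable on the synthetic cohort.

All gradients are exact hand-derived reverse-mode adjoints (through the
Euler shooting and through the varifold face quantities); they are checked
against central finite differences in the test suite.  The O(F_a·F_b)
pairwise kernel sums are evaluated by fused numba kernels with equivalent
numpy fallbacks; both paths are compared to a brute-force double-sum
oracle.  There is no stochastic step anywhere in the optimizer; runs are
deterministic given the inputs and configuration.

### Train/test consistency

At test time each new eye is registered to the *frozen* template.  Because
desk-scale runs truncate the optimization rather than run it to
convergence, the per-eye registration budget at test time defaults to the
same number of parameter updates the training eyes received inside the
atlas loop; otherwise train and test residuals sit at different points of
the shrinkage path and the SVM's decision threshold (though not its
ranking) is biased.

## Features and classification

The residual of eye i is f_m − f̃_i on the template mesh.  Residual
matrices (N eyes × M vertices, M ≫ N) are reduced by PCA: eigenvalues of
the row covariance via SVD of the centered matrix, retained dimension k
chosen as the smallest k whose marginal cumulative-eigenvalue-ratio gain
falls below 0.01 (a reproducible proxy for "where the scree curve
flattens"), overridable to a fixed k.  PCA is applied only when the
feature dimension exceeds the sample count, so the nine-sector baseline
goes to the SVM directly.

The SVM is selected by leave-one-out grid search: every configuration in
the grid is scored by the fraction of correctly classified held-out
samples over N single-sample folds, ties broken by grid order, and the
winner is refit on all training eyes.  The four kernels (linear,
polynomial, RBF, sigmoid) follow their standard forms; fitting is
delegated to scikit-learn's SVC with exactly those kernels.  MS is the
positive class.  ROC curves sweep the SVM decision score; AUC is the
trapezoidal area.

The ETDRS baseline computes mean GCIPL thickness in the nine macular
sectors (central 1 mm disc; 1–3 mm and 3–6 mm rings split into quadrants
by the ±45° diagonals, nasal right, superior up), with boundary pixels
assigned by center-of-pixel radius and radius ties going inward.  Sector
means feed the same LOO-grid-search SVM on the same train/test split.

## Synthetic cohort

The generator emulates the statistical structure the method assumes:

- **Topography** — a deterministic radial profile with a thin foveal
  center, an annular peak near 1 mm eccentricity and gentle peripheral
  decay, rescaled so the map mean equals the group mean.
- **Group effect** — healthy maps average 75.9 µm (SD 6.2) and MS maps
  62.9 µm (SD 5.4) across eyes; the MS template is obtained by thinning a
  horseshoe annulus (0.5–2.5 mm radius, 90° temporal gap, smooth-stepped
  edges) by exactly the factor that moves the map mean from the healthy to
  the MS value.  Group SDs are injected as one scalar per eye, because the
  published SDs describe between-eye, not between-pixel, variability.
- **Anatomy** — each eye is warped by a Gaussian-correlated random
  displacement field (default RMS amplitude 0.2 mm, correlation length
  1.5 mm) applied identically to the thickness map and the ILM dome
  (300 µm amplitude), emulating between-subject anatomical variability the
  atlas must absorb; the ground-truth field is recorded.
- **Noise** — i.i.d. Gaussian measurement noise (default SD 3 µm), clipped
  at zero thickness.

What this does **not** model: OCT speckle, segmentation failures, vendor
grid geometry, inter-eye correlation within subjects (eyes are sampled
independently), or focal pathology outside the horseshoe.  Passing the
synthetic experiments therefore demonstrates the machinery — meshing,
registration, feature extraction, model selection — under the published
effect size, not clinical performance on real OCT data.

## Problem sizes

The default experiment configuration runs the full pipeline at desk scale:
a 131×131 lattice (≈0.046 mm pitch), a proportionally scaled ROI,
template meshes of ≈390 vertices / 680 faces, 37+35 eyes split 28+26
training and 9+9 test, 12 atlas sweeps with one parameter-block update per
subject per sweep and frozen template geometry.  At these sizes one full
experiment takes a few minutes on a single core.  The full-resolution ROI
(396×361 lattice and up, ~3,800 mesh vertices) is exercised by the
geometry and counting tests; atlas estimation at that scale is possible
with the same code but is not part of the default experiments.

## Known limitations

- Plain gradient descent (as specified for this method) converges slowly
  in the flat tail of the varifold landscape; truncated desk-scale runs
  rely on the train/test budget matching described above.
- The ridge shrinkage of ζ means residual amplitudes underestimate true
  signal offsets by a roughly constant factor; rankings, t-statistics and
  linear decision boundaries are unaffected.
- The forward-Euler shooting is a first-order integrator; for large
  momenta the flow is only approximately a geodesic.  The adjoint is exact
  for the discrete scheme, so descent is unaffected.
- With `fraction` values far from 4%, snapped rectangle legs may fall
  outside {4, 5}; the {4, 5} inventory is a property of the standard
  density on the standard ROI.
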