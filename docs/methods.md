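# Methods

This note documents the model, the numerical choices and the synthetic
evaluation protocol implemented in `pbnrr`, and what the tests do and do
not establish about behaviour on real clinical data.

## Model and assumptions

The deformation between a moving (e.g. preoperative) and a fixed (e.g.
intraoperative) image is modelled as the displacement field of an isotropic
linear-elastic body occupying the masked object. Linear elasticity is a
small-strain approximation: it is adequate for brain-shift-scale motion
(millimetres to a couple of centimetres over a ~150 mm organ) and degrades
for large rotations or strains. The model is driven purely by the sparse
block-matching displacements; no boundary conditions are imposed, so the
solvable system relies on the data term `HᵀSH` to fix the rigid-body modes.
A factorisation failure therefore reports "supply more well-distributed
points" rather than silently regularizing.

Fixed and moving images must share dimensionality; for block matching they
must share the full grid geometry, which keeps the voxel-offset ↔ mm
conversion exact and matches the intra-patient use case. Any prior rigid
alignment is assumed to be baked into the image headers.

## Stage parameters

| parameter | default | units | role |
|---|---|---|---|
| `block_radius` | 1 | voxels | half-width of the variance/matching block (3³ voxels) |
| `search_radius` | 3 | voxels | half-width of the exhaustive search window (7³ offsets) |
| `select_fraction` | 0.05 | — | fraction of eligible block centres kept |
| `non_connectivity` | vertex | — | prohibited neighbourhood between selected points |
| `youngs_modulus` | 700 | Pa | soft-tissue-scale stiffness; only the ratio to S matters |
| `poisson_ratio` | 0.45 | — | near-incompressible tissue |
| `balance` (λ) | 1 | — | data-vs-regularizer trade-off |
| `outlier_fraction` | 0.05 | — | fraction of current inliers dropped per LTS round |
| `n_outlier_iters` | 5 | — | LTS rejection rounds |
| `n_interp_iters` | 10 | — | approximation→interpolation rounds |
| `mesh_spacing` | 20 | mm | pitch of the built-in rectilinear mesh |
| `linear_tol` | 1e-10 | — | relative residual demanded of each sparse solve |

The displacement search is integer-voxel and translational only; there is
no subvoxel refinement, so a matched displacement is always a lattice
vector of the fixed grid. Ties in NCC are broken toward the smallest
offset norm, then lexicographically — preferring the smallest motion is
the conservative choice and makes the search fully deterministic.
Negative correlations are clamped to zero confidence: an anti-correlated
match signals mismatch, not "negative trust".

Variance ranking uses the population (divide-by-m) variance; only the
ranking matters. Ties are broken by lexicographic index order, making
selection deterministic. The eligibility margin uses
`search_radius + block_radius` so the downstream matcher can never read
out of bounds, and a block is "in the mask" when its centre voxel is — the
margin rule is about centres, and requiring whole blocks inside thin masks
would starve the selector.

## The matching stiffness S

`S_k = λ · c_k · (n/p) · S_k^avg` couples the data term to the elastic
model: `c_k` weights by matching confidence, `n/p` removes the dependence
on mesh and point-set sizes, and `S_k^avg` carries stiffness units so both
energy terms are commensurable. `S_k^avg` is implemented as `σ·I` with

    σ = trace-average diagonal stiffness block of a fully-connected
        interior node of K   (fem_solver.average_node_stiffness)

so that a registration point resists displacement like an interior mesh
node — this realizes the "elastic node" role of the matching term and
makes the approximation→interpolation iteration contract at a useful rate
(a σ much smaller than a nodal stiffness makes the data force too weak to
cancel the internal stress in few iterations). `σ` can be overridden via
`SolverParams.stiffness_scale`. With structure tensors enabled,
`S_k^avg = σ·d·T_k/trace(T_k)`: the match then constrains mainly the
edge-normal direction, the component that local intensity can actually
observe (aperture problem); a zero tensor falls back to the isotropic
block.

## The robust loop

Phase 1 (least-trimmed-squares flavour): solve `[K+HᵀSH]U = HᵀSD (+F)`,
rank current inliers by the unweighted residual norm `‖(HU−D)_k‖`
(unweighted, so rejection is independent of the confidence scaling), drop
the worst `outlier_fraction`, re-solve. The elastic force `F = KU` is
carried between rejection rounds (switchable via
`SolverParams.force_in_rejection`). Because the per-round drop count is
`floor(fraction · inliers)` with `fraction < 0.5`, the loop terminates
early rather than ever emptying the point set.

Phase 2: iterate `U_{i+1} = [K+HᵀSH]⁻¹[HᵀSD + K U_i]` on the final inlier
set. Writing `e_i = HU_i − D`, the iteration is
`e_{i+1} = (I − H A⁻¹ HᵀS) e_i`: the residual decays mode-by-mode at rate
`1/(1+μ)` where `μ` measures how strongly the data observe the mode
relative to its elastic energy. Consequences worth knowing:

* on clean mesh-representable data with every element sampled, the max
  residual decays below 10% of its initial value within the default 10
  rounds and is monotone non-increasing;
* a nodal mode touched by no (or almost no) sample points is approached
  arbitrarily slowly regardless of how large S is — this is a property of
  the scheme, not a defect, and is why the convergence tests use
  well-distributed sample points.

Linear systems are solved by SuperLU factorisation of the sparse symmetric
matrix, with one iterative-refinement step if the relative residual
exceeds tolerance; a dense direct solve is used as the oracle in tests.

## Mesh

The built-in mesh is an axis-aligned quad4/hex8 grid: per axis
`ceil(extent/spacing) + 1` cells centred on the bounding box of masked
voxel centres, giving at least half an element of symmetric overhang so
every boundary voxel is strictly interior (no edge-of-domain
extrapolation). Cells containing no masked voxel centre are pruned and
orphan nodes removed, so the stiffness matrix carries no fully-exterior
elements. Node ordering follows the VTK convention, and user tetrahedral
meshes (e.g. anatomically adapted ones) are read from VTK legacy files;
tet4 is read-only — the package does not generate tetrahedral meshes.
Stiffness integration uses 2-point Gauss per axis (quad/hex) and the
1-point rule (tet4); 2D problems use plane strain. Point location uses the
exact per-axis affine inverse on rectilinear meshes, the barycentric solve
for tet4, and Newton inversion of the multilinear map otherwise.

## Field handling

The dense field is rasterized on the moving grid (the mesh lives on the
moving image's mask) and points moving → fixed. Warping the moving image
is backward: `output(x) = moving(x + g(x))` needs the inverse field `g`,
computed by the fixed-point iteration `g ← −f(x + g)` with 0.5 damping
whenever the update stops shrinking (max 50 iterations, 0.01 mm
tolerance). Out-of-mesh voxels get zero displacement and are counted in
the report; out-of-image warp samples get intensity 0.

## Synthetic evaluation protocol

The fixture generator emulates a sparse-to-dense recovery study with exact
ground truth: a textured phantom (Gaussian-filtered noise inside an
ellipse/ellipsoid mask), an analytic fold-free deformation field, edge
points of the phantom (gradient-magnitude threshold at 25% of the maximum
— simpler and exactly specifiable, in place of a Canny detector), and the
exact field value at each edge voxel as the sparse payload. Prescribing
the field analytically is stronger than deriving it from a registration:
the oracle has no error of its own. The default study is a 128×128 image
at 1×1 mm with a 20 mm rectilinear mesh and a 6 mm-amplitude field of
32 mm correlation length; the boundary support window uses a 16 mm margin
because the window ramp alone contributes slope ≈ amplitude·π/(2·margin),
which must stay below 1 to keep the map fold-free. A finite-difference
Jacobian scan rejects folding parameter combinations outright.

Under those conditions the pipeline recovers the field with ≈0.5 mm mean
error (seed 1; other seeds range ≈0.5–1.5 mm as the random field's local
curvature varies relative to the 20 mm elements), and with 10% injected
gross outliers (norms in [30, 60] mm) the default LTS schedule captures
all labelled outliers and the recovered field's mean error stays within
~1.2× the clean run.

What the synthetic tests do *not* show: robustness to MRI intensity
inhomogeneity, noise, resection cavities, or real anatomical geometry —
the phantom texture is stationary and the mask convex. Clinical use also
requires a prior rigid alignment and a segmentation mask, both outside
this package's scope.

## Problem sizes

Tests and the acceptance script run 2D studies at 128×128 and 3D studies
at 36³–48³ with meshes of 27–64 elements; these sizes exercise every code
path (selection, matching, assembly, LTS, inversion) while keeping the
whole suite under a minute of compute. The implementation is dimension-
and size-agnostic; clinical-resolution volumes simply take longer in the
pure-Python matching loop.

## Known limitations

* NCC is the only similarity metric (no MSD or mutual information).
* No subvoxel matching: the sparse field is quantised to the voxel
  lattice, so the FEM smoothing is also what removes quantisation noise.
* No multiresolution search: motions beyond `search_radius` voxels are
  invisible to the matcher.
* K carries no Dirichlet boundary conditions; heavily clustered or
  near-collinear point sets can leave the system singular.
* The LTS schedule always trims `fraction` per round, even on clean data;
  the trimmed points are simply re-fitted by the elastic model.
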