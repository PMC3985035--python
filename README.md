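# pbnrr — physics-based non-rigid registration

`pbnrr` registers volumetric medical images non-rigidly by combining local
block matching with a linear-elastic biomechanical model. The motivating
use case is image-guided neurosurgery: during a craniotomy the brain shifts
and deforms, so the preoperative (moving) MRI must be warped onto the
intraoperative (fixed) MRI before it can keep guiding the surgeon. The same
machinery applies to any intra-patient registration problem where the
deformation should be physically plausible and the similarity signal is
sparse and noisy.

The pipeline has three stages:

1. **Feature point selection.** Candidate block centres inside a binary
   object mask are ranked by the intensity variance of a small
   `(2r+1)^d` block; a *prohibited connectivity* (face/edge/vertex
   neighbourhood) suppresses crowded selections, and a boundary margin of
   `search_radius + block_radius` voxels keeps every later search window
   in-bounds. Optionally each point carries its structure tensor
   `Σ ∇I ∇Iᵀ`, whose eigenstructure encodes the local edge orientation.
2. **Block matching.** For each feature point the block of the moving
   image is compared, by normalized cross-correlation, against every
   integer-voxel translation within a search window of the fixed image.
   The exhaustive argmax yields a sparse displacement field `D` (physical
   mm, moving → fixed) and per-point confidences `c_k = max(NCC, 0)`.
3. **Robust finite-element solve.** The dense nodal displacement `U` on a
   quad4/hex8/tet4 mesh of the object minimises

   ```
   W(U) = Uᵀ K U + (H U − D)ᵀ S (H U − D)
   ```

   where `K` is the linear-elastic stiffness matrix, `H` interpolates
   nodal displacements to the `p` matching points through element shape
   functions, and `S` is block-diagonal with
   `S_k = λ · c_k · (n/p) · S_k^avg`. The stationarity condition gives
   `[K + HᵀSH] U = HᵀS D`. Outliers are rejected by a least-trimmed-squares
   loop (solve → rank residuals → drop the worst fraction → re-solve), then
   the external-force iteration `U_{i+1} = [K+HᵀSH]⁻¹[HᵀSD + K U_i]`
   drives the solution from the smooth approximation toward interpolation
   of the surviving inliers.

The nodal solution is rasterized to a dense displacement field on the
moving grid, inverted by damped fixed-point iteration, and used to warp the
moving image. Evaluation helpers (directed Hausdorff distance, landmark
error) are included.

## Worked example

The package ships a synthetic-fixture module that reproduces a
sparse-to-dense recovery study with exactly known ground truth: a textured
128×128 phantom at 1 mm spacing, a smooth fold-free deformation of 6 mm
peak amplitude, and exact field samples at the phantom's edge voxels.

```python
import numpy as np
from pbnrr.synthetic import (PhantomSpec, DeformationSpec, make_phantom,
                             make_deformation, sample_sparse_field)
from pbnrr.fem_solver import MaterialParams, SolverParams
from pbnrr.mesh import build_rectilinear_mesh
from pbnrr.registration import solve_scattered_data, rasterize_field

phantom, mask = make_phantom(PhantomSpec(shape=(128, 128), spacing=1.0, seed=1))
truth = make_deformation(DeformationSpec(amplitude_mm=6.0, smoothness_mm=32.0,
                                         seed=1), phantom)
sparse = sample_sparse_field(truth, phantom, edge_threshold=0.25)
mesh = build_rectilinear_mesh(mask, element_spacing=20.0)
states, kept = solve_scattered_data(sparse.points, sparse.payloads, mesh,
                                    MaterialParams(), SolverParams())
dense = rasterize_field(mesh, states[-1].U, phantom)
err = np.linalg.norm(dense.vectors - truth.vectors, axis=-1)[mask.pixels != 0]
print(f"sparse points: {len(sparse)}, mesh: {mesh.n} nodes / {len(mesh.elements)} elements")
print(f"rejected as outliers: {int((~states[-1].inlier_mask).sum())}")
print(f"recovery error: {err.mean():.2f} +/- {err.std():.2f} mm (max {err.max():.2f})")
```

prints

```
sparse points: 611, mesh: 52 nodes / 37 elements
rejected as outliers: 136
recovery error: 0.49 +/- 0.29 mm (max 1.10)
```

i.e. from 611 exact edge samples the 20 mm bilinear mesh recovers the 6 mm
deformation with half-voxel mean error; the rejected points are those whose
local deformation the coarse mesh cannot represent, trimmed by the LTS
schedule (5% of inliers per round, 5 rounds).

## Command line

```
pbnrr synth           --shape 128,128 --amplitude 6 --outdir fixtures/
pbnrr select-features --image moving.nii.gz --mask mask.nii.gz --out feats.csv
pbnrr block-match     --fixed fixed.nii.gz --moving moving.nii.gz \
                      --features feats.csv --out-displacements d.csv \
                      --out-similarities s.csv
pbnrr make-mesh       --mask mask.nii.gz --spacing 20 --out mesh.vtk
pbnrr fem-solve       --mesh mesh.vtk --displacements d.csv --similarities s.csv \
                      --reference-image moving.nii.gz --out-field field.nii.gz
pbnrr register        --fixed fixed.nii.gz --moving moving.nii.gz \
                      --mask mask.nii.gz --out-field field.nii.gz \
                      --out-warped warped.nii.gz --report report.json
pbnrr evaluate        --edges-a a.csv --edges-b b.csv
```

`register` runs the whole pipeline; the JSON report records point counts,
per-iteration energies and residuals, and rejected-outlier counts.

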