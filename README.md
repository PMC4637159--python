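# purkinje3d

Image-based structural modeling of the cardiac Purkinje network: project a
flat, photograph-derived network tracing onto the endocardial surface of a
voxelized ventricular model, and validate the resulting 3D structure by
simulating Purkinje-driven ventricular activation in two coupled
monodomain models.

**Who it is for.** Computational cardiac electrophysiologists who have (a)
a ventricular anatomy as a phase-field volume on a regular grid and (b) a
digitized Purkinje network image with coupling sites marked at fiber tips,
and who want an anatomically grounded ventricle–Purkinje conduction model
rather than a hand-drawn or fractal network.

## Method in brief

1. **Curvilinear chart.** A closed Bézier curve `C` (arc length `s ∈
   [0, L]`, outward normals `N(s) = [[0,1],[−1,0]] C′(s)`) approximates the
   endocardial cross-section. The inverse-distance average of the normals,

   `V(x) = ∮ N(s) d(x,C(s))⁻¹ ds / ∮ d(x,C(s))⁻¹ ds`,

   converges to `N` on `C`; trajectories of `dx/dt = V(x)` induce
   curvilinear coordinates `(s, t)` in which the cylinder `C × R` is the
   surface `t = 0`. On a circle the chart is exactly polar coordinates.
2. **Texture projection.** The binary network image `T` is placed on the
   cylinder through a rectangle `[a,b]×[c,d]` in `(s, z)`; extending its
   values along trajectories defines `F(x,y,z)`, and evaluating `F` inside
   a thin endocardial voxel shell (chamber flood-fill → spherical-kernel
   convolution, entries > 1 → intersect tissue) yields the 3D network and
   its coupling-site voxels.
3. **Coupled simulation.** Monodomain excitation (two-variable membrane
   model; Purkinje diffusivity 20× ventricular, so conduction is √20
   faster) with two-way resistive exchange at the coupling sites, in two
   constructions: *3D-3D* (network voxelized on the ventricular grid) and
   *3D-2D* (network solved on its own pixel raster, spacing
   `Δx = (b−a)/W`, `Δy = (d−c)/H`).
4. **Comparison.** Per-node activation-time differences
   `A₃ − A₂ + c` under three offsets — stimulus start (`c = 0`), first
   activation (`c = −(f₃−f₂)`), and the least-squares offset
   (`c = −mean(A₃−A₂)`) — reported as RMS / std / min / max.

No anatomical data ship with the package; a fixtures module generates
phase-field ventricles (ellipsoid pair, exact cylinder, hollow sphere) and
branching network images with terminal coupling sites, all bit-reproducible
from a seed.

## Worked example

```bash
purkinje3d synth --seed 7 --out fixtures/
purkinje3d simulate --model 3d3d --phase fixtures/cylinder_phase.nii \
    --network fixtures/network.png --sites fixtures/sites.csv \
    --seed-voxel 32 32 24 --config fixtures/run.yaml --out sim/
purkinje3d simulate --model 3d2d --phase fixtures/cylinder_phase.nii \
    --network fixtures/network.png --sites fixtures/sites.csv \
    --seed-voxel 32 32 24 --config fixtures/run.yaml --out sim/
purkinje3d compare --a sim/activation_ventricle_3d3d.nii \
    --b sim/activation_ventricle_3d2d.nii --scheme all --out sim/metrics.csv
```

The compare step prints (cylinder fixture, seed 7):

```
          scheme         c      rms      std       min      max  n_common  n_excluded
  stimulus_start  0.000000 4.998645 0.680458  3.312204 6.174403     57024      139584
first_activation -4.309045 0.936248 0.680458 -0.996841 1.865357     57024      139584
         min_rms -4.952113 0.680458 0.680458 -1.639909 1.222289     57024      139584
```

Reading: both models fully activate the ventricles from a His-bundle-only
stimulus; on the shared stimulus clock the 3D-3D model here runs ≈ 5 ms
behind the 3D-2D model (a constant lag — the voxelized network's staircase
paths are slightly longer than the flat raster's), and once that constant
offset is removed the two activation sequences agree to 0.68 ms RMS over
all 57 024 tissue voxels. `n_excluded` counts non-tissue grid nodes.

The same pipeline is available as a library; see
`purkinje3d.pipeline.map_network` / `build_models` and
`purkinje3d.coupled.run_simulation`.

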