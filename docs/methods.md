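# Methods

## Problem

The cardiac Purkinje network is a fast-conducting fiber system lying on the
endocardial (inner) surface of the ventricles. It can be photographed after
dissection and Lugol staining, and traced into a flat binary image with
coupling sites (Purkinje–myocardial junctions) marked at fiber tips — but
the photograph is two-dimensional. This package reconstructs a
three-dimensional network structure by projecting the flat image onto the
endocardial surface of a voxelized ventricular model, and validates the
reconstruction by simulating ventricular activation driven purely through
the network in two coupled electrophysiological models.

## Curvilinear projection chart

The endocardial surface is approximated by a right cylinder whose base is a
closed planar curve `C : [0, L] → R²`, represented as a closed piecewise
cubic Bézier spline through user-chosen control points and reparameterized
by arc length through a dense chordal sampling (200 samples per segment;
closed-form Bézier arc length does not exist). The curve must be simple
and counterclockwise; clockwise input is reversed automatically. The
outward unit normal is `N(s) = [[0,1],[-1,0]] C'(s)`.

The chart is induced by the inverse-distance-weighted average of the curve
normals,

    V(x) = ∮ N(s) / d(x, C(s)) ds  /  ∮ 1 / d(x, C(s)) ds ,

whose defining property is `V → N` on the curve (both integrals diverge
there). Trajectories of `dx/dt = V(x)`, seeded at evenly spaced arc
lengths and integrated forward (outward) and backward (inward), foliate a
neighbourhood of `C`; a point's curvilinear coordinates `(s, t)` are the
seeding arc length of its trajectory and the signed path length along it
(`t < 0` inside the curve — the sign is a bookkeeping convention; texture
values are constant along trajectories, so only `s` fidelity matters).
On a circle of radius R the construction degenerates to polar coordinates
(`s = Rθ`, radial rays), which is the analytic oracle used throughout the
tests.

Numerics: periodic trapezoid quadrature over 512 curve nodes (spectrally
accurate for smooth closed curves); on-curve evaluations substitute the
limit `N(s)`. The field is precomputed on a regular grid at the
ventricular voxel spacing and interpolated bilinearly. Trajectories use
classical fixed-step RK4 on the unit-normalized field, so the step
parameter is path length — a pure reparameterization of the artificial
time variable that leaves traced paths unchanged. 256 seed trajectories
by default; the gridded `s`/`t` maps are built by inverse-distance
weighting over the 4 nearest trajectory points, with `s` interpolated on
the unit-circle embedding `(cos 2πs/L, sin 2πs/L)` to avoid a seam at the
`s = 0/L` branch cut. Cells farther than 2 grid cells from any trajectory
point are left uncharted and counted. Trajectories that stagnate (e.g. at
the interior singular point where `V = 0`) are truncated and flagged.

## Geometry: phase fields and the endocardial shell

Ventricles are phase fields `φ ∈ [0,1]` on a uniform grid (0.025 cm
spacing throughout, matching the anatomical datasets this method targets).
The chamber cavity is the 6-connected component of `{φ < 0.5}` containing
a seed voxel. The endocardial shell is extracted by convolving the
chamber indicator with a voxelized spherical kernel (default radius
3 voxels), keeping counts strictly greater than 1, and intersecting with
the tissue `{φ ≥ 0.5}`; the shell overlaps the wall by roughly the kernel
radius. The cylinder axis must be a principal grid axis; rotating
misaligned data is out of scope.

Synthetic geometries (the package ships no anatomical data): a hollow
sphere, an exact right cylinder (zero approximation error, used for
oracle tests), and an ellipsoid pair — two ellipsoidal cavities sharing a
septal wall inside one tissue ellipsoid, emulating a two-chamber
topology. Boundaries use a 2-voxel tanh profile as phase-field methods
require; the ellipsoid cavities carry a small seeded low-order angular
perturbation (default amplitude 0.5 voxel) so the fixture is not
perfectly symmetric. What these fixtures do **not** emulate: real wall
thickness variation, trabeculation, fiber orientation, or valve
openings — so passing tests demonstrate correctness of the mapping and
coupling machinery, not anatomical fidelity on real hearts.

## Texture placement and projection

The network image `T : [0,W]×[0,H] → {0,1}` is positioned on the cylinder
through a rectangle `[a,b]×[c,d]` in `(s, z)` coordinates; pixel
`(u1, u2)` lands at `s = a + (u1/W)(b−a)`, `z = c + (u2/H)(d−c)`. Aspect
ratio may be preserved (`(b−a)/(d−c) = W/H`) but usually is not — covering
the endocardium realistically requires distortion, which is logged. The
extended texture `F(x,y,z)` looks up `s` from the chart at `(x,y)` and is
constant along trajectories by construction. Pixel convention: origin at
the image's lower left, `u1` rightward → increasing `s`, `u2` upward →
increasing `z`; files with top-left origin are flipped on read. Binary
lookups use the nearest pixel.

The 3D network is the set of shell voxels where `F = 1`, augmented and
repaired for electrical connectivity:

1. **Forward pass** — every fiber pixel also contributes the shell voxel
   nearest (3D Euclidean) to its `(s, z)` trajectory; thin 1-pixel fibers
   otherwise slip between voxel centers.
2. **Face-connectivity repair** — the diffusion stencil couples only
   face-adjacent (6-neighbor) voxels, so voxel pairs whose source pixels
   are 8-adjacent are joined by staircases of face steps constrained to
   the shell.
3. **Fragment merge** — any residual 6-connectivity fragments are joined
   along shortest face-step paths *within the shell* (breadth-first
   search), largest component first.

Coupling sites map to the shell voxel nearest their `(s, z)` trajectory
(ties resolve to the lowest linear voxel index; sites farther than
3 voxels are reported unmapped). The same rule serves both coupled
models, so they couple at identical shell voxels. 2D network rasters fed
to the 3D-2D model should be 4-connected (the synthetic generator inserts
an elbow pixel at each diagonal stroke step); 8-connected-only strokes
would be electrically broken on the 2D grid.

## Electrophysiology

Monodomain reaction–diffusion, `∂v/∂t = −I_ion + ∇·(D∇v)`, with the
two-variable membrane model

    −I_ion = h v²(1−v)/τ_in − v/τ_out
    dh/dt  = (1−h)/τ_open  if v < v_gate,  else  −h/τ_close .

Defaults (ms): τ_in 0.3, τ_out 6, τ_open 120, τ_close 150, v_gate 0.13 —
standard values for this model family, configurable; the gate advances by
the exact exponential solution of its piecewise-linear ODE, keeping
`h ∈ [0,1]` unconditionally. `v` uses explicit forward Euler with the
phase-field no-flux discretization: edge weights
`w_ij = ½(φ_i+φ_j)·½(D_i+D_j)/h²` are symmetric, so the scheme is in
divergence form and conserves `Σ φ_i v_i` exactly under pure diffusion.
The construction-time stability bound `dt ≤ 1/max_i(Σ_j w_ij/φ_i)` reduces
to `h²/(2·dim·D)` on a uniform interior; runs reduce `dt` automatically
when a domain (typically the fine 2D raster) demands it. Diffusivities:
ventricle `D₀ = 0.001 cm²/ms` isotropic; Purkinje `20·D₀`, which speeds
conduction by √20 ≈ 4.47 (verified on cable fixtures to < 2%). Scalar,
per-node and per-node *diagonal* tensors are accepted; full anisotropic
tensors with off-diagonal terms are not (no fiber-orientation data ship
with the package). Activation is the first upward crossing of `v = 0.5`,
linearly interpolated between steps.

The inner step kernel is numba-compiled when numba is available; a numpy
gather implementation is the reference and fallback. Both are
deterministic.

## Coupled models

**3D-3D**: ventricle and projected network solved on the same voxel grid
as separate variables; **3D-2D**: the network solved on its own pixel
raster, one node per pixel, with physical spacing `Δx = (b−a)/W`,
`Δy = (d−c)/H` (the placement rectangle converted through
ventricular-grid-index units — one texture pixel is one 2D node). Each
step advances both domains independently (phase 1), then every coupled
pair relaxes toward its mean (phase 2) by the exact exponential update

    δ = ½(1 − e^(−2 g_c dt)) (v_P − v_V),   v_V += δ,  v_P −= δ,

which equals the forward-Euler resistive exchange to first order, is
unconditionally stable in `g_c`, conserves the pairwise sum, and clamps
the pair together as `g_c → ∞`. Default `g_c = 100/ms`: a junction is a
small current source against a 3D diffusive sink near the liminal
(nucleation) size at 0.025 cm resolution, so it must hold its voxel near
the Purkinje plateau for the handover to ignite a ventricular wave;
weaker coupling (≲ 50/ms at a deep interior voxel) fails to nucleate.
Endocardial surface voxels see roughly half the sink, which is the regime
the models operate in. The His-bundle stimulus (default 50/ms for 2 ms on
the flagged bundle node) must likewise beat the 20×-diffusivity sink of
the network it targets. Sites pushed across threshold by the exchange
itself are time-stamped at the end of the step.

## Activation comparison

Per-node first-activation maps of the two models are compared through
`d(x) = A₃(x) − A₂(x) + c` under three offsets: `c = 0` (shared stimulus
clock), `c = −(f₃−f₂)` (clocks re-zeroed at each model's first
activation), and the least-squares offset, whose closed form is
`c = −mean(A₃−A₂)` (the brute-force grid search is retained as a test
oracle only). RMS, standard deviation, min and max are reported; offsets
shift but never reshape the distribution, so the standard deviation and
range width are scheme-invariant. Only nodes finite in both maps enter
the statistics; the exclusion count is reported. Statistics are computed
over the full common node set (no per-ventricle split).

## Problem sizes and expected behaviour

The shipped reference fixture uses an 80³ ellipsoid pair, a 64×64×48
cylinder and a depth-4 (16-site) network at 0.025 cm — sizes chosen so
the full suite and the reproduction script each run in minutes on one
CPU; full-size grids (≈ 400³) are supported by the same code. On the
reference fixture a bundle-branch-only stimulus fully activates both
models' ventricles in ≈ 40–60 ms of simulated time, the first ventricular
voxels to activate are coupling sites, and the two models' ventricular
activation maps agree to ≈ 0.3–1.5 ms RMS after the least-squares offset
(sub-millisecond on the distortion-free cylinder). These numbers are
whatever the tests and `scripts/acceptance.py` compute at run time; none
are hard-coded.

## Known limitations

- Charts of strongly non-convex curves can have multivalued regions far
  from the curve; the chart flags coverage gaps but does not resolve
  crossings (only cylinder-like surfaces are supported).
- The region near the chart's interior stagnation point has noisy `s`;
  projections are reliable on the shell, not near the cavity axis.
- Staircase voxelization lengthens 3D network paths slightly relative to
  the flat raster, so the 3D-3D network tends to conduct marginally
  slower than the 3D-2D raster at equal diffusivity.
- Junctional behaviour is symmetric: no anterograde/retrograde asymmetry
  or junctional delay; no bidomain model; no ECG.
- Automatic curve fitting (`synth_curve_for`) is a convenience for
  synthetic chambers; real anatomies warrant manually chosen curves.
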