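# Methods

`airwayseg` segments the pulmonary airway tree in chest CT by wavefront
propagation constrained to adaptively sized quasi-spherical regions, with
leak detection, threshold decay, and morphological sealing of
low-brightness tracheal-wall gaps. This note describes the model, its
parameters, the synthetic phantoms used to exercise it, and the design
choices made where the method left room.

## The segmentation model

### Quasi-spherical constraint regions

Segmentation proceeds region by region. The seed set of a region is a
*seed surface*: the 26-connected patch where the previous region's result
crossed that region's boundary shell (the very first region uses a single
user-supplied trachea voxel). Because such a surface approximates the
airway cross-section, its voxel count stands in for the cross-sectional
area and fixes the region radius

    R = 3 * ceil(area / 100) + 5,

never below 8 voxels. The constraint region is the dilation of the seed
surface by a Euclidean ball of radius `R` — ball-like, but shaped by the
surface, hence *quasi-spherical*. Its boundary shell is the region minus
the dilation by `Sphere(R-1)`, and the *restricted image* equals the CT
block inside the region and the CT floor (−2048 HU) outside. Dilation by
`Sphere(R)` is evaluated through the exact Euclidean distance transform
(`distance ≤ R`), which is voxel-identical to structuring-element dilation
and costs the same for every `R` (asserted against explicit dilation in
the tests).

The threshold window of a region comes from the HU values on its seed
surface: `Seed = min`, `Threshold = max − min + 1`. A voxel is *rejected*
when `v − Seed ≥ Threshold`; the criterion is one-sided (anything darker
than the window top is airway-like) and out-of-region voxels are excluded
by region membership, not by the window. On piecewise-constant synthetic
images the surface range collapses to the noise spread, far narrower than
the 100–200 HU dynamic range a partial-volume-affected surface spans in
real CT, so the configuration applies a floor (`initial_threshold_override`,
default 100 HU) to every region's initial threshold. This floor is part of
the study conditions: it restores the operating regime in which airway
leakage is possible at all and the leak machinery has work to do.

### Wavefront propagation and leak rules

Within a region, each iteration dilates the current result by `Sphere(1)`
(the 6-neighborhood), keeps the candidates passing the threshold
criterion, and superposes them; the region ends when nothing new is
accepted. Two leak rules watch every attempt:

* **iteration cap** `2R + 4`: a front advancing one face-step per
  iteration crosses the region in at most `2R` steps; the slack absorbs
  seed-surface thickness;
* **growth rule**: the voxels accepted in a single iteration may not
  exceed `growth_factor` (default 2.5) times the seed-surface area —
  airway width decreases gradually, so an explosive front means the
  window escaped the lumen.

On a leak the attempt rewinds to the seed surface and the threshold decays
by one; at zero the region is abandoned and handed to gap sealing.
Successful results are hole-filled (6-connected background components not
reaching the crop border), the *bifurcation count* is the number of
26-connected components of result ∩ shell, and radius adaptation shrinks
`R` by 2 while the count is 0 or above 2 (floor 8). Boundary components
whose area exceeds `area_factor` (default 1.5) times the seed area fail
the gradual-width rule and are dropped. A global forbidden mask of
previously segmented voxels blocks backward regrowth, which is what makes
the bifurcation count of a straight tube exactly one. Both the growth and
the area rule are suspended for the single-voxel bootstrap region, where a
seed area of one would cap growth at two voxels per iteration and deadlock
the trachea.

### Tracheal-wall gap sealing

A wall gap is a stretch of wall whose HU has been dragged into the
segmentation window by noise and partial-volume averaging; the front
escapes through it into the parenchyma. Sealing raises the CT value at the
gap voxels to `Seed + Threshold0 + 201` — above every window the loop can
reach — and re-segments with a +1 threshold ratchet that stops when the
threshold has climbed 200 HU above its pre-sealing value (the approximate
lumen/wall contrast at small airways): at that point the gap is either
sealed or unsealable.

Locating an already-crossed breach on noisy digital tubes is the delicate
part. The implementation reasons with the standard chest-CT certainty
bands (below −950 HU definitely airway, above −775 HU definitely not) and
three morphological facts:

1. **wall-slab interior**: a gap voxel is wall material — dark, but with
   certain-wall tissue at least two voxels deep on two opposing sides
   within a combined span of `close_radius + 2`. A breach wider than
   `close_radius + 1` voxels (3 at the default closing radius 2) has
   mid-layers failing this test, which reproduces the method's 3-voxel
   sealing limit without any extra rule.
2. **true-airway side**: derived from the settled clean segmentation by
   removing wall-slab voxels and keeping the components holding the seed
   surface; removed components are reattached when everything beyond them
   is definitely-airway material (pinched or tilted digital lumen), judged
   on the *neighborhood* HU of each far component — member voxels alone
   are biased dark because threshold growing only ever accepts dark
   voxels.
3. **breach mouth**: the leak (everything a free bloom at the working
   threshold reaches beyond the airway side) touching the airway side
   face-on, inside the wall slab, and lying on a short straight all-dark
   line from the airway side to the substantial leak mass beyond the wall.
   Finally, causal pruning re-blooms with candidate components sealed and
   keeps only those whose sealing is necessary to contain the leak.

The *bloom* — letting the error expand to convergence inside the
constraint region before locating it — is essential: the leak rules catch
an escape within an iteration or two, long before the leak is
morphologically visible. Containment is guaranteed throughout because
propagation cannot leave the quasi-sphere. Sealed voxels are written back
to a working copy of the volume, so downstream regions that overlap the
same wall stretch inherit a sealed wall. Boundary surfaces whose median HU
lies above the definitely-airway band are discarded as leak-grown before
they can seed new regions.

The public `locate_gaps` operation implements the purely geometric variant
for *uncrossed* slits: the closing residue `close(X) − X` between two
disconnected masses, width-limited by the opposing-span test and completed
out to the slit mouth where the ball no longer fits. The closing alone
would also bridge slits of width `2 * close_radius`, slightly beyond the
intended sealing range, which is why the span test is part of the
operation.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `region.initial_threshold_override` | 100 | HU | floor on each region's initial threshold width |
| `region.enhancement` / `enhancement_strength` | on / 300 | – / HU | raise the thinned wall sheet found by per-axis gradient maxima |
| `region.enhancement_min_gradient` | 100 | HU | gradient floor so enhancement never fires on noise |
| `region.next_surface_max_hu` | −950 | HU | median-HU ceiling for next-stage seed surfaces |
| `wavefront.growth_factor` | 2.5 | – | per-iteration growth limit as a multiple of seed area |
| `wavefront.area_factor` | 1.5 | – | boundary-surface area limit |
| `wavefront.radius_step` | 2 | voxels | radius decrement per adaptation step (floor 8, fixed) |
| `wavefront.iteration_slack` | 4 | iterations | slack on the 2R iteration cap |
| `sealing.close_radius` | 2 | voxels | ball radius for gap morphology; seals gaps up to 3 voxels |
| `sealing.cap` | 200 | HU | threshold ratchet bound (method constant, read-only) |
| `run.max_regions` | 10000 | – | safety valve on the region stack |

All geometry is in voxel units; spacing enters only when converting
evaluation metrics to millimetres.

## The synthetic phantoms

The generator rasterizes a binary tree of straight cylindrical segments by
exact distance-to-segment: lumen (`d ≤ r`), a wall shell of fixed
thickness (`r < d ≤ r + t`), parenchyma elsewhere. The root enters through
the z = 0 face like a trachea in a real scan; bifurcation planes alternate
so the tree spreads in 3D; child radius and length decay geometrically.
Ground truth (lumen, wall, per-branch centerlines) is voxel-exact, and the
exact-distance rasterization guarantees a continuous wall: a 6-connected
path from lumen to parenchyma must cross the shell.

Default palette: lumen −1000, parenchyma −940, wall −400 HU, Gaussian
noise sd 10, rounded and clamped at −2048. The parenchyma sits at the dark
end of the uncertain band, close enough to the lumen that realistic
~100 HU windows reach it — the regime in which leakage happens and the
constraint region and sealing have observable work. A brighter parenchyma
would make every threshold trivially safe and the leak machinery dead
code. Wall gaps are rings of chosen axial extent written into the wall at
a chosen HU; the study conditions use −970 (a gap so severe it reads as
airway, which survives threshold decay and guarantees measurable leakage
when sealing is off) and −935 (the canonical low-brightness wall in the
uncertain band).

What the phantoms do **not** emulate: partial-volume blur (plateaus are
sharp), cartilage rings, vessels and lung texture, curved or tapering
airways, anisotropic spacing. Passing the phantom suite therefore
demonstrates the mechanics of the method — initialization formulas,
containment, leak detection, sealing, the width limit, determinism — not
clinical performance; headline numbers on clinical data depend on exactly
the image properties the phantoms idealize away.

## Numerical choices and degenerate inputs

* 0-based `(x, y, z)` indices; half-open crop boxes; 26-connectivity for
  component labeling of surfaces and masks, `Sphere(1)` (6-neighborhood)
  for propagation and hole filling.
* Components and the surface stack are ordered by each component's
  lexicographic minimum voxel; the stack is LIFO. Together with seeded
  noise this makes every run bit-reproducible.
* Hole filling runs once per region at acceptance, not per iteration.
* Wall enhancement marks local maxima of |forward difference| per axis
  (at or above the gradient floor), takes the brighter voxel of each
  difference pair, collapses runs along the differencing axis, and unions
  the three axis maps — producing the one-voxel-wide wall sheet that a
  curve-skeletonization thinning would destroy.
* `sealing_loop` re-segments only in rounds that sealed new voxels; when
  nothing new is sealable the result provably cannot change, and the
  round degenerates to a threshold-ratchet increment, so the 201-round
  cap path costs seconds, not minutes.
* The clamp-not-reject rule at the CT floor tolerates scanner padding
  values below −2048.

## Known limitations

* Gap localization is accurate to about one voxel: sealed voxels can
  include the diagonal neighbors of the true ring (the breach mouth seen
  from the leak side).
* On strongly tilted branches the digital staircase of a thin wall slab
  degrades the wall-interior classification; the causal-pruning and
  reattachment safeguards prevent damage, but a tilted gap may end in the
  threshold cap (conservative truncation) rather than a seal. The study
  conditions place gaps on the axis-aligned main bronchus for this
  reason.
* A genuinely narrow airway (diameter comparable to the closing radius)
  can be mistaken for wall interior; the reattachment and causal-pruning
  steps exist to release such false candidates, but a narrow mutation
  immediately next to a true gap may lose a few voxels of lumen.
* A marginal leak — a window that barely grazes the parenchyma — may not
  produce enough leak mass for the detector's noise floor (27 voxels), in
  which case decay handles containment and the region exits through the
  cap.
* Sealing gaps wider than 3 voxels is out of reach by construction; such
  gaps end in the 200-HU cap with the leak confined to the failed region.
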