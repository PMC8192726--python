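# Methods

`hiervess` segments vascular structures in large 3D light-sheet microscopy
volumes with a hierarchical random-walker scheme, extracts a centerline
graph from the binary result, prunes it with a dimensionless branch
statistic, and reports vessel morphometrics.  This note records the model,
its parameters, the numerical choices, and what the synthetic validation
does and does not demonstrate.

## Seeded random walker

For a voxel lattice with intensities $I$, each unlabeled voxel is assigned
the probability that a random walker started there reaches a foreground
seed before a background seed.  The field $p$ is the solution of the
discrete Dirichlet problem on the 6-connected lattice graph with edge
weights

$$w_{ij} = \exp\!\big(-\beta\, ((I_i - I_j)/s)^2\big) + w_{\min},
\qquad w_{ij} \leftarrow w_{ij} / h_{ij}^2,$$

where $s$ normalizes intensity differences to $[0,1]$ (by default the
global intensity range of the volume, so that every brick of a large
volume uses the same contrast model), $h_{ij}$ is the physical edge length
(voxel spacing in micrometers; anisotropy-aware), $\beta = 90$ controls
contrast sensitivity, and $w_{\min} = 10^{-5}$ keeps the lattice connected
where the Gaussian term underflows.  Seeds are clamped to 1 (foreground)
or 0 (background); every unconstrained voxel satisfies the harmonic
condition $p_i = \sum_j w_{ij} p_j / \sum_j w_{ij}$, which implies
$p \in [0,1]$ (maximum principle) and exact complement symmetry under
seed-set swap.

The sparse SPD system is solved by conjugate gradients with Jacobi
preconditioning, initial guess 0.5, and an internal relative-residual
target two orders below the configured tolerance (`solver_tol`, default
$10^{-6}$), so the harmonicity residual of the returned field stays well
within $10\times$ the configured tolerance.  Systems with at most ~1200
unknowns go through a sparse direct solve.  Everything is deterministic.

## Octree pyramid and hierarchical refinement

The volume is stored as a bricked level-of-detail pyramid: cubic bricks
(default $32^3$ voxels), each coarser level obtained by averaging
$2\times2\times2$ voxel blocks (cells truncated at the volume border
average only existing children), until the top level fits a single root
brick.  Levels live in one chunked HDF5 container, chunk = brick, with
attributes for spacing, brick size, level count, and the global intensity
range.  All brick access flows through an instrumented LRU cache; the peak
number of resident bricks never exceeds the configured budget, which is
the contract that lets volumes far larger than memory be processed.  (The
pyramid *build* currently streams level arrays through memory; the
out-of-core guarantee applies to segmentation-time access, which the
instrumentation asserts.)

Segmentation runs coarse-to-fine.  The root brick is solved with the user
seeds scaled to that level (coordinates integer-divided by $2^L$;
duplicates collapse; a coarse voxel receiving both labels is a conflict
and drops out of both sets).  Each finer brick is then solved with the
hard seeds inside it plus soft Dirichlet values on its border, sampled
from the already-solved coarser level (trilinear by default) — the coarse
probabilities act as non-binary border seeds, so large-scale shape flows
down while the fine level refines object borders.  Two mechanisms keep
work far below "solve every brick":

* **Homogeneous pruning.** A brick whose coarse footprint is entirely
  $\ge 1-\varepsilon$ (or $\le \varepsilon$, default
  $\varepsilon = 0.01$), with no seed of the opposite class inside, is
  filled with a constant and its whole subtree skipped.  The footprint is
  padded by one coarse voxel: a structure thinner than a coarse voxel that
  pokes across a brick face is invisible in the unpadded footprint but
  shows in the neighboring cell, and the padding prevents such slivers
  from being misclassified away.
* **Incremental reuse.** On a re-run with edited seeds, a brick is
  re-solved only if its seed content changed or its coarse-supplied border
  values moved by more than `reuse_eps` (default 0.01, L-infinity);
  otherwise the previous brick is reused verbatim.  Unchanged seeds
  reproduce the previous result bit-for-bit with zero solves.

Two design choices here departed from the most literal reading of
"non-binary seeds at the border of the current block", because that
reading does not reproduce the monolithic solver:

1. **Confidence-filtered border values.** Border values are imposed only
   where the coarse level is *decided* — within `shell_confidence_eps`
   (default 0.02) of 0 or 1, eroded by one voxel along the shell.  A
   coarse level cannot localize an object boundary below its own
   resolution; clamping its interpolation ramp onto the fine lattice
   misplaces boundaries by a voxel and shows up as full-swing errors
   against the flat solver.  Transition-zone border voxels are left free,
   so the fine solve positions the boundary from local contrast.
2. **Solve halo.** Each brick is solved on a domain extended by `halo`
   voxels (default 8, a quarter brick), with the Dirichlet shell on the
   extended domain and only the brick's own voxels written back.
   Structures clipped off at a brick face or corner (slivers, enclosed
   background pockets) would otherwise lose their context and drift to
   the wrong class.  If a brick's shell has *no* decided coarse values at
   all (noisy two-level pyramids), the halo is widened to a full brick.
   Bricks within a level still exchange no information — all coupling
   flows through the coarser level — so results are independent of brick
   order.

With these, hierarchical level-0 probabilities agree with the monolithic
random walker to L-infinity $\le 0.05$ on the phantom suite (typically
$\le 0.02$), single-brick volumes are bit-identical, and thresholded masks
match.  Binary segmentation thresholds at 0.5 with ties to foreground.

## Mask cleanup

Median smoothing uses the cubic $(2r+1)^3$ majority (default $r=1$;
edge-truncated neighborhoods use existing voxels only; ties go to
foreground).  Connected components are labeled by a two-pass
brick-streaming algorithm: bricks are labeled independently, equivalences
are collected by re-labeling the two-voxel slabs straddling every brick
boundary plane (this catches face, edge and corner adjacencies for
26-connectivity), and a union-find resolves global labels — peak memory is
one slab plus the label table.  Foreground uses 26-connectivity,
background 6 (the standard dual pair).  Cleanup keeps the largest
foreground component by default (one vascular tree) and fills cavities —
background components with no voxel on the volume hull, e.g. the enclosed
lumen of hollow vessels — so thinning sees solid tubes.  The operation is
idempotent.

## Skeleton, graph, and bulge-size pruning

Thinning follows the 6-subiteration directional border-thinning scheme of
the classic 3D medial-axis algorithm, with point deletability decided by
the standard local simple-point characterization (exactly one 26-connected
foreground component in the 26-neighborhood, and exactly one 6-connected
background component in the 18-neighborhood adjacent to the center);
endpoints (one foreground neighbor) are preserved.  Within one directional
pass, two 26-adjacent voxels are never both deleted: without that guard,
sequential re-checked deletion cascades along two-voxel-wide rods and can
consume a whole straight even-width tube end-to-end (a failure mode we
verified in a widely used implementation).  The guard makes each pass
delete an independent set of simple points, which is topology-safe in any
order and deterministic.  The numba-compiled passes take well under a
second per megavoxel of foreground.

Thinning artifacts are cleaned with scale-free rules:

* leaf chains that never protrude beyond the attachment radius of the
  remaining skeleton (surface ridges) are removed; a genuine side branch
  reaches beyond its parent radius and is kept;
* branch-branch segments shorter than $2\times$ the larger node radius lie
  inside one junction ball and are contracted; self-loops whose reach
  (half length) stays within $2\times$ the node radius are dropped;
* two parallel strands joining the same node pair ("theta" artifacts from
  thinning a junction plate) lose the shorter strand while it is below
  $2\times$ the summed node radii.

Skeleton voxels with one 26-neighbor become endpoint nodes; clusters of
voxels with three or more neighbors collapse to a node at their centroid
(snapped to the nearest cluster voxel); maximal degree-2 chains become
segments.  Centerlines are physical (voxel-centered, micrometers) and
lightly smoothed with a 5-point moving average (endpoints fixed), which
removes most of the staircase length overestimate of rasterized paths.
Radii come from the anisotropy-aware Euclidean distance transform of the
mask, plus half a voxel: the EDT measures to the nearest background voxel
*center* while the physical surface lies about half a voxel closer, and
for vessels only 2–3 voxels in radius the uncorrected value understates
diameters by up to half.

Each leaf segment's **bulge size** is its proper length — total arc length
minus the parent vessel radius at the bifurcation, clamped at zero —
divided by its diameter at the bifurcation.  The diameter is sampled where
the segment emerges from the parent node's radius ball (just outside the
cluster, the distance transform still reflects the junction blob).  Being
a ratio of lengths the statistic is dimensionless: uniform scaling of the
geometry changes no pruning decision, which is what makes one threshold
work across vessels whose radii span orders of magnitude.  Pruning
repeatedly deletes the below-threshold leaf with the *smallest* bulge and
merges any degree-2 node left behind (lengths add exactly; radius samples
concatenate).  Deleting smallest-first matters: a spurious stub attached
mid-segment splits a true vessel in two, and batch deletion could discard
the true terminal piece in the same sweep as the stub, whereas delete-min
removes the stub first and the merge restores the full segment before it
is judged.  It also makes the surviving segment set nested (monotone) in
the threshold.  Isolated segments (both ends degree 1) have no parent and
are never pruned.  The default threshold is 3.0; segments are exported as
CSV tables (all metrics, centerlines as JSON columns), GraphML, and legacy
ASCII VTK polylines.

Straightness is the chord between segment endpoints divided by centerline
arc length (1 = straight).  Both the bifurcation-diameter sampling point
and the straightness formula are interpretation choices; they are local to
`graph.py` and configurable in the obvious places.

## Morphometrics

Per-segment diameter is twice the mean radius sample.  The frequency
histogram uses 2 µm left-closed bins from zero.  Caliber classes are
small ($d < 0.02$ mm), medium ($0.02 \le d < 0.1$ mm), and large
($0.1\,\mathrm{mm} \le d$), boundaries closed upward.  Per class the
report carries five-number summaries (median, quartiles, 1.5×IQR whiskers
clipped to the data).  Totals: summed centerline length (mm); vessel
volume (mm³) by truncated-cone quadrature
$\sum \frac{\pi}{3}(r_i^2 + r_i r_{i+1} + r_{i+1}^2)\,\Delta s$ along the
centerlines, so the volume describes the graph actually reported
(voxel-count volume is also emitted when a mask is supplied); organ volume
as foreground voxel count times voxel volume.

## Synthetic phantoms

The generator grows a seeded binary tree of straight tube segments: a
root centered in the volume, then bifurcations inserted at leaf tips
(shallowest leaves first, so radii stay rasterizable over many
generations), child radius = parent radius × decay (default 0.85), branch
angles 20–60° from the parent axis with roughly opposed azimuths, and a
center-steering fallback when free growth leaves the bounds.  Segment
lengths default to 5.5–7.5× the segment diameter, so every true branch
sits well above the pruning threshold; an absolute length range can
override this for small solver-test volumes.  Candidate segments keep at
least two voxels of clearance from non-adjacent tubes so separate branches
cannot fuse when rasterized.  Solid mode renders voxels within the radius
of any segment (a capsule per segment); hollow mode brightens only a wall
shell — cross-sections show the double-line appearance of lumen-bearing
vessels — and caps terminal openings so the lumen is an enclosed cavity
for the fill step.  Additive Gaussian noise with a seeded generator
completes the image; everything is deterministic per seed.

Spurious stubs for pruning tests attach at fully internal segments
(attaching mid-leaf would legitimately split a true terminal below the
retention length), with length 1.5× their diameter plus the local parent
radius — below the threshold by construction — and are rendered into the
volume but excluded from the ground-truth topology.

Seed annotations emulate an interactive user: foreground strokes along
the true centerlines of (by default) every segment — in the interactive
workflow the user labels each vessel they want measured, and the hierarchy
propagates labels across scales rather than inventing unseeded objects —
plus broad background coverage from a jittered lattice (pitch 12 voxels,
margin 3 voxels from the object), which survives coarse-level seed
scaling.

**What the phantoms do not emulate:** light-sheet PSF blur, shot noise,
stripe artifacts, intensity inhomogeneity, curved or tapering vessels, and
touching/overlapping trees.  Passing the suite shows the solver, pruning
and morphometry machinery are correct and scale-consistent under the
stated conditions; it does not by itself certify recall on real cleared
tissue, where seed placement quality dominates.

## Validation problem sizes

The shipped validation uses 20 phantoms of $16^3$–$64^3$ for
flat-vs-hierarchical equivalence, one $192^3$ phantom with a 16-brick
cache budget for the out-of-core contract, ten $160^3$ stub phantoms for
pruning semantics, trees of 1–10 bifurcations in $128^3$–$224^3$ volumes
for topology recovery, and two $160^3$ phantoms at SNR 5 for the
noisy-pipeline recall check.  These sizes were chosen so the complete
suite and the reproduction script each run in minutes on a single CPU
while still exercising multi-level pyramids, multi-brick coupling, and
radii spanning the caliber classes.

## Known limitations

* Homogeneous-brick pruning is evaluated against a one-voxel-padded
  coarse footprint; objects thinner than half a coarse voxel that never
  register at the coarser level can still be pruned away if no seed marks
  them.  This mirrors the interactive workflow, where the user adds seeds
  where structures are missing.
* The thinning's adjacency guard trades a little extra junction debris
  (handled by the scale-free cleanup rules) for robustness on symmetric
  even-width tubes.
* Vessel volume from centerline quadrature under-reports junction overlap
  volume slightly; the voxel-count volume is reported alongside.
* The stage-level CLI caches by content hash but does not parallelize;
  bricks within a level are independent, so parallel solving would be a
  straightforward extension.
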