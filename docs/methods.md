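# Methods

This note describes the measurement model implemented by `sulcmorph`, the
choices made where the design was genuinely open, what the synthetic data
generator emulates, and the limitations of both.

## Inputs and frames

The estimator consumes four FreeSurfer artifacts per hemisphere: the pial
surface (`?h.pial`), the Destrieux (a2009s) annotation, the convexity
overlay (`?h.sulc`), and the smoothed enclosing surface
(`?h.pial-outer-smoothed`) produced by the gyrification analysis. Only the
binary *triangle*-surface dialect and the *new* scalar-overlay dialect are
read (the ones current FreeSurfer emits); legacy quad and old-curv files are
rejected with explicit format errors rather than risk misparsing. All
coordinates stay in the surface's native RAS frame in mm — every quantity
the package computes is a relative distance, so no volume geometry is
needed. Vertex indices are 0-based internally regardless of on-disk
conventions. The outer surface is consumed as produced by the gyrification
pipeline; the package never reconstructs an outer hull from the pial surface
for real data (the synthetic generator emits its own).

## Sulcus isolation and the boundary edge loop

A face belongs to a sulcus region iff **all three** of its vertices carry
the target label. This is the conservative membership rule: it places the
region boundary strictly between labels, so the extracted loop sits on the
sulcogyral transition. (The permissive any-vertex rule would push the
boundary one face ring into the neighboring gyri and systematically widen
every estimate by about one edge length.)

The region boundary is defined as the set of edges incident to exactly one
region face — a brute-force definition that doubles as the oracle in the
test suite. Chaining starts from the smallest boundary vertex id and follows
the unused boundary edge at each step, tie-breaking toward the smaller
vertex id, so the loop (and everything downstream) is deterministic.

Three conditions make a region un-loopable, and each is reported as a
machine-readable failure value rather than an exception, because a cohort
run must count failures, not crash:

* `discontinuous-region` — the label comprises ≥ 2 edge-connected face
  components (faces sharing only a vertex are *not* connected);
* `multiple-loops` — one component whose boundary has several cycles
  (annulus topology);
* `non-manifold-boundary` — a boundary vertex with more than two incident
  boundary edges (pinch point). No heuristic repair is attempted; a
  pinched boundary is a failure by design, matching the per-sulcus
  exclusion behavior of the measurement procedure. An opt-in
  `allow_largest_component` mode measures the largest patch of a
  discontinuous label and flags the result.

A sulcus failing in more than 10% of a cohort's subjects is flagged by QC as
unsupported for that cohort; the temporal and intraparietal sulci, known to
fail at that rate under Destrieux parcellations, ship behind an
`experimental` switch.

## Width

Every loop vertex contributes one bridge: the nearest loop vertex in 3-D
Euclidean distance (no projection) that is *not neighboring in the loop*,
refined by an exhaustive walk of up to `walk_steps` (default 4, ≤ 9
candidates) cyclic positions around the initial match, still honoring the
exclusion constraint. Width is the median bridge length; an even count takes
the midpoint of the central pair. Distance ties break toward the smaller
cyclic loop distance, then the smaller vertex id — ties occur in symmetric
meshes and must not make output order-dependent.

"Not neighboring" is formalized as a cyclic **exclusion window** (default 5
loop positions on either side). The window is expressed in positions, not
mm, so its physical size scales with mesh resolution; it must be chosen so
the excluded arc length (window × typical edge length) exceeds the widths
being measured, otherwise the nearest admissible candidate is an along-wall
neighbor rather than the opposite bank. The default suits FreeSurfer meshes
(~1 mm edges, widths of a few mm). The recovery studies in the test suite
and acceptance script use regular 0.5 mm meshes with widths up to 6 mm and
therefore set the window to 15 (7.5 mm of excluded arc); the cohort studies
on 1 mm meshes use 8. Short-end loop vertices are *not* excluded from
bridging: robustness is delegated entirely to the median, which keeps the
aggregation rule single and simple.

A loop shorter than `min_loop_size` (default `2·window + 2`, the smallest
loop with any admissible candidate) yields a failed width, reported not
raised.

## Depth

The fundus is the `n_fundus` (default 100) region vertices most extreme in
the convexity overlay, ties broken toward the smaller vertex id; regions
smaller than `n_fundus` use all their vertices and carry a shortfall flag.
Depth is the median of the fundus vertices' shortest Euclidean distances to
the outer surface.

Distances are exact point-to-triangle by default (interior / edge / vertex
case analysis, exhaustive over all outer faces, vectorized and chunked to
bound memory at ~2·10⁶ point-triangle pairs). The outer surface is coarse,
so nearest-*vertex* distance overestimates; that mode is retained for
comparison with implementations that used it, and point-to-triangle ≤
point-to-vertex holds on every query by construction. No spatial index is
used: region sizes (100 fundus points) and outer-surface sizes keep the
exhaustive computation cheap, and exactness makes the oracle comparison
trivial.

Overlay sign conventions differ across toolchain versions, so the deep-end
selector is configurable (`lowest`, the default, or `highest`), and every
depth result is sanity-checked: if the selected fundus is *not* farther from
the outer surface on average than the rest of the region (a deterministic
subsample of ≤ 256 vertices keeps this cheap), the result carries a
`sign-convention-suspect` flag. Euclidean depth underestimates the true
along-wall (geodesic) depth of curved sulci; this is accepted for
robustness, and the synthetic curved-fundus fixtures verify the
underestimation direction explicitly.

## Statistics

ICC(1,1) is computed from one-way ANOVA mean squares,
`(MSB − MSW)/(MSB + (k−1)·MSW)`, with the single-measurement one-way
F-interval for the 95% CI: `FL = F/F₀.₉₇₅(n−1, n(k−1))`,
`FU = F·F₀.₉₇₅(n(k−1), n−1)`, each mapped through `(F* − 1)/(F* + k − 1)`.
Zero total variance yields an explicitly *undefined* result, never 1.0.
Bands: ≥ .75 excellent, .60–.74 good, .40–.59 fair, < .40 poor.

Correlations are product-moment with t-based two-sided p; partial
correlations use the residual-regression method (OLS with intercept on the
controls, correlation of residuals, df reduced by the number of controls).
Missing measures are explicit NaNs: correlations use pairwise complete
cases, ICC drops incomplete subject rows listwise — matching the
per-analysis exclusions that differing final Ns in cohort studies imply. The
per-subject mean width/depth over the 16 per-hemisphere sulci requires all
16 present by default (an option averages over available measures and
records the count). No multiple-testing correction is applied; downstream
users can correct externally.

## The synthetic generator

Real cortical surfaces give no ground truth, so validation rests on
generated subjects whose geometry is analytic: a flat plate with a U-shaped
box-canyon fold — two parallel vertical walls `true_width` apart descending
`true_depth` below the plate to a flat fundus floor, extruded `length` mm,
meshed as a regular grid at `mesh_spacing`. The fold interior carries a
chosen Destrieux label, the overlay encodes signed depth (with a
configurable sign convention so the depth module's sanity check can be
tested in both polarities), and the outer surface is the plate's plane
spanning the fold mouth. True width and depth are exact by construction;
interior faces, the boundary loop and the deepest-100 list are recorded as
ground truth. Optional deviations: converging walls (`wall_tilt`), a
hook-shaped canyon (`fundus_curvature` κ, giving geodesic depth D but
straight-line fundus depth sin(κD)/κ — the configuration under which the
estimator's underestimation is provable), and Gaussian vertex jitter.
Labels are assigned by construction before jitter, so jitter never moves a
vertex across the label boundary and ground truth stays exact. Generation
is byte-deterministic given the seed (fixed creation stamps in all written
files).

Cohorts draw per-subject true width/depth from linear age trends plus
between-subject noise, with optional per-session within-subject noise. The
defaults emulate adult-lifespan magnitudes: mean width 3 mm widening
0.02 mm/yr, mean depth 10 mm shallowing 0.06 mm/yr, ages uniform over
20–80 y, with between-subject SDs (0.60 / 1.80 mm) chosen so the generating
age correlations are +0.5 and −0.5. Values are clipped to physically
meshable minima (width 0.9 mm, depth 3 mm); the clip binds with probability
< 1% and is recorded. Cohort meshes use 1 mm spacing and 30 mm length to
keep a 150-subject run in seconds; recovery studies use finer 0.5 mm
meshes, 50 mm long.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: closed brain-like topology, curvature of the
gyral crowns, labeling noise at the sulcogyral transition, scanner- and
segmentation-induced surface error, and FreeSurfer's actual outer-hull
geometry. Recovery being exact on box canyons demonstrates correctness of
the algorithmic chain, not field accuracy on cortices; the failure-mode
fixtures (split label, annulus, pinch, undersized region) cover the
topological pathologies real parcellations do produce.

## Numerical choices and degenerate inputs

* Medians with even counts take the central-pair midpoint, fixed for
  determinism.
* All tie-breaks (loop chaining, bridge candidates, fundus cutoff) resolve
  toward smaller indices, making every pipeline output a pure function of
  its inputs.
* Scalar overlays and surface coordinates are stored as float32 on disk
  (the format's precision); round trips are exact at that precision.
* Empty regions, labels missing from the annotation table, undersized
  regions and short loops are distinct reported outcomes, not exceptions;
  missing *files* are configuration errors that skip the subject and leave
  the cohort run alive.
* An annotation's label ids are preserved through files by packing `id + 1`
  into the color-table RGB triple; annotation value 0 and entries named
  `unknown` map to the no-label id.

## Known limitations

* Width is a single scalar per sulcus (median of bridges); no width profile
  along the sulcus, geodesic width, or per-vertex maps.
* Depth is Euclidean to the outer hull, not geodesic along the wall, and is
  a known underestimate for curved sulci.
* The loop-based width requires a simply-connected label; discontinuous
  parcellations are failures by design (opt-in largest-component mode
  aside).
* The statistics layer intentionally stops at the analyses the measurement
  procedure calls for (ICC, Pearson/partial correlations, means, QC);
  mixed-effects or spline age models are out of scope.
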