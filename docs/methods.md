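# Methods

`antcompass` simulates retinotopic visual-compass navigation in a walking
insect whose head pitch is not stabilised, and measures how pitch variation
degrades heading recovery and route following.  This note documents the
models, the synthetic study setting, the numerical choices, and what the
package's tests do and do not establish.

## The visual compass

A stored panoramic view `I^r` (a *snapshot*) is fixed in retinal coordinates.
The compass recovers the heading at which the snapshot was taken by rotating
the current viewpoint in yaw and evaluating the pixel-wise image difference

    D(theta) = sum_i ( I_i(theta) - I_i^r )^2

over a full turn.  `D(theta)` as a function of rotation is the rotational
image difference function (rIDF); its global minimum is the recovered
heading.  Two scalar metrics summarise compass quality:

* **heading error** — circular absolute difference (degrees, in [0, 180])
  between the rIDF minimum and the true heading;
* **detectability** — median rIDF divided by minimum rIDF.  Values near 1
  mean the rIDF valley has collapsed and carries almost no directional
  information; a perfect match (minimum 0) maps to +inf.

Rotations are scanned in 2 degree steps everywhere (`DEFAULT_RIDF_STEP_DEG`),
so recovered headings are quantised to a 2 degree grid; ties are broken
towards the smallest absolute offset, then negative before positive.

## The eye model

The retina is a window in a uniformly curved (spherical) visual field:
296 degrees horizontally by 76 degrees vertically at 4 degrees per pixel —
74 x 19 = 1406 pixels, with a 64 degree blindspot centred directly behind.
Rows are centred on elevations +36 .. -36 degrees, so at zero pitch the
central row looks at the horizon.  Because the column count is even and the
blindspot is kept symmetric, column centres sit at azimuths +/-2, +/-6, ...
+/-146 degrees: there is no exact forward-looking pixel; the two central
columns straddle the forward direction within half a pixel.

Head-frame pixel directions are rotated first by pitch about the head's
transverse axis (positive pitch = head up; the pivot is the eye centre), then
by yaw about the world vertical.  Roll is always zero.  The eye sits 5 mm
above the ground plane (`DEFAULT_EYE_HEIGHT_M`, configurable); the habitat
is flat, so pitch is imposed on the head rather than derived from the
substrate.

Rendering casts rays against the world's triangles (Möller–Trumbore, nearest
hit), with per-tussock bounding spheres as the acceleration structure; rays
that miss every blade hit an infinite ground plane when pointing downward,
otherwise the sky.  Each pixel averages an `s x s` grid of sub-rays spanning
its 4 x 4 degree footprint (`RetinaSpec.supersampling`, default 2).  This
within-pixel anti-aliasing matters scientifically, not just cosmetically:
with single centre rays, a 1–2 cm change in position re-assigns every pixel
that looks at nearby grass, the image difference between a view and a memory
stored 1 cm away becomes as large as the difference to an arbitrary distant
view, and closed-loop route following fails even with zero pitch everywhere —
contradicting the zero-pitch control the analysis is anchored to.  `s = 2`
restores smooth dependence of the image on pose while leaving multi-pixel
effects (such as pitch shifting the horizon by a pixel per 4 degrees)
untouched.  Point sampling (`supersampling=1`) remains available and is what
the exactness tests against the brute-force ray oracle use.

## The synthetic world

No reconstruction of the original field site is available, so the package
generates worlds with the statistical structure the analysis assumes: a
10 x 10 m flat area whose only visual structure is grass tussocks — clumps of
shaded triangular blades — under uniform ground (0.65) and sky (1.0)
intensities, with blade intensities drawn uniformly from [0, 0.55] (ground
and sky deliberately lie outside the blade range).  Defaults, all
overridable in `WorldParams`:

* 60 tussocks, 40 blades each; tussock radius 0.05–0.25 m and height
  0.05–0.35 m, drawn uniformly per tussock;
* Thomas-style clustered placement (parent points with 0.7 m Gaussian
  scatter, about one parent per 7 tussocks).  Clustering gives the patchy
  dense-and-open structure of natural scrub; statistically uniform scatter
  makes every neighbourhood look alike and the route memory aliases badly;
* elliptical clump outlines (axis ratio up to 1.6) with random orientation,
  and a per-tussock blade coarseness class (mean blade half-width 2–5 cm);
  both individuate clumps at a distance;
* blade geometry: bases 1.6–6 cm wide on the ground, apices at 60–100 % of
  the tussock height, leaning gently outward.

The blade scale was chosen so that the ant-eye view is substantially
structured by grass (several percent of pixels, with near clumps filling
large parts of the panorama), which reproduces the qualitative compass
regime of a densely cluttered natural habitat: near-zero heading error
within +/-5 degrees of pitch, rapid degradation beyond +/-10.  With much thinner
blades the panorama is almost entirely uniform ground/sky and the compass is
far more fragile than the study describes.

## Routes

`generate_route` emulates a homing path through clutter: a steered random
walk that heads from tussock to tussock (switching targets when within
0.6 m), with mean-reverting turn-rate noise, a hard per-step curvature cap
(2 degrees/cm), a soft sustained-curvature limit (0.4 degrees/cm from the
steering term), and boundary steering that keeps the route at least 1.5 m
inside the extent.  Candidate routes in which any two points more than 1 m
apart in arc length come closer than 0.6 m in space are rejected and
regenerated from a derived seed, so no route section (in particular the end
point) is spatially ambiguous with another.  Low sustained curvature is
deliberate: nest-bound ant routes are not tortuous, and on a gently curving
route the residual confusions between stored views a few tens of cm apart
cost only a few degrees of heading.

Routes are sampled at exactly the memory spacing (1 cm), so an 8.12 m route
defines 812 storage positions (at 1..812 cm of arc; the 0 cm start is the
first test origin, not a memory) and 81 test locations on the 10 cm grid.

## Head-pitch distributions

Per-frame head-pitch pools emulate the measured load conditions: after
mean-shifting to zero, the small-load condition spans [-20.6, 12.99] degrees
and the large-load condition [-40.4, 21.69].  Pools are 2000 truncated
skew-normal samples (skewness -4; scale 8 and 14 degrees respectively,
biased downward — heavy loads pitch the head down), iteratively re-centred
so the mean is exactly zero while every sample stays inside the stated
range, with the range endpoints pinned (they are attained by definition in
mean-shifted empirical data).  The resulting pools have standard deviations
of about 5 degrees (small) and 9 degrees (large), with 5 % and 26 % of
samples beyond +/-10 degrees.  An `empirical` kind accepts a user-supplied
angle list; `zero` is the stabilised-head control.  Traces are i.i.d. draws
with replacement — pitch is treated as uncorrelated between learning and
test and between successive frames.

## Memory strategies

Views are stored every 1 cm along the route, facing the route tangent, at
the pitch given by the learning trace.  At a test location (co-located
memory always excluded, so the nearest usable memory is 1 cm away) a heading
is recovered by scanning 360 degrees of yaw and matching against:

I.   **closest** — only the memory 1 cm further along the route;
II.  **local** — all memories within +/-15 cm;
III. **full** — all 812 memories;
IV.  **limited** — as full, but memories stored at |pitch| > 10 degrees are
     discarded; if the current view exceeds the gate, the heading computed
     at the previous location is kept (route-start tangent for the first);
V.   **averaged** — as full, over a bank whose k-th image is the pixel-wise
     mean of stored images k-4..k (the window shrinks at the route start, so
     entry 1 is unchanged).

"Best match" is the smallest global rIDF minimum across candidates; exact
ties (which essentially never occur with float sums) go to the spatially
nearer memory.  Spatial mismatch of a match is reported along-route (arc
length), not Euclidean.

## Closed-loop route recapitulation

The simulated ant starts at the route origin facing the route tangent.  Each
step: draw a pitch from the test distribution (one head posture per scan),
scan +/-90 degrees about the current heading in 2 degree steps, match
against the full bank (strategy III), turn to the best-matching yaw, advance
1 cm.  Halt rules: *completed* within 5 cm of the route end (one memory
spacing below the test-grid spacing); *deviated* if more than 1 m from the
route polyline; *overshot* once the travelled path exceeds the route length
by 0.1 m — which also bounds the loop (822 steps for the 8.12 m route).
The overshoot budget is deliberately brutal: barely 1 % of slack, so any
milling episode fails the run.

## Head-pitch measurement from landmarks

Frames of a side-view video are labelled with the mandible centre, the
dorsal head–neck joint and the ventral alitrunk–petiole joint (pixels, image
y down).  The head angle is the direction of the neck-to-mandible segment
against the image horizontal, the body angle that of the petiole-to-neck
segment; by convention +90 degrees points straight down, and a flag flips
the convention for y-up coordinate systems.  The angle is invariant to
uniform scaling and translation, and vertical flips negate it.  No video
decoding or labelling UI is included — labelling is manual by design; the
analysis driver demonstrates the pipeline on synthetic landmark tables
generated from known angle traces.

## Seeds and determinism

Every generator is a pure function of its parameters and a seed.  A single
master seed fans out to per-stage seeds via `numpy.random.SeedSequence`
(`spawn_seeds`, values kept below 2^31), so a full experiment is reproducible
byte for byte; the route generator's rejection loop draws candidate seeds
from the same mechanism.

## Problem sizes and numerical choices

* Full-scale analyses use the defaults: 81 test locations x 9 pitch levels
  for the sweep, 5 scenarios x 5 strategies x 81 locations for the strategy
  comparison, 812-entry banks for route following.  The closed-loop
  robustness test in the suite uses a 4 m route (412 memories, 40 test
  locations) — the same generator and halt rules at a size that keeps
  fifteen runs tractable on one CPU.
* Pairwise image differences in the multi-memory strategies use the Gram
  expansion ||a-b||^2 = ||a||^2 + ||b||^2 - 2ab (clipped at zero), which is
  exact to ~1e-9 relative; the single-reference operations
  (`image_difference`, `compute_ridf`) use direct summation, so perfect
  self-matches are exactly zero.
* The rank-sum comparisons between strategy error distributions are
  two-sample Wilcoxon tests from `scipy.stats.ranksums` — standard
  statistics, not re-derived here.
* Degenerate inputs: a world with no blades renders pure ground/sky views
  (the rIDF is flat; closed-loop runs then terminate by the overshoot
  bound); an empty pitch pool, a mismatched trace length, or a strategy with
  no surviving candidate memories raise errors rather than guessing.

## What the synthetic setting does and does not show

The generator reproduces the *statistical* conditions of the study — ranges
and shapes of the pitch distributions, memory/test-grid geometry, clutter
that structures the panorama, and a route with realistic curvature — but not
any particular field site or trajectory.  Absolute error magnitudes depend
on the specific world realisation and are not comparable across habitats;
what transfers, and what the tests assert, are the control values that are
forced at this scale (exact self-match at zero pitch, 812/81 counts), the
qualitative orderings (local search at least as good as closest-memory under
large pitch; detectability falling monotonically with |pitch|; matched-
distribution route completion), and the failure modes (aliasing of the
full-route search under pitch, catastrophic mismatched-scenario errors).
Real panoramas also contain distal landmarks, skyline texture and lighting
variation that this world lacks; robustness measured here is if anything
conservative in that respect.  Roll, colour/UV, polarisation and acceptance-
function optics are out of scope.
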