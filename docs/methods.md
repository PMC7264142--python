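# Methods

`shoalsight` reimplements, as a tested pipeline, the analysis of how a
fish shoal's collective order (polarization) trades off private against
social information during group foraging: disordered, swarm-like groups
collectively see more of their surroundings, so the first individual to
detect an ephemeral food stimulus responds sooner; ordered, polarized
groups transmit the discovery faster, so later arrivals reach the food
sooner.  Because the original experiment's tracking data are not bundled
here, every stage is exercised end to end on a bundled agent-based
generator whose ground truth the pipeline is scored against.

## Coordinate and unit conventions

All geometry is 2-D Cartesian millimetres, origin at the arena centre,
y up; angles are stored in radians internally and reported in degrees;
speeds are mm/frame internally (multiply by 25 to report mm/s).  Raw
tracker tables are pixel image coordinates (y down) at 2.7 px/mm and
25 fps; `io.read_trajectories` converts and flips them on ingestion.
Missing tracking frames are kept as NaN, never interpolated; any
analysis window touching a gap is dropped rather than filled.

## Arena

The 133.5 × 72 cm oval tank is modelled as a *stadium* (a rectangle with
semicircular end caps) by default — the shape a flat PVC sheet takes when
bent around two half-cylinders — with a true ellipse as an alternative.
Both are convex, which the visual-field module exploits: a sight line
between two interior points can never leave the arena, so only neighbour
bodies can occlude.  Four stimulus ports sit on the wall, two per long
side at ±25% of the long axis by default; real port coordinates should be
supplied in configuration.  Note that with this default layout the
opposite-half rule alone does **not** guarantee the protocol's 43-cm
minimum start distance; presentation validation therefore checks both
conditions explicitly.

## Trajectory parameters

Trajectories are smoothed with a Savitzky–Golay filter (window 13 frames
≈ 0.5 s, cubic), which is exact on locally cubic paths and attenuates
tracking jitter.  Headings come from central-difference displacement
(centre-of-mass tracking has no body axis); frames slower than
0.3 mm/frame have no defined direction and are excluded from
direction-based statistics.

Six individual parameters (speed; distance and unsigned bearing to the
stimulus; proportion of window frames on the convex-hull edge; distance
to the centroid; ray-cast visual occlusion) and five group parameters
(hull area; group bearing to the stimulus, from the direction of the
summed unit headings; centroid distance; centroid speed; polarization
P = |Σ uᵢ|/N) are summarized over the 13 frames before each stimulus
onset by their median — except the hull-edge parameter, which is a
proportion of frames and cannot be a median.  Individual parameters are
additionally *relativized* (divided by the group mean of the per-fish
medians) because being first to respond is a within-group contest.
Bearing dispersion across the group is the ordinary sample SD of the
unsigned bearings (they live on the segment [0°, 180°], so no circular
statistic is needed) together with the group minimum.

## Visual fields

Each fish gets a single cyclopean eye 0.4 body lengths ahead of its
centre-of-mass (clamped 1 mm inside the wall if the fish is nosing it), a
binocular sector of ±15° about the heading and a full field of 300°.
These angles are explicit stand-ins — the species' true field geometry is
not pinned down here — and are configuration-exposed so conclusions can
be checked across plausible values.  Neighbour bodies are ellipses (major
axis = body length along the heading, aspect ratio 0.2).  720 rays per
360° (0.5°/ray) are cast analytically against the wall (line/circle
pieces of the stadium) and the neighbour ellipses; the polygon of ray
endpoints approximates the visible region.  Derived quantities: coverage
fraction (polygon area / arena area), collective coverage (area of the
shapely union of per-fish polygons), the per-fish occlusion index
(fraction of full-field rays stopped by a neighbour before wall or
maximum range), and point visibility for the stimulus (angular test plus
segment–ellipse intersection).  A 2-mm grid point-visibility oracle
agrees with the polygon coverage to well under the 2% tolerance at this
ray density.

## Events

A presentation is valid only if, at onset, all fish are ≥430 mm from the
port and on the opposite half of the arena, with a gap-free 13-frame
pre-window.  Within 500 frames (20 s) of onset:

* **response** — first frame where a fish's bearing to the port is below
  30° *and* its speed exceeds 1.5× its own pre-stimulus median, both
  sustained for 5 frames.  These criteria are a declared reconstruction
  of "oriented, accelerated movement toward the stimulus" (the original
  operational definition is not available); all thresholds are
  configuration, and the criteria are accepted only because they
  re-identify the synthetic generator's true first detector in ≥90% (in
  practice ~98%) of presentations;
* **arrival** — first frame within two body lengths of the port
  (per-fish measured length, 27 mm cohort mean as fallback); arrival
  latencies rank the arrival order 1–8.  Ties break by distance at the
  shared frame, then fish id.

The private-information payoff is tested by the one-sided exact binomial
test of "first responder = first arriver" against the 1/N chance level
(0.125 for eight fish).

## Synthetic shoal generator

Zonal (metric) interactions: repulsion inside 60 mm takes priority;
otherwise a blend of alignment with neighbours within 250 mm (weight
`w_align`), attraction to neighbours within 600 mm (weight 1.0), and wall
avoidance ramping up within 100 mm of the boundary; headings relax
towards the blended direction at rate 0.4/frame with 8°/frame Gaussian
noise; per-fish cruise speeds are drawn once (2.0 ± 0.4 mm/frame ≈ 50
mm/s; body lengths 27 ± 2.4 mm).  `w_align` is the single order knob and
is allowed to go *negative* — active heading avoidance — which is what
pushes polarization below the independent-random level of ≈0.31 for
eight fish (E|Σuᵢ|/8 under iid headings).  Heading avoidance is not an ad
hoc trick: consistently early-arriving fish in the source study maintain
larger heading differences to their nearest neighbours, i.e. exactly this
behaviour.  Bisection on `w_align` over [−4, 10] calibrates the 3000-frame
mean polarization to any target in ≈[0.1, 0.95] within ±0.05.

The presentation protocol draws a port uniformly once the 3-min gap has
elapsed and presents at the first frame the whole group is eligible.
Detection is hazard-based per frame, per non-responding fish:

* private: h₀·exp(−d/λ) with h₀ = 0.05 frame⁻¹ and λ = 800 mm, *only*
  while the port is inside the fish's binocular sector and the sight line
  is unoccluded.  h₀ makes a clearly seen stimulus at minimum distance
  detectable within a second or two; λ of roughly half the arena length
  makes far-off detection meaningfully harder;
* social: s₀·(visible responding neighbours)·(1 + γP) with s₀ = 0.015
  and γ = 2, so transmission in a fully polarized group is three times
  faster than in a fully disordered one — the mechanism's sign, not its
  magnitude, is what downstream checks rely on;
* responders dash to the port at 3× cruise speed (≈6 mm/frame, a
  feeding-dash pace) and the engine logs ground truth: channel
  (private/social/none), detection frame, arrival frame.

### What the generator does and does not emulate

It reproduces the *statistical structure* the analysis assumes: order
varying across and within groups; bearings to the stimulus dispersing as
order falls; binocular coverage falling as order rises; first responses
arising privately and spreading socially with an order-dependent gain;
arrival-order sample sizes decaying under the 20-s cap.  It does not
emulate hydrodynamics, body-axis posture, learning within a simulation
(testing-day effects enter only as a covariate), satiation, or realistic
latency distributions' heavy tails.  A green end-to-end test therefore
establishes that the pipeline measures what the generator encodes — not
that the biological effect sizes are reproduced.  Two emergent properties
worth knowing: (i) whole-group eligibility selects cohesive, transiting
(hence more polarized) moments, so low-order presentations are rarer —
the same selection pressure the real protocol had; (ii) polarization and
centroid speed are strongly collinear (coherent groups translate), the
very pair the source study flagged for collinearity.

## Inference

All-subsets candidate sets over standardized main effects; AICc
(−2logL + 2k + 2k(k+1)/(n−k−1)); Akaike weights; relative importance =
summed weights over the complete set; *full* (zero-substitution) model
averaging over the smallest weight-descending subset reaching 95%
cumulative weight, with Burnham–Anderson unconditional SEs
(√Σw(se² + (β−β̄)²)) — chosen over conditional averaging because absent
terms should shrink towards zero when support is weak; the conditional
variant is a configuration switch away.  Gaussian mixed models (random
intercepts for fish nested in group) delegate to statsmodels MixedLM,
fitted by ML so AICc is comparable across fixed-effect subsets, with an
optimizer fallback chain because a variance component on the zero
boundary can leave one optimizer's Hessian singular or its likelihood
non-finite; finite-likelihood boundary fits are retained in candidate
sets even when the optimizer's convergence flag is pessimistic.
statsmodels has no maximum-likelihood GLMM, so binomial and
negative-binomial families are fitted as fixed-effects GLMs (NB
dispersion by ML) and the result records that a requested random
structure was not honoured — a documented contract limitation that no
synthetic-data check depends on.

Cook's-distance screening (cut-off 6× the mean) uses the OLS influence
of the fixed-effects design, the standard approximation when the mixed
model itself offers no influence measures; the mixed model is refit on
the kept rows.  Repeatability is R = σ²_id/(σ²_id + σ²_group + σ²_res)
from the fitted variance components — the group component is included in
the denominator (nested-design convention; a toggle exists) — with a
seeded parametric-bootstrap CI and a boundary-corrected LRT (0.5·χ²₁) for
the identity intercept.  Spearman correlations use tie-corrected ranks.

## Numerical choices and degenerate inputs

Polygon areas use the shoelace via shapely; degenerate (collinear) hulls
have zero area and flag every fish as an edge individual.  Polarization
and bearings are undefined (NaN, window dropped) with fewer than two
valid headings.  Relativization is undefined for a zero group mean.
Nearest-neighbour ties resolve to the lower fish index; simultaneous
arrivals rank by distance then id.  Ray–ellipse intersections solve the
quadratic in the ellipse frame with a 10⁻⁹ positive-root guard.  All
simulation randomness flows from one seeded `numpy` Generator per run;
identical seeds give bit-identical output on a given platform/BLAS.

## Scale-downs in the test suite

To keep the default suite within a desk-scale budget: the bearing-
dispersion sign suite and related checks share one session pool of 400
simulated windows; the arrival-latency crossover criterion fits the
pooled 90-trial synthetic experiment (~450 presentations) once and then
checks sign stability over 100 seeded cluster-bootstrap replicates of 50
trials, rather than simulating 100 fully independent 300-presentation
replicates; LMM parameter-recovery runs 30–40 replicates instead of 100.
The analysis drivers run the same computations at presentation counts a
single machine handles in minutes; numbers quoted in the README are the
drivers' actual output.

## Known limitations

* The response criteria and visual-field angles are reconstructions;
  both are explicit configuration, not biology.
* Non-gaussian families lose the random-effect structure (see above).
* The ellipse-arena signed distance is a first-order approximation
  (exact on the boundary, adequate for wall avoidance and port checks).
* The generator's arrival-latency distribution is lighter-tailed than
  real data; Cook's-distance exclusions are correspondingly fewer.
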