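# Methods

This note documents the models and procedures implemented in `sealscape`,
the parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical decisions taken where the methodology was
genuinely open.

## Dive processing

A time-depth record is corrected for surface-sensor drift by subtracting a
rolling low quantile (default 2 %) of depth over a window (default 3600 s)
and clipping at zero. The window must exceed the longest dive so that every
window sees true surface; for a forager that surfaces between dives lasting
minutes, an hour-long window removes both constant offsets and slow drift
(a linear 3 m drift over 6 h leaves residual surface depths below 0.5 m).

Dives are maximal submergence intervals — depth above a 0.5 m surface
threshold — whose maximum depth reaches 5 m. The 5 m floor is the
conventional threshold for this species' recorders; the surface threshold is
needed to delimit submergences and is exposed as a parameter.

Each dive is summarised by duration, maximum depth, and the bottom-time
proportion: the time-weighted fraction of the dive spent at depth ≥ 80 % of
its maximum. The 80 % bottom definition is the common TDR convention (the
bottom phase is not otherwise defined) and is a parameter. The
classification score is bottom proportion × maximum depth: flat-bottomed
dives to the sea floor score near the local water depth, V-shaped pelagic
dives score far lower. A Gaussian KDE (Silverman bandwidth, 512-point grid
over [0, max score]) of the per-trip scores is bimodal for a benthic
forager; the density minimum between the two highest modes (ties broken
toward the lower score) is the benthic/pelagic boundary. A unimodal density
is signalled rather than silently split; the pipeline then falls back to
treating all dives as benthic, which is conservative for foraging detection
in an almost-exclusively-benthic forager.

## Track processing

Positions are projected to planar metres (equirectangular, centred on the
colony) before any filtering, because all downstream distances (cells,
buffers, speeds) are metric and the study region spans few degrees. The
speed filter iteratively deletes the worst offending fix until no
consecutive pair implies a speed above `vmax` (default 3 m/s, a sustained
otariid swim-speed ceiling). The offender within an over-speed neighbourhood
is the fix whose *smaller* adjacent speed is largest: a genuine position
spike forces both of its adjacent speeds high, while its innocent neighbours
show only one. Endpoints are never removed; removing every interior fix sets
a warning flag. The filter only deletes — coordinates are never edited — and
is idempotent.

The filtered track is linearly interpolated at a fixed interval (default
600 s) starting at the first retained fix, never extrapolating. Dives are
positioned by linear interpolation at their start time; dives outside the
track span are dropped and counted. Whether the original analysis
interpolated at dive times or snapped to the nearest fix is not documented;
interpolation at the dive start is the choice here.

## First-passage diving

Each regular track interval carries the summed duration of dives *starting*
in it. For a focal point and radius r, the passage runs from first entry to
first exit of the circle (the classic first-passage definition); underwater
seconds accumulate over whole intervals inside the circle plus
linearly pro-rated partial intervals at the two boundary crossings
(the crossing parameter solves the segment–circle intersection exactly).
Two closed forms anchor the implementation: a stationary diver yields the
trip's total underwater time at any radius, and a straight transit at speed
v with uniform dive fraction f yields FPD(r) = 2rf/v.

The radius grid is 15 log-spaced radii from 250 m (one grid cell) to 20 km
(trip extent). The operational scale maximises the variance of log FPD
across track points, excluding zero passages; if the variance is degenerate
everywhere (uniform behaviour) the smallest radius is returned with a
warning. All dives — benthic and pelagic — count toward underwater time,
but only benthic dives become foraging events (there is a switch); this
mirrors locating "foraging (benthic)" dives while measuring total diving
effort.

Intensive foraging: track points whose FPD at the operational scale exceeds
the per-trip 75th percentile are flagged; benthic dives in flagged intervals
map to 250 m grid cells; dives sharing a cell collapse to one foraging event
(avoiding pseudo-replication), carrying the dive count and the maximum FPD
among contributing points. The quantile rule is a simple reproducible
stand-in for the peak-extraction step of the source first-passage
literature, and is configurable.

Scale-selection validation uses an idealised two-patch track
(`simulate.two_patch_track`): one travel speed throughout, with hard
confinement to a disc of radius R during bouts. Under those conditions the
log-FPD variance peaks near R (the implementation selects ≈1.6 R, within a
factor of two). The full trip generator's foraging state moves much slower
than transit, which shifts the variance peak below the patch radius — a real
property of tortuous search, not an implementation artefact — so the
factor-of-two recovery is asserted on the idealised track.

## Covariate stack

Seven layers share one north-up 250 m grid: water depth; terrain complexity;
and Euclidean distances to colony, coast, pipes/cables (one layer — they are
modelled as a single variable), wells, and shipwrecks. Cells are half-open
squares sampled at their centres; distances are exact planar
point-to-geometry distances (shapely), with no land mask. Complexity is the
rate of change of slope: the Horn 3×3 gradient magnitude applied twice, with
mirrored edge padding — zero for flat and uniformly sloping terrain,
invariant to datum shifts and sign conventions. Collinearity is screened
with VIF = 1/(1 − R²) per variable (threshold 3); perfectly collinear
variables report infinity. In the synthetic world the colony sits near the
coast, so distance-to-colony and distance-to-coast correlate and the VIF
screen flags them — the screen reports rather than drops, matching a
check-then-decide workflow.

## Habitat model

The maximum-entropy model estimates the Gibbs density
P(x) = exp(w·f(x))/Z over background cells, maximising the L1-penalised
log gain (mean presence score minus log mean background exponential score).
Features are linear and quadratic transforms of each covariate scaled to
[0, 1] by the background range; hinge/product/threshold classes of the
original MaxEnt software are deliberately out of scope (a documented
deviation — at the presence sample sizes here, its "auto features" setting
would mostly restrict to linear+quadratic anyway). The per-feature penalty
is r·β·s_f/√m with β = 0.05, s_f the presence-sample feature SD and m the
presence count; r is the regularisation multiplier (default 1). Defaults
follow the original software's conventions: 10 000 background points,
convergence tolerance 1e−5, 1000 iterations maximum, 70/30 train/test
split, and a floor of 5 presence cells below which no model is attempted
for that individual.

Optimisation is greedy coordinate-wise Newton ascent: each iteration updates
the single feature with the largest penalised gradient, with backtracking
(gain never decreases) and a soft threshold so a weight cannot jump across
zero. Because exactly one feature moves per iteration, the gain increment is
credited unambiguously to that feature's variable; summed positive credits,
normalised to 100 %, are the percent contributions. Permutation importance
(AUC drop when one variable is shuffled across presence + background rows)
is available as a cross-check. Discrimination is the rank-based AUC
(midrank ties) of held-out presences against the background sample —
identical to the Mann–Whitney U statistic scaled by the comparison count.

## Association statistics

Buffer occupancy tests each regular interval's midpoint against the
250 m-buffered union of each structure type's geometries, accruing the full
interval on a hit; the midpoint rule is the simplest unbiased time-accrual
scheme for a regular track (alternatives are a parameter away). The union
("any structure") allows type overlap, so per-type seconds can exceed it in
sum. Cohort tabulation counts any positive occupancy as visiting, with
per-type percentages relative to visitors.

Kruskal–Wallis uses the tie-corrected H with the chi-square approximation
(df = k − 1). On tiny groups (N = 9) the chi-square p deviates from the
exact permutation null by up to ~0.1 — the tests characterise the
approximation at that tolerance rather than pretending exactness.

The AICc model set fits OLS candidates (all subsets of the named predictors
by default), with AICc = AIC + 2k(k+1)/(n−k−1) counting the residual
variance in k, Akaike weights, and full model averaging (absent terms
contribute zero with their models' weights). The published morphometric
comparison is reproduced exactly — ΔAICc 0.00/1.75/2.11/2.26/4.29 and
weights 0.409/0.171/0.142/0.132/0.048 for the top five of the eight subsets
of {mass, FL/SL, axis/SL} — when the response is the *plain* arcsine of the
combined structure contribution (as a proportion). The conventional
variance-stabilising transform is arcsin(√p), and the exported
`arcsin_transform` defaults to it with `sqrt=False` available; the
reproduction pins down which variant the original analysis used. The one
discrepancy is cosmetic: the best model's R² computes to 0.125 here and is
printed as 0.13 in the source table.

In a noise-recovery simulation (y = 2x₁ + ε, n = 30, candidates {x₁}, {x₂},
{x₁,x₂}), the pure-noise model always ranks last, while {x₁} beats the
over-parameterised {x₁,x₂} in ~90 % of replicates — the theoretical rate,
since AICc prefers the larger model whenever x₂ absorbs more than ~2.9
deviance of noise (a ~9 % chi-square(1) event). Tests assert that rate, not
an unattainable one.

## Synthetic data

The generator emulates the study conditions: a 160×160-cell (40 km) shelf at
a 60 m mean depth with smooth low relief (amplitude ~5 m, zero allowed), a
coastline along the northern edge with the colony just offshore, and sparse
structures (2 pipelines, 1 cable, 8 wells, 5 shipwrecks by default) kept
≥3 km from the colony so occupancy reflects foraging, not colony attendance.
Trips are a two-state correlated random walk: directed transit at 1.2 m/s
toward patch targets, slow tortuous search (0.35 m/s, high turning variance,
soft tether) within 1 km patches, ~40 % of trip time in bouts, and a homing
rule that returns the animal to the colony by the scheduled trip end. Patch
centres are structure-placed with probability a/(1+a) for attraction
strength a (0 = neutral). Dives occur continuously (~6/h): flat-bottomed
benthic dives to local bathymetric depth during bouts, a configurable
benthic/pelagic mixture in transit, sampled into a 5 s depth trace. GPS
fixes are the true path plus 25 m noise and occasional 5 km outliers, so
the speed filter has real work.

Ground truth per dive (bout membership, structure-driven flag, true class)
supports recovery tests. What the generator does **not** emulate:
oceanography (tides, currents), haul-outs, energetics, Fastloc fix-rate
irregularity, prey dynamics, or inter-individual foraging-site fidelity.
Passing recovery tests therefore demonstrates that the method stack
recovers its own generative signals at realistic noise levels — not that
field effect sizes would match.

The neutral-occupancy null is tested by isotropy: structures are placed
independently of trips, so rotating a neutral trip about the colony leaves
its expected buffer occupancy unchanged, and the rotated-trip ensemble is
the Monte-Carlo null. (A naive buffered-area-fraction null is biased for a
central-place walk, which oversamples the colony's vicinity.) Attraction
trips must exceed their paired neutral trips; in paired cohorts the
combined structure-layer contribution is higher for the attracted seal in
~80–90 % of seed pairs.

## Problem sizes and determinism

Tests and the acceptance script run cohorts of 0.75–1.5 d trips on 100–160
cell grids with 2 000–10 000 background points — sizes chosen so the full
suite and script each complete in minutes while leaving every stage's
statistics well resolved; field-scale runs (3–7 d trips, larger grids) use
the same code paths via configuration. All randomness flows from explicit
seeds (`numpy.random.default_rng` / `SeedSequence`); a fixed seed makes the
pipeline byte-identical across runs, and the run manifest records inputs,
parameters and seed for exact re-execution.

## Known limitations

- Only linear + quadratic feature classes in the habitat model; per-seal
  contribution values from richer feature sets are not reproducible
  cell-by-cell, only cohort summaries.
- The intensive-foraging threshold (75th percentile of FPD at the
  operational scale) is a documented stand-in for the source literature's
  peak-extraction step.
- Distances are planar; geodesic error is negligible at the study extent
  but the package is not suitable for basin-scale grids.
- No spatial autocorrelation handling beyond cell-level deduplication of
  presences; no mixed-effects structure in the morphometric models.
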