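# Methods

## Scope and units

`shoalforage` models groups of k fish foraging for small food flakes in a
circular arena. All distances are in body lengths (BL), with
1 BL = 95/32 cm ≈ 2.97 cm so that the 95 cm arena has radius 32 BL.
Trajectory data are frame-level at 50 frames/s; simulations advance in
discrete bouts ("ticks").

## Trajectory processing

Raw positions are smoothed with a Savitzky–Golay filter (window 17 frames
≈ 1/3 s, polynomial order 2). Edge frames take values from the polynomial
fitted to the terminal full window (`scipy` mode `"interp"`), which
preserves series length and passes constants and linear motion through
unchanged. Velocity is the central difference with dt of one frame
(one-sided at the ends); heading is the unit velocity, carried forward
through zero-speed frames and flagged invalid there. Curvature
c(t) = 1/R(t) comes from an algebraic (Kasa) least-squares circle fit on a
600 ms window centered on t; exactly collinear windows are rank-deficient
for that system, so a PCA guard returns curvature 0 (infinite radius)
instead of the spurious minimal-norm circle.

Bout segmentation finds local minima of the speed profile
(`scipy.signal.find_peaks` on the negated speed) with a minimum prominence
of 5% of the fish's median speed and a minimum separation of 5 frames; these conservative
defaults suppress jitter minima while passing every genuine inter-bout
trough in rendered test data. A recording endpoint additionally counts as a
bout delimiter when its speed is below that of its interior neighbor; fewer
than three delimiters yield an empty bout sequence, since a single bout has
no defined turning angle. Bout length L is the path length between
delimiters; θ is the signed (CCW-positive) angle between successive bout
displacement vectors, stored in (−180°, 180°].

## The simulator

**Motion.** Each agent draws (L, θ) from its step distributions — empirical
resamples when segmented bouts are supplied, otherwise a surrogate with
gamma-distributed L matched to the recorded group moments (2.85 ± 1.7 BL
for k ≤ 3, 3.1 ± 1.9 BL for larger groups) and wrapped-normal θ (SD 50° /
46°). The gamma/wrapped-normal forms are the standard positive-support and
circular choices for matching a mean and SD.

**Decision hierarchy.** Per tick, each agent evaluates in order: flake
orientation (nearest live flake within D_f, probability `exp(−d_f/D_f)`),
attraction to the nearest remembered neighbor-consumption location within
D_n from the last τ = 5 ticks (`exp(−d_n/D_n)`), then the model's
neighbor response within D_n. Attraction heads to the neighbors' center of
mass and alignment adopts the normalized mean neighbor heading, both firing
with probability `exp(−d_com/D_n)` where d_com is the distance to the
in-range neighbors' center of mass. The zoned Att+Align response aligns
with neighbors closer than D_n/2 and attracts to the center of mass of
those between D_n/2 and D_n, averaging the two unit responses when both
zones are occupied; a zero-norm average falls through to a random bout.
If nothing fires, θ is drawn from the turning distribution. Step lengths
are always drawn from the L distribution.

**Tick semantics.** Agents complete one bout per tick, synchronously, in an
order re-randomized each tick. This is the simplest scheme consistent with
a shared discrete clock and a memory horizon counted in ticks; when two
agents could reach the same flake in one tick, the earlier agent in that
tick's order consumes it.

**Boundary.** A bout whose endpoint would leave the arena is discarded and
redrawn (for random bouts both θ and L; for directed bouts L only), up to
100 attempts, after which the agent deterministically heads toward the
arena center — a fallback that in practice never triggers at the default
step scale.

**Capture.** A flake is consumed when it lies within 0.25 BL of the agent's
straight bout segment (endpoint inclusive). One consumption per agent per
tick: the bout ends at the first capture point along the segment, since the
consumption maneuver interrupts swimming. Without truncation a single bout
crossing a dense cluster would sweep several flakes at once, which neither
real fish nor the one-flake-at-a-time picture of the decision hierarchy
supports. Consumed flakes spawn their child flakes (disintegration
parentage) as live targets from that moment on.

**Time.** A bout of length L lasts L / v̄ seconds, with v̄ the average
swimming speed of real foraging fish. The default v̄ = 4 BL/s is a realistic adult-zebrafish foraging speed and makes
a mean bout last ≈ 0.7 s, putting simulated group completions under two
minutes as observed in experiments. v̄ scales all consumption times by a
constant, so it shifts the intercept a_k but never the slope b_k or r² of
a consumption-curve fit. A consumption event's time is the consumer's own
cumulative path length divided by v̄.

**Mixed groups.** `make_mixed_group` assigns a social strategy to n_social
seeded-randomly chosen agents and independent foraging to the rest; agents
keep their identities so per-capita consumption is attributable.

## Flake environments

Clustered fields place flakes uniformly inside one to three circles of
diameter 9.5 cm (≈ 3.2 BL) whose centers sit 20 cm from the wall, maximally
separated (single offset center; ends of a diameter; vertices of an
equilateral triangle at fixed orientation — exact center coordinates are
constants of the generator). Random fields redraw uniform placements until
the Clark–Evans-type coefficient satisfies |C| < 0.01. The coefficient is the
Clark–Evans ratio minus one, C = NN1 / (0.5 ρ^(−1/2)) − 1 = 2·NN1·√ρ − 1,
so complete spatial randomness gives C ≈ 0 and the |C| < 0.01 acceptance
band measures deviation from randomness directly. Hexagonal-grid fields tune a triangular
lattice constant until exactly N+1 sites fall inside the arena, then remove
the center site so foragers can start there. The Monte-Carlo clustering
score D̂(n) = (NN1 − μ_rand)/σ_rand uses a null of uniform placements of the
same flake count in the same arena (100,000 draws at production scale;
tests scale down to a few hundred, which is sufficient because only the
first two moments of the null enter).

## Consumption-maneuver analysis

Event-aligned templates average speed and curvature in a symmetric window
around consumption events, with curvature reported relative to the
recording mean (so average curvature is zero) and reference profiles drawn
from random trajectory points at least one window away from every event.
Crossing attraction is P_crossing − ⟨P_null⟩: the fraction of events where
another fish passes within 2 BL of the event location 1–4 s afterwards,
against a null that resamples the same number of (fish, time) positions
from frames at least 8 s away from every event. Pseudo-consumption
detection scans each fish's speed with the template's mean-speed profile
using normalized, mean-removed sliding cross-correlation — raw convolution
would be amplitude-biased, and a quantile threshold only makes sense on a
shape-matching score. Correlation values are pooled per group
rather than per fish — the pooled distribution is the larger and more
stable sample for a quantile threshold — thresholded at the 97.5th percentile, and local maxima
strictly above threshold are reported, merged within one full template
width: the correlation of a single maneuver has sidelobes just beyond half
a width, so the narrower merge window would double-count single episodes.
Zero-variance correlation pools are flagged degenerate and yield no
detections.

## Model fitting

For every (D_f, D_n) cell — production grids D_f ∈ {1..20},
D_n ∈ {1..25}, with the IND model occupying the D_n = 0 column — an
ensemble of simulations (default 100 repetitions) runs from the observed
group's initial positions, flake field, and step distributions. Three
errors are computed per cell:

* **E_cons** — minus the log-likelihood of the observed consumption-time
  sequence, Σ_i log P(T_data(i)), where P is a Gaussian kernel density over
  the ensemble's i-th consumption times with Silverman bandwidth floored at
  1% of the ensemble median (so zero-variance ensembles stay finite), the
  density floored at 10⁻¹², and the likelihood evaluated on raw times (the
  log-time alternative changes no selection in testing and is not exposed).
  Flake indices fewer than two repetitions ever reached contribute the
  floored density.
* **E_pol**, **E_dnn** — normalized squared errors
  (⟨Ŝ⟩ − S_obs)² / SD(Ŝ) of polarity and nearest-neighbor distance; a
  zero-variance ensemble scores +∞ for that cell.

Each error surface is standardized across finite cells (mean 0, SD 1) and
summed; the argmin cell is the fit, with ties broken toward smaller D_n
then smaller D_f. Standardization makes selection invariant to affine
rescaling of any one raw surface. Report-style metrics (signed
polarity/D_nn deviations scaled by the observed across-frame SD, mean
squared log-time error, and a [0,1]-scaled cross-model combination) are
emitted alongside but never drive selection.

Parameter recovery is validated by synthesizing an "observed"
Att_feed+Align group at (D_f, D_n) = (3, 12) on a CSR-certified random
field and refitting over a reduced grid (D_f ∈ {1..7},
D_n ∈ {4, 6, …, 20}, 20 repetitions per cell, 10 replicates). The random
field is the informative design for this experiment: on a single-cluster
field the consumption sequence collapses to one search time and D_f is
nearly unidentifiable, whereas on a dispersed field both ranges shape the
observables throughout the run. Recovery within ±2 grid cells holds in
≥ 80% of replicates.

## Synthetic fixtures

The generator renders bout-level correlated random walks to 50-fps
positions with a half-sine within-bout speed profile, so speed minima fall
at bout boundaries and the same segmentation pipeline used on real data
recovers the generating bouts (round-trip moment recovery within 5% at
10⁴ bouts). Random bouts that would exit the arena are discarded and
redrawn — the same boundary rule as the simulator; specular reflection was
measured to inflate the realized turning-angle SD by ~13% over the nominal
50° through wall-interaction turns, while redraw keeps it within ~4%.
Planted structure provides ground-truth positives: consumption maneuvers
(speed ramping +2 BL/s over 0.45 s then collapsing within 0.15 s, followed
by a ≥ 90° turn) and neighbor attraction (after an event, fish within the
attraction range reroute toward it with a configured probability). The
generator does **not** emulate tracking noise, identity swaps, thigmotaxis,
within-bout heading drift, or flake physics — so green tests on fixtures
validate the machinery and its statistical calibration, not robustness to
real-data artifacts.

## Problem sizes and determinism

The packaged experiments run desk-scale versions of the full sweeps: the
consumption-curve grid uses both models, k ∈ {3, 6}, D_f ∈ {1..5},
D_n ∈ {0, 5, …, 25}, one clustered and one CSR random field, 20
repetitions per cell; the mixed-group advantage grid uses 100 repetitions
per cell on the clustered field. Every stochastic component (field
generation, per-repetition simulator seeds derived from a master seed by a
fixed counter scheme, null resampling) is reproducible from a single seed.

## Known limitations

* **Exponential consumption law is field-dependent.** On dispersed
  (empirical-like or CSR) fields, log T(n) is close to linear; on an
  idealized single cluster, foraging is search-dominated — T(1) is large
  and the remaining flakes follow within a few bouts — so the exponential
  fit degrades badly (the packaged grid experiment measures minimum r²
  ≈ 0.4–0.7 depending on the seed, driven by clustered cells at small D_f
  and large D_n). Even on CSR fields the coupon-collector curvature of
  log(H_N − H_{N−n}) caps r² near 0.93–0.95.
* **Lone-forager advantage is unbounded on concentrated food.** In mixed
  groups on a single cluster, a social forager shadows whichever agent
  discovers the cluster while independent companions must each find it
  unaided; its per-capita excess can exceed 100% at small D_f and large
  D_n. Bounded (~tens of percent) advantages arise only on dispersed
  fields.
* Agents are point-like (no body-shape collision), interactions are
  deterministic functions of geometry (no per-fish personality), strategies
  are fixed within a run, and continuous-time dynamics and hydrodynamics
  are out of scope.
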