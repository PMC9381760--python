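# Methods

## The problem

Groups of cohesively moving animals continuously reach consensus on two
distinct quantities: where to go and how fast to go. `groupinfluence`
quantifies, from simultaneous ~1 Hz position tracks of all group members,
how much each individual's movement predicts the group's subsequent
direction and speed changes — two per-individual probability-scale scores
(*turn influence* and *speed influence*) — together with front-half
occupancy (*frontness*) and group-level statistics relating influence,
social status, and frontness. The target system is a terrestrial forager
such as the meerkat: groups of ~5–20 individuals travel at 0.1–0.3 m/s
while members dig and pause independently, dispersed 1–10 m from their
neighbours.

## Spatially-discretized kinematics

Stop-and-go foraging makes fixed-time velocity estimates either noisy
(short windows, GPS jitter dominates) or blurred (long windows). All
velocities here are therefore *spatially* discretized: the velocity at
time t is the displacement to the first fix at least R meters away
(forward for the future velocity, backward for the past one) divided by
the elapsed time. R defaults to 10 m — a biologically meaningful scale
for a group spread over a few meters — and the robustness sweep repeats
the analysis at 5, 15 and 20 m. The R-crossing uses straight-line
displacement from the anchor fix (first crossing), not cumulative path
length: in-place digging jitter accumulates path length without
displacement and would otherwise trigger spurious crossings
(`displacement_mode="path"` is available for comparison). Scans never
bridge invalid samples: gaps longer than `max_gap` (default 10 s; shorter
gaps are linearly interpolated), observer-flagged disturbance windows
(half-open `[start, end)` intervals), and session boundaries all terminate
a scan, leaving the velocity unattained.

At each second and for each focal individual the pipeline computes:

- the **leave-one-out centroid**: the mean position of all valid group
  members excluding the focal, so that the focal's own movement cannot
  trivially predict "the group" (the paper-level circularity concern);
- the **group frame**: front = unit vector of the leave-one-out
  centroid's past velocity; right = front rotated 90° clockwise
  (x east, y north);
- **turn/speed labels** from the centroid's past vs. future velocity:
  `turn_right = 1` iff the planar cross product past × future is negative
  (clockwise); `speed_up = 1` iff |v_future| > |v_past|. Exact ties are
  dropped, never assigned;
- the focal's **LRM** (left–right movement): component of its own past
  velocity along the right axis, in m/s, rightward positive;
- the focal's **fb-speed difference**: its past-velocity component along
  the front axis minus the group's past speed (individual-minus-group, so
  a positive predictor means the focal outruns the group);
- the focal's **fb/lr positions** in the *full-group* centroid frame
  (used for frontness and the positional variants; positional ranking
  does not suffer the movement-circularity problem, and the full-group
  frame makes front–back positions sum to zero across members).

## Influence curves and scores

For each individual and metric, the binary group outcome is modeled
against the focal predictor with a four-parameter logistic

    P(x) = c + (d − c) / (1 + exp(−k (x − x0))),    0 ≤ c ≤ d ≤ 1,

fitted by Bernoulli maximum likelihood (L-BFGS-B, a fixed five-point
multi-start seeded from empirical class rates; deterministic given the
data). The lower/upper asymptotes c, d allow saturating, sub-unit
plateaus; the steepness k is unconstrained in sign, so below-baseline
(negative) influence is representable. A curve needs at least `min_obs`
(default 200) rows and both outcome classes; otherwise it is *unfit* and
the score is reported as missing, never as zero. Two canonicalizations
make the fit exactly symmetric: solutions with c > d are mapped to the
equivalent (d, c, −k), and the fit is performed on the orientation with
positive predictor sum and mapped back — mirrored inputs therefore yield
exactly mirrored curves, to floating-point round-off.

The per-individual score evaluates the fitted curve at the group-pooled
90% quantile (type-7, linear interpolation) of the signed predictor over
all individuals of the group. The turn score is symmetrized by default,

    score = (P(q90) + 1 − P(q10)) / 2,

which is exactly invariant under a left–right mirror of the raw tracks
(q90 of the mirrored pool is −q10 of the original); the speed score is the
plain P(q90) because its baseline is not 1/2 and symmetrization would
collapse a flat curve to 0.5 rather than to the empirical baseline.
Baselines: 0.5 for turning (left/right symmetry); for speeding up, the
empirical fraction of unique (session, time) steps with `speed_up = 1`
(deduplicated so group size does not weight the estimate).

Uncertainty is a session-level bootstrap: recording sessions (days) are
resampled with replacement, the curve is refitted per replicate with the
reference quantiles held at their full-data values (isolating curve
uncertainty from quantile uncertainty), and the 5%/95% quantiles of the
replicate scores form the 90% interval. The interval requires at least
two sessions with data for the individual.

## Frontness

An individual is in the front half at time t iff its front–back position
in the full-group frame is strictly positive (exactly zero counts as
back). Proportions are reported per contiguous segment (default 3600 s,
aligned to session start, final partial segment kept when it has at least
`min_valid` = 600 valid samples) and as a per-individual overall mean over
all valid time points — the covariate used in the mixed models and
correlations.

## Group-level statistics

Influence scores (one row per individual) and hourly frontness records
are modeled with linear mixed models: response ~ status (+ frontness),
random intercept per group, REML (statsmodels `MixedLM`). The marginal
F-test for status uses a containment-style denominator df,
ddf = N − rank(X) − (n_groups − 1); df conventions differ across
mixed-model stacks, so both df are always reported alongside the
statistic, and a singular fit falls back to the fixed-effects model with
a flag. Pairwise status contrasts use a single-step Tukey adjustment via
the studentized range distribution on the contrast t-statistics.
Associations among metrics use Spearman multilevel correlations: both
variables are rank-transformed over the pooled sample and a
random-intercept model of y-ranks on x-ranks yields
r = slope · sd(rank_x)/sd(rank_y), with a t-test on the slope
(ddf = N − n_groups − 1). With a single group this reduces to ordinary
Spearman; rank transforms make it invariant to monotone transforms of
either variable. Note the estimator recovers the within-group rank
association; strong between-group offsets attenuate the pooled ranks and
hence the estimate — by design, matching the standard
rank-then-multilevel construction.

## The synthetic cohort generator

The simulator provides ground truth for every pipeline stage. Its
defaults are the study conditions and describe slow cohesive foraging:

| parameter | default | meaning |
|---|---|---|
| `base_speed` | 0.2 m/s | latent group travel speed |
| `cohesion_sd` | 4 m | OU dispersion of members around the path |
| `pause_prob`, `pause_mean_s` | 0.03 /s, 8 s | digging pauses |
| `turn_rate`, `turn_sd_deg`, `turn_dur_s` | 0.5 /min, 60°, 20 s | discrete reorientations |
| `heading_diffusion_deg` | 3 °/√s | continuous heading wander |
| `burst_rate`, `burst_gain` | 0.5 /min, 1.5 | speed bursts |
| `burst_rise_s`, `burst_decay_s` | 5 s, 40 s | sharp rise, slow decay |
| `gps_noise_sd` | 0.5 m | iid position noise |
| `v_max` | 1 m/s | individual speed cap |

The latent group path is a correlated random walk: Poisson-timed heading
changes executed over ~20 s on top of continuous heading diffusion, and
speed bursts that rise within seconds and decay over ~40 s — so the
probability of speeding up at a random moment is below one half, as in
groups that accelerate in bursts and decelerate gradually. Continuous
heading wander matters: with a piecewise-straight path, the centroid's
direction fluctuations are dominated by the *mean-reverting* lateral
meander induced by cohesion noise, and the turn label then partly encodes
that reversion, which every forward-moving member's LRM trivially
predicts. Agents track a target point (latent position + a slowly-varying
world-frame OU offset) with zero systematic lag: movement is rate-limited
at `v_max`, and digging pauses freeze the agent briefly. Nearest-neighbour
spacing, travel speed, and stop-and-go cadence match the intended
phenomenology; the generator does not emulate terrain, predator events,
vocalizations, or group splits, so passing tests say nothing about those.

Influence ground truth is injected by *temporal anticipation at the
velocity level*: a direction driver follows a phase-advanced path that
executes the group's heading changes `lead_s` seconds early at the
group's current speed; a speed driver executes the speed profile early
along the current heading. A weak tether (60 s relaxation, slower than
the R-crossing window) keeps the advanced paths cohesive. The coupling
weight w ∈ [0, 1] blends the anticipatory and ordinary targets, and the
two drivers are independent knobs, which is what makes the
turn/speed-dissociation test meaningful. `lead_s` defaults to 20 s, about
half the R-crossing window: this is a deliberate design point —
bounded *positional* target shifts are provably ineffective (a bounded
offset enters a chord velocity as a time difference whose trailing term
anti-correlates with the label's momentum), and anticipation much shorter
than the window is invisible to chord-based velocity estimates.

Scenario presets (`null`, `direction_leader`, `speed_leader`,
`dual_leader`, `front_biased`) use 10 individuals and 3 sessions of 1 h
by default and write the same CSV dialect the reader accepts plus a
ground-truth JSON sidecar. All randomness flows from a single seed
through spawned per-session generators; outputs are byte-identical across
runs.

## Numerical choices and degenerate inputs

- Fixes are snapped to the session's integer-second grid; colliding
  timestamps for one individual are a data error.
- Geographic input is projected with an exact spherical transverse
  Mercator centered on the session's median coordinate (mean Earth radius
  6 371 008.8 m); scale error grows as (x/R_earth)²/2 and is far below
  0.1% over a foraging territory.
- Quantiles are type-7 (linear interpolation) throughout.
- Exact label ties (zero cross product, equal speeds) are dropped;
  assigning them would bias the 50% turn baseline.
- Logistic predictions are clipped to [1e-12, 1 − 1e-12] inside the
  likelihood; probabilities at evaluation are exact curve values.
- Degenerate curve inputs (single class, constant predictor, fewer than
  `min_obs` rows) yield unfit curves and missing scores; bootstrap
  replicates that fail to fit are dropped and counted.
- Sessions with fewer than two individuals yield an empty kinematic
  table with a warning, not an error.

## Scales used in the packaged checks

The acceptance-style tests run the full pipeline at reduced but
informative scales, chosen so the whole suite completes on a single CPU:
label balance pools 20 null cohorts of 3 h; null score calibration uses
the reference null scenario (3 × 1 h, ~100k rows); leader recovery and
dissociation use 100 cohorts of 5 × 30 min per scenario; the robustness
sweep uses 3 × 30 min cohorts at four thresholds plus graded-coupling
cohorts at 5 × 30 min. The acceptance script reports the pooled
right-turn label fraction at the full 3 h × 20 seed scale.

## Known limitations

- **Freshness bias of the influence metrics.** An individual's
  discretized-velocity window is systematically shorter ("fresher") than
  the leave-one-out centroid's, because a single track accumulates extra
  displacement from dispersion wander, GPS noise, and catch-up bouts that
  the centroid averages away. Group labels carry momentum from the past
  window, so a fresher focal chord predicts the label for *any* co-moving
  agent: on null cohorts with no designated drivers, per-individual
  scores land roughly 0.03–0.12 above their baselines rather than on
  them, on both metrics. Ablations (frozen offsets, pauses only, OU only,
  fully independent walkers) show the effect is intrinsic to the
  chord-and-label construction, not to any one generator ingredient — the
  speed metric shows it even for independent random walkers through the
  shared centroid-past-speed term in predictor and label. Rankings are
  much less affected than levels (drivers separate cleanly from
  followers), but absolute scores should be read relative to an empirical
  null, not to the nominal baseline.
- The bootstrap resamples sessions; with few sessions per group the
  interval is coarse and the 90% level approximate.
- The containment df convention is one of several defensible choices;
  F statistics match other stacks, denominator df may not.
- The simulator's agents respond to the latent path, not to each other;
  emergent local interactions (alignment, attraction hierarchies) are out
  of scope.
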