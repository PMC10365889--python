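# Methods

`swimgait` quantifies swim-function recovery of adult zebrafish after
complete spinal-cord transection from dorsal-centerline pose data. This note
documents the models and estimators, the synthetic swimmer that stands in
for tracked video and histology, the numerical choices, and the limits of
what the package's tests can show about real data.

## Posture representation

Each frame carries 10 annotated dorsal-centerline keypoints (head to
tail-base) plus a tail-fin-tip point, in pixels, with a per-keypoint
detection likelihood. A natural cubic spline is fitted through the 10
centerline points and re-sampled at 10 arc-length-equidistant points; the 8
interior keypoint triplets then yield the **angle pose**: signed angles
alpha_1..alpha_8 (counterclockwise-positive), where the angle at B for
triplet (A, B, C) is the rotation taking direction(AB) onto direction(BC).
The summed angle pose of a straight resting fish is zero, which makes the
sum a natural lateral-scoliosis scale. Angle poses are invariant to rigid
motion, so all gait scores inherit that invariance.

Four per-frame quality filters reject unusable poses: every keypoint
likelihood must exceed 0.5; the total polyline length must lie within 8
median absolute deviations (raw MAD, no normal-consistency factor) of the
assay median; every angle's within-assay z-score must stay below 8 in
magnitude; and every keypoint must move at most 45 px relative to the
nearest previously accepted frame within 3 frames (the jump criterion is
skipped when no accepted frame is that close — the reference choice after a
rejected run is otherwise ambiguous). Pose length uses the raw polyline, not
the spline arc length. Wall proximity can additionally be masked with a
configurable margin (default one body length).

## Behavior annotation

Every quality-passing frame whose 13-frame neighborhood also passes is
represented by a **pose window**: the angle pose concatenated with the six
poses before and after (104 components), labeled by the center frame's
behavior (rest, cruise, clockwise or counterclockwise turn). Training
balances classes with SMOTE (k = 20 same-class neighbors, clamped with a
warning for small classes; synthetic members are convex combinations of
neighbor pairs), embeds windows with UMAP (2 components, 50 neighbors,
fixed seed), and fits a random forest on the embedding. A posture-change
threshold then re-labels near-static frames as rest: if the center pose
differs from the previous *or* next pose by at most the threshold (max
absolute angle change), the frame is rest. The threshold is chosen by grid
search (50 log-spaced values over [1e-4, 0.5] rad) maximizing balanced
accuracy of the deployed path — classifier scores are computed through the
fitted model's out-of-sample transform, since that is how new assays are
labeled. 25% of annotated windows are withheld; held-out accuracy is
reported on the raw validation split by default (an oversampled validation
report is available behind a flag, but oversampling the validation set
inflates apparent independence). Turns are trained so the model does not
collapse every non-rest behavior into cruise; they are not analyzed
downstream.

Frames without windows inherit the nearest labeled frame's label within 6
frames (earlier frame wins ties). Maximal same-label runs become episodes;
a cruise run must contain at least 5 lateral extrema (about three body
oscillations), counted on the mean rostro-caudal angle trace, else it is
demoted to unlabeled.

## Capacity metrics

From the centroid (mean of the 10 centerline points; rejected frames
excluded, displacements bridge gaps): swim distance (summed frame-to-frame
displacement over the whole assay), activity (fraction of frames whose
displacement exceeds a threshold), centroid and pose burst frequencies
(maximal active runs per minute, still water only; pose bursts use non-rest
behavior labels), time against flow (flowing periods only; displacement
above threshold within +/-45 degrees, boundary inclusive, of the upstream
direction), and mean y-position (flowing periods only; higher y is closer
to the flow source). The activity threshold is configurable and recorded in
output metadata; the function default is 0.25 px/frame scaled by
frame_rate/70, while the pipeline default is 2.0 px/frame, above the
centroid tracking-noise floor (~0.3 px/frame at 0.6 px keypoint noise) so
resting fish do not register as active.

## Gait metrics

**Cruise curvature profile.** Per angle position, the center-to-peak
amplitude is estimated per half-cycle as half the peak-to-trough excursion
between consecutive extrema (Savitzky-Golay smoothing, window 7, order 3;
prominence 0.3 sd), averaged within an episode and then across episodes
(per position, ignoring positions unmeasurable in an episode). The
half-cycle estimator is robust to the asymmetric waveforms of injured fish,
which a sinusoidal fit is not. The **control profile** pools all uninjured
assays (sexes pooled by default; per-sex behind a flag).

**Rostral compensation** is the maximum absolute difference between an
assay's profile and the control profile over the five rostral positions
alpha_1..alpha_5 — acutely injured fish swim with elevated rostral
curvature, and the score decays toward control as the cord regenerates.
**Summed rostral amplitude** is the sum of the profile over the same five
positions.

**Cruise angular frequency** uses same-sign extrema intervals per position
(window-11 smoothing, prominence 0.7 sd, median interval — the median
resists spurious noise extrema at the low-amplitude rostral positions),
averaged over positions then cruises. **Tail-beat frequency** measures the
tail-tip trace perpendicular to the smoothed heading axis (tail-base to
head, half-second smoothing). **Strouhal number** St = f·A/U (A peak-to-peak
tail-tip excursion, U mean centroid speed) is computed per still-water
cruise and averaged weighted by observed period count; still water only,
because cruise ground speed under flow is not measurable from position
alone.

**Scoliosis** is the rest-bout-weighted mean of |mean summed angle pose|
per bout. Taking the magnitude per bout rather than averaging signed
posture over the assay keeps the score high for fish that flip
dorso-ventrally between bouts (sign inversions would otherwise cancel).

**Posture novelty** trains a Local Outlier Factor model (20 neighbors,
novelty mode, contamination "auto") on 1,200 poses per control assay — 100
drawn from each of 12 per-assay k-means clusters (seeded; with replacement
when a cluster is small) — and reports the fraction of an assay's poses
flagged novel.

## Cruise embedding

Cruise episodes are projected onto 5 principal components of the angle
poses. The PCA is fitted over the union of embedded assays so traces share
one coordinate system (per-assay fits would not be comparable). Pairwise
distances between traces use classic dynamic time warping: Euclidean local
cost over the 5-component frames, symmetric step pattern with the diagonal
step weighted twice, no window, no path normalization (a length-normalized
variant exists behind a flag). Affinity propagation (precomputed negative
distances, damping 0.9, median preference, 200-iteration convergence
window) selects exemplar cruises per assay; on non-convergence a seeded
random sample of at most 16 cruises substitutes. Exemplars are always real
cruises. The pooled exemplar distance matrix is embedded with UMAP
(precomputed metric, 20 neighbors, 3 components, fixed seed), and per-week
Gaussian kernel density estimates plus weekly means summarize gait-recovery
trajectories. Fish with scoliosis scores above 0.35 are excluded before
embedding so body shape does not dominate gait structure.

## Tensor component analysis

Per-assay metrics form a fish x assay x measurement tensor; each
measurement is z-scored over all cells, and fish with any missing cell are
excluded with a recorded reason (no interpolation). Canonical polyadic
decomposition is fitted by alternating least squares with random restarts;
reconstruction error is the normalized Frobenius residual, and replicate
similarity is the mean matched congruence coefficient (columns normalized,
similarity averaged over the three modes, greedy matching). Model selection
takes the largest rank whose mean replicate similarity clears 0.8, then the
lowest-error replicate. The default rank scan is 1-6 at the package's
simulated-cohort sizes (overridable; much larger scans are only meaningful
for larger cohorts). Fish are clustered on their factor rows with Ward
agglomerative clustering; the distance threshold is chosen by scanning
1,000 evenly spaced values over [0.001, 5] and maximizing the number of
clusters subject to a minimum-cluster-size floor (default 5; largest
qualifying threshold on ties). Cluster summaries sort by mean glial
bridging.

## Outcome statistics and prediction

At 8 wpi, functional and cellular metrics of fish complete in every column
are correlated pairwise with Spearman's r_s (tie-corrected; exact
permutation p-values below n = 10, t-approximation otherwise). Metrics
whose cohort mean rose at 1 wpi relative to control are negated (and
prefixed "(-)") so the correlation clustering is interpretable; average
linkage on 1 - r_s gives the metric dendrogram. Monotone curves (isotonic
regression with a light edge-preserving smoothing, direction from the sign
of r_s) are fitted only to pairs with p < 0.05, for visualization.

The **wellness score** averages each fish's 1 and 2 wpi swim distance and
rostral compensation, ranks distance descending and compensation ascending
within sex, and sums the two ranks. Fish below the per-sex median form the
highly regenerative prediction group; fish at or above it form the poorly
regenerative group (ties conservatively assigned low). Group outcomes
(glial bridging, proximal and distal axon regrowth) are compared with
Welch's two-sample t-test.

## The synthetic swimmer

The package ships no tracking or histology data; a simulator generates all
three input kinds with exact ground truth, so every estimator can be tested
end to end.

**Gait model.** The 8 angles follow a traveling wave alpha_i(t) = A_i
sin(2 pi f t - 2 pi s_i / lambda) + kappa_scol,i with a healthy envelope
rising linearly from 0.055 to 0.27 rad head to tail, wavelength 1.3 body
lengths, and healthy frequency 3 Hz (scaled by a per-fish baseline). A
latent recovery capacity rho in [0, 1] drives injury and recovery: the
rostral boost delta(week, rho) (acute value 0.22·(1 - 0.75 rho) rad) is
added at positions 1-5 and caudal damping (acute 0.45·(1 - 0.6 rho))
multiplies positions 6-8; both decay piecewise-exponentially and plateau at
3 wpi, faster for higher rho — mirroring the observed early plateau of gait
recovery. Angles are integrated to keypoints (20 px segments, 26 px tail
segment) with a yaw-compensation term that zeroes the net rigid rotation of
the oscillation (a free body conserves angular momentum; without it,
rostral boosts would inflate tail-tip excursion instead of representing
wasted effort) and the center of mass is advected at U = f·A/St* with
St* = 0.3, the mid-range of efficient undulatory swimming. Scoliotic fish
(25% prevalence, log-normal magnitude around 0.9 rad) carry a constant
summed curvature from 2 wpi onward — onset timing matches the observed
irreversibility of injury-induced scoliosis by 2 wpi.

**Assays.** Each assay runs the tunnel protocol (70 fps; 0, 10, 20 cm/s for
5 min each, shrinkable by `duration_scale` for tests) as a semi-Markov
alternation of rest, cruise and turn bouts whose cruise propensity rises
with flow and with the capacity factor c(week, rho) (drops to 0.15-0.35 at
1 wpi, recovers toward 0.45-0.95 by 8 wpi). Oscillation ramps in and out
over 0.2 s at bout edges (transition frames with under half amplitude are
ground-truth rest); heading re-orients gradually; fish bounce off walls by
direction reversal so cruise ground speed is preserved. Resting fish drift
down-stream under flow. Keypoints carry AR(1)-correlated Gaussian noise
(default 0.6 px marginal sd, lag-1 correlation 0.9 — detector errors
persist across adjacent, nearly identical frames), Beta(20, 1) likelihoods,
a slow 1.2% body-length "breathing" so the length filter has a
physiological scale, and a `dropout_rate` fraction of frames corrupted with
one of four planted defect types (low likelihood from Beta(1, 5),
teleported pose, length outlier, curvature kink) to exercise the filters.

**Outcomes.** Percent glial bridging is a monotone function of rho plus
noise (100·clip(0.04 + 0.90 rho + N(0, 0.07))); axon regrowth measures are
monotone in bridging plus noise, keeping rank correlations with bridging
above 0.6 at cohort scale, as observed. Because the same rho drives both
early function and outcomes, early wellness ranks predict outcomes by
construction — the simulator encodes the study's central hypothesis and the
pipeline's job is to recover it from pixels.

**Metrics-level generator.** For replicate studies that need hundreds of
cohorts (e.g. the predictor power property), `simulate_cohort_metrics`
draws per-assay swim distance and rostral compensation directly from the
same capacity/boost schedules plus measurement noise, and outcomes from the
same coupling model, skipping frame synthesis. The frame-level and
metrics-level paths share the schedule functions, so statistical properties
established on one transfer to the other up to measurement noise.

**What the simulator does not emulate.** No pixel rendering, hydrodynamics
or dorso-ventral motion; sex is a label with no gait effect (spinal
transection disrupts cruise gait in both sexes alike; sexes differ in
capacity, which the simulator leaves to per-fish variation);
heading dynamics and wall behavior are caricatures; detector failure modes
are stylized. Passing tests therefore demonstrate that the estimators
recover planted kinematic and statistical structure through the full
pipeline — not that biological effect sizes in new experiments will match.

## Numerical choices and degenerate inputs

- Extremum detection: prominence thresholds relative to the trace sd with
  small absolute floors; traces shorter than the smoothing window skip
  smoothing. Undefined measurements (no cruise, no rest, static tail,
  fewer than 3 extrema) are NaN and excluded downstream, mirroring the
  exclusion of non-cruising fish.
- Rostral amplitudes sit near the angle-noise floor (~0.065 rad at 0.6 px
  keypoint noise), so absolute amplitudes carry a small positive bias that
  cancels in the control-profile difference; rank-based uses (wellness,
  correlations) are unaffected.
- CP-ALS: normal-equation solves with a 1e-12 ridge; columns norm-balanced
  across modes and sorted by weight; convergence at 1e-12 error change or
  500 iterations.
- Desk-scale runs (shrunk assays, few fish) can leave sparse metrics
  (Strouhal needs a still-water cruise); pipeline stages drop measurements
  undefined in more than 10% (tensor) / 25% (correlations) of assays
  before excluding incomplete fish.
- All randomness flows from explicit integer seeds (numpy `SeedSequence`;
  fish-level streams keyed by CRC32 of the fish id), so cohorts, training
  and embeddings are bit-reproducible.

## Known limitations

- UMAP's out-of-sample transform is the accuracy bottleneck of frame
  labeling; the rest threshold recovers most transform leakage but
  transitional bout-edge frames remain ambiguous.
- DTW is quadratic per pair; embedding very long cruises is slow (the
  pipeline caps exemplar candidates per assay).
- The correlation heatmap and monotone fits are exploratory; only the
  planted-structure recovery and the prediction experiment are treated as
  confirmatory surfaces.
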