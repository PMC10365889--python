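# swimgait

Longitudinal swim-gait analysis of zebrafish spinal-cord regeneration.

Adult zebrafish recover swimming after complete spinal-cord transection.
Most established functional readouts measure swim *capacity* (how much a
fish swims); this package implements a full pipeline around the idea that
gait *quality* — how a fish swims — tracks neurological repair more
directly. Starting from dorsal-centerline keypoint trajectories (10
centerline points plus a tail-fin tip per frame, with detection
likelihoods), it produces behavior labels, capacity and gait metrics,
low-dimensional cruise embeddings, tensor-decomposed recovery trajectories,
correlation structure against 8-weeks-post-injury (wpi) cellular outcomes,
and an early-timepoint prediction of those outcomes. A synthetic swimmer
simulator with exact ground truth stands in for tracked video and
histology, so every estimator is testable end to end.

The core quantity is **rostral compensation**. Per assay, the *cruise
curvature profile* is the mean center-to-peak angular amplitude at the 8
centerline angle positions alpha_1..alpha_8 during cruise episodes
(forward swims with >= 5 lateral extrema). With a control profile C_i
averaged over uninjured assays,

    rostral_compensation = max over i in 1..5 of | profile_i - C_i |

— the maximal rostral deviation from healthy gait, in radians. Acutely
injured fish compensate for caudal paralysis with head-heavy swimming, so
the score spikes at 1 wpi and decays as the cord regenerates. The
**wellness score** ranks each fish within its sex by mean 1-2 wpi swim
distance (descending) and mean 1-2 wpi rostral compensation (ascending),
sums the ranks, and splits at the per-sex median into highly / poorly
regenerative prediction groups whose 8 wpi glial bridging and axon
regrowth are compared by Welch's t-test.

Other measurements: swim distance, activity, centroid/pose burst
frequency, time against flow, mean y-position; cruise angular frequency,
tail-beat frequency, Strouhal number (still water), lateral scoliosis,
posture novelty (local-outlier-factor fraction vs control posture); a
UMAP embedding of cruise exemplars from precomputed dynamic-time-warping
distances; and a canonical polyadic (CP-ALS) decomposition of the
fish x assay x measurement tensor with factor-based fish clustering.
See `docs/methods.md` for definitions, assumptions and limitations.

## Worked example

```python
import numpy as np
from swimgait import (FishPhenotype, SimConfig, simulate_assay,
                      process_assay, behavior, gait)
from swimgait.behavior import segment_episodes
from swimgait.gait import (cruise_curvature_profile, control_profile,
                           rostral_compensation, episode_angles)

# a healthy fish and a poorly recovering fish, one week after injury
cfg = SimConfig(duration_scale=0.1, rng_seed=7)
control = simulate_assay(FishPhenotype("a", "male", 0.9), "control", cfg)
injured = simulate_assay(FishPhenotype("b", "male", 0.1), "1", cfg)

profiles = {}
for name, rec in [("control", control), ("1wpi", injured)]:
    proc = process_assay(rec.poses)                  # splines + filters
    eps = segment_episodes(rec.truth.labels, proc["angles"],
                           rec.poses.frame_rate, rec.poses.flow_velocity())
    cruises = episode_angles(proc["angles"], eps, "cruise")
    profiles[name] = cruise_curvature_profile(cruises)

ctrl = control_profile([profiles["control"]])
print("injured rostral compensation:",
      round(rostral_compensation(profiles["1wpi"], ctrl), 3))
print("true injected boost:         ", round(injured.truth.delta, 3))
```

prints

```
injured rostral compensation: 0.198
true injected boost:          0.204
```

i.e. the pipeline reads the injured fish's head-heavy gait (a 0.204 rad
rostral amplitude boost injected by the simulator) back off the noisy
keypoint data to within a few thousandths of a radian.

The full pipeline (simulate -> pose -> classifier -> labels -> metrics ->
embedding -> tensor components -> statistics) also runs from the shell:

```bash
swimgait run-all --n-fish 6 --seed 0 --duration-scale 0.05 --out results/demo
```

which leaves per-assay pose tables, a metrics CSV, cruise-embedding
coordinates, CP factors and cluster tables, the 8 wpi correlation matrix,
and the wellness-score prediction report in `results/demo/`.

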