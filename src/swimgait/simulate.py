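"""Synthetic swimmer: cohorts of virtual zebrafish recovering from spinal-cord
transection.

The simulator emits the same three inputs the analysis pipeline consumes from
a real tracking experiment: per-frame centerline keypoint tables (10 dorsal
centerline points plus a tail-fin tip, with detection likelihoods), per-assay
metadata (fish id, sex, week post-injury, 70 fps, 0/10/20 cm/s flow periods),
and per-fish cellular outcomes at 8 wpi (percent glial bridging, proximal and
distal axon regrowth).  Every assay also carries exact ground truth (behavior
labels, injected rostral boost, caudal damping, scoliosis curvature, cruise
frequency, tail amplitude, forward speed) for parameter-recovery tests.

Gait model
----------
Body posture is generated directly in angle space: the 8 interior centerline
angles follow a traveling wave

    alpha_i(t) = A_i * sin(2*pi*f*t - 2*pi*s_i/lambda) + kappa_scol_i

with a healthy amplitude envelope ``A_i`` increasing head -> tail.  Injury
adds a rostral boost ``delta(week, rho)`` to the five rostral positions and
damps the caudal envelope; both decay with recovery capacity ``rho`` and
plateau at 3 wpi.  Angles are integrated to 10 evenly spaced keypoints plus a
tail-tip point, and the body is advected at the true forward speed, chosen so
cruises hold a target Strouhal number (0.3 by default).  Assays alternate
rest, cruise and turn bouts on a semi-Markov schedule whose cruise propensity
rises with flow velocity and swim capacity.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (DEFAULT_FLOW_SCHEDULE, DEFAULT_FRAME_RATE, N_ANGLES,
                   N_KEYPOINTS, WEEKS, PoseSequence, week_index)

# ---------------------------------------------------------------------------
# geometry constants (pixels)

SEG_LEN = 20.0          # arc length between adjacent centerline keypoints
TAIL_SEG_LEN = 26.0     # tail-base -> tail-fin-tip segment
BODY_LEN = 9 * SEG_LEN + TAIL_SEG_LEN
ARENA = (0.0, 0.0, 600.0, 1400.0)
PX_PER_CM = 8.0         # flow velocity (cm/s) -> drift speed scale

# healthy cruise parameters
HEALTHY_ENVELOPE = np.linspace(0.055, 0.27, N_ANGLES)  # rad, head -> tail
TAIL_ANGLE_GAIN = 1.25          # tail-fin angle amplitude vs last body angle
WAVELENGTH = 1.3 * BODY_LEN     # traveling-wave wavelength
HEALTHY_FREQ = 3.0              # Hz, cruise tail-beat frequency
ST_TARGET = 0.3                 # Strouhal number held by cruising fish
BREATHING_AMP = 0.012           # relative body-length oscillation
BREATHING_FREQ = 0.3            # Hz
NOISE_AR1 = 0.9                 # lag-1 autocorrelation of keypoint noise
                                # (detector errors persist across frames)

N_ROSTRAL = 5                   # angle positions alpha_1..alpha_5 are rostral

_AMP_RAMP_S = 0.2               # oscillation ramp-in/out at cruise bout edges
_HEADING_BLEND_S = 0.3          # heading re-orientation window


@dataclass(frozen=True)
class FishPhenotype:
    """Latent per-fish parameters driving recovery and gait."""

    fish_id: str
    sex: str                       # "male" | "female"
    recovery_capacity: float       # rho in [0, 1]
    scoliosis_prone: bool = False
    scoliosis_magnitude: float = 0.0   # rad, summed-curvature scale
    baseline_speed: float = 3.0        # body lengths / s (scales frequency)

    def __post_init__(self) -> None:
        if not 0.0 <= self.recovery_capacity <= 1.0:
            raise ValueError("recovery_capacity must lie in [0, 1]")
        if self.scoliosis_magnitude < 0:
            raise ValueError("scoliosis_magnitude must be >= 0")
        if not self.scoliosis_prone and self.scoliosis_magnitude != 0:
            raise ValueError("non-prone fish must have zero scoliosis magnitude")


@dataclass(frozen=True)
class CellularOutcome:
    """8 wpi histology readouts, all percent in [0, 100]."""

    glial_bridging: float
    axon_proximal: float
    axon_distal: float

    def __post_init__(self) -> None:
        for v in (self.glial_bridging, self.axon_proximal, self.axon_distal):
            if not 0.0 <= v <= 100.0:
                raise ValueError("cellular outcomes must lie in [0, 100]")


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for the simulator."""

    n_fish: int = 60
    weeks: tuple[str, ...] = WEEKS
    frame_rate: float = DEFAULT_FRAME_RATE
    flow_schedule: tuple[tuple[float, float], ...] = DEFAULT_FLOW_SCHEDULE
    rng_seed: int = 0
    noise_sd: float = 0.6          # px, Gaussian keypoint noise
    dropout_rate: float = 0.05     # fraction of frames given corrupt poses
    duration_scale: float = 1.0    # shrink assay periods for tests
    outcome_noise: float = 1.0     # multiplier on outcome-model noise
    mortality: bool = False

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if any(d <= 0 for _, d in self.flow_schedule):
            raise ValueError("flow period durations must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.duration_scale <= 0:
            raise ValueError("duration_scale must be positive")

    def scaled_schedule(self) -> tuple[tuple[float, float], ...]:
        return tuple((v, d * self.duration_scale) for v, d in self.flow_schedule)


@dataclass
class GroundTruth:
    """Exact generative parameters of one assay."""

    labels: np.ndarray             # per-frame behavior label
    delta: float                   # true rostral boost (rad)
    caudal_damping: float          # true caudal amplitude damping (fraction)
    scoliosis: float               # true summed scoliosis curvature (rad)
    cruise_frequency: float        # Hz
    tail_amplitude: float          # px, peak-to-peak tail-tip lateral
    speed: float                   # px/s, true forward speed during cruises
    corrupt: np.ndarray | None = None   # per-frame corruption flag


@dataclass
class AssayRecord:
    poses: PoseSequence
    truth: GroundTruth
    fish_id: str
    week: str


@dataclass
class FishRecord:
    phenotype: FishPhenotype
    outcome: CellularOutcome
    assays: dict[str, AssayRecord]
    survived: bool = True
    rho_true: float = 0.0


# ---------------------------------------------------------------------------
# injury schedules (shared by the frame-level and metrics-level generators)

def delta_schedule(week: str, rho: float, delta_acute: float = 0.22) -> float:
    """Rostral boost delta(week, rho), rad.

    Zero before injury; largest at 1 wpi; piecewise-exponential decay with
    recovery that plateaus at 3 wpi (gait recovery slows around 3 wpi).
    Higher recovery capacity rho gives both a smaller acute boost and a
    faster decay.
    """
    w = week_index(week)
    if w == 0:
        return 0.0
    tau = 0.5 + 2.5 * (1.0 - 0.7 * rho)
    w_eff = min(w, 3)
    return delta_acute * (1.0 - 0.75 * rho) * math.exp(-(w_eff - 1) / tau)


def caudal_damping_schedule(week: str, rho: float, damp_acute: float = 0.45) -> float:
    """Fractional caudal amplitude loss; same decay shape as the boost."""
    w = week_index(week)
    if w == 0:
        return 0.0
    tau = 0.5 + 2.5 * (1.0 - 0.7 * rho)
    w_eff = min(w, 3)
    return damp_acute * (1.0 - 0.6 * rho) * math.exp(-(w_eff - 1) / tau)


def capacity_schedule(week: str, rho: float) -> float:
    """Swim-capacity factor in (0, 1]: 1 before injury, drops at 1 wpi and
    recovers toward a rho-dependent plateau by 8 wpi."""
    w = week_index(week)
    if w == 0:
        return 1.0
    c1 = 0.15 + 0.20 * rho
    c8 = 0.45 + 0.50 * rho
    return c1 + (c8 - c1) * (1.0 - math.exp(-(w - 1) / 2.2))


def frequency_schedule(week: str, rho: float, f0: float) -> float:
    """Cruise frequency: mildly depressed acutely, recovering by 3 wpi."""
    w = week_index(week)
    if w == 0:
        return f0
    w_eff = min(w, 3)
    drop = 0.18 * (1.0 - 0.6 * rho) * math.exp(-(w_eff - 1) / 1.5)
    return f0 * (1.0 - drop)


def scoliosis_schedule(phenotype: FishPhenotype, week: str) -> float:
    """True summed scoliosis curvature: onset at 2 wpi, fixed thereafter."""
    if not phenotype.scoliosis_prone or week_index(week) < 2:
        return 0.0
    return phenotype.scoliosis_magnitude


def gait_envelope(week: str, rho: float,
                  delta_override: float | None = None) -> tuple[np.ndarray, float]:
    """Angle-amplitude envelope A_i for an assay and the rostral boost used.

    The rostral boost is added at positions 1..5; caudal damping multiplies
    positions 6..8.
    """
    delta = delta_schedule(week, rho) if delta_override is None else float(delta_override)
    damping = 0.0 if week_index(week) == 0 else caudal_damping_schedule(week, rho)
    env = HEALTHY_ENVELOPE.copy()
    env[:N_ROSTRAL] += delta
    env[N_ROSTRAL:] *= (1.0 - damping)
    return env, delta


# ---------------------------------------------------------------------------
# angle-space wave synthesis and integration to keypoints

def _angle_phases() -> np.ndarray:
    """Traveling-wave phase lag 2*pi*s_i/lambda at the 8 angle positions."""
    s = SEG_LEN * np.arange(1, N_ANGLES + 1)
    return 2.0 * np.pi * s / WAVELENGTH


_TAIL_PHASE = None


def _tail_phase() -> float:
    global _TAIL_PHASE
    if _TAIL_PHASE is None:
        _TAIL_PHASE = -float(_angle_phases()[-1]) - 2 * np.pi * TAIL_SEG_LEN / WAVELENGTH
    return _TAIL_PHASE


def _wave_angles(t: np.ndarray, freq: float, envelope: np.ndarray,
                 kappa_scol: np.ndarray, phase0: float = 0.0,
                 ramp: np.ndarray | None = None) -> np.ndarray:
    """(n, 8) angle traces of a cruise wave; ``ramp`` scales the oscillation
    (not the scoliosis offset)."""
    phases = _angle_phases()
    arg = 2.0 * np.pi * freq * t[:, None] - phases[None, :] + phase0
    osc = envelope[None, :] * np.sin(arg)
    if ramp is not None:
        osc = osc * ramp[:, None]
    return osc + kappa_scol[None, :]


def angles_to_keypoints(angles: np.ndarray, tail_angle: np.ndarray,
                        head_xy: np.ndarray, heading: np.ndarray) -> np.ndarray:
    """Integrate angle poses to 11 keypoints.

    ``heading`` is the tailward direction of the first segment, measured
    counterclockwise from straight-downstream (-y); a fish facing the flow
    source with heading 0 has its head at the highest y.
    """
    angles = np.atleast_2d(angles)
    n = angles.shape[0]
    # cumulative segment directions: phi_j = heading + sum_{i<=j} alpha_i
    phi = np.empty((n, N_KEYPOINTS - 1))
    phi[:, 0] = heading
    phi[:, 1:N_ANGLES + 1] = heading[:, None] + np.cumsum(angles, axis=1)
    phi[:, N_ANGLES + 1] = phi[:, N_ANGLES] + tail_angle
    seg_lens = np.full(N_KEYPOINTS - 1, SEG_LEN)
    seg_lens[-1] = TAIL_SEG_LEN
    dxy = np.stack([np.sin(phi), -np.cos(phi)], axis=-1) * seg_lens[None, :, None]
    xy = np.empty((n, N_KEYPOINTS, 2))
    xy[:, 0] = head_xy
    xy[:, 1:] = head_xy[:, None, :] + np.cumsum(dxy, axis=1)
    return xy


#: share of the 9 body segments rotated by each angle position
_YAW_WEIGHTS = (9 - np.arange(1, N_ANGLES + 1)) / 9.0


def _yaw_compensation(osc_angles: np.ndarray) -> np.ndarray:
    """Counter-yaw that zeroes the mean body rotation of the oscillation.

    Without it, rostral angle oscillations rigidly rotate the whole caudal
    chain, inflating tail excursion; a free-swimming body conserves angular
    momentum, so the head counter-rotates instead.
    """
    return -(osc_angles * _YAW_WEIGHTS[None, :]).sum(axis=1)


def _scoliosis_profile(total: float) -> np.ndarray:
    """Distribute a summed scoliosis curvature over the 8 angle positions."""
    return np.full(N_ANGLES, total / N_ANGLES)


def _probe_tail_amplitude(freq: float, envelope: np.ndarray,
                          frame_rate: float) -> float:
    """Peak-to-peak lateral tail-tip amplitude of a noise-free wave cycle,
    measured in the body frame (head fixed, heading 0)."""
    n = max(int(round(4 * frame_rate / freq)), 16)
    t = np.arange(n) / frame_rate
    ang = _wave_angles(t, freq, envelope, np.zeros(N_ANGLES))
    tail = TAIL_ANGLE_GAIN * envelope[-1] * np.sin(
        2 * np.pi * freq * t + _tail_phase())
    xy = angles_to_keypoints(ang, tail, np.zeros((n, 2)),
                             _yaw_compensation(ang))
    lateral = xy[:, -1, 0] - xy[:, 0, 0]
    return float(lateral.max() - lateral.min())


def cruise_speed(freq: float, envelope: np.ndarray, frame_rate: float,
                 st_target: float = ST_TARGET) -> tuple[float, float]:
    """True forward speed U = f * A / St* and the tail amplitude A (px)."""
    amp = _probe_tail_amplitude(freq, envelope, frame_rate)
    return freq * amp / st_target, amp


def simulate_cruise_wave(phenotype: FishPhenotype, week: str, duration: float,
                         config: SimConfig | None = None,
                         delta_override: float | None = None,
                         phase0: float = 0.0,
                         head_xy: tuple[float, float] | None = None,
                         st_target: float = ST_TARGET) -> tuple[np.ndarray, GroundTruth]:
    """Generate one noise-free cruise bout.

    Returns the (n_frames, 11, 2) keypoint array and the ground truth.  The
    body is advected straight upstream at the true forward speed.

    Raises ``ValueError`` if the duration covers fewer than one oscillation
    period (an unusable cruise).
    """
    config = config or SimConfig()
    week = str(week)
    rho = phenotype.recovery_capacity
    freq = frequency_schedule(week, rho, HEALTHY_FREQ * phenotype.baseline_speed / 3.0)
    if duration * freq < 1.0:
        raise ValueError(
            f"duration {duration:.3f}s covers less than one oscillation at {freq:.2f} Hz")
    envelope, delta = gait_envelope(week, rho, delta_override)
    kappa = _scoliosis_profile(scoliosis_schedule(phenotype, week))
    n = int(round(duration * config.frame_rate))
    t = np.arange(n) / config.frame_rate
    angles = _wave_angles(t, freq, envelope, kappa, phase0)
    tail_angle = TAIL_ANGLE_GAIN * envelope[-1] * np.sin(
        2 * np.pi * freq * t + phase0 + _tail_phase())
    speed, tail_amp = cruise_speed(freq, envelope, config.frame_rate, st_target)
    x0, y0 = head_xy if head_xy is not None else (ARENA[2] / 2, ARENA[1] + BODY_LEN + 50)
    path = np.column_stack([np.full(n, x0), y0 + speed * t])
    xy = angles_to_keypoints(angles, tail_angle, np.zeros((n, 2)),
                             _yaw_compensation(angles - kappa[None, :]))
    # anchor the center of mass on the advected path
    xy += (path - xy[:, :10].mean(axis=1))[:, None, :]
    truth = GroundTruth(labels=np.full(n, "cruise", dtype=object), delta=delta,
                        caudal_damping=caudal_damping_schedule(week, rho)
                        if week_index(week) else 0.0,
                        scoliosis=float(kappa.sum()), cruise_frequency=freq,
                        tail_amplitude=tail_amp, speed=speed)
    return xy, truth


# ---------------------------------------------------------------------------
# full assays: semi-Markov bout schedule + noise + corruption

def _bout_schedule(rng: np.random.Generator, schedule, capacity: float,
                   freq: float) -> list[tuple[str, float, float]]:
    """Alternating rest/active bouts per flow period.

    Returns (state, duration_s, flow_velocity) tuples.  Cruise propensity
    grows with flow velocity and with the fish's current swim capacity.
    Every flow period is guaranteed at least one cruise bout.
    """
    bouts: list[tuple[str, float, float]] = []
    min_cruise = max(1.0, 4.0 / freq)       # long enough for >= 5 extrema
    for vel, dur in schedule:
        q = float(np.clip((0.30 + 0.50 * vel / 20.0) * (0.25 + 0.75 * capacity),
                          0.05, 0.92))
        cruise_mean = max(min_cruise * 1.3, 1.8)
        rest_mean = max(cruise_mean * (1 - q) / q, 0.25)
        period: list[tuple[str, float, float]] = []
        t, resting = 0.0, True
        while t < dur:
            if resting:
                d = min(rng.gamma(2.0, rest_mean / 2.0), dur / 3.0)
                state = "rest"
            elif rng.random() < 0.12:
                d = rng.uniform(0.35, 0.6)
                state = "turn_cw" if rng.random() < 0.5 else "turn_ccw"
            else:
                d = max(rng.gamma(2.0, cruise_mean / 2.0), min_cruise)
                state = "cruise"
            d = min(d, dur - t)
            if d > 0:
                period.append((state, d, vel))
            t += d
            resting = not resting
        if not any(s == "cruise" for s, _, _ in period) and dur >= 2 * min_cruise:
            # carve a cruise out of the longest rest bout
            j = max(range(len(period)), key=lambda k: period[k][1]
                    if period[k][0] == "rest" else -1.0)
            s, d, v = period[j]
            period[j] = (s, d / 2, v)
            period.insert(j + 1, ("cruise", d / 2, v))
        bouts.extend(period)
    return bouts


def _reflect(pos: float, lo: float, hi: float) -> float:
    span = hi - lo
    p = (pos - lo) % (2 * span)
    return lo + (p if p <= span else 2 * span - p)


def _ar1_noise(rng: np.random.Generator, shape: tuple, sd: float,
               rho: float = NOISE_AR1) -> np.ndarray:
    """Temporally correlated keypoint noise (stationary AR(1) along axis 0)."""
    from scipy.signal import lfilter
    burn = 60
    e = rng.standard_normal((shape[0] + burn,) + tuple(shape[1:]))
    x = lfilter([1.0], [1.0, -rho], e, axis=0)[burn:]
    return sd * math.sqrt(1.0 - rho**2) * x


_TURN_SHAPE = np.array([0.25, 0.40, 0.55, 0.65, 0.65, 0.55, 0.45, 0.30])


def _fish_seed(fish_id: str) -> int:
    return zlib.crc32(fish_id.encode()) % (2**31)


def simulate_assay(phenotype: FishPhenotype, week: str,
                   config: SimConfig) -> AssayRecord:
    """Simulate one full assay (three flow periods) for one fish."""
    if str(week) not in [str(w) for w in config.weeks]:
        raise ValueError(f"week {week!r} not in config.weeks")
    week = str(week)
    rho = phenotype.recovery_capacity
    rng = np.random.default_rng(np.random.SeedSequence(
        [config.rng_seed, _fish_seed(phenotype.fish_id), week_index(week)]))
    fr = config.frame_rate
    schedule = config.scaled_schedule()
    capacity = capacity_schedule(week, rho)
    freq = frequency_schedule(week, rho, HEALTHY_FREQ * phenotype.baseline_speed / 3.0)
    envelope, delta = gait_envelope(week, rho)
    kappa = _scoliosis_profile(scoliosis_schedule(phenotype, week))
    speed, tail_amp = cruise_speed(freq, envelope, fr)

    bouts = _bout_schedule(rng, schedule, capacity, freq)
    nfs = [int(round(d * fr)) for _, d, _ in bouts]
    n_total = sum(nfs)
    angles = np.zeros((n_total, N_ANGLES))
    tail_angles = np.zeros(n_total)
    labels = np.full(n_total, "rest", dtype=object)
    head = np.zeros((n_total, 2))
    heading = np.zeros(n_total)

    xmin, ymin, xmax, ymax = ARENA
    margin = 0.35 * BODY_LEN        # lateral clearance for the centroid
    margin_y = 0.65 * BODY_LEN      # along-body clearance for the centroid
    x, y = (xmin + xmax) / 2, (ymin + ymax) / 2
    psi = 0.0               # heading deviation from upstream
    ramp_n = max(int(round(_AMP_RAMP_S * fr)), 2)
    blend_n = max(int(round(_HEADING_BLEND_S * fr)), 2)
    i = 0
    for (state, _, vel), nf in zip(bouts, nfs):
        if nf == 0:
            continue
        sl = slice(i, i + nf)
        t = np.arange(nf) / fr
        labels[sl] = state
        if state == "cruise":
            phase0 = rng.uniform(0, 2 * np.pi)
            ramp = np.minimum.reduce([np.ones(nf),
                                      np.arange(nf) / ramp_n,
                                      (nf - 1 - np.arange(nf)) / ramp_n])
            ramp = np.clip(ramp, 0.0, 1.0)
            # transition frames with little oscillation read as rest
            labels[sl] = np.where(ramp >= 0.5, "cruise", "rest")
            angles[sl] = _wave_angles(t, freq, envelope, kappa, phase0, ramp)
            tail_angles[sl] = ramp * TAIL_ANGLE_GAIN * envelope[-1] * np.sin(
                2 * np.pi * freq * t + phase0 + _tail_phase())
            psi_new = float(np.clip(
                rng.normal(0.0, 0.30 + 0.45 * (1 - capacity)) if vel > 0
                else rng.normal(0.0, 0.9), -1.5, 1.5))
            # re-orient gradually: cap the heading step so the tail sweep
            # stays well under the jump-filter threshold
            n_blend = int(np.clip(math.ceil(abs(psi_new - psi) * BODY_LEN / 8.0),
                                  blend_n, max(nf - 1, blend_n)))
            blend = np.clip(np.arange(nf) / n_blend, 0.0, 1.0)
            heading[sl] = psi + (psi_new - psi) * blend \
                + _yaw_compensation(angles[sl] - kappa[None, :])
            psi = psi_new
            u = speed if vel == 0 else max(speed - 0.5 * vel * PX_PER_CM, 0.3 * speed)
            # bounce off walls by flipping travel direction (the body keeps
            # undulating at full speed, so cruise ground speed stays true)
            sx, sy = 1.0, 1.0
            xlo, xhi = xmin + margin, xmax - margin
            ylo, yhi = ymin + margin_y, ymax - margin_y
            for k in range(nf):
                hdg = heading[i + k]
                vx = sx * u * math.sin(hdg) / fr
                vy = sy * u * math.cos(hdg) / fr
                if not xlo <= x + vx <= xhi:
                    sx, vx = -sx, -vx
                if not ylo <= y + vy <= yhi:
                    sy, vy = -sy, -vy
                x = min(max(x + vx, xlo), xhi)
                y = min(max(y + vy, ylo), yhi)
                head[i + k] = (x, y)
        elif state.startswith("turn"):
            direction = 1.0 if state == "turn_ccw" else -1.0
            bend = direction * 0.55 * np.sin(np.pi * np.arange(nf) / max(nf - 1, 1))
            angles[sl] = kappa[None, :] + bend[:, None] * _TURN_SHAPE[None, :]
            tail_angles[sl] = bend * 0.35
            dpsi = direction * rng.uniform(0.7, 1.2)
            heading[sl] = psi + dpsi * np.linspace(0, 1, nf)
            psi = float(heading[i + nf - 1])
            head[sl] = (x, y)
        else:  # rest: hold posture, drift downstream under flow
            angles[sl] = kappa[None, :] + rng.normal(0.0, 0.004, size=(nf, N_ANGLES))
            tail_angles[sl] = rng.normal(0.0, 0.004, size=nf)
            drift = 0.35 * vel * PX_PER_CM / fr
            for k in range(nf):
                y = max(y - drift, ymin + margin_y)
                head[i + k] = (x, y)
                heading[i + k] = psi
        i += nf

    xy = angles_to_keypoints(angles, tail_angles, np.zeros((n_total, 2)), heading)
    # anchor the center of mass on the tracked path
    xy += (head - xy[:, :10].mean(axis=1))[:, None, :]
    # slow body-length "breathing" so measured pose length has physiological
    # variation (keeps the MAD-based length filter meaningfully scaled)
    tt = np.arange(n_total) / fr
    breathe = 1.0 + BREATHING_AMP * np.sin(
        2 * np.pi * BREATHING_FREQ * tt + rng.uniform(0, 2 * np.pi))
    centroid = xy[:, :10].mean(axis=1, keepdims=True)
    xy = centroid + (xy - centroid) * breathe[:, None, None]

    likelihood = rng.beta(20.0, 1.0, size=(n_total, N_KEYPOINTS))
    if config.noise_sd > 0:
        xy = xy + _ar1_noise(rng, xy.shape, config.noise_sd)

    corrupt = np.zeros(n_total, dtype=bool)
    if config.dropout_rate > 0:
        n_bad = int(round(config.dropout_rate * n_total))
        bad = rng.choice(n_total, size=n_bad, replace=False)
        corrupt[bad] = True
        kinds = rng.integers(0, 4, size=n_bad)
        for j, kind in zip(bad, kinds):
            if kind == 0:       # low likelihood at one keypoint
                likelihood[j, rng.integers(N_KEYPOINTS)] = rng.beta(1.0, 5.0)
            elif kind == 1:     # teleported pose
                ang = rng.uniform(0, 2 * np.pi)
                r = rng.uniform(70, 160)
                xy[j] += np.array([r * math.cos(ang), r * math.sin(ang)])
            elif kind == 2:     # length outlier: uniform scale about centroid
                c = xy[j, :10].mean(axis=0)
                xy[j] = c + (xy[j] - c) * rng.uniform(1.6, 2.2)
            else:               # curvature outlier: kink one interior keypoint
                kp = rng.integers(2, 8)
                seg = xy[j, kp + 1] - xy[j, kp - 1]
                perp = np.array([-seg[1], seg[0]])
                perp /= max(np.linalg.norm(perp), 1e-9)
                xy[j, kp] += perp * rng.uniform(28, 40)

    poses = PoseSequence(
        xy=xy, likelihood=likelihood, frame_rate=fr,
        flow_schedule=schedule, arena=ARENA,
        meta={"fish_id": phenotype.fish_id, "week": week, "sex": phenotype.sex})
    truth = GroundTruth(labels=labels, delta=delta,
                        caudal_damping=caudal_damping_schedule(week, rho)
                        if week_index(week) else 0.0,
                        scoliosis=float(kappa.sum()), cruise_frequency=freq,
                        tail_amplitude=tail_amp, speed=speed, corrupt=corrupt)
    return AssayRecord(poses=poses, truth=truth, fish_id=phenotype.fish_id, week=week)


# ---------------------------------------------------------------------------
# cohorts

def _draw_phenotypes(n_fish: int, rng: np.random.Generator) -> list[FishPhenotype]:
    phenos = []
    for i in range(n_fish):
        sex = "male" if i < (n_fish + 1) // 2 else "female"
        prone = bool(rng.random() < 0.25)
        mag = float(np.exp(rng.normal(np.log(0.9), 0.6))) if prone else 0.0
        phenos.append(FishPhenotype(
            fish_id=f"fish{i:03d}", sex=sex,
            recovery_capacity=float(rng.uniform(0.02, 0.98)),
            scoliosis_prone=prone, scoliosis_magnitude=mag,
            baseline_speed=float(np.clip(rng.normal(3.0, 0.25), 2.2, 3.8))))
    return phenos


def cellular_outcomes(rho: float, rng: np.random.Generator,
                      noise: float = 1.0) -> CellularOutcome:
    """Draw 8 wpi outcomes coupled to recovery capacity.

    Bridging is a monotone function of rho plus noise; axon regrowth measures
    are monotone in bridging plus noise, keeping their rank correlation with
    bridging above 0.6 at cohort scale.
    """
    bridging = 100.0 * np.clip(0.04 + 0.90 * rho + noise * rng.normal(0, 0.07), 0, 1)
    prox = np.clip(5.0 + 0.75 * bridging + noise * rng.normal(0, 8.0), 0, 100)
    dist = np.clip(2.0 + 0.50 * bridging + noise * rng.normal(0, 7.0), 0, 100)
    return CellularOutcome(float(bridging), float(prox), float(dist))


def simulate_cohort(n_fish: int, config: SimConfig) -> list[FishRecord]:
    """Simulate a full cohort: all assays plus cellular outcomes per fish."""
    if n_fish < 2:
        raise ValueError("need at least 2 fish")
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 777]))
    phenos = _draw_phenotypes(n_fish, rng)
    records = []
    for ph in phenos:
        outcome = cellular_outcomes(ph.recovery_capacity, rng, config.outcome_noise)
        survived = True
        weeks = [str(w) for w in config.weeks]
        if config.mortality and rng.random() < 0.1:
            survived = False
            weeks = weeks[:int(rng.integers(1, len(weeks)))]
        assays = {w: simulate_assay(ph, w, config) for w in weeks}
        records.append(FishRecord(phenotype=ph, outcome=outcome, assays=assays,
                                  survived=survived, rho_true=ph.recovery_capacity))
    return records


def outcomes_frame(records: list[FishRecord]) -> pd.DataFrame:
    """Per-fish outcome table (one row per fish)."""
    rows = [{"fish_id": r.phenotype.fish_id, "sex": r.phenotype.sex,
             "survived": r.survived, "rho_true": r.rho_true,
             "glial_bridging": r.outcome.glial_bridging,
             "axon_proximal": r.outcome.axon_proximal,
             "axon_distal": r.outcome.axon_distal} for r in records]
    return pd.DataFrame(rows)


def simulate_cohort_metrics(n_fish: int, seed: int,
                            weeks: tuple[str, ...] = WEEKS,
                            outcome_noise: float = 1.0
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Metrics-level cohort generator for large replicate studies.

    Draws per-assay swim distance and rostral compensation directly from the
    same capacity/boost schedules that drive the frame-level simulator
    (distance proportional to cruise fraction x speed; compensation equal to
    the injected boost plus measurement noise), plus coupled outcomes.
    Returns (metrics, outcomes) DataFrames.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 999]))
    phenos = _draw_phenotypes(n_fish, rng)
    mrows, orows = [], []
    for ph in phenos:
        rho = ph.recovery_capacity
        out = cellular_outcomes(rho, rng, outcome_noise)
        orows.append({"fish_id": ph.fish_id, "sex": ph.sex, "rho_true": rho,
                      "glial_bridging": out.glial_bridging,
                      "axon_proximal": out.axon_proximal,
                      "axon_distal": out.axon_distal})
        for w in weeks:
            w = str(w)
            c = capacity_schedule(w, rho)
            env, _ = gait_envelope(w, rho)
            f = frequency_schedule(w, rho, HEALTHY_FREQ * ph.baseline_speed / 3.0)
            # relative distance ~ cruise fraction x speed (speed ~ f x amplitude)
            dist = (0.25 + 0.75 * c) * f * env[-1] * 1e4 / 3.0
            dist *= max(1.0 + rng.normal(0, 0.18), 0.05)
            comp = delta_schedule(w, rho) + abs(rng.normal(0, 0.006)) \
                + rng.normal(0, 0.010)
            mrows.append({"fish_id": ph.fish_id, "sex": ph.sex, "week": w,
                          "distance": dist, "rostral_compensation": max(comp, 0.0)})
    return pd.DataFrame(mrows), pd.DataFrame(orows)


# ---------------------------------------------------------------------------
# constructed fixture for the pose-quality filters

def planted_violation_fixture(seed: int = 0, n_frames: int = 200
                              ) -> tuple[PoseSequence, dict[int, str]]:
    """A 200-frame resting sequence with 10 planted filter violations.

    Returns the sequence and a {frame: reason} map with 3 likelihood, 3
    length, 2 curvature and 2 jump violations, each constructed to trip only
    its own filter.  All other frames pass all four filters.
    """
    rng = np.random.default_rng(seed)
    fr = DEFAULT_FRAME_RATE
    t = np.arange(n_frames) / fr
    angles = rng.normal(0.0, 0.004, size=(n_frames, N_ANGLES))
    tail = rng.normal(0.0, 0.004, size=n_frames)
    head = np.column_stack([np.full(n_frames, 300.0), np.full(n_frames, 700.0)])
    xy = angles_to_keypoints(angles, tail, head, np.zeros(n_frames))
    breathe = 1.0 + 0.015 * np.sin(2 * np.pi * 0.4 * t)
    centroid = xy[:, :10].mean(axis=1, keepdims=True)
    xy = centroid + (xy - centroid) * breathe[:, None, None]
    xy += _ar1_noise(rng, xy.shape, 0.6)
    lik = rng.beta(20.0, 1.0, size=(n_frames, N_KEYPOINTS))

    planted: dict[int, str] = {}
    for f in (20, 80, 140):                      # likelihood: one keypoint < 0.5
        lik[f, int(rng.integers(N_KEYPOINTS))] = 0.40
        planted[f] = "likelihood"
    for f in (35, 95, 155):                      # length: uniform scale, angles kept
        c = xy[f, :10].mean(axis=0)
        xy[f] = c + (xy[f] - c) * 1.35
        planted[f] = "length"
    for f in (50, 110):                          # curvature: kink one keypoint
        seg = xy[f, 5] - xy[f, 3]
        perp = np.array([-seg[1], seg[0]]) / np.linalg.norm(seg)
        xy[f, 4] += perp * 15.0
        planted[f] = "curvature"
    for f in (65, 170):                          # jump: rigid translation > 45 px
        xy[f] += np.array([42.0, 42.0])
        planted[f] = "jump"

    seq = PoseSequence(xy=xy, likelihood=lik, frame_rate=fr,
                       flow_schedule=((0.0, n_frames / fr),), arena=ARENA,
                       meta={"fish_id": "fixture", "week": "control"})
    return seq, planted
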