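import warnings

import numpy as np
import pytest

from swimgait import behavior, gait
from swimgait.pose import process_assay
from swimgait.simulate import (FishPhenotype, SimConfig, simulate_assay,
                               simulate_cruise_wave)

warnings.filterwarnings("ignore", message=".*n_jobs value.*")
warnings.filterwarnings("ignore", message=".*force_all_finite.*")


@pytest.fixture(scope="session")
def healthy_assay():
    """One clean control assay with ground truth and processed poses."""
    ph = FishPhenotype("healthy0", "male", 0.85)
    cfg = SimConfig(duration_scale=0.1, rng_seed=42, dropout_rate=0.02)
    rec = simulate_assay(ph, "control", cfg)
    proc = process_assay(rec.poses)
    return rec, proc


@pytest.fixture(scope="session")
def long_assay():
    """A long control assay (many cruises) for stability properties."""
    ph = FishPhenotype("long0", "male", 0.85)
    cfg = SimConfig(duration_scale=0.3, rng_seed=42, dropout_rate=0.02)
    rec = simulate_assay(ph, "control", cfg)
    proc = process_assay(rec.poses)
    eps = behavior.segment_episodes(rec.truth.labels, proc["angles"],
                                    rec.poses.frame_rate,
                                    rec.poses.flow_velocity())
    return rec, proc, eps


@pytest.fixture(scope="session")
def healthy_episodes(healthy_assay):
    """Ground-truth-labeled episodes of the healthy assay."""
    rec, proc = healthy_assay
    return behavior.segment_episodes(rec.truth.labels, proc["angles"],
                                     rec.poses.frame_rate,
                                     rec.poses.flow_velocity())


@pytest.fixture(scope="session")
def control_profile_sim():
    """Control cruise-curvature profile pooled over 4 uninjured assays."""
    profiles = []
    for i in range(4):
        ph = FishPhenotype(f"ctrl{i}", "male", 0.6)
        rec = simulate_assay(ph, "control",
                             SimConfig(duration_scale=0.08, rng_seed=300 + i))
        proc = process_assay(rec.poses)
        eps = behavior.segment_episodes(rec.truth.labels, proc["angles"],
                                        rec.poses.frame_rate,
                                        rec.poses.flow_velocity())
        cruises = gait.episode_angles(proc["angles"], eps, "cruise")
        prof = gait.cruise_curvature_profile(cruises)
        if prof is not None:
            profiles.append(prof)
    return gait.control_profile(profiles)


def make_training_windows(seeds=(0,), duration_scale=0.06):
    """Ground-truth-labeled pose windows from a small simulated cohort."""
    phenos = [
        FishPhenotype("tw0", "male", 0.15),
        FishPhenotype("tw1", "male", 0.55),
        FishPhenotype("tw2", "female", 0.9),
        FishPhenotype("tw3", "female", 0.4, scoliosis_prone=True,
                      scoliosis_magnitude=1.2),
    ]
    X_parts, y_parts = [], []
    for i, ph in enumerate(phenos):
        for wk in ("control", "1", "4"):
            rec = simulate_assay(ph, wk, SimConfig(
                duration_scale=duration_scale, rng_seed=100 + 7 * i + seeds[0]))
            proc = process_assay(rec.poses)
            labels = rec.truth.labels
            wins, centers, y = behavior.build_pose_windows(
                proc["angles"], proc["valid"], labels)
            if len(centers) == 0:
                continue
            span = np.array([len(set(labels[c - 6:c + 7])) == 1
                             for c in centers])
            X_parts.append(wins[span])
            y_parts.append(y[span])
    X = np.vstack(X_parts)
    y = np.concatenate(y_parts)
    rng = np.random.default_rng(seeds[0])
    keep = []
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        if len(idx) > 500:
            idx = rng.choice(idx, 500, replace=False)
        keep.append(idx)
    keep = np.sort(np.concatenate(keep))
    return X[keep], y[keep]


@pytest.fixture(scope="session")
def trained_classifier():
    """Behavior classifier trained once on simulator windows (shared by the
    behavior unit tests and the acceptance suite)."""
    X, y = make_training_windows()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf = behavior.train_behavior_classifier(X, y, rng_seed=1)
    return clf


@pytest.fixture(scope="session")
def noise_free_cruise():
    """Noise-free healthy cruise wave and its ground truth."""
    ph = FishPhenotype("wave0", "male", 0.8)
    cfg = SimConfig(noise_sd=0.0)
    xy, truth = simulate_cruise_wave(ph, "control", 8.0, cfg)
    return xy, truth, cfg
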