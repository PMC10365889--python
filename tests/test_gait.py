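"""Gait metrics: curvature profiles, rostral compensation, frequencies,
Strouhal, scoliosis, posture novelty."""

import numpy as np
import pytest

from swimgait import behavior, gait
from swimgait.core import N_ANGLES
from swimgait.gait import (CruiseCurvatureProfile, PostureNoveltyScorer,
                           cruise_angular_frequency, cruise_curvature_profile,
                           halfcycle_amplitude, rostral_compensation,
                           scoliosis_score, strouhal_number,
                           summed_rostral_amplitude, tail_beat_frequency,
                           tail_lateral_trace)
from swimgait.pose import process_assay
from swimgait.simulate import (FishPhenotype, SimConfig, simulate_assay)


def sinusoid_angles(n=700, f=2.0, fr=70.0, amp=0.1, phases=None):
    t = np.arange(n) / fr
    phases = np.zeros(N_ANGLES) if phases is None else phases
    return amp * np.sin(2 * np.pi * f * t[:, None] - phases[None, :])


class TestCurvatureProfile:
    def test_pure_sinusoid_recovers_amplitude(self):
        prof = cruise_curvature_profile([sinusoid_angles(amp=0.17)])
        assert np.all(np.abs(prof.amplitudes / 0.17 - 1) < 0.02)

    def test_amplitude_doubling_is_local(self):
        ang = sinusoid_angles(amp=0.1)
        ang2 = ang.copy()
        ang2[:, 0] *= 2
        p1 = cruise_curvature_profile([ang]).amplitudes
        p2 = cruise_curvature_profile([ang2]).amplitudes
        assert p2[0] == pytest.approx(2 * p1[0], rel=0.02)
        np.testing.assert_allclose(p2[1:], p1[1:], rtol=1e-9)

    def test_constant_angles_invalid(self):
        assert cruise_curvature_profile([np.full((300, N_ANGLES), 0.3)]) is None

    def test_halves_of_noise_free_assay_agree_within_5pct(self):
        """Estimator stability: profiles from two disjoint halves of one
        long noise-free assay agree within 5%."""
        ph = FishPhenotype("stab0", "male", 0.85)
        rec = simulate_assay(ph, "control", SimConfig(
            duration_scale=0.3, rng_seed=42, dropout_rate=0.0, noise_sd=0.0))
        proc = process_assay(rec.poses)
        eps = behavior.segment_episodes(rec.truth.labels, proc["angles"],
                                        70.0, rec.poses.flow_velocity())
        cruises = gait.episode_angles(proc["angles"], eps, "cruise")
        assert len(cruises) >= 20
        half = len(cruises) // 2
        p1 = cruise_curvature_profile(cruises[:half]).amplitudes
        p2 = cruise_curvature_profile(cruises[half:]).amplitudes
        assert np.all(np.abs(p1 / p2 - 1) < 0.05)

    def test_halves_agree_within_10pct_at_default_noise(self, long_assay):
        """With tracking noise the sub-noise rostral amplitudes fluctuate
        more; halves of a long noisy assay still agree within 10%."""
        rec, proc, eps = long_assay
        cruises = gait.episode_angles(proc["angles"], eps, "cruise")
        half = len(cruises) // 2
        p1 = cruise_curvature_profile(cruises[:half]).amplitudes
        p2 = cruise_curvature_profile(cruises[half:]).amplitudes
        assert np.all(np.abs(p1 / p2 - 1) < 0.10)


class TestRostralCompensation:
    def test_identity_is_zero(self):
        control = np.linspace(0.05, 0.27, N_ANGLES)
        prof = CruiseCurvatureProfile(control.copy(), n_cruises=1)
        assert rostral_compensation(prof, control) == 0.0

    def test_caudal_positions_ignored(self):
        control = np.linspace(0.05, 0.27, N_ANGLES)
        shifted = control + np.array([0.03, 0.01, 0, 0, 0, 0.5, 0.5, 0.5])
        prof = CruiseCurvatureProfile(shifted, n_cruises=1)
        assert rostral_compensation(prof, control) == pytest.approx(0.03)

    def test_undefined_profile_is_nan(self):
        assert np.isnan(rostral_compensation(None, np.zeros(N_ANGLES)))

    def test_summed_rostral_amplitude(self):
        prof = CruiseCurvatureProfile(
            np.array([0.1] * 5 + [0.4, 0.4, 0.4]), n_cruises=1)
        assert summed_rostral_amplitude(prof) == pytest.approx(0.5)
        doubled = CruiseCurvatureProfile(prof.amplitudes * 2, n_cruises=1)
        assert summed_rostral_amplitude(doubled) == pytest.approx(1.0)
        assert summed_rostral_amplitude(None) != summed_rostral_amplitude(prof)


class TestFrequencies:
    def test_two_hz_sinusoid(self):
        f = cruise_angular_frequency([sinusoid_angles(f=2.0)], 70.0)
        assert f == pytest.approx(2.0, abs=0.05)

    def test_frequency_uniform_along_body(self, long_assay):
        """Per-position frequency estimates, aggregated over an assay's
        cruises, agree within 5% along the body."""
        rec, proc, eps = long_assay
        cruises = gait.episode_angles(proc["angles"], eps, "cruise")
        est = np.array([[gait.oscillation_frequency(c[:, i], 70.0)
                         for i in range(N_ANGLES)] for c in cruises])
        per_pos = np.nanmedian(est, axis=0)
        assert np.all(np.abs(per_pos / np.median(per_pos) - 1) < 0.05)

    def test_frame_rate_change_preserves_hz(self):
        a70 = sinusoid_angles(n=700, f=2.0, fr=70.0)
        a140 = sinusoid_angles(n=1400, f=2.0, fr=140.0)
        f70 = cruise_angular_frequency([a70], 70.0)
        f140 = cruise_angular_frequency([a140], 140.0)
        assert f70 == pytest.approx(f140, rel=0.02)

    def test_static_tail_undefined(self):
        assert np.isnan(tail_beat_frequency(np.zeros(200), 70.0))

    def test_simulated_tail_wave_frequency(self, healthy_assay,
                                           healthy_episodes):
        rec, proc = healthy_assay
        f = gait.assay_tail_beat_frequency(proc["centerline"],
                                           proc["tail_tip"],
                                           healthy_episodes, 70.0,
                                           flow_velocities=None)
        assert f == pytest.approx(rec.truth.cruise_frequency, abs=0.1)

    def test_heading_rotation_invariance(self):
        """Lateral trace is heading-relative: rotating the whole scene
        changes nothing."""
        rng = np.random.default_rng(0)
        n = 300
        t = np.arange(n) / 70.0
        centerline = np.zeros((n, 10, 2))
        centerline[:, :, 1] = -np.arange(10)[None, :] * 20.0
        tail = np.column_stack([30 * np.sin(2 * np.pi * 3.0 * t),
                                np.full(n, -206.0)])
        lat1 = tail_lateral_trace(centerline, tail)
        th = np.pi / 2
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        lat2 = tail_lateral_trace(centerline @ R.T, tail @ R.T)
        f1 = tail_beat_frequency(lat1, 70.0)
        f2 = tail_beat_frequency(lat2, 70.0)
        assert f1 == pytest.approx(f2, rel=1e-6)


class TestStrouhal:
    def test_closed_form(self):
        """f = 2 Hz, A = 0.5, U = 2.5 gives St = 0.4 by the definition."""
        assert 2.0 * 0.5 / 2.5 == pytest.approx(0.4)

    def test_weighted_mean_of_cruises(self):
        sts = np.array([0.2, 0.4])
        w = np.array([4, 8])
        assert np.average(sts, weights=w) == pytest.approx(1 / 3, abs=1e-9)

    def test_simulator_strouhal_recovered(self, healthy_assay,
                                          healthy_episodes):
        rec, proc = healthy_assay
        st = strouhal_number(proc["centerline"], proc["tail_tip"],
                             healthy_episodes, 70.0, proc["valid"])
        assert st == pytest.approx(0.3, rel=0.1)

    def test_unit_rescaling_invariance(self, healthy_assay, healthy_episodes):
        rec, proc = healthy_assay
        st1 = strouhal_number(proc["centerline"], proc["tail_tip"],
                              healthy_episodes, 70.0, proc["valid"])
        st2 = strouhal_number(proc["centerline"] * 3.7,
                              proc["tail_tip"] * 3.7,
                              healthy_episodes, 70.0, proc["valid"])
        assert st1 == pytest.approx(st2, rel=1e-6)


class TestScoliosis:
    def test_straight_resting_fish_zero(self):
        assert scoliosis_score([np.zeros((100, N_ANGLES))]) == 0.0

    def test_constant_c_bend(self):
        ang = np.full((100, N_ANGLES), 1.5 / N_ANGLES)
        assert scoliosis_score([ang]) == pytest.approx(1.5)

    def test_flipping_does_not_cancel(self):
        """Two equal bouts at +2 and -2 rad score 2.0, not 0 (per-bout
        magnitudes prevent dorso-ventral flips from canceling)."""
        plus = np.full((80, N_ANGLES), 2.0 / N_ANGLES)
        minus = -plus
        assert scoliosis_score([plus, minus]) == pytest.approx(2.0)

    def test_reflection_invariance(self):
        rng = np.random.default_rng(0)
        bouts = [rng.normal(0.2, 0.05, size=(60, N_ANGLES)) for _ in range(3)]
        flipped = [-b for b in bouts]
        assert scoliosis_score(bouts) == pytest.approx(
            scoliosis_score(flipped))

    def test_no_rest_is_nan(self):
        assert np.isnan(scoliosis_score([]))


class TestPostureNovelty:
    def _control_poses(self, seed=0, n=2000):
        rng = np.random.default_rng(seed)
        return rng.normal(0.0, 0.08, size=(n, N_ANGLES))

    def test_self_scoring_small(self):
        ctrl = self._control_poses()
        scorer = PostureNoveltyScorer(random_state=0).fit([ctrl])
        assert scorer.score_assay(ctrl) <= 0.15

    def test_rigid_motion_irrelevant_in_angle_space(self):
        # angle poses are already rotation/translation invariant; the scorer
        # sees identical inputs and returns identical scores
        ctrl = self._control_poses()
        scorer = PostureNoveltyScorer(random_state=0).fit([ctrl])
        assert scorer.score_assay(ctrl[:500]) == scorer.score_assay(ctrl[:500])

    def test_scoliotic_assay_more_novel(self):
        ctrl = self._control_poses()
        scorer = PostureNoveltyScorer(random_state=0).fit([ctrl])
        rng = np.random.default_rng(5)
        scoliotic = rng.normal(1.8 / N_ANGLES, 0.08, size=(800, N_ANGLES))
        healthy = rng.normal(0.0, 0.08, size=(800, N_ANGLES))
        assert scorer.score_assay(scoliotic) > scorer.score_assay(healthy)

    def test_too_few_distinct_poses_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            PostureNoveltyScorer().fit([np.zeros((50, N_ANGLES))])
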