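"""Synthetic swimmer: wave geometry, schedules, cohorts, determinism."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from swimgait.core import N_ANGLES
from swimgait.pose import compute_angle_pose, process_assay
from swimgait.simulate import (HEALTHY_ENVELOPE, CellularOutcome,
                               FishPhenotype, SimConfig,
                               caudal_damping_schedule, cellular_outcomes,
                               delta_schedule, gait_envelope,
                               planted_violation_fixture, simulate_assay,
                               simulate_cohort, simulate_cohort_metrics,
                               simulate_cruise_wave)
from swimgait import gait


@pytest.fixture(scope="module")
def healthy_pheno():
    return FishPhenotype("sim0", "male", 0.8)


class TestPhenotypeInvariants:
    def test_capacity_bounds_enforced(self):
        with pytest.raises(ValueError):
            FishPhenotype("x", "male", 1.2)

    def test_nonprone_fish_cannot_carry_scoliosis(self):
        with pytest.raises(ValueError):
            FishPhenotype("x", "male", 0.5, scoliosis_prone=False,
                          scoliosis_magnitude=1.0)

    def test_outcomes_bounded(self):
        with pytest.raises(ValueError):
            CellularOutcome(120.0, 50.0, 50.0)


class TestCruiseWave:
    def test_healthy_amplitudes_match_envelope(self, noise_free_cruise):
        """Center-to-peak amplitudes read back by peak detection equal the
        configured envelope within 5%."""
        xy, truth, _ = noise_free_cruise
        ang = compute_angle_pose(xy[:, :10])
        amps = np.array([gait.halfcycle_amplitude(ang[:, i])
                         for i in range(N_ANGLES)])
        assert np.all(np.abs(amps / HEALTHY_ENVELOPE - 1) < 0.05)

    def test_zero_boost_reproduces_control_envelope(self, healthy_pheno):
        env, delta = gait_envelope("1", healthy_pheno.recovery_capacity,
                                   delta_override=0.0)
        assert delta == 0.0
        np.testing.assert_allclose(env[:5], HEALTHY_ENVELOPE[:5])

    def test_boost_larger_for_poor_recoverers(self):
        assert delta_schedule("1", 0.1) > delta_schedule("1", 0.9)

    def test_boost_zero_at_control_and_plateaus_by_3wpi(self):
        assert delta_schedule("control", 0.3) == 0.0
        d3 = delta_schedule("3", 0.3)
        for wk in ("4", "5", "8"):
            assert delta_schedule(wk, 0.3) == pytest.approx(d3)
        assert delta_schedule("1", 0.3) > d3

    def test_too_short_duration_rejected(self, healthy_pheno):
        with pytest.raises(ValueError, match="oscillation"):
            simulate_cruise_wave(healthy_pheno, "control", 0.2,
                                 SimConfig(noise_sd=0.0))

    def test_boost_monotone_on_delta_grid(self, healthy_pheno):
        cfg = SimConfig(noise_sd=0.0)
        scores = []
        ctrl, _ = simulate_cruise_wave(healthy_pheno, "control", 6.0, cfg)
        ctrl_prof = gait.cruise_curvature_profile(
            [compute_angle_pose(ctrl[:, :10])]).amplitudes
        for d in (0.0, 0.05, 0.1, 0.2):
            xy, _ = simulate_cruise_wave(healthy_pheno, "1", 6.0, cfg,
                                         delta_override=d)
            prof = gait.cruise_curvature_profile([compute_angle_pose(xy[:, :10])])
            scores.append(gait.rostral_compensation(prof, ctrl_prof))
        assert all(b > a for a, b in zip(scores, scores[1:]))


class TestAssay:
    def test_no_dropout_all_frames_pass_filters(self):
        ph = FishPhenotype("clean", "male", 0.3)
        rec = simulate_assay(ph, "1", SimConfig(
            dropout_rate=0.0, duration_scale=0.1, rng_seed=5))
        proc = process_assay(rec.poses)
        assert proc["valid"].all()

    def test_rejection_rate_tracks_dropout(self):
        ph = FishPhenotype("drop", "male", 0.7)
        cfg = SimConfig(dropout_rate=0.05, duration_scale=0.25, rng_seed=4)
        rec = simulate_assay(ph, "1", cfg)
        proc = process_assay(rec.poses)
        rate = (~proc["valid"]).mean()
        n = len(proc["valid"])
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(rate - 0.05) < 2 * se

    def test_scoliosis_onset_at_2wpi_then_stable(self):
        ph = FishPhenotype("scol", "female", 0.5, scoliosis_prone=True,
                           scoliosis_magnitude=1.5)
        from swimgait.behavior import segment_episodes
        scores = {}
        for wk in ("1", "2", "8"):
            rec = simulate_assay(ph, wk, SimConfig(duration_scale=0.08,
                                                   rng_seed=8))
            proc = process_assay(rec.poses)
            eps = segment_episodes(rec.truth.labels, proc["angles"],
                                   rec.poses.frame_rate,
                                   rec.poses.flow_velocity())
            rests = gait.episode_angles(proc["angles"], eps, "rest")
            scores[wk] = gait.scoliosis_score(rests)
        assert scores["1"] < 0.1
        assert scores["2"] == pytest.approx(scores["8"], rel=0.05)
        assert scores["2"] == pytest.approx(1.5, rel=0.05)

    def test_cruises_present_at_every_flow_period(self):
        ph = FishPhenotype("flow", "male", 0.9)
        rec = simulate_assay(ph, "control", SimConfig(duration_scale=0.08,
                                                      rng_seed=12))
        flow = rec.poses.flow_velocity()
        for vel in (0.0, 10.0, 20.0):
            sel = np.isclose(flow, vel)
            assert "cruise" in set(rec.truth.labels[sel])

    def test_week_must_be_configured(self):
        ph = FishPhenotype("w", "male", 0.5)
        with pytest.raises(ValueError, match="weeks"):
            simulate_assay(ph, "99", SimConfig())

    def test_same_seed_byte_identical(self):
        ph = FishPhenotype("det", "male", 0.5)
        cfg = SimConfig(duration_scale=0.04, rng_seed=9)
        a = simulate_assay(ph, "2", cfg)
        b = simulate_assay(ph, "2", cfg)
        assert np.array_equal(a.poses.xy, b.poses.xy)
        assert np.array_equal(a.poses.likelihood, b.poses.likelihood)
        assert np.array_equal(a.truth.labels, b.truth.labels)


class TestCohort:
    def test_outcome_coupling_and_monotonicity(self):
        rng = np.random.default_rng(0)
        rhos = rng.uniform(0, 1, size=40)
        outs = [cellular_outcomes(r, rng) for r in rhos]
        bridging = np.array([o.glial_bridging for o in outs])
        prox = np.array([o.axon_proximal for o in outs])
        dist = np.array([o.axon_distal for o in outs])
        assert spearmanr(bridging, prox).statistic > 0.6
        assert spearmanr(bridging, dist).statistic > 0.6
        # noiseless: bridging strictly monotone in rho
        noiseless = [cellular_outcomes(r, rng, noise=0.0).glial_bridging
                     for r in np.linspace(0.02, 0.95, 15)]
        assert all(b > a for a, b in zip(noiseless, noiseless[1:]))

    def test_metrics_cohort_reproducible_and_coupled(self):
        m1, o1 = simulate_cohort_metrics(40, seed=3)
        m2, o2 = simulate_cohort_metrics(40, seed=3)
        assert m1.equals(m2) and o1.equals(o2)
        d8 = m1[m1.week == "8"].set_index("fish_id")["distance"]
        rho = o1.set_index("fish_id")["rho_true"]
        rs, p = spearmanr(rho[d8.index], d8)
        assert rs > 0 and p < 0.01

    def test_cohort_requires_two_fish(self):
        with pytest.raises(ValueError):
            simulate_cohort(1, SimConfig())

    def test_frame_level_cohort_deterministic(self):
        cfg = SimConfig(duration_scale=0.02, rng_seed=11,
                        weeks=("control", "1"))
        a = simulate_cohort(3, cfg)
        b = simulate_cohort(3, cfg)
        for ra, rb in zip(a, b):
            assert ra.outcome == rb.outcome
            for wk in ra.assays:
                assert np.array_equal(ra.assays[wk].poses.xy,
                                      rb.assays[wk].poses.xy)


def test_fixture_has_ten_planted_violations():
    seq, planted = planted_violation_fixture(0)
    assert len(planted) == 10
    assert sorted(np.unique(list(planted.values()))) == [
        "curvature", "jump", "length", "likelihood"]
    assert seq.n_frames == 200
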