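"""Synthetic-cohort generator: schedule arithmetic, latents, noise,
missingness, transfer linkage and trajectory fixtures."""

import numpy as np
import pytest

import climblearn as cl
from climblearn.constants import ROUTE_CONTROL, ROUTE_TRANSFER, ROUTE_VARIANT
from climblearn.synth import training_slots


class TestSchedule:
    def test_default_protocol_counts(self, default_config):
        for group in cl.GROUPS:
            sched = cl.build_schedule(default_config, group)
            train = training_slots(sched)
            assert len(train) == 84
            assert len(sched) == 85
            per_session = {}
            for s in train:
                per_session[s.session] = per_session.get(s.session, 0) + 1
            assert [per_session[s] for s in range(1, 11)] == [6, 9, 9, 9, 9, 9, 9, 9, 9, 6]
            # global index is a chronological bijection onto 0..T-1
            assert [s.global_index for s in train] == list(range(84))
            assert sched[-1].route_label == ROUTE_TRANSFER

    def test_route_labels_by_group(self, default_config):
        cp = training_slots(cl.build_schedule(default_config, "CP"))
        assert all(s.route_label == ROUTE_CONTROL for s in cp)
        for group in ("VP1", "VP2"):
            train = training_slots(cl.build_schedule(default_config, group))
            for s in train:
                expected = ROUTE_CONTROL if s.within_session_index <= 3 else ROUTE_VARIANT
                assert s.route_label == expected
        # sessions 2-9 split 3 control + 6 variant
        mid = [s for s in training_slots(cl.build_schedule(default_config, "VP1"))
               if 2 <= s.session <= 9]
        assert len(mid) == 72
        assert sum(s.route_label == ROUTE_VARIANT for s in mid) == 48

    def test_single_session_degenerate(self):
        config = cl.ProtocolConfig(
            n_sessions=1, control_trials_per_session=3,
            variant_trials_per_session=(0,),
        )
        train = training_slots(cl.build_schedule(config, "VP1"))
        assert [s.global_index for s in train] == [0, 1, 2]
        assert all(s.route_label == ROUTE_CONTROL for s in train)

    def test_config_validation(self):
        with pytest.raises(cl.ConfigurationError):
            cl.ProtocolConfig(n_sessions=3, variant_trials_per_session=(6, 6))
        with pytest.raises(cl.ConfigurationError):
            cl.ProtocolConfig(group_sizes={"XX": 5})
        with pytest.raises(cl.ConfigurationError):
            cl.build_schedule(cl.ProtocolConfig(), "nope")


class TestLearners:
    def test_group_sizes(self, default_config, rng):
        learners = cl.sample_learners(default_config, cl.LatentPrior(), rng)
        assert len(learners) == 30
        assert sum(l.group == "VP2" for l in learners) == 12

    def test_degenerate_prior_gives_identical_latents(self, default_config, rng):
        prior = cl.LatentPrior(a_sd=0, b_sd=0, c_sd=0)
        learners = cl.sample_learners(default_config, prior, rng)
        first = learners[0]
        for l in learners[1:]:
            assert l.a == first.a and l.b == first.b and l.c == first.c

    def test_seed_determinism(self, default_config):
        draws = [
            cl.sample_learners(default_config, cl.LatentPrior(), np.random.default_rng(5))
            for _ in range(2)
        ]
        for l1, l2 in zip(*draws):
            assert l1 == l2

    def test_latents_respect_truncation(self, default_config):
        prior = cl.LatentPrior(b_mean=0.0, b_sd=0.5, c_mean=0.0, c_sd=0.5)
        learners = cl.sample_learners(default_config, prior, np.random.default_rng(0))
        for l in learners:
            assert all(v >= 0 for v in l.b.values())
            assert all(v >= 0 for v in l.c.values())


def _latent(a, b, c, noise):
    return cl.LearnerLatent(
        group="CP",
        a={m: a for m in cl.METRICS},
        b={m: b for m in cl.METRICS},
        c={m: c for m in cl.METRICS},
        noise_sd={m: noise for m in cl.METRICS},
    )


class TestMetricSeries:
    def test_noiseless_formula(self, default_config, rng):
        sched = cl.build_schedule(default_config, "CP")
        series = cl.generate_metric_series(_latent(1.0, 0.1, 2.0, 0.0), sched, rng)
        assert series["GE"][0] == pytest.approx(3.0)
        t = np.arange(84)
        np.testing.assert_allclose(series["JE"], 1.0 + 2.0 * np.exp(-0.1 * t))

    def test_zero_rate_is_constant(self, default_config, rng):
        sched = cl.build_schedule(default_config, "CP")
        series = cl.generate_metric_series(_latent(1.0, 0.0, 2.0, 0.0), sched, rng)
        np.testing.assert_allclose(series["IM"], 3.0)

    def test_noise_mean_within_clt_bound(self, default_config):
        sched = cl.build_schedule(default_config, "CP")
        rng = np.random.default_rng(99)
        series = cl.generate_metric_series(_latent(1.0, 0.1, 2.0, 0.1), sched, rng)
        t = np.arange(84)
        resid = series["GE"] - (1.0 + 2.0 * np.exp(-0.1 * t))
        assert abs(resid.mean()) < 3 * 0.1 / np.sqrt(84)


class TestMissingness:
    def test_zero_rates_identity(self, default_config, rng):
        sched = cl.build_schedule(default_config, "CP")
        series = cl.generate_metric_series(_latent(1, 0.1, 2, 0.1), sched, rng)
        out = cl.inject_missingness(series, sched, rng, point_rate=0, block_rate=0)
        for m in cl.METRICS:
            np.testing.assert_array_equal(out[m], series[m])

    def test_survival_floor(self, default_config, rng):
        sched = cl.build_schedule(default_config, "CP")
        series = cl.generate_metric_series(_latent(1, 0.1, 2, 0.1), sched, rng)
        out = cl.inject_missingness(series, sched, rng, point_rate=1.0, block_rate=0)
        for m in cl.METRICS:
            assert np.isfinite(out[m]).sum() == 4

    def test_point_missingness_rate(self, default_config):
        sched = cl.build_schedule(default_config, "CP")
        rng = np.random.default_rng(3)
        series = cl.generate_metric_series(_latent(1, 0.1, 2, 0.0), sched, rng)
        count = 0
        reps = 1000
        for _ in range(reps):
            out = cl.inject_missingness(series, sched, rng, point_rate=0.1, block_rate=0)
            count += np.isnan(out["GE"]).sum()
        mean = count / reps
        se = np.sqrt(84 * 0.1 * 0.9 / reps)
        assert abs(mean - 8.4) < 3 * se

    def test_session_block_hits_only_jerk(self, default_config, rng):
        sched = cl.build_schedule(default_config, "CP")
        series = cl.generate_metric_series(_latent(1, 0.1, 2, 0.1), sched, rng)
        out = cl.inject_missingness(series, sched, rng, point_rate=0, block_rate=1.0)
        assert np.isfinite(out["GE"]).all()
        sessions = np.array([s.session for s in training_slots(sched)])
        missing_sessions = np.unique(sessions[np.isnan(out["JE"])])
        assert len(missing_sessions) == 1
        gone = sessions == missing_sessions[0]
        assert np.isnan(out["JE"][gone]).all()


class TestTransfer:
    def test_single_feature_linkage(self, rng):
        w = np.zeros(8)
        w[0] = 1.0
        linkage = cl.TransferLinkage(
            weights={m: w for m in cl.TARGET_METRICS},
            intercepts={m: 0.0 for m in cl.TARGET_METRICS},
            residual_sd={g: 0.0 for g in cl.GROUPS},
        )
        feats = np.zeros(8)
        feats[0] = 1.5
        out = cl.generate_transfer(feats, linkage, "CP", rng)
        assert out["GE"] == pytest.approx(1.5)

    def test_constant_target(self, rng):
        linkage = cl.TransferLinkage(
            weights={m: np.zeros(8) for m in cl.TARGET_METRICS},
            intercepts={m: 7.0 for m in cl.TARGET_METRICS},
            residual_sd={g: 0.0 for g in cl.GROUPS},
        )
        out = cl.generate_transfer(rng.normal(size=8), linkage, "VP2", rng)
        assert all(v == pytest.approx(7.0) for v in out.values())

    def test_vp2_advantage_preset_ordering(self):
        sd = cl.TransferLinkage.vp2_advantage().residual_sd
        assert sd["VP2"] < sd["VP1"] and sd["VP2"] < sd["CP"]


class TestTrajectoryGenerator:
    def test_straight_line(self):
        traj = cl.generate_trajectory(duration=30, wobble_amplitude=0, pause_fraction=0)
        assert len(traj) == 750
        assert cl.climb_duration(traj) == pytest.approx(29.96)
        np.testing.assert_allclose(traj.xy[:, 0], 0.0)
        steps = np.diff(traj.xy[:, 1])
        np.testing.assert_allclose(steps, steps[0])

    def test_pause_fraction_reaches_immobility(self, rng):
        traj = cl.generate_trajectory(duration=30, pause_fraction=0.5, rng=rng)
        assert abs(cl.immobility_ratio(traj) - 0.5) <= 1.0 / len(traj)

    def test_wobble_increases_path_length(self, rng):
        lengths = [
            cl.path_length(
                cl.generate_trajectory(duration=30, wobble_amplitude=w,
                                       rng=np.random.default_rng(0))
            )
            for w in (0.0, 0.1, 0.3)
        ]
        assert lengths[0] < lengths[1] < lengths[2]


class TestDataset:
    def test_determinism_and_truth_consistency(self):
        d1 = cl.generate_dataset(seed=11)
        d2 = cl.generate_dataset(seed=11)
        assert d1.scores_frame().equals(d2.scores_frame())
        assert d1.transfer_frame().equals(d2.transfer_frame())
        for p in d1.participants:
            a_e = []
            for m in cl.METRICS:
                a_e += [p.latent.a[m], p.latent.c[m] * np.exp(-p.latent.b[m])]
            np.testing.assert_allclose(p.true_features, a_e)

    def test_extending_cohort_keeps_existing_participants(self):
        small = cl.generate_dataset(cl.ProtocolConfig(group_sizes={"CP": 2}), seed=4)
        big = cl.generate_dataset(cl.ProtocolConfig(group_sizes={"CP": 3}), seed=4)
        for p_small, p_big in zip(small.participants, big.participants):
            np.testing.assert_array_equal(p_small.series["GE"], p_big.series["GE"])
            assert p_small.transfer == p_big.transfer

    def test_transfer_targets_never_missing(self, small_cohort):
        for p in small_cohort.participants:
            assert all(np.isfinite(v) for v in p.transfer.values())
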