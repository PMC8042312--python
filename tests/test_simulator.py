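import numpy as np
import pytest

from gazeforage import (
    PatchClass,
    SceneSpec,
    SimConfig,
    SpatialConfig,
    Trajectory,
    generate_scene,
    oracle_events,
    random_baseline,
    run_cohort,
    simulate,
)

from conftest import make_patch, static_landscape


class TestSimulate:
    def test_same_seed_identical_streams(self, default_scene, sim_config):
        a = simulate(default_scene, sim_config, seed=5)
        b = simulate(default_scene, sim_config, seed=5)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)
        assert np.array_equal(a.regime, b.regime)
        assert np.array_equal(a.attractor, b.attractor)

    def test_different_seeds_differ(self, default_scene, sim_config):
        a = simulate(default_scene, sim_config, seed=5)
        b = simulate(default_scene, sim_config, seed=6)
        assert not np.array_equal(a.x, b.x)

    def test_sampling_grid(self, default_scene, sim_config):
        traj = simulate(default_scene, sim_config, seed=1)
        assert traj.n_samples == round(default_scene.duration / sim_config.decision.dt)
        assert traj.dt == pytest.approx(sim_config.decision.dt)
        assert np.all((traj.x >= 0) & (traj.x <= default_scene.frame_w))
        assert np.all((traj.y >= 0) & (traj.y <= default_scene.frame_h))

    def test_single_patch_landscape_mostly_exploiting(self):
        patch = make_patch(1, 700, 400, sd=40, value=0.5, klass=PatchClass.SPEAKER)
        scene = static_landscape([patch])
        frac_exploit, frac_inside = [], []
        for seed in range(20):
            traj = simulate(scene, SimConfig(duration_s=1 / 30.0 * 600), seed=seed)
            # ignore the initial relocation from the frame center
            arrived = np.flatnonzero(traj.regime == 0)
            assert len(arrived) > 0
            after = slice(arrived[0], None)
            frac_exploit.append(np.mean(traj.regime[after] == 0))
            d = np.hypot(traj.x[after] - 700, traj.y[after] - 400)
            frac_inside.append(np.mean(d <= 3 * 40))
        assert np.mean(frac_exploit) >= 0.99
        assert np.mean(frac_inside) >= 0.99

    def test_regime_transitions_legal(self, default_scene, sim_config):
        """Regimes only move 0->1 (give-up) and 1->0 (arrival); the attractor
        label changes only when a relocation starts or while in flight."""
        traj = simulate(default_scene, sim_config, seed=9)
        for i in range(1, traj.n_samples):
            if traj.attractor[i] != traj.attractor[i - 1]:
                assert traj.regime[i] == 1
        # after the initial approach, every relocation episode terminates
        assert traj.regime[-1] in (0, 1)
        assert (traj.regime == 0).sum() > 0

    def test_high_value_patch_attracts_more_time(self):
        # close enough that the visibility term exp(-kappa d/diag) lets the
        # race interact; the 10x value gap then dominates patch choice
        lo = make_patch(1, 565, 360, sd=35, value=0.05)
        hi = make_patch(2, 715, 360, sd=35, value=0.5, klass=PatchClass.SPEAKER)
        scene = static_landscape([lo, hi])
        frac_hi = []
        for seed in range(30):
            traj = simulate(scene, SimConfig(duration_s=10.0), seed=seed)
            exploit = traj.regime == 0
            if exploit.sum():
                frac_hi.append(np.mean(traj.attractor[exploit] == 2))
        assert np.mean(frac_hi) > 0.5

    def test_duration_longer_than_landscape_rejected(self, default_scene, sim_config):
        cfg = SimConfig(duration_s=default_scene.duration + 5)
        with pytest.raises(ValueError, match="duration"):
            simulate(default_scene, cfg, seed=0)

    def test_unvalued_landscape_rejected(self):
        scene = static_landscape([make_patch(1, 100, 100, value=0.0)])
        with pytest.raises(ValueError, match="valued"):
            simulate(scene, SimConfig(duration_s=0.03), seed=0)

    def test_relocations_terminate_across_random_configs(self):
        """No relocation episode stalls for a broad sample of spatial constants."""
        rng = np.random.default_rng(0)
        scene = generate_scene(SceneSpec(duration_s=4.0), seed=2)
        for _ in range(15):
            cfg = SimConfig(
                duration_s=4.0,
                spatial=SpatialConfig(
                    k_b_local=float(rng.uniform(10, 100)),
                    k_b_global=float(rng.uniform(5, 100)),
                    k_sigma_global=float(rng.uniform(0.05, 0.5)),
                    b_min=float(rng.uniform(0.1, 1.0)),
                    b_max=float(rng.uniform(20, 100)),
                ),
            )
            traj = simulate(scene, cfg, seed=int(rng.integers(2**16)))
            # longest uninterrupted relocation stays below two seconds
            from gazeforage.scanpath import _runs

            flight_runs = [b - a for a, b, v in _runs(traj.regime == 1) if v]
            if flight_runs:
                assert max(flight_runs) * traj.dt < 2.0

    def test_exploitation_episode_durations_right_skewed(self):
        from scipy.stats import skew

        durations = []
        for seed in range(25):
            scene = generate_scene(SceneSpec(), seed=500 + seed)
            traj = simulate(scene, SimConfig(), seed=seed)
            durations.extend(oracle_events(traj).duration)
        assert skew(np.array(durations)) > 0


class TestHotLoopConsistency:
    def test_inline_drifts_match_decision_module(self, params):
        """The simulator's array-form drift computation agrees with
        decision.drift_rates on the same frame."""
        from gazeforage import RaceState, drift_rates
        from gazeforage.simulator import _drifts

        rng = np.random.default_rng(17)
        frame = [
            make_patch(i, float(rng.uniform(100, 1100)), float(rng.uniform(100, 600)),
                       value=float(rng.uniform(0.1, 0.6)))
            for i in range(1, 6)
        ]
        ids = [p.id for p in frame]
        mus = np.array([p.mu for p in frame])
        vals = np.array([p.value for p in frame])
        diag = float(np.hypot(1280, 720))
        for p_star in ids:
            for t_on in (0.0, 2.5):
                state = RaceState.fresh(ids, p_star, t_on)
                expected = drift_rates(state, frame, params, diag)
                got = _drifts(ids, mus, vals, p_star, t_on, params, diag)
                assert np.allclose(got, expected)

    def test_spatial_stream_replays_through_ou_step(self, two_patch_scene):
        """The full coordinate stream of a simulation is reproduced by
        replaying ou_params_for + ou_step against the recorded regime and
        attractor labels with the same spatial noise stream."""
        from gazeforage import GazeState, ou_params_for, ou_step

        cfg = SimConfig(duration_s=2.0)
        traj = simulate(two_patch_scene, cfg, seed=3)
        _, spa_seed = np.random.SeedSequence(3).spawn(2)
        rng = np.random.default_rng(spa_seed)
        r = two_patch_scene.center.copy()
        for i in range(traj.n_samples):
            frame = two_patch_scene.frame_at(traj.t[i])
            patch = {p.id: p for p in frame}[traj.attractor[i]]
            assert min(max(r[0], 0.0), 1280.0) == pytest.approx(traj.x[i])
            assert min(max(r[1], 0.0), 720.0) == pytest.approx(traj.y[i])
            gstate = GazeState(
                r=r, regime=int(traj.regime[i]), attractor=int(traj.attractor[i]),
                t=float(traj.t[i]),
            )
            ou = ou_params_for(gstate, patch, frame, cfg.spatial,
                               diag=two_patch_scene.diag)
            r = ou_step(r, patch.mu, ou, traj.dt, rng)


class TestTrajectoryIO:
    def test_csv_round_trip(self, default_scene, sim_config, tmp_path):
        traj = simulate(default_scene, sim_config, seed=2)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = Trajectory.from_csv(path)
        assert np.allclose(back.x, traj.x)
        assert np.array_equal(back.attractor, traj.attractor)
        assert back.meta["seed"] == 2

    def test_nonuniform_time_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            Trajectory(
                t=np.array([0.0, 0.1, 0.3]), x=np.zeros(3), y=np.zeros(3),
                regime=np.zeros(3, int), attractor=np.zeros(3, int),
            )


class TestRandomBaseline:
    def test_durations_within_human_quantile_bounds(self):
        sp = random_baseline(1280, 720, 60.0, seed=3)
        assert np.all(sp.duration >= 0.067) and np.all(sp.duration <= 1.699)

    def test_mean_position_is_frame_center(self):
        rng = np.random.default_rng(11)
        sp = random_baseline(1280, 720, 10000.0, seed=rng)
        n = sp.n_fixations
        sd = 720 / 6.0
        assert abs(sp.x.mean() - 640) < 4 * sd / np.sqrt(n)
        assert abs(sp.y.mean() - 360) < 4 * sd / np.sqrt(n)

    def test_mean_duration_matches_uniform_law(self):
        sp = random_baseline(1280, 720, 10000.0, seed=5)
        n = sp.n_fixations
        sd = (1.699 - 0.067) / np.sqrt(12)
        assert abs(sp.duration.mean() - (0.067 + 1.699) / 2) < 4 * sd / np.sqrt(n)

    def test_covers_requested_duration(self):
        sp = random_baseline(1280, 720, 20.0, seed=0)
        assert sp.onset[-1] + sp.duration[-1] >= 20.0

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            random_baseline(1280, 720, 0.0, seed=0)


class TestRunCohort:
    def test_cohort_size(self, default_scene, sim_config):
        trajs = run_cohort(default_scene, SimConfig(duration_s=2.0), 4, base_seed=10)
        assert len(trajs) == 4

    def test_single_member_equals_simulate(self, default_scene):
        cfg = SimConfig(duration_s=2.0)
        cohort = run_cohort(default_scene, cfg, 1, base_seed=20)
        solo = simulate(default_scene, cfg, seed=20)
        assert np.array_equal(cohort[0].x, solo.x)

    def test_members_differ(self, default_scene):
        cfg = SimConfig(duration_s=2.0)
        a, b = run_cohort(default_scene, cfg, 2, base_seed=30)
        assert not np.array_equal(a.x, b.x)

    def test_zero_observers_rejected(self, default_scene, sim_config):
        with pytest.raises(ValueError):
            run_cohort(default_scene, sim_config, 0, base_seed=0)
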