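"""Tracking, displacement statistics, action spectra, balance point, group tests."""

import numpy as np
import pytest
from scipy import stats as sstats

from depthgauge import behavior as bhv
from depthgauge import synthetic as syn


def _linear_trajectory(lid="l0", v=1.0 / 30.0, duration=240.0, z0=20.0, height=160.0):
    t = np.arange(0.0, duration + 0.5, 1.0)
    return bhv.Trajectory(lid, t, np.zeros_like(t), z0 + v * t, height)


# ---------------------------------------------------------------------------
# tracking


def _lane_trajectories(n=20, v=0.15, duration=90.0, arena_h=70.0, seed=42):
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + 0.5, 1.0)
    trajs = []
    for i in range(n):
        x = np.full_like(t, 2.0 + i * 3.9)
        z = np.clip(5.0 + (i % 4) * 2.0 + v * t + np.cumsum(rng.normal(0, 0.05, t.size)), 0, arena_h)
        trajs.append(bhv.Trajectory(f"l{i}", t, x, z, arena_h))
    return trajs


def test_track_single_stationary_particle():
    arena_h, ppm = 30.0, 2.0
    t = np.arange(0.0, 20.5, 1.0)
    traj = bhv.Trajectory("l0", t, np.full_like(t, 10.0), np.full_like(t, 15.0), arena_h)
    stack, _ = syn.render_video([traj], (61, 48), ppm, particle_radius_px=1.5, seed=0)
    tracks = bhv.track_particles(stack, 60.0, 5.0, 5, px_per_mm=ppm, arena_height_mm=arena_h)
    assert len(tracks) == 1
    assert np.all(np.abs(tracks[0].z_mm - 15.0) < 1.0 / ppm)
    assert np.all(np.abs(tracks[0].x_mm - 10.0) < 1.0 / ppm)


def test_track_empty_frames_no_tracks():
    stack = np.zeros((10, 32, 32))
    assert bhv.track_particles(stack, 10.0, 5.0, 3, px_per_mm=1.0) == []


def test_track_twenty_noncrossing_larvae_against_truth():
    """Rendered non-crossing larvae: positions within 2 px, one track each."""
    arena_h, ppm, H, W = 70.0, 2.0, 141, 164
    trajs = _lane_trajectories(arena_h=arena_h)
    stack, truth = syn.render_video(trajs, (H, W), ppm, particle_radius_px=1.5, seed=1)
    tracks = bhv.track_particles(stack, 60.0, 5.0, 5, px_per_mm=ppm, arena_height_mm=arena_h)
    assert len(tracks) == len(trajs)
    ok = total = 0
    for tr in tracks:
        for t, x, z in zip(tr.t_s, tr.x_mm, tr.z_mm):
            fi = int(round(t))
            row, col = H - 1 - z * ppm, x * ppm
            d = np.min(np.hypot(truth[fi, :, 0] - row, truth[fi, :, 1] - col))
            total += 1
            ok += d <= 2.0
    assert ok / total >= 0.95


def test_track_requires_calibration():
    with pytest.raises(ValueError, match="px_per_mm"):
        bhv.track_particles(np.zeros((3, 8, 8)), 1.0, 5.0, px_per_mm=0.0)


# ---------------------------------------------------------------------------
# displacement


def test_bin_displacement_constant_velocity():
    series = bhv.bin_displacement([_linear_trajectory(v=1.0 / 30.0)], 30.0)
    assert np.allclose(series.mean_mm, 1.0)
    assert np.all(series.n == 1)


def test_bin_displacement_symmetric_pair_cancels():
    up = _linear_trajectory("a", v=2.0 / 30.0, z0=20.0)
    down = _linear_trajectory("b", v=-2.0 / 30.0, z0=120.0)
    series = bhv.bin_displacement([up, down], 30.0)
    assert np.allclose(series.mean_mm, 0.0, atol=1e-9)


def test_bin_displacement_excludes_partial_presence():
    full = _linear_trajectory("a", duration=120.0)
    t_late = np.arange(45.0, 121.0, 1.0)
    late = bhv.Trajectory("b", t_late, np.zeros_like(t_late), np.full_like(t_late, 10.0))
    series = bhv.bin_displacement([full, late], 30.0, t_end_s=120.0)
    assert list(series.n) == [1, 1, 2, 2]


def test_bin_displacement_telescopes_to_net(rng):
    t = np.arange(0.0, 121.0, 1.0)
    z = np.clip(60 + np.cumsum(rng.normal(0, 0.5, t.size)), 0, 160)
    traj = bhv.Trajectory("a", t, np.zeros_like(t), z)
    series = bhv.bin_displacement([traj], 30.0, t_end_s=120.0)
    net = bhv.net_displacement([traj], (0.0, 120.0))
    assert np.nansum(series.mean_mm) == pytest.approx(net.mean_mm)


def test_net_displacement_closed_forms():
    stationary = _linear_trajectory(v=0.0)
    assert bhv.net_displacement([stationary], (0.0, 120.0)).mean_mm == 0.0
    descent = _linear_trajectory(v=-0.5, z0=150.0, duration=240.0)
    stat = bhv.net_displacement([descent], (30.0, 150.0))
    assert stat.mean_mm == pytest.approx(-60.0)


def test_net_displacement_matches_per_larva_subtraction(rng):
    trajs = syn.simulate_trajectories(syn.BehaviorModelParams(), 480.0, 20, 120.0, seed=4)
    stat = bhv.net_displacement(trajs, (30.0, 90.0))
    direct = np.array([tr.z_at(90.0) - tr.z_at(30.0) for tr in trajs])
    assert np.allclose(stat.per_larva_mm, direct)
    assert stat.mean_mm == pytest.approx(direct.mean())


def test_net_displacement_window_validation():
    with pytest.raises(ValueError):
        bhv.net_displacement([_linear_trajectory()], (100.0, 50.0))
    with pytest.raises(ValueError, match="covers"):
        bhv.net_displacement([_linear_trajectory(duration=60.0)], (0.0, 120.0))


# ---------------------------------------------------------------------------
# action spectrum


def test_action_spectrum_sign_pattern_wild_type():
    """UV-violet wavelengths drive downward, blue-green upward swimming."""
    params = syn.BehaviorModelParams()
    trials = {
        float(wl): syn.simulate_trajectories(params, float(wl), 40, 240.0, seed=10 + wl)
        for wl in (340, 360, 380, 400, 440, 480, 520, 560, 600)
    }
    spec = bhv.action_spectrum(trials, bhv.ANALYSIS_WINDOWS["column"])
    by_wl = dict(zip(spec.wavelengths_nm, spec.displacement_mm))
    for wl in (340, 360, 380, 400):
        assert by_wl[wl] < 0, f"{wl} nm should drive downward swimming"
    for wl in (440, 480, 520, 560, 600):
        assert by_wl[wl] > 0, f"{wl} nm should drive upward swimming"


def test_action_spectrum_knockout_upward_at_uv():
    params = syn.BehaviorModelParams(knockout=True)
    trials = {395.0: syn.simulate_trajectories(params, 395.0, 40, 240.0, seed=5)}
    spec = bhv.action_spectrum(trials)
    assert spec.displacement_mm[0] > 0


def test_action_spectrum_zero_drive_near_zero():
    params = syn.BehaviorModelParams(phototaxis_speed_mm_s=0.0, avoidance_speed_mm_s=0.0)
    trials = {
        wl: syn.simulate_trajectories(params, wl, 60, 240.0, seed=int(wl))
        for wl in (380.0, 480.0)
    }
    spec = bhv.action_spectrum(trials)
    assert np.all(np.abs(spec.displacement_mm) < 3 * spec.sem_mm + 1e-9)


def test_action_spectrum_empty_trials():
    with pytest.raises(ValueError, match="empty"):
        bhv.action_spectrum({})


# ---------------------------------------------------------------------------
# balance point


def test_balance_point_linear_interpolation_midpoint():
    r = bhv.RatioResponse(np.array([0.2, 0.6]), np.array([10.0, -10.0]))
    assert bhv.balance_point(r) == pytest.approx(0.4)


def test_balance_point_no_sign_change_raises():
    """A UV/red mixture never drives upward swimming: no balance point."""
    r = bhv.RatioResponse(np.linspace(0, 1, 11), -np.linspace(1, 21, 11))
    with pytest.raises(bhv.NoSignChangeError):
        bhv.balance_point(r)


def test_balance_point_picks_crossing_from_largest_positive():
    f = np.array([0.0, 0.2, 0.4, 0.6, 0.8])
    d = np.array([1.0, -0.5, 5.0, -5.0, -8.0])
    assert bhv.balance_point(bhv.RatioResponse(f, d)) == pytest.approx(0.5)


def test_balance_point_generator_recovery_multi_seed():
    """Over generator seeds at true balance 0.4, recovery within 0.05."""
    params = syn.BehaviorModelParams()
    fractions = np.arange(0.0, 1.0001, 0.1)
    estimates = []
    for seed in range(20):
        disp = []
        for i, f in enumerate(fractions):
            from depthgauge import stimulus as st

            sched = st.duty_cycle_schedule(float(f))
            trajs = syn.simulate_trajectories(
                params, sched, 50, 240.0, seed=1000 * seed + i
            )
            disp.append(bhv.net_displacement(trajs, (90.0, 210.0)).mean_mm)
        estimates.append(
            bhv.balance_point(bhv.RatioResponse(fractions, np.array(disp)))
        )
    assert abs(np.mean(estimates) - 0.40) <= 0.05


# ---------------------------------------------------------------------------
# group comparisons


def test_compare_groups_identical_no_rejection(rng):
    a = rng.normal(size=20)
    table = bhv.compare_groups([a], [a.copy()], "holm_sidak")
    assert not table["reject"].any()
    assert table["p"].iloc[0] == pytest.approx(1.0)


def test_compare_groups_single_comparison_reduces_to_plain_t_test(rng):
    a, b = rng.normal(0, 1, 15), rng.normal(1.5, 1, 15)
    table = bhv.compare_groups([a], [b], "holm_sidak", alpha=0.05)
    t_ref, p_ref = sstats.ttest_ind(a, b, equal_var=False)
    assert table["t"].iloc[0] == pytest.approx(float(t_ref))
    assert table["p"].iloc[0] == pytest.approx(float(p_ref))
    assert bool(table["reject"].iloc[0]) == (p_ref <= 0.05)


def test_compare_groups_degenerate_flagged():
    a = np.full(5, 2.0)
    table = bhv.compare_groups([a], [a.copy()], "sidak_bonferroni")
    assert table["degenerate"].iloc[0]
    assert not table["reject"].iloc[0]


def test_compare_groups_validation(rng):
    with pytest.raises(ValueError, match="at least 2"):
        bhv.compare_groups([np.array([1.0])], [rng.normal(size=5)])
    with pytest.raises(ValueError, match="correction"):
        bhv.compare_groups([rng.normal(size=5)], [rng.normal(size=5)], "bonferroni")


def test_holm_sidak_rejections_superset_of_sidak(rng):
    """Step-down Holm-Sidak dominates the single-step Sidak correction."""
    for _ in range(200):
        p = rng.uniform(0, 0.2, size=int(rng.integers(2, 12)))
        holm = bhv.holm_sidak_reject(p, 0.05)
        sidak = bhv.sidak_bonferroni_reject(p, 0.05)
        assert np.all(holm | ~sidak), (p, holm, sidak)


def test_holm_sidak_fwer_controlled_under_null(rng):
    """Family-wise error rate stays at or below alpha for m=10 null tests."""
    reps, m, n = 10_000, 10, 10
    a = rng.normal(size=(reps, m, n))
    b = rng.normal(size=(reps, m, n))
    _, p = sstats.ttest_ind(a, b, axis=-1, equal_var=False)
    fwer = np.mean([bhv.holm_sidak_reject(pv, 0.05).any() for pv in p])
    # 0.05 plus three binomial standard errors of Monte-Carlo slack
    assert fwer <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)
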