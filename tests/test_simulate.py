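"""Synthetic-data generators: determinism, constraints, parameter recovery."""

import math

import numpy as np
import pytest
from scipy import stats

from flagrelics.simulate import (
    DetachedFlagellum,
    PatternModel,
    PhantomSpec,
    PopulationModel,
    build_phantom,
    simulate_detached_flagella,
    simulate_periplasm_measurements,
    simulate_pole,
    simulate_population,
    simulate_tracks,
)
from flagrelics.spatial import (
    SaturationError,
    nearest_neighbor_distances_bruteforce,
)


def in_ellipse(xy, a, b):
    return np.all((xy[:, 0] / a) ** 2 + (xy[:, 1] / b) ** 2 <= 1.0 + 1e-12)


class TestSimulatePole:
    @pytest.mark.parametrize("kind", ["uniform", "hardcore", "grid", "cluster"])
    def test_point_count_and_containment(self, kind):
        m = PatternModel(kind=kind, n_points=6, semi_axis_x_nm=200, semi_axis_y_nm=150)
        p = simulate_pole(m, seed=0)
        assert p.n_points == 6
        assert in_ellipse(p.xy, 200, 150)

    def test_deterministic_given_seed(self):
        m = PatternModel(kind="uniform", n_points=9)
        np.testing.assert_array_equal(
            simulate_pole(m, seed=7).xy, simulate_pole(m, seed=7).xy
        )

    def test_hardcore_respects_exclusion(self):
        m = PatternModel(kind="hardcore", n_points=8, semi_axis_x_nm=150,
                         semi_axis_y_nm=150, exclusion_diameter_nm=45.0)
        for seed in range(20):
            p = simulate_pole(m, seed=seed)
            assert nearest_neighbor_distances_bruteforce(p.xy).min() >= 45.0

    def test_infeasible_hardcore_raises_saturation(self):
        m = PatternModel(kind="hardcore", n_points=40, semi_axis_x_nm=60,
                         semi_axis_y_nm=60, exclusion_diameter_nm=45.0)
        with pytest.raises(SaturationError):
            simulate_pole(m, seed=0)

    def test_uniform_centroid_converges_to_center(self):
        m = PatternModel(kind="uniform", n_points=10_000,
                         semi_axis_x_nm=200, semi_axis_y_nm=150)
        p = simulate_pole(m, seed=3)
        # SE of the mean of x: sd(x) = a/2 for uniform-in-ellipse marginals
        se_x, se_y = 200 / 2 / 100, 150 / 2 / 100
        assert abs(p.xy[:, 0].mean()) < 3 * se_x
        assert abs(p.xy[:, 1].mean()) < 3 * se_y

    def test_uniform_passes_quadrat_uniformity(self):
        """Chi-square uniformity after the area-preserving disc transform,
        alpha = 0.01, >= 95 of 100 seeded replicates."""
        a, b = 200.0, 150.0
        m = PatternModel(kind="uniform", n_points=200,
                         semi_axis_x_nm=a, semi_axis_y_nm=b)
        passes = 0
        for seed in range(100):
            xy = simulate_pole(m, seed=seed).xy
            u = (xy[:, 0] / a) ** 2 + (xy[:, 1] / b) ** 2  # r^2 ~ U(0,1)
            v = (np.arctan2(xy[:, 1] / b, xy[:, 0] / a) + np.pi) / (2 * np.pi)
            cells = np.histogram2d(u, v, bins=4, range=[[0, 1], [0, 1]])[0]
            p = stats.chisquare(cells.ravel()).pvalue
            passes += p > 0.01
        assert passes >= 95

    def test_grid_lies_on_jittered_lattice(self):
        m = PatternModel(kind="grid", n_points=7, lattice_spacing_nm=64.0,
                         jitter_sd_nm=2.0)
        p = simulate_pole(m, seed=9)
        d = nearest_neighbor_distances_bruteforce(p.xy)
        # every NN distance close to the lattice constant
        assert np.all(np.abs(d - 64.0) < 5 * 2.0 * math.sqrt(2))

    def test_motor_fraction_extremes(self):
        all_motor = simulate_pole(
            PatternModel(kind="uniform", n_points=20, motor_fraction=1.0), 1
        )
        all_relic = simulate_pole(
            PatternModel(kind="uniform", n_points=20, motor_fraction=0.0), 1
        )
        assert set(all_motor.labels) == {"motor"}
        assert set(all_relic.labels) == {"relic"}


class TestSimulatePopulation:
    def test_zero_rates_conserve_flagella(self):
        m = PopulationModel(
            growth_rate_per_h=0.0,
            assembly_rate_per_h=0.0,
            ejection_rate_post_trigger_per_h=0.0,
        )
        tps = simulate_population(m, [0.0, 2.0, 5.0], seed=1, n_cells=50)
        np.testing.assert_array_equal(tps[0].counts, tps[1].counts)
        np.testing.assert_array_equal(tps[0].counts, tps[2].counts)

    def test_absolute_flagella_decline_after_trigger(self):
        m = PopulationModel()
        t_trig = m.trigger_time_h()
        tps = simulate_population(
            m, [t_trig, t_trig + 1.0, t_trig + 2.0], seed=2, n_cells=150
        )
        absolute = [tp.counts.mean() * tp.cfu_per_ml for tp in tps]
        assert absolute[-1] < absolute[0]

    def test_peritrichous_mode_never_ejects_absolute_grows(self):
        m = PopulationModel(mode="peritrichous_dilution")
        tps = simulate_population(m, [0.0, 1.5, 3.0], seed=3, n_cells=150)
        absolute = [tp.counts.mean() * tp.cfu_per_ml for tp in tps]
        assert absolute[-1] > absolute[0]

    def test_mean_trajectory_matches_fixed_step_oracle(self):
        """Event-driven simulation agrees with an independent fixed-step
        stochastic oracle within Monte-Carlo error."""
        m = PopulationModel()
        t_eval = [1.0, 2.5]
        n_cells = 300
        tps = simulate_population(m, t_eval, seed=4, n_cells=n_cells)

        # oracle: Bernoulli-step simulation, dt = 0.002 h
        rng = np.random.default_rng(104)
        dt = 0.002
        t_trig = m.trigger_time_h()
        counts = rng.poisson(m.initial_mean_flagella, n_cells).astype(int)
        t = 0.0
        oracle_means = []
        for t_end in t_eval:
            while t < t_end - 1e-12:
                post = t >= t_trig
                od = float(m.od_at(t))
                div_p = m.growth_rate_per_h * max(0.0, 1 - od / m.carrying_od) * dt
                asm_p = 0.0 if post else m.assembly_rate_per_h * dt
                divs = rng.random(n_cells) < div_p
                keep = rng.random(n_cells) < 0.5
                counts = np.where(divs & ~keep, 0, counts)
                counts = counts + (rng.random(n_cells) < asm_p)
                if post:
                    ej = rng.binomial(
                        counts, min(1.0, m.ejection_rate_post_trigger_per_h * dt)
                    )
                    counts = counts - ej
                t += dt
            oracle_means.append(counts.mean())

        for tp, om in zip(tps, oracle_means):
            se = tp.counts.std(ddof=1) / math.sqrt(n_cells)
            se_o = 1.0 / math.sqrt(n_cells)  # rough oracle SE floor
            assert abs(tp.counts.mean() - om) < 4 * max(se, se_o, 0.05)

    def test_timepoints_must_increase(self):
        with pytest.raises(ValueError):
            simulate_population(PopulationModel(), [1.0, 0.5], seed=0)


class TestDetachedFlagella:
    def test_base_of_hook_one_hook_per_flagellum(self):
        flg = simulate_detached_flagella(100, "base_of_hook", seed=0)
        assert len(flg) == 100
        assert all(sum(f.hook_at_end) == 1 for f in flg)
        assert sum(h for f in flg for h in f.hook_at_end) == 100

    def test_midfilament_has_no_hooks(self):
        flg = simulate_detached_flagella(70, "midfilament", seed=0)
        assert sum(h for f in flg for h in f.hook_at_end) == 0

    def test_invariant_enforced_at_construction(self):
        with pytest.raises(ValueError):
            DetachedFlagellum("x", "base_of_hook", (True, True))
        with pytest.raises(ValueError):
            DetachedFlagellum("x", "midfilament", (True, False))


class TestSimulateTracks:
    def test_noiseless_track_recovers_speed_exactly(self):
        tr = simulate_tracks(1, speed_mean_um_s=37.0, speed_sd_um_s=0.0,
                             heading_sd_rad=0.0, seed=0)[0]
        path = np.hypot(np.diff(tr.x_um), np.diff(tr.y_um)).sum()
        assert path / (tr.t_s[-1] - tr.t_s[0]) == pytest.approx(37.0)

    def test_parameter_recovery_at_scale(self):
        tracks = simulate_tracks(1000, speed_mean_um_s=40.0, speed_sd_um_s=5.0,
                                 seed=1)
        speeds = np.array([t.true_speed_um_s for t in tracks])
        assert abs(speeds.mean() - 40.0) < 3 * 5.0 / math.sqrt(1000)

    def test_zero_speed_track_is_stationary(self):
        tr = simulate_tracks(1, speed_mean_um_s=0.0, speed_sd_um_s=0.0, seed=2)[0]
        assert np.all(tr.x_um == 0.0) and np.all(tr.y_um == 0.0)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            simulate_tracks(1, duration_s=0.01, frame_dt_s=0.1, seed=0)


class TestPeriplasmMeasurements:
    def test_configured_ranges_recovered_in_order(self):
        df = simulate_periplasm_measurements(
            {"relic": (30.0, 13.9), "motor": (30.0, 7.9)},
            n_per_class=60, seed=0, dist="uniform",
        )
        r = df[df.klass == "relic"].distance_nm
        m = df[df.klass == "motor"].distance_nm
        assert (r.max() - r.min()) > (m.max() - m.min())
        assert (df.distance_nm > 0).all()

    def test_zero_spread_gives_zero_range(self):
        df = simulate_periplasm_measurements({"motor": (30.0, 0.0)},
                                             n_per_class=10, seed=0)
        assert df.distance_nm.max() - df.distance_nm.min() == 0.0

    def test_normal_sd_moment_recovery(self):
        df = simulate_periplasm_measurements({"motor": (30.0, 2.0)},
                                             n_per_class=10_000, seed=1,
                                             dist="normal")
        assert df.distance_nm.std(ddof=1) == pytest.approx(2.0, rel=0.05)


class TestBuildPhantom:
    def test_plug_fills_aperture_above_solvent(self):
        spec = PhantomSpec()
        motor = build_phantom(spec).data
        relic = build_phantom(PhantomSpec(plug_present=True)).data
        N = spec.box_size
        c = N // 2
        z_mem = int(round((N - 1) / 2.0 + 13.0 / spec.voxel_size_nm))
        axis = (slice(z_mem, z_mem + 1), slice(c - 1, c + 1), slice(c - 1, c + 1))
        assert relic[axis].mean() > 0.5  # plugged: near membrane level
        assert motor[axis].mean() < 0.1  # open: near solvent

    def test_single_subunit_is_rotationally_smooth(self):
        from flagrelics.maps import detect_symmetry_order

        smooth = build_phantom(PhantomSpec(n_subunits=1))
        det = detect_symmetry_order(smooth, (18.0, 26.0), orders=range(2, 21))
        assert det.order is None

    def test_ring_diameter_matches_spec_within_a_voxel(self):
        from flagrelics.maps import measure_ring

        spec = PhantomSpec()
        meas = measure_ring(build_phantom(spec))
        assert abs(meas.ring_diameter_nm - spec.t_ring_diameter_nm) <= spec.voxel_size_nm

    def test_oversized_geometry_rejected(self):
        from flagrelics.simulate import PhantomSizingError

        with pytest.raises(PhantomSizingError):
            build_phantom(PhantomSpec(t_ring_diameter_nm=120.0, box_size=32))

    def test_noise_is_seeded(self):
        a = build_phantom(PhantomSpec(), noise_sd=0.5, seed=5).data
        b = build_phantom(PhantomSpec(), noise_sd=0.5, seed=5).data
        np.testing.assert_array_equal(a, b)
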