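"""Generators: determinism, parameter errors, and statistical structure."""

import numpy as np
import pytest
from scipy.integrate import quad

from ktrkit import contacts, deer, fits, synthetic
from ktrkit.synthetic import (ClassImageParams, DeerTraceParams,
                              MeltCurveParams, ThermogramParams,
                              ToyTrajectoryParams, UptakeParams,
                              generate_class_image, generate_deer_trace,
                              generate_idr_membrane_trajectory,
                              generate_itc_thermogram, generate_melt_curve,
                              generate_uptake_timecourses)


def tail_lipid_contact_fraction(traj):
    """Brute-force fraction of frames with >= 1 tail-lipid atom pair
    within 3.5 Å (independent of the contacts module)."""
    tail = traj.segment == "tail"
    lip = (traj.segment == "lipid-phosphate") | (traj.segment == "lipid-acyl")
    hits = 0
    for f in range(traj.n_frames):
        xyz = traj.frame(f)
        d = np.linalg.norm(xyz[tail][:, None] - xyz[lip][None], axis=2)
        hits += bool((d <= 3.5).any())
    return hits / traj.n_frames


class TestTrajectoryGenerator:
    def test_frame_count(self):
        traj = generate_idr_membrane_trajectory(
            ToyTrajectoryParams(n_frames=100, seed=0))
        assert traj.n_frames == 100

    @pytest.mark.parametrize("kw", [{"n_frames": 0}, {"tail_length": 1},
                                    {"membrane_affinity": -1.0}])
    def test_invalid_params(self, kw):
        with pytest.raises(ValueError):
            ToyTrajectoryParams(**kw)

    def test_no_affinity_rarely_touches_membrane(self):
        traj = generate_idr_membrane_trajectory(ToyTrajectoryParams(
            n_frames=100, membrane_affinity=0.0, anchor_z=30.0, seed=0))
        assert tail_lipid_contact_fraction(traj) < 0.05

    def test_strong_affinity_binds_membrane(self):
        traj = generate_idr_membrane_trajectory(ToyTrajectoryParams(
            n_frames=100, membrane_affinity=50.0, anchor_z=30.0, seed=0))
        assert tail_lipid_contact_fraction(traj) > 0.9

    def test_seed_reproducibility(self):
        p = ToyTrajectoryParams(n_frames=10, seed=42)
        a = generate_idr_membrane_trajectory(p)
        b = generate_idr_membrane_trajectory(ToyTrajectoryParams(
            n_frames=10, seed=42))
        assert np.array_equal(a.coords, b.coords)

    def test_affinity_monotonicity_sign_test(self):
        """Mean lipid-contact count does not decrease with affinity
        (paired over seeds, exact binomial sign test)."""
        from scipy.stats import binomtest
        spec = contacts.ContactSpec()
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            means = []
            for aff in (2.0, 20.0):
                traj = generate_idr_membrane_trajectory(ToyTrajectoryParams(
                    n_frames=60, membrane_affinity=aff, seed=seed))
                ts, _ = contacts.lipid_contacts(traj, range(2, 22), spec)
                means.append(ts.value.mean())
            wins += means[1] >= means[0]
        assert binomtest(wins, n_seeds, 0.5,
                         alternative="greater").pvalue < 0.05

    def test_docked_reference_frame_has_native_contacts(self):
        traj = generate_idr_membrane_trajectory(
            ToyTrajectoryParams(n_frames=3, seed=5))
        spec = contacts.ContactSpec()
        ncs = contacts.build_native_contacts(traj, spec)
        assert len(ncs) >= 7  # one per tail residue 7-13 at least
        q = contacts.fraction_native_contacts(traj.frame(0), ncs, spec)
        assert q > 0.95


class TestMeltCurveGenerator:
    @pytest.mark.parametrize("tm", [67.0, 55.0])
    def test_derivative_peak_at_tm(self, tm):
        curve = generate_melt_curve(MeltCurveParams(tm=tm, noise_sd=0.0))
        d = np.gradient(curve.fluorescence, curve.temperature)
        assert curve.temperature[np.argmax(d)] == pytest.approx(tm)

    def test_flat_when_baselines_equal(self):
        curve = generate_melt_curve(MeltCurveParams(
            baseline_low=5.0, baseline_high=5.0, noise_sd=0.0))
        d = np.gradient(curve.fluorescence, curve.temperature)
        assert np.allclose(d, 0.0, atol=1e-12)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            MeltCurveParams(t_range=np.array([]))

    def test_noiseless_deterministic(self):
        a = generate_melt_curve(MeltCurveParams(seed=1))
        b = generate_melt_curve(MeltCurveParams(seed=2))
        assert np.array_equal(a.fluorescence, b.fluorescence)


class TestItcGenerator:
    def test_zero_enthalpy_zero_heats(self):
        tg = generate_itc_thermogram(ThermogramParams(dh=0.0))
        assert np.allclose(tg.heats, 0.0)

    def test_no_binding_limit(self):
        """Heats vanish monotonically as K_D grows without bound."""
        scales = [np.max(np.abs(generate_itc_thermogram(
            ThermogramParams(kd=kd, dh=-10.0)).heats))
            for kd in (1e3, 1e6, 1e9)]
        assert scales[-1] < 1e-3
        assert scales[0] > scales[1] > scales[2]

    def test_round_trip_recovers_kd(self):
        tg = generate_itc_thermogram(ThermogramParams(kd=2.4, noise_sd=0.0))
        res = fits.fit_one_site_itc(tg)
        assert res.kd == pytest.approx(2.4, rel=1e-6)

    def test_seeded_noise_reproducible(self):
        a = generate_itc_thermogram(ThermogramParams(noise_sd=0.1, seed=9))
        b = generate_itc_thermogram(ThermogramParams(noise_sd=0.1, seed=9))
        assert np.array_equal(a.heats, b.heats)


class TestUptakeGenerator:
    def test_half_saturation_identity(self):
        p = UptakeParams(vmax=100.0, km=0.2, substrate_concs=(0.2,))
        ds = generate_uptake_timecourses(p)
        v, _ = ds.initial_velocities()
        assert v[0] == pytest.approx(50.0)

    def test_saturation_limit(self):
        p = UptakeParams(vmax=100.0, km=0.2, substrate_concs=(200.0,))
        ds = generate_uptake_timecourses(p)
        v, _ = ds.initial_velocities()
        assert v[0] == pytest.approx(100.0, rel=1e-3)

    def test_slopes_equal_closed_form(self):
        p = UptakeParams(vmax=197.0, km=0.2)
        ds = generate_uptake_timecourses(p)
        v, _ = ds.initial_velocities()
        expected = 197.0 * ds.substrate_concs / (0.2 + ds.substrate_concs)
        assert np.allclose(v, expected, rtol=1e-9)

    def test_empty_substrates_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            UptakeParams(substrate_concs=())


class TestClassImageGenerator:
    def test_circle_ratio_one(self):
        from ktrkit.shapes import measure_diameters
        img = generate_class_image(ClassImageParams(long_axis=6.3,
                                                    short_axis=6.3))
        long_nm, short_nm = measure_diameters(img)
        assert long_nm / short_nm == pytest.approx(1.0, abs=0.01)

    def test_oversized_ellipse_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            ClassImageParams(long_axis=20.0, short_axis=6.0,
                             image_size=100, pixel_size=0.05)

    def test_rotation_leaves_axes(self):
        from ktrkit.shapes import measure_diameters
        base = generate_class_image(ClassImageParams(angle_deg=0.0))
        rot = generate_class_image(ClassImageParams(angle_deg=37.0))
        la, sa = measure_diameters(base)
        lb, sb = measure_diameters(rot)
        px = base.pixel_size
        assert abs(la - lb) < px and abs(sa - sb) < px


class TestDeerGenerator:
    r = np.arange(1.5, 8.0 + 1e-9, 0.02)

    def test_v0_is_one(self):
        dist = deer.gaussian_distribution(self.r, 3.3, 0.15)
        tr = generate_deer_trace(DeerTraceParams(distribution=dist,
                                                 noise_sd=0.02, seed=3))
        assert tr.V[0] == pytest.approx(1.0)

    def test_zero_modulation_is_pure_background(self):
        dist = deer.gaussian_distribution(self.r, 3.3, 0.15)
        tr = generate_deer_trace(DeerTraceParams(
            distribution=dist, modulation_depth=0.0, background_rate=0.1))
        assert np.allclose(tr.V, np.exp(-0.1 * tr.t))

    def test_delta_distribution_oscillates_at_dipolar_frequency(self):
        """A single 4.0 nm distance produces the oscillation of the
        quadrature-evaluated kernel at that distance."""
        r = np.array([3.98, 4.0, 4.02])
        p = np.array([0.0, 1.0, 0.0])
        dist = deer.DistanceDistribution(r, p).normalized()
        tr = generate_deer_trace(DeerTraceParams(
            distribution=dist, modulation_depth=1.0, background_rate=0.0,
            t_max=2.0))
        om = 2 * np.pi * 52.04 / 4.0 ** 3
        oracle = np.array([
            quad(lambda x: np.cos((1 - 3 * x * x) * om * t), 0, 1,
                 limit=200)[0]
            for t in tr.t])
        assert np.allclose(tr.V, oracle, atol=5e-3)

    def test_unnormalized_distribution_rejected(self):
        bad = deer.DistanceDistribution(self.r, np.full_like(self.r, 2.0))
        with pytest.raises(ValueError, match="normalized"):
            generate_deer_trace(DeerTraceParams(distribution=bad))
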