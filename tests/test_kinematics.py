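"""Angle definitions, the velocity/angle-of-attack chain, averaging, deconfliction."""
import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mothfan as mf
from mothfan.errors import ConfigurationError, DegenerateGeometryError
from mothfan.geometry import wing_tip_direction
from mothfan.kinematics import (
    FluidConstants,
    WingMorphology,
    angle_of_attack,
    average_cycles,
    body_angle,
    deconflict_sagittal,
    feathering_from_3d_contours,
    fit_feathering,
    fit_stroke_plane,
    mean_tip_speed,
    pose_wing_surface,
    positional_elevation,
    reynolds,
    schmidt,
    wing_velocity_components,
)

D2R = np.pi / 180.0


class TestBodyAngle:
    @pytest.mark.parametrize(
        "head, abdomen, expected_deg",
        [
            ((1, 0, 0), (0, 0, 0), 0.0),
            ((1, 0, 1), (0, 0, 0), 45.0),
            ((0, 1, -1), (0, 0, 0), -45.0),
            ((0, 0, 1), (0, 0, 0), 90.0),
        ],
    )
    def test_known_geometries(self, head, abdomen, expected_deg):
        assert np.degrees(body_angle(head, abdomen)) == pytest.approx(expected_deg)

    def test_coincident_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            body_angle((1, 2, 3), (1, 2, 3))

    def test_recovers_generator_body_angle(self, recon_kin):
        assert np.degrees(recon_kin.chi) == pytest.approx(-0.6, abs=0.01)


class TestStrokePlane:
    def test_recovers_inclined_plane_exactly(self):
        """Tips exactly in a 99.5 deg plane through the pivot give 99.5 deg."""
        beta = 99.5 * D2R
        phi = np.linspace(-0.5, 1.2, 40)
        tips = 0.02 * wing_tip_direction(phi, np.zeros_like(phi), beta)
        assert np.degrees(fit_stroke_plane(tips, np.zeros(3))) == pytest.approx(99.5, abs=1e-9)

    def test_horizontal_path_gives_zero(self):
        x = np.linspace(0, 0.02, 10)
        tips = np.column_stack([x, np.zeros(10), np.full(10, 0.01)])
        assert fit_stroke_plane(tips, np.zeros(3)) == pytest.approx(0.0, abs=1e-12)

    def test_vertical_path_well_posed(self):
        """Total least squares keeps a 90 deg stroke plane non-singular."""
        z = np.linspace(0, 0.02, 10)
        tips = np.column_stack([np.full(10, 0.005), np.zeros(10), z])
        assert np.degrees(fit_stroke_plane(tips, np.zeros(3))) == pytest.approx(90.0, abs=1e-9)

    def test_noisy_vertical_plane_recovered_monte_carlo(self):
        """0.1 mm tracking noise leaves a 90 deg plane within 0.5 deg (100 seeds)."""
        phi = np.linspace(-0.8, 0.8, 50)
        clean = 0.0173 * wing_tip_direction(phi, np.zeros_like(phi), np.pi / 2)
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = clean + rng.normal(0, 1e-4, clean.shape)
            errs.append(np.degrees(fit_stroke_plane(noisy, np.zeros(3))) - 90.0)
        assert np.max(np.abs(errs)) < 0.5

    def test_invariant_under_rigid_translation(self):
        phi = np.linspace(-0.5, 1.0, 30)
        tips = 0.02 * wing_tip_direction(phi, np.full_like(phi, -0.3), 1.7)
        b1 = fit_stroke_plane(tips, np.zeros(3))
        b2 = fit_stroke_plane(tips + np.array([0.4, -0.2, 0.9]), np.array([0.4, -0.2, 0.9]))
        assert b1 == pytest.approx(b2, abs=1e-12)


class TestPositionalElevation:
    def test_in_plane_horizontal_tip(self):
        beta = 99.5 * D2R
        tip = wing_tip_direction(0.0, 0.0, beta)
        phi, theta = positional_elevation(tip, np.zeros(3), beta)
        assert phi == pytest.approx(0.0, abs=1e-12)
        assert theta == pytest.approx(0.0, abs=1e-12)

    def test_in_plane_vertical_tip(self):
        beta = np.pi / 2
        tip = wing_tip_direction(np.pi / 2, 0.0, beta)
        phi, theta = positional_elevation(tip, np.zeros(3), beta)
        assert phi == pytest.approx(np.pi / 2, abs=1e-12)
        assert theta == pytest.approx(0.0, abs=1e-12)

    def test_roundtrip_random_angles(self):
        rng = np.random.default_rng(3)
        beta = 1.7
        phis = rng.uniform(-1.2, 1.4, 50)
        thetas = rng.uniform(-0.6, 0.6, 50)
        tips = 0.0173 * wing_tip_direction(phis, thetas, beta)
        phi_r, theta_r = positional_elevation(tips, np.zeros(3), beta)
        assert np.allclose(phi_r, phis, atol=1e-12)
        assert np.allclose(theta_r, thetas, atol=1e-12)

    def test_recovers_generator_mean_elevation(self, recon_kin):
        assert np.degrees(np.mean(recon_kin.theta)) == pytest.approx(-23.8, abs=0.1)

    def test_normal_tip_flagged_degenerate(self):
        beta = np.pi / 2
        tip = wing_tip_direction(0.0, np.pi / 2, beta)  # straight along the plane normal
        phi, theta = positional_elevation(tip[None, :], np.zeros(3), beta)
        assert np.isnan(phi[0])
        assert theta[0] == pytest.approx(np.pi / 2, abs=1e-9)


class TestVelocityAoAChain:
    @pytest.mark.parametrize(
        "alpha_deg, vh_expected, vv_expected",
        [(90.0, 0.0, 1.0), (0.0, -1.0, 0.0), (45.0, -np.sqrt(2) / 2, np.sqrt(2) / 2)],
    )
    def test_velocity_components_closed_form(self, alpha_deg, vh_expected, vv_expected):
        """Section velocities for r=1, phi_dot=1, theta=theta_dot=0."""
        vh, vv = wing_velocity_components(1.0, 1.0, 0.0, alpha_deg * D2R, 0.0)
        assert vh == pytest.approx(vh_expected, abs=1e-12)
        assert vv == pytest.approx(vv_expected, abs=1e-12)

    @pytest.mark.parametrize(
        "vh, vv, raw_deg, folded_deg",
        [(0.0, 1.0, 90.0, 90.0), (1.0, 0.0, 0.0, 0.0),
         (-np.sqrt(2) / 2, np.sqrt(2) / 2, 135.0, 45.0)],
    )
    def test_angle_of_attack_values(self, vh, vv, raw_deg, folded_deg):
        assert np.degrees(angle_of_attack(vh, vv)) == pytest.approx(raw_deg, abs=1e-9)
        assert np.degrees(angle_of_attack(vh, vv, folded=True)) == pytest.approx(folded_deg, abs=1e-9)

    def test_zero_speed_gives_nan_sentinel(self):
        assert np.isnan(angle_of_attack(0.0, 0.0))

    @given(
        alpha=st.floats(-np.pi, np.pi),
        theta=st.floats(-1.2, 1.2),
        phi_dot=st.floats(-50, 50),
        theta_dot=st.floats(-50, 50),
        r=st.floats(1e-4, 0.02),
    )
    @settings(max_examples=200, deadline=None)
    def test_aoa_always_in_valid_range(self, alpha, theta, phi_dot, theta_dot, r):
        vh, vv = wing_velocity_components(r, phi_dot, theta_dot, alpha, theta)
        aoa = angle_of_attack(vh, vv)
        assert np.isnan(aoa) or 0.0 <= aoa <= np.pi

    @given(alpha=st.floats(-np.pi, np.pi), theta=st.floats(-1.2, 1.2), rate=st.floats(0.1, 50))
    @settings(max_examples=100, deadline=None)
    def test_single_rate_speed_magnitude(self, alpha, theta, rate):
        """With one angular rate active the section speed has closed magnitude."""
        vh, vv = wing_velocity_components(1.0, rate, 0.0, alpha, theta)
        assert np.hypot(vh, vv) == pytest.approx(abs(rate * np.cos(theta)), rel=1e-9)
        vh, vv = wing_velocity_components(1.0, 0.0, rate, alpha, theta)
        assert np.hypot(vh, vv) == pytest.approx(abs(rate), rel=1e-9)


def _cycles_series(f=40.0, n_cycles=4, fs=2000.0, offset=0.0, perturb=None):
    t = np.arange(int(n_cycles * fs / f) + 1) / fs
    phi = 0.5 * np.cos(2 * np.pi * f * t) + offset
    theta = -0.4 + 0.05 * np.cos(2 * np.pi * f * t + np.pi / 2)
    if perturb is not None:
        phi = phi + perturb(t)
    return {"time": t, "phi": phi, "theta": theta}


class TestAverageCycles:
    def test_identical_cycles_average_to_one_cycle(self):
        ser = _cycles_series()
        kin = average_cycles({"L": ser}, beta=1.7, chi=0.0, R=0.0173)
        # the averaged cycle reproduces the generating sinusoid
        expected = 0.5 * np.cos(2 * np.pi * kin.t_hat)
        assert np.allclose(kin.phi, expected, atol=2e-3)
        assert kin.f == pytest.approx(40.0, rel=1e-3)

    def test_left_right_mirror_average_equals_both(self):
        ser = _cycles_series()
        one = average_cycles({"L": ser}, beta=1.7, chi=0.0, R=0.0173)
        both = average_cycles({"L": ser, "R": dict(ser)}, beta=1.7, chi=0.0, R=0.0173)
        assert np.allclose(one.phi, both.phi, atol=1e-12)

    def test_symmetric_perturbations_cancel(self):
        """Cycles perturbed by +d and -d average back to the clean cycle."""
        f, fs = 40.0, 2000.0
        delta = lambda t: 0.03 * np.sin(2 * np.pi * f * 2 * t) * np.where((t * f) % 2 < 1, 1, -1)
        clean = average_cycles({"L": _cycles_series()}, beta=1.7, chi=0.0, R=0.0173)
        pert = average_cycles({"L": _cycles_series(perturb=delta)}, beta=1.7, chi=0.0, R=0.0173)
        assert np.allclose(clean.phi, pert.phi, atol=5e-3)

    def test_commutes_with_constant_offset(self):
        a = average_cycles({"L": _cycles_series()}, beta=1.7, chi=0.0, R=0.0173)
        b = average_cycles({"L": _cycles_series(offset=0.25)}, beta=1.7, chi=0.0, R=0.0173)
        assert np.allclose(b.phi - a.phi, 0.25, atol=1e-6)

    def test_periodic_series_close_smoothly(self, recon_kin):
        recon_kin.assert_periodic()
        assert recon_kin.amplitude == pytest.approx(np.ptp(recon_kin.phi))


class TestFeathering:
    def test_uniform_twist_recovered_from_cameras(self, clean_track, stereo_cameras, default_spec):
        """Contours generated at alpha = 90 deg everywhere are fitted back to 90 deg."""
        uniform = mf.KinematicsSpec(
            feathering=mf.synthetic.FeatheringProfile(amp1=0.0, amp2=0.0), n_cycles=1
        )
        track = mf.generate_landmarks(uniform, 0.0, 0)
        morph = WingMorphology(R=uniform.wing_length)
        pivot = track.landmark("wing_root", "L").mean(axis=0)
        tips = track.landmark("wing_tip", "L")[:3]
        phi, theta = positional_elevation(tips, pivot, uniform.stroke_plane_angle)
        sub = track.frames[
            (track.frames["side"] == "L") & track.frames["landmark"].str.startswith("contour_")
        ]
        n_pts = sub["landmark"].nunique()
        pts3 = sub[["x_m", "y_m", "z_m"]].to_numpy().reshape(-1, n_pts, 3)[:3]
        obs = np.stack([cam.project(pts3) for cam in stereo_cameras])
        alpha = fit_feathering(
            obs, stereo_cameras, morph, pivot, uniform.stroke_plane_angle, phi, theta
        )
        assert np.max(np.abs(np.degrees(alpha) - 90.0)) < 0.1

    def test_linear_spanwise_twist_recovered(self, stereo_cameras):
        """A 60->120 deg linear twist is recovered within 1 deg RMS."""
        stations = np.array([0.2, 0.4, 0.6, 0.8, 1.0])
        prof = mf.synthetic.FeatheringProfile(
            stations=stations,
            mean=np.radians(60 + 60 * (stations - 0.2) / 0.8),
            amp1=0.0,
            amp2=0.0,
        )
        spec = mf.KinematicsSpec(feathering=prof, n_cycles=1)
        track = mf.generate_landmarks(spec, 0.0, 0)
        morph = WingMorphology(R=spec.wing_length)
        pivot = track.landmark("wing_root", "L").mean(axis=0)
        tips = track.landmark("wing_tip", "L")[:2]
        phi, theta = positional_elevation(tips, pivot, spec.stroke_plane_angle)
        sub = track.frames[
            (track.frames["side"] == "L") & track.frames["landmark"].str.startswith("contour_")
        ]
        n_pts = sub["landmark"].nunique()
        pts3 = sub[["x_m", "y_m", "z_m"]].to_numpy().reshape(-1, n_pts, 3)[:2]
        obs = np.stack([cam.project(pts3) for cam in stereo_cameras])
        alpha = fit_feathering(
            obs, stereo_cameras, morph, pivot, spec.stroke_plane_angle, phi, theta, stations=stations
        )
        truth = np.degrees(prof.evaluate(np.zeros(2)))
        rms = np.sqrt(np.mean((np.degrees(alpha) - truth) ** 2))
        assert rms < 1.0

    def test_tip_varies_more_than_root(self, recon_kin):
        """Feathering variation grows from root to tip, notably in upstroke."""
        up = recon_kin.t_hat >= 0.5
        tip_var = np.ptp(recon_kin.alpha[up, -1])
        root_var = np.ptp(recon_kin.alpha[up, 0])
        assert tip_var > root_var

    def test_3d_contour_inversion_matches_truth(self, clean_track, default_spec):
        sub = clean_track.frames[
            (clean_track.frames["side"] == "L")
            & clean_track.frames["landmark"].str.startswith("contour_")
        ]
        n_pts = sub["landmark"].nunique()
        pts3 = sub[["x_m", "y_m", "z_m"]].to_numpy().reshape(-1, n_pts, 3)[:50]
        truth = clean_track.truth
        pivot = clean_track.landmark("wing_root", "L").mean(axis=0)
        spans = WingMorphology(R=default_spec.wing_length).contour[0::2, 0]
        alpha = feathering_from_3d_contours(
            pts3, pivot, default_spec.stroke_plane_angle, truth["phi"][:50], truth["theta"][:50], spans
        )
        expected = np.apply_along_axis(
            lambda row: np.interp(spans, default_spec.feathering.stations, row), 1, truth["alpha"][:50]
        )
        assert np.max(np.abs(alpha - expected)) < 1e-9


@pytest.fixture(scope="module")
def interfering_kin():
    """Kinematics whose upper stroke reversal crosses the sagittal plane."""
    spec = mf.KinematicsSpec(mean_positional=np.radians(53.0))
    return mf.reconstruct(mf.generate_landmarks(spec, 0.0, 0))


class TestDeconflict:
    def test_clear_kinematics_untouched(self, recon_kin):
        out, rot = deconflict_sagittal(recon_kin, clearance=0.0)
        assert rot == 0.0
        assert np.allclose(out.phi, recon_kin.phi)

    def test_known_penetration_matches_brute_force(self, interfering_kin):
        """The reported rotation matches a 0.01 deg brute-force scan."""
        out, rot = deconflict_sagittal(interfering_kin, clearance=0.0)
        morph = WingMorphology(R=interfering_kin.R)
        base = pose_wing_surface(interfering_kin, morph, side="L")
        rel = base - interfering_kin.pivot
        scan = np.radians(np.arange(0.0, 15.0, 0.01))
        miny = np.array(
            [
                np.min(
                    interfering_kin.pivot[1]
                    + rel[..., 1] * np.cos(d)
                    + rel[..., 2] * np.sin(d)
                )
                for d in scan
            ]
        )
        oracle = scan[np.argmax(miny >= 0.0)]
        assert np.degrees(abs(rot - oracle)) < 0.2
        # wing speed is unchanged by the rigid rotation
        assert out.tip_speed() == pytest.approx(interfering_kin.tip_speed())

    def test_mild_interference_needs_single_digit_rotation(self, interfering_kin):
        """A mild sagittal interference resolves with a rotation in the 5-8 deg range."""
        _, rot = deconflict_sagittal(interfering_kin, clearance=0.0)
        assert 5.0 <= np.degrees(rot) <= 8.0

    def test_excessive_interference_rejected(self, recon_kin):
        far = dataclasses.replace(recon_kin, pivot=recon_kin.pivot - np.array([0, 30e-3, 0]))
        with pytest.raises(ConfigurationError):
            deconflict_sagittal(far, clearance=0.0)


class TestDimensionlessNumbers:
    def test_schmidt_number_of_bombykol_in_air(self):
        assert schmidt(FluidConstants()) == 6.0

    def test_mean_tip_speed_from_typical_parameters(self):
        v = mean_tip_speed(np.radians(98.0), 48.9, 17.3e-3)
        assert v == pytest.approx(2.894, abs=0.005)
        # within one standard deviation of the measured 2.97 +/- 0.72 m/s
        assert abs(v - 2.97) < 0.72

    def test_linearity_in_amplitude(self):
        assert mean_tip_speed(2.0, 48.9, 0.0173) == pytest.approx(
            2 * mean_tip_speed(1.0, 48.9, 0.0173)
        )
        m = WingMorphology()
        assert reynolds(2.0, 48.9, m) == pytest.approx(2 * reynolds(1.0, 48.9, m))

    def test_reynolds_positive_and_scaled(self):
        m = WingMorphology()
        re = reynolds(np.radians(98.0), 48.9, m)
        assert re == pytest.approx(mean_tip_speed(np.radians(98.0), 48.9, m.R) * m.mean_chord / 1.5e-5)


class TestReconstructionIdentity:
    def test_all_angle_series_recovered(self, clean_track, recon_kin, default_spec):
        """Noise-free generation then reconstruction returns the prescribed series
        within 0.1 deg RMS."""
        t_grid = recon_kin.t_hat / recon_kin.f
        phi_true, theta_true, alpha_true = default_spec.angles(t_grid)
        assert np.sqrt(np.mean((recon_kin.phi - phi_true) ** 2)) < 0.1 * D2R
        assert np.sqrt(np.mean((recon_kin.theta - theta_true) ** 2)) < 0.1 * D2R
        assert np.sqrt(np.mean((recon_kin.alpha - alpha_true) ** 2)) < 0.1 * D2R

    def test_scalar_parameters_recovered(self, recon_kin, default_spec):
        assert recon_kin.f == pytest.approx(default_spec.frequency, rel=5e-3)
        assert recon_kin.amplitude == pytest.approx(default_spec.amplitude, abs=0.1 * D2R)
        assert recon_kin.beta == pytest.approx(default_spec.stroke_plane_angle, abs=0.1 * D2R)
        assert np.mean(recon_kin.theta) == pytest.approx(default_spec.mean_elevation, abs=0.1 * D2R)
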