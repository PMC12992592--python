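import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lnpstruct.membrane_features import (
    PressureProfile,
    Shape,
    classify_shape,
    classify_stability,
    compute_area_compressibility,
    compute_cpp_rg,
    compute_cpp_v,
    compute_density_profile,
    compute_lipid_geometry,
    compute_thickness,
    compute_torque_density,
)
from lnpstruct.synthetic_data import (
    EscapeEvent,
    SyntheticBilayerSpec,
    analytic_area_compressibility,
    make_area_series,
    make_bilayer_trajectory,
    make_pressure_profile,
)
from lnpstruct.trajectory_model import Trajectory

from conftest import single_lipid_system


def circle(n, radius, z):
    ang = 2 * np.pi * np.arange(n) / n
    return np.stack([radius * np.cos(ang), radius * np.sin(ang), np.full(n, z)], axis=1)


def cone_lipid(r_head, r_tail, length, n=6):
    """Single noiseless truncated-cone lipid (head plane above tail)."""
    return single_lipid_system(circle(n, r_head, length), circle(n, r_tail, 0.0))


def reduced_cpp_v(r_h, r_t):
    return (r_h**2 + r_h * r_t + r_t**2) / (3 * r_h**2)


class TestLipidGeometry:
    def test_disc_radius_recovered_exactly(self):
        traj, topo = cone_lipid(4.0, 6.0, 15.0)
        (g,) = compute_lipid_geometry(traj, topo)
        assert g.r_head == pytest.approx(4.0)
        assert g.r_tail == pytest.approx(6.0)
        assert g.a_0 == pytest.approx(np.pi * 16.0)
        # l_c is the mean head-centroid-to-tail-end distance
        assert g.l_c == pytest.approx(np.hypot(6.0, 15.0))

    def test_single_head_atom_is_degenerate(self):
        traj, topo = single_lipid_system([[0, 0, 15.0]], circle(4, 3.0, 0.0))
        (g,) = compute_lipid_geometry(traj, topo)
        assert g.r_head == 0.0 and g.degenerate

    def test_rigid_translation_leaves_geometry_unchanged(self):
        traj, topo = cone_lipid(4.0, 6.0, 15.0)
        moved = Trajectory(
            times=traj.times, coords=traj.coords + np.array([7.0, -3.0, 12.0]),
            box=traj.box,
        )
        g0 = compute_lipid_geometry(traj, topo)[0]
        g1 = compute_lipid_geometry(moved, topo)[0]
        for attr in ("r_head", "r_tail", "l_c", "V"):
            assert getattr(g0, attr) == pytest.approx(getattr(g1, attr), abs=1e-9)

    def test_empty_frame_selection_is_an_error(self):
        traj, topo = cone_lipid(4.0, 6.0, 15.0)
        with pytest.raises(ValueError, match="empty"):
            compute_lipid_geometry(traj, topo, frames=[])


class TestCppV:
    @given(
        r_h=st.floats(min_value=0.5, max_value=20.0),
        ratio=st.floats(min_value=0.0, max_value=3.0),
        length=st.floats(min_value=1.0, max_value=40.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_truncated_cone_formula_reduces_to_radii_only(self, r_h, ratio, length):
        """V/(a0 l_c) through the coordinate pipeline equals
        (r_h^2 + r_h r_t + r_t^2)/(3 r_h^2); the length cancels."""
        r_t = r_h * ratio
        traj, topo = cone_lipid(r_h, r_t, length)
        res = compute_cpp_v(compute_lipid_geometry(traj, topo))
        assert res.pooled_mean == pytest.approx(reduced_cpp_v(r_h, r_t), abs=1e-12)

    def test_cylinder_limit_is_one(self):
        traj, topo = cone_lipid(4.0, 4.0, 11.0)
        res = compute_cpp_v(compute_lipid_geometry(traj, topo))
        assert res.pooled_mean == pytest.approx(1.0, abs=1e-12)

    def test_point_tail_limit_is_one_third(self):
        traj, topo = single_lipid_system(circle(6, 4.0, 15.0), [[0.0, 0.0, 0.0]])
        res = compute_cpp_v(compute_lipid_geometry(traj, topo))
        assert res.pooled_mean == pytest.approx(1 / 3, abs=1e-12)

    def test_strictly_increasing_in_tail_head_ratio(self):
        vals = [reduced_cpp_v(4.0, 4.0 * rho) for rho in np.linspace(0, 2.5, 30)]
        assert np.all(np.diff(vals) > 0)

    def test_sem_is_sd_of_lipid_means_over_sqrt_n(self, noisy_bilayer):
        traj, topo, _ = noisy_bilayer
        res = compute_cpp_v(compute_lipid_geometry(traj, topo))
        means = np.array(list(res.per_lipid_means.values()))
        assert res.pooled_mean == pytest.approx(means.mean())
        assert res.dispersion == pytest.approx(
            means.std(ddof=1) / np.sqrt(len(means))
        )

    def test_all_degenerate_raises(self):
        traj, topo = single_lipid_system([[0, 0, 15.0]], [[0, 0, 0.0]])
        with pytest.raises(ValueError, match="degenerate"):
            compute_cpp_v(compute_lipid_geometry(traj, topo))

    def test_disjoint_subsets_reproduce_weighted_pooled_mean(self, noisy_bilayer):
        traj, topo, _ = noisy_bilayer
        lipids = topo.ionizable_lipids()
        a, b = lipids[: len(lipids) // 2], lipids[len(lipids) // 2 :]
        res_a = compute_cpp_v(compute_lipid_geometry(traj, topo, lipids=a))
        res_b = compute_cpp_v(compute_lipid_geometry(traj, topo, lipids=b))
        res_all = compute_cpp_v(compute_lipid_geometry(traj, topo))
        weighted = (
            res_a.pooled_mean * res_a.n_lipids + res_b.pooled_mean * res_b.n_lipids
        ) / (res_a.n_lipids + res_b.n_lipids)
        assert res_all.pooled_mean == pytest.approx(weighted, abs=1e-12)


class TestCppRg:
    def test_equal_mass_circles_give_radius_ratio(self):
        # planar Rg of equal-mass points on a circle equals its radius
        traj, topo = single_lipid_system(circle(4, 2.0, 10.0), circle(4, 3.0, 0.0))
        res = compute_cpp_rg(traj, topo)
        assert res.pooled_mean == pytest.approx(1.5, abs=1e-12)

    def test_equal_radii_give_unity(self):
        traj, topo = single_lipid_system(circle(5, 2.5, 10.0), circle(5, 2.5, 0.0))
        res = compute_cpp_rg(traj, topo)
        assert res.pooled_mean == pytest.approx(1.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        """Rotating and translating the whole lipid must not change
        CPP_Rg beyond numerical tolerance (the aligner undoes it)."""
        traj, topo = single_lipid_system(circle(4, 2.0, 10.0), circle(4, 3.0, 0.0))
        base = compute_cpp_rg(traj, topo).pooled_mean
        rng = np.random.default_rng(3)
        for _ in range(25):
            angles = rng.uniform(0, 2 * np.pi, 3)
            cx, cy = np.cos(angles), np.sin(angles)
            Rz = np.array([[cx[0], -cy[0], 0], [cy[0], cx[0], 0], [0, 0, 1]])
            Ry = np.array([[cx[1], 0, cy[1]], [0, 1, 0], [-cy[1], 0, cx[1]]])
            R = Rz @ Ry
            shift = rng.uniform(-30, 30, 3)
            moved = Trajectory(
                times=traj.times, coords=traj.coords @ R.T + shift, box=traj.box
            )
            assert compute_cpp_rg(moved, topo).pooled_mean == pytest.approx(
                base, abs=1e-9
            )

    def test_uniform_mass_rescaling_invariance(self):
        traj, topo = single_lipid_system(circle(4, 2.0, 10.0), circle(4, 3.0, 0.0))
        scaled = topo.table.copy()
        scaled["mass"] *= 7.5
        from lnpstruct.trajectory_model import Topology

        res0 = compute_cpp_rg(traj, topo).pooled_mean
        res1 = compute_cpp_rg(traj, Topology(scaled)).pooled_mean
        assert res0 == pytest.approx(res1, abs=1e-12)

    def test_mass_weighting_matters_for_unequal_masses(self):
        # heavier outer tail atoms pull Rg_tail up relative to the
        # equal-mass case
        head = circle(4, 2.0, 10.0)
        tail = np.concatenate([circle(4, 3.0, 0.0), [[0.0, 0.0, 0.0]]])
        masses_eq = [1.0] * 4 + [1.0] * 5
        masses_hvy = [1.0] * 4 + [5.0, 5.0, 5.0, 5.0, 1.0]
        t_eq, topo_eq = single_lipid_system(head, tail, masses=masses_eq)
        t_h, topo_h = single_lipid_system(head, tail, masses=masses_hvy)
        assert (
            compute_cpp_rg(t_h, topo_h).pooled_mean
            > compute_cpp_rg(t_eq, topo_eq).pooled_mean
        )

    def test_coincident_centers_are_excluded_with_warning(self):
        # head and tail discs at the same z: no axis to align
        traj, topo = single_lipid_system(circle(4, 2.0, 0.0), circle(4, 3.0, 0.0))
        with pytest.warns(UserWarning, match="degenerate axis"):
            with pytest.raises(ValueError, match="no lipids"):
                compute_cpp_rg(traj, topo)


class TestShapeClassification:
    @pytest.mark.parametrize(
        "cpp, expected",
        [
            (0.8, Shape.CONE),
            (1.0, Shape.CYLINDER),
            (1.04, Shape.CYLINDER),
            (1.4, Shape.INVERTED_CONE),
            (1 / 3, Shape.CONE),
        ],
    )
    def test_thresholds(self, cpp, expected):
        assert classify_shape(cpp) is expected

    def test_negative_cpp_is_domain_error(self):
        with pytest.raises(ValueError):
            classify_shape(-0.1)


class TestDensityProfile:
    def test_integral_recovers_component_counts(self, noisy_bilayer):
        traj, topo, truth = noisy_bilayer
        profiles = compute_density_profile(traj, topo, bin_width=1.0)
        centers, dens = profiles["ionizable"]
        assert dens.sum() * 1.0 == pytest.approx(truth.n_lipids)

    def test_mirrored_leaflets_give_two_symmetric_peaks(self, noiseless_bilayer):
        traj, topo, truth = noiseless_bilayer
        centers, dens = compute_density_profile(traj, topo, bin_width=1.0)["ionizable"]
        peaks = centers[dens > 0]
        half = truth.expected_thickness / 2
        assert peaks.min() == pytest.approx(-half, abs=1.0)
        assert peaks.max() == pytest.approx(half, abs=1.0)


class TestThickness:
    def test_constructed_separation_recovered_exactly(self, noiseless_bilayer):
        traj, topo, truth = noiseless_bilayer
        _, mean = compute_thickness(traj, topo)
        assert mean == pytest.approx(truth.expected_thickness, abs=1e-9)

    def test_translation_invariance(self, noiseless_bilayer):
        traj, topo, _ = noiseless_bilayer
        moved = Trajectory(
            times=traj.times, coords=traj.coords + np.array([0, 0, 33.0]),
            box=traj.box,
        )
        _, m0 = compute_thickness(traj, topo)
        _, m1 = compute_thickness(moved, topo)
        assert m0 == pytest.approx(m1, abs=1e-12)

    def test_noisy_leaflets_within_three_sem(self):
        spec = SyntheticBilayerSpec(
            n_lipids_per_leaflet=16, positional_noise_sd=1.0, n_frames=50, seed=21
        )
        traj, topo, truth = make_bilayer_trajectory(spec)
        series, mean = compute_thickness(traj, topo)
        sem = series.std(ddof=1) / np.sqrt(len(series))
        assert abs(mean - truth.expected_thickness) < 3 * max(sem, 1e-3)


class TestTorqueDensity:
    def test_piecewise_constant_matches_closed_form(self):
        prof, truth = make_pressure_profile(
            "piecewise_constant", {"p": 2.0, "z_lo": 5.0, "z_hi": 10.0},
            bin_width=0.2,
        )
        res = compute_torque_density(prof)
        assert res.tau_upper == pytest.approx(truth.tau_upper, rel=5e-3)
        assert res.tau_lower == pytest.approx(0.0, abs=1e-9)
        assert res.tau_mean_literal == pytest.approx(truth.tau_upper / 2, rel=5e-3)

    def test_symmetric_profile_literal_mean_vanishes(self):
        prof, truth = make_pressure_profile(
            "symmetric_gaussian", {"amplitude": 3.0, "sigma": 6.0}
        )
        res = compute_torque_density(prof)
        assert res.tau_mean_literal == pytest.approx(0.0, abs=1e-9)
        assert res.tau_mean_leaflet == pytest.approx(res.tau_upper)
        assert res.tau_upper == pytest.approx(truth.tau_upper, rel=5e-3)

    def test_antisymmetric_profile_closed_form(self):
        prof, truth = make_pressure_profile(
            "antisymmetric", {"amplitude": 1.5, "sigma": 7.0}
        )
        res = compute_torque_density(prof)
        assert res.tau_upper == pytest.approx(truth.tau_upper, rel=5e-3)
        assert res.tau_lower == pytest.approx(truth.tau_lower, rel=5e-3)

    def test_zero_profile_gives_zero_torques(self):
        prof, _ = make_pressure_profile(
            "piecewise_constant", {"p": 0.0, "z_lo": 0.0, "z_hi": 1.0}
        )
        res = compute_torque_density(prof)
        assert res.tau_upper == res.tau_lower == 0.0

    def test_printed_normal_convention_kills_isotropic_stress(self):
        # with p_N = p_xx, isotropic lateral stress gives p = (p_yy - p_xx)/2 = 0
        prof, _ = make_pressure_profile(
            "piecewise_constant", {"p": 2.0, "z_lo": 5.0, "z_hi": 10.0}
        )
        res = compute_torque_density(prof, normal_component="p_xx")
        assert res.tau_upper == pytest.approx(0.0, abs=1e-9)

    def test_nonuniform_bins_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            PressureProfile(
                z=np.array([0.0, 0.2, 0.5]),
                p_xx=np.zeros(3), p_yy=np.zeros(3), p_zz=np.zeros(3),
            )


class TestCompressibility:
    def test_known_moments_give_known_modulus(self):
        # constructed series with exact sample moments is impossible;
        # instead verify against the closed form at the sample moments
        a = make_area_series(4900.0, 10.0, 3000, seed=5)
        res = compute_area_compressibility(a, 310.0)
        assert res.K_A == pytest.approx(
            analytic_area_compressibility(res.mean_area, res.area_variance, 310.0)
        )

    def test_doubling_variance_halves_modulus(self):
        rng = np.random.default_rng(8)
        base = 4900.0 + rng.standard_normal(2000)
        # rescale fluctuations about the *sample* mean so the mean is
        # preserved and only the variance doubles
        doubled = base.mean() + (base - base.mean()) * np.sqrt(2)
        k1 = compute_area_compressibility(base, 310.0).K_A
        k2 = compute_area_compressibility(doubled, 310.0).K_A
        assert k1 / k2 == pytest.approx(2.0, rel=1e-9)

    def test_constant_series_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            compute_area_compressibility(np.full(10, 4900.0), 310.0)


class TestStability:
    def test_no_escapes_is_stable(self, noisy_bilayer):
        traj, topo, _ = noisy_bilayer
        report = classify_stability(traj, topo)
        assert report.stable and report.escaped_lipids == []

    def test_injected_escape_is_detected_at_start_frame(self):
        spec = SyntheticBilayerSpec(
            n_lipids_per_leaflet=5, n_frames=80,
            escape_events=(EscapeEvent(lipid_id=3, start_frame=50, z_offset=30.0),),
            seed=2,
        )
        traj, topo, _ = make_bilayer_trajectory(spec)
        report = classify_stability(traj, topo, escape_margin=10.0, persistence=5)
        assert not report.stable
        assert report.escaped_lipids == [(3, 50)]

    def test_transient_excursion_survives_persistence_rule(self):
        spec = SyntheticBilayerSpec(n_lipids_per_leaflet=5, n_frames=40, seed=4)
        traj, topo, _ = make_bilayer_trajectory(spec)
        coords = traj.coords.copy()
        atoms = topo.atoms_of(2)
        coords[10, atoms, 2] += 40.0  # single-frame spike
        spiked = Trajectory(times=traj.times, coords=coords, box=traj.box)
        report = classify_stability(spiked, topo, persistence=5)
        assert report.stable
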