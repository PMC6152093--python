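import numpy as np
import pytest
from scipy import integrate
from scipy.spatial.transform import Rotation

import trajlens as tl
from trajlens.mmgbsa import (
    COULOMB_CONSTANT,
    GBSettings,
    born_radii,
    coulomb_energy,
    frame_binding_energy,
    gb_energy,
    lj_energy,
    nonpolar_energy,
    sasa,
)


def _pair():
    return (np.array([0]), np.array([1]))


class TestCoulomb:
    def test_unit_charges_at_scaled_distance(self):
        coords = np.array([[0.0, 0, 0], [3.320636, 0, 0]])
        e = coulomb_energy(coords, np.array([1.0, -1.0]), _pair())
        assert e == pytest.approx(-100.0, rel=1e-9)

    def test_zero_charge_partner_contributes_nothing(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert coulomb_energy(coords, np.array([1.0, 0.0]), _pair()) == 0.0

    def test_inverse_distance_scaling(self):
        q = np.array([0.5, 0.5])
        near = coulomb_energy(np.array([[0.0, 0, 0], [2.0, 0, 0]]), q, _pair())
        far = coulomb_energy(np.array([[0.0, 0, 0], [4.0, 0, 0]]), q, _pair())
        assert near == pytest.approx(2 * far, rel=1e-12)

    def test_coincident_pair_is_error(self):
        coords = np.zeros((2, 3))
        with pytest.raises(ValueError, match=r"pair \(0, 1\)"):
            coulomb_energy(coords, np.array([1.0, 1.0]), _pair())


class TestLennardJones:
    def test_minimum_is_minus_epsilon_at_rmin(self):
        rh = np.array([1.6, 1.8])
        eps = np.array([0.09, 0.16])
        coords = np.array([[0.0, 0, 0], [rh.sum(), 0, 0]])
        e = lj_energy(coords, rh, eps, _pair())
        assert e == pytest.approx(-np.sqrt(eps[0] * eps[1]), rel=1e-12)

    def test_vanishes_from_below_at_long_range(self):
        rh = np.array([1.7, 1.7])
        eps = np.array([0.1, 0.1])
        e = lj_energy(np.array([[0.0, 0, 0], [60.0, 0, 0]]), rh, eps, _pair())
        assert -1e-6 < e < 0

    def test_three_atom_sum_matches_term_by_term(self, rng):
        coords = rng.normal(size=(3, 3)) * 4
        rh = rng.uniform(1.4, 2.0, 3)
        eps = rng.uniform(0.05, 0.2, 3)
        pairs = (np.array([0, 0, 1]), np.array([1, 2, 2]))
        total = lj_energy(coords, rh, eps, pairs)
        by_hand = 0.0
        for i, j in zip(*pairs):
            r = np.linalg.norm(coords[i] - coords[j])
            rmin = rh[i] + rh[j]
            e = np.sqrt(eps[i] * eps[j])
            by_hand += e * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
        assert total == pytest.approx(by_hand, abs=1e-12)


def _descreening_quadrature(r, rho_i, a):
    """(1/4pi) integral of d^-4 over neighbour sphere outside atom i."""

    def inner(z):
        smax2 = a * a - (z - r) ** 2
        if smax2 <= 0:
            return 0.0
        smax = np.sqrt(smax2)
        smin = np.sqrt(rho_i**2 - z * z) if z * z < rho_i**2 else 0.0
        if smin >= smax:
            return 0.0
        v, _ = integrate.quad(
            lambda s: s / (z * z + s * s) ** 2, smin, smax, epsabs=1e-13
        )
        return v

    v, _ = integrate.quad(inner, r - a, r + a, epsabs=1e-13, limit=300)
    return 0.5 * v


class TestBornRadii:
    def test_isolated_atom_is_intrinsic_radius(self):
        rho = np.array([1.7])
        assert born_radii(np.zeros((1, 3)), rho, np.array([0.8]))[0] == 1.7

    def test_infinite_separation_limit(self):
        coords = np.array([[0.0, 0, 0], [1e6, 0, 0]])
        rho = np.array([1.5, 1.7])
        radii = born_radii(coords, rho, np.array([0.8, 0.8]))
        assert np.allclose(radii, rho, rtol=1e-9)

    @pytest.mark.parametrize(
        "r,rho_i,rho_j,s",
        [(4.0, 1.5, 1.5, 0.8), (2.0, 1.5, 1.5, 0.9), (0.3, 0.5, 1.6, 1.0)],
    )
    def test_matches_descreening_quadrature(self, r, rho_i, rho_j, s):
        coords = np.array([[0.0, 0, 0], [r, 0, 0]])
        radii = born_radii(coords, np.array([rho_i, rho_j]), np.array([s, s]))
        h = 1 / rho_i - 1 / radii[0]
        assert h == pytest.approx(
            _descreening_quadrature(r, rho_i, s * rho_j), abs=1e-6
        )

    def test_descreening_grows_radius(self):
        coords = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        rho = np.array([1.5, 1.7])
        radii = born_radii(coords, rho, np.array([0.8, 0.8]))
        assert np.all(radii > rho)


class TestGbEnergy:
    def test_single_ion_born_formula(self):
        q, a = 1.3, 2.1
        e = gb_energy(np.zeros((1, 3)), np.array([q]), np.array([a]))
        born = -0.5 * COULOMB_CONSTANT * (1 - 1 / 78.5) * q * q / a
        assert e == pytest.approx(born, rel=1e-12)

    def test_zero_charges_zero_energy(self):
        coords = np.random.default_rng(0).normal(size=(4, 3)) * 3
        e = gb_energy(coords, np.zeros(4), np.full(4, 1.5))
        assert e == 0.0

    def test_two_ion_term_by_term(self):
        r = 3.4
        coords = np.array([[0.0, 0, 0], [r, 0, 0]])
        q = np.array([0.8, -0.5])
        a = np.array([1.6, 1.9])
        pref = -0.5 * COULOMB_CONSTANT * (1 - 1 / 78.5)
        fgb = np.sqrt(r * r + a[0] * a[1] * np.exp(-r * r / (4 * a[0] * a[1])))
        by_hand = pref * (
            q[0] ** 2 / a[0] + q[1] ** 2 / a[1] + 2 * q[0] * q[1] / fgb
        )
        e = gb_energy(coords, q, a)
        assert e == pytest.approx(by_hand, abs=1e-10)

    def test_invalid_dielectric_is_error(self):
        with pytest.raises(ValueError):
            gb_energy(np.zeros((1, 3)), np.ones(1), np.ones(1), dielectric_in=0)


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        areas = sasa(np.zeros((1, 3)), np.array([1.7]), probe=1.4,
                     n_sphere_points=960)
        exact = 4 * np.pi * (1.7 + 1.4) ** 2
        assert abs(areas.sum() - exact) / exact < 0.01

    def test_far_spheres_are_additive(self):
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        radii = np.array([1.5, 2.0])
        areas = sasa(coords, radii)
        singles = [sasa(np.zeros((1, 3)), radii[i : i + 1]).sum() for i in range(2)]
        assert areas.sum() == pytest.approx(sum(singles), rel=1e-9)

    def test_two_intersecting_spheres_analytic(self):
        r, w, d = 1.7, 1.4, 2.0
        big = r + w
        areas = sasa(np.array([[0.0, 0, 0], [d, 0, 0]]), np.array([r, r]),
                     probe=w, n_sphere_points=960)
        cap = 2 * np.pi * big * (big - d / 2)
        analytic = 2 * (4 * np.pi * big**2 - cap)
        assert abs(areas.sum() - analytic) / analytic < 0.02

    def test_rigid_motion_exact_invariance(self, rng):
        coords = rng.normal(size=(6, 3)) * 3
        radii = rng.uniform(1.3, 1.9, 6)
        base = sasa(coords, radii)
        rot = Rotation.random(random_state=8).as_matrix()
        moved = coords @ rot.T + np.array([7.0, -2.0, 3.0])
        assert np.allclose(sasa(moved, radii), base, atol=1e-9)


class TestNonpolar:
    def test_affine_in_sasa(self):
        assert nonpolar_energy(0.0, 0.005, 0.7) == 0.7
        assert nonpolar_energy(1000.0, 0.005, 0.0) == pytest.approx(5.0)
        assert nonpolar_energy(400.0, 0.005, 0.0) == pytest.approx(
            2 * nonpolar_energy(200.0, 0.005, 0.0)
        )


class TestFrameBindingEnergy:
    def test_two_ion_assembled_term_oracle(self, two_ion):
        topo, params, traj = two_ion
        rec = tl.make_selection(topo, "chain A")
        lig = tl.make_selection(topo, "chain B")
        b = frame_binding_energy(traj.frames[0], rec, lig, params)
        coords = traj.frames[0]
        s = GBSettings()
        cross_coulomb = coulomb_energy(coords, params.charge, _pair())
        cross_lj = lj_energy(coords, params.lj_rmin_half, params.lj_epsilon, _pair())
        radii_c = born_radii(coords, params.gb_radius, params.gb_screen)
        gb_c = gb_energy(coords, params.charge, radii_c)
        gb_sep = sum(
            gb_energy(coords[i : i + 1], params.charge[i : i + 1],
                      params.gb_radius[i : i + 1])
            for i in range(2)
        )
        assert b.e_elec == pytest.approx(cross_coulomb, abs=1e-10)
        assert b.e_vdw == pytest.approx(cross_lj, abs=1e-10)
        assert b.g_gb == pytest.approx(gb_c - gb_sep, abs=1e-10)
        # SASA difference: both spheres partially buried in the complex
        assert b.g_sa < 0
        assert b.e_internal == 0.0
        assert b.total == pytest.approx(
            b.e_elec + b.e_vdw + b.g_gb + b.g_sa, abs=1e-12
        )

    def test_separated_ligand_all_terms_vanish(self):
        spec = tl.ToyComplexSpec(
            geometry="helix-pair", receptor_atoms=16, ligand_atoms=8,
            n_frames=1, seed=9, apolar_ligand=True,
        )
        topo, params, traj = tl.generate_toy_complex(spec)
        rec = tl.make_selection(topo, "chain A")
        lig = tl.make_selection(topo, "chain B")
        coords = traj.frames[0].copy()
        coords[lig.indices] += np.array([500.0, 0.0, 0.0])
        b = frame_binding_energy(coords, rec, lig, params)
        assert abs(b.e_elec) < 1e-6
        assert abs(b.e_vdw) < 1e-6
        assert abs(b.g_gb) < 1e-6
        assert abs(b.g_sa) < 1e-6
        assert abs(b.total) < 1e-6

    def test_charged_pair_decays_with_distance(self, two_ion):
        topo, params, traj = two_ion
        rec = tl.make_selection(topo, "chain A")
        lig = tl.make_selection(topo, "chain B")
        totals = []
        for sep in (5.0, 50.0, 500.0):
            coords = traj.frames[0].copy()
            coords[1] = [sep, 0.0, 0.0]
            totals.append(abs(frame_binding_energy(coords, rec, lig, params).total))
        assert totals[0] > totals[1] > totals[2]

    def test_rotation_translation_invariance(self, helix_pair):
        topo, params, traj = helix_pair
        rec = tl.make_selection(topo, "chain A")
        lig = tl.make_selection(topo, "chain B")
        b0 = frame_binding_energy(traj.frames[0], rec, lig, params)
        rot = Rotation.random(random_state=3).as_matrix()
        moved = traj.frames[0] @ rot.T + np.array([12.0, -5.0, 9.0])
        b1 = frame_binding_energy(moved, rec, lig, params)
        for term in ("e_elec", "e_vdw", "g_gb", "g_sa", "total"):
            assert getattr(b1, term) == pytest.approx(
                getattr(b0, term), abs=1e-9
            )

    def test_charge_antisymmetry(self, helix_pair):
        topo, params, traj = helix_pair
        rec = tl.make_selection(topo, "chain A")
        lig = tl.make_selection(topo, "chain B")
        b0 = frame_binding_energy(traj.frames[0], rec, lig, params)
        flipped = tl.EnergyParameters(
            charge=-params.charge,
            lj_rmin_half=params.lj_rmin_half,
            lj_epsilon=params.lj_epsilon,
            gb_radius=params.gb_radius,
            gb_screen=params.gb_screen,
        )
        b1 = frame_binding_energy(traj.frames[0], rec, lig, flipped)
        assert b1.e_elec == pytest.approx(b0.e_elec, abs=1e-12)
        assert b1.g_gb == pytest.approx(b0.g_gb, abs=1e-12)

    def test_overlapping_selections_rejected(self, helix_pair):
        topo, params, traj = helix_pair
        rec = tl.make_selection(topo, "chain A")
        with pytest.raises(ValueError, match="overlap"):
            frame_binding_energy(traj.frames[0], rec, rec, params)


class TestTrajectoryBindingEnergy:
    def test_constant_trajectory_zero_sd(self, two_ion):
        topo, params, _ = two_ion
        frames = np.repeat(topo.coordinates[None], 4, axis=0)
        traj = tl.Trajectory(frames=frames, times=np.arange(4.0), topology=topo)
        rec = tl.make_selection(topo, "chain A")
        lig = tl.make_selection(topo, "chain B")
        res = tl.trajectory_binding_energy(traj, rec, lig, params)
        assert res.sd == pytest.approx(0.0, abs=1e-12)
        single = frame_binding_energy(frames[0], rec, lig, params)
        assert res.mean == pytest.approx(single.total, abs=1e-12)

    def test_two_frame_population_statistics(self, two_ion):
        topo, params, traj = two_ion
        rec = tl.make_selection(topo, "chain A")
        lig = tl.make_selection(topo, "chain B")
        sub = tl.Trajectory(
            frames=traj.frames[:2], times=traj.times[:2], topology=topo
        )
        res = tl.trajectory_binding_energy(sub, rec, lig, params)
        a = frame_binding_energy(sub.frames[0], rec, lig, params).total
        b = frame_binding_energy(sub.frames[1], rec, lig, params).total
        assert res.mean == pytest.approx((a + b) / 2, abs=1e-12)
        assert res.sd == pytest.approx(abs(a - b) / 2, abs=1e-12)

    def test_empty_window_is_error(self, two_ion):
        topo, params, traj = two_ion
        rec = tl.make_selection(topo, "chain A")
        lig = tl.make_selection(topo, "chain B")
        with pytest.raises(ValueError, match="empty"):
            tl.trajectory_binding_energy(traj, rec, lig, params,
                                         start=traj.n_frames)

    def test_small_jitter_stays_near_ideal_value(self, two_ion):
        topo, params, traj = two_ion
        rec = tl.make_selection(topo, "chain A")
        lig = tl.make_selection(topo, "chain B")
        res = tl.trajectory_binding_energy(traj, rec, lig, params)
        ideal = frame_binding_energy(topo.coordinates, rec, lig, params).total
        assert abs(res.mean - ideal) < 1.0  # 0.02 Å jitter on a ~30 kcal term


class TestPerResidueDecomposition:
    def test_conservation_per_frame(self, helix_pair):
        topo, params, traj = helix_pair
        rec = tl.make_selection(topo, "chain A")
        lig = tl.make_selection(topo, "chain B")
        dec = tl.per_residue_decomposition(traj, rec, lig, params)
        be = tl.trajectory_binding_energy(traj, rec, lig, params)
        for fi, breakdown in enumerate(be.per_frame):
            assert dec.per_frame_totals[fi].sum() == pytest.approx(
                breakdown.total, abs=1e-6
            )
        assert dec.table["total"].sum() == pytest.approx(be.mean, abs=1e-6)

    def test_two_residue_hand_partition(self, two_ion):
        topo, params, traj = two_ion
        rec = tl.make_selection(topo, "chain A")
        lig = tl.make_selection(topo, "chain B")
        single = tl.Trajectory(
            frames=topo.coordinates[None], times=np.array([0.0]), topology=topo
        )
        dec = tl.per_residue_decomposition(single, rec, lig, params)
        b = frame_binding_energy(topo.coordinates, rec, lig, params)
        # two one-atom residues: cross terms split half-half
        assert np.allclose(dec.table["elec"], b.e_elec / 2, atol=1e-10)
        assert np.allclose(dec.table["vdw"], b.e_vdw / 2, atol=1e-10)
        assert dec.table["gb"].sum() == pytest.approx(b.g_gb, abs=1e-10)
        assert dec.table["sa"].sum() == pytest.approx(b.g_sa, abs=1e-10)

    def test_reporting_filter_keeps_large_contributors(self, two_ion):
        topo, params, traj = two_ion
        rec = tl.make_selection(topo, "chain A")
        lig = tl.make_selection(topo, "chain B")
        dec = tl.per_residue_decomposition(traj, rec, lig, params)
        sig = dec.significant(1.0)
        assert (sig["total"].abs() > 1.0).all()

    def test_uncharged_apolar_residue_with_unchanged_geometry(self):
        # an atom far from the interface, with zero charge and epsilon,
        # contributes nothing: its GB/SASA environment is unchanged too
        coords = np.array([
            [0.0, 0.0, 0.0],
            [200.0, 0.0, 0.0],  # spectator, same chain as receptor
            [4.0, 0.0, 0.0],
        ])
        topo = tl.Structure(
            atom_names=np.array(["NA", "C", "CL"], dtype=object),
            residue_ids=np.array([1, 2, 11]),
            residue_names=np.array(["ION", "SPEC", "ION"], dtype=object),
            chain_ids=np.array(["A", "A", "B"], dtype=object),
            coordinates=coords,
            masses=np.array([22.99, 12.011, 35.45]),
        )
        params = tl.EnergyParameters(
            charge=np.array([1.0, 0.0, -1.0]),
            lj_rmin_half=np.array([1.37, 1.7, 2.27]),
            lj_epsilon=np.array([0.0874, 0.0, 0.1]),
            gb_radius=np.array([1.5, 1.7, 1.7]),
            gb_screen=np.array([0.8, 0.8, 0.8]),
        )
        traj = tl.Trajectory(
            frames=coords[None], times=np.array([0.0]), topology=topo
        )
        rec = tl.make_selection(topo, "chain A")
        lig = tl.make_selection(topo, "chain B")
        dec = tl.per_residue_decomposition(traj, rec, lig, params)
        spectator = dec.table[dec.table["resid"] == 2]
        assert abs(spectator["total"].iloc[0]) < 1e-6
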