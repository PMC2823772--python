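import numpy as np
import pytest

from pbsalink.constants import COULOMB_K
from pbsalink.model_io import Atom, ParameterizedStructure
from pbsalink import pb, synth
from pbsalink.pb import (
    GridSpec,
    build_maps,
    charging_energy,
    elec_solvation_binding,
    focus,
    kappa2_bar,
    potential_difference_map,
    reaction_field_energy,
    solve_ladder,
    solve_lpbe,
    write_dx,
)


def _ion(q=1.0, r=2.0, pos=(0, 0, 0)):
    return ParameterizedStructure(
        [Atom(1, "ION", "ION", 1, "I", np.asarray(pos, float), charge=q,
              lj_epsilon=0.0, lj_rmin_half=r, pb_radius=r)]
    )


def _two_ions(q1, q2, d, r=2.0):
    return ParameterizedStructure(
        [
            Atom(1, "I1", "ION", 1, "I", [0.0, 0, 0], charge=q1, lj_epsilon=0.0,
                 lj_rmin_half=r, pb_radius=r),
            Atom(2, "I2", "ION", 2, "I", [d, 0.0, 0], charge=q2, lj_epsilon=0.0,
                 lj_rmin_half=r, pb_radius=r),
        ]
    )


SPEC = GridSpec((0, 0, 0), 33, 1.0)


class TestBuildMaps:
    def test_eps_map_inside_outside(self):
        maps = build_maps(_ion(), [0], SPEC, 1.0, 80.0, 0.0)
        ex, ey, ez = maps.eps_faces
        # a face deep inside the ion is at protein dielectric
        assert ex[16, 16, 16] == pytest.approx(1.0)
        # far corner faces see solvent
        assert ex[0, 0, 0] == pytest.approx(80.0)
        for f in (ex, ey, ez):
            assert f.min() >= 1.0 - 1e-12 and f.max() <= 80.0 + 1e-12

    def test_charge_conservation(self, toy):
        spec = GridSpec(tuple(toy.coords.mean(0)), 41, 1.2)
        maps = build_maps(toy, np.arange(len(toy)), spec)
        assert maps.charge_grid.sum() == pytest.approx(toy.net_charge, abs=1e-9)

    def test_kappa_zero_within_stern_layer(self):
        maps = build_maps(_ion(r=2.0), [0], SPEC, 1.0, 80.0, 150.0, stern=2.0)
        ax = maps.spec.axes()
        c = maps.spec.n // 2
        # node 3 Å from center: inside radius+stern=4 -> excluded
        k_in = maps.kappa2[c + 3, c, c]
        k_out = maps.kappa2[c + 10, c, c]
        assert k_in == 0.0
        assert k_out > 0.0

    def test_kappa2_matches_debye_length_from_si_constants(self):
        """Independent route: Debye length from SI constants at 150 mM,
        eps 80, 300 K; compare kbar2 / eps_w with 1/lambda_D^2."""
        from scipy import constants as si

        I = 150.0  # mol/m^3  (0.15 mol/L)
        eps_w = 80.0
        lam2 = (eps_w * si.epsilon_0 * si.k * 300.0) / (
            2 * si.N_A * si.e**2 * I
        )  # m^2
        lam2_A2 = lam2 * 1e20
        kappa2 = kappa2_bar(150.0) / eps_w
        assert kappa2 == pytest.approx(1.0 / lam2_A2, rel=1e-3)

    def test_charge_outside_grid_rejected(self):
        s = _ion(pos=(100, 0, 0))
        with pytest.raises(ValueError, match="outside grid"):
            build_maps(s, [0], SPEC)


class TestSolver:
    def test_zero_charges_give_zero_potential(self):
        s = _ion(q=0.0)
        maps = build_maps(s, [0], SPEC, 1.0, 80.0, 0.0)
        phi = solve_lpbe(maps, "zero")
        assert np.allclose(phi.values, 0.0)

    def test_point_charge_uniform_eps_matches_coulomb(self):
        """Uniform dielectric, no salt: interior potential approaches
        k q / (eps r) away from the source."""
        eps = 4.0
        s = _ion(q=1.0, r=0.5)
        maps = build_maps(s, [0], SPEC, eps, eps, 0.0)
        phi = solve_lpbe(maps, "debye-huckel-sum")
        interp = phi.interpolator()
        for r in (4.0, 6.0, 8.0):
            val = float(interp([[r, 0.0, 0.0]])[0])
            assert val == pytest.approx(COULOMB_K / (eps * r), rel=0.02)

    def test_linearity_in_source_charge(self):
        maps_p = build_maps(_ion(q=1.0), [0], SPEC)
        maps_m = build_maps(_ion(q=-1.0), [0], SPEC)
        phi_p = solve_lpbe(maps_p, "zero")
        phi_m = solve_lpbe(maps_m, "zero")
        np.testing.assert_allclose(phi_m.values, -phi_p.values, atol=1e-10)

    def test_superposition_of_sources(self):
        s12 = _two_ions(0.7, -0.4, 6.0)
        m12 = build_maps(s12, [0, 1], SPEC)
        m1 = build_maps(s12, [0], SPEC)
        m2 = build_maps(s12, [1], SPEC)
        # identical dielectric geometry for all three solves
        m1 = pb.DielectricMaps(m12.spec, m12.eps_faces, m12.kappa2,
                               m1.charge_grid, 1.0, 80.0,
                               m1.source_positions, m1.source_charges)
        m2 = pb.DielectricMaps(m12.spec, m12.eps_faces, m12.kappa2,
                               m2.charge_grid, 1.0, 80.0,
                               m2.source_positions, m2.source_charges)
        p12 = solve_lpbe(m12, "zero", tol=1e-9)
        p1 = solve_lpbe(m1, "zero", tol=1e-9)
        p2 = solve_lpbe(m2, "zero", tol=1e-9)
        np.testing.assert_allclose(p12.values, p1.values + p2.values, atol=1e-6)

    def test_deterministic(self):
        maps = build_maps(_ion(), [0], SPEC)
        a = solve_lpbe(maps).values
        b = solve_lpbe(maps).values
        assert np.array_equal(a, b)


class TestFocusingAndEnergies:
    def test_child_equal_parent_unchanged(self):
        maps = build_maps(_ion(), [0], SPEC)
        phi = solve_lpbe(maps, "debye-huckel-sum", tol=1e-8)
        phi2 = focus(phi, maps, tol=1e-8)
        assert np.allclose(phi.values, phi2.values, atol=1e-4)

    def test_child_outside_parent_rejected(self):
        maps = build_maps(_ion(), [0], SPEC)
        phi = solve_lpbe(maps)
        big = build_maps(_ion(), [0], GridSpec((0, 0, 0), 33, 2.0))
        with pytest.raises(ValueError, match="inside the parent"):
            focus(phi, big)

    def test_born_ladder_converges_toward_analytic(self):
        s, analytic = synth.born_fixture(1.0, 2.0)
        errors = []
        ladders = [
            [GridSpec((0, 0, 0), 33, 2.0)],
            [GridSpec((0, 0, 0), 33, 2.0), GridSpec((0, 0, 0), 33, 1.0)],
            [GridSpec((0, 0, 0), 33, 2.0), GridSpec((0, 0, 0), 33, 1.0),
             GridSpec((0, 0, 0), 33, 0.5)],
        ]
        for specs in ladders:
            w = reaction_field_energy(s, [0], specs, 1.0, 80.0, 0.0)
            errors.append(abs(w - analytic))
        assert errors[2] < errors[1] < errors[0]

    def test_four_step_ladder_runs_and_refines(self):
        s, analytic = synth.born_fixture(1.0, 2.0)
        specs = [GridSpec((0, 0, 0), 33, h) for h in (2.0, 1.0, 0.5, 0.25)]
        w = reaction_field_energy(s, [0], specs, 1.0, 80.0, 0.0)
        assert w == pytest.approx(analytic, rel=0.02)

    def test_charging_energy_quadratic_in_charge(self):
        s1, _ = synth.born_fixture(1.0, 2.0)
        s2, _ = synth.born_fixture(2.0, 2.0)
        specs = [GridSpec((0, 0, 0), 33, 1.0)]
        w1 = reaction_field_energy(s1, [0], specs, 1.0, 80.0, 0.0)
        w2 = reaction_field_energy(s2, [0], specs, 1.0, 80.0, 0.0)
        assert w2 == pytest.approx(4 * w1, rel=1e-6)

    def test_charging_energy_zero_for_zero_charge(self):
        s, _ = synth.born_fixture(0.0, 2.0)
        maps = build_maps(s, [0], SPEC, 1.0, 80.0, 0.0)
        phi = solve_lpbe(maps, "zero")
        assert charging_energy(phi, maps) == 0.0

    def test_mismatched_grids_rejected(self):
        maps = build_maps(_ion(), [0], SPEC)
        phi = solve_lpbe(maps)
        other = build_maps(_ion(), [0], GridSpec((0, 0, 0), 33, 0.9))
        with pytest.raises(ValueError, match="different grids"):
            charging_energy(phi, other)


class TestSolvationBinding:
    def test_far_separated_groups_bind_nothing(self):
        s = _two_ions(1.0, -1.0, 55.0)
        specs = [GridSpec((27.5, 0, 0), 41, 2.0), GridSpec((27.5, 0, 0), 41, 1.75)]
        w = elec_solvation_binding(s, [0], [1], specs, 1.0, 80.0, 0.0)
        assert abs(w) < 0.6  # residual grid noise only

    def test_born_solvation_through_binding_route(self):
        s, analytic = synth.born_fixture(1.0, 2.0)
        specs = [GridSpec((0, 0, 0), 41, h) for h in (2.0, 1.0, 0.5, 0.25)]
        w = reaction_field_energy(s, [0], specs, 1.0, 80.0, 0.0)
        assert w == pytest.approx(analytic, rel=0.02)

    def test_opposite_charges_at_6A_self_convergence(self):
        """Binding electrostatics of a +/- pair brought to 6 Å in water:
        the production ladder agrees with a 0.125 Å high-resolution
        reference solve within 5%."""
        s = _two_ions(1.0, -1.0, 6.0)
        prod = [GridSpec((3, 0, 0), 33, 1.5), GridSpec((3, 0, 0), 33, 0.75),
                GridSpec((3, 0, 0), 33, 0.375), GridSpec((3, 0, 0), 45, 0.25)]
        ref = prod + [GridSpec((3, 0, 0), 81, 0.125)]
        w_p = elec_solvation_binding(s, [0], [1], prod, 1.0, 80.0, 0.0)
        w_r = elec_solvation_binding(s, [0], [1], ref, 1.0, 80.0, 0.0)
        assert w_p == pytest.approx(w_r, rel=0.05)

    def test_grid_too_small_rejected(self, toy):
        a, b = toy.groups["A"], toy.groups["B"]
        with pytest.raises(ValueError, match="margin"):
            elec_solvation_binding(toy, a, b, [GridSpec((0, 0, 0), 9, 1.0)])


class TestDifferenceMap:
    def test_identical_models_give_zero_map(self):
        s = _ion()
        specs = [GridSpec((0, 0, 0), 21, 1.0), GridSpec((0, 0, 0), 21, 0.5)]
        d = potential_difference_map(s, [0], s, [0], specs, 1.0, 80.0, 0.0)
        assert np.allclose(d.values, 0.0, atol=1e-10)

    def test_difference_of_2q_and_q_equals_phi_of_q(self):
        s1 = _ion(q=2.0)
        s2 = _ion(q=1.0)
        specs = [GridSpec((0, 0, 0), 21, 1.0)]
        d = potential_difference_map(s1, [0], s2, [0], specs, 1.0, 80.0, 0.0)
        phi_q, _ = solve_ladder(s2, [0], specs, 1.0, 80.0, 0.0)
        np.testing.assert_allclose(d.values, phi_q.values, atol=1e-6)

    def test_distant_extra_charge_barely_alters_window(self):
        """Adding a charge ~25 Å from a small focused window (150 mM salt)
        perturbs the window potential by far less than the isosurface
        level used for display (1 kcal/(mol e))."""
        s1 = _two_ions(1.0, 1.0, 25.0)
        s2 = _ion(1.0)
        specs = [GridSpec((0, 0, 0), 61, 1.0), GridSpec((0, 0, 0), 21, 0.4)]
        phi1, _ = solve_ladder(s1, [0, 1], specs, 1.0, 80.0, 150.0)
        phi2, _ = solve_ladder(s2, [0], specs, 1.0, 80.0, 150.0)
        diff = np.abs(phi1.values - phi2.values)
        assert diff.max() < 0.2


def test_write_dx_round_numbers(tmp_path):
    maps = build_maps(_ion(), [0], GridSpec((0, 0, 0), 9, 2.0), 1.0, 80.0, 0.0)
    phi = solve_lpbe(maps, "zero")
    p = tmp_path / "grid.dx"
    write_dx(phi, p)
    text = p.read_text()
    assert "gridpositions counts 9 9 9" in text
    assert "items 729" in text
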