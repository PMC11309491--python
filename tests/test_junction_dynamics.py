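"""Front/back junction springs and supracellular actin torques."""

import numpy as np
import pytest

from cellalign.engine import ModelParams, Population, simulate
from cellalign.junction_dynamics import (Junction, actin_rotation_term,
                                         bending_energy, cell_endpoints,
                                         find_junctions, junction_rotation_term,
                                         junction_translation_term,
                                         junctions_of)
from cellalign.experiments import two_cell_fixture

SQ2 = np.sqrt(2.0)


def make_cell(x, y, alpha, r, box=20.0):
    return Population(np.array([[x, y]], float), np.array([float(alpha)]),
                      np.array([float(r)]), box).cells()[0]


class TestCellEndpoints:
    def test_r2_cell_along_x(self):
        front, back = cell_endpoints(make_cell(0, 0, 0.0, 2.0))
        assert front == pytest.approx((SQ2, 0.0))
        assert back == pytest.approx((-SQ2, 0.0))

    def test_unit_circle_vertical(self):
        front, back = cell_endpoints(make_cell(1, 1, np.pi / 2, 1.0))
        assert front == pytest.approx((1.0, 2.0))
        assert back == pytest.approx((1.0, 0.0))

    def test_alpha_plus_pi_swaps_front_and_back(self, rng):
        for _ in range(10):
            x, y, al, r = rng.uniform(2, 18), rng.uniform(2, 18), \
                rng.uniform(0, 2 * np.pi), rng.uniform(1, 4)
            f1, b1 = cell_endpoints(make_cell(x, y, al, r))
            f2, b2 = cell_endpoints(make_cell(x, y, al + np.pi, r))
            assert f1 == pytest.approx(b2) and b1 == pytest.approx(f2)


class TestFindJunctions:
    def test_collinear_pair_forms_one_fb_junction(self):
        pop = two_cell_fixture("fb_junction_pair")
        jns = find_junctions(pop, 0.2, pop.box)
        assert len(jns) == 1
        (jn,) = jns
        assert jn.type == "fb"
        assert {(jn.i, jn.end_i), (jn.j, jn.end_j)} == {(0, "front"), (1, "back")}
        assert np.linalg.norm(jn.separation) == pytest.approx(0.1)

    def test_below_range_no_junction(self):
        pop = two_cell_fixture("fb_junction_pair")
        assert find_junctions(pop, 0.05, pop.box) == []

    def test_three_cell_chain_degrees(self):
        gap = 0.1
        dx = 2 * SQ2 + gap
        pop = Population(np.array([[3.0, 5.0], [3.0 + dx, 5.0],
                                   [3.0 + 2 * dx, 5.0]]),
                         np.zeros(3), np.full(3, 2.0), 20.0)
        jns = find_junctions(pop, 0.2, pop.box)
        assert len(jns) == 2 and all(j.type == "fb" for j in jns)
        deg = {i: sum(1 for j in jns if i in (j.i, j.j)) for i in range(3)}
        assert deg == {0: 1, 1: 2, 2: 1}

    def test_stateless_and_idempotent(self):
        pop = two_cell_fixture("ff_junction_pair")
        a = find_junctions(pop, 0.3, pop.box)
        b = find_junctions(pop, 0.3, pop.box)
        assert len(a) == len(b) == 1
        assert (a[0].i, a[0].end_i, a[0].j, a[0].end_j, a[0].type) == \
            (b[0].i, b[0].end_i, b[0].j, b[0].end_j, b[0].type)
        assert np.array_equal(a[0].separation, b[0].separation)


class TestJunctionTerms:
    def fb(self, sep, end_i="front"):
        return Junction(0, end_i, 1, "back", "fb", np.asarray(sep, float))

    def test_translation_single_junction(self):
        assert junction_translation_term([self.fb((0.1, 0.0))], 1.0) == \
            pytest.approx((0.1, 0.0))

    def test_translation_no_junctions(self):
        assert junction_translation_term([], 2.0) == pytest.approx((0.0, 0.0))

    def test_translation_cancellation(self):
        jns = [self.fb((0.1, 0.0)), self.fb((-0.1, 0.0))]
        assert junction_translation_term(jns, 2.0) == pytest.approx((0.0, 0.0))

    def test_rotation_parallel_separation_no_torque(self):
        assert junction_rotation_term([self.fb((0.1, 0.0))], 2.0, 0.0, 1.0) \
            == pytest.approx(0.0)

    def test_rotation_front_attachment(self):
        # r=1, κ=1, sep=(0,0.1) ⊥ e(0): (4·1/2)·0.1 = 0.2
        assert junction_rotation_term([self.fb((0.0, 0.1))], 1.0, 0.0, 1.0) \
            == pytest.approx(0.2)

    def test_rotation_back_attachment_flips_sign(self):
        jn = Junction(0, "back", 1, "front", "fb", np.array([0.0, 0.1]))
        assert junction_rotation_term([jn], 1.0, 0.0, 1.0) == pytest.approx(-0.2)


class TestActinTorque:
    def test_aligned_fb_pair_no_torque(self):
        jn = Junction(0, "front", 1, "back", "fb", np.zeros(2))
        assert actin_rotation_term([jn], 1.0, 0.7, np.array([0.0, 0.7]), 1.0) \
            == pytest.approx(0.0)

    def test_fb_rotates_toward_partner(self):
        jn = Junction(0, "front", 1, "back", "fb", np.zeros(2))
        got = actin_rotation_term([jn], 1.0, np.pi / 2, np.array([0.0, 0.0]),
                                  1.0)
        assert got == pytest.approx(-0.5)

    def test_ff_antipolar_equilibrium(self):
        jn = Junction(0, "front", 1, "front", "ffbb", np.zeros(2))
        assert actin_rotation_term([jn], 1.0, np.pi, np.array([0.0, 0.0]), 1.0) \
            == pytest.approx(0.0, abs=1e-12)

    def test_torque_is_gradient_of_bending_energy(self, rng):
        """The actin torque equals -(4r/(r²+1))·∂E_bend/∂α_i with the cable
        bending strength m = μ·a/2 (finite differences, both fb and ff/bb)."""
        h = 1e-7
        for _ in range(50):
            ai_, aj_ = rng.uniform(0, 2 * np.pi, 2)
            r = rng.uniform(1, 4)
            mu = rng.uniform(0.1, 5)
            a = np.sqrt(r)
            m = mu * a / 2.0
            for jtype in ("fb", "ffbb"):
                jn = Junction(0, "front", 1,
                              "back" if jtype == "fb" else "front",
                              jtype, np.zeros(2))
                got = actin_rotation_term([jn], r, ai_, np.array([0.0, aj_]),
                                          mu)
                dE = (bending_energy(ai_ + h, aj_, a, m, jtype)
                      - bending_energy(ai_ - h, aj_, a, m, jtype)) / (2 * h)
                want = -4.0 * r / (r ** 2 + 1.0) * dE
                assert abs(got - want) < 1e-6 * max(abs(got), 1e-3)


class TestBendingEnergy:
    @pytest.mark.parametrize("ai_, aj_, a, m, jtype, expected", [
        (0.3, 0.3, 1.0, 1.0, "fb", 0.0),
        (0.0, np.pi / 2, SQ2, 1.0, "fb", 2.0 / (4 * SQ2)),
        (0.0, np.pi, 1.3, 2.0, "ffbb", 0.0),
    ])
    def test_examples(self, ai_, aj_, a, m, jtype, expected):
        assert bending_energy(ai_, aj_, a, m, jtype) == pytest.approx(
            expected, abs=1e-12)


class TestTwoCellRelaxation:
    def test_fb_pair_converges_to_common_orientation(self):
        """Two cells joined front-to-back under junction + actin terms only
        relax to α1 = α2 with coincident connection points."""
        r, kappa, mu, dt = 2.0, 1.0, 1.0, 0.01
        a = np.sqrt(r)
        X = np.array([[0.0, 0.0], [2 * a + 0.05, 0.3]])
        alpha = np.array([0.15, -0.1])
        for _ in range(5000):   # T = 50
            e = np.stack([np.cos(alpha), np.sin(alpha)], axis=1)
            ep = np.stack([-np.sin(alpha), np.cos(alpha)], axis=1)
            p1 = X[0] + a * e[0]     # front of cell 1
            p2 = X[1] - a * e[1]     # back of cell 2
            sep = p2 - p1
            dX = np.array([kappa * sep, -kappa * sep])
            pref = 4 * kappa * r ** 1.5 / (r ** 2 + 1)
            ac = mu * r / (r ** 2 + 1)
            dal = np.array([
                pref * (sep @ ep[0]) - ac * np.sin(alpha[0] - alpha[1]),
                pref * (-sep @ (-ep[1])) - ac * np.sin(alpha[1] - alpha[0]),
            ])
            X += dt * dX
            alpha += dt * dal
        assert abs(alpha[0] - alpha[1]) < 1e-3
        p1 = X[0] + a * np.array([np.cos(alpha[0]), np.sin(alpha[0])])
        p2 = X[1] - a * np.array([np.cos(alpha[1]), np.sin(alpha[1])])
        assert np.linalg.norm(p1 - p2) < 1e-3


class TestReductionToBaseModel:
    def test_kappa_mu_zero_reproduces_base_trajectories_bitwise(self):
        base = ModelParams(nu=0.4, n_cells=16, box=8.0, t_end=5.0, seed=11,
                           r_init=2.0)
        withj = ModelParams(nu=0.4, n_cells=16, box=8.0, t_end=5.0, seed=11,
                            r_init=2.0, junctions_on=True, kappa=0.0, mu=0.0,
                            lam=0.2)
        t1, t2 = simulate(base), simulate(withj)
        for f1, f2 in zip(t1.frames, t2.frames):
            assert np.array_equal(f1.X, f2.X)
            assert np.array_equal(f1.alpha, f2.alpha)
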