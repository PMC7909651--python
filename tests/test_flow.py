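"""Poiseuille relations and the nodal flow solver against hand oracles.

The initial A-branch admits a closed-form series-parallel reduction: with
all 40 segments at the same conductance G_seg, the network resistance is
(5 + 10*20/(10+20) + 5) segment resistances, giving per-segment pressure
drops of 6/4/2 Pa (feeding & draining / proximal / distal) under 100 Pa.
"""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import flowmigrate as fm

W = 5e-6
MU = 0.0035
L = 1e-5

# frozen hand-oracle values for n = 8 cells
G8 = 8**4 * W**4 / (128 * np.pi**3 * MU * L)  # 1.84295e-14 m^3/s/Pa
Q_IN = 6.0 * G8  # 1.10577e-13 m^3/s


class TestConstitutive:
    @pytest.mark.parametrize(
        "n,expected",
        [(0, 0.0), (8, 1.2732395447e-5), (16, 2.5464790895e-5)],
    )
    def test_lumen_diameter(self, n, expected):
        assert fm.lumen_diameter(n, W) == pytest.approx(expected, rel=1e-9)

    def test_conductance_value_and_floor(self):
        assert fm.segment_conductance(8, W, MU, L) == pytest.approx(1.843e-14, rel=1e-3)
        assert fm.segment_conductance(0, W, MU, L) == fm.ZERO_LUMEN_CONDUCTANCE
        # quartic scaling
        ratio = fm.segment_conductance(2, W, MU, L) / fm.segment_conductance(1, W, MU, L)
        assert ratio == pytest.approx(16.0)

    def test_resistance_reciprocal_and_errors(self):
        for n in range(1, 21):
            rg = fm.resistance(n, W, MU, L) * fm.segment_conductance(n, W, MU, L)
            assert rg == pytest.approx(1.0, rel=1e-14)
        assert fm.resistance(8, W, MU, L) == pytest.approx(5.426e13, rel=1e-3)
        with pytest.raises(ZeroDivisionError):
            fm.resistance(0, W, MU, L)

    @pytest.mark.parametrize(
        "n,dp,expected",
        [(8, 6.0, 1.9098593), (8, -6.0, 1.9098593), (0, 10.0, 0.0)],
    )
    def test_wall_shear_stress(self, n, dp, expected):
        assert fm.segment_wss(n, W, L, dp) == pytest.approx(expected, rel=1e-6)

    @given(st.integers(1, 50), st.floats(0.1, 100.0))
    def test_wss_linear_in_n_at_fixed_dp(self, n, dp):
        assert fm.segment_wss(2 * n, W, L, dp) == pytest.approx(
            2 * fm.segment_wss(n, W, L, dp)
        )


class TestSolver:
    def test_series_parallel_oracle(self, a_branch, initial_flow):
        st_ = initial_flow
        for lab, dp_expected in [
            ("feeding", 6.0), ("proximal", 4.0), ("distal", 2.0), ("draining", 6.0),
        ]:
            segs = a_branch.branch_order[lab]
            assert np.abs(st_.dp[segs]) == pytest.approx(
                np.full(len(segs), dp_expected), rel=1e-9
            )
        assert st_.q[0] == pytest.approx(Q_IN, rel=1e-9)

    def test_boundary_pressures_exact(self, a_branch, initial_flow):
        assert initial_flow.p[a_branch.inlet_nodes[0]] == 100.0
        assert initial_flow.p[a_branch.outlet_node] == 0.0

    def test_flow_conservation(self, a_branch, initial_flow):
        assert initial_flow.max_relative_imbalance(a_branch) <= 1e-10

    def test_q_equals_minus_G_dp(self, initial_flow):
        np.testing.assert_allclose(
            initial_flow.q, -initial_flow.G * initial_flow.dp, rtol=1e-12
        )

    def test_convergent_shear_ratio_two_to_one(self, a_branch, initial_flow):
        b1, b2 = a_branch.convergent_branch_segments
        assert initial_flow.tau[b1] / initial_flow.tau[b2] == pytest.approx(2.0)
        assert initial_flow.tau[b1] == pytest.approx(2 * 1.9098593 / 3, rel=1e-6)

    def test_initial_shear_in_physiological_range(self, a_branch, initial_flow):
        # feeding and proximal sit in the 1-5 Pa regime the BCs target
        for lab in ("feeding", "proximal"):
            taus = initial_flow.tau[a_branch.branch_order[lab]]
            assert np.all((taus >= 1.0) & (taus <= 5.0))
        distal = initial_flow.tau[a_branch.branch_order["distal"]]
        assert np.all(distal < initial_flow.tau[a_branch.branch_order["proximal"]].min())

    def test_zero_driving_pressure_gives_zero_flow(self, a_branch):
        st_ = fm.solve_flow(a_branch, fm.PressureBC(50.0, 50.0))
        np.testing.assert_allclose(st_.q, 0.0, atol=1e-25)
        np.testing.assert_allclose(st_.tau, 0.0, atol=1e-20)

    def test_removing_cells_increases_branch_pressure_drop(self, a_branch, initial_flow):
        b1, _ = a_branch.convergent_branch_segments
        net = a_branch.copy()
        net.n[b1] = 4
        st_ = fm.solve_flow(net)
        assert abs(st_.dp[b1]) > abs(initial_flow.dp[b1])

    def test_inlet_flow_bc_reproduces_pressure_driven_state(self, a_branch, initial_flow):
        st_ = fm.solve_flow(a_branch, fm.InletFlowBC(q_in=float(initial_flow.q[0]), p_out=0.0))
        np.testing.assert_allclose(st_.dp, initial_flow.dp, rtol=1e-9, atol=1e-12)
        assert st_.max_relative_imbalance(a_branch) <= 1e-10

    def test_ten_x_distal_gives_ten_to_one_shear(self, params):
        net = fm.build_a_branch(params, 10)
        st_ = fm.solve_flow(net)
        b1, b2 = net.convergent_branch_segments
        assert st_.tau[b1] / st_.tau[b2] == pytest.approx(10.0, rel=1e-9)

    def test_empty_branch_still_solvable_via_floor(self, params):
        net = fm.build_y_branch(params)
        net.n[net.branch_order["left"]] = 0
        st_ = fm.solve_flow(net)
        assert np.all(np.isfinite(st_.p))
        # the dead branch carries only the floor-conductance trickle
        dead = net.branch_order["left"][0]
        alive = net.branch_order["right"][0]
        assert abs(st_.q[dead]) < 1e-6 * abs(st_.q[alive])


class TestYBranchFlow:
    def test_equal_pressures_give_equal_shear(self, params):
        net = fm.build_y_branch(params)
        st_ = fm.solve_flow(net)
        l1, l2 = net.convergent_branch_segments
        assert st_.tau[l1] == pytest.approx(st_.tau[l2], rel=1e-9)
        ptau = fm.shear_probability(float(st_.tau[l1]), float(st_.tau[l2]))
        assert ptau == pytest.approx((0.5, 0.5))

    @pytest.mark.parametrize("ratio", [10.0, 20.0])
    def test_inlet_flow_ratio_sets_initial_shear_ratio(self, params, ratio):
        net = fm.build_y_branch(params, inlet_flow_ratio=ratio)
        st_ = fm.solve_flow(net)
        l1, l2 = net.convergent_branch_segments
        assert st_.tau[l1] / st_.tau[l2] == pytest.approx(ratio, rel=1e-9)
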