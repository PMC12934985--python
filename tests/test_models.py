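"""Colonization-model unit and property tests: closed-form oracles,
conservation laws, symmetry, and derived milestones."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microdev.models import (
    InvalidParameterError,
    LinearSourceParams,
    LogisticParams,
    SolverConfig,
    Trajectory,
    TwoPopParams,
    UnsupportedModelError,
    VolumeParams,
    doubling_time,
    environmental_factor,
    predict_observables,
    rhs_linear_source,
    rhs_logistic,
    rhs_two_population,
    simulate_model,
    subpopulation_fractions,
    switch_time,
    volume_trajectory,
)
from microdev.topology import RegionTopology


class TestVolume:
    def test_initial_condition(self):
        vp = VolumeParams(v0=2.0, v_inf=4.0, g=0.7)
        assert volume_trajectory(vp, 0.0) == pytest.approx(2.0)

    def test_frozen_growth(self):
        vp = VolumeParams(v0=1.5, v_inf=1.5, g=0.0)
        t = np.linspace(0, 50, 7)
        assert volume_trajectory(vp, t) == pytest.approx(np.full(7, 1.5))

    def test_logistic_closed_form(self):
        # V(t) = v_inf v0 e^{gt} / (v_inf + v0 (e^{gt} - 1)), v0=1, v_inf=4, g=1, t=2
        expected = 4 * 1 * np.exp(2) / (4 + 1 * (np.exp(2) - 1))
        assert volume_trajectory(VolumeParams(1, 4, 1), 2.0) == pytest.approx(expected, rel=1e-12)

    def test_monotone_and_saturating(self):
        vp = VolumeParams(0.5, 3.0, 0.4)
        t = np.linspace(0, 40, 200)
        v = volume_trajectory(vp, t)
        assert np.all(np.diff(v) >= 0)
        assert v[-1] == pytest.approx(3.0, rel=1e-5)

    @pytest.mark.parametrize("bad", [dict(v0=-1, v_inf=2, g=1), dict(v0=1, v_inf=-2, g=1),
                                     dict(v0=2, v_inf=1, g=1), dict(v0=1, v_inf=2, g=-0.1)])
    def test_invalid_parameters(self, bad):
        with pytest.raises(InvalidParameterError):
            VolumeParams(**bad)


class TestEnvironmentalFactor:
    @pytest.mark.parametrize("v,ref,expected", [(3.0, 3.0, 1.0), (0.0, 2.0, 0.0), (1.0, 2.0, 0.5)])
    def test_normalization(self, v, ref, expected):
        assert environmental_factor(v, ref) == expected

    def test_invalid_reference(self):
        with pytest.raises(InvalidParameterError):
            environmental_factor(1.0, 0.0)


class TestRightHandSides:
    def test_logistic_zero_growth_at_equilibrium(self, single_layer_topo, const_volume):
        # M = kappa / V is the equilibrium density: pure growth term vanishes
        p = LogisticParams(r=1.3, kappa=4.0, c=0.0, m0={"L": 1.0}, volume=const_volume)
        d = rhs_logistic(np.array([4.0 / 2.0]), 0.0, p, single_layer_topo)
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_extinction_absorbing(self, chain_topo):
        vol = {l: VolumeParams(1.0, 1.0, 0.0) for l in chain_topo.layers}
        p = LogisticParams(r=2.0, kappa=5.0, c=0.3, m0={}, volume=vol,
                           beta={("a", "b"): 0.5, ("b", "c"): 0.5})
        d = rhs_logistic(np.zeros(3), 1.0, p, chain_topo)
        assert np.all(d == 0)

    def test_linear_balanced_birth_death(self, single_layer_topo, const_volume):
        p = LinearSourceParams(p=0.7, c=0.7, s0={"L": 0.0}, lam=1.0, m0={"L": 5.0},
                               volume=const_volume)
        d = rhs_linear_source(np.array([5.0]), 2.0, p, single_layer_topo)
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_state_shape_mismatch(self, chain_topo):
        vol = {l: VolumeParams(1.0, 1.0, 0.0) for l in chain_topo.layers}
        p = LogisticParams(r=1.0, kappa=1.0, c=0.0, m0={}, volume=vol)
        with pytest.raises(ValueError, match="state"):
            rhs_logistic(np.zeros(2), 0.0, p, chain_topo)

    def test_two_pop_all_rates_zero_constant(self, single_layer_topo, const_volume):
        p = TwoPopParams(A0={"L": 3.0}, B0={"L": 1.0}, volume=const_volume)
        d = rhs_two_population(np.array([3.0, 1.0]), 0.5, p, single_layer_topo)
        assert np.all(d == 0)


class TestSolverOracles:
    """The three closed-form integration cases, through the full solver."""

    T_GRID = np.linspace(0.0, 1.0, 11)

    def test_logistic_closed_form(self, single_layer_topo, const_volume):
        # single layer, c=0, constant V=2, kappa=4 -> K = 2; r=1, M0=1, t=1
        p = LogisticParams(r=1.0, kappa=4.0, c=0.0, m0={"L": 1.0}, volume=const_volume)
        traj = simulate_model("logistic", p, single_layer_topo, self.T_GRID)
        expected = 2 * np.e / (1 + np.e)
        assert traj.M[0, -1] == pytest.approx(expected, rel=1e-6)

    def test_linear_source_closed_form(self, single_layer_topo, const_volume):
        # p=0, c=1, s0=1, lam=2, M0=0 -> M(t) = e^{-t} - e^{-2t}
        p = LinearSourceParams(p=0.0, c=1.0, s0={"L": 1.0}, lam=2.0, m0={"L": 0.0},
                               volume=const_volume)
        traj = simulate_model("linear", p, single_layer_topo, self.T_GRID)
        assert traj.M[0, -1] == pytest.approx(np.exp(-1) - np.exp(-2), rel=1e-6)

    def test_two_pop_decoupled_closed_form(self, single_layer_topo, decoupled_two_pop):
        # A(t) = e^{0.2 t}; B(t) = e^{0.2 t} - 1 (a1_B = c_B = 0)
        grid = np.linspace(0, 5, 26)
        traj = simulate_model("two_pop", decoupled_two_pop, single_layer_topo, grid)
        assert traj.A[0, -1] == pytest.approx(np.e, rel=1e-6)
        assert traj.B[0, -1] == pytest.approx(np.e - 1, rel=1e-6)

    def test_tolerance_halving_self_consistency(self, single_layer_topo, const_volume):
        p = LogisticParams(r=1.0, kappa=4.0, c=0.0, m0={"L": 1.0}, volume=const_volume)
        a = simulate_model("logistic", p, single_layer_topo, self.T_GRID,
                           SolverConfig(rtol=1e-8, atol=1e-10))
        b = simulate_model("logistic", p, single_layer_topo, self.T_GRID,
                           SolverConfig(rtol=5e-9, atol=5e-11))
        assert np.max(np.abs(a.M - b.M) / (np.abs(b.M) + 1e-12)) < 1e-6

    def test_fixed_grid_fast_path_matches_bdf(self, single_layer_topo, decoupled_two_pop):
        grid = np.linspace(0, 5, 26)
        ref = simulate_model("two_pop", decoupled_two_pop, single_layer_topo, grid,
                             SolverConfig(rtol=1e-10, atol=1e-12))
        fast = simulate_model("two_pop", decoupled_two_pop, single_layer_topo, grid,
                              SolverConfig(method="RK4"))
        assert np.max(np.abs(ref.M - fast.M) / (np.abs(ref.M) + 1e-12)) < 1e-6

    def test_zero_rates_constant_trajectory(self, single_layer_topo, const_volume):
        p = TwoPopParams(A0={"L": 7.0}, B0={"L": 2.0}, volume=const_volume)
        traj = simulate_model("two_pop", p, single_layer_topo, self.T_GRID)
        assert np.allclose(traj.A, 7.0) and np.allclose(traj.B, 2.0)

    def test_bad_grid_rejected(self, single_layer_topo, const_volume):
        p = TwoPopParams(A0={"L": 1.0}, volume=const_volume)
        with pytest.raises(ValueError):
            simulate_model("two_pop", p, single_layer_topo, np.array([1.0, 0.5]))


class TestConservationAndBounds:
    def test_spreading_conserves_total_count(self, chain_topo):
        # frozen volumes, no birth/death: sum_i M_i V_i constant under spreading
        vol = {"a": VolumeParams(2.0, 2.0, 0.0), "b": VolumeParams(1.0, 1.0, 0.0),
               "c": VolumeParams(0.5, 0.5, 0.0)}
        p = LogisticParams(r=0.0, kappa=1.0, c=0.0,
                           m0={"a": 10.0, "b": 4.0, "c": 1.0}, volume=vol,
                           beta={("a", "b"): 0.8, ("b", "c"): 0.3})
        traj = simulate_model("logistic", p, chain_topo, np.linspace(0, 10, 21))
        counts = (traj.M * traj.V).sum(axis=0)
        assert np.max(np.abs(counts - counts[0]) / counts[0]) < 1e-6

    def test_logistic_boundedness(self, single_layer_topo, const_volume):
        p = LogisticParams(r=2.0, kappa=4.0, c=0.0, m0={"L": 5.0}, volume=const_volume)
        traj = simulate_model("logistic", p, single_layer_topo, np.linspace(0, 20, 41))
        K = 4.0 / 2.0
        assert traj.M.max() <= max(5.0, K) + 1e-9

    @settings(max_examples=25, deadline=None)
    @given(
        a1=st.floats(0, 2), a2=st.floats(0, 2), c=st.floats(0, 1),
        beta=st.floats(0, 1), a0=st.floats(0, 100), b0=st.floats(0, 100),
    )
    def test_nonnegativity_under_random_rates(self, a1, a2, c, beta, a0, b0):
        topo = RegionTopology("r2", ("x", "y"), (("x", "y"),))
        vol = {"x": VolumeParams(1.0, 2.0, 0.3), "y": VolumeParams(0.5, 1.5, 0.2)}
        p = TwoPopParams(a1_int_A=a1, a2_ext_AB=a2, c_A=c, c_B=c,
                         A0={"x": a0, "y": b0}, B0={},
                         volume=vol, beta_A={("x", "y"): beta})
        traj = simulate_model("two_pop", p, topo, np.linspace(0, 10, 21),
                              SolverConfig(method="RK4"))
        assert traj.M.min() >= 0.0  # clamped within solver tolerance

    def test_relabeling_symmetry(self, single_layer_topo, const_volume):
        p = TwoPopParams(a1_int_A=0.4, a1_int_B=0.1, a2_int_AB=0.3, a2_int_BA=0.05,
                         c_A=0.02, c_B=0.2, A0={"L": 5.0}, B0={"L": 1.0},
                         volume=const_volume)
        grid = np.linspace(0, 4, 9)
        fwd = simulate_model("two_pop", p, single_layer_topo, grid)
        swp = simulate_model("two_pop", p.swapped(), single_layer_topo, grid)
        assert np.allclose(fwd.A, swp.B, rtol=1e-8, atol=1e-10)
        assert np.allclose(fwd.B, swp.A, rtol=1e-8, atol=1e-10)


class TestObservables:
    def _traj(self, params, topo, grid=np.linspace(0, 2, 5)):
        return simulate_model("two_pop", params, topo, grid)

    def test_zero_proliferation_means_zero_ki67(self, single_layer_topo, const_volume):
        p = TwoPopParams(a2_int_AB=0.3, A0={"L": 5.0}, volume=const_volume)
        obs = predict_observables(self._traj(p, single_layer_topo), tau_k=0.4)
        assert np.all(obs.pct_ki67 == 0)

    def test_single_population_rate_window_product(self, single_layer_topo, const_volume):
        # B=0, total a1_A = 2/day, tau_k = 0.2 -> 40%
        p = TwoPopParams(a1_int_A=2.0, A0={"L": 1.0}, volume=const_volume)
        traj = self._traj(p, single_layer_topo)
        obs = predict_observables(traj, tau_k=0.2)
        assert obs.pct_ki67[0, 0] == pytest.approx(40.0)

    def test_population_weighted_mean(self, single_layer_topo, const_volume):
        # A=B with a1_A=1, a1_B=0, tau_k=0.5 -> 25%
        p = TwoPopParams(a1_int_A=1.0, A0={"L": 3.0}, B0={"L": 3.0}, volume=const_volume)
        traj = Trajectory(
            times=np.array([0.0, 1.0]), topo=single_layer_topo, model_kind="two_pop",
            M=np.full((1, 2), 6.0), V=np.full((1, 2), 2.0), params=p,
            A=np.full((1, 2), 3.0), B=np.full((1, 2), 3.0),
        )
        obs = predict_observables(traj, tau_k=0.5)
        assert obs.pct_ki67[0, 0] == pytest.approx(25.0)

    def test_invalid_tau_k(self, single_layer_topo, const_volume):
        p = TwoPopParams(A0={"L": 1.0}, volume=const_volume)
        with pytest.raises(InvalidParameterError):
            predict_observables(self._traj(p, single_layer_topo), tau_k=2.0)


def _analytic_fraction_trajectory(topo, grid):
    """A = e^{-t}, B = 1 - e^{-t}: fraction_B crosses 1/2 at ln 2."""
    A = np.exp(-grid)[None, :]
    B = (1 - np.exp(-grid))[None, :]
    return Trajectory(
        times=grid, topo=topo, model_kind="two_pop", M=A + B,
        V=np.ones_like(A), params=None, A=A, B=B,
    )


class TestMilestones:
    def test_fractions_initial_and_normalized(self, single_layer_topo, decoupled_two_pop):
        traj = simulate_model("two_pop", decoupled_two_pop, single_layer_topo,
                              np.linspace(0, 5, 11))
        fa, fb = subpopulation_fractions(traj)
        assert fa[0, 0] == pytest.approx(1.0)
        assert np.allclose(fa + fb, 1.0)

    def test_fractions_reject_one_population(self, single_layer_topo, const_volume):
        p = LogisticParams(r=1.0, kappa=4.0, c=0.0, m0={"L": 1.0}, volume=const_volume)
        traj = simulate_model("logistic", p, single_layer_topo, np.linspace(0, 1, 5))
        with pytest.raises(UnsupportedModelError):
            subpopulation_fractions(traj)

    def test_switch_time_analytic_crossing(self, single_layer_topo):
        grid = np.linspace(0, 3, 301)
        traj = _analytic_fraction_trajectory(single_layer_topo, grid)
        assert switch_time(traj, "L") == pytest.approx(np.log(2), abs=1e-4)

    def test_switch_time_none_without_quiescents(self, single_layer_topo, const_volume):
        p = TwoPopParams(a1_int_A=0.1, A0={"L": 1.0}, volume=const_volume)
        traj = simulate_model("two_pop", p, single_layer_topo, np.linspace(0, 5, 11))
        assert switch_time(traj, "L") is None

    def test_switch_time_grid_refinement(self, single_layer_topo):
        # coarse-grid interpolation within one coarse step of the fine answer
        coarse = np.linspace(0, 3, 7)
        fine = np.linspace(0, 3, 601)
        t_coarse = switch_time(_analytic_fraction_trajectory(single_layer_topo, coarse), "L")
        t_fine = switch_time(_analytic_fraction_trajectory(single_layer_topo, fine), "L")
        assert abs(t_coarse - t_fine) < coarse[1] - coarse[0]

    def test_doubling_time_pure_exponential(self, single_layer_topo, const_volume):
        p = TwoPopParams(a1_int_A=np.log(2), A0={"L": 1.0}, volume=const_volume)
        traj = simulate_model("two_pop", p, single_layer_topo, np.linspace(0, 3, 7))
        for t in (0.0, 1.5, 3.0):
            assert doubling_time(traj, "L", t) == pytest.approx(1.0, rel=1e-6)

    def test_doubling_time_ln2_over_rate(self, single_layer_topo, const_volume):
        p = TwoPopParams(a1_int_A=0.3465, A0={"L": 1.0}, volume=const_volume)
        traj = simulate_model("two_pop", p, single_layer_topo, np.linspace(0, 3, 7))
        assert doubling_time(traj, "L", 1.0) == pytest.approx(np.log(2) / 0.3465, rel=1e-6)

    def test_doubling_time_shrinking_population_is_infinite(self, single_layer_topo, const_volume):
        p = TwoPopParams(c_A=0.5, A0={"L": 1.0}, volume=const_volume)
        traj = simulate_model("two_pop", p, single_layer_topo, np.linspace(0, 3, 7))
        assert doubling_time(traj, "L", 1.0) == np.inf

    def test_doubling_time_out_of_window(self, single_layer_topo, const_volume):
        p = TwoPopParams(a1_int_A=0.1, A0={"L": 1.0}, volume=const_volume)
        traj = simulate_model("two_pop", p, single_layer_topo, np.linspace(0, 3, 7))
        with pytest.raises(ValueError):
            doubling_time(traj, "L", 5.0)

    def test_doubling_time_increases_as_proliferation_wanes(self):
        from microdev.synthetic import hippocampus_like_truth

        truth = hippocampus_like_truth()
        traj = simulate_model("two_pop", truth.params, truth.topo, np.linspace(2, 14, 49))
        times = [2.0, 3.0, 4.0, 5.0, 6.0]
        dts = [doubling_time(traj, "CA", t) for t in times]
        assert all(b >= a for a, b in zip(dts, dts[1:]))

    def test_switch_time_monotone_in_extrinsic_differentiation(self, single_layer_topo):
        # over a 5x5 grid, increasing a2_ext never delays the P/Q switch
        vol = {"L": VolumeParams(0.5, 1.5, 0.3)}
        grid = np.linspace(0, 25, 251)
        for a1 in np.linspace(0.3, 0.9, 5):
            previous = np.inf
            for a2e in np.linspace(1.2, 4.0, 5):
                p = TwoPopParams(a1_int_A=a1, a2_ext_AB=a2e, c_A=0.05, c_B=0.1,
                                 A0={"L": 1.0}, volume=vol)
                traj = simulate_model("two_pop", p, single_layer_topo, grid,
                                      SolverConfig(method="RK4"))
                ts = switch_time(traj, "L")
                assert ts is not None and ts <= previous + 1e-9
                previous = ts
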