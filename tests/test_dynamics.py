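"""Unit dynamics, pool dynamics, depletion, plasticity and the integrator."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from copingsim.dynamics import (
    IntegrationError,
    IntegratorConfig,
    ModulationSpec,
    NeuromodPool,
    PlasticRule,
    UnitSpec,
    UnitState,
    depletion_step,
    hebbian_step,
    integrate,
    pool_step,
    unit_drive,
    unit_step,
)
from copingsim.circuit import CircuitSpec
from copingsim.dynamics import Connection


def _unit(tau=5.0, baseline=0.0):
    return UnitSpec(id="u", tau=tau, baseline=baseline)


class TestUnitDrive:
    def test_no_modulators_is_plain_leaky_drive(self):
        unit = _unit(baseline=0.2)
        incoming = [(0.5, 0.4), (-1.0, 0.3)]
        expected = 0.2 + 0.5 * 0.4 - 1.0 * 0.3
        assert unit_drive(unit, incoming) == pytest.approx(expected)

    def test_zero_pool_levels_identical_to_unmodulated(self):
        unit = _unit(baseline=0.3)
        incoming = [(1.2, 0.5)]
        mods = [
            (ModulationSpec("p", "u", mul_excit=2.0, add_excit=1.0), 0.0),
            (ModulationSpec("q", "u", mul_inhib=3.0, add_inhib=0.5), 0.0),
        ]
        assert unit_drive(unit, incoming, mods) == unit_drive(unit, incoming)

    def test_additive_only(self):
        unit = _unit(baseline=0.0)
        mods = [(ModulationSpec("p", "u", add_excit=0.6), 0.5)]
        assert unit_drive(unit, [], mods) == pytest.approx(0.3)

    def test_balanced_multiplicative_factors_cancel(self):
        # b=0.5 plus synaptic 0.5, one pool with equal mul gains: drive = 1.0
        unit = _unit(baseline=0.5)
        mods = [(ModulationSpec("p", "u", mul_excit=2.0, mul_inhib=2.0), 0.7)]
        assert unit_drive(unit, [(1.0, 0.5)], mods) == pytest.approx(1.0)

    def test_negative_pool_level_rejected(self):
        with pytest.raises(ValueError):
            unit_drive(_unit(), [], [(ModulationSpec("p", "u"), -0.1)])

    def test_non_finite_weight_rejected(self):
        with pytest.raises(ValueError):
            unit_drive(_unit(), [(float("nan"), 0.5)])

    @given(
        b=st.floats(-1, 1),
        w=st.floats(-2, 2),
        a=st.floats(0, 0.99),
        level=st.floats(0, 2),
        mul_e=st.floats(0, 3),
        mul_d=st.floats(0, 3),
    )
    @settings(derandomize=True, max_examples=50)
    def test_modulated_drive_matches_closed_form(self, b, w, a, level, mul_e, mul_d):
        unit = _unit(baseline=b)
        mods = [(ModulationSpec("p", "u", mul_excit=mul_e, mul_inhib=mul_d), level)]
        got = unit_drive(unit, [(w, a)], mods)
        expected = (b + w * a) * (1 + mul_e * level) / (1 + mul_d * level)
        assert got == pytest.approx(expected, rel=1e-12)


class TestUnitStep:
    def test_rest_state_stays_at_rest(self):
        state = UnitState.from_potential(0.0)
        out = unit_step(state, _unit(), drive=0.0, dt=0.1)
        assert out.potential == 0.0 and out.activation == 0.0

    def test_constant_drive_converges_to_drive_value(self):
        # Fixed point u* = D, a* = [tanh D]+, against the closed-form
        # first-order response u(t) = D (1 - exp(-t/tau)).
        unit = _unit(tau=3.0)
        D, dt = 0.8, 0.001
        state = UnitState.from_potential(0.0)
        for _ in range(int(30 / dt)):  # 10 time constants
            state = unit_step(state, unit, D, dt)
        assert state.potential == pytest.approx(D, rel=1e-3)
        assert state.activation == pytest.approx(math.tanh(D), rel=1e-3)

    def test_negative_steady_potential_is_rectified(self):
        state = UnitState.from_potential(-0.5)
        assert state.activation == 0.0

    def test_activation_saturates_in_unit_interval(self):
        # mathematically a < 1; in floats tanh saturates to exactly 1.0
        state = UnitState.from_potential(50.0)
        assert 0.0 <= state.activation <= 1.0
        assert UnitState.from_potential(2.0).activation < 1.0


class TestPoolStep:
    def test_empty_pool_with_silent_source_stays_empty(self):
        pool = NeuromodPool(id="p", source="s", target_area="t")
        out = pool_step(pool, source_activation=0.0, dt=0.1)
        assert out.level == 0.0

    def test_subthreshold_release_equilibrates_at_artanh(self):
        # tau l' = -th tanh(l) + w a; for w a = 0.5 th the fixed point is
        # l* = artanh(0.5) ~ 0.5493.
        pool = NeuromodPool(id="p", source="s", target_area="t", tau=5.0,
                            reuptake_threshold=1.0, release_weight=1.0)
        a = 0.5
        for _ in range(20000):
            pool = pool_step(pool, a, dt=0.01)
        assert pool.level == pytest.approx(math.atanh(0.5), rel=0.01)

    def test_suprathreshold_release_grows_linearly(self):
        # Above the reuptake capacity the level grows without bound with
        # asymptotic slope (w a - th) / tau per minute.
        pool = NeuromodPool(id="p", source="s", target_area="t", tau=5.0,
                            reuptake_threshold=0.4, release_weight=1.0)
        a = 0.8
        levels = []
        for k in range(60000):
            pool = pool_step(pool, a, dt=0.01)
            levels.append(pool.level)
        slope = (levels[-1] - levels[-1001]) / (1000 * 0.01)
        assert slope == pytest.approx((a - 0.4) / 5.0, rel=0.01)

    def test_depletion_scales_release_only(self):
        full = NeuromodPool(id="p", source="s", target_area="t", level=0.0)
        depleted = dataclasses.replace(full, depletion=0.5)
        step_full = pool_step(full, 0.6, dt=0.1).level
        step_half = pool_step(depleted, 0.6, dt=0.1).level
        assert step_half == pytest.approx(step_full / 2)

    def test_level_clamped_at_zero(self):
        pool = NeuromodPool(id="p", source="s", target_area="t", tau=0.1,
                            reuptake_threshold=5.0, level=0.01)
        out = pool_step(pool, 0.0, dt=0.5)
        assert out.level == 0.0


class TestDepletionStep:
    def test_zero_target_stays_zero(self):
        pool = NeuromodPool(id="p", source="s", target_area="t")
        assert depletion_step(pool, dt=0.1).depletion == 0.0

    def test_matches_exponential_closed_form(self):
        # d(t) = d' (1 - exp(-t / tau_d)); at t = tau_d this is 1 - 1/e.
        pool = NeuromodPool(id="p", source="s", target_area="t",
                            depletion_target=1.0, depletion_tau=20.0)
        dt = 0.001
        for _ in range(int(20.0 / dt)):
            pool = depletion_step(pool, dt)
        assert pool.depletion == pytest.approx(1 - math.exp(-1), rel=1e-3)

    def test_recovery_direction(self):
        pool = NeuromodPool(id="p", source="s", target_area="t",
                            depletion=1.0, depletion_target=0.0,
                            depletion_tau=5.0)
        out = depletion_step(pool, dt=0.5)
        assert 0.0 < out.depletion < 1.0


class TestHebbianStep:
    RULE = PlasticRule(source="IL", target="PL", learning_rate=0.1,
                       pre_threshold=0.5, post_threshold=0.5, sign=-1)

    def test_subthreshold_pre_freezes_weight(self):
        w = hebbian_step(self.RULE, pre_activation=0.4, post_activation=0.9,
                         current_weight=-0.2)
        assert w == -0.2

    def test_documented_increment(self):
        # eta=0.1, both activations 1.0 against thresholds 0.5, sign -1:
        # increment magnitude 0.1 * 0.5 * 0.5 = 0.025.
        w = hebbian_step(self.RULE, 1.0, 1.0, -0.2)
        assert w == pytest.approx(-0.225)

    def test_threshold_boundary_gives_zero_increment(self):
        w = hebbian_step(self.RULE, 0.5, 0.5, -0.2)
        assert w == -0.2

    @given(
        pre=st.floats(0, 0.999),
        post=st.floats(0, 0.999),
        w=st.floats(-2, 0),
        eta=st.floats(0, 1),
    )
    @settings(derandomize=True, max_examples=100)
    def test_magnitude_never_shrinks(self, pre, post, w, eta):
        rule = PlasticRule(source="a", target="b", learning_rate=eta,
                           pre_threshold=0.3, post_threshold=0.3, sign=-1)
        new = hebbian_step(rule, pre, post, w)
        assert abs(new) >= abs(w)
        assert new <= w  # inhibitory connection only grows more negative


def _single_unit_circuit(tau=5.0):
    return CircuitSpec(
        units=(UnitSpec(id="x", tau=tau, baseline=0.0),),
        connections=(),
        pools=(),
        modulations=(),
        plastic_rules=(),
        external_targets={"x": 1.0},
    )


class TestIntegrate:
    def test_zero_input_zero_baseline_stays_silent(self):
        circuit = _single_unit_circuit()
        config = IntegratorConfig(dt=0.1, total_time=50.0)
        trace = integrate(circuit, config, external=0.0)
        assert np.all(trace.unit_activations == 0.0)

    def test_step_response_matches_analytic_solution(self):
        # One leaky unit under a constant step D: u(t) = D (1 - e^(-t/tau)).
        tau, D = 5.0, 0.7
        circuit = _single_unit_circuit(tau=tau)
        config = IntegratorConfig(dt=0.01, total_time=30.0, record_stride=100)
        trace = integrate(circuit, config, external=D)
        expected = D * (1 - np.exp(-trace.times / tau))
        assert np.allclose(trace.unit_potentials[:, 0], expected, rtol=0.01,
                           atol=1e-4)

    def test_step_halving_convergence(self, reference_circuit):
        # Halving dt changes every recorded value by well under 0.5%.
        coarse = IntegratorConfig(dt=0.1, total_time=120.0, record_stride=100)
        fine = IntegratorConfig(dt=0.05, total_time=120.0, record_stride=200)
        a = integrate(reference_circuit, coarse, external=1.0)
        b = integrate(reference_circuit, fine, external=1.0)
        assert np.allclose(a.times, b.times)
        assert np.allclose(a.pool_levels, b.pool_levels, rtol=5e-3, atol=2e-3)
        # activations pass through rectification zeros, so a small absolute
        # floor accompanies the relative tolerance
        assert np.allclose(a.unit_activations, b.unit_activations, rtol=5e-3,
                           atol=5e-3)

    def test_deterministic_repeatability(self, reference_circuit):
        config = IntegratorConfig(dt=0.1, total_time=60.0)
        a = integrate(reference_circuit, config, external=1.0)
        b = integrate(reference_circuit, config, external=1.0)
        assert np.array_equal(a.unit_activations, b.unit_activations)
        assert np.array_equal(a.pool_levels, b.pool_levels)
        assert np.array_equal(a.plastic_weights, b.plastic_weights)

    def test_instability_abort_names_the_unit(self):
        circuit = CircuitSpec(
            units=(UnitSpec(id="runaway", tau=1.0, baseline=0.0),),
            connections=(Connection("runaway", "runaway", weight=200.0),),
            pools=(),
            modulations=(),
            plastic_rules=(),
            external_targets={"runaway": 1.0},
        )
        config = IntegratorConfig(dt=0.1, total_time=50.0, stability_bound=50.0)
        with pytest.raises(IntegrationError, match="runaway"):
            integrate(circuit, config, external=100.0)

    def test_dt_stability_guard(self, reference_circuit):
        config = IntegratorConfig(dt=1.0, total_time=10.0)
        with pytest.raises(ValueError, match="stability guard"):
            integrate(reference_circuit, config, external=0.0)
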