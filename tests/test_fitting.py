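"""Target curves, fitting objective and the genetic algorithm."""

import numpy as np
import pytest

from copingsim import Protocol
from copingsim.circuit import CircuitSpec
from copingsim.dynamics import Connection, IntegratorConfig, NeuromodPool, UnitSpec, integrate
from copingsim.fitting import (
    CONDITIONS,
    GAConfig,
    ShapeConstraint,
    TargetCurveSet,
    canonical_targets,
    check_constraints,
    ga_fit,
    load_reference_fit,
    weighted_sq_error,
)


class TestCanonicalTargets:
    def test_sham_ne_peaks_in_the_printed_window(self):
        t = canonical_targets("sham")
        ne = t.curves["vmPFC-NE"]
        onset = Protocol().stress_onset
        peak_rel = t.grid[int(np.argmax(ne))] - onset
        assert peak_rel in (20.0, 40.0)

    def test_sham_accumbal_da_below_baseline_from_100_min(self):
        t = canonical_targets("sham")
        rel = t.grid - Protocol().stress_onset
        late = t.curves["NAcc-DA"][rel >= 100.0]
        assert np.all(late < 100.0)

    def test_da_depleted_accumbal_da_never_below_baseline(self):
        t = canonical_targets("DA-depleted")
        assert np.all(t.curves["NAcc-DA"] >= 100.0)

    def test_pre_stress_bins_sit_at_baseline(self):
        for condition in CONDITIONS:
            t = canonical_targets(condition)
            pre = t.curves["NAcc-DA"][t.grid <= Protocol().stress_onset]
            assert np.all(pre == 100.0)

    def test_constraint_bins_carry_double_weight(self):
        t = canonical_targets("sham")
        assert t.weights["NAcc-DA"].max() == 2.0
        assert t.weights["NAcc-DA"].min() == 1.0


class TestWeightedSquaredError:
    def _suite_from(self, target, values):
        class FakeSeries:
            def __init__(self, bin_times, vals):
                self.bin_times = bin_times
                self.values = vals

        series = {
            analyte: FakeSeries(target.grid, np.asarray(values[analyte]))
            for analyte in target.curves
        }
        return {target.condition: {"series": series}}

    def test_exact_match_scores_zero(self):
        t = canonical_targets("sham")
        suite = self._suite_from(t, t.curves)
        assert weighted_sq_error(suite, [t]) == 0.0

    def test_single_bin_deviation_arithmetic(self):
        t = canonical_targets("sham")
        values = {k: v.copy() for k, v in t.curves.items()}
        k = 0  # first bin has weight 1
        values["vmPFC-NE"][k] += 10.0
        suite = self._suite_from(t, values)
        assert weighted_sq_error(suite, [t]) == pytest.approx(100.0)

    def test_linearity_in_weights(self):
        t = canonical_targets("sham")
        values = {k: v + 3.0 for k, v in t.curves.items()}
        doubled = TargetCurveSet(
            condition=t.condition,
            grid=t.grid,
            curves=t.curves,
            weights={k: 2.0 * w for k, w in t.weights.items()},
        )
        e1 = weighted_sq_error(self._suite_from(t, values), [t])
        e2 = weighted_sq_error(self._suite_from(t, values), [doubled])
        assert e2 == pytest.approx(2.0 * e1)

    def test_grid_mismatch_raises(self):
        t = canonical_targets("sham")
        shifted = TargetCurveSet(
            condition=t.condition, grid=t.grid + 1.0, curves=t.curves,
            weights=t.weights,
        )
        with pytest.raises(ValueError, match="grid"):
            weighted_sq_error(self._suite_from(t, t.curves), [shifted])


def _toy_circuit(release_weight: float, coupling: float = 0.8) -> CircuitSpec:
    """Three units in a chain feeding one neuromodulator pool."""
    return CircuitSpec(
        units=(
            UnitSpec(id="input", tau=4.0, baseline=0.0),
            UnitSpec(id="relay", tau=4.0, baseline=0.1),
            UnitSpec(id="source", tau=4.0, baseline=0.2),
        ),
        connections=(
            Connection("input", "relay", weight=coupling),
            Connection("relay", "source", weight=0.9),
        ),
        pools=(
            NeuromodPool(id="analyte", source="source", target_area="area",
                         tau=8.0, reuptake_threshold=1.2,
                         release_weight=release_weight),
        ),
        modulations=(),
        plastic_rules=(),
        external_targets={"input": 1.0},
    )


def _toy_trace(release_weight, coupling=0.8):
    config = IntegratorConfig(dt=0.1, total_time=120.0, record_stride=10)
    ext = np.where(np.arange(1200) * 0.1 >= 30.0, 1.0, 0.0)
    circuit = _toy_circuit(release_weight, coupling)
    return integrate(circuit, config, external=ext).pool_levels[:, 0]


class TestGeneticAlgorithm:
    def _objective_for(self, truth):
        target = _toy_trace(**truth)

        def objective(params):
            sim = _toy_trace(
                release_weight=params["release_weight"],
                coupling=params.get("coupling", 0.8),
            )
            return float(np.sum((sim - target) ** 2))

        return objective

    def test_zero_generations_returns_best_of_initial_population(self):
        objective = self._objective_for({"release_weight": 1.3})
        ga = GAConfig(population_size=8, generations=0, seed=7,
                      parameter_bounds={"release_weight": (0.5, 2.0)})
        result = ga_fit(objective, ga, template={"release_weight": 1.0})
        assert len(result.error_history) == 1
        assert result.best_error == result.error_history[0]

    def test_same_seed_reproduces_the_fit_exactly(self):
        objective = self._objective_for({"release_weight": 1.3})
        ga = GAConfig(population_size=10, generations=4, seed=42,
                      parameter_bounds={"release_weight": (0.5, 2.0)})
        a = ga_fit(objective, ga, template={"release_weight": 1.0})
        b = ga_fit(objective, ga, template={"release_weight": 1.0})
        assert a.best_parameters == b.best_parameters
        assert a.error_history == b.error_history

    def test_single_gain_recovered_within_two_percent(self):
        truth = 1.37
        objective = self._objective_for({"release_weight": truth})
        ga = GAConfig(population_size=16, generations=12, seed=11,
                      mutation_rate=0.4, mutation_scale=0.1,
                      parameter_bounds={"release_weight": (0.5, 2.0)})
        result = ga_fit(objective, ga, template={"release_weight": 1.0})
        assert result.best_parameters["release_weight"] == pytest.approx(
            truth, rel=0.02
        )

    def test_elitism_keeps_the_error_history_non_increasing(self):
        objective = self._objective_for({"release_weight": 1.3})
        ga = GAConfig(population_size=12, generations=10, seed=3,
                      parameter_bounds={"release_weight": (0.5, 2.0)})
        result = ga_fit(objective, ga, template={"release_weight": 1.0})
        assert all(b <= a for a, b in zip(result.error_history,
                                          result.error_history[1:]))

    def test_missing_bounds_rejected(self):
        with pytest.raises(ValueError, match="parameter_bounds"):
            ga_fit(lambda p: 0.0, GAConfig(parameter_bounds={}))


class TestConstraints:
    def test_flat_model_fails_every_rise_constraint(self, sham_protocol):
        # Zeroing the stressor gains leaves every curve flat at 100%.
        flat = {f"ext:{u}": 0.0 for u in ("OFC/ACC", "PL", "IL", "CeA", "DR")}
        report = check_constraints(flat)
        failing_kinds = {r["kind"] for r in report if not r["passed"]}
        # a flat series never rises a second time nor drops below baseline
        assert "second-rise-after" in failing_kinds
        assert "below-baseline-after" in failing_kinds

    def test_reference_fit_passes_the_full_constraint_suite(self):
        report = load_reference_fit().constraints_report
        assert report, "committed fit carries a constraints report"
        assert all(r["passed"] for r in report)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ShapeConstraint("NAcc-DA", "sham", "wiggles", (0, 10))
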