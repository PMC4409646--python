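"""Canonical target curves, the fitting objective, and the genetic algorithm.

The in vivo microdialysis curves this model was designed to reproduce are
not available as machine-readable data, but their published description
pins down every feature that matters: peak windows, return-to-baseline
times, the below-baseline onset of accumbal dopamine, and the qualitative
effect of each depletion.  :func:`canonical_targets` turns those timing and
shape statements into smooth piecewise-linear curves on the 20-min sampling
grid (amplitudes are package defaults, not measurements), and
:class:`ShapeConstraint` re-expresses each statement as a pass/fail check
that can be evaluated against any simulated condition suite.

Parameters are searched with a seeded genetic algorithm (tournament
selection, uniform crossover, Gaussian mutation, elitism) minimising the
weighted quadratic error between simulated and target %-of-baseline curves,
optionally penalised by failed shape constraints.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .circuit import (
    CircuitSpec,
    ExperiencePreset,
    apply_experience,
    build_reference_circuit,
    extract_parameters,
)
from .dynamics import IntegratorConfig
from .protocols import (
    NEVER,
    PhaseMetrics,
    Protocol,
    default_conditions,
    phase_metrics,
    run_condition_suite,
    run_experiment,
    dialysis_sample,
)

__all__ = [
    "TargetCurveSet",
    "ShapeConstraint",
    "GAConfig",
    "FitResult",
    "canonical_targets",
    "default_constraints",
    "weighted_sq_error",
    "ga_fit",
    "check_constraints",
    "sweep_experience",
    "reference_bounds",
    "load_reference_fit",
    "fitted_reference_circuit",
]

CONDITIONS = ("sham", "NE-depleted", "DA-depleted")
FIT_ANALYTES = ("vmPFC-NE", "vmPFC-DA", "NAcc-DA")


@dataclass(frozen=True)
class TargetCurveSet:
    """Per-analyte target curves (percent of baseline) for one condition.

    ``grid`` holds the bin right-edges in minutes of recorded time;
    ``weights`` are per-point fitting weights (doubled on bins that carry a
    shape constraint).
    """

    condition: str
    grid: np.ndarray
    curves: Mapping[str, np.ndarray]
    weights: Mapping[str, np.ndarray]


@dataclass(frozen=True)
class ShapeConstraint:
    """One printed timing/shape statement as a pass/fail check.

    ``kind`` is one of ``peak-in-window``, ``below-baseline-after``,
    ``return-by``, ``no-rise``, ``stays-at-baseline``, ``within-band``,
    ``second-rise-after``; ``window`` is (start, end) in minutes after
    stress onset.  ``margin`` is the tolerance in percentage points where
    the kind needs one.
    """

    analyte: str
    condition: str
    kind: str
    window: tuple[float, float]
    margin: float = 5.0

    KINDS = (
        "peak-in-window",
        "below-baseline-after",
        "return-by",
        "no-rise",
        "stays-at-baseline",
        "within-band",
        "second-rise-after",
    )

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown constraint kind {self.kind!r}")

    def evaluate(self, series, metrics: PhaseMetrics) -> tuple[bool, float]:
        """Return (passed, measured quantity) for one condition's series."""
        lo, hi = self.window
        if self.kind == "peak-in-window":
            return lo <= metrics.peak_time <= hi, metrics.peak_time
        if self.kind == "below-baseline-after":
            onset = metrics.below_baseline_onset
            if onset == NEVER:
                return False, np.inf
            return lo <= onset <= hi, onset
        if self.kind == "return-by":
            ret = metrics.return_to_baseline_time
            if ret == NEVER:
                return False, np.inf
            return ret <= hi, ret
        times, values = series.post_onset(0.0)
        sel = (times >= lo) & (times <= hi)
        if self.kind == "no-rise":
            peak = float(values[sel].max())
            return peak <= 100.0 + self.margin, peak
        if self.kind == "stays-at-baseline":
            low = float(values[sel].min())
            return low >= 100.0 - self.margin, low
        if self.kind == "within-band":
            dev = float(np.abs(values[sel] - 100.0).max())
            return dev <= self.margin, dev
        # second-rise-after: the late rise exceeds the early one and is
        # sustained above baseline from the window's end onward.
        early = float(values[times < lo].max(initial=0.0))
        late = float(values[times >= lo].max(initial=0.0))
        sustained = float(values[times >= hi].min(initial=np.inf))
        ok = late > early and sustained >= 100.0 + self.margin
        return ok, late - early


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings (all rates in [0, 1], seeded)."""

    population_size: int = 100
    generations: int = 200
    crossover_rate: float = 0.7
    mutation_rate: float = 0.1
    mutation_scale: float = 0.1  # fraction of each bound's width
    tournament_size: int = 3
    elitism_count: int = 2
    seed: int = 1234
    parameter_bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for key, (lo, hi) in self.parameter_bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError(f"bounds for {key!r} must be finite with lo <= hi")


@dataclass
class FitResult:
    """Outcome of a GA run: best parameters, error, and per-generation history."""

    best_parameters: dict[str, float]
    best_error: float
    error_history: list[float]
    constraints_report: list[dict] = field(default_factory=list)
    config: GAConfig | None = None

    def to_json(self, path: str | Path) -> None:
        data = {
            "best_parameters": self.best_parameters,
            "best_error": self.best_error,
            "error_history": self.error_history,
            "constraints_report": self.constraints_report,
        }
        if self.config is not None:
            cfg = dataclasses.asdict(self.config)
            cfg["parameter_bounds"] = {
                k: list(v) for k, v in self.config.parameter_bounds.items()
            }
            data["config"] = cfg
        Path(path).write_text(json.dumps(data, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FitResult":
        data = json.loads(Path(path).read_text())
        config = None
        if "config" in data:
            cfg = dict(data["config"])
            cfg["parameter_bounds"] = {
                k: tuple(v) for k, v in cfg.get("parameter_bounds", {}).items()
            }
            config = GAConfig(**cfg)
        return cls(
            best_parameters=dict(data["best_parameters"]),
            best_error=float(data["best_error"]),
            error_history=[float(x) for x in data["error_history"]],
            constraints_report=list(data.get("constraints_report", [])),
            config=config,
        )


# ---------------------------------------------------------------------------
# Canonical targets
# ---------------------------------------------------------------------------

#: Default target amplitudes (percent of baseline); free choices, not data.
TARGET_AMPLITUDES = {
    "NE-peak": 400.0,
    "DA-cortex-early": 140.0,
    "DA-cortex-late": 360.0,
    "DA-accumbens-peak": 270.0,
    "DA-accumbens-floor": 80.0,
    "NE-depleted-residual": 120.0,
    "DA-accumbens-depleted-peak": 115.0,
    "DA-accumbens-elevated": 265.0,
}


def _curve(grid: np.ndarray, onset: float, knots: Sequence[tuple[float, float]]):
    """Piecewise-linear curve through (minutes-after-onset, percent) knots."""
    t = np.asarray([k[0] for k in knots])
    v = np.asarray([k[1] for k in knots])
    rel = grid - onset
    return np.interp(rel, t, v, left=100.0, right=v[-1])


def canonical_targets(
    condition: str,
    protocol: Protocol | None = None,
    amplitudes: Mapping[str, float] | None = None,
) -> TargetCurveSet:
    """Target %-of-baseline curves for one condition on the sampling grid.

    Sham encodes: cortical NE peaking 20-40 min after onset and back to
    baseline 120 min after the peak; cortical DA with a modest early rise
    and a much larger sustained rise from 60-80 min; accumbal DA peaking at
    20-40 min and below baseline from 80-100 min on.  NE depletion abolishes
    the accumbal first-phase rise and delays the below-baseline onset; DA
    depletion suppresses cortical DA and keeps accumbal DA elevated, never
    below baseline.
    """
    if protocol is None:
        protocol = Protocol()
    amp = dict(TARGET_AMPLITUDES)
    if amplitudes:
        amp.update(amplitudes)
    onset = protocol.stress_onset
    interval = protocol.sampling_interval
    n_bins = int(round(protocol.total_time / interval))
    grid = interval * np.arange(1, n_bins + 1)

    ne_peak = amp["NE-peak"]
    da_c_early, da_c_late = amp["DA-cortex-early"], amp["DA-cortex-late"]
    da_a_peak, da_a_floor = amp["DA-accumbens-peak"], amp["DA-accumbens-floor"]

    if condition == "sham":
        curves = {
            "vmPFC-NE": _curve(grid, onset, [(0, 100), (30, ne_peak), (90, 140),
                                             (150, 100), (240, 100)]),
            "vmPFC-DA": _curve(grid, onset, [(0, 100), (30, da_c_early), (50, 160),
                                             (80, 270), (120, 330), (240, da_c_late)]),
            "NAcc-DA": _curve(grid, onset, [(0, 100), (30, da_a_peak), (60, 220),
                                            (90, 100), (120, da_a_floor),
                                            (240, da_a_floor)]),
        }
    elif condition == "NE-depleted":
        res = amp["NE-depleted-residual"]
        curves = {
            "vmPFC-NE": _curve(grid, onset, [(0, 100), (40, res), (120, res - 10),
                                             (240, 100)]),
            "vmPFC-DA": _curve(grid, onset, [(0, 100), (40, 200), (120, 300),
                                             (240, 335)]),
            "NAcc-DA": _curve(grid, onset, [(0, 100), (40, amp["DA-accumbens-depleted-peak"]),
                                            (100, 105), (160, 92), (240, 85)]),
        }
    elif condition == "DA-depleted":
        curves = {
            "vmPFC-NE": _curve(grid, onset, [(0, 100), (30, ne_peak), (120, ne_peak + 130),
                                             (240, ne_peak + 160)]),
            "vmPFC-DA": _curve(grid, onset, [(0, 100), (30, 130), (90, 100),
                                             (240, 80)]),
            "NAcc-DA": _curve(grid, onset, [(0, 100), (40, 250),
                                            (120, amp["DA-accumbens-elevated"]),
                                            (240, amp["DA-accumbens-elevated"])]),
        }
    else:
        raise ValueError(f"unknown condition {condition!r}")

    weights = {}
    for analyte, curve in curves.items():
        w = np.ones_like(curve)
        for cons in default_constraints():
            if cons.condition != condition or cons.analyte != analyte:
                continue
            lo, hi = cons.window
            sel = (grid - onset >= lo) & (grid - onset <= hi)
            w[sel] = 2.0  # bins carrying a shape constraint count double
        weights[analyte] = w
    return TargetCurveSet(condition=condition, grid=grid, curves=curves,
                          weights=weights)


def default_constraints() -> list[ShapeConstraint]:
    """The qualitative acceptance surface of the fitted reference model."""
    return [
        # sham: biphasic dynamics
        ShapeConstraint("vmPFC-NE", "sham", "peak-in-window", (20, 40)),
        ShapeConstraint("vmPFC-NE", "sham", "return-by", (0, 120)),
        ShapeConstraint("vmPFC-DA", "sham", "second-rise-after", (60, 120)),
        ShapeConstraint("NAcc-DA", "sham", "peak-in-window", (20, 40)),
        ShapeConstraint("NAcc-DA", "sham", "below-baseline-after", (80, 100)),
        # NE depletion: first-phase accumbal rise abolished, phase 2 delayed
        ShapeConstraint("NAcc-DA", "NE-depleted", "no-rise", (0, 80), margin=25.0),
        ShapeConstraint("NAcc-DA", "NE-depleted", "below-baseline-after", (120, 240)),
        # DA depletion: no below-baseline accumbal drop
        ShapeConstraint("NAcc-DA", "DA-depleted", "stays-at-baseline", (0, 240)),
    ]


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

def weighted_sq_error(
    suite: Mapping[str, Mapping],
    targets: Sequence[TargetCurveSet],
) -> float:
    """Sum of weighted squared deviations between simulated and target curves.

    Zero iff the simulation matches every weighted target point exactly.
    """
    total = 0.0
    for target in targets:
        if target.condition not in suite:
            raise KeyError(f"condition {target.condition!r} missing from suite")
        series = suite[target.condition]["series"]
        for analyte, curve in target.curves.items():
            s = series[analyte]
            if s.bin_times.shape != target.grid.shape or not np.allclose(
                s.bin_times, target.grid
            ):
                raise ValueError(
                    f"{target.condition}/{analyte}: sampling grid mismatch"
                )
            w = target.weights[analyte]
            total += float(np.sum(w * (s.values - curve) ** 2))
    return total


def evaluate_parameters(
    parameters: Mapping[str, float],
    targets: Sequence[TargetCurveSet],
    protocols: Mapping[str, Protocol] | None = None,
    integrator_config: IntegratorConfig | None = None,
    constraints: Sequence[ShapeConstraint] = (),
    constraint_penalty: float = 0.0,
    penalty_error: float = 1e12,
) -> float:
    """Objective for one parameter assignment; instabilities score a penalty."""
    from .dynamics import IntegrationError

    if protocols is None:
        protocols = default_conditions()
    try:
        circuit = build_reference_circuit(parameters)
        suite = run_condition_suite(circuit, protocols, integrator_config)
        err = weighted_sq_error(suite, targets)
        if constraint_penalty and constraints:
            for cons in constraints:
                bundle = suite.get(cons.condition)
                if bundle is None:
                    continue
                ok, _ = cons.evaluate(
                    bundle["series"][cons.analyte], bundle["metrics"][cons.analyte]
                )
                if not ok:
                    err += constraint_penalty
        return err
    except (IntegrationError, ValueError, FloatingPointError, OverflowError):
        return penalty_error


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------

def ga_fit(
    objective: "Callable[[Mapping[str, float]], float] | None",
    ga: GAConfig,
    template: Mapping[str, float] | None = None,
    targets: Sequence[TargetCurveSet] | None = None,
    constraints: Sequence[ShapeConstraint] = (),
    constraint_penalty: float = 0.0,
    integrator_config: IntegratorConfig | None = None,
) -> FitResult:
    """Seeded GA minimisation over the bounded free parameters.

    ``objective`` maps a full parameter dict to a scalar error; when omitted
    it defaults to the weighted quadratic error of the reference circuit
    against ``targets`` (plus the optional constraint penalty).  Free
    parameters and their boxes come from ``ga.parameter_bounds``; parameters
    absent from the bounds stay at their ``template`` values.  ``template``
    (default: the reference assignment) also seeds one individual of the
    initial population, the rest are drawn uniformly from the bounds.

    Elitism guarantees a non-increasing best-error history; the same seed
    reproduces the same :class:`FitResult` exactly.
    """
    if not ga.parameter_bounds:
        raise ValueError("ga.parameter_bounds must name at least one free parameter")
    if template is None:
        template = dict(extract_parameters(build_reference_circuit()))
    else:
        template = dict(template)
    if objective is None:
        if targets is None:
            targets = [canonical_targets(c) for c in CONDITIONS]

        def objective(params: Mapping[str, float]) -> float:
            return evaluate_parameters(
                params,
                targets,
                integrator_config=integrator_config,
                constraints=constraints,
                constraint_penalty=constraint_penalty,
            )

    keys = list(ga.parameter_bounds)
    lo = np.array([ga.parameter_bounds[k][0] for k in keys])
    hi = np.array([ga.parameter_bounds[k][1] for k in keys])
    span = hi - lo
    rng = np.random.default_rng(ga.seed)

    def clip(x: np.ndarray) -> np.ndarray:
        return np.minimum(np.maximum(x, lo), hi)

    def decode(x: np.ndarray) -> dict[str, float]:
        params = dict(template)
        params.update({k: float(v) for k, v in zip(keys, x)})
        return params

    pop = rng.uniform(lo, hi, size=(ga.population_size, len(keys)))
    seed_vec = clip(np.array([template.get(k, (l + h) / 2)
                              for k, l, h in zip(keys, lo, hi)]))
    pop[0] = seed_vec
    fitness = np.array([objective(decode(x)) for x in pop])

    history = [float(fitness.min())]
    for _ in range(ga.generations):
        order = np.argsort(fitness, kind="stable")
        elites = pop[order[: ga.elitism_count]].copy()
        children = []
        while len(children) < ga.population_size - ga.elitism_count:
            picks = rng.integers(0, ga.population_size, size=(2, ga.tournament_size))
            parents = []
            for row in picks:
                parents.append(pop[row[np.argmin(fitness[row])]])
            a, b = parents
            if rng.random() < ga.crossover_rate:
                mask = rng.random(len(keys)) < 0.5
                child = np.where(mask, a, b)
            else:
                child = a.copy()
            mutate = rng.random(len(keys)) < ga.mutation_rate
            child = child + mutate * rng.normal(0.0, ga.mutation_scale * span)
            children.append(clip(child))
        pop = np.vstack([elites, np.array(children)])
        fitness = np.array([objective(decode(x)) for x in pop])
        history.append(min(history[-1], float(fitness.min())))

    best_idx = int(np.argmin(fitness))
    # Elites are carried unchanged, so the best of the last generation can
    # never be worse than the history minimum.
    best = decode(pop[best_idx])
    return FitResult(
        best_parameters=best,
        best_error=float(fitness[best_idx]),
        error_history=history,
        config=ga,
    )


def check_constraints(
    fit_or_params,
    constraints: Sequence[ShapeConstraint] | None = None,
    protocols: Mapping[str, Protocol] | None = None,
    integrator_config: IntegratorConfig | None = None,
) -> list[dict]:
    """Evaluate each shape constraint against the fitted circuit.

    Accepts a :class:`FitResult` or a parameter mapping; returns one record
    per constraint with the measured quantity attached.
    """
    if constraints is None:
        constraints = default_constraints()
    if isinstance(fit_or_params, FitResult):
        params = fit_or_params.best_parameters
    else:
        params = fit_or_params
    circuit = build_reference_circuit(params)
    if protocols is None:
        protocols = default_conditions()
    suite = run_condition_suite(circuit, protocols, integrator_config)
    report = []
    for cons in constraints:
        bundle = suite[cons.condition]
        ok, measured = cons.evaluate(
            bundle["series"][cons.analyte], bundle["metrics"][cons.analyte]
        )
        report.append(
            {
                "condition": cons.condition,
                "analyte": cons.analyte,
                "kind": cons.kind,
                "window": list(cons.window),
                "passed": bool(ok),
                "measured": None if measured in (np.inf, -np.inf) else float(measured),
            }
        )
    return report


def sweep_experience(
    circuit: CircuitSpec,
    weights: Sequence[float],
    protocol: Protocol | None = None,
    integrator_config: IntegratorConfig | None = None,
    analyte: str = "NAcc-DA",
    baseline_band: float = 5.0,
) -> list[tuple[float, PhaseMetrics]]:
    """Accumbal-DA phase metrics as a function of the initial IL->PL weight.

    ``weights`` must be sorted descending (naive first, most experienced
    last); used to locate the discontinuity in the below-baseline onset.
    """
    ws = list(weights)
    if any(b > a for a, b in zip(ws, ws[1:])):
        raise ValueError("weights must be sorted descending (naive -> long)")
    if protocol is None:
        protocol = Protocol()
    out = []
    for w in ws:
        c = apply_experience(circuit, ExperiencePreset("sweep", float(w)))
        trace = run_experiment(c, protocol, integrator_config)
        series = dialysis_sample(trace, analyte, protocol)
        out.append((float(w), phase_metrics(series, protocol.stress_onset,
                                            baseline_band)))
    return out


# ---------------------------------------------------------------------------
# Reference fit: free-parameter boxes and the committed fixture
# ---------------------------------------------------------------------------

def reference_bounds(width: float = 0.3) -> dict[str, tuple[float, float]]:
    """Bounded boxes around the reference assignment for the free parameters.

    Signs are fixed by the architecture (weights are stored as magnitudes),
    so every box is one-sided in sign; ``width`` is the fractional half-width
    around the reference value.  Thresholds of the plastic rule are boxed in
    absolute units.
    """
    template = extract_parameters(build_reference_circuit())
    free = [
        "ext:PL", "ext:DR", "ext:CeA",
        "conn:CeA->LC", "conn:PL->CeA", "conn:PL->DR", "conn:IL->ITC",
        "conn:ITC->CeA", "conn:IL->mlVTA-GABA", "conn:CeA->mlVTA-GABA",
        "conn:mlVTA-GABA->mlVTA-DA", "conn:DR->mcVTA-DA",
        "pool:vmPFC-NE:tau", "pool:vmPFC-DA:tau", "pool:NAcc-DA:tau",
        "mod:vmPFC-NE->PL:mul_excit", "mod:vmPFC-NE->IL:mul_inhib",
        "mod:vmPFC-DA->IL:mul_excit", "mod:vmPFC-DA->IL:add_excit",
        "plastic:IL->PL:learning_rate",
    ]
    bounds = {}
    for key in free:
        ref = template[key]
        bounds[key] = (max(ref * (1 - width), 1e-6), ref * (1 + width))
    return bounds


def _reference_fit_path() -> Path:
    return Path(__file__).parent / "data" / "reference_fit.json"


def load_reference_fit() -> FitResult:
    """The committed reference fit (produced by scripts/fit_reference.py)."""
    return FitResult.from_json(_reference_fit_path())


def fitted_reference_circuit() -> CircuitSpec:
    """Reference circuit with the committed fitted parameters applied."""
    return build_reference_circuit(load_reference_fit().best_parameters)
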