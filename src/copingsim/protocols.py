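"""Named restraint experiments and microdialysis-style measurement.

A protocol is a restraint session: the circuit settles to rest, a
pre-stress baseline window is recorded, then a constant stressor drive is
applied for the stress duration.  Pool trajectories are binned every
``sampling_interval`` minutes (value at the bin's end, emulating the
collection of a dialysate fraction) and expressed as percent of the
baseline, defined as the mean of the three samples collected immediately
before stress onset -- the same normalisation used for in vivo dialysates.

Phase metrics reduce a binned series to the quantities the coping
literature reports: the post-onset peak, the first post-peak sample below
the baseline band (onset of the passive phase for accumbal dopamine), and
the first post-peak sample back inside the band.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .circuit import (
    CircuitSpec,
    DepletionSchedule,
    ExperiencePreset,
    LesionSpec,
    apply_experience,
    apply_lesion,
    validate_circuit,
)
from .dynamics import IntegratorConfig, SimTrace, integrate

__all__ = [
    "Protocol",
    "DialysisSeries",
    "PhaseMetrics",
    "run_experiment",
    "dialysis_sample",
    "phase_metrics",
    "run_condition_suite",
    "default_conditions",
    "NEVER",
]

#: Sentinel for a phase event that does not occur within the session.
NEVER = "never"

ANALYTES = ("vmPFC-NE", "vmPFC-DA", "NAcc-DA", "vmPFC-5HT")


@dataclass(frozen=True)
class Protocol:
    """One restraint session.

    ``pre_stress_duration`` must hold at least three sampling intervals so a
    three-sample baseline exists; ``settle_time`` is the unrecorded
    equilibration period before the session starts.
    """

    pre_stress_duration: float = 60.0
    stress_duration: float = 240.0
    stress_magnitude: float = 1.0
    sampling_interval: float = 20.0
    settle_time: float = 240.0
    depletions: tuple[DepletionSchedule, ...] = ()
    lesion: LesionSpec | None = None
    experience: ExperiencePreset | None = None

    def __post_init__(self) -> None:
        if self.stress_magnitude < 0:
            raise ValueError("stress_magnitude must be >= 0")
        for dur, name in (
            (self.pre_stress_duration, "pre_stress_duration"),
            (self.stress_duration, "stress_duration"),
        ):
            k = dur / self.sampling_interval
            if abs(k - round(k)) > 1e-9:
                raise ValueError(f"sampling_interval must divide {name}")
        if self.pre_stress_duration < 3 * self.sampling_interval:
            raise ValueError(
                "pre_stress_duration must cover at least three baseline samples"
            )
        object.__setattr__(self, "depletions", tuple(self.depletions))

    @property
    def total_time(self) -> float:
        return self.pre_stress_duration + self.stress_duration

    @property
    def stress_onset(self) -> float:
        return self.pre_stress_duration


@dataclass(frozen=True)
class DialysisSeries:
    """Binned %-of-baseline readout for one analyte.

    ``bin_times`` are the bins' right edges in recorded minutes; ``values``
    are 100 * level / baseline with baseline the mean of the three samples
    immediately preceding stress onset.
    """

    analyte: str
    bin_times: np.ndarray
    values: np.ndarray
    baseline: float

    def post_onset(self, onset: float) -> tuple[np.ndarray, np.ndarray]:
        """(times after onset, values) for bins strictly past the onset."""
        mask = self.bin_times > onset + 1e-9
        return self.bin_times[mask] - onset, self.values[mask]


@dataclass(frozen=True)
class PhaseMetrics:
    """Peak and phase-transition timing of one binned series.

    Times are minutes after stress onset, except ``return_to_baseline_time``
    which is minutes after the peak sample; ``NEVER`` marks events that do
    not occur.
    """

    peak_time: float
    peak_value: float
    below_baseline_onset: "float | str"
    return_to_baseline_time: "float | str"


def _depletion_targets(
    protocol: Protocol, circuit: CircuitSpec, n_steps: int, dt: float, settle: bool
):
    """Per-step depletion-target arrays for the settle or recorded phase."""
    if not protocol.depletions:
        return None
    targets: dict[str, np.ndarray] = {}
    for sched in protocol.depletions:
        circuit.pool_index(sched.pool)  # raises on unknown pool
        arr = np.zeros(n_steps)
        if settle:
            if sched.onset == 0.0:
                arr[:] = sched.target_fraction
        else:
            k = int(round(sched.onset / dt))
            arr[k:] = sched.target_fraction
        targets[sched.pool] = arr
    return targets


def _integrator_config(protocol: Protocol, config: IntegratorConfig | None):
    if config is None:
        config = IntegratorConfig(total_time=protocol.total_time)
    elif config.total_time != protocol.total_time:
        config = dataclasses.replace(config, total_time=protocol.total_time)
    return config


def run_experiment(
    circuit: CircuitSpec,
    protocol: Protocol,
    integrator_config: IntegratorConfig | None = None,
) -> SimTrace:
    """Settle the circuit, then run one recorded restraint session.

    The stressor drive is 0 before ``pre_stress_duration`` and
    ``stress_magnitude`` thereafter, delivered to the circuit's external
    targets through their gains.  The protocol's lesion, experience preset
    and depletion schedules are applied before simulation.
    """
    violations = validate_circuit(circuit)
    if violations:
        raise ValueError("invalid circuit: " + "; ".join(violations))
    if protocol.experience is not None:
        circuit = apply_experience(circuit, protocol.experience)
    if protocol.lesion is not None:
        circuit = apply_lesion(circuit, protocol.lesion)

    config = _integrator_config(protocol, integrator_config)

    # Unrecorded settling to the resting (or chronically depleted) state.
    pre_depl = {
        s.pool: s.target_fraction for s in protocol.depletions if s.onset == 0.0
    }
    settle_steps = int(round(protocol.settle_time / config.dt))
    initial = None
    if settle_steps > 0:
        settle_cfg = dataclasses.replace(config, total_time=protocol.settle_time)
        settle = integrate(
            circuit,
            settle_cfg,
            external=0.0,
            depletion_targets={k: np.full(settle_steps, v) for k, v in pre_depl.items()}
            or None,
        )
        initial = settle.final_state

    n_steps = config.n_steps
    t = np.arange(n_steps) * config.dt
    ext = np.where(t >= protocol.stress_onset - 1e-9, protocol.stress_magnitude, 0.0)

    dtar = _depletion_targets(protocol, circuit, n_steps, config.dt, settle=False)
    if dtar is None and pre_depl:
        dtar = {}
    if dtar is not None:
        for pid, frac in pre_depl.items():
            dtar.setdefault(pid, np.full(n_steps, frac))
    try:
        return integrate(circuit, config, external=ext, depletion_targets=dtar,
                         initial=initial)
    except Exception as err:
        raise type(err)(f"{err} (protocol: onset {protocol.stress_onset} min, "
                        f"magnitude {protocol.stress_magnitude})") from err


def dialysis_sample(
    trace: SimTrace, analyte: str, protocol: Protocol
) -> DialysisSeries:
    """Bin one pool trajectory into a %-of-baseline dialysis series.

    The value of each bin is the instantaneous level at the bin's end; the
    baseline is the mean of the three bins immediately preceding stress
    onset.
    """
    level = trace.pool_level(analyte)
    interval = protocol.sampling_interval
    n_bins = int(round(protocol.total_time / interval))
    bin_times = interval * np.arange(1, n_bins + 1)
    idx = []
    for bt in bin_times:
        j = int(np.argmin(np.abs(trace.times - bt)))
        if abs(trace.times[j] - bt) > 1e-6:
            raise ValueError(
                f"bin edge {bt} min not on the recorded grid (stride too coarse)"
            )
        idx.append(j)
    raw = level[idx]
    n_pre = int(round(protocol.pre_stress_duration / interval))
    baseline = float(np.mean(raw[n_pre - 3 : n_pre]))
    if baseline <= 0:
        raise ValueError(
            f"{analyte}: baseline is {baseline}; the pool never equilibrated"
        )
    return DialysisSeries(
        analyte=analyte,
        bin_times=bin_times,
        values=100.0 * raw / baseline,
        baseline=baseline,
    )


def phase_metrics(
    series: DialysisSeries, stress_onset: float, baseline_band: float = 5.0
) -> PhaseMetrics:
    """Peak and baseline-crossing metrics of a binned series.

    The peak is the maximum post-onset bin; ``below_baseline_onset`` is the
    first post-peak bin at or below ``100 - baseline_band``;
    ``return_to_baseline_time`` the first post-peak bin within the band
    around 100, reported relative to the peak sample.
    """
    times, values = series.post_onset(stress_onset)
    if times.size == 0:
        raise ValueError("series has no post-onset samples")
    k_peak = int(np.argmax(values))
    peak_time = float(times[k_peak])
    peak_value = float(values[k_peak])
    below: "float | str" = NEVER
    ret: "float | str" = NEVER
    for k in range(k_peak + 1, times.size):
        if below == NEVER and values[k] <= 100.0 - baseline_band:
            below = float(times[k])
        if ret == NEVER and abs(values[k] - 100.0) <= baseline_band:
            ret = float(times[k] - peak_time)
    return PhaseMetrics(
        peak_time=peak_time,
        peak_value=peak_value,
        below_baseline_onset=below,
        return_to_baseline_time=ret,
    )


def run_condition_suite(
    circuit: CircuitSpec,
    conditions: Mapping[str, Protocol],
    integrator_config: IntegratorConfig | None = None,
    analytes: Sequence[str] = ("vmPFC-NE", "vmPFC-DA", "NAcc-DA"),
    baseline_band: float = 5.0,
) -> dict:
    """Run named protocols and bundle series + metrics per condition.

    Returns ``{condition: {"trace": SimTrace, "series": {analyte: series},
    "metrics": {analyte: metrics}}}``; deterministic, suitable for fitting
    and acceptance checks.
    """
    if len(set(conditions)) != len(conditions):
        raise ValueError("condition names must be unique")
    out: dict = {}
    for name, protocol in conditions.items():
        trace = run_experiment(circuit, protocol, integrator_config)
        series = {a: dialysis_sample(trace, a, protocol) for a in analytes}
        metrics = {
            a: phase_metrics(s, protocol.stress_onset, baseline_band)
            for a, s in series.items()
        }
        out[name] = {"trace": trace, "series": series, "metrics": metrics}
    return out


def default_conditions(
    depletion_fraction: float = 0.9,
    depletion_tau: float = 20.0,
) -> dict[str, Protocol]:
    """The three tuning conditions: sham, NE depletion, DA depletion in vmPFC."""
    return {
        "sham": Protocol(),
        "NE-depleted": Protocol(
            depletions=(
                DepletionSchedule("vmPFC-NE", depletion_fraction, 0.0, depletion_tau),
            )
        ),
        "DA-depleted": Protocol(
            depletions=(
                DepletionSchedule("vmPFC-DA", depletion_fraction, 0.0, depletion_tau),
            )
        ),
    }
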