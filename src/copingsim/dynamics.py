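"""Leaky-unit circuit dynamics with neuromodulator pools and Hebbian plasticity.

The building block is a rate ("leaky") unit describing a whole neural
population on the minutes timescale of tonic activity changes::

    tau_j du_j/dt = -u_j + b_j + sum_i w_ji a_i,      a_j = [tanh(u_j)]+

where ``tau_j`` is the unit's time constant (minutes), ``b_j`` its intrinsic
drive and ``[.]+`` the positive part, so activations live in ``[0, 1)``.

Extrasynaptic neuromodulator accumulation in a target area is a leaky pool
with a saturating reuptake term and a depletion coefficient ``d`` scaling
release::

    tau du/dt = -th * tanh(l) + (1 - d) * w * a_source

Below the reuptake capacity ``th`` the level equilibrates at
``artanh(w * a / th)``; above it the level grows without bound at asymptotic
slope ``(w * a - th) / tau``.  The depletion coefficient relaxes toward its
target ``d'`` with its own time constant (first-order exponential).

Neuromodulators act on units multiplicatively (gating the summed synaptic
input) and additively (acting as a direct input)::

    drive = (b + sum w a) * (1 + sum mu_e l) / (1 + sum mu_d l)
            + sum alpha_e l - sum alpha_d l

which collapses to the plain leaky drive when every pool level is zero.

Finally a threshold-gated Hebbian rule grows the magnitude of a plastic
connection whenever both pre- and post-synaptic activations exceed their
thresholds; the growth direction follows the connection's anatomical sign
(inhibitory connections become more inhibitory).

Everything here is deterministic; :func:`integrate` is a fixed-step explicit
Euler loop over these updates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .circuit import CircuitSpec

__all__ = [
    "UnitSpec",
    "UnitState",
    "Connection",
    "NeuromodPool",
    "ModulationSpec",
    "PlasticRule",
    "IntegratorConfig",
    "SimTrace",
    "IntegrationError",
    "rectified_tanh",
    "unit_drive",
    "unit_step",
    "pool_step",
    "depletion_step",
    "hebbian_step",
    "integrate",
]


def _check_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


def rectified_tanh(u):
    """Positive-saturation transfer function ``[tanh(u)]+``."""
    return np.maximum(np.tanh(u), 0.0)


@dataclass(frozen=True)
class UnitSpec:
    """One neural population: identifier, time constant (min), intrinsic drive.

    A negative ``baseline`` acts as an activation threshold: the unit stays
    silent until its synaptic input overcomes it.
    """

    id: str
    tau: float = 8.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"unit {self.id!r}: tau must be > 0, got {self.tau}")
        _check_finite(f"unit {self.id!r} baseline", self.baseline)


@dataclass(frozen=True)
class UnitState:
    """Instantaneous potential and its rectified-saturating activation."""

    potential: float
    activation: float

    @classmethod
    def from_potential(cls, potential: float) -> "UnitState":
        return cls(potential=potential, activation=float(rectified_tanh(potential)))


@dataclass(frozen=True)
class Connection:
    """Signed synaptic connection ``source -> target`` between units."""

    source: str
    target: str
    weight: float
    plastic: bool = False

    def __post_init__(self) -> None:
        _check_finite(f"connection {self.source}->{self.target} weight", self.weight)


@dataclass
class NeuromodPool:
    """Extrasynaptic neuromodulator level for one (source nucleus, target area).

    ``reuptake_threshold`` is the overall reuptake capacity of the target
    area; ``release_weight`` the release gain on the source activation;
    ``depletion`` the current fraction of release suppressed experimentally.
    """

    id: str
    source: str
    target_area: str
    tau: float = 15.0
    reuptake_threshold: float = 1.3
    release_weight: float = 1.0
    level: float = 0.0
    depletion: float = 0.0
    depletion_target: float = 0.0
    depletion_tau: float = 20.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"pool {self.id!r}: tau must be > 0")
        if self.reuptake_threshold <= 0:
            raise ValueError(f"pool {self.id!r}: reuptake_threshold must be > 0")
        if self.depletion_tau <= 0:
            raise ValueError(f"pool {self.id!r}: depletion_tau must be > 0")
        if not 0.0 <= self.depletion <= 1.0:
            raise ValueError(f"pool {self.id!r}: depletion must be in [0, 1]")
        if not 0.0 <= self.depletion_target <= 1.0:
            raise ValueError(f"pool {self.id!r}: depletion_target must be in [0, 1]")
        if self.level < 0:
            raise ValueError(f"pool {self.id!r}: level must be >= 0")


@dataclass(frozen=True)
class ModulationSpec:
    """Multiplicative/additive excitatory/inhibitory action of a pool on a unit.

    All coefficients are non-negative; the sign of the effect is carried by
    the excitatory/inhibitory slot, not by the coefficient.
    """

    pool: str
    target: str
    mul_excit: float = 0.0
    mul_inhib: float = 0.0
    add_excit: float = 0.0
    add_inhib: float = 0.0

    def __post_init__(self) -> None:
        for name in ("mul_excit", "mul_inhib", "add_excit", "add_inhib"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(
                    f"modulation {self.pool}->{self.target}: {name} must be >= 0"
                )


@dataclass(frozen=True)
class PlasticRule:
    """Threshold-gated Hebbian rule on one connection.

    ``learning_rate`` is in weight units per minute of joint supra-threshold
    activity.  ``sign`` is the direction in which the weight magnitude grows
    (-1 for an inhibitory connection).
    """

    source: str
    target: str
    learning_rate: float
    pre_threshold: float = 0.0
    post_threshold: float = 0.0
    sign: int = -1

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        for name in ("pre_threshold", "post_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")


@dataclass(frozen=True)
class IntegratorConfig:
    """Fixed-step explicit-Euler settings.

    ``dt`` must respect a stability guard of one tenth of the fastest unit
    time constant; ``stability_bound`` aborts the run if any potential
    escapes it (tanh saturates near 1, so |u| of that size signals parameter
    pathology, not biology).
    """

    dt: float = 0.1
    total_time: float = 300.0
    record_stride: int = 10
    stability_bound: float = 50.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.total_time <= 0:
            raise ValueError("total_time must be > 0")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")
        n = self.total_time / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("total_time must be an integer multiple of dt")

    @property
    def n_steps(self) -> int:
        return int(round(self.total_time / self.dt))

    def validate_for(self, min_tau: float) -> None:
        if self.dt > min_tau / 10.0 + 1e-12:
            raise ValueError(
                f"dt={self.dt} exceeds stability guard min(tau)/10={min_tau / 10.0}"
            )


class IntegrationError(RuntimeError):
    """Raised when the integrator detects a diverging unit potential."""


# ---------------------------------------------------------------------------
# Elementary update steps (scalar form; the fast path lives in _engine)
# ---------------------------------------------------------------------------

def unit_drive(
    unit: UnitSpec,
    incoming: Sequence[tuple[float, float]] = (),
    modulators: Sequence[tuple[ModulationSpec, float]] = (),
) -> float:
    """Total drive on a unit: gated synaptic sum plus additive modulation.

    ``incoming`` is a sequence of (weight, source activation) pairs;
    ``modulators`` pairs each modulation spec with the current pool level.
    With no modulators this is exactly the plain leaky drive
    ``b + sum w a``.
    """
    syn = unit.baseline
    for w, a in incoming:
        _check_finite("connection weight", w)
        syn += w * a
    mul_e = mul_d = add = 0.0
    for spec, level in modulators:
        _check_finite(f"pool {spec.pool!r} level", level)
        if level < 0:
            raise ValueError(f"pool {spec.pool!r} level must be >= 0, got {level}")
        mul_e += spec.mul_excit * level
        mul_d += spec.mul_inhib * level
        add += (spec.add_excit - spec.add_inhib) * level
    return syn * (1.0 + mul_e) / (1.0 + mul_d) + add


def unit_step(state: UnitState, unit: UnitSpec, drive: float, dt: float) -> UnitState:
    """One explicit-Euler step of the leaky-unit equation."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    _check_finite("drive", drive)
    u = state.potential + (dt / unit.tau) * (drive - state.potential)
    return UnitState.from_potential(u)


def pool_step(pool: NeuromodPool, source_activation: float, dt: float) -> NeuromodPool:
    """One Euler step of the release/reuptake equation, release scaled by (1-d).

    The level is clamped at zero: a concentration cannot be negative, and a
    large step can transiently undershoot.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    release = (1.0 - pool.depletion) * pool.release_weight * source_activation
    reuptake = pool.reuptake_threshold * math.tanh(pool.level)
    level = pool.level + (dt / pool.tau) * (release - reuptake)
    return replace(pool, level=max(level, 0.0))


def depletion_step(pool: NeuromodPool, dt: float) -> NeuromodPool:
    """First-order relaxation of the depletion coefficient toward its target."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    d = pool.depletion + (dt / pool.depletion_tau) * (
        pool.depletion_target - pool.depletion
    )
    return replace(pool, depletion=min(max(d, 0.0), 1.0))


def hebbian_step(
    rule: PlasticRule,
    pre_activation: float,
    post_activation: float,
    current_weight: float,
    dt: float = 1.0,
) -> float:
    """Threshold-gated Hebbian update of a signed weight.

    The increment magnitude is
    ``dt * eta * [a_post - th_post]+ * [a_pre - th_pre]+`` applied in the
    direction of ``rule.sign``, so the weight magnitude never shrinks.  With
    the default ``dt = 1`` this is the discrete per-tick form; the integrator
    applies it as a per-minute rate.
    """
    pre = max(pre_activation - rule.pre_threshold, 0.0)
    post = max(post_activation - rule.post_threshold, 0.0)
    return current_weight + rule.sign * dt * rule.learning_rate * post * pre


# ---------------------------------------------------------------------------
# Traces and the integration loop
# ---------------------------------------------------------------------------

@dataclass
class FinalState:
    """Snapshot of the integrator state, usable as the next run's start."""

    potentials: np.ndarray
    pool_levels: np.ndarray
    depletions: np.ndarray
    plastic_weights: np.ndarray


@dataclass
class SimTrace:
    """Recorded trajectories of a single integration run.

    All series share the ``times`` grid (minutes).  ``unit_activations`` and
    ``unit_potentials`` are (n_times, n_units); ``pool_levels`` is
    (n_times, n_pools); ``plastic_weights`` is (n_times, n_rules).
    """

    times: np.ndarray
    unit_ids: list[str]
    pool_ids: list[str]
    rule_labels: list[str]
    unit_activations: np.ndarray
    unit_potentials: np.ndarray
    pool_levels: np.ndarray
    plastic_weights: np.ndarray
    final_state: FinalState = field(repr=False, default=None)

    def activation(self, unit_id: str) -> np.ndarray:
        return self.unit_activations[:, self.unit_ids.index(unit_id)]

    def pool_level(self, pool_id: str) -> np.ndarray:
        return self.pool_levels[:, self.pool_ids.index(pool_id)]

    def plastic_weight(self, label: str) -> np.ndarray:
        return self.plastic_weights[:, self.rule_labels.index(label)]

    def to_frame(self):
        """Tidy long-format DataFrame (kind, name, time_min, value)."""
        import pandas as pd

        rows = []
        for j, uid in enumerate(self.unit_ids):
            rows.append(
                pd.DataFrame(
                    {
                        "kind": "activation",
                        "name": uid,
                        "time_min": self.times,
                        "value": self.unit_activations[:, j],
                    }
                )
            )
        for j, pid in enumerate(self.pool_ids):
            rows.append(
                pd.DataFrame(
                    {
                        "kind": "pool_level",
                        "name": pid,
                        "time_min": self.times,
                        "value": self.pool_levels[:, j],
                    }
                )
            )
        for j, lab in enumerate(self.rule_labels):
            rows.append(
                pd.DataFrame(
                    {
                        "kind": "plastic_weight",
                        "name": lab,
                        "time_min": self.times,
                        "value": self.plastic_weights[:, j],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


ExternalInput = "float | np.ndarray | Callable[[float], float] | None"


def _external_series(
    external, config: IntegratorConfig
) -> np.ndarray:
    n = config.n_steps
    if external is None:
        return np.zeros(n)
    if callable(external):
        # value during step k, evaluated at the step's start time
        t = np.arange(n) * config.dt
        return np.asarray([float(external(tk)) for tk in t], dtype=float)
    arr = np.asarray(external, dtype=float)
    if arr.ndim == 0:
        return np.full(n, float(arr))
    if arr.shape != (n,):
        raise ValueError(f"external drive must have {n} entries, got {arr.shape}")
    return arr


def integrate(
    circuit: "CircuitSpec",
    config: IntegratorConfig,
    external=None,
    depletion_targets: Mapping[str, "float | np.ndarray"] | None = None,
    initial: FinalState | None = None,
) -> SimTrace:
    """Fixed-step integration of a full circuit.

    ``external`` is the scalar stressor drive over time (constant, per-step
    array of length ``n_steps``, or callable of time); it is distributed to
    the circuit's external targets through their gains.  ``depletion_targets``
    optionally overrides each pool's depletion target (scalar or per-step
    array).  ``initial`` chains runs (settling, repeated sessions).

    Deterministic: identical inputs and config give identical traces.
    Raises :class:`IntegrationError` naming the first unit whose potential
    exceeds the stability bound.
    """
    from ._engine import run_packed

    packed = circuit.packed()
    config.validate_for(min(u.tau for u in circuit.units))

    n = config.n_steps
    ext = _external_series(external, config)

    m = len(circuit.pools)
    dtar = np.zeros((n, m))
    for j, pool in enumerate(circuit.pools):
        dtar[:, j] = pool.depletion_target
    if depletion_targets:
        ids = [p.id for p in circuit.pools]
        for pid, val in depletion_targets.items():
            if pid not in ids:
                raise KeyError(f"unknown pool id {pid!r}")
            arr = np.asarray(val, dtype=float)
            dtar[:, ids.index(pid)] = arr if arr.ndim else float(arr)

    if initial is None:
        u0 = np.zeros(len(circuit.units))
        l0 = np.array([p.level for p in circuit.pools], dtype=float)
        d0 = np.array([p.depletion for p in circuit.pools], dtype=float)
        W0 = packed.weights.copy()
    else:
        u0 = np.asarray(initial.potentials, dtype=float).copy()
        l0 = np.asarray(initial.pool_levels, dtype=float).copy()
        d0 = np.asarray(initial.depletions, dtype=float).copy()
        W0 = packed.weights.copy()
        for k, (post, pre) in enumerate(zip(packed.rule_post, packed.rule_pre)):
            W0[post, pre] = initial.plastic_weights[k]

    (
        status,
        bad_unit,
        times,
        potentials,
        activations,
        levels,
        plastic,
        u_f,
        l_f,
        d_f,
        w_f,
    ) = run_packed(
        u0,
        W0,
        l0,
        d0,
        packed.unit_tau,
        packed.unit_baseline,
        packed.mul_excit,
        packed.mul_inhib,
        packed.add_excit,
        packed.add_inhib,
        packed.pool_source,
        packed.pool_weight,
        packed.pool_threshold,
        packed.pool_tau,
        packed.pool_depletion_tau,
        packed.ext_gain,
        ext,
        dtar,
        packed.rule_post,
        packed.rule_pre,
        packed.rule_eta,
        packed.rule_th_post,
        packed.rule_th_pre,
        packed.rule_sign,
        config.dt,
        config.record_stride,
        config.stability_bound,
    )
    if status != 0:
        uid = circuit.units[bad_unit].id
        raise IntegrationError(
            f"unit {uid!r} potential exceeded the stability bound "
            f"{config.stability_bound}; parameters are pathological"
        )
    return SimTrace(
        times=times,
        unit_ids=[u.id for u in circuit.units],
        pool_ids=[p.id for p in circuit.pools],
        rule_labels=[f"{r.source}->{r.target}" for r in circuit.plastic_rules],
        unit_activations=activations,
        unit_potentials=potentials,
        pool_levels=levels,
        plastic_weights=plastic,
        final_state=FinalState(
            potentials=u_f, pool_levels=l_f, depletions=d_f, plastic_weights=w_f
        ),
    )
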