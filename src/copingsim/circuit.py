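"""Reference corticolimbic architecture, validators and protocol-level mutators.

The wiring encodes two competing loops that share the stressor input:

* an active-coping loop dominated by the prelimbic cortex (PL): PL excites
  the central amygdala (CeA), CeA excites the locus coeruleus (LC), and the
  resulting cortical norepinephrine multiplicatively boosts PL -- a
  self-feeding arousal circuit.  CeA also inhibits the GABAergic gate of the
  mesolimbic VTA, disinhibiting accumbal dopamine (the "double inhibition");
* a passive-coping loop dominated by the infralimbic cortex (IL): IL excites
  the intercalated amygdala nuclei (ITC) which inhibit CeA, excites the
  mesolimbic GABA gate directly, and is itself boosted by mesocortical
  dopamine, whose source (mcVTA, driven by the dorsal raphe) is released as
  PL's inhibition of the raphe wanes.

A single threshold-gated Hebbian connection IL -> PL, growing more negative
while the stressor persists, is what tips the competition from the first
loop to the second.

Mutators (lesions, depletion schedules, experience presets) always return a
new :class:`CircuitSpec`; a fitted circuit is never modified in place.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .dynamics import (
    Connection,
    ModulationSpec,
    NeuromodPool,
    PlasticRule,
    UnitSpec,
)

__all__ = [
    "CircuitSpec",
    "PackedCircuit",
    "ExperiencePreset",
    "LesionSpec",
    "DepletionSchedule",
    "EXPERIENCE_PRESETS",
    "LESION_PRESETS",
    "build_reference_circuit",
    "validate_circuit",
    "apply_lesion",
    "apply_experience",
    "apply_parameters",
    "extract_parameters",
    "simulate_repeated_sessions",
    "load_circuit",
    "save_circuit",
]


# Analyte/pool identifiers (pool id doubles as the analyte label).
NE_POOL = "vmPFC-NE"
DA_CORTEX_POOL = "vmPFC-DA"
DA_ACCUMBENS_POOL = "NAcc-DA"
SEROTONIN_POOL = "vmPFC-5HT"


@dataclass
class PackedCircuit:
    """Dense-array view of a circuit, consumed by the integrator."""

    unit_ids: list[str]
    pool_ids: list[str]
    unit_tau: np.ndarray
    unit_baseline: np.ndarray
    weights: np.ndarray  # weights[j, i] = weight of connection i -> j
    ext_gain: np.ndarray
    pool_source: np.ndarray
    pool_weight: np.ndarray
    pool_threshold: np.ndarray
    pool_tau: np.ndarray
    pool_depletion_tau: np.ndarray
    mul_excit: np.ndarray  # (n_units, n_pools)
    mul_inhib: np.ndarray
    add_excit: np.ndarray
    add_inhib: np.ndarray
    rule_post: np.ndarray
    rule_pre: np.ndarray
    rule_eta: np.ndarray
    rule_th_post: np.ndarray
    rule_th_pre: np.ndarray
    rule_sign: np.ndarray


@dataclass(frozen=True)
class CircuitSpec:
    """Full wiring: units, signed connections, pools, modulations, plasticity.

    ``external_targets`` maps unit ids to the gain with which each receives
    the scalar stressor drive.
    """

    units: tuple[UnitSpec, ...]
    connections: tuple[Connection, ...]
    pools: tuple[NeuromodPool, ...]
    modulations: tuple[ModulationSpec, ...]
    plastic_rules: tuple[PlasticRule, ...]
    external_targets: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "units", tuple(self.units))
        object.__setattr__(self, "connections", tuple(self.connections))
        object.__setattr__(self, "pools", tuple(self.pools))
        object.__setattr__(self, "modulations", tuple(self.modulations))
        object.__setattr__(self, "plastic_rules", tuple(self.plastic_rules))
        ext = self.external_targets
        if not isinstance(ext, Mapping):
            ext = {uid: 1.0 for uid in ext}
        object.__setattr__(self, "external_targets", dict(ext))

    # -- lookups ----------------------------------------------------------
    def unit_index(self, unit_id: str) -> int:
        for k, u in enumerate(self.units):
            if u.id == unit_id:
                return k
        raise KeyError(f"unknown unit id {unit_id!r}")

    def pool_index(self, pool_id: str) -> int:
        for k, p in enumerate(self.pools):
            if p.id == pool_id:
                return k
        raise KeyError(f"unknown pool id {pool_id!r}")

    def connection(self, source: str, target: str) -> Connection:
        for c in self.connections:
            if c.source == source and c.target == target:
                return c
        raise KeyError(f"unknown connection {source}->{target}")

    def packed(self) -> PackedCircuit:
        n = len(self.units)
        m = len(self.pools)
        uidx = {u.id: k for k, u in enumerate(self.units)}
        W = np.zeros((n, n))
        for c in self.connections:
            W[uidx[c.target], uidx[c.source]] += c.weight
        ext = np.zeros(n)
        for uid, gain in self.external_targets.items():
            ext[uidx[uid]] = gain
        mue = np.zeros((n, m))
        mud = np.zeros((n, m))
        ae = np.zeros((n, m))
        ad = np.zeros((n, m))
        pidx = {p.id: k for k, p in enumerate(self.pools)}
        for mod in self.modulations:
            j, k = uidx[mod.target], pidx[mod.pool]
            mue[j, k] += mod.mul_excit
            mud[j, k] += mod.mul_inhib
            ae[j, k] += mod.add_excit
            ad[j, k] += mod.add_inhib
        return PackedCircuit(
            unit_ids=[u.id for u in self.units],
            pool_ids=[p.id for p in self.pools],
            unit_tau=np.array([u.tau for u in self.units]),
            unit_baseline=np.array([u.baseline for u in self.units]),
            weights=W,
            ext_gain=ext,
            pool_source=np.array([uidx[p.source] for p in self.pools], dtype=np.int64),
            pool_weight=np.array([p.release_weight for p in self.pools]),
            pool_threshold=np.array([p.reuptake_threshold for p in self.pools]),
            pool_tau=np.array([p.tau for p in self.pools]),
            pool_depletion_tau=np.array([p.depletion_tau for p in self.pools]),
            mul_excit=mue,
            mul_inhib=mud,
            add_excit=ae,
            add_inhib=ad,
            rule_post=np.array(
                [uidx[r.target] for r in self.plastic_rules], dtype=np.int64
            ),
            rule_pre=np.array(
                [uidx[r.source] for r in self.plastic_rules], dtype=np.int64
            ),
            rule_eta=np.array([r.learning_rate for r in self.plastic_rules]),
            rule_th_post=np.array([r.post_threshold for r in self.plastic_rules]),
            rule_th_pre=np.array([r.pre_threshold for r in self.plastic_rules]),
            rule_sign=np.array([float(r.sign) for r in self.plastic_rules]),
        )


@dataclass(frozen=True)
class ExperiencePreset:
    """Prior-restraint memory, encoded as the initial IL->PL weight.

    More negative means more prior experience; the transition between
    "timing as in naive animals" and "anticipated passive phase" sits near
    a critical weight of about -1.
    """

    label: str
    initial_ilpl_weight: float
    rationale: str = ""


@dataclass(frozen=True)
class LesionSpec:
    """Disconnection: the listed connection weights are set to exactly zero."""

    label: str
    connections_to_zero: tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class DepletionSchedule:
    """Experimental depletion of one pool's release.

    ``onset`` is in minutes of recorded time; an onset of 0 means the
    depletion is established before the session (it is active throughout the
    pre-recording settling period, as after a depletion surgery).
    """

    pool: str
    target_fraction: float
    onset: float = 0.0
    tau: float = 20.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_fraction <= 1.0:
            raise ValueError("target_fraction must be in [0, 1]")
        if self.onset < 0:
            raise ValueError("onset must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")


# ---------------------------------------------------------------------------
# Reference architecture
# ---------------------------------------------------------------------------

#: Default parameter assignment of the reference circuit.  These values are
#: the fitted reference parameters (see data/reference_fit.json); signs are
#: fixed by anatomy, magnitudes by the fit.
REFERENCE_PARAMETERS: dict[str, float] = {
    # unit intrinsic drives (negative = activation threshold)
    "unit:OFC/ACC:baseline": 0.0,
    "unit:PL:baseline": 0.0,
    "unit:IL:baseline": 0.05,
    "unit:ITC:baseline": 0.0,
    "unit:CeA:baseline": -0.44,
    "unit:LC:baseline": 0.3,
    "unit:DR:baseline": 0.15,
    "unit:mcVTA-DA:baseline": -0.05,
    "unit:mlVTA-GABA:baseline": 0.7,
    "unit:mlVTA-DA:baseline": 1.1,
    # unit time constants (minutes)
    "unit:OFC/ACC:tau": 5.0,
    "unit:PL:tau": 5.0,
    "unit:IL:tau": 5.0,
    "unit:ITC:tau": 4.0,
    "unit:CeA:tau": 5.0,
    "unit:LC:tau": 5.0,
    "unit:DR:tau": 4.0,
    "unit:mcVTA-DA:tau": 5.0,
    "unit:mlVTA-DA:tau": 5.0,
    "unit:mlVTA-GABA:tau": 5.0,
    # stressor gains
    "ext:OFC/ACC": 1.0,
    "ext:PL": 0.15,
    "ext:IL": 0.01,
    "ext:CeA": 0.08,
    "ext:DR": 0.35,
    # connection weights (magnitudes; signs fixed by anatomy)
    "conn:OFC/ACC->LC": 0.01,
    "conn:CeA->LC": 1.8,
    "conn:PL->CeA": 2.6,
    "conn:PL->DR": 0.38,
    "conn:PL->mlVTA-GABA": 0.05,
    "conn:IL->ITC": 0.6,
    "conn:ITC->CeA": 0.4,
    "conn:IL->mlVTA-GABA": 0.6,
    "conn:CeA->mlVTA-GABA": 1.8,
    "conn:mlVTA-GABA->mlVTA-DA": 1.2,
    "conn:DR->mcVTA-DA": 1.2,
    "conn:IL->PL": 0.1,  # magnitude of the naive initial plastic weight
    # pools
    "pool:vmPFC-NE:tau": 6.0,
    "pool:vmPFC-NE:reuptake_threshold": 1.05,
    "pool:vmPFC-NE:release_weight": 1.0,
    "pool:vmPFC-DA:tau": 60.0,
    "pool:vmPFC-DA:reuptake_threshold": 1.3,
    "pool:vmPFC-DA:release_weight": 1.0,
    "pool:NAcc-DA:tau": 7.0,
    "pool:NAcc-DA:reuptake_threshold": 1.3,
    "pool:NAcc-DA:release_weight": 1.0,
    "pool:vmPFC-5HT:tau": 20.0,
    "pool:vmPFC-5HT:reuptake_threshold": 1.3,
    "pool:vmPFC-5HT:release_weight": 1.0,
    # modulation coefficients
    "mod:vmPFC-NE->PL:mul_excit": 12.0,
    "mod:vmPFC-NE->IL:mul_inhib": 0.8,
    "mod:vmPFC-DA->IL:mul_excit": 6.0,
    "mod:vmPFC-DA->IL:add_excit": 0.3,
    # plasticity
    "plastic:IL->PL:learning_rate": 1.6,
    "plastic:IL->PL:pre_threshold": 0.03,
    "plastic:IL->PL:post_threshold": 0.3,
}

#: Sign of each connection in the reference wiring (+1 excitatory,
#: -1 inhibitory); parameters store magnitudes only.
CONNECTION_SIGNS: dict[tuple[str, str], int] = {
    ("OFC/ACC", "LC"): +1,
    ("CeA", "LC"): +1,
    ("PL", "CeA"): +1,
    ("PL", "DR"): -1,
    ("PL", "mlVTA-GABA"): +1,
    ("IL", "ITC"): +1,
    ("ITC", "CeA"): -1,
    ("IL", "mlVTA-GABA"): +1,
    ("CeA", "mlVTA-GABA"): -1,
    ("mlVTA-GABA", "mlVTA-DA"): -1,
    ("DR", "mcVTA-DA"): +1,
    ("IL", "PL"): -1,
}

_UNIT_IDS = (
    "OFC/ACC",
    "PL",
    "IL",
    "ITC",
    "CeA",
    "LC",
    "DR",
    "mcVTA-DA",
    "mlVTA-DA",
    "mlVTA-GABA",
)

_POOLS = (
    # (id, source unit, target area)
    (NE_POOL, "LC", "vmPFC"),
    (DA_CORTEX_POOL, "mcVTA-DA", "vmPFC"),
    (DA_ACCUMBENS_POOL, "mlVTA-DA", "NAcc"),
    (SEROTONIN_POOL, "DR", "vmPFC"),
)


def build_reference_circuit(
    parameters: Mapping[str, float] | None = None,
) -> CircuitSpec:
    """Canonical 10-population wiring with the fitted reference parameters.

    ``parameters`` overrides entries of :data:`REFERENCE_PARAMETERS` (flat
    keys such as ``"conn:PL->CeA"`` or ``"mod:vmPFC-NE->PL:mul_excit"``);
    connection values are magnitudes, signed by the anatomy.
    """
    p = dict(REFERENCE_PARAMETERS)
    if parameters:
        unknown = set(parameters) - set(p)
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        p.update(parameters)

    units = tuple(
        UnitSpec(
            id=uid,
            tau=p[f"unit:{uid}:tau"],
            baseline=p[f"unit:{uid}:baseline"],
        )
        for uid in _UNIT_IDS
    )
    connections = []
    for (src, tgt), sign in CONNECTION_SIGNS.items():
        mag = p[f"conn:{src}->{tgt}"]
        connections.append(
            Connection(
                source=src,
                target=tgt,
                weight=sign * abs(mag),
                plastic=(src, tgt) == ("IL", "PL"),
            )
        )
    pools = tuple(
        NeuromodPool(
            id=pid,
            source=src,
            target_area=area,
            tau=p[f"pool:{pid}:tau"],
            reuptake_threshold=p[f"pool:{pid}:reuptake_threshold"],
            release_weight=p[f"pool:{pid}:release_weight"],
        )
        for pid, src, area in _POOLS
    )
    modulations = (
        ModulationSpec(
            pool=NE_POOL, target="PL", mul_excit=p["mod:vmPFC-NE->PL:mul_excit"]
        ),
        ModulationSpec(
            pool=NE_POOL, target="IL", mul_inhib=p["mod:vmPFC-NE->IL:mul_inhib"]
        ),
        ModulationSpec(
            pool=DA_CORTEX_POOL,
            target="IL",
            mul_excit=p["mod:vmPFC-DA->IL:mul_excit"],
            add_excit=p["mod:vmPFC-DA->IL:add_excit"],
        ),
    )
    rules = (
        PlasticRule(
            source="IL",
            target="PL",
            learning_rate=p["plastic:IL->PL:learning_rate"],
            pre_threshold=p["plastic:IL->PL:pre_threshold"],
            post_threshold=p["plastic:IL->PL:post_threshold"],
            sign=-1,
        ),
    )
    external = {uid: p[f"ext:{uid}"] for uid in ("OFC/ACC", "PL", "IL", "CeA", "DR")}
    return CircuitSpec(
        units=units,
        connections=tuple(connections),
        pools=pools,
        modulations=modulations,
        plastic_rules=rules,
        external_targets=external,
    )


#: Experience presets: naive = fitted initial weight; medium sits at the
#: critical value of about -1; short/long straddle it.
EXPERIENCE_PRESETS: dict[str, ExperiencePreset] = {
    "naive": ExperiencePreset("naive", -REFERENCE_PARAMETERS["conn:IL->PL"],
                              "first restraint exposure (fitted value)"),
    "short": ExperiencePreset("short", -0.5, "few brief prior exposures"),
    "medium": ExperiencePreset("medium", -1.0, "critical prior experience"),
    "long": ExperiencePreset("long", -1.5, "repeated prolonged exposures"),
}

LESION_PRESETS: dict[str, LesionSpec] = {
    "PL-VTA": LesionSpec("PL-VTA", (("PL", "mlVTA-GABA"),)),
    "IL-VTA": LesionSpec("IL-VTA", (("IL", "mlVTA-GABA"),)),
}


# ---------------------------------------------------------------------------
# Validation and mutators
# ---------------------------------------------------------------------------

def validate_circuit(circuit: CircuitSpec) -> list[str]:
    """Referential and sign checks; returns one message per violation."""
    violations: list[str] = []
    unit_ids = [u.id for u in circuit.units]
    if len(set(unit_ids)) != len(unit_ids):
        violations.append("duplicate unit ids")
    pool_ids = [p.id for p in circuit.pools]
    if len(set(pool_ids)) != len(pool_ids):
        violations.append("duplicate pool ids")
    for c in circuit.connections:
        for endpoint in (c.source, c.target):
            if endpoint not in unit_ids:
                violations.append(
                    f"connection {c.source}->{c.target}: unknown unit {endpoint!r}"
                )
        if c.source == c.target:
            violations.append(f"connection {c.source}->{c.target}: self-recurrence")
    for p in circuit.pools:
        if p.source not in unit_ids:
            violations.append(f"pool {p.id!r}: unknown source unit {p.source!r}")
    for mod in circuit.modulations:
        if mod.pool not in pool_ids:
            violations.append(f"modulation on {mod.target!r}: unknown pool {mod.pool!r}")
        if mod.target not in unit_ids:
            violations.append(f"modulation of {mod.pool!r}: unknown unit {mod.target!r}")
    conn_map = {(c.source, c.target): c for c in circuit.connections}
    for r in circuit.plastic_rules:
        key = (r.source, r.target)
        if key not in conn_map:
            violations.append(f"plastic rule on unknown connection {r.source}->{r.target}")
            continue
        conn = conn_map[key]
        if not conn.plastic:
            violations.append(
                f"plastic rule on connection {r.source}->{r.target} not marked plastic"
            )
        if conn.weight != 0.0 and np.sign(conn.weight) != r.sign:
            violations.append(
                f"plastic rule sign {r.sign:+d} contradicts connection "
                f"{r.source}->{r.target} weight {conn.weight}"
            )
    for uid in circuit.external_targets:
        if uid not in unit_ids:
            violations.append(f"external target {uid!r} is not a unit")
    if not circuit.external_targets:
        violations.append("external_targets is empty")
    return violations


def apply_lesion(circuit: CircuitSpec, lesion: LesionSpec) -> CircuitSpec:
    """Copy of the circuit with the listed connection weights set to zero."""
    pairs = set(lesion.connections_to_zero)
    existing = {(c.source, c.target) for c in circuit.connections}
    missing = pairs - existing
    if missing:
        raise KeyError(f"lesion {lesion.label!r}: unknown connections {sorted(missing)}")
    connections = tuple(
        dataclasses.replace(c, weight=0.0) if (c.source, c.target) in pairs else c
        for c in circuit.connections
    )
    return dataclasses.replace(circuit, connections=connections)


def apply_experience(circuit: CircuitSpec, preset: ExperiencePreset) -> CircuitSpec:
    """Copy of the circuit with the plastic IL->PL weight initialised to the preset."""
    connections = tuple(
        dataclasses.replace(c, weight=float(preset.initial_ilpl_weight))
        if c.plastic
        else c
        for c in circuit.connections
    )
    return dataclasses.replace(circuit, connections=connections)


def apply_parameters(
    circuit_or_params: Mapping[str, float], parameters: Mapping[str, float] | None = None
) -> CircuitSpec:
    """Build a reference-architecture circuit from a flat parameter mapping."""
    if parameters is None:
        parameters = circuit_or_params
    return build_reference_circuit(parameters)


def extract_parameters(circuit: CircuitSpec) -> dict[str, float]:
    """Flat parameter mapping (magnitudes) for a reference-architecture circuit."""
    p: dict[str, float] = {}
    for u in circuit.units:
        p[f"unit:{u.id}:baseline"] = u.baseline
        p[f"unit:{u.id}:tau"] = u.tau
    for c in circuit.connections:
        p[f"conn:{c.source}->{c.target}"] = abs(c.weight)
    for pool in circuit.pools:
        p[f"pool:{pool.id}:tau"] = pool.tau
        p[f"pool:{pool.id}:reuptake_threshold"] = pool.reuptake_threshold
        p[f"pool:{pool.id}:release_weight"] = pool.release_weight
    for mod in circuit.modulations:
        base = f"mod:{mod.pool}->{mod.target}"
        for name in ("mul_excit", "mul_inhib", "add_excit", "add_inhib"):
            v = getattr(mod, name)
            if v:
                p[f"{base}:{name}"] = v
    for r in circuit.plastic_rules:
        base = f"plastic:{r.source}->{r.target}"
        p[f"{base}:learning_rate"] = r.learning_rate
        p[f"{base}:pre_threshold"] = r.pre_threshold
        p[f"{base}:post_threshold"] = r.post_threshold
    for uid, gain in circuit.external_targets.items():
        p[f"ext:{uid}"] = gain
    return p


def simulate_repeated_sessions(
    circuit: CircuitSpec,
    n_sessions: int,
    recovery_fraction: float = 0.05,
    protocol=None,
    integrator_config=None,
):
    """Run the restraint protocol repeatedly with partial overnight recovery.

    Between sessions the learned IL->PL weight relaxes toward the circuit's
    initial (naive) value by ``recovery_fraction`` (1 = full recovery, 0 =
    none; the 5% default keeps five daily sessions inside the
    long-experience regime).  Returns the list of per-session traces.
    """
    from .protocols import Protocol, run_experiment

    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    if not 0.0 <= recovery_fraction <= 1.0:
        raise ValueError("recovery_fraction must be in [0, 1]")
    if protocol is None:
        protocol = Protocol()
    naive = next(c.weight for c in circuit.connections if c.plastic)
    traces = []
    current = circuit
    for _ in range(n_sessions):
        trace = run_experiment(current, protocol, integrator_config)
        traces.append(trace)
        w_final = float(trace.final_state.plastic_weights[0])
        w_next = w_final + recovery_fraction * (naive - w_final)
        current = apply_experience(
            current, ExperiencePreset("session-start", w_next)
        )
    return traces


# ---------------------------------------------------------------------------
# Serialization (lossless YAML/JSON round trip)
# ---------------------------------------------------------------------------

def circuit_to_dict(circuit: CircuitSpec) -> dict:
    return {
        "units": [dataclasses.asdict(u) for u in circuit.units],
        "connections": [dataclasses.asdict(c) for c in circuit.connections],
        "pools": [dataclasses.asdict(p) for p in circuit.pools],
        "modulations": [dataclasses.asdict(m) for m in circuit.modulations],
        "plastic_rules": [dataclasses.asdict(r) for r in circuit.plastic_rules],
        "external_targets": dict(circuit.external_targets),
    }


def circuit_from_dict(data: Mapping) -> CircuitSpec:
    return CircuitSpec(
        units=tuple(UnitSpec(**u) for u in data["units"]),
        connections=tuple(Connection(**c) for c in data["connections"]),
        pools=tuple(NeuromodPool(**p) for p in data["pools"]),
        modulations=tuple(ModulationSpec(**m) for m in data["modulations"]),
        plastic_rules=tuple(PlasticRule(**r) for r in data["plastic_rules"]),
        external_targets=dict(data["external_targets"]),
    )


def save_circuit(circuit: CircuitSpec, path: str | Path) -> None:
    path = Path(path)
    data = circuit_to_dict(circuit)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))


def load_circuit(path: str | Path) -> CircuitSpec:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return circuit_from_dict(data)
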