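#!/usr/bin/env python
"""Produce the committed reference fit (src/copingsim/data/reference_fit.json).

Runs the package's seeded genetic algorithm against the canonical target
curves for the sham and two depletion conditions, with the qualitative
shape-constraint suite (including the long-experience and IL-VTA lesion
predictions) as a penalty so the polished optimum stays inside the regime
that satisfies every printed statement.  The hand-designed reference
assignment seeds the initial population.

Usage: python scripts/fit_reference.py [--population N] [--generations N]
"""

from __future__ import annotations

import argparse
import dataclasses
from pathlib import Path

from copingsim.circuit import (
    EXPERIENCE_PRESETS,
    LESION_PRESETS,
    build_reference_circuit,
    extract_parameters,
)
from copingsim.fitting import (
    CONDITIONS,
    GAConfig,
    ShapeConstraint,
    canonical_targets,
    check_constraints,
    default_constraints,
    evaluate_parameters,
    ga_fit,
    reference_bounds,
)
from copingsim.protocols import Protocol, default_conditions


def extended_conditions():
    conditions = default_conditions()
    conditions["long"] = dataclasses.replace(
        Protocol(), experience=EXPERIENCE_PRESETS["long"]
    )
    conditions["IL-VTA"] = dataclasses.replace(
        Protocol(), lesion=LESION_PRESETS["IL-VTA"]
    )
    return conditions


def extended_constraints():
    cons = default_constraints()
    cons += [
        # anticipated passive phase and lost NE response with long experience
        ShapeConstraint("NAcc-DA", "long", "below-baseline-after", (20, 60)),
        ShapeConstraint("NAcc-DA", "long", "no-rise", (0, 60), margin=10.0),
        ShapeConstraint("vmPFC-NE", "long", "no-rise", (0, 240), margin=25.0),
        # IL-VTA disconnection: baseline accumbal DA in the second half
        ShapeConstraint("NAcc-DA", "IL-VTA", "within-band", (160, 240), margin=5.0),
    ]
    return cons


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--population", type=int, default=48)
    parser.add_argument("--generations", type=int, default=40)
    parser.add_argument("--seed", type=int, default=1234)
    parser.add_argument(
        "--out",
        default=str(
            Path(__file__).resolve().parents[1]
            / "src" / "copingsim" / "data" / "reference_fit.json"
        ),
    )
    args = parser.parse_args()

    targets = [canonical_targets(c) for c in CONDITIONS]
    conditions = extended_conditions()
    constraints = extended_constraints()

    def objective(params):
        return evaluate_parameters(
            params,
            targets,
            protocols=conditions,
            constraints=constraints,
            constraint_penalty=2e4,
        )

    ga = GAConfig(
        population_size=args.population,
        generations=args.generations,
        seed=args.seed,
        parameter_bounds=reference_bounds(width=0.15),
    )
    template = extract_parameters(build_reference_circuit())
    result = ga_fit(objective, ga, template=template)
    result.constraints_report = check_constraints(
        result, constraints=constraints, protocols=conditions
    )
    failed = [r for r in result.constraints_report if not r["passed"]]
    print(f"best error: {result.best_error:.1f}")
    for r in result.constraints_report:
        mark = "PASS" if r["passed"] else "FAIL"
        print(f"  {mark} {r['condition']:12s} {r['analyte']:9s} {r['kind']:22s}"
              f" measured={r['measured']}")
    if failed:
        raise SystemExit(f"{len(failed)} constraints failed; not writing the fixture")
    result.to_json(args.out)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
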