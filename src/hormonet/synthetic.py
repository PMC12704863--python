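"""Seeded generators for synthetic logic-based networks, plus oracles.

These networks exist so that every pipeline stage (simulation, calibration,
screens, Sobol analysis) can be exercised and property-tested without the
packaged hypertrophy network: bounded activities, AND/OR rule combination,
inhibitor terms, source-driven inputs, and at least one negative-feedback
motif in the cyclic generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import (
    ACTIVATOR,
    INHIBITOR,
    HillParams,
    NetworkModel,
    ReactionRule,
    SimulationResult,
    SpeciesNode,
)

__all__ = [
    "SyntheticSpec",
    "generate",
    "fixed_point_oracle",
    "planted_calibration_fixture",
]

TOPOLOGIES = (
    "chain",
    "tree",
    "random_dag",
    "random_cyclic",
    "motif_and",
    "motif_or",
    "motif_inhibition",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic network; generation is seed-deterministic."""

    n_species: int = 6
    topology: str = "random_dag"
    edge_density: float = 0.4
    inhibitor_fraction: float = 0.25
    input_weight: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.topology.startswith("motif"):
            pass  # motifs have fixed size
        elif self.n_species < 3:
            raise ValueError("need at least 3 species (input, interior, output)")
        if not 0.0 < self.edge_density <= 1.0:
            raise ValueError("edge density must be in (0, 1]")


def _species(names, tau=0.1):
    return [SpeciesNode(name=n, tau=tau) for n in names]


def _rule(product, *terms, weight=1.0):
    return ReactionRule(product=product, terms=tuple(terms), weight=weight,
                        hill=HillParams())


def generate(spec: SyntheticSpec) -> NetworkModel:
    """Build a validated :class:`NetworkModel` from a :class:`SyntheticSpec`."""
    rng = np.random.default_rng(spec.seed)
    w = spec.input_weight

    if spec.topology == "motif_and":
        names = ["U1", "U2", "OUT"]
        rules = [
            _rule("U1", weight=w),
            _rule("U2", weight=w),
            _rule("OUT", ("U1", ACTIVATOR), ("U2", ACTIVATOR)),
        ]
        return NetworkModel(_species(names), rules, inputs=["U1", "U2"], output="OUT")
    if spec.topology == "motif_or":
        names = ["U1", "U2", "OUT"]
        rules = [
            _rule("U1", weight=w),
            _rule("U2", weight=w),
            _rule("OUT", ("U1", ACTIVATOR)),
            _rule("OUT", ("U2", ACTIVATOR)),
        ]
        return NetworkModel(_species(names), rules, inputs=["U1", "U2"], output="OUT")
    if spec.topology == "motif_inhibition":
        names = ["U", "R", "OUT"]
        rules = [
            _rule("U", weight=w),
            _rule("R", ("U", ACTIVATOR)),
            _rule("OUT", ("R", INHIBITOR)),
        ]
        return NetworkModel(_species(names), rules, inputs=["U"], output="OUT")

    n = spec.n_species
    names = ["IN"] + [f"N{i}" for i in range(1, n - 1)] + ["OUT"]
    rules = [_rule("IN", weight=w)]

    if spec.topology == "chain":
        for prev, cur in zip(names, names[1:]):
            rules.append(_rule(cur, (prev, ACTIVATOR)))
    elif spec.topology == "tree":
        for i, cur in enumerate(names[1:], start=1):
            parent = names[int(rng.integers(0, i))]
            rules.append(_rule(cur, (parent, ACTIVATOR)))
    elif spec.topology in ("random_dag", "random_cyclic"):
        for i, cur in enumerate(names[1:], start=1):
            k = max(1, int(rng.binomial(i, spec.edge_density)))
            parents = rng.choice(i, size=min(k, i), replace=False)
            terms = []
            for p in parents:
                sign = (
                    INHIBITOR
                    if rng.random() < spec.inhibitor_fraction
                    else ACTIVATOR
                )
                terms.append((names[int(p)], sign))
            if len(terms) > 1 and rng.random() < 0.5:
                # split into OR-combined single-term rules
                for t in terms:
                    rules.append(_rule(cur, t))
            else:
                rules.append(_rule(cur, *terms))
        if spec.topology == "random_cyclic":
            # back-edges, including one guaranteed negative feedback
            hi = int(rng.integers(1, n - 1))
            lo = int(rng.integers(1, hi + 1))
            rules.append(_rule(names[lo], (names[hi], INHIBITOR)))
            n_extra = max(0, int(rng.binomial(n, spec.edge_density / 2)) - 1)
            for _ in range(n_extra):
                a = int(rng.integers(1, n))
                b = int(rng.integers(1, n))
                if a == b:
                    continue
                src, dst = max(a, b), min(a, b)
                sign = (
                    INHIBITOR
                    if rng.random() < spec.inhibitor_fraction
                    else ACTIVATOR
                )
                rules.append(_rule(names[dst], (names[src], sign)))
    return NetworkModel(_species(names), rules, inputs=["IN"], output="OUT")


def fixed_point_oracle(
    model: NetworkModel,
    clamps=None,
    y_start=None,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    alpha: float = 0.5,
) -> SimulationResult:
    """Damped fixed-point iteration ``y <- (1-a) y + a Phi(y) ymax``.

    Solves the same steady-state equation as the ODE integrator through an
    entirely different route; used as an independent oracle in tests and as
    a fast path for large perturbation batches.  Non-convergence after
    ``max_iter`` sweeps is flagged in the result, not raised.
    """
    clamps = dict(clamps or {})
    y = model.y0.copy() if y_start is None else np.array(y_start, dtype=float)
    cidx = np.array([model.index[k] for k in clamps], dtype=int)
    cval = np.array([clamps[k] for k in clamps])
    if cidx.size:
        y[cidx] = cval
    converged = False
    for it in range(max_iter):
        target = model.phi(y) * model.ymax
        if cidx.size:
            target[cidx] = cval
        y_new = (1.0 - alpha) * y + alpha * target
        delta = float(np.max(np.abs(y_new - y)))
        y = y_new
        if delta < tol * alpha:
            converged = True
            break
    if cidx.size:
        y[cidx] = cval
    dy = (model.phi(y) * model.ymax - y) / model.tau
    if cidx.size:
        dy[cidx] = 0.0
    residual = float(np.max(np.abs(dy)))
    names = [s.name for s in model.species]
    return SimulationResult(
        times=np.array([0.0]),
        activities=y[None, :],
        species=names,
        steady_state=dict(zip(names, y)),
        converged=converged,
        residual=residual,
    )


def planted_calibration_fixture(seed: int, n_species: int = 6):
    """Network with a hidden input weight for calibration recovery tests.

    Generates a monotone (inhibitor-free) random DAG, draws a true input
    weight, records the steady-state output it produces, then resets the
    weight.  Returns ``(model, weight_name, true_weight, target_value)``.
    """
    rng = np.random.default_rng(seed)
    spec = SyntheticSpec(
        n_species=n_species,
        topology="random_dag",
        edge_density=0.6,
        inhibitor_fraction=0.0,
        input_weight=0.5,
        seed=seed,
    )
    model = generate(spec)
    w_true = float(rng.uniform(0.15, 0.85))
    planted = model.with_input_weights({"IN": w_true})
    target = fixed_point_oracle(planted).steady_state[model.output]
    return model.with_input_weights({"IN": 0.5}), "IN", w_true, target
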