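"""Logic-based normalized-Hill ODE engine.

Every species in a network carries a dimensionless activity ``y`` in
``[ymin, ymax]`` (``ymin`` is 0 network-wide).  A reaction transmits the
activity of its regulators to a product through normalized Hill functions

    f_act(x) = W * B * x**n / (K**n + x**n)
    f_inh(x) = W - f_act(x)

with the gain ``B`` and half-saturation constant ``K`` fixed by the
half-maximal point ``EC50``:

    B = (EC50**n - 1) / (2 * EC50**n - 1),     K = (B - 1) ** (1 / n)

so that ``f_act(0) = 0``, ``f_act(EC50) = W/2`` and ``f_act(1) = W``.
Multi-regulator reactions combine term values with AND (product); several
reactions sharing a product combine with inclusion-exclusion OR.  Each
species then relaxes toward its logic drive:

    dy_i/dt = (Phi_i(y) * ymax_i - y_i) / tau_i

Clamped species are pinned exactly: the state is overwritten with the clamp
value and the derivative is zero (the "tau -> infinity" contract).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "HillParams",
    "SpeciesNode",
    "ReactionRule",
    "NetworkModel",
    "SimulationResult",
    "hill_activation",
    "hill_inhibition",
    "logic_and",
    "logic_or",
    "build_rhs",
    "integrate_to_steady_state",
    "DEFAULT_HILL_N",
    "DEFAULT_EC50",
    "DEFAULT_TAU",
    "STEADY_STATE_TOL",
]

DEFAULT_HILL_N = 1.4
DEFAULT_EC50 = 0.5
DEFAULT_TAU = 0.1  # hours
STEADY_STATE_TOL = 1e-6  # h^-1, max |dy/dt| accepted as steady


class ModelError(ValueError):
    """Raised for structurally invalid networks or clamp targets."""


@dataclass(frozen=True)
class HillParams:
    """Hill coefficient and EC50 of one reaction, with derived B and K.

    Parameters
    ----------
    n : float
        Hill coefficient; must exceed 1 for B and K to be defined.
    ec50 : float
        Regulator activity at which the reaction is half-maximal, in (0, 1).
    """

    n: float = DEFAULT_HILL_N
    ec50: float = DEFAULT_EC50

    def __post_init__(self) -> None:
        if not self.n > 1:
            raise ValueError(f"Hill coefficient must be > 1, got {self.n}")
        if not 0.0 < self.ec50 < 1.0:
            raise ValueError(f"EC50 must lie in (0, 1), got {self.ec50}")
        if 2.0 * self.ec50**self.n - 1.0 >= 0.0:
            # B would be negative and K complex; the normalized form needs
            # EC50**n < 1/2, i.e. EC50 below 2**(-1/n)
            raise ValueError(
                f"EC50={self.ec50} too large for n={self.n}; "
                f"requires EC50 < {2 ** (-1 / self.n):.4f}"
            )

    @property
    def B(self) -> float:
        e = self.ec50**self.n
        return (e - 1.0) / (2.0 * e - 1.0)

    @property
    def K(self) -> float:
        return (self.B - 1.0) ** (1.0 / self.n)


def hill_activation(x, W=1.0, hill: HillParams = HillParams()):
    """Normalized Hill activation ``f_act(x) = W B x^n / (K^n + x^n)``.

    ``x`` may be a scalar or array of activities in [0, 1]; ``W`` is the
    reaction weight in [0, 1].  The result lies in [0, W].
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < -1e-12) or np.any(x > 1.0 + 1e-12):
        raise ValueError(f"activity outside [0, 1]: {x}")
    if not 0.0 <= W <= 1.0:
        raise ValueError(f"weight outside [0, 1]: {W}")
    x = np.clip(x, 0.0, 1.0)
    xn = x**hill.n
    out = W * hill.B * xn / (hill.K**hill.n + xn)
    return out if out.ndim else float(out)


def hill_inhibition(x, W=1.0, hill: HillParams = HillParams()):
    """Normalized Hill inhibition ``f_inh(x) = W - f_act(x)``."""
    act = hill_activation(x, W, hill)
    return W - act


def _check_unit(name, *vals) -> None:
    for v in vals:
        if np.any(np.asarray(v) < -1e-12) or np.any(np.asarray(v) > 1 + 1e-12):
            raise ValueError(f"{name}: operand outside [0, 1]: {v}")


def logic_and(a, b):
    """AND gate: product of two term activities; bounded by min(a, b)."""
    _check_unit("logic_and", a, b)
    return a * b


def logic_or(a, b):
    """OR gate: inclusion-exclusion ``a + b - a*b``; at least max(a, b).

    Folded left-to-right over more than two reactions; the operation is
    associative and commutative, so the fold order only matters at the
    level of floating-point round-off.
    """
    _check_unit("logic_or", a, b)
    return a + b - a * b


ACTIVATOR = 1
INHIBITOR = -1


@dataclass(frozen=True)
class SpeciesNode:
    """One network species.

    Activity is bounded in ``[0, ymax]`` (ymin is fixed at 0); ``tau`` is
    the relaxation time constant in hours.
    """

    name: str
    y0: float = 0.0
    ymax: float = 1.0
    tau: float = DEFAULT_TAU
    display_name: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.y0 <= self.ymax:
            raise ValueError(
                f"{self.name}: y0={self.y0} outside [0, ymax={self.ymax}]"
            )
        if self.tau <= 0:
            raise ValueError(f"{self.name}: tau must be positive, got {self.tau}")


@dataclass(frozen=True)
class ReactionRule:
    """One reaction: signed regulator terms -> product.

    An empty term list denotes a source (input) reaction whose drive is the
    constant ``weight``; interior reactions AND their terms together, each
    term contributing ``f_act`` (activator) or ``f_inh`` (inhibitor).
    """

    product: str
    terms: tuple[tuple[str, int], ...] = ()
    weight: float = 1.0
    hill: HillParams = field(default_factory=HillParams)

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"{self.product}: weight outside [0, 1]: {self.weight}")
        for _, sign in self.terms:
            if sign not in (ACTIVATOR, INHIBITOR):
                raise ValueError(f"bad term sign {sign}")

    @property
    def is_source(self) -> bool:
        return not self.terms

    def contribution(self, activities: Mapping[str, float] | np.ndarray,
                     index: Mapping[str, int] | None = None):
        """Evaluate this reaction's drive given current activities."""
        if self.is_source:
            return self.weight
        c = None
        for name, sign in self.terms:
            x = activities[name] if index is None else activities[..., index[name]]
            f = (hill_activation if sign == ACTIVATOR else hill_inhibition)(
                x, self.weight, self.hill
            )
            # weight applies once per reaction; fold further terms at W=1
            if c is None:
                c = f
            else:
                g = (hill_activation if sign == ACTIVATOR else hill_inhibition)(
                    x, 1.0, self.hill
                )
                c = logic_and(c, g)
        return c


class NetworkModel:
    """Species, reactions and input/output designations; compiles to an ODE.

    Parameters
    ----------
    species : sequence of SpeciesNode
    rules : sequence of ReactionRule
    inputs : names of species driven only by source reactions
    output : designated output species (e.g. ``CellArea``)
    """

    def __init__(
        self,
        species: Sequence[SpeciesNode],
        rules: Sequence[ReactionRule],
        inputs: Sequence[str] = (),
        output: str | None = None,
    ) -> None:
        self.species = list(species)
        self.rules = list(rules)
        self.inputs = list(inputs)
        self.output = output
        self.index = {s.name: i for i, s in enumerate(self.species)}
        if len(self.index) != len(self.species):
            raise ModelError("duplicate species names")
        self._validate()
        self._compile()

    # -- construction -----------------------------------------------------
    def _validate(self) -> None:
        products = {r.product for r in self.rules}
        for r in self.rules:
            if r.product not in self.index:
                raise ModelError(f"rule product {r.product!r} not in species list")
            for name, _ in r.terms:
                if name not in self.index:
                    raise ModelError(f"rule term {name!r} not in species list")
        for s in self.species:
            if s.name not in products and s.name not in self.inputs:
                raise ModelError(
                    f"species {s.name!r} has no reaction and is not a declared input"
                )
        for name in self.inputs:
            if name not in self.index:
                raise ModelError(f"declared input {name!r} not in species list")
            if any(r.product == name and not r.is_source for r in self.rules):
                raise ModelError(f"input {name!r} has a non-source reaction")
        if self.output is not None and self.output not in self.index:
            raise ModelError(f"output {self.output!r} not in species list")

    def _compile(self) -> None:
        # group reactions by product, preserving file order for the OR fold
        self._by_product: dict[int, list[ReactionRule]] = {}
        for r in self.rules:
            self._by_product.setdefault(self.index[r.product], []).append(r)
        self.ymax = np.array([s.ymax for s in self.species])
        self.tau = np.array([s.tau for s in self.species])
        self.y0 = np.array([s.y0 for s in self.species])
        # flat arrays for vectorized evaluation: rules sorted by product,
        # terms concatenated in rule order (OR is associative, so grouping
        # by product is equivalent to file-order folding up to round-off)
        order = sorted(range(len(self.rules)), key=lambda k: self.index[self.rules[k].product])
        t_idx, t_inh, t_B, t_Kn, t_n, t_rule = [], [], [], [], [], []
        r_prod, r_w, r_nterm = [], [], []
        for pos, k in enumerate(order):
            r = self.rules[k]
            r_prod.append(self.index[r.product])
            r_w.append(r.weight)
            r_nterm.append(len(r.terms))
            for name, sign in r.terms:
                t_idx.append(self.index[name])
                t_inh.append(sign == INHIBITOR)
                t_B.append(r.hill.B)
                t_Kn.append(r.hill.K ** r.hill.n)
                t_n.append(r.hill.n)
                t_rule.append(pos)
        self._t_idx = np.array(t_idx, dtype=int)
        self._t_inh = np.array(t_inh, dtype=bool)
        self._t_B = np.array(t_B)
        self._t_Kn = np.array(t_Kn)
        self._t_n = np.array(t_n)
        self._r_prod = np.array(r_prod, dtype=int)
        self._r_w = np.array(r_w)
        self._r_is_source = np.array(r_nterm, dtype=int) == 0
        # reduceat boundaries over terms (per rule) and rules (per product)
        self._term_starts = np.concatenate(([0], np.cumsum(r_nterm)))[:-1]
        prod_changes = np.flatnonzero(np.diff(self._r_prod, prepend=-1))
        self._rule_starts = prod_changes
        self._prod_of_group = self._r_prod[prod_changes]

    # -- convenience ------------------------------------------------------
    def with_input_weights(self, weights: Mapping[str, float]) -> "NetworkModel":
        """Return a copy with source-reaction weights replaced per input."""
        unknown = set(weights) - set(self.inputs)
        if unknown:
            raise ModelError(f"not input species: {sorted(unknown)}")
        new_rules = []
        for r in self.rules:
            if r.is_source and r.product in weights:
                new_rules.append(replace(r, weight=float(weights[r.product])))
            else:
                new_rules.append(r)
        return NetworkModel(self.species, new_rules, self.inputs, self.output)

    def input_weights(self) -> dict[str, float]:
        return {
            r.product: r.weight for r in self.rules if r.is_source
        }

    # -- evaluation -------------------------------------------------------
    def phi(self, y: np.ndarray) -> np.ndarray:
        """Logic drive Phi(y): OR over reactions per product, in [0, 1].

        ``y`` may be a single state vector or a batch ``(..., n_species)``.
        State entries are clipped to [0, 1] before evaluation so that
        transient solver overshoot cannot produce invalid Hill arguments.
        """
        y = np.asarray(y, dtype=float)
        rule_vals = np.broadcast_to(
            self._r_w, y.shape[:-1] + self._r_w.shape
        ).copy()
        if self._t_idx.size:
            x = np.clip(y[..., self._t_idx], 0.0, 1.0)
            xn = x**self._t_n
            f = self._t_B * xn / (self._t_Kn + xn)
            f[..., self._t_inh] = 1.0 - f[..., self._t_inh]
            ns_pos = np.flatnonzero(~self._r_is_source)
            starts = self._term_starts[ns_pos]
            rule_vals[..., ns_pos] *= np.multiply.reduceat(f, starts, axis=-1)
        out = np.zeros(y.shape)
        grouped = np.multiply.reduceat(1.0 - rule_vals, self._rule_starts, axis=-1)
        out[..., self._prod_of_group] = 1.0 - grouped
        return out

    def rhs(self, y: np.ndarray) -> np.ndarray:
        return (self.phi(y) * self.ymax - y) / self.tau


def build_rhs(
    model: NetworkModel, clamps: Mapping[str, float] | None = None
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Compile the model (plus clamps) to a ``f(t, y) -> dy/dt`` callable.

    Clamped species have exactly zero derivative and their state entry is
    pinned to the clamp value before the logic drive is evaluated, so a
    clamp is exact rather than a stiff approximation.
    """
    clamps = dict(clamps or {})
    for name, value in clamps.items():
        if name not in model.index:
            raise ModelError(f"clamp target {name!r} not in model")
        if not 0.0 <= value <= 1.0:
            raise ModelError(f"clamp value for {name} outside [0, 1]: {value}")
    cidx = np.array([model.index[n] for n in clamps], dtype=int)
    cval = np.array([clamps[n] for n in clamps])

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        y = np.array(y, dtype=float)
        if cidx.size:
            y[cidx] = cval
        dy = (model.phi(y) * model.ymax - y) / model.tau
        if cidx.size:
            dy[cidx] = 0.0
        return dy

    return rhs


@dataclass
class SimulationResult:
    """Trajectories plus terminal state and convergence diagnostics."""

    times: np.ndarray
    activities: np.ndarray  # shape (n_times, n_species)
    species: list[str]
    steady_state: dict[str, float]
    converged: bool
    residual: float

    def __getitem__(self, name: str) -> float:
        return self.steady_state[name]

    @property
    def state_vector(self) -> np.ndarray:
        return self.activities[-1]


def integrate_to_steady_state(
    model: NetworkModel,
    clamps: Mapping[str, float] | None = None,
    y_start: np.ndarray | None = None,
    t_max: float | None = None,
    tol: float = STEADY_STATE_TOL,
    n_eval: int = 60,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SimulationResult:
    """Integrate the network ODE until ``t_max`` and report the end state.

    ``t_max`` defaults to ``20 * max(tau)`` so even the slowest species has
    relaxed to well below solver tolerance (e^-20 of the initial gap).  ``converged`` is true iff ``max |dy/dt| < tol`` at the end;
    non-convergence is flagged, not raised.  Chained protocols pass the
    previous steady state as ``y_start``.
    """
    clamps = dict(clamps or {})
    if t_max is None:
        t_max = 20.0 * float(np.max(model.tau))
    y0 = model.y0.copy() if y_start is None else np.array(y_start, dtype=float)
    for name, value in clamps.items():
        y0[model.index[name]] = value
    rhs = build_rhs(model, clamps)
    # Relaxation of a deep cascade takes a multiple of the per-species tau
    # proportional to the cascade depth, so integrate in windows of t_max
    # until the steady-state criterion is met (bounded number of windows).
    max_windows = 25
    times_parts, act_parts = [], []
    t0, y = 0.0, y0
    residual = np.inf
    for _ in range(max_windows):
        t_eval = np.linspace(t0, t0 + t_max, n_eval)
        sol = solve_ivp(
            rhs,
            (t0, t0 + t_max),
            y,
            method="LSODA",
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success or np.any(~np.isfinite(sol.y)):
            raise RuntimeError(f"ODE solver failed: {sol.message}")
        times_parts.append(sol.t)
        act_parts.append(sol.y.T)
        t0, y = sol.t[-1], sol.y[:, -1]
        residual = float(np.max(np.abs(rhs(t0, y))))
        if residual < tol:
            break
    yT = np.clip(y, 0.0, model.ymax)
    for name, value in clamps.items():
        yT[model.index[name]] = value
    names = [s.name for s in model.species]
    return SimulationResult(
        times=np.concatenate(times_parts),
        activities=np.concatenate(act_parts, axis=0),
        species=names,
        steady_state=dict(zip(names, yT)),
        converged=residual < tol,
        residual=residual,
    )


def steady_state(
    model: NetworkModel,
    clamps: Mapping[str, float] | None = None,
    method: str = "ode",
    **kwargs,
) -> SimulationResult:
    """Steady state via the ODE integrator or damped fixed-point iteration.

    ``method="fixed_point"`` solves ``y = Phi(y) * ymax`` directly (fast,
    used for large perturbation batches); both routes agree to tight
    tolerance on the networks this package targets.
    """
    if method == "ode":
        return integrate_to_steady_state(model, clamps, **kwargs)
    if method == "fixed_point":
        from .synthetic import fixed_point_oracle

        return fixed_point_oracle(model, clamps=clamps, **kwargs)
    raise ValueError(f"unknown method {method!r}")
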