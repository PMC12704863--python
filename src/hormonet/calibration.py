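"""Input-weight calibration against steady-state targets.

The baseline model is calibrated by constraining all five input source
weights to a single shared value and solving for the value at which the
steady-state output (CellArea) equals 0.5, the homeostatic midpoint of its
[0, 1] range.  Demographic variants then move only the hormone weights:

==================  =======================  =====================
model               hormone weight           CellArea
==================  =======================  =====================
pre-menopausal      wE2 = 0.5 (chosen)       simulated, not solved
post-menopausal     wE2 = 0.01               ~0.54
younger male        wT solved for 0.65       0.65 by construction
older male          wT = 0.8 x younger wT    prediction (~0.53)
==================  =======================  =====================

All remaining inputs (AngII, ET-1, Strain) stay at the shared baseline.
Calibration works on the steady-state map directly (simulate inside a
bracketed scalar root-finder); the network contains cycles through its
inhibitor gates, so algebraic elimination is not attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.optimize import brentq

from .engine import NetworkModel, steady_state

__all__ = [
    "CalibrationError",
    "CalibrationSpec",
    "DemographicModel",
    "steady_output",
    "calibrate_shared_weight",
    "calibrate_single_weight",
    "build_demographic_models",
    "save_registry",
    "load_registry",
]

DEFAULT_TOL = 1e-4


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class CalibrationSpec:
    """Which weights are free, which are fixed, and the target to hit."""

    free: tuple[str, ...]
    target_species: str
    target_value: float
    fixed: dict[str, float] = field(default_factory=dict)
    shared: bool = True  # all free weights tied to one scalar
    tolerance: float = DEFAULT_TOL

    def __post_init__(self) -> None:
        overlap = set(self.free) & set(self.fixed)
        if overlap:
            raise ValueError(f"weights both free and fixed: {sorted(overlap)}")


@dataclass(frozen=True)
class DemographicModel:
    """A named hormone condition: input weights plus its baseline output."""

    label: str
    weights: dict[str, float]
    cell_area: float

    def apply(self, model: NetworkModel) -> NetworkModel:
        return model.with_input_weights(self.weights)


def steady_output(
    model: NetworkModel,
    weights: dict[str, float] | None = None,
    species: str | None = None,
    method: str = "ode",
) -> float:
    """Steady-state activity of one species under the given input weights."""
    m = model.with_input_weights(weights) if weights else model
    species = species or model.output
    result = steady_state(m, method=method)
    if not result.converged:
        raise CalibrationError(
            f"steady state did not converge (residual {result.residual:.2e})"
        )
    return result.steady_state[species]


def _solve(f, bounds, tol, what):
    lo, hi = bounds
    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if f_lo * f_hi > 0:
        raise CalibrationError(
            f"{what}: target not bracketed in [{lo}, {hi}]; achieved range "
            f"[{min(f_lo, f_hi):+.4f}, {max(f_lo, f_hi):+.4f}] around target"
        )
    return float(brentq(f, lo, hi, xtol=tol))


def calibrate_shared_weight(
    model: NetworkModel,
    target_species: str | None = None,
    target_value: float = 0.5,
    bounds: tuple[float, float] = (0.0, 1.0),
    tol: float = DEFAULT_TOL,
    method: str = "ode",
) -> float:
    """Single shared weight for *all* inputs hitting the steady-state target."""
    target_species = target_species or model.output

    def f(w: float) -> float:
        weights = {name: w for name in model.inputs}
        return steady_output(model, weights, target_species, method) - target_value

    return _solve(f, bounds, tol, f"shared weight for {target_species}={target_value}")


def calibrate_single_weight(
    model: NetworkModel,
    weight_name: str,
    target_species: str | None = None,
    target_value: float = 0.5,
    bounds: tuple[float, float] = (0.0, 1.0),
    fixed: dict[str, float] | None = None,
    tol: float = DEFAULT_TOL,
    method: str = "ode",
) -> float:
    """One free input weight, all others fixed (at the model's current values
    unless overridden through ``fixed``)."""
    if weight_name not in model.inputs:
        raise CalibrationError(f"{weight_name!r} is not an input of the model")
    target_species = target_species or model.output
    base = model.input_weights()
    base.update(fixed or {})

    def f(w: float) -> float:
        weights = dict(base)
        weights[weight_name] = w
        return steady_output(model, weights, target_species, method) - target_value

    return _solve(
        f, bounds, tol, f"{weight_name} for {target_species}={target_value}"
    )


def calibrate(
    model: NetworkModel, spec: CalibrationSpec, method: str = "ode"
) -> dict[str, float]:
    """Dispatch a :class:`CalibrationSpec` to the appropriate solver.

    Shared or single-weight specs use bracketed root finding.  The general
    multi-weight case is deliberately an explicit optimization — it
    minimizes the squared steady-state residual ``(y_target - y)^2`` over
    the box [0, 1]^k and is degenerate by construction (many weight
    combinations reach the same output), so the returned solution is just
    one member of the solution set, dependent on the initial guess (0.5).
    """
    fixed = dict(spec.fixed)
    if spec.shared or len(spec.free) == 1:
        if spec.shared and set(spec.free) == set(model.inputs):
            w = calibrate_shared_weight(
                model, spec.target_species, spec.target_value,
                tol=spec.tolerance, method=method,
            )
            return {name: w for name in spec.free}
        name = spec.free[0]
        w = calibrate_single_weight(
            model, name, spec.target_species, spec.target_value,
            fixed=fixed, tol=spec.tolerance, method=method,
        )
        return {name: w}
    from scipy.optimize import minimize

    base = model.input_weights()
    base.update(fixed)

    def objective(x):
        weights = dict(base)
        weights.update(zip(spec.free, x))
        y = steady_output(model, weights, spec.target_species, method)
        return (y - spec.target_value) ** 2

    res = minimize(
        objective,
        x0=np.full(len(spec.free), 0.5),
        bounds=[(0.0, 1.0)] * len(spec.free),
        method="L-BFGS-B",
        options={"ftol": spec.tolerance**2},
    )
    if res.fun > spec.tolerance**2 * 100:
        raise CalibrationError(
            f"multi-weight calibration stalled at residual {res.fun**0.5:.2e}"
        )
    return dict(zip(spec.free, res.x))


# demographic targets: (hormone, prescription)
PRE_MENOPAUSAL_WE2 = 0.5
POST_MENOPAUSAL_WE2 = 0.01
YOUNGER_MALE_CELLAREA = 0.65
OLDER_MALE_T_FRACTION = 0.8


def build_demographic_models(
    model: NetworkModel,
    baseline_weight: float | None = None,
    method: str = "ode",
) -> dict[str, DemographicModel]:
    """Baseline plus the four hormone-condition models.

    The younger-male testosterone weight is solved so CellArea reaches
    0.65; the older-male weight is defined as 80 % of that (a 20 % age
    decline), and its CellArea is a prediction rather than a fit.
    """
    if baseline_weight is None:
        baseline_weight = calibrate_shared_weight(model, method=method)
    base_w = {name: baseline_weight for name in model.inputs}

    def ca(weights):
        return steady_output(model, weights, model.output, method)

    models = {
        "baseline": DemographicModel("baseline", dict(base_w), ca(base_w))
    }
    pre = dict(base_w, E2=PRE_MENOPAUSAL_WE2)
    post = dict(base_w, E2=POST_MENOPAUSAL_WE2)
    w_t_young = calibrate_single_weight(
        model,
        "T",
        target_value=YOUNGER_MALE_CELLAREA,
        fixed=base_w,
        method=method,
    )
    young = dict(base_w, T=w_t_young)
    old = dict(base_w, T=OLDER_MALE_T_FRACTION * w_t_young)
    for label, w in [
        ("pre_menopausal", pre),
        ("post_menopausal", post),
        ("younger_male", young),
        ("older_male", old),
    ]:
        models[label] = DemographicModel(label, w, ca(w))
    return models


def save_registry(models: dict[str, DemographicModel], path) -> None:
    payload = {
        label: {"weights": m.weights, "cell_area": float(m.cell_area)}
        for label, m in models.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_registry(path) -> dict[str, DemographicModel]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return {
        label: DemographicModel(label, dict(entry["weights"]), float(entry["cell_area"]))
        for label, entry in payload.items()
    }
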