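"""Clamp-based influence/sensitivity screens, response curves, crosstalk
landscapes, and first-order Sobol sensitivity of the input weights.

Screens clamp every node once per direction (up-regulation at 0.8,
knockdown at 0.1) by pinning the state and zeroing its derivative, then
record the steady-state change ``dy_ij`` of every other node j.  Influence
of node i sums ``|dy_ij|`` over j; sensitivity of node j sums ``|dy_ij|``
over i; the diagonal is excluded from both.

The Sobol analysis follows the Saltelli scheme: two independent
quasi-random sample matrices A and B over the input-weight hypercube and
the hybrid matrices AB_i, with the first-order estimator
``S_i = mean(f(B) * (f(AB_i) - f(A))) / Var(f)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .engine import NetworkModel, steady_state

__all__ = [
    "X_UP",
    "X_DOWN",
    "ClampExperiment",
    "PerturbationReport",
    "influence_sensitivity_screen",
    "response_curve",
    "crosstalk_landscape",
    "SobolResult",
    "sobol_first_order",
    "batch_steady_states",
]

X_UP = 0.8  # clamp value for up-regulation
X_DOWN = 0.1  # clamp value for knockdown
SOBOL_DEFAULT_SEED = 20250101
SOBOL_DEFAULT_N_BASE = 1024


@dataclass(frozen=True)
class ClampExperiment:
    node: str
    value: float
    background: str = "baseline"

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"clamp value outside [0, 1]: {self.value}")


@dataclass
class PerturbationReport:
    """Influence/sensitivity scores and the full delta matrix."""

    delta: pd.DataFrame  # rows: clamped node i, cols: responding node j
    influence: pd.Series  # I_i = sum_j |delta_ij|, j != i
    sensitivity: pd.Series  # S_j = sum_i |delta_ij|, i != j
    clamp_value: float
    background: str
    failed: list[str]

    def rank_table(self) -> pd.DataFrame:
        inf = self.influence.sort_values(ascending=False)
        sen = self.sensitivity.sort_values(ascending=False)
        return pd.DataFrame(
            {
                "influence_rank": inf.rank(ascending=False, method="min").astype(int),
                "influence": inf,
                "sensitivity_rank": sen.rank(ascending=False, method="min").astype(int),
                "sensitivity": sen,
            }
        )


def influence_sensitivity_screen(
    model: NetworkModel,
    clamp_value: float,
    background: str = "baseline",
    method: str = "ode",
) -> PerturbationReport:
    """Clamp each node at ``clamp_value`` and collect steady-state changes.

    Experiments are independent, so their order is irrelevant.  Clamps that
    fail to converge are reported in ``failed`` and excluded from the sums.
    """
    base = steady_state(model, method=method)
    if not base.converged:
        raise RuntimeError("background steady state did not converge")
    names = [s.name for s in model.species]
    base_vec = np.array([base.steady_state[n] for n in names])
    rows, failed = {}, []
    for node in names:
        res = steady_state(
            model, clamps={node: clamp_value}, y_start=base_vec, method=method
        )
        if not res.converged:
            failed.append(node)
            continue
        d = np.array([res.steady_state[n] for n in names]) - base_vec
        d[names.index(node)] = 0.0  # diagonal excluded by construction
        rows[node] = d
    delta = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    influence = delta.abs().sum(axis=1)
    sensitivity = delta.abs().sum(axis=0)
    return PerturbationReport(
        delta=delta,
        influence=influence,
        sensitivity=sensitivity,
        clamp_value=clamp_value,
        background=background,
        failed=failed,
    )


def response_curve(
    model: NetworkModel,
    node: str,
    grid=None,
    mode: str | None = None,
    method: str = "ode",
) -> pd.DataFrame:
    """Steady-state output versus a swept node activity or input weight.

    Inputs default to sweeping their source weight (``mode="weight"``);
    interior nodes can only be swept by clamping (``mode="clamp"``).
    """
    grid = np.linspace(0.0, 1.0, 21) if grid is None else np.asarray(grid, float)
    if mode is None:
        mode = "weight" if node in model.inputs else "clamp"
    if mode == "weight" and node not in model.inputs:
        raise ValueError(f"{node!r} is not an input; weight sweep unavailable")
    out = []
    for x in grid:
        if mode == "weight":
            res = steady_state(
                model.with_input_weights({node: float(x)}), method=method
            )
        elif mode == "clamp":
            res = steady_state(model, clamps={node: float(x)}, method=method)
        else:
            raise ValueError(f"unknown sweep mode {mode!r}")
        out.append(
            {
                "node": node,
                "mode": mode,
                "value": float(x),
                "output": res.steady_state[model.output],
                "converged": res.converged,
            }
        )
    return pd.DataFrame(out)


def crosstalk_landscape(
    model: NetworkModel,
    input_x: str,
    input_y: str,
    grid=None,
    method: str = "fixed_point",
) -> pd.DataFrame:
    """Steady-state output over a 2-D grid of two input weights.

    Other inputs stay at their current (baseline) weights.  Output > 0.5 is
    classified as hypertrophy, < 0.5 as atrophy.  Returned as a matrix with
    ``input_y`` values as the index and ``input_x`` values as columns.
    """
    for name in (input_x, input_y):
        if name not in model.inputs:
            raise ValueError(f"{name!r} is not an input")
    grid = np.linspace(0.0, 1.0, 11) if grid is None else np.asarray(grid, float)
    mat = np.empty((len(grid), len(grid)))
    for i, wy in enumerate(grid):
        for j, wx in enumerate(grid):
            res = steady_state(
                model.with_input_weights({input_x: float(wx), input_y: float(wy)}),
                method=method,
            )
            mat[i, j] = res.steady_state[model.output]
    return pd.DataFrame(mat, index=pd.Index(grid, name=input_y),
                        columns=pd.Index(grid, name=input_x))


# ---------------------------------------------------------------------------
# Sobol / Saltelli
# ---------------------------------------------------------------------------


def batch_steady_states(
    model: NetworkModel,
    weight_samples: np.ndarray,
    inputs: list[str],
    tol: float = 1e-10,
    max_iter: int = 100_000,
    alpha: float = 0.5,
) -> np.ndarray:
    """Vectorized steady states for many input-weight samples at once.

    Input activities equal their source weights at steady state, so the
    samples are pinned as clamped input states while the remaining species
    relax by damped fixed-point iteration.  Returns ``(n_samples,
    n_species)`` activities.
    """
    w = np.asarray(weight_samples, dtype=float)
    idx = np.array([model.index[n] for n in inputs], dtype=int)
    y = np.tile(model.y0, (w.shape[0], 1))
    y[:, idx] = w
    for _ in range(max_iter):
        target = model.phi(y) * model.ymax
        target[:, idx] = w
        y_new = (1.0 - alpha) * y + alpha * target
        delta = float(np.max(np.abs(y_new - y)))
        y = y_new
        if delta < tol * alpha:
            break
    else:
        raise RuntimeError("batch fixed-point iteration did not converge")
    return y


@dataclass
class SobolResult:
    """First-order indices (inputs x monitored outputs) with MC error."""

    indices: pd.DataFrame
    se: pd.DataFrame
    n_base: int
    seed: int


def sobol_first_order(
    model: NetworkModel,
    inputs: list[str] | None = None,
    ranges: dict[str, tuple[float, float]] | None = None,
    n_base: int = SOBOL_DEFAULT_N_BASE,
    seed: int = SOBOL_DEFAULT_SEED,
    outputs: list[str] | None = None,
    n_boot: int = 200,
) -> SobolResult:
    """First-order Sobol indices of steady-state activities w.r.t. inputs.

    Saltelli sampling over ``(d + 2)`` matrices of ``n_base`` quasi-random
    points; ``n_base`` is rounded up to a power of two if needed.  Standard
    errors come from a bootstrap over sample rows.
    """
    inputs = list(inputs or model.inputs)
    outputs = list(outputs or [s.name for s in model.species])
    ranges = ranges or {}
    d = len(inputs)
    m = int(np.ceil(np.log2(max(2, n_base))))
    if 2**m != n_base:
        warnings.warn(
            f"n_base={n_base} is not a power of two; using {2 ** m}", stacklevel=2
        )
        n_base = 2**m
    sampler = qmc.Sobol(d=2 * d, scramble=True, seed=seed)
    ab = sampler.random_base2(m)
    A, B = ab[:, :d].copy(), ab[:, d:].copy()
    lo = np.array([ranges.get(k, (0.0, 1.0))[0] for k in inputs])
    hi = np.array([ranges.get(k, (0.0, 1.0))[1] for k in inputs])
    A = lo + (hi - lo) * A
    B = lo + (hi - lo) * B
    out_idx = np.array([model.index[n] for n in outputs], dtype=int)

    fA = batch_steady_states(model, A, inputs)[:, out_idx]
    fB = batch_steady_states(model, B, inputs)[:, out_idx]
    fAB = np.empty((d,) + fA.shape)
    for i in range(d):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        fAB[i] = batch_steady_states(model, ABi, inputs)[:, out_idx]

    var = np.var(np.concatenate([fA, fB], axis=0), axis=0)
    var = np.where(var > 0, var, np.nan)
    elem = fB[None, :, :] * (fAB - fA[None, :, :])  # (d, N, n_out)
    S = elem.mean(axis=1) / var

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, d, len(outputs)))
    for b in range(n_boot):
        rows = rng.integers(0, n_base, size=n_base)
        v = np.var(np.concatenate([fA[rows], fB[rows]], axis=0), axis=0)
        v = np.where(v > 0, v, np.nan)
        boot[b] = elem[:, rows, :].mean(axis=1) / v
    se = boot.std(axis=0)

    return SobolResult(
        indices=pd.DataFrame(S, index=inputs, columns=outputs),
        se=pd.DataFrame(se, index=inputs, columns=outputs),
        n_base=n_base,
        seed=seed,
    )
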