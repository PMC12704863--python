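"""Qualitative and quantitative validation protocols.

Qualitative protocol: each stimulus is up-regulated by adding 0.3 to its
source weight (clipped to [0, 1]); steady-state changes of every node are
ternarized with a +/-0.05 dead band (increase / decrease / no_change) and
compared with a literature-observation table.  Single-stimulus conditions
are referenced to the calibrated baseline; stimulus+hormone conditions are
referenced to the stimulus alone, simulated sequentially from the stimulus
steady state.

Quantitative protocol: three independent experimental studies are encoded
as input-weight prescriptions; the percent change of steady-state CellArea
for each arm is reported relative to the study's own control arm (and, for
hormone arms, additionally relative to the stimulus-alone arm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .engine import NetworkModel, SimulationResult, integrate_to_steady_state, steady_state

__all__ = [
    "PerturbationCondition",
    "TernaryCall",
    "ternary_call",
    "run_condition",
    "qualitative_screen",
    "qualitative_agreement",
    "load_literature_observations",
    "STUDIES",
    "simulate_study",
    "propagate_error",
    "DELTA_UP",
    "CALL_BAND",
]

DELTA_UP = 0.3  # standardized node up-regulation added to a source weight
CALL_BAND = 0.05  # |delta| below this is "no change"


@dataclass(frozen=True)
class PerturbationCondition:
    """A named input-weight perturbation and its reference condition."""

    label: str
    overrides: dict[str, float] = field(default_factory=dict)
    increments: dict[str, float] = field(default_factory=dict)
    reference: str | None = None  # label of reference condition; None = baseline

    def weights(self, base: dict[str, float]) -> dict[str, float]:
        w = dict(base)
        w.update(self.overrides)
        for k, dv in self.increments.items():
            w[k] = w.get(k, 0.0) + dv
        return {k: min(1.0, max(0.0, v)) for k, v in w.items()}


@dataclass(frozen=True)
class TernaryCall:
    node: str
    delta: float
    call: str  # increase | decrease | no_change


def ternary_call(delta: float, band: float = CALL_BAND) -> str:
    if delta > band:
        return "increase"
    if delta < -band:
        return "decrease"
    return "no_change"


def run_condition(
    model: NetworkModel,
    condition: PerturbationCondition,
    reference: SimulationResult,
    method: str = "ode",
) -> tuple[SimulationResult, dict[str, float]]:
    """Simulate a condition from its reference steady state.

    Returns the condition's steady state and per-node deltas against the
    reference.  A non-converged reference aborts with a diagnostic.
    """
    if not reference.converged:
        raise RuntimeError(
            f"reference state for {condition.label!r} is not converged "
            f"(residual {reference.residual:.2e})"
        )
    weights = condition.weights(model.input_weights())
    perturbed = model.with_input_weights(weights)
    result = steady_state(perturbed, method=method, y_start=reference.state_vector)
    deltas = {
        name: result.steady_state[name] - reference.steady_state[name]
        for name in result.steady_state
    }
    return result, deltas


def _validation_conditions() -> list[PerturbationCondition]:
    singles = [
        PerturbationCondition(h, increments={h: DELTA_UP})
        for h in ["E2", "T", "Strain", "AngII", "ET1"]
    ]
    combos = [
        PerturbationCondition(
            f"{s}+{h}",
            increments={s: DELTA_UP, h: DELTA_UP},
            reference=s,
        )
        for s in ["Strain", "AngII", "ET1"]
        for h in ["E2", "T"]
    ]
    return singles + combos


def qualitative_screen(
    model: NetworkModel,
    band: float = CALL_BAND,
    method: str = "ode",
) -> pd.DataFrame:
    """Ternary model calls for the full single + combined stimulus panel.

    Returns a tidy frame (condition, node, delta, call).
    """
    baseline = steady_state(model, method=method)
    results: dict[str, SimulationResult] = {}
    rows = []
    for cond in _validation_conditions():
        ref = baseline if cond.reference is None else results[cond.reference]
        res, deltas = run_condition(model, cond, ref, method=method)
        results[cond.label] = res
        for node, d in deltas.items():
            rows.append(
                {
                    "condition": cond.label,
                    "node": node,
                    "delta": d,
                    "call": ternary_call(d, band),
                }
            )
    return pd.DataFrame(rows)


def load_literature_observations() -> pd.DataFrame:
    """Packaged literature-observation table (condition, node, call, source).

    The published observation matrix is only available as a figure; this
    table is a reconstruction — rows whose source starts with ``text:`` are
    anchored in the running description of the validation outcome, the rest
    encode the canonical pathway expectations the network was assembled
    from.  It is an editable fixture, not primary data.
    """
    path = resources.files("hormonet").joinpath("data", "literature_observations.csv")
    with resources.as_file(path) as p:
        return pd.read_csv(p)


def qualitative_agreement(
    calls: pd.DataFrame, observations: pd.DataFrame
) -> tuple[int, int, float | None, pd.DataFrame]:
    """Exact-match counting of model calls against observations.

    Returns ``(n_match, n_total, fraction, mismatches)``; fraction is None
    for an empty observation table.  Observations referencing unknown
    condition/node pairs raise.
    """
    key = calls.set_index(["condition", "node"])["call"]
    n_match, rows = 0, []
    for _, obs in observations.iterrows():
        k = (obs["condition"], obs["node"])
        if k not in key.index:
            raise ValueError(f"observation references unknown condition/node {k}")
        model_call = key.loc[k]
        ok = model_call == obs["call"]
        n_match += bool(ok)
        if not ok:
            rows.append(
                {
                    "condition": k[0],
                    "node": k[1],
                    "observed": obs["call"],
                    "model": model_call,
                }
            )
    n_total = len(observations)
    fraction = n_match / n_total if n_total else None
    return n_match, n_total, fraction, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# quantitative studies
# ---------------------------------------------------------------------------

# Each study: background weights layered on the calibrated baseline, a
# control arm, and stimulus arms.  Hormone increments for the in vivo
# studies add 0.3 to the background estradiol weight.
STUDIES: dict[str, dict] = {
    # in vitro neonatal/pregnant rat cardiomyocytes; serum AngII / ET-1
    # near maximum, hormone arms at half-maximal E2
    "pedram_invitro": {
        "background": {},
        "control": {},
        "arms": {
            "AngII": {"AngII": 0.9},
            "AngII+E2": {"AngII": 0.9, "E2": 0.5},
            "ET1": {"ET1": 0.9},
            "ET1+E2": {"ET1": 0.9, "E2": 0.5},
        },
        "stimulus_of": {"AngII+E2": "AngII", "ET1+E2": "ET1"},
    },
    # aortic banding in non-ovariectomized female rats: strain 0.6,
    # AngII doubled from baseline, background estradiol 0.5
    "donaldson_banding": {
        "background": {"E2": 0.5},
        "control": {},
        "arms": {
            "Strain": {"Strain": 0.6, "AngII": "2x"},
            "Strain+E2": {"Strain": 0.6, "AngII": "2x", "E2": "+0.3"},
        },
        "stimulus_of": {"Strain+E2": "Strain"},
    },
    # spontaneously hypertensive rats with OVX: background estradiol 0.01,
    # AngII doubled, strain 0.6 present in all arms including control
    "chen_shr": {
        "background": {"E2": 0.01, "AngII": "2x", "Strain": 0.6},
        "control": {},
        "arms": {
            "E2": {"E2": "+0.3"},
            "E2+T": {"E2": "+0.3", "T": 0.21},
        },
        "stimulus_of": {},
    },
}


def _resolve(spec_weights: dict, base: dict[str, float]) -> dict[str, float]:
    out = dict(base)
    for name, v in spec_weights.items():
        if v == "2x":
            out[name] = min(1.0, 2.0 * base[name])
        elif isinstance(v, str) and v.startswith("+"):
            out[name] = min(1.0, out[name] + float(v))
        else:
            out[name] = float(v)
    return out


def simulate_study(
    model: NetworkModel, study: str, method: str = "ode"
) -> pd.DataFrame:
    """Percent CellArea changes for all arms of one encoded study.

    ``pct_vs_control`` compares each arm with the study control;
    ``pct_vs_stimulus`` additionally compares hormone arms with the
    stimulus-alone arm.
    """
    if study not in STUDIES:
        raise KeyError(f"unknown study {study!r}; options: {sorted(STUDIES)}")
    spec = STUDIES[study]
    baseline = model.input_weights()
    background = _resolve(spec["background"], baseline)

    def cell_area(weights):
        res = steady_state(model.with_input_weights(weights), method=method)
        if not res.converged:
            raise RuntimeError(f"arm did not converge (residual {res.residual:.2e})")
        return res.steady_state[model.output]

    control = cell_area(_resolve(spec["control"], background))
    values = {
        arm: cell_area(_resolve(w, background)) for arm, w in spec["arms"].items()
    }
    rows = [
        {
            "arm": "control",
            "cell_area": control,
            "pct_vs_control": 0.0,
            "pct_vs_stimulus": math.nan,
        }
    ]
    for arm, ca in values.items():
        stim = spec["stimulus_of"].get(arm)
        rows.append(
            {
                "arm": arm,
                "cell_area": ca,
                "pct_vs_control": 100.0 * (ca - control) / control,
                "pct_vs_stimulus": (
                    100.0 * (ca - values[stim]) / values[stim]
                    if stim
                    else math.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def propagate_error(
    mean_num: float, sd_num: float, mean_den: float, sd_den: float
) -> float:
    """First-order error propagation for a ratio of independent quantities.

    sigma_R = |num/den| * sqrt((sd_num/num)^2 + (sd_den/den)^2)
    """
    if mean_num == 0.0 or mean_den == 0.0:
        raise ZeroDivisionError("error propagation undefined for zero means")
    r = mean_num / mean_den
    return abs(r) * math.sqrt(
        (sd_num / mean_num) ** 2 + (sd_den / mean_den) ** 2
    )
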