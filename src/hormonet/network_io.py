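"""Reaction-table parsing, serialization and graph statistics.

The on-disk dialect follows the Netflux-style spreadsheet convention used
throughout logic-based signaling modeling: a *species* sheet (name, y0,
ymax, tau) and a *reactions* sheet (rule string, weight W, Hill n, EC50,
free-text source annotation).  Rule strings obey the grammar

    rule     := [ term ( "&" term )* ] "=>" product
    term     := [ "!" ] name

where an empty left-hand side denotes a source/input reaction, ``!`` marks
an inhibitor term, ``&`` an AND gate, and OR is implicit across reactions
sharing a product.

Two physical formats are supported: an ``.xlsx`` workbook with sheets
``species`` and ``reactions``, and a diff-friendly CSV mirror (a directory
holding ``species.csv`` and ``reactions.csv``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import networkx as nx
import pandas as pd

from .engine import (
    ACTIVATOR,
    DEFAULT_EC50,
    DEFAULT_HILL_N,
    DEFAULT_TAU,
    INHIBITOR,
    HillParams,
    NetworkModel,
    ReactionRule,
    SpeciesNode,
)

__all__ = [
    "ParseError",
    "LoadError",
    "NetworkStats",
    "parse_rule",
    "format_rule",
    "load_network",
    "write_network",
    "network_to_json",
    "compute_bottlenecks",
    "rule_graph",
    "load_hypertrophy_network",
]

SPECIES_COLUMNS = ["name", "display_name", "y0", "ymax", "tau", "role"]
REACTION_COLUMNS = ["rule", "weight", "n", "ec50", "source", "sex_evidence"]


class ParseError(ValueError):
    pass


class LoadError(ValueError):
    pass


def parse_rule(text: str, weight: float = 1.0, hill: HillParams | None = None,
               line: int | None = None) -> ReactionRule:
    """Parse one rule string into a :class:`ReactionRule`."""
    where = "" if line is None else f" (line {line})"
    if "=>" not in text:
        raise ParseError(f"missing '=>' in rule {text!r}{where}")
    lhs, _, rhs = text.partition("=>")
    product = rhs.strip()
    if not product:
        raise ParseError(f"empty product in rule {text!r}{where}")
    if not product.isidentifier():
        raise ParseError(f"bad product token {product!r}{where}")
    terms: list[tuple[str, int]] = []
    lhs = lhs.strip()
    if lhs:
        for raw in lhs.split("&"):
            tok = raw.strip()
            sign = ACTIVATOR
            if tok.startswith("!"):
                sign = INHIBITOR
                tok = tok[1:].strip()
            if not tok or not tok.isidentifier():
                raise ParseError(f"bad term token {raw.strip()!r} in {text!r}{where}")
            terms.append((tok, sign))
    return ReactionRule(
        product=product,
        terms=tuple(terms),
        weight=weight,
        hill=hill or HillParams(),
    )


def format_rule(rule: ReactionRule) -> str:
    """Inverse of :func:`parse_rule` (canonical spacing)."""
    lhs = " & ".join(
        ("!" if sign == INHIBITOR else "") + name for name, sign in rule.terms
    )
    return f"{lhs} => {rule.product}" if lhs else f"=> {rule.product}"


def _read_tables(path: str | Path, dialect: str | None) -> tuple[pd.DataFrame, pd.DataFrame]:
    path = Path(path)
    if dialect is None:
        dialect = "xlsx" if path.suffix == ".xlsx" else "csv"
    if dialect == "xlsx":
        if not path.exists():
            raise LoadError(f"no such workbook: {path}")
        species = pd.read_excel(path, sheet_name="species")
        reactions = pd.read_excel(path, sheet_name="reactions")
    elif dialect == "csv":
        sp_file, rx_file = path / "species.csv", path / "reactions.csv"
        for f in (sp_file, rx_file):
            if not f.exists():
                raise LoadError(f"missing table file: {f}")
        species = pd.read_csv(sp_file)
        reactions = pd.read_csv(rx_file)
    else:
        raise LoadError(f"unknown dialect {dialect!r}")
    return species, reactions


def _get(row, col, default):
    val = row.get(col)
    if val is None or (isinstance(val, float) and pd.isna(val)) or val == "":
        return default
    return val


def load_network(path: str | Path, dialect: str | None = None) -> NetworkModel:
    """Load a reaction table into a validated :class:`NetworkModel`.

    Blank parameter cells receive the uniform defaults: interior weight 1,
    n 1.4, EC50 0.5, tau 0.1 h, ymax 1, y0 0.
    """
    species_df, reactions_df = _read_tables(path, dialect)
    problems: list[str] = []
    species: list[SpeciesNode] = []
    inputs: list[str] = []
    output = None
    for i, row in species_df.iterrows():
        name = str(row["name"]).strip()
        try:
            species.append(
                SpeciesNode(
                    name=name,
                    display_name=_get(row, "display_name", None),
                    y0=float(_get(row, "y0", 0.0)),
                    ymax=float(_get(row, "ymax", 1.0)),
                    tau=float(_get(row, "tau", DEFAULT_TAU)),
                )
            )
        except (ValueError, KeyError) as exc:
            problems.append(f"species row {i}: {exc}")
            continue
        role = str(_get(row, "role", "")).strip().lower()
        if role == "input":
            inputs.append(name)
        elif role == "output":
            output = name
    rules: list[ReactionRule] = []
    for i, row in reactions_df.iterrows():
        try:
            hill = HillParams(
                n=float(_get(row, "n", DEFAULT_HILL_N)),
                ec50=float(_get(row, "ec50", DEFAULT_EC50)),
            )
            rules.append(
                parse_rule(
                    str(row["rule"]),
                    weight=float(_get(row, "weight", 1.0)),
                    hill=hill,
                    line=i + 2,  # header is line 1
                )
            )
        except (ParseError, ValueError, KeyError) as exc:
            problems.append(f"reaction row {i}: {exc}")
    if problems:
        raise LoadError("invalid reaction table:\n  " + "\n  ".join(problems))
    known = {s.name for s in species}
    missing = sorted(
        {t for r in rules for t, _ in r.terms if t not in known}
        | {r.product for r in rules if r.product not in known}
    )
    if missing:
        raise LoadError(f"rule species not in species sheet: {missing}")
    try:
        return NetworkModel(species, rules, inputs=inputs, output=output)
    except ValueError as exc:
        raise LoadError(str(exc)) from exc


def _tables_from_model(model: NetworkModel) -> tuple[pd.DataFrame, pd.DataFrame]:
    sp_rows = []
    for s in model.species:
        role = (
            "input" if s.name in model.inputs
            else "output" if s.name == model.output
            else ""
        )
        sp_rows.append(
            {
                "name": s.name,
                "display_name": s.display_name or s.name,
                "y0": s.y0,
                "ymax": s.ymax,
                "tau": s.tau,
                "role": role,
            }
        )
    rx_rows = [
        {
            "rule": format_rule(r),
            "weight": r.weight,
            "n": r.hill.n,
            "ec50": r.hill.ec50,
            "source": "",
            "sex_evidence": "",
        }
        for r in model.rules
    ]
    return pd.DataFrame(sp_rows), pd.DataFrame(rx_rows)


def write_network(model: NetworkModel, path: str | Path, dialect: str | None = None) -> None:
    """Serialize a model back to a reaction table (inverse of load)."""
    path = Path(path)
    species_df, reactions_df = _tables_from_model(model)
    if dialect is None:
        dialect = "xlsx" if path.suffix == ".xlsx" else "csv"
    if dialect == "xlsx":
        # spreadsheet engines read a leading "=" as a formula; pad source
        # rules with a space (the rule parser strips surrounding whitespace)
        reactions_df = reactions_df.copy()
        reactions_df["rule"] = reactions_df["rule"].map(
            lambda s: " " + s if s.startswith("=") else s
        )
        with pd.ExcelWriter(path) as xl:
            species_df.to_excel(xl, sheet_name="species", index=False)
            reactions_df.to_excel(xl, sheet_name="reactions", index=False)
    elif dialect == "csv":
        path.mkdir(parents=True, exist_ok=True)
        species_df.to_csv(path / "species.csv", index=False)
        reactions_df.to_csv(path / "reactions.csv", index=False)
    else:
        raise LoadError(f"unknown dialect {dialect!r}")


def network_to_json(model: NetworkModel) -> str:
    """JSON export of the full model for downstream tooling."""
    payload = {
        "species": [
            {
                "name": s.name,
                "y0": s.y0,
                "ymax": s.ymax,
                "tau": s.tau,
            }
            for s in model.species
        ],
        "reactions": [
            {
                "rule": format_rule(r),
                "weight": r.weight,
                "n": r.hill.n,
                "ec50": r.hill.ec50,
            }
            for r in model.rules
        ],
        "inputs": model.inputs,
        "output": model.output,
    }
    return json.dumps(payload, indent=2)


def rule_graph(model: NetworkModel) -> nx.DiGraph:
    """Directed regulator->product graph (unique edges, unit weights)."""
    g = nx.DiGraph()
    g.add_nodes_from(s.name for s in model.species)
    for r in model.rules:
        for name, sign in r.terms:
            g.add_edge(name, r.product, sign=sign)
    return g


@dataclass
class NetworkStats:
    n_nodes: int
    n_edges: int  # signed (term, product) pairs across non-source rules
    bottlenecks: list[tuple[str, float]]  # betweenness ranking, descending

    @property
    def top3(self) -> list[str]:
        return [name for name, _ in self.bottlenecks[:3]]


def compute_bottlenecks(model: NetworkModel) -> NetworkStats:
    """Betweenness-centrality bottleneck ranking of the rule digraph.

    Computed on the directed, unit-weight regulator->product graph with
    path endpoints excluded; ties broken lexicographically.
    """
    g = rule_graph(model)
    bc = nx.betweenness_centrality(g) if g.number_of_nodes() else {}
    ranking = sorted(bc.items(), key=lambda kv: (-kv[1], kv[0]))
    n_edges = sum(len(r.terms) for r in model.rules)
    return NetworkStats(
        n_nodes=len(model.species), n_edges=n_edges, bottlenecks=ranking
    )


def load_hypertrophy_network() -> NetworkModel:
    """The packaged sex-hormone cardiomyocyte hypertrophy network.

    29 species, 49 signed edges; inputs E2, T, Strain, AngII, ET1 with
    source weights at the calibrated baseline (0.15 each); output CellArea.
    The transcription provenance of every reaction is annotated in the
    packaged ``reactions.csv``.
    """
    root = resources.files("hormonet").joinpath("data", "hypertrophy")
    with resources.as_file(root) as path:
        return load_network(path, dialect="csv")
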