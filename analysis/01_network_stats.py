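#!/usr/bin/env python
"""Inspect the packaged hypertrophy network: counts, inputs/outputs, and
betweenness bottlenecks; export the model as JSON for downstream tooling."""

from pathlib import Path

import pandas as pd

from hormonet.network_io import (
    compute_bottlenecks,
    load_hypertrophy_network,
    network_to_json,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    model = load_hypertrophy_network()
    stats = compute_bottlenecks(model)
    print(f"species: {stats.n_nodes}, signed edges: {stats.n_edges}")
    print(f"inputs:  {', '.join(model.inputs)}")
    print(f"output:  {model.output}")
    print("top-5 bottlenecks (betweenness on the rule digraph):")
    for name, value in stats.bottlenecks[:5]:
        print(f"  {name:10s} {value:.4f}")
    pd.DataFrame(stats.bottlenecks, columns=["node", "betweenness"]).to_csv(
        RESULTS / "bottlenecks.csv", index=False
    )
    (RESULTS / "network.json").write_text(network_to_json(model))
    print(f"wrote {RESULTS/'bottlenecks.csv'} and {RESULTS/'network.json'}")


if __name__ == "__main__":
    main()
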