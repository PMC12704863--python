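#!/usr/bin/env python
"""Quantitative validation: simulate the three independent experimental
studies (in vitro AngII/ET-1 with estradiol; aortic banding; spontaneously
hypertensive rats) and report percent CellArea changes per arm."""

from pathlib import Path

import pandas as pd

from hormonet.network_io import load_hypertrophy_network
from hormonet.validation import STUDIES, simulate_study

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    model = load_hypertrophy_network()
    frames = []
    for study in STUDIES:
        df = simulate_study(model, study)
        df.insert(0, "study", study)
        frames.append(df)
        print(f"== {study}")
        print(df.round(3).to_string(index=False))
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(RESULTS / "quantitative_validation.csv", index=False)
    print(f"wrote {RESULTS/'quantitative_validation.csv'}")


if __name__ == "__main__":
    main()
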