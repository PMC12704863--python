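#!/usr/bin/env python
"""Qualitative validation: up-regulate each stimulus (and each stimulus plus
a sex hormone) by 0.3, ternarize the steady-state responses, and score them
against the packaged literature-observation table."""

import json
from pathlib import Path

from hormonet.network_io import load_hypertrophy_network
from hormonet.validation import (
    load_literature_observations,
    qualitative_agreement,
    qualitative_screen,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    model = load_hypertrophy_network()
    calls = qualitative_screen(model)
    obs = load_literature_observations()
    n, total, frac, mismatches = qualitative_agreement(calls, obs)
    print(f"agreement with literature observations: {n}/{total} ({100*frac:.0f}%)")
    if len(mismatches):
        print("mismatching cells:")
        print(mismatches.to_string(index=False))
    calls.to_csv(RESULTS / "qualitative_calls.csv", index=False)
    (RESULTS / "qualitative_summary.json").write_text(
        json.dumps({"n_match": n, "n_total": total, "fraction": frac}, indent=2)
    )
    print(f"wrote {RESULTS/'qualitative_calls.csv'}")


if __name__ == "__main__":
    main()
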