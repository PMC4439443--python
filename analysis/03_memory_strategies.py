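#!/usr/bin/env python
"""Five memory-retrieval strategies under realistic pitch variation.

Builds 1-cm-spaced memory banks whose capture pitches follow the zero, small-
load or large-load distributions, then recovers headings at the 81 test
locations under matched and mismatched test-pitch scenarios using the
closest-memory, local-search, full-route, pitch-limited and averaged-image
strategies.  Reports median heading error, pitch mismatch and along-route
spatial mismatch per cell, with rank-sum comparisons against the full-route
strategy.
"""

import sys
from pathlib import Path

from antcompass import (ExperimentConfig, build_environment,
                        run_strategy_evaluation)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    config = ExperimentConfig(master_seed=seed)
    env = build_environment(config)
    rows, summary = run_strategy_evaluation(config, env)
    RESULTS.mkdir(exist_ok=True)
    rows.to_csv(RESULTS / "strategy_rows.csv", index=False)
    summary.to_csv(RESULTS / "strategy_summary.csv", index=False)

    print(summary.to_string(index=False,
                            float_format=lambda v: f"{v:.3f}"))
    piv = summary.pivot(index="scenario", columns="strategy",
                        values="median_error_deg")
    print("\nmedian heading error (deg) by scenario and strategy:")
    print(piv.to_string(float_format=lambda v: f"{v:.2f}"))
    closest_iqr = summary[summary["strategy"] == "closest"]
    print("\nthe closest-memory strategy keeps a 1 cm spatial match but "
          "inherits whatever pitch was stored there: its error IQR grows "
          f"to {closest_iqr['iqr_error_deg'].max():.0f} deg under large "
          "pitch, while local search can pick a nearby memory at a matching "
          "pitch")
    print(f"wrote {RESULTS}/strategy_rows.csv and strategy_summary.csv")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
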