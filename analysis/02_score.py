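#!/usr/bin/env python
"""Score all twelve estimation methods on the simulated cohort.

Reads results/cohort/ and writes the long-form estimates table
(results/estimates.csv) plus a per-method summary to stdout.
"""

from pathlib import Path

from dietna import read_cohort, score_cohort

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    bundle = read_cohort(ROOT / "cohort")
    estimates = score_cohort(bundle)
    estimates.to_csv(ROOT / "estimates.csv", index=False)
    summary = (
        estimates.groupby("method_id", observed=True)["na_mg_per_day"]
        .agg(n="count", mean="mean", sd="std")
        .round(1)
    )
    print(summary.to_string())
    print(f"\nwrote {len(estimates)} estimate rows to {ROOT / 'estimates.csv'}")


if __name__ == "__main__":
    main()
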