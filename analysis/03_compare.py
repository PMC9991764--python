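#!/usr/bin/env python
"""Run the agreement battery of every method against the 24-h collection.

Reads results/estimates.csv and the cohort, screens collection
completeness, and writes the main comparison table, its sensitivity
re-run on complete collections only, and per-method Bland-Altman plot
data under results/.
"""

from pathlib import Path

import pandas as pd

from dietna import CompletenessRules, compare_all, comparison_table, read_cohort
from dietna.agreement import bland_altman, paired_series
from dietna.pipeline import screen_cohort

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    bundle = read_cohort(ROOT / "cohort")
    estimates = pd.read_csv(ROOT / "estimates.csv")
    completeness = screen_cohort(bundle, CompletenessRules())
    print(f"incomplete collections: {int((~completeness).sum())}"
          f"/{len(completeness)} ({100 * (~completeness).mean():.1f}%)")

    results = compare_all(estimates, completeness, sensitivity=False)
    comparison_table(results).to_csv(ROOT / "comparison_table.csv", index=False)
    sens = compare_all(estimates, completeness, sensitivity=True)
    comparison_table(sens).to_csv(ROOT / "comparison_table_sensitivity.csv", index=False)

    for comp in results:
        pairs, *_ = bland_altman(paired_series(estimates, comp.method_id))
        pairs.to_csv(ROOT / f"bland_altman_{comp.method_id}.csv", index=False)

    spot = [c for c in results if c.method_id.startswith("spot_")]
    diet = [c for c in results if not c.method_id.startswith("spot_")]
    print(f"spot methods: bias range {min(c.bias_mean for c in spot):.0f} to "
          f"{max(c.bias_mean for c in spot):.0f} mg (negative = overestimation)")
    print(f"dietary methods: bias range {min(c.bias_mean for c in diet):.0f} to "
          f"{max(c.bias_mean for c in diet):.0f} mg (positive = underestimation)")
    print(f"wrote comparison tables and {len(results)} Bland-Altman files to {ROOT}")


if __name__ == "__main__":
    main()
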