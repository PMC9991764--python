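#!/usr/bin/env python
"""Render the human-readable comparison report for the analysis run.

Equivalent to one `dietna run`, reusing the same seed as 01_simulate so
the tables match the staged outputs; writes results/run/report.txt and
prints it.
"""

from pathlib import Path

from dietna import GeneratorParams, render_report, run_pipeline
from dietna.pipeline import RunConfig

SEED = 20_220_401
ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    config = RunConfig(
        generator=GeneratorParams(n_participants=122, seed=SEED), sensitivity=True
    )
    bundle = run_pipeline(config, out_dir=ROOT / "run")
    print(render_report(bundle))


if __name__ == "__main__":
    main()
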