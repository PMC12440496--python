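#!/usr/bin/env python
"""Run the full screening cascade on the toy panel from 01_simulate_cohorts.

Forward screen (exposures -> outcome), reverse screen (outcome -> passing
exposures), mediator screen, exposure->mediator fits and mediation for the
surviving pairs. Reports land in results/screen/ (per-stage TSVs plus
manifest.json with the gate counts); this driver prints the gate summary.

The designed truth: E1 affects the outcome directly and through M1; E2 is
null; M1-M3 are causal for the outcome, M4-M6 are null.
"""

import json
from pathlib import Path

from mrmediate.screen import ScreenConfig, run_pipeline

SIM = Path("results/sim_data/toy_screen")
SEED = 20250912


def main() -> None:
    if not SIM.exists():
        raise SystemExit("run analysis/01_simulate_cohorts.py first")
    cfg = ScreenConfig(
        seed=SEED,
        outcome_path=str(SIM / "outcome.tsv"),
        exposure_paths=sorted(str(p) for p in (SIM / "exposures").iterdir()),
        mediator_paths=sorted(str(p) for p in (SIM / "mediators").iterdir()),
        presso_nsim=1000,
        boot=1000,
        out_dir="results/screen",
    )
    manifest = run_pipeline(cfg)
    print(json.dumps(manifest["gates"], indent=2))
    print("\nmediation table:")
    print((Path("results/screen") / "mediation.tsv").read_text())


if __name__ == "__main__":
    main()
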