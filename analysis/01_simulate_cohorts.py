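#!/usr/bin/env python
"""Generate the synthetic study panels used by the downstream analyses.

Writes three bundles under results/sim_data/:

* ``pair/``      — one exposure/outcome two-sample panel (30 instruments,
  50k per cohort, true log-odds effect 0.2) with its ground truth;
* ``mediation/`` — one exposure/mediator/outcome three-trait panel
  (theta_xm=0.3, theta_my=0.4, direct=0.08; true proportion mediated 0.6);
* ``toy_screen/`` — the 2-exposure x 6-mediator x 1-outcome screening panel
  with designed pass/fail structure.
"""

from pathlib import Path

from mrmediate.sumstats import write_sumstats
from mrmediate.synthdata import SimTruth, make_fixture, simulate_mediation, simulate_pair

OUT = Path("results/sim_data")
SEED = 20250912


def main() -> None:
    pair_dir = OUT / "pair"
    pair_dir.mkdir(parents=True, exist_ok=True)
    truth = SimTruth(theta_xy_direct=0.2, seed=SEED)
    exposure, outcome = simulate_pair(truth)
    write_sumstats(exposure, pair_dir / "exposure.tsv")
    write_sumstats(outcome, pair_dir / "outcome.tsv")
    (pair_dir / "truth.json").write_text(truth.to_json())
    print(f"pair: {len(exposure)} instruments, true effect {truth.theta_total}")

    med_dir = OUT / "mediation"
    med_dir.mkdir(parents=True, exist_ok=True)
    truth_m = SimTruth(theta_xm=0.3, theta_my=0.4, theta_xy_direct=0.08,
                       n_exp=100_000, n_med=100_000, n_out=100_000, seed=SEED)
    for table, name in zip(simulate_mediation(truth_m), ("exposure", "mediator", "outcome")):
        write_sumstats(table, med_dir / f"{name}.tsv")
    (med_dir / "truth.json").write_text(truth_m.to_json())
    print(f"mediation: true indirect {truth_m.theta_xm * truth_m.theta_my:.3f}, "
          f"true proportion {truth_m.theta_xm * truth_m.theta_my / truth_m.theta_total:.2f}")

    make_fixture("toy_screen", OUT / "toy_screen")
    print(f"toy_screen bundle written under {OUT / 'toy_screen'}")


if __name__ == "__main__":
    main()
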