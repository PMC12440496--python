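#!/usr/bin/env python
"""Recompute the published mediation table from printed stage estimates.

Feeds the published protein->metabolite (beta1) and metabolite->UC (beta2)
IVW coefficients through the product-method mediation machinery and compares
the mediated effects and proportions with the published decomposition.
Writes results/worked_examples/mediation_recomputed.tsv.

Note the proportions: recomputed values differ slightly from the published
ones (e.g. 8.8% vs 8.6%) because the publication used unrounded stage
estimates while only 3-dp values are printed; the mediated effects agree
exactly at 3 dp.
"""

from pathlib import Path

import numpy as np

from mrmediate.studies import or_transform_report, published_mediation_recomputed

OUT = Path("results/worked_examples")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    df = published_mediation_recomputed()
    df.to_csv(OUT / "mediation_recomputed.tsv", sep="\t", index=False)

    print("mediated effects (recomputed vs published):")
    for row in df.itertuples(index=False):
        print(f"  {row.exposure:7s} via {row.mediator[:45]:45s} "
              f"{row.indirect:+.3f} (pub {row.published_effect:+.3f})  "
              f"proportion {row.proportion_pct:+.1f}% (pub {row.published_proportion_pct:+.1f}%)  "
              f"Sobel p={row.sobel_p:.3f}")
    assert np.array_equal(df["indirect"].round(3), df["published_effect"])

    rep = or_transform_report()
    print(f"\nOR transform: {rep['n_rows']} published rows, "
          f"max |e^beta - OR_printed| = {rep['max_abs_discrepancy']:.4f}")


if __name__ == "__main__":
    main()
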