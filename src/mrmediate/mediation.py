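"""Two-step Mendelian-randomization mediation.

Three univariable MR fits — exposure→mediator (β₁), mediator→outcome (β₂)
and exposure→outcome (β_t) — combine by the product method:

* indirect effect = β₁β₂, with Sobel SE √(β₁²·SE₂² + β₂²·SE₁²) and a
  two-sided normal test Z = β₁β₂ / SE;
* direct effect = β_t − β₁β₂;
* proportion mediated = β₁β₂ / β_t, with a delta-method CI treating the
  indirect and total estimates as independent (they come from different
  instrument sets).

Negative proportions are legal (the indirect path opposes the total effect);
|proportion| > 1 is reported untruncated with an inconsistent-mediation flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mr import MRFit


def sobel_test(beta1: float, se1: float, beta2: float, se2: float) -> tuple[float, float, float]:
    """Sobel product-of-coefficients inference.

    Returns (se_indirect, z, p) with se = √(β₁²SE₂² + β₂²SE₁²),
    z = β₁β₂/se and p = 2Φ(−|z|). The degenerate β₁ = β₂ = 0 case takes the
    limit convention z = 0, p = 1.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    se_ind = float(np.sqrt(beta1**2 * se2**2 + beta2**2 * se1**2))
    if se_ind == 0.0:
        return 0.0, 0.0, 1.0
    z = beta1 * beta2 / se_ind
    p = float(2 * stats.norm.sf(abs(z)))
    return se_ind, float(z), p


@dataclass
class MediationResult:
    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta1: float
    se1: float
    beta2: float
    se2: float
    beta_total: float
    se_total: float
    indirect: float
    se_indirect: float
    sobel_z: float
    sobel_p: float
    indirect_ci: tuple[float, float]
    direct: float
    proportion: float | None
    proportion_se: float | None
    proportion_ci: tuple[float, float] | None
    inconsistent: bool = False  # |proportion| > 1: suppression/inconsistent mediation


def mediate(fit_xm: MRFit, fit_my: MRFit, fit_xy: MRFit, level: float = 0.95,
            exposure_id: str = "X", mediator_id: str = "M", outcome_id: str = "Y") -> MediationResult:
    """Combine the three stage fits into a mediation decomposition.

    When β_t = 0 the proportion is undefined and reported as missing; the
    effect decomposition is still returned.
    """
    b1, s1 = fit_xm.beta, fit_xm.se
    b2, s2 = fit_my.beta, fit_my.se
    bt, st = fit_xy.beta, fit_xy.se

    se_ind, z, p = sobel_test(b1, s1, b2, s2)
    indirect = b1 * b2
    zq = stats.norm.ppf(0.5 + level / 2)
    ind_ci = (indirect - zq * se_ind, indirect + zq * se_ind)
    direct = bt - indirect

    proportion = proportion_se = proportion_ci = None
    inconsistent = False
    if bt != 0:
        proportion = indirect / bt
        # delta method, indirect and total treated as independent
        var_prop = se_ind**2 / bt**2 + (indirect**2 * st**2) / bt**4
        proportion_se = float(np.sqrt(var_prop))
        proportion_ci = (proportion - zq * proportion_se, proportion + zq * proportion_se)
        inconsistent = abs(proportion) > 1

    return MediationResult(
        exposure_id=exposure_id,
        mediator_id=mediator_id,
        outcome_id=outcome_id,
        beta1=b1, se1=s1, beta2=b2, se2=s2,
        beta_total=bt, se_total=st,
        indirect=indirect, se_indirect=se_ind,
        sobel_z=z, sobel_p=p,
        indirect_ci=ind_ci,
        direct=direct,
        proportion=proportion,
        proportion_se=proportion_se,
        proportion_ci=proportion_ci,
        inconsistent=inconsistent,
    )


def proportion_summary(results: list[MediationResult]) -> pd.DataFrame:
    """Report table: one row per (exposure, mediator, outcome) triple with
    the mediated effect (95% CI, 3 dp) and mediated proportion (95% CI, 1 dp %)."""
    seen = set()
    rows = []
    for r in results:
        key = (r.exposure_id, r.mediator_id, r.outcome_id)
        if key in seen:
            raise ValueError(f"duplicate mediation triple {key}")
        seen.add(key)
        if r.proportion is not None:
            prop = f"{r.proportion * 100:.1f}% ({r.proportion_ci[0] * 100:.1f}%, {r.proportion_ci[1] * 100:.1f}%)"
        else:
            prop = "NA"
        rows.append(
            {
                "exposure": r.exposure_id,
                "mediator": r.mediator_id,
                "outcome": r.outcome_id,
                "mediated_effect_95ci": f"{r.indirect:.3f} ({r.indirect_ci[0]:.3f}, {r.indirect_ci[1]:.3f})",
                "mediated_proportion_95ci": prop,
                "sobel_p": r.sobel_p,
                "flag": "inconsistent_mediation" if r.inconsistent else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "exposure", "mediator", "outcome",
            "mediated_effect_95ci", "mediated_proportion_95ci", "sobel_p", "flag",
        ],
    )
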