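# mrmediate

Two-sample Mendelian randomization (MR) and metabolite-mediation analysis
on GWAS summary statistics.

The package is built around the screening design used to ask whether
circulating inflammatory proteins act on ulcerative colitis (UC) risk
through plasma metabolites: select genetic instruments from each exposure
GWAS (p < 1×10⁻⁵, LD clumping at r² < 0.001 within 1000 kb, weak-instrument
filter F ≥ 10, Steiger directionality filter), harmonize them against the
outcome GWAS (palindromic variants aligned by allele frequency or dropped
at intermediate MAF), estimate causal effects with an estimator suite —
inverse-variance weighting with heterogeneity-driven fixed/random model
choice, MR-Egger, the weighted median, MR-PRESSO outlier correction,
leave-one-out — and decompose exposure→outcome effects through mediators by
the product method:

    indirect = β₁·β₂          β₁: exposure→mediator, β₂: mediator→outcome
    direct   = β_t − β₁·β₂     β_t: total exposure→outcome effect
    proportion mediated = β₁·β₂ / β_t

with Sobel inference (SE = √(β₁²SE₂² + β₂²SE₁²), Z = β₁β₂/SE) and
delta-method confidence intervals for the proportion. Binary-outcome
effects are log odds, reported as OR = e^β with 95% CIs.

Because the original cohort-level GWAS are not redistributable, the package
ships a seeded synthetic generator (`mrmediate.synthdata`) that draws
individual-level genotype cohorts under an additive model with known causal
effects, mediation structure, horizontal pleiotropy, reverse-causal
instruments and optional block LD, and emits the same summary-statistic
tables the real pipeline consumes — so every stage is tested against known
ground truth. The published stage estimates of the UC study are bundled as
worked examples (`mrmediate.worked_examples`) to exercise the mediation
arithmetic against printed numbers.

## Worked example

Feeding the published IL10RB→tetradecadienoate(14:2) and
tetradecadienoate→UC estimates through the mediation machinery:

```python
import numpy as np
from mrmediate.mediation import mediate
from mrmediate.mr import MRFit, to_odds_ratio

def fit(beta, se):
    or_, lo, hi = to_odds_ratio(beta, se)
    return MRFit("ivw_fixed", 0, beta, se, 1.0, or_, lo, hi)

res = mediate(
    fit(0.075, 0.026),          # β₁: IL10RB -> tetradecadienoate (14:2)
    fit(-0.211, 0.068),         # β₂: tetradecadienoate -> UC
    fit(np.log(1.15), 0.05),    # β_t: IL10RB -> UC (OR 1.15)
)
print(f"indirect {res.indirect:.3f}, Sobel z {res.sobel_z:.3f} "
      f"(p={res.sobel_p:.4f}), proportion {100*res.proportion:.1f}%")
```

prints

```
indirect -0.016, Sobel z -2.113 (p=0.0346), proportion -11.3%
```

— the mediated effect −0.016 matches the published decomposition at 3
decimals; the indirect path is protective while the total IL10RB effect is
harmful, so the proportion mediated is negative (the published value,
−11.7%, was computed from unrounded stage estimates). The analysis drivers
under `analysis/` run the full story end to end:

```bash
python analysis/01_simulate_cohorts.py      # synthetic study panels
python analysis/02_run_screen_pipeline.py   # screening cascade + mediation
python analysis/03_worked_examples.py       # published-table arithmetic
python analysis/04_calibration_studies.py   # Monte-Carlo calibration
```

A `mrmediate` CLI exposes the same stages (`run`, `harmonize`, `mr`,
`presso`, `mediate`, `simulate`); see `mrmediate --help`.

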