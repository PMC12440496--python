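"""Published two-sample MR estimates used as worked examples.

These are the printed summary estimates from a bidirectional MR mediation
study of 91 circulating inflammatory proteins, 1400 plasma metabolites and
ulcerative colitis (UC; FinnGen, 5931 cases / 405,386 controls). They serve
as fixed inputs for exercising the mediation arithmetic (product method,
Sobel test, delta-method CIs) and the OR = e^β transform against published
numbers — no genotype-level data are needed for that.

Effects are log odds (outcome UC) or SD units (protein/metabolite outcomes).
Values retain the precision at which they were printed.
"""

from __future__ import annotations

import pandas as pd

# Reverse-direction screen: UC as exposure, the six forward-significant
# inflammatory proteins as outcomes (IVW; all null). CCL8's beta was printed
# only as "<0.001" and is stored as missing.
REVERSE_UC_ON_PROTEINS = pd.DataFrame(
    [
        ("UC", "CCL11", 42, -0.007, 0.013, 0.62, 0.993, 0.968, 1.020),
        ("UC", "CCL4", 42, 0.031, 0.054, 0.567, 1.032, 0.927, 1.147),
        ("UC", "Flt3L", 42, -0.016, 0.015, 0.307, 0.985, 0.955, 1.014),
        ("UC", "IL10RB", 42, 0.04, 0.044, 0.362, 1.041, 0.955, 1.135),
        ("UC", "CCL8", 42, None, 0.016, 0.99, 1.000, 0.969, 1.032),
        ("UC", "PD-L1", 42, -0.01, 0.013, 0.453, 0.990, 0.964, 1.016),
    ],
    columns=["exposure", "outcome", "nsnp", "beta", "se", "pval", "or_", "ci_low", "ci_high"],
)

# Metabolite -> UC screen (IVW), the 21 metabolites retained after QC.
METABOLITES_ON_UC = pd.DataFrame(
    [
        ("Stearoylcarnitine", 20, -0.193, 0.069, 0.005, 0.824, 0.719, 0.944),
        ("1-Arachidonoyl-GPC (20:4n6)", 27, -0.109, 0.037, 0.003, 0.897, 0.835, 0.964),
        ("3-Methoxycatechol sulfate (2)", 22, 0.132, 0.05, 0.009, 1.141, 1.034, 1.259),
        ("Nonanoylcarnitine (C9)", 20, 0.114, 0.038, 0.003, 1.120, 1.039, 1.207),
        ("1-Stearoyl-2-linoleoyl-GPC (18:0/18:2)", 20, 0.232, 0.061, 0.0005, 1.262, 1.119, 1.423),
        ("1-Palmitoyl-2-docosahexaenoyl-GPC (16:0/22:6)", 23, -0.153, 0.053, 0.004, 0.858, 0.774, 0.951),
        ("1-Stearoyl-2-docosahexaenoyl-GPC (18:0/22:6)", 27, -0.117, 0.044, 0.008, 0.890, 0.817, 0.970),
        ("1-(1-Enyl-stearoyl)-2-arachidonoyl-GPE (p-18:0/20:4)", 24, -0.154, 0.05, 0.002, 0.857, 0.778, 0.945),
        ("1-Oleoyl-2-linoleoyl-GPE (18:1/18:2)", 33, 0.099, 0.029, 0.001, 1.104, 1.043, 1.169),
        ("Arachidonoylcholine", 19, -0.149, 0.057, 0.008, 0.861, 0.771, 0.962),
        ("Tetradecadienoate (14:2)", 15, -0.211, 0.068, 0.002, 0.810, 0.709, 0.925),
        ("X-11308", 29, -0.106, 0.039, 0.007, 0.900, 0.833, 0.971),
        ("X-15461", 24, 0.147, 0.053, 0.005, 1.159, 1.045, 1.285),
        ("X-17351", 17, 0.147, 0.057, 0.010, 1.159, 1.036, 1.296),
        ("X-19438", 24, 0.182, 0.048, 0.0005, 1.199, 1.092, 1.317),
        ("X-24494", 19, -0.153, 0.048, 0.002, 0.858, 0.781, 0.943),
        ("2'-O-methylcytidine", 19, 0.072, 0.026, 0.006, 1.075, 1.021, 1.131),
        ("Arachidonate (20:4n6) to oleate to vaccenate (18:1) ratio", 19, -0.121, 0.044, 0.006, 0.886, 0.813, 0.966),
        ("Oleoyl-linoleoyl-glycerol [2] to linoleoyl-arachidonoyl-glycerol [1] ratio", 25, 0.103, 0.028, 0.0005, 1.108, 1.049, 1.171),
        ("Phosphate to threonine ratio", 33, -0.111, 0.043, 0.01, 0.895, 0.823, 0.973),
        ("Cholesterol to cortisol ratio", 17, -0.17, 0.064, 0.008, 0.844, 0.745, 0.956),
    ],
    columns=["exposure", "nsnp", "beta", "se", "pval", "or_", "ci_low", "ci_high"],
)

# Stage-1 fits (beta1): inflammatory protein -> mediating metabolite (IVW).
PROTEIN_ON_METABOLITE = pd.DataFrame(
    [
        ("CCL4", "1-(1-Enyl-stearoyl)-2-arachidonoyl-GPE (p-18:0/20:4)", 30, -0.065, 0.028, 0.020, 0.937, 0.887, 0.990),
        ("CCL4", "X-24494", 30, 0.065, 0.03, 0.033, 1.067, 1.005, 1.133),
        ("IL10RB", "1-Arachidonoyl-GPC (20:4n6)", 20, 0.059, 0.025, 0.019, 1.061, 1.009, 1.114),
        ("IL10RB", "2'-O-methylcytidine", 20, 0.062, 0.026, 0.016, 1.063, 1.011, 1.118),
        ("IL10RB", "Tetradecadienoate (14:2)", 20, 0.075, 0.026, 0.003, 1.078, 1.025, 1.134),
    ],
    columns=["exposure", "mediator", "nsnp", "beta1", "se1", "pval", "or_", "ci_low", "ci_high"],
)

# Stage-2 fits (beta2): mediating metabolite -> UC (IVW).
METABOLITE_ON_UC_STAGE2 = pd.DataFrame(
    [
        ("1-Arachidonoyl-GPC (20:4n6)", 27, -0.109, 0.037, 0.0030, 0.897, 0.835, 0.964),
        ("1-(1-Enyl-stearoyl)-2-arachidonoyl-GPE (p-18:0/20:4)", 24, -0.154, 0.050, 0.0020, 0.857, 0.778, 0.945),
        ("Tetradecadienoate (14:2)", 15, -0.211, 0.068, 0.0019, 0.810, 0.709, 0.925),
        ("X-24494", 19, -0.153, 0.048, 0.0015, 0.858, 0.781, 0.943),
        ("2'-O-methylcytidine", 19, 0.072, 0.026, 0.0062, 1.075, 1.021, 1.131),
    ],
    columns=["mediator", "nsnp", "beta2", "se2", "pval", "or_", "ci_low", "ci_high"],
)

# Published mediation decomposition for the five triples (outcome UC):
# mediated effect (beta1*beta2) with CI, and the published mediated
# proportion (computed by the authors from unrounded stage estimates).
MEDIATION_PUBLISHED = pd.DataFrame(
    [
        ("CCL4", "1-(1-Enyl-stearoyl)-2-arachidonoyl-GPE (p-18:0/20:4)", 0.010, -0.001, 0.021, 8.6),
        ("CCL4", "X-24494", -0.010, -0.021, 0.001, -8.6),
        ("IL10RB", "1-Arachidonoyl-GPC (20:4n6)", -0.006, -0.013, 0.000, -4.7),
        ("IL10RB", "Tetradecadienoate (14:2)", -0.016, -0.031, -0.001, -11.7),
        ("IL10RB", "2'-O-methylcytidine", 0.004, -0.001, 0.009, 3.3),
    ],
    columns=["exposure", "mediator", "mediated_effect", "eff_ci_low", "eff_ci_high", "proportion_pct"],
)

# Forward totals for the two risk proteins (OR scale, IVW).
TOTAL_EFFECTS = {
    "CCL4": {"or_": 1.12, "ci_low": 1.03, "ci_high": 1.22, "pval": 0.008, "nsnp": 31},
    "IL10RB": {"or_": 1.15, "ci_low": 1.03, "ci_high": 1.27, "pval": 0.011},
}

# Exact-roundable OR spot checks: printed beta -> printed OR at 3 dp.
OR_SPOT_CHECKS = [
    (-0.193, 0.824),
    (-0.153, 0.858),
    (-0.211, 0.810),
    (0.072, 1.075),
]
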