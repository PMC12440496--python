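"""Synthetic GWAS summary statistics with known ground truth.

Individual-level cohorts are drawn from an additive genetic model —
genotypes g ~ Binomial(2, MAF) in Hardy–Weinberg equilibrium, exposure
X = Σγ_j g_j + ε standardized to unit variance — in strictly non-overlapping
samples per trait (the two-sample assumption). Outcome liability adds the
causal path, optional per-variant horizontal pleiotropy (directional when
its mean is nonzero) and, for binary outcomes, a logistic residual
thresholded at the prevalence quantile; per-variant log-odds effects then
come from logistic score statistics, so downstream odds ratios e^β are on
the right scale. Continuous traits use per-variant simple linear regression.

A three-trait mode generates exposure → mediator → outcome panels with a
known indirect effect θ_xm·θ_my and direct effect, for end-to-end mediation
recovery studies. Everything is driven by one seeded generator: the same
SimTruth gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import LDMatrix
from .sumstats import HarmonizedSet, SumStatTable, write_sumstats

DEFAULT_SEED = 20250912


@dataclass
class SimTruth:
    """Ground-truth parameters of the synthetic generator.

    For a plain exposure→outcome pair set ``theta_xy_direct`` to the causal
    effect and leave the mediation parameters at zero; the marginal
    exposure→outcome effect is always ``theta_xy_direct + theta_xm·theta_my``.
    ``outcome_prevalence=None`` makes the outcome continuous.
    """

    n_snp: int = 30
    maf: np.ndarray | None = None          # per-SNP, drawn U(0.05, 0.5) if None
    gamma: np.ndarray | None = None        # per-SNP exposure effects; scaled to h2_exposure if None
    h2_exposure: float = 0.075
    theta_xm: float = 0.0                  # X -> M
    theta_my: float = 0.0                  # M -> Y (log-odds per unit M for binary Y)
    theta_xy_direct: float = 0.0           # X -> Y not through M
    pleio_prop: float = 0.0                # fraction of X instruments with direct outcome effects
    pleio_mean: float = 0.0                # directional when != 0
    pleio_sd: float = 0.0
    n_exp: int = 50_000
    n_med: int = 50_000
    n_out: int = 50_000
    outcome_prevalence: float | None = 0.1
    seed: int = DEFAULT_SEED
    # mediator-specific genetics (three-trait mode)
    n_snp_med: int = 30
    h2_mediator: float = 0.075
    # reverse-causal instruments (outcome-first variants, directionality studies)
    reverse_prop: float = 0.0
    reverse_feedback: float = 0.1          # loading of the outcome-genetic score on X
    h2_reverse: float = 0.03
    # optional AR(1) block LD (Gaussian-copula haplotypes)
    ld_block_size: int = 1
    ld_rho: float = 0.0

    def __post_init__(self) -> None:
        if self.maf is not None:
            self.maf = np.asarray(self.maf, dtype=float)
            if len(self.maf) != self.n_snp:
                raise ValueError("maf length must equal n_snp")
            if (self.maf <= 0).any() or (self.maf > 0.5).any():
                raise ValueError("maf must lie in (0, 0.5]")
        if not 0 <= self.pleio_prop <= 1:
            raise ValueError("pleio_prop must be in [0, 1]")
        if not 0 <= self.reverse_prop <= 1:
            raise ValueError("reverse_prop must be in [0, 1]")
        for nm in ("n_exp", "n_med", "n_out"):
            if getattr(self, nm) < 100:
                raise ValueError(f"{nm} must be >= 100")
        if self.outcome_prevalence is not None and not 0 < self.outcome_prevalence < 1:
            raise ValueError("outcome_prevalence must be in (0, 1)")
        if not 0 < self.h2_exposure < 1:
            raise ValueError("h2_exposure must be in (0, 1)")

    @property
    def theta_total(self) -> float:
        return self.theta_xy_direct + self.theta_xm * self.theta_my

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return json.dumps(d, indent=2, sort_keys=True)


def _draw_maf(rng: np.random.Generator, truth: SimTruth, m: int) -> np.ndarray:
    if truth.maf is not None and m == truth.n_snp:
        return truth.maf
    return rng.uniform(0.05, 0.5, m)


def _scaled_effects(rng: np.random.Generator, maf: np.ndarray, mask: np.ndarray, h2: float) -> np.ndarray:
    """Per-allele effects on the masked SNPs, jointly scaled so the additive
    variance Σ 2p(1−p)β² equals h2; magnitudes U(0.5, 1.5) with random sign
    keep instrument strengths within a factor ~10 of one another."""
    beta = np.zeros(len(maf))
    k = int(mask.sum())
    if k == 0 or h2 == 0:
        return beta
    raw = rng.uniform(0.5, 1.5, k) * rng.choice([-1.0, 1.0], k)
    var_unit = 2 * maf[mask] * (1 - maf[mask]) * raw**2
    beta[mask] = raw * np.sqrt(h2 / var_unit.sum())
    return beta


def _draw_genotypes(rng: np.random.Generator, n: int, maf: np.ndarray, truth: SimTruth) -> np.ndarray:
    m = len(maf)
    if truth.ld_block_size <= 1 or truth.ld_rho == 0.0:
        # two Bernoulli haplotypes from float32 uniforms: same Binomial(2, maf)
        # law as rng.binomial but several times faster at cohort scale
        p = maf.astype(np.float32)
        G = (rng.random((n, m), dtype=np.float32) < p).astype(np.float32)
        G += rng.random((n, m), dtype=np.float32) < p
        return G
    # AR(1) latent Gaussian per haplotype within blocks, thresholded at the MAF
    b = truth.ld_block_size
    rho = truth.ld_rho
    G = np.empty((n, m))
    thr = stats.norm.ppf(maf)
    for start in range(0, m, b):
        stop = min(start + b, m)
        width = stop - start
        hap = np.zeros((2, n, width))
        for h in range(2):
            z = rng.standard_normal((n, width))
            lat = np.empty_like(z)
            lat[:, 0] = z[:, 0]
            for j in range(1, width):
                lat[:, j] = rho * lat[:, j - 1] + np.sqrt(1 - rho**2) * z[:, j]
            hap[h] = lat < thr[start:stop]
        G[:, start:stop] = hap.sum(axis=0)
    return G


def _centered_moments(G: np.ndarray, resid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(Σ gc², Σ gc·resid) per SNP without materialising the centered
    genotype matrix; ``resid`` must already be mean-centered."""
    n = G.shape[0]
    sg = G.sum(axis=0, dtype=np.float64)
    sgg = (G * G).sum(axis=0, dtype=np.float64)
    sxx = sgg - sg**2 / n
    sxy = (G.T @ resid.astype(G.dtype, copy=False)).astype(np.float64)
    return sxx, sxy



def _gv(G: np.ndarray, v: np.ndarray) -> np.ndarray:
    """G @ v keeping the genotype matrix in its compact dtype."""
    return (G @ v.astype(G.dtype, copy=False)).astype(np.float64)

def _linear_summary(G: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-SNP simple linear regression of y on genotype dosage."""
    n = len(y)
    y64 = np.asarray(y, np.float64)
    yc = y64 - y64.mean()
    sxx, sxy = _centered_moments(G, yc)
    beta = sxy / sxx
    syy = float(yc @ yc)
    sigma2 = np.maximum((syy - beta**2 * sxx) / (n - 2), 0.0)
    se = np.sqrt(sigma2 / sxx)
    t = beta / se
    pval = np.clip(2 * stats.t.sf(np.abs(t), n - 2), 1e-300, 1.0)
    return beta, se, pval


def _logistic_score_summary(G: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-SNP log-odds effects from the logistic score test (valid for the
    small per-variant effects of a polygenic trait)."""
    y64 = np.asarray(y, np.float64)
    ybar = y64.mean()
    sxx, U = _centered_moments(G, y64 - ybar)
    info = ybar * (1 - ybar) * sxx
    beta = U / info
    se = 1.0 / np.sqrt(info)
    z = beta / se
    pval = np.clip(2 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    return beta, se, pval


def _table(trait_id, trait_type, ids, chrom, pos, eaf, beta, se, pval, n) -> SumStatTable:
    df = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": n,
        }
    )
    return SumStatTable(trait_id, trait_type, df)


def _positions(m: int, block_size: int) -> tuple[list[str], np.ndarray]:
    """Chrom-1 positions: independent SNPs 2 Mb apart; LD-block members 10 kb
    apart so clumping windows span a block but not its neighbours."""
    if block_size <= 1:
        pos = 1 + 2_000_000 * np.arange(m)
    else:
        block = np.arange(m) // block_size
        within = np.arange(m) % block_size
        pos = 1 + 2_000_000 * block + 10_000 * within
    return ["1"] * m, pos.astype(int)


def pair_design(truth: SimTruth) -> dict:
    """Deterministic per-variant design of a two-sample simulation: MAFs,
    exposure effects, reverse-causal assignment, pleiotropy effects. Drawn
    from a child generator of the truth seed so callers can recover the
    assignment without replaying the cohort stream."""
    rng = np.random.default_rng([truth.seed, 0])
    m = truth.n_snp
    maf = _draw_maf(rng, truth, m)

    n_rev = int(round(truth.reverse_prop * m))
    rev_mask = np.zeros(m, bool)
    if n_rev:
        rev_mask[rng.choice(m, n_rev, replace=False)] = True
    fwd_mask = ~rev_mask

    gamma = (
        np.asarray(truth.gamma, float)
        if truth.gamma is not None
        else _scaled_effects(rng, maf, fwd_mask, truth.h2_exposure)
    )
    rho = _scaled_effects(rng, maf, rev_mask, truth.h2_reverse)

    alpha = np.zeros(m)
    if truth.pleio_prop > 0:
        cand = np.flatnonzero(fwd_mask)
        n_pleio = int(round(truth.pleio_prop * len(cand)))
        if n_pleio:
            chosen = rng.choice(cand, n_pleio, replace=False)
            alpha[chosen] = rng.normal(truth.pleio_mean, truth.pleio_sd, n_pleio)

    return {
        "maf": maf,
        "reverse_mask": rev_mask,
        "gamma": gamma,
        "rho": rho,
        "alpha": alpha,
        "variant_ids": [f"rs{i + 1}" for i in range(m)],
    }


def simulate_pair(truth: SimTruth, return_ld: bool = False):
    """Two-sample exposure/outcome summary statistics with known causal effect.

    Returns ``(exposure, outcome)`` SumStatTables, plus an empirical
    :class:`LDMatrix` from the exposure cohort's genotypes when
    ``return_ld=True``.
    """
    design = pair_design(truth)
    maf, gamma, rho, alpha = design["maf"], design["gamma"], design["rho"], design["alpha"]
    m = truth.n_snp
    ids = design["variant_ids"]
    chrom, pos = _positions(m, truth.ld_block_size)
    rng = np.random.default_rng([truth.seed, 1])

    sd_eps = np.sqrt(max(1.0 - truth.h2_exposure, 0.05))
    loadings = gamma + truth.reverse_feedback * rho

    # exposure cohort
    G1 = _draw_genotypes(rng, truth.n_exp, maf, truth)
    x1 = _gv(G1, loadings) + rng.normal(0, sd_eps, truth.n_exp)
    x1 = (x1 - x1.mean()) / x1.std()
    b_e, s_e, p_e = _linear_summary(G1, x1)
    exposure = _table("X", "continuous", ids, chrom, pos, G1.mean(0) / 2, b_e, s_e, p_e, truth.n_exp)

    # outcome cohort (non-overlapping)
    G2 = _draw_genotypes(rng, truth.n_out, maf, truth)
    x2 = _gv(G2, loadings) + rng.normal(0, sd_eps, truth.n_out)
    x2 = (x2 - x2.mean()) / x2.std()
    liability = truth.theta_total * x2 + _gv(G2, alpha + rho)
    if truth.outcome_prevalence is None:
        y = liability + rng.standard_normal(truth.n_out)
        b_o, s_o, p_o = _linear_summary(G2, y)
        out_type = "continuous"
    else:
        liability = liability + rng.logistic(0, 1, truth.n_out)
        thr = np.quantile(liability, 1 - truth.outcome_prevalence)
        y = (liability > thr).astype(float)
        b_o, s_o, p_o = _logistic_score_summary(G2, y)
        out_type = "binary"
    outcome = _table("Y", out_type, ids, chrom, pos, G2.mean(0) / 2, b_o, s_o, p_o, truth.n_out)

    if return_ld:
        r = np.corrcoef(G1, rowvar=False)
        ld = LDMatrix(ids, r**2, pd.DataFrame({"chrom": chrom, "pos": pos}, index=ids))
        return exposure, outcome, ld
    return exposure, outcome


def simulate_mediation(truth: SimTruth):
    """Three-trait panels (exposure, mediator, outcome) in non-overlapping
    cohorts, with exposure instruments, mediator-specific instruments, the
    X→M→Y chain and a direct X→Y path. True indirect effect is
    ``theta_xm·theta_my``; true total is ``theta_total``."""
    rng = np.random.default_rng(truth.seed)
    m = truth.n_snp + truth.n_snp_med
    maf = _draw_maf(rng, truth, m)
    ids = [f"rs{i + 1}" for i in range(m)]
    chrom, pos = _positions(m, truth.ld_block_size)

    x_mask = np.zeros(m, bool)
    x_mask[: truth.n_snp] = True
    gamma = _scaled_effects(rng, maf, x_mask, truth.h2_exposure)
    delta = _scaled_effects(rng, maf, ~x_mask, truth.h2_mediator)

    alpha = np.zeros(m)
    if truth.pleio_prop > 0:
        cand = np.flatnonzero(x_mask)
        n_pleio = int(round(truth.pleio_prop * len(cand)))
        if n_pleio:
            chosen = rng.choice(cand, n_pleio, replace=False)
            alpha[chosen] = rng.normal(truth.pleio_mean, truth.pleio_sd, n_pleio)

    sd_x = np.sqrt(max(1.0 - truth.h2_exposure, 0.05))
    sd_m = np.sqrt(max(1.0 - truth.h2_mediator, 0.05))

    def draw_x(G, n):
        x = _gv(G, gamma) + rng.normal(0, sd_x, n)
        return (x - x.mean()) / x.std()

    def draw_m(G, x, n):
        return truth.theta_xm * x + _gv(G, delta) + rng.normal(0, sd_m, n)

    # exposure cohort
    G1 = _draw_genotypes(rng, truth.n_exp, maf, truth)
    x1 = draw_x(G1, truth.n_exp)
    b, s, p = _linear_summary(G1, x1)
    exposure = _table("X", "continuous", ids, chrom, pos, G1.mean(0) / 2, b, s, p, truth.n_exp)

    # mediator cohort
    G2 = _draw_genotypes(rng, truth.n_med, maf, truth)
    m2 = draw_m(G2, draw_x(G2, truth.n_med), truth.n_med)
    b, s, p = _linear_summary(G2, m2)
    mediator = _table("M", "continuous", ids, chrom, pos, G2.mean(0) / 2, b, s, p, truth.n_med)

    # outcome cohort
    G3 = _draw_genotypes(rng, truth.n_out, maf, truth)
    x3 = draw_x(G3, truth.n_out)
    m3 = draw_m(G3, x3, truth.n_out)
    liability = truth.theta_my * m3 + truth.theta_xy_direct * x3 + _gv(G3, alpha)
    if truth.outcome_prevalence is None:
        y = liability + rng.standard_normal(truth.n_out)
        b, s, p = _linear_summary(G3, y)
        out_type = "continuous"
    else:
        liability = liability + rng.logistic(0, 1, truth.n_out)
        thr = np.quantile(liability, 1 - truth.outcome_prevalence)
        y = (liability > thr).astype(float)
        b, s, p = _logistic_score_summary(G3, y)
        out_type = "binary"
    outcome = _table("Y", out_type, ids, chrom, pos, G3.mean(0) / 2, b, s, p, truth.n_out)

    return exposure, mediator, outcome


def outlier_demo_set(seed: int = DEFAULT_SEED, n_snp: int = 30, theta: float = 0.3,
                     displacement: float = 10.0) -> tuple[HarmonizedSet, str]:
    """Harmonized set of ``n_snp`` instruments, all consistent with slope
    ``theta`` except the last, whose outcome effect is displaced by
    ``displacement`` outcome standard errors. Returns (set, outlier_id)."""
    rng = np.random.default_rng(seed)
    k = n_snp
    beta_exp = rng.uniform(0.1, 0.3, k) * rng.choice([-1.0, 1.0], k)
    se_exp = np.full(k, 0.01)
    se_out = np.full(k, 0.02)
    beta_out = theta * beta_exp + rng.normal(0, se_out)
    beta_out[-1] += displacement * se_out[-1]
    ids = [f"rs{i + 1}" for i in range(k)]
    rows = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": "1",
            "pos": 1 + 2_000_000 * np.arange(k),
            "effect_allele": "A",
            "other_allele": "G",
            "beta_exp": beta_exp,
            "se_exp": se_exp,
            "eaf_exp": 0.3,
            "n_exp": 50_000,
            "beta_out": beta_out,
            "se_out": se_out,
            "eaf_out": 0.3,
            "n_out": 50_000,
        }
    )
    audit = pd.DataFrame({"variant_id": ids, "action": "kept"})
    return HarmonizedSet("X", "Y", rows, audit), ids[-1]


# ---------------------------------------------------------------------------
# deterministic fixture bundles

#: structural effects of the toy screening panel: 2 exposures, 6 mediators,
#: 1 binary outcome. E1 acts on Y directly and through M1; E2 is null.
#: M1-M3 have true effects on Y; M4-M6 are null.
TOY_SCREEN_DESIGN = {
    "theta_e1_m1": 0.5,
    "theta_e1_y_direct": 0.2,
    "theta_m_y": {"M1": 0.6, "M2": 0.5, "M3": 0.45, "M4": 0.0, "M5": 0.0, "M6": 0.0},
    "n_per_cohort": 20_000,
    "snps_per_trait": 12,
    "prevalence": 0.1,
    "h2_trait": 0.05,
    "h2_outcome_direct": 0.15,  # outcome-specific liability block -> reverse-MR instruments
}


def simulate_toy_screen(seed: int = DEFAULT_SEED) -> dict:
    """2-exposure / 6-mediator / 1-outcome panel with designed pass/fail
    structure (see TOY_SCREEN_DESIGN). All traits share one SNP panel in
    which each trait owns a disjoint instrument block; the outcome block acts
    on liability only, giving the reverse screen genuine instruments."""
    d = TOY_SCREEN_DESIGN
    rng = np.random.default_rng(seed)
    traits = ["E1", "E2", "M1", "M2", "M3", "M4", "M5", "M6", "Y"]
    per = d["snps_per_trait"]
    m = per * len(traits)
    maf = rng.uniform(0.1, 0.5, m)
    ids = [f"rs{i + 1}" for i in range(m)]
    chrom, pos = _positions(m, 1)
    n = d["n_per_cohort"]

    effects = {}
    for i, t in enumerate(traits):
        mask = np.zeros(m, bool)
        mask[i * per : (i + 1) * per] = True
        h2 = d["h2_outcome_direct"] if t == "Y" else d["h2_trait"]
        effects[t] = _scaled_effects(rng, maf, mask, h2)

    def genetic(G, t):
        return _gv(G, effects[t])

    def trait_value(G, t, n_):
        """Structural equation for trait t in cohort of size n_."""
        base = genetic(G, t) + rng.normal(0, np.sqrt(0.95), n_)
        if t == "M1":
            e1 = genetic(G, "E1") + rng.normal(0, np.sqrt(0.95), n_)
            base = base + d["theta_e1_m1"] * (e1 - e1.mean()) / e1.std()
        return (base - base.mean()) / base.std()

    tables = {}
    for t in traits:
        if t == "Y":
            continue
        G = _draw_genotypes(rng, n, maf, SimTruth(n_snp=m, maf=maf, seed=seed))
        v = trait_value(G, t, n)
        b, s, p = _linear_summary(G, v)
        tables[t] = _table(t, "continuous", ids, chrom, pos, G.mean(0) / 2, b, s, p, n)

    # outcome cohort: liability collects every causal path plus the
    # outcome-specific genetic block
    G = _draw_genotypes(rng, n, maf, SimTruth(n_snp=m, maf=maf, seed=seed))
    e1 = trait_value(G, "E1", n)
    liability = d["theta_e1_y_direct"] * e1 + genetic(G, "Y")
    for t, th in d["theta_m_y"].items():
        if th:
            liability = liability + th * trait_value(G, t, n)
    liability = liability + rng.logistic(0, 1, n)
    thr = np.quantile(liability, 1 - d["prevalence"])
    y = (liability > thr).astype(float)
    b, s, p = _logistic_score_summary(G, y)
    tables["Y"] = _table("Y", "binary", ids, chrom, pos, G.mean(0) / 2, b, s, p, n)
    return tables


def make_fixture(name: str, out_dir) -> Path:
    """Write a deterministic fixture bundle under ``out_dir``.

    Known names: ``tables_worked_examples`` (the published protein/metabolite/
    UC estimates as TSVs), ``toy_screen`` (the 2×6×1 screening panel),
    ``outlier_demo`` (29 concordant + 1 displaced instrument set).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if name == "tables_worked_examples":
        from . import worked_examples as we

        we.REVERSE_UC_ON_PROTEINS.to_csv(out / "reverse_uc_on_proteins.tsv", sep="\t", index=False)
        we.METABOLITES_ON_UC.to_csv(out / "metabolites_on_uc.tsv", sep="\t", index=False)
        we.PROTEIN_ON_METABOLITE.to_csv(out / "protein_on_metabolite.tsv", sep="\t", index=False)
        we.METABOLITE_ON_UC_STAGE2.to_csv(out / "metabolite_on_uc_stage2.tsv", sep="\t", index=False)
        we.MEDIATION_PUBLISHED.to_csv(out / "mediation_published.tsv", sep="\t", index=False)
    elif name == "toy_screen":
        tables = simulate_toy_screen()
        (out / "exposures").mkdir(exist_ok=True)
        (out / "mediators").mkdir(exist_ok=True)
        for t, tab in tables.items():
            if t.startswith("E"):
                write_sumstats(tab, out / "exposures" / f"{t}.tsv")
            elif t.startswith("M"):
                write_sumstats(tab, out / "mediators" / f"{t}.tsv")
            else:
                write_sumstats(tab, out / "outcome.tsv")
        (out / "truth.json").write_text(json.dumps(TOY_SCREEN_DESIGN, indent=2, sort_keys=True))
    elif name == "outlier_demo":
        h, outlier_id = outlier_demo_set()
        h.rows.to_csv(out / "harmonized.tsv", sep="\t", index=False)
        (out / "truth.json").write_text(json.dumps({"outlier": outlier_id, "theta": 0.3}, indent=2))
    else:
        raise ValueError(f"unknown fixture {name!r}")
    return out
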