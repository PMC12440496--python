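"""Causal-effect estimators on harmonized exposure/outcome summary statistics.

Per-variant Wald ratios (beta_out/beta_exp, first-order SE se_out/|beta_exp|)
are combined by:

* inverse-variance weighting (IVW) — fixed effects, or additive random
  effects with tau² by REML when heterogeneity warrants (Cochran Q p < .05
  or I² > 25% under ``model="auto"``);
* MR-Egger weighted regression with intercept (directional-pleiotropy test);
* the weighted median (consistent while valid instruments carry >50% of
  weight), with a seeded parametric-bootstrap standard error;
* leave-one-out IVW refits for influence diagnostics.

Binary-outcome effects are log odds, so estimates exponentiate to odds
ratios with normal-theory confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import HarmonizedSet

DEFAULT_SEED = 20250912


class DegenerateInstrumentError(ValueError):
    pass


class InsufficientInstrumentsError(ValueError):
    pass


@dataclass
class MRFit:
    """One estimator's causal estimate with inference and heterogeneity."""

    method: str  # ivw_fixed | ivw_random | egger | weighted_median | wald_single
    n_snp: int
    beta: float
    se: float
    pval: float
    or_: float
    ci_low: float
    ci_high: float
    q: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    i2: float | None = None
    tau2: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None

    def as_row(self) -> dict:
        return {
            "method": self.method,
            "nsnp": self.n_snp,
            "beta": self.beta,
            "se": self.se,
            "pval": self.pval,
            "or": self.or_,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


def to_odds_ratio(beta: float, se: float, level: float = 0.95) -> tuple[float, float, float]:
    """OR = e^beta with a normal-theory CI at the given coverage."""
    if se <= 0:
        raise ValueError("se must be positive")
    z = stats.norm.ppf(0.5 + level / 2)
    return float(np.exp(beta)), float(np.exp(beta - z * se)), float(np.exp(beta + z * se))


def wald_ratios(h: HarmonizedSet) -> pd.DataFrame:
    """Per-variant ratio estimates: ratio, se_ratio (first-order), weight."""
    df = h.rows
    zero = df.loc[df["beta_exp"] == 0, "variant_id"].tolist()
    if zero:
        raise DegenerateInstrumentError(f"beta_exp = 0 for {zero}")
    ratio = df["beta_out"] / df["beta_exp"]
    se_ratio = df["se_out"] / df["beta_exp"].abs()
    return pd.DataFrame(
        {
            "variant_id": df["variant_id"].to_numpy(),
            "ratio": ratio.to_numpy(float),
            "se_ratio": se_ratio.to_numpy(float),
            "weight": 1.0 / se_ratio.to_numpy(float) ** 2,
        }
    )


def cochran_q(ratios: pd.DataFrame, center: float) -> tuple[float, int, float, float]:
    """Cochran's Q about ``center`` with df = k−1 and I² = max(0,(Q−df)/Q)·100."""
    k = len(ratios)
    if k < 2:
        raise ValueError("Cochran Q requires at least 2 instruments")
    w = ratios["weight"].to_numpy()
    q = float(np.sum(w * (ratios["ratio"].to_numpy() - center) ** 2))
    df = k - 1
    q_pval = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return q, df, q_pval, i2


def _tau2_dl(y: np.ndarray, v: np.ndarray) -> float:
    """DerSimonian–Laird moment estimate (initialization for REML)."""
    w = 1.0 / v
    mu = np.sum(w * y) / np.sum(w)
    q = np.sum(w * (y - mu) ** 2)
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    return max(0.0, (q - (len(y) - 1)) / c)


def tau2_reml(y: np.ndarray, v: np.ndarray, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Additive between-instrument variance by REML fixed-point iteration."""
    tau2 = _tau2_dl(y, v)
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        mu = np.sum(w * y) / np.sum(w)
        num = np.sum(w**2 * ((y - mu) ** 2 - v))
        new = num / np.sum(w**2) + 1.0 / np.sum(w)
        new = max(0.0, float(new))
        if abs(new - tau2) < tol:
            tau2 = new
            break
        tau2 = new
    return tau2


def _finish(method: str, k: int, beta: float, se: float, level: float = 0.95, **extra) -> MRFit:
    pval = float(2 * stats.norm.sf(abs(beta / se)))
    or_, lo, hi = to_odds_ratio(beta, se, level)
    return MRFit(method, k, float(beta), float(se), pval, or_, lo, hi, **extra)


def ivw(h: HarmonizedSet, model: str = "auto") -> MRFit:
    """Inverse-variance-weighted estimate.

    ``model``: ``fixed``, ``random``, or ``auto`` (random effects when the
    Cochran Q p-value < .05 or I² > 25%). A single instrument yields a
    ``wald_single`` fit with no heterogeneity statistics.
    """
    if model not in ("fixed", "random", "auto"):
        raise ValueError(f"unknown model {model!r}")
    r = wald_ratios(h)
    k = len(r)
    if k == 0:
        raise InsufficientInstrumentsError("no instruments")
    if k == 1:
        return _finish("wald_single", 1, r["ratio"].iloc[0], r["se_ratio"].iloc[0])

    w = r["weight"].to_numpy()
    y = r["ratio"].to_numpy()
    beta_f = np.sum(w * y) / np.sum(w)
    se_f = np.sqrt(1.0 / np.sum(w))
    q, df, q_pval, i2 = cochran_q(r, beta_f)

    use_random = model == "random" or (model == "auto" and (q_pval < 0.05 or i2 > 25.0))
    if not use_random:
        return _finish("ivw_fixed", k, beta_f, se_f, q=q, q_df=df, q_pval=q_pval, i2=i2)

    v = r["se_ratio"].to_numpy() ** 2
    tau2 = tau2_reml(y, v)
    wr = 1.0 / (v + tau2)
    beta_r = np.sum(wr * y) / np.sum(wr)
    se_r = np.sqrt(1.0 / np.sum(wr))
    return _finish("ivw_random", k, beta_r, se_r, q=q, q_df=df, q_pval=q_pval, i2=i2, tau2=tau2)


def egger(h: HarmonizedSet) -> MRFit:
    """MR-Egger: weighted regression of beta_out on beta_exp with intercept.

    Rows are oriented so beta_exp ≥ 0 (flipping both betas), weights are
    1/se_out²; the intercept and its test quantify directional pleiotropy.
    The covariance uses a multiplicative residual-variance inflation floored
    at 1 (never reporting less than the fixed-effect precision).
    """
    df = h.rows
    k = len(df)
    if k < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs >= 3 instruments, got {k}")
    sign = np.where(df["beta_exp"].to_numpy() < 0, -1.0, 1.0)
    x = df["beta_exp"].to_numpy() * sign
    y = df["beta_out"].to_numpy() * sign
    w = 1.0 / df["se_out"].to_numpy() ** 2

    # weighted normal equations for [intercept, slope]
    X = np.column_stack([np.ones(k), x])
    XtW = X.T * w
    A = XtW @ X
    coef = np.linalg.solve(A, XtW @ y)
    resid = y - X @ coef
    scale = float(np.sum(w * resid**2) / (k - 2)) if k > 2 else 1.0
    scale = max(1.0, scale)
    cov = scale * np.linalg.inv(A)

    inter, slope = float(coef[0]), float(coef[1])
    se_inter, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    p_inter = float(2 * stats.norm.sf(abs(inter / se_inter)))
    fit = _finish("egger", k, slope, se_slope)
    fit.egger_intercept = inter
    fit.egger_intercept_se = se_inter
    fit.egger_intercept_pval = p_inter
    return fit


def _weighted_median_point(ratio: np.ndarray, weight: np.ndarray) -> float:
    order = np.argsort(ratio, kind="mergesort")
    r = ratio[order]
    w = weight[order]
    s = (np.cumsum(w) - w / 2) / np.sum(w)
    return float(np.interp(0.5, s, r))


def weighted_median(
    h: HarmonizedSet, n_boot: int = 5000, seed: int = DEFAULT_SEED
) -> MRFit:
    """Weighted-median estimate with parametric-bootstrap SE.

    The point estimate interpolates the inverse-variance-weighted empirical
    CDF of Wald ratios at 0.5; the SE is the SD of the estimate over
    ``n_boot`` replicates resampling each ratio from N(ratio_j, se_ratio_j).
    """
    r = wald_ratios(h)
    k = len(r)
    if k < 3:
        raise InsufficientInstrumentsError(f"weighted median needs >= 3 instruments, got {k}")
    ratio = r["ratio"].to_numpy()
    weight = r["weight"].to_numpy()
    est = _weighted_median_point(ratio, weight)

    rng = np.random.default_rng(seed)
    draws = rng.normal(ratio, r["se_ratio"].to_numpy(), size=(n_boot, k))
    boot = np.empty(n_boot)
    for b in range(n_boot):
        boot[b] = _weighted_median_point(draws[b], weight)
    se = float(np.std(boot, ddof=1))
    if se == 0:  # all ratios identical and noise-free
        se = np.finfo(float).tiny
    return _finish("weighted_median", k, est, se)


def leave_one_out(h: HarmonizedSet, model: str = "auto") -> list[tuple[str, MRFit]]:
    """IVW refits each omitting one variant; model choice re-evaluated per fit."""
    k = len(h.rows)
    if k < 2:
        raise ValueError("leave-one-out requires at least 2 instruments")
    out: list[tuple[str, MRFit]] = []
    for vid in h.rows["variant_id"]:
        out.append((vid, ivw(h.drop([vid]), model=model)))
    return out


def fits_table(fits: list[MRFit], exposure_id: str, outcome_id: str) -> pd.DataFrame:
    """Estimate table in the conventional report layout:
    exposure, outcome, method, nsnp, beta, se, pval, OR (95% CI)."""
    rows = []
    for f in fits:
        rows.append(
            {
                "exposure": exposure_id,
                "outcome": outcome_id,
                "method": f.method,
                "nsnp": f.n_snp,
                "beta": f.beta,
                "se": f.se,
                "pval": f.pval,
                "or_95ci": f"{f.or_:.3f} ({f.ci_low:.3f}-{f.ci_high:.3f})",
            }
        )
    return pd.DataFrame(rows)
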