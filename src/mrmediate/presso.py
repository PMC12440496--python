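"""MR-PRESSO: pleiotropy residual sum and outlier test.

The global test compares the observed leave-one-out residual sum of squares
against its parametric-bootstrap null distribution; the outlier test does the
same per variant (Bonferroni-adjusted over the k variants); the distortion
test asks whether removing the flagged outliers shifts the causal estimate
more than removing random subsets of the same size. All Monte-Carlo p-values
carry the add-one correction, so they live in [1/(n_sim+1), 1] and are never
exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mr import InsufficientInstrumentsError, MRFit, ivw, wald_ratios
from .sumstats import HarmonizedSet

DEFAULT_SEED = 20250912


class DegenerateCorrectionError(ValueError):
    """Every instrument was flagged as an outlier; no corrected fit exists."""


@dataclass
class PressoResult:
    rss_obs: float
    global_pval: float
    n_sim: int
    outlier_pvals: dict[str, float] = field(repr=False)
    outliers: set[str] = field(default_factory=set)
    distortion_pval: float | None = None
    beta_raw: MRFit | None = None
    beta_corrected: MRFit | None = None
    seed: int = DEFAULT_SEED


def _loo_slopes(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """IVW (origin-through WLS) slope excluding each variant in turn.

    Works on 1-D observed data or a (n_sim, k) batch of simulated draws.
    """
    a = x * y * w
    b = x * x * w
    A = a.sum(axis=-1, keepdims=True)
    B = b.sum(axis=-1, keepdims=True)
    return (A - a) / (B - b)


def presso(
    h: HarmonizedSet,
    n_sim: int = 10_000,
    outlier_alpha: float = 0.05,
    seed: int = DEFAULT_SEED,
    ivw_model: str = "auto",
) -> PressoResult:
    """Run the global, outlier and distortion tests and the corrected fit.

    Requires k ≥ 4 instruments so every leave-one-out slope is estimable
    from at least 3 variants. Deterministic given (data, n_sim, seed).
    """
    df = h.rows
    k = len(df)
    if k < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO needs >= 4 instruments, got {k}")
    wald_ratios(h)  # validates beta_exp != 0

    ids = df["variant_id"].to_numpy()
    x = df["beta_exp"].to_numpy(float)
    y = df["beta_out"].to_numpy(float)
    sx = df["se_exp"].to_numpy(float)
    sy = df["se_out"].to_numpy(float)
    w = 1.0 / sy**2

    slopes = _loo_slopes(x, y, w)  # (k,)
    resid_obs = w * (y - slopes * x) ** 2
    rss_obs = float(resid_obs.sum())

    rng = np.random.default_rng(seed)
    xs = rng.normal(x, sx, size=(n_sim, k))
    ys = rng.normal(slopes * x, sy, size=(n_sim, k))
    slopes_sim = _loo_slopes(xs, ys, w)
    resid_sim = w * (ys - slopes_sim * xs) ** 2  # (n_sim, k)
    rss_sim = resid_sim.sum(axis=1)

    global_pval = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    raw_p = (1 + np.sum(resid_sim >= resid_obs, axis=0)) / (n_sim + 1)
    adj_p = np.minimum(1.0, raw_p * k)
    outlier_pvals = {vid: float(p) for vid, p in zip(ids, adj_p)}
    outliers = {vid for vid, p in outlier_pvals.items() if p < outlier_alpha}
    if len(outliers) == k:
        raise DegenerateCorrectionError("all instruments flagged as outliers")

    beta_raw = ivw(h, model=ivw_model)
    if outliers:
        beta_corrected = ivw(h.drop(outliers), model=ivw_model)
    else:
        beta_corrected = beta_raw

    distortion_pval = None
    if outliers:
        # contrast on the fixed-effect slope scale for all subsets alike
        m = len(outliers)
        slope_all = np.sum(x * y * w) / np.sum(x * x * w)
        keep_mask = ~np.isin(ids, list(outliers))
        slope_corr = np.sum(x[keep_mask] * y[keep_mask] * w[keep_mask]) / np.sum(
            x[keep_mask] ** 2 * w[keep_mask]
        )
        d_obs = abs(slope_all - slope_corr)
        d_sim = np.empty(n_sim)
        idx = np.arange(k)
        for b in range(n_sim):
            drop = rng.choice(idx, size=m, replace=False)
            mask = np.ones(k, bool)
            mask[drop] = False
            beta_sub = np.sum(x[mask] * y[mask] * w[mask]) / np.sum(x[mask] ** 2 * w[mask])
            d_sim[b] = abs(slope_all - beta_sub)
        distortion_pval = float((1 + np.sum(d_sim >= d_obs)) / (n_sim + 1))

    return PressoResult(
        rss_obs=rss_obs,
        global_pval=global_pval,
        n_sim=n_sim,
        outlier_pvals=outlier_pvals,
        outliers=outliers,
        distortion_pval=distortion_pval,
        beta_raw=beta_raw,
        beta_corrected=beta_corrected,
        seed=seed,
    )
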