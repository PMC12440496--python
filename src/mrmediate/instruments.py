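"""Instrument selection: p-value thresholding, greedy LD clumping,
instrument strength (R², F), weak-instrument and Steiger directionality
filters, and confounder exclusion lists.

The F statistic uses F = R²(N−2)/(1−R²) with R² = t²/(t²+N−2) derived from
the observed per-variant t statistic, so it needs only beta, se and N.
The Steiger filter compares the variance a variant explains in the exposure
against the outcome via a z-test on Fisher-transformed correlations
(variances 1/(N−3)); a variant is excluded only when the reverse direction
is both present and significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import HarmonizedSet, SumStatTable

logger = logging.getLogger(__name__)


class LDMatrixError(ValueError):
    pass


@dataclass
class LDMatrix:
    """Pairwise LD r² with per-variant positions for distance windowing."""

    variant_ids: list[str]
    r2: np.ndarray = field(repr=False)
    positions: pd.DataFrame = field(repr=False)  # index variant_id, cols chrom, pos

    def __post_init__(self) -> None:
        r2 = np.asarray(self.r2, dtype=float)
        k = len(self.variant_ids)
        if r2.shape != (k, k):
            raise LDMatrixError(f"r2 shape {r2.shape} does not match {k} ids")
        if not np.allclose(r2, r2.T, atol=1e-12):
            raise LDMatrixError("LD matrix is not symmetric")
        if not np.allclose(np.diag(r2), 1.0, atol=1e-9):
            raise LDMatrixError("LD matrix diagonal is not 1")
        if (r2 < -1e-12).any() or (r2 > 1 + 1e-9).any():
            raise LDMatrixError("LD r2 values outside [0, 1]")
        self.r2 = np.clip(r2, 0.0, 1.0)
        self._idx = {v: i for i, v in enumerate(self.variant_ids)}

    def lookup(self, a: str, b: str) -> float:
        return float(self.r2[self._idx[a], self._idx[b]])

    def __contains__(self, vid: str) -> bool:
        return vid in self._idx

    @classmethod
    def from_square_tsv(cls, path, positions: pd.DataFrame) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float), positions)

    @classmethod
    def from_long_tsv(cls, path, positions: pd.DataFrame) -> "LDMatrix":
        """Long-format triplets (id1, id2, r2); unlisted pairs default to 0."""
        tri = pd.read_csv(path, sep="\t")
        ids = sorted(set(tri.iloc[:, 0].astype(str)) | set(tri.iloc[:, 1].astype(str)))
        idx = {v: i for i, v in enumerate(ids)}
        r2 = np.eye(len(ids))
        for a, b, v in tri.itertuples(index=False):
            i, j = idx[str(a)], idx[str(b)]
            r2[i, j] = r2[j, i] = float(v)
        return cls(ids, r2, positions)


def select_by_pvalue(table: SumStatTable, threshold: float = 1e-5) -> SumStatTable:
    """Keep records with p strictly below the instrument threshold."""
    return table.subset((table.records["pval"] < threshold).to_numpy())


def clump(
    table: SumStatTable,
    ld: LDMatrix,
    r2_max: float = 0.001,
    window_kb: int = 1000,
    missing: str = "drop",
) -> SumStatTable:
    """Greedy LD clumping.

    Repeatedly takes the lowest-p unclaimed variant as an index and removes
    unclaimed variants on the same chromosome within ±``window_kb`` kb having
    r² ≥ ``r2_max`` with it. Ties in p break by (chrom, pos, variant_id).
    Variants absent from the LD matrix are dropped with a warning
    (``missing="drop"``) or raise (``missing="error"``).
    """
    df = table.records
    present = df["variant_id"].isin(ld.variant_ids)
    if not present.all():
        absent = df.loc[~present, "variant_id"].tolist()
        if missing == "error":
            raise LDMatrixError(f"variants missing from LD matrix: {absent}")
        logger.warning("clump: dropping %d variants missing from LD matrix", len(absent))
        df = df[present]

    cand = df.assign(
        _chrom=df["chrom"].astype(str),
        _pos=df["pos"].astype(float),
    ).sort_values(["pval", "_chrom", "_pos", "variant_id"], kind="mergesort")

    window_bp = window_kb * 1000
    unclaimed = list(cand["variant_id"])
    info = cand.set_index("variant_id")
    keep: list[str] = []
    claimed: set[str] = set()
    for vid in unclaimed:
        if vid in claimed:
            continue
        keep.append(vid)
        claimed.add(vid)
        chrom, pos = info.at[vid, "_chrom"], info.at[vid, "_pos"]
        for other in unclaimed:
            if other in claimed:
                continue
            if info.at[other, "_chrom"] != chrom:
                continue
            if abs(info.at[other, "_pos"] - pos) > window_bp:
                continue
            if ld.lookup(vid, other) >= r2_max:
                claimed.add(other)
    return table.subset(keep)


def variance_explained(beta: float, se: float, n: int) -> float:
    """Proportion of trait variance explained by one variant,
    r² = t²/(t² + n − 2) with t = beta/se."""
    if n <= 2:
        raise ValueError(f"n must exceed 2, got {n}")
    if se <= 0:
        raise ValueError("se must be positive")
    t2 = (beta / se) ** 2
    return t2 / (t2 + n - 2)


def f_statistic(r2: float, n: int) -> float:
    """Instrument-strength F = R²(N−2)/(1−R²)."""
    if not 0 <= r2 < 1:
        raise ValueError(f"r2 must be in [0, 1), got {r2}")
    if n <= 2:
        raise ValueError(f"n must exceed 2, got {n}")
    return r2 * (n - 2) / (1 - r2)


def annotate_strength(table: SumStatTable) -> pd.DataFrame:
    """Records plus r2_explained and f_stat columns (per-variant strength)."""
    df = table.records.copy()
    r2 = [variance_explained(b, s, n) for b, s, n in zip(df["beta"], df["se"], df["n"])]
    df["r2_explained"] = r2
    df["f_stat"] = [f_statistic(r, n) for r, n in zip(r2, df["n"])]
    return df


def filter_weak(instruments: pd.DataFrame, f_min: float = 10.0) -> pd.DataFrame:
    """Keep instruments with f_stat ≥ f_min; log what was removed."""
    weak = instruments[instruments["f_stat"] < f_min]
    if len(weak):
        logger.warning(
            "filter_weak: removing %d weak instruments (F < %g): %s",
            len(weak), f_min, list(weak["variant_id"]),
        )
    kept = instruments[instruments["f_stat"] >= f_min].reset_index(drop=True)
    if not len(kept):
        logger.warning("filter_weak: no instruments survive F >= %g", f_min)
    return kept


@dataclass
class SteigerResult:
    variant_id: str
    r2_exposure: float
    r2_outcome: float
    z: float
    p: float
    direction_ok: bool


def steiger_filter(
    h: HarmonizedSet, alpha: float = 0.05
) -> tuple[HarmonizedSet, list[SteigerResult]]:
    """Directionality filter: exclude variants explaining significantly more
    outcome than exposure variance (reverse-causation signature).

    Per variant, r² on each side comes from the t statistic; the difference
    of correlations is tested via Fisher's z with variances 1/(N−3). A row
    is excluded only when r²_outcome > r²_exposure AND p < alpha.
    Rows with N ≤ 3 on either side are dropped with a diagnostic.
    """
    results: list[SteigerResult] = []
    keep_ids: list[str] = []
    for row in h.rows.itertuples(index=False):
        if row.n_exp <= 3 or row.n_out <= 3:
            logger.warning("steiger: dropping %s (n too small for Fisher z)", row.variant_id)
            continue
        r2e = variance_explained(row.beta_exp, row.se_exp, row.n_exp)
        r2o = variance_explained(row.beta_out, row.se_out, row.n_out)
        ze = np.arctanh(np.sqrt(r2e))
        zo = np.arctanh(np.sqrt(r2o))
        sd = np.sqrt(1.0 / (row.n_exp - 3) + 1.0 / (row.n_out - 3))
        z = (ze - zo) / sd
        p = 2 * stats.norm.sf(abs(z))
        ok = r2e > r2o
        results.append(SteigerResult(row.variant_id, r2e, r2o, float(z), float(p), bool(ok)))
        if r2o > r2e and p < alpha:
            continue
        keep_ids.append(row.variant_id)
    return h.subset(keep_ids), results


def apply_exclusion_list(table: SumStatTable, excluded_ids) -> SumStatTable:
    """Remove listed variant ids (e.g. known-confounder associations),
    preserving order."""
    omit = set(excluded_ids)
    return table.subset((~table.records["variant_id"].isin(omit)).to_numpy())
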