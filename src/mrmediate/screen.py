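"""Screening cascade orchestration.

Per exposure/outcome pair the pipeline runs: instrument selection at the IV
p-threshold → LD clumping → confounder exclusion list → allele
harmonization → Steiger directionality filter → weak-instrument filter →
the estimator suite (IVW with heterogeneity-driven model choice, MR-Egger,
weighted median, MR-PRESSO, leave-one-out). A pair passes the screen when
the IVW p-value clears the screening alpha, the three estimators (IVW,
weighted median, PRESSO-corrected) agree in sign, and leave-one-out refits
are sign-stable. Bonferroni adjustment over the panel is reported as a flag,
not a gate. The full pipeline (forward screen → reverse screen → mediator
screen → exposure→mediator fits → mediation) writes per-stage TSV reports
and a JSON manifest with gate counts, and is byte-reproducible for a fixed
seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import instruments as ins
from . import mr
from .mediation import MediationResult, mediate, proportion_summary
from .mr import MRFit
from .presso import PressoResult, presso
from .sumstats import EmptyOverlapError, HarmonizedSet, SumStatTable, harmonize, read_sumstats

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class IncompleteEvidenceError(ValueError):
    """A concordance check was asked for with one of its three fits missing."""


@dataclass
class ScreenConfig:
    """All thresholds and paths of one pipeline run; seed is mandatory."""

    seed: int
    outcome_path: str | None = None
    exposure_paths: list[str] = field(default_factory=list)
    mediator_paths: list[str] = field(default_factory=list)
    ld_path: str | None = None
    exclusion_path: str | None = None
    iv_pval: float = 1e-5
    clump_r2: float = 0.001
    clump_kb: int = 1000
    palindrome_maf_window: tuple[float, float] = (0.40, 0.60)
    f_min: float = 10.0
    steiger_alpha: float = 0.05
    screen_alpha: float = 0.05
    bonferroni_m: int | None = None      # defaults to the panel size
    presso_nsim: int = 10_000
    boot: int = 5000
    strict_loo: bool = False
    outcome_trait_type: str = "binary"
    out_dir: str = "results/screen"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        for nm, v, lo, hi in [
            ("iv_pval", self.iv_pval, 0, 1),
            ("clump_r2", self.clump_r2, 0, 1),
            ("steiger_alpha", self.steiger_alpha, 0, 1),
            ("screen_alpha", self.screen_alpha, 0, 1),
        ]:
            if not lo < v <= hi:
                raise ConfigError(f"{nm} out of range: {v}")

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "palindrome_maf_window" in raw:
            raw["palindrome_maf_window"] = tuple(raw["palindrome_maf_window"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["palindrome_maf_window"] = list(d["palindrome_maf_window"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


@dataclass
class ScreenRecord:
    """One exposure/outcome pair's evidence and gate decisions."""

    exposure_id: str
    outcome_id: str
    status: str                      # ok | no_instruments | insufficient_instruments
    n_instruments: int = 0
    fits: dict[str, MRFit] = field(default_factory=dict)
    presso_result: PressoResult | None = None
    loo: list[tuple[str, MRFit]] = field(default_factory=list)
    concordant: bool | None = None
    loo_stable: bool | None = None
    passes: bool = False
    p_adj: float | None = None
    bonferroni_significant: bool | None = None

    @property
    def primary_fit(self) -> MRFit | None:
        """IVW, replaced by the PRESSO-corrected fit when outliers were
        flagged ("corrected analyses")."""
        if self.presso_result is not None and self.presso_result.outliers:
            return self.presso_result.beta_corrected
        return self.fits.get("ivw")


def triple_concordance(
    fits: dict[str, MRFit],
    loo: list[tuple[str, MRFit]],
    screen_alpha: float = 0.05,
    strict_loo: bool = False,
) -> tuple[bool, bool]:
    """Direction agreement of IVW / weighted median / PRESSO-corrected fits,
    and leave-one-out stability.

    Lenient (default) leave-one-out stability requires each refit to keep the
    full fit's sign; strict mode additionally requires every refit to stay
    below ``screen_alpha`` whenever the full fit does.
    """
    needed = ("ivw", "weighted_median", "presso_corrected")
    missing = [k for k in needed if k not in fits or fits[k] is None]
    if missing:
        raise IncompleteEvidenceError(f"missing fits for concordance: {missing}")
    signs = {np.sign(fits[k].beta) for k in needed}
    concordant = len(signs) == 1 and 0.0 not in signs

    full = fits["ivw"]
    sign_ok = all(np.sign(f.beta) == np.sign(full.beta) for _, f in loo)
    if strict_loo and full.pval < screen_alpha:
        sign_ok = sign_ok and all(f.pval < screen_alpha for _, f in loo)
    return bool(concordant), bool(sign_ok)


def bonferroni(pvals, m: int) -> np.ndarray:
    """p_adj = min(1, p·m)."""
    pvals = np.asarray(pvals, float)
    if m < len(pvals):
        raise ValueError(f"m = {m} smaller than the number of tests {len(pvals)}")
    return np.minimum(1.0, pvals * m)


def _pair_seed(seed: int, exposure_id: str, outcome_id: str) -> int:
    """Deterministic, order-independent per-pair seed below 2^31."""
    h = zlib.crc32(f"{exposure_id}::{outcome_id}".encode())
    return (seed ^ h) & 0x7FFFFFFF


def analyze_pair(
    exposure: SumStatTable,
    outcome: SumStatTable,
    cfg: ScreenConfig,
    ld: ins.LDMatrix | None = None,
    excluded_ids=None,
) -> ScreenRecord:
    """Full per-pair analysis; never raises for thin instrument sets —
    the record's status says what could not be computed."""
    rec = ScreenRecord(exposure.trait_id, outcome.trait_id, status="ok")
    sel = ins.select_by_pvalue(exposure, cfg.iv_pval)
    if ld is not None and len(sel):
        sel = ins.clump(sel, ld, cfg.clump_r2, cfg.clump_kb)
    if excluded_ids:
        sel = ins.apply_exclusion_list(sel, excluded_ids)
    if len(sel) == 0:
        rec.status = "no_instruments"
        return rec
    try:
        h = harmonize(sel, outcome, cfg.palindrome_maf_window)
    except EmptyOverlapError:
        rec.status = "no_instruments"
        return rec
    h, steiger_results = ins.steiger_filter(h, cfg.steiger_alpha)

    # weak-instrument filter on the harmonized exposure side
    if len(h):
        f = np.array(
            [
                ins.f_statistic(ins.variance_explained(b, s, n), n)
                for b, s, n in zip(h.rows["beta_exp"], h.rows["se_exp"], h.rows["n_exp"])
            ]
        )
        weak = h.rows.loc[f < cfg.f_min, "variant_id"]
        if len(weak):
            logger.info("%s: removing %d weak instruments", exposure.trait_id, len(weak))
            h = h.drop(weak)

    rec.n_instruments = len(h)
    if len(h) == 0:
        rec.status = "no_instruments"
        return rec

    seed = _pair_seed(cfg.seed, exposure.trait_id, outcome.trait_id)
    rec.fits["ivw"] = mr.ivw(h, model="auto")
    if len(h) >= 2:
        rec.loo = mr.leave_one_out(h)
    if len(h) >= 3:
        rec.fits["egger"] = mr.egger(h)
        rec.fits["weighted_median"] = mr.weighted_median(h, n_boot=cfg.boot, seed=seed)
    if len(h) >= 4:
        rec.presso_result = presso(h, n_sim=cfg.presso_nsim, seed=seed)
        rec.fits["presso_corrected"] = rec.presso_result.beta_corrected

    if {"weighted_median", "presso_corrected"} <= rec.fits.keys():
        rec.concordant, rec.loo_stable = triple_concordance(
            rec.fits, rec.loo, cfg.screen_alpha, cfg.strict_loo
        )
        rec.passes = bool(
            rec.concordant and rec.loo_stable and rec.fits["ivw"].pval < cfg.screen_alpha
        )
    else:
        rec.status = "insufficient_instruments"
    return rec


def _screen(tables, outcome, cfg, ld=None, excluded_ids=None) -> list[ScreenRecord]:
    ids = [t.trait_id for t in tables]
    if len(set(ids)) != len(ids):
        raise ConfigError(f"duplicate trait ids in panel: {ids}")
    records = [analyze_pair(t, outcome, cfg, ld, excluded_ids) for t in tables]
    m = cfg.bonferroni_m if cfg.bonferroni_m is not None else max(1, len(records))
    scored = [r for r in records if r.fits.get("ivw") is not None]
    if scored:
        adj = bonferroni([r.fits["ivw"].pval for r in scored], max(m, len(scored)))
        for r, a in zip(scored, adj):
            r.p_adj = float(a)
            r.bonferroni_significant = bool(a < cfg.screen_alpha)
    return records


def forward_screen(exposures, outcome, cfg, ld=None, excluded_ids=None) -> list[ScreenRecord]:
    """Exposure panel → outcome."""
    return _screen(exposures, outcome, cfg, ld, excluded_ids)


def reverse_screen(outcome_as_exposure, targets, cfg, ld=None, excluded_ids=None) -> list[ScreenRecord]:
    """Outcome as the exposure, against each original exposure in turn
    (reverse-causation check); instruments come from the outcome GWAS."""
    out = []
    for t in targets:
        out.append(analyze_pair(outcome_as_exposure, t, cfg, ld, excluded_ids))
    return out


def mediator_screen(mediators, outcome, cfg, ld=None, excluded_ids=None) -> list[ScreenRecord]:
    """Mediator panel → outcome, same gates as the forward screen."""
    return _screen(mediators, outcome, cfg, ld, excluded_ids)


def _screen_table(records: list[ScreenRecord], outcome_id: str | None = None) -> pd.DataFrame:
    rows = []
    for r in records:
        base = {
            "exposure": r.exposure_id,
            "outcome": r.outcome_id,
            "status": r.status,
            "nsnp": r.n_instruments,
            "concordant": r.concordant,
            "loo_stable": r.loo_stable,
            "passes": r.passes,
            "p_adj": r.p_adj,
            "bonferroni_significant": r.bonferroni_significant,
        }
        if not r.fits:
            rows.append(base)
        for name, f in r.fits.items():
            rows.append({**base, **{f"fit_{k}": v for k, v in f.as_row().items()}})
    return pd.DataFrame(rows)


def _ratio_table(records: list[ScreenRecord]) -> pd.DataFrame:
    """Variant-level Wald-ratio export for external forest/scatter plotting."""
    frames = []
    for r in records:
        for vid, f in r.loo:
            frames.append(
                {
                    "exposure": r.exposure_id,
                    "outcome": r.outcome_id,
                    "dropped_variant": vid,
                    "beta": f.beta,
                    "se": f.se,
                    "pval": f.pval,
                }
            )
    return pd.DataFrame(frames, columns=["exposure", "outcome", "dropped_variant", "beta", "se", "pval"])


def _counts(records: list[ScreenRecord]) -> dict:
    return {
        "candidates": len(records),
        "passed": sum(r.passes for r in records),
        "failed": sum((not r.passes) and r.status == "ok" for r in records),
        "no_instruments": sum(r.status == "no_instruments" for r in records),
        "insufficient_instruments": sum(r.status == "insufficient_instruments" for r in records),
    }


def run_pipeline(cfg: ScreenConfig) -> dict:
    """Forward → reverse → mediator screens → exposure→mediator MR for
    passing pairs → mediation. Writes per-stage TSVs and a JSON manifest
    under ``cfg.out_dir``; returns the manifest."""
    if cfg.outcome_path is None:
        raise ConfigError("outcome_path is required")
    if not cfg.exposure_paths:
        raise ConfigError("at least one exposure path is required")
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    outcome = read_sumstats(cfg.outcome_path, trait_type=cfg.outcome_trait_type,
                            trait_id=Path(cfg.outcome_path).stem)
    exposures = [read_sumstats(p, trait_id=Path(p).stem) for p in cfg.exposure_paths]
    mediators = [read_sumstats(p, trait_id=Path(p).stem) for p in cfg.mediator_paths]
    excluded = None
    if cfg.exclusion_path:
        excluded = [line.strip() for line in Path(cfg.exclusion_path).read_text().splitlines() if line.strip()]
    ld = None
    if cfg.ld_path:
        pos = pd.concat([t.records.set_index("variant_id")[["chrom", "pos"]] for t in exposures])
        pos = pos[~pos.index.duplicated()]
        ld = ins.LDMatrix.from_square_tsv(cfg.ld_path, pos)

    fwd = forward_screen(exposures, outcome, cfg, ld, excluded)
    fwd_pass = [r for r in fwd if r.passes]

    rev = reverse_screen(outcome, [e for e in exposures if any(r.exposure_id == e.trait_id for r in fwd_pass)], cfg)
    med = mediator_screen(mediators, outcome, cfg, ld, excluded) if mediators else []
    med_pass = [r for r in med if r.passes]

    exp_by_id = {t.trait_id: t for t in exposures}
    med_by_id = {t.trait_id: t for t in mediators}
    xm_records: list[ScreenRecord] = []
    mediations: list[MediationResult] = []
    for fr in fwd_pass:
        for mrec in med_pass:
            xm = analyze_pair(exp_by_id[fr.exposure_id], med_by_id[mrec.exposure_id], cfg, ld, excluded)
            xm_records.append(xm)
            fit_xm = xm.primary_fit
            if xm.status != "ok" or fit_xm is None or fit_xm.pval >= cfg.screen_alpha:
                continue
            mediations.append(
                mediate(
                    fit_xm,
                    mrec.primary_fit,
                    fr.primary_fit,
                    exposure_id=fr.exposure_id,
                    mediator_id=mrec.exposure_id,
                    outcome_id=outcome.trait_id,
                )
            )

    _screen_table(fwd).to_csv(out_dir / "forward_screen.tsv", sep="\t", index=False)
    _screen_table(rev).to_csv(out_dir / "reverse_screen.tsv", sep="\t", index=False)
    _screen_table(med).to_csv(out_dir / "mediator_screen.tsv", sep="\t", index=False)
    _screen_table(xm_records).to_csv(out_dir / "exposure_mediator_fits.tsv", sep="\t", index=False)
    proportion_summary(mediations).to_csv(out_dir / "mediation.tsv", sep="\t", index=False)
    _ratio_table(fwd + med).to_csv(out_dir / "leave_one_out.tsv", sep="\t", index=False)

    manifest = {
        "seed": cfg.seed,
        "thresholds": {
            "iv_pval": cfg.iv_pval,
            "clump_r2": cfg.clump_r2,
            "clump_kb": cfg.clump_kb,
            "f_min": cfg.f_min,
            "steiger_alpha": cfg.steiger_alpha,
            "screen_alpha": cfg.screen_alpha,
            "presso_nsim": cfg.presso_nsim,
            "boot": cfg.boot,
        },
        "gates": {
            "forward": _counts(fwd),
            "reverse": _counts(rev),
            "mediator": _counts(med),
            "exposure_mediator_pairs": len(xm_records),
            "exposure_mediator_passed": sum(
                1 for x in xm_records
                if x.status == "ok" and x.primary_fit is not None and x.primary_fit.pval < cfg.screen_alpha
            ),
            "mediations": len(mediations),
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
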