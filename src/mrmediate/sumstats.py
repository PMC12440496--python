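"""GWAS summary-statistic tables and exposure/outcome harmonization.

Summary statistics are carried as pandas DataFrames wrapped in a thin
:class:`SumStatTable` container with canonical GWAS-SSF-like columns::

    variant_id  chrom  pos  effect_allele  other_allele  eaf  beta  se  pval  n

``beta`` is the per-effect-allele effect: log-odds units for binary traits,
SD units for continuous traits. Harmonization puts an exposure/outcome pair
of tables onto one shared effect-allele frame, resolving swapped allele
coding, strand complements, and palindromic (A/T, C/G) ambiguity by allele
frequency, with intermediate-frequency palindromes dropped as unresolvable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CANONICAL_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

#: columns that must be present and non-missing in every record
MANDATORY_COLUMNS = ["variant_id", "effect_allele", "other_allele", "beta", "se", "pval", "n"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: harmonization audit actions
KEPT = "kept"
FLIPPED = "flipped"
PALINDROME_ALIGNED = "palindrome_aligned"
DROPPED_PALINDROME_MAF = "dropped_palindrome_maf"
DROPPED_INCOMPATIBLE = "dropped_incompatible"
DROPPED_MISSING = "dropped_missing"

DROPPED_ACTIONS = frozenset(
    {DROPPED_PALINDROME_MAF, DROPPED_INCOMPATIBLE, DROPPED_MISSING}
)


class SumStatFormatError(ValueError):
    """A file is missing mandatory columns or is otherwise unparseable."""


class SumStatValidationError(ValueError):
    """One or more rows violate record invariants; offending rows are listed."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__(
            "summary-statistics validation failed:\n  " + "\n  ".join(problems)
        )


class EmptyOverlapError(ValueError):
    """Exposure and outcome share zero variant ids (wrong build/ID scheme?)."""


@dataclass
class SumStatTable:
    """One trait's GWAS summary statistics.

    Parameters
    ----------
    trait_id
        Identifier of the trait (e.g. a protein, metabolite or disease name).
    trait_type
        ``"binary"`` (beta on the log-odds scale) or ``"continuous"``.
    records
        DataFrame with the canonical columns; ``chrom``/``pos``/``eaf`` may
        be missing (NaN).
    """

    trait_id: str
    trait_type: str
    records: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "continuous"):
            raise ValueError(f"trait_type must be binary|continuous, got {self.trait_type!r}")
        df = self.records
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise SumStatFormatError(f"missing columns: {missing}")
        self.records = df[CANONICAL_COLUMNS].reset_index(drop=True)
        problems = _validate_records(self.records)
        if problems:
            raise SumStatValidationError(problems)

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, mask_or_ids) -> "SumStatTable":
        """New table keeping rows by boolean mask or iterable of variant ids."""
        df = self.records
        if isinstance(mask_or_ids, (pd.Series, np.ndarray, list)) and len(mask_or_ids) == len(df) and (
            getattr(mask_or_ids, "dtype", None) == bool
            or (len(mask_or_ids) > 0 and isinstance(mask_or_ids[0], (bool, np.bool_)))
        ):
            out = df[np.asarray(mask_or_ids, dtype=bool)]
        else:
            keep = set(mask_or_ids)
            out = df[df["variant_id"].isin(keep)]
        return SumStatTable(self.trait_id, self.trait_type, out.reset_index(drop=True))


def _validate_records(df: pd.DataFrame) -> list[str]:
    problems: list[str] = []
    for col in MANDATORY_COLUMNS:
        bad = df.index[df[col].isna()]
        for i in bad:
            problems.append(f"row {i}: missing {col}")
    if problems:
        return problems

    for i, rec in df.iterrows():
        ea, oa = str(rec["effect_allele"]).upper(), str(rec["other_allele"]).upper()
        if not ea or not oa or any(b not in _COMPLEMENT for b in ea + oa):
            problems.append(f"row {i}: alleles must be over A/C/G/T, got {ea}/{oa}")
        elif ea == oa:
            problems.append(f"row {i}: effect_allele equals other_allele ({ea})")
        if rec["se"] <= 0:
            problems.append(f"row {i}: se must be > 0, got {rec['se']}")
        if not (0 < rec["pval"] <= 1):
            problems.append(f"row {i}: pval must be in (0, 1], got {rec['pval']}")
        if not pd.isna(rec["eaf"]) and not (0 <= rec["eaf"] <= 1):
            problems.append(f"row {i}: eaf must be in [0, 1], got {rec['eaf']}")
        if rec["n"] <= 0 or rec["n"] != int(rec["n"]):
            problems.append(f"row {i}: n must be a positive integer, got {rec['n']}")

    dup = df["variant_id"][df["variant_id"].duplicated()]
    for i, v in dup.items():
        problems.append(f"row {i}: duplicate variant_id {v}")
    return problems


def read_sumstats(path, column_map: dict[str, str] | None = None, trait_type: str = "continuous",
                  trait_id: str | None = None) -> SumStatTable:
    """Read a tab-separated summary-statistics file.

    ``column_map`` maps file headers to canonical field names, e.g.
    ``{"BETA": "beta", "SE": "se"}``; headers already canonical need no entry.
    """
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "chrom": str})
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SumStatFormatError(f"{path}: missing mandatory columns {missing}")
    for c in CANONICAL_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    df["chrom"] = df["chrom"].astype("string")
    if trait_id is None:
        trait_id = str(path)
    return SumStatTable(trait_id, trait_type, df[CANONICAL_COLUMNS])


def write_sumstats(table: SumStatTable, path) -> None:
    """Write a table as TSV; floats use shortest round-trip decimals so that
    ``read_sumstats(write_sumstats(t))`` reproduces ``t`` field-for-field."""
    table.records.to_csv(path, sep="\t", index=False, na_rep="NA")


def is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def _maf(eaf: float) -> float:
    return min(eaf, 1.0 - eaf)


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs on one shared effect-allele frame.

    ``rows`` columns: variant_id, chrom, pos, effect_allele, other_allele,
    beta_exp, se_exp, eaf_exp, n_exp, beta_out, se_out, eaf_out, n_out.
    ``audit`` has one row per shared variant with its harmonization action.
    """

    exposure_id: str
    outcome_id: str
    rows: pd.DataFrame = field(repr=False)
    audit: pd.DataFrame = field(repr=False)

    def __len__(self) -> int:
        return len(self.rows)

    def subset(self, variant_ids) -> "HarmonizedSet":
        keep = set(variant_ids)
        return HarmonizedSet(
            self.exposure_id,
            self.outcome_id,
            self.rows[self.rows["variant_id"].isin(keep)].reset_index(drop=True),
            self.audit,
        )

    def drop(self, variant_ids) -> "HarmonizedSet":
        omit = set(variant_ids)
        return HarmonizedSet(
            self.exposure_id,
            self.outcome_id,
            self.rows[~self.rows["variant_id"].isin(omit)].reset_index(drop=True),
            self.audit,
        )


def harmonize(
    exposure: SumStatTable,
    outcome: SumStatTable,
    palindrome_maf_window: tuple[float, float] = (0.40, 0.60),
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect allele, variant by variant.

    Policy per shared variant:

    * same allele pair, same orientation -> kept unchanged;
    * same pair, swapped orientation -> outcome beta sign-flipped and
      ``eaf_out := 1 - eaf_out``;
    * alleles match only after strand complement (non-palindromic) ->
      complemented, then as above;
    * palindromic (A/T or C/G): dropped when the minor-allele frequency of
      either table lies inside ``palindrome_maf_window`` (inclusive) or when
      either eaf is missing — at intermediate frequency strand cannot be
      resolved; otherwise orientations are chosen so both eafs fall on the
      same side of 0.5;
    * indels, multi-allelic or irreconcilable pairs -> dropped as incompatible.
    """
    lo, hi = palindrome_maf_window
    exp = exposure.records.set_index("variant_id", drop=False)
    out = outcome.records.set_index("variant_id", drop=False)
    shared = [v for v in exp.index if v in out.index]
    if not shared:
        raise EmptyOverlapError(
            f"no shared variants between {exposure.trait_id!r} and {outcome.trait_id!r}"
        )

    rows = []
    audit = []

    for vid in shared:
        e = exp.loc[vid]
        o = out.loc[vid]
        ea_e, oa_e = str(e["effect_allele"]).upper(), str(e["other_allele"]).upper()
        ea_o, oa_o = str(o["effect_allele"]).upper(), str(o["other_allele"]).upper()

        if len(ea_e) != 1 or len(oa_e) != 1 or len(ea_o) != 1 or len(oa_o) != 1:
            audit.append((vid, DROPPED_INCOMPATIBLE))
            continue

        beta_o, eaf_o = float(o["beta"]), o["eaf"]
        action = None

        if is_palindromic(ea_e, oa_e):
            # palindrome in the exposure frame; the outcome pair necessarily
            # "matches" in all four orientations if it is the same palindrome
            if {ea_o, oa_o} != {ea_e, oa_e}:
                action = DROPPED_INCOMPATIBLE
            elif pd.isna(e["eaf"]) or pd.isna(eaf_o):
                action = DROPPED_PALINDROME_MAF
            elif lo <= _maf(float(e["eaf"])) <= hi or lo <= _maf(float(eaf_o)) <= hi:
                action = DROPPED_PALINDROME_MAF
            else:
                # orient the outcome so both eafs sit on the same side of 0.5
                if (float(e["eaf"]) - 0.5) * (float(eaf_o) - 0.5) < 0:
                    beta_o, eaf_o = -beta_o, 1.0 - float(eaf_o)
                action = PALINDROME_ALIGNED
        else:
            pair_o = (ea_o, oa_o)
            comp = (_COMPLEMENT[ea_o], _COMPLEMENT[oa_o])
            if pair_o == (ea_e, oa_e):
                action = KEPT
            elif pair_o == (oa_e, ea_e):
                beta_o = -beta_o
                if not pd.isna(eaf_o):
                    eaf_o = 1.0 - float(eaf_o)
                action = FLIPPED
            elif comp == (ea_e, oa_e):
                action = KEPT
            elif comp == (oa_e, ea_e):
                beta_o = -beta_o
                if not pd.isna(eaf_o):
                    eaf_o = 1.0 - float(eaf_o)
                action = FLIPPED
            else:
                action = DROPPED_INCOMPATIBLE

        audit.append((vid, action))
        if action in DROPPED_ACTIONS:
            continue
        rows.append(
            {
                "variant_id": vid,
                "chrom": e["chrom"],
                "pos": e["pos"],
                "effect_allele": ea_e,
                "other_allele": oa_e,
                "beta_exp": float(e["beta"]),
                "se_exp": float(e["se"]),
                "eaf_exp": float(e["eaf"]) if not pd.isna(e["eaf"]) else np.nan,
                "n_exp": int(e["n"]),
                "beta_out": beta_o,
                "se_out": float(o["se"]),
                "eaf_out": float(eaf_o) if not pd.isna(eaf_o) else np.nan,
                "n_out": int(o["n"]),
            }
        )

    rows_df = pd.DataFrame(
        rows,
        columns=[
            "variant_id", "chrom", "pos", "effect_allele", "other_allele",
            "beta_exp", "se_exp", "eaf_exp", "n_exp",
            "beta_out", "se_out", "eaf_out", "n_out",
        ],
    )
    audit_df = pd.DataFrame(audit, columns=["variant_id", "action"])
    return HarmonizedSet(exposure.trait_id, outcome.trait_id, rows_df, audit_df)
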