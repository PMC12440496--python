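"""Parsing, validation, round-trip and harmonization behaviour."""

import numpy as np
import pandas as pd
import pytest

from mrmediate.sumstats import (
    CANONICAL_COLUMNS,
    DROPPED_ACTIONS,
    EmptyOverlapError,
    SumStatFormatError,
    SumStatTable,
    SumStatValidationError,
    harmonize,
    read_sumstats,
    write_sumstats,
)
from .conftest import make_table


def _write_tsv(path, df):
    df.to_csv(path, sep="\t", index=False)


class TestReadWrite:
    def test_parses_canonical_tsv(self, tmp_path):
        t = make_table()
        p = tmp_path / "x.tsv"
        _write_tsv(p, t.records)
        got = read_sumstats(p, trait_id="X")
        assert len(got) == 3
        pd.testing.assert_frame_equal(got.records, t.records, check_dtype=False)

    def test_se_zero_rejected_with_row_index(self, tmp_path):
        df = make_table().records.copy()
        df.loc[1, "se"] = 0.0
        p = tmp_path / "bad.tsv"
        _write_tsv(p, df)
        with pytest.raises(SumStatValidationError, match="row 1"):
            read_sumstats(p)

    def test_column_map_equivalent_to_canonical(self, tmp_path):
        t = make_table()
        renamed = t.records.rename(columns={"beta": "BETA", "se": "SE", "pval": "P"})
        p1, p2 = tmp_path / "canon.tsv", tmp_path / "alias.tsv"
        _write_tsv(p1, t.records)
        _write_tsv(p2, renamed)
        a = read_sumstats(p1, trait_id="X")
        b = read_sumstats(p2, column_map={"BETA": "beta", "SE": "se", "P": "pval"}, trait_id="X")
        pd.testing.assert_frame_equal(a.records, b.records, check_dtype=False)

    def test_missing_mandatory_column_is_format_error(self, tmp_path):
        df = make_table().records.drop(columns=["beta"])
        p = tmp_path / "x.tsv"
        _write_tsv(p, df)
        with pytest.raises(SumStatFormatError, match="beta"):
            read_sumstats(p)

    def test_empty_table_roundtrips_as_header_only(self, tmp_path):
        t = SumStatTable("X", "continuous", make_table().records.iloc[:0])
        p = tmp_path / "empty.tsv"
        write_sumstats(t, p)
        assert p.read_text().strip() == "\t".join(CANONICAL_COLUMNS)
        assert len(read_sumstats(p, trait_id="X")) == 0

    def test_random_table_roundtrip_is_identity(self, rng, tmp_path):
        k = 100
        df = pd.DataFrame(
            {
                "variant_id": [f"rs{i}" for i in range(k)],
                "chrom": rng.choice(["1", "2", "X"], k),
                "pos": rng.integers(1, 10**8, k),
                "effect_allele": rng.choice(list("ACGT"), k),
                "other_allele": "N",
                "eaf": rng.uniform(0.01, 0.99, k),
                "beta": rng.standard_normal(k),
                "se": rng.uniform(1e-4, 0.5, k),
                "pval": rng.uniform(1e-12, 1.0, k),
                "n": rng.integers(100, 10**6, k),
            }
        )
        # other allele must differ from effect allele
        comp = {"A": "G", "C": "T", "G": "A", "T": "C"}
        df["other_allele"] = [comp[a] for a in df["effect_allele"]]
        t = SumStatTable("X", "continuous", df)
        p = tmp_path / "r.tsv"
        write_sumstats(t, p)
        got = read_sumstats(p, trait_id="X")
        pd.testing.assert_frame_equal(got.records, t.records, check_dtype=False)

    @pytest.mark.parametrize(
        "field,value,msg",
        [
            ("pval", 0.0, "pval"),
            ("pval", 1.5, "pval"),
            ("eaf", -0.1, "eaf"),
            ("n", 0, "n"),
        ],
    )
    def test_record_invariants_enforced(self, field, value, msg):
        df = make_table().records.copy()
        df.loc[0, field] = value
        with pytest.raises(SumStatValidationError, match=msg):
            SumStatTable("X", "continuous", df)

    def test_duplicate_variant_ids_rejected(self):
        df = make_table().records.copy()
        df.loc[2, "variant_id"] = "rs1"
        with pytest.raises(SumStatValidationError, match="duplicate"):
            SumStatTable("X", "continuous", df)

    def test_same_alleles_rejected(self):
        df = make_table().records.copy()
        df.loc[0, "other_allele"] = "A"
        with pytest.raises(SumStatValidationError, match="effect_allele equals"):
            SumStatTable("X", "continuous", df)


def _pair(exp_rows, out_rows):
    exp = make_table(**exp_rows)
    out = make_table(trait_id="Y", **out_rows)
    return exp, out


def one_variant(ea, oa, beta, eaf, **extra):
    rec = {
        "variant_id": ["rs1"],
        "chrom": ["1"],
        "pos": [1000],
        "effect_allele": [ea],
        "other_allele": [oa],
        "eaf": [eaf],
        "beta": [beta],
        "se": [0.01],
        "pval": [1e-8],
        "n": [10000],
    }
    rec.update(extra)
    return rec


class TestHarmonize:
    def test_identical_orientation_kept(self):
        e, o = _pair(one_variant("A", "G", 0.10, 0.2), one_variant("A", "G", 0.05, 0.25))
        h = harmonize(e, o)
        assert list(h.audit["action"]) == ["kept"]
        assert h.rows.loc[0, "beta_out"] == 0.05

    def test_swapped_orientation_flips_beta_and_eaf(self):
        e, o = _pair(one_variant("A", "G", 0.10, 0.2), one_variant("G", "A", -0.05, 0.7))
        h = harmonize(e, o)
        assert list(h.audit["action"]) == ["flipped"]
        assert h.rows.loc[0, "beta_out"] == pytest.approx(0.05)
        assert h.rows.loc[0, "eaf_out"] == pytest.approx(0.3)

    def test_strand_complement_resolved(self):
        # exposure A/G; outcome reported on the other strand as T/C
        e, o = _pair(one_variant("A", "G", 0.10, 0.2), one_variant("T", "C", 0.05, 0.22))
        h = harmonize(e, o)
        assert list(h.audit["action"]) == ["kept"]
        assert h.rows.loc[0, "beta_out"] == 0.05

    @pytest.mark.parametrize("eaf", [0.45, 0.40, 0.60, 0.5])
    def test_palindrome_intermediate_maf_dropped(self, eaf):
        e, o = _pair(one_variant("A", "T", 0.10, eaf), one_variant("A", "T", 0.05, eaf))
        h = harmonize(e, o)
        assert list(h.audit["action"]) == ["dropped_palindrome_maf"]
        assert len(h) == 0

    def test_palindrome_low_maf_aligned_by_frequency(self):
        e, o = _pair(one_variant("A", "T", 0.10, 0.10), one_variant("A", "T", 0.05, 0.12))
        h = harmonize(e, o)
        assert list(h.audit["action"]) == ["palindrome_aligned"]
        assert h.rows.loc[0, "beta_out"] == 0.05

    def test_palindrome_opposite_frequency_sides_flipped(self):
        e, o = _pair(one_variant("C", "G", 0.10, 0.10), one_variant("C", "G", 0.05, 0.88))
        h = harmonize(e, o)
        assert h.rows.loc[0, "beta_out"] == pytest.approx(-0.05)
        assert h.rows.loc[0, "eaf_out"] == pytest.approx(0.12)

    def test_palindrome_missing_eaf_dropped(self):
        e, o = _pair(one_variant("A", "T", 0.10, 0.1), one_variant("A", "T", 0.05, np.nan))
        h = harmonize(e, o)
        assert list(h.audit["action"]) == ["dropped_palindrome_maf"]

    def test_irreconcilable_alleles_dropped(self):
        e, o = _pair(one_variant("A", "G", 0.10, 0.2), one_variant("A", "C", 0.05, 0.2))
        h = harmonize(e, o)
        assert list(h.audit["action"]) == ["dropped_incompatible"]

    def test_indel_dropped_incompatible(self):
        e, o = _pair(one_variant("A", "G", 0.10, 0.2), one_variant("AT", "A", 0.05, 0.2))
        h = harmonize(e, o)
        assert list(h.audit["action"]) == ["dropped_incompatible"]
        assert len(h) == 0

    def test_empty_overlap_raises(self):
        e = make_table()
        o = make_table(trait_id="Y", variant_id=["rs9", "rs10", "rs11"])
        with pytest.raises(EmptyOverlapError):
            harmonize(e, o)

    def test_action_conservation(self, rng):
        # every shared variant gets exactly one audit action and the kept
        # rows are exactly the non-dropped ones
        e = make_table()
        o = make_table(
            trait_id="Y",
            effect_allele=["G", "C", "C"],   # rs1 swapped, rs2 same, rs3 incompatible
            other_allele=["A", "T", "T"],
        )
        h = harmonize(e, o)
        assert len(h.audit) == 3
        n_dropped = h.audit["action"].isin(DROPPED_ACTIONS).sum()
        assert len(h.rows) + n_dropped == 3

    def test_harmonization_idempotent(self):
        e, o = _pair(one_variant("A", "G", 0.10, 0.2), one_variant("G", "A", -0.05, 0.7))
        h1 = harmonize(e, o)
        # re-express the harmonized outcome as a table and harmonize again
        out2 = make_table(
            trait_id="Y",
            **one_variant("A", "G", float(h1.rows.loc[0, "beta_out"]), float(h1.rows.loc[0, "eaf_out"])),
        )
        h2 = harmonize(e, out2)
        assert list(h2.audit["action"]) == ["kept"]
        assert h2.rows.loc[0, "beta_out"] == pytest.approx(h1.rows.loc[0, "beta_out"])

    def test_flip_involution(self):
        # flipping the outcome allele coding twice restores the original exactly
        orig = one_variant("A", "G", -0.05, 0.7)
        once = one_variant("G", "A", 0.05, 0.3)
        e = make_table(**one_variant("A", "G", 0.10, 0.2))
        h_orig = harmonize(e, make_table(trait_id="Y", **orig))
        h_once = harmonize(e, make_table(trait_id="Y", **once))
        assert h_orig.rows.loc[0, "beta_out"] == h_once.rows.loc[0, "beta_out"]
        assert h_orig.rows.loc[0, "eaf_out"] == h_once.rows.loc[0, "eaf_out"]
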