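"""Reading, validation, and allele harmonization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_table
from mrmediation import (
    IEU_DIALECT,
    ConfigError,
    InputError,
    UsageError,
    align_alleles,
    harmonize_multi,
    harmonize_pair,
    read_summary_stats,
    validate_table,
    write_summary_stats,
)
from mrmediation.gwas_io import RETAINED_ACTIONS


def _rec(vid="rs1", ea="A", oa="G", eaf=0.3, beta=0.2, se=0.05):
    return {
        "variant_id": vid,
        "effect_allele": ea,
        "other_allele": oa,
        "eaf": eaf,
        "beta": beta,
        "se": se,
    }


class TestReadSummaryStats:
    def test_round_trip(self, tmp_path):
        table = make_table(["rs1", "rs2", "rs3"], beta=[0.1, -0.2, 0.3], se=0.05)
        path = tmp_path / "t.tsv"
        write_summary_stats(table, path)
        got, rejects = read_summary_stats(path, return_rejects=True)
        assert len(got) == 3 and rejects.empty
        np.testing.assert_allclose(got["beta"], table["beta"])

    def test_invalid_rows_rejected_with_reasons(self):
        table = make_table(
            ["rs1", "rs2", "rs3", "rs4", "rs4"],
            beta=0.1,
            se=[0.05, 0.0, 0.05, 0.05, 0.05],
        )
        table.loc[2, "other_allele"] = "AG"  # indel
        valid, rejects = validate_table(table)
        assert list(valid["variant_id"]) == ["rs1", "rs4"]
        reasons = dict(zip(rejects["variant_id"], rejects["reason"]))
        assert reasons["rs2"] == "nonpositive SE"
        assert reasons["rs3"] == "not a biallelic SNP"
        assert "duplicate" in reasons["rs4"]

    def test_lowercase_alleles_normalized(self):
        table = make_table(["rs1"], beta=0.1, se=0.05, effect_allele="a", other_allele="g")
        valid, rejects = validate_table(table)
        assert rejects.empty
        assert valid.loc[0, "effect_allele"] == "A"
        assert valid.loc[0, "other_allele"] == "G"

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "t.tsv"
        make_table(["rs1"], beta=0.1, se=0.05).drop(columns=["eaf"]).to_csv(
            path, sep="\t", index=False
        )
        with pytest.raises(ConfigError, match="eaf"):
            read_summary_stats(path)

    def test_empty_table_is_input_error(self, tmp_path):
        path = tmp_path / "t.tsv"
        make_table([], beta=[], se=[]).to_csv(path, sep="\t", index=False)
        with pytest.raises(InputError):
            read_summary_stats(path)

    def test_ieu_dialect(self, tmp_path):
        table = make_table(["rs1", "rs2"], beta=0.1, se=0.05)
        renamed = table.rename(
            columns={"variant_id": "SNP", "n": "samplesize"}
        )
        path = tmp_path / "ieu.tsv"
        renamed.to_csv(path, sep="\t", index=False)
        got = read_summary_stats(path, dialect=IEU_DIALECT)
        assert list(got["variant_id"]) == ["rs1", "rs2"]


class TestAlignAlleles:
    @pytest.mark.parametrize(
        "exp, out, action, beta, eaf",
        [
            # identical pair
            (("A", "G", 0.3), ("A", "G", 0.3), "kept", 0.2, 0.3),
            # swapped pair: beta negated, frequency reflected
            (("A", "G", 0.3), ("G", "A", 0.3), "flipped", -0.2, 0.7),
            # strand complement, same order
            (("A", "G", 0.3), ("T", "C", 0.3), "strand_complemented", 0.2, 0.3),
            # strand complement of the swapped pair
            (("A", "G", 0.3), ("C", "T", 0.3), "strand_complemented", -0.2, 0.7),
            # incompatible alleles
            (("A", "G", 0.3), ("A", "C", 0.3), "dropped_incompatible", 0.2, 0.3),
            # palindromic, intermediate frequency in the outcome study
            (("A", "T", 0.3), ("A", "T", 0.50), "dropped_palindromic", 0.2, 0.5),
            # palindromic, intermediate frequency in the exposure study
            (("A", "T", 0.45), ("A", "T", 0.3), "dropped_palindromic", 0.2, 0.3),
            # palindromic, frequencies on the same side of 0.5
            (("C", "G", 0.2), ("C", "G", 0.25), "kept", 0.2, 0.25),
            # palindromic, frequencies on opposite sides: strand flip inferred
            (("C", "G", 0.2), ("C", "G", 0.75), "flipped", -0.2, 0.25),
        ],
    )
    def test_alignment_rules(self, exp, out, action, beta, eaf):
        ea, oa, fx = exp
        eb, ob, fy = out
        got = align_alleles(
            _rec(ea=ea, oa=oa, eaf=fx), _rec(ea=eb, oa=ob, eaf=fy, beta=0.2)
        )
        assert got.action == action
        if action in RETAINED_ACTIONS:
            assert got.outcome_beta == pytest.approx(beta)
            assert got.outcome_eaf == pytest.approx(eaf)

    def test_variant_mismatch_is_usage_error(self):
        with pytest.raises(UsageError):
            align_alleles(_rec(vid="rs1"), _rec(vid="rs2"))

    @given(beta=st.floats(-2, 2), eaf=st.floats(0.01, 0.99))
    @settings(max_examples=50, deadline=None)
    def test_flip_involution(self, beta, eaf):
        """Aligning a swapped record, then swapping again, restores the original."""
        exposure = _rec()
        swapped = _rec(ea="G", oa="A", beta=beta, eaf=eaf)
        once = align_alleles(exposure, swapped)
        assert once.action == "flipped"
        again = _rec(ea="G", oa="A", beta=once.outcome_beta, eaf=once.outcome_eaf)
        # interpret the aligned record back in the swapped frame
        twice = align_alleles(_rec(ea="G", oa="A"), again)
        assert twice.action == "kept"
        back = align_alleles(exposure, _rec(beta=once.outcome_beta, eaf=once.outcome_eaf))
        assert back.outcome_beta == pytest.approx(-beta)
        assert back.outcome_eaf == pytest.approx(1 - eaf)


class TestHarmonizePair:
    def test_disjoint_tables_error(self):
        a = make_table(["rs1"], beta=0.1, se=0.05)
        b = make_table(["rs2"], beta=0.1, se=0.05)
        with pytest.raises(InputError):
            harmonize_pair(a, b)

    def test_identity_harmonization(self):
        t = make_table(["rs1", "rs2", "rs3"], beta=[0.1, 0.2, 0.3], se=0.05)
        h = harmonize_pair(t, t)
        assert set(h.actions["action"]) == {"kept"}
        np.testing.assert_allclose(h.outcome_beta, t["beta"])

    def test_palindromic_dropped_from_five(self):
        ids = [f"rs{i}" for i in range(1, 6)]
        exp = make_table(
            ids,
            beta=0.1,
            se=0.05,
            effect_allele=["A", "A", "A", "A", "A"],
            other_allele=["G", "G", "G", "G", "T"],
            eaf=[0.3, 0.3, 0.3, 0.3, 0.5],
        )
        out = exp.copy()
        h = harmonize_pair(exp, out)
        assert h.nsnp == 4
        assert (
            h.actions.set_index("variant_id").loc["rs5", "action"]
            == "dropped_palindromic"
        )

    def test_every_input_variant_logged_once(self):
        exp = make_table(["rs1", "rs2", "rs3"], beta=0.1, se=0.05)
        out = make_table(["rs1", "rs3"], beta=0.1, se=0.05)
        h = harmonize_pair(exp, out)
        assert sorted(h.actions["variant_id"]) == ["rs1", "rs2", "rs3"]
        assert h.actions["variant_id"].is_unique
        assert (
            h.actions.set_index("variant_id").loc["rs2", "action"]
            == "dropped_unmatched"
        )

    def test_idempotence(self, rng):
        """Harmonizing an already-harmonized pair changes nothing."""
        exp = make_table(
            ["rs1", "rs2", "rs3"],
            beta=[0.1, -0.2, 0.3],
            se=0.05,
            effect_allele=["A", "T", "C"],
            other_allele=["G", "G", "A"],
        )
        out = make_table(
            ["rs1", "rs2", "rs3"],
            beta=[0.05, 0.07, -0.09],
            se=0.04,
            effect_allele=["G", "T", "A"],  # rs1 swapped
            other_allele=["A", "G", "C"],
        )
        h1 = harmonize_pair(exp, out)
        aligned = exp.copy()
        aligned["beta"] = h1.outcome_beta
        aligned["se"] = h1.outcome_se
        h2 = harmonize_pair(exp, aligned)
        assert set(h2.actions["action"]) == {"kept"}
        np.testing.assert_allclose(h2.outcome_beta, h1.outcome_beta)


class TestHarmonizeMulti:
    def test_extra_exposure_aligned_and_missing_dropped(self):
        ids = ["rs1", "rs2", "rs3"]
        prim = make_table(ids, beta=[0.1, 0.2, 0.3], se=0.05)
        outc = make_table(ids, beta=[0.02, 0.04, 0.06], se=0.04)
        extra = make_table(
            ["rs1", "rs2"],
            beta=[0.5, -0.6],
            se=0.03,
            effect_allele=["G", "A"],  # rs1 reported on the swapped orientation
            other_allele=["A", "G"],
        )
        h = harmonize_multi(prim, {"bmi": extra}, outc)
        assert list(h.variants) == ["rs1", "rs2"]  # rs3 missing from extra
        b, s = h.extra_exposures["bmi"]
        np.testing.assert_allclose(b, [-0.5, -0.6])  # rs1 flipped into primary frame
        np.testing.assert_allclose(s, [0.03, 0.03])
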