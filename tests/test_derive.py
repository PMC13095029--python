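"""Regressor derivation: hard calls, ligand groups, parental origin."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import c2_count, enumerate_transmissions
from kirhla import (classify_c_group, derive_pairs, dosage_from_posteriors,
                    fetal_c2_presence, hardcall_from_dosage,
                    mendelian_consistent, paternal_c2_indicator,
                    relative_c2_coding)
from kirhla.errors import InputError, MendelianError, UnclassifiedAlleleError

GENOTYPES = [("C1", "C1"), ("C1", "C2"), ("C2", "C2")]


@pytest.mark.parametrize("dosage,call", [
    (0.0, 0), (0.3, 0), (0.31, None), (0.5, None), (0.69, None),
    (0.7, 1), (1.0, 1), (1.3, 1), (1.31, None), (1.5, None), (1.69, None),
    (1.7, 2), (1.85, 2), (2.0, 2),
])
def test_hardcall_thresholds(dosage, call):
    assert hardcall_from_dosage(dosage) == call


def test_hardcall_rejects_out_of_range():
    for d in (-0.1, 2.1, np.nan):
        with pytest.raises(InputError):
            hardcall_from_dosage(d)


@given(st.floats(0, 2), st.floats(0, 2))
@settings(max_examples=200, deadline=None)
def test_hardcall_monotone(d1, d2):
    """Hard calls are monotone non-decreasing over the non-missing range."""
    c1, c2 = hardcall_from_dosage(min(d1, d2)), hardcall_from_dosage(max(d1, d2))
    if c1 is not None and c2 is not None:
        assert c1 <= c2


@pytest.mark.parametrize("family,group", [
    (1, "C1"), (3, "C1"), (7, "C1"), (8, "C1"), (12, "C1"), (14, "C1"), (16, "C1"),
    (2, "C2"), (4, "C2"), (5, "C2"), (6, "C2"), (15, "C2"), (17, "C2"), (18, "C2"),
])
def test_all_fourteen_ligand_families(family, group):
    assert classify_c_group(f"C*{family:02d}:01") == group


@pytest.mark.parametrize("name,group", [
    ("C*04:01", "C2"), ("C*07:02", "C1"), ("HLA-C*03:04", "C1"), ("c*05:01", "C2"),
])
def test_allele_name_dialects(name, group):
    assert classify_c_group(name) == group


def test_unknown_family_rejected():
    with pytest.raises(UnclassifiedAlleleError):
        classify_c_group("C*99:01")
    with pytest.raises(UnclassifiedAlleleError):
        classify_c_group("B*07:02")


def test_fetal_presence_saturates():
    assert fetal_c2_presence(("C1", "C2")) == 1
    assert fetal_c2_presence(("C2", "C2")) == 1
    assert fetal_c2_presence(("C1", "C1")) == 0


def test_relative_coding_examples():
    assert relative_c2_coding(("C1", "C2"), ("C1", "C1")) == 0
    assert relative_c2_coding(("C1", "C1"), ("C1", "C2")) == 2
    assert relative_c2_coding(("C1", "C2"), ("C2", "C2")) == 2
    assert relative_c2_coding(("C2", "C2"), ("C2", "C2")) == 1


def test_paternal_indicator_examples():
    assert paternal_c2_indicator(("C1", "C1"), ("C1", "C2")) == 1
    assert paternal_c2_indicator(("C1", "C2"), ("C1", "C2")) is None  # ambiguous
    assert paternal_c2_indicator(("C2", "C2"), ("C1", "C2")) == 0
    assert paternal_c2_indicator(("C1", "C2"), ("C2", "C2")) == 0


def test_mendelian_inconsistent_pairs_raise():
    for mother, fetus in ((("C1", "C1"), ("C2", "C2")), (("C2", "C2"), ("C1", "C1"))):
        assert not mendelian_consistent(mother, fetus)
        with pytest.raises(MendelianError):
            relative_c2_coding(mother, fetus)
        with pytest.raises(MendelianError):
            paternal_c2_indicator(mother, fetus)


def test_codings_match_transmission_enumerator():
    """Brute-force enumeration over all 9 genotype combinations agrees with
    the closed-form codings (the oracle re-appears in the acceptance suite)."""
    for mother, fetus in itertools.product(GENOTYPES, repeat=2):
        assignments = enumerate_transmissions(mother, fetus)
        if not assignments:
            assert not mendelian_consistent(mother, fetus)
            continue
        assert mendelian_consistent(mother, fetus)
        rel = 1 + int(np.sign(c2_count(fetus) - c2_count(mother)))
        assert relative_c2_coding(mother, fetus) == rel
        paternal_only = {pat == "C2" and mat == "C1" for mat, pat in assignments}
        expected = int(paternal_only.pop()) if len(paternal_only) == 1 else None
        assert paternal_c2_indicator(mother, fetus) == expected


def test_dosage_expectation():
    assert dosage_from_posteriors({0: 1.0, 1: 0.0, 2: 0.0}) == 0.0
    assert dosage_from_posteriors({0: 0.0, 1: 1.0, 2: 0.0}) == 1.0
    assert dosage_from_posteriors({0: 0.2, 1: 0.5, 2: 0.3}) == pytest.approx(1.1)
    with pytest.raises(InputError):
        dosage_from_posteriors({0: 0.5, 1: 0.3, 2: 0.1})


class TestDerivePairs:
    def test_roundtrip_with_exact_channel(self, observed_exact):
        """At accuracy 1 derivation reproduces the simulated truth."""
        pairs, truth, hla, kir = observed_exact
        derived, audit = derive_pairs(pairs, hla, kir)
        assert len(audit) == 0
        merged = derived.merge(truth, on="pair_id", suffixes=("", "_t"))
        assert (merged["fetal_c2_count"] == merged["fetal_c2_count_t"]).all()
        assert (merged["c2_presence"] == (merged["fetal_c2_count_t"] > 0)).all()
        assert (merged["kir2ds1_dosage"] == merged["mother_2ds1_copies"]).all()
        amb = (merged["mother_c2_count"] == 1) & (merged["fetal_c2_count"] == 1)
        assert (merged["po_ambiguous"] == amb).all()

    def test_mendelian_violations_audited(self, observed_exact):
        pairs, truth, hla, kir = observed_exact
        bad = hla.copy()
        # force one child call inconsistent with a C2/C2 mother
        mothers2 = truth.loc[truth["mother_c2_count"] == 2, "pair_id"].iloc[0]
        bad.loc[(bad["role"] == "child") & (bad["sample_id"] == mothers2), "c2_dosage"] = 0.0
        derived, audit = derive_pairs(pairs, bad, kir)
        assert list(audit["reason"]) == ["MENDELIAN_INCONSISTENT"]
        assert audit["pair_id"].iloc[0] == mothers2
        assert len(derived) + len(audit) == len(pairs)

    def test_uncallable_dosage_audited(self, observed_exact):
        pairs, truth, hla, kir = observed_exact
        bad = hla.copy()
        target = pairs["pair_id"].iloc[3]
        bad.loc[(bad["role"] == "child") & (bad["sample_id"] == target), "c2_dosage"] = 0.5
        derived, audit = derive_pairs(pairs, bad, kir)
        assert set(audit["reason"]) == {"HLA_MISSING_CHILD"}
        assert target not in set(derived["pair_id"])

    def test_allele_name_path(self):
        pairs = pd.DataFrame({
            "pair_id": ["P0"], "mother_id": ["M0"], "birth_weight": [3400.0],
        })
        hla = pd.DataFrame({
            "sample_id": ["M0", "P0"], "role": ["mother", "child"],
            "allele1": ["C*07:01", "C*07:01"], "allele2": ["C*04:01", "C*07:02"],
            "quality": [1.0, 1.0],
        })
        kir = pd.DataFrame({
            "sample_id": ["M0"] * 6,
            "locus": ["KIR_B_HAPLOTYPE"] * 3 + ["KIR2DS1"] * 3,
            "state": [0, 1, 2] * 2,
            "posterior": [0.0, 1.0, 0.0, 1.0, 0.0, 0.0],
        })
        derived, audit = derive_pairs(pairs, hla, kir)
        assert len(audit) == 0
        row = derived.iloc[0]
        assert row["mother_c2_count"] == 1 and row["fetal_c2_count"] == 0
        assert row["relative_c2"] == 0 and row["kir_b_dosage"] == 1.0
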