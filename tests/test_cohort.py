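"""Variant filtering, the two classification rules, and marginal-exact
fixture reconstruction."""

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from melpath.cohort import (
    CSD,
    NEVOGENIC,
    UNCLASSIFIABLE,
    ClassificationRules,
    InfeasibleMarginalsError,
    PatientRecord,
    VariantCall,
    VariantFilterConfig,
    classify_group,
    classify_subtype,
    elastosis_band,
    filter_variants,
    fixture_from_marginals,
    is_overlap_label,
    melanoma_cohort_fixture,
    read_cohort_tsv,
    subtype_counts,
    write_cohort_tsv,
)
from melpath.reference import GROUP_MUTATION_COUNTS


class TestFilterVariants:
    @pytest.mark.parametrize(
        "vaf,pathogenicity,kept",
        [
            (0.04, "pathogenic", False),  # at/below the 5% VAF cut
            (0.30, "benign", False),
            (0.30, "vus", False),
            (0.30, "likely_pathogenic", True),
            (0.051, "predicted_pathogenic", True),
            (0.05, "pathogenic", False),  # strict inequality
        ],
    )
    def test_vaf_and_class_filter(self, vaf, pathogenicity, kept):
        calls = [VariantCall("T1", "BRAF", vaf, pathogenicity)]
        assert bool(filter_variants(calls)) is kept

    def test_unknown_gene_reported_not_silently_dropped(self):
        calls = [
            VariantCall("T1", "BRAF", 0.4, "pathogenic"),
            VariantCall("T1", "MYC", 0.4, "pathogenic"),
        ]
        with pytest.warns(UserWarning, match="T1/MYC"):
            kept = filter_variants(calls)
        assert [c.gene for c in kept] == ["BRAF"]

    def test_idempotent_and_order_preserving(self):
        calls = [
            VariantCall("T1", "BRAF", 0.4, "pathogenic"),
            VariantCall("T2", "NF1", 0.2, "benign"),
            VariantCall("T3", "NRAS", 0.1, "likely_pathogenic"),
        ]
        once = filter_variants(calls)
        assert [c.tumor_id for c in once] == ["T1", "T3"]
        assert filter_variants(once) == once

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            VariantFilterConfig(min_vaf=1.5)


class TestClassifyGroup:
    @pytest.mark.parametrize(
        "nevi,grade,expected",
        [
            (60, "0", NEVOGENIC),
            (10, "2", CSD),
            (10, "3+", CSD),
            (35, "1", UNCLASSIFIABLE),  # satisfies neither rule
            (50, "0", UNCLASSIFIABLE),  # boundary: strictly more than 50
            (20, "3", UNCLASSIFIABLE),  # boundary: strictly fewer than 20
            (60, "1-", UNCLASSIFIABLE),  # many nevi but some elastosis
            (10, "1+", UNCLASSIFIABLE),  # few nevi but only mild elastosis
        ],
    )
    def test_rule(self, nevi, grade, expected):
        rec = PatientRecord("T", nevus_count=nevi, elastosis_grade=grade)
        assert classify_group(rec) == expected

    def test_missing_fields_unclassifiable_with_reason(self):
        lbl, reason = classify_group(PatientRecord("T"), with_reason=True)
        assert lbl == UNCLASSIFIABLE and reason == "missing_nevus_count"
        lbl, reason = classify_group(
            PatientRecord("T", nevus_count=5), with_reason=True
        )
        assert lbl == UNCLASSIFIABLE and reason == "missing_elastosis"

    @given(nevi=st.integers(0, 300), ordinal=st.integers(0, 10))
    def test_total_deterministic_mutually_exclusive(self, nevi, ordinal):
        rec = PatientRecord("T", nevus_count=nevi, elastosis_grade=ordinal)
        a, b = classify_group(rec), classify_group(rec)
        assert a == b in {NEVOGENIC, CSD, UNCLASSIFIABLE}
        # nevogenic and CSD rules can never both hold
        if a == NEVOGENIC:
            assert nevi > 50 and elastosis_band(ordinal) == "none"
        if a == CSD:
            assert nevi < 20 and elastosis_band(ordinal) in {"moderate", "severe"}

    def test_rules_invariant(self):
        with pytest.raises(ValueError):
            ClassificationRules(nevogenic_min_nevi=10, csd_max_nevi=20)


class TestClassifySubtype:
    @pytest.mark.parametrize(
        "mut,expected",
        [
            (["BRAF"], "BRAF+"),
            (["NRAS"], "RAS+"),
            (["HRAS"], "RAS+"),
            (["KRAS"], "RAS+"),
            (["NF1"], "NF1+"),
            ([], "3wt"),
            (["BRAF", "NF1"], "BRAF+NF1+"),
            (["BRAF", "NRAS"], "BRAF+RAS+"),
            (["KRAS", "NF1"], "RAS+NF1+"),
            (["BRAF", "HRAS", "NF1"], "BRAF+RAS+NF1+"),
        ],
    )
    def test_labels(self, mut, expected):
        row = {g: (1 if g in mut else 0) for g in ["BRAF", "NRAS", "HRAS", "KRAS", "NF1"]}
        assert classify_subtype(row) == expected

    def test_missing_driver_column_is_hard_error(self):
        with pytest.raises(KeyError, match="NF1"):
            classify_subtype({"BRAF": 1, "NRAS": 0, "HRAS": 0, "KRAS": 0})

    def test_non_driver_genes_ignored(self):
        row = {"BRAF": 0, "NRAS": 0, "HRAS": 0, "KRAS": 0, "NF1": 0, "TERTp": 1, "TP53": 1}
        assert classify_subtype(row) == "3wt"


class TestFixtureFromMarginals:
    def test_reproduces_every_marginal(self, cohort_fixture):
        matrix, records = cohort_fixture
        df = matrix.df
        assert len(df) == 119
        for gene, (nev, csd) in GROUP_MUTATION_COUNTS.items():
            col = df[gene]
            assert int((col[:82] == 1).sum()) == nev, gene
            assert int((col[82:] == 1).sum()) == csd, gene
        assert int(df["TERTp"].isna().sum()) == 6
        assert int(df["TERTp"][:82].isna().sum()) == 3

    def test_reproduces_driver_overlaps(self, cohort_fixture):
        matrix, _ = cohort_fixture
        df = matrix.df
        ras = (df[["NRAS", "HRAS", "KRAS"]] == 1).any(axis=1)
        assert int(((df["BRAF"] == 1) & ras).sum()) == 3
        assert int(((df["BRAF"] == 1) & (df["NF1"] == 1)).sum()) == 9
        assert int((ras & (df["NF1"] == 1)).sum()) == 1

    def test_partition_sums_to_cohort(self, cohort_fixture):
        counts = subtype_counts(cohort_fixture[0])
        assert sum(counts.values()) == 119
        # marginal consistency: singles + labels containing the class = total
        braf_total = counts["BRAF+"] + sum(
            v for k, v in counts.items() if is_overlap_label(k) and "BRAF" in k
        )
        assert braf_total == 60

    def test_deterministic_per_seed(self):
        a, _ = melanoma_cohort_fixture(seed=3)
        b, _ = melanoma_cohort_fixture(seed=3)
        c, _ = melanoma_cohort_fixture(seed=4)
        pd.testing.assert_frame_equal(a.df, b.df)
        assert not a.df.equals(c.df)  # non-driver placement is seed-dependent

    def test_all_zero_counts(self):
        m, recs = fixture_from_marginals({"BRAF": (0, 0), "NF1": (0, 0)}, {}, 4, 3)
        assert (m.df.to_numpy() == 0).all() and len(recs) == 7

    def test_infeasible_overlap_errors(self):
        with pytest.raises(InfeasibleMarginalsError):
            fixture_from_marginals(
                {"BRAF": (2, 1), "NF1": (1, 0)}, {("BRAF", "NF1"): 5}, 10, 10
            )

    def test_counts_exceeding_group_size_error(self):
        with pytest.raises(InfeasibleMarginalsError):
            fixture_from_marginals({"BRAF": (11, 0)}, {}, 10, 10)

    def test_patient_metadata_consistent_with_group(self, cohort_fixture):
        _, records = cohort_fixture
        for r in records:
            assert classify_group(r) == r.group


def test_cohort_tsv_round_trip(tmp_path, cohort_fixture):
    matrix, records = cohort_fixture
    path = tmp_path / "cohort.tsv"
    write_cohort_tsv(path, matrix, records)
    m2, r2 = read_cohort_tsv(path)
    pd.testing.assert_frame_equal(matrix.df, m2.df, check_names=False)
    assert [r.tumor_id for r in r2] == [r.tumor_id for r in records]
    assert [r.group for r in r2] == [r.group for r in records]
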