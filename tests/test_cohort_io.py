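"""Curation rules: variant categories, exclusions, gene selection, splits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcbnet.cohort_io import (
    CLINICAL_FEATURES,
    EVIDENCE_GENESET,
    CohortTable,
    FeatureSpec,
    VariantRecord,
    apply_exclusions,
    binarize_variants,
    build_feature_table,
    curate,
    read_clinical_table,
    read_mutation_table,
    select_frequency_geneset,
    split_by_cohort,
    split_train_test,
)


def _clinical(rows):
    cols = ["patient_id", "age", "sex", "smoker", "histology", "dcb",
            "pfs_months", "pfs_event", "cohort"]
    return pd.DataFrame(rows, columns=cols)


def _row(pid, age=55, sex="female", smoker="never", hist="adenocarcinoma",
         dcb="benefit", pfs=10.0, event=1, cohort="A"):
    return (pid, age, sex, smoker, hist, dcb, pfs, event, cohort)


class TestBinarizeVariants:
    @pytest.mark.parametrize(
        "vclass,expected",
        [
            ("missense", 1),
            ("Missense_Mutation", 1),
            ("Frame_Shift_Del", 1),
            ("In_Frame_Del", 1),
            ("Splice_Site", 1),
            ("splice variant", 1),
            ("deletion", 1),
            ("silent", 0),
            ("Nonsense_Mutation", 0),
            ("amplification", 0),
        ],
    )
    def test_qualifying_categories(self, vclass, expected):
        records = [VariantRecord("P1", "TP53", vclass)]
        table = binarize_variants(records, ["P1"], ["TP53"])
        assert table.loc["P1", "TP53"] == expected

    def test_patient_without_records_is_wild_type(self):
        table = binarize_variants(
            [VariantRecord("P1", "TP53", "missense")], ["P1", "P2"], ["TP53", "KRAS"]
        )
        assert table.loc["P2"].sum() == 0
        assert table.loc["P1", "KRAS"] == 0

    def test_duplicate_records_are_idempotent(self):
        rec = VariantRecord("P1", "TP53", "missense")
        once = binarize_variants([rec], ["P1"], ["TP53"])
        thrice = binarize_variants([rec, rec, rec], ["P1"], ["TP53"])
        pd.testing.assert_frame_equal(once, thrice)

    def test_unknown_patient_raises_with_ids(self):
        with pytest.raises(ValueError, match="PX"):
            binarize_variants([VariantRecord("PX", "TP53", "missense")],
                              ["P1"], ["TP53"])

    def test_empty_fields_rejected(self):
        with pytest.raises(ValueError):
            VariantRecord("", "TP53", "missense")
        with pytest.raises(ValueError):
            VariantRecord("P1", " ", "missense")


class TestFrequencyGeneset:
    def test_strictly_above_threshold(self):
        # geneA in 3/20 patients (0.15), geneB in 1/20 (0.05)
        ind = pd.DataFrame(0, index=[f"P{i}" for i in range(20)],
                           columns=["geneA", "geneB"])
        ind.iloc[:3, 0] = 1
        ind.iloc[0, 1] = 1
        assert select_frequency_geneset(ind, 0.10) == ["geneA"]

    def test_boundary_is_excluded(self):
        ind = pd.DataFrame(0, index=[f"P{i}" for i in range(20)], columns=["g"])
        ind.iloc[:2, 0] = 1  # exactly 0.10
        assert select_frequency_geneset(ind, 0.10) == []

    def test_order_descending_frequency_then_alpha(self):
        ind = pd.DataFrame(0, index=[f"P{i}" for i in range(10)],
                           columns=["b", "a", "c"])
        ind.loc[:, "b"] = 1
        ind.iloc[:5, 1] = 1
        ind.iloc[:5, 2] = 1
        assert select_frequency_geneset(ind, 0.2) == ["b", "a", "c"]

    def test_invariant_to_patient_order(self):
        rng = np.random.default_rng(0)
        ind = pd.DataFrame(rng.integers(0, 2, (30, 4)),
                           index=[f"P{i}" for i in range(30)],
                           columns=list("dcba"))
        shuffled = ind.sample(frac=1, random_state=1)
        assert select_frequency_geneset(ind, 0.3) == \
            select_frequency_geneset(shuffled, 0.3)


class TestBuildFeatureTable:
    def test_age_dichotomized_at_65(self):
        spec = FeatureSpec(features=CLINICAL_FEATURES)
        clinical = _clinical([_row("P1", age=64), _row("P2", age=65)])
        table = build_feature_table(clinical, pd.DataFrame(index=["P1", "P2"]), spec)
        assert table.data.loc["P1", "age"] == "<65"
        assert table.data.loc["P2", "age"] == ">=65"

    def test_missing_smoker_kept_as_missing(self):
        spec = FeatureSpec(features=CLINICAL_FEATURES)
        clinical = _clinical([_row("P1", smoker=None)])
        table = build_feature_table(clinical, pd.DataFrame(index=["P1"]), spec)
        assert pd.isna(table.data.loc["P1", "smoker"])
        assert len(table) == 1

    def test_value_outside_domain_names_row_and_feature(self):
        spec = FeatureSpec(features=CLINICAL_FEATURES)
        clinical = _clinical([_row("P9", sex="hermaphrodite")])
        with pytest.raises(ValueError, match="P9.*sex|sex.*P9"):
            build_feature_table(clinical, pd.DataFrame(index=["P9"]), spec)

    def test_evidence_geneset_genes(self):
        spec = FeatureSpec.with_genes(EVIDENCE_GENESET, "evidence")
        assert spec.gene_names == ("KRAS", "STK11", "TP53", "EGFR", "ALK", "ROS1")
        clinical = _clinical([_row("P1")])
        ind = pd.DataFrame({"KRAS": [1]}, index=["P1"])
        table = build_feature_table(clinical, ind, spec)
        assert table.data.loc["P1", "KRAS"] == "variant"
        # genes without indicator columns default to wild type
        assert table.data.loc["P1", "ROS1"] == "wt"


class TestExclusions:
    def _table(self, rows):
        spec = FeatureSpec(features=CLINICAL_FEATURES)
        clinical = _clinical(rows)
        return build_feature_table(
            clinical, pd.DataFrame(index=clinical["patient_id"]), spec)

    def test_missing_histology_removed(self):
        rows = [_row(f"P{i}") for i in range(8)]
        rows += [_row("P8", hist=None), _row("P9", hist="NSCLC")]
        table = self._table(rows)
        assert len(apply_exclusions(table)) == 8

    def test_no_exclusions_is_identity(self):
        table = self._table([_row("P1"), _row("P2", hist="squamous")])
        out = apply_exclusions(table, excluded_histologies=set())
        assert out.patient_ids == table.patient_ids

    def test_rare_subtype_removed_by_raw_label(self):
        table = self._table(
            [_row("P1"), _row("P2", hist="large cell neuroendocrine carcinoma")])
        # the rare subtype maps to the generic 'other' level...
        assert table.data.loc["P2", "histology"] == "other"
        # ...but is still excluded by its raw label
        out = apply_exclusions(table)
        assert out.patient_ids == ["P1"]

    def test_everything_removed_is_an_error(self):
        table = self._table([_row("P1", hist="large cell neuroendocrine carcinoma")])
        with pytest.raises(ValueError):
            apply_exclusions(table)


class TestSplits:
    def _cohort(self, n, labels=None):
        rows = [_row(f"P{i}", cohort=(labels[i] if labels else "A"))
                for i in range(n)]
        spec = FeatureSpec(features=CLINICAL_FEATURES)
        clinical = _clinical(rows)
        return build_feature_table(
            clinical, pd.DataFrame(index=clinical["patient_id"]), spec)

    @given(n=st.integers(min_value=3, max_value=200), seed=st.integers(0, 2**16))
    @settings(max_examples=25, deadline=None)
    def test_two_to_one_partition_law(self, n, seed):
        cohort = self._cohort(n)
        train, test = split_train_test(cohort, seed=seed)
        assert len(test) == n // 3
        assert len(train) == n - n // 3
        assert set(train.patient_ids) | set(test.patient_ids) == set(cohort.patient_ids)
        assert not set(train.patient_ids) & set(test.patient_ids)

    def test_same_seed_same_partition(self):
        cohort = self._cohort(30)
        a = split_train_test(cohort, seed=5)
        b = split_train_test(cohort, seed=5)
        assert a[0].patient_ids == b[0].patient_ids
        assert a[1].patient_ids == b[1].patient_ids

    def test_too_small_cohort_raises(self):
        with pytest.raises(ValueError):
            split_train_test(self._cohort(2), seed=0)

    def test_split_by_cohort_routes_and_preserves_order(self):
        cohort = self._cohort(3, labels=["A", "A", "B"])
        train, ev = split_by_cohort(cohort, "A", "B")
        assert train.patient_ids == ["P0", "P1"]
        assert ev.patient_ids == ["P2"]

    def test_split_by_cohort_degenerate_and_unknown(self):
        cohort = self._cohort(3, labels=["A", "A", "B"])
        with pytest.raises(ValueError):
            split_by_cohort(cohort, "A", "A")
        with pytest.raises(ValueError):
            split_by_cohort(cohort, "A", "Z")


class TestReadersAndCurate(object):
    def test_full_curation_round(self, tmp_path):
        clinical = _clinical(
            [_row("P1", age=70, dcb="DCB"),
             _row("P2", age=50, sex="M", smoker="Current", dcb="NDB",
                  hist="Lung Squamous Cell Carcinoma"),
             _row("P3", hist="NSCLC, not otherwise specified"),
             *[_row(f"Q{i}") for i in range(7)]]
        )
        muts = pd.DataFrame(
            {
                "Tumor_Sample_Barcode": ["P1", "P1", "P2", "Q0", "Q1"],
                "Hugo_Symbol": ["TP53", "KRAS", "TP53", "TP53", "TP53"],
                "Variant_Classification": [
                    "Missense_Mutation", "Silent", "Frame_Shift_Del",
                    "Missense_Mutation", "Missense_Mutation"],
            }
        )
        cpath, mpath = tmp_path / "c.csv", tmp_path / "m.csv"
        clinical.to_csv(cpath, index=False)
        muts.to_csv(mpath, index=False)

        table = curate(read_clinical_table(cpath), read_mutation_table(mpath),
                       frequency_threshold=0.10)
        assert "P3" not in table.patient_ids  # NOS excluded
        # TP53 mutated in 4/9 kept patients > 0.10; KRAS only silent
        assert table.spec.gene_names == ("TP53",)
        assert table.data.loc["P1", "TP53"] == "variant"
        assert table.data.loc["P1", "age"] == ">=65"
        assert table.data.loc["P1", "dcb"] == "benefit"
        assert table.data.loc["P2", "dcb"] == "no_benefit"
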