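"""Filtering, median aggregation and activity labeling."""


import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dtitransfer.curation import (
    ACTIVE,
    INACTIVE,
    CurationConfig,
    aggregate_duplicates,
    apply_filters,
    curate,
    label_activity,
    pchembl_to_xc50,
)
from dtitransfer.io import ActivityRecord


def _rec(**kw):
    base = dict(compound_id="C1", smiles="CCO", target_id="T1",
                target_type="SINGLE PROTEIN", taxonomy="human",
                assay_type="binding", standard_type="IC50",
                pchembl=7.5, family="kinase")
    base.update(kw)
    return ActivityRecord(**base)


class TestApplyFilters:
    @pytest.mark.parametrize(
        "violation",
        [
            {"assay_type": "functional"},
            {"taxonomy": "rat"},
            {"target_type": "PROTEIN COMPLEX"},
            {"standard_type": "AUC"},
            {"pchembl": None},
        ],
        ids=["functional-assay", "non-human", "non-single-protein",
             "disallowed-standard-type", "missing-pchembl"],
    )
    def test_each_rule_removes_its_violator(self, violation):
        records = [_rec(), _rec(compound_id="C2", **violation)]
        kept = apply_filters(records)
        assert [r.compound_id for r in kept] == ["C1"]

    def test_empty_input(self):
        assert apply_filters([]) == []

    def test_toy_fixture_leaves_eight(self, toy_records):
        assert len(apply_filters(toy_records)) == 8

    def test_order_preserved_and_input_unmodified(self, toy_records):
        snapshot = list(toy_records)
        kept = apply_filters(toy_records)
        assert toy_records == snapshot
        ids = [id(r) for r in toy_records]
        assert all(id(r) in ids for r in kept)

    def test_functional_retention_via_config(self):
        cfg = CurationConfig(allowed_assay_types=frozenset({"binding", "functional"}))
        records = [_rec(assay_type="functional")]
        assert len(apply_filters(records, cfg)) == 1

    def test_filtering_never_changes_pchembl(self, toy_records):
        kept = apply_filters(toy_records)
        originals = {id(r): r.pchembl for r in toy_records}
        assert all(r.pchembl == originals[id(r)] for r in kept)


class TestAggregateDuplicates:
    def test_median_of_three(self):
        records = [_rec(pchembl=v) for v in (6.5, 7.2, 7.8)]
        (out,) = aggregate_duplicates(records)
        assert out.pchembl == 7.2

    def test_even_count_median_is_mean_of_middle_two(self):
        records = [_rec(pchembl=6.0), _rec(pchembl=8.0)]
        (out,) = aggregate_duplicates(records)
        assert out.pchembl == 7.0

    def test_distinct_pairs_untouched(self):
        records = [_rec(), _rec(compound_id="C2", pchembl=6.0)]
        assert aggregate_duplicates(records) == records

    def test_missing_pchembl_is_an_error(self):
        with pytest.raises(ValueError, match="pChEMBL"):
            aggregate_duplicates([_rec(pchembl=None)])

    def test_non_pchembl_fields_from_first_record(self):
        records = [_rec(standard_type="IC50", pchembl=6.0),
                   _rec(standard_type="Ki", pchembl=8.0)]
        (out,) = aggregate_duplicates(records)
        assert out.standard_type == "IC50"

    @given(values=st.lists(st.floats(min_value=1.0, max_value=13.0), min_size=1,
                           max_size=8))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_permutation_invariance(self, values):
        forward = aggregate_duplicates([_rec(pchembl=v) for v in values])
        backward = aggregate_duplicates([_rec(pchembl=v) for v in reversed(values)])
        assert forward[0].pchembl == pytest.approx(backward[0].pchembl)


class TestLabeling:
    @pytest.mark.parametrize("pchembl,threshold,expected",
                             [(8.0, 7.0, ACTIVE), (6.9, 7.0, INACTIVE),
                              (7.0, 7.0, ACTIVE)])
    def test_threshold_convention(self, pchembl, threshold, expected):
        assert label_activity(pchembl, threshold) == expected

    def test_strict_boundary_switch(self):
        assert label_activity(7.0, 7.0, active_at_threshold=False) == INACTIVE

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            label_activity(float("nan"), 7.0)

    @pytest.mark.parametrize("pchembl,nm", [(7.0, 100.0), (9.0, 1.0), (6.0, 1000.0)])
    def test_pchembl_to_xc50(self, pchembl, nm):
        assert pchembl_to_xc50(pchembl) == pytest.approx(nm)


class TestCurate:
    def test_toy_fixture_full_trace(self, toy_records):
        by_family = curate(toy_records)
        assert set(by_family) == {"kinase"}
        compounds = by_family["kinase"]
        assert len(compounds) == 7
        by_id = {c.compound_id: c for c in compounds}
        # the duplicated pair collapses to its median, labeled active at >= 7.0
        assert by_id["TOY_C1"].pchembl == 7.0
        assert by_id["TOY_C1"].label == ACTIVE
        assert by_id["TOY_C7"].label == INACTIVE  # 6.9 just below threshold

    def test_all_inactive_input(self):
        records = [_rec(compound_id=f"C{i}", pchembl=5.0) for i in range(4)]
        out = curate(records)["kinase"]
        assert all(c.label == INACTIVE for c in out)

    def test_families_partition_output(self):
        records = [_rec(), _rec(compound_id="C2", family="protease")]
        out = curate(records)
        assert {c.family for c in out["kinase"]} == {"kinase"}
        assert {c.family for c in out["protease"]} == {"protease"}

    def test_counts_monotone(self, toy_records):
        filtered = apply_filters(toy_records)
        curated = [c for fam in curate(toy_records).values() for c in fam]
        assert len(curated) <= len(filtered) <= len(toy_records)


class TestCuratedDatasetIO:
    def test_roundtrip_identity(self, tmp_path, toy_records):
        from dtitransfer.curation import read_labeled_compounds, write_labeled_compounds

        compounds = curate(toy_records)["kinase"]
        path = tmp_path / "kinase.csv"
        write_labeled_compounds(compounds, path)
        assert read_labeled_compounds(path) == compounds

    def test_missing_column_rejected(self, tmp_path):
        from dtitransfer.curation import read_labeled_compounds

        path = tmp_path / "bad.csv"
        path.write_text("compound_id,smiles\nC1,CCO\n")
        with pytest.raises(ValueError, match="label"):
            read_labeled_compounds(path)


class TestCurationConfig:
    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            CurationConfig(pchembl_threshold=0.0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            CurationConfig(allowed_assay_types=frozenset())

    def test_from_yaml_roundtrip(self, tmp_path):
        cfg_file = tmp_path / "cfg.yaml"
        cfg_file.write_text(
            "curation:\n  pchembl_threshold: 6.5\n  allowed_taxonomy: [human, rat]\n"
        )
        cfg = CurationConfig.from_yaml(cfg_file)
        assert cfg.pchembl_threshold == 6.5
        assert cfg.allowed_taxonomy == frozenset({"human", "rat"})
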