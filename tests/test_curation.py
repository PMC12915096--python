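"""Curation rules: canonicalization, labeling, dedup, filters, splits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluorscreen.curation import (
    FLUORESCENT,
    NON_FLUORESCENT,
    MoleculeRecord,
    PhotophysicalMeasurement,
    canonicalize,
    canonicalize_records,
    curate,
    deduplicate_and_resolve,
    filter_measurements,
    label_from_score,
    split_dataset,
)
from fluorscreen.errors import ConfigurationError, DomainError, InvalidStructureError


class TestCanonicalize:
    def test_equivalent_spellings_map_to_same_canonical_form(self):
        assert canonicalize("C1=CC=CC=C1") == canonicalize("c1ccccc1")

    def test_idempotent(self):
        for s in ["CCO", "c1ccncc1", "CC(=O)[O-].[Na+]"]:
            assert canonicalize(canonicalize(s)) == canonicalize(s)

    @pytest.mark.parametrize("bad", ["C1CC", "", "not smiles", None])
    def test_unparsable_input_raises_with_offender(self, bad):
        with pytest.raises(InvalidStructureError):
            canonicalize(bad)


class TestLabelFromScore:
    def test_threshold_is_inclusive(self):
        assert label_from_score(20.0) == FLUORESCENT

    @pytest.mark.parametrize("score,expected", [(0, NON_FLUORESCENT),
                                                (19.99, NON_FLUORESCENT),
                                                (100, FLUORESCENT)])
    def test_binarization(self, score, expected):
        assert label_from_score(score) == expected

    @pytest.mark.parametrize("score", [-1, 100.5])
    def test_out_of_scale_scores_rejected(self, score):
        with pytest.raises(DomainError):
            label_from_score(score)

    @given(st.floats(0, 100), st.floats(0, 100))
    @settings(max_examples=50, derandomize=True)
    def test_consistent_with_threshold(self, score, threshold):
        label = label_from_score(score, threshold)
        assert (label == FLUORESCENT) == (score >= threshold)


def _rec(smiles, label=None, condition=None, measurements=()):
    rec = MoleculeRecord(smiles, fluorescence_label=label, condition=condition,
                         measurements=list(measurements))
    rec.canonical_smiles = canonicalize(smiles)
    return rec


class TestDeduplicate:
    def test_identical_entries_merge(self):
        records = [_rec("c1ccccc1", FLUORESCENT, (400.0, 500.0)),
                   _rec("C1=CC=CC=C1", FLUORESCENT, (400.0, 500.0))]
        out, audit = deduplicate_and_resolve(records, "classification")
        assert len(out) == 1
        assert audit.counts["duplicates_merged"] == 1

    def test_conflicting_labels_remove_structure_entirely(self):
        records = [_rec("CCO", FLUORESCENT), _rec("OCC", NON_FLUORESCENT)]
        out, audit = deduplicate_and_resolve(records, "classification")
        assert out == []
        assert audit.counts["conflicting_label"] == 2

    def test_different_conditions_are_not_duplicates(self):
        records = [_rec("c1ccccc1", FLUORESCENT, (400.0, 500.0)),
                   _rec("c1ccccc1", FLUORESCENT, (450.0, 550.0))]
        out, _ = deduplicate_and_resolve(records, "classification")
        assert len(out) == 2

    def test_empty_input(self):
        out, audit = deduplicate_and_resolve([], "classification")
        assert out == [] and audit.counts["retained"] == 0

    def test_unknown_task_rejected(self):
        with pytest.raises(ConfigurationError):
            deduplicate_and_resolve([], "ranking")


def M(prop, value, solvent="O"):
    return PhotophysicalMeasurement(prop, value, solvent)


class TestFilterMeasurements:
    def test_quantum_yield_above_one_dropped(self):
        out, audit = filter_measurements([_rec("CC=O", measurements=[M("plqy", 1.2)])])
        assert out == [] and audit.counts["range_plqy"] == 1

    def test_wavelength_outside_window_dropped(self):
        _, audit = filter_measurements(
            [_rec("CCN", measurements=[M("abs_wavelength", 1600.0)])]
        )
        assert audit.counts["range_abs_wavelength"] == 1

    def test_consistent_replicates_average(self):
        out, audit = filter_measurements(
            [_rec("c1ccncc1", measurements=[M("em_wavelength", 500.0),
                                            M("em_wavelength", 503.0)])]
        )
        assert len(out) == 1
        (m,) = out[0].measurements
        assert m.value == pytest.approx(501.5)
        assert audit.counts["replicates_averaged"] == 1

    def test_inconsistent_replicate_pair_fully_dropped(self):
        # median is 510; both points deviate by 10 > 5 nm tolerance
        out, audit = filter_measurements(
            [_rec("CCOCC", measurements=[M("em_wavelength", 500.0),
                                         M("em_wavelength", 520.0)])]
        )
        assert out == []
        assert audit.counts["replicate_inconsistency"] == 2

    def test_missing_and_gaseous_solvents_excluded(self):
        _, audit = filter_measurements(
            [_rec("CCN", measurements=[M("em_wavelength", 450.0, None)]),
             _rec("CCC", measurements=[M("em_wavelength", 450.0, "gas")])]
        )
        assert audit.counts["missing_or_gaseous_solvent"] == 2

    def test_unknown_property_in_tolerances_rejected(self):
        with pytest.raises(ConfigurationError):
            filter_measurements([], tolerances={"brightness": 1.0})

    def test_idempotent_on_own_output(self):
        records = [_rec("c1ccncc1", measurements=[M("em_wavelength", 500.0),
                                                  M("em_wavelength", 503.0)]),
                   _rec("c1ccccc1", FLUORESCENT)]
        once, _ = filter_measurements(records)
        twice, audit = filter_measurements(once)
        assert [r.canonical_smiles for r in twice] == [r.canonical_smiles for r in once]
        assert [m for r in twice for m in r.measurements] == \
               [m for r in once for m in r.measurements]
        assert audit.counts.get("replicate_inconsistency", 0) == 0


class TestCurationFixture:
    def test_fixture_survivors_and_audit_counts(self, curation_fixture_records):
        out, audits = curate(curation_fixture_records, task="classification")
        survivors = {r.canonical_smiles for r in out}
        assert survivors == {canonicalize("c1ccccc1"), canonicalize("c1ccncc1")}
        pyridine = next(r for r in out if r.canonical_smiles == canonicalize("c1ccncc1"))
        assert [m.value for m in pyridine.measurements] == [pytest.approx(501.5)]

        a_canon, a_dedup, a_filter = audits
        assert a_canon.counts == {"invalid_smiles": 1, "retained": 11}
        assert a_dedup.counts == {"conflicting_label": 2, "duplicates_merged": 3,
                                  "retained": 6}
        assert a_filter.counts == {
            "missing_or_gaseous_solvent": 2, "range_plqy": 1,
            "range_abs_wavelength": 1, "range_log10_eps": 1,
            "replicate_inconsistency": 2, "replicates_averaged": 1, "retained": 1,
        }

    def test_audit_counts_conserve_inputs(self, curation_fixture_records):
        _, audits = curate(curation_fixture_records, task="classification")
        for audit in audits:
            dropped = sum(v for k, v in audit.counts.items()
                          if k not in ("retained", "replicates_averaged"))
            merged = audit.counts.get("replicates_averaged", 0)
            # conservation: every input is dropped, merged away, or retained
            assert dropped + merged + audit.counts["retained"] == audit.n_input

    def test_order_invariance(self, curation_fixture_records):
        out1, _ = curate(list(curation_fixture_records), task="classification")
        out2, _ = curate(list(reversed(curation_fixture_records)),
                         task="classification")
        assert {r.canonical_smiles for r in out1} == {r.canonical_smiles for r in out2}

    def test_rerunning_curation_changes_nothing(self, curation_fixture_records):
        out1, _ = curate(curation_fixture_records, task="classification")
        out2, audits = curate(out1, task="classification")
        assert {r.canonical_smiles for r in out2} == {r.canonical_smiles for r in out1}
        assert audits[1].counts.get("duplicates_merged", 0) == 0


class TestSplit:
    def test_7_1_2_sizes_at_n_100(self):
        records = list(range(100))
        train, val, test = split_dataset(records, seed=0)
        assert (len(train), len(val), len(test)) == (70, 10, 20)

    def test_partition_is_exhaustive_and_disjoint(self):
        records = list(range(103))
        train, val, test = split_dataset(records, seed=5)
        assert sorted(train + val + test) == records
        assert len(train) == 103 - 10 - 20  # remainder goes to train

    def test_deterministic_per_seed(self):
        records = list(range(50))
        assert split_dataset(records, seed=3) == split_dataset(records, seed=3)
        assert split_dataset(records, seed=3) != split_dataset(records, seed=4)

    def test_degenerate_all_train(self):
        train, val, test = split_dataset(list(range(10)), ratios=(1, 0, 0), seed=0)
        assert len(train) == 10 and not val and not test

    @pytest.mark.parametrize("ratios", [(-0.1, 0.6, 0.5), (0.5, 0.2, 0.2)])
    def test_invalid_ratios_rejected(self, ratios):
        with pytest.raises(DomainError):
            split_dataset(list(range(10)), ratios=ratios, seed=0)


def test_score_derived_labels_applied_during_canonicalization():
    records = [MoleculeRecord("CCO", activity_score=55.0),
               MoleculeRecord("CCC", activity_score=5.0)]
    out, _ = canonicalize_records(records)
    assert out[0].fluorescence_label == FLUORESCENT
    assert out[1].fluorescence_label == NON_FLUORESCENT
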