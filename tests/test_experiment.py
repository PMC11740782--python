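"""Study orchestration: combination table, splitting, assembly, reports."""

import numpy as np
import pytest

from usexpand import (COMBINATIONS, CohortManifest, ExperimentConfig, ImageRecord,
                      assemble_combination, patient_split, report_tables)
from usexpand.experiment import StudyReport, _jsonable


class TestCombinationTable:
    def test_sixteen_combinations_in_two_augmentation_blocks(self):
        assert set(COMBINATIONS) == set(range(1, 17))
        for i in range(1, 9):
            assert not COMBINATIONS[i].augmented
            assert COMBINATIONS[i + 8].augmented
            assert COMBINATIONS[i].components == COMBINATIONS[i + 8].components

    def test_specific_entries(self):
        assert COMBINATIONS[1].components == frozenset({"pocus"})
        assert COMBINATIONS[6].components == frozenset({"pocus", "cyclegan3"})
        assert COMBINATIONS[7].components == frozenset({"pocus", "standard", "cyclegan1"})
        assert COMBINATIONS[16].components == frozenset({"pocus", "standard", "cyclegan3"})
        assert COMBINATIONS[16].augmented

    def test_expansions_are_exclusive_within_a_combination(self):
        exclusive = {"hist_match", "hist_eq", "cyclegan1", "cyclegan3"}
        for spec in COMBINATIONS.values():
            assert len(spec.components & exclusive) <= 1


def _manifest(n, domain, prefix, imgs_per_patient=2):
    recs = []
    for i in range(n):
        pid = f"{prefix}{i // imgs_per_patient}"
        recs.append(ImageRecord(np.zeros((8, 8), dtype=np.uint8), "normal",
                                domain, pid))
    return CohortManifest(recs)


class TestPatientSplit:
    def test_patients_never_span_both_sides(self):
        m = _manifest(40, "pocus", "p")
        split = patient_split(m, 0.4, seed=1)
        train = {r.patient_id for r in split.subset("train")}
        test = {r.patient_id for r in split.subset("test")}
        assert train and test and not (train & test)

    def test_same_seed_identical_split(self):
        m = _manifest(40, "pocus", "p")
        assert patient_split(m, 0.4, seed=2).split == patient_split(m, 0.4, seed=2).split

    def test_realized_fraction_near_request(self):
        m = _manifest(120, "pocus", "p", imgs_per_patient=3)
        split = patient_split(m, 0.4, seed=3)
        frac = len(split.subset("test")) / len(m)
        assert abs(frac - 0.4) <= 0.1

    def test_single_patient_rejected(self):
        m = _manifest(3, "pocus", "p", imgs_per_patient=3)
        with pytest.raises(ValueError, match="2 patients"):
            patient_split(m, 0.5, seed=0)


class TestAssembleCombination:
    def test_size_arithmetic_at_any_scale(self):
        n_p, n_s = 13, 21
        pocus = _manifest(n_p, "pocus", "p")
        expanded = {
            "standard": _manifest(n_s, "standard", "s"),
            "hist_match": _manifest(n_s, "standard", "s"),
            "hist_eq": _manifest(n_s, "standard", "s"),
            "cyclegan1": _manifest(n_s, "translated", "s"),
            "cyclegan3": _manifest(n_s, "translated", "s"),
        }
        for cid, expect in [(1, n_p), (2, n_p + n_s), (3, n_p + n_s), (4, n_p + n_s),
                            (5, n_p + n_s), (6, n_p + n_s), (7, n_p + 2 * n_s),
                            (8, n_p + 2 * n_s)]:
            assert len(assemble_combination(COMBINATIONS[cid], pocus, expanded)) == expect
            assert len(assemble_combination(COMBINATIONS[cid + 8], pocus, expanded)) == expect

    def test_union_contains_both_sources_without_duplicates(self):
        pocus = _manifest(4, "pocus", "p")
        std = _manifest(6, "standard", "s")
        out = assemble_combination(COMBINATIONS[2], pocus, {"standard": std})
        assert out.records[:4] == pocus.records
        assert out.records[4:] == std.records

    def test_missing_component_rejected(self):
        pocus = _manifest(4, "pocus", "p")
        with pytest.raises(ValueError, match="cyclegan1"):
            assemble_combination(COMBINATIONS[5], pocus, {})


class TestReportSerialization:
    def _report(self):
        return StudyReport(
            config={"seed": 0},
            metrics={1: {"acc": 0.5, "acc_ci": (0.4, 0.6), "auc": 0.7,
                         "auc_ci": (0.6, 0.8), "sens": 0.9, "sens_ci": (0.8, 1.0),
                         "spec": 0.3, "spec_ci": (0.2, 0.4), "threshold": 0.5,
                         "youden_j": 0.2, "label": "P", "n_train": 10}},
            significance={"ids": [1, 2], "stars": [["ns", "*"], ["*", "ns"]],
                          "raw_p": [[1.0, 0.01], [0.01, 1.0]],
                          "adjusted_p": [[1.0, 0.02], [0.02, 1.0]], "alpha": 0.05},
            fid_table={"standard": 1.5}, histories={}, leakage_audit={"passed": True})

    def test_json_roundtrip_preserves_content(self, tmp_path):
        rep = self._report()
        rep.to_json(tmp_path / "r.json")
        back = StudyReport.from_json(tmp_path / "r.json")
        assert back.fid_table == {"standard": 1.5}
        assert back.significance["stars"] == rep.significance["stars"]
        assert _jsonable(rep.metrics[1]) == back.metrics["1"]

    def test_tables_have_expected_columns(self, tmp_path):
        import pandas as pd
        paths = report_tables(self._report(), tmp_path)
        acc = pd.read_csv(paths["metrics"])
        assert list(acc.columns) == ["combination", "acc", "acc_ci_lo", "acc_ci_hi",
                                     "auc", "auc_ci_lo", "auc_ci_hi"]
        ss = pd.read_csv(paths["sens_spec"])
        assert list(ss.columns) == ["combination", "sens", "sens_ci_lo", "sens_ci_hi",
                                    "spec", "spec_ci_lo", "spec_ci_hi"]
        stars = pd.read_csv(paths["significance"], index_col=0)
        assert set(np.unique(stars.values)) <= {"ns", "*", "**"}


class TestExperimentConfigPresets:
    def test_desk_preset_determines_sizes(self):
        cfg = ExperimentConfig(scale="desk")
        assert cfg.phantom_config().image_side == 32
        assert cfg.cnn_spec().input_side == 32
        assert cfg.cyclegan_config(0).image_side == 32
        paper = ExperimentConfig(scale="paper")
        assert paper.cnn_spec().input_side == 180
        assert paper.cyclegan_config(0).epochs == 200

    def test_unknown_combination_rejected(self):
        cfg = ExperimentConfig(combinations=(1, 99))
        from usexpand import run_study
        with pytest.raises(ValueError, match="99"):
            run_study(cfg)
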