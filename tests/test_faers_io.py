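"""Ingestion, assembly and deduplication of FAERS-style quarterly tables."""

import pandas as pd
import pytest

from renalpv.faers_io import (
    RawQuarter,
    ReferentialIntegrityError,
    ReportDataset,
    assemble_reports,
    deduplicate,
    read_quarter,
    write_quarter,
)
from renalpv.synthetic_data import GeneratorConfig, generate

from conftest import make_quarter


def _write(quarter, tmp_path):
    return write_quarter(quarter, tmp_path)


class TestReadQuarter:
    def test_identity_parse_of_fixture(self, tiny_quarter, tmp_path):
        paths = _write(tiny_quarter, tmp_path)
        quarter = read_quarter(paths)
        assert len(quarter.demo) == 3
        assert len(quarter.drug) == 4
        assert len(quarter.reac) == 5
        assert len(quarter.outc) == 3
        assert quarter.parse_stats["demo_unparseable"] == 0

    def test_orphan_child_row_is_fatal_and_named(self, tiny_quarter, tmp_path):
        tiny_quarter.drug.loc[len(tiny_quarter.drug)] = ["99", "1", "aspirin", "C"]
        paths = _write(tiny_quarter, tmp_path)
        with pytest.raises(ReferentialIntegrityError, match="99"):
            read_quarter(paths)

    def test_missing_file_is_fatal(self, tiny_quarter, tmp_path):
        paths = _write(tiny_quarter, tmp_path)
        paths["reac"].unlink()
        with pytest.raises(FileNotFoundError):
            read_quarter(paths)

    def test_missing_mandatory_column_is_fatal_with_name(self, tiny_quarter, tmp_path):
        tiny_quarter.drug = tiny_quarter.drug.drop(columns=["drugname"])
        paths = _write(tiny_quarter, tmp_path)
        with pytest.raises(ValueError, match="drugname"):
            read_quarter(paths)

    def test_synthetic_round_trip_preserves_row_multisets(self, tmp_path):
        quarter, _ = generate(GeneratorConfig(n_reports=300), seed=5)
        paths = _write(quarter, tmp_path)
        back = read_quarter(paths)
        for name in ("demo", "drug", "reac", "outc"):
            left = quarter.table(name).astype(str).sort_values(
                list(quarter.table(name).columns)).reset_index(drop=True)
            right = back.table(name)[left.columns].astype(str).sort_values(
                list(left.columns)).reset_index(drop=True)
            pd.testing.assert_frame_equal(left, right)


class TestAssembleReports:
    def test_multi_drug_multi_pt_report(self, tiny_quarter):
        dataset = assemble_reports(tiny_quarter)
        report = {r.report_id: r for r in dataset.to_reports()}["11"]
        assert len(report.drugs) == 2
        assert len(report.reactions) == 3
        assert report.outcomes == {"DE", "HO"}
        assert report.sex == "male"
        assert report.age_years == 63
        assert report.event_year == 2018
        assert report.country == "US"

    def test_age_unit_conversion(self, tiny_quarter):
        dataset = assemble_reports(tiny_quarter)
        report = {r.report_id: r for r in dataset.to_reports()}["21"]
        assert report.age_years == pytest.approx(60.0)  # 720 months

    def test_unconvertible_age_becomes_missing(self, tiny_quarter):
        tiny_quarter.demo.loc[0, "age_cod"] = "LIGHTYEARS"
        report = {r.report_id: r for r in assemble_reports(tiny_quarter).to_reports()}["11"]
        assert report.age_years is None

    def test_report_without_reactions_excluded_and_counted(self):
        quarter = make_quarter(
            demo_rows=[{"primaryid": "1", "caseid": "1"}, {"primaryid": "2", "caseid": "2"}],
            drug_rows=[{"primaryid": "1", "drugname": "aspirin"},
                       {"primaryid": "2", "drugname": "aspirin"}],
            reac_rows=[{"primaryid": "1", "pt": "Nausea"}],
            outc_rows=[],
        )
        dataset = assemble_reports(quarter)
        assert len(dataset) == 1
        assert dataset.meta["excluded_no_reaction"] == 1
        assert dataset.meta["excluded_no_drug"] == 0

    def test_planted_drug_name_missingness_count(self):
        config = GeneratorConfig(n_reports=1000, drug_missing_rate=0.05, duplicate_rate=0.0)
        quarter, truth = generate(config, seed=11)
        dataset = assemble_reports(quarter)
        assert len(truth.missing_drug_case_ids) == 50
        assert dataset.meta["excluded_no_drug"] == 50
        assert len(dataset) == 950

    def test_assembly_is_deterministic(self, tiny_quarter):
        a = assemble_reports(tiny_quarter)
        b = assemble_reports(tiny_quarter)
        pd.testing.assert_frame_equal(a.index, b.index)
        pd.testing.assert_frame_equal(a.drugs, b.drugs)


class TestDeduplicate:
    def test_highest_case_version_retained(self, tiny_quarter):
        dataset = deduplicate(assemble_reports(tiny_quarter))
        ids = set(dataset.report_ids)
        assert "22" in ids and "21" not in ids
        assert dataset.meta["dropped_duplicate_cases"] == 1

    def test_repeated_drug_and_pt_collapse_to_sets(self):
        quarter = make_quarter(
            demo_rows=[{"primaryid": "1", "caseid": "1"}],
            drug_rows=[{"primaryid": "1", "drugname": "OPDIVO"},
                       {"primaryid": "1", "drugname": "OPDIVO"}],
            reac_rows=[{"primaryid": "1", "pt": "Nephritis"},
                       {"primaryid": "1", "pt": "Nephritis"}],
            outc_rows=[],
        )
        report = deduplicate(assemble_reports(quarter)).to_reports()[0]
        assert report.drugs == {"OPDIVO"}
        assert report.reactions == {"Nephritis"}

    def test_planted_duplicates_removed_exactly(self):
        config = GeneratorConfig(n_reports=2000, duplicate_rate=0.05, drug_missing_rate=0.0)
        quarter, truth = generate(config, seed=3)
        dataset = deduplicate(assemble_reports(quarter))
        assert len(dataset) == truth.n_unique_cases
        # the retained version of each duplicated case is version 2
        dup_versions = dataset.index.loc[
            dataset.index["case_id"].isin(truth.duplicate_case_ids), "case_version"
        ]
        assert (dup_versions == 2).all()

    def test_idempotent(self):
        quarter, _ = generate(GeneratorConfig(n_reports=1500), seed=9)
        once = deduplicate(assemble_reports(quarter))
        twice = deduplicate(once)
        assert len(once) == len(twice)
        pd.testing.assert_frame_equal(
            once.drugs.reset_index(drop=True), twice.drugs.reset_index(drop=True)
        )

    def test_input_not_mutated(self, tiny_quarter):
        dataset = assemble_reports(tiny_quarter)
        before = dataset.index.copy()
        deduplicate(dataset)
        pd.testing.assert_frame_equal(dataset.index, before)


class TestReportDataset:
    def test_round_trip_through_report_records(self, tiny_quarter):
        dataset = deduplicate(assemble_reports(tiny_quarter))
        back = ReportDataset.from_reports(dataset.to_reports())
        assert set(back.report_ids) == set(dataset.report_ids)
        left = {r.report_id: (r.drugs, r.reactions, r.outcomes) for r in dataset.to_reports()}
        right = {r.report_id: (r.drugs, r.reactions, r.outcomes) for r in back.to_reports()}
        assert left == right

    def test_masks(self, tiny_quarter):
        dataset = assemble_reports(tiny_quarter)
        assert dataset.event_mask(["ACUTE KIDNEY INJURY"]).sum() == 1
        assert dataset.drug_mask(["OPDIVO"]).sum() == 1
        assert dataset.outcome_mask("DE").sum() == 1
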