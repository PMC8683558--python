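"""The synthetic reporting-process generator and its ground truth."""

import numpy as np
import pandas as pd
import pytest

from renalpv.disproportionality import ContingencyTable, ror_classical
from renalpv.synthetic_data import (
    GeneratorConfig,
    PlantedAssociation,
    generate,
    generate_files,
    simulate_contingency,
    table2_fixture,
)


def _quarter_contingency(quarter, drugs, pt):
    """Contingency directly from raw tables (no-duplicate, no-missingness runs)."""
    ids = quarter.demo["primaryid"]
    drug_ids = set(ids)
    target = None
    for d in drugs:
        with_d = set(quarter.drug.loc[quarter.drug["drugname"] == d.upper(), "primaryid"])
        target = with_d if target is None else target & with_d
    event = set(quarter.reac.loc[quarter.reac["pt"] == pt, "primaryid"])
    a = len(target & event)
    b = len(target - event)
    c = len(event - target)
    d_ = len(drug_ids - target - event)
    return ContingencyTable(a, b, c, d_)


class TestGenerate:
    def test_reproducible_byte_for_byte(self, tmp_path):
        config = GeneratorConfig(n_reports=500)
        p1, _ = generate_files(config, tmp_path / "a", seed=42)
        p2, _ = generate_files(config, tmp_path / "b", seed=42)
        for table in p1:
            assert p1[table].read_bytes() == p2[table].read_bytes()

    def test_different_seeds_differ(self):
        config = GeneratorConfig(n_reports=500)
        q1, _ = generate(config, seed=1)
        q2, _ = generate(config, seed=2)
        assert not q1.reac.equals(q2.reac)

    def test_marginal_fidelity(self):
        # realized frequencies of unperturbed drugs and renal events stay
        # within 3 binomial SE of their configured probabilities
        config = GeneratorConfig(n_reports=20_000, duplicate_rate=0.0, drug_missing_rate=0.0)
        quarter, truth = generate(config, seed=13)
        n = config.n_reports
        perturbed = {"ipilimumab", "tremelimumab"}  # co-prescription targets
        chemo = set(config.chemo_drugs)
        for name, p in config.drug_probs.items():
            if name in perturbed or name in chemo:
                continue
            se = np.sqrt(p * (1 - p) / n)
            assert abs(truth.drug_counts[name] / n - p) < 3 * se + 1e-9, name
        for pt in config.renal_pts:
            p = config.event_probs[pt]
            se = np.sqrt(p * (1 - p) / n)
            assert abs(truth.event_counts[pt] / n - p) < 3 * se + 1e-9, pt

    def test_every_report_has_a_drug_row_and_reaction(self):
        config = GeneratorConfig(n_reports=1000, drug_missing_rate=0.0,
                                 duplicate_rate=0.0)
        quarter, _ = generate(config, seed=7)
        ids = set(quarter.demo["primaryid"])
        assert set(quarter.drug.loc[quarter.drug["drugname"] != "", "primaryid"]) == ids
        assert set(quarter.reac["primaryid"]) == ids

    def test_probability_truncation_is_counted(self):
        config = GeneratorConfig(
            n_reports=500,
            planted=(PlantedAssociation(frozenset({"nivolumab"}), "Acute kidney injury", 1000.0),),
        )
        _, truth = generate(config, seed=3)
        assert truth.n_truncated_probabilities > 0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            generate(GeneratorConfig(n_reports=0), seed=1)
        with pytest.raises(ValueError):
            generate(GeneratorConfig(duplicate_rate=1.5), seed=1)
        with pytest.raises(ValueError):
            PlantedAssociation(frozenset({"x"}), "Y", -1.0)

    def test_ground_truth_serializes(self, tmp_path):
        _, truth = generate_files(GeneratorConfig(n_reports=200), tmp_path, seed=1)
        import json

        data = json.loads((tmp_path / "ground_truth.json").read_text())
        assert data["n_unique_cases"] == 200


class TestNullCalibration:
    def test_ror_centers_on_one_without_planted_associations(self):
        # theta = 1 everywhere: the mean log ROR over replicates is within
        # 3 standard errors of 0
        config = GeneratorConfig(
            n_reports=10_000,
            drug_probs={"drugA": 0.08, "drugB": 0.10, "drugC": 0.12},
            event_probs={"Acute kidney injury": 0.03, "Nausea": 0.25, "Fatigue": 0.25},
            co_prescription=(), chemo_drugs=(), ici_drugs=(),
            duplicate_rate=0.0, drug_missing_rate=0.0,
        )
        log_rors = []
        for seed in range(500):
            quarter, _ = generate(config, seed=seed)
            t = _quarter_contingency(quarter, ["drugA"], "Acute kidney injury")
            log_rors.append(np.log(ror_classical(t).ror))
        mean, se = np.mean(log_rors), np.std(log_rors, ddof=1) / np.sqrt(len(log_rors))
        assert abs(mean) < 3 * se


class TestSimulateContingency:
    def test_margins_fixed_by_design(self):
        rng = np.random.default_rng(0)
        t = simulate_contingency(1000, 9000, 0.02, 2.0, rng)
        assert t.n_drug == 1000
        assert t.c + t.d == 9000


class TestTable2Fixture:
    def test_all_fixtures_satisfy_invariants(self):
        for label, t in table2_fixture().items():
            assert min(t.a, t.b, t.c, t.d) >= 0, label
            assert t.n_total == t.a + t.b + t.c + t.d
            assert t.expected > 0

    def test_key_rows(self):
        fx = table2_fixture()
        assert (fx["Total"].a, fx["Total"].b, fx["Total"].c, fx["Total"].d) == (
            4578, 138168, 1104288, 29367235)
        assert (fx["Atezolizumab"].a, fx["Atezolizumab"].b) == (337, 5861)

    def test_regimen_rows_near_the_database_total(self):
        # every regimen-vs-rest row spans (almost exactly) the whole database;
        # the published cells carry small internal inconsistencies, so exact
        # equality across rows is not expected
        fx = table2_fixture()
        for label, t in fx.items():
            if "vs" in label:
                continue
            assert t.n_total == pytest.approx(30_602_758, rel=5e-4), label
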