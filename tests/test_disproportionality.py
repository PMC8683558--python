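"""The 2x2 statistics core: ROR, IC, signal rule, comparative ROR."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from renalpv.disproportionality import (
    ContingencyTable,
    SignalEstimate,
    build_contingency,
    classify_signal,
    comparative_ror,
    estimate_signal,
    ic,
    ror_classical,
    ror_shrunken,
)
from renalpv.faers_io import ReportDataset, SafetyReport, assemble_reports, deduplicate
from renalpv.synthetic_data import GeneratorConfig, generate
from renalpv.vocabulary import builtin_ici_vocabulary, normalize_dataset

cells = st.integers(min_value=1, max_value=500)


class TestContingencyTable:
    def test_derived_margins(self):
        t = ContingencyTable(3, 7, 9, 81)
        assert (t.n_drug, t.n_event, t.n_total) == (10, 12, 100)
        assert t.expected == pytest.approx(1.2)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)

    def test_empty_table_expected_zero(self):
        assert ContingencyTable(0, 0, 0, 0).expected == 0.0


class TestBuildContingency:
    def test_simple_counts(self):
        reports = (
            [SafetyReport(f"t{i}", f"t{i}", frozenset({"drugA"}),
                          frozenset({"Nephritis"} if i < 3 else {"Nausea"})) for i in range(10)]
            + [SafetyReport(f"c{i}", f"c{i}", frozenset({"drugB"}),
                            frozenset({"Nephritis"} if i < 9 else {"Nausea"})) for i in range(90)]
        )
        dataset = ReportDataset.from_reports(reports)
        t = build_contingency(dataset, dataset.drug_mask(["drugA"]), ["Nephritis"])
        assert (t.a, t.b, t.c, t.d) == (3, 7, 9, 81)

    def test_event_never_observed(self):
        reports = [SafetyReport("1", "1", frozenset({"drugA"}), frozenset({"Nausea"})),
                   SafetyReport("2", "2", frozenset({"drugB"}), frozenset({"Nausea"}))]
        dataset = ReportDataset.from_reports(reports)
        t = build_contingency(dataset, ["1"], ["Nephritis"])
        assert t.a == 0 and t.c == 0

    def test_overlapping_groups_fatal(self):
        reports = [SafetyReport("1", "1", frozenset({"d"}), frozenset({"E"}))]
        dataset = ReportDataset.from_reports(reports)
        with pytest.raises(ValueError, match="overlap"):
            build_contingency(dataset, ["1"], ["E"], comparator=["1"])

    def test_matches_brute_force_recount(self, vocab, renal_dict):
        quarter, _ = generate(GeneratorConfig(n_reports=2000), seed=31)
        dataset = normalize_dataset(deduplicate(assemble_reports(quarter)), vocab)
        t = build_contingency(dataset, dataset.drug_mask(["nivolumab"]),
                              renal_dict.normalized_pts)
        a = b = c = d = 0
        for r in dataset.to_reports():
            target = "nivolumab" in r.drugs
            event = any(pt.upper().strip() in renal_dict.normalized_pts for pt in r.reactions)
            a += target and event
            b += target and not event
            c += (not target) and event
            d += (not target) and not event
        assert (t.a, t.b, t.c, t.d) == (a, b, c, d)
        assert t.a + t.b + t.c + t.d == len(dataset)


class TestRorClassical:
    def test_symmetric_table_is_exactly_one(self):
        for k in (1, 5, 250):
            assert ror_classical(ContingencyTable(k, k, k, k)).ror == pytest.approx(1.0)

    def test_zero_cell_triggers_continuity_correction(self):
        r = ror_classical(ContingencyTable(0, 10, 5, 85))
        assert r.continuity_corrected
        assert np.isfinite(r.ror) and r.ror > 0

    def test_agrees_with_statsmodels_on_small_tables(self):
        # independent oracle: statsmodels' log-normal odds-ratio interval
        import statsmodels.api as sm

        for a, b, c, d in itertools.product(range(1, 7), repeat=4):
            ours = ror_classical(ContingencyTable(a, b, c, d))
            oracle = sm.stats.Table2x2(np.array([[a, b], [c, d]]), shift_zeros=False)
            lo, hi = oracle.oddsratio_confint(0.05)
            assert ours.ror == pytest.approx(oracle.oddsratio, rel=1e-12)
            assert ours.ror_025 == pytest.approx(lo, rel=1e-12)
            assert ours.ror_975 == pytest.approx(hi, rel=1e-12)

    @given(cells, cells, cells, cells)
    def test_swap_symmetry(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        fwd, rev = ror_classical(t), ror_classical(t.swapped())
        assert rev.ror == pytest.approx(1 / fwd.ror)
        assert np.log(rev.ror_025) == pytest.approx(-np.log(fwd.ror_975), abs=1e-9)
        assert np.log(rev.ror_975) == pytest.approx(-np.log(fwd.ror_025), abs=1e-9)

    @given(cells, cells, cells)
    def test_ror_monotone_in_observed_count(self, b, c, d):
        rors = [ror_classical(ContingencyTable(a, b, c, d)).ror for a in (1, 5, 25)]
        assert rors[0] < rors[1] < rors[2]

    @given(cells, cells)
    def test_ic_monotone_in_observed_count_sparse_regime(self, b, c):
        # in the pharmacovigilance regime (a small against a huge database)
        # the shrunken O/E, hence the IC, strictly increases with a
        ics = [ic(ContingencyTable(a, b, c, 1_000_000)).ic for a in (1, 5, 25)]
        assert ics[0] < ics[1] < ics[2]

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            ror_classical(ContingencyTable(1, 1, 1, 1), alpha=1.2)


class TestShrunkenEstimators:
    def test_empty_table_is_exactly_one(self):
        assert ror_shrunken(ContingencyTable(0, 0, 0, 0)) == 1.0

    def test_observed_equal_expected_is_one(self):
        # a = expected for the symmetric table
        assert ror_shrunken(ContingencyTable(5, 5, 5, 5)) == pytest.approx(1.0)

    def test_shrinkage_pulls_toward_one(self):
        # tiny counts: shrunken ratio closer to 1 than the raw O/E ratio
        t = ContingencyTable(2, 8, 10, 980)
        raw = t.a / t.expected
        assert 1 < ror_shrunken(t) < raw

    def test_ic_zero_for_empty_table(self):
        assert ic(ContingencyTable(0, 0, 0, 0)).ic == 0.0

    def test_ic_bounds_bracket_center(self):
        r = ic(ContingencyTable(40, 1000, 2000, 100000))
        assert r.ic_025 < r.ic < r.ic_975


class TestSignalRule:
    def test_strong_lower_bounds_flag_signal(self):
        est = estimate_signal(ContingencyTable(337, 5861, 1108529, 29488088))
        assert est.eligible and est.is_signal

    def test_below_min_reports_is_ineligible(self):
        est = classify_signal(
            SignalEstimate(ror=9.0, ror_025=5.0, ror_975=12.0, ic=1.0, ic_025=0.5,
                           ic_975=2.0, n_observed=2)
        )
        assert not est.eligible and not est.is_signal

    def test_weak_bounds_not_signal(self):
        est = classify_signal(
            SignalEstimate(ror=1.0, ror_025=0.9, ror_975=1.2, ic=0.0, ic_025=-0.1,
                           ic_975=0.1, n_observed=100)
        )
        assert est.eligible and not est.is_signal

    def test_threshold_ties_are_not_signals(self):
        est = classify_signal(
            SignalEstimate(ror=1.5, ror_025=1.0, ror_975=2.0, ic=0.2, ic_025=0.0,
                           ic_975=0.4, n_observed=50)
        )
        assert not est.is_signal

    def test_either_criterion_suffices(self):
        by_ror = classify_signal(SignalEstimate(2.0, 1.1, 3.0, 0.1, -0.1, 0.3, 10))
        by_ic = classify_signal(SignalEstimate(1.4, 0.9, 2.0, 0.5, 0.1, 0.9, 10))
        assert by_ror.is_signal and by_ic.is_signal


class TestComparativeRor:
    def test_exchangeable_groups_give_unit_ror(self):
        reports = []
        for g in ("x", "y"):
            for i in range(50):
                reports.append(SafetyReport(
                    f"{g}{i}", f"{g}{i}", frozenset({g}),
                    frozenset({"Nephritis"} if i < 10 else {"Nausea"})))
        dataset = ReportDataset.from_reports(reports)
        r = comparative_ror(dataset, dataset.drug_mask(["x"]), dataset.drug_mask(["y"]),
                            ["Nephritis"])
        assert r.ror == pytest.approx(1.0)
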