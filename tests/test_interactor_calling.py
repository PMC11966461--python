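"""NSAF arithmetic, criterion boundaries, oracle equivalence of the filter,
and the partner-table headline counts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neurointeract.interactor_calling import (
    call_interactors,
    compute_nsaf,
    count_summary,
    criterion1_control_clean,
    criterion2_test_supported,
    criterion3_nsaf_enriched,
)

from conftest import BAIT_CONDITIONS, CONTROL_CONDITIONS, make_table, random_table

APC_SET = {"CDC27", "ANAPC4", "CDC23", "CDC16", "ANAPC7"}


# ---------------------------------------------------------------- NSAF

class TestNsaf:
    def test_single_protein_normalizes_to_one(self):
        table = make_table({"AAA": {"Cter": [2, 3, 1]}}, {"AAA": 500},
                           conditions=["Cter"])
        nsaf = compute_nsaf(table)
        assert nsaf.loc["P000", "Cter"] == pytest.approx(1.0)

    def test_equal_counts_equal_lengths_split_evenly(self):
        table = make_table(
            {"AAA": {"Cter": [2, 2, 2]}, "BBB": {"Cter": [2, 2, 2]}},
            {"AAA": 300, "BBB": 300}, conditions=["Cter"],
        )
        nsaf = compute_nsaf(table)
        assert list(nsaf["Cter"]) == pytest.approx([0.5, 0.5])

    def test_three_protein_hand_oracle(self):
        # counts 10, 5, 5 over lengths 100, 100, 200: SAF 0.1, 0.05, 0.025
        # normalized by 0.175 -> 4/7, 2/7, 1/7
        table = make_table(
            {"AAA": {"Cter": [4, 3, 3]}, "BBB": {"Cter": [2, 2, 1]},
             "CCC": {"Cter": [1, 2, 2]}},
            {"AAA": 100, "BBB": 100, "CCC": 200}, conditions=["Cter"],
        )
        nsaf = compute_nsaf(table)
        assert list(nsaf["Cter"]) == pytest.approx([4 / 7, 2 / 7, 1 / 7])

    def test_normalization_sums_to_one_on_random_tables(self, rng):
        for _ in range(20):
            table = random_table(rng, int(rng.integers(2, 15)))
            nsaf = compute_nsaf(table)
            sums = nsaf.sum(axis=0)
            nonzero = table.condition_sums().sum(axis=0) > 0
            for cond in table.conditions:
                if nonzero[cond]:
                    assert abs(sums[cond] - 1.0) < 1e-9

    def test_all_zero_scope_flagged_and_zero(self, recwarn):
        table = make_table(
            {"AAA": {"Cter": [1, 1, 1], "Beads": [0, 0, 0]}},
            {"AAA": 100}, conditions=["Cter", "Beads"],
        )
        with pytest.warns(UserWarning, match="all-zero"):
            nsaf = compute_nsaf(table)
        assert nsaf.loc["P000", "Beads"] == 0.0

    def test_per_run_scope_normalizes_each_injection(self, rng):
        table = random_table(rng, 8)
        nsaf = compute_nsaf(table, scope="run")
        for col in nsaf.columns:
            colsum = nsaf[col].sum()
            assert colsum == pytest.approx(1.0, abs=1e-9) or colsum == 0.0


# ---------------------------------------------------------------- criteria

class TestCriteria:
    def test_all_zero_controls_clean(self):
        assert criterion1_control_clean({"Beads": 0, "MAR": 0, "RAM": 0})

    def test_control_sum_at_bound_fails(self):
        # "inferior to 5" is strict: a control summing to exactly 5 fails
        assert not criterion1_control_clean({"Beads": 5, "MAR": 0, "RAM": 0})

    def test_each_control_below_bound_passes(self):
        assert criterion1_control_clean({"Beads": 3, "MAR": 0, "RAM": 4})

    def test_grand_sum_mode_is_weaker(self):
        sums = {"Beads": 2, "MAR": 2, "RAM": 2}
        assert criterion1_control_clean(sums)  # each < 5
        assert not criterion1_control_clean(sums, mode="grand_sum")  # total 6

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            criterion1_control_clean({"Beads": 0}, mode="median")

    @pytest.mark.parametrize("reps,expected", [
        ((2, 2, 1), True),    # sum 5, all positive
        ((5, 0, 0), False),   # zero replicate
        ((1, 1, 2), False),   # sum 4
        ((2, 2, 2), True),
    ])
    def test_test_support_boundaries(self, reps, expected):
        assert criterion2_test_supported(reps) is expected

    @pytest.mark.parametrize("test,controls,passed,ratio", [
        (0.03, (0.01, 0.0, 0.0), True, 3.0),
        (0.0, (0.0, 0.0, 0.0), False, 0.0),
        (0.014, (0.01, 0.01, 0.01), False, 1.4),
        (0.015, (0.01, 0.0, 0.0), True, 1.5),   # ratio exactly 1.5 passes
        (0.02, (0.0, 0.0, 0.0), True, math.inf),
    ])
    def test_nsaf_enrichment(self, test, controls, passed, ratio):
        got_pass, got_ratio = criterion3_nsaf_enriched(test, controls)
        assert got_pass is passed
        assert got_ratio == pytest.approx(ratio)

    def test_negative_nsaf_rejected(self):
        with pytest.raises(ValueError):
            criterion3_nsaf_enriched(-0.1, (0.0,))

    @given(st.lists(st.integers(0, 30), min_size=1, max_size=6))
    @settings(derandomize=True)
    def test_test_support_matches_definition(self, reps):
        assert criterion2_test_supported(reps) == (
            sum(reps) >= 5 and all(r > 0 for r in reps)
        )


# ---------------------------------------------------------------- filter

def oracle_calls(table, bait_conditions, control_conditions,
                 control_bound=5, test_min=5, ratio_threshold=1.5):
    """Straight-line re-evaluation of the three criteria, independent of the
    implementation under test."""
    # condition-sum NSAF from first principles
    nsaf = {}
    for cond in table.conditions:
        saf = {}
        for acc in table.accessions:
            total = sum(table.replicate_counts(acc, cond))
            saf[acc] = total / table.length(acc)
        denom = sum(saf.values())
        nsaf[cond] = {a: (v / denom if denom else 0.0) for a, v in saf.items()}
    called = {}
    for acc in table.accessions:
        per_ab = {}
        for bait_cond in bait_conditions:
            ok1 = all(
                sum(table.replicate_counts(acc, c)) < control_bound
                for c in control_conditions
            )
            reps = table.replicate_counts(acc, bait_cond)
            ok2 = sum(reps) >= test_min and all(r > 0 for r in reps)
            test_val = nsaf[bait_cond][acc]
            ref = max(nsaf[c][acc] for c in control_conditions)
            if ref == 0:
                ok3 = test_val > 0
            else:
                ok3 = test_val / ref >= ratio_threshold
            per_ab[bait_cond] = ok1 and ok2 and ok3
        called[acc] = per_ab
    return called


class TestCallInteractors:
    def test_identical_bait_and_control_counts_never_called(self):
        counts = {f"S{i}": {c: [3, 3, 3] for c in BAIT_CONDITIONS + CONTROL_CONDITIONS}
                  for i in range(6)}
        table = make_table(counts, {f"S{i}": 300 for i in range(6)})
        calls = call_interactors(table, BAIT_CONDITIONS, CONTROL_CONDITIONS)
        assert not any(c.called for c in calls)

    def test_planted_strong_enrichment_recovered_exactly(self):
        counts = {
            "DYRK1A": {"Cter": [30, 30, 30], "Nter": [30, 30, 30]},
            "HIT1": {"Cter": [10, 12, 8]},
            "HIT2": {"Nter": [9, 9, 9]},
            "STICKY": {c: [4, 4, 4] for c in BAIT_CONDITIONS + CONTROL_CONDITIONS},
            "ABSENT": {},
        }
        lengths = {s: 500 for s in counts}
        table = make_table(counts, lengths)
        calls = call_interactors(table, BAIT_CONDITIONS, CONTROL_CONDITIONS,
                                 bait_symbol="DYRK1A")
        by_symbol = {c.symbol: c for c in calls}
        assert by_symbol["DYRK1A"].is_bait and by_symbol["DYRK1A"].called
        assert by_symbol["HIT1"].support_class == "Cter-only"
        assert by_symbol["HIT2"].support_class == "Nter-only"
        assert not by_symbol["STICKY"].called  # control sums 12 >= 5
        assert not by_symbol["ABSENT"].called
        partners = {c.symbol for c in calls if c.called and not c.is_bait}
        assert partners == {"HIT1", "HIT2"}

    def test_oracle_equivalence_on_random_tables(self, rng):
        for _ in range(50):
            table = random_table(rng, int(rng.integers(1, 21)))
            calls = call_interactors(table, BAIT_CONDITIONS, CONTROL_CONDITIONS)
            expected = oracle_calls(table, BAIT_CONDITIONS, CONTROL_CONDITIONS)
            for c in calls:
                for ab, ab_call in c.per_antibody.items():
                    assert ab_call.called == expected[c.accession][ab], (
                        f"{c.symbol}/{ab}"
                    )

    def test_monotone_in_bait_and_control_counts(self, rng):
        table = random_table(rng, 10)
        calls = {c.accession: c.called
                 for c in call_interactors(table, BAIT_CONDITIONS, CONTROL_CONDITIONS)}
        called_accs = [a for a, ok in calls.items() if ok]
        if called_accs:
            acc = called_accs[0]
            boosted = table.counts.copy()
            boosted.loc[acc, ("Cter", 1)] += 20
            from neurointeract.tables_io import SpectralCountTable
            t2 = SpectralCountTable(counts=boosted, meta=table.meta.copy())
            calls2 = {c.accession: c.called
                      for c in call_interactors(t2, BAIT_CONDITIONS, CONTROL_CONDITIONS)}
            assert calls2[acc]  # raising a called protein's bait count keeps it
        # raising a control count never adds a call for that protein
        uncalled = [a for a, ok in calls.items() if not ok]
        if uncalled:
            acc = uncalled[0]
            worse = table.counts.copy()
            worse.loc[acc, ("Beads", 1)] += 20
            from neurointeract.tables_io import SpectralCountTable
            t3 = SpectralCountTable(counts=worse, meta=table.meta.copy())
            calls3 = {c.accession: c.called
                      for c in call_interactors(t3, BAIT_CONDITIONS, CONTROL_CONDITIONS)}
            assert not calls3[acc]

    def test_relaxed_thresholds_reduce_to_criterion2(self, rng):
        table = random_table(rng, 15)
        calls = call_interactors(
            table, BAIT_CONDITIONS, CONTROL_CONDITIONS,
            control_psm_bound=10**9, nsaf_ratio_threshold=1e-12,
        )
        for c in calls:
            for ab, ab_call in c.per_antibody.items():
                reps = table.replicate_counts(c.accession, ab)
                want = sum(reps) >= 5 and all(r > 0 for r in reps)
                # with a zero test NSAF criterion 3 still fails (no evidence)
                if sum(reps) == 0:
                    want = False
                assert ab_call.called == want

    def test_annotation_input_redirected_to_count_summary(self, table1):
        with pytest.raises(TypeError, match="count_summary"):
            call_interactors(table1, BAIT_CONDITIONS, CONTROL_CONDITIONS)

    def test_unknown_condition_rejected(self, rng):
        table = random_table(rng, 3)
        with pytest.raises(KeyError):
            call_interactors(table, ["Cter"], ["GAR"])


# ---------------------------------------------------------------- summary

class TestCountSummary:
    def test_fixture_headline_counts(self, table1):
        s = count_summary(table1)
        assert s.n_partners == 35
        assert s.n_both_antibodies == 7
        assert s.n_known == 15
        assert s.n_novel == 20
        assert s.n_disease == 16
        assert s.n_ndd == 9
        assert s.n_coexpressed == 11
        assert s.n_phospho_partners == 3

    def test_fixture_apc_membership(self, table1):
        s = count_summary(table1, gene_set=APC_SET, gene_set_name="APC")
        assert s.n_in_set == 5
        assert s.n_in_set_novel == 2  # CDC16/ANAPC6 and ANAPC7

    def test_bait_never_counted(self, table1):
        s = count_summary(table1)
        # DYRK1A's own PSM sums (97, 80) would qualify as dual-antibody
        assert s.n_both_antibodies == 7
        assert s.n_partners == 35

    def test_missing_correlation_excluded(self, table1_partners):
        # AGO1 (missing rho) must not flip to coexpressed at any threshold
        s = count_summary(table1_partners, corr_threshold=-1.0)
        assert s.n_coexpressed == 34  # all partners with data, not 35
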