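"""Directional exact testing, HWE QC, and the panel pipeline."""

import math
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from panelscan import (
    AlleleTable,
    MarkerRecord,
    bonferroni_adjust,
    build_allele_table,
    call_rate_filter,
    hwe_exact_test,
    one_sided_fisher,
    one_sided_fisher_counts,
    run_panel,
    simulate_case_control_genotypes,
)
from panelscan.simulate import PanelSpec

MARKER = MarkerRecord("rs1", "1", 100, "A", "G")


def upper_tail_oracle(case_risk, case_other, ctrl_risk, ctrl_other):
    """Exact-integer hypergeometric tail P(X >= case_risk), fixed margins."""
    n_total = case_risk + case_other + ctrl_risk + ctrl_other
    n_risk = case_risk + ctrl_risk
    n_case = case_risk + case_other
    lo = max(0, n_risk - (n_total - n_case))
    hi = min(n_risk, n_case)
    num = sum(
        comb(n_risk, x) * comb(n_total - n_risk, n_case - x)
        for x in range(case_risk, hi + 1)
    )
    if case_risk <= lo:
        return 1.0
    return num / comb(n_total, n_case)


class TestBuildAlleleTable:
    @pytest.mark.parametrize(
        "case_geno, expected",
        [
            ([("A", "A")] * 3, (6, 0)),
            ([("A", "G")], (1, 1)),
            ([("A", "G")] * 8 + [(".", ".")] * 2, (8, 8)),  # missing contribute 0
            ([("A", ".")], (0, 0)),  # half-missing genotype dropped entirely
        ],
    )
    def test_counting_rules(self, case_geno, expected):
        t = build_allele_table(case_geno, [("G", "G")], MARKER)
        assert (t.case_risk, t.case_other) == expected

    def test_foreign_allele_names_snp_and_symbol(self):
        with pytest.raises(ValueError, match=r"rs1.*'T'"):
            build_allele_table([("A", "T")], [], MARKER)


class TestOneSidedFisher:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((0, 10, 5, 5), 1.0),  # whole support is in the upper tail
            ((3, 1, 1, 3), 17 / 70),
            ((10, 0, 0, 10), 1 / comb(20, 10)),
        ],
    )
    def test_frozen_examples(self, table, expected):
        assert one_sided_fisher(AlleleTable(*table)) == pytest.approx(expected, rel=1e-12)

    def test_matches_enumeration_on_small_tables(self):
        # exhaustive check for every table with total alleles <= 14
        for n_case in range(1, 14):
            for n_ctrl in range(1, 15 - n_case):
                for case_risk in range(n_case + 1):
                    for ctrl_risk in range(n_ctrl + 1):
                        got = float(
                            one_sided_fisher_counts(
                                case_risk, n_case - case_risk,
                                ctrl_risk, n_ctrl - ctrl_risk,
                            )
                        )
                        want = upper_tail_oracle(
                            case_risk, n_case - case_risk,
                            ctrl_risk, n_ctrl - ctrl_risk,
                        )
                        assert got == pytest.approx(want, rel=1e-10, abs=1e-14)

    @given(
        case_risk=st.integers(0, 12), case_other=st.integers(0, 12),
        ctrl_risk=st.integers(0, 12), ctrl_other=st.integers(0, 12),
    )
    def test_two_tails_sum_to_one_plus_point_mass(
        self, case_risk, case_other, ctrl_risk, ctrl_other
    ):
        # Swapping arms turns P(X >= x) into P(X <= x); the tails overlap at x.
        if (case_risk + case_other) == 0 or (ctrl_risk + ctrl_other) == 0:
            return
        n_total = case_risk + case_other + ctrl_risk + ctrl_other
        n_risk = case_risk + ctrl_risk
        n_case = case_risk + case_other
        point = (
            comb(n_risk, case_risk)
            * comb(n_total - n_risk, case_other)
            / comb(n_total, n_case)
        )
        up = float(one_sided_fisher_counts(case_risk, case_other, ctrl_risk, ctrl_other))
        # swapping arms maps the upper tail onto P(X <= case_risk)
        down = float(one_sided_fisher_counts(ctrl_risk, ctrl_other, case_risk, case_other))
        assert up + down == pytest.approx(1.0 + point, rel=1e-9, abs=1e-12)

    def test_degenerate_table_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert one_sided_fisher(AlleleTable(0, 0, 3, 5)) == 1.0

    def test_mid_p_is_smaller_than_standard(self):
        t = AlleleTable(6, 4, 3, 7)
        assert one_sided_fisher(t, mid_p=True) < one_sided_fisher(t)


class TestBonferroni:
    @pytest.mark.parametrize(
        "p, n, expected", [(0.001, 37, 0.037), (0.5, 37, 1.0), (1.0, 1, 1.0)]
    )
    def test_examples(self, p, n, expected):
        assert bonferroni_adjust(p, n) == pytest.approx(expected, rel=1e-12)

    def test_rejects_bad_family_size(self):
        with pytest.raises(ValueError):
            bonferroni_adjust(0.1, 0)

    @given(
        p=st.floats(1e-6, 1.0), q=st.floats(1e-6, 1.0),
        n=st.integers(1, 100), m=st.integers(1, 100),
    )
    def test_monotone_in_both_arguments(self, p, q, n, m):
        lo_p, hi_p = sorted((p, q))
        lo_n, hi_n = sorted((n, m))
        assert bonferroni_adjust(lo_p, lo_n) <= bonferroni_adjust(hi_p, lo_n)
        assert bonferroni_adjust(lo_p, lo_n) <= bonferroni_adjust(lo_p, hi_n)
        assert bonferroni_adjust(1.0, n) == 1.0


def hwe_oracle(n_aa, n_ab, n_bb):
    """Full enumeration over heterozygote counts with exact integers."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab

    def weight(h):
        hom_a = (n_a - h) // 2
        hom_b = n - h - hom_a
        return (
            2**h
            * math.factorial(n)
            // (math.factorial(h) * math.factorial(hom_a) * math.factorial(hom_b))
        )

    hets = [h for h in range(min(n_a, 2 * n - n_a) + 1) if (n_a - h) % 2 == 0]
    weights = {h: weight(h) for h in hets}
    total = sum(weights.values())
    w_obs = weights[n_ab]
    return sum(w for w in weights.values() if w <= w_obs) / total


class TestHWEExactTest:
    def test_modal_configuration_has_p_one(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0, abs=1e-12)

    def test_monomorphic_marker_has_single_configuration(self):
        assert hwe_exact_test(0, 0, 10) == 1.0

    @pytest.mark.parametrize(
        "counts", [(2, 2, 2), (5, 1, 5), (0, 6, 0), (10, 3, 1), (7, 12, 4), (1, 1, 40)]
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(hwe_oracle(*counts), rel=1e-9)

    def test_rejects_empty_and_negative(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)

    def test_conservative_on_hwe_genotypes(self, rng):
        # dosage draws already in HWE: rejection at 5% must not exceed nominal
        dosage = rng.binomial(2, 0.3, size=(400, 120))
        pvals = [
            hwe_exact_test(int((d == 2).sum()), int((d == 1).sum()), int((d == 0).sum()))
            for d in dosage.T
        ]
        rate = np.mean(np.asarray(pvals) <= 0.05)
        assert rate <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / 120)


class TestCallRateFilter:
    def _table(self, n_called, n_total, sample="s1"):
        rows = [
            (sample, f"snp{j + 1}", "A" if j < n_called else ".", "A")
            for j in range(n_total)
        ]
        return pd.DataFrame(rows, columns=["sample_id", "snp_id", "allele1", "allele2"])

    def test_sample_at_36_of_37_retained(self):
        report = call_rate_filter(self._table(36, 37), threshold=0.97)
        assert report.excluded_samples.empty

    def test_sample_at_35_of_37_excluded(self):
        report = call_rate_filter(self._table(35, 37), threshold=0.97)
        assert list(report.excluded_samples["sample_id"]) == ["s1"]
        assert report.excluded_samples["call_rate"].iloc[0] == pytest.approx(35 / 37)

    def test_zero_threshold_retains_everything(self):
        table = self._table(10, 37)
        report = call_rate_filter(table, threshold=0.0)
        assert len(report.retained) == len(table)
        assert report.n_excluded == 0


class TestRunPanel:
    def test_missing_marker_raises_with_ids(self, small_genotype_tables):
        case, ctrl = small_genotype_tables
        markers = [MarkerRecord(f"snp{i}", "1", i, "A", "G") for i in (1, 2, 3)]
        with pytest.raises(ValueError, match="snp3"):
            run_panel(case, ctrl, markers)

    def test_identical_arms_give_large_p(self, small_genotype_tables):
        case, _ = small_genotype_tables
        ctrl = case.assign(arm="control")
        markers = [MarkerRecord(f"snp{i}", "1", i, "A", "G") for i in (1, 2)]
        results = run_panel(case, ctrl, markers, call_rate_threshold=0.0)
        assert all(r.nominal_p >= 0.5 for r in results)

    def test_established_markers_excluded_from_family(self):
        panel = simulate_case_control_genotypes(
            PanelSpec(n_snps=39, n_cases=60, n_controls=60, seed=11), n_established=2
        )
        case, ctrl = panel.to_long()
        results = run_panel(case, ctrl, list(panel.markers), call_rate_threshold=0.0)
        new = [r for r in results if not r.established]
        est = [r for r in results if r.established]
        assert len(new) == 37 and len(est) == 2
        assert all(r.n_tests == 37 for r in results)
        assert all(not math.isnan(r.adjusted_p) for r in new)
        assert all(math.isnan(r.adjusted_p) for r in est)
        assert all(r.adjusted_p >= r.nominal_p - 1e-15 for r in new)

    def test_causal_snp_ranks_first_in_power_simulation(self):
        # one OR = 3 SNP among nulls at n = 500/500, maf 0.3: it should attain
        # the smallest nominal p in >= 95% of seeded replicates
        wins = 0
        n_rep = 200
        for seed in range(n_rep):
            spec = PanelSpec(
                n_snps=10, n_cases=500, n_controls=500, maf=0.3,
                odds_ratio=[3.0] + [1.0] * 9, seed=seed,
            )
            counts = simulate_case_control_genotypes(spec).allele_counts()
            p = one_sided_fisher_counts(
                counts["case_risk"], counts["case_other"],
                counts["ctrl_risk"], counts["ctrl_other"],
            )
            wins += int(np.argmin(p) == 0)
        assert wins / n_rep >= 0.95
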