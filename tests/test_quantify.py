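"""Tier filters, RPM, differential abundance and correlation statistics."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from circkit.quantify import (
    CountMatrix,
    apply_tier_filters,
    circ_linear_correlation,
    differential_abundance,
    direction_summary,
    rpm_normalize,
)


def matrix_from(rows, libs=None):
    counts = pd.DataFrame(
        rows, columns=[f"s{i}" for i in range(len(rows[0]))]
    )
    libs = libs or [1_000_000] * counts.shape[1]
    return CountMatrix(counts, pd.Series(libs, index=counts.columns, dtype=float))


def brute_force_tiers(row, n, presence_threshold=1):
    """Literal, independent evaluation of the three tier predicates."""
    present = sum(1 for c in row if c >= presence_threshold)
    return {
        "tier1": max(row) >= 2,
        "tier2": present >= 2 and sum(row) >= 5,
        "tier3": present >= max(1, n - 1),
    }


class TestTierFilters:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ([5, 0, 0, 0], {"tier1"}),  # one sample present
            ([1, 1, 1, 1], {"tier3"}),  # sum 4 < 5 blocks tier 2
            ([0, 0, 0, 0], set()),
            ([2, 2, 1, 0], {"tier1", "tier2", "tier3"}),
        ],
    )
    def test_rule_examples(self, row, expected):
        tiers = apply_tier_filters(matrix_from([row]))
        got = {t for t in ("tier1", "tier2", "tier3") if tiers.iloc[0][t]}
        assert got == expected

    def test_single_sample_matrix(self):
        tiers = apply_tier_filters(matrix_from([[2]]))
        assert tiers.iloc[0].to_dict() == {"tier1": True, "tier2": False, "tier3": True}

    def test_per_sample_tier2_rule(self):
        tiers = apply_tier_filters(
            matrix_from([[5, 5, 0], [3, 2, 1]]), tier2_rule="per_sample"
        )
        assert tiers["tier2"].tolist() == [True, False]

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n_circ = int(rng.integers(1, 51))
            n_samp = int(rng.integers(1, 11))
            counts = rng.integers(0, 8, size=(n_circ, n_samp))
            tiers = apply_tier_filters(matrix_from(counts.tolist()))
            for i, row in enumerate(counts.tolist()):
                assert tiers.iloc[i].to_dict() == brute_force_tiers(row, n_samp)


class TestRpm:
    def test_forced_values(self):
        m = matrix_from([[0], [10]], libs=[2_000_000])
        rpm = rpm_normalize(m)
        assert rpm.iloc[0, 0] == 0.0
        assert rpm.iloc[1, 0] == 5.0

    def test_inverse_identity(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 1000, size=(40, 6))
        libs = rng.integers(1_000_000, 5_000_000, size=6).tolist()
        m = matrix_from(counts.tolist(), libs=libs)
        rpm = rpm_normalize(m)
        back = rpm * m.mappable_reads / 1e6
        assert np.abs(back.to_numpy() - counts).max() < 1e-9

    def test_nonpositive_library_rejected(self):
        with pytest.raises(ValueError):
            matrix_from([[1]], libs=[0])


def sheet_for(case, ctrl):
    return pd.DataFrame(
        {
            "sample_id": list(case) + list(ctrl),
            "group": ["case"] * len(case) + ["control"] * len(ctrl),
            "mappable_reads": [1_000_000] * (len(case) + len(ctrl)),
        }
    )


def rpm_frame(case_vals, ctrl_vals):
    data = {f"c{i}": v for i, v in enumerate(case_vals)}
    data.update({f"k{i}": v for i, v in enumerate(ctrl_vals)})
    sheet = sheet_for(
        [f"c{i}" for i in range(len(case_vals))],
        [f"k{i}" for i in range(len(ctrl_vals))],
    )
    return pd.DataFrame(data, index=["x"]), sheet


def welch_oracle(a, b):
    """Textbook Welch t statistic, df and two-tailed p."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va / na + vb / nb)
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    return 2 * tdist.sf(abs(t), df)


class TestDifferentialAbundance:
    def test_identical_groups_give_no_direction(self):
        rpm, sheet = rpm_frame([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        res = differential_abundance(rpm, sheet)
        assert res.loc["x", "log2fc"] == 0.0
        assert res.loc["x", "direction"] == "none"
        assert res.loc["x", "p_value"] == 1.0

    def test_forced_log2fc_without_pseudocount(self):
        rpm, sheet = rpm_frame([4.0, 4.0], [1.0, 1.0])
        res = differential_abundance(rpm, sheet, epsilon=0.0)
        assert res.loc["x", "log2fc"] == pytest.approx(2.0)

    def test_welch_p_matches_closed_form(self):
        case, ctrl = [3.1, 2.8, 3.5, 3.0], [1.0, 1.3, 0.9, 1.1]
        rpm, sheet = rpm_frame(case, ctrl)
        res = differential_abundance(rpm, sheet)
        assert res.loc["x", "p_value"] == pytest.approx(welch_oracle(case, ctrl), rel=1e-12)

    def test_student_variant(self):
        from scipy.stats import ttest_ind

        case, ctrl = [3.1, 2.8, 3.5, 3.0], [1.0, 1.3, 0.9, 1.1]
        rpm, sheet = rpm_frame(case, ctrl)
        res = differential_abundance(rpm, sheet, test="student")
        expected = ttest_ind(case, ctrl, equal_var=True).pvalue
        assert res.loc["x", "p_value"] == pytest.approx(expected, rel=1e-12)

    def test_small_group_rejected(self):
        rpm, sheet = rpm_frame([1.0], [2.0, 3.0])
        with pytest.raises(ValueError, match="case"):
            differential_abundance(rpm, sheet)

    def test_scaling_invariance(self):
        """Scaling all counts and library sizes jointly leaves results fixed."""
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 400, size=(30, 8))
        libs = rng.integers(1_000_000, 3_000_000, size=8)
        sheet = sheet_for([f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)])
        sheet["sample_id"] = [f"s{i}" for i in range(8)]
        sheet["mappable_reads"] = libs

        def run(k):
            m = CountMatrix(
                pd.DataFrame(counts * k, columns=[f"s{i}" for i in range(8)]),
                pd.Series(libs * k, index=[f"s{i}" for i in range(8)], dtype=float),
            )
            return differential_abundance(rpm_normalize(m), sheet)

        a, b = run(1), run(7)
        assert np.allclose(a["log2fc"], b["log2fc"], atol=1e-9)
        assert np.allclose(a["p_value"], b["p_value"], atol=1e-9)


def results_frame(n_up, n_down, n_none=0):
    return pd.DataFrame(
        {"direction": ["up"] * n_up + ["down"] * n_down + ["none"] * n_none}
    )


class TestDirectionSummary:
    def test_pct_up_forced(self):
        s = direction_summary(results_frame(18, 6))
        assert s.pct_up == 75.0

    def test_identical_proportions_give_zero_chi2(self):
        s = direction_summary(results_frame(10, 5), results_frame(20, 10))
        assert s.chi2 == pytest.approx(0.0)
        assert s.chi2_p == pytest.approx(1.0)

    def test_chi2_matches_pearson_by_hand(self):
        # 2x2 table [[18,6],[10,10]]: sum of (O-E)^2/E over cells
        obs = np.array([[18, 6], [10, 10]], float)
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        chi2_hand = ((obs - exp) ** 2 / exp).sum()
        s = direction_summary(results_frame(18, 6), results_frame(10, 10))
        assert s.chi2 == pytest.approx(chi2_hand, rel=1e-12)
        assert s.chi2 == pytest.approx(2.95, abs=0.01)

    def test_no_significant_calls(self):
        s = direction_summary(results_frame(0, 0, 5))
        assert s.pct_up is None and s.chi2 is None


class TestCircLinearCorrelation:
    def test_perfect_linear(self):
        r = circ_linear_correlation([1, 2, 3, 4], [2, 4, 6, 8])
        assert r.r2 == pytest.approx(1.0)
        assert r.slope == pytest.approx(2.0)

    def test_constant_input_flagged_missing(self):
        r = circ_linear_correlation([1, 2, 3], [5, 5, 5])
        assert not r.ok and r.r2 is None

    def test_hand_computed_pearson_squared(self):
        # x=(1,2,3,4), y=(2,1,4,3): r = 3/5 -> r2 = 0.36
        r = circ_linear_correlation([1, 2, 3, 4], [2, 1, 4, 3])
        assert r.r2 == pytest.approx(0.36, rel=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            circ_linear_correlation([1, 2, 3], [1, 2])


@given(
    arrays(
        np.int64,
        st.tuples(st.integers(1, 12), st.integers(1, 6)),
        elements=st.integers(0, 9),
    )
)
@settings(derandomize=True, max_examples=60)
def test_tier_filters_equal_brute_force_property(counts):
    tiers = apply_tier_filters(matrix_from(counts.tolist()))
    for i, row in enumerate(counts.tolist()):
        assert tiers.iloc[i].to_dict() == brute_force_tiers(row, counts.shape[1])
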