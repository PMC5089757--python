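"""Pearson, Mann-Whitney, summaries, counts and the replication report."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

import cereflow as cf
from cereflow.stats import round_half_up


# --------------------------------------------------------------------------
# from-scratch oracles
# --------------------------------------------------------------------------

def pearson_oracle(x, y):
    """Textbook Pearson r and two-tailed p via numeric integration of the
    t density with n-2 degrees of freedom (independent of scipy.stats)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    xc, yc = x - x.mean(), y - y.mean()
    r = float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))
    df = n - 2
    t = abs(r) * math.sqrt(df / (1.0 - r * r))

    def t_pdf(u):
        c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi)
                                        * math.gamma(df / 2))
        return c * (1.0 + u * u / df) ** (-(df + 1) / 2)

    tail, _ = quad(t_pdf, t, np.inf)
    return r, min(1.0, 2.0 * tail)


def mannwhitney_exact_oracle(a, b):
    """Exact two-tailed p by enumerating every assignment of the pooled
    values to the two groups (tie-free inputs)."""
    pooled = list(a) + list(b)
    n1 = len(a)

    def u_stat(group_vals, rest):
        u = 0
        for x in group_vals:
            for v in rest:
                if x > v:
                    u += 1
        return u

    u_obs = u_stat(a, b)
    us = []
    idx = range(len(pooled))
    for comb in combinations(idx, n1):
        g = [pooled[i] for i in comb]
        rest = [pooled[i] for i in idx if i not in comb]
        us.append(u_stat(g, rest))
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(p_le, p_ge))


# --------------------------------------------------------------------------
# pearson
# --------------------------------------------------------------------------

class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        res = cf.pearson(x, x)
        assert res.r == pytest.approx(1.0)

    def test_matches_formula_oracle_on_random_inputs(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            x = rng.standard_normal(10)
            y = rng.standard_normal(10) + 0.4 * x
            res = cf.pearson(x, y)
            r0, p0 = pearson_oracle(x, y)
            assert res.r == pytest.approx(r0, abs=1e-12)
            assert res.p_two_tailed == pytest.approx(p0, abs=1e-7)
            assert res.n_pairs == 10

    def test_missing_values_dropped_pairwise(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([2.0, np.nan, 3.0, 8.0, 10.0])
        res = cf.pearson(x, y)
        assert res.n_pairs == 3  # only rows 0, 3, 4 are complete

    def test_symmetric_in_its_arguments(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(15), rng.standard_normal(15)
        assert cf.pearson(x, y).r == pytest.approx(cf.pearson(y, x).r)

    @given(scale=st.floats(0.1, 50), shift=st.floats(-100, 100))
    def test_invariant_to_affine_transforms(self, scale, shift):
        rng = np.random.default_rng(7)
        x, y = rng.standard_normal(12), rng.standard_normal(12)
        base = cf.pearson(x, y)
        res = cf.pearson(scale * x + shift, y)
        assert res.r == pytest.approx(base.r, abs=1e-9)
        assert res.p_two_tailed == pytest.approx(base.p_two_tailed, abs=1e-9)

    def test_constant_variable_named_in_error(self):
        with pytest.raises(cf.ValidationError, match="hb"):
            cf.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0],
                       variables=("hb", "ttp"))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(cf.ValidationError):
            cf.pearson([1.0, 2.0], [3.0, 4.0])


# --------------------------------------------------------------------------
# mann-whitney
# --------------------------------------------------------------------------

class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        """{1,2,3} vs {4,5,6}: U = 0 for the first group; the exact
        two-tailed p enumerates to 2/20 = 0.1."""
        res = cf.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0.0
        assert res.p_two_tailed == pytest.approx(0.1)
        assert res.method == "exact"
        assert res.p_two_tailed == pytest.approx(
            mannwhitney_exact_oracle([1, 2, 3], [4, 5, 6]))

    def test_identical_multisets_do_not_separate(self):
        res = cf.mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.p_two_tailed >= 0.99

    def test_matches_enumeration_oracle_on_random_inputs(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            a = rng.permutation(20)[:4].astype(float)
            b = np.setdiff1d(np.arange(20), a)[:5].astype(float)
            res = cf.mann_whitney_u(a, b)
            assert res.method == "exact"
            assert res.p_two_tailed == pytest.approx(
                mannwhitney_exact_oracle(list(a), list(b)), abs=1e-12)

    def test_u_bounded_by_product_of_group_sizes(self):
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal(8), rng.standard_normal(13)
        res = cf.mann_whitney_u(a, b)
        assert 0 <= res.u_statistic <= 8 * 13

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal(25)
        b = rng.standard_normal(30) + 0.5
        base = cf.mann_whitney_u(a, b)
        for f in (np.exp, lambda v: v ** 3, lambda v: 5 * v - 2):
            res = cf.mann_whitney_u(f(a), f(b))
            assert res.u_statistic == pytest.approx(base.u_statistic)
            assert res.p_two_tailed == pytest.approx(base.p_two_tailed)

    def test_empty_group_rejected(self):
        with pytest.raises(cf.ValidationError):
            cf.mann_whitney_u([], [1.0, 2.0])


# --------------------------------------------------------------------------
# summaries and counts
# --------------------------------------------------------------------------

class TestSummaries:
    def test_ttp_summary_reproduces_reported_values(self, hus_cohort):
        s = cf.summarize(hus_cohort.column("ttp_frames")).rounded(1)
        assert s == {"n": 36, "mean": 7.9, "sd": 1.4, "min": 3.7, "max": 10.2}

    def test_etco2_summary_over_13_recorded_values(self, hus_cohort):
        s = cf.summarize(hus_cohort.column("etco2_mmHg"))
        assert s.n == 13
        assert round_half_up(s.mean, 1) == 30.9
        assert round_half_up(s.sd, 1) == 5.5

    def test_single_value_has_undefined_sd(self):
        s = cf.summarize([4.2])
        assert s.mean == 4.2
        assert s.sd is None

    def test_all_missing_rejected(self):
        with pytest.raises(cf.ValidationError):
            cf.summarize([np.nan, np.nan])

    @pytest.mark.parametrize("value,expected", [
        (7.45, 7.5), (1.35, 1.4), (7.44999, 7.4), (-0.05, -0.1)])
    def test_rounding_is_half_up(self, value, expected):
        assert round_half_up(value, 1) == expected


class TestCounts:
    @pytest.mark.parametrize("predicate,kwargs,expected", [
        ("complete_loss", {}, 19),
        ("low_contrast", {}, 33),
        ("etco2_above", {"threshold": 35}, 2),
        ("mri_abnormal", {}, 16),
    ])
    def test_builtin_predicates_on_fixture(self, hus_cohort, predicate,
                                           kwargs, expected):
        assert cf.count_by_predicate(hus_cohort, predicate, **kwargs) == expected

    def test_callable_predicate(self, hus_cohort):
        n = cf.count_by_predicate(
            hus_cohort, lambda rec: rec.anesthesia and rec.swi_score == 1)
        assert n == 11

    def test_predicate_on_all_missing_field_rejected(self):
        table = cf.CohortTable([
            cf.PatientRecord(patient_id="a", sex="f", age_years=30.0),
            cf.PatientRecord(patient_id="b", sex="m", age_years=40.0),
        ])
        with pytest.raises(cf.ValidationError, match="missing"):
            cf.count_by_predicate(table, "etco2_above", threshold=35)

    def test_unknown_predicate_rejected(self, hus_cohort):
        with pytest.raises(cf.ValidationError):
            cf.count_by_predicate(hus_cohort, "nonexistent")


# --------------------------------------------------------------------------
# replication report
# --------------------------------------------------------------------------

class TestReplicationReport:
    def test_fixture_only_report(self, hus_cohort):
        rep = cf.replicate_published_statistics(hus_cohort).report
        c = rep["correlations"]["swi_score__ttp_frames"]
        assert round_half_up(c["r"], 2) == 0.35
        assert c["n"] == 36
        assert rep["counts"]["complete_loss"] == 19
        assert rep["counts"]["low_contrast"] == 33
        assert rep["counts"]["etco2_above_35"] == 2
        assert rep["published_comparison"]["r_swi_ttp"]["reproduced"]

    def test_chemistry_statistics_skipped_without_clinical_table(self, hus_cohort):
        rep = cf.replicate_published_statistics(hus_cohort).report
        assert "swi_score__hemoglobin_g_dl" not in rep["correlations"]
        msgs = [m for m in rep["skipped"] if "hemoglobin" in m]
        assert msgs and "clinical table not provided" in msgs[0]

    def test_clinical_csv_enables_chemistry_correlations(self, hus_cohort,
                                                         tmp_path):
        # synthetic stand-in for the unavailable supplementary chemistry
        # table: hemoglobin loosely tracking the venous-contrast score
        rng = np.random.default_rng(0)
        rows = ["patient_id,sex,age_years,hemoglobin_g_dl,hematocrit_pct\n"]
        for rec in hus_cohort:
            hb = 6.5 + 0.8 * rec.swi_score + rng.normal(0, 0.8)
            rows.append(f"{rec.patient_id},{rec.sex},{rec.age_years},"
                        f"{hb:.2f},{2.9 * hb:.2f}\n")
        path = tmp_path / "synthetic_clinical.csv"
        path.write_text("".join(rows))
        rep = cf.replicate_published_statistics(hus_cohort, clinical_csv=path).report
        assert "swi_score__hemoglobin_g_dl" in rep["correlations"]
        assert rep["correlations"]["swi_score__hemoglobin_g_dl"]["n"] == 36

    def test_report_renders_json_and_markdown(self, hus_cohort):
        rep = cf.replicate_published_statistics(hus_cohort)
        assert rep.to_json().startswith("{")
        md = rep.to_markdown()
        assert "Mann-Whitney" in md and "swi_score__ttp_frames" in md
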