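import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

from pnenmeth.arrays_io import SampleSheet
from pnenmeth.clinstats import (
    association_report,
    coxph_fit,
    fisher_exact,
    km_estimate,
    two_group_location_test,
)
from pnenmeth.clinstats import _fisher_rxc
from pnenmeth.validation import TABLE1_CONTINGENCY, cox_toy_check


def brute_force_fisher(table):
    """Enumerate every margin-fixed table via itertools; sum probabilities
    of tables no more probable than the observed."""
    t = np.asarray(table, dtype=int)
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    n = t.sum()

    def log_prob(cells):
        arr = np.asarray(cells)
        return (
            gammaln(row_sums + 1).sum()
            + gammaln(col_sums + 1).sum()
            - gammaln(n + 1)
            - gammaln(arr + 1).sum()
        )

    lp_obs = log_prob(t)
    total = 0.0
    rows_options = [
        [
            comb
            for comb in itertools.product(*(range(r + 1) for _ in col_sums))
            if sum(comb) == r
        ]
        for r in row_sums
    ]
    for choice in itertools.product(*rows_options):
        arr = np.asarray(choice)
        if not np.array_equal(arr.sum(axis=0), col_sums):
            continue
        lp = log_prob(arr)
        if lp <= lp_obs + np.log1p(1e-7):
            total += np.exp(lp)
    return min(total, 1.0)


class TestFisherExact:
    def test_balanced_table_gives_one(self):
        assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_2x2_matches_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            t = rng.integers(0, 25, size=(2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            expected = stats.fisher_exact(t)[1]
            assert fisher_exact(t) == pytest.approx(expected, rel=1e-9)

    def test_rxc_matches_bruteforce_enumeration(self):
        tables = [
            [[2, 1], [1, 2], [0, 3]],
            [[3, 0, 1], [1, 2, 2]],
            [[4, 1], [2, 3], [1, 1], [0, 2]],
        ]
        for t in tables:
            assert fisher_exact(t) == pytest.approx(brute_force_fisher(t), rel=1e-9)

    def test_rxc_path_agrees_with_2x2_path(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            t = rng.integers(1, 15, size=(2, 2))
            assert _fisher_rxc(t) == pytest.approx(fisher_exact(t), rel=1e-9)

    def test_invariant_to_permutation_and_transposition(self):
        t = np.array([[2, 7, 3], [5, 1, 4]])
        p = fisher_exact(t)
        assert fisher_exact(t[:, ::-1]) == pytest.approx(p, rel=1e-9)
        assert fisher_exact(t[::-1, :]) == pytest.approx(p, rel=1e-9)
        assert fisher_exact(t.T) == pytest.approx(p, rel=1e-9)

    def test_negative_and_fractional_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -2], [3, 4]])
        with pytest.raises(ValueError):
            fisher_exact([[1.5, 2], [3, 4]])

    def test_enumeration_guard(self):
        big = np.full((6, 6), 80)
        with pytest.raises(ValueError, match="enumeration"):
            fisher_exact(big)

    def test_published_table_values(self):
        p = fisher_exact(TABLE1_CONTINGENCY["gender"])
        assert p == pytest.approx(0.20, abs=0.005)
        p = fisher_exact(TABLE1_CONTINGENCY["who_grade"])
        assert p == pytest.approx(0.66, abs=0.005)


class TestLocationTests:
    def test_identical_groups_give_p_one(self):
        stat, p = two_group_location_test(
            [1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3, kind="t"
        )
        assert stat == 0.0 and p == 1.0

    def test_mann_whitney_exact_small_samples(self):
        stat, p = two_group_location_test(
            [1, 2, 100, 101], ["a", "a", "b", "b"], kind="mann_whitney"
        )
        assert p == pytest.approx(2 / 6)

    def test_welch_matches_closed_form(self):
        x = np.array([1.1, 2.3, 0.7, 1.9, 2.8])
        y = np.array([3.2, 4.1, 2.9, 3.8])
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t_exp = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
        p_exp = 2 * stats.t.sf(abs(t_exp), df)
        stat, p = two_group_location_test(
            np.r_[x, y], ["a"] * 5 + ["b"] * 4, kind="t"
        )
        assert stat == pytest.approx(t_exp, rel=1e-12)
        assert p == pytest.approx(p_exp, rel=1e-12)

    def test_student_flavor_available(self):
        x = [1.0, 2.0, 3.0]
        y = [2.0, 3.0, 4.0]
        stat, p = two_group_location_test(
            x + y, ["a"] * 3 + ["b"] * 3, kind="t", welch=False
        )
        expected = stats.ttest_ind(x, y, equal_var=True)
        assert stat == pytest.approx(expected.statistic)


class TestCoxPH:
    def test_identical_survival_in_both_levels_gives_hr_one(self):
        times = [1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0]
        events = [1, 1, 0, 1, 1, 1, 0, 1]
        x = pd.DataFrame({"g": [0, 0, 0, 0, 1, 1, 1, 1]})
        fit = coxph_fit(times, events, x)
        assert fit.hr.iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_toy_matches_bruteforce_partial_likelihood(self):
        assert cox_toy_check() <= 1e-6

    def test_coefficient_sign_flips_with_coding(self):
        rng = np.random.default_rng(2)
        n = 40
        g = rng.integers(0, 2, n).astype(float)
        times = rng.exponential(1.0 / np.exp(-0.8 * g))
        events = np.ones(n, dtype=int)
        f1 = coxph_fit(times, events, pd.DataFrame({"g": g}))
        f2 = coxph_fit(times, events, pd.DataFrame({"g": 1 - g}))
        assert f1.coef.iloc[0] == pytest.approx(-f2.coef.iloc[0], rel=1e-6)
        assert f1.hr.iloc[0] == pytest.approx(1.0 / f2.hr.iloc[0], rel=1e-6)

    def test_matches_lifelines_with_ties(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(3)
        n = 60
        x1 = rng.integers(0, 2, n).astype(float)
        x2 = rng.normal(0, 1, n)
        t = np.round(rng.exponential(1.0 / np.exp(0.7 * x1 - 0.3 * x2)), 1) + 0.1
        e = (rng.random(n) < 0.8).astype(int)
        fit = coxph_fit(t, e, pd.DataFrame({"x1": x1, "x2": x2}))
        df = pd.DataFrame({"T": t, "E": e, "x1": x1, "x2": x2})
        cph = lifelines.CoxPHFitter().fit(df, "T", "E")  # Efron ties default
        assert fit.coef["x1"] == pytest.approx(cph.params_["x1"], abs=1e-5)
        assert fit.coef["x2"] == pytest.approx(cph.params_["x2"], abs=1e-5)
        assert fit.se["x1"] == pytest.approx(cph.standard_errors_["x1"], abs=1e-4)
        assert fit.log_likelihood == pytest.approx(cph.log_likelihood_, abs=1e-5)

    def test_complete_separation_flagged(self):
        # covariate perfectly orders the events: monotone likelihood
        times = np.arange(1.0, 9.0)
        events = np.ones(8, dtype=int)
        x = pd.DataFrame({"g": np.arange(8.0)})
        fit = coxph_fit(times, events, x)
        assert not fit.converged

    def test_ci_and_hr_consistent(self):
        rng = np.random.default_rng(4)
        n = 50
        g = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / np.exp(0.5 * g))
        fit = coxph_fit(t, np.ones(n, int), pd.DataFrame({"g": g}))
        assert fit.ci_lower.iloc[0] <= fit.hr.iloc[0] <= fit.ci_upper.iloc[0]
        assert fit.hr.iloc[0] == pytest.approx(np.exp(fit.coef.iloc[0]))
        assert np.isfinite(fit.prop_p.iloc[0])

    def test_requires_an_event(self):
        with pytest.raises(ValueError, match="event"):
            coxph_fit([1.0, 2.0], [0, 0], pd.DataFrame({"g": [0.0, 1.0]}))


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        km = km_estimate([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])["all"]
        assert np.allclose(km.table["survival"], [0.8, 0.6, 0.4, 0.2, 0.0])
        assert km.median == 3.0

    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])["all"]
        assert (km.table["survival"] == 1.0).all()
        assert not km.median_reached

    def test_mixed_censoring_matches_hand_computed_product_limit(self):
        # times 1,2+,3,4+,5 (+ = censored)
        km = km_estimate([1, 2, 3, 4, 5], [1, 0, 1, 0, 1])["all"]
        expected = [4 / 5, 4 / 5, 4 / 5 * 2 / 3, 4 / 5 * 2 / 3, 0.0]
        assert np.allclose(km.table["survival"], expected)

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(5)
        t = rng.exponential(5, 40)
        e = (rng.random(40) < 0.7).astype(int)
        km = km_estimate(t, e)["all"]
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        ours = km.table.set_index("time")["survival"]
        theirs = kmf.survival_function_["KM_estimate"]
        for time in ours.index:
            assert ours.loc[time] == pytest.approx(theirs.loc[time], abs=1e-10)

    def test_groups_estimated_separately(self):
        km = km_estimate([1, 2, 10, 20], [1, 1, 1, 1], ["a", "a", "b", "b"])
        assert km["a"].median == 1.0 and km["b"].median == 10.0


def _table1_sheet_and_calls():
    """Reconstruct a cohort sheet whose per-variable counts match the
    published association table (unknowns pad the varying denominators)."""
    n_a, n_b = 62, 21
    rows = []
    calls = []

    def fill(values, counts, total):
        out = []
        for v, c in zip(values, counts):
            out += [v] * c
        out += ["unknown"] * (total - len(out))
        return out

    spec = {
        "gender": (["F", "M"], [25, 32], [13, 8]),
        "adm_mutated": (["no", "yes"], [10, 38], [13, 2]),
        "who_grade": (["G1", "G2", "G3"], [27, 22, 3], [12, 8, 0]),
        "functionality": (
            ["gastrinoma", "glucagonoma", "insulinoma", "non-functional", "VIPoma"],
            [1, 1, 2, 46, 2],
            [1, 0, 6, 13, 0],
        ),
        "lvi": (["no", "yes"], [14, 31], [8, 5]),
        "distant_metastasis": (["no", "yes"], [32, 21], [18, 2]),
        "recurrence": (["no", "yes"], [14, 13], [16, 0]),
    }
    cols = {"A": {}, "B": {}}
    for var, (levels, ca, cb) in spec.items():
        cols["A"][var] = fill(levels, ca, n_a)
        cols["B"][var] = fill(levels, cb, n_b)
    # gender has no unknown level; pad with alternating valid values
    for st, n in (("A", n_a), ("B", n_b)):
        g = [v for v in cols[st]["gender"] if v != "unknown"]
        g += ["F", "M"] * ((n - len(g) + 1) // 2)
        cols[st]["gender"] = g[:n]

    i = 0
    for st, n in (("A", n_a), ("B", n_b)):
        for k in range(n):
            sid = f"t{i:03d}"
            i += 1
            rows.append(
                {
                    "sample_id": sid,
                    "group": "tumor",
                    "platform": "epic",
                    "adm_mutated": cols[st]["adm_mutated"][k],
                    "who_grade": cols[st]["who_grade"][k],
                    "functionality": cols[st]["functionality"][k],
                    "lvi": cols[st]["lvi"][k],
                    "distant_metastasis": cols[st]["distant_metastasis"][k],
                    "recurrence": cols[st]["recurrence"][k],
                    "gender": cols[st]["gender"][k],
                    "age": 60.0,
                    "tumor_size": 3.0,
                    "os_time": 5.0,
                    "os_event": 0,
                    "tumor_purity": 0.9,
                }
            )
            calls.append({"sample_id": sid, "subtype": st, "cluster_au": 1.0})
    sheet = SampleSheet(pd.DataFrame(rows))
    calls = pd.DataFrame(calls).set_index("sample_id")
    return sheet, calls


class TestAssociationReport:
    def test_reconstructed_cohort_reproduces_published_pvalues(self):
        sheet, calls = _table1_sheet_and_calls()
        rep = association_report(sheet, calls)
        assert f"{rep.loc['adm_mutated', 'p']:.1E}" == "7.6E-06"
        assert rep.loc["functionality", "p"] == pytest.approx(0.011, abs=5e-4)
        assert rep.loc["distant_metastasis", "p"] == pytest.approx(0.022, abs=5e-4)
        assert f"{rep.loc['recurrence', 'p']:.1E}" == "5.9E-04"
        assert rep.loc["lvi", "p"] == pytest.approx(0.059, abs=5e-4)
        assert not rep.loc["gender", "significant"]
        assert rep.loc["adm_mutated", "significant"]

    def test_complete_case_denominators(self):
        sheet, calls = _table1_sheet_and_calls()
        rep = association_report(sheet, calls)
        joined = sheet.data.join(calls[["subtype"]], how="inner")
        for var in ("adm_mutated", "lvi", "recurrence"):
            expected = int((joined[var] != "unknown").sum())
            assert rep.loc[var, "n_used"] == expected

    def test_single_subtype_reported_without_pvalues(self):
        sheet, calls = _table1_sheet_and_calls()
        only_a = calls[calls["subtype"] == "A"]
        rep = association_report(sheet, only_a)
        assert rep["p"].isna().all()
        assert (rep["note"] != "").all()
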