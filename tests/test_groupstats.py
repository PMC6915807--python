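"""Summary-statistic comparisons: Welch t, chi-square, tallies, BH, MANCOVA."""

import numpy as np
import pandas as pd
import pytest

from bodymap import (
    Affect,
    ConcernEntry,
    GroupSummary,
    SubjectRecord,
    bh_adjust,
    chi_square,
    mancova_wilks,
    pooled_t,
    tally,
    welch_t,
)


# --- Welch t ----------------------------------------------------------------

def test_equal_means_give_zero_t():
    t, _ = welch_t(GroupSummary(5.0, 1.0, 10), GroupSummary(5.0, 2.0, 12))
    assert t == 0.0


def test_welch_matches_scipy_reference():
    from scipy.stats import ttest_ind_from_stats

    a, b = GroupSummary(56.9, 8.4, 38), GroupSummary(57.5, 4.4, 65)
    t, df = welch_t(a, b)
    ref = ttest_ind_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=False)
    assert t == pytest.approx(ref.statistic, abs=1e-12)


def test_welch_sign_flip_and_df_bound(rng):
    for _ in range(10):
        a = GroupSummary(rng.normal(), rng.uniform(0.5, 3), int(rng.integers(3, 40)))
        b = GroupSummary(rng.normal(), rng.uniform(0.5, 3), int(rng.integers(3, 40)))
        t_ab, df_ab = welch_t(a, b)
        t_ba, df_ba = welch_t(b, a)
        assert t_ab == -t_ba and df_ab == df_ba
        assert df_ab <= a.n + b.n - 2 + 1e-9
        assert df_ab >= min(a.n, b.n) - 1 - 1e-9


def test_degenerate_zero_variance_errors():
    with pytest.raises(ValueError, match="zero variance"):
        welch_t(GroupSummary(5.0, 0.0, 10), GroupSummary(5.0, 0.0, 10))
    with pytest.raises(ValueError, match="zero variance"):
        pooled_t(GroupSummary(5.0, 0.0, 10), GroupSummary(6.0, 0.0, 10))


def test_summary_stats_validation():
    with pytest.raises(ValueError):
        GroupSummary(1.0, -0.1, 10)
    with pytest.raises(ValueError):
        GroupSummary(1.0, 1.0, 1)


# --- chi-square -------------------------------------------------------------

def test_proportional_rows_give_zero():
    stat, df = chi_square([[10, 20, 30], [1, 2, 3]])
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert df == 2


def test_invariant_under_row_and_column_permutation(rng):
    tab = rng.integers(1, 30, size=(3, 4))
    s0, _ = chi_square(tab)
    s1, _ = chi_square(tab[::-1])
    s2, _ = chi_square(tab[:, rng.permutation(4)])
    assert s0 == pytest.approx(s1, abs=1e-9) == pytest.approx(s2, abs=1e-9)


def test_degenerate_tables_rejected():
    with pytest.raises(ValueError, match="all-zero"):
        chi_square([[0, 0], [1, 2]])
    with pytest.raises(ValueError, match="non-negative"):
        chi_square([[1, -2], [3, 4]])
    with pytest.raises(ValueError):
        chi_square(np.zeros((2, 2)))


# --- tallies ----------------------------------------------------------------

def _endorsing_subjects(group, n, label, k):
    """k of n subjects endorse `label`, one of them twice (dedup check)."""
    subs = []
    tri = [(1, 1), (5, 1), (3, 4)]
    for i in range(n):
        concerns = []
        if i < k:
            concerns.append(ConcernEntry(polygon=tri, affects=[Affect(label)]))
            if i == 0:
                concerns.append(ConcernEntry(polygon=tri, affects=[Affect(label)]))
        subs.append(SubjectRecord(id=f"{group}{i}", group=group, concerns=concerns))
    return subs


def test_subject_counts_once_per_label():
    subs = _endorsing_subjects("m", 65, "frustrated", 19)
    tal = tally(subs, "affects")
    row = tal[(tal.label == "frustrated") & (tal.group == "m")].iloc[0]
    assert row["count"] == 19
    assert row["percent"] == 29.2


@pytest.mark.parametrize("count,n,expect", [(46, 48, 95.8), (15, 17, 88.2), (19, 65, 29.2)])
def test_percentages_round_half_up_to_one_decimal(count, n, expect):
    subs = _endorsing_subjects("g", n, "too large", count)
    tal = tally(subs, "affects")
    assert tal[tal.label == "too large"].iloc[0]["percent"] == expect


def test_label_endorsed_by_nobody_and_unknown_field():
    subs = _endorsing_subjects("g", 5, "sad", 0)
    tal = tally(subs, "affects")
    assert len(tal) == 0  # no labels seen at all
    with pytest.raises(ValueError, match="field"):
        tally(subs, "emotions")


def test_concern_type_tally_counts_groups_separately():
    tri = [(1, 1), (5, 1), (3, 4)]
    subs = [
        SubjectRecord(id="a0", group="a",
                      concerns=[ConcernEntry(polygon=tri, concern_types=["acne", "bulgy"])]),
        SubjectRecord(id="a1", group="a", concerns=[]),
        SubjectRecord(id="b0", group="b",
                      concerns=[ConcernEntry(polygon=tri, concern_types=["acne"])]),
    ]
    tal = tally(subs, "concern_types")
    acne = tal[tal.label == "acne"].set_index("group")
    assert acne.loc["a", "count"] == 1 and acne.loc["a", "percent"] == 50.0
    assert acne.loc["b", "count"] == 1 and acne.loc["b", "percent"] == 100.0


# --- Benjamini-Hochberg -----------------------------------------------------

def test_bh_single_p_unchanged_and_stepup_minima():
    assert bh_adjust([0.03]) == [0.03]
    adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])


def test_bh_monotone_order_preserving_capped(rng):
    p = np.sort(rng.uniform(size=12))
    adj = np.array(bh_adjust(p))
    assert (adj >= p - 1e-15).all()
    assert (np.diff(adj) >= -1e-15).all()          # order preserved on sorted input
    assert (adj <= 1.0).all()
    # re-adjusting can only move values up, never below the first adjustment
    assert (np.array(bh_adjust(adj)) >= adj - 1e-15).all()
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


# --- MANCOVA ----------------------------------------------------------------

def _toy_mancova_data():
    rng = np.random.default_rng(2024)
    n = 12
    group = np.array(["a"] * 6 + ["b"] * 6)
    cov = rng.normal(size=n)
    y1 = 0.5 * cov + (group == "b") * 1.2 + rng.normal(scale=0.7, size=n)
    y2 = -0.3 * cov + (group == "b") * 0.4 + rng.normal(scale=0.5, size=n)
    return np.column_stack([y1, y2]), group, cov


def test_wilks_lambda_matches_independent_reference():
    Y, group, cov = _toy_mancova_data()
    res = mancova_wilks(Y, group, [cov], response_names=["y1", "y2"])
    # oracle: statsmodels MANOVA on the identical design
    from statsmodels.multivariate.manova import MANOVA

    df = pd.DataFrame({"y1": Y[:, 0], "y2": Y[:, 1], "g": group, "cov": cov})
    tab = MANOVA.from_formula("y1 + y2 ~ cov + g", data=df).mv_test().results["g"]["stat"]
    assert res.wilks_lambda == pytest.approx(tab.loc["Wilks' lambda", "Value"], abs=1e-9)
    assert res.F == pytest.approx(tab.loc["Wilks' lambda", "F Value"], abs=1e-6)
    assert 0 < res.wilks_lambda <= 1


def test_posthoc_ancova_matches_ols_f_test():
    Y, group, cov = _toy_mancova_data()
    res = mancova_wilks(Y, group, [cov], response_names=["y1", "y2"])
    import statsmodels.api as sm

    X_full = sm.add_constant(np.column_stack([cov, (group == "b").astype(float)]))
    X_red = sm.add_constant(cov)
    for j, post in enumerate(res.posthoc):
        full = sm.OLS(Y[:, j], X_full).fit()
        red = sm.OLS(Y[:, j], X_red).fit()
        F_ref = ((red.ssr - full.ssr) / 1) / (full.ssr / full.df_resid)
        assert post.F == pytest.approx(F_ref, abs=1e-9)
        eta = (red.ssr - full.ssr) / red.ssr
        assert post.partial_eta_sq == pytest.approx(eta, abs=1e-9)
        assert post.cohen_f == pytest.approx(np.sqrt(eta / (1 - eta)), abs=1e-9)


def test_identical_adjusted_means_give_lambda_one():
    rng = np.random.default_rng(7)
    n = 16
    group = np.array(["a", "b"] * 8)
    cov = rng.normal(size=n)
    Y = np.column_stack([cov + rng.normal(scale=0.3, size=n),
                         rng.normal(size=n)])
    # force exactly equal group means after covariate adjustment by
    # symmetrizing responses across the paired a/b subjects
    Y[1::2] = Y[0::2]
    cov[1::2] = cov[0::2]
    res = mancova_wilks(Y, group, [cov])
    assert res.wilks_lambda == pytest.approx(1.0, abs=1e-9)
    assert res.F == pytest.approx(0.0, abs=1e-9)


def test_constant_covariate_is_dropped_leaving_lambda_unchanged():
    Y, group, cov = _toy_mancova_data()
    base = mancova_wilks(Y, group, [cov])
    with_const = mancova_wilks(Y, group, [cov, np.full(len(group), 3.7)])
    assert with_const.wilks_lambda == pytest.approx(base.wilks_lambda, abs=1e-12)


def test_collinear_covariates_rejected_with_names():
    Y, group, cov = _toy_mancova_data()
    with pytest.raises(ValueError, match="collinear"):
        mancova_wilks(Y, group, [cov, 2.0 * cov])


def test_sample_size_guard():
    rng = np.random.default_rng(0)
    Y = rng.normal(size=(5, 3))
    with pytest.raises(ValueError, match="too small"):
        mancova_wilks(Y, ["a", "a", "b", "b", "b"], [rng.normal(size=5)])
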