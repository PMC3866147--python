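"""Exact association tests, the hierarchical cascade, and the log-linear
model against a statsmodels GLM oracle."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from contactzone import assoc


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------


def test_uniform_table_p_one():
    assert assoc.fisher_exact([[1, 1], [1, 1]]) == pytest.approx(1.0)


def test_diagonal_table_hypergeometric():
    # 2 of the 20 equally-margined tables are as or more extreme
    assert assoc.fisher_exact([[3, 0], [0, 3]]) == pytest.approx(0.1)


def test_2x2_matches_scipy():
    from scipy.stats import fisher_exact as scipy_fisher

    tables = [[[5, 1], [2, 7]], [[8, 2], [3, 9]], [[1, 4], [6, 2]]]
    for t in tables:
        ours = assoc.fisher_exact(t)
        theirs = scipy_fisher(np.array(t)).pvalue
        assert ours == pytest.approx(theirs, abs=1e-9)


def test_mc_agrees_with_enumeration_3x3():
    t = [[4, 1, 2], [2, 5, 1], [1, 2, 6]]
    p_enum = assoc.fisher_exact(t, method="enumerate")
    n_mc = 10_000
    p_mc = assoc.fisher_exact(t, method="mc", n_mc=n_mc, seed=2)
    se = math.sqrt(p_enum * (1 - p_enum) / n_mc)
    assert abs(p_mc - p_enum) < 3 * se + 1 / n_mc


def test_p_invariant_to_row_column_permutation():
    rng = np.random.default_rng(4)
    t = rng.integers(0, 5, size=(3, 3))
    t[0, 0] += 1  # ensure non-degenerate margins
    base = assoc.fisher_exact(t, method="enumerate")
    for rp in ((1, 0, 2), (2, 1, 0), (1, 2, 0)):
        tp = t[list(rp)][:, [2, 0, 1]]
        assert assoc.fisher_exact(tp, method="enumerate") == \
            pytest.approx(base, abs=1e-9)


def test_zero_margins_dropped_with_warning():
    with pytest.warns(UserWarning, match="zero-margin"):
        p = assoc.fisher_exact([[3, 0, 2], [1, 0, 4], [0, 0, 0]])
    assert 0 < p <= 1


# ---------------------------------------------------------------------------
# Hierarchical cascade
# ---------------------------------------------------------------------------


def _individuals(spec):
    """spec: list of (group label, trait, count)."""
    rows = []
    for grp, trait, n in spec:
        rows += [dict(group=grp, trait=trait)] * n
    return pd.DataFrame(rows)


def test_single_test_correction_is_identity_and_cascade_descends():
    data = _individuals([
        ("1-1", "x", 25), ("1-2", "y", 15),
        ("2-1", "y", 17), ("2-1", "x", 2),
        ("2-2", "y", 18), ("2-2", "x", 3),
    ])
    rep = assoc.hierarchical_association(data, "group", "trait", seed=1)
    top = rep.rows[rep.rows["level"] == 0].iloc[0]
    assert top["n_tests"] == 1
    assert top["corrected_p"] == pytest.approx(top["raw_p"])
    assert top["corrected_p"] < 0.05
    # group 1 splits perfectly -> significant; group 2 is uniform -> not
    lvl1 = rep.rows[rep.rows["level"] == 1].set_index("parent")
    assert lvl1.loc["1", "corrected_p"] < 0.05
    assert lvl1.loc["2", "corrected_p"] > 0.05


def test_bonferroni_cap_and_monotonicity():
    data = _individuals([
        ("1-1", "x", 6), ("1-1", "y", 5), ("1-2", "x", 5), ("1-2", "y", 6),
        ("2-1", "x", 6), ("2-1", "y", 5), ("2-2", "x", 5), ("2-2", "y", 6),
        ("3-1", "x", 30), ("3-2", "y", 30),
    ])
    rep = assoc.hierarchical_association(data, "group", "trait", seed=2)
    tested = rep.rows[rep.rows["status"] == "tested"]
    assert (tested["corrected_p"] >= tested["raw_p"] - 1e-12).all()
    assert (tested["corrected_p"] <= 1.0).all()


def test_non_significant_overall_stops_cascade():
    data = _individuals([
        ("1-1", "x", 5), ("1-1", "y", 5), ("1-2", "x", 5), ("1-2", "y", 5),
        ("2-1", "x", 5), ("2-1", "y", 5), ("2-2", "x", 5), ("2-2", "y", 5),
    ])
    rep = assoc.hierarchical_association(data, "group", "trait", seed=3)
    assert (rep.rows["level"] == 0).all()  # no descent attempted


def test_untestable_branch_flagged():
    data = _individuals([
        ("1-1", "x", 25), ("1-2", "y", 25),
        ("2-1", "x", 30), ("2-2", "x", 5),  # trait constant within group 2
    ])
    rep = assoc.hierarchical_association(data, "group", "trait", seed=4)
    lvl1 = rep.rows[rep.rows["level"] == 1].set_index("parent")
    assert lvl1.loc["2", "status"] == "unable to test"
    assert math.isnan(lvl1.loc["2", "raw_p"])


def test_no_signal_rejection_rate_bounded():
    """Trait independent of group: level-0 rejection rate <= alpha-ish."""
    rng = np.random.default_rng(5)
    rejections = 0
    n_rep = 200
    for _ in range(n_rep):
        grp = rng.choice(["1", "2", "3"], size=36)
        trait = rng.choice(["x", "y"], size=36)
        data = pd.DataFrame({"group": grp, "trait": trait})
        rep = assoc.hierarchical_association(data, "group", "trait",
                                             n_mc=500,
                                             seed=int(rng.integers(2**31)))
        top = rep.rows[rep.rows["level"] == 0]
        if len(top) and top.iloc[0]["status"] == "tested" and \
                top.iloc[0]["corrected_p"] <= 0.05:
            rejections += 1
    # exact tests are conservative; allow binomial noise around alpha
    assert rejections / n_rep <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_rep)


# ---------------------------------------------------------------------------
# Log-linear / IPF
# ---------------------------------------------------------------------------


def test_exact_independence_all_terms_zero():
    a = np.array([10.0, 20.0])
    b = np.array([5.0, 15.0])
    c = np.array([8.0, 12.0])
    table = np.einsum("i,j,k->ijk", a, b, c) / (a.sum() * b.sum())
    res = assoc.loglinear_independence(table)
    assert (res.terms["g2"].abs() < 1e-8).all()


def test_ipf_matches_statsmodels_glm_oracle():
    """2x2x2: homogeneous-association expecteds equal a Poisson GLM with
    all two-way interactions."""
    import statsmodels.api as sm

    obs = np.array([[[12.0, 5.0], [7.0, 9.0]], [[3.0, 14.0], [10.0, 4.0]]])
    exp = assoc.ipf(obs, [(0, 1), (0, 2), (1, 2)], tol=1e-12)

    rows = []
    for i, j, k in itertools.product(range(2), repeat=3):
        rows.append(dict(y=obs[i, j, k], a=i, b=j, c=k))
    df = pd.DataFrame(rows)
    X = pd.get_dummies(df[["a", "b", "c"]].astype("category"),
                       drop_first=True).astype(float)
    X["ab"] = X.iloc[:, 0] * X.iloc[:, 1]
    X["ac"] = X.iloc[:, 0] * X.iloc[:, 2]
    X["bc"] = X.iloc[:, 1] * X.iloc[:, 2]
    X = sm.add_constant(X)
    fit = sm.GLM(df["y"], X, family=sm.families.Poisson()).fit()
    oracle = fit.fittedvalues.to_numpy().reshape(2, 2, 2)
    assert np.allclose(exp, oracle, atol=1e-6)


def test_three_way_df_formula():
    rng = np.random.default_rng(6)
    table = rng.integers(1, 20, size=(3, 4, 2)).astype(float)
    res = assoc.loglinear_independence(table)
    assert res.term("three-way")["df"] == (3 - 1) * (4 - 1) * (2 - 1)


def test_ipf_mask_excludes_structural_zeros():
    obs = np.array([[[5.0, 0.0], [3.0, 2.0]], [[4.0, 1.0], [0.0, 6.0]]])
    mask = obs > 0
    exp = assoc.ipf(obs, [(0, 1), (0, 2), (1, 2)], mask=mask, tol=1e-10)
    assert exp[~mask].sum() == 0
    res = assoc.loglinear_independence(obs, mask=mask)
    assert res.term("three-way")["df"] == max((2 - 1) ** 3 - 2, 0)
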