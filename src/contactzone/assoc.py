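"""Cross-variable concordance tests.

Fisher's exact test on r x c contingency tables (full enumeration when the
fixed-margin table space is small, else seeded Monte Carlo), a hierarchical
testing cascade with per-level Bonferroni correction that descends only
below significant parents, and a log-linear (iterative proportional
fitting) test of three-trait independence with G-squared statistics.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# Fisher's exact test for r x c tables
# ---------------------------------------------------------------------------


def _log_table_prob(table: np.ndarray) -> float:
    """Log hypergeometric probability of a table given its margins."""
    t = np.asarray(table)
    lp = sum(math.lgamma(m + 1) for m in t.sum(axis=1))
    lp += sum(math.lgamma(m + 1) for m in t.sum(axis=0))
    lp -= math.lgamma(t.sum() + 1)
    lp -= sum(math.lgamma(v + 1) for v in t.ravel())
    return lp


def _enumerate_fixed_margins(rows: np.ndarray, cols: np.ndarray,
                             cap: int):
    """Yield all tables with the given margins (stops past ``cap``)."""
    r, c = len(rows), len(cols)
    count = 0

    def rec(i: int, remaining_cols: np.ndarray, current: list):
        nonlocal count
        if count > cap:
            return
        if i == r - 1:
            if np.all(remaining_cols >= 0):
                count += 1
                yield np.array(current + [remaining_cols.tolist()])
            return
        # enumerate row i summing to rows[i], bounded by remaining columns
        def cells(j: int, left: int, row: list):
            if j == c - 1:
                if left <= remaining_cols[j]:
                    yield row + [left]
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                yield from cells(j + 1, left - v, row + [v])

        for row in cells(0, int(rows[i]), []):
            yield from rec(i + 1, remaining_cols - np.array(row),
                           current + [row])

    yield from rec(0, cols.astype(int).copy(), [])


def _count_tables_upper_bound(rows: np.ndarray, cols: np.ndarray) -> float:
    """Crude upper bound on the number of fixed-margin tables."""
    c = len(cols)
    # float arithmetic: integer powers overflow silently for big tables
    out = 1.0
    for ri in rows[:-1]:
        out *= float(min(ri + 1, cols.sum() + 1)) ** (c - 1)
    return out


def fisher_exact(table, method: str = "auto", n_mc: int = 100_000,
                 seed: int = 0, max_enumeration: int = 1_000_000) -> float:
    """Conditional exact test of independence with probability ordering.

    p = Pr(P(T) <= P(observed)) over tables with the observed margins.
    Zero-margin rows/columns are dropped with a warning. ``method`` is
    ``auto`` (enumerate when feasible, else Monte Carlo), ``enumerate`` or
    ``mc``. The Monte Carlo p carries the +1 correction.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or np.any(t < 0) or t.sum() < 1:
        raise ValueError("need a non-negative 2-D table with total >= 1")
    keep_r = t.sum(axis=1) > 0
    keep_c = t.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("dropping zero-margin rows/columns")
        t = t[keep_r][:, keep_c]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return 1.0
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    lp_obs = _log_table_prob(t)

    do_enum = method == "enumerate" or (
        method == "auto"
        and _count_tables_upper_bound(rows, cols) <= max_enumeration)
    if do_enum:
        total = 0.0
        hit = 0.0
        complete = True
        for tab in _enumerate_fixed_margins(rows, cols, cap=max_enumeration):
            lp = _log_table_prob(tab)
            total += math.exp(lp)
            if lp <= lp_obs + 1e-9:
                hit += math.exp(lp)
        if method == "enumerate" or abs(total - 1) < 1e-6:
            return min(hit / total, 1.0)
        complete = False  # bound lied; fall through to MC
    rng = np.random.default_rng(seed)
    # individuals-with-labels representation: permuting column labels samples
    # the fixed-margin null exactly
    row_lab = np.repeat(np.arange(len(rows)), rows)
    col_lab = np.repeat(np.arange(len(cols)), cols)
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(col_lab)
        sim = np.zeros_like(t)
        np.add.at(sim, (row_lab, perm), 1)
        if _log_table_prob(sim) <= lp_obs + 1e-9:
            hits += 1
    return (1 + hits) / (1 + n_mc)


# ---------------------------------------------------------------------------
# Hierarchical testing cascade
# ---------------------------------------------------------------------------


@dataclass
class HierarchicalTestReport:
    rows: pd.DataFrame  # analysis, level, raw_p, corrected_p, n_tests, status

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        ok = self.rows["status"] == "tested"
        return self.rows[ok & (self.rows["corrected_p"] <= alpha)]


def _children(parent: str | None, labels: pd.Series) -> list[str]:
    """Distinct child prefixes one level below ``parent`` ("1" -> 1-1, 1-2)."""
    if parent is None:
        depth = 1
    else:
        depth = parent.count("-") + 2
    kids = set()
    for lab in labels.dropna():
        parts = str(lab).split("-")
        if len(parts) >= depth and (parent is None or
                                    "-".join(parts[:depth - 1]) == parent):
            kids.add("-".join(parts[:depth]))
    return sorted(kids)


def hierarchical_association(
    data: pd.DataFrame,
    group_col: str,
    trait_col: str,
    alpha: float = 0.05,
    min_per_cell: int = 1,
    n_mc: int = 100_000,
    seed: int = 0,
) -> HierarchicalTestReport:
    """Fisher-exact cascade down a hierarchy of nested group labels.

    ``data`` holds one row per individual with a hierarchical group label
    (e.g. "1-1-2") and a trait category. The overall test compares the
    top-level groups; the cascade then descends only into branches whose
    test was significant after the per-level Bonferroni correction
    (corrected p = min(1, raw p x number of tests attempted at that level)).
    Branches whose individuals lack both data types, or that have fewer than
    two testable categories, are flagged "unable to test".
    """
    df = data[[group_col, trait_col]].dropna()
    rng = np.random.default_rng(seed)

    levels: list[list[str | None]] = [[None]]
    results = []
    level_no = 0
    while levels[-1]:
        parents = levels[-1]
        attempted = []
        for parent in parents:
            kids = _children(parent, df[group_col])
            if len(kids) < 2:
                continue
            sub = df[[any(str(g) == k or str(g).startswith(k + "-")
                          for k in kids) for g in df[group_col]]].copy()
            sub["grp"] = [next(k for k in kids if str(g) == k or
                               str(g).startswith(k + "-"))
                          for g in sub[group_col]]
            tab = pd.crosstab(sub["grp"], sub[trait_col])
            tab = tab.loc[tab.sum(axis=1) > 0, tab.sum(axis=0) > 0]
            name = " v ".join(kids)
            if tab.shape[0] < 2 or tab.shape[1] < 2 or \
                    tab.to_numpy().sum() < 2 * min_per_cell:
                attempted.append(dict(analysis=name, parent=parent,
                                      level=level_no, raw_p=np.nan,
                                      status="unable to test", kids=kids))
                continue
            p = fisher_exact(tab.to_numpy(), n_mc=n_mc,
                             seed=int(rng.integers(2**31)))
            attempted.append(dict(analysis=name, parent=parent,
                                  level=level_no, raw_p=p, status="tested",
                                  kids=kids))
        n_tests = sum(1 for a in attempted if a["status"] == "tested")
        next_parents = []
        for a in attempted:
            if a["status"] == "tested":
                a["corrected_p"] = min(1.0, a["raw_p"] * n_tests)
                if a["corrected_p"] <= alpha:
                    next_parents.extend(a["kids"])
            else:
                a["corrected_p"] = np.nan
            a["n_tests"] = n_tests
            a.pop("kids")
            results.append(a)
        levels.append(sorted(set(next_parents)))
        level_no += 1
    return HierarchicalTestReport(rows=pd.DataFrame(
        results, columns=["analysis", "parent", "level", "raw_p",
                          "corrected_p", "n_tests", "status"]))


# ---------------------------------------------------------------------------
# Log-linear three-trait independence (IPF)
# ---------------------------------------------------------------------------


@dataclass
class LogLinearResult:
    terms: pd.DataFrame  # term, g2, df, p
    expected: dict = field(default_factory=dict)

    def term(self, name: str) -> pd.Series:
        return self.terms.set_index("term").loc[name]


def ipf(observed: np.ndarray, margins: list[tuple[int, ...]],
        mask: np.ndarray | None = None, tol: float = 1e-10,
        max_iter: int = 10_000) -> np.ndarray:
    """Iterative proportional fitting of a log-linear model.

    Fits expected counts matching the observed totals over each margin in
    ``margins`` (tuples of axis indices to keep). ``mask`` marks structural
    zeros (False = structurally impossible cell, held at 0).
    """
    obs = np.asarray(observed, dtype=float)
    if mask is None:
        mask = np.ones_like(obs, dtype=bool)
    exp = np.where(mask, 1.0, 0.0)
    exp *= obs.sum() / exp.sum()
    axes_all = set(range(obs.ndim))
    floor = 1e-12 * obs.sum()
    for it in range(max_iter):
        delta = 0.0
        for keep in margins:
            drop = tuple(sorted(axes_all - set(keep)))
            target = obs.sum(axis=drop, keepdims=True)
            current = exp.sum(axis=drop, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(current > 0, target / current, 1.0)
            new = exp * ratio
            delta = max(delta, float(np.max(np.abs(new - exp))))
            exp = new
        if delta < tol:
            return exp
        if it % 50 == 49:
            # sampling-zero patterns put the MLE on the boundary, where
            # plain IPF converges only as 1/iteration; freezing cells that
            # are collapsing towards zero restores geometric convergence
            exp = np.where(exp < floor, 0.0, exp)
    raise RuntimeError(f"IPF did not converge within {max_iter} iterations "
                       f"(last change {delta:.3g})")


def _g2(obs: np.ndarray, exp: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    return float(2 * terms.sum())


def loglinear_independence(counts: np.ndarray,
                           mask: np.ndarray | None = None,
                           tol: float = 1e-10,
                           max_iter: int = 10_000) -> LogLinearResult:
    """Hierarchical log-linear analysis of a three-way count table.

    The three-way interaction is tested as saturated versus the homogeneous
    association (all two-way) model; each two-way term is tested by dropping
    it from the homogeneous-association model. G2 = 2 sum obs ln(obs/exp).
    Structurally impossible cells are excluded by ``mask`` with the degrees
    of freedom reduced by the number of masked cells.
    """
    obs = np.asarray(counts, dtype=float)
    if obs.ndim != 3:
        raise ValueError("need a 3-dimensional count table")
    if mask is None:
        mask = np.ones_like(obs, dtype=bool)
    r, c, l = obs.shape
    from scipy.stats import chi2

    all_two_way = [(0, 1), (0, 2), (1, 2)]
    exp_hom = ipf(obs, all_two_way, mask=mask, tol=tol, max_iter=max_iter)
    df3 = (r - 1) * (c - 1) * (l - 1) - int((~mask).sum())
    df3 = max(df3, 0)
    g2_3 = _g2(obs, np.where(exp_hom > 0, exp_hom, np.nan))
    rows = [dict(term="three-way", g2=g2_3, df=df3,
                 p=float(chi2.sf(g2_3, df3)) if df3 > 0 else np.nan)]
    expected = {"homogeneous": exp_hom}
    dims = {0: r, 1: c, 2: l}
    for pair in all_two_way:
        reduced = [m for m in all_two_way if m != pair]
        # keep single-factor margins implied by the dropped term
        reduced = reduced + [(pair[0],), (pair[1],)]
        exp_red = ipf(obs, reduced, mask=mask, tol=tol, max_iter=max_iter)
        g2_term = _g2(obs, np.where(exp_red > 0, exp_red, np.nan)) - g2_3
        a, b = pair
        other = ({0, 1, 2} - set(pair)).pop()
        df_term = (dims[a] - 1) * (dims[b] - 1)
        rows.append(dict(term=f"two-way {a}x{b}", g2=max(g2_term, 0.0),
                         df=df_term,
                         p=float(chi2.sf(max(g2_term, 0.0), df_term))))
        expected[f"drop {a}x{b}"] = exp_red
    return LogLinearResult(terms=pd.DataFrame(rows), expected=expected)
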