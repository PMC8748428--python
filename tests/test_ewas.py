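"""EWAS statistics against closed forms and independent brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import special

from equiclock import BetaMatrix
from equiclock.errors import DomainError
from equiclock.ewas import (
    bh_fdr,
    category_association,
    cohens_d_screen,
    correlation_screen,
    fisher_z,
    overlap_test,
    select_top,
    stouffer_meta,
)


def _beta(values, sample_prefix="s", columns=None):
    values = np.asarray(values, dtype=float)
    idx = pd.Index([f"{sample_prefix}{i}" for i in range(values.shape[0])],
                   name="sample_id")
    cols = columns or [f"cg{j}" for j in range(values.shape[1])]
    return BetaMatrix(pd.DataFrame(values, index=idx, columns=cols))


# --- correlation screen ----------------------------------------------------


def test_fisher_z_closed_forms():
    assert fisher_z(0.0, 100) == 0.0
    # r = 0.5, n = 39: z = 6 * atanh(0.5)
    assert fisher_z(0.5, 39) == pytest.approx(6 * math.atanh(0.5), abs=1e-12)
    assert fisher_z(0.5, 39) == pytest.approx(3.2958368660, abs=1e-9)


def test_screen_closed_form_r_half_n39():
    """Construct data with exact r = 0.5 at n = 39 and check t, p, z."""
    n = 39
    rng = np.random.default_rng(8)
    x = rng.normal(size=n)
    e = rng.normal(size=n)
    # orthogonalize e against x, then mix for exact correlation 0.5
    x = (x - x.mean()) / x.std()
    e = e - e.mean()
    e = e - x * (x @ e) / (x @ x)
    e /= np.linalg.norm(e)
    y = 0.5 * x / np.linalg.norm(x) + np.sqrt(1 - 0.25) * e
    col = 0.5 + 0.4 * y / np.max(np.abs(y))
    beta = _beta(col[:, None])
    tab = correlation_screen(beta, x)
    assert tab["r"].iloc[0] == pytest.approx(0.5, abs=1e-12)
    assert tab["t"].iloc[0] == pytest.approx(
        0.5 * math.sqrt(37 / 0.75), abs=1e-9)        # 3.51188...
    assert tab["p"].iloc[0] == pytest.approx(0.00121, abs=2e-5)
    assert tab["z"].iloc[0] == pytest.approx(3.29584, abs=1e-5)


def test_screen_matches_per_cpg_loop_oracle():
    """Vectorised screen equals a naive loop (incl. missing values) to 1e-12."""
    rng = np.random.default_rng(17)
    X = rng.uniform(size=(50, 200))
    X[rng.uniform(size=X.shape) < 0.05] = np.nan  # pairwise-complete handling
    trait = rng.uniform(0, 30, 50)
    tab = correlation_screen(_beta(X), trait)
    for j in rng.choice(200, 60, replace=False):
        col = X[:, j]
        ok = np.isfinite(col)
        n = ok.sum()
        r = np.corrcoef(col[ok], trait[ok])[0, 1]
        t = r * math.sqrt((n - 2) / (1 - r * r))
        p = special.betainc((n - 2) / 2.0, 0.5, (n - 2) / ((n - 2) + t * t))
        z = math.sqrt(n - 3) * math.atanh(r)
        row = tab.iloc[j]
        assert row["n"] == n
        assert row["r"] == pytest.approx(r, abs=1e-12)
        assert row["t"] == pytest.approx(t, abs=1e-10)
        assert row["p"] == pytest.approx(p, abs=1e-12)
        assert row["z"] == pytest.approx(z, abs=1e-10)


def test_screen_flags_constant_cpg():
    X = np.column_stack([np.linspace(0.1, 0.9, 20), np.full(20, 0.5)])
    tab = correlation_screen(_beta(X), np.arange(20.0))
    assert np.isnan(tab["r"].iloc[1])
    assert np.isnan(tab["q"].iloc[1])
    assert np.isfinite(tab["q"].iloc[0])


# --- Stouffer --------------------------------------------------------------


def _table(z, n=50):
    idx = pd.Index([f"cg{j}" for j in range(len(z))], name="cpg_id")
    z = np.asarray(z, dtype=float)
    return pd.DataFrame({"n": n, "r": 0.1, "t": 1.0, "p": 0.5, "z": z,
                         "q": 0.5}, index=idx)


def test_stouffer_closed_forms():
    meta = stouffer_meta({"blood": _table([2.0, 3.0]), "liver": _table([2.0, -3.0])})
    assert meta["meta_z"].iloc[0] == pytest.approx(4 / math.sqrt(2), abs=1e-12)
    assert meta["meta_z"].iloc[1] == pytest.approx(0.0, abs=1e-12)
    assert meta["meta_p"].iloc[1] == pytest.approx(1.0, abs=1e-12)


def test_stouffer_identical_tissues_scale_sqrt_k():
    z = [1.3, -0.7, 2.2]
    for k in (2, 4):
        tables = {f"t{i}": _table(z) for i in range(k)}
        meta = stouffer_meta(tables)
        np.testing.assert_allclose(meta["meta_z"], np.array(z) * math.sqrt(k),
                                   atol=1e-12)


def test_stouffer_order_invariant_and_needs_two():
    a = stouffer_meta({"x": _table([1.0, 2.0]), "y": _table([0.5, -1.0])})
    b = stouffer_meta({"y": _table([0.5, -1.0]), "x": _table([1.0, 2.0])})
    pd.testing.assert_frame_equal(a, b)
    with pytest.raises(DomainError):
        stouffer_meta({"x": _table([1.0])})


def test_stouffer_flags_single_tissue_cpgs():
    t1 = _table([1.0, 2.0])
    t2 = _table([1.0]).iloc[:1]  # only cg0
    meta = stouffer_meta({"a": t1, "b": t2})
    assert np.isfinite(meta.loc["cg0", "meta_z"])
    assert np.isnan(meta.loc["cg1", "meta_z"])


# --- BH FDR ----------------------------------------------------------------


def _bh_oracle(p):
    """Independent step-up implementation."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        val = min(prev, p[idx] * m / rank)
        q[idx] = val
        prev = val
    return q


def test_bh_hand_example_and_single():
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04], atol=1e-15)
    assert bh_fdr([0.37])[0] == 0.37


def test_bh_matches_brute_force_oracle():
    rng = np.random.default_rng(23)
    p = rng.uniform(size=10_000)
    np.testing.assert_allclose(bh_fdr(p), _bh_oracle(p), rtol=0, atol=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(DomainError):
        bh_fdr([0.5, 1.2])


# --- top-k selection -------------------------------------------------------


def test_select_top_basic_and_ties():
    tab = pd.DataFrame({"z": [2.0, -1.0, 5.0]},
                       index=pd.Index(["cgA", "cgB", "cgC"], name="cpg_id"))
    pos, neg = select_top(tab, k=1)
    assert list(pos) == ["cgC"] and list(neg) == ["cgB"]
    tied = pd.DataFrame({"z": [3.0, 3.0, -3.0, -3.0]},
                        index=pd.Index(["cgZ", "cgA", "cgY", "cgB"],
                                       name="cpg_id"))
    pos, neg = select_top(tied, k=1)
    assert list(pos) == ["cgA"] and list(neg) == ["cgB"]  # lexicographic ties


# --- overlap test ----------------------------------------------------------


def _hypergeom_oracle(shared, N, nA, nB):
    """Exact upper tail by enumeration."""
    total = math.comb(N, nB)
    return sum(math.comb(nA, k) * math.comb(N - nA, nB - k)
               for k in range(shared, min(nA, nB) + 1)) / total


def test_overlap_exact_example():
    shared, odds, p = overlap_test({"a", "b", "c", "d", "e"},
                                   {"a", "b", "c", "x"}, universe_size=10)
    assert shared == 3
    assert p == pytest.approx(55 / 210, abs=1e-12)
    assert odds == pytest.approx(6.0, abs=1e-12)


def test_overlap_disjoint_cover_and_identity():
    p_disjoint = overlap_test(set("abcde"), set("fghij"), 10)[2]
    assert p_disjoint == pytest.approx(1.0, abs=1e-12)
    s = set("abcd")
    shared, _, p = overlap_test(s, s, 12)
    assert shared == 4
    assert p == pytest.approx(_hypergeom_oracle(4, 12, 4, 4), abs=1e-12)


def test_overlap_matches_enumeration_oracle():
    rng = np.random.default_rng(31)
    universe = [f"u{i}" for i in range(40)]
    for _ in range(20):
        nA, nB = rng.integers(1, 25, 2)
        A = set(rng.choice(universe, nA, replace=False))
        B = set(rng.choice(universe, nB, replace=False))
        shared, _, p = overlap_test(A, B, 40)
        assert p == pytest.approx(_hypergeom_oracle(shared, 40, nA, nB),
                                  abs=1e-12)
    with pytest.raises(DomainError):
        overlap_test(set(universe), {"extra"}, 40)


# --- Cohen's d -------------------------------------------------------------


def test_cohens_d_hand_example():
    X = np.array([[0.2], [0.3], [0.4], [0.6], [0.7], [0.8]])
    labels = ["young"] * 3 + ["old"] * 3
    tab = cohens_d_screen(_beta(X), labels, old_label="old", young_label="young")
    assert tab["d"].iloc[0] == pytest.approx(4.0, abs=1e-12)
    assert tab["pooled_sd"].iloc[0] == pytest.approx(0.1, abs=1e-12)


def test_cohens_d_identical_groups_zero():
    X = np.tile(np.array([[0.2], [0.5], [0.8]]), (2, 1))
    labels = ["young"] * 3 + ["old"] * 3
    tab = cohens_d_screen(_beta(X), labels, "old", "young")
    assert tab["d"].iloc[0] == 0.0


def test_cohens_d_matches_loop_oracle():
    rng = np.random.default_rng(41)
    X = rng.uniform(size=(30, 1000))
    labels = np.array(["young"] * 12 + ["old"] * 14 + ["mid"] * 4)
    tab = cohens_d_screen(_beta(X), labels, "old", "young")
    old, young = X[labels == "old"], X[labels == "young"]
    for j in rng.choice(1000, 50, replace=False):
        s1 = np.var(old[:, j], ddof=1)
        s2 = np.var(young[:, j], ddof=1)
        pooled = math.sqrt((13 * s1 + 11 * s2) / 24)
        d = (old[:, j].mean() - young[:, j].mean()) / pooled
        assert tab["d"].iloc[j] == pytest.approx(d, abs=1e-12)


# --- Kruskal-Wallis --------------------------------------------------------


def test_kruskal_hand_value():
    h, p = category_association([1, 2, 3, 4, 5, 6],
                                ["a", "a", "a", "b", "b", "b"])
    assert h == pytest.approx(27 / 7, abs=1e-12)  # 3.857142...


def test_kruskal_all_tied_and_null_uniformity():
    h, p = category_association([2.0] * 6, ["a", "a", "a", "b", "b", "b"])
    assert h == 0.0 and p == 1.0
    rng = np.random.default_rng(57)
    pvals = []
    for _ in range(300):
        vals = rng.normal(size=40)
        cats = np.array(["a"] * 20 + ["b"] * 20)
        pvals.append(category_association(vals, cats)[1])
    # uniform null: KS-style coarse check on the empirical CDF
    pvals = np.sort(pvals)
    assert abs(np.mean(np.array(pvals) < 0.5) - 0.5) < 0.1
    with pytest.raises(DomainError):
        category_association([1, 2, 3], ["a", "a", "a"])


def test_stouffer_sqrt_n_weighting():
    """sqrt(n) weights equal the unweighted combination at equal n and
    tilt toward the larger tissue otherwise."""
    equal = stouffer_meta({"a": _table([2.0], n=50), "b": _table([1.0], n=50)},
                          weights="sqrt_n")
    plain = stouffer_meta({"a": _table([2.0], n=50), "b": _table([1.0], n=50)})
    assert equal["meta_z"].iloc[0] == pytest.approx(plain["meta_z"].iloc[0],
                                                    abs=1e-12)
    skew = stouffer_meta({"a": _table([2.0], n=200), "b": _table([1.0], n=8)},
                         weights="sqrt_n")
    # oracle: (w_a z_a + w_b z_b) / sqrt(w_a^2 + w_b^2)
    wa, wb = math.sqrt(200), math.sqrt(8)
    expect = (wa * 2.0 + wb * 1.0) / math.sqrt(wa**2 + wb**2)
    assert skew["meta_z"].iloc[0] == pytest.approx(expect, abs=1e-12)
    assert skew["meta_z"].iloc[0] > plain["meta_z"].iloc[0]
    with pytest.raises(DomainError):
        stouffer_meta({"a": _table([1.0]), "b": _table([1.0])}, weights="mean")
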