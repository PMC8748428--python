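"""Epigenome-wide association screens of a numeric trait and their meta-analysis.

The per-tissue screen is the classical Pearson-correlation EWAS: for each
CpG, the correlation r between its beta values and the trait (age), the
Student statistic t = r*sqrt((n-2)/(1-r^2)) with its two-sided p-value,
and the variance-stabilised Fisher statistic z = sqrt(n-3)*atanh(r).
Per-tissue results are combined across tissues with Stouffer's method
(sum of z over contributing tissues divided by sqrt(k)); false-discovery
control uses Benjamini-Hochberg, computed within tissue and within the
meta-analysis separately.

Missing beta values are handled pairwise-complete per CpG.  CpGs with a
constant beta vector or fewer than four complete pairs are flagged (NaN
statistics) and excluded from the q-value computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import BetaMatrix
from .errors import DomainError, ValidationError

#: clamp |r| below 1 before atanh so perfect correlations map to a large
#: finite z instead of infinity
R_CLAMP = 1.0 - 1e-15

MIN_PAIRS = 4


def fisher_z(r, n):
    """Fisher-transformed correlation statistic sqrt(n-3) * atanh(r)."""
    r = np.clip(np.asarray(r, dtype=float), -R_CLAMP, R_CLAMP)
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore"):
        z = np.where(n > 3, np.sqrt(np.maximum(n - 3.0, 0.0)) * np.arctanh(r), np.nan)
    return z if z.ndim else float(z)


def correlation_screen(beta: BetaMatrix, trait) -> pd.DataFrame:
    """Per-CpG Pearson EWAS of a numeric trait.

    Parameters
    ----------
    beta : BetaMatrix
    trait : array-like or pandas.Series
        One numeric value per sample, aligned with ``beta.sample_ids``
        (a Series is reindexed by sample id).

    Returns
    -------
    pandas.DataFrame indexed by cpg_id with columns ``n, r, t, p, z, q``.
    Flagged CpGs (constant, or < 4 complete pairs) carry NaN statistics
    and do not enter the BH adjustment.
    """
    if isinstance(trait, pd.Series):
        trait = trait.reindex(beta.sample_ids).to_numpy(dtype=float)
    else:
        trait = np.asarray(trait, dtype=float)
    if trait.shape[0] != beta.shape[0]:
        raise ValidationError(
            f"trait has {trait.shape[0]} values for {beta.shape[0]} samples")

    X = beta.values.to_numpy(dtype=float)
    finite = np.isfinite(X) & np.isfinite(trait)[:, None]

    # pairwise-complete moments per CpG, vectorised over CpGs
    n = finite.sum(axis=0).astype(float)
    Xf = np.where(finite, X, 0.0)
    yf = np.where(finite, trait[:, None], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = Xf.sum(0) / n
        my = yf.sum(0) / n
        sxx = (Xf * Xf).sum(0) / n - mx * mx
        syy = (yf * yf).sum(0) / n - my * my
        sxy = (Xf * yf).sum(0) / n - mx * my
        r = sxy / np.sqrt(sxx * syy)

    valid = (n >= MIN_PAIRS) & (sxx > 0) & (syy > 0) & np.isfinite(r)
    r = np.where(valid, np.clip(r, -1.0, 1.0), np.nan)

    rc = np.clip(r, -R_CLAMP, R_CLAMP)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rc * np.sqrt((n - 2.0) / (1.0 - rc * rc))
        p = 2.0 * stats.t.sf(np.abs(t), n - 2.0)
        z = fisher_z(r, n)

    q = np.full_like(p, np.nan)
    if valid.any():
        q[valid] = bh_fdr(p[valid])

    return pd.DataFrame(
        {"n": n.astype(int), "r": r, "t": t, "p": p, "z": z, "q": q},
        index=beta.cpg_ids,
    )


def stouffer_meta(tables: dict[str, pd.DataFrame],
                  weights: str = "equal") -> pd.DataFrame:
    """Combine per-tissue EWAS tables with Stouffer's method.

    Parameters
    ----------
    tables : dict tissue -> EWAS table (from :func:`correlation_screen`)
    weights : "equal" (default) or "sqrt_n"
        Equal weighting combines k finite z as sum(z)/sqrt(k);
        ``sqrt_n`` weights each tissue by sqrt(sample size).

    Returns
    -------
    DataFrame indexed by the union of CpGs with columns ``z_<tissue>`` per
    tissue, ``k`` (contributing tissues), ``meta_z``, ``meta_p``,
    ``meta_q``.  CpGs with fewer than two contributing tissues are flagged
    (NaN meta statistics).
    """
    if len(tables) < 2:
        raise DomainError("Stouffer meta-analysis needs at least 2 tissues")
    if weights not in ("equal", "sqrt_n"):
        raise DomainError(f"unknown weighting {weights!r}")

    tissues = sorted(tables)
    universe = tables[tissues[0]].index
    for t in tissues[1:]:
        universe = universe.union(tables[t].index)

    z_cols = {}
    n_cols = {}
    for t in tissues:
        z_cols[t] = tables[t]["z"].reindex(universe)
        n_cols[t] = tables[t]["n"].reindex(universe)
    Z = pd.DataFrame(z_cols)
    finite = Z.notna()
    k = finite.sum(axis=1)

    if weights == "equal":
        W = finite.astype(float)
    else:
        W = pd.DataFrame(n_cols).pow(0.5).where(finite, 0.0)
    num = (Z.fillna(0.0) * W).sum(axis=1)
    den = np.sqrt((W * W).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        meta_z = num / den
    meta_z[k < 2] = np.nan
    meta_p = pd.Series(2.0 * stats.norm.sf(np.abs(meta_z)), index=universe)
    meta_p[k < 2] = np.nan

    meta_q = pd.Series(np.nan, index=universe)
    ok = meta_p.notna()
    if ok.any():
        meta_q[ok] = bh_fdr(meta_p[ok].to_numpy())

    out = Z.rename(columns={t: f"z_{t}" for t in tissues})
    out["k"] = k
    out["meta_z"] = meta_z
    out["meta_p"] = meta_p
    out["meta_q"] = meta_q
    out.index.name = "cpg_id"
    return out


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_top(table: pd.DataFrame, k: int = 500,
               column: str = "z") -> tuple[pd.Index, pd.Index]:
    """Top-k positively and top-k negatively associated CpGs.

    Ranked by ``column`` descending (positive set) / ascending (negative
    set); exact ties broken by lexicographic cpg_id.  If fewer than k CpGs
    are available in a direction the set is truncated.
    """
    z = table[column].dropna()
    frame = pd.DataFrame({"stat": z.to_numpy(), "cpg": z.index.to_numpy()})
    pos = frame.sort_values(["stat", "cpg"], ascending=[False, True]).head(k)
    neg = frame.sort_values(["stat", "cpg"], ascending=[True, True]).head(k)
    return pd.Index(pos["cpg"], name="cpg_id"), pd.Index(neg["cpg"], name="cpg_id")


def overlap_test(set_a, set_b, universe_size: int):
    """Overlap of two CpG sets: count, odds ratio, upper-tail hypergeometric p.

    The odds ratio comes from the induced 2x2 table with a Haldane 0.5
    correction applied when any cell is zero.
    """
    a = set(set_a)
    b = set(set_b)
    union = a | b
    if universe_size < len(union):
        raise DomainError(
            f"universe size {universe_size} smaller than |A union B| = {len(union)}")
    shared = len(a & b)
    n_a, n_b = len(a), len(b)
    # P(X >= shared), X ~ Hypergeom(N=universe, K=n_a, n=n_b)
    p = float(stats.hypergeom.sf(shared - 1, universe_size, n_a, n_b))
    t11 = shared
    t12 = n_a - shared
    t21 = n_b - shared
    t22 = universe_size - n_a - n_b + shared
    cells = np.array([t11, t12, t21, t22], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    odds = (cells[0] * cells[3]) / (cells[1] * cells[2])
    return shared, float(odds), p


def cohens_d_screen(beta: BetaMatrix, group_labels,
                    old_label, young_label) -> pd.DataFrame:
    """Per-CpG Cohen's d between two age groups (old minus young).

    ``group_labels`` assigns each sample to a group; samples in neither
    group are ignored.  Pooled standard deviation uses the Bessel-corrected
    group variances.  CpGs with zero pooled sd are flagged (NaN d).
    """
    labels = pd.Series(np.asarray(group_labels, dtype=object),
                       index=beta.sample_ids)
    X = beta.values.to_numpy(dtype=float)
    old = (labels == old_label).to_numpy()
    young = (labels == young_label).to_numpy()
    n1, n2 = int(old.sum()), int(young.sum())
    if n1 < 2 or n2 < 2:
        raise DomainError("both groups need at least 2 samples")
    m_old = np.nanmean(X[old], axis=0)
    m_young = np.nanmean(X[young], axis=0)
    v_old = np.nanvar(X[old], axis=0, ddof=1)
    v_young = np.nanvar(X[young], axis=0, ddof=1)
    pooled = np.sqrt(((n1 - 1) * v_old + (n2 - 1) * v_young) / (n1 + n2 - 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(pooled > 0, (m_old - m_young) / pooled, np.nan)
    return pd.DataFrame(
        {"d": d, "n_old": n1, "n_young": n2, "pooled_sd": pooled},
        index=beta.cpg_ids,
    )


def category_association(values, categories):
    """Kruskal-Wallis test of a statistic (e.g. Fisher z) across CpG categories.

    Returns ``(H, p)`` with the tie-corrected H statistic and a chi-square
    p-value on (number of groups - 1) degrees of freedom.  All-tied input
    yields ``H = 0, p = 1`` rather than an error.
    """
    values = np.asarray(values, dtype=float)
    categories = np.asarray(categories)
    keep = np.isfinite(values)
    values, categories = values[keep], categories[keep]
    groups = [values[categories == c] for c in np.unique(categories)]
    if len(groups) < 2:
        raise DomainError("need at least 2 categories")
    if any(len(g) < 2 for g in groups):
        raise DomainError("every category needs at least 2 members")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)
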