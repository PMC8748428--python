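"""Castration EWAS and gelding-vs-stallion sector classification.

The castration screen regresses each CpG's beta values, in male samples
only, on a castration indicator (1 = gelding/castrated, 0 = stallion)
and chronological age in years; the castration coefficient is reported
with its t statistic, two-sided p-value and BH q-value.  Age enters
untransformed as a nuisance covariate.

The sector classification compares per-CpG aging signals (Fisher z of
the age correlation) between two groups, labelling each CpG as

shared       strong in both groups (p < p_strong) with the same sign;
A_specific   strong in A while null in B (p > p_null); symmetric for B;
neither      everything else,

with the conventional thresholds p_strong = 1e-4 and p_null = 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import BetaMatrix, SampleSheet
from .errors import AlignmentError, DesignError
from .ewas import bh_fdr

SECTOR_CLASSES = ("shared", "A_specific", "B_specific", "neither")


def covariate_screen(beta: BetaMatrix, sheet: SampleSheet,
                     extra_covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-CpG OLS of beta on castration status and age, in males.

    ``sheet`` must already be restricted to male samples with both
    castration states present.  ``extra_covariates`` (samples x columns,
    e.g. a dummy-coded breed) are appended to the design if given.

    Returns a DataFrame indexed by cpg_id with columns
    ``castration_coef`` (beta-fraction units, positive = higher
    methylation in geldings), ``t``, ``p``, ``q`` and ``age_coef``.
    """
    if not beta.sample_ids.equals(sheet.sample_ids):
        raise AlignmentError("beta and sheet must cover the same samples")
    if (sheet.table["sex"] != "male").any():
        raise DesignError("castration screen expects male samples only")
    cast = (sheet.table["castrated"] == "yes").to_numpy(dtype=float)
    if cast.min() == cast.max():
        raise DesignError("both castration states must be present")
    n = len(cast)
    if n < 10:
        raise DesignError(f"need >= 10 male samples, got {n}")

    cols = [np.ones(n), cast, sheet.age.to_numpy(dtype=float)]
    if extra_covariates is not None:
        extra = extra_covariates.reindex(sheet.sample_ids).to_numpy(dtype=float)
        cols.extend(extra.T)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("regression design is rank deficient")

    Y = beta.values.to_numpy(dtype=float)
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y                      # p_design x n_cpgs
    resid = Y - X @ B
    dof = n - X.shape[1]
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se_cast = np.sqrt(sigma2 * XtX_inv[1, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se_cast > 0, B[1] / se_cast, np.nan)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = bh_fdr(p[ok])
    return pd.DataFrame(
        {"castration_coef": B[1], "t": t, "p": p, "q": q, "age_coef": B[2]},
        index=beta.cpg_ids,
    )


def sector_classify(z_a: pd.Series, z_b: pd.Series,
                    p_strong: float = 1e-4,
                    p_null: float = 0.05) -> pd.DataFrame:
    """Classify CpGs by agreement of two groups' aging signals.

    ``z_a`` and ``z_b`` are Fisher z statistics aligned on cpg_id
    (standard-normal under the null, so p-values come from the normal).

    Returns a DataFrame with columns ``z_A``, ``z_B``, ``class``; the four
    classes are exhaustive and mutually exclusive.
    """
    if not z_a.index.equals(z_b.index):
        if set(z_a.index) != set(z_b.index):
            only_a = sorted(set(z_a.index) - set(z_b.index))[:5]
            only_b = sorted(set(z_b.index) - set(z_a.index))[:5]
            raise AlignmentError(
                f"cpg_ids differ between groups; A-only {only_a}, B-only {only_b}")
        z_b = z_b.reindex(z_a.index)
    za = z_a.to_numpy(dtype=float)
    zb = z_b.to_numpy(dtype=float)
    pa = 2.0 * stats.norm.sf(np.abs(za))
    pb = 2.0 * stats.norm.sf(np.abs(zb))

    strong_a = pa < p_strong
    strong_b = pb < p_strong
    null_a = pa > p_null
    null_b = pb > p_null
    same_sign = np.sign(za) == np.sign(zb)

    cls = np.full(len(za), "neither", dtype=object)
    cls[strong_a & strong_b & same_sign] = "shared"
    cls[strong_a & null_b] = "A_specific"
    cls[strong_b & null_a] = "B_specific"
    return pd.DataFrame({"z_A": za, "z_B": zb, "class": cls}, index=z_a.index)
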