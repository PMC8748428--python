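"""Cross-tissue coupling between promoter methylation and gene expression.

Given a methylation matrix and a log-scale expression matrix over the
same tissue samples, each promoter-window CpG is correlated (Pearson,
across samples) with the expression of its nearest gene; the correlation
is variance-stabilised to the Fisher statistic z = sqrt(n-3)*atanh(r).
CpGs with |z| > 2.8 (two-sided p < 0.005) are flagged significant, and
the significant set is summarised per chromatin state by the median z
with a notch interval (1.57 * IQR / sqrt(n), the conventional 95% CI of
a boxplot median).

Nearest-gene assignment minimises the absolute CpG-to-TSS distance; the
signed distance convention is negative upstream of the TSS relative to
gene strand, 0 at the TSS.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import BetaMatrix, CpGAnnotation
from .errors import DomainError, ValidationError
from .ewas import R_CLAMP, fisher_z

#: |z| threshold flagging a significant DNAm-mRNA association
Z_SIGNIFICANT = 2.8

#: promoter window around the TSS, signed bp (negative = upstream)
DEFAULT_PROMOTER_WINDOW = (-10_000.0, 1_000.0)


def assign_nearest_gene(cpg_positions: pd.DataFrame,
                        tss_table: pd.DataFrame) -> pd.DataFrame:
    """Assign each CpG to the gene with the closest TSS on its sequence.

    Parameters
    ----------
    cpg_positions : DataFrame indexed by cpg_id with columns ``chrom``, ``pos``.
    tss_table : DataFrame with columns ``gene``, ``chrom``, ``tss``, ``strand``
        (strand in {'+', '-'}).

    Returns
    -------
    DataFrame indexed by cpg_id with columns ``gene`` and ``tss_distance``
    (signed, negative upstream relative to gene strand).  CpGs on a
    sequence with no TSS get gene ``unassigned`` and NaN distance.
    Ties (equal absolute distance) go to the lexicographically first gene.
    """
    for col in ("chrom", "pos"):
        if col not in cpg_positions.columns:
            raise ValidationError(f"cpg_positions missing column {col!r}")
    for col in ("gene", "chrom", "tss", "strand"):
        if col not in tss_table.columns:
            raise ValidationError(f"tss_table missing column {col!r}")

    out_gene = pd.Series("unassigned", index=cpg_positions.index, dtype=object)
    out_dist = pd.Series(np.nan, index=cpg_positions.index, dtype=float)

    for chrom, cpgs in cpg_positions.groupby("chrom"):
        genes = tss_table[tss_table["chrom"] == chrom]
        if genes.empty:
            continue
        # sort TSS by position, tie-ordered by gene id so searchsorted
        # neighbours already respect the lexicographic tie rule
        genes = genes.sort_values(["tss", "gene"], kind="mergesort")
        tss = genes["tss"].to_numpy(dtype=float)
        pos = cpgs["pos"].to_numpy(dtype=float)
        right = np.searchsorted(tss, pos)
        left = np.clip(right - 1, 0, len(tss) - 1)
        right = np.clip(right, 0, len(tss) - 1)
        d_left = np.abs(pos - tss[left])
        d_right = np.abs(pos - tss[right])
        gene_names = genes["gene"].to_numpy()
        pick = np.where(d_right < d_left, right, left)
        # exact distance tie between two distinct TSS: lexicographic gene
        tie = (d_right == d_left) & (left != right)
        for i in np.flatnonzero(tie):
            cand = sorted([(gene_names[left[i]], left[i]),
                           (gene_names[right[i]], right[i])])
            pick[i] = cand[0][1]
        chosen = genes.iloc[pick]
        signed = pos - chosen["tss"].to_numpy(dtype=float)
        signed = np.where(chosen["strand"].to_numpy() == "-", -signed, signed)
        out_gene[cpgs.index] = chosen["gene"].to_numpy()
        out_dist[cpgs.index] = signed
    return pd.DataFrame({"gene": out_gene, "tss_distance": out_dist})


def coupling_screen(beta: BetaMatrix, expression: pd.DataFrame,
                    mapping: pd.DataFrame,
                    promoter_window: tuple[float, float] = DEFAULT_PROMOTER_WINDOW,
                    average_replicates_by: pd.Series | None = None) -> pd.DataFrame:
    """Per-CpG Pearson correlation of beta with nearest-gene log expression.

    Parameters
    ----------
    beta : BetaMatrix (samples x CpGs)
    expression : DataFrame, genes x samples, log scale
    mapping : DataFrame indexed by cpg_id with columns ``gene``,
        ``tss_distance`` (e.g. from :func:`assign_nearest_gene` or the
        annotation table).
    promoter_window : (lo, hi) signed-bp window; CpGs outside are excluded.
    average_replicates_by : optional per-sample labels (e.g. tissue); when
        given, samples sharing a label are averaged before correlating.

    Returns
    -------
    DataFrame indexed by the promoter-window cpg_ids with columns
    ``gene``, ``tss_distance``, ``n``, ``r``, ``z``, ``p``,
    ``significant`` (|z| > 2.8).  CpGs whose gene has constant expression
    are flagged missing (NaN statistics).
    """
    shared = beta.sample_ids.intersection(expression.columns)
    if len(shared) < 5:
        raise DomainError(
            f"need >= 5 samples shared between matrices, got {len(shared)}")
    B = beta.values.loc[shared]
    E = expression[shared]

    if average_replicates_by is not None:
        labels = average_replicates_by.reindex(shared)
        B = B.groupby(labels).mean()
        E = E.T.groupby(labels).mean().T

    lo, hi = promoter_window
    in_window = mapping["tss_distance"].between(lo, hi)
    cpgs = mapping.index[in_window].intersection(B.columns)

    rows = []
    n_samples = B.shape[0]
    for cpg in cpgs:
        gene = mapping.at[cpg, "gene"]
        if gene not in E.index:
            rows.append((cpg, gene, mapping.at[cpg, "tss_distance"],
                         n_samples, np.nan, np.nan, np.nan, False))
            continue
        x = B[cpg].to_numpy(dtype=float)
        y = E.loc[gene].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        n = int(ok.sum())
        if n < 4 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
            rows.append((cpg, gene, mapping.at[cpg, "tss_distance"],
                         n, np.nan, np.nan, np.nan, False))
            continue
        r = float(np.corrcoef(x[ok], y[ok])[0, 1])
        z = fisher_z(r, n) if n > 3 else np.nan
        rc = np.clip(r, -R_CLAMP, R_CLAMP)
        t = rc * np.sqrt((n - 2) / (1 - rc * rc))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
        rows.append((cpg, gene, mapping.at[cpg, "tss_distance"], n, r, z, p,
                     bool(np.isfinite(z) and abs(z) > Z_SIGNIFICANT)))
    return pd.DataFrame(
        rows,
        columns=["cpg_id", "gene", "tss_distance", "n", "r", "z", "p",
                 "significant"],
    ).set_index("cpg_id")


def state_summary(table: pd.DataFrame, annotation: CpGAnnotation,
                  z_threshold: float = Z_SIGNIFICANT) -> pd.DataFrame:
    """Summarise significant DNAm-mRNA couplings per chromatin state.

    ``table`` is a coupling table (see :func:`coupling_screen`); only rows
    with ``significant == True`` contribute.  For each chromatin state
    with at least one member the output reports the member count, median
    z, the notch interval ``median +- 1.57*IQR/sqrt(n)`` and a
    ``reported`` flag marking states whose |median z| exceeds the
    threshold.  An empty significant set yields an empty summary.
    """
    sig = table[table["significant"].fillna(False)]
    states = annotation.table["chrom_state"].reindex(sig.index)
    rows = []
    for state, idx in states.groupby(states).groups.items():
        z = sig.loc[idx, "z"].to_numpy(dtype=float)
        n = len(z)
        med = float(np.median(z))
        iqr = float(np.subtract(*np.percentile(z, [75, 25])))
        notch = 1.57 * iqr / np.sqrt(n)
        rows.append((state, n, med, med - notch, med + notch,
                     abs(med) > z_threshold))
    out = pd.DataFrame(
        rows,
        columns=["chrom_state", "n", "median_z", "notch_lo", "notch_hi",
                 "reported"],
    ).set_index("chrom_state").sort_index()
    return out
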