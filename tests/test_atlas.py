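"""Nearest-gene assignment, DNAm-mRNA coupling and state summaries."""

import numpy as np
import pandas as pd
import pytest

from equiclock import BetaMatrix, CpGAnnotation
from equiclock.atlas import (
    assign_nearest_gene,
    coupling_screen,
    state_summary,
)
from equiclock.synthetic_data import AtlasSimConfig, simulate_atlas


def _positions(rows):
    return pd.DataFrame(rows, columns=["cpg_id", "chrom", "pos"]).set_index("cpg_id")


def _tss(rows):
    return pd.DataFrame(rows, columns=["gene", "chrom", "tss", "strand"])


def test_nearest_gene_basic_and_strand_sign():
    mapping = assign_nearest_gene(
        _positions([("cg0", "chr1", 500)]),
        _tss([("GENEA", "chr1", 400, "+")]),
    )
    assert mapping.loc["cg0", "gene"] == "GENEA"
    assert mapping.loc["cg0", "tss_distance"] == 100  # downstream on + strand
    # same geometry on the minus strand flips the sign
    mapping = assign_nearest_gene(
        _positions([("cg0", "chr1", 500)]),
        _tss([("GENEA", "chr1", 400, "-")]),
    )
    assert mapping.loc["cg0", "tss_distance"] == -100  # upstream of - strand gene


def test_nearest_gene_tie_goes_lexicographic():
    mapping = assign_nearest_gene(
        _positions([("cg0", "chr1", 500)]),
        _tss([("GENEB", "chr1", 400, "+"), ("GENEA", "chr1", 600, "+")]),
    )
    assert mapping.loc["cg0", "gene"] == "GENEA"


def test_nearest_gene_unassigned_chromosome():
    mapping = assign_nearest_gene(
        _positions([("cg0", "chrU", 500)]),
        _tss([("GENEA", "chr1", 400, "+")]),
    )
    assert mapping.loc["cg0", "gene"] == "unassigned"
    assert np.isnan(mapping.loc["cg0", "tss_distance"])


def test_nearest_gene_matches_all_pairs_oracle():
    rng = np.random.default_rng(13)
    chroms = ["chr1", "chr2", "chr3"]
    cpgs = _positions([
        (f"cg{i}", rng.choice(chroms), int(rng.integers(0, 1_000_000)))
        for i in range(1000)
    ])
    tss = _tss([
        (f"G{i:03d}", rng.choice(chroms), int(rng.integers(0, 1_000_000)),
         rng.choice(["+", "-"]))
        for i in range(50)
    ])
    mapping = assign_nearest_gene(cpgs, tss)
    for cpg_id, row in cpgs.iterrows():
        cands = tss[tss["chrom"] == row["chrom"]]
        if cands.empty:
            assert mapping.loc[cpg_id, "gene"] == "unassigned"
            continue
        dist = (row["pos"] - cands["tss"]).abs()
        best = cands.assign(d=dist).sort_values(["d", "gene"]).iloc[0]
        assert mapping.loc[cpg_id, "gene"] == best["gene"]
        signed = row["pos"] - best["tss"]
        if best["strand"] == "-":
            signed = -signed
        assert mapping.loc[cpg_id, "tss_distance"] == signed


def test_perfect_negative_coupling_flagged():
    rng = np.random.default_rng(2)
    b = rng.uniform(0.2, 0.8, 8)
    beta = BetaMatrix(pd.DataFrame(
        {"cg0": b}, index=pd.Index([f"t{i}" for i in range(8)],
                                   name="sample_id")))
    expr = pd.DataFrame([5.0 - b], index=pd.Index(["GENEA"], name="gene_id"),
                        columns=beta.sample_ids)
    mapping = pd.DataFrame({"gene": ["GENEA"], "tss_distance": [-100.0]},
                           index=pd.Index(["cg0"], name="cpg_id"))
    out = coupling_screen(beta, expr, mapping)
    assert out.loc["cg0", "r"] == pytest.approx(-1.0, abs=1e-12)
    assert out.loc["cg0", "significant"]
    assert out.loc["cg0", "z"] < -2.8


def test_constant_expression_flagged_missing():
    beta = BetaMatrix(pd.DataFrame(
        {"cg0": np.linspace(0.2, 0.8, 6)},
        index=pd.Index([f"t{i}" for i in range(6)], name="sample_id")))
    expr = pd.DataFrame([[3.0] * 6], index=pd.Index(["GENEA"], name="gene_id"),
                        columns=beta.sample_ids)
    mapping = pd.DataFrame({"gene": ["GENEA"], "tss_distance": [0.0]},
                           index=pd.Index(["cg0"], name="cpg_id"))
    out = coupling_screen(beta, expr, mapping)
    assert np.isnan(out.loc["cg0", "z"])
    assert not out.loc["cg0", "significant"]


def test_window_discipline():
    """CpGs outside the promoter window never enter the coupling table."""
    cfg = AtlasSimConfig(n_genes=50, n_distal_cpgs=50, seed=21)
    beta, expr, sheet, annot, truth = simulate_atlas(cfg)
    out = coupling_screen(beta, expr, annot.table[["gene", "tss_distance"]])
    dist = annot.table.loc[out.index, "tss_distance"]
    assert dist.between(-10_000, 1_000).all()
    assert len(out) == 50  # only the promoter CpGs


def test_state_summary_single_state_and_empty():
    idx = pd.Index(["cg0", "cg1", "cg2"], name="cpg_id")
    table = pd.DataFrame({
        "z": [-3.0, -4.0, -5.0], "significant": [True, True, True],
    }, index=idx)
    annot = CpGAnnotation(pd.DataFrame({
        "gene": "G", "tss_distance": 0, "island": "non-island",
        "position_class": "promoter", "chrom_state": "EnhA",
    }, index=idx))
    out = state_summary(table, annot)
    assert list(out.index) == ["EnhA"]
    assert out.loc["EnhA", "median_z"] == -4.0
    assert out.loc["EnhA", "n"] == 3
    assert bool(out.loc["EnhA", "reported"])
    empty = state_summary(table.assign(significant=False), annot)
    assert empty.empty


def test_planted_state_directions_recovered():
    cfg = AtlasSimConfig(seed=4)
    beta, expr, sheet, annot, truth = simulate_atlas(cfg)
    table = coupling_screen(beta, expr, annot.table[["gene", "tss_distance"]])
    out = state_summary(table, annot)
    for state in ("EnhA", "EnhWk", "TxEnh"):
        if state in out.index and out.loc[state, "n"] >= 20:
            assert out.loc[state, "median_z"] < 0
    for state in ("BivProm", "TSS", "PromF", "ReprPC"):
        if state in out.index and out.loc[state, "n"] >= 20:
            assert out.loc[state, "median_z"] > 0


def test_distance_decay_gives_monotone_z_profile():
    """Coupling decaying with |TSS distance| shows in binned median |z|."""
    cfg = AtlasSimConfig(n_genes=600, n_distal_cpgs=0,
                         distance_decay_bp=4000.0, seed=6)
    beta, expr, sheet, annot, truth = simulate_atlas(cfg)
    table = coupling_screen(beta, expr, annot.table[["gene", "tss_distance"]])
    absd = annot.table.loc[table.index, "tss_distance"].abs()
    bins = pd.cut(absd, [0, 2500, 5000, 10_000])
    med = table["z"].abs().groupby(bins, observed=True).median()
    assert med.is_monotonic_decreasing


def test_extreme_tissue_removal_keeps_state_signs():
    """Dropping the most extreme tissue rarely flips a state's median z sign."""
    flips, total = 0, 0
    for seed in range(5):
        cfg = AtlasSimConfig(n_genes=250, n_distal_cpgs=0, seed=40 + seed)
        beta, expr, sheet, annot, truth = simulate_atlas(cfg)
        full = state_summary(
            coupling_screen(beta, expr, annot.table[["gene", "tss_distance"]]),
            annot)
        # most extreme tissue = largest mean |deviation| in expression
        dev = (expr - expr.mean(axis=1).to_numpy()[:, None]).abs().mean(axis=0)
        worst_tissue = sheet.tissue[dev.idxmax()]
        keep = sheet.sample_ids[sheet.tissue != worst_tissue]
        reduced = state_summary(
            coupling_screen(beta.subset_samples(keep), expr[keep],
                            annot.table[["gene", "tss_distance"]]),
            annot)
        for state in full.index[full["n"] >= 20]:
            if state in reduced.index:
                total += 1
                if np.sign(full.loc[state, "median_z"]) != np.sign(
                        reduced.loc[state, "median_z"]):
                    flips += 1
    assert total > 0
    assert flips / total < 0.05
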