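"""End-to-end reproducible workflows: simulate/load -> clock CV -> EWAS -> extras.

A workflow is described by a single YAML/JSON-able mapping (RunConfig),
executed into an output directory, and accompanied by a manifest listing
every written file with its SHA-256 digest, the seed, and the package
version.  Re-running the same config and seed reproduces byte-identical
statistical tables.  If a stage fails, the partial outputs are moved to a
``failed/`` subdirectory rather than being left in place.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import pandas as pd

from . import __version__
from .age_transforms import TransformSpec
from .clock import cross_validate, fit_clock
from .core_io import load_dataset, save_clock
from .errors import ConfigError
from .ewas import correlation_screen, select_top, stouffer_meta
from .group_effects import covariate_screen, sector_classify
from .synthetic_data import (
    AtlasSimConfig,
    Cohort,
    SimConfig,
    simulate_atlas,
    simulate_methylation,
)
from .atlas import coupling_screen, state_summary

log = logging.getLogger("equiclock")

DEFAULT_THRESHOLDS = {
    "alpha": 0.5,        # elastic-net mixing
    "top_k": 500,        # top CpGs per direction
    "p_strong": 1e-4,    # sector plot: strong-association threshold
    "p_null": 0.05,      # sector plot: null threshold
    "fdr": 0.05,
    "atlas_z": 2.8,      # |z| significance for DNAm-mRNA coupling
}


@dataclass
class RunConfig:
    """Validated workflow configuration."""

    seed: Optional[int]
    output_dir: Path
    transform: str = "identity"
    cv_scheme: str = "LOO"
    thresholds: dict = field(default_factory=dict)
    simulate: Optional[dict] = None            # SimConfig overrides
    simulate_atlas: Optional[dict] = None      # AtlasSimConfig overrides
    beta_path: Optional[Path] = None
    sheet_path: Optional[Path] = None
    annot_path: Optional[Path] = None
    species_table_path: Optional[Path] = None
    stages: tuple = ("clock", "ewas", "castration")

    @classmethod
    def from_mapping(cls, cfg: Mapping[str, Any]) -> "RunConfig":
        cfg = dict(cfg)
        unknown = set(cfg) - {
            "seed", "output_dir", "transform", "cv_scheme", "thresholds",
            "simulate", "simulate_atlas", "beta", "sheet", "annotation",
            "species_table", "stages",
        }
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "output_dir" not in cfg:
            raise ConfigError("config must set output_dir")
        sim = cfg.get("simulate")
        sim_atlas = cfg.get("simulate_atlas")
        files = cfg.get("beta") is not None
        if files and (sim is not None or sim_atlas is not None):
            raise ConfigError("config must use input files XOR simulation")
        if not files and sim is None and sim_atlas is None:
            raise ConfigError("config needs either file inputs or a simulate block")
        seed = cfg.get("seed")
        if (sim is not None or sim_atlas is not None) and seed is None:
            raise ConfigError("seed is mandatory when simulation is enabled")
        stages = tuple(cfg.get("stages", ("clock", "ewas", "castration")))
        return cls(
            seed=seed,
            output_dir=Path(cfg["output_dir"]),
            transform=cfg.get("transform", "identity"),
            cv_scheme=cfg.get("cv_scheme", "LOO"),
            thresholds={**DEFAULT_THRESHOLDS, **cfg.get("thresholds", {})},
            simulate=sim,
            simulate_atlas=sim_atlas,
            beta_path=Path(cfg["beta"]) if files else None,
            sheet_path=Path(cfg["sheet"]) if cfg.get("sheet") else None,
            annot_path=Path(cfg["annotation"]) if cfg.get("annotation") else None,
            species_table_path=(Path(cfg["species_table"])
                                if cfg.get("species_table") else None),
            stages=stages,
        )


def _build_sim_config(overrides: Mapping[str, Any], seed: int) -> SimConfig:
    kwargs = dict(overrides or {})
    if "cohorts" in kwargs:
        kwargs["cohorts"] = tuple(Cohort(**c) for c in kwargs["cohorts"])
    kwargs.setdefault("seed", seed)
    return SimConfig(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Run:
    """Tracks written files for the manifest."""

    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.files: list[Path] = []

    def write_df(self, df: pd.DataFrame, name: str, sep: str = ",",
                 index: bool = True) -> Path:
        path = self.outdir / name
        df.to_csv(path, sep=sep, index=index)
        self.files.append(path)
        return path

    def add(self, path: Path) -> None:
        self.files.append(path)


def run_workflow(config: RunConfig | Mapping[str, Any]) -> Path:
    """Execute a workflow; returns the output directory.

    The directory receives the generated/loaded dataset (when simulated),
    per-stage statistical tables and ``manifest.json``.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.from_mapping(config)
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    run = _Run(outdir)
    t_start = time.time()
    try:
        _execute(config, run)
    except Exception:
        failed = outdir / "failed"
        failed.mkdir(exist_ok=True)
        for f in run.files:
            if f.exists():
                shutil.move(str(f), failed / f.name)
        raise
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": _jsonable(config),
        "elapsed_s": round(time.time() - t_start, 3),
        "outputs": {
            str(f.relative_to(outdir)): _sha256(f) for f in sorted(run.files)
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return outdir


def _jsonable(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    for key, val in d.items():
        if isinstance(val, Path):
            d[key] = str(val)
    d["stages"] = list(d["stages"])
    return d


def _execute(config: RunConfig, run: _Run) -> None:
    th = {**DEFAULT_THRESHOLDS, **config.thresholds}

    # --- atlas-only workflow
    if config.simulate_atlas is not None:
        kwargs = dict(config.simulate_atlas)
        kwargs.setdefault("seed", config.seed)
        acfg = AtlasSimConfig(**kwargs)
        beta, expression, sheet, annot, truth = simulate_atlas(acfg)
        run.write_df(truth, "atlas_truth.tsv", sep="\t", index=False)
        coupling = coupling_screen(beta, expression,
                                   annot.table[["gene", "tss_distance"]],
                                   promoter_window=acfg.promoter_window)
        run.write_df(coupling, "atlas_coupling.tsv", sep="\t")
        summary = state_summary(coupling, annot, z_threshold=th["atlas_z"])
        run.write_df(summary, "atlas_state_summary.tsv", sep="\t")
        log.info("atlas: %d promoter CpGs screened, %d significant",
                 len(coupling), int(coupling["significant"].sum()))
        return

    # --- aging workflow: obtain dataset
    if config.simulate is not None:
        sim = _build_sim_config(config.simulate, config.seed)
        beta, sheet, annot, truth = simulate_methylation(sim)
        beta.to_csv(run.outdir / "beta.csv")
        run.add(run.outdir / "beta.csv")
        sheet.to_csv(run.outdir / "sheet.csv")
        run.add(run.outdir / "sheet.csv")
        annot.to_tsv(run.outdir / "annotation.tsv")
        run.add(run.outdir / "annotation.tsv")
        run.write_df(truth, "truth.tsv", sep="\t", index=False)
        species_table = sim.species_table
    else:
        beta, sheet, annot = load_dataset(config.beta_path, config.sheet_path,
                                          config.annot_path)
        if config.species_table_path is not None:
            from .core_io import SpeciesTable
            species_table = SpeciesTable.from_csv(config.species_table_path)
        else:
            from .synthetic_data import DEFAULT_SPECIES
            species_table = DEFAULT_SPECIES
    log.info("dataset: %d samples x %d CpGs", *beta.shape)

    spec = TransformSpec.from_species_table(config.transform, species_table) \
        if config.transform != "identity" else TransformSpec.identity()

    if "clock" in config.stages:
        t0 = time.time()
        model = fit_clock(beta, sheet, spec, seed=config.seed or 0,
                          alpha=th["alpha"])
        clock_path = run.outdir / "clock.csv"
        save_clock(model, clock_path)
        run.add(clock_path)
        cv = cross_validate(beta, sheet, spec, config.cv_scheme,
                            seed=config.seed or 0, alpha=th["alpha"])
        preds = cv.predictions.copy()
        preds["residual"] = preds["dnam_age"] - preds["age"]
        run.write_df(preds, "cv_predictions.csv")
        metrics = cv.per_species.copy()
        metrics.loc["__overall__"] = [len(preds), cv.overall[0], cv.overall[1]]
        run.write_df(metrics, "cv_metrics.csv")
        log.info("clock %s CV: r=%.3f mae=%.2fy (%.1fs)", config.cv_scheme,
                 cv.overall[0], cv.overall[1], time.time() - t0)

    if "ewas" in config.stages:
        tissues = sorted(sheet.tissue.unique())
        tables = {}
        for tissue in tissues:
            ids = sheet.sample_ids[sheet.tissue == tissue]
            sub_sheet = sheet.subset(ids)
            tab = correlation_screen(beta.subset_samples(ids), sub_sheet.age)
            tables[tissue] = tab
            run.write_df(tab, f"ewas_{tissue}.tsv", sep="\t")
            log.info("ewas %s: n=%d, %d CpGs q<%.2g", tissue, len(ids),
                     int((tab["q"] < th["fdr"]).sum()), th["fdr"])
        if len(tables) >= 2:
            meta = stouffer_meta(tables)
            run.write_df(meta, "ewas_meta.tsv", sep="\t")
            pos, neg = select_top(meta, k=th["top_k"], column="meta_z")
            top = pd.DataFrame({
                "cpg_id": list(pos) + list(neg),
                "direction": ["positive"] * len(pos) + ["negative"] * len(neg),
            })
            run.write_df(top, "ewas_top.tsv", sep="\t", index=False)

    if "castration" in config.stages:
        males = sheet.table[(sheet.table["sex"] == "male")
                            & (sheet.table["tissue"] == "blood")
                            & sheet.table["castrated"].isin(("yes", "no"))]
        if males["castrated"].nunique() == 2 and len(males) >= 10:
            male_sheet = sheet.subset(males.index)
            male_beta = beta.subset_samples(males.index)
            screen = covariate_screen(male_beta, male_sheet)
            run.write_df(screen, "castration.tsv", sep="\t")
            geld = males.index[males["castrated"] == "yes"]
            stal = males.index[males["castrated"] == "no"]
            if len(geld) >= 4 and len(stal) >= 4:
                z_g = correlation_screen(beta.subset_samples(geld),
                                         sheet.subset(geld).age)["z"]
                z_s = correlation_screen(beta.subset_samples(stal),
                                         sheet.subset(stal).age)["z"]
                sector = sector_classify(z_g, z_s, p_strong=th["p_strong"],
                                         p_null=th["p_null"])
                run.write_df(sector, "sector.tsv", sep="\t")
        else:
            log.info("castration stage skipped: no two-state male blood cohort")
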