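"""Synthetic methylation / expression datasets with planted, known effects.

The generators emulate the statistical structure that the downstream
analyses assume, at the cohort sizes of a typical equid aging study
(blood from four equid species, a smaller liver cohort, and a multi-tissue
two-animal atlas), so the whole pipeline is exercisable without any
external download.  Every planted effect is recorded in a truth table,
which is the oracle for all sensitivity/specificity tests.

Generating model (aging datasets)::

    beta_ij = clip( mu_j(species)            # per-CpG baseline
                    + b_j * g(age_i)         # planted age trend
                    + gamma_j * castrated_i  # planted castration shift
                    + eps_ij , 0, 1 )

with ``g`` the age scaled to [0,1] over the tissue's age range and
``eps`` Gaussian with sd ``noise_sd``.  The per-CpG slope magnitude
``|b_j|`` is chosen so that the population Pearson correlation between
beta and age equals ``effect_scale`` for a uniform age distribution:

    |b| = r * sigma / ( sd(g) * sqrt(1 - r^2) ),   sd(g) = 1/sqrt(12)

CpG-island CpGs draw their slope from a 1.5x scale, reproducing the
island > non-island ordering of age effects by construction.  Species
differ only by baseline offsets (plus optional constant offsets on causal
CpGs, used to emulate the systematic clock offset seen when predicting a
species absent from training).

Clipping at the [0,1] boundary is monitored: configurations that clip
more than 20% of entries are rejected rather than silently shrinking the
planted effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    CHROM_STATES,
    POSITION_CLASSES,
    BetaMatrix,
    CpGAnnotation,
    SampleSheet,
    SpeciesEntry,
    SpeciesTable,
)
from .errors import ConfigError

MAX_CLIP_FRACTION = 0.20

#: default life-history constants (years): maximum recorded lifespan and
#: average age at sexual maturity per species
DEFAULT_SPECIES = SpeciesTable({
    "horse": SpeciesEntry(57.0, 3.0),
    "plains_zebra": SpeciesEntry(38.0, 2.5),
    "grevys_zebra": SpeciesEntry(31.0, 3.0),
    "somali_wild_ass": SpeciesEntry(40.0, 2.5),
    "human": SpeciesEntry(122.5, 15.0),
})


@dataclass(frozen=True)
class Cohort:
    """One tissue x species sampling block."""

    tissue: str
    species: str
    n: int
    age_min: float
    age_max: float
    n_female: int
    n_gelding: int = 0  # castrated males, only meaningful where castration applies

    def __post_init__(self):
        if self.n < 0 or self.n_female < 0 or self.n_gelding < 0:
            raise ConfigError("cohort counts must be non-negative")
        if self.n_female + self.n_gelding > self.n:
            raise ConfigError(
                f"cohort {self.tissue}/{self.species}: females + geldings exceed n")
        if not (0 <= self.age_min < self.age_max):
            raise ConfigError("need 0 <= age_min < age_max")


#: cohort layout of the default aging study: blood from four equid species
#: (188 + 76 + 5 + 7) and a horse liver cohort of 48; the horse blood males
#: split into 48 geldings and 10 stallions
DEFAULT_COHORTS = (
    Cohort("blood", "horse", 188, 0.005, 28.0, n_female=130, n_gelding=48),
    Cohort("blood", "plains_zebra", 76, 0.16, 20.2, n_female=42),
    Cohort("blood", "grevys_zebra", 5, 2.3, 18.5, n_female=1),
    Cohort("blood", "somali_wild_ass", 7, 2.4, 10.0, n_female=1),
    Cohort("liver", "horse", 48, 0.04, 28.0, n_female=24),
)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the aging-methylation simulator."""

    n_cpgs: int = 2000
    n_causal_pos: int = 150
    n_causal_neg: int = 150
    cohorts: Sequence[Cohort] = DEFAULT_COHORTS
    species_table: SpeciesTable = field(default_factory=lambda: DEFAULT_SPECIES)
    effect_scale: float = 0.8        # target per-CpG |r(beta, age)| of causal CpGs
    shared_fraction: float = 0.5     # causal CpGs active in every tissue
    island_fraction: float = 0.30
    island_multiplier: float = 1.5
    castration_effect: float = 0.1   # |gamma|, beta-fraction units
    n_castration_cpgs: int = 50
    noise_sd: float = 0.04
    species_baseline_sd: float = 0.01   # per-species random baseline jitter
    #: constant offset added to causal CpGs of one species (LOSO bias scenario)
    species_offset: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_cpgs, self.n_causal_pos, self.n_causal_neg,
               self.n_castration_cpgs) < 0:
            raise ConfigError("counts must be non-negative")
        if self.n_causal_pos + self.n_causal_neg > self.n_cpgs:
            raise ConfigError("causal CpGs exceed n_cpgs")
        if not (0 <= self.effect_scale < 1):
            raise ConfigError("effect_scale must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        for c in self.cohorts:
            if c.species not in self.species_table:
                raise ConfigError(f"species {c.species!r} missing from species table")

    def slope_magnitude(self) -> float:
        """|b| giving Pearson |r| = effect_scale for uniform g over [0,1]."""
        r = self.effect_scale
        if r == 0:
            return 0.0
        sd_g = 1.0 / np.sqrt(12.0)
        return r * self.noise_sd / (sd_g * np.sqrt(1.0 - r * r))


def _cpg_ids(n: int) -> pd.Index:
    return pd.Index([f"cg{j:05d}" for j in range(n)], name="cpg_id")


def _annotation(rng: np.random.Generator, cpg_ids: pd.Index,
                island: np.ndarray) -> CpGAnnotation:
    n = len(cpg_ids)
    genes = np.array([f"GENE{j // 4:04d}" for j in range(n)])
    tss = rng.integers(-50_000, 50_000, size=n)
    pos_class = rng.choice(POSITION_CLASSES, size=n)
    state = rng.choice(CHROM_STATES, size=n)
    table = pd.DataFrame(
        {
            "gene": genes,
            "tss_distance": tss,
            "island": np.where(island, "island", "non-island"),
            "position_class": pos_class,
            "chrom_state": state,
        },
        index=cpg_ids,
    )
    return CpGAnnotation(table)


def simulate_methylation(config: SimConfig):
    """Generate (BetaMatrix, SampleSheet, CpGAnnotation, truth table).

    The truth table has one row per (cpg, tissue) planted age effect plus
    one row per planted castration effect; columns ``cpg_id``, ``tissue``,
    ``planted_b`` (slope over the scaled age g in beta units) and
    ``planted_gamma``.  Identical config (including seed) gives identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    n_cpgs = config.n_cpgs
    cpg_ids = _cpg_ids(n_cpgs)
    tissues = sorted({c.tissue for c in config.cohorts})

    island = rng.random(n_cpgs) < config.island_fraction

    # --- assign causal structure
    causal = rng.choice(n_cpgs, size=config.n_causal_pos + config.n_causal_neg,
                        replace=False)
    pos_idx = causal[:config.n_causal_pos]
    neg_idx = causal[config.n_causal_pos:]
    base_b = config.slope_magnitude()
    b = np.zeros(n_cpgs)
    b[pos_idx] = base_b * rng.uniform(0.9, 1.1, size=len(pos_idx))
    b[neg_idx] = -base_b * rng.uniform(0.9, 1.1, size=len(neg_idx))
    b[island & (b != 0)] *= config.island_multiplier

    # shared vs tissue-specific causal CpGs
    shared = np.zeros(n_cpgs, dtype=bool)
    shared[causal] = rng.random(len(causal)) < config.shared_fraction
    home_tissue = np.array([""] * n_cpgs, dtype=object)
    home_tissue[causal] = rng.choice(tissues, size=len(causal))

    # castration-responsive CpGs, disjoint from age-causal ones
    non_causal = np.setdiff1d(np.arange(n_cpgs), causal)
    n_cast = min(config.n_castration_cpgs, len(non_causal))
    cast_idx = rng.choice(non_causal, size=n_cast, replace=False)
    gamma = np.zeros(n_cpgs)
    gamma[cast_idx] = config.castration_effect * rng.choice([-1.0, 1.0], size=n_cast)

    # baselines keeping the noiseless trajectory inside [0.08, 0.92]
    lo, hi = 0.08, 0.92
    mu = np.empty(n_cpgs)
    span = hi - lo - np.abs(b)
    if np.any(span <= 0):
        raise ConfigError("effect size too large for the beta scale")
    mu = lo + np.where(b < 0, -b, 0.0) + rng.random(n_cpgs) * span

    # per-species baseline jitter
    species_list = sorted({c.species for c in config.cohorts})
    sp_jitter = {
        sp: rng.normal(0.0, config.species_baseline_sd, size=n_cpgs)
        for sp in species_list
    }

    tissue_range = {
        t: (min(c.age_min for c in config.cohorts if c.tissue == t),
            max(c.age_max for c in config.cohorts if c.tissue == t))
        for t in tissues
    }

    rows, sheet_rows, ids = [], [], []
    for cohort in config.cohorts:
        ages = rng.uniform(cohort.age_min, cohort.age_max, size=cohort.n)
        sex = np.array(["female"] * cohort.n_female
                       + ["male"] * (cohort.n - cohort.n_female))
        # castration status is only recorded in cohorts where it is studied
        # (n_gelding > 0); males elsewhere (wild equids) are not_applicable
        castrated = np.array(["not_applicable"] * cohort.n, dtype=object)
        if cohort.n_gelding:
            male_positions = np.arange(cohort.n_female, cohort.n)
            castrated[male_positions] = "no"
            castrated[male_positions[:cohort.n_gelding]] = "yes"

        amin, amax = tissue_range[cohort.tissue]
        g = (ages - amin) / (amax - amin)
        active = shared | (home_tissue == cohort.tissue)
        b_t = np.where(active, b, 0.0)
        offset = config.species_offset.get(cohort.species, 0.0)
        base = mu + sp_jitter[cohort.species]
        # the offset shifts causal CpGs along their aging direction, making
        # the species look systematically older (or younger) at baseline
        base = base + offset * np.sign(b)

        is_gelding = (castrated == "yes").astype(float)
        noiseless = (base[None, :]
                     + np.outer(g, b_t)
                     + np.outer(is_gelding, gamma))
        noisy = noiseless + rng.normal(0.0, config.noise_sd, size=noiseless.shape)
        rows.append(noisy)
        for i in range(cohort.n):
            sid = f"{cohort.tissue}_{cohort.species}_{len(ids):04d}"
            ids.append(sid)
            sheet_rows.append((sid, ages[i], cohort.species, cohort.tissue,
                               sex[i], castrated[i]))

    raw = np.vstack(rows)
    clipped_fraction = float(np.mean((raw < 0.0) | (raw > 1.0)))
    if clipped_fraction > MAX_CLIP_FRACTION:
        raise ConfigError(
            f"effect/noise configuration clips {clipped_fraction:.1%} of "
            f"entries (> {MAX_CLIP_FRACTION:.0%}); reduce effect sizes or noise")
    values = np.clip(raw, 0.0, 1.0)

    beta = BetaMatrix(pd.DataFrame(values, index=pd.Index(ids, name="sample_id"),
                                   columns=cpg_ids))
    sheet = SampleSheet(
        pd.DataFrame(sheet_rows, columns=["sample_id", "age", "species",
                                          "tissue", "sex", "castrated"])
        .set_index("sample_id")
    )
    annot = _annotation(rng, cpg_ids, island)

    truth_rows = []
    for j in causal:
        for t in tissues:
            if shared[j] or home_tissue[j] == t:
                truth_rows.append((cpg_ids[j], t, b[j], 0.0))
    for j in cast_idx:
        truth_rows.append((cpg_ids[j], "blood", 0.0, gamma[j]))
    truth = pd.DataFrame(truth_rows,
                         columns=["cpg_id", "tissue", "planted_b", "planted_gamma"])
    return beta, sheet, annot, truth


# ---------------------------------------------------------------------------
# tissue atlas: coupled methylation + expression


#: default coupling (log2-expression units per unit beta) between promoter
#: methylation and expression by chromatin state: repressive in enhancer
#: states, activating in polycomb/bivalent/TSS states, absent elsewhere
DEFAULT_STATE_COUPLING: Mapping[str, float] = {
    "TSS": 3.0, "Prom": 0.0, "PromF": 2.5, "BivProm": 3.0, "ReprPC": 2.5,
    "EnhA": -3.0, "EnhWk": -2.5, "TxEnh": -2.5,
    "Tx": 0.0, "TxEx": 0.0, "Acet": 0.0, "Het": 0.0, "Quies": 0.0,
}


@dataclass(frozen=True)
class AtlasSimConfig:
    """Configuration of the multi-tissue methylation/expression simulator."""

    n_tissues: int = 29
    n_animals: int = 2
    n_genes: int = 450
    n_distal_cpgs: int = 150          # CpGs far outside any promoter window
    state_coupling: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STATE_COUPLING))
    tissue_beta_sd: float = 0.15      # between-tissue methylation spread
    beta_noise_sd: float = 0.03       # within-tissue replicate noise
    expression_noise_sd: float = 0.30  # log2 expression noise
    #: if set, coupling is damped by exp(-|tss_distance| / decay_bp)
    distance_decay_bp: Optional[float] = None
    promoter_window: tuple[float, float] = (-10_000.0, 1_000.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_tissues < 3:
            raise ConfigError("n_tissues must be >= 3")
        if self.n_animals < 1:
            raise ConfigError("n_animals must be >= 1")
        for state, coupling in self.state_coupling.items():
            if not np.isfinite(coupling):
                raise ConfigError(f"non-finite coupling for state {state!r}")


def simulate_atlas(config: AtlasSimConfig):
    """Generate a coupled methylation + expression atlas.

    Returns ``(BetaMatrix, expression, SampleSheet, CpGAnnotation, truth)``
    where ``expression`` is a genes x samples DataFrame of log2 expression
    and truth records per CpG the gene, chromatin state and the effective
    coupling used.  One promoter CpG drives each gene's expression::

        log2expr_gt = baseline_g + coupling(state_g) * beta_{cpg(g), t} + noise

    Samples are tissue x animal combinations; both animals of a tissue
    share the tissue's methylation level (plus replicate noise), as two
    individuals of the same tissue type would.
    """
    rng = np.random.default_rng(config.seed)
    n_genes, n_distal = config.n_genes, config.n_distal_cpgs
    n_cpgs = n_genes + n_distal
    cpg_ids = _cpg_ids(n_cpgs)
    genes = [f"GENE{g:04d}" for g in range(n_genes)]

    tissue_names = [f"tissue{t:02d}" for t in range(config.n_tissues)]
    samples = [f"{t}_animal{a}" for t in tissue_names for a in range(config.n_animals)]
    n_samples = len(samples)

    # promoter CpGs: one per gene, inside the window; distal CpGs outside
    win_lo, win_hi = config.promoter_window
    prom_dist = rng.uniform(win_lo, win_hi, size=n_genes).round()
    distal_dist = rng.choice([-1.0, 1.0], size=n_distal) * rng.uniform(
        3e4, 2e5, size=n_distal).round()
    tss_distance = np.concatenate([prom_dist, distal_dist])
    gene_of_cpg = np.array(genes + list(rng.choice(genes, size=n_distal)))
    states = rng.choice(list(config.state_coupling), size=n_cpgs)

    # methylation: per-CpG baseline + tissue effect (shared by animals) + noise
    mu = rng.uniform(0.15, 0.85, size=n_cpgs)
    tissue_effect = rng.normal(0.0, config.tissue_beta_sd,
                               size=(config.n_tissues, n_cpgs))
    raw = (mu[None, :]
           + np.repeat(tissue_effect, config.n_animals, axis=0)
           + rng.normal(0.0, config.beta_noise_sd, size=(n_samples, n_cpgs)))
    clipped_fraction = float(np.mean((raw < 0) | (raw > 1)))
    if clipped_fraction > MAX_CLIP_FRACTION:
        raise ConfigError(
            f"atlas configuration clips {clipped_fraction:.1%} of beta entries")
    beta_values = np.clip(raw, 0.0, 1.0)

    coupling = np.array([config.state_coupling[s] for s in states])
    if config.distance_decay_bp is not None:
        coupling = coupling * np.exp(-np.abs(tss_distance) / config.distance_decay_bp)

    baseline = rng.uniform(2.0, 10.0, size=n_genes)
    expr = np.empty((n_genes, n_samples))
    for g in range(n_genes):
        expr[g] = baseline[g] + coupling[g] * beta_values[:, g]
    expr += rng.normal(0.0, config.expression_noise_sd, size=expr.shape)

    beta = BetaMatrix(pd.DataFrame(beta_values,
                                   index=pd.Index(samples, name="sample_id"),
                                   columns=cpg_ids))
    expression = pd.DataFrame(expr, index=pd.Index(genes, name="gene_id"),
                              columns=samples)
    sheet = SampleSheet(pd.DataFrame(
        {
            "age": 4.5,
            "species": "horse",
            "tissue": [s.rsplit("_", 1)[0] for s in samples],
            "sex": "female",
            "castrated": "not_applicable",
        },
        index=pd.Index(samples, name="sample_id"),
    ))
    annot = CpGAnnotation(pd.DataFrame(
        {
            "gene": gene_of_cpg,
            "tss_distance": tss_distance.astype(int),
            "island": np.where(rng.random(n_cpgs) < 0.3, "island", "non-island"),
            "position_class": np.where(
                (tss_distance >= win_lo) & (tss_distance <= win_hi),
                "promoter", "intergenic"),
            "chrom_state": states,
        },
        index=cpg_ids,
    ))
    truth = pd.DataFrame(
        {
            "cpg_id": cpg_ids,
            "gene": gene_of_cpg,
            "chrom_state": states,
            "state_coupling": coupling,
            "is_promoter_driver": np.arange(n_cpgs) < n_genes,
        }
    )
    return beta, expression, sheet, annot, truth
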