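"""Typed containers for methylation datasets and their on-disk formats.

All tabular exchange uses plain CSV/TSV (UTF-8, RFC-4180).  The beta
matrix is stored sample-major: one row per sample, first column
``sample_id``, one column per CpG.  Floats are written with Python's
shortest round-trip representation so write -> read is exact.

Containers validate their invariants on construction; malformed input
raises a typed error from :mod:`equiclock.errors`, never a silent fix-up.
Missing beta values are permitted (empty cells on disk, NaN in memory)
and downstream screens use pairwise-complete observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Optional

import numpy as np
import pandas as pd

from .age_transforms import TransformSpec
from .errors import AlignmentError, FormatError, ValidationError

SEXES = ("female", "male")
CASTRATION_STATES = ("yes", "no", "not_applicable")

#: controlled vocabulary of stacked-chromatin-state labels used by the
#: annotation table and the atlas simulator (consensus states in the style
#: of stacked ChromHMM annotations across many cell types)
CHROM_STATES = (
    "TSS", "Prom", "PromF", "BivProm", "ReprPC",
    "EnhA", "EnhWk", "TxEnh", "Tx", "TxEx", "Acet", "Het", "Quies",
)

POSITION_CLASSES = (
    "promoter", "5utr", "exon", "intron", "3utr", "intergenic",
)


# ---------------------------------------------------------------------------
# containers


class BetaMatrix:
    """Samples x CpGs matrix of methylation beta fractions in [0, 1].

    Wraps a :class:`pandas.DataFrame` whose index is ``sample_id`` and whose
    columns are ``cpg_id``.  NaN marks a missing measurement.
    """

    def __init__(self, values: pd.DataFrame):
        if not isinstance(values, pd.DataFrame):
            values = pd.DataFrame(values)
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample_ids: {dups}")
        if values.columns.has_duplicates:
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate cpg_ids: {dups}")
        arr = values.to_numpy(dtype=float, copy=False)
        bad = ~(np.isnan(arr) | ((arr >= 0.0) & (arr <= 1.0)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                "beta values must be in [0,1]; first offender at "
                f"sample {values.index[i]!r}, cpg {values.columns[j]!r} "
                f"(value {arr[i, j]!r})"
            )
        values = values.astype(float)
        values.index.name = "sample_id"
        values.columns.name = "cpg_id"
        self.values = values

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cpg_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[sample_ids])

    def subset_cpgs(self, cpg_ids) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[:, cpg_ids])

    def to_csv(self, path) -> None:
        df = self.values.copy()
        df.index.name = "sample_id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "BetaMatrix":
        df = pd.read_csv(path)
        if df.columns[0] != "sample_id":
            raise FormatError(
                f"{path}: first column must be 'sample_id', got {df.columns[0]!r}")
        df = df.set_index("sample_id")
        try:
            return cls(df)
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}") from exc

    def __eq__(self, other) -> bool:
        return isinstance(other, BetaMatrix) and self.values.equals(other.values)


class SampleSheet:
    """Per-sample covariates: age, species, tissue, sex, castration status.

    Index is ``sample_id``; columns ``age`` (years), ``species``, ``tissue``,
    ``sex`` in {female, male}, ``castrated`` in {yes, no, not_applicable},
    optional ``breed``.
    """

    REQUIRED = ("age", "species", "tissue", "sex", "castrated")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        if table.index.has_duplicates:
            dups = table.index[table.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample_ids in sheet: {dups}")
        age = pd.to_numeric(table["age"], errors="coerce")
        if age.isna().any():
            bad = table.index[age.isna()].tolist()
            raise ValidationError(f"non-numeric age for samples: {bad}")
        if (age < 0).any():
            bad = table.index[age < 0].tolist()
            raise ValidationError(f"negative age for samples: {bad}")
        bad_sex = ~table["sex"].isin(SEXES)
        if bad_sex.any():
            raise ValidationError(
                f"sex must be one of {SEXES}: offenders "
                f"{table.index[bad_sex].tolist()}")
        bad_cast = ~table["castrated"].isin(CASTRATION_STATES)
        if bad_cast.any():
            raise ValidationError(
                f"castrated must be one of {CASTRATION_STATES}: offenders "
                f"{table.index[bad_cast].tolist()}")
        female_castrated = (table["sex"] == "female") & (table["castrated"] == "yes")
        if female_castrated.any():
            raise ValidationError(
                "castrated=yes requires sex=male: offenders "
                f"{table.index[female_castrated].tolist()}")
        table = table.copy()
        table["age"] = age.astype(float)
        self.table = table

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def age(self) -> pd.Series:
        return self.table["age"]

    @property
    def species(self) -> pd.Series:
        return self.table["species"]

    @property
    def tissue(self) -> pd.Series:
        return self.table["tissue"]

    def subset(self, sample_ids) -> "SampleSheet":
        return SampleSheet(self.table.loc[sample_ids])

    def males(self) -> "SampleSheet":
        return SampleSheet(self.table[self.table["sex"] == "male"])

    def to_csv(self, path) -> None:
        df = self.table.copy()
        df.index.name = "sample_id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "SampleSheet":
        df = pd.read_csv(path)
        if "sample_id" not in df.columns:
            raise FormatError(f"{path}: missing 'sample_id' column")
        return cls(df.set_index("sample_id"))

    def __eq__(self, other) -> bool:
        return isinstance(other, SampleSheet) and self.table.equals(other.table)


@dataclass(frozen=True)
class SpeciesEntry:
    """Life-history constants of one species (years)."""

    max_lifespan: float
    maturity_age: float

    def __post_init__(self):
        if not (0 < self.maturity_age < self.max_lifespan):
            raise ValidationError(
                "need 0 < maturity_age < max_lifespan, got "
                f"maturity={self.maturity_age}, lifespan={self.max_lifespan}")


class SpeciesTable:
    """Mapping species label -> :class:`SpeciesEntry`."""

    def __init__(self, entries: Mapping[str, SpeciesEntry]):
        self.entries = {
            sp: e if isinstance(e, SpeciesEntry) else SpeciesEntry(*e)
            for sp, e in entries.items()
        }

    def __getitem__(self, species: str) -> SpeciesEntry:
        return self.entries[species]

    def __contains__(self, species: str) -> bool:
        return species in self.entries

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def items(self):
        return self.entries.items()

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            [(sp, e.max_lifespan, e.maturity_age) for sp, e in sorted(self.entries.items())],
            columns=["species", "max_lifespan", "maturity_age"],
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpeciesTable":
        df = pd.read_csv(path)
        for col in ("species", "max_lifespan", "maturity_age"):
            if col not in df.columns:
                raise FormatError(f"{path}: missing column {col!r}")
        return cls({
            row.species: SpeciesEntry(float(row.max_lifespan), float(row.maturity_age))
            for row in df.itertuples()
        })

    def __eq__(self, other) -> bool:
        return isinstance(other, SpeciesTable) and self.entries == other.entries


class CpGAnnotation:
    """Per-CpG genomic context.

    Index ``cpg_id``; columns ``gene``, ``tss_distance`` (signed bp,
    negative = upstream of the TSS), ``island`` in {island, non-island},
    ``position_class``, ``chrom_state`` from :data:`CHROM_STATES`.
    CpGs with no annotation are represented by NaN/''-free explicit
    ``unassigned`` rows rather than being dropped.
    """

    REQUIRED = ("gene", "tss_distance", "island", "chrom_state")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValidationError(f"annotation missing columns: {missing}")
        if table.index.has_duplicates:
            dups = table.index[table.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate cpg_ids in annotation: {dups}")
        known = table["chrom_state"].isin(CHROM_STATES) | (table["chrom_state"] == "unassigned")
        if not known.all():
            bad = sorted(table.loc[~known, "chrom_state"].unique().tolist())
            raise ValidationError(f"chrom_state outside controlled vocabulary: {bad}")
        bad_island = ~table["island"].isin(("island", "non-island"))
        if bad_island.any():
            raise ValidationError(
                "island must be 'island' or 'non-island': offenders "
                f"{table.index[bad_island].tolist()}")
        self.table = table.copy()

    @property
    def cpg_ids(self) -> pd.Index:
        return self.table.index

    def to_tsv(self, path) -> None:
        df = self.table.copy()
        df.index.name = "cpg_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CpGAnnotation":
        df = pd.read_csv(path, sep="\t")
        if "cpg_id" not in df.columns:
            raise FormatError(f"{path}: missing 'cpg_id' column")
        return cls(df.set_index("cpg_id"))

    def __eq__(self, other) -> bool:
        return isinstance(other, CpGAnnotation) and self.table.equals(other.table)


@dataclass
class ClockModel:
    """A fitted penalized-regression age clock.

    ``intercept`` is in transformed-age units; ``coefficients`` maps
    ``cpg_id -> weight`` on the original beta scale (only nonzero weights
    are stored); ``alpha`` is the elastic-net mixing (0.5 throughout);
    ``penalty`` the selected regularization strength; ``transform`` the
    age transform used at training (needed to invert predictions).
    """

    intercept: float
    coefficients: pd.Series
    alpha: float
    penalty: float
    transform: TransformSpec
    missing_policy: str = "strict"  # or "impute_mean"
    training_means: Optional[pd.Series] = None

    def __post_init__(self):
        if not isinstance(self.coefficients, pd.Series):
            self.coefficients = pd.Series(self.coefficients, dtype=float)
        self.coefficients = self.coefficients.astype(float)
        if self.coefficients.index.has_duplicates:
            raise ValidationError("duplicate cpg_ids among clock coefficients")
        if self.missing_policy not in ("strict", "impute_mean"):
            raise FormatError(f"unknown missing policy {self.missing_policy!r}")

    @property
    def cpg_ids(self) -> pd.Index:
        return self.coefficients.index

    def __eq__(self, other) -> bool:
        if not isinstance(other, ClockModel):
            return NotImplemented
        a = self.coefficients.sort_index()
        b = other.coefficients.sort_index()
        return (
            self.intercept == other.intercept
            and a.equals(b)
            and self.alpha == other.alpha
            and self.penalty == other.penalty
            and self.transform == other.transform
            and self.missing_policy == other.missing_policy
        )


# ---------------------------------------------------------------------------
# dataset loading


def align_dataset(beta: BetaMatrix, sheet: SampleSheet) -> None:
    """Raise :class:`AlignmentError` unless matrix and sheet cover the same samples."""
    m = set(beta.sample_ids)
    s = set(sheet.sample_ids)
    only_sheet = sorted(s - m)
    only_matrix = sorted(m - s)
    if only_sheet or only_matrix:
        raise AlignmentError(
            "sample identifiers differ between beta matrix and sheet; "
            f"sheet-only: {only_sheet}; matrix-only: {only_matrix}")


def load_dataset(beta_path, sheet_path, annot_path=None):
    """Load a beta matrix + sample sheet (+ optional annotation) from disk.

    The sheet is reordered to the matrix's sample order.  CpGs absent from
    the annotation are added as explicit ``unassigned`` rows so that no CpG
    is silently dropped.

    Returns ``(BetaMatrix, SampleSheet, CpGAnnotation | None)``.
    """
    beta = BetaMatrix.from_csv(beta_path)
    sheet = SampleSheet.from_csv(sheet_path)
    align_dataset(beta, sheet)
    sheet = sheet.subset(beta.sample_ids)
    annot = None
    if annot_path is not None:
        annot = CpGAnnotation.from_tsv(annot_path)
        missing = beta.cpg_ids.difference(annot.cpg_ids)
        if len(missing):
            filler = pd.DataFrame(
                {
                    "gene": "unassigned",
                    "tss_distance": np.nan,
                    "island": "non-island",
                    "position_class": "intergenic",
                    "chrom_state": "unassigned",
                },
                index=missing,
            )
            annot = CpGAnnotation(pd.concat([annot.table, filler]))
    return beta, sheet, annot


# ---------------------------------------------------------------------------
# clock serialization


def save_clock(model: ClockModel, path) -> None:
    """Write a clock as CSV with a commented ``# key=value`` header block.

    Floats use ``repr`` (shortest round-trip form) so reload is lossless.
    """
    lines = [
        f"# intercept={model.intercept!r}",
        f"# alpha={model.alpha!r}",
        f"# penalty={model.penalty!r}",
        f"# missing_policy={model.missing_policy}",
    ]
    for key, val in model.transform.to_header_items():
        lines.append(f"# {key}={val}")
    lines.append("cpg_id,coefficient")
    for cpg, coef in model.coefficients.items():
        lines.append(f"{cpg},{coef!r}")
    if model.training_means is not None:
        for cpg, mean in model.training_means.items():
            lines.append(f"# trainmean.{cpg}={mean!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_clock(path) -> ClockModel:
    """Inverse of :func:`save_clock`."""
    header: dict[str, str] = {}
    coef_index: list[str] = []
    coef_values: list[float] = []
    train_means: dict[str, float] = {}
    saw_columns = False
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" not in body:
                raise FormatError(f"{path}:{lineno}: bad header line {raw!r}")
            key, val = body.split("=", 1)
            key = key.strip()
            if key.startswith("trainmean."):
                train_means[key[len("trainmean."):]] = float(val)
            else:
                header[key] = val.strip()
            continue
        if not saw_columns:
            if line != "cpg_id,coefficient":
                raise FormatError(f"{path}:{lineno}: expected column header, got {raw!r}")
            saw_columns = True
            continue
        cpg, _, coef = line.partition(",")
        try:
            coef_values.append(float(coef))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad coefficient {coef!r}") from exc
        coef_index.append(cpg)
    for key in ("intercept", "alpha", "penalty"):
        if key not in header:
            raise FormatError(f"{path}: missing header field {key!r}")
    transform = TransformSpec.from_header_items(header)
    return ClockModel(
        intercept=float(header["intercept"]),
        coefficients=pd.Series(coef_values, index=coef_index, dtype=float),
        alpha=float(header["alpha"]),
        penalty=float(header["penalty"]),
        transform=transform,
        missing_policy=header.get("missing_policy", "strict"),
        training_means=pd.Series(train_means, dtype=float) if train_means else None,
    )
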