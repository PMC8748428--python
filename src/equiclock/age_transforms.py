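"""Dependent-variable transformations for multi-species epigenetic clocks.

A clock fitted jointly on species with very different lifespans cannot
regress on raw chronological age: a 20-year-old horse and a 20-year-old
human are at completely different life stages.  Two standard remedies are
implemented here, both with exact inverses so that predictions can always
be reported back in years.

``relative_age``
    age divided by the species' maximum recorded lifespan.  The ratio is
    unitless and lies in [0, ~1], aligning species on a common life-course
    axis (horse maximum lifespan 57 y, human 122.5 y are the canonical
    constants).

``loglinear``
    the log-linear transform anchored at the species' average age at
    sexual maturity ``m`` with a positive offset constant ``c``:

        f(a) = log((a + c) / (m + c))      for a <= m
        f(a) = (a - m) / (m + c)           for a >  m

    Both branches meet at ``f(m) = 0`` with matching first derivative
    ``1/(m+c)``, so f is strictly increasing and C^1.  Juvenile ages are
    expanded logarithmically (methylation change is fastest early in
    life), adult ages are linear.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import DomainError, FormatError, LookupSpeciesError

TRANSFORM_KINDS = ("identity", "relative_age", "loglinear")

#: default offset constant for the log-linear transform, in years
DEFAULT_LOGLINEAR_OFFSET = 2.0


def relative_age(age, max_lifespan):
    """Age as a fraction of the species' maximum lifespan.

    Parameters
    ----------
    age : float or array-like
        Chronological age in years, >= 0.
    max_lifespan : float
        Maximum recorded lifespan of the species in years, > 0.

    Returns
    -------
    float or ndarray
        ``age / max_lifespan``, unitless.
    """
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise DomainError("age must be non-negative")
    if max_lifespan <= 0:
        raise DomainError("max_lifespan must be positive")
    out = age / max_lifespan
    return float(out) if out.ndim == 0 else out


def inverse_relative_age(value, max_lifespan):
    """Invert :func:`relative_age`: years = value * max_lifespan."""
    if max_lifespan <= 0:
        raise DomainError("max_lifespan must be positive")
    value = np.asarray(value, dtype=float)
    out = value * max_lifespan
    return float(out) if out.ndim == 0 else out


def loglinear(age, m, c=DEFAULT_LOGLINEAR_OFFSET):
    """Log-linear age transform anchored at age of sexual maturity ``m``.

    Logarithmic below maturity, linear above, continuous with continuous
    first derivative at ``a = m``; ``f(m) = 0``.
    """
    if m <= 0:
        raise DomainError("maturity age m must be positive")
    if c <= 0:
        raise DomainError("offset constant c must be positive")
    age = np.asarray(age, dtype=float)
    if np.any(age + c <= 0):
        raise DomainError("age + c must be positive")
    out = np.where(
        age <= m,
        np.log((age + c) / (m + c)),
        (age - m) / (m + c),
    )
    return float(out) if out.ndim == 0 else out


def inverse_loglinear(value, m, c=DEFAULT_LOGLINEAR_OFFSET):
    """Exact piecewise inverse of :func:`loglinear`."""
    if m <= 0 or c <= 0:
        raise DomainError("m and c must be positive")
    value = np.asarray(value, dtype=float)
    out = np.where(
        value <= 0,
        (m + c) * np.exp(value) - c,
        m + value * (m + c),
    )
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TransformSpec:
    """The age transform a clock was trained with, plus per-species parameters.

    ``kind`` is one of ``identity``, ``relative_age``, ``loglinear``.
    ``params`` maps species label to the parameters the kind needs:
    ``{"max_lifespan": ...}`` for relative_age, ``{"maturity_age": ...,
    "offset": ...}`` for loglinear, ``{}`` for identity.
    """

    kind: str
    params: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in TRANSFORM_KINDS:
            raise FormatError(f"unknown transform kind: {self.kind!r}")

    @classmethod
    def identity(cls) -> "TransformSpec":
        return cls("identity")

    @classmethod
    def from_species_table(cls, kind: str, species_table,
                           offset: float = DEFAULT_LOGLINEAR_OFFSET) -> "TransformSpec":
        """Build a spec for every species in a :class:`~equiclock.core_io.SpeciesTable`."""
        if kind == "identity":
            return cls.identity()
        params = {}
        for sp, entry in species_table.items():
            if kind == "relative_age":
                params[sp] = {"max_lifespan": float(entry.max_lifespan)}
            elif kind == "loglinear":
                params[sp] = {"maturity_age": float(entry.maturity_age),
                              "offset": float(offset)}
            else:
                raise FormatError(f"unknown transform kind: {kind!r}")
        return cls(kind, params)

    def _species_params(self, species: str) -> Mapping[str, float]:
        if self.kind == "identity":
            return {}
        try:
            return self.params[species]
        except KeyError:
            raise LookupSpeciesError(
                f"no transform parameters for species {species!r}") from None

    def forward(self, age, species: str):
        """Transform chronological age (years) for one species."""
        p = self._species_params(species)
        if self.kind == "identity":
            age = np.asarray(age, dtype=float)
            return float(age) if age.ndim == 0 else age.copy()
        if self.kind == "relative_age":
            return relative_age(age, p["max_lifespan"])
        return loglinear(age, p["maturity_age"], p["offset"])

    def inverse(self, value, species: str):
        """Map a transformed value back to chronological age in years."""
        p = self._species_params(species)
        if self.kind == "identity":
            value = np.asarray(value, dtype=float)
            return float(value) if value.ndim == 0 else value.copy()
        if self.kind == "relative_age":
            return inverse_relative_age(value, p["max_lifespan"])
        return inverse_loglinear(value, p["maturity_age"], p["offset"])

    def forward_array(self, ages, species_labels) -> np.ndarray:
        """Vectorised :meth:`forward` over per-sample species labels."""
        ages = np.asarray(ages, dtype=float)
        out = np.empty_like(ages)
        for sp in np.unique(species_labels):
            mask = np.asarray(species_labels) == sp
            out[mask] = self.forward(ages[mask], sp)
        return out

    def inverse_array(self, values, species_labels) -> np.ndarray:
        """Vectorised :meth:`inverse` over per-sample species labels."""
        values = np.asarray(values, dtype=float)
        out = np.empty_like(values)
        for sp in np.unique(species_labels):
            mask = np.asarray(species_labels) == sp
            out[mask] = self.inverse(values[mask], sp)
        return out

    # -- serialization (clock file header) ---------------------------------

    def to_header_items(self) -> list[tuple[str, str]]:
        """Flatten to key=value pairs for the commented clock-file header."""
        items = [("transform", self.kind)]
        for sp in sorted(self.params):
            for key, val in sorted(self.params[sp].items()):
                items.append((f"param.{sp}.{key}", repr(float(val))))
        return items

    @classmethod
    def from_header_items(cls, items: Mapping[str, str]) -> "TransformSpec":
        kind = items.get("transform")
        if kind not in TRANSFORM_KINDS:
            raise FormatError(f"unknown transform label in clock file: {kind!r}")
        params: dict[str, dict[str, float]] = {}
        for key, val in items.items():
            if not key.startswith("param."):
                continue
            try:
                _, sp, name = key.split(".", 2)
                params.setdefault(sp, {})[name] = float(val)
            except ValueError as exc:
                raise FormatError(f"bad transform parameter line: {key}={val}") from exc
        return cls(kind, params)


def inverse_transform(spec: TransformSpec, value, species: str):
    """Functional alias for ``spec.inverse(value, species)``."""
    return spec.inverse(value, species)
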