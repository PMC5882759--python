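"""Quasi-identifiers: canonical attribute combinations and identifiability.

A quasi-identifier is the SHA-256 digest of a canonicalized combination of
personal attributes (e.g. name, birthday, address). This module builds
those digests and quantifies how identifying a combination is: empirical
entropy, duplicate-group histograms, and a Zipf rank-frequency model of
name sharing.
"""

from __future__ import annotations

import hashlib
import math
import unicodedata
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PersonRecord",
    "AttributeOption",
    "QuasiID",
    "ZipfModel",
    "DuplicateHistogram",
    "MissingAttributeError",
    "DEFAULT_OPTION",
    "canonicalize",
    "quasi_id",
    "duplicate_histogram",
    "empirical_entropy",
    "model_entropy_sum",
    "expected_classes",
    "zipf_count",
    "zipf_total_population",
    "zipf_constant_from_population",
    "fit_zipf",
]

SCHEMA_ATTRIBUTES = (
    "name_kana",
    "name_kanji",
    "sex",
    "birthday",
    "address",
    "prefecture",
    "city",
)

_SEP = b"\x1f"  # ASCII unit separator: cannot occur in NFKC-normalized text values


class MissingAttributeError(KeyError):
    """An attribute required by the active option is absent from a record."""


@dataclass
class PersonRecord:
    """One person's attribute tuple plus optional study labels."""

    attributes: dict[str, str]
    exposure_class: str | None = None
    is_case: bool | None = None


@dataclass(frozen=True)
class AttributeOption:
    """A named, ordered combination of attributes used as the join key."""

    name: str
    attribute_list: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.attribute_list:
            raise ValueError("attribute_list must be non-empty")

    @classmethod
    def from_csv(cls, spec: str, name: str = "custom") -> "AttributeOption":
        return cls(name, tuple(a.strip() for a in spec.split(",") if a.strip()))


DEFAULT_OPTION = AttributeOption("E", ("name_kana", "birthday", "address"))


@dataclass(frozen=True)
class QuasiID:
    """Fixed 32-byte digest of a canonicalized attribute combination."""

    digest: bytes

    def __post_init__(self) -> None:
        if len(self.digest) != 32:
            raise ValueError("digest must be 32 bytes")

    @property
    def hex(self) -> str:
        return self.digest.hex()


def canonicalize(record: PersonRecord, option: AttributeOption) -> bytes:
    """Join the option's attribute values into one unambiguous byte string.

    Values are NFKC-normalized, stripped, lower-cased, then joined with the
    0x1F unit separator in option order, so ("ab","c") and ("a","bc") never
    collide.
    """
    parts = []
    for attr in option.attribute_list:
        value = record.attributes.get(attr)
        if value is None:
            raise MissingAttributeError(attr)
        norm = unicodedata.normalize("NFKC", value).strip().lower()
        parts.append(norm.encode("utf-8"))
    return _SEP.join(parts)


def quasi_id(record: PersonRecord, option: AttributeOption) -> QuasiID:
    """SHA-256 of the canonical form; stable across runs and platforms."""
    return QuasiID(hashlib.sha256(canonicalize(record, option)).digest())


@dataclass
class DuplicateHistogram:
    """counts[x] = number of individuals in groups of exactly x identical tuples."""

    counts: dict[int, int] = field(default_factory=dict)

    @property
    def total_records(self) -> int:
        return sum(self.counts.values())

    @property
    def max_group_size(self) -> int:
        return max(self.counts) if self.counts else 0

    @property
    def unresolved(self) -> int:
        """Individuals that share their tuple with at least one other record."""
        return sum(n for x, n in self.counts.items() if x >= 2)

    def group_counts(self) -> dict[int, int]:
        """counts[x] // x: the number of distinct groups of each size."""
        return {x: n // x for x, n in self.counts.items()}


def duplicate_histogram(
    records: Sequence[PersonRecord], option: AttributeOption
) -> DuplicateHistogram:
    """Group records by exact (pre-hash) attribute tuple and bin by group size."""
    if not records:
        raise ValueError("records must be non-empty")
    groups = Counter(canonicalize(r, option) for r in records)
    hist: Counter[int] = Counter()
    for size in groups.values():
        hist[size] += size
    return DuplicateHistogram(dict(sorted(hist.items())))


def empirical_entropy(
    records: Sequence[PersonRecord], attribute_list: Sequence[str]
) -> float:
    """Shannon entropy (base 2) of the empirical attribute-tuple distribution."""
    if not records:
        raise ValueError("records must be non-empty")
    option = AttributeOption("entropy", tuple(attribute_list))
    counts = np.array(
        list(Counter(canonicalize(r, option) for r in records).values()), dtype=float
    )
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def model_entropy_sum(component_entropies: Iterable[float]) -> float:
    """Entropy budget of combined attributes under the independence assumption."""
    total = 0.0
    for h in component_entropies:
        if h < 0:
            raise ValueError("component entropies must be non-negative")
        total += h
    return total


def expected_classes(entropy_bits: float) -> float:
    """Average number of distinguishable equivalence classes, 2**H."""
    if entropy_bits < 0:
        raise ValueError("entropy must be non-negative")
    return 2.0 ** entropy_bits


@dataclass(frozen=True)
class ZipfModel:
    """Rank-frequency law f(x) = a / x**s for duplicate-name group sizes."""

    a: float
    s: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("a must be positive")
        if self.s <= 1:
            raise ValueError("s must exceed 1 for the population sum to converge")


def zipf_count(x: int, model: ZipfModel) -> float:
    """Expected number of individuals at duplication rank x."""
    if x < 1:
        raise ValueError("rank must be >= 1")
    return model.a / x ** model.s


def _zipf_norm_sum(s: float, k_max: int | None) -> float:
    """sum_{k=1}^{k_max} k**-s; k_max=None truncates when increments vanish."""
    if k_max is not None:
        if k_max < 1:
            raise ValueError("k_max must be >= 1")
        return float(sum(k ** -s for k in range(1, k_max + 1)))
    if s <= 1:
        raise ValueError("sum diverges for s <= 1")
    total, k = 0.0, 1
    while True:
        term = k ** -s
        total += term
        if term < 1e-12 * total:
            return total
        k += 1


def zipf_total_population(model: ZipfModel, k_max: int | None = None) -> float:
    """Total population D = a * sum over ranks of k**-s."""
    return model.a * _zipf_norm_sum(model.s, k_max)


def zipf_constant_from_population(
    D: float, s: float, rounding: int | None = None
) -> float:
    """Invert the population sum: a = D / sum(k**-s).

    ``rounding`` optionally rounds the normalizing sum to that many
    significant figures before dividing (reporting convention).
    """
    if D <= 0:
        raise ValueError("D must be positive")
    norm = _zipf_norm_sum(s, None)
    if rounding is not None:
        exp = math.floor(math.log10(abs(norm)))
        norm = round(norm, rounding - 1 - exp)
    return D / norm


def fit_zipf(histogram: DuplicateHistogram) -> ZipfModel:
    """Least squares on (log x, log f(x)) over ranks with nonzero counts."""
    pairs = [(x, n) for x, n in histogram.counts.items() if n > 0]
    ranks = np.array([x for x, _ in pairs], dtype=float)
    vals = np.array([n for _, n in pairs], dtype=float)
    if len(ranks) < 2:
        raise ValueError("need at least 2 nonzero ranks to fit a Zipf model")
    slope, intercept = np.polyfit(np.log(ranks), np.log(vals), 1)
    s = -float(slope)
    if s <= 1:
        warnings.warn(
            f"fitted exponent s={s:.3f} <= 1: counts are not Zipf-like", stacklevel=2
        )
        # still return something inspectable; clamp into the valid domain
        return ZipfModel(a=float(np.exp(intercept)), s=max(s, 1.0) + 1e-9)
    return ZipfModel(a=float(np.exp(intercept)), s=s)


def records_from_rows(
    rows: Iterable[Mapping[str, str]],
    class_column: str = "exposure_class",
    case_column: str = "is_case",
) -> list[PersonRecord]:
    """Build records from dict rows; non-schema columns carry study labels."""
    out = []
    for row in rows:
        attrs = {k: v for k, v in row.items() if k not in (class_column, case_column)}
        case = row.get(case_column)
        out.append(
            PersonRecord(
                attributes=attrs,
                exposure_class=row.get(class_column) or None,
                is_case=None if case in (None, "") else case in ("1", "true", "True"),
            )
        )
    return out
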