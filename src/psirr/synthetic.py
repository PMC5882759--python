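"""Synthetic linked-cohort generator with exact ground truth.

Produces an Alice table (case registry) and a Bob table (survey with
exposure-class labels) over a shared population, so the whole encrypted
pipeline can be exercised and checked against known counts without any
external dataset. A hidden integer person-ID drives linkage; the emitted
records carry only attribute columns.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import numpy as np

from .quasi_id import PersonRecord, ZipfModel

__all__ = ["CohortSpec", "generate_cohort", "generate_from_counts", "GroundTruth"]


@dataclass
class CohortSpec:
    """Parameters of one synthetic population draw.

    ``survey_coverage`` is the fraction of the population that answered
    Bob's survey; every diseased person enters Alice's registry, so the
    registry/survey overlap per class is what the protocol must recover.
    """

    population: int
    class_labels: tuple[str, ...]
    class_probs: tuple[float, ...]
    disease_probs: tuple[float, ...]
    survey_coverage: float
    name_model: ZipfModel
    seed: int
    birth_year_range: tuple[int, int] = (1930, 1970)
    address_pool: int = 500

    def __post_init__(self) -> None:
        if self.population < 1:
            raise ValueError("population must be positive")
        if len(self.class_labels) != len(self.class_probs) or len(
            self.class_labels
        ) != len(self.disease_probs):
            raise ValueError("labels, class_probs and disease_probs must align")
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ValueError("class probabilities must sum to 1")
        if any(not 0 <= p <= 1 for p in self.disease_probs):
            raise ValueError("disease probabilities must lie in [0, 1]")
        if not 0 <= self.survey_coverage <= 1:
            raise ValueError("survey_coverage must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Exact per-class overlap counts, computed on hidden person-IDs."""

    intersections: dict[str, int] = field(default_factory=dict)  # a_p
    class_sizes: dict[str, int] = field(default_factory=dict)  # |Y_p|
    n_cases: int = 0  # |X|


def _zipf_names(n: int, model: ZipfModel, rng: np.random.Generator) -> list[str]:
    """Assign names so duplicate-group sizes follow f(x) = a/x**s.

    The planned number of individuals at duplication level x is scaled so
    levels sum to n; each level x contributes floor(f(x)/x) groups of x
    people sharing one name. Leftover individuals get unique names (level 1),
    so the realized histogram matches the plan up to rounding.
    """
    s = model.s
    x_max = max(2, int(round(n ** (1.0 / s))) * 4)
    weights = np.array([x ** -s for x in range(1, x_max + 1)])
    a = n / weights.sum()
    sizes: list[int] = []
    for x in range(x_max, 1, -1):
        n_groups = int(a * x ** -s / x)
        sizes.extend([x] * n_groups)
    planned = sum(sizes)
    sizes.extend([1] * max(n - planned, 0))
    # trim overshoot from the unique tail, never from planted duplicate groups
    while sum(sizes) > n and sizes and sizes[-1] == 1:
        sizes.pop()
    names: list[str] = []
    for g, size in enumerate(sizes):
        names.extend([f"name{g:07d}"] * size)
    names = names[:n]
    perm = rng.permutation(len(names))
    return [names[i] for i in perm]


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[PersonRecord], list[PersonRecord], GroundTruth]:
    """Draw one population and split it into Alice and Bob tables.

    Deterministic per spec.seed. Alice receives every diseased individual;
    Bob receives a survey_coverage fraction sampled without replacement,
    labelled with their exposure class.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.population

    names = _zipf_names(n, spec.name_model, rng)
    y0, y1 = spec.birth_year_range
    start = datetime.date(y0, 1, 1).toordinal()
    end = datetime.date(y1, 12, 31).toordinal()
    birthdays = [
        datetime.date.fromordinal(int(o)).isoformat()
        for o in rng.integers(start, end + 1, size=n)
    ]
    addresses = [f"addr{i:05d}" for i in rng.integers(0, spec.address_pool, size=n)]
    sexes = ["m" if b else "f" for b in rng.integers(0, 2, size=n)]

    class_idx = rng.choice(len(spec.class_labels), size=n, p=spec.class_probs)
    risk = np.array(spec.disease_probs)[class_idx]
    diseased = rng.random(n) < risk

    surveyed = np.zeros(n, dtype=bool)
    k = int(round(spec.survey_coverage * n))
    surveyed[rng.choice(n, size=k, replace=False)] = True

    def person(i: int) -> dict[str, str]:
        return {
            "name_kana": names[i],
            "sex": sexes[i],
            "birthday": birthdays[i],
            "address": addresses[i],
        }

    alice = [
        PersonRecord(person(i), is_case=True) for i in range(n) if diseased[i]
    ]
    bob = [
        PersonRecord(person(i), exposure_class=spec.class_labels[class_idx[i]])
        for i in range(n)
        if surveyed[i]
    ]

    truth = GroundTruth(n_cases=int(diseased.sum()))
    for j, label in enumerate(spec.class_labels):
        in_class = class_idx == j
        truth.class_sizes[label] = int((in_class & surveyed).sum())
        truth.intersections[label] = int((in_class & surveyed & diseased).sum())
    return alice, bob, truth


def generate_from_counts(
    class_cells: dict[str, tuple[int, int]],
    seed: int = 0,
    extra_alice: int = 0,
) -> tuple[list[PersonRecord], list[PersonRecord]]:
    """Construct a cohort realizing exact per-class (a_p, b_p) cells.

    Every individual gets a collision-free attribute tuple, so the PSI join
    over any option containing the name attribute returns precisely the
    requested counts. ``extra_alice`` adds registry cases absent from the
    survey (they never enter any intersection).
    """
    for label, (a, b) in class_cells.items():
        if a < 0 or b < 0:
            raise ValueError(f"negative counts for class {label!r}")
    rng = np.random.default_rng(seed)
    alice: list[PersonRecord] = []
    bob: list[PersonRecord] = []
    idx = 0

    def make(i: int) -> dict[str, str]:
        year = 1930 + i % 40
        month = 1 + (i // 40) % 12
        day = 1 + (i // 480) % 28
        return {
            "name_kana": f"p{i:07d}",
            "sex": "m" if i % 2 else "f",
            "birthday": f"{year:04d}-{month:02d}-{day:02d}",
            "address": f"addr{i:07d}",
        }

    for label in sorted(class_cells):
        a, b = class_cells[label]
        for _ in range(a):
            attrs = make(idx)
            idx += 1
            alice.append(PersonRecord(dict(attrs), is_case=True))
            bob.append(PersonRecord(dict(attrs), exposure_class=label))
        for _ in range(b):
            bob.append(PersonRecord(make(idx), exposure_class=label))
            idx += 1
    for _ in range(extra_alice):
        alice.append(PersonRecord(make(idx), is_case=True))
        idx += 1
    rng.shuffle(alice)  # type: ignore[arg-type]
    rng.shuffle(bob)  # type: ignore[arg-type]
    return alice, bob
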