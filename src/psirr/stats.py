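"""Contingency-table relative risk, chi-squared tests, and SMR/Poisson tests.

Orientation convention: rows are exposure classes. ``a``/``b`` are cases and
non-cases in the exposed class, ``c``/``d`` cases and non-cases in the
unexposed reference class. Margins: n1 = a+b, n2 = c+d, m1 = a+c, m2 = b+d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

from scipy import special
from scipy import stats as _scipy_stats

__all__ = [
    "ContingencyTable",
    "ClassRow",
    "StratifiedResult",
    "SMRInput",
    "TestResult",
    "UndefinedStatisticError",
    "relative_risk",
    "odds_ratio",
    "chi_square_uncorrected",
    "chi_square_yates",
    "z_statistic",
    "critical_value",
    "stratified_rr",
    "expected_deaths",
    "smr",
    "poisson_tail_p",
    "smr_z",
]


class UndefinedStatisticError(ZeroDivisionError):
    """A cell or margin needed by the statistic is zero."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: a, b = exposed cases/non-cases; c, d = reference ditto."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or cell != int(cell):
                raise ValueError("cells must be non-negative integers")
        if self.N < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def n1(self) -> int:
        return self.a + self.b

    @property
    def n2(self) -> int:
        return self.c + self.d

    @property
    def m1(self) -> int:
        return self.a + self.c

    @property
    def m2(self) -> int:
        return self.b + self.d

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d


def relative_risk(table: ContingencyTable) -> float:
    """Risk ratio (a/(a+b)) / (c/(c+d))."""
    if table.n1 == 0:
        raise UndefinedStatisticError("no exposed observations (a+b = 0)")
    if table.c == 0:
        raise UndefinedStatisticError("no reference cases (c = 0)")
    return (table.a / table.n1) / (table.c / table.n2)


def odds_ratio(table: ContingencyTable) -> float:
    """ad/(bc); approximates the risk ratio for rare outcomes."""
    if table.b == 0 or table.c == 0:
        raise UndefinedStatisticError("odds ratio undefined with b = 0 or c = 0")
    return (table.a * table.d) / (table.b * table.c)


def _check_margins(table: ContingencyTable) -> None:
    if 0 in (table.n1, table.n2, table.m1, table.m2):
        raise UndefinedStatisticError("all four margins must be positive")


def chi_square_uncorrected(table: ContingencyTable) -> float:
    """N(ad - bc)^2 / (n1 n2 m1 m2), one degree of freedom, no correction.

    The cross product and margins are computed in exact integer arithmetic;
    division happens last.
    """
    _check_margins(table)
    cross = table.a * table.d - table.b * table.c
    return table.N * cross * cross / (table.n1 * table.n2 * table.m1 * table.m2)


def chi_square_yates(table: ContingencyTable) -> float:
    """Continuity-corrected statistic N(max(|ad-bc| - N/2, 0))^2 / (n1 n2 m1 m2).

    Algebraically identical to the four-cell sum of (|O_i - E_i| - 1/2)^2 / E_i
    with E_i = row*col/N, with the correction floored at zero so small tables
    cannot produce a negative-squared artifact.
    """
    _check_margins(table)
    corrected = max(abs(table.a * table.d - table.b * table.c) - table.N / 2, 0.0)
    return table.N * corrected * corrected / (table.n1 * table.n2 * table.m1 * table.m2)


def z_statistic(
    table: ContingencyTable, correction_sign: int | None = None
) -> float:
    """Normal-deviate form sqrt(N-1) * ((ad-bc) +/- N/2) / sqrt(n1 n2 m1 m2).

    With ``correction_sign`` None (default) the N/2 term shrinks |ad - bc|
    toward zero and is floored at zero; passing +1 or -1 applies the term
    literally with that sign.
    """
    _check_margins(table)
    if table.N < 2:
        raise UndefinedStatisticError("z statistic needs N >= 2")
    cross = table.a * table.d - table.b * table.c
    half = table.N / 2
    if correction_sign is None:
        corrected = math.copysign(max(abs(cross) - half, 0.0), cross)
    elif correction_sign in (1, -1):
        corrected = cross + correction_sign * half
    else:
        raise ValueError("correction_sign must be None, +1 or -1")
    denom = math.sqrt(table.n1 * table.n2 * table.m1 * table.m2)
    return math.sqrt(table.N - 1) * corrected / denom


def critical_value(
    kind: Literal["chi2_1df", "normal_two_sided", "normal_one_sided"], alpha: float
) -> float:
    """Upper-tail rejection threshold from the inverse CDF (no lookup table)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if kind == "chi2_1df":
        return float(_scipy_stats.chi2.ppf(1 - alpha, df=1))
    if kind == "normal_two_sided":
        return float(_scipy_stats.norm.ppf(1 - alpha / 2))
    if kind == "normal_one_sided":
        return float(_scipy_stats.norm.ppf(1 - alpha))
    raise ValueError(f"unknown critical-value kind: {kind!r}")


@dataclass
class ClassRow:
    """One exposure-class row of the stratified output table."""

    label: str
    a: int  # cases in this class
    b: int  # non-cases in this class
    rr: float | None
    n_p: int | None  # this class + reference size; None only when undefined
    chi2: float | None  # None for the reference row
    is_reference: bool = False


@dataclass
class StratifiedResult:
    rows: list[ClassRow] = field(default_factory=list)
    reference_label: str | None = None
    chi2_variant: str = "uncorrected"

    def row(self, label: str) -> ClassRow:
        for r in self.rows:
            if r.label == label:
                return r
        raise KeyError(label)


def stratified_rr(
    class_counts: Sequence[tuple[str, int, int]],
    reference_label: str,
    chi2_variant: Literal["uncorrected", "yates"] = "uncorrected",
) -> StratifiedResult:
    """Per-class relative risk and chi-squared against one reference class.

    ``class_counts`` holds (label, cases, non-cases) per exposure class.
    The reference row gets RR exactly 1.0 and no statistic; every other row
    is tested as a 2x2 table against the reference cells.
    """
    labels = [lab for lab, _, _ in class_counts]
    if reference_label not in labels:
        raise ValueError(f"reference label {reference_label!r} not among classes")
    c, d = next((a, b) for lab, a, b in class_counts if lab == reference_label)
    if c == 0:
        raise UndefinedStatisticError("reference class has zero cases")
    chi2_fn = chi_square_uncorrected if chi2_variant == "uncorrected" else chi_square_yates
    result = StratifiedResult(reference_label=reference_label, chi2_variant=chi2_variant)
    for label, a, b in class_counts:
        if label == reference_label:
            result.rows.append(
                ClassRow(label, a, b, rr=1.0, n_p=c + d, chi2=None, is_reference=True)
            )
            continue
        table = ContingencyTable(a, b, c, d)
        result.rows.append(
            ClassRow(
                label,
                a,
                b,
                rr=relative_risk(table),
                n_p=table.N,
                chi2=chi2_fn(table),
            )
        )
    return result


@dataclass
class SMRInput:
    """Age-stratified mortality input: (observed deaths, reference rate, population)."""

    strata: list[tuple[int, float, float]]

    def __post_init__(self) -> None:
        for d_j, q_j, n_j in self.strata:
            if d_j < 0 or d_j != int(d_j):
                raise ValueError("observed deaths must be non-negative integers")
            if not 0 <= q_j <= 1:
                raise ValueError("death rates must lie in [0, 1]")
            if n_j < 0:
                raise ValueError("populations must be non-negative")

    @property
    def observed(self) -> int:
        return sum(d for d, _, _ in self.strata)

    @property
    def expected(self) -> float:
        return expected_deaths(self.strata)


def expected_deaths(strata: Sequence[tuple[int, float, float]]) -> float:
    """E = sum of q_j * n_j over age strata."""
    if not strata:
        raise ValueError("strata must be non-empty")
    return float(sum(q_j * n_j for _, q_j, n_j in strata))


def smr(O: float, E: float) -> float:
    """Standardized mortality ratio O/E."""
    if E <= 0:
        raise UndefinedStatisticError("SMR undefined for E <= 0")
    return O / E


def poisson_tail_p(O: int, E: float) -> float:
    """One-sided upper tail P(X >= O) for X ~ Poisson(E).

    Computed as the regularized lower incomplete gamma gammainc(O, E), which
    equals 1 - sum_{j<O} E^j e^-E / j! with stable accumulation for large E.
    """
    if O < 0 or O != int(O):
        raise ValueError("O must be a non-negative integer")
    if E <= 0:
        raise ValueError("E must be positive")
    if O == 0:
        return 1.0
    return float(special.gammainc(O, E))


@dataclass
class TestResult:
    statistic: float
    kind: str  # "chi2_1df" | "z"
    alpha: float
    critical: float
    reject: bool
    p_value: float | None = None
    warning: str | None = None


def smr_z(
    O: int,
    E: float,
    sided: Literal["one", "two"] = "two",
    alpha: float = 0.05,
) -> TestResult:
    """Continuity-corrected normal approximation to the Poisson SMR test.

    Two-sided: Z = (|O - E| - 0.5)/sqrt(E) against the upper alpha/2 normal
    quantile. One-sided: Z = (O - E - 0.5)/sqrt(E) against the upper alpha
    quantile. The approximation is only advertised for E >= 5; smaller E
    attaches a warning rather than failing.
    """
    if E <= 0:
        raise UndefinedStatisticError("E must be positive")
    warning = None
    if E < 5:
        warning = f"normal approximation unreliable for E = {E} < 5"
    if sided == "two":
        z = (abs(O - E) - 0.5) / math.sqrt(E)
        crit = critical_value("normal_two_sided", alpha)
        p = 2 * float(_scipy_stats.norm.sf(z))
    elif sided == "one":
        z = (O - E - 0.5) / math.sqrt(E)
        crit = critical_value("normal_one_sided", alpha)
        p = float(_scipy_stats.norm.sf(z))
    else:
        raise ValueError("sided must be 'one' or 'two'")
    return TestResult(
        statistic=z,
        kind="z",
        alpha=alpha,
        critical=crit,
        reject=z > crit,
        p_value=min(p, 1.0),
        warning=warning,
    )
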