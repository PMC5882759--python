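"""Readers and writers for every exchange format.

CSV is UTF-8, comma-separated, RFC-4180 quoted, header row mandatory.
Transcripts are JSON lines (one round per line, integers as decimal
strings); parameters and results are plain JSON.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .crypto import GroupParams, RoundMessage
from .quasi_id import PersonRecord
from .stats import ClassRow

__all__ = [
    "FormatError",
    "RunConfig",
    "read_records_csv",
    "write_records_csv",
    "read_counts_csv",
    "write_counts_csv",
    "read_smr_strata_csv",
    "read_params",
    "write_params",
    "read_transcript",
    "write_transcript",
    "rows_to_dict",
    "render_rows",
]


class FormatError(ValueError):
    """Malformed input file; message names the offending line."""


@dataclass
class RunConfig:
    """Resolved configuration of one protocol run."""

    option_attributes: tuple[str, ...]
    reference_label: str = "L"
    chi2_variant: str = "uncorrected"
    alpha: float = 0.05
    seed: int = 0
    hash_name: str = "sha256"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def read_records_csv(path: str | Path) -> list[PersonRecord]:
    """Person records; columns 'exposure_class' / 'is_case' are study labels,
    everything else is an attribute."""
    records: list[PersonRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: missing header row")
        for lineno, row in enumerate(reader, start=2):
            if None in row or any(v is None for v in row.values()):
                raise FormatError(f"{path}: line {lineno}: ragged row")
            attrs = {
                k: v for k, v in row.items() if k not in ("exposure_class", "is_case")
            }
            case_raw = row.get("is_case", "")
            records.append(
                PersonRecord(
                    attributes=attrs,
                    exposure_class=row.get("exposure_class") or None,
                    is_case=None if case_raw == "" else case_raw in ("1", "true", "True"),
                )
            )
    return records


def write_records_csv(path: str | Path, records: Sequence[PersonRecord]) -> None:
    if not records:
        raise ValueError("cannot write an empty record table")
    attr_names = sorted({k for r in records for k in r.attributes})
    has_class = any(r.exposure_class is not None for r in records)
    has_case = any(r.is_case is not None for r in records)
    fields = list(attr_names)
    if has_class:
        fields.append("exposure_class")
    if has_case:
        fields.append("is_case")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for r in records:
            row = dict(r.attributes)
            if has_class:
                row["exposure_class"] = r.exposure_class or ""
            if has_case:
                row["is_case"] = "" if r.is_case is None else ("1" if r.is_case else "0")
            writer.writerow(row)


def read_counts_csv(path: str | Path) -> list[tuple[str, int, int]]:
    """Per-class counts: columns label, cases, noncases."""
    out: list[tuple[str, int, int]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"label", "cases", "noncases"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise FormatError(f"{path}: header must contain {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                out.append((row["label"], int(row["cases"]), int(row["noncases"])))
            except (ValueError, TypeError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_counts_csv(path: str | Path, counts: Sequence[tuple[str, int, int]]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "cases", "noncases"])
        writer.writerows(counts)


def read_smr_strata_csv(path: str | Path) -> list[tuple[int, float, float]]:
    """Age strata: columns age_group, deaths, rate, population."""
    out: list[tuple[int, float, float]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"age_group", "deaths", "rate", "population"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise FormatError(f"{path}: header must contain {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                out.append(
                    (int(row["deaths"]), float(row["rate"]), float(row["population"]))
                )
            except (ValueError, TypeError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return out


def read_params(path: str | Path) -> GroupParams:
    return GroupParams.from_json(Path(path).read_text(encoding="utf-8"))


def write_params(path: str | Path, params: GroupParams) -> None:
    Path(path).write_text(params.to_json() + "\n", encoding="utf-8")


def read_transcript(path: str | Path) -> list[RoundMessage]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    out = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        try:
            out.append(RoundMessage.from_json(line))
        except (json.JSONDecodeError, KeyError) as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_transcript(path: str | Path, transcript: Sequence[RoundMessage]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for msg in transcript:
            fh.write(msg.to_json() + "\n")


def rows_to_dict(rows: Sequence[ClassRow]) -> list[dict]:
    """Full-precision JSON form of a stratified result."""
    return [
        {
            "label": r.label,
            "cases": r.a,
            "noncases": r.b,
            "class_size": r.a + r.b,
            "rr": r.rr,
            "n_p": r.n_p,
            "chi2": r.chi2,
            "reference": r.is_reference,
        }
        for r in rows
    ]


def render_rows(rows: Sequence[ClassRow]) -> str:
    """Plain-text table, statistics rounded to 2 decimals."""
    header = f"{'class':>8} {'cases':>8} {'noncases':>10} {'|Y_p|':>8} {'RR':>8} {'N_p':>8} {'chi2':>8}"
    lines = [header, "-" * len(header)]
    for r in rows:
        rr = "undef" if r.rr is None else f"{r.rr:.2f}"
        chi2 = "Reference" if r.is_reference else (
            "undef" if r.chi2 is None else f"{r.chi2:.2f}"
        )
        n_p = "" if r.n_p is None else str(r.n_p)
        lines.append(
            f"{r.label:>8} {r.a:>8} {r.b:>10} {r.a + r.b:>8} {rr:>8} {n_p:>8} {chi2:>9}"
        )
    return "\n".join(lines)
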