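"""Two-party stratified relative-risk protocol.

Alice holds the case registry X; Bob holds survey records partitioned into
disjoint exposure classes Y_1..Y_q. They jointly compute the per-class
intersection counts a_p = |X ∩ Y_p| through commutative-encryption PSI and
derive the stratified RR / chi-squared table, without exchanging plaintext
quasi-identifiers.

Message flow (one commutative key pair per run, fresh permutations per
message):

  1. alice -> bob : layer-1 encryptions of X               (one round)
  2. bob -> alice : layer-2 re-encryption of round 1       (one round)
  3. bob -> alice : layer-1 encryptions of each Y_p        (q rounds, labelled)

Alice then adds her layer to each Y_p round and counts collisions with
round 2. Declared leakage: |X|, each |Y_p|, and the counts a_p.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

from . import crypto, stats
from .crypto import CommutativeKey, GroupParams, RoundMessage
from .quasi_id import AttributeOption, PersonRecord, quasi_id

__all__ = [
    "AliceState",
    "BobState",
    "ProtocolResult",
    "LeakageReport",
    "AuditError",
    "alice_start",
    "bob_respond",
    "alice_finish",
    "run_protocol",
    "audit_transcript",
]


class AuditError(AssertionError):
    """A protocol transcript leaked plaintext material."""


@dataclass
class AliceState:
    params: GroupParams
    key: CommutativeKey
    qids: list[bytes]  # deduplicated case quasi-identifiers
    seed: int

    def __post_init__(self) -> None:
        if len(set(self.qids)) != len(self.qids):
            raise ValueError("Alice's quasi-ID set must be deduplicated")


@dataclass
class BobState:
    params: GroupParams
    key: CommutativeKey
    class_qids: dict[str, list[bytes]]  # label -> deduplicated quasi-IDs
    seed: int
    reference_label: str

    def __post_init__(self) -> None:
        seen: set[bytes] = set()
        for label, qids in self.class_qids.items():
            s = set(qids)
            if len(s) != len(qids):
                raise ValueError(f"class {label!r} contains duplicate quasi-IDs")
            if seen & s:
                raise ValueError("exposure classes must be pairwise disjoint")
            seen |= s
        if self.reference_label not in self.class_qids:
            raise ValueError(f"reference class {self.reference_label!r} missing")


@dataclass
class ProtocolResult:
    """Joint output: the Table-4-shaped stratified RR table plus leakage."""

    rows: list[stats.ClassRow] = field(default_factory=list)
    reference_label: str | None = None
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)  # label -> (a_p, b_p)
    x_size: int = 0
    chi2_variant: str = "uncorrected"

    def row(self, label: str) -> stats.ClassRow:
        for r in self.rows:
            if r.label == label:
                return r
        raise KeyError(label)


def _records_to_qids(
    records: Sequence[PersonRecord], option: AttributeOption
) -> list[bytes]:
    seen: dict[bytes, None] = {}
    for rec in records:
        seen.setdefault(quasi_id(rec, option).digest, None)
    return list(seen)


def _classes_from_records(
    records: Sequence[PersonRecord], option: AttributeOption
) -> dict[str, list[bytes]]:
    classes: dict[str, dict[bytes, None]] = {}
    for rec in records:
        if rec.exposure_class is None:
            raise ValueError("every Bob record needs an exposure_class label")
        classes.setdefault(rec.exposure_class, {}).setdefault(
            quasi_id(rec, option).digest, None
        )
    return {label: list(qids) for label, qids in classes.items()}


def alice_start(state: AliceState) -> list[RoundMessage]:
    """Round 1: Alice's layer-1 encrypted, shuffled case set."""
    params = state.params
    ea = [
        crypto.commute_encrypt(crypto.hash_to_group(q, params), state.key, params).value
        for q in state.qids
    ]
    rng = random.Random(f"alice-perm-{state.seed}-0")
    rng.shuffle(ea)
    return [RoundMessage("alice", 1, ea, set_size=len(state.qids))]


def bob_respond(state: BobState, incoming: list[RoundMessage]) -> list[RoundMessage]:
    """Rounds 2..2+q: double-encrypt Alice's set; send each class layer-1."""
    params = state.params
    (msg1,) = [m for m in incoming if m.role == "alice" and m.layer == 1]
    out: list[RoundMessage] = []

    dea = [pow(e, state.key.exponent, params.p) for e in msg1.elements]
    rng = random.Random(f"bob-perm-{state.seed}-0")
    rng.shuffle(dea)
    out.append(RoundMessage("bob", 2, dea))

    for idx, (label, qids) in enumerate(sorted(state.class_qids.items()), start=1):
        eb = [
            crypto.commute_encrypt(crypto.hash_to_group(q, params), state.key, params).value
            for q in qids
        ]
        rng = random.Random(f"bob-perm-{state.seed}-{idx}")
        rng.shuffle(eb)
        out.append(RoundMessage("bob", 1, eb, label=label, set_size=len(qids)))
    return out


def alice_finish(
    state: AliceState, incoming: list[RoundMessage]
) -> dict[str, tuple[int, int]]:
    """Alice adds her layer to each class set and counts double collisions.

    Returns label -> (a_p, b_p) with a_p = |X ∩ Y_p| and b_p = |Y_p| - a_p.
    """
    params = state.params
    (msg2,) = [m for m in incoming if m.role == "bob" and m.layer == 2]
    double_x = set(msg2.elements)
    counts: dict[str, tuple[int, int]] = {}
    for msg in incoming:
        if msg.role == "bob" and msg.layer == 1:
            deb = {pow(e, state.key.exponent, params.p) for e in msg.elements}
            a_p = len(double_x & deb)
            counts[msg.label or ""] = (a_p, (msg.set_size or len(msg.elements)) - a_p)
    return counts


def _result_from_counts(
    counts: dict[str, tuple[int, int]],
    reference_label: str,
    x_size: int,
    chi2_variant: str,
) -> ProtocolResult:
    result = ProtocolResult(
        reference_label=reference_label,
        counts=dict(counts),
        x_size=x_size,
        chi2_variant=chi2_variant,
    )
    c, _d = counts[reference_label]
    if c == 0:
        # No reference cases: every RR is undefined; surface per-row flags.
        for label in sorted(counts):
            a, b = counts[label]
            result.rows.append(
                stats.ClassRow(
                    label, a, b, rr=None, n_p=None, chi2=None,
                    is_reference=label == reference_label,
                )
            )
        return result
    ordered = [reference_label] + sorted(set(counts) - {reference_label})
    strat = stats.stratified_rr(
        [(label, *counts[label]) for label in ordered],
        reference_label,
        chi2_variant=chi2_variant,  # type: ignore[arg-type]
    )
    result.rows = strat.rows
    return result


def run_protocol(
    alice_records: Sequence[PersonRecord],
    bob_records: Sequence[PersonRecord],
    option: AttributeOption,
    params: GroupParams,
    seed: int,
    reference_label: str = "L",
    chi2_variant: str = "uncorrected",
) -> tuple[ProtocolResult, list[RoundMessage]]:
    """Execute both roles in-process; fully deterministic for a given seed.

    Returns the joint result and the complete message transcript (the union
    of both parties' views; each party's own view is the subset it sent or
    received, which here is every round).
    """
    rng = random.Random(f"protocol-{seed}")
    alice = AliceState(
        params=params,
        key=crypto.generate_key(params, rng.getrandbits(64)),
        qids=_records_to_qids(alice_records, option),
        seed=rng.getrandbits(64),
    )
    bob = BobState(
        params=params,
        key=crypto.generate_key(params, rng.getrandbits(64)),
        class_qids=_classes_from_records(bob_records, option),
        seed=rng.getrandbits(64),
        reference_label=reference_label,
    )
    round1 = alice_start(alice)
    rounds_b = bob_respond(bob, round1)
    counts = alice_finish(alice, rounds_b)
    result = _result_from_counts(counts, reference_label, len(alice.qids), chi2_variant)
    return result, round1 + rounds_b


@dataclass
class LeakageReport:
    """What each party could read off the transcript: sizes and counts only."""

    x_size: int | None
    class_sizes: dict[str, int]
    intersections: dict[str, int]
    rounds_checked: int


def audit_transcript(
    transcript: Sequence[RoundMessage],
    plaintext_ids: Sequence[bytes],
    result: ProtocolResult | None = None,
) -> LeakageReport:
    """Assert no plaintext quasi-ID appears in any serialized round.

    Each quasi-ID is checked both as its hex form and as the decimal integer
    a naive encoder might emit. Raises AuditError naming the offending round;
    otherwise returns the declared leakage surface.
    """
    needles: list[str] = []
    for qid in plaintext_ids:
        needles.append(qid.hex())
        needles.append(str(int.from_bytes(qid, "big")))
    x_size: int | None = None
    class_sizes: dict[str, int] = {}
    for i, msg in enumerate(transcript):
        line = msg.to_json()
        for needle in needles:
            if needle in line:
                raise AuditError(f"plaintext quasi-ID leaked in round {i}")
        if msg.role == "alice" and msg.layer == 1 and msg.set_size is not None:
            x_size = msg.set_size
        if msg.role == "bob" and msg.layer == 1 and msg.label is not None:
            class_sizes[msg.label] = msg.set_size or len(msg.elements)
    intersections = (
        {label: a for label, (a, _) in result.counts.items()} if result else {}
    )
    return LeakageReport(
        x_size=x_size,
        class_sizes=class_sizes,
        intersections=intersections,
        rounds_checked=len(transcript),
    )
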