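"""Commutative encryption over a prime-order subgroup and PSI-cardinality.

The cipher is Pohlig–Hellman style modular exponentiation: each party keeps
a secret exponent and maps a hashed input ``e`` to ``e**exponent mod p``.
Because exponentiation commutes, two parties can double-encrypt their sets
in either order and compare the results without ever exchanging plaintext.
"""

from __future__ import annotations

import hashlib
import json
import random
import secrets
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "GroupParams",
    "CommutativeKey",
    "GroupElement",
    "RoundMessage",
    "ParameterSearchError",
    "MalformedCiphertextError",
    "is_probable_prime",
    "generate_params",
    "generate_key",
    "hash_to_group",
    "commute_encrypt",
    "commute_decrypt",
    "psi_cardinality",
    "psi_elements",
]

# Small primes for fast trial-division rejection before Miller-Rabin.
_SMALL_PRIMES: list[int] = []
_sieve = bytearray([1]) * 1000
_sieve[0:2] = b"\x00\x00"
for _i in range(2, 1000):
    if _sieve[_i]:
        _SMALL_PRIMES.append(_i)
        for _j in range(_i * _i, 1000, _i):
            _sieve[_j] = 0
del _sieve, _i


class ParameterSearchError(RuntimeError):
    """Raised when no valid (p, q) pair is found within the candidate budget."""


class MalformedCiphertextError(ValueError):
    """Raised when a ciphertext value lies outside the group."""


def is_probable_prime(n: int, rounds: int = 40) -> bool:
    """Miller-Rabin with `rounds` bases; error probability < 4**-rounds < 2**-80.

    Bases are drawn from an RNG seeded by ``n`` itself, so the verdict is
    deterministic per input without global state.
    """
    if n < 2:
        return False
    for sp in _SMALL_PRIMES:
        if n % sp == 0:
            return n == sp
    d, r = n - 1, 0
    while d % 2 == 0:
        d //= 2
        r += 1
    rng = random.Random(n)
    for _ in range(rounds):
        a = rng.randrange(2, n - 1)
        x = pow(a, d, n)
        if x == 1 or x == n - 1:
            continue
        for _ in range(r - 1):
            x = x * x % n
            if x == n - 1:
                break
        else:
            return False
    return True


@dataclass(frozen=True)
class GroupParams:
    """Prime modulus ``p`` with an order-``q`` subgroup; cofactor = (p-1)//q."""

    p: int
    q: int
    cofactor: int
    hash_name: str = "sha256"

    def __post_init__(self) -> None:
        if self.cofactor * self.q != self.p - 1:
            raise ValueError("cofactor * q must equal p - 1")
        if not is_probable_prime(self.p):
            raise ValueError("p is not prime")
        if not is_probable_prime(self.q):
            raise ValueError("q is not prime")

    @classmethod
    def from_pq(cls, p: int, q: int, hash_name: str = "sha256") -> "GroupParams":
        if (p - 1) % q != 0:
            raise ValueError("q must divide p - 1")
        return cls(p=p, q=q, cofactor=(p - 1) // q, hash_name=hash_name)

    def to_json(self) -> str:
        return json.dumps(
            {
                "p": str(self.p),
                "q": str(self.q),
                "cofactor": str(self.cofactor),
                "hash": self.hash_name,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GroupParams":
        d = json.loads(text)
        return cls(
            p=int(d["p"]),
            q=int(d["q"]),
            cofactor=int(d["cofactor"]),
            hash_name=d.get("hash", "sha256"),
        )


@dataclass(frozen=True)
class CommutativeKey:
    """A secret exponent in [1, q-1]."""

    exponent: int
    q: int

    def __post_init__(self) -> None:
        if not 1 <= self.exponent <= self.q - 1:
            raise ValueError("exponent must lie in [1, q-1]")

    def inverse(self) -> "CommutativeKey":
        return CommutativeKey(pow(self.exponent, -1, self.q), self.q)


@dataclass(frozen=True)
class GroupElement:
    """An element of the order-q subgroup of Z_p^*."""

    value: int

    def in_group(self, params: GroupParams) -> bool:
        return 1 <= self.value <= params.p - 1 and pow(self.value, params.q, params.p) == 1


def generate_params(
    p_bits: int = 2048,
    q_bits: int = 160,
    rng_seed: int | None = None,
    max_tries: int | None = None,
) -> GroupParams:
    """Find primes q (q_bits) and p = cofactor*q + 1 (p_bits).

    Deterministic for a given ``rng_seed``. Bit lengths down to 16 are
    accepted so toy groups for tests can be built in milliseconds.
    """
    if q_bits >= p_bits:
        raise ValueError("q_bits must be smaller than p_bits")
    if p_bits < 16 or q_bits < 16:
        raise ValueError("bit lengths below 16 are not supported")
    if rng_seed is None:
        rng_seed = secrets.randbits(64)
    rng = random.Random(f"psirr-params-{rng_seed}")
    budget = max_tries if max_tries is not None else 400 * p_bits

    q = 0
    for _ in range(budget):
        cand = rng.getrandbits(q_bits) | (1 << (q_bits - 1)) | 1
        if is_probable_prime(cand):
            q = cand
            break
    else:
        raise ParameterSearchError(f"no {q_bits}-bit prime q found in {budget} tries")

    c_bits = p_bits - q_bits
    for _ in range(budget):
        c = rng.getrandbits(c_bits) | (1 << (c_bits - 1))
        c &= ~1  # cofactor must be even so p is odd
        if c == 0:
            continue
        p = c * q + 1
        if p.bit_length() != p_bits:
            continue
        if is_probable_prime(p):
            return GroupParams(p=p, q=q, cofactor=c)
    raise ParameterSearchError(
        f"no {p_bits}-bit prime p = c*q+1 found in {budget} tries for q={q}"
    )


def generate_key(params: GroupParams, rng_seed: int | None = None) -> CommutativeKey:
    """Draw a secret exponent uniformly from [1, q-1]; seeded for replay."""
    if rng_seed is None:
        return CommutativeKey(secrets.randbelow(params.q - 1) + 1, params.q)
    rng = random.Random(f"psirr-key-{rng_seed}")
    return CommutativeKey(rng.randrange(1, params.q), params.q)


def hash_to_group(message: bytes, params: GroupParams, max_tries: int = 10_000) -> GroupElement:
    """Map bytes into the order-q subgroup by cofactor exponentiation.

    digest = SHA-256(message || counter) as an integer mod p, then raised to
    the cofactor; the counter (8-byte big-endian) is the least value >= 0
    for which the result is neither 0 nor 1.
    """
    if not message:
        raise ValueError("message must be non-empty")
    h = getattr(hashlib, params.hash_name)
    for counter in range(max_tries):
        digest = h(message + counter.to_bytes(8, "big")).digest()
        x = int.from_bytes(digest, "big") % params.p
        e = pow(x, params.cofactor, params.p)
        if e not in (0, 1):
            return GroupElement(e)
    raise RuntimeError("hash_to_group failed to find a non-identity element")


def commute_encrypt(elem: GroupElement, key: CommutativeKey, params: GroupParams) -> GroupElement:
    """elem ** key.exponent mod p. Commutes across independent keys."""
    if not 1 <= elem.value <= params.p - 1:
        raise MalformedCiphertextError(f"element {elem.value} outside [1, p-1]")
    return GroupElement(pow(elem.value, key.exponent, params.p))


def commute_decrypt(elem: GroupElement, key: CommutativeKey, params: GroupParams) -> GroupElement:
    """Undo one encryption layer via the inverse exponent mod q."""
    return commute_encrypt(elem, key.inverse(), params)


@dataclass
class RoundMessage:
    """One protocol round on the wire: who sent what, at which layer."""

    role: str  # "alice" | "bob"
    layer: int  # 1 = single-encrypted, 2 = double-encrypted
    elements: list[int] = field(default_factory=list)
    label: str | None = None  # exposure-class label for per-class rounds
    set_size: int | None = None
    pairs: list[tuple[int, int]] | None = None  # (single, double) for psi_elements

    def to_json(self) -> str:
        d: dict = {"role": self.role, "layer": self.layer}
        if self.label is not None:
            d["label"] = self.label
        if self.set_size is not None:
            d["set_size"] = self.set_size
        if self.pairs is not None:
            d["pairs"] = [[str(s), str(t)] for s, t in self.pairs]
        else:
            d["elements"] = [str(v) for v in self.elements]
        return json.dumps(d, separators=(",", ":"))

    @classmethod
    def from_json(cls, line: str) -> "RoundMessage":
        d = json.loads(line)
        pairs = None
        if "pairs" in d:
            pairs = [(int(s), int(t)) for s, t in d["pairs"]]
        return cls(
            role=d["role"],
            layer=d["layer"],
            elements=[int(v) for v in d.get("elements", [])],
            label=d.get("label"),
            set_size=d.get("set_size"),
            pairs=pairs,
        )


def _dedupe(items: Iterable[bytes]) -> list[bytes]:
    seen: dict[bytes, None] = {}
    for it in items:
        seen.setdefault(it, None)
    return list(seen)


def _shuffled(values: list, rng: random.Random) -> list:
    out = list(values)
    rng.shuffle(out)
    return out


def psi_cardinality(
    set_a: Sequence[bytes],
    set_b: Sequence[bytes],
    params: GroupParams,
    seed_a: int = 0,
    seed_b: int = 1,
) -> tuple[int, list[RoundMessage]]:
    """Two-party PSI cardinality via commutative encryption.

    Alice single-encrypts her hashed set; Bob double-encrypts it and
    single-encrypts his own; Alice adds her layer to Bob's set and counts
    coinciding double encryptions. Every outgoing list is shuffled with a
    seeded Fisher-Yates permutation so ordering leaks nothing.

    Returns the intersection size and the full message transcript.
    """
    set_a = _dedupe(set_a)
    set_b = _dedupe(set_b)
    u = generate_key(params, seed_a)
    v = generate_key(params, seed_b)
    rng_a = random.Random(f"perm-a-{seed_a}")
    rng_b = random.Random(f"perm-b-{seed_b}")
    transcript: list[RoundMessage] = []

    ea = [commute_encrypt(hash_to_group(m, params), u, params).value for m in set_a]
    msg1 = RoundMessage("alice", 1, _shuffled(ea, rng_a), set_size=len(set_a))
    transcript.append(msg1)

    dea = [pow(e, v.exponent, params.p) for e in msg1.elements]
    transcript.append(RoundMessage("bob", 2, _shuffled(dea, rng_b)))

    eb = [commute_encrypt(hash_to_group(m, params), v, params).value for m in set_b]
    msg3 = RoundMessage("bob", 1, _shuffled(eb, rng_b), set_size=len(set_b))
    transcript.append(msg3)

    deb = {pow(e, u.exponent, params.p) for e in msg3.elements}
    count = len(set(transcript[1].elements) & deb)
    return count, transcript


def psi_elements(
    set_a: Sequence[bytes],
    set_b: Sequence[bytes],
    params: GroupParams,
    seed_a: int = 0,
    seed_b: int = 1,
) -> tuple[list[bytes], list[RoundMessage]]:
    """Element-revealing PSI variant: Bob returns (single, double) pairs for
    Alice's ciphertexts, letting Alice (and only Alice) map matches back to
    her plaintext inputs."""
    set_a = _dedupe(set_a)
    set_b = _dedupe(set_b)
    u = generate_key(params, seed_a)
    v = generate_key(params, seed_b)
    rng_a = random.Random(f"perm-a-{seed_a}")
    rng_b = random.Random(f"perm-b-{seed_b}")
    transcript: list[RoundMessage] = []

    single_of = {
        m: commute_encrypt(hash_to_group(m, params), u, params).value for m in set_a
    }
    msg1 = RoundMessage("alice", 1, _shuffled(list(single_of.values()), rng_a),
                        set_size=len(set_a))
    transcript.append(msg1)

    pairs = [(e, pow(e, v.exponent, params.p)) for e in msg1.elements]
    transcript.append(RoundMessage("bob", 2, pairs=_shuffled(pairs, rng_b)))

    eb = [commute_encrypt(hash_to_group(m, params), v, params).value for m in set_b]
    msg3 = RoundMessage("bob", 1, _shuffled(eb, rng_b), set_size=len(set_b))
    transcript.append(msg3)

    double_of = dict(transcript[1].pairs or [])
    deb = {pow(e, u.exponent, params.p) for e in msg3.elements}
    common = [m for m, s in single_of.items() if double_of[s] in deb]
    return common, transcript
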