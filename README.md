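# psirr

Two-party privacy-preserving estimation of stratified relative risk.

One party (Alice) holds a disease case registry; another (Bob) holds a
survey that partitions people into exposure classes (e.g. physical-activity
quartiles L/S/T/H). `psirr` lets them jointly compute the per-class
2×2 contingency counts — and from them relative risks and chi-squared
statistics — without either side revealing who is in its table. Record
linkage uses hashed quasi-identifiers (canonicalized name ‖ birthday ‖
address), and the joint counts are obtained with a commutative-encryption
private-set-intersection-cardinality protocol (Pohlig–Hellman style
exponentiation in a prime-order subgroup).

The library also includes:

- **`psirr.quasi_id`** — attribute canonicalization (NFKC + unit-separator
  joining), SHA-256 quasi-identifiers, empirical entropy of attribute
  combinations, duplicate-group histograms, and a Zipf rank-frequency model
  of name sharing (fitting, population totals, constant estimation).
- **`psirr.stats`** — relative risk, odds ratio, uncorrected and
  Yates-corrected chi-squared, normal-deviate form, inverse-CDF critical
  values, stratified tables, and SMR testing (exact Poisson tail and the
  continuity-corrected normal approximation).
- **`psirr.crypto`** — group-parameter generation (default 2048-bit modulus,
  160-bit prime-order subgroup; toy sizes accepted for tests), hash-to-group
  by cofactor exponentiation, commutative encryption, and PSI in both
  cardinality-only and element-revealing variants, with JSON-lines
  transcripts.
- **`psirr.protocol`** — the two-party orchestration (in-process or
  round-by-round over message files) plus a transcript auditor that asserts
  nothing beyond set sizes and intersection counts is derivable.
- **`psirr.synthetic`** — a linked-cohort generator with exact ground truth
  (Zipf-distributed name duplication, class-specific disease risks), and a
  constructor that realizes exact per-class cell counts.

## CLI

```sh
# group parameters (deterministic for a given seed)
psirr params --p-bits 512 --q-bits 160 --seed 7 --out params.json

# synthetic linked cohort with known ground truth
psirr simulate --spec cohort.json --out-dir cohort/

# full two-party run in one process
psirr run-local --alice cohort/alice.csv --bob cohort/bob.csv \
    --params params.json --seed 11 --out result.json --transcript t.jsonl

# or role by role, over message files
psirr alice start --records alice.csv --params params.json --seed 42 \
    --state alice_state.json --out msg1.jsonl
psirr bob --records bob.csv --params params.json --seed 43 \
    --in msg1.jsonl --out msg2.jsonl
psirr alice finish --state alice_state.json --in msg2.jsonl --out result.json

# plaintext statistics from a counts CSV (label,cases,noncases)
psirr analyze --counts counts.csv --reference L

# quasi-identifier identifiability report
psirr audit-qid --records bob.csv --attributes name_kana,birthday

# standardized mortality ratio tests
psirr smr-test --observed 30 --expected 20
psirr smr-test --strata strata.csv --sided one
```

Record CSVs are UTF-8 with a header row; attribute columns are free-form,
and `exposure_class` / `is_case` are reserved label columns.

## Security model

Honest-but-curious parties only. Declared leakage is the set sizes and the
per-class intersection counts; `psirr.protocol.audit_transcript` checks a
recorded session against that surface. No constant-time arithmetic, no
malicious-model defenses, no network hardening — transport is files/pipes.
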