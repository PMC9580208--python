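"""Demultiplexing and tiered read quality control.

Each incoming read is assigned to exactly one of three tiers:

* ``HIGH``  — passes the full filter battery after truncation; only these
  reads enter dereplication and clustering.
* ``MID``   — fails only "soft" filters (expected errors, the Poisson
  binomial test, or a moderate length shortfall), or is a second-of-pair
  read.  MID reads are excluded from clustering but recovered later by
  backmapping onto cluster representatives.
* ``REJECT`` — fails a "hard" filter (average quality, homopolymer run,
  ambiguous bases, severe length shortfall) and is dropped.

The rationale is that sequencing errors inflate observed diversity, so the
error-sensitive clustering step sees only strictly filtered, truncated
first-of-pair reads, while abundance estimates are later topped up from the
more permissive MID pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .formats import ReadRecord, SampleSpec

# IUPAC nucleotide codes -> the set of bases each matches
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class ConfigError(ValueError):
    pass


@dataclass(slots=True)
class FilterConfig:
    """Tunable thresholds of the read filter battery.

    ``truncate_len`` is the clustering read length in nt: first-of-pair reads
    are cut to this length before filtering, so all clustered sequences are
    directly comparable.  ``max_expected_errors`` bounds the Phred-implied
    expected number of errors in the truncated read; the Poisson binomial
    test additionally rejects reads whose probability of carrying more than
    ``pb_max_errors`` errors exceeds ``pb_alpha``.
    """

    truncate_len: int = 200
    max_expected_errors: float = 1.0
    pb_max_errors: int = 2
    pb_alpha: float = 0.005
    min_avg_quality: float = 27.0
    max_homopolymer: int = 8
    max_ambiguous: int = 0
    barcode_mismatches: int = 0
    primer_fwd: str = ""
    primer_rev: str = ""
    primer_mismatches: int = 1
    require_primer: bool = True

    def __post_init__(self) -> None:
        if self.truncate_len <= 0:
            raise ConfigError("truncate_len must be positive")
        if not 0 < self.pb_alpha < 1:
            raise ConfigError("pb_alpha must be in (0, 1)")
        for name in ("pb_max_errors", "max_homopolymer", "max_ambiguous",
                     "barcode_mismatches", "primer_mismatches"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for p in (self.primer_fwd, self.primer_rev):
            for ch in p:
                if ch not in IUPAC:
                    raise ConfigError(f"invalid IUPAC letter {ch!r} in primer")

    @classmethod
    def from_file(cls, path) -> "FilterConfig":
        """Load overrides from a ``key = value`` config file."""
        kwargs = {}
        bools = {"require_primer"}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigError(f"malformed config line: {line!r}")
                key, val = (s.strip() for s in line.split("=", 1))
                if key not in cls.__dataclass_fields__:
                    raise ConfigError(f"unknown filter parameter {key!r}")
                typ = cls.__dataclass_fields__[key].type
                if key in bools:
                    kwargs[key] = val.lower() in ("1", "true", "yes")
                elif typ == "int":
                    kwargs[key] = int(val)
                elif typ == "float":
                    kwargs[key] = float(val)
                else:
                    kwargs[key] = val.upper()
        return cls(**kwargs)


@dataclass(slots=True)
class TieredRead:
    """A read after demultiplexing/QC: its (possibly truncated) record,
    sample assignment, tier and — for MID/REJECT — the filters it failed."""

    record: ReadRecord
    sample_id: str
    tier: str  # HIGH | MID | REJECT
    reject_reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tier not in ("HIGH", "MID", "REJECT"):
            raise ValueError(f"invalid tier {self.tier!r}")
        if self.tier == "HIGH" and self.reject_reasons:
            raise ValueError("HIGH reads cannot carry reject reasons")


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    record: ReadRecord, specs: list[SampleSpec], max_mismatch: int = 0
) -> tuple[str | None, ReadRecord]:
    """Assign a read to a sample by its barcode prefix.

    Returns ``(sample_id, read-with-barcode-removed)``; ``(None, record)``
    if no barcode matches within ``max_mismatch`` or if two barcodes match
    equally well (ambiguity is unassigned, not an error).
    """
    best: list[SampleSpec] = []
    best_d = max_mismatch + 1
    for spec in specs:
        bc = spec.barcode
        if not bc or len(record.sequence) < len(bc):
            continue
        d = hamming(record.sequence[: len(bc)], bc)
        if d < best_d:
            best, best_d = [spec], d
        elif d == best_d:
            best.append(spec)
    if len(best) != 1 or best_d > max_mismatch:
        return None, record
    spec = best[0]
    return spec.sample_id, record.slice(len(spec.barcode))


def iupac_match(seq: str, pattern: str) -> int:
    """Number of mismatches of ``seq`` against an IUPAC ``pattern``
    (compared over ``len(pattern)``; assumes ``len(seq) >= len(pattern)``)."""
    mm = 0
    for base, code in zip(seq, pattern):
        if base not in IUPAC[code]:
            mm += 1
    return mm


def find_trim_primer(
    seq: str, primer: str, max_mismatch: int = 1, scan_window: int = 16
) -> str | None:
    """Locate an IUPAC primer near the 5' end and strip it.

    The primer is scanned at offsets ``0..scan_window``; on the best
    acceptable match the primer *and any preceding bases* are removed.
    Returns the trimmed sequence, or None if the primer is not found.
    """
    idx = find_primer_offset(seq, primer, max_mismatch, scan_window)
    if idx is None:
        return None
    return seq[idx + len(primer):]


def find_primer_offset(
    seq: str, primer: str, max_mismatch: int = 1, scan_window: int = 16
) -> int | None:
    if not primer:
        raise ConfigError("empty primer")
    for ch in primer:
        if ch not in IUPAC:
            raise ConfigError(f"invalid IUPAC letter {ch!r} in primer")
    best_idx, best_mm = None, max_mismatch + 1
    for off in range(0, scan_window + 1):
        if off + len(primer) > len(seq):
            break
        mm = iupac_match(seq[off:], primer)
        if mm < best_mm:
            best_idx, best_mm = off, mm
            if mm == 0:
                break
    return best_idx


def phred_to_prob(qualities) -> np.ndarray:
    return np.power(10.0, -np.asarray(qualities, dtype=float) / 10.0)


def expected_errors(qualities) -> float:
    """Expected number of sequencing errors: sum of Phred-implied
    per-base error probabilities, sum_i 10^(-q_i/10)."""
    return float(phred_to_prob(qualities).sum())


def poisson_binomial_tail(error_probs, max_errors: int) -> float:
    """P(X > max_errors) for X ~ PoissonBinomial(error_probs).

    Standard O(n*k) dynamic programme over the distribution of the number
    of errors, tracking P(X = 0..max_errors) exactly.
    """
    k = max_errors
    probs = np.asarray(error_probs, dtype=float)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("error probabilities must lie in [0, 1]")
    # state[j] = P(exactly j errors among bases seen so far), j <= k
    state = np.zeros(k + 1)
    state[0] = 1.0
    for p in probs:
        # mass spilling past k (= state[k]*p) is silently absorbed into the tail
        state[1:] = state[1:] * (1.0 - p) + state[:-1] * p
        state[0] *= 1.0 - p
    tail = 1.0 - state.sum()
    return max(0.0, min(1.0, tail))


def poisson_binomial_reject(error_probs, max_errors: int, alpha: float) -> bool:
    """True (reject) iff P(more than ``max_errors`` errors) exceeds ``alpha``."""
    return poisson_binomial_tail(error_probs, max_errors) > alpha


def max_homopolymer_run(seq: str) -> int:
    best = run = 0
    prev = ""
    for ch in seq:
        run = run + 1 if ch == prev else 1
        prev = ch
        best = max(best, run)
    return best


# Filters whose failure is recoverable by backmapping (-> MID tier).
SOFT_FILTERS = ("expected_errors", "poisson_binomial", "short_truncation")


def tier_read(record: ReadRecord, cfg: FilterConfig, sample_id: str = "") -> TieredRead:
    """Assign a demultiplexed, primer-trimmed read to a quality tier.

    First-of-pair (and single) reads are truncated to ``cfg.truncate_len``
    and must pass every filter to be HIGH.  Failing only soft filters
    (expected errors, Poisson binomial, or a length shortfall down to
    0.8 x truncate_len) demotes to MID; any hard failure is REJECT.
    Second-of-pair reads are MID by construction — they are never
    clustered, only consulted during seed extension.
    """
    if record.mate == "R2":
        return TieredRead(record, sample_id, "MID", ["mate_r2"])

    trunc = record.slice(0, cfg.truncate_len)
    hard: list[str] = []
    soft: list[str] = []

    if len(trunc) < cfg.truncate_len:
        if len(trunc) >= 0.8 * cfg.truncate_len:
            soft.append("short_truncation")
        else:
            hard.append("too_short")
    if len(trunc) == 0:
        return TieredRead(trunc, sample_id, "REJECT", ["too_short"])

    quals = np.asarray(trunc.qualities, dtype=float)
    if quals.mean() < cfg.min_avg_quality:
        hard.append("avg_quality")
    if max_homopolymer_run(trunc.sequence) > cfg.max_homopolymer:
        hard.append("homopolymer")
    if trunc.sequence.count("N") > cfg.max_ambiguous:
        hard.append("ambiguous_bases")

    probs = phred_to_prob(trunc.qualities)
    if float(probs.sum()) > cfg.max_expected_errors:
        soft.append("expected_errors")
    if poisson_binomial_reject(probs, cfg.pb_max_errors, cfg.pb_alpha):
        soft.append("poisson_binomial")

    if hard:
        return TieredRead(trunc, sample_id, "REJECT", hard + soft)
    if soft:
        return TieredRead(trunc, sample_id, "MID", soft)
    return TieredRead(trunc, sample_id, "HIGH", [])
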