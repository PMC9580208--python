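"""Dereplication at 100% identity and the count-per-sample acceptance grammar.

HIGH-tier reads are collapsed into unique sequences with per-sample counts.
A unique enters clustering only if it satisfies the dereplication grammar,
a comma-separated list of ``count:samples`` terms such as the default
``8:1,4:2,3:3``: accept a sequence if it occurs >= 8 times in one sample,
OR >= 4 times in total while present in >= 2 samples, OR >= 3 times in
total while present in >= 3 samples.  Uniques failing every term are not
discarded — they are forwarded to the backmapping pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .qc import ConfigError


@dataclass(frozen=True)
class DerepSpec:
    """Ordered acceptance terms ``(min_count, min_samples)``."""

    terms: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ConfigError("dereplication spec must have at least one term")
        for c, s in self.terms:
            if c < 1 or s < 1:
                raise ConfigError(f"invalid dereplication term {c}:{s}")

    def __str__(self) -> str:
        return ",".join(f"{c}:{s}" for c, s in self.terms)


DEFAULT_DEREP = DerepSpec(((8, 1), (4, 2), (3, 3)))


def parse_derep_spec(text: str) -> DerepSpec:
    """Parse ``"8:1,4:2,3:3"``-style grammar text."""
    terms = []
    for part in text.split(","):
        bits = part.strip().split(":")
        if len(bits) != 2:
            raise ConfigError(f"malformed dereplication term {part!r}")
        try:
            terms.append((int(bits[0]), int(bits[1])))
        except ValueError as exc:
            raise ConfigError(f"malformed dereplication term {part!r}") from exc
    return DerepSpec(tuple(terms))


@dataclass(slots=True)
class UniqueSequence:
    """A dereplicated sequence with per-sample counts and read provenance."""

    sequence: str
    per_sample_counts: dict[str, int]
    total_count: int
    read_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        if self.total_count != sum(self.per_sample_counts.values()):
            raise ValueError("total_count != sum of per-sample counts")


def dereplicate(reads: Iterable[tuple]) -> list[UniqueSequence]:
    """Collapse ``(sample_id, sequence[, read_id])`` tuples at 100% identity.

    Output is sorted by total count descending, ties broken by lexicographic
    sequence order, so downstream greedy clustering is deterministic.
    """
    counts: dict[str, dict[str, int]] = {}
    ids: dict[str, list[str]] = {}
    for item in reads:
        sample, seq = item[0], item[1]
        per = counts.setdefault(seq, {})
        per[sample] = per.get(sample, 0) + 1
        if len(item) > 2:
            ids.setdefault(seq, []).append(item[2])
    uniques = [
        UniqueSequence(seq, per, sum(per.values()), ids.get(seq, []))
        for seq, per in counts.items()
    ]
    uniques.sort(key=lambda u: (-u.total_count, u.sequence))
    return uniques


def passes_derep(u: UniqueSequence, spec: DerepSpec = DEFAULT_DEREP) -> bool:
    """True iff any grammar term accepts the unique.

    A term ``(c, 1)`` requires a single sample with count >= c; a term
    ``(c, s)`` with s >= 2 requires presence in >= s samples and a total
    count across samples >= c.
    """
    n_samples = len(u.per_sample_counts)
    for c, s in spec.terms:
        if s == 1:
            if any(v >= c for v in u.per_sample_counts.values()):
                return True
        elif n_samples >= s and u.total_count >= c:
            return True
    return False


def split_by_spec(
    uniques: Iterable[UniqueSequence], spec: DerepSpec = DEFAULT_DEREP
) -> tuple[list[UniqueSequence], list[UniqueSequence]]:
    """Partition uniques into (accepted, rejected) under the grammar."""
    acc: list[UniqueSequence] = []
    rej: list[UniqueSequence] = []
    for u in uniques:
        (acc if passes_derep(u, spec) else rej).append(u)
    return acc, rej
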