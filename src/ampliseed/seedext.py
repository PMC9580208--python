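"""Seed extension: choosing the best representative read (pair) per cluster,
merging read pairs, and backmapping recovered reads onto clusters.

Clustering operates on truncated, high-quality first reads only.  To obtain
a long, high-confidence representative ("seed") per OTU, every raw read
(pair) that contributed to a cluster is compared against the cluster's
consensus; the best candidate is chosen by, in strict priority order:

1. highest identity to the consensus (full untruncated read, and the mate
   when present),
2. mergeable read pairs before unmergeable ones,
3. lowest mean expected error,
4. longest usable (merged, else read) length,
5. lexicographic read id (a pure determinism tie-break).

The winner's merged pair (or full first read) becomes the published seed.
MID-tier reads and uniques that failed the dereplication grammar are then
mapped back onto these extended seeds at >= 97% identity, enriching the
abundance matrix without having let those reads influence clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cluster import Cluster, pairwise_identity
from .formats import ReadRecord, revcomp
from .qc import expected_errors

_BASE_ORDER = "ACGT"  # also the tie order for consensus voting


@dataclass(slots=True)
class SeedCandidate:
    read_id: str
    identity_to_consensus: float
    mergeable: bool
    mean_expected_error: float
    usable_length: int

    def sort_key(self) -> tuple:
        return (
            -self.identity_to_consensus,
            not self.mergeable,
            self.mean_expected_error,
            -self.usable_length,
            self.read_id,
        )


@dataclass(slots=True)
class SeedResult:
    cluster_id: str
    seed_sequence: str
    merged: bool
    read_id: str = ""
    identity_to_consensus: float = 100.0


def _encode(seqs: Iterable[str], length: int) -> np.ndarray:
    rows = [
        np.frombuffer(s.encode().ljust(length, b"N"), dtype=np.uint8) for s in seqs
    ]
    return np.vstack(rows)


def consensus(members: Sequence[tuple[str, int]]) -> str:
    """Per-column count-weighted majority sequence.

    Sequences are padded with N to the longest member; N never votes unless
    a column is all-N.  Ties break in fixed base order A < C < G < T.
    """
    if not members:
        raise ValueError("consensus of zero members")
    length = max(len(s) for s, _ in members)
    mat = _encode((s for s, _ in members), length)
    weights = np.array([c for _, c in members], dtype=float)
    out = []
    base_codes = [ord(b) for b in _BASE_ORDER]
    for j in range(length):
        col = mat[:, j]
        votes = [weights[col == code].sum() for code in base_codes]
        best = int(np.argmax(votes))  # argmax takes first max -> A<C<G<T ties
        out.append(_BASE_ORDER[best] if votes[best] > 0 else "N")
    return "".join(out)


def positional_identity(seq: str, cons: str) -> tuple[int, int]:
    """(matches, columns) comparing two sequences position by position;
    columns = the longer length (tail overhang counts as mismatch)."""
    n = min(len(seq), len(cons))
    a = np.frombuffer(seq[:n].encode(), dtype=np.uint8)
    b = np.frombuffer(cons[:n].encode(), dtype=np.uint8)
    return int((a == b).sum()), max(len(seq), len(cons))


def merge_pair(
    r1: ReadRecord,
    r2: ReadRecord,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
) -> ReadRecord | None:
    """Merge a read pair over its best ungapped 3' overlap.

    ``r2`` is given in sequencing orientation and reverse-complemented
    internally.  Overlaps are scored matches - mismatches; the merge is
    accepted iff the best overlap is >= ``min_overlap`` long with a
    mismatch fraction <= ``max_mismatch_frac``.  In the overlap, agreeing
    bases get quality min(q1+q2, 60); conflicting bases keep the
    higher-quality base with quality |q1-q2|.
    """
    s1 = np.frombuffer(r1.sequence.encode(), dtype=np.uint8)
    rc_seq = revcomp(r2.sequence)
    s2 = np.frombuffer(rc_seq.encode(), dtype=np.uint8)
    q1 = np.asarray(r1.qualities)
    q2 = np.asarray(r2.qualities)[::-1]

    best_ov, best_score, best_matches = 0, None, 0
    for ov in range(min_overlap, min(len(s1), len(s2)) + 1):
        eq = s1[len(s1) - ov :] == s2[:ov]
        matches = int(eq.sum())
        score = 2 * matches - ov  # matches - mismatches
        if best_score is None or score > best_score or (
            score == best_score and ov > best_ov
        ):
            best_ov, best_score, best_matches = ov, score, matches
    if best_score is None:
        return None
    mismatches = best_ov - best_matches
    if mismatches / best_ov > max_mismatch_frac:
        return None

    ov = best_ov
    left_seq = r1.sequence[: len(s1) - ov]
    left_q = list(q1[: len(s1) - ov])
    right_seq = rc_seq[ov:]
    right_q = list(q2[ov:])
    mid_seq = []
    mid_q = []
    for i in range(ov):
        b1, b2 = r1.sequence[len(s1) - ov + i], rc_seq[i]
        a, b = int(q1[len(s1) - ov + i]), int(q2[i])
        if b1 == b2:
            mid_seq.append(b1)
            mid_q.append(min(a + b, 60))
        else:
            mid_seq.append(b1 if a >= b else b2)
            mid_q.append(abs(a - b))
    return ReadRecord(
        r1.read_id,
        left_seq + "".join(mid_seq) + right_seq,
        left_q + mid_q + right_q,
        "single",
    )


def select_seed(
    cluster: Cluster,
    originals: Mapping[str, tuple[ReadRecord, ReadRecord | None]],
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
) -> SeedResult:
    """Pick the representative read (pair) of a cluster and extend it.

    The consensus is built over the full (untruncated) first reads of all
    members, weighted equally per read, with a separate consensus for the
    mates.  Candidate reads are ranked by the lexicographic criterion
    described in the module docstring; the winner's merged pair — or its
    full-length first read if the pair cannot be merged — becomes the seed.
    """
    read_ids = [rid for m in cluster.members for rid in m.read_ids]
    traced = [rid for rid in read_ids if rid in originals]
    if not traced:
        raise ValueError(
            f"cluster {cluster.cluster_id}: no member read traces to an original"
        )
    r1s = [originals[rid][0] for rid in traced]
    r2s = [originals[rid][1] for rid in traced if originals[rid][1] is not None]
    cons1 = consensus([(r.sequence, 1) for r in r1s])
    cons2 = consensus([(r.sequence, 1) for r in r2s]) if r2s else None

    # identity first: it dominates the ranking, so the expensive merge and
    # quality statistics are only computed for the top-identity candidates
    idents: list[tuple[float, str]] = []
    for rid in traced:
        r1, r2 = originals[rid]
        m, c = positional_identity(r1.sequence, cons1)
        if r2 is not None and cons2 is not None:
            m2, c2 = positional_identity(r2.sequence, cons2)
            m, c = m + m2, c + c2
        idents.append((100.0 * m / c, rid))
    best_ident = max(i for i, _ in idents)
    top = [rid for i, rid in idents if i == best_ident]

    candidates: list[tuple[SeedCandidate, ReadRecord | None, ReadRecord]] = []
    for rid in top:
        r1, r2 = originals[rid]
        merged = (
            merge_pair(r1, r2, min_overlap, max_mismatch_frac)
            if r2 is not None
            else None
        )
        ee1 = expected_errors(r1.qualities)
        ee = (ee1 + expected_errors(r2.qualities)) / 2 if r2 is not None else ee1
        usable = len(merged) if merged is not None else len(r1)
        cand = SeedCandidate(rid, best_ident, merged is not None, ee, usable)
        candidates.append((cand, merged, r1))
    cand, merged, r1 = min(candidates, key=lambda t: t[0].sort_key())
    if merged is not None:
        return SeedResult(cluster.cluster_id, merged.sequence, True, cand.read_id, best_ident)
    return SeedResult(cluster.cluster_id, r1.sequence, False, cand.read_id, best_ident)


@dataclass(slots=True)
class PoolRead:
    """One backmapping candidate: a MID read or an expanded derep reject."""

    sample_id: str
    sequence: str
    count: int = 1
    read_id: str = ""


def backmap(
    pool: Iterable[PoolRead],
    seeds: Sequence[SeedResult],
    cluster_totals: Mapping[str, int],
    id_threshold: float = 97.0,
) -> tuple[dict[tuple[str, str], int], list[str], list[str]]:
    """Map pool reads onto extended seeds at >= ``id_threshold`` identity.

    Each read goes to the single best-identity seed; ties go to the larger
    cluster, then to cluster id order.  Returns (increments keyed by
    (cluster_id, sample_id), mapped read ids, unmapped read ids).
    """
    order = {s.cluster_id: i for i, s in enumerate(seeds)}
    cache: dict[str, str | None] = {}
    increments: dict[tuple[str, str], int] = {}
    mapped: list[str] = []
    unmapped: list[str] = []
    for read in pool:
        if read.sequence in cache:
            target = cache[read.sequence]
        else:
            best_key, target = None, None
            for s in seeds:
                pid = pairwise_identity(read.sequence, s.seed_sequence)
                if pid < id_threshold:
                    continue
                key = (-pid, -cluster_totals.get(s.cluster_id, 0), order[s.cluster_id])
                if best_key is None or key < best_key:
                    best_key, target = key, s.cluster_id
            cache[read.sequence] = target
        if target is None:
            unmapped.append(read.read_id)
        else:
            key2 = (target, read.sample_id)
            increments[key2] = increments.get(key2, 0) + read.count
            mapped.append(read.read_id)
    return increments, mapped, unmapped
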