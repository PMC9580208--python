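"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own code paths: the
Poisson-binomial tail is computed by exhaustive enumeration over all error
configurations, the dereplication grammar is applied term by term from its
textual definition, and the LCA vote is a naive filter/truncate/vote loop.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from ampliseed.formats import ReadRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def make_read(seq: str, q: int | list = 40, mate: str = "R1", rid: str = "r1") -> ReadRecord:
    quals = [q] * len(seq) if isinstance(q, int) else list(q)
    return ReadRecord(rid, seq, quals, mate)


# --- Poisson binomial: exhaustive 2^n enumeration -------------------------

def pb_tail_bruteforce(probs, max_errors: int) -> float:
    """P(X > max_errors) by summing over every one of the 2^n error
    configurations (vectorised enumeration, exact for n <= ~20)."""
    probs = np.asarray(probs, dtype=float)
    n = len(probs)
    masks = np.arange(2**n)[:, None]
    bits = (masks >> np.arange(n)) & 1
    config_probs = np.prod(np.where(bits == 1, probs, 1.0 - probs), axis=1)
    return float(config_probs[bits.sum(axis=1) > max_errors].sum())


# --- dereplication grammar: term-by-term literal rule ---------------------

def derep_accept_bruteforce(counts: dict[str, int], terms) -> bool:
    """Accept iff ANY term (c, s) holds: with s == 1, some single sample has
    count >= c; with s >= 2, the sequence is present in >= s samples and its
    total count is >= c."""
    present = [v for v in counts.values() if v >= 1]
    total = sum(counts.values())
    for c, s in terms:
        if s == 1 and any(v >= c for v in counts.values()):
            return True
        if s >= 2 and len(present) >= s and total >= c:
            return True
    return False


# --- LCA: naive filter / truncate / vote loop -----------------------------

def lca_bruteforce(hits, agreement, id_window, thresholds, min_coverage, ranks):
    kept = [h for h in hits if h.query_coverage > min_coverage]
    if not kept:
        return ["?"] * len(ranks)
    best = max(h.percent_identity for h in kept)
    kept = [h for h in kept if h.percent_identity >= best - id_window]
    truncated = []
    for h in kept:
        depth = 1  # domain always admissible
        for r in ranks[1:]:
            if r in thresholds and h.percent_identity >= thresholds[r]:
                depth += 1
            else:
                break
        truncated.append(
            [n if i < depth else "?" for i, n in enumerate(h.subject_lineage.ranks)]
        )
    out = []
    for i in range(len(ranks)):
        tally: dict[str, int] = {}
        for lin in truncated:
            if lin[i] != "?":
                tally[lin[i]] = tally.get(lin[i], 0) + 1
        winner = None
        for name in sorted(tally):
            if tally[name] / len(truncated) >= agreement:
                winner = name
                break
        if winner is None:
            break
        out.append(winner)
    return out + ["?"] * (len(ranks) - len(out))
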