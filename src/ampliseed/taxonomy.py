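"""Identity-gated least-common-ancestor (LCA) taxonomy assignment.

Each cluster seed is aligned against one or more reference databases; the
resulting hits vote on a ranked lineage.  Three safeguards keep
assignments conservative:

* hits must cover more than half of the query sequence;
* a hit's lineage is truncated at the deepest rank its percent identity
  admits (e.g. a 94%-identity hit can support family, but never species);
* walking ranks from domain to species, a name is kept only while a
  qualifying fraction (default 80%) of the retained hits agree on it —
  the first disagreement and everything below become unclassified ("?").

Only hits within ``id_window`` percentage points of the best hit vote.
With several databases, each is assigned independently and the most deeply
resolved lineage wins, ties broken by the user's database order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formats import AbundanceMatrix

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
UNCLASSIFIED = "?"

#: deepest rank admissible at a given alignment percent identity
DEFAULT_RANK_THRESHOLDS = {
    "species": 97.0,
    "genus": 95.0,
    "family": 93.0,
    "order": 91.0,
    "class": 88.0,
    "phylum": 78.0,
}

DEFAULT_MIN_COVERAGE = 0.5  # hits must cover > half of the query
DEFAULT_AGREEMENT = 0.8
DEFAULT_ID_WINDOW = 1.5


@dataclass(frozen=True)
class TaxonomyPath:
    """A ranked lineage (domain -> species); "?" marks unclassified ranks.

    Prefix-closed: once a rank is unclassified, all deeper ranks are too.
    """

    ranks: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ranks) != len(RANKS):
            raise ValueError(f"lineage must have {len(RANKS)} ranks")
        seen_unclassified = False
        for r in self.ranks:
            if r == UNCLASSIFIED:
                seen_unclassified = True
            elif seen_unclassified:
                raise ValueError("lineage is not prefix-closed")

    @classmethod
    def from_names(cls, names: Sequence[str]) -> "TaxonomyPath":
        """Build a path from up to 7 names, padding/normalising to "?"."""
        ranks = [n.strip() if n and n.strip() else UNCLASSIFIED for n in names]
        ranks += [UNCLASSIFIED] * (len(RANKS) - len(ranks))
        # enforce prefix closure: blank out everything below the first gap
        out = []
        broken = False
        for r in ranks[: len(RANKS)]:
            broken = broken or r == UNCLASSIFIED
            out.append(UNCLASSIFIED if broken else r)
        return cls(tuple(out))

    @classmethod
    def from_string(cls, text: str, sep: str = ";") -> "TaxonomyPath":
        return cls.from_names(text.split(sep))

    @classmethod
    def unclassified(cls) -> "TaxonomyPath":
        return cls(tuple([UNCLASSIFIED] * len(RANKS)))

    def depth(self) -> int:
        """Number of resolved ranks (0 = fully unclassified)."""
        for i, r in enumerate(self.ranks):
            if r == UNCLASSIFIED:
                return i
        return len(RANKS)

    def truncate(self, depth: int) -> "TaxonomyPath":
        ranks = tuple(
            r if i < depth else UNCLASSIFIED for i, r in enumerate(self.ranks)
        )
        return TaxonomyPath(ranks)

    def at(self, rank: str) -> str:
        return self.ranks[RANKS.index(rank)]

    def prefix_string(self, rank: str) -> str:
        """Lineage string truncated at ``rank`` (inclusive)."""
        i = RANKS.index(rank)
        return ";".join(self.ranks[: i + 1])

    def __str__(self) -> str:
        return ";".join(self.ranks)


@dataclass(slots=True)
class HitRecord:
    """One alignment hit of a query (cluster seed) against a reference."""

    query_id: str
    subject_id: str
    percent_identity: float
    query_coverage: float
    subject_lineage: TaxonomyPath
    db_rank: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.query_coverage <= 1.0:
            raise ValueError("coverage must be in [0, 1]")


def max_rank_for_identity(
    pid: float, thresholds: Mapping[str, float] = DEFAULT_RANK_THRESHOLDS
) -> str:
    """Deepest rank whose identity threshold the hit meets (domain if none)."""
    deepest = "domain"
    for rank in RANKS[1:]:
        thr = thresholds.get(rank)
        if thr is not None and pid >= thr:
            deepest = rank
        else:
            break
    return deepest


def lca_assign(
    hits: Sequence[HitRecord],
    agreement: float = DEFAULT_AGREEMENT,
    id_window: float = DEFAULT_ID_WINDOW,
    thresholds: Mapping[str, float] = DEFAULT_RANK_THRESHOLDS,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> TaxonomyPath:
    """LCA voting over a query's hits (one database).

    Hits with coverage <= ``min_coverage`` are dropped; of the rest, only
    those within ``id_window`` %-points of the best identity vote.  Each
    voting lineage is truncated at the rank its identity admits; a rank's
    name is kept iff >= ``agreement`` of the voters carry that name.
    """
    hits = [h for h in hits if h.query_coverage > min_coverage]
    if not hits:
        return TaxonomyPath.unclassified()
    best = max(h.percent_identity for h in hits)
    voters = [h for h in hits if h.percent_identity >= best - id_window]
    lineages = [
        h.subject_lineage.truncate(
            RANKS.index(max_rank_for_identity(h.percent_identity, thresholds)) + 1
        )
        for h in voters
    ]
    out: list[str] = []
    for i in range(len(RANKS)):
        names = [lin.ranks[i] for lin in lineages]
        counts: dict[str, int] = {}
        for n in names:
            if n != UNCLASSIFIED:
                counts[n] = counts.get(n, 0) + 1
        winner = None
        for name, c in sorted(counts.items()):
            if c / len(voters) >= agreement:
                winner = name
                break
        if winner is None:
            break
        out.append(winner)
    return TaxonomyPath.from_names(out)


def merge_databases(per_db: Sequence[TaxonomyPath]) -> TaxonomyPath:
    """Pick the most deeply resolved lineage; ties go to the earlier
    (higher-priority) database."""
    if not per_db:
        return TaxonomyPath.unclassified()
    best = per_db[0]
    for path in per_db[1:]:
        if path.depth() > best.depth():
            best = path
    return best


def aggregate_by_rank(
    matrix: AbundanceMatrix,
    taxa: Mapping[str, TaxonomyPath],
    rank: str,
) -> pd.DataFrame:
    """Sum cluster counts by rank-truncated lineage (taxon x sample table).

    Clusters unclassified at ``rank`` are pooled under their deepest
    resolved prefix (with "?" padding), so column sums are preserved.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    groups: dict[str, list[str]] = {}
    for cid in matrix.cluster_ids:
        key = taxa[cid].prefix_string(rank)
        groups.setdefault(key, []).append(cid)
    rows = {key: matrix.df.loc[cids].sum(axis=0) for key, cids in groups.items()}
    out = pd.DataFrame(rows).T.astype(int)
    out = out.reindex(sorted(out.index))
    out.columns = matrix.sample_ids
    return out


# ---------------------------------------------------------------------------
# reference database I/O and the built-in seed-vs-reference aligner

HIT_TABLE_COLUMNS = [
    "query_id", "subject_id", "percent_identity", "aln_len", "mismatches",
    "gaps", "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_lineage_table(path) -> dict[str, TaxonomyPath]:
    """2-column TSV: subject id <tab> semicolon-delimited lineage."""
    out: dict[str, TaxonomyPath] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            sid, lineage = line.split("\t")[:2]
            out[sid] = TaxonomyPath.from_string(lineage)
    return out


def read_hit_table(
    path,
    lineages: Mapping[str, TaxonomyPath],
    db_rank: int = 0,
    query_lengths: Mapping[str, int] | None = None,
) -> dict[str, list[HitRecord]]:
    """Parse a 12-column tabular alignment file into hits per query.

    Query coverage is ``(qend - qstart + 1) / query length``; when
    ``query_lengths`` is not supplied, the query extent seen in the table
    (max of qstart/qend across that query's hits) stands in for its length.
    Hits whose subject has no lineage entry are skipped.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=HIT_TABLE_COLUMNS)
    extent: dict[str, int] = {}
    for row in df.itertuples(index=False):
        qid = str(row.query_id)
        extent[qid] = max(extent.get(qid, 0), int(row.qend), int(row.qstart))
    hits: dict[str, list[HitRecord]] = {}
    for row in df.itertuples(index=False):
        lineage = lineages.get(str(row.subject_id))
        if lineage is None:
            continue
        span = abs(int(row.qend) - int(row.qstart)) + 1
        qlen = (
            query_lengths.get(str(row.query_id), 0)
            if query_lengths is not None
            else extent[str(row.query_id)]
        )
        coverage = min(1.0, span / qlen) if qlen else 0.0
        hits.setdefault(str(row.query_id), []).append(
            HitRecord(
                str(row.query_id),
                str(row.subject_id),
                float(row.percent_identity),
                coverage,
                lineage,
                db_rank,
            )
        )
    return hits


def align_hits(
    queries: Mapping[str, str],
    references: Mapping[str, str],
    lineages: Mapping[str, TaxonomyPath],
    db_rank: int = 0,
    min_identity: float = 75.0,
) -> dict[str, list[HitRecord]]:
    """Built-in aligner: semi-global alignment of each query against each
    reference (query end-gap-free within the reference).  Produces
    full-coverage hits; references more dissimilar than ``min_identity``
    are not reported."""
    from .cluster import pairwise_identity

    hits: dict[str, list[HitRecord]] = {qid: [] for qid in queries}
    for qid, qseq in queries.items():
        for sid, sseq in references.items():
            if sid not in lineages:
                continue
            pid = pairwise_identity(qseq, sseq)
            if pid < min_identity:
                continue
            hits[qid].append(HitRecord(qid, sid, pid, 1.0, lineages[sid], db_rank))
    return hits


def classify_clusters(
    seeds: Mapping[str, str],
    databases: Sequence[tuple[Mapping[str, str], Mapping[str, TaxonomyPath]]],
    agreement: float = DEFAULT_AGREEMENT,
    id_window: float = DEFAULT_ID_WINDOW,
) -> dict[str, TaxonomyPath]:
    """Assign every cluster a lineage from an ordered list of
    (reference sequences, lineage map) databases."""
    per_cluster: dict[str, TaxonomyPath] = {}
    per_db_hits = [
        align_hits(seeds, refs, lin, db_rank=i)
        for i, (refs, lin) in enumerate(databases)
    ]
    for cid in seeds:
        paths = [
            lca_assign(db_hits.get(cid, []), agreement, id_window)
            for db_hits in per_db_hits
        ]
        per_cluster[cid] = merge_databases(paths)
    return per_cluster
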