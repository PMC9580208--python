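"""Greedy centroid clustering of accepted unique sequences into OTUs.

The built-in clusterer scans uniques in dereplication order (most abundant
first).  Each unique joins the existing cluster whose centroid it matches
at the highest identity >= the threshold (default 97%); otherwise it founds
a new cluster with itself as centroid.  This mirrors the classic greedy
OTU-picking strategy and is fully deterministic given the input order.

Pairwise identity is computed from a semi-global alignment (the shorter
sequence aligned end-gap-free within the longer) as
``matches / alignment columns * 100``; the alignment engine is edlib
(unit-cost edit distance), which for the substitution-dominated amplicon
reads handled here recovers the canonical alignment.

External clustering/denoising engines (e.g. VSEARCH, CD-HIT, DADA2) are not
reimplemented; :func:`external_cluster_adapter` defines the contract they
plug into: size-annotated FASTA out, UC-style membership table back in.
"""

from __future__ import annotations

import re
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib

from .derep import UniqueSequence

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


class EngineError(RuntimeError):
    pass


@dataclass(slots=True)
class Cluster:
    """An OTU: centroid sequence, member uniques and per-sample counts."""

    cluster_id: str
    centroid: str
    members: list[UniqueSequence]
    per_sample_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.per_sample_counts.values())

    def recompute_counts(self) -> None:
        counts: dict[str, int] = {}
        for m in self.members:
            for s, c in m.per_sample_counts.items():
                counts[s] = counts.get(s, 0) + c
        self.per_sample_counts = counts


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(matches, alignment columns) from an edlib extended cigar."""
    matches = cols = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        cols += n
        if op == "=":
            matches += n
    return matches, cols


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity between two sequences under semi-global alignment.

    The shorter sequence is aligned end-gap-free within the longer;
    identity = matches / alignment columns * 100.  Symmetric by
    construction.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if a == b:
        return 100.0
    query, target = (a, b) if len(a) <= len(b) else (b, a)
    res = edlib.align(query, target, mode="HW", task="path")
    matches, cols = _cigar_stats(res["cigar"])
    return 100.0 * matches / cols


def greedy_cluster(
    uniques: Sequence[UniqueSequence], id_threshold: float = 97.0
) -> list[Cluster]:
    """Greedy centroid clustering; ``uniques`` must be in dereplication
    order (total count descending).  Ties between equally good centroids go
    to the larger cluster, then to the earlier-created one."""
    clusters: list[Cluster] = []
    for u in uniques:
        best: Cluster | None = None
        best_key: tuple | None = None
        for order, cl in enumerate(clusters):
            pid = pairwise_identity(u.sequence, cl.centroid)
            if pid < id_threshold:
                continue
            key = (-pid, -cl.total_count, order)
            if best_key is None or key < best_key:
                best, best_key = cl, key
        if best is None:
            cl = Cluster(f"OTU_{len(clusters) + 1}", u.sequence, [u])
            cl.recompute_counts()
            clusters.append(cl)
        else:
            best.members.append(u)
            best.recompute_counts()
    return clusters


@dataclass(slots=True)
class EngineSpec:
    """How to invoke an external clustering engine.

    ``args_template`` may reference ``{input}`` (size-annotated FASTA),
    ``{output}`` (UC-style membership file) and ``{threshold}``.
    """

    name: str
    executable: str
    args_template: list[str]


def write_size_fasta(uniques: Sequence[UniqueSequence], path) -> list[str]:
    """Write uniques as ``;size=N`` annotated FASTA; returns the labels."""
    labels = []
    with open(path, "w") as fh:
        for i, u in enumerate(uniques):
            label = f"Uniq{i};size={u.total_count}"
            labels.append(label)
            fh.write(f">{label}\n{u.sequence}\n")
    return labels


def parse_uc_membership(lines: Iterable[str]) -> dict[str, str]:
    """Parse UC-style cluster membership into ``{member_label: centroid_label}``.

    ``S`` records open a cluster (centroid maps to itself), ``H`` records
    assign a member to a centroid.  A member listed twice is an error.
    """
    mapping: dict[str, str] = {}
    for line in lines:
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        rectype = fields[0]
        if rectype == "S":
            label = fields[8]
            target = label
        elif rectype == "H":
            label, target = fields[8], fields[9]
        else:
            continue
        if label in mapping:
            raise EngineError(f"member {label!r} listed twice in membership output")
        mapping[label] = target
    return mapping


def clusters_from_membership(
    uniques: Sequence[UniqueSequence],
    labels: Sequence[str],
    membership: dict[str, str],
) -> list[Cluster]:
    by_label = dict(zip(labels, uniques))
    groups: dict[str, list[str]] = {}
    for label in labels:
        if label not in membership:
            raise EngineError(f"unique {label!r} missing from membership output")
        groups.setdefault(membership[label], []).append(label)
    clusters = []
    for i, (centroid_label, member_labels) in enumerate(sorted(groups.items())):
        if centroid_label not in by_label:
            raise EngineError(f"unknown centroid {centroid_label!r}")
        members = [by_label[m] for m in member_labels]
        # centroid first, remaining members in derep order
        members.sort(key=lambda u: (u.sequence != by_label[centroid_label].sequence,
                                    -u.total_count, u.sequence))
        cl = Cluster(f"OTU_{i + 1}", by_label[centroid_label].sequence, members)
        cl.recompute_counts()
        clusters.append(cl)
    return clusters


def external_cluster_adapter(
    uniques: Sequence[UniqueSequence],
    engine: EngineSpec,
    workdir,
    id_threshold: float = 97.0,
) -> list[Cluster]:
    """Run an external clustering engine and map its output back to Clusters.

    The engine must exist on PATH (or be an absolute path); its membership
    output is parsed as UC-style records.  Absence of the engine raises
    :class:`EngineError` — falling back to the built-in greedy clusterer is
    a pipeline-level decision, never implicit.
    """
    exe = shutil.which(engine.executable)
    if exe is None:
        raise EngineError(
            f"clustering engine {engine.name!r} not found (executable "
            f"{engine.executable!r} is not on PATH)"
        )
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    fasta = workdir / "derep.fasta"
    ucfile = workdir / "clusters.uc"
    labels = write_size_fasta(uniques, fasta)
    args = [exe] + [
        a.format(input=fasta, output=ucfile, threshold=id_threshold / 100.0)
        for a in engine.args_template
    ]
    proc = subprocess.run(args, capture_output=True, text=True)
    if proc.returncode != 0:
        raise EngineError(f"engine {engine.name!r} failed: {proc.stderr[:500]}")
    with open(ucfile) as fh:
        membership = parse_uc_membership(fh)
    return clusters_from_membership(uniques, labels, membership)
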