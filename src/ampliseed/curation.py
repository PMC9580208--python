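"""Post-clustering curation: cross-talk count zeroing, off-target
(phiX/host) cluster removal, and adapter contracts for wrapped tools.

Cross-talk (index hopping between multiplexed samples) leaves a faint,
roughly uniform smear of a cluster's reads across all samples.  The filter
models the expected leak per cell as ``e_i = gamma * T_i / S`` (cluster
total ``T_i`` over ``S`` samples) and zeroes any positive cell whose score
``pi_ij = 2 * e_i / (c_ij + e_i)`` reaches the cut-off: cells barely above
the expected leak are indistinguishable from hopping artefacts.

Off-target screening (phiX spike-ins, host DNA) is implemented natively
with a k-mer prefilter plus semi-global windowed alignment, so the default
pipeline needs no external aligner.  Chimera removal, ITS extraction and
co-occurrence curation are only available through the external-tool adapter
contract; their algorithms are not reimplemented here.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib

from .cluster import EngineError, _cigar_stats
from .formats import AbundanceMatrix, read_fasta
from .seedext import SeedResult


def crosstalk_filter(
    matrix: AbundanceMatrix, gamma: float = 0.01, score_cut: float = 0.5
) -> tuple[AbundanceMatrix, int]:
    """Zero cells that look like cross-talk; returns (matrix, reads removed).

    For each cluster i with total T_i over S samples, the expected leak is
    e_i = gamma * T_i / S; a positive cell c gets score pi = 2e/(c+e) and is
    zeroed iff pi >= score_cut.  gamma=0 is the identity.
    """
    df = matrix.df.copy()
    n_samples = df.shape[1]
    removed = 0
    if gamma > 0 and n_samples > 0:
        for cid in df.index:
            row = df.loc[cid]
            e = gamma * row.sum() / n_samples
            if e == 0:
                continue
            for sid in df.columns:
                c = row[sid]
                if c > 0 and 2.0 * e / (c + e) >= score_cut:
                    removed += int(c)
                    df.loc[cid, sid] = 0
    return AbundanceMatrix(df), removed


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _window_identity(query: str, target: str) -> float:
    res = edlib.align(query, target, mode="HW", task="path")
    matches, cols = _cigar_stats(res["cigar"])
    return 100.0 * matches / cols if cols else 0.0


def offtarget_screen(
    seeds: Sequence[SeedResult],
    contaminant_refs: Mapping[str, str] | str,
    min_identity: float = 90.0,
    min_coverage: float = 0.5,
    k: int = 15,
) -> set[str]:
    """Flag clusters whose seed aligns to a contaminant reference.

    A seed is flagged iff some window covering >= ``min_coverage`` of its
    length aligns end-gap-free within a contaminant at >= ``min_identity``.
    A shared-k-mer prefilter skips references with no exact ``k``-mer in
    common with the seed (sound for the identity levels screened here).
    """
    if isinstance(contaminant_refs, str):
        contaminant_refs = read_fasta(contaminant_refs)
    flagged: set[str] = set()
    for seed in seeds:
        q = seed.seed_sequence
        n = len(q)
        w = max(int(min_coverage * n), k)
        windows = [q]
        if w < n:
            windows += [q[:w], q[-w:], q[(n - w) // 2 : (n - w) // 2 + w]]
        seed_kmers = _kmers(q, k)
        for ref in contaminant_refs.values():
            if not seed_kmers & _kmers(ref, k):
                continue
            if any(_window_identity(win, ref) >= min_identity for win in windows):
                flagged.add(seed.cluster_id)
                break
    return flagged


CURATION_STAGES = ("chimera", "itsx", "lulu")


@dataclass(slots=True)
class CurationTool:
    stage: str
    executable: str
    args_template: list[str]


def apply_survivors(matrix: AbundanceMatrix, survivors: Iterable[str], stage: str) -> AbundanceMatrix:
    """Keep only the surviving cluster ids; unknown survivors are an error."""
    survivors = list(survivors)
    unknown = set(survivors) - set(matrix.cluster_ids)
    if unknown:
        raise EngineError(f"{stage}: survivor ids not in matrix: {sorted(unknown)[:5]}")
    drop = [c for c in matrix.cluster_ids if c not in set(survivors)]
    return matrix.drop_clusters(drop)


def external_curation_adapter(
    stage: str,
    matrix: AbundanceMatrix,
    seeds: Mapping[str, str],
    tool: CurationTool,
    workdir,
) -> AbundanceMatrix:
    """Contract for wrapped curation tools (UCHIME3-style chimera removal,
    ITS extraction, co-occurrence curation).

    Serialises the seed FASTA, invokes the tool, reads the surviving cluster
    id list (one id per line in ``{output}``), and drops everything else.
    A missing executable raises :class:`EngineError`.
    """
    if stage not in CURATION_STAGES:
        raise ValueError(f"unknown curation stage {stage!r}")
    exe = shutil.which(tool.executable)
    if exe is None:
        raise EngineError(
            f"curation stage {stage!r} enabled but executable "
            f"{tool.executable!r} is not on PATH"
        )
    from pathlib import Path

    from .formats import write_fasta

    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    fasta = workdir / f"{stage}_input.fasta"
    outfile = workdir / f"{stage}_survivors.txt"
    write_fasta({cid: seeds[cid] for cid in matrix.cluster_ids}, fasta)
    args = [exe] + [a.format(input=fasta, output=outfile) for a in tool.args_template]
    proc = subprocess.run(args, capture_output=True, text=True)
    if proc.returncode != 0:
        raise EngineError(f"{stage} tool failed: {proc.stderr[:500]}")
    with open(outfile) as fh:
        survivors = [line.strip() for line in fh if line.strip()]
    return apply_survivors(matrix, survivors, stage)
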