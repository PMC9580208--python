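"""Single-command orchestration: demultiplex -> tier -> dereplicate ->
cluster -> seed-extend -> backmap -> curate -> classify -> tables.

The pipeline is fully deterministic: two runs over identical inputs produce
byte-identical count tables.  A read-fate ledger is maintained across every
stage boundary and embedded in the machine-readable run report, so the
arithmetic ``input = unassigned + rejected + clustered + backmapped +
unmapped`` can always be audited.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .cluster import Cluster, greedy_cluster
from .curation import crosstalk_filter, offtarget_screen
from .derep import DEFAULT_DEREP, DerepSpec, dereplicate, parse_derep_spec, split_by_spec
from .formats import (
    AbundanceMatrix,
    MappingFileError,
    ReadRecord,
    SampleSpec,
    parse_mapping,
    read_fasta,
    read_fastq,
    write_outputs,
)
from .qc import FilterConfig, demultiplex, find_primer_offset, tier_read
from .seedext import PoolRead, SeedResult, backmap, select_seed
from .taxonomy import TaxonomyPath, classify_clusters, read_lineage_table


class PipelineError(RuntimeError):
    """A stage failure with a structured remedy suggestion."""

    def __init__(self, stage: str, message: str, remedy: str = ""):
        self.stage = stage
        self.remedy = remedy
        super().__init__(f"[{stage}] {message}" + (f" — suggestion: {remedy}" if remedy else ""))


@dataclass(slots=True)
class PipelineOptions:
    filters: FilterConfig = field(default_factory=FilterConfig)
    derep_min: str = str(DEFAULT_DEREP)
    cluster_threshold: float = 97.0
    backmap_enabled: bool = True
    backmap_threshold: float = 97.0
    min_overlap: int = 10
    max_mismatch_frac: float = 0.1
    xtalk: bool = False
    xtalk_gamma: float = 0.01
    xtalk_score_cut: float = 0.5
    keep_unclassified: bool = True
    refdbs: list[tuple[str, str]] = field(default_factory=list)
    contaminant_fasta: str = ""
    tax_agreement: float = 0.8
    tax_id_window: float = 1.5


@dataclass(slots=True)
class PipelineResult:
    matrix: AbundanceMatrix
    clusters: list[Cluster]
    seeds: list[SeedResult]
    taxonomy: dict[str, TaxonomyPath]
    ledger: dict[str, int]
    report: dict
    outputs: dict[str, str]
    clustered_read_ids: list[str] = field(default_factory=list)
    mapped_read_ids: list[str] = field(default_factory=list)


def _find_pooled_files(input_dir: Path) -> tuple[Path, Path | None]:
    candidates = sorted(
        p
        for p in input_dir.iterdir()
        if p.name.endswith((".fastq", ".fq", ".fastq.gz", ".fq.gz"))
    )
    if not candidates:
        raise PipelineError(
            "input",
            f"no FASTQ files found in {input_dir}",
            "check the input directory path (-i)",
        )
    fwd = [p for p in candidates if "_R1" in p.name or "_1." in p.name]
    rev = [p for p in candidates if "_R2" in p.name or "_2." in p.name]
    if fwd and rev:
        return fwd[0], rev[0]
    return candidates[0], None


def _iter_read_pairs(specs: Sequence[SampleSpec], input_dir: Path):
    """Yield (preassigned_sample_or_None, r1, r2_or_None) tuples."""
    by_path = all(s.fwd_path for s in specs)
    if by_path:
        for spec in specs:
            fwd = input_dir / spec.fwd_path
            if not fwd.exists():
                raise PipelineError(
                    "input", f"missing file {fwd} for sample {spec.sample_id}",
                    "fix the fastqFile column of the mapping file",
                )
            fwd_iter = read_fastq(fwd, "R1")
            if spec.rev_path:
                rev_iter = read_fastq(input_dir / spec.rev_path, "R2")
                for r1, r2 in zip(fwd_iter, rev_iter):
                    yield spec.sample_id, r1, r2
            else:
                for r1 in fwd_iter:
                    yield spec.sample_id, r1, None
    else:
        fwd, rev = _find_pooled_files(input_dir)
        fwd_iter = read_fastq(fwd, "R1")
        if rev is not None:
            for r1, r2 in zip(fwd_iter, read_fastq(rev, "R2")):
                yield None, r1, r2
        else:
            for r1 in fwd_iter:
                yield None, r1, None


def run(
    input_dir,
    mapping_file,
    output_dir,
    options: PipelineOptions | None = None,
) -> PipelineResult:
    """Execute the full pipeline and write the output bundle."""
    options = options or PipelineOptions()
    cfg = options.filters
    input_dir = Path(input_dir)
    output_dir = Path(output_dir)
    try:
        specs = parse_mapping(mapping_file)
    except FileNotFoundError:
        raise PipelineError(
            "input", f"mapping file {mapping_file} not found",
            "pass the mapping file path with -m/--mapping",
        )
    except MappingFileError as exc:
        raise PipelineError("input", str(exc), "fix the mapping file")
    try:
        derep_spec = parse_derep_spec(options.derep_min)
    except Exception as exc:
        raise PipelineError("config", str(exc), "use count:samples pairs, e.g. 8:1,4:2,3:3")

    samples = [s.sample_id for s in specs]
    ledger: dict[str, int] = {
        "input_reads": 0,
        "unassigned": 0,
        "primer_missing": 0,
        "tier_high": 0,
        "tier_mid": 0,
        "tier_reject": 0,
    }
    high: list[tuple[str, str, str]] = []  # (sample, truncated seq, read id)
    mid_pool: list[PoolRead] = []
    originals: dict[str, tuple[ReadRecord, ReadRecord | None]] = {}
    read_sample: dict[str, str] = {}

    barcode_specs = [s for s in specs if s.barcode]
    for preassigned, r1, r2 in _iter_read_pairs(specs, input_dir):
        ledger["input_reads"] += 1
        if preassigned is None:
            sample, r1 = demultiplex(r1, barcode_specs, cfg.barcode_mismatches)
            if sample is None:
                ledger["unassigned"] += 1
                continue
        else:
            sample = preassigned
        if cfg.primer_fwd:
            off = find_primer_offset(r1.sequence, cfg.primer_fwd, cfg.primer_mismatches)
            if off is None:
                if cfg.require_primer:
                    ledger["primer_missing"] += 1
                    ledger["tier_reject"] += 1
                    continue
            else:
                r1 = r1.slice(off + len(cfg.primer_fwd))
        tiered = tier_read(r1, cfg, sample)
        if tiered.tier == "HIGH":
            ledger["tier_high"] += 1
            high.append((sample, tiered.record.sequence, r1.read_id))
            originals[r1.read_id] = (r1, r2)
            read_sample[r1.read_id] = sample
        elif tiered.tier == "MID":
            ledger["tier_mid"] += 1
            mid_pool.append(PoolRead(sample, tiered.record.sequence, 1, r1.read_id))
            read_sample[r1.read_id] = sample
        else:
            ledger["tier_reject"] += 1

    uniques = dereplicate(high)
    accepted, derep_rejected = split_by_spec(uniques, derep_spec)
    ledger["uniques"] = len(uniques)
    ledger["uniques_accepted"] = len(accepted)
    ledger["reads_in_accepted_uniques"] = sum(u.total_count for u in accepted)
    if not accepted:
        raise PipelineError(
            "clustering", "no unique sequence passed the dereplication filter",
            "relax -derepMin (e.g. 1:1) or check read quality settings",
        )

    clusters = greedy_cluster(accepted, options.cluster_threshold)
    ledger["clusters"] = len(clusters)
    clustered_ids = [rid for cl in clusters for m in cl.members for rid in m.read_ids]

    seeds = [
        select_seed(cl, originals, options.min_overlap, options.max_mismatch_frac)
        for cl in clusters
    ]
    seed_seqs = {s.cluster_id: s.seed_sequence for s in seeds}

    counts: dict[tuple[str, str], int] = {}
    for cl in clusters:
        for sid, c in cl.per_sample_counts.items():
            counts[(cl.cluster_id, sid)] = counts.get((cl.cluster_id, sid), 0) + c
    matrix = AbundanceMatrix.from_counts(counts, [c.cluster_id for c in clusters], samples)
    ledger["reads_clustered"] = matrix.total()

    mapped_ids: list[str] = []
    if options.backmap_enabled:
        pool = list(mid_pool)
        for u in derep_rejected:
            for rid in u.read_ids:
                pool.append(PoolRead(read_sample[rid], u.sequence, 1, rid))
        totals = {cl.cluster_id: cl.total_count for cl in clusters}
        increments, mapped_ids, unmapped = backmap(
            pool, seeds, totals, options.backmap_threshold
        )
        for (cid, sid), c in increments.items():
            matrix.df.loc[cid, sid] += c
        ledger["backmap_pool"] = len(pool)
        ledger["backmapped"] = len(mapped_ids)
        ledger["unmapped"] = len(unmapped)
    else:
        ledger["backmap_pool"] = 0
        ledger["backmapped"] = 0
        ledger["unmapped"] = 0

    if options.contaminant_fasta:
        refs = read_fasta(options.contaminant_fasta)
        flagged = offtarget_screen(seeds, refs)
        ledger["offtarget_clusters"] = len(flagged)
        matrix = matrix.drop_clusters(flagged)
        seeds = [s for s in seeds if s.cluster_id not in flagged]
        seed_seqs = {k: v for k, v in seed_seqs.items() if k not in flagged}
    else:
        ledger["offtarget_clusters"] = 0

    if options.xtalk:
        matrix, removed = crosstalk_filter(matrix, options.xtalk_gamma, options.xtalk_score_cut)
        ledger["crosstalk_removed"] = removed
    else:
        ledger["crosstalk_removed"] = 0

    if options.refdbs:
        try:
            databases = [
                (read_fasta(fa), read_lineage_table(tax)) for fa, tax in options.refdbs
            ]
        except FileNotFoundError as exc:
            raise PipelineError("taxonomy", str(exc), "check the -refdb fasta,tax paths")
        taxonomy = classify_clusters(
            {cid: seed_seqs[cid] for cid in matrix.cluster_ids},
            databases,
            options.tax_agreement,
            options.tax_id_window,
        )
        if not options.keep_unclassified:
            drop = [cid for cid, p in taxonomy.items() if p.depth() == 0]
            matrix = matrix.drop_clusters(drop)
            ledger["unclassified_dropped"] = len(drop)
        else:
            ledger["unclassified_dropped"] = 0
    else:
        taxonomy = {cid: TaxonomyPath.unclassified() for cid in matrix.cluster_ids}
        ledger["unclassified_dropped"] = 0

    ledger["final_matrix_total"] = matrix.total()

    report = {
        "version": __version__,
        "parameters": {
            "derep_min": str(derep_spec),
            "cluster_threshold": options.cluster_threshold,
            "backmap": options.backmap_enabled,
            "backmap_threshold": options.backmap_threshold,
            "truncate_len": cfg.truncate_len,
            "xtalk": options.xtalk,
            "keep_unclassified": options.keep_unclassified,
            "refdbs": [list(db) for db in options.refdbs],
        },
        "ledger": ledger,
        "samples": samples,
    }
    log_lines = [f"ampliseed {__version__}"] + [
        f"{k}\t{v}" for k, v in ledger.items()
    ]
    try:
        outputs = write_outputs(
            output_dir,
            matrix,
            {cid: taxonomy[cid] for cid in matrix.cluster_ids},
            seed_seqs,
            log_lines,
        )
    except OSError as exc:
        raise PipelineError("output", str(exc), "check that the output directory is writable")
    report_path = output_dir / "run_report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2)
    outputs["report"] = str(report_path)

    return PipelineResult(
        matrix,
        clusters,
        seeds,
        taxonomy,
        ledger,
        report,
        outputs,
        clustered_ids,
        mapped_ids,
    )


def classify_fasta(
    fasta_path, refdbs: Sequence[tuple[str, str]], agreement: float = 0.8,
    id_window: float = 1.5,
) -> dict[str, TaxonomyPath]:
    """Classify an arbitrary FASTA against reference databases without
    running the read pipeline (taxonomy-only mode)."""
    queries = read_fasta(fasta_path)
    databases = [(read_fasta(fa), read_lineage_table(tax)) for fa, tax in refdbs]
    return classify_clusters(queries, databases, agreement, id_window)
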