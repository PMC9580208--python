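"""Readers and writers for the external formats the pipeline touches.

This module is deliberately free of any science: FASTQ/FASTA I/O, the
tab-delimited sample mapping file, count-table TSVs, BIOM 1.0 JSON and the
plain-text run log all live here, together with the core containers
(:class:`ReadRecord`, :class:`SampleSpec`, :class:`AbundanceMatrix`).

All sequence input is uppercased and RNA ``U`` is normalised to ``T`` on
read.  Phred qualities are decoded at ASCII offset 33 (Sanger/modern
Illumina); offset-64 encodings are not supported.
"""

from __future__ import annotations

import gzip
import io
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

PHRED_OFFSET = 33
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class FastqParseError(ValueError):
    """Raised when a FASTQ stream violates the 4-line record structure."""


class MappingFileError(ValueError):
    """Raised for malformed sample mapping files."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_seq(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(slots=True)
class ReadRecord:
    """A single sequencing read (or pair member) with Phred qualities."""

    read_id: str
    sequence: str
    qualities: list[int]
    mate: str = "single"  # one of R1, R2, single

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )
        if self.mate not in ("R1", "R2", "single"):
            raise ValueError(f"invalid mate {self.mate!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, stop: int | None = None) -> "ReadRecord":
        """Return a copy restricted to ``[start:stop]``."""
        return ReadRecord(
            self.read_id,
            self.sequence[start:stop],
            self.qualities[start:stop],
            self.mate,
        )


@dataclass(slots=True)
class SampleSpec:
    """One row of the mapping file: how to find/assign a sample's reads."""

    sample_id: str
    barcode: str = ""
    fwd_path: str = ""
    rev_path: str = ""
    run_id: str = ""


def _open_maybe_gzip(path: str | os.PathLike, mode: str = "rt"):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | os.PathLike, mate: str = "single") -> Iterator[ReadRecord]:
    """Yield :class:`ReadRecord` objects from a plain or gzipped FASTQ file.

    Qualities are decoded at offset 33.  Malformed records raise
    :class:`FastqParseError` naming the (0-based) record index.
    """
    with _open_maybe_gzip(path) as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            header = header.rstrip("\n")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+") or qual == "":
                raise FastqParseError(f"malformed FASTQ record at index {idx}")
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"record {idx}: sequence length {len(seq)} != quality length {len(qual)}"
                )
            quals = [ord(c) - PHRED_OFFSET for c in qual]
            if any(q < 0 or q > 60 for q in quals):
                raise FastqParseError(f"record {idx}: Phred value outside [0, 60]")
            yield ReadRecord(header[1:].split()[0], normalize_seq(seq), quals, mate)
            idx += 1


def write_fastq(records: Iterable[ReadRecord], path: str | os.PathLike) -> int:
    """Write records as FASTQ (gzipped if the path ends in .gz); return count."""
    n = 0
    with _open_maybe_gzip(path, "wt") as fh:
        for rec in records:
            qual = "".join(chr(q + PHRED_OFFSET) for q in rec.qualities)
            fh.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{qual}\n")
            n += 1
    return n


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` dict."""
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with _open_maybe_gzip(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    out[name] = normalize_seq("".join(chunks))
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        out[name] = normalize_seq("".join(chunks))
    return out


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike, width: int = 80) -> None:
    with _open_maybe_gzip(path, "wt") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def parse_mapping(path: str | os.PathLike) -> list[SampleSpec]:
    """Parse a tab-delimited mapping file into :class:`SampleSpec` rows.

    Dialect: a header line starting with ``#SampleID``; other ``#`` lines are
    comments.  Recognised columns: ``BarcodeSequence``, ``fastqFile`` (a
    comma-separated pair for paired-end data) and ``RunID``.  Each row must
    carry either a barcode or file path(s), not neither.
    """
    with _open_maybe_gzip(path) as fh:
        lines = fh.read().splitlines()
    header = None
    rows = []
    for line in lines:
        if not line.strip():
            continue
        if line.startswith("#SampleID"):
            header = line.lstrip("#").split("\t")
        elif line.startswith("#"):
            continue
        else:
            rows.append(line.split("\t"))
    if header is None:
        raise MappingFileError("mapping file lacks a '#SampleID' header line")
    col = {name: i for i, name in enumerate(header)}
    specs: list[SampleSpec] = []
    seen: set[str] = set()
    for row in rows:
        def get(name: str) -> str:
            i = col.get(name)
            return row[i].strip() if i is not None and i < len(row) else ""

        sid = row[0].strip()
        if sid in seen:
            raise MappingFileError(f"duplicate sample id {sid!r}")
        seen.add(sid)
        barcode = normalize_seq(get("BarcodeSequence"))
        if "N" in barcode:
            raise MappingFileError(f"sample {sid!r}: barcode contains N")
        files = get("fastqFile")
        fwd, rev = "", ""
        if files:
            parts = [p.strip() for p in files.split(",")]
            fwd = parts[0]
            rev = parts[1] if len(parts) > 1 else ""
        if not barcode and not fwd:
            raise MappingFileError(
                f"sample {sid!r}: neither BarcodeSequence nor fastqFile given"
            )
        specs.append(SampleSpec(sid, barcode, fwd, rev, get("RunID")))
    return specs


class AbundanceMatrix:
    """Clusters x samples integer count matrix, the pipeline's main output.

    Thin wrapper over a pandas DataFrame (rows = cluster ids, columns =
    sample ids, values = non-negative ints) with format round-trips.
    """

    def __init__(self, df: pd.DataFrame):
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise ValueError("cluster/sample labels must be unique")
        if (df.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.df = df.astype(int)

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[tuple[str, str], int],
        cluster_ids: Sequence[str],
        sample_ids: Sequence[str],
    ) -> "AbundanceMatrix":
        df = pd.DataFrame(0, index=list(cluster_ids), columns=list(sample_ids), dtype=int)
        for (cid, sid), c in counts.items():
            df.loc[cid, sid] += c
        return cls(df)

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    def total(self) -> int:
        return int(self.df.values.sum())

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.df.copy())

    def drop_clusters(self, cluster_ids: Iterable[str]) -> "AbundanceMatrix":
        drop = [c for c in cluster_ids if c in self.df.index]
        return AbundanceMatrix(self.df.drop(index=drop))

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.df.to_csv(path, sep="\t", index_label="#OTU_ID")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "AbundanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(df)

    def to_biom_json(self, path: str | os.PathLike, table_id: str = "ampliseed") -> None:
        """Write a (sparse) BIOM 1.0 JSON table."""
        rows = [{"id": cid, "metadata": None} for cid in self.cluster_ids]
        cols = [{"id": sid, "metadata": None} for sid in self.sample_ids]
        data = []
        vals = self.df.values
        for i in range(vals.shape[0]):
            for j in range(vals.shape[1]):
                if vals[i, j]:
                    data.append([i, j, int(vals[i, j])])
        biom = {
            "id": table_id,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "ampliseed",
            "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": [len(rows), len(cols)],
            "rows": rows,
            "columns": cols,
            "data": data,
        }
        with open(path, "w") as fh:
            json.dump(biom, fh)

    @classmethod
    def from_biom_json(cls, path: str | os.PathLike) -> "AbundanceMatrix":
        with open(path) as fh:
            biom = json.load(fh)
        index = [r["id"] for r in biom["rows"]]
        columns = [c["id"] for c in biom["columns"]]
        df = pd.DataFrame(0, index=index, columns=columns, dtype=int)
        for i, j, v in biom["data"]:
            df.iloc[i, j] = int(v)
        return cls(df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbundanceMatrix):
            return NotImplemented
        return self.df.equals(other.df)


def write_outputs(
    outdir: str | os.PathLike,
    matrix: AbundanceMatrix,
    taxonomy: Mapping[str, "object"],
    seeds: Mapping[str, str],
    log_lines: Sequence[str] = (),
) -> dict[str, str]:
    """Write the standard output bundle to ``outdir``.

    Emits the cluster x sample count TSV, the seed FASTA, per-rank taxon
    abundance TSVs, a BIOM 1.0 JSON table and the run log.  Every cluster in
    the matrix must have a taxonomy path and a seed sequence.
    """
    from .taxonomy import RANKS, aggregate_by_rank, TaxonomyPath

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    missing_tax = set(matrix.cluster_ids) - set(taxonomy)
    if missing_tax:
        raise ValueError(f"clusters missing from taxonomy: {sorted(missing_tax)[:5]}")
    missing_seed = set(taxonomy) - set(seeds)
    if missing_seed:
        raise ValueError(f"clusters missing from seeds: {sorted(missing_seed)[:5]}")

    paths: dict[str, str] = {}
    table = outdir / "otu_table.tsv"
    matrix.to_tsv(table)
    paths["table"] = str(table)

    fasta = outdir / "otu_seeds.fasta"
    write_fasta({cid: seeds[cid] for cid in matrix.cluster_ids}, fasta)
    paths["seeds"] = str(fasta)

    taxfile = outdir / "taxonomy.tsv"
    with open(taxfile, "w") as fh:
        fh.write("#OTU_ID\tlineage\n")
        for cid in matrix.cluster_ids:
            fh.write(f"{cid}\t{taxonomy[cid]}\n")
    paths["taxonomy"] = str(taxfile)

    for rank in RANKS:
        agg = aggregate_by_rank(matrix, taxonomy, rank)
        p = outdir / f"abundance_{rank}.tsv"
        agg.to_csv(p, sep="\t", index_label="#Taxon")
        paths[f"rank_{rank}"] = str(p)

    biom = outdir / "otu_table.biom.json"
    matrix.to_biom_json(biom)
    paths["biom"] = str(biom)

    log = outdir / "run.log"
    with open(log, "w") as fh:
        for line in log_lines:
            fh.write(line.rstrip("\n") + "\n")
    paths["log"] = str(log)
    return paths
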