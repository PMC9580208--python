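"""Synthetic mock communities and raw amplicon runs with known truth.

The generator emulates a paired-end Illumina V4 16S amplicon experiment:
templates of ~450 nt flanked by the 515F/806R primer sites, log-normal
species abundances, per-genome marker copy numbers, position-dependent
substitution errors with honest Phred scores (the second read pair at twice
the first's error rate), PCR chimeras spliced from two templates, and
cross-talk (index hopping) that relabels a read's sample.  Every read is
logged to a truth table, so each pipeline stage can be scored exactly.

The error model is substitution-only (no indels), which keeps alignment
identities in tests exactly computable; quality scores are drawn from a
heavy-tailed per-read quality factor so that — as in real runs — a core of
near-error-free reads coexists with a long tail of poor ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .formats import ReadRecord, revcomp, write_fastq
from .qc import IUPAC
from .taxonomy import RANKS, TaxonomyPath

PRIMER_515F = "GTGCCAGCMGCCGCGGTAA"
PRIMER_806R = "GGACTACHVGGGTWTCTAAT"

_BASES = "ACGT"


@dataclass(slots=True)
class MockTruth:
    """A known community: templates, lineages, abundances, copy numbers."""

    references: dict[str, str]
    lineages: dict[str, TaxonomyPath]
    abundances: dict[str, float]
    copy_numbers: dict[str, int]

    def __post_init__(self) -> None:
        if abs(sum(self.abundances.values()) - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")
        missing = set(self.references) - set(self.lineages)
        if missing:
            raise ValueError(f"references without lineage: {sorted(missing)[:5]}")

    def genus_set(self) -> set[str]:
        return {p.at("genus") for p in self.lineages.values()}

    def species_set(self) -> set[str]:
        return {p.at("species") for p in self.lineages.values()}


def _instantiate_iupac(pattern: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(IUPAC[c])) for c in pattern)


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_BASES)) for _ in range(n))


def make_mock(
    n_species: int = 12,
    seed: int = 0,
    divergence: float = 0.1,
    template_len: int = 450,
    copy_number_range: tuple[int, int] = (1, 4),
    n_copy_variants: int = 0,
    fwd_primer: str = PRIMER_515F,
    rev_primer: str = PRIMER_806R,
) -> MockTruth:
    """Generate a mock community of ``n_species`` amplicon templates.

    Templates carry concrete instantiations of the (degenerate) primers at
    both ends around an independent random core, and are re-drawn until all
    pairwise identities are <= ``(1 - divergence) * 100``.  Lineages are
    synthetic, with one genus per species; abundances are log-normal.
    ``n_copy_variants`` adds within-genome marker-copy variants (<= 1%
    diverged from their parent) to emulate intragenomic rRNA copies.
    """
    from .cluster import pairwise_identity

    rng = np.random.default_rng(seed)
    core_len = template_len - len(fwd_primer) - len(rev_primer)
    refs: dict[str, str] = {}
    max_ident = (1.0 - divergence) * 100.0
    for i in range(n_species):
        for _ in range(100):
            seq = (
                _instantiate_iupac(fwd_primer, rng)
                + _random_seq(core_len, rng)
                + revcomp(_instantiate_iupac(rev_primer, rng))
            )
            if all(pairwise_identity(seq, other) <= max_ident for other in refs.values()):
                break
        else:
            raise RuntimeError("could not satisfy divergence constraint")
        refs[f"ref_{i:03d}"] = seq

    phyla = ["Pseudomonadota", "Bacillota", "Bacteroidota", "Actinomycetota"]
    lineages: dict[str, TaxonomyPath] = {}
    for i, rid in enumerate(refs):
        phylum = phyla[i % len(phyla)]
        lineages[rid] = TaxonomyPath.from_names(
            [
                "Bacteria",
                phylum,
                f"{phylum}_class_{i % 3}",
                f"Order_{i % 5:02d}",
                f"Family_{i:02d}",
                f"Genus_{i:02d}",
                f"Genus_{i:02d} species_{i:02d}",
            ]
        )

    raw = rng.lognormal(mean=0.0, sigma=1.0, size=n_species)
    abund = raw / raw.sum()
    abundances = {rid: float(a) for rid, a in zip(refs, abund)}
    lo, hi = copy_number_range
    copies = {rid: int(rng.integers(lo, hi + 1)) for rid in refs}

    # optional intragenomic copy variants: near-identical siblings sharing
    # the parent's lineage and a slice of its abundance
    for v in range(n_copy_variants):
        parent = list(refs)[v % n_species]
        seq = list(refs[parent])
        n_mut = max(1, int(0.01 * len(seq) * rng.random()))
        for pos in rng.choice(len(seq), size=n_mut, replace=False):
            seq[pos] = rng.choice([b for b in _BASES if b != seq[pos]])
        vid = f"{parent}_v{v}"
        refs[vid] = "".join(seq)
        lineages[vid] = lineages[parent]
        abundances[parent] /= 2.0
        abundances[vid] = abundances[parent]
        copies[vid] = 1

    total = sum(abundances.values())
    abundances = {k: v / total for k, v in abundances.items()}
    return MockTruth(refs, lineages, abundances, copies)


@dataclass(slots=True)
class SimulatedRun:
    fwd_path: str
    rev_path: str
    mapping_path: str
    truth_table: pd.DataFrame
    truth_path: str


def simulate_run(
    truth: MockTruth,
    n_read_pairs: int,
    barcodes: Mapping[str, str],
    seed: int,
    outdir,
    read_len: int = 250,
    error_rate: float = 0.005,
    chimera_rate: float = 0.0,
    crosstalk_rate: float = 0.0,
    quality_sigma: float = 1.6,
    gzip_output: bool = False,
) -> SimulatedRun:
    """Emit a pooled paired-end FASTQ run of ``n_read_pairs`` per sample.

    Per-base error probabilities follow a linear 0.5x -> 1.5x ramp along the
    read (3' quality decay), scaled by a per-read log-normal quality factor
    with unit mean, so the run-wide mean substitution rate equals
    ``error_rate`` (the mate uses twice that rate).  Phred scores encode the
    true per-base probabilities.  Deterministic and byte-identical per seed.
    """
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = list(barcodes)
    ref_ids = list(truth.references)
    weights = np.array(
        [truth.abundances[r] * truth.copy_numbers[r] for r in ref_ids], dtype=float
    )
    weights /= weights.sum()
    ramp_cache: dict[int, np.ndarray] = {}

    def ramp(n: int) -> np.ndarray:
        if n not in ramp_cache:
            ramp_cache[n] = np.linspace(0.5, 1.5, n) if n > 1 else np.ones(1)
        return ramp_cache[n]

    def noisy(seq: str, rate: float, factor: float) -> tuple[str, list[int]]:
        n = len(seq)
        p = np.clip(rate * factor * ramp(n), 0.0, 0.75)
        quals = np.clip(
            np.rint(-10.0 * np.log10(np.maximum(p, 1e-5))), 2, 41
        ).astype(int)
        hits = rng.random(n) < p
        if hits.any():
            chars = list(seq)
            for pos in np.nonzero(hits)[0]:
                chars[pos] = _BASES[
                    (_BASES.index(chars[pos]) + rng.integers(1, 4)) % 4
                ]
            seq = "".join(chars)
        return seq, quals.tolist()

    r1_records: list[ReadRecord] = []
    r2_records: list[ReadRecord] = []
    rows = []
    idx = 0
    norm = float(np.exp(quality_sigma**2 / 2.0))
    for sample in samples:
        for _ in range(n_read_pairs):
            rid_i = ref_ids[rng.choice(len(ref_ids), p=weights)]
            fragment = truth.references[rid_i]
            is_chimera = False
            if chimera_rate > 0 and rng.random() < chimera_rate:
                other = ref_ids[rng.choice(len(ref_ids), p=weights)]
                frag_b = truth.references[other]
                lo = 50
                hi = min(len(fragment), len(frag_b)) - 50
                bp = int(rng.integers(lo, hi))
                fragment = fragment[:bp] + frag_b[bp:]
                is_chimera = True
            emit_sample = sample
            was_crosstalk = False
            if crosstalk_rate > 0 and len(samples) > 1 and rng.random() < crosstalk_rate:
                others = [s for s in samples if s != sample]
                emit_sample = others[int(rng.integers(len(others)))]
                was_crosstalk = True
            factor = float(rng.lognormal(0.0, quality_sigma)) / norm
            read_id = f"read_{idx:07d}"
            idx += 1
            bc = barcodes[emit_sample]
            r1_template = bc + fragment[: read_len - len(bc)]
            r1_seq, r1_q = noisy(r1_template, error_rate, factor)
            r2_template = revcomp(fragment)[:read_len]
            r2_seq, r2_q = noisy(r2_template, 2.0 * error_rate, factor)
            r1_records.append(ReadRecord(read_id, r1_seq, r1_q, "R1"))
            r2_records.append(ReadRecord(read_id, r2_seq, r2_q, "R2"))
            rows.append(
                {
                    "read_id": read_id,
                    "source_ref": rid_i,
                    "sample": emit_sample,
                    "is_chimera": is_chimera,
                    "was_crosstalk": was_crosstalk,
                }
            )

    ext = ".fastq.gz" if gzip_output else ".fastq"
    fwd = outdir / f"run_R1{ext}"
    rev = outdir / f"run_R2{ext}"
    write_fastq(r1_records, fwd)
    write_fastq(r2_records, rev)

    mapping = outdir / "mapping.tsv"
    with open(mapping, "w") as fh:
        fh.write("#SampleID\tBarcodeSequence\tfastqFile\tRunID\n")
        for sample in samples:
            fh.write(f"{sample}\t{barcodes[sample]}\t\trun1\n")

    truth_table = pd.DataFrame(rows)
    truth_path = outdir / "read_truth.tsv"
    truth_table.to_csv(truth_path, sep="\t", index=False)
    return SimulatedRun(str(fwd), str(rev), str(mapping), truth_table, str(truth_path))


def write_mock_refdb(truth: MockTruth, outdir) -> tuple[str, str]:
    """Write the mock references as a (FASTA, lineage TSV) reference
    database pair usable for taxonomy assignment."""
    from .formats import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "mock_refs.fasta"
    tax = outdir / "mock_refs.tax"
    write_fasta(truth.references, fasta)
    with open(tax, "w") as fh:
        for rid, lineage in truth.lineages.items():
            fh.write(f"{rid}\t{lineage}\n")
    return str(fasta), str(tax)
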