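"""Evaluation mathematics: mock-community accuracy and replicate
reproducibility measures.

Accuracy against a known community is scored as set-based precision
(TP/(TP+FP)), recall (TP/(TP+FN)) and F-score (harmonic mean), plus the
fraction of reads assigned to true taxa.  Reproducibility between
technical replicates uses Bray-Curtis dissimilarity on relative abundances
and Jaccard distance on presence/absence, optionally after rarefying all
samples to a common depth.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import AbundanceMatrix


def precision_recall_f(
    expected: set, observed: set
) -> tuple[float, float, float]:
    """Precision TP/(TP+FP), recall TP/(TP+FN), F = 2PR/(P+R).

    An empty observed set yields (0, 0, 0) by convention (precision is
    formally undefined there).
    """
    tp = len(expected & observed)
    fp = len(observed - expected)
    fn = len(expected - observed)
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f = (
        2 * precision * recall / (precision + recall)
        if (precision + recall)
        else 0.0
    )
    return precision, recall, f


def fraction_reads_true(taxon_table: pd.DataFrame, truth: set) -> float:
    """Fraction of all counts that sit in rows whose taxon is in ``truth``."""
    total = taxon_table.values.sum()
    if total == 0:
        return 0.0
    true_rows = [t for t in taxon_table.index if t in truth]
    return float(taxon_table.loc[true_rows].values.sum() / total)


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity on relative-abundance-normalised vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.sum() > 0:
        a = a / a.sum()
    if b.sum() > 0:
        b = b / b.sum()
    denom = (a + b).sum()
    if denom == 0:
        return 0.0
    return float(np.abs(a - b).sum() / denom)


def jaccard_presence(a, b) -> float:
    """Jaccard distance 1 - |A∩B|/|A∪B| on presence/absence."""
    a = np.asarray(a) > 0
    b = np.asarray(b) > 0
    union = int((a | b).sum())
    if union == 0:
        return 0.0
    return 1.0 - int((a & b).sum()) / union


def rarefy(
    matrix: AbundanceMatrix, depth: int | str = "auto", seed: int = 0
) -> AbundanceMatrix:
    """Subsample each sample without replacement to a common depth.

    ``depth="auto"`` uses the total of the first sample (input order) with
    more than 1000 reads.  Samples with fewer reads than the depth are
    dropped.  Draws are multivariate hypergeometric, so repeated runs with
    one seed are identical.
    """
    totals = matrix.df.sum(axis=0)
    if depth == "auto":
        eligible = [s for s in matrix.sample_ids if totals[s] > 1000]
        if not eligible:
            raise ValueError("no sample has more than 1000 reads; give an explicit depth")
        depth = int(totals[eligible[0]])
    depth = int(depth)
    rng = np.random.default_rng(seed)
    keep = [s for s in matrix.sample_ids if totals[s] >= depth]
    out = pd.DataFrame(0, index=matrix.cluster_ids, columns=keep, dtype=int)
    for s in keep:
        col = matrix.df[s].values
        out[s] = rng.multivariate_hypergeometric(col, depth)
    return AbundanceMatrix(out)


def distance_matrix(matrix: AbundanceMatrix, metric: str = "bray_curtis") -> pd.DataFrame:
    """All-pairs sample distances (``bray_curtis`` or ``jaccard``)."""
    fn = {"bray_curtis": bray_curtis, "jaccard": jaccard_presence}[metric]
    samples = matrix.sample_ids
    out = pd.DataFrame(0.0, index=samples, columns=samples)
    for i, a in enumerate(samples):
        for b in samples[i + 1 :]:
            d = fn(matrix.df[a].values, matrix.df[b].values)
            out.loc[a, b] = out.loc[b, a] = d
    return out


def closest_replicate_fraction(
    distances: pd.DataFrame, pairing: Mapping[str, str]
) -> float:
    """Fraction of samples whose nearest neighbour is its designated
    technical replicate.  A tie for nearest counts as a failure."""
    n = ok = 0
    for sample, replicate in pairing.items():
        others = [s for s in distances.index if s != sample]
        d = distances.loc[sample, others]
        nearest = d.min()
        winners = [s for s in others if distances.loc[sample, s] == nearest]
        n += 1
        if winners == [replicate]:
            ok += 1
    return ok / n if n else 0.0
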