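# Methods

This note documents the models, defaults and numerical choices behind
`ampliseed`, and what the synthetic benchmark does and does not show.

## Quality tiers

Observed amplicon diversity is inflated by sequencing errors: over
millions of reads, rare error patterns recur often enough to masquerade as
rare taxa. The pipeline therefore treats clustering as the error-sensitive
step and feeds it only "HIGH"-tier reads — truncated first-of-pair reads
that pass the full filter battery — while recovering everything else later
by backmapping, which is robust because it only *re-distributes* reads
among already-established clusters.

A first read is truncated to `truncate_len` (default **200 nt**, so all
clustered sequences are directly comparable) and must pass:

| filter | default | failure class |
|---|---|---|
| length ≥ truncate_len | 200 nt | soft down to 0.8× (160 nt), hard below |
| mean Phred quality | ≥ 27 | hard |
| homopolymer run | ≤ 8 | hard |
| ambiguous bases (N) | 0 | hard |
| expected errors Σ 10^(−q/10) | ≤ 1.0 | soft |
| Poisson-binomial tail | P(X > 2) ≤ 0.005 | soft |

Hard failures are rejected outright; soft failures demote to MID (kept for
backmapping). Second-of-pair reads are MID by construction: they are never
clustered, only consulted during seed extension. Barcode demultiplexing is
exact-prefix Hamming matching (default 0 mismatches; ambiguous matches are
unassigned, not errors), and primer finding is IUPAC-aware within a 16-nt
5′ scan window (default 1 mismatch; reads without the primer are
rejected). Only a subset of conceivable read-quality metrics is
implemented — the battery is the set of filters that are well defined from
first principles; the thresholds above are conventional values for V4
MiSeq-type data and are all overridable via the `key = value` filter
config file.

The Poisson-binomial tail P(X > k) for per-base error probabilities
p_1..p_n is computed by the standard exact dynamic programme over
P(X = 0..k) in O(n·k); it is validated against exhaustive 2^n enumeration.
It asks a sharper question than the expected-error filter: not "how many
errors on average" but "how likely is this read to carry more than k
errors", which penalises reads with many mediocre bases more than reads
with a few bad ones.

## Dereplication grammar

HIGH reads are collapsed at 100% identity with per-sample counts. A unique
sequence enters clustering only if it satisfies the acceptance grammar
(default `8:1,4:2,3:3`): at least 8 copies in some single sample, or ≥ 4
copies in total while present in ≥ 2 samples, or ≥ 3 in total across ≥ 3
samples. All comparisons are inclusive (≥); for multi-sample terms the
count is the total across samples with presence required in the stated
number of samples. The grammar encodes the multiple-testing intuition that
a sequence seen independently in several samples needs less per-sample
evidence. Rejected uniques are not discarded — they join the backmapping
pool.

## Clustering and identity

The built-in clusterer is greedy centroid clustering in dereplication
order (abundance descending, ties lexicographic): each unique joins the
best existing centroid at ≥ 97% identity (ties → larger cluster, then
earlier-created) or founds a new cluster. Denoising algorithms are not
reimplemented; external engines plug in through a size-annotated FASTA /
UC-style membership contract, and their absence is an explicit error,
never a silent fallback.

**Identity** is defined as matches / alignment columns × 100 under a
semi-global alignment (the shorter sequence end-gap-free within the
longer). Alignments are computed with edlib's unit-cost (edit-distance)
aligner and match counts taken from the extended CIGAR. Unit costs rather
than an affine gap scheme are a deliberate numerical choice: they make the
many pairwise comparisons (clustering, backmapping, screening) fast and
deterministic, and for the substitution-dominated data this pipeline
targets the optimal unit-cost and affine alignments coincide. With gappy
sequences (e.g. long indel variants) identities can differ slightly from
an affine-gap aligner's.

## Seed extension

Clusters are built from 200-nt truncated reads, but published
representative sequences should be as long and as accurate as possible.
For each cluster, consensus sequences are built from the **full-length**
raw first reads (and mates, separately) of all members — per-column,
count-weighted majority, N never votes unless a column is all-N, ties in
fixed base order A<C<G<T. Candidates are then ranked lexicographically:

1. identity to the consensus (R1 and R2 combined, positional comparison),
2. mergeable pairs before unmergeable,
3. mean expected error (ascending),
4. usable length (merged length, else read length; descending),
5. read id (pure determinism tie-break).

Comparing the *full* read against a full-length consensus is essential:
errors beyond the truncation point would otherwise be invisible to the
ranking, and the selected "best" pair would carry hidden 3′ errors into
the published seed.

Pair merging uses the best ungapped 3′ overlap (score = matches −
mismatches), accepted at ≥ 10 nt overlap and ≤ 10% overlap mismatches.
Quality arithmetic follows read-merging convention: agreeing bases get
min(q1+q2, 60), conflicts keep the higher-quality base at |q1−q2|. Gapped
overlaps are out of scope (substitution errors dominate in the target
data).

**Backmapping**: MID reads (first reads only — mapping mates as well would
count the same fragment twice) and derep-rejected uniques are assigned to
the single best seed at ≥ 97% identity (ties → larger cluster, then
cluster order); unmapped reads are counted and logged. Backmapping only
increments matrix cells, so it is monotone enrichment by construction.

## Curation

*Cross-talk* (index hopping) is modelled as a uniform leak: for cluster i
with total T_i over S samples, the expected leaked count per cell is
e_i = γ·T_i/S (γ default 0.01) and a positive cell c is zeroed iff
π = 2e_i/(c + e_i) ≥ 0.5. The filter is off by default. *Off-target*
screening aligns seed windows (full, halves, centre; ≥ 50% of seed length)
end-gap-free against contaminant references (phiX, host) after a shared
15-mer prefilter, flagging at ≥ 90% identity. Chimera removal, ITS
extraction and co-occurrence curation exist only as adapter contracts to
external tools.

## Taxonomy

Each seed is aligned against every reference (built-in edlib aligner or a
precomputed 12-column hit table). Hits must cover > 50% of the query. Per
database, hits within 1.5 identity points of the best hit vote; each
voting lineage is first truncated to the deepest rank its identity admits
(species 97, genus 95, family 93, order 91, class 88, phylum 78 — the
conventional amplicon gating ladder, config-exposed), and a rank's name is
kept iff ≥ 80% of voters agree; the first failing rank and everything
below become "?". Lineages are prefix-closed by construction. With
multiple databases the deepest-resolved lineage wins, ties broken by the
user's database order. Fully unclassified clusters are kept by default
(`-keepUnclassified 1`).

Rank aggregation pools unclassified clusters under their deepest resolved
prefix, so column sums are conserved at every rank.

## Metrics

Precision TP/(TP+FP), recall TP/(TP+FN), F = 2PR/(P+R) over taxon sets
(empty observed set → 0 by convention); fraction of reads in true taxa as
the relative-abundance sum of true-positive rows. Bray-Curtis operates on
relative abundances, Jaccard on presence/absence. Rarefaction is
multivariate-hypergeometric (without replacement) under an explicit seed;
automatic depth is the total of the first sample (input order) exceeding
1000 reads, and shallower samples are dropped.

## Synthetic data generator

The generator emulates a paired-end V4-style experiment: templates of
450 nt flanked by concrete instantiations of the degenerate 515F/806R
primer sites around independent random cores (pairwise identity forced
≤ 90%), synthetic 7-rank lineages (one genus per species), log-normal
abundances (σ = 1), per-genome marker copy numbers 1–4, optional ≤ 1%
diverged within-genome copy variants. Reads carry substitution errors at
a linear 0.5×–1.5× positional ramp (3′ decay), scaled by a per-read
log-normal quality factor (σ = 1.6, unit mean) so a run mixes a core of
near-error-free reads with a heavy tail of poor ones — without this
between-read spread, a uniform 0.5% error rate would fail the
Poisson-binomial gate for every read, which no real run does. Mates use
twice the first-read error rate. Phred scores encode the true per-base
probabilities. Chimeras splice two templates at a uniform breakpoint
(≥ 50 nt from both ends); cross-talk relabels a read's sample. Everything
is deterministic and byte-identical per seed, and every read is logged to
a truth table.

**What passing the synthetic benchmark does not show**: the error model
has no indels, no PCR bias, no correlated (Markov) quality structure, no
real reference-database ambiguity — so accuracy figures here bound the
method's behaviour under its own assumptions, not its field performance on
real runs.

## Benchmark scale and defaults

The acceptance analysis (`scripts/acceptance.py`, also mirrored in the
test suite) uses a 12-species community, two technical replicates of 3000
read pairs each, 0.5% mean error and 5% chimeras — large enough that
every species clears the dereplication grammar and replicate Bray-Curtis
distances are dominated by genuine multinomial sampling noise (~0.03–0.05)
rather than pipeline artefacts, and small enough to run in seconds on one
CPU. Chimeric reads need no dedicated removal step at this scale: their
random breakpoints make them fail dereplication and (when the breakpoint
falls inside the clustered prefix) the 97% backmapping gate, so they drain
into the unmapped pool.

## Known limitations

- Offset-64 Phred encodings, 454/PacBio flowgram formats and dual-index
  demultiplexing are unsupported.
- ASV denoising is available only through external-engine adapters.
- The "lower truncation never shrinks the HIGH set" monotonicity holds
  for 3′-decaying quality profiles (the platform norm); adversarial
  quality vectors with bad 5′ ends can violate it through the
  average-quality filter.
- The off-target screen's k-mer prefilter assumes ≥ 90% identity targets;
  highly diverged contaminants below that are out of its design range.
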