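"""Consensus, read-pair merging, seed selection and backmapping."""

import numpy as np
import pytest

from conftest import make_read
from ampliseed.cluster import Cluster, pairwise_identity
from ampliseed.derep import UniqueSequence
from ampliseed.formats import ReadRecord, revcomp
from ampliseed.seedext import (
    PoolRead,
    SeedResult,
    backmap,
    consensus,
    merge_pair,
    select_seed,
)


class TestConsensus:
    def test_count_weighted_majority(self):
        assert consensus([("AAA", 5), ("AAC", 1)]) == "AAA"

    def test_single_member_identity(self):
        assert consensus([("ACGT", 1)]) == "ACGT"

    def test_tie_breaks_in_base_order(self):
        # column 0 split 3:3 between C and G -> C wins (A < C < G < T)
        assert consensus([("C", 3), ("G", 3)]) == "C"

    def test_n_excluded_unless_all_n(self):
        assert consensus([("AN", 1), ("AN", 1), ("AC", 1)]) == "AC"
        assert consensus([("N", 2)]) == "N"

    def test_padding_to_longest(self):
        assert consensus([("ACGT", 2), ("AC", 1)]) == "ACGT"


class TestMergePair:
    def test_exact_four_base_overlap(self):
        r1 = make_read("AAAACCCC", 30, "R1")
        r2 = make_read(revcomp("CCCCGGGG"), 30, "R2", "r1")
        merged = merge_pair(r1, r2, min_overlap=4)
        assert merged is not None
        assert merged.sequence == "AAAACCCCGGGG"
        # agreement in the overlap doubles (capped) quality
        assert merged.qualities[4:8] == [60, 60, 60, 60]

    def test_too_many_overlap_mismatches_unmerged(self):
        # best ungapped overlap is 4 bases with 2 mismatches: 0.5 > 0.25
        r1 = make_read("AAAAACGT", 30, "R1")
        r2 = make_read(revcomp("AGCTGGGG"), 30, "R2")
        assert merge_pair(r1, r2, min_overlap=4, max_mismatch_frac=0.25) is None

    def test_conflict_keeps_higher_quality_base(self):
        # overlap GGGA vs GGGC: conflict A(Q30) vs C(Q10) -> A with Q20
        r1 = ReadRecord("r", "TTTTGGGA", [30] * 8, "R1")
        r2 = ReadRecord("r", revcomp("GGGCAAAA"), [10] * 8, "R2")
        merged = merge_pair(r1, r2, min_overlap=4, max_mismatch_frac=0.3)
        assert merged.sequence == "TTTTGGGAAAAA"
        assert merged.sequence[7] == "A"
        assert merged.qualities[7] == 20

    def test_below_min_overlap_unmerged(self):
        r1 = make_read("AAAACC", 30, "R1")
        r2 = make_read(revcomp("CCGGGG"), 30, "R2")
        assert merge_pair(r1, r2, min_overlap=10) is None

    def test_swap_symmetry(self, rng):
        """Merging (r2, r1) with re-orientation gives the reverse complement
        of merging (r1, r2)."""
        template = "".join(rng.choice(list("ACGT"), size=120))
        r1 = make_read(template[:80], 35, "R1")
        r2 = make_read(revcomp(template)[:80], 30, "R2")
        fwd = merge_pair(r1, r2, min_overlap=10)
        swapped = merge_pair(
            ReadRecord("r", r2.sequence, r2.qualities, "R1"),
            ReadRecord("r", r1.sequence, r1.qualities, "R2"),
            min_overlap=10,
        )
        assert fwd is not None and swapped is not None
        assert swapped.sequence == revcomp(fwd.sequence)


def _cluster_from_reads(reads, truncate=20):
    """Build a single cluster (with originals lookup) from R1/R2 pairs."""
    originals = {}
    members = []
    for r1, r2 in reads:
        originals[r1.read_id] = (r1, r2)
        members.append(
            UniqueSequence(r1.sequence[:truncate], {"S1": 1}, 1, [r1.read_id])
        )
    cl = Cluster("OTU_1", members[0].sequence, members)
    cl.recompute_counts()
    return cl, originals


class TestSelectSeed:
    def test_single_member_cluster_is_its_own_seed(self):
        r1 = make_read("ACGTACGTACGTACGTACGTACGT", 40, "R1", "only")
        cl, orig = _cluster_from_reads([(r1, None)])
        seed = select_seed(cl, orig)
        assert seed.read_id == "only"
        assert seed.seed_sequence == r1.sequence
        assert not seed.merged

    def test_lower_expected_error_wins_tie(self):
        seq = "ACGT" * 10
        a = make_read(seq, 33, "R1", "a")  # EE higher
        b = make_read(seq, 40, "R1", "b")
        cl, orig = _cluster_from_reads([(a, None), (b, None)])
        assert select_seed(cl, orig).read_id == "b"

    def test_recovers_planted_template(self, rng):
        """With an error-free pair present, the seed equals the template."""
        template = "".join(rng.choice(list("ACGT"), size=400))
        reads = []
        for i in range(20):
            r1_seq = list(template[:250])
            r2_seq = list(revcomp(template)[:250])
            if i > 0:  # read 0 is the pristine pair
                for seq in (r1_seq, r2_seq):
                    for pos in rng.choice(250, size=2, replace=False):
                        seq[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
            reads.append(
                (
                    ReadRecord(f"r{i:02d}", "".join(r1_seq), [38] * 250, "R1"),
                    ReadRecord(f"r{i:02d}", "".join(r2_seq), [38] * 250, "R2"),
                )
            )
        cl, orig = _cluster_from_reads(reads, truncate=200)
        seed = select_seed(cl, orig, min_overlap=10)
        assert seed.merged
        assert seed.seed_sequence == template

    def test_untraceable_cluster_errors(self):
        cl = Cluster("OTU_1", "ACGT", [UniqueSequence("ACGT", {"S": 1}, 1, ["ghost"])])
        with pytest.raises(ValueError, match="trace"):
            select_seed(cl, {})


class TestBackmap:
    SEEDS = [
        SeedResult("OTU_1", "ACGTACGTACGTACGTACGT" * 5, True),
        SeedResult("OTU_2", "TTGGCCAATTGGCCAATTGG" * 5, True),
    ]
    TOTALS = {"OTU_1": 10, "OTU_2": 3}

    def test_identical_read_maps(self):
        seed = self.SEEDS[0].seed_sequence
        inc, mapped, unmapped = backmap(
            [PoolRead("S1", seed[:60], 1, "p1")], self.SEEDS, self.TOTALS
        )
        assert inc == {("OTU_1", "S1"): 1}
        assert mapped == ["p1"] and unmapped == []

    def test_dissimilar_read_unmapped(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=80))
        assert all(
            pairwise_identity(seq, s.seed_sequence) < 97 for s in self.SEEDS
        ), "fixture must be dissimilar"
        inc, mapped, unmapped = backmap(
            [PoolRead("S1", seq, 1, "p1")], self.SEEDS, self.TOTALS
        )
        assert inc == {} and unmapped == ["p1"]

    def test_tie_goes_to_larger_cluster(self):
        seeds = [SeedResult("OTU_1", "ACGT" * 30, True), SeedResult("OTU_2", "ACGT" * 30, True)]
        inc, _, _ = backmap(
            [PoolRead("S1", "ACGT" * 15, 1, "p1")], seeds, {"OTU_1": 3, "OTU_2": 10}
        )
        assert inc == {("OTU_2", "S1"): 1}

    def test_counts_accumulate(self):
        seed = self.SEEDS[0].seed_sequence
        pool = [PoolRead("S1", seed[:40], 2, "a"), PoolRead("S1", seed[:40], 3, "b")]
        inc, mapped, _ = backmap(pool, self.SEEDS, self.TOTALS)
        assert inc == {("OTU_1", "S1"): 5}
        assert mapped == ["a", "b"]
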