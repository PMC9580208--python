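"""Demultiplexing, primer handling and the tiered filter battery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_read, pb_tail_bruteforce
from ampliseed.formats import SampleSpec
from ampliseed.qc import (
    ConfigError,
    FilterConfig,
    demultiplex,
    expected_errors,
    find_trim_primer,
    max_homopolymer_run,
    poisson_binomial_reject,
    poisson_binomial_tail,
    tier_read,
)


SPECS = [SampleSpec("S1", "ACGT"), SampleSpec("S2", "ACGA")]


class TestDemultiplex:
    def test_exact_match_removes_barcode(self):
        sid, rec = demultiplex(make_read("ACGTTTTT"), [SampleSpec("S1", "ACGT")], 0)
        assert sid == "S1"
        assert rec.sequence == "TTTT"
        assert len(rec.qualities) == 4

    def test_exact_beats_one_mismatch(self):
        sid, _ = demultiplex(make_read("ACGACCCC"), SPECS, 1)
        assert sid == "S2"

    def test_equidistant_is_unassigned(self):
        # ACGC is 1 mismatch from both barcodes
        sid, rec = demultiplex(make_read("ACGCCCCC"), SPECS, 1)
        assert sid is None
        assert rec.sequence == "ACGCCCCC"  # untouched

    def test_no_match_within_budget_unassigned(self):
        sid, _ = demultiplex(make_read("TTTTCCCC"), SPECS, 0)
        assert sid is None


class TestPrimer:
    P515F = "GTGYCAGCMGCCGCGGTAA"  # degenerate V4 forward primer

    def test_finds_and_trims_printed_primer(self):
        seq = "GTGTCAGCAGCCGCGGTAA" + "TTTTCCCC"
        assert find_trim_primer(seq, self.P515F, 0) == "TTTTCCCC"

    def test_absent_primer_not_found(self):
        assert find_trim_primer("T" * 60, self.P515F, 1) is None

    @pytest.mark.parametrize("base", ["C", "T"])
    def test_iupac_y_matches_both_pyrimidines(self, base):
        assert find_trim_primer(f"A{base}GTTTT", "AYG", 0) == "TTTT"

    def test_preceding_bases_removed_with_primer(self):
        assert find_trim_primer("NNNACGTTTT", "ACGT", 0) == "TTT"

    def test_invalid_iupac_letter_is_config_error(self):
        with pytest.raises(ConfigError):
            find_trim_primer("ACGT", "AXG", 0)


class TestExpectedErrors:
    def test_ten_q20_bases(self):
        assert expected_errors([20] * 10) == pytest.approx(0.1, abs=1e-12)

    def test_single_q0_base(self):
        assert expected_errors([0]) == pytest.approx(1.0)

    def test_mixed(self):
        assert expected_errors([10, 20, 30]) == pytest.approx(0.111, abs=1e-6)


class TestPoissonBinomial:
    def test_all_zero_probs_keep(self):
        assert poisson_binomial_tail([0.0] * 10, 2) == 0.0
        assert not poisson_binomial_reject([0.0] * 10, 2, 0.005)

    def test_two_coin_flips(self):
        # P(X > 1) with two p=0.5 bases: only the both-error outcome
        assert poisson_binomial_tail([0.5, 0.5], 1) == pytest.approx(0.25, abs=1e-12)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12),
        st.integers(min_value=0, max_value=4),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_dp_equals_enumeration(self, probs, k):
        assert poisson_binomial_tail(probs, k) == pytest.approx(
            pb_tail_bruteforce(probs, k), abs=1e-10
        )

    def test_rejects_invalid_probabilities(self):
        with pytest.raises(ValueError):
            poisson_binomial_tail([1.5], 2)


class TestTierRead:
    CFG = FilterConfig()

    def test_perfect_long_read_is_high_and_truncated(self):
        t = tier_read(make_read("ACGT" * 65, 40), self.CFG, "S1")
        assert t.tier == "HIGH"
        assert t.reject_reasons == []
        assert len(t.record) == 200

    def test_r2_is_always_mid(self):
        t = tier_read(make_read("A" * 250, 2, mate="R2"), self.CFG, "S1")
        assert t.tier == "MID"

    def test_homopolymer_is_hard_reject(self):
        t = tier_read(make_read("ACGT" * 20 + "G" * 9 + "ACGT" * 35, 40), self.CFG)
        assert t.tier == "REJECT"
        assert "homopolymer" in t.reject_reasons

    def test_low_avg_quality_is_hard_reject(self):
        t = tier_read(make_read("ACGT" * 60, 20), self.CFG)
        assert t.tier == "REJECT"
        assert "avg_quality" in t.reject_reasons

    def test_ambiguous_base_is_hard_reject(self):
        t = tier_read(make_read("ACGT" * 49 + "ACGN" + "ACGT" * 10, 40), self.CFG)
        assert t.tier == "REJECT"
        assert "ambiguous_bases" in t.reject_reasons

    def test_moderate_length_shortfall_is_mid(self):
        t = tier_read(make_read("ACGT" * 45, 40), self.CFG)  # 180 >= 0.8*200
        assert t.tier == "MID"
        assert "short_truncation" in t.reject_reasons

    def test_severe_length_shortfall_is_reject(self):
        t = tier_read(make_read("ACGT" * 30, 40), self.CFG)  # 120 < 160
        assert t.tier == "REJECT"

    def test_high_expected_errors_is_mid(self):
        # Q22 -> p=0.0063 per base, EE = 1.26 > 1.0 but avg quality fine at 27?
        # use Q27 mix: 150 bases Q40 + 50 bases Q13 -> EE = 150*1e-4+50*0.05 = 2.5
        quals = [40] * 150 + [13] * 50
        t = tier_read(make_read("ACGT" * 50, quals), self.CFG)
        assert t.tier == "MID"
        assert "expected_errors" in t.reject_reasons


def test_tier_partition_and_monotonicity(rng):
    """Every read lands in exactly one tier, and raising the expected-error
    budget can only grow the HIGH set."""
    cfg_tight = FilterConfig(max_expected_errors=0.5, pb_alpha=0.9)
    cfg_loose = FilterConfig(max_expected_errors=2.0, pb_alpha=0.9)
    reads = []
    for i in range(300):
        n = int(rng.integers(150, 260))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        # decaying quality profile typical of the platform
        quals = np.clip(40 - (np.arange(n) * rng.uniform(0, 0.12)).astype(int), 2, 41)
        reads.append(make_read(seq, list(quals), rid=f"r{i}"))
    high_tight, high_loose = set(), set()
    for r in reads:
        tier_t = tier_read(r, cfg_tight).tier
        tier_l = tier_read(r, cfg_loose).tier
        assert tier_t in ("HIGH", "MID", "REJECT")
        assert tier_l in ("HIGH", "MID", "REJECT")
        if tier_t == "HIGH":
            high_tight.add(r.read_id)
        if tier_l == "HIGH":
            high_loose.add(r.read_id)
    assert high_tight <= high_loose


def test_shorter_truncation_never_shrinks_high_set(rng):
    """With 3'-decaying qualities, truncating earlier only removes the worst
    bases, so the HIGH set can only grow."""
    cfg200 = FilterConfig(truncate_len=200)
    cfg150 = FilterConfig(truncate_len=150)
    for i in range(100):
        n = int(rng.integers(150, 260))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        quals = np.clip(40 - (np.arange(n) * 0.08).astype(int), 2, 41)
        r = make_read(seq, list(quals), rid=f"r{i}")
        if tier_read(r, cfg200).tier == "HIGH":
            assert tier_read(r, cfg150).tier == "HIGH"


def test_max_homopolymer_run():
    assert max_homopolymer_run("AACCCCGT") == 4
    assert max_homopolymer_run("") == 0


def test_filter_config_file_roundtrip(tmp_path):
    p = tmp_path / "filters.cfg"
    p.write_text("truncate_len = 150\nmax_expected_errors = 2.0\nprimer_fwd = acgt\n")
    cfg = FilterConfig.from_file(p)
    assert (cfg.truncate_len, cfg.max_expected_errors, cfg.primer_fwd) == (150, 2.0, "ACGT")
    p.write_text("not_a_param = 3\n")
    with pytest.raises(ConfigError):
        FilterConfig.from_file(p)
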