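"""Identity-gated LCA assignment, database merging and rank aggregation."""

import pandas as pd
import pytest

from conftest import lca_bruteforce
from ampliseed.formats import AbundanceMatrix
from ampliseed.taxonomy import (
    DEFAULT_MIN_COVERAGE,
    DEFAULT_RANK_THRESHOLDS,
    RANKS,
    HitRecord,
    TaxonomyPath,
    aggregate_by_rank,
    lca_assign,
    max_rank_for_identity,
    merge_databases,
    read_hit_table,
    read_lineage_table,
)

FULL = TaxonomyPath.from_names(
    ["Bacteria", "Bacillota", "Bacilli", "Lactobacillales", "Lactobacillaceae",
     "Lactobacillus", "Lactobacillus crispatus"]
)


def hit(pid, lineage=FULL, cov=1.0, db=0):
    return HitRecord("q", "s", pid, cov, lineage, db)


class TestPathInvariants:
    def test_prefix_closure_enforced(self):
        with pytest.raises(ValueError):
            TaxonomyPath(("Bacteria", "?", "Bacilli", "?", "?", "?", "?"))

    def test_from_names_pads_and_closes(self):
        p = TaxonomyPath.from_names(["Bacteria", "", "Bacilli"])
        assert p.ranks == ("Bacteria",) + ("?",) * 6
        assert p.depth() == 1

    def test_depth_and_truncate(self):
        assert FULL.depth() == 7
        assert FULL.truncate(2).ranks[:3] == ("Bacteria", "Bacillota", "?")


@pytest.mark.parametrize(
    "pid, rank",
    [(98.0, "species"), (97.0, "species"), (96.0, "genus"), (94.0, "family"),
     (91.5, "order"), (89.0, "class"), (80.0, "phylum"), (50.0, "domain")],
)
def test_max_rank_for_identity(pid, rank):
    assert max_rank_for_identity(pid) == rank


class TestLcaAssign:
    def test_single_strong_hit_gives_full_lineage(self):
        assert lca_assign([hit(99.0)]) == FULL

    def test_species_disagreement_truncates_to_genus(self):
        paths = [FULL] * 3 + [
            TaxonomyPath.from_names(list(FULL.ranks[:6]) + ["Lactobacillus iners"])
        ] * 2
        out = lca_assign([hit(99.0, p) for p in paths])
        assert out.at("genus") == "Lactobacillus"
        assert out.at("species") == "?"

    def test_identity_gate_blocks_species(self):
        out = lca_assign([hit(96.0)])
        assert out.at("species") == "?"
        assert out.at("genus") == "Lactobacillus"

    def test_low_coverage_hits_ignored(self):
        assert lca_assign([hit(99.0, cov=0.4)]) == TaxonomyPath.unclassified()

    def test_empty_hit_list_fully_unclassified(self):
        assert lca_assign([]) == TaxonomyPath.unclassified()

    def test_id_window_excludes_weak_hits(self):
        other = TaxonomyPath.from_names(
            ["Bacteria", "Pseudomonadota", "Gamma", "Ps", "Psf", "Pseudomonas", "P x"]
        )
        # the 95%-hit is outside the 1.5-point window of the 99%-hit
        out = lca_assign([hit(99.0), hit(95.0, other)])
        assert out == FULL

    def test_agrees_with_naive_oracle(self, rng):
        genera = [f"G{i}" for i in range(4)]
        for _ in range(200):
            hits = []
            for _ in range(int(rng.integers(1, 8))):
                g = genera[rng.integers(4)]
                lineage = TaxonomyPath.from_names(
                    ["Bacteria", "P", "C", "O", f"F{g}", g, f"{g} sp{rng.integers(3)}"]
                )
                hits.append(
                    hit(float(rng.uniform(75, 100)), lineage, float(rng.uniform(0.3, 1.0)))
                )
            ours = lca_assign(hits)
            oracle = lca_bruteforce(
                hits, 0.8, 1.5, DEFAULT_RANK_THRESHOLDS, DEFAULT_MIN_COVERAGE, RANKS
            )
            assert list(ours.ranks) == oracle
            # prefix closure on every emitted path
            TaxonomyPath(ours.ranks)

    def test_removing_id_window_never_deepens(self, rng):
        for _ in range(50):
            hits = [
                hit(float(rng.uniform(80, 100)),
                    FULL if rng.random() < 0.5 else TaxonomyPath.from_names(
                        ["Bacteria", "P2", "C2", "O2", "F2", "G2", "G2 s"]))
                for _ in range(int(rng.integers(1, 6)))
            ]
            assert lca_assign(hits, id_window=1e9).depth() <= lca_assign(hits).depth()


class TestMergeDatabases:
    GENUS = FULL.truncate(6)

    def test_deeper_resolution_wins(self):
        assert merge_databases([self.GENUS, FULL]) == FULL

    def test_tie_prefers_earlier_database(self):
        other = TaxonomyPath.from_names(
            ["Bacteria", "P", "C", "O", "F", "G", "G other"]
        )
        assert merge_databases([FULL, other]) == FULL

    def test_single_database(self):
        assert merge_databases([self.GENUS]) == self.GENUS


class TestAggregate:
    def setup_method(self):
        self.m = AbundanceMatrix(
            pd.DataFrame(
                [[5, 1], [2, 2], [0, 7]], index=["a", "b", "c"], columns=["S1", "S2"]
            )
        )
        g = ["Bacteria", "P", "C", "O", "F", "G1"]
        self.taxa = {
            "a": TaxonomyPath.from_names(g + ["G1 x"]),
            "b": TaxonomyPath.from_names(g + ["G1 y"]),
            "c": TaxonomyPath.unclassified(),
        }

    def test_same_genus_rows_merge(self):
        out = aggregate_by_rank(self.m, self.taxa, "genus")
        assert len(out) == 2  # G1 + unclassified pool
        genus_row = [k for k in out.index if "G1" in k][0]
        assert list(out.loc[genus_row]) == [7, 3]

    @pytest.mark.parametrize("rank", RANKS)
    def test_column_sums_preserved_at_every_rank(self, rank):
        out = aggregate_by_rank(self.m, self.taxa, rank)
        assert list(out.sum(axis=0)) == [7, 10]

    def test_domain_level_true_rows_pool(self):
        out = aggregate_by_rank(self.m, self.taxa, "domain")
        assert list(out.loc["Bacteria"]) == [7, 3]
        assert list(out.loc["?"]) == [0, 7]


def test_reference_tables_roundtrip(tmp_path):
    tax = tmp_path / "db.tax"
    tax.write_text("ref1\tBacteria;P;C;O;F;G;G s\nref2\tBacteria;P\n")
    lineages = read_lineage_table(tax)
    assert lineages["ref1"].depth() == 7
    assert lineages["ref2"].depth() == 2

    hitfile = tmp_path / "hits.tsv"
    hitfile.write_text(
        "q1\tref1\t99.0\t200\t2\t0\t1\t200\t1\t200\t1e-50\t360\n"
        "q1\tref2\t90.0\t80\t8\t0\t1\t80\t1\t80\t1e-10\t100\n"
    )
    hits = read_hit_table(hitfile, lineages, query_lengths={"q1": 200})
    assert len(hits["q1"]) == 2
    assert hits["q1"][0].query_coverage == 1.0
    assert hits["q1"][1].query_coverage == pytest.approx(0.4)
    # the low-coverage weak hit is filtered, leaving the species-level call
    assert lca_assign(hits["q1"]).depth() == 7
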