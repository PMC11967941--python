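"""Gene-set operations, z-score screen, synthetic data generator."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from provflow.canonical import canonical_json
from provflow.fixtures.genesets import (
    GeneSet,
    GeneSetLibrary,
    GMTParseError,
    combine_sets,
    overlap_regions,
    parse_gmt,
    ranked_to_set,
    write_gmt,
)
from provflow.fixtures.screen import (
    CountMatrix,
    parse_counts_tsv,
    synth_counts,
    write_counts_tsv,
    zscore_screen,
)
from provflow.fixtures.views import tissue_bar_view


def _sets(*gene_lists):
    return [GeneSet(f"s{i}", tuple(g)) for i, g in enumerate(gene_lists)]


class TestGMT:
    def test_parse_simple_line(self):
        lib = parse_gmt("s1\td\tTP53\tEGFR\n")
        assert len(lib) == 1
        assert lib.sets()[0].as_set == {"TP53", "EGFR"}

    def test_duplicate_genes_collapse(self):
        lib = parse_gmt("s1\td\tTP53\tTP53\n")
        assert len(lib.sets()[0]) == 1

    def test_too_few_fields_cites_line_number(self):
        with pytest.raises(GMTParseError, match="line 1"):
            parse_gmt("s1\td\n")

    def test_blank_gene_fields_dropped_and_symbols_uppercased(self):
        lib = parse_gmt("s1\td\ttp53\t\tegfr\t\n")
        assert lib.sets()[0].genes == ("TP53", "EGFR")

    def test_round_trip_stable_after_normalization(self):
        text = "s1\tdesc\ttp53\tEGFR\ttp53\ns2\t\tMYC\n"
        once = write_gmt(parse_gmt(text))
        assert write_gmt(parse_gmt(once)) == once

    def test_duplicate_terms_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            parse_gmt("s1\td\tA\ns1\td\tB\n")


class TestCombine:
    def test_consensus_k2_hand_example(self):
        # {A,B},{B,C},{B,D}: only B occurs in ≥2 sets
        sets = _sets("AB", "BC", "BD")
        assert combine_sets(sets, "consensus", k=2).as_set == {"B"}

    def test_union_collects_everything(self):
        sets = _sets("AB", "BC", "BD")
        assert combine_sets(sets, "union").as_set == {"A", "B", "C", "D"}

    def test_consensus_beyond_set_count_is_empty(self):
        assert combine_sets(_sets("AB", "BC", "BD"), "consensus", k=4).as_set == set()

    def test_consensus_k1_equals_union(self):
        sets = _sets("ABC", "CD")
        assert combine_sets(sets, "consensus", k=1).as_set == combine_sets(sets, "union").as_set

    def test_default_consensus_is_majority(self):
        # 3 sets -> k = 2
        sets = _sets("AB", "BC", "BD")
        assert combine_sets(sets, "consensus").as_set == {"B"}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            combine_sets([], "union")

    @settings(max_examples=60, derandomize=True)
    @given(
        st.lists(
            st.sets(st.sampled_from("ABCDEFGH"), min_size=0, max_size=8),
            min_size=1, max_size=6,
        ),
        st.integers(min_value=1, max_value=6),
    )
    def test_consensus_antitone_in_k(self, gene_lists, k):
        sets = [GeneSet(f"s{i}", tuple(sorted(g))) for i, g in enumerate(gene_lists)]
        tighter = combine_sets(sets, "consensus", k=k + 1).as_set
        looser = combine_sets(sets, "consensus", k=k).as_set
        assert tighter <= looser


class TestRankedToSet:
    def test_top_n_by_score(self):
        scores = [("G1", 3.0), ("G2", 2.0), ("G3", 1.0)]
        assert ranked_to_set(scores, 2).as_set == {"G1", "G2"}

    def test_boundary_tie_broken_lexicographically(self):
        scores = [("G1", 3.0), ("G3", 2.0), ("G2", 2.0)]
        assert ranked_to_set(scores, 2).as_set == {"G1", "G2"}

    def test_zero_cutoff_empty_and_oversized_cutoff_everything(self):
        scores = [("G1", 3.0), ("G2", 2.0)]
        assert ranked_to_set(scores, 0).as_set == set()
        assert ranked_to_set(scores, 10).as_set == {"G1", "G2"}


class TestOverlapRegions:
    def test_two_set_hand_example(self):
        lib = GeneSetLibrary((
            ("A", "", GeneSet("A", ("g1", "g2"))),
            ("B", "", GeneSet("B", ("g2", "g3"))),
        ))
        viz = overlap_regions(lib)
        regions = {tuple(r["sets"]): r["count"] for r in viz["data"]}
        assert regions == {("A",): 1, ("B",): 1, ("A", "B"): 1}
        assert sum(regions.values()) == viz["union_size"] == 3

    def test_single_set_single_region(self):
        lib = GeneSetLibrary((("A", "", GeneSet("A", tuple("VWXYZ"))),))
        viz = overlap_regions(lib)
        assert viz["data"] == [{"sets": ["A"], "count": 5}]

    def test_disjoint_sets_have_no_joint_region(self):
        lib = GeneSetLibrary((
            ("A", "", GeneSet("A", ("g1",))),
            ("B", "", GeneSet("B", ("g2",))),
        ))
        patterns = {tuple(r["sets"]) for r in overlap_regions(lib)["data"]}
        assert ("A", "B") not in patterns

    def test_refuses_more_than_sixteen_sets(self):
        lib = GeneSetLibrary(tuple(
            (f"s{i}", "", GeneSet(f"s{i}", (f"g{i}",))) for i in range(17)
        ))
        with pytest.raises(ValueError, match="16"):
            overlap_regions(lib)

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(
        st.sets(st.sampled_from("ABCDEFGHIJ"), min_size=0, max_size=10),
        min_size=1, max_size=5,
    ))
    def test_region_counts_sum_to_union_size(self, gene_lists):
        lib = GeneSetLibrary(tuple(
            (f"s{i}", "", GeneSet(f"s{i}", tuple(sorted(g))))
            for i, g in enumerate(gene_lists)
        ))
        viz = overlap_regions(lib)
        union = set().union(*(s.as_set for s in lib.sets()))
        assert sum(r["count"] for r in viz["data"]) == len(union)
        assert len(viz["data"]) <= 2 ** len(gene_lists) - 1


class TestZScoreScreen:
    def _matrix(self, rows, case, background):
        import pandas as pd
        df = pd.DataFrame(rows, index=[f"G{i}" for i in range(len(rows))],
                          columns=case + background)
        return CountMatrix(df)

    def test_equal_means_give_zero(self):
        m = self._matrix([[2, 2, 1, 2, 3]], ["c0", "c1"], ["b0", "b1", "b2"])
        scores = dict(zscore_screen(m, ["c0", "c1"], ["b0", "b1", "b2"]))
        assert scores["G0"] == 0.0

    def test_zero_background_variance_is_infinite(self):
        # constant background [2,2,2], case mean 10 -> +inf; mirrored -> -inf
        m = self._matrix([[10, 2, 2, 2], [0, 2, 2, 2], [2, 2, 2, 2]],
                         ["c0"], ["b0", "b1", "b2"])
        scores = dict(zscore_screen(m, ["c0"], ["b0", "b1", "b2"]))
        assert scores["G0"] == math.inf
        assert scores["G1"] == -math.inf
        assert scores["G2"] == 0.0

    def test_hand_computed_z_of_two(self):
        # case mean 4, background [1,2,3]: mean 2, sample sd (ddof=1) = 1 -> z = 2
        m = self._matrix([[4, 4, 1, 2, 3]], ["c0", "c1"], ["b0", "b1", "b2"])
        scores = dict(zscore_screen(m, ["c0", "c1"], ["b0", "b1", "b2"]))
        assert scores["G0"] == pytest.approx(2.0)

    def test_infinite_scores_rank_above_finite(self):
        m = self._matrix([[4, 1, 2, 3], [9, 2, 2, 2]], ["c0"], ["b0", "b1", "b2"])
        ranked = zscore_screen(m, ["c0"], ["b0", "b1", "b2"])
        assert ranked[0] == ("G1", math.inf)

    def test_background_permutation_invariant(self):
        m = self._matrix([[5, 1, 2, 3, 4]], ["c0"], ["b0", "b1", "b2", "b3"])
        fwd = zscore_screen(m, ["c0"], ["b0", "b1", "b2", "b3"])
        rev = zscore_screen(m, ["c0"], ["b3", "b1", "b0", "b2"])
        assert fwd == rev

    def test_gene_relabeling_equivariant(self):
        import pandas as pd
        rows = [[7, 1, 2, 3], [4, 2, 2, 2]]
        m1 = CountMatrix(pd.DataFrame(rows, index=["AAA", "BBB"],
                                      columns=["c0", "b0", "b1", "b2"]))
        m2 = CountMatrix(pd.DataFrame(rows, index=["XXX", "YYY"],
                                      columns=["c0", "b0", "b1", "b2"]))
        s1 = dict(zscore_screen(m1, ["c0"], ["b0", "b1", "b2"]))
        s2 = dict(zscore_screen(m2, ["c0"], ["b0", "b1", "b2"]))
        assert s1["AAA"] == s2["XXX"] and s1["BBB"] == s2["YYY"]

    def test_preconditions_enforced(self):
        m = self._matrix([[1, 1, 1]], ["c0"], ["b0", "b1"])
        with pytest.raises(ValueError, match="non-empty"):
            zscore_screen(m, [], ["b0", "b1"])
        with pytest.raises(ValueError, match="disjoint"):
            zscore_screen(m, ["b0"], ["b0", "b1"])
        with pytest.raises(ValueError, match="unknown"):
            zscore_screen(m, ["c0"], ["b0", "nope"])


class TestSynthCounts:
    def test_same_seed_identical_matrices(self):
        a = synth_counts(11, 30, 3, 5, [(2, 10.0)])
        b = synth_counts(11, 30, 3, 5, [(2, 10.0)])
        assert a.counts.equals(b.counts)

    def test_shape_and_labels(self):
        m = synth_counts(1, n_genes=12, n_case=3, n_background=4)
        assert m.counts.shape == (12, 7)
        assert len(m.samples_with_label("case")) == 3
        assert len(m.samples_with_label("background")) == 4

    def test_planted_fold50_gene_ranks_first(self):
        m = synth_counts(5, n_genes=100, n_case=5, n_background=8,
                         planted=[(7, 50.0)])
        ranked = zscore_screen(m, m.samples_with_label("case"),
                               m.samples_with_label("background"))
        assert ranked[0][0] == "G007"

    def test_recovery_rate_across_seeds(self):
        """The fold-50 planted gene attains rank 1 in ≥19/20 seeded runs."""
        hits = 0
        for seed in range(20):
            m = synth_counts(seed, n_genes=100, n_case=5, n_background=8,
                             planted=[(3, 50.0)])
            ranked = zscore_screen(m, m.samples_with_label("case"),
                                   m.samples_with_label("background"))
            hits += ranked[0][0] == "G003"
        assert hits >= 19

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            synth_counts(0, n_genes=0)
        with pytest.raises(ValueError):
            synth_counts(0, planted=[(999, 2.0)])

    def test_tsv_round_trip(self):
        m = synth_counts(3, n_genes=8, n_case=2, n_background=3)
        again = parse_counts_tsv(write_counts_tsv(m))
        assert again.counts.equals(m.counts)
        assert dict(again.sample_labels) == dict(m.sample_labels)


class TestBarView:
    def test_bars_preserve_order_and_values(self):
        viz = tissue_bar_view([("liver", 3.0), ("lung", 1.5), ("heart", 2.0)])
        assert viz["labels"] == ["liver", "lung", "heart"]
        assert viz["data"] == [3.0, 1.5, 2.0]

    def test_values_survive_canonical_json(self):
        import json
        viz = tissue_bar_view([("a", 1.25), ("b", -0.5)])
        assert json.loads(canonical_json(dict(viz))) == dict(viz)

    def test_infinite_scores_kept_with_explicit_marker(self):
        import json
        viz = tissue_bar_view([("top", math.inf), ("bottom", -math.inf)])
        parsed = json.loads(canonical_json(dict(viz)))
        assert parsed["data"] == ["inf", "-inf"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            tissue_bar_view([])
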