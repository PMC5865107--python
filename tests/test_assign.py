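import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pollinet.assign import (
    AssignmentRule,
    CurationMap,
    CurationRule,
    apply_curation,
    assign_reads,
    consensus_assign,
    length_filter,
    select_top_hits,
    tally,
)


def make_hits(subjects, scores=None, query="q1"):
    scores = scores if scores is not None else [100.0] * len(subjects)
    return pd.DataFrame({
        "qseqid": query, "sseqid": subjects,
        "bitscore": [float(s) for s in scores],
    })


class TestRuleValidation:
    @pytest.mark.parametrize("kwargs", [
        {"top_k": 0}, {"genus_fraction": 0.0}, {"genus_fraction": 1.2},
        {"min_length_exclusive": -1},
    ])
    def test_invalid_thresholds_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AssignmentRule(**kwargs)


class TestLengthFilter:
    def test_boundary_is_strictly_greater_than_450(self):
        reads = [("keep", "A" * 451), ("drop", "A" * 450), ("short", "A" * 10)]
        kept = length_filter(reads)
        assert [r[0] for r in kept] == ["keep"]

    def test_empty_input_gives_empty_output(self):
        assert length_filter([]) == []


class TestSelectTopHits:
    def test_twenty_five_distinct_scores_keep_twenty_best(self):
        hits = make_hits([f"r{i}" for i in range(25)], scores=range(25))
        top = select_top_hits(hits)
        assert len(top) == 20
        assert top["bitscore"].min() == 5.0

    def test_all_tied_scores_are_all_retained(self):
        hits = make_hits([f"r{i}" for i in range(30)])
        assert len(select_top_hits(hits)) == 30

    def test_fewer_hits_than_top_k_all_retained(self):
        hits = make_hits(["r1", "r2", "r3"], scores=[9, 8, 7])
        assert len(select_top_hits(hits)) == 3

    def test_ties_at_the_cutoff_level_are_included(self):
        hits = make_hits(["a", "b", "c", "d"], scores=[10, 5, 5, 1])
        top = select_top_hits(hits, AssignmentRule(top_k=2))
        assert set(top["sseqid"]) == {"a", "b", "c"}


class TestConsensus:
    def test_unanimous_species_assigns_species(self, tiny_taxonomy):
        hits = make_hits(["ref0"] * 20)
        out = consensus_assign(hits, tiny_taxonomy)
        assert (out["rank"], out["label"]) == ("species", "Alpha una")

    def test_sixty_percent_genus_boundary_assigns_genus(self, tiny_taxonomy):
        # 12/20 hits in genus Alpha (exactly 60%), 8 spread elsewhere
        hits = make_hits(["ref0"] * 6 + ["ref1"] * 6 + ["ref2"] * 4
                         + ["ref4"] * 2 + ["ref5"] * 2)
        out = consensus_assign(hits, tiny_taxonomy)
        assert (out["rank"], out["label"]) == ("genus", "Alpha")

    def test_fifty_five_percent_falls_to_various(self, tiny_taxonomy):
        hits = make_hits(["ref0"] * 6 + ["ref1"] * 5 + ["ref2"] * 5
                         + ["ref4"] * 2 + ["ref5"] * 2)
        out = consensus_assign(hits, tiny_taxonomy)
        assert (out["rank"], out["label"]) == ("various", "various")

    def test_signature_lists_sorted_distinct_families(self, tiny_taxonomy):
        hits = make_hits(["ref0", "ref4", "ref5", "ref4"])
        assert consensus_assign(hits, tiny_taxonomy)["signature"] == "F1;F2"

    def test_unknown_subject_id_is_a_hard_error(self, tiny_taxonomy):
        with pytest.raises(ValueError, match="refX"):
            consensus_assign(make_hits(["refX"]), tiny_taxonomy)

    def test_zero_hit_reads_become_unknown(self, tiny_taxonomy):
        out = assign_reads(make_hits(["ref0"], query="q1"), tiny_taxonomy,
                           query_ids=["q1", "q2"])
        by_query = out.set_index("query_id")
        assert by_query.loc["q2", "rank"] == "unknown"
        assert by_query.loc["q2", "reason"] == "zero_hits"

    def test_tied_qualifying_genera_fall_to_various(self, tiny_taxonomy):
        # 50%/50% split qualifies both genera at threshold 0.5
        hits = make_hits(["ref0", "ref0", "ref4", "ref4"])
        out = consensus_assign(hits, tiny_taxonomy,
                               AssignmentRule(genus_fraction=0.5))
        assert out["rank"] == "various"


@st.composite
def hit_tables(draw):
    n_queries = draw(st.integers(1, 3))
    rows = []
    for q in range(n_queries):
        for _ in range(draw(st.integers(1, 8))):
            rows.append({
                "qseqid": f"q{q}",
                "sseqid": f"ref{draw(st.integers(0, 5))}",
                "bitscore": float(draw(st.integers(1, 5)) * 10),
            })
    return pd.DataFrame(rows)


class TestBulkEquivalenceAndOrderInvariance:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(table=hit_tables(), top_k=st.integers(1, 4),
           fraction=st.sampled_from([0.4, 0.5, 0.6, 1.0]))
    def test_bulk_path_matches_per_query_consensus(self, tiny_taxonomy, table,
                                                   top_k, fraction):
        rule = AssignmentRule(top_k=top_k, genus_fraction=fraction)
        bulk = assign_reads(table, tiny_taxonomy, rule).set_index("query_id")
        for _, group in table.groupby("qseqid"):
            ref = consensus_assign(group, tiny_taxonomy, rule)
            row = bulk.loc[ref["query_id"]]
            assert row["label"] == ref["label"]
            assert row["rank"] == ref["rank"]
            assert row["signature"] == ref["signature"]
            assert row["n_hits_considered"] == ref["n_hits_considered"]

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(table=hit_tables(), seed=st.integers(0, 100))
    def test_assignments_invariant_to_hit_row_order(self, tiny_taxonomy,
                                                    table, seed):
        shuffled = table.sample(frac=1.0, random_state=seed).reset_index(drop=True)
        a = assign_reads(table, tiny_taxonomy)
        b = assign_reads(shuffled, tiny_taxonomy)
        pd.testing.assert_frame_equal(a, b)


class TestCuration:
    def base_assignments(self):
        return pd.DataFrame({
            "query_id": ["q1", "q2", "q3"],
            "label": ["various", "various", "Alpha una"],
            "rank": ["various", "various", "species"],
            "n_hits_considered": [4, 4, 20],
            "signature": ["F2", "F1;F2", "F1"],
            "reason": ["", "", ""],
        })

    def test_signature_rule_resolves_to_family(self, tiny_taxonomy):
        cmap = CurationMap([CurationRule("signature", "F2", "family", "F2")])
        out, audit = apply_curation(self.base_assignments(), cmap, tiny_taxonomy)
        row = out.set_index("query_id").loc["q1"]
        assert (row["rank"], row["label"]) == ("family", "F2")
        assert audit.set_index("query_id").loc["q1", "reason"] == "curated"

    def test_unmatched_various_falls_through_to_unknown(self, tiny_taxonomy):
        out, audit = apply_curation(self.base_assignments(), CurationMap([]),
                                    tiny_taxonomy)
        q2 = out.set_index("query_id").loc["q2"]
        assert (q2["rank"], q2["label"]) == ("unknown", "unknown")
        assert (audit["reason"] == "curation_fallthrough").all()

    def test_species_assignment_passes_through_unchanged(self, tiny_taxonomy):
        out, _ = apply_curation(self.base_assignments(), CurationMap([]),
                                tiny_taxonomy)
        q3 = out.set_index("query_id").loc["q3"]
        assert (q3["rank"], q3["label"]) == ("species", "Alpha una")

    def test_rule_naming_unknown_family_is_an_error(self, tiny_taxonomy):
        cmap = CurationMap([CurationRule("signature", "F2", "family", "Nope")])
        with pytest.raises(ValueError, match="Nope"):
            apply_curation(self.base_assignments(), cmap, tiny_taxonomy)

    def test_tribe_rule_checked_against_taxonomy(self, tiny_taxonomy):
        good = CurationMap([CurationRule("query", "q1", "tribe", "T2")])
        out, _ = apply_curation(self.base_assignments(), good, tiny_taxonomy)
        assert out.set_index("query_id").loc["q1", "rank"] == "tribe"


class TestTally:
    def insects(self):
        return pd.DataFrame({
            "pollinator_species": ["Hov a", "Hov b"],
            "genus": ["Hov", "Hov"],
            "site": ["S1", "S1"],
        }, index=["i1", "i2"])

    def assignments(self):
        return pd.DataFrame({
            "query_id": ["i1|r1", "i1|r2", "i1|r3", "i2|r1", "i2|r2"],
            "label": ["Alpha una", "Alpha una", "unknown", "Beta una", "Alpha una"],
            "rank": ["species", "species", "unknown", "species", "species"],
            "n_hits_considered": [1, 1, 0, 1, 1],
            "signature": [""] * 5,
            "reason": [""] * 5,
        })

    def test_row_sums_conserve_reads_and_unknown_column_exists(self):
        pcm = tally(self.assignments(), self.insects())
        assert pcm.counts.loc["i1"].sum() == 3
        assert pcm.counts.loc["i2"].sum() == 2
        assert pcm.counts.loc["i1", "unknown"] == 1
        assert pcm.ranks["unknown"] == "unknown"

    def test_shuffled_assignment_order_gives_identical_matrix(self):
        a = tally(self.assignments(), self.insects())
        shuffled = self.assignments().sample(frac=1.0, random_state=1)
        b = tally(shuffled, self.insects())
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_orphan_reads_are_listed_in_error(self):
        bad = self.assignments()
        bad.loc[0, "query_id"] = "ghost|r1"
        with pytest.raises(ValueError, match="ghost"):
            tally(bad, self.insects())

    def test_explicit_read_to_insect_mapping(self):
        mapping = {q: "i1" for q in self.assignments()["query_id"]}
        pcm = tally(self.assignments(), self.insects(), query_to_insect=mapping)
        assert pcm.counts.loc["i1"].sum() == 5
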