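"""The BLAST identification ladder, optimized score and consensus."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from ethnoquant.barcode import (
    AprioriEvidence,
    integrate_identification,
    marker_summary,
    optimized_call,
    optimized_score,
    score_window,
    simple_call,
)
from ethnoquant.io import BlastHit


def hit(species, score, cover=100.0, identity=99.0, marker="ITS", genus="", family=""):
    return BlastHit(
        query_id="q1", marker=marker, subject_species=species,
        max_score=score, query_cover=cover, percent_identity=identity,
        subject_genus=genus, subject_family=family,
    )


class TestScoreWindow:
    def test_boundary_inclusive_at_exactly_minus_delta(self):
        hits = [hit("A a", 500), hit("B b", 496), hit("C c", 495), hit("D d", 494.9)]
        window = score_window(hits, delta=5)
        assert [h.max_score for h in window] == [500, 496, 495]

    def test_single_hit(self):
        h = hit("A a", 321)
        assert score_window([h], 5) == [h]

    def test_all_equal_scores_all_retained(self):
        hits = [hit(f"S s{i}", 400) for i in range(4)]
        assert len(score_window(hits, 5)) == 4

    def test_empty_hits_empty_window(self):
        assert score_window([], 5) == []

    @given(
        st.lists(st.floats(1, 1000), min_size=1, max_size=20),
        st.floats(0.5, 50),
    )
    @settings(max_examples=80, deadline=None)
    def test_equals_brute_force_threshold_filter(self, scores, delta):
        hits = [hit(f"S s{i}", s) for i, s in enumerate(scores)]
        window = score_window(hits, delta)
        expected = {h for h in hits if h.max_score >= max(scores) - delta}
        assert set(window) == expected


class TestSimpleCall:
    def test_single_species_window(self):
        window = [hit("Jatropha curcas", 500), hit("Jatropha curcas", 498)]
        assert simple_call(window) == ("species", frozenset({"Jatropha curcas"}))

    def test_congeneric_window_goes_to_genus(self):
        window = [hit("Premna serratifolia", 500), hit("Premna odorata", 497)]
        assert simple_call(window) == ("genus", frozenset({"Premna"}))

    def test_confamilial_window_goes_to_family(self):
        window = [
            hit("Homalanthus nutans", 500, family="Euphorbiaceae"),
            hit("Triadica sebifera", 498, family="Euphorbiaceae"),
        ]
        assert simple_call(window) == ("family", frozenset({"Euphorbiaceae"}))

    def test_cross_family_window_is_ambiguous(self):
        window = [
            hit("Waltheria indica", 500, family="Malvaceae"),
            hit("Ipomoea setifera", 499, family="Convolvulaceae"),
        ]
        rank, taxa = simple_call(window)
        assert rank == "ambiguous"
        assert taxa == frozenset({"Malvaceae", "Convolvulaceae"})

    def test_synonyms_merge_before_species_test(self):
        syn = {"Solenostemon scutellarioides": "Coleus scutellarioides"}
        window = [hit("Coleus scutellarioides", 500), hit("Solenostemon scutellarioides", 499)]
        assert simple_call(window, synonyms=syn)[0] == "species"

    def test_empty_window_indeterminate(self):
        assert simple_call([]) == ("indeterminate", frozenset())

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_rank_monotone_under_added_hits(self, data):
        """Adding a hit can only keep or coarsen the rank, never refine it."""
        taxa = [
            ("Ficus septica", "Ficus", "Moraceae"),
            ("Ficus concinna", "Ficus", "Moraceae"),
            ("Artocarpus altilis", "Artocarpus", "Moraceae"),
            ("Vitex negundo", "Vitex", "Lamiaceae"),
        ]
        base = data.draw(st.lists(st.sampled_from(taxa), min_size=1, max_size=4))
        extra = data.draw(st.sampled_from(taxa))
        order = ["species", "genus", "family", "ambiguous"]
        mk = lambda lst: [hit(s, 500, genus=g, family=f) for s, g, f in lst]
        before = order.index(simple_call(mk(base))[0])
        after = order.index(simple_call(mk(base + [extra]))[0])
        assert after >= before


class TestOptimizedScore:
    def test_unit_ratio(self):
        assert optimized_score(hit("A a", 500, cover=100, identity=100)) == pytest.approx(500)

    def test_arithmetic(self):
        assert optimized_score(hit("A a", 480, cover=98, identity=96)) == pytest.approx(490.0)

    def test_zero_cover_gives_zero(self):
        assert optimized_score(hit("A a", 480, cover=0, identity=96)) == 0.0


class TestOptimizedCall:
    def test_lower_scoring_hit_with_better_ratio_wins(self):
        hits = [
            hit("A a", 500, cover=90, identity=100),
            hit("B b", 499, cover=99, identity=97),   # optimized 509.3, the winner
            hit("C c", 498, cover=91, identity=99),
            hit("D d", 497, cover=90, identity=99),
            hit("E e", 496, cover=90, identity=99),
        ]
        winner = optimized_call(hits)
        assert winner.subject_species == "B b"
        # independent enumeration over the same pool
        assert winner == max(hits, key=lambda h: (optimized_score(h), h.max_score, h.percent_identity))

    def test_only_five_best_distinct_taxa_considered(self):
        hits = [hit(f"S s{i}", 500 - i, cover=90, identity=99) for i in range(6)]
        hits.append(hit("S s5", 300, cover=100, identity=90))  # huge ratio, outside top 5
        winner = optimized_call(hits)
        assert winner.subject_species != "S s5"

    def test_duplicate_taxa_collapsed_to_best_row(self):
        hits = [
            hit("A a", 500, cover=95, identity=99),
            hit("A a", 499, cover=99, identity=95),  # same taxon, lower score
            hit("B b", 498, cover=90, identity=99),
        ]
        pool_winner = optimized_call(hits)
        assert pool_winner.max_score == 500  # the kept row per taxon is its best by score

    def test_single_hit_is_its_own_winner(self):
        h = hit("A a", 400)
        assert optimized_call([h]) == h

    def test_all_equal_metrics_ties_to_score_order(self):
        hits = [hit("A a", 400, cover=95, identity=99), hit("B b", 400, cover=95, identity=99)]
        assert optimized_call(hits).subject_species == "A a"

    def test_needs_a_hit(self):
        with pytest.raises(ValueError):
            optimized_call([])


class TestMarkerSummary:
    def test_congeneric_fixture_gives_genus_call(self):
        # the pattern of an ITS window holding several congeners
        hits = [
            hit("Cinnamomum paiei", 900),
            hit("Cinnamomum reticulatum", 898),
            hit("Cinnamomum verum", 896),
            hit("Vitex negundo", 700, family="Lamiaceae"),
        ]
        mc = marker_summary(hits, "ITS")
        assert mc.rank == "genus" and mc.taxa == frozenset({"Cinnamomum"})
        assert mc.best_by_score.max_score == 900
        assert mc.optimized_best is not None

    def test_empty_hits_give_indeterminate_none_note(self):
        mc = marker_summary([], "matK")
        assert mc.rank == "indeterminate"
        assert "NONE" in mc.note
        assert mc.window == ()

    def test_single_hit_species_call(self):
        mc = marker_summary([hit("Premna odorata", 512)], "trnL-F")
        assert mc.rank == "species"
        assert mc.taxa == frozenset({"Premna odorata"})


class TestIntegration:
    def markers_for(self, taxa_by_marker):
        calls = []
        for marker, species_list in taxa_by_marker.items():
            hits = [hit(s, 900 - i, marker=marker) for i, s in enumerate(species_list)]
            calls.append(marker_summary(hits, marker))
        return calls

    def test_species_consensus_with_morphology_and_allow_list(self):
        # three markers agree on the species; morphology is a tentative match;
        # the occurrence allow-list contains it (under its accepted spelling)
        syn = {"Jatropha gossypiifolia": "Jatropha gossypifolia"}
        calls = self.markers_for({
            "ITS": ["Jatropha gossypiifolia", "Jatropha gossypiifolia"],
            "psbA-trnH": ["Jatropha gossypiifolia"],
            "trnL-F": ["Jatropha gossypiifolia"],
        })
        apriori = AprioriEvidence(
            local_name="Tuba-tuba (tapol)",
            dictionary_putative=("Jatropha curcas", "Jatropha gossypiifolia"),
            morphology_determination="Jatropha cf. gossypiifolia",
            morphology_rank="cf.",
        )
        call = integrate_identification(
            calls, apriori, allow_list=["Jatropha gossypifolia", "Jatropha curcas"], synonyms=syn
        )
        assert call.final_rank == "species"
        assert call.final_taxon == "Jatropha gossypifolia"

    def test_split_genera_with_genus_morphology_demotes_to_genus(self):
        # markers disagree across related genera; morphology says the genus
        calls = self.markers_for({
            "ITS": ["Bauhinia touranensis", "Bauhinia kockiana"],
            "psbA-trnH": ["Lasiobema championii"],
            "trnL-F": ["Phanera bidentata"],
        })
        apriori = AprioriEvidence(
            local_name="Talimughat 3",
            morphology_determination="Bauhinia sp.",
            morphology_rank="genus",
        )
        call = integrate_identification(calls, apriori)
        assert call.final_rank == "genus"
        assert call.final_taxon == "Bauhinia"

    def test_ambiguous_congeners_without_apriori_give_genus(self):
        calls = self.markers_for({
            "ITS": ["Ficus glabella", "Ficus ingens"],
            "psbA-trnH": ["Ficus carica", "Ficus simplicissima"],
            "trnL-F": ["Ficus pumila"],
        })
        call = integrate_identification(calls, apriori=None)
        assert call.final_rank == "genus"
        assert call.final_taxon == "Ficus"

    def test_allow_list_blocks_unrecorded_species(self):
        calls = self.markers_for({"ITS": ["Ficus carica"], "matK": ["Ficus carica"]})
        call = integrate_identification(calls, allow_list=["Ficus septica", "Ficus concinna"])
        assert call.final_rank == "genus"  # species candidate removed, genus survives
        assert call.final_taxon == "Ficus"

    def test_no_evidence_is_an_error(self):
        with pytest.raises(ValueError):
            integrate_identification([], apriori=None)

    def test_deterministic_provenance(self):
        calls = self.markers_for({"ITS": ["Premna odorata", "Premna serratifolia"]})
        apriori = AprioriEvidence(local_name="Abgaw", dictionary_putative=("Premna odorata",))
        a = integrate_identification(calls, apriori)
        b = integrate_identification(calls, apriori)
        assert a == b
        assert a.provenance == b.provenance
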