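import numpy as np
import pytest

from varpanel.association import (
    PairStatus,
    assign_disease,
    baseline_assign,
    collect_closest_diseases,
    link_variant_gene,
    load_resolver_table,
    resolve_coordinates,
    score_candidate,
    sentiment_polarity,
    token_distance,
)
from varpanel.corpus_io import EntityClass
from varpanel.ner import dictionary_match, find_variant_mentions, normalize_variant

from conftest import make_doc


def mentions_for(doc, genes=(), diseases=()):
    vms = find_variant_mentions(doc)
    gms = dictionary_match(doc, {g: g for g in genes}, EntityClass.GENE) if genes else []
    dms = (
        dictionary_match(doc, {d: d.upper() for d in diseases}, EntityClass.DISEASE)
        if diseases
        else []
    )
    return vms, gms, dms


def oracle_token_distance(doc, loc_a, loc_b):
    """Count document tokens lying strictly between two spans by character
    position — independent of the token-index arithmetic under test."""
    lo = min(loc_a.char_end, loc_b.char_end)
    hi = max(loc_a.char_start, loc_b.char_start)
    return sum(1 for t in doc.tokens if t.char_start >= lo and t.char_end <= hi)


class TestLinkVariantGene:
    def test_single_pair_same_sentence(self):
        doc = make_doc("The A123V mutation in TP53 was studied.")
        vms, gms, _ = mentions_for(doc, genes=["TP53"])
        result = link_variant_gene(doc, vms, gms)
        (pair,) = result.pairs
        assert pair.gene == "TP53" and pair.variant.canonical == "p.A123V"

    def test_same_sentence_beats_closer_other_paragraph(self):
        """A gene twelve tokens away in the variant's sentence outranks a
        gene three tokens away in another paragraph."""
        doc = make_doc(
            "GENEA one two three four five six seven eight nine ten eleven A123V here.\n\n"
            "Nearby words GENEB."
        )
        vms, gms, _ = mentions_for(doc, genes=["GENEA", "GENEB"])
        result = link_variant_gene(doc, vms, gms)
        (pair,) = result.pairs
        assert pair.gene == "GENEA"
        # brute-force confirmation under the sentence > paragraph > document priority
        v = vms[0]
        def tier(g):
            same_par = g.location.paragraph_index == v.location.paragraph_index
            same_sent = same_par and g.location.sentence_index == v.location.sentence_index
            return 0 if same_sent else (1 if same_par else 2)
        best = min(gms, key=lambda g: (tier(g), oracle_token_distance(doc, v.location, g.location)))
        assert best.normalized_id == pair.gene

    def test_tie_prefers_preceding_gene(self):
        doc = make_doc("GENEA binds A123V binds GENEB today.")
        vms, gms, _ = mentions_for(doc, genes=["GENEA", "GENEB"])
        (pair,) = link_variant_gene(doc, vms, gms).pairs
        assert pair.gene == "GENEA"

    def test_no_gene_mentions_reported_unpaired(self):
        doc = make_doc("Only the A123V variant appears here.")
        vms, _, _ = mentions_for(doc)
        result = link_variant_gene(doc, vms, [])
        assert result.pairs == [] and len(result.unpaired) == 1


class TestResolveCoordinates:
    def make_pairs(self):
        doc = make_doc("The A123V mutation in TP53 was studied.")
        vms, gms, _ = mentions_for(doc, genes=["TP53"])
        return link_variant_gene(doc, vms, gms).pairs

    def test_pair_in_table_resolved(self, tmp_path):
        table = tmp_path / "resolver.tsv"
        table.write_text("TP53\tp.A123V\t17\t7579472\tG\tC\n")
        resolver = load_resolver_table(table)
        (pair,) = resolve_coordinates(self.make_pairs(), resolver)
        assert pair.status is PairStatus.RESOLVED
        assert pair.coordinates.pos == 7579472

    def test_absent_pair_unresolved(self):
        (pair,) = resolve_coordinates(self.make_pairs(), {})
        assert pair.status is PairStatus.UNRESOLVED and pair.coordinates is None

    def test_malformed_row_rejected_at_load(self, tmp_path):
        table = tmp_path / "resolver.tsv"
        table.write_text("TP53\tp.A123V\t17\tnot_a_position\tG\tC\n")
        with pytest.raises(ValueError, match="resolver.tsv:1"):
            load_resolver_table(table)


class TestCollectClosestDiseases:
    def test_single_occurrence_single_disease(self):
        doc = make_doc("The A123V variant was linked to anemia in our cohort.")
        vms, _, dms = mentions_for(doc, diseases=["anemia"])
        (cand,) = collect_closest_diseases(doc, normalize_variant("A123V"), vms, dms)
        assert cand.disease_id == "ANEMIA"
        assert cand.distance_tokens == oracle_token_distance(
            doc, cand.occurrence_location, cand.disease_location
        )

    def test_minimal_distance_wins(self):
        doc = make_doc(
            "Cases of anemia one two three four five six seven and glaucoma near A123V appeared."
        )
        vms, _, dms = mentions_for(doc, diseases=["anemia", "glaucoma"])
        (cand,) = collect_closest_diseases(doc, normalize_variant("A123V"), vms, dms)
        assert cand.disease_id == "GLAUCOMA"

    def test_equidistant_tie_prefers_preceding(self):
        doc = make_doc("Severe anemia near A123V near glaucoma cases.")
        vms, _, dms = mentions_for(doc, diseases=["anemia", "glaucoma"])
        (cand,) = collect_closest_diseases(doc, normalize_variant("A123V"), vms, dms)
        d_an = oracle_token_distance(doc, vms[0].location, dms[0].location)
        d_gl = oracle_token_distance(doc, vms[0].location, dms[1].location)
        assert d_an == d_gl  # genuinely equidistant
        assert cand.disease_id == "ANEMIA"

    def test_k_matches_occurrences(self):
        doc = make_doc("A123V was seen. Later A123V recurred near anemia.")
        vms, _, dms = mentions_for(doc, diseases=["anemia"])
        cands = collect_closest_diseases(doc, normalize_variant("A123V"), vms, dms)
        assert [c.occurrence_index for c in cands] == [1, 2]

    def test_no_disease_mentions(self):
        doc = make_doc("A123V was seen.")
        vms, _, _ = mentions_for(doc)
        assert collect_closest_diseases(doc, normalize_variant("A123V"), vms, []) == []


class TestSentimentPolarity:
    def test_empty_text(self):
        assert sentiment_polarity("") == 0.0

    def test_mean_of_matched_valences(self):
        lex = {"associated": 0.4, "increased": 0.3, "risk": -0.2}
        got = sentiment_polarity("significantly associated with increased risk of", lexicon=lex)
        assert got == pytest.approx((0.4 + 0.3 - 0.2) / 3)

    def test_negation_flips_sign(self):
        lex = {"associated": 0.4}
        assert sentiment_polarity("not associated with", lexicon=lex) == pytest.approx(-0.4)
        assert sentiment_polarity("was associated with", lexicon=lex) == pytest.approx(0.4)

    def test_negator_window_is_three_tokens(self):
        lex = {"associated": 0.4}
        assert sentiment_polarity("not one two associated", lexicon=lex) == pytest.approx(-0.4)
        assert sentiment_polarity("not one two three associated", lexicon=lex) == pytest.approx(0.4)

    def test_clamped_to_unit_interval(self):
        lex = {"good": 2.0}
        assert sentiment_polarity("good good", lexicon=lex) == 1.0


class TestScoreCandidate:
    def get_candidate(self, body, lexicon=None):
        doc = make_doc(body)
        vms, _, dms = mentions_for(doc, diseases=["anemia"])
        (cand,) = collect_closest_diseases(doc, normalize_variant("A123V"), vms, dms)
        return doc, score_candidate(doc, cand, lexicon=lexicon or {})

    def test_same_sentence_neutral(self):
        _, cand = self.get_candidate("The A123V variant occurred with anemia here.")
        assert (cand.sso, cand.spo, cand.ss, cand.total) == (1, 1, 0.0, 2.0)

    def test_different_paragraphs_neutral(self):
        _, cand = self.get_candidate("The A123V variant occurred.\n\nSevere anemia was noted.")
        assert (cand.sso, cand.spo, cand.ss, cand.total) == (0, 0, 0.0, 0.0)

    def test_same_paragraph_with_scored_between_text(self):
        # hand-sum: matched valences 0.7 and 0.3 -> mean 0.5; spo only
        lex = {"strongly": 0.7, "linked": 0.3}
        doc, cand = self.get_candidate(
            "The A123V variant occurred. It was strongly linked to anemia.", lexicon=lex
        )
        assert (cand.sso, cand.spo) == (0, 1)
        assert cand.ss == pytest.approx(0.5)
        assert cand.total == pytest.approx(1.5)

    def test_text_after_both_mentions_ignored(self):
        lex = {"terrible": -1.0, "linked": 0.3}
        _, plain = self.get_candidate("A123V was linked to anemia.", lexicon=lex)
        _, suffixed = self.get_candidate(
            "A123V was linked to anemia. This was terrible terrible terrible.", lexicon=lex
        )
        assert plain.total == pytest.approx(suffixed.total)


def random_scored_candidates(n_docs=30, seed=123):
    """Score candidates over randomized small documents."""
    rng = np.random.default_rng(seed)
    words = ["alpha", "beta", "gamma", "delta", "linked", "unrelated", "risk"]
    out = []
    for i in range(n_docs):
        n_par = int(rng.integers(1, 4))
        paragraphs = []
        for _ in range(n_par):
            sents = []
            for _ in range(int(rng.integers(1, 4))):
                toks = [str(words[j]) for j in rng.integers(0, len(words), int(rng.integers(3, 8)))]
                if rng.random() < 0.5:
                    toks.insert(int(rng.integers(0, len(toks))), "A123V")
                if rng.random() < 0.6:
                    toks.insert(int(rng.integers(0, len(toks))), "anemia")
                text = " ".join(toks)
                sents.append(text[0].upper() + text[1:] + ".")
            paragraphs.append(" ".join(sents))
        doc = make_doc("\n\n".join(paragraphs), doc_id=f"r{i}")
        vms, _, dms = mentions_for(doc, diseases=["anemia"])
        for c in collect_closest_diseases(doc, normalize_variant("A123V"), vms, dms):
            out.append(score_candidate(doc, c))
    return out


def test_score_invariants_on_randomized_candidates():
    cands = random_scored_candidates()
    assert cands, "randomized corpus produced no candidates"
    for c in cands:
        assert c.sso <= c.spo  # same sentence implies same paragraph
        assert -1.0 <= c.total <= 3.0
        assert c.total == pytest.approx(c.sso + c.spo + c.ss)


class TestAssignDisease:
    def test_single_candidate_assigned(self):
        doc = make_doc("A123V was linked to anemia.")
        vms, _, dms = mentions_for(doc, diseases=["anemia"])
        res = assign_disease(doc, normalize_variant("A123V"), vms, dms)
        assert res.assigned_disease == "ANEMIA" and res.k == 1

    def test_argmax_over_totals(self):
        # anemia shares the variant's sentence; glaucoma is a paragraph away
        doc = make_doc("A123V was linked to anemia here.\n\nSeparately, glaucoma was common.")
        vms, _, dms = mentions_for(doc, diseases=["anemia", "glaucoma"])
        res = assign_disease(doc, normalize_variant("A123V"), vms, dms)
        assert res.assigned_disease == "ANEMIA"
        assert res.winning_candidate.total >= max(c.total for c in res.all_candidates)

    def test_tie_broken_by_supporting_occurrences(self):
        """Two diseases reach the same best score, but one is the closest
        disease for two occurrences — exhaustive check over candidates."""
        doc = make_doc(
            "A123V was near anemia today.\n\n"
            "A123V was near anemia again.\n\n"
            "Nearby A123V met glaucoma."
        )
        vms, _, dms = mentions_for(doc, diseases=["anemia", "glaucoma"])
        res = assign_disease(doc, normalize_variant("A123V"), vms, dms, lexicon={})
        per_disease = {}
        for c in res.all_candidates:
            per_disease.setdefault(c.disease_id, []).append(c.total)
        assert max(per_disease["ANEMIA"]) == max(per_disease["GLAUCOMA"])  # tied
        assert len(per_disease["ANEMIA"]) > len(per_disease["GLAUCOMA"])
        assert res.assigned_disease == "ANEMIA"

    def test_no_occurrence_no_assignment(self):
        doc = make_doc("Nothing at all here about anemia.")
        _, _, dms = mentions_for(doc, diseases=["anemia"])
        res = assign_disease(doc, normalize_variant("A123V"), [], dms)
        assert res.assigned_disease is None and res.k == 0

    def test_sum_aggregation_option(self):
        doc = make_doc(
            "A123V occurred near anemia. A123V occurred near anemia.\n\n"
            "A123V strongly linked glaucoma."
        )
        vms, _, dms = mentions_for(doc, diseases=["anemia", "glaucoma"])
        res_sum = assign_disease(doc, normalize_variant("A123V"), vms, dms,
                                 aggregation="sum", lexicon={})
        assert res_sum.assigned_disease == "ANEMIA"  # 2 + 2 > 2


class TestBaselineAssign:
    def test_more_cosentences_wins(self):
        doc = make_doc(
            "A123V was seen with anemia. A123V recurred with anemia. "
            "A123V once appeared with glaucoma."
        )
        vms, _, dms = mentions_for(doc, diseases=["anemia", "glaucoma"])
        res = baseline_assign(doc, normalize_variant("A123V"), vms, dms)
        assert res.assigned_disease == "ANEMIA" and res.score == 2.0

    def test_no_cosentential_disease_no_assignment(self):
        doc = make_doc("A123V was seen.\n\nSevere anemia was noted elsewhere.")
        vms, _, dms = mentions_for(doc, diseases=["anemia"])
        res = baseline_assign(doc, normalize_variant("A123V"), vms, dms)
        assert res.assigned_disease is None

    def test_agrees_with_composite_when_cosentential_and_neutral(self):
        """With every candidate co-sentential and a sentiment lexicon that
        matches nothing, the two methods coincide."""
        bodies = [
            "A123V occurred with anemia. A123V recurred with anemia. A123V met glaucoma.",
            "Alpha A123V beta anemia gamma. Delta glaucoma A123V epsilon.",
        ]
        for body in bodies:
            doc = make_doc(body)
            vms, _, dms = mentions_for(doc, diseases=["anemia", "glaucoma"])
            v = normalize_variant("A123V")
            proposed = assign_disease(doc, v, vms, dms, lexicon={})
            baseline = baseline_assign(doc, v, vms, dms)
            assert proposed.assigned_disease == baseline.assigned_disease


def test_token_distance_symmetric_and_adjacent_zero():
    doc = make_doc("A123V anemia appear adjacent here.")
    vms, _, dms = mentions_for(doc, diseases=["anemia"])
    a, b = vms[0].location, dms[0].location
    assert token_distance(a, b) == 0
    assert token_distance(a, b) == token_distance(b, a)
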