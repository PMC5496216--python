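"""Error-taxonomy grading: pairwise classification, assignment, whole queries."""

import itertools

import pytest

from meshlingua import (
    ErrorKind,
    GoldStandard,
    TermNode,
    classify_pair,
    grade,
    match_terms,
)


def K(*kinds):
    return tuple(kinds)


class TestClassifyPair:
    def test_identical(self, thesaurus):
        t = TermNode("D001249")
        assert classify_pair(t, t, thesaurus) == ()

    def test_missing_required_qualifier(self, thesaurus):
        cand = TermNode("D000505")
        gold = TermNode("D000505", "Q000517")
        assert classify_pair(cand, gold, thesaurus) == K(ErrorKind.UNDERSPEC_QUALIFIER)

    def test_broader_descriptor(self, thesaurus):
        cand = TermNode("D013651")  # taste disorders
        gold = TermNode("D004408")  # dysgeusia
        assert classify_pair(cand, gold, thesaurus) == K(ErrorKind.UNDERSPEC_DESCRIPTOR)

    def test_narrower_descriptor(self, thesaurus):
        cand = TermNode("D004408")
        gold = TermNode("D013651")
        assert classify_pair(cand, gold, thesaurus) == K(ErrorKind.OVERSPEC_DESCRIPTOR)

    def test_unrelated_descriptor_short_circuits_qualifier(self, thesaurus):
        cand = TermNode("D009147", "Q000628")  # decoy with a qualifier
        gold = TermNode("D000505", "Q000517")
        assert classify_pair(cand, gold, thesaurus) == K(ErrorKind.IRRELEVANT_TERM)

    def test_spurious_qualifier(self, thesaurus):
        cand = TermNode("D001249", "Q000628")
        gold = TermNode("D001249")
        assert classify_pair(cand, gold, thesaurus) == K(ErrorKind.OVERSPEC_QUALIFIER)

    def test_narrower_qualifier(self, thesaurus):
        cand = TermNode("D001943", "Q000188")  # /drug therapy
        gold = TermNode("D001943", "Q000628")  # /therapy
        assert classify_pair(cand, gold, thesaurus) == K(ErrorKind.OVERSPEC_QUALIFIER)

    def test_broader_qualifier(self, thesaurus):
        cand = TermNode("D014807", "Q000032")  # /analysis
        gold = TermNode("D014807", "Q000097")  # /blood
        assert classify_pair(cand, gold, thesaurus) == K(ErrorKind.UNDERSPEC_QUALIFIER)

    def test_unrelated_qualifier_counts_once(self, thesaurus):
        cand = TermNode("D001943", "Q000453")  # /epidemiology
        gold = TermNode("D001943", "Q000628")  # /therapy
        assert classify_pair(cand, gold, thesaurus) == K(ErrorKind.UNDERSPEC_QUALIFIER)

    def test_descriptor_and_qualifier_errors_stack(self, thesaurus):
        cand = TermNode("D013651")            # broader, unqualified
        gold = TermNode("D004408", "Q000175")  # narrower, qualified
        assert sorted(classify_pair(cand, gold, thesaurus)) == sorted(
            K(ErrorKind.UNDERSPEC_DESCRIPTOR, ErrorKind.UNDERSPEC_QUALIFIER)
        )

    def test_publication_type_identity_only(self, thesaurus):
        pg = TermNode("D016431")
        topic = TermNode("D017410")
        assert classify_pair(pg, pg, thesaurus) == ()
        assert classify_pair(topic, pg, thesaurus) == K(ErrorKind.IRRELEVANT_TERM)


def brute_force_min_errors(cands, golds, thesaurus):
    """Independent oracle: enumerate every injective partial assignment."""
    best = None
    nc, ng = len(cands), len(golds)
    for k in range(0, min(nc, ng) + 1):
        for c_idx in itertools.combinations(range(nc), k):
            for g_idx in itertools.permutations(range(ng), k):
                total = nc - k + ng - k  # unmatched on both sides
                for ci, gi in zip(c_idx, g_idx):
                    total += len(classify_pair(cands[ci], golds[gi], thesaurus))
                if best is None or total < best:
                    best = total
    return best


def report_total(matches):
    return sum(len(m.errors) for m in matches)


class TestMatchTerms:
    def test_equal_multisets(self, thesaurus):
        terms = [TermNode("D001249"), TermNode("D010146")]
        matches = match_terms(terms, list(terms), thesaurus)
        assert report_total(matches) == 0

    def test_missing_gold_term(self, thesaurus):
        a, b = TermNode("D001249"), TermNode("D010146")
        matches = match_terms([a], [a, b], thesaurus)
        assert report_total(matches) == 1
        kinds = [m.errors for m in matches if m.candidate is None]
        assert kinds == [(ErrorKind.UNDERSPEC_DESCRIPTOR,)]

    def test_hierarchy_preferred_over_nonmatch(self, thesaurus):
        parent, child = TermNode("D013651"), TermNode("D004408")
        matches = match_terms([parent], [child], thesaurus)
        assert report_total(matches) == 1
        assert matches[0].errors == (ErrorKind.UNDERSPEC_DESCRIPTOR,)

    def test_size_guard(self, thesaurus):
        t = [TermNode("D001249")] * 9
        with pytest.raises(ValueError):
            match_terms(t, t[:1], thesaurus)

    def test_matches_exhaustive_oracle(self, thesaurus):
        """Assignment optimality versus full enumeration, lists up to 4x4."""
        import random

        rng = random.Random(7)
        uis = sorted(thesaurus.descriptors)
        quals = sorted(thesaurus.qualifiers)

        def random_term():
            ui = rng.choice(uis)
            q = rng.choice(quals) if rng.random() < 0.4 else None
            return TermNode(ui, q)

        for _ in range(60):
            cands = [random_term() for _ in range(rng.randint(0, 4))]
            golds = [random_term() for _ in range(rng.randint(1, 4))]
            got = report_total(match_terms(cands, golds, thesaurus))
            want = brute_force_min_errors(cands, golds, thesaurus)
            assert got == want, (cands, golds)


class TestGrade:
    def test_gold_vs_self_perfect(self, thesaurus, gold_questions):
        for gs in gold_questions:
            for v in gs.variants:
                assert grade(v, gs, thesaurus).perfect, (gs.question_id, v)

    def test_operator_swap(self, thesaurus, gold_questions):
        gs = gold_questions[0]
        rep = grade("leiomyoma OR rupture, spontaneous", gs, thesaurus)
        assert rep.counts[ErrorKind.INCORRECT_OPERATOR] == 1
        assert rep.total == 1 and not rep.perfect

    def test_syntax_only_error_still_recovers_terms(self, thesaurus, gold_questions):
        gs = gold_questions[0]
        rep = grade("(leiomyoma AND rupture, spontaneous", gs, thesaurus)
        assert rep.counts[ErrorKind.SYNTAX_ERROR] == 1
        assert rep.total == 1

    def test_empty_query(self, thesaurus, gold_questions):
        rep = grade("   ", gold_questions[0], thesaurus)
        assert rep.counts[ErrorKind.SYNTAX_ERROR] == 1

    def test_dropped_qualifier(self, thesaurus, gold_questions):
        gs = gold_questions[1]  # alopecia areata/prevention and control
        rep = grade("alopecia areata", gs, thesaurus)
        assert rep.counts[ErrorKind.UNDERSPEC_QUALIFIER] == 1
        assert rep.total == 1

    def test_broader_descriptor_not_colliding_with_variant(self, thesaurus, gold_questions):
        gs = gold_questions[8]  # salty taste; taste disorders is itself a variant
        rep = grade("salts AND dysgeusia", gs, thesaurus)
        assert rep.counts[ErrorKind.UNDERSPEC_DESCRIPTOR] == 1
        assert rep.total == 1

    def test_monotonic_extra_term(self, thesaurus, gold_questions):
        """Adding one unrelated MeSH term to a perfect query adds one error."""
        for gs in gold_questions[:4]:
            rep = grade(gs.variants[0] + " AND music therapy", gs, thesaurus)
            assert rep.counts[ErrorKind.IRRELEVANT_TERM] == 1
            assert rep.total == 1

    def test_variant_minimization(self, thesaurus, gold_questions):
        """Grading against more variants never increases the error total."""
        for gs in gold_questions:
            if len(gs.variants) < 2:
                continue
            single = GoldStandard(gs.question_id, gs.difficulty,
                                  gs.question_text, [gs.variants[0]])
            candidate = gs.variants[-1]
            assert grade(candidate, gs, thesaurus).total <= grade(
                candidate, single, thesaurus
            ).total

    def test_french_candidate_against_gold(self, thesaurus, gold_questions):
        rep = grade("pelade/prévention et contrôle", gold_questions[1],
                    thesaurus, language="fr")
        assert rep.perfect
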