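"""The 20-criterion rubric: registry, detectors, manual ingest,
reconciliation and inter-rater agreement."""

import itertools

import pandas as pd
import pytest

from mediascorecard import (
    ALL_CODES,
    CodingRecord,
    CodingValidationError,
    NEGATIVE_CODES,
    POSITIVE_CODES,
    code_article_auto,
    detect_criterion,
    get_criterion,
    ingest_manual_codes,
    interrater_agreement,
    load_criteria,
    reconcile,
    resolve_discrepancy,
)

from conftest import make_article


class TestRegistry:
    def test_twenty_criteria_ten_per_polarity(self):
        crits = load_criteria()
        assert len(crits) == 20
        assert sum(c.polarity == "positive" for c in crits) == 10
        assert sum(c.polarity == "negative" for c in crits) == 10

    def test_codes_ordered_and_unique(self):
        codes = [c.code for c in load_criteria()]
        assert codes == list(POSITIVE_CODES) + list(NEGATIVE_CODES)
        assert len(set(codes)) == 20

    def test_scopes(self):
        assert get_criterion("N2").scope == frozenset({"headline"})
        assert "metadata" in get_criterion("N7").scope
        assert "metadata" in get_criterion("N10").scope
        assert get_criterion("P2").detection_mode == "hybrid"


# Worked phrases from the rubric's own acceptance/rejection sub-rules.
RUBRIC_FIXTURES = [
    ("N1", "He committed suicide on Monday", 1),
    ("N1", "He died by suicide on Monday", 0),
    ("P3", "she had been depressed for months", 1),
    ("P3", "he was stressed", 0),
    ("P3", "neighbours called him crazy", 0),
    ("P10", "according to sources, he was alone", 0),
    ("P10", "police officers confirmed the report", 1),
    ("P4", "he struggled with alcohol addiction for years", 1),
    ("P4", "he was drunk at the time", 0),
]


@pytest.mark.parametrize("code,body,expected", RUBRIC_FIXTURES)
def test_rubric_worked_phrases(code, body, expected, lexicon, registry):
    """Each acceptance/rejection example phrase in the rubric behaves as stated."""
    got, evidence = detect_criterion(make_article(body=body), code, lexicon, registry)
    assert got == expected
    if expected == 1:
        assert evidence, "a code of 1 must carry evidence"


class TestDetectors:
    def test_n1_evidence_span_covers_phrase(self, lexicon):
        art = make_article(body="He committed suicide on Monday")
        code, ev = detect_criterion(art, "N1", lexicon)
        assert code == 1
        span = ev[0]
        assert art.body[span.start : span.end].lower() == "committed suicide"

    @pytest.mark.parametrize(
        "headline,expected",
        [
            ("Man ends life by hanging", 1),  # method term
            ("City reels after suicide of trader", 1),  # the word itself
            ("Student ends life after exam setback", 1),  # reason cue + stressor
            ("Helpline calls rise in city", 0),
            ("Family gathers after the funeral", 0),  # cue without stressor
        ],
    )
    def test_n2_headline_rule(self, headline, expected, lexicon):
        art = make_article(headline=headline, body="irrelevant")
        assert detect_criterion(art, "N2", lexicon)[0] == expected

    def test_n4_needs_two_distinct_details(self, lexicon):
        one = make_article(body="A nylon rope was found.")
        two = make_article(body="A nylon rope tied to the ceiling fan was found.")
        assert detect_criterion(one, "N4", lexicon)[0] == 0
        assert detect_criterion(two, "N4", lexicon)[0] == 1

    def test_n6_speculation_suppresses(self, lexicon):
        plain = make_article(body="Relatives attributed the suicide to debt.")
        hedged = make_article(
            body="Relatives attributed the suicide to debt, but the reason may be more complex."
        )
        assert detect_criterion(plain, "N6", lexicon)[0] == 1
        assert detect_criterion(hedged, "N6", lexicon)[0] == 0

    def test_n7_n10_metadata_driven(self, lexicon):
        art = make_article(body="x", page_number=3, has_photo=True, photo_kinds=frozenset({"method"}))
        assert detect_criterion(art, "N7", lexicon)[0] == 1
        assert detect_criterion(art, "N10", lexicon)[0] == 0
        front = make_article(body="x", page_number=1)
        assert detect_criterion(front, "N10", lexicon)[0] == 1
        jump = make_article(body="x", page_number=5, continues_from_front_page=True)
        assert detect_criterion(jump, "N10", lexicon)[0] == 1

    def test_n9_needs_note_term_and_quote(self, lexicon):
        quoted = make_article(body='A suicide note read, "goodbye".')
        unquoted = make_article(body="A suicide note was found.")
        assert detect_criterion(quoted, "N9", lexicon)[0] == 1
        assert detect_criterion(unquoted, "N9", lexicon)[0] == 0

    def test_p1_p2_registry_coupling(self, lexicon, registry):
        registered = make_article(
            body="Call the Sneha Suicide Prevention Centre on 044-24640050."
        )
        unregistered = make_article(body="Call the Harmony Care helpline on 1800-000-2210.")
        assert detect_criterion(registered, "P1", lexicon, registry)[0] == 1
        assert detect_criterion(registered, "P2", lexicon, registry)[0] == 1
        assert detect_criterion(unregistered, "P1", lexicon, registry)[0] == 1
        assert detect_criterion(unregistered, "P2", lexicon, registry)[0] == 0

    def test_p5_needs_role_and_attribution_in_sentence(self, lexicon):
        good = make_article(body='"Support helps," said a psychiatrist.')
        no_role = make_article(body='"Support helps," said a neighbour.')
        split = make_article(body="A psychiatrist attended. Someone said so.")
        assert detect_criterion(good, "P5", lexicon)[0] == 1
        assert detect_criterion(no_role, "P5", lexicon)[0] == 0
        assert detect_criterion(split, "P5", lexicon)[0] == 0

    def test_p7_digit_and_marker_cooccur(self, lexicon):
        good = make_article(body="The suicide rate stood at 10.4 per 100,000.")
        no_digit = make_article(body="The suicide rate is discussed in the report.")
        assert detect_criterion(good, "P7", lexicon)[0] == 1
        assert detect_criterion(no_digit, "P7", lexicon)[0] == 0

    def test_determinism(self, lexicon, registry):
        art = make_article(body="He committed suicide. Police officers confirmed it.")
        runs = [code_article_auto(art, lexicon, registry) for _ in range(3)]
        assert runs[0].codes == runs[1].codes == runs[2].codes
        assert runs[0].evidence == runs[1].evidence

    def test_evidence_soundness(self, lexicon, registry):
        from mediascorecard import GeneratorConfig, generate_corpus
        from mediascorecard.textmatch import contains_any

        corpus, _ = generate_corpus(GeneratorConfig(n_articles=40, seed=11))
        purposes = [k for k in lexicon.lists if not k.endswith("patterns")]
        terms = [t for k in purposes for t in lexicon.lists[k]]
        for art in corpus:
            rec = code_article_auto(art, lexicon, registry)
            for code, evs in rec.evidence.items():
                for ev in evs:
                    if ev.field == "metadata":
                        continue
                    field_text = getattr(art, ev.field)
                    assert field_text[ev.start : ev.end] == ev.text
                    if code in ("P1", "P2"):  # phone patterns allowed
                        continue
                    assert contains_any(ev.text.lower(), terms), (code, ev.text)

    @pytest.mark.parametrize(
        "code,trigger",
        [
            ("P6", "Experts emphasised that suicides are preventable."),
            ("P9", "She overcame suicidal thoughts and now mentors others."),
            ("N3", "He was found hanging at home."),
            ("N5", "The spot was the railway bridge near the station."),
            ("N8", "His grieving family spoke to reporters."),
        ],
    )
    def test_monotone_criteria_flip_up_only(self, code, trigger, lexicon):
        base = "The man died by suicide on Tuesday."
        before = detect_criterion(make_article(body=base), code, lexicon)[0]
        after = detect_criterion(make_article(body=base + " " + trigger), code, lexicon)[0]
        more = detect_criterion(
            make_article(body=base + " " + trigger + " The council met."), code, lexicon
        )[0]
        assert (before, after, more) == (0, 1, 1)


class TestAutoCoding:
    def test_empty_body_all_body_codes_zero(self, lexicon, registry):
        rec = code_article_auto(make_article(body="", page_number=2), lexicon, registry)
        assert all(rec.codes[c] == 0 for c in ALL_CODES if c not in ("N2",))

    def test_planted_codes_recovered_exactly(self, lexicon, registry):
        from mediascorecard import TruthRecord, render_article

        truth = TruthRecord(
            article_id="t1",
            true_codes={
                c: (1 if c in ("P1", "P2", "P3", "N1", "N2", "N3") else 0) for c in ALL_CODES
            },
            screening_category="included",
        )
        art = render_article(truth, lexicon=lexicon)
        rec = code_article_auto(art, lexicon, registry)
        assert rec.codes == truth.true_codes

    def test_p2_never_exceeds_p1(self, lexicon, registry):
        from mediascorecard import GeneratorConfig, generate_corpus

        corpus, _ = generate_corpus(GeneratorConfig(n_articles=50, seed=2))
        for art in corpus:
            rec = code_article_auto(art, lexicon, registry)
            assert rec.codes["P2"] <= rec.codes["P1"]


class TestManualIngest:
    def _sheet(self, tmp_path, rows):
        header = "article_id,coder_id," + ",".join(ALL_CODES) + ",notes"
        path = tmp_path / "sheet.csv"
        path.write_text("\n".join([header] + rows) + "\n", encoding="utf-8")
        return path

    def test_wellformed_row(self, tmp_path):
        row = "a1,coderA," + ",".join(["0"] * 20) + ","
        recs = ingest_manual_codes(self._sheet(tmp_path, [row]))
        assert len(recs) == 1 and recs[0].coder_id == "coderA"
        assert set(recs[0].codes) == set(ALL_CODES)

    def test_nonbinary_cell_named(self, tmp_path):
        codes = ["0"] * 20
        codes[4] = "2"  # P5 column
        row = "a1,coderA," + ",".join(codes) + ","
        with pytest.raises(CodingValidationError, match="P5.*'2'"):
            ingest_manual_codes(self._sheet(tmp_path, [row]))

    def test_p2_without_p1_inconsistent(self, tmp_path):
        codes = ["0"] * 20
        codes[1] = "1"  # P2 = 1 while P1 = 0
        row = "a1,coderA," + ",".join(codes) + ","
        with pytest.raises(CodingValidationError, match="P2=1 with P1=0"):
            ingest_manual_codes(self._sheet(tmp_path, [row]))

    def test_unknown_column_rejected(self, tmp_path):
        path = tmp_path / "sheet.csv"
        header = "article_id,coder_id," + ",".join(ALL_CODES) + ",notes,P11"
        path.write_text(header + "\n", encoding="utf-8")
        with pytest.raises(CodingValidationError, match="P11"):
            ingest_manual_codes(path)


def _rec(coder, codes):
    return CodingRecord("a1", coder, dict(codes))


def _codes(**overrides):
    base = {c: 0 for c in ALL_CODES}
    base.update(overrides)
    return base


class TestReconcile:
    def test_identical_records_no_discrepancies(self):
        a, b = _rec("A", _codes(N1=1)), _rec("B", _codes(N1=1))
        rc = reconcile(a, b, "flag")
        assert rc.discrepancies == [] and rc.final_codes == a.codes

    def test_flag_leaves_unresolved(self):
        a, b = _rec("A", _codes(N1=1)), _rec("B", _codes())
        rc = reconcile(a, b, "flag")
        assert rc.unresolved == ["N1"]
        assert "N1" not in rc.final_codes
        d = rc.discrepancies[0]
        assert (d.criterion, d.code_a, d.code_b, d.resolution) == ("N1", 1, 0, "unresolved")

    def test_conservative_takes_stricter_reading(self):
        # disagree on P5 (1 vs 0) and N4 (0 vs 1)
        a = _rec("A", _codes(P5=1))
        b = _rec("B", _codes(N4=1))
        rc = reconcile(a, b, "conservative")
        assert rc.final_codes["P5"] == 0 and rc.final_codes["N4"] == 1

    @pytest.mark.parametrize("code", ["P3", "N6"])
    @pytest.mark.parametrize("a_val,b_val", [(0, 1), (1, 0)])
    def test_conservative_enumerated_disagreements(self, code, a_val, b_val):
        rc = reconcile(
            _rec("A", _codes(**{code: a_val})), _rec("B", _codes(**{code: b_val})), "conservative"
        )
        assert rc.final_codes[code] == (0 if code.startswith("P") else 1)

    def test_prefer_strategies(self):
        a, b = _rec("A", _codes(P3=1)), _rec("B", _codes())
        assert reconcile(a, b, "prefer_A").final_codes["P3"] == 1
        assert reconcile(a, b, "prefer_B").final_codes["P3"] == 0

    def test_mismatched_article_ids(self):
        a = _rec("A", _codes())
        b = CodingRecord("other", "B", _codes())
        with pytest.raises(ValueError, match="different articles"):
            reconcile(a, b)

    def test_resolve_discrepancy_enters_consensus(self):
        rc = reconcile(_rec("A", _codes(N1=1)), _rec("B", _codes()), "flag")
        done = resolve_discrepancy(rc, "N1", 1, resolved_by="panel")
        assert done.final_codes["N1"] == 1 and done.unresolved == []


class TestAgreement:
    def test_identical_pairs_full_agreement(self):
        pairs = [(_rec("A", _codes(N1=1)), _rec("B", _codes(N1=1)))] * 5
        table = interrater_agreement(pairs)
        assert (table["percent_agreement"] == 1.0).all()
        # degenerate marginals: kappa undefined
        assert pd.isna(table.loc["P1", "kappa"])

    def test_confusion_40_5_5_50(self):
        # a=40 (both 1), b=5 (A=1,B=0), c=5 (A=0,B=1), d=50 (both 0) on N1
        pairs = (
            [(_rec("A", _codes(N1=1)), _rec("B", _codes(N1=1)))] * 40
            + [(_rec("A", _codes(N1=1)), _rec("B", _codes()))] * 5
            + [(_rec("A", _codes()), _rec("B", _codes(N1=1)))] * 5
            + [(_rec("A", _codes()), _rec("B", _codes()))] * 50
        )
        table = interrater_agreement(pairs)
        assert table.loc["N1", "percent_agreement"] == pytest.approx(0.90)
        # hand-computed kappa: po=0.9, pe=0.45*0.45+0.55*0.55=0.505,
        # kappa=(0.9-0.505)/(1-0.505)=0.395/0.495=0.79797979...
        assert table.loc["N1", "kappa"] == pytest.approx(0.395 / 0.495, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            interrater_agreement([])
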