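"""Synthetic-corpus generator: determinism, round trips, corruption."""

from collections import Counter

import pytest

from statextract import (
    ExtractionOptions,
    FixtureSpec,
    corrupt_for_pdf,
    extract_text,
    generate_corpus,
    parse_jats,
    process_article,
    render_article,
    select_scope,
)
from statextract.fixtures import ARTIFACT_DIALECTS
from statextract.records import SENTINEL


def test_same_seed_gives_byte_identical_corpus():
    a = generate_corpus(FixtureSpec(n_articles=5, seed=3))
    b = generate_corpus(FixtureSpec(n_articles=5, seed=3))
    assert [x.xml for x in a] == [x.xml for x in b]
    assert [x.plants for x in a] == [x.plants for x in b]


def test_different_seed_changes_corpus():
    a = generate_corpus(FixtureSpec(n_articles=3, seed=3))
    b = generate_corpus(FixtureSpec(n_articles=3, seed=4))
    assert [x.xml for x in a] != [x.xml for x in b]


def test_empty_corpus_is_an_error():
    with pytest.raises(ValueError):
        generate_corpus(FixtureSpec(n_articles=0, seed=1))


def test_rendered_article_has_four_titled_sections():
    art = render_article(FixtureSpec(seed=5), article_id="a")
    parsed = parse_jats(art.xml)
    assert [s.title for s in parsed.sections] == [
        "Introduction", "Method", "Results", "Discussion",
    ]


def test_single_plant_round_trip():
    spec = FixtureSpec(
        n_articles=1, results_low=1, results_high=1,
        dialect_weights={"apa_t": 1.0}, seed=2,
    )
    (art,) = generate_corpus(spec)
    rep = process_article(parse_jats(art.xml), 1, ExtractionOptions(T2t=True))
    assert rep.counts["checkable"] == 1


def test_fraction_plant_compiles_to_decimal():
    spec = FixtureSpec(
        n_articles=1, results_low=1, results_high=1,
        dialect_weights={"fraction": 1.0}, seed=9,
    )
    (art,) = generate_corpus(spec)
    rep = process_article(parse_jats(art.xml), 1, ExtractionOptions())
    (plant,) = art.plants
    num, den = plant.input_text.split("=")[1].split(",")[0].strip().split("/")
    (rec,) = [r for r in rep.records if r.symbol == "t"]
    assert rec.stat_value == pytest.approx(float(num) / float(den))


def _extract_stats(art, opts):
    parsed = parse_jats(art.xml)
    stats = []
    for block in select_scope(parsed, 1).blocks:
        stats.extend(extract_text(block, opts).stats)
    return stats


def test_clean_corpus_recall_and_precision(small_corpus, default_opts):
    """Every planted non-interval result is recovered exactly once, and
    every checkable record corresponds to a plant expected to be
    checkable (no false positives)."""
    from statextract.render import render_record

    for art in small_corpus:
        stats = Counter(_extract_stats(art, default_opts))
        expected = Counter(
            p.expected_canonical
            for p in art.plants
            if p.dialect not in ARTIFACT_DIALECTS
        )
        for canon, n in expected.items():
            assert stats[canon] == n

        rep = process_article(parse_jats(art.xml), 1, default_opts)
        got_checkable = Counter(
            render_record(r)
            for r, c in zip(rep.records, rep.categories)
            if c == "checkable"
        )
        exp_checkable = Counter(
            p.expected_canonical
            for p in art.plants
            if p.expected_category == "checkable"
        )
        assert got_checkable == exp_checkable


def test_corruption_rate_zero_is_identity():
    art = render_article(FixtureSpec(seed=6), article_id="a")
    xml, info = corrupt_for_pdf(art.xml, seed=1, rate=0.0)
    assert info.n_destroyed == 0 and info.n_garbled == 0
    assert xml == art.xml


def test_partial_corruption_bookkeeping_matches_sentinels():
    from statextract import normalize

    art = render_article(FixtureSpec(seed=6, results_low=4, results_high=6),
                         article_id="a")
    xml, info = corrupt_for_pdf(art.xml, seed=1, rate=0.5)
    repaired = normalize(xml).text
    assert repaired.count(SENTINEL) == info.n_destroyed


def test_garbled_operators_are_restored_exactly():
    from statextract import normalize

    art = render_article(FixtureSpec(seed=8), article_id="a")
    xml, info = corrupt_for_pdf(art.xml, seed=2, rate=1.0, garble_frac=1.0)
    assert info.n_garbled > 0 and info.n_destroyed == 0
    assert SENTINEL not in normalize(xml).text
    # after repair the canonical extraction is unchanged
    opts = ExtractionOptions(T2t=True)
    clean = _extract_stats(art, opts)
    from statextract.fixtures import FixtureArticle

    fixed = _extract_stats(FixtureArticle("a", xml), opts)
    assert fixed == clean


def test_full_corruption_makes_reported_p_indeterminate(default_opts):
    from statextract import check_consistency, is_significant, recompute

    corpus = generate_corpus(FixtureSpec(n_articles=6, seed=13))
    for art in corpus:
        xml, _ = corrupt_for_pdf(art.xml, seed=1, rate=1.0)
        rep = process_article(parse_jats(xml), 1, default_opts)
        for rec in rep.records:
            if rec.p_reported is None:
                continue
            assert rec.p_op == SENTINEL
            recomp = recompute(rec)
            flag = check_consistency(rec, recomp)
            assert flag.verdict in ("indeterminate", "not_checkable")
            # a destroyed 'p > alpha' is never silently non-significant
            if rec.p_reported <= 0.05:
                assert is_significant(rec, recomp) is True


def test_write_corpus_emits_xml_and_ground_truth(tmp_path):
    from statextract.fixtures import write_corpus

    write_corpus(FixtureSpec(n_articles=3, seed=4), tmp_path)
    files = sorted(p.name for p in tmp_path.iterdir())
    assert "ground_truth.jsonl" in files
    assert sum(f.endswith(".xml") for f in files) == 3
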