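"""Consistency verdicts, significance filtering, and corpus summaries."""

import pytest

from statextract import (
    check_consistency,
    is_significant,
    parse_one,
    recompute,
    summarize,
)
from statextract.checker import DocumentReport


def _flag(text, **kwargs):
    (rec,) = parse_one(text)
    return check_consistency(rec, recompute(rec, one_sided=kwargs.get("one_sided", False)), **kwargs), rec


def test_exact_p_consistent_within_rounding_interval():
    # two-sided p for t(28) = 2.2 is ~.0362, which rounds to .036
    flag, _ = _flag("t(28) = 2.2, p = .036")
    assert flag.verdict == "consistent"
    lo, hi = flag.reported_interval
    assert lo == pytest.approx(0.0355) and hi == pytest.approx(0.0365)


def test_exact_p_outside_interval_is_inconsistent():
    flag, _ = _flag("t(28) = 2.2, p = .012")
    assert flag.verdict == "inconsistent"


def test_bound_violation_same_side_of_alpha_is_plain_inconsistent():
    # recomputed ~.0362 is not < .01, but both claim significance at .05
    flag, _ = _flag("t(28) = 2.2, p < .01")
    assert flag.verdict == "inconsistent"


def test_opposite_sides_of_alpha_is_decision_error():
    # recomputed ~.0362 <= .05, but the report claims non-significance
    flag, _ = _flag("t(28) = 2.2, p > .05")
    assert flag.verdict == "decision_error"


def test_sentinel_operator_is_always_indeterminate():
    flag, rec = _flag("t(12) = 1.9, p .05")  # operator lost, repaired to <=>
    assert rec.p_op == "<=>"
    assert flag.verdict == "indeterminate"


def test_non_checkable_records_get_no_verdict():
    flag, _ = _flag("r = .12, p < .05")
    assert flag.verdict == "not_checkable"


def test_one_sided_rescue_is_opt_in():
    # one-sided p for t(28) = 2.2 is ~.0181
    (rec,) = parse_one("t(28) = 2.2, p = .018")
    two = check_consistency(rec, recompute(rec))
    assert two.verdict in ("inconsistent", "decision_error")
    rescued = check_consistency(rec, recompute(rec, one_sided=True), one_sided=True)
    assert rescued.verdict == "consistent"
    assert "one-sided" in rescued.note


def test_more_reported_decimals_narrow_the_interval():
    # recomputed p is ~.036225: fine at 4 decimals for .0362 ...
    flag, _ = _flag("t(28) = 2.2, p = .0362")
    assert flag.verdict == "consistent"
    lo, hi = flag.reported_interval
    assert hi - lo == pytest.approx(1e-4)
    # ... but a trailing zero claims precision the recomputation contradicts
    flag, _ = _flag("t(28) = 2.2, p = .0360")
    assert flag.verdict == "inconsistent"


@pytest.mark.parametrize(
    "text, expected",
    [
        ("t(12) = 1.9, p > .05", False),  # recomputed ~.082
        ("F(2, 12) = 3.12, p < .05", True),  # reported bound <= alpha
        ("t(12) = 3.5, p > .05", True),  # recomputed ~.0044 wins
        ("p = .20", False),
        ("p = .05", True),
    ],
)
def test_significance_filter(text, expected):
    (rec,) = parse_one(text)
    assert is_significant(rec, recompute(rec)) is expected


def test_sentinel_p_at_alpha_counts_significant_with_flag():
    (rec,) = parse_one("p <=> .05")
    assert is_significant(rec, recompute(rec)) is True
    assert "ambiguous_operator" in rec.flags


def test_consistency_invariant_to_reporting_dialect():
    dialects = [
        "t(28) = 2.2, p = .036",
        "t = 2.2, df = 28, p = .036",
        "t(28) = 2.2; p = .036",
        "tcontrast(28) = 2.2, p = .036",
    ]
    verdicts = set()
    for text in dialects:
        (rec,) = parse_one(text)
        verdicts.add(check_consistency(rec, recompute(rec)).verdict)
    assert verdicts == {"consistent"}


def test_summary_hand_arithmetic():
    reports = [
        DocumentReport("a", counts={"checkable": 2, "sticked": 2}),
        DocumentReport("b", counts={"checkable": 4, "sticked": 4}),
    ]
    summary = summarize(reports)
    row = summary.per_article.loc["checkable"]
    assert row["mean"] == 3 and row["median"] == 3 and row["max"] == 4
    assert summary.totals["checkable"] == 6


def test_zero_count_articles_excluded_from_distribution():
    reports = [
        DocumentReport("a", counts={"checkable": 3}),
        DocumentReport("b", counts={"checkable": 0}),
    ]
    summary = summarize(reports)
    assert summary.n_with_result["checkable"] == 1
    assert summary.per_article.loc["checkable", "mean"] == 3.0


def test_summarize_rejects_empty_input():
    with pytest.raises(ValueError):
        summarize([])


def test_recount_identity_and_filter_nesting(small_corpus, default_opts):
    from statextract import parse_jats, process_article

    for art in small_corpus:
        rep = process_article(parse_jats(art.xml), 1, default_opts)
        assert rep.counts == rep.recount()
        c = rep.counts
        assert c["checkable"] <= c["computable"] <= c["standard"] <= c["sticked"]
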